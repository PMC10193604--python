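"""File formats, run configuration and end-to-end pipeline orchestration.

Formats are deliberately plain: tidy CSV for tables and curves (with a
``# schema:`` tag line), JSON for bundles and reports, YAML for run
configuration.  Every persisted report embeds the parameter values, the
seed and a provenance hash of its inputs, and none embeds wall-clock
timestamps — two runs from the same configuration are byte-identical.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .beam import (
    BeamComponentField,
    BeamModel,
    ZStarTable,
    default_beam_model,
)
from .benchmark import (
    calibrate_fclin,
    evaluate_suite,
    extract_zstar_depth,
    mask_by_prescription,
    reference_records,
)
from .conversion import mkm_effective_lq, run_conversion_study
from .params import MKMParams, load_params, preset
from .planning import (
    SOBPPlan,
    compute_profile,
    optimize_weights,
    representative_plan,
    table1_suite,
)

__all__ = [
    "write_zstar_csv",
    "read_zstar_csv",
    "write_field_csv",
    "read_field_csv",
    "write_beam_model_json",
    "read_beam_model_json",
    "write_plan_json",
    "read_plan_json",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("mkmdose")

_ZSTAR_SCHEMA = "mkmdose/zstar-v1"
_FIELD_SCHEMA = "mkmdose/field-v1"
_MODEL_SCHEMA = "mkmdose/beam-model-v1"
_PLAN_SCHEMA = "mkmdose/plan-v1"

_ZSTAR_COLUMNS = ["species", "energy_mev_u", "zstar_gy", "ceiling_gy"]
_FIELD_COLUMNS = [
    "species", "depth_cm", "dose_gy", "zstar_gy", "letd_kev_um",
    "energy_mev_u",
]


def _check_schema(found: str | None, expected: str) -> None:
    if found != expected:
        raise ValueError(
            f"schema mismatch: expected {expected!r}, found {found!r}"
        )


def _read_tagged_csv(path: Path, expected_schema: str) -> tuple[pd.DataFrame, dict]:
    """Read a tidy CSV with leading ``# key: value`` comment lines."""
    meta: dict = {}
    lines = path.read_text().splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
            body_start = i + 1
        else:
            break
    _check_schema(meta.get("schema"), expected_schema)
    frame = pd.read_csv(
        _io.StringIO("\n".join(lines[body_start:])),
        float_precision="round_trip",
    )
    return frame, meta


# ---------------------------------------------------------------------------
# z* tables


def write_zstar_csv(table: ZStarTable, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(
        {
            "species": table.species,
            "energy_mev_u": table.energy_grid,
            "zstar_gy": table.zstar,
            "ceiling_gy": table.ceiling,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# schema: {_ZSTAR_SCHEMA}\n")
        frame.to_csv(fh, index=False)


def read_zstar_csv(path: str | Path) -> ZStarTable:
    frame, _ = _read_tagged_csv(Path(path), _ZSTAR_SCHEMA)
    if list(frame.columns) != _ZSTAR_COLUMNS:
        raise ValueError(
            f"column mismatch: expected {_ZSTAR_COLUMNS}, "
            f"found {list(frame.columns)}"
        )
    species = frame["species"].unique()
    if len(species) != 1:
        raise ValueError("z* table file must contain exactly one species")
    return ZStarTable(
        species=int(species[0]),
        energy_grid=frame["energy_mev_u"].to_numpy(),
        zstar=frame["zstar_gy"].to_numpy(),
        ceiling=float(frame["ceiling_gy"].iloc[0]),
    )


# ---------------------------------------------------------------------------
# depth-dose fields and beam models


def write_field_csv(layer: BeamComponentField, path: str | Path) -> None:
    path = Path(path)
    n = layer.depth.size
    frame = pd.DataFrame(
        {
            "species": np.repeat(np.arange(1, 7), n),
            "depth_cm": np.tile(layer.depth, 6),
            "dose_gy": layer.dose_by_species.ravel(),
            "zstar_gy": layer.zstar_by_species.ravel(),
            "letd_kev_um": layer.letd_by_species.ravel(),
            "energy_mev_u": layer.energy_by_species.ravel(),
        }
    )
    with path.open("w") as fh:
        fh.write(f"# schema: {_FIELD_SCHEMA}\n")
        fh.write(f"# layer_id: {layer.layer_id}\n")
        fh.write(f"# nominal_energy: {layer.nominal_energy!r}\n")
        fh.write(f"# range_cm: {layer.range_cm!r}\n")
        frame.to_csv(fh, index=False)


def read_field_csv(path: str | Path) -> BeamComponentField:
    frame, meta = _read_tagged_csv(Path(path), _FIELD_SCHEMA)
    if list(frame.columns) != _FIELD_COLUMNS:
        raise ValueError(
            f"column mismatch: expected {_FIELD_COLUMNS}, "
            f"found {list(frame.columns)}"
        )
    depth = frame.loc[frame["species"] == 1, "depth_cm"].to_numpy()
    n = depth.size

    def matrix(col: str) -> np.ndarray:
        return frame[col].to_numpy().reshape(6, n)

    return BeamComponentField(
        layer_id=meta["layer_id"],
        nominal_energy=float(meta["nominal_energy"]),
        range_cm=float(meta["range_cm"]),
        depth=depth,
        dose_by_species=matrix("dose_gy"),
        zstar_by_species=matrix("zstar_gy"),
        letd_by_species=matrix("letd_kev_um"),
        energy_by_species=matrix("energy_mev_u"),
    )


def _layer_payload(layer: BeamComponentField) -> dict:
    return {
        "layer_id": layer.layer_id,
        "nominal_energy": layer.nominal_energy,
        "range_cm": layer.range_cm,
        "dose_by_species": layer.dose_by_species.tolist(),
        "zstar_by_species": layer.zstar_by_species.tolist(),
        "letd_by_species": layer.letd_by_species.tolist(),
        "energy_by_species": layer.energy_by_species.tolist(),
    }


def write_beam_model_json(model: BeamModel, path: str | Path) -> None:
    payload = {
        "schema": _MODEL_SCHEMA,
        "provenance": model.provenance,
        "depth": model.depth.tolist(),
        "layers": [_layer_payload(l) for l in model.layers],
    }
    Path(path).write_text(json.dumps(payload) + "\n")


def read_beam_model_json(path: str | Path) -> BeamModel:
    payload = json.loads(Path(path).read_text())
    _check_schema(payload.get("schema"), _MODEL_SCHEMA)
    depth = np.asarray(payload["depth"], dtype=float)
    layers = tuple(
        BeamComponentField(
            layer_id=entry["layer_id"],
            nominal_energy=entry["nominal_energy"],
            range_cm=entry["range_cm"],
            depth=depth,
            dose_by_species=np.asarray(entry["dose_by_species"]),
            zstar_by_species=np.asarray(entry["zstar_by_species"]),
            letd_by_species=np.asarray(entry["letd_by_species"]),
            energy_by_species=np.asarray(entry["energy_by_species"]),
        )
        for entry in payload["layers"]
    )
    return BeamModel(layers=layers, provenance=payload["provenance"])


def model_hash(model: BeamModel) -> str:
    """Stable hash of the generator provenance identifying a beam model."""
    text = json.dumps(model.provenance, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def write_plan_json(
    plan: SOBPPlan, path: str | Path, beam_model: BeamModel | None = None
) -> None:
    payload = {
        "schema": _PLAN_SCHEMA,
        "name": plan.name,
        "range_cm": plan.range_cm,
        "modulation_cm": plan.modulation_cm,
        "prescription": plan.prescription,
        "centre_cm": plan.centre_cm,
        "layer_ids": list(plan.layer_ids) if plan.layer_ids else None,
        "layer_weights": (
            plan.layer_weights.tolist()
            if plan.layer_weights is not None
            else None
        ),
        "beam_model_hash": model_hash(beam_model) if beam_model else None,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_plan_json(path: str | Path) -> SOBPPlan:
    payload = json.loads(Path(path).read_text())
    _check_schema(payload.get("schema"), _PLAN_SCHEMA)
    return SOBPPlan(
        range_cm=payload["range_cm"],
        modulation_cm=payload["modulation_cm"],
        prescription=payload["prescription"],
        centre_cm=payload["centre_cm"],
        name=payload["name"],
        layer_ids=tuple(payload["layer_ids"]) if payload["layer_ids"] else None,
        layer_weights=(
            np.asarray(payload["layer_weights"])
            if payload["layer_weights"] is not None
            else None
        ),
    )


# ---------------------------------------------------------------------------
# run configuration and pipeline


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    Precedence when built through the CLI: command-line overrides > config
    file > defaults.
    """

    out_dir: str = "mkmdose-out"
    preset_name: str = "nirs2015"
    params_path: str | None = None
    beam_model_path: str | None = None
    simulate: bool = True
    cache_model: bool = False
    seed: int = 0
    opt_tol: float = 0.005
    calib_tol: float = 1e-4
    convert: bool = False
    photon_alpha: float | None = None
    photon_beta: float | None = None
    log_level: str = "INFO"

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer")
        if self.opt_tol <= 0 or self.calib_tol <= 0:
            raise ValueError("tolerances must be positive")
        for attr in ("params_path", "beam_model_path"):
            value = getattr(self, attr)
            if value is not None and not Path(value).exists():
                raise ValueError(f"{attr} does not exist: {value}")
        if not self.simulate and self.beam_model_path is None:
            raise ValueError(
                "either enable simulate or provide beam_model_path"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        text = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _load_params(config: RunConfig) -> MKMParams:
    if config.params_path:
        return load_params(config.params_path)
    return preset(config.preset_name)


def _json_out(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: RunConfig) -> Path:
    """Deterministic end-to-end run: simulate, plan, benchmark, evaluate,
    extract z*, and optionally convert.

    Every output carries the config hash and seed; a stage failure aborts
    with the stage name while earlier outputs remain on disk.  Returns the
    artifact directory.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "seed": config.seed}
    params = _load_params(config)
    stage = "simulate"
    try:
        if config.beam_model_path:
            model = read_beam_model_json(config.beam_model_path)
            logger.info("loaded beam model from %s", config.beam_model_path)
        else:
            cache = out / "beam_model.json"
            if config.cache_model and cache.exists():
                model = read_beam_model_json(cache)
                logger.info("reusing cached beam model %s", cache)
            else:
                model = default_beam_model(seed=config.seed)
                logger.info("simulated default beam model")
                if config.cache_model:
                    write_beam_model_json(model, cache)
                    logger.info("cached beam model at %s", cache)

        stage = "benchmark"
        references = reference_records()
        rep = representative_plan()
        calibrated, trace = calibrate_fclin(
            model, rep, references[rep.name], params, tol=config.calib_tol
        )
        _json_out(
            out / "calibration.json",
            {
                **stamp,
                "f_clin": calibrated.f_clin,
                "trace": trace.to_dict(orient="records"),
                "parameters": calibrated.to_dict(),
            },
        )
        logger.info("calibrated F_clin = %.4f", calibrated.f_clin)

        stage = "evaluate"
        report = evaluate_suite(model, table1_suite(), references, calibrated)
        with (out / "evaluation.csv").open("w") as fh:
            fh.write(f"# config_hash: {stamp['config_hash']}\n")
            fh.write(f"# seed: {stamp['seed']}\n")
            report.rounded().to_csv(fh, index=False)
        _json_out(
            out / "evaluation.json",
            {
                **stamp,
                "rows": report.table.to_dict(orient="records"),
                "summary": report.summary(),
            },
        )

        stage = "extract-zstar"
        for plan in table1_suite():
            optimized = optimize_weights(
                model, plan, calibrated, tol=config.opt_tol
            )
            profile = compute_profile(model, optimized, calibrated)
            mask = mask_by_prescription(profile, plan.prescription)
            zstar = extract_zstar_depth(
                profile.d_rbe, profile.d_abs, calibrated, mask
            )
            frame = pd.DataFrame(
                {
                    "depth_cm": profile.depth,
                    "zstar_gy": zstar,
                    "masked": ~mask,
                }
            )
            with (out / f"zstar_{plan.name}.csv").open("w") as fh:
                fh.write(f"# config_hash: {stamp['config_hash']}\n")
                frame.to_csv(fh, index=False)

        if config.convert:
            stage = "convert"
            table = mkm_effective_lq(calibrated)
            conv = run_conversion_study(model, calibrated, table)
            with (out / "conversion.csv").open("w") as fh:
                fh.write(f"# config_hash: {stamp['config_hash']}\n")
                conv.table.to_csv(fh, index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return out
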