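"""Model parameter sets for the modified microdosimetric kinetic model (MKM).

The clinical dose engine is parameterized by the linear-quadratic (LQ)
coefficients of the reference cell line (human salivary gland tumour, HSG),
a carbon reference-radiation linear coefficient ``alpha_r``, and a
facility-calibrated clinical dose scaling factor ``F_clin``.  Two presets
ship with the package:

``ray2019``
    ``F_clin = 2.40``, the value obtained by benchmarking an active-energy
    scanned beamline against the NIRS reference beam.
``nirs2015``
    ``F_clin = 2.41``, the NIRS broad-beam value.

Note on units: some published tables interchange the units of the linear and
quadratic coefficients; dimensional analysis of the clinical-dose equation
requires ``alpha0``/``alpha_r`` in 1/Gy and ``beta`` in 1/Gy^2, which is the
convention used throughout this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import yaml

__all__ = ["MKMParams", "load_params", "preset"]

#: units attached to serialized parameter files
_UNITS = {
    "alpha0": "Gy^-1",
    "beta": "Gy^-2",
    "alpha_r": "Gy^-1",
    "f_clin": "dimensionless",
    "domain_radius": "um",
    "nucleus_radius": "um",
    "zstar_ref": "Gy",
}

_SCHEMA = "mkmdose/params-v1"


@dataclass(frozen=True)
class MKMParams:
    """Scalar constants of the MKM clinical-dose equations.

    Parameters
    ----------
    alpha0:
        Initial slope of the HSG survival curve in the limit LET -> 0, 1/Gy.
    beta:
        Quadratic LQ coefficient, constant and radiation-type independent,
        1/Gy^2.
    alpha_r:
        Linear coefficient of the carbon reference radiation, 1/Gy.
    f_clin:
        Clinical dose scaling factor (dimensionless) connecting the MKM
        biological dose to the clinical dose scale.
    domain_radius, nucleus_radius:
        Track-model radii in micrometres.  Metadata only: the amorphous
        track-structure calculation that consumes them is upstream of this
        package.
    zstar_ref:
        Saturation-corrected dose-mean specific energy at the centre of the
        representative reference beam, Gy.  Derived: must equal
        ``(alpha_r - alpha0) / beta``.
    """

    alpha0: float = 0.172
    beta: float = 0.0615
    alpha_r: float = 0.764
    f_clin: float = 2.40
    domain_radius: float = 0.32
    nucleus_radius: float = 3.9
    zstar_ref: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("alpha0", "beta", "alpha_r", "f_clin"):
            value = getattr(self, name)
            if not value > 0:
                raise ValueError(f"{name} must be > 0, got {value!r}")
        derived = (self.alpha_r - self.alpha0) / self.beta
        if self.zstar_ref is None:
            object.__setattr__(self, "zstar_ref", derived)
        elif abs(self.zstar_ref - derived) > 1e-9 * abs(derived):
            raise ValueError(
                f"zstar_ref={self.zstar_ref} inconsistent with "
                f"(alpha_r - alpha0)/beta = {derived}"
            )

    def with_f_clin(self, f_clin: float) -> "MKMParams":
        """Return a copy with a different clinical dose scaling factor."""
        return replace(self, f_clin=f_clin)

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        payload = {
            name: {"value": getattr(self, name), "unit": _UNITS[name]}
            for name in _UNITS
        }
        return {"schema": _SCHEMA, "parameters": payload}

    @classmethod
    def from_dict(cls, data: dict) -> "MKMParams":
        if data.get("schema") != _SCHEMA:
            raise ValueError(
                f"parameter schema mismatch: expected {_SCHEMA!r}, "
                f"found {data.get('schema')!r}"
            )
        values = {k: v["value"] for k, v in data["parameters"].items()}
        unknown = set(values) - set(_UNITS)
        if unknown:
            raise ValueError(f"unknown parameter fields: {sorted(unknown)}")
        return cls(**values)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_params(path: str | Path) -> MKMParams:
    """Read an :class:`MKMParams` set from a JSON or YAML file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    return MKMParams.from_dict(data)


def preset(name: str) -> MKMParams:
    """Load a shipped parameter preset (``ray2019`` or ``nirs2015``)."""
    ref = resources.files("mkmdose.data").joinpath(f"{name}.json")
    try:
        data = json.loads(ref.read_text())
    except FileNotFoundError:
        raise KeyError(f"unknown preset {name!r}; available: ray2019, nirs2015")
    return MKMParams.from_dict(data)
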