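"""Cube-target SOBP plan construction and RBE-weighted inverse optimization.

A spread-out Bragg peak (SOBP) plan stacks weighted monoenergetic energy
layers so the MKM RBE-weighted dose — not the absorbed dose — is flat at the
prescription across the target span ``[range - modulation, range]``.  Plans
are named ``R{range}M{modulation}D{prescription}`` after their water-
equivalent range (cm), modulation width (cm) and prescribed RBE-weighted
dose (Gy(RBE)).

The optimizer is a damped multiplicative fixed point on the RBE-weighted
dose at each layer's peak depth followed by a non-negative least-squares
polish on the linearized absorbed-dose operator; it is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.typing import NDArray
from scipy.optimize import lsq_linear, nnls

from .beam import BeamComponentField, BeamModel
from .core import DoseProfile, clinical_dose, zstar_mix
from .params import MKMParams

__all__ = [
    "SOBPPlan",
    "FieldAssembly",
    "table1_suite",
    "representative_plan",
    "select_layers",
    "optimize_weights",
    "compute_profile",
    "target_mean_metrics",
    "OptimizationError",
]

#: tolerance (cm) for the centre = range - modulation/2 identity; published
#: plan tables quote centres to within a few hundredths of a cm of it
CENTRE_TOL = 0.05


class OptimizationError(RuntimeError):
    """Raised when the weight optimizer fails to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


def _format_name(range_cm: float, modulation_cm: float, prescription: float) -> str:
    return f"R{range_cm:g}M{modulation_cm:g}D{prescription:.1f}"


@dataclass(frozen=True)
class SOBPPlan:
    """One single-beam SOBP specification, optionally with optimized weights."""

    range_cm: float
    modulation_cm: float
    prescription: float
    centre_cm: float = None  # type: ignore[assignment]
    name: str = None  # type: ignore[assignment]
    layer_ids: tuple[str, ...] | None = None
    layer_weights: NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if self.modulation_cm < 0 or self.range_cm <= 0:
            raise ValueError("range must be positive, modulation non-negative")
        derived_centre = self.range_cm - self.modulation_cm / 2.0
        if self.centre_cm is None:
            object.__setattr__(self, "centre_cm", derived_centre)
        elif abs(self.centre_cm - derived_centre) > CENTRE_TOL:
            raise ValueError(
                f"centre {self.centre_cm} cm inconsistent with "
                f"range - modulation/2 = {derived_centre} cm"
            )
        derived_name = _format_name(
            self.range_cm, self.modulation_cm, self.prescription
        )
        if self.name is None:
            object.__setattr__(self, "name", derived_name)
        elif self.name != derived_name:
            raise ValueError(
                f"name {self.name!r} not regenerable from fields "
                f"({derived_name!r})"
            )
        if self.layer_weights is not None:
            w = np.asarray(self.layer_weights, dtype=float)
            if np.any(w < 0) or not np.any(w > 0):
                raise ValueError("weights must be >= 0 and not all zero")
            object.__setattr__(self, "layer_weights", w)

    @property
    def target_span(self) -> tuple[float, float]:
        return (self.range_cm - self.modulation_cm, self.range_cm)


def table1_suite() -> tuple[SOBPPlan, ...]:
    """The seven-plan evaluation suite spanning range, width and dose.

    Three ranges at fixed M6/D5.8, three modulation widths at R21.1/D5.8 and
    three prescriptions at R21.1/M6, sharing the representative plan
    R21.1M6D5.8.
    """
    specs = [
        (15.2, 6.0, 5.8),
        (21.1, 3.0, 5.8),
        (21.1, 6.0, 5.8),
        (21.1, 12.0, 5.8),
        (21.1, 6.0, 3.6),
        (21.1, 6.0, 8.0),
        (26.5, 6.0, 5.8),
    ]
    return tuple(SOBPPlan(r, m, d) for r, m, d in specs)


def representative_plan() -> SOBPPlan:
    """The reference ("representative") beam geometry: R21.1M6D5.8."""
    return SOBPPlan(21.1, 6.0, 5.8)


# ---------------------------------------------------------------------------
# component assembly


@dataclass(frozen=True)
class FieldAssembly:
    """Species-resolved dose components of the layers entering one plan.

    Wraps ``(n_layers, 6, n_depth)`` stacks of per-unit-weight dose, z*_1D
    and representative energy so the optimizer and the mixed-field averaging
    see one uniform component structure for single beams and for composed
    multi-beam geometries alike.  ``anchor_depths`` holds the depth at which
    each layer's multiplicative update is evaluated (its Bragg-peak depth for
    a single beam).
    """

    depth: NDArray[np.float64]
    dose: NDArray[np.float64]       # (n_layers, n_components, n_depth)
    zstar: NDArray[np.float64]      # (n_layers, n_components, n_depth)
    energy: NDArray[np.float64]     # (n_layers, n_components, n_depth)
    species: NDArray[np.int64]      # (n_components,) atomic numbers
    layer_ids: tuple[str, ...]
    anchor_depths: NDArray[np.float64]

    @classmethod
    def from_layers(
        cls, layers: list[BeamComponentField] | tuple[BeamComponentField, ...]
    ) -> "FieldAssembly":
        depth = layers[0].depth
        return cls(
            depth=depth,
            dose=np.stack([l.dose_by_species for l in layers]),
            zstar=np.stack([l.zstar_by_species for l in layers]),
            energy=np.stack([l.energy_by_species for l in layers]),
            species=np.arange(1, 7),
            layer_ids=tuple(l.layer_id for l in layers),
            anchor_depths=np.array([l.peak_depth for l in layers]),
        )

    @property
    def n_layers(self) -> int:
        return self.dose.shape[0]

    def layer_dose(self) -> NDArray[np.float64]:
        """Species-summed dose per layer, (n_layers, n_depth)."""
        return self.dose.sum(axis=1)

    def d_abs(self, weights: NDArray) -> NDArray[np.float64]:
        return np.einsum("l,lx->x", weights, self.layer_dose())

    def zstar_mix(self, weights: NDArray) -> NDArray[np.float64]:
        d = self.dose.reshape(-1, self.depth.size)
        z = self.zstar.reshape(-1, self.depth.size)
        w = np.repeat(np.asarray(weights, dtype=float), self.dose.shape[1])
        return zstar_mix(d, z, w)

    def profile(self, weights: NDArray, params: MKMParams) -> DoseProfile:
        d_abs = self.d_abs(weights)
        zmix = self.zstar_mix(weights)
        z_eval = np.where(np.isnan(zmix), 0.0, zmix)
        d_rbe = np.asarray(clinical_dose(d_abs, z_eval, params))
        d_rbe[d_abs == 0] = 0.0
        rbe = np.full_like(d_abs, np.nan)
        ok = d_abs > 0
        rbe[ok] = d_rbe[ok] / d_abs[ok]
        return DoseProfile(
            depth=self.depth, d_abs=d_abs, zstar_mix=zmix, d_rbe=d_rbe, rbe=rbe
        )


#: spacing between selected energy layers along range, cm water-equivalent
SELECTION_PITCH = 0.3


def select_layers(
    model: BeamModel, plan: SOBPPlan, pitch: float = SELECTION_PITCH
) -> list[int]:
    """Indices of the layers feeding a plan: an aligned comb plus guards.

    Picks the library layer whose range is closest to the plan range, then
    steps proximally at ``pitch`` spacing until the target span
    ``[range - modulation, range]`` is covered, adding one proximal guard
    layer when the library provides it.  Anchoring the comb at the plan
    range puts the deepest layer's Bragg peak on the distal target edge,
    which is what makes a flat RBE-weighted plateau reachable there; no
    layer is placed beyond the range — as in clinical scanned-ion plans,
    the deepest layer itself defines the distal falloff.  Deterministic.
    Raises when the library does not cover the span.
    """
    lo, hi = plan.target_span
    ranges = model.ranges
    lib_pitch = float(np.median(np.diff(ranges))) if len(ranges) > 1 else pitch
    distal = int(np.argmin(np.abs(ranges - hi)))
    if abs(ranges[distal] - hi) > lib_pitch / 2 + 1e-9:
        raise ValueError(
            f"no library layer within half a pitch of the plan range "
            f"{hi:.2f} cm (closest: {ranges[distal]:.2f} cm)"
        )
    if ranges[0] > lo + lib_pitch / 2 + 1e-9:
        raise ValueError(
            f"beam model ranges start at {ranges[0]:.2f} cm and do not cover "
            f"the target span [{lo:.2f}, {hi:.2f}] cm of plan {plan.name}"
        )
    stride = max(int(round(pitch / lib_pitch)), 1)
    comb = []
    i = distal
    while ranges[i] > lo - 1e-9:
        comb.append(i)
        if i - stride < 0:
            break
        i -= stride
    idx = set(comb)
    proximal = min(comb)
    if proximal - stride >= 0:
        idx.add(proximal - stride)  # proximal guard
    return sorted(idx)


def _target_mask(depth: NDArray, span: tuple[float, float]) -> NDArray:
    eps = 1e-9
    return (depth >= span[0] - eps) & (depth <= span[1] + eps)


def _absorbed_for_clinical(
    d_rbe: NDArray, zstar: NDArray, params: MKMParams
) -> NDArray:
    """Absorbed dose delivering a requested RBE-weighted dose at fixed z*.

    Quadratic inversion of the clinical-dose equation in D:
    ``beta*D^2 + (alpha0 + beta*z*)*D = beta*(S^2 - A^2)`` with
    ``A = alpha_r/2beta`` and ``S = d_rbe/f_clin + A``.
    """
    a0, b, ar, f = params.alpha0, params.beta, params.alpha_r, params.f_clin
    half = ar / (2.0 * b)
    rhs = b * ((np.asarray(d_rbe) / f + half) ** 2 - half**2)
    alpha = a0 + b * np.asarray(zstar)
    return (-alpha + np.sqrt(alpha**2 + 4.0 * b * rhs)) / (2.0 * b)


def optimize_weights(
    model_or_assembly: BeamModel | FieldAssembly,
    plan: SOBPPlan,
    params: MKMParams,
    tol: float = 0.005,
    max_iter: int = 60,
    target_weights: NDArray | None = None,
) -> SOBPPlan:
    """Optimize layer weights for a flat RBE-weighted dose at prescription.

    Phase 1 is a damped multiplicative fixed point: each layer's weight is
    scaled by ``(prescription / D_RBE at the layer's anchor depth)**0.7``.
    Phase 2 polishes with non-negative least squares on the linearized
    absorbed-dose operator, holding the mixed-field z* of the previous
    iterate fixed, and re-mixes until the (optionally ``target_weights``-
    weighted) RMS deviation of D_RBE from the prescription over the target
    span is at most ``tol`` (fraction of prescription).

    Returns a copy of the plan carrying layer ids and weights.  Raises
    :class:`OptimizationError` with the last residual on non-convergence.
    """
    if isinstance(model_or_assembly, BeamModel):
        idx = select_layers(model_or_assembly, plan)
        assembly = FieldAssembly.from_layers(
            [model_or_assembly.layers[i] for i in idx]
        )
    else:
        assembly = model_or_assembly
    if tol <= 0:
        raise ValueError("tol must be positive")
    span = plan.target_span
    mask = _target_mask(assembly.depth, span)
    if not np.any(mask):
        raise ValueError(f"target span {span} contains no grid points")
    p = plan.prescription
    if target_weights is None:
        tw = np.ones(int(mask.sum()))
    else:
        tw = np.asarray(target_weights, dtype=float)[mask]
    tw = tw / tw.sum()
    sqrt_tw = np.sqrt(tw)

    a0, b, ar, f = params.alpha0, params.beta, params.alpha_r, params.f_clin
    half = ar / (2.0 * b)
    dose_l = assembly.layer_dose()[:, mask]                  # (L, n)
    znum_l = (assembly.dose * assembly.zstar).sum(axis=1)[:, mask]
    if np.any(dose_l.sum(axis=0) <= 0):
        raise OptimizationError("target span contains zero-dose depths")

    def d_rbe_of(w: NDArray) -> tuple[NDArray, NDArray, NDArray]:
        d = w @ dose_l
        z = (w @ znum_l) / np.maximum(d, 1e-300)
        d_rbe = f * (-half + np.sqrt(half**2 + (a0 * d + b * z * d + b * d * d) / b))
        return d, z, d_rbe

    def rms_of(w: NDArray) -> float:
        _, _, d_rbe = d_rbe_of(w)
        return float(np.sqrt(np.sum(tw * ((d_rbe - p) / p) ** 2)))

    # phase 1: damped multiplicative fixed point at the layer anchor depths
    depth_in = assembly.depth[mask]
    anchors = np.clip(assembly.anchor_depths, span[0], span[1])
    anchor_idx = np.array(
        [int(np.argmin(np.abs(depth_in - a))) for a in anchors]
    )
    gamma = 0.7
    w = np.ones(assembly.n_layers)
    for _ in range(max_iter):
        _, _, d_rbe = d_rbe_of(w)
        at_anchor = d_rbe[anchor_idx]
        if np.any(at_anchor <= 0):
            raise OptimizationError(
                "zero RBE-weighted dose at a layer anchor depth"
            )
        factor = (p / at_anchor) ** gamma
        w = w * factor
        if np.max(np.abs(factor - 1.0)) < 1e-3:
            break

    # phase 2: non-negative least-squares polish on the linearized
    # RBE-weighted dose operator (Gauss-Newton with w + dw >= 0 bounds)
    rms = rms_of(w)
    for _ in range(max_iter):
        d, z, d_rbe = d_rbe_of(w)
        root = d_rbe / f + half
        dd = f / (2.0 * root) * (a0 + b * z + 2.0 * b * d) / b
        dz = f * d / (2.0 * root)
        jac = (
            dd[None, :] * dose_l
            + dz[None, :] * (znum_l - z[None, :] * dose_l)
            / np.maximum(d[None, :], 1e-300)
        )
        sol = lsq_linear(
            (jac * sqrt_tw[None, :]).T,
            (p - d_rbe) * sqrt_tw,
            bounds=(-w, np.inf),
            max_iter=500,
            tol=1e-12,
        )
        step, improved = 1.0, False
        for _ in range(12):
            candidate = rms_of(w + step * sol.x)
            if candidate < rms:
                w = w + step * sol.x
                rms = candidate
                improved = True
                break
            step *= 0.5
        if not improved:
            # Gauss-Newton line search exhausted: try one frozen-z* NNLS
            # step (fit the absorbed-dose target implied by the current
            # mixed-field z*) to escape the stall
            z_frozen = (w @ znum_l) / (w @ dose_l)
            d_target = _absorbed_for_clinical(
                np.full(z_frozen.shape, p), z_frozen, params
            )
            w_nnls, _ = nnls(
                dose_l.T * sqrt_tw[:, None], d_target * sqrt_tw
            )
            if np.any(w_nnls > 0) and rms_of(w_nnls) < rms:
                w = w_nnls
                rms = rms_of(w)
                improved = True
        if rms <= tol or not improved:
            break
    if rms > tol:
        raise OptimizationError(
            f"optimizer did not reach tol={tol} for {plan.name}: "
            f"RMS residual {rms:.4g}",
            residual=rms,
        )
    if not np.any(w > 0):
        raise OptimizationError("optimizer returned all-zero weights")
    return replace(plan, layer_ids=assembly.layer_ids, layer_weights=w)


def compute_profile(
    model_or_assembly: BeamModel | FieldAssembly,
    plan: SOBPPlan,
    params: MKMParams,
) -> DoseProfile:
    """Depth profile (D_abs, z*_mix, D_RBE, RBE) of an optimized plan."""
    if plan.layer_weights is None or plan.layer_ids is None:
        raise ValueError(f"plan {plan.name} carries no optimized weights")
    if isinstance(model_or_assembly, BeamModel):
        by_id = {l.layer_id: l for l in model_or_assembly.layers}
        assembly = FieldAssembly.from_layers(
            [by_id[i] for i in plan.layer_ids]
        )
    else:
        assembly = model_or_assembly
        if assembly.layer_ids != plan.layer_ids:
            raise ValueError("assembly layers do not match the plan's layers")
    return assembly.profile(plan.layer_weights, params)


def target_mean_metrics(
    profile: DoseProfile,
    plan: SOBPPlan,
    target_weights: NDArray | None = None,
) -> tuple[float, float, float]:
    """Target means: (mean D_RBE, mean D_abs, mean RBE).

    Means are arithmetic over grid points in ``[range - modulation, range]``
    (optionally weighted); the mean RBE is the ratio of the mean doses, not
    the mean of pointwise ratios.
    """
    mask = _target_mask(profile.depth, plan.target_span)
    if not np.any(mask):
        raise ValueError("target span contains no grid points")
    if target_weights is None:
        tw = np.ones(int(mask.sum()))
    else:
        tw = np.asarray(target_weights, dtype=float)[mask]
    tw = tw / tw.sum()
    mean_rbe_dose = float(np.sum(tw * profile.d_rbe[mask]))
    mean_abs = float(np.sum(tw * profile.d_abs[mask]))
    return mean_rbe_dose, mean_abs, mean_rbe_dose / mean_abs
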