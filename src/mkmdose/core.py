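"""Clinical-dose mathematics of the modified microdosimetric kinetic model.

The RBE-weighted ("clinical") dose at a point with absorbed dose ``D`` and
mixed-field saturation-corrected dose-mean specific energy ``z*`` is

.. math::

    D_{RBE} = F_{clin}\\left(-\\frac{\\alpha_r}{2\\beta}
        + \\sqrt{\\left(\\frac{\\alpha_r}{2\\beta}\\right)^2
        + \\frac{\\alpha_0 D + \\beta z^* D + \\beta D^2}{\\beta}}\\right)

which is the LQ photon-equivalence construction with carbon as the reference
radiation (linear coefficient ``alpha_r``) and a mixed-field linear
coefficient ``alpha(z*) = alpha0 + beta * z*``.  The expression inverts in
closed form for ``z*`` given a profile pair ``(D_RBE, D_abs)``.

Depths with zero absorbed dose carry an explicit not-a-value sentinel
(``nan``) wherever a ratio or mixed-field average is undefined; they are
never silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .params import MKMParams

__all__ = [
    "DoseProfile",
    "zstar_mix",
    "clinical_dose",
    "invert_zstar",
    "rbe_profile",
    "low_dose_rbe_limit",
]


@dataclass(frozen=True)
class DoseProfile:
    """Depth-resolved dose description of one plan.

    Attributes
    ----------
    depth:
        Water-equivalent depth grid, cm, strictly increasing and uniform.
    d_abs:
        Absorbed dose per depth, Gy.
    zstar_mix:
        Mixed-field z*_1D per depth, Gy; ``nan`` where no dose is deposited.
    d_rbe:
        RBE-weighted dose per depth, Gy(RBE).
    rbe:
        d_rbe / d_abs; ``nan`` where d_abs == 0.
    """

    depth: NDArray[np.float64]
    d_abs: NDArray[np.float64]
    zstar_mix: NDArray[np.float64]
    d_rbe: NDArray[np.float64]
    rbe: NDArray[np.float64]

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        n = depth.size
        if n < 2:
            raise ValueError("depth grid needs at least two points")
        steps = np.diff(depth)
        if not np.all(steps > 0):
            raise ValueError("depth grid must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-12):
            raise ValueError("depth grid must be uniform")
        for name in ("d_abs", "zstar_mix", "d_rbe", "rbe"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != depth.shape:
                raise ValueError(f"{name} must match the depth grid shape")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "depth", depth)
        if np.any(self.d_abs < 0) or np.any(self.d_rbe < 0):
            raise ValueError("doses must be non-negative")
        zero = self.d_abs == 0
        if np.any(self.d_rbe[zero] != 0):
            raise ValueError("d_rbe must be 0 wherever d_abs is 0")

    @property
    def spacing(self) -> float:
        return float(self.depth[1] - self.depth[0])


def _as_params(params: MKMParams) -> tuple[float, float, float, float]:
    return params.alpha0, params.beta, params.alpha_r, params.f_clin


def zstar_mix(
    doses_by_component: ArrayLike,
    zstars_by_component: ArrayLike,
    weights: ArrayLike,
) -> NDArray[np.float64]:
    """Mixed-field z*_1D: the dose-and-weight weighted mean of component z*.

    ``doses_by_component`` and ``zstars_by_component`` are
    ``(n_components, n_depths)`` matrices; ``weights`` is a per-component
    vector.  At depths where the total weighted dose vanishes the mixed
    value is undefined and returned as ``nan``.
    """
    d = np.atleast_2d(np.asarray(doses_by_component, dtype=float))
    z = np.atleast_2d(np.asarray(zstars_by_component, dtype=float))
    w = np.atleast_1d(np.asarray(weights, dtype=float))
    if d.shape != z.shape:
        raise ValueError(f"dose/zstar shape mismatch: {d.shape} vs {z.shape}")
    if w.shape[0] != d.shape[0]:
        raise ValueError(
            f"weights length {w.shape[0]} != component count {d.shape[0]}"
        )
    if np.any(w < 0) or np.any(d < 0):
        raise ValueError("doses and weights must be non-negative")
    if not np.any(w > 0):
        raise ValueError("at least one weight must be positive")
    wd = d * w[:, None]
    total = wd.sum(axis=0)
    out = np.full(d.shape[1], np.nan)
    ok = total > 0
    out[ok] = (wd[:, ok] * z[:, ok]).sum(axis=0) / total[ok]
    return out


def clinical_dose(
    d_abs: ArrayLike, zstar: ArrayLike, params: MKMParams
) -> NDArray[np.float64] | float:
    """RBE-weighted dose from absorbed dose and mixed-field z*_1D.

    Vectorizes over depth.  Returns 0 where ``d_abs`` is 0 (the limit is
    exact, not a convention).  When ``alpha0 + beta*zstar == alpha_r`` the
    radicand is a perfect square and the result reduces to
    ``f_clin * d_abs``.
    """
    a0, b, ar, f = _as_params(params)
    d = np.asarray(d_abs, dtype=float)
    z = np.asarray(zstar, dtype=float)
    if np.any(d < 0):
        raise ValueError("d_abs must be non-negative")
    if np.any(z < 0):
        raise ValueError("zstar must be non-negative")
    half = ar / (2.0 * b)
    radicand = half**2 + (a0 * d + b * z * d + b * d * d) / b
    out = f * (-half + np.sqrt(radicand))
    out = np.where(d == 0, 0.0, out)
    return float(out) if out.ndim == 0 else out


def invert_zstar(
    d_rbe: ArrayLike,
    d_abs: ArrayLike,
    params: MKMParams,
    *,
    warn_negative: bool = True,
) -> NDArray[np.float64] | float:
    """Exact algebraic inverse of :func:`clinical_dose` for z*_1D.

    .. math::

        z^* = \\frac{\\beta\\left[(D_{RBE}/F_{clin} + \\alpha_r/2\\beta)^2
               - (\\alpha_r/2\\beta)^2\\right] - \\alpha_0 D - \\beta D^2}
              {\\beta D}

    A profile pair implying ``z* < 0`` is physically inconsistent; the
    negative value is returned as-is with a warning so callers can flag it.
    """
    a0, b, ar, f = _as_params(params)
    dr = np.asarray(d_rbe, dtype=float)
    d = np.asarray(d_abs, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d_abs must be positive for z* extraction")
    if np.any(dr <= 0):
        raise ValueError("d_rbe must be positive for z* extraction")
    half = ar / (2.0 * b)
    out = (b * ((dr / f + half) ** 2 - half**2) - a0 * d - b * d * d) / (b * d)
    if warn_negative and np.any(out < 0):
        warnings.warn(
            "extracted z* < 0: (d_rbe, d_abs) pair is physically "
            "inconsistent with the parameter set",
            stacklevel=2,
        )
    return float(out) if np.ndim(out) == 0 else out


def rbe_profile(profile: DoseProfile) -> NDArray[np.float64]:
    """Pointwise RBE = d_rbe / d_abs; ``nan`` where d_abs == 0."""
    out = np.full_like(profile.d_abs, np.nan)
    ok = profile.d_abs > 0
    out[ok] = profile.d_rbe[ok] / profile.d_abs[ok]
    return out


def low_dose_rbe_limit(
    zstar: ArrayLike, params: MKMParams
) -> NDArray[np.float64] | float:
    """Limit of D_RBE / D_abs as the absorbed dose tends to zero.

    First-order expansion of the clinical-dose equation:
    ``f_clin * (alpha0 + beta * z*) / alpha_r``.
    """
    a0, b, ar, f = _as_params(params)
    z = np.asarray(zstar, dtype=float)
    if np.any(z < 0):
        raise ValueError("zstar must be non-negative")
    out = f * (a0 + b * z) / ar
    return float(out) if out.ndim == 0 else out
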