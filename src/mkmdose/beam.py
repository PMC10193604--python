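"""Synthetic scanned carbon-ion beam model.

Clinical MKM dose engines consume two precalculated tables: the
saturation-corrected dose-mean specific energy z*_1D as a function of kinetic
energy for ion species Z = 1..6, and depth-dependent fragment dose spectra of
the primary carbon beam.  In production those come from an amorphous
track-structure calculation and a Monte Carlo transport code.  This module
provides a deterministic parametric surrogate with the same qualitative
structure — a saturating z*(LET) response, range–energy and LET–energy power
laws, a plateau-plus-Bragg-peak primary depth dose with nuclear attenuation,
and fragment build-up with a distal tail — so the full planning, benchmarking
and conversion pipeline runs without external data.  Externally supplied real
tables are first-class inputs through the same file schema (see
:mod:`mkmdose.io`).

The surrogate is not transport physics: no lateral dose, no cross-sections,
no energy-loss straggling theory.  Its defaults are chosen so the
representative reference plan produces a target-centre z*_1D,mix near the
published reference value of ~9.6 Gy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.typing import NDArray

__all__ = [
    "BeamKnobs",
    "ZStarTable",
    "BeamComponentField",
    "BeamModel",
    "default_depth_grid",
    "default_beam_model",
    "make_zstar_table",
    "make_pristine_peak",
    "make_beam_model",
    "letd_profile",
    "find_neutron_equivalent_depth",
    "NEUTRON_EQUIVALENT_LETD",
]

#: species bookkeeping: atomic number -> (mass number, range multiplier vs C-12)
#: range multiplier = (A/Z^2) / (12/36), same velocity
_SPECIES = (1, 2, 3, 4, 5, 6)
_MASS = {1: 1, 2: 4, 3: 7, 4: 9, 5: 11, 6: 12}
_RANGE_MULT = {z: (3.0 * _MASS[z] / z**2) for z in _SPECIES}

#: dose-averaged LET defining the historical neutron-equivalent position, keV/um
NEUTRON_EQUIVALENT_LETD = 80.0


@dataclass(frozen=True)
class BeamKnobs:
    """Tunable constants of the beam surrogate.

    range_coeff / range_exp
        Range–energy power law R = range_coeff * E**range_exp (cm, MeV/u);
        defaults give ~27 cm at 400 MeV/u, matching clinical carbon beams.
    let_coeff / let_exp
        LET surrogate L(Z, E) = let_coeff * Z^2 * E**(-let_exp), keV/um;
        ~11 keV/um for carbon at 400 MeV/u.
    zstar_sat, zstar_let_half, zstar_shape
        Saturating z*(L) response  z* = zstar_sat * u^q / (1 + u^q)  with
        u = L / zstar_let_half and q = zstar_shape.  zstar_sat (Gy) is the
        saturation ceiling; the response is monotone in L so higher-Z ions
        at fixed velocity always carry higher z*.
    attenuation_length
        Depth constant (cm) of the primary-carbon dose fraction
        exp(-x / attenuation_length) modelling nuclear attenuation.
    straggle_frac, straggle_floor
        Gaussian range-straggling width sigma = straggle_frac * R +
        straggle_floor (cm).
    peak_sharpness
        Exponent of the stopping-power rise (R - x)^(-peak_sharpness) toward
        the Bragg peak.
    fragment_fractions
        Relative dose shares of fragment species Z = 1..5 (normalized
        internally).
    fragment_tail_lengths
        Distal exponential tail lengths per fragment species, cm.
    noise_level
        Optional multiplicative dose jitter (fractional sigma); 0 keeps the
        generator fully deterministic.
    """

    range_coeff: float = 31.0 / 430.0**1.8
    range_exp: float = 1.8
    let_coeff: float = 37.0
    let_exp: float = 0.8
    zstar_sat: float = 35.0
    zstar_let_half: float = 68.0
    zstar_shape: float = 3.0
    attenuation_length: float = 130.0
    straggle_frac: float = 0.006
    straggle_floor: float = 0.12
    peak_sharpness: float = 0.445
    fragment_fractions: tuple[float, ...] = (0.34, 0.30, 0.13, 0.11, 0.12)
    fragment_tail_lengths: tuple[float, ...] = (6.0, 5.0, 2.5, 1.8, 1.2)
    noise_level: float = 0.0
    min_energy: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "range_coeff", "range_exp", "let_coeff", "let_exp", "zstar_sat",
            "zstar_let_half", "zstar_shape", "attenuation_length",
            "straggle_frac", "straggle_floor", "peak_sharpness", "min_energy",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"knob {name} must be > 0")
        if len(self.fragment_fractions) != 5 or len(self.fragment_tail_lengths) != 5:
            raise ValueError("fragment knobs need one entry per species Z=1..5")
        if any(f < 0 for f in self.fragment_fractions) or not any(
            f > 0 for f in self.fragment_fractions
        ):
            raise ValueError("fragment_fractions must be non-negative, not all zero")
        if any(t <= 0 for t in self.fragment_tail_lengths):
            raise ValueError("fragment_tail_lengths must be positive")
        if self.noise_level < 0:
            raise ValueError("noise_level must be >= 0")

    # -- range/energy/LET power laws --------------------------------------

    def range_from_energy(self, energy: NDArray | float) -> NDArray | float:
        return self.range_coeff * np.asarray(energy, dtype=float) ** self.range_exp

    def energy_from_range(self, range_cm: NDArray | float) -> NDArray | float:
        r = np.maximum(np.asarray(range_cm, dtype=float), 0.0)
        return (r / self.range_coeff) ** (1.0 / self.range_exp)

    def let_surrogate(self, z: int, energy: NDArray | float) -> NDArray | float:
        e = np.maximum(np.asarray(energy, dtype=float), self.min_energy)
        return self.let_coeff * z**2 * e ** (-self.let_exp)

    def zstar_from_let(self, let: NDArray | float) -> NDArray | float:
        u = (np.asarray(let, dtype=float) / self.zstar_let_half) ** self.zstar_shape
        return self.zstar_sat * u / (1.0 + u)


def default_depth_grid(max_depth: float = 32.0, spacing: float = 0.05) -> NDArray:
    """Uniform water-equivalent depth grid in cm, beam entering at 0."""
    n = int(round(max_depth / spacing)) + 1
    return np.linspace(0.0, max_depth, n)


# ---------------------------------------------------------------------------
# z* table


@dataclass(frozen=True)
class ZStarTable:
    """z*_1D (Gy) versus kinetic energy (MeV/u) for one ion species."""

    species: int
    energy_grid: NDArray[np.float64]
    zstar: NDArray[np.float64]
    ceiling: float

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise ValueError(f"species must be in 1..6, got {self.species}")
        e = np.asarray(self.energy_grid, dtype=float)
        z = np.asarray(self.zstar, dtype=float)
        if e.ndim != 1 or z.shape != e.shape:
            raise ValueError("energy_grid and zstar must be matching 1-D arrays")
        if not np.all(np.diff(e) > 0):
            raise ValueError("energy_grid must be strictly increasing")
        if not np.all(np.isfinite(z)) or np.any(z <= 0):
            raise ValueError("zstar must be finite and positive")
        if np.any(z > self.ceiling * (1 + 1e-12)):
            raise ValueError("zstar exceeds the configured saturation ceiling")
        object.__setattr__(self, "energy_grid", e)
        object.__setattr__(self, "zstar", z)

    def __call__(self, energy: NDArray | float) -> NDArray | float:
        """Linear interpolation, clamped to the grid ends."""
        return np.interp(energy, self.energy_grid, self.zstar)


def make_zstar_table(
    species: int,
    energy_grid: NDArray | None = None,
    knobs: BeamKnobs | None = None,
) -> ZStarTable:
    """Evaluate the z* surrogate for one species on an energy grid.

    The grid must cover at least 1–430 MeV/u so every representative energy
    the depth-dose generator produces falls inside it.
    """
    knobs = knobs or BeamKnobs()
    if energy_grid is None:
        energy_grid = np.geomspace(1.0, 430.0, 240)
    e = np.asarray(energy_grid, dtype=float)
    if e[0] > 1.0 or e[-1] < 430.0:
        raise ValueError("energy grid must cover at least 1-430 MeV/u")
    let = knobs.let_surrogate(species, e)
    zstar = knobs.zstar_from_let(let)
    return ZStarTable(species=species, energy_grid=e, zstar=zstar,
                      ceiling=knobs.zstar_sat)


# ---------------------------------------------------------------------------
# depth-dose fields


@dataclass(frozen=True)
class BeamComponentField:
    """Per-species depth dose of one monoenergetic energy layer.

    Dose is per unit layer weight (arbitrary but fixed units); the species
    axis is Z = 1..6 with carbon (Z = 6) the primary.  ``zstar_by_species``
    and ``letd_by_species`` carry the representative-energy beam-quality
    values aligned with the dose matrix.
    """

    layer_id: str
    nominal_energy: float
    range_cm: float
    depth: NDArray[np.float64]
    dose_by_species: NDArray[np.float64]       # (6, n_depth), Gy per weight
    zstar_by_species: NDArray[np.float64]      # (6, n_depth), Gy
    letd_by_species: NDArray[np.float64]       # (6, n_depth), keV/um
    energy_by_species: NDArray[np.float64]     # (6, n_depth), MeV/u

    def __post_init__(self) -> None:
        depth = np.asarray(self.depth, dtype=float)
        n = depth.size
        for name in ("dose_by_species", "zstar_by_species",
                     "letd_by_species", "energy_by_species"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (6, n):
                raise ValueError(f"{name} must have shape (6, {n})")
            object.__setattr__(self, name, arr)
        object.__setattr__(self, "depth", depth)
        if np.any(self.dose_by_species < 0):
            raise ValueError("dose_by_species must be non-negative")

    @property
    def total_dose(self) -> NDArray[np.float64]:
        return self.dose_by_species.sum(axis=0)

    @property
    def peak_depth(self) -> float:
        return float(self.depth[int(np.argmax(self.total_dose))])


def make_pristine_peak(
    range_cm: float,
    depth_grid: NDArray,
    knobs: BeamKnobs | None = None,
    layer_id: str | None = None,
) -> BeamComponentField:
    """Parametric depth dose of one monoenergetic carbon layer.

    Primary carbon: stopping-power rise (R - x)^(-p) times nuclear-survival
    attenuation, Gaussian-smeared for range straggling, hard-zeroed beyond
    R + 5 sigma.  Fragments (Z = 1..5): dose share (1 - exp(-x/lambda)) of
    the primary envelope before the peak and per-species exponential tails
    beyond it, truncated at each fragment's own range.  Per-species z*, LETd
    and representative energy follow from residual range through the
    surrogate power laws.
    """
    knobs = knobs or BeamKnobs()
    x = np.asarray(depth_grid, dtype=float)
    if range_cm <= x[0] or range_cm > x[-1]:
        raise ValueError(
            f"range {range_cm} cm outside depth grid [{x[0]}, {x[-1]}]"
        )
    dx = x[1] - x[0]
    sigma = knobs.straggle_frac * range_cm + knobs.straggle_floor
    half_k = max(int(np.ceil(4 * sigma / dx)), 1)
    kx = np.arange(-half_k, half_k + 1) * dx
    kernel = np.exp(-0.5 * (kx / sigma) ** 2)
    kernel /= kernel.sum()

    # primary carbon: S(rho) * survival, then Gaussian smear in depth.
    # smearing the one-sided stopping-power rise pulls the maximum proximal
    # of the nominal range, so build once, measure the offset, and rebuild
    # with the range advanced by it: the smeared peak then sits on range_cm.
    def _smeared_primary(r_eff: float) -> NDArray:
        rho = r_eff - x
        raw = np.where(
            rho > 0, (np.abs(rho) + 0.5 * dx) ** (-knobs.peak_sharpness), 0.0
        )
        raw *= np.exp(-x / knobs.attenuation_length)
        return np.convolve(raw, kernel, mode="same")

    first = _smeared_primary(range_cm)
    offset = range_cm - x[int(np.argmax(first))]
    d_primary = _smeared_primary(range_cm + offset)
    d_primary[x > range_cm + 5 * sigma] = 0.0
    d_primary /= d_primary.max()  # peak of primary = 1 per unit weight
    peak_idx = int(np.argmax(d_primary))

    # fragment dose: share of the primary envelope growing with depth
    frac = np.asarray(knobs.fragment_fractions, dtype=float)
    frac = frac / frac.sum()
    buildup = -np.expm1(-x / knobs.attenuation_length)  # 1 - exp(-x/lambda)
    frag_total = d_primary * buildup / (1.0 - buildup)
    dose = np.zeros((6, x.size))
    dose[5] = d_primary
    for i, z in enumerate((1, 2, 3, 4, 5)):
        fz = frac[i] * frag_total
        tail = (
            fz[peak_idx]
            * np.exp(-(x - x[peak_idx]) / knobs.fragment_tail_lengths[i])
        )
        tail[x <= x[peak_idx]] = 0.0
        tail[x > _RANGE_MULT[z] * range_cm] = 0.0
        dose[z - 1] = np.maximum(fz, tail)

    # representative energy per species from residual range (deterministic)
    tables = {z: make_zstar_table(z, knobs=knobs) for z in _SPECIES}
    energy = np.zeros((6, x.size))
    zstar = np.zeros((6, x.size))
    letd = np.zeros((6, x.size))
    for z in _SPECIES:
        r_species = _RANGE_MULT[z] * range_cm
        e = knobs.energy_from_range(np.maximum(r_species - x, 0.0) / _RANGE_MULT[z])
        e = np.maximum(e, knobs.min_energy)
        energy[z - 1] = e
        letd[z - 1] = knobs.let_surrogate(z, e)
        zstar[z - 1] = tables[z](e)

    return BeamComponentField(
        layer_id=layer_id or f"R{range_cm:.2f}",
        nominal_energy=float(knobs.energy_from_range(range_cm)),
        range_cm=float(range_cm),
        depth=x,
        dose_by_species=dose,
        zstar_by_species=zstar,
        letd_by_species=letd,
        energy_by_species=energy,
    )


@dataclass(frozen=True)
class BeamModel:
    """Library of energy layers sharing one depth grid, plus provenance."""

    layers: tuple[BeamComponentField, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("a beam model needs at least one layer")
        depth0 = self.layers[0].depth
        for layer in self.layers:
            if layer.depth.shape != depth0.shape or not np.array_equal(
                layer.depth, depth0
            ):
                raise ValueError("all layers must share one depth grid")
        ranges = [l.range_cm for l in self.layers]
        energies = [l.nominal_energy for l in self.layers]
        if not all(a < b for a, b in zip(ranges, ranges[1:])):
            raise ValueError("layer ranges must be strictly increasing")
        if not all(a < b for a, b in zip(energies, energies[1:])):
            raise ValueError("layer ranges must increase with nominal energy")

    @property
    def depth(self) -> NDArray[np.float64]:
        return self.layers[0].depth

    @property
    def ranges(self) -> NDArray[np.float64]:
        return np.array([l.range_cm for l in self.layers])


def default_beam_model(
    knobs: BeamKnobs | None = None, seed: int | None = None
) -> BeamModel:
    """The default scanned-beam layer library: ranges 2.0–27.7 cm at 0.1 cm.

    The fine 0.1 cm library pitch lets plan optimization pick a coarser
    (0.3 cm) sub-comb whose deepest layer peaks exactly at any plan range
    quoted to millimetre precision.
    """
    ranges = np.round(np.arange(1.0, 27.75, 0.1), 10)
    return make_beam_model(ranges, knobs=knobs, seed=seed)


def make_beam_model(
    ranges: NDArray | list[float],
    depth_grid: NDArray | None = None,
    knobs: BeamKnobs | None = None,
    seed: int | None = None,
) -> BeamModel:
    """Build a scanned-beam layer library for the given Bragg-peak ranges.

    Deterministic given identical inputs; the seed only feeds the optional
    multiplicative dose jitter (``noise_level`` knob) and is recorded in the
    provenance either way.
    """
    knobs = knobs or BeamKnobs()
    if depth_grid is None:
        depth_grid = default_depth_grid()
    r = np.sort(np.asarray(ranges, dtype=float))
    if np.any(np.diff(r) <= 0):
        raise ValueError("layer ranges must be distinct")
    rng = np.random.default_rng(seed)
    layers = []
    for i, range_cm in enumerate(r):
        layer = make_pristine_peak(
            range_cm, depth_grid, knobs, layer_id=f"L{i:03d}"
        )
        if knobs.noise_level > 0:
            jitter = rng.normal(1.0, knobs.noise_level, layer.dose_by_species.shape)
            layer = BeamComponentField(
                layer_id=layer.layer_id,
                nominal_energy=layer.nominal_energy,
                range_cm=layer.range_cm,
                depth=layer.depth,
                dose_by_species=np.maximum(layer.dose_by_species * jitter, 0.0),
                zstar_by_species=layer.zstar_by_species,
                letd_by_species=layer.letd_by_species,
                energy_by_species=layer.energy_by_species,
            )
        layers.append(layer)
    # normalize through JSON so provenance survives serialization verbatim
    provenance = json.loads(json.dumps(
        {"generator": "mkmdose.beam", "seed": seed, "knobs": asdict(knobs)}
    ))
    return BeamModel(layers=tuple(layers), provenance=provenance)


# ---------------------------------------------------------------------------
# LET utilities


def letd_profile(model: BeamModel, weights: NDArray | list[float]) -> NDArray:
    """Dose-averaged LET over all layers and species per depth, keV/um.

    Depths with zero total dose are undefined (``nan``).
    """
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(model.layers):
        raise ValueError("one weight per layer required")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    num = np.zeros(model.depth.size)
    den = np.zeros(model.depth.size)
    for wi, layer in zip(w, model.layers):
        d = wi * layer.dose_by_species
        num += (d * layer.letd_by_species).sum(axis=0)
        den += d.sum(axis=0)
    out = np.full(model.depth.size, np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def find_neutron_equivalent_depth(
    letd: NDArray,
    depth: NDArray,
    threshold: float = NEUTRON_EQUIVALENT_LETD,
) -> float:
    """Shallowest depth where LETd crosses the given threshold (keV/um).

    Linear interpolation between grid points; exact grid hits are returned
    as-is.  Raises if the profile never reaches the threshold.
    """
    letd = np.asarray(letd, dtype=float)
    depth = np.asarray(depth, dtype=float)
    ok = np.isfinite(letd)
    l, x = letd[ok], depth[ok]
    hit = np.nonzero(l == threshold)[0]
    cross = np.nonzero((l[:-1] - threshold) * (l[1:] - threshold) < 0)[0]
    first_hit = hit[0] if hit.size else np.inf
    first_cross = cross[0] if cross.size else np.inf
    if first_hit <= first_cross:
        if np.isinf(first_hit):
            raise ValueError(f"LETd never crosses {threshold} keV/um")
        return float(x[first_hit])
    i = int(first_cross)
    t = (threshold - l[i]) / (l[i + 1] - l[i])
    return float(x[i] + t * (x[i + 1] - x[i]))
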