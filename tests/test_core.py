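"""Unit and property tests of the clinical-dose mathematics.

The independent oracles here are closed forms and brute-force arithmetic:
the z* inversion example is recomputed term by term, and the perfect-square
identity at the reference beam quality is verified symbolically with sympy
before being asserted numerically.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mkmdose import (
    DoseProfile,
    clinical_dose,
    invert_zstar,
    low_dose_rbe_limit,
    rbe_profile,
    zstar_mix,
)
from mkmdose.params import MKMParams

PARAMS = MKMParams(f_clin=2.40)
ZREF = (0.764 - 0.172) / 0.0615  # 9.62602 Gy


def brute_force_zstar(d_rbe, d_abs, p=PARAMS):
    """Term-by-term arithmetic of the inversion formula, kept independent
    of the library implementation."""
    half = p.alpha_r / (2 * p.beta)
    term1 = p.beta * ((d_rbe / p.f_clin + half) ** 2 - half**2)
    term2 = p.alpha0 * d_abs
    term3 = p.beta * d_abs**2
    return (term1 - term2 - term3) / (p.beta * d_abs)


# ---------------------------------------------------------------------------
# mixed-field averaging


class TestZstarMix:
    def test_single_component_identity(self):
        d = np.ones((1, 5))
        z = np.full((1, 5), 7.0)
        assert np.allclose(zstar_mix(d, z, [3.2]), 7.0)

    def test_symmetric_and_weighted_means(self):
        d = np.array([[1.0], [1.0]])
        z = np.array([[5.0], [15.0]])
        assert np.isclose(zstar_mix(d, z, [1, 1])[0], 10.0)
        d = np.array([[3.0], [1.0]])
        assert np.isclose(zstar_mix(d, z, [1, 1])[0], 7.5)

    def test_zero_dose_depth_is_undefined_not_zero(self):
        d = np.array([[1.0, 0.0]])
        z = np.array([[5.0, 5.0]])
        out = zstar_mix(d, z, [1.0])
        assert out[0] == 5.0 and np.isnan(out[1])

    def test_shape_mismatch_and_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            zstar_mix(np.ones((2, 3)), np.ones((2, 4)), [1, 1])
        with pytest.raises(ValueError, match="weight"):
            zstar_mix(np.ones((2, 3)), np.ones((2, 3)), [0, 0])

    @given(
        st.integers(2, 5),
        st.integers(1, 4),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=50, deadline=None)
    def test_convexity_and_weight_scale_invariance(self, n_comp, n_depth, seed):
        r = np.random.default_rng(seed)
        d = r.uniform(0.01, 5, (n_comp, n_depth))
        z = r.uniform(0.1, 40, (n_comp, n_depth))
        w = r.uniform(0.1, 3, n_comp)
        out = zstar_mix(d, z, w)
        assert np.all(out >= z.min(axis=0) - 1e-12)
        assert np.all(out <= z.max(axis=0) + 1e-12)
        assert np.allclose(out, zstar_mix(d, z, 7.3 * w))


# ---------------------------------------------------------------------------
# clinical dose and its inverse


class TestClinicalDose:
    def test_zero_dose_gives_zero(self):
        assert clinical_dose(0.0, 12.0, PARAMS) == 0.0

    def test_perfect_square_identity_symbolically(self):
        """At alpha0 + beta z* = alpha_r the radicand is a perfect square
        and the dose scales by exactly f_clin."""
        import sympy as sp

        a0, b, ar, D = sp.symbols("a0 b ar D", positive=True)
        z = (ar - a0) / b
        radicand = (ar / (2 * b)) ** 2 + (a0 * D + b * z * D + b * D**2) / b
        simplified = sp.simplify(
            -ar / (2 * b) + sp.sqrt(sp.factor(radicand)) - D
        )
        assert simplified == 0

    @pytest.mark.parametrize("d", [0.0, 0.5, 1.0, 2.4, 10.0])
    def test_reference_beam_quality_scales_by_f_clin(self, d):
        assert clinical_dose(d, ZREF, PARAMS) == pytest.approx(
            2.40 * d, rel=1e-13, abs=1e-13
        )

    def test_known_value_from_inversion_oracle(self):
        z = brute_force_zstar(5.8, 2.40)
        assert z == pytest.approx(9.7457, abs=5e-5)
        assert clinical_dose(2.40, z, PARAMS) == pytest.approx(5.800, rel=1e-10)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            clinical_dose(-1.0, 5.0, PARAMS)
        with pytest.raises(ValueError):
            clinical_dose(1.0, -5.0, PARAMS)

    def test_strictly_increasing_in_dose_and_beam_quality(self):
        d = np.linspace(0.05, 20, 200)
        out = clinical_dose(d, 9.0, PARAMS)
        assert np.all(np.diff(out) > 0)
        z = np.linspace(0, 50, 200)
        out = clinical_dose(np.full_like(z, 2.0), z, PARAMS)
        assert np.all(np.diff(out) > 0)


class TestInvertZstar:
    def test_brute_force_example(self):
        assert invert_zstar(5.8, 2.40, PARAMS) == pytest.approx(
            brute_force_zstar(5.8, 2.40), rel=1e-14
        )
        assert invert_zstar(5.8, 2.40, PARAMS) == pytest.approx(9.7457, abs=5e-5)

    @given(
        st.floats(0.01, 20.0),
        st.floats(0.0, 50.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_round_trip_identity(self, d, z):
        d_rbe = clinical_dose(d, z, PARAMS)
        recovered = invert_zstar(d_rbe, d, PARAMS, warn_negative=False)
        assert recovered == pytest.approx(z, rel=1e-10, abs=1e-10)

    def test_f_clin_scaled_dose_recovers_reference_zstar(self):
        for d in (0.3, 2.4, 11.0):
            assert invert_zstar(2.40 * d, d, PARAMS) == pytest.approx(
                ZREF, rel=1e-12
            )

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            invert_zstar(5.8, 0.0, PARAMS)
        with pytest.raises(ValueError):
            invert_zstar(0.0, 2.4, PARAMS)

    def test_inconsistent_pair_warns_and_returns_negative(self):
        with pytest.warns(UserWarning, match="inconsistent"):
            out = invert_zstar(0.1, 5.0, PARAMS)
        assert out < 0


# ---------------------------------------------------------------------------
# RBE utilities


def _profile(d_abs, d_rbe):
    depth = np.arange(len(d_abs), dtype=float) * 0.05
    d_abs = np.asarray(d_abs, dtype=float)
    d_rbe = np.asarray(d_rbe, dtype=float)
    rbe = np.where(d_abs > 0, np.divide(d_rbe, np.where(d_abs > 0, d_abs, 1)),
                   np.nan)
    return DoseProfile(depth, d_abs, np.full_like(d_abs, 9.0), d_rbe, rbe)


class TestRBEProfile:
    def test_table_row_ratio(self):
        prof = _profile([2.39, 2.39], [5.8, 5.8])
        assert rbe_profile(prof)[0] == pytest.approx(5.8 / 2.39, rel=1e-12)
        assert rbe_profile(prof)[0] == pytest.approx(2.4268, abs=5e-5)

    def test_unity_and_undefined(self):
        prof = _profile([1.5, 0.0], [1.5, 0.0])
        out = rbe_profile(prof)
        assert out[0] == 1.0 and np.isnan(out[1])


class TestLowDoseLimit:
    def test_reference_quality_gives_f_clin(self):
        assert low_dose_rbe_limit(ZREF, PARAMS) == pytest.approx(2.40, rel=1e-12)

    def test_zero_zstar(self):
        assert low_dose_rbe_limit(0.0, PARAMS) == pytest.approx(
            2.40 * 0.172 / 0.764, rel=1e-12
        )

    @pytest.mark.parametrize("z", [0.0, 5.0, 9.63, 20.0])
    def test_agrees_with_numerical_limit(self, z):
        ratio = clinical_dose(1e-6, z, PARAMS) / 1e-6
        assert ratio == pytest.approx(low_dose_rbe_limit(z, PARAMS), rel=1e-4)


class TestDoseProfileValidation:
    def test_rbe_zero_dose_consistency_enforced(self):
        depth = np.array([0.0, 0.05])
        with pytest.raises(ValueError, match="d_rbe"):
            DoseProfile(depth, np.array([0.0, 1.0]), np.array([1.0, 1.0]),
                        np.array([1.0, 2.0]), np.array([np.nan, 2.0]))

    def test_nonuniform_grid_rejected(self):
        depth = np.array([0.0, 0.05, 0.2])
        ones = np.ones(3)
        with pytest.raises(ValueError, match="uniform"):
            DoseProfile(depth, ones, ones, ones, ones)
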