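"""SOBP plan construction, layer selection, inverse optimization and
target statistics."""

import numpy as np
import pytest

from mkmdose import (
    SOBPPlan,
    compute_profile,
    optimize_weights,
    select_layers,
    table1_suite,
    target_mean_metrics,
)
from mkmdose.core import DoseProfile
from mkmdose.planning import FieldAssembly, OptimizationError


def target_deviation(profile, plan):
    lo, hi = plan.target_span
    mask = (profile.depth >= lo - 1e-9) & (profile.depth <= hi + 1e-9)
    return (profile.d_rbe[mask] - plan.prescription) / plan.prescription


class TestSOBPPlan:
    def test_name_and_centre_derived(self):
        plan = SOBPPlan(21.1, 6.0, 5.8)
        assert plan.name == "R21.1M6D5.8"
        assert plan.centre_cm == pytest.approx(18.1)

    def test_published_centres_accepted_within_grid_tolerance(self):
        # quoted centres deviate from range - mod/2 by a few hundredths cm
        assert SOBPPlan(21.1, 6.0, 5.8, centre_cm=18.12).centre_cm == 18.12
        assert SOBPPlan(26.5, 6.0, 5.8, centre_cm=23.47).centre_cm == 23.47

    def test_inconsistent_centre_or_name_rejected(self):
        with pytest.raises(ValueError, match="centre"):
            SOBPPlan(21.1, 6.0, 5.8, centre_cm=17.0)
        with pytest.raises(ValueError, match="name"):
            SOBPPlan(21.1, 6.0, 5.8, name="R99M9D9.9")

    def test_prescription_name_formatting(self):
        assert SOBPPlan(21.1, 6.0, 8.0).name == "R21.1M6D8.0"
        assert SOBPPlan(15.2, 12.0, 3.6).name == "R15.2M12D3.6"

    def test_suite_reproduces_published_plan_set(self):
        suite = table1_suite()
        names = {p.name for p in suite}
        assert len(suite) == 7
        assert names == {
            "R15.2M6D5.8", "R21.1M3D5.8", "R21.1M6D5.8", "R21.1M12D5.8",
            "R21.1M6D3.6", "R21.1M6D8.0", "R26.5M6D5.8",
        }


class TestSelectLayers:
    def test_m6_layer_count(self, model):
        idx = select_layers(model, SOBPPlan(21.1, 6.0, 5.8))
        # 21 in-span layers at 0.3 cm pitch plus one proximal guard
        assert len(idx) == 22

    def test_distal_layer_at_plan_range(self, model):
        idx = select_layers(model, SOBPPlan(21.1, 6.0, 5.8))
        assert model.layers[idx[-1]].range_cm == pytest.approx(21.1)

    def test_degenerate_modulation_single_layer_plus_guard(self, model):
        idx = select_layers(model, SOBPPlan(21.1, 0.1, 5.8))
        assert len(idx) == 2  # the edge layer and its proximal guard

    def test_plan_deeper_than_library_rejected(self, model):
        with pytest.raises(ValueError, match="layer"):
            select_layers(model, SOBPPlan(30.0, 6.0, 5.8))


class TestOptimizeWeights:
    def test_representative_plan_flatness(self, suite_results):
        plan, profile = suite_results["R21.1M6D5.8"]
        dev = target_deviation(profile, plan)
        assert np.sqrt(np.mean(dev**2)) <= 0.005
        assert np.abs(dev).max() <= 0.01

    def test_all_suite_plans_reach_tolerance(self, suite_results):
        for name, (plan, profile) in suite_results.items():
            dev = target_deviation(profile, plan)
            assert np.sqrt(np.mean(dev**2)) <= 0.005, name

    def test_deterministic(self, model, ray_params):
        plan = SOBPPlan(15.2, 6.0, 5.8)
        a = optimize_weights(model, plan, ray_params)
        b = optimize_weights(model, plan, ray_params)
        assert np.array_equal(a.layer_weights, b.layer_weights)

    def test_single_point_plan_is_exact_fixed_point(self, model, ray_params):
        # degenerate plan (zero modulation): the prescription at the single
        # target point is exactly achievable by scaling the edge layer
        plan = SOBPPlan(21.1, 0.0, 5.8)
        optimized = optimize_weights(model, plan, ray_params)
        profile = compute_profile(model, optimized, ray_params)
        dev = target_deviation(profile, plan)
        assert np.abs(dev).max() <= 1e-4

    def test_mean_rbe_decreases_with_prescription(self, suite_results):
        _, rbe_lo = suite_results["R21.1M6D3.6"][0], None
        plans = {
            name: target_mean_metrics(prof, plan)
            for name, (plan, prof) in suite_results.items()
        }
        assert plans["R21.1M6D8.0"][2] < plans["R21.1M6D3.6"][2]

    def test_distal_falloff_below_half_prescription(self, suite_results):
        for name, (plan, profile) in suite_results.items():
            beyond = profile.depth >= plan.range_cm + 0.5
            assert (
                profile.d_rbe[beyond][0] < 0.5 * plan.prescription
            ), name

    def test_nonconvergence_carries_residual(self, model, ray_params):
        plan = SOBPPlan(21.1, 6.0, 5.8)
        with pytest.raises(OptimizationError) as err:
            optimize_weights(model, plan, ray_params, tol=1e-9)
        assert err.value.residual is not None and err.value.residual > 1e-9


class TestProfileAlgebra:
    def test_dose_linearity_and_zstar_scale_invariance(self, model, ray_params):
        plan = SOBPPlan(21.1, 6.0, 5.8)
        idx = select_layers(model, plan)
        asm = FieldAssembly.from_layers([model.layers[i] for i in idx])
        w = np.linspace(0.5, 1.5, asm.n_layers)
        assert np.allclose(asm.d_abs(3.0 * w), 3.0 * asm.d_abs(w))
        za, zb = asm.zstar_mix(w), asm.zstar_mix(3.0 * w)
        assert np.allclose(za[np.isfinite(za)], zb[np.isfinite(zb)])

    def test_single_layer_weight_recovers_that_field(self, model, ray_params):
        plan = SOBPPlan(21.1, 6.0, 5.8)
        idx = select_layers(model, plan)
        asm = FieldAssembly.from_layers([model.layers[i] for i in idx])
        w = np.zeros(asm.n_layers)
        w[4] = 2.0
        assert np.allclose(
            asm.d_abs(w), 2.0 * model.layers[idx[4]].total_dose
        )


class TestTargetMeanMetrics:
    def test_flat_profile_constants(self):
        depth = np.arange(0, 25, 0.05)
        d_abs = np.full(depth.size, 2.40)
        d_rbe = np.full(depth.size, 5.8)
        prof = DoseProfile(depth, d_abs, np.full(depth.size, 9.7),
                           d_rbe, d_rbe / d_abs)
        plan = SOBPPlan(21.1, 6.0, 5.8)
        m = target_mean_metrics(prof, plan)
        assert m[0] == pytest.approx(5.8)
        assert m[1] == pytest.approx(2.40)
        assert m[2] == pytest.approx(5.8 / 2.40, rel=1e-12)
        assert m[2] == pytest.approx(2.41667, abs=5e-5)

    def test_published_row_ratio(self):
        assert 5.8 / 2.39 == pytest.approx(2.4268, abs=5e-5)

    def test_empty_target_rejected(self):
        depth = np.arange(0, 1, 0.05)
        ones = np.ones(depth.size)
        prof = DoseProfile(depth, ones, ones, ones, ones)
        with pytest.raises(ValueError, match="span"):
            target_mean_metrics(prof, SOBPPlan(21.1, 6.0, 5.8))

    def test_means_stable_under_grid_refinement(self, suite_results):
        # Riemann-sum convergence: halving the sampling step of the same
        # physical profile leaves the target means essentially unchanged
        plan, profile = suite_results["R21.1M6D5.8"]
        fine_depth = np.arange(
            profile.depth[0], profile.depth[-1] + 1e-9, profile.spacing / 2
        )

        def refine(arr):
            return np.interp(fine_depth, profile.depth, arr)

        fine = DoseProfile(
            fine_depth,
            refine(profile.d_abs),
            refine(np.nan_to_num(profile.zstar_mix)),
            refine(profile.d_rbe),
            refine(np.nan_to_num(profile.rbe)),
        )
        coarse_means = target_mean_metrics(profile, plan)
        fine_means = target_mean_metrics(fine, plan)
        for a, b in zip(coarse_means, fine_means):
            assert abs(a - b) / a < 1e-3
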