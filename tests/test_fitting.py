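"""Objective function, multi-start optimisation and model comparison."""

import numpy as np
import pytest

import duonet as dn
from duonet.fitting import (
    TopologyFit,
    estimate_degradation_rates,
    link_elimination_error_change,
)
from duonet.parameters import ModelParameters
from duonet.topology import RegulatoryTopology


@pytest.fixture(scope="module")
def truth_model(noise_free_data, ground_truth):
    topo, _ = ground_truth
    return TopologyFit(noise_free_data, topo)


class TestDegradationEstimation:
    def test_exact_on_noise_free_data(self, noise_free_data, ground_truth):
        _, params = ground_truth
        k_e, k_g = estimate_degradation_rates(noise_free_data)
        assert k_e == pytest.approx(params.k_e, rel=1e-9)
        assert k_g == pytest.approx(params.k_g, rel=1e-9)

    def test_close_on_noisy_data(self, study_data, ground_truth):
        _, params = ground_truth
        k_e, k_g = estimate_degradation_rates(study_data)
        assert k_e == pytest.approx(params.k_e, rel=0.15)
        assert k_g == pytest.approx(params.k_g, rel=0.15)

    def test_requires_paired_phases(self, noise_free_data):
        depletion_only = [d for d in noise_free_data if d.phase == "depletion"]
        with pytest.raises(ValueError, match="paired"):
            estimate_degradation_rates(depletion_only)


class TestFitError:
    def test_zero_at_generating_parameters(self, truth_model, ground_truth):
        _, params = ground_truth
        assert truth_model.fit_error(params) < 1e-8

    def test_perturbing_a_parameter_strictly_increases_error(self, truth_model, ground_truth):
        _, params = ground_truth
        for j in (2, 3, 4):
            bumped = params.with_fold(j, params.f[j - 1] * 1.5).normalized()
            assert truth_model.fit_error(bumped) > 1e-2

    def test_all_null_error_matches_linear_closed_form(self, ground_truth):
        """For the all-null topology every trajectory has the closed form
        x(t) = x_ss + (x0 - x_ss) exp(-k t); the objective computed through
        the ODE integrator must agree with a direct reimplementation."""
        _, params = ground_truth
        config = dn.GeneratorConfig(noise_cv=0.1, n_replicates=3, seed=21)
        data = dn.generate_study(config)
        null = RegulatoryTopology.from_string("0000")
        model = TopologyFit(data, null, k_e=params.k_e, k_g=params.k_g, sd_floor=0.05)
        results = model.fit(n_starts=1, seed=0)  # no free parameters
        expected = 0.0
        for ds in data:
            for sp, k in (("era", params.k_e), ("gata3", params.k_g)):
                t, lev, sd = ds.series(sp)
                s = dict(zip(("era", "gata3"), ds.condition.synthesis_scales))[sp]
                if ds.phase == "depletion":
                    sim = s + (1.0 - s) * np.exp(-k * t)
                else:
                    x48 = s + (1.0 - s) * np.exp(-k * 48.0)
                    x0 = x48 * np.exp(-k * 15.0)
                    sim = s + (x0 - s) * np.exp(-k * t)
                expected += np.sum(((sim - lev) / np.maximum(sd, 0.05)) ** 2)
        assert results.error == pytest.approx(expected, rel=1e-8)

    def test_integration_failure_gives_finite_penalty(self, truth_model):
        x = truth_model.pack_params(truth_model.build_params(truth_model.lower))
        r = truth_model.residuals(x)
        assert np.all(np.isfinite(r))


class TestMultiStartFit:
    def test_identical_seed_gives_identical_results(self, study_data, ground_truth):
        topo, _ = ground_truth
        a = TopologyFit(study_data, topo).fit(n_starts=8, seed=42)
        b = TopologyFit(study_data, topo).fit(n_starts=8, seed=42)
        assert [r.error for r in a.results] == [r.error for r in b.results]
        assert np.array_equal(a.best.x, b.best.x)

    def test_nested_topology_never_beats_warm_started_superset(self, noise_free_data):
        """A super-model warm-started with the sub-model optimum can only
        match or improve its error (nested-model monotonicity)."""
        sub = TopologyFit(noise_free_data, RegulatoryTopology.from_string("0+-0"))
        sub_res = sub.fit(n_starts=10, seed=6)
        sup = TopologyFit(noise_free_data, RegulatoryTopology.from_string("0+-+"))
        sup_res = sup.fit(n_starts=5, seed=6, extra_starts=[sub_res.params])
        assert sup_res.error <= sub_res.error * (1 + 1e-9)

    def test_pack_build_round_trip(self, truth_model, ground_truth):
        _, params = ground_truth
        rebuilt = truth_model.build_params(truth_model.pack_params(params))
        assert np.allclose(rebuilt.packed(), params.packed(), rtol=1e-12)


def test_plot_fit_smoke(study_data, ground_truth):
    import matplotlib

    matplotlib.use("Agg")
    topo, params = ground_truth
    res = TopologyFit(study_data, topo, k_e=params.k_e, k_g=params.k_g).fit(n_starts=1, seed=0)
    ax = res.plot_fit()
    assert len(ax.lines) > 0
    import matplotlib.pyplot as plt

    plt.close("all")


class TestLinkElimination:
    def test_eliminating_an_already_null_link_changes_nothing(self, study_data, ground_truth):
        topo, params = ground_truth
        model = TopologyFit(study_data, topo, k_e=params.k_e, k_g=params.k_g)
        assert link_elimination_error_change(model, params, 1) == pytest.approx(0.0, abs=1e-9)

    def test_eliminating_a_load_bearing_link_blows_up_the_error(self, study_data, ground_truth):
        topo, params = ground_truth
        model = TopologyFit(study_data, topo, k_e=params.k_e, k_g=params.k_g)
        assert link_elimination_error_change(model, params, 2) > 100.0

    def test_zero_reference_error_raises(self, truth_model, ground_truth):
        _, params = ground_truth
        with pytest.raises(ZeroDivisionError, match="absolute"):
            link_elimination_error_change(truth_model, params, 2)


class TestSignRecovery:
    @pytest.mark.parametrize("true_f4,true_sign", [(3.0, "+"), (0.35, "-")])
    def test_gata3_autoregulation_sign_is_recovered(self, ground_truth, true_f4, true_sign):
        """Refitting the three GATA3-autoregulation variants to moderately
        noisy data generated from a known sign ranks the true sign first."""
        _, params = ground_truth
        truth = params.with_fold(4, true_f4).normalized()
        config = dn.GeneratorConfig(
            topology=truth.topology(atol=1e-12),
            params=truth,
            noise_cv=0.1,
            n_replicates=3,
            seed=31,
        )
        data = dn.generate_study(config)
        errors = {}
        for sign in ("+", "-", "0"):
            topo = RegulatoryTopology.from_string(f"0+-{sign}")
            errors[sign] = TopologyFit(data, topo).fit(n_starts=25, seed=8).error
        assert errors[true_sign] == min(errors.values())
        conflicting = {"+": "-", "-": "+"}[true_sign]
        assert errors[conflicting] > 2.0 * errors[true_sign]
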