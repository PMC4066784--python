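"""LNA noise, Gillespie oracle, controlled link removal, extrinsic noise."""

import numpy as np
import pytest

import duonet as dn
from duonet.conditions import CONTROL
from duonet.noise import (
    StochasticSystem,
    calibrate_omega,
    extrinsic_noise,
    gillespie,
    lna_noise,
    remove_link_controlled,
)
from duonet.parameters import ModelParameters


def _all_null(b_e=0.2, b_g=0.3, k_e=0.1, k_g=0.15):
    return ModelParameters(b_e, b_g, k_e, k_g)


@pytest.fixture(scope="module")
def truth_system(ground_truth):
    topo, params = ground_truth
    return StochasticSystem(params, topo, omega=500.0)


class TestLNA:
    def test_all_null_topology_is_exactly_poisson(self):
        """Independent birth-death species are Poisson at stationarity, so
        cv^2 = 1/(omega * mean) must hold to machine precision."""
        system = StochasticSystem(_all_null(), omega=200.0)
        ns = lna_noise(system)
        assert ns.mean_e == pytest.approx(2.0, abs=1e-10)
        assert ns.cv_e**2 * 200.0 * ns.mean_e == pytest.approx(1.0, rel=1e-12)
        assert ns.cv_g**2 * 200.0 * ns.mean_g == pytest.approx(1.0, rel=1e-12)
        assert ns.covariance[0, 1] == pytest.approx(0.0, abs=1e-15)

    def test_covariance_symmetric_positive_semidefinite(self, truth_system):
        ns = lna_noise(truth_system)
        C = ns.covariance
        assert np.allclose(C, C.T)
        assert np.all(np.linalg.eigvalsh(C) >= -1e-15)

    def test_cv_scales_as_inverse_sqrt_omega(self, truth_system):
        a = lna_noise(truth_system.with_omega(100.0))
        b = lna_noise(truth_system.with_omega(400.0))
        assert a.cv_e / b.cv_e == pytest.approx(2.0, rel=1e-9)
        assert a.cv_g / b.cv_g == pytest.approx(2.0, rel=1e-9)

    def test_multistable_system_rejected(self):
        bistable = ModelParameters(
            1, 1, 0.2, 0.2,
            f=np.array([1.0, 10.0, 10.0, 1.0]),
            K=np.array([1.0, 0.5, 0.5, 1.0]),
            n=np.array([1.0, 4.0, 4.0, 1.0]),
        ).normalized()
        with pytest.raises(RuntimeError, match="unique stable"):
            lna_noise(StochasticSystem(bistable, omega=500.0))


class TestGillespie:
    def test_identical_seed_identical_trajectory(self, truth_system):
        a = gillespie(truth_system, t_end=50.0, seed=7)
        b = gillespie(truth_system, t_end=50.0, seed=7)
        assert np.array_equal(a.counts, b.counts)
        c = gillespie(truth_system, t_end=50.0, seed=8)
        assert not np.array_equal(a.counts, c.counts)

    def test_all_null_counts_are_poisson(self):
        # omega * b_e / k_e = 100 molecules on average
        system = StochasticSystem(_all_null(b_e=0.2, k_e=0.2, b_g=0.2, k_g=0.2), omega=100.0)
        res = gillespie(system, t_end=3000.0, seed=3)
        x = res.stationary[:, 0]
        assert x.mean() == pytest.approx(100.0, abs=3.0)
        assert x.var(ddof=1) == pytest.approx(100.0, rel=0.15)

    def test_near_pure_death_decays_exponentially(self):
        """With negligible synthesis the count decays as N0 exp(-k t)."""
        params = ModelParameters(1e-8, 1e-8, 0.2, 0.2)
        system = StochasticSystem(params, omega=400.0)
        means = []
        for seed in range(8):
            res = gillespie(system, t_end=5.0, seed=seed, sample_dt=5.0, initial_state=(2.0, 2.0))
            means.append(res.counts[-1, 0])
        expected = 800.0 * np.exp(-0.2 * 5.0)
        sd = np.sqrt(800.0 * np.exp(-1.0) * (1 - np.exp(-1.0)) / 8)
        assert np.mean(means) == pytest.approx(expected, abs=4 * sd)

    def test_agrees_with_lna_on_the_consensus_system(self, truth_system):
        est = gillespie(truth_system, t_end=4000.0, seed=11).cv_estimates()
        lna = lna_noise(truth_system)
        assert abs(est["cv_e"] - lna.cv_e) < 3 * est["se_cv_e"]
        assert abs(est["cv_g"] - lna.cv_g) < 3 * est["se_cv_g"]


class TestControlledRemoval:
    def test_removing_a_null_link_is_identity(self, ground_truth):
        _, params = ground_truth
        system = StochasticSystem(params, omega=500.0)
        removed = remove_link_controlled(system, 1)
        assert np.allclose(removed.params.packed(), params.packed(), rtol=1e-12)

    @pytest.mark.parametrize("j", [2, 3])
    def test_means_are_preserved(self, truth_system, j):
        removed = remove_link_controlled(truth_system, j)
        fp = dn.stable_steady_state(removed.params)
        assert np.allclose(fp, [1.0, 1.0], atol=1e-6)

    def test_breaking_the_feedback_raises_noise(self, truth_system):
        """Cutting the GATA3→ERα arm leaves GATA3 noise undamped (its
        positive autoregulation amplifies intrinsic fluctuations that the
        loop normally buffers) while ERα stops inheriting GATA3 noise."""
        wt = lna_noise(truth_system)
        removed = lna_noise(remove_link_controlled(truth_system, 2))
        assert removed.cv_g > wt.cv_g * 1.1
        assert removed.cv_e < wt.cv_e


class TestExtrinsicNoise:
    def test_single_varying_rate_propagates_exactly(self):
        """All-null topology with only b_e varying: steady-state e is
        b_e/k_e, so the ensemble CV equals the parameter CV."""
        system = StochasticSystem(_all_null(), omega=500.0)
        ns = extrinsic_noise(system, parameter_cv=0.1, n_samples=600, seed=2, vary=("b_e",))
        assert ns.cv_e == pytest.approx(0.1, abs=0.015)
        assert ns.cv_g == pytest.approx(0.0, abs=1e-12)

    def test_small_parameter_cv_limit(self, truth_system):
        ns = extrinsic_noise(truth_system, parameter_cv=0.01, n_samples=200, seed=2)
        assert ns.cv_e < 0.03 and ns.cv_g < 0.03

    def test_feedback_removal_raises_extrinsic_noise_of_the_affected_species(self, truth_system):
        removed = remove_link_controlled(truth_system, 2)
        wt = extrinsic_noise(truth_system, parameter_cv=0.1, n_samples=400, seed=5)
        cut = extrinsic_noise(removed, parameter_cv=0.1, n_samples=400, seed=5)
        assert cut.cv_g > wt.cv_g

    def test_parameter_cv_bounds_enforced(self, truth_system):
        with pytest.raises(ValueError):
            extrinsic_noise(truth_system, parameter_cv=0.9)
        with pytest.raises(ValueError):
            extrinsic_noise(truth_system, parameter_cv=0.1, n_samples=10)


class TestCalibrateOmega:
    def test_poisson_inversion_for_null_topology(self):
        system = StochasticSystem(_all_null(0.2, 0.2, 0.2, 0.2), omega=123.0)  # means (1, 1)
        target = 0.08
        omega = calibrate_omega(system, (target, target))
        assert omega == pytest.approx(1.0 / (target**2 * 1.0), rel=1e-9)

    def test_doubling_targets_quarters_omega(self):
        system = StochasticSystem(_all_null(0.2, 0.2, 0.2, 0.2), omega=1.0)
        w1 = calibrate_omega(system, (0.05, 0.05))
        w2 = calibrate_omega(system, (0.1, 0.1))
        assert w1 / w2 == pytest.approx(4.0, rel=1e-9)

    def test_round_trip_reproduces_consistent_targets(self, truth_system):
        base = lna_noise(truth_system.with_omega(1.0))
        scale = 1.0 / np.sqrt(300.0)
        targets = (base.cv_e * scale, base.cv_g * scale)
        omega = calibrate_omega(truth_system, targets)
        assert omega == pytest.approx(300.0, rel=1e-9)
        ns = lna_noise(truth_system.with_omega(omega))
        assert ns.cv_e == pytest.approx(targets[0], rel=1e-9)
        assert ns.cv_g == pytest.approx(targets[1], rel=1e-9)

    def test_inconsistent_targets_warn(self, truth_system):
        with pytest.warns(RuntimeWarning, match="mismatch"):
            calibrate_omega(truth_system, (0.5, 0.001))
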