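"""Hill regulation, ODE integration and steady-state analysis."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import duonet as dn
from duonet.conditions import CONTROL, ExperimentalCondition
from duonet.model import (
    derivatives,
    hill_fold,
    log_gain,
    simulate,
    stable_steady_state,
    steady_states,
)
from duonet.parameters import ModelParameters

folds = st.one_of(st.floats(0.02, 0.999), st.floats(1.001, 50.0))
halfsats = st.floats(0.05, 20.0)
coops = st.floats(1.0, 4.0)
rates = st.floats(np.log(2) / 24, np.log(2) / 0.5)


def _all_null(b_e=0.2, b_g=0.3, k_e=0.1, k_g=0.15):
    return ModelParameters(b_e, b_g, k_e, k_g)


class TestHillFold:
    @pytest.mark.parametrize(
        "x,f,K,n,expected",
        [
            (0.0, 5.0, 0.3, 2.0, 1.0),  # no regulator -> basal fold 1
            (0.5, 3.0, 0.5, 2.0, 2.0),  # half-saturation -> (1+f)/2
            (7.3, 1.0, 0.9, 3.0, 1.0),  # null regulation is constant
            (2.0, 0.2, 1.0, 1.0, (1 + 0.4) / 3.0),
        ],
    )
    def test_reference_values(self, x, f, K, n, expected):
        assert hill_fold(x, f, K, n) == pytest.approx(expected, rel=1e-12)

    @given(f=folds, K=halfsats, n=coops, x=st.floats(1e-3, 50.0))
    def test_bounded_between_one_and_fold(self, f, K, n, x):
        value = hill_fold(x, f, K, n)
        assert min(1.0, f) < value < max(1.0, f)

    @given(f=folds, K=halfsats, n=coops, x=st.floats(1e-3, 20.0), dx=st.floats(1e-3, 5.0))
    def test_monotone_with_the_sign_of_f_minus_one(self, f, K, n, x, dx):
        lo, hi = hill_fold(x, f, K, n), hill_fold(x + dx, f, K, n)
        if f > 1:
            assert hi > lo
        else:
            assert hi < lo

    def test_saturates_to_fold(self):
        assert hill_fold(1e9, 7.0, 0.5, 2.0) == pytest.approx(7.0, rel=1e-6)

    @pytest.mark.parametrize("bad", [dict(f=-1.0), dict(K=0.0), dict(f=np.nan), dict(n=0.5)])
    def test_invalid_parameters_rejected(self, bad):
        kwargs = dict(x=1.0, f=2.0, K=1.0, n=2.0)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            hill_fold(**kwargs)


class TestLogGain:
    def test_null_regulation_has_zero_gain(self):
        for x in (0.1, 1.0, 5.0):
            assert log_gain(1.0, 0.7, 3.0, x) == 0.0

    def test_half_saturation_reference_value(self):
        # x = K, f = 3, n = 2: n*u*(f-1)/((1+u)(1+f*u)) = 2*1*2/(2*4) = 0.5
        assert log_gain(3.0, 0.5, 2.0, 0.5) == pytest.approx(0.5, rel=1e-12)

    @given(f=folds, K=halfsats, n=coops, x=st.floats(0.05, 10.0))
    def test_matches_finite_difference_of_log_hill(self, f, K, n, x):
        h = 1e-6
        fd = (
            np.log(hill_fold(x * np.exp(h), f, K, n)) - np.log(hill_fold(x * np.exp(-h), f, K, n))
        ) / (2 * h)
        assert log_gain(f, K, n, x) == pytest.approx(fd, abs=1e-6)

    @given(f=st.floats(0.02, 0.999), K=halfsats, n=coops, x=st.floats(0.05, 10.0))
    def test_repression_gain_is_negative(self, f, K, n, x):
        assert log_gain(f, K, n, x) < 0


class TestDerivatives:
    def test_vanishes_at_normalized_wild_type(self, ground_truth):
        _, params = ground_truth
        de, dg = derivatives((1.0, 1.0), params, CONTROL)
        assert abs(de) < 1e-10 and abs(dg) < 1e-10

    @given(
        b_e=st.floats(0.01, 2), b_g=st.floats(0.01, 2), k_e=rates, k_g=rates,
        e=st.floats(0, 5), g=st.floats(0, 5),
    )
    def test_all_null_topology_is_linear_birth_death(self, b_e, b_g, k_e, k_g, e, g):
        de, dg = derivatives((e, g), _all_null(b_e, b_g, k_e, k_g), CONTROL)
        assert de == pytest.approx(b_e - k_e * e, rel=1e-12, abs=1e-12)
        assert dg == pytest.approx(b_g - k_g * g, rel=1e-12, abs=1e-12)

    def test_cycloheximide_window_shuts_synthesis_off(self, ground_truth):
        _, params = ground_truth
        condition = ExperimentalCondition(chx_window=(0.0, 15.0))
        de, dg = derivatives((0.8, 1.1), params, condition, t=5.0)
        assert de == pytest.approx(-params.k_e * 0.8, rel=1e-12)
        assert dg == pytest.approx(-params.k_g * 1.1, rel=1e-12)
        # outside the window synthesis resumes
        de2, _ = derivatives((0.8, 1.1), params, condition, t=16.0)
        assert de2 > de

    def test_unknown_sirna_target_rejected(self):
        with pytest.raises(ValueError, match="unknown siRNA target"):
            ExperimentalCondition(sirna_target="foxa1")


class TestNormalizeToWT:
    def test_all_null_basal_equals_degradation(self):
        p = ModelParameters(5.0, 5.0, 0.2, 0.3).normalized()
        assert p.b_e == pytest.approx(0.2) and p.b_g == pytest.approx(0.3)

    def test_half_saturated_activation_reference(self):
        p = ModelParameters(1, 1, 0.1, 0.1, f=np.array([1, 4, 1, 1.0])).normalized()
        # F2(1) with f=4, K=1, n=1 is (1+4)/2, so b_e = 0.1 / 2.5
        assert p.b_e == pytest.approx(0.04, rel=1e-12)

    def test_idempotent(self, ground_truth):
        _, params = ground_truth
        again = params.normalized()
        assert np.allclose(again.packed(), params.packed(), rtol=0, atol=0)

    @given(
        f2=folds, f3=folds, f4=st.floats(0.02, 0.999), K2=halfsats, K3=halfsats,
        n2=coops, n3=coops, k_e=rates, k_g=rates,
    )
    def test_wild_type_is_exact_fixed_point(self, f2, f3, f4, K2, K3, n2, n3, k_e, k_g):
        p = ModelParameters(
            1, 1, k_e, k_g,
            f=np.array([1.0, f2, f3, f4]),
            K=np.array([1.0, K2, K3, 1.0]),
            n=np.array([1.0, n2, n3, 1.0]),
        ).normalized()
        de, dg = derivatives((1.0, 1.0), p, CONTROL)
        assert abs(de) < 1e-10 and abs(dg) < 1e-10


class TestSimulate:
    def test_pure_decay_matches_closed_form(self):
        p = _all_null()
        condition = ExperimentalCondition(chx_window=(0.0, 50.0))
        t = np.linspace(0.0, 40.0, 30)[1:]
        traj = simulate(p, condition=condition, t_grid=t, initial_state=(0.9, 1.4))
        assert np.allclose(traj.e, 0.9 * np.exp(-p.k_e * t), rtol=1e-6)
        assert np.allclose(traj.g, 1.4 * np.exp(-p.k_g * t), rtol=1e-6)

    def test_all_null_saturation_matches_closed_form(self):
        p = _all_null()
        t = np.linspace(0.0, 60.0, 25)[1:]
        traj = simulate(p, t_grid=t, initial_state=(0.0, 0.0))
        expected_e = p.b_e / p.k_e * (1 - np.exp(-p.k_e * t))
        expected_g = p.b_g / p.k_g * (1 - np.exp(-p.k_g * t))
        assert np.allclose(traj.e, expected_e, rtol=1e-6)
        assert np.allclose(traj.g, expected_g, rtol=1e-6)

    def test_agrees_with_scipy_lsoda(self, ground_truth):
        _, params = ground_truth
        t = np.linspace(0.0, 48.0, 20)[1:]
        for condition in (dn.GATA3_KNOCKDOWN, dn.ERA_KNOCKDOWN):
            a = simulate(params, condition=condition, t_grid=t, method="dopri")
            b = simulate(params, condition=condition, t_grid=t, method="lsoda", rtol=1e-10)
            assert np.allclose(a.e, b.e, rtol=1e-6, atol=1e-9)
            assert np.allclose(a.g, b.g, rtol=1e-6, atol=1e-9)

    def test_continuous_across_chx_window(self, ground_truth):
        _, params = ground_truth
        condition = ExperimentalCondition(sirna_target="gata3", chx_window=(10.0, 20.0))
        t = np.linspace(0.1, 40.0, 400)
        traj = simulate(params, condition=condition, t_grid=t)
        jumps = np.abs(np.diff(traj.e))
        assert jumps.max() < 0.05  # no discontinuity at the window edges

    def test_long_horizon_reaches_steady_state(self, ground_truth):
        _, params = ground_truth
        traj = simulate(params, condition=dn.GATA3_KNOCKDOWN, t_grid=[500.0], initial_state=(3.0, 2.0))
        fp = stable_steady_state(params, dn.GATA3_KNOCKDOWN)
        assert np.allclose([traj.e[-1], traj.g[-1]], fp, atol=1e-7)

    @given(
        f2=folds, f3=folds, K2=halfsats, K3=halfsats, n2=coops, n3=coops,
        e0=st.floats(0, 3), g0=st.floats(0, 3),
    )
    @settings(max_examples=15)
    def test_non_negativity(self, f2, f3, K2, K3, n2, n3, e0, g0):
        p = ModelParameters(
            1, 1, 0.2, 0.1,
            f=np.array([1.0, f2, f3, 1.0]),
            K=np.array([1.0, K2, K3, 1.0]),
            n=np.array([1.0, n2, n3, 1.0]),
        ).normalized()
        traj = simulate(p, condition=dn.ERA_KNOCKDOWN, t_grid=np.linspace(0.5, 80, 40), initial_state=(e0, g0))
        assert np.all(traj.e >= 0) and np.all(traj.g >= 0)

    def test_unsorted_grid_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            simulate(_all_null(), t_grid=[1.0, 0.5])


def _nullcline_roots(params, condition=CONTROL, n_grid=400, box=6.0):
    """Independent fixed-point oracle for systems without GATA3 autoregulation.

    With f4 = 1 the g-nullcline is explicit, g(e) = s_g b_g F3(e) / k_g, so
    fixed points are sign changes of the 1-D residual of the e-equation on
    a dense grid, refined by bisection.
    """
    from scipy.optimize import brentq

    s_e, s_g = condition.synthesis_scales

    def g_of_e(e):
        return s_g * params.b_g * hill_fold(e, params.f[2], params.K[2], params.n[2]) / params.k_g

    def resid(e):
        g = g_of_e(e)
        return (
            s_e
            * params.b_e
            * hill_fold(e, params.f[0], params.K[0], params.n[0])
            * hill_fold(g, params.f[1], params.K[1], params.n[1])
            - params.k_e * e
        )

    grid = np.linspace(0.0, box, n_grid)
    values = np.array([resid(e) for e in grid])
    roots = []
    for a, b, fa, fb in zip(grid[:-1], grid[1:], values[:-1], values[1:]):
        if fa == 0.0:
            roots.append(a)
        elif fa * fb < 0:
            e = brentq(resid, a, b, xtol=1e-12)
            roots.append(e)
    return [(e, g_of_e(e)) for e in roots]


class TestSteadyStates:
    def test_all_null_unique_stable_point(self):
        p = _all_null()
        fps = steady_states(p)
        assert len(fps) == 1
        fp, stable = fps[0]
        assert stable
        assert np.allclose(fp, [p.b_e / p.k_e, p.b_g / p.k_g], atol=1e-9)

    def test_strong_mutual_activation_is_bistable(self):
        p = ModelParameters(
            1, 1, 0.2, 0.2,
            f=np.array([1.0, 10.0, 10.0, 1.0]),
            K=np.array([1.0, 0.5, 0.5, 1.0]),
            n=np.array([1.0, 4.0, 4.0, 1.0]),
        ).normalized()
        fps = steady_states(p)
        oracle = _nullcline_roots(p)
        assert len(fps) == len(oracle) == 3
        for (fp, _), (eo, go) in zip(fps, oracle):
            assert np.allclose(fp, [eo, go], atol=1e-6)
        stabilities = [s for _, s in fps]
        assert stabilities == [True, False, True]  # low state, saddle, wild type

    def test_consensus_network_is_monostable(self, ground_truth):
        _, params = ground_truth
        for condition in (CONTROL, dn.ERA_KNOCKDOWN, dn.GATA3_KNOCKDOWN):
            fps = steady_states(params, condition=condition)
            assert sum(stable for _, stable in fps) == 1

    @given(
        f1=folds, f2=folds, f3=folds,
        K1=st.floats(0.2, 5.0), K2=st.floats(0.2, 5.0), K3=st.floats(0.2, 5.0),
        n1=coops, n2=coops, n3=coops,
    )
    @settings(max_examples=20)
    def test_matches_nullcline_oracle_without_gata3_autoregulation(
        self, f1, f2, f3, K1, K2, K3, n1, n2, n3
    ):
        p = ModelParameters(
            1, 1, 0.2, 0.1,
            f=np.array([f1, f2, f3, 1.0]),
            K=np.array([K1, K2, K3, 1.0]),
            n=np.array([n1, n2, n3, 1.0]),
        ).normalized()
        found = steady_states(p, box_hi=6.0)
        oracle = _nullcline_roots(p)
        assert len(found) == len(oracle)
        for (fp, _), (eo, go) in zip(found, sorted(oracle)):
            assert np.allclose(fp, [eo, go], atol=1e-5)
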