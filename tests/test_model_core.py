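"""Wilson-Cowan core: rate function, flow field, fixed points, barrier, noise."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import fsolve

from catabarrier.errors import RegimeError
from catabarrier.model_core import (
    ModelParams,
    NoiseSpec,
    RateState,
    compute_barrier,
    derivatives,
    find_fixed_points,
    jacobian,
    load_params,
    minimal_escape_perturbation,
    save_params,
    simulate,
    spike_rate,
    x0_nullcline,
)


class TestSpikeRate:
    @pytest.mark.parametrize(
        "x,mu,theta,expected",
        [
            (2.8, 1.2, 2.8, 0.5),  # midpoint at threshold
            (4.0, 1.0, 4.0, 0.5),
            (0.0, 1.2, 2.8, 1.0 / (1.0 + np.exp(3.36))),
        ],
    )
    def test_values(self, x, mu, theta, expected):
        assert spike_rate(x, mu, theta) == pytest.approx(expected, rel=1e-12)

    @given(st.floats(-10, 10), st.floats(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing(self, a, b):
        lo, hi = sorted((a, b))
        if hi - lo > 1e-9:
            assert spike_rate(hi, 1.2, 2.8) > spike_rate(lo, 1.2, 2.8)

    def test_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            spike_rate(1.0, 0.0, 2.8)


class TestDerivatives:
    def test_zero_at_fixed_points(self, baseline):
        for fp in find_fixed_points(baseline):
            d0, d1 = derivatives(fp.state, baseline)
            assert abs(d0) < 1e-10 and abs(d1) < 1e-10

    def test_origin_is_quiescent(self, baseline):
        # the rest-normalized rate function makes (0, 0) an exact rest state
        d0, d1 = derivatives((0.0, 0.0), baseline)
        assert d0 == pytest.approx(0.0, abs=1e-14)
        assert d1 == pytest.approx(0.0, abs=1e-14)

    def test_jacobian_matches_finite_differences(self, baseline):
        rng = np.random.default_rng(0)
        eps = 1e-6
        for _ in range(20):
            x = rng.uniform(0.05, 0.95, size=2)
            J = jacobian(x, baseline)
            for j in range(2):
                xp, xm = x.copy(), x.copy()
                xp[j] += eps
                xm[j] -= eps
                fd = (np.array(derivatives(xp, baseline))
                      - np.array(derivatives(xm, baseline))) / (2 * eps)
                assert np.allclose(J[:, j], fd, atol=1e-5)


class TestFixedPoints:
    def test_baseline_is_bistable(self, baseline):
        fps = find_fixed_points(baseline)
        assert len(fps) == 3
        kinds = [f.kind for f in fps]
        assert kinds == ["stable_low", "saddle", "stable_high"]

    def test_baseline_geometry(self, baseline):
        low, saddle, high = find_fixed_points(baseline)
        assert low.state.x1 < 0.1
        assert 0.3 < saddle.state.x1 < 0.55
        assert 0.8 < high.state.x1 < 0.95

    def test_classification_consistent_with_eigenvalues(self, baseline):
        for fp in find_fixed_points(baseline):
            re = np.real(fp.eigenvalues)
            if fp.kind.startswith("stable"):
                assert np.all(re < 0)
            else:
                assert re[0] * re[1] < 0

    def test_agrees_with_multistart_fsolve_oracle(self, baseline):
        # independent root search from a coarse grid of starting points
        found = []
        for a in np.linspace(0, 1, 15):
            for b in np.linspace(0, 1, 15):
                s, _, ier, _ = fsolve(
                    lambda v: derivatives(v, baseline), [a, b], full_output=True
                )
                if ier == 1 and -0.05 <= s[0] <= 1.05 and -0.05 <= s[1] <= 1.05:
                    if not any(np.allclose(s, f, atol=1e-4) for f in found):
                        found.append(s)
        ours = [f.state for f in find_fixed_points(baseline)]
        assert len(found) == len(ours) == 3
        for f in found:
            assert any(np.allclose(f, o, atol=1e-6) for o in ours)

    def test_regime_error_when_not_bistable(self, baseline):
        mono = baseline.replace(w01=baseline.w01 * 2.0)
        with pytest.raises(RegimeError):
            find_fixed_points(mono, require_bistable=True)


class TestNullcline:
    def test_residuals_below_tolerance(self, baseline):
        xs = np.linspace(0, 1, 200)
        x0 = x0_nullcline(baseline, xs)
        from catabarrier.model_core import _S

        res = -x0 + _S(baseline.w01 * xs - baseline.w00 * x0,
                       baseline.mu0, baseline.theta0)
        assert np.max(np.abs(res)) < 1e-8

    def test_passes_through_fixed_points(self, baseline):
        for fp in find_fixed_points(baseline):
            assert x0_nullcline(baseline, fp.state.x1) == pytest.approx(
                fp.state.x0, abs=1e-7
            )

    def test_monotone_in_x1(self, baseline):
        xs = np.linspace(0, 1, 500)
        x0 = x0_nullcline(baseline, xs)
        assert np.all(np.diff(x0) >= -1e-10)


class TestBarrier:
    def test_positive_at_baseline(self, baseline_barrier):
        assert baseline_barrier.B > 0

    def test_lattice_contract(self, baseline, baseline_barrier):
        lat = baseline_barrier.lattice
        assert len(lat) == 100
        low, saddle, high = baseline_barrier.fixed_points
        assert lat[0].x1 == pytest.approx(high.state.x1, abs=1e-9)
        assert lat[-1].x1 == pytest.approx(saddle.state.x1, abs=1e-9)

    def test_refinement_convergence(self, baseline, baseline_barrier):
        fine = compute_barrier(baseline, n_lattice=10000)
        assert abs(baseline_barrier.B - fine.B) / fine.B < 0.02

    def test_raw_sum_equals_scaled_B_at_default_lattice(self, baseline_barrier):
        assert baseline_barrier.B == pytest.approx(baseline_barrier.raw_sum)

    def test_inhibitory_weight_increase_lowers_barrier(self, baseline, baseline_barrier):
        up = baseline.replace(w00=baseline.w00 * 1.1, w01=baseline.w01 * 1.1)
        assert compute_barrier(up).B < baseline_barrier.B

    def test_barrier_ranks_escape_difficulty(self, baseline):
        # barrier must order parameter sets like the minimal noiseless kick
        # that escapes the high-rate basin (independent bisection measure)
        from scipy.stats import spearmanr

        Bs, kicks = [], []
        for f00 in (0.95, 1.0, 1.05):
            for f01 in (0.97, 1.0, 1.03):
                q = baseline.replace(w00=baseline.w00 * f00,
                                     w01=baseline.w01 * f01)
                Bs.append(compute_barrier(q).B)
                kicks.append(minimal_escape_perturbation(q))
        assert spearmanr(Bs, kicks).statistic >= 0.9


class TestSimulate:
    def test_noiseless_stability_at_high_state(self, baseline, baseline_barrier):
        high = baseline_barrier.fixed_points[2].state
        tr = simulate(baseline, high, NoiseSpec(std=0.0, seed=0), t_max=200, dt=0.1)
        assert np.abs(tr.states - np.array(high)).max() < 1e-3

    def test_deterministic_for_fixed_seed(self, baseline):
        a = simulate(baseline, RateState(0.6, 0.9), NoiseSpec(seed=42), t_max=50)
        b = simulate(baseline, RateState(0.6, 0.9), NoiseSpec(seed=42), t_max=50)
        assert np.array_equal(a.states, b.states)

    def test_noise_drives_transition_to_low_state(self, baseline):
        n_hit = 0
        for seed in range(20):
            tr = simulate(baseline, RateState(0.6, 0.9),
                          NoiseSpec(std=0.19, seed=seed), t_max=2000, dt=0.1)
            n_hit += tr.transition_time is not None
        assert n_hit >= 19

    def test_lower_barrier_shortens_dwell_time(self, baseline):
        # benzodiazepine-like transform reduces B by ~30%; at moderate noise
        # the median dwell time in the high-rate state must drop
        low_b = baseline.replace(w00=baseline.w00 * 1.06, w01=baseline.w01 * 1.06)
        assert compute_barrier(low_b).B < 0.8 * compute_barrier(baseline).B
        t_base, t_low = [], []
        for seed in range(40):
            for p, acc in ((baseline, t_base), (low_b, t_low)):
                tr = simulate(p, RateState(0.6, 0.9),
                              NoiseSpec(std=0.06, seed=seed), t_max=1000, dt=0.1)
                acc.append(tr.transition_time
                           if tr.transition_time is not None else 1000.0)
        assert np.median(t_low) < np.median(t_base)

    def test_states_stay_in_unit_box(self, baseline):
        tr = simulate(baseline, RateState(0.5, 0.5),
                      NoiseSpec(std=0.5, seed=3), t_max=50)
        assert tr.states.min() >= 0.0 and tr.states.max() <= 1.0


def test_params_roundtrip(tmp_path, baseline):
    for name in ("p.yaml", "p.json"):
        path = tmp_path / name
        save_params(baseline, path)
        assert load_params(path) == baseline


def test_params_validation():
    with pytest.raises(ValueError):
        ModelParams(w00=-1.0)
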