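"""Wiener first-passage density, choice probability, ML fitting and the
v-ratio decision + confidence model."""

import numpy as np
import pytest
from scipy.integrate import quad

from bodymeta import (DDMObserverParams, DDMParams, DriftDiffusionModel,
                      HierarchicalDDMModel, MCMCConfig, VRatioModel,
                      choice_probability, fit_vratio, simulate_ddm_dataset,
                      simulate_ddm_trials, wiener_fpt_density)
from bodymeta.sdt import EstimationError


def _params(v=1.0, a=2.0, w=0.5, t0=0.3):
    return DDMParams(v={1: v}, a=a, w=w, t0=t0)


class TestDensity:
    def test_zero_before_nondecision_time(self):
        p = _params(t0=0.3)
        assert wiener_fpt_density(0.29, "upper", p) == 0.0
        assert wiener_fpt_density(0.3, "lower", p) == 0.0

    @pytest.mark.parametrize("v,a,w", [(1.0, 2.0, 0.5), (-0.6, 1.2, 0.3),
                                       (0.0, 1.5, 0.6), (2.5, 0.8, 0.5)])
    def test_integrates_to_choice_probability(self, v, a, w):
        p = _params(v=v, a=a, w=w, t0=0.0)
        up, _ = quad(lambda t: wiener_fpt_density(t, "upper", p), 0, 80,
                     limit=300)
        lo, _ = quad(lambda t: wiener_fpt_density(t, "lower", p), 0, 80,
                     limit=300)
        assert up == pytest.approx(choice_probability(p), abs=1e-4)
        assert up + lo == pytest.approx(1.0, abs=1e-4)

    def test_nonnegative_everywhere(self, rng):
        t = np.linspace(1e-4, 8, 300)
        for _ in range(10):
            p = _params(v=float(rng.uniform(-3, 3)),
                        a=float(rng.uniform(0.5, 3)),
                        w=float(rng.uniform(0.1, 0.9)), t0=0.0)
            assert (wiener_fpt_density(t, "upper", p) >= 0).all()
            assert (wiener_fpt_density(t, "lower", p) >= 0).all()

    def test_boundary_symmetry(self):
        t = np.linspace(0.31, 6, 50)
        pa = _params(v=0.8, a=1.5, w=0.35, t0=0.3)
        pb = _params(v=-0.8, a=1.5, w=0.65, t0=0.3)
        np.testing.assert_allclose(wiener_fpt_density(t, "upper", pa),
                                   wiener_fpt_density(t, "lower", pb),
                                   atol=1e-12)

    def test_matches_euler_simulation_histogram(self):
        p = _params(v=1.0, a=2.0, w=0.5, t0=0.3)
        obs = DDMObserverParams(drift_by_condition={(52, 15): 1.0},
                                boundary=2.0, start_point=0.5,
                                nondecision_t0=0.3)
        tr = simulate_ddm_trials(obs, 100_000, seed=42)
        right = tr.sync_side == "right"
        n = int(right.sum())
        frac = float(((tr.response_side == "right") & right).sum() / n)
        pc = choice_probability(p)
        assert abs(frac - pc) < 3 * np.sqrt(pc * (1 - pc) / n)
        rt = tr[right & (tr.response_side == "right")].rt_decision_s.to_numpy()
        edges = np.arange(0.3, 4.0, 0.1)
        hist, _ = np.histogram(rt, bins=edges)
        probs = np.array([quad(lambda t: wiener_fpt_density(t, "upper", p),
                               lo, hi)[0] for lo, hi in zip(edges, edges[1:])])
        expected = probs * n
        z = (hist - expected) / np.sqrt(np.maximum(expected * (1 - probs), 1))
        assert np.abs(z).max() < 5.0  # binwise Monte-Carlo agreement


class TestChoiceProbability:
    def test_symmetric_limits(self):
        assert choice_probability(_params(v=0.0, w=0.5)) == 0.5
        assert choice_probability(_params(v=50.0)) == pytest.approx(1.0, abs=1e-9)
        assert choice_probability(_params(v=-50.0)) == pytest.approx(0.0, abs=1e-9)

    def test_start_point_bias_at_zero_drift(self):
        assert choice_probability(_params(v=0.0, w=0.7)) == pytest.approx(0.7)


class TestMLFit:
    def test_parameter_recovery_bias_under_ten_percent(self):
        obs = DDMObserverParams(drift_by_condition={(88, 15): 1.2},
                                boundary=1.8, start_point=0.5,
                                nondecision_t0=0.35)
        tr = simulate_ddm_trials(obs, 1_000, seed=77)
        fit = DriftDiffusionModel(tr).fit()
        assert fit.params.v[88] == pytest.approx(1.2, rel=0.10)
        assert fit.params.a == pytest.approx(1.8, rel=0.10)
        assert fit.params.t0 == pytest.approx(0.35, rel=0.10)

    def test_degenerate_rts_rejected(self, ddm_trials_single):
        tr = ddm_trials_single.copy()
        tr["rt_decision_s"] = 1.0
        with pytest.raises(EstimationError):
            DriftDiffusionModel(tr)

    def test_single_choice_outcome_rejected(self, ddm_trials_single):
        tr = ddm_trials_single.copy()
        tr["response_side"] = "right"
        with pytest.raises(EstimationError):
            DriftDiffusionModel(tr)


class TestHierarchical:
    def test_small_group_recovery(self):
        obs = DDMObserverParams(drift_by_condition={(52, 15): 0.8, (150, 15): 1.8},
                                boundary=1.8, start_point=0.5,
                                nondecision_t0=0.35)
        tr = simulate_ddm_dataset(obs, 6, 75, seed=13)
        res = HierarchicalDDMModel(tr, min_trials=100).fit(
            MCMCConfig(chains=2, iterations=800, burn_in=400, seed=2))
        assert res.group_drift_mean(52) == pytest.approx(0.8, abs=0.25)
        assert res.group_drift_mean(150) == pytest.approx(1.8, abs=0.25)
        assert res.drift_ordering_posterior() > 0.95


class TestVRatio:
    def test_equal_rates_give_unit_ratio(self, ddm_trials_single):
        res = fit_vratio(ddm_trials_single)
        assert 0.85 <= res.vratio <= 1.15

    def test_uninformative_confidence_gives_zero_ratio(self):
        obs = DDMObserverParams(drift_by_condition={(88, 15): 1.0},
                                boundary=1.8, start_point=0.5,
                                nondecision_t0=0.35, postdecision_drift=0.0,
                                confidence_cutpoints=(-0.5, 0.5))
        tr = simulate_ddm_trials(obs, 2_000, seed=91)
        res = fit_vratio(tr)
        assert abs(res.vratio) < 0.15

    def test_half_rate_distinguished_from_full(self):
        lows, highs = [], []
        for seed in range(3):
            for vp, acc in ((0.5, lows), (1.0, highs)):
                obs = DDMObserverParams(
                    drift_by_condition={(88, 15): 1.0}, boundary=1.8,
                    start_point=0.5, nondecision_t0=0.35,
                    postdecision_drift=vp, confidence_cutpoints=(-0.3, 0.9))
                tr = simulate_ddm_trials(obs, 1_000, seed=300 + seed)
                acc.append(fit_vratio(tr).vratio)
        assert max(lows) < min(highs)

    def test_constant_pas_rejected(self, ddm_trials_single):
        tr = ddm_trials_single.copy()
        tr["pas"] = 2
        with pytest.raises(EstimationError):
            VRatioModel(tr)
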