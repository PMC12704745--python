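"""Meta-d' MLE: recovery, destroyed type-2 information, grid-scan oracle
equivalence and likelihood-model consistency."""

import numpy as np
import pytest

from bodymeta import (DesignSpec, MetaDModel, SDTObserverParams, fit_metad,
                      simulate_sdt_dataset, tabulate_counts)
from bodymeta.metad import rating_probabilities
from bodymeta.sdt import CountTable, EstimationError


def _simulate_counts(dprime, mratio, n_trials, seed, criterion=0.0):
    design = DesignSpec(asynchrony_levels_ms=(52,), trials_per_condition=n_trials,
                        n_subjects=1, seed=0)
    params = SDTObserverParams(dprime_by_condition={(52, 6): dprime},
                               criterion_c=criterion, mratio_true=mratio)
    return tabulate_counts(simulate_sdt_dataset(design, params, seed=seed))


def grid_scan_oracle(counts, coarse=0.06, fine=0.01, span=0.1):
    """Independent two-stage grid scan over meta-d' with the type-2 criteria
    optimised by Nelder-Mead at every node."""
    from scipy.optimize import minimize
    from bodymeta.metad import metad_log_likelihood, _counts_by_stim
    from bodymeta.sdt import dprime_2afc

    t2 = np.asarray(counts.type2, float) + 1.0 / 6.0
    cstim = _counts_by_stim(t2)
    type1 = dprime_2afc(counts)
    d_int = type1.dprime * np.sqrt(2.0)
    c_prime = type1.criterion_c / d_int if abs(d_int) > 1e-8 else 0.0

    warm = {"x": None}

    def profile(md, tight=False):
        best, best_x = -np.inf, None
        starts = [np.log(np.full(4, 0.5))]
        if warm["x"] is not None:
            starts.append(warm["x"])
        opts = ({"xatol": 1e-6, "fatol": 1e-9, "maxiter": 800} if tight
                else {"xatol": 1e-5, "fatol": 1e-7, "maxiter": 300})
        for x0 in starts:
            res = minimize(
                lambda lt: -metad_log_likelihood(md, np.exp(lt), cstim, c_prime),
                x0, method="Nelder-Mead", options=opts)
            if -res.fun > best:
                best, best_x = -res.fun, res.x
        warm["x"] = best_x
        return best

    lo, hi = -1.0, max(2.0 * d_int, 1.0) + 0.5
    grid1 = np.arange(lo, hi, coarse)
    vals1 = np.array([profile(m) for m in grid1])
    centre = grid1[np.argmax(vals1)]
    grid2 = np.arange(centre - span, centre + span, fine)
    vals2 = np.array([profile(m, tight=True) for m in grid2])
    i = int(np.argmax(vals2))
    return grid2[i] / np.sqrt(2.0), vals2[i]


class TestMetaDFit:
    def test_ideal_observer_efficiency_near_one(self, sdt_trials_large):
        res = fit_metad(tabulate_counts(sdt_trials_large))
        assert 0.95 <= res.mratio <= 1.05
        assert res.converged

    def test_shuffled_ratings_destroy_sensitivity(self, sdt_trials_large, rng):
        tr = sdt_trials_large.copy()
        for side in ("left", "right"):
            idx = tr.index[tr.response_side == side]
            tr.loc[idx, "pas"] = rng.permutation(tr.loc[idx, "pas"].to_numpy())
        res = fit_metad(tabulate_counts(tr))
        assert abs(res.meta_dprime) < 0.1

    @pytest.mark.parametrize("mratio", [0.5, 0.8, 1.0])
    def test_recovery_across_efficiencies(self, mratio):
        counts = _simulate_counts(1.4, mratio, 10_000, seed=int(mratio * 100))
        res = fit_metad(counts)
        assert res.mratio == pytest.approx(mratio, abs=0.1)

    def test_group_mean_mratio_recovered_at_study_scale(self):
        # 40 subjects x 300 trials, generative efficiency 0.7
        from bodymeta import DesignSpec, simulate_sdt_dataset
        design = DesignSpec(asynchrony_levels_ms=(52,),
                            trials_per_condition=300, n_subjects=40, seed=0)
        params = SDTObserverParams(dprime_by_condition={(52, 6): 1.4},
                                   mratio_true=0.7)
        trials = simulate_sdt_dataset(design, params, seed=808)
        mratios = [fit_metad(tabulate_counts(sub)).mratio
                   for _, sub in trials.groupby("subject")]
        assert np.mean(mratios) == pytest.approx(0.7, abs=0.1)

    def test_optimum_matches_grid_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            counts = _simulate_counts(
                float(rng.uniform(0.6, 2.0)), float(rng.uniform(0.3, 1.2)),
                500, seed=int(rng.integers(1 << 30)),
                criterion=float(rng.uniform(-0.4, 0.4)))
            fit = fit_metad(counts)
            md_grid, ll_grid = grid_scan_oracle(counts)
            assert abs(fit.log_likelihood - ll_grid) < 1e-3
            assert abs(fit.meta_dprime - md_grid) < 0.02

    def test_fit_never_beaten_by_matched_metad(self, sdt_trials_small):
        counts = tabulate_counts(sdt_trials_small)
        model = MetaDModel(counts)
        res = model.fit()
        # likelihood at the optimum >= likelihood at meta-d' = d' with the
        # same fitted criteria offsets
        taus = np.concatenate([
            -np.diff(np.concatenate([[res.type1_c_prime * res.meta_dprime * np.sqrt(2)],
                                     list(res.type2_criteria_left)])),
            np.diff(np.concatenate([[res.type1_c_prime * res.meta_dprime * np.sqrt(2)],
                                    list(res.type2_criteria_right)])),
        ])
        assert model.loglike(res.meta_dprime, taus) >= \
            model.loglike(res.dprime, taus) - 1e-9

    def test_predicted_probabilities_valid(self):
        for md, cp in [(1.0, 0.1), (0.3, -0.2), (2.5, 0.0)]:
            p = rating_probabilities(md, cp, np.array([0.4, 0.6, 0.5, 0.7]))
            assert (p >= 0).all()
            assert np.allclose(p.sum(axis=2), 1.0, atol=1e-9)

    def test_no_errors_without_padding_rejected(self):
        t2 = np.zeros((2, 2, 3))
        t2[1, 1] = [10, 20, 30]
        t2[0, 1] = [12, 18, 30]
        ct = CountTable(60, 0, 0, 60, t2)
        with pytest.raises(EstimationError):
            MetaDModel(ct, pad=False)
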