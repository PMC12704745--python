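"""Hierarchical Bayesian estimation of group metacognitive efficiency.

Model
-----
For subject *s* in condition *c* the log M-ratio is drawn from a group
distribution,

    log M_sc ~ Normal(mu_c, sigma_c),   mu_c ~ Normal(0, 1),
    sigma_c ~ half-Normal(1),

and the rating counts of that cell follow the meta-d' observation model with
meta-d' = exp(log M_sc) * d'_sc, where the type-1 sensitivity d'_sc and the
relative criterion are fixed at their point estimates.  The subject-level
type-2 criteria are profiled out: for every cell the profile log-likelihood
of log M (criteria maximised at each grid node) is precomputed on a grid and
interpolated, after which MCMC over {log M_sc, mu_c, sigma_c} is cheap.
All conditions share one joint model, so every pairwise contrast is computed
from the joint posterior.

Sampling uses Metropolis-within-Gibbs: elementwise adaptive random-walk
updates for the (conditionally independent) subject effects, a conjugate
Gaussian draw for mu_c, slice sampling for sigma_c, plus joint
translation and scale moves of each condition's subject effects (the
non-centred updates that defeat the hierarchical funnel).
Comparisons between conditions are reported as posterior differences of
mu_c in log units with 95% highest-density intervals; an interval excluding
zero flags a credible difference.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize

from .design import ConfigurationError, ValidationError
from .mcmc import MCMCConfig, PosteriorSamples, hdi
from .metad import metad_log_likelihood, _counts_by_stim
from .sdt import CountTable, dprime_2afc

__all__ = ["HierarchicalMRatioModel", "HierarchicalMRatioResults",
           "HDIComparison", "fit_hmeta_group", "compare_conditions"]

_SQRT2 = np.sqrt(2.0)

# profile-likelihood grid on log M-ratio: node grid for the criteria
# optimisation, dense grid for the interpolated sampler look-ups
_NODE_GRID = np.linspace(-4.0, 1.6, 19)
_DENSE_LO, _DENSE_HI, _DENSE_N = -4.0, 1.6, 281


def _profile_grid(counts: CountTable, n_ratings: int = 3,
                  pad: bool = False) -> np.ndarray:
    """Dense grid of the profile log-likelihood of log M for one cell.

    Type-1 d' and the relative criterion are fixed at their point estimates;
    at each node the 2*(n_ratings-1) type-2 criterion offsets are maximised
    (warm-started along the grid, with a cold restart as guard), then a
    shape-preserving interpolant densifies the curve.  Unlike the MLE
    front-end, the Bayesian model needs no zero-cell padding (the exact
    multinomial likelihood stays finite), so padding is off by default.
    """
    t2 = np.asarray(counts.type2, float)
    if pad:
        t2 = t2 + 1.0 / (2.0 * n_ratings)
    cstim = _counts_by_stim(t2)
    type1 = dprime_2afc(counts)
    d_int = max(type1.dprime * _SQRT2, 1e-3)
    c_prime = type1.criterion_c / d_int
    k = 2 * (n_ratings - 1)
    cold = np.log(np.full(k, 0.5))
    x0 = cold
    bounds = [(-12, 3)] * k
    vals = np.empty(_NODE_GRID.size)
    for i, logm in enumerate(_NODE_GRID):
        meta_d = np.exp(logm) * d_int

        def nll(logtau):
            return -metad_log_likelihood(meta_d, np.exp(logtau), cstim,
                                         c_prime, n_ratings)

        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        res_cold = minimize(nll, cold, method="L-BFGS-B", bounds=bounds)
        if res_cold.fun < res.fun:
            res = res_cold
        x0 = res.x  # warm start the next node
        vals[i] = -res.fun
    dense = np.linspace(_DENSE_LO, _DENSE_HI, _DENSE_N)
    # shape-preserving interpolation: cubic splines overshoot badly where
    # the profile falls off steeply, creating spurious likelihood spikes
    return PchipInterpolator(_NODE_GRID, vals)(dense)


def _interp_ll(tables: np.ndarray, logm: np.ndarray) -> np.ndarray:
    """Vectorised linear interpolation of cell log-likelihood tables."""
    h = (_DENSE_HI - _DENSE_LO) / (_DENSE_N - 1)
    pos = np.clip((logm - _DENSE_LO) / h, 0, _DENSE_N - 1 - 1e-9)
    i = pos.astype(int)
    f = pos - i
    rows = np.arange(tables.shape[0])
    return tables[rows, i] * (1 - f) + tables[rows, i + 1] * f


def _slice_logpost_sigma(ls, ssq, n):
    """Conditional log-density of log sigma given the subject effects:
    Normal layer + half-Normal(1) prior + log-Jacobian."""
    s2 = np.exp(2.0 * ls)
    return -(n - 1.0) * ls - 0.5 * ssq / s2 - 0.5 * s2


def _slice_sigma(rng, sigma, ssq, n, w: float = 1.0, max_steps: int = 30,
                 lo: float = -9.0, hi: float = 3.0):
    """Vectorised stepping-out slice sampler for each condition's log sigma."""
    ls0 = np.log(sigma)
    f0 = _slice_logpost_sigma(ls0, ssq, n)
    logy = f0 + np.log(rng.random(sigma.shape))
    left = ls0 - w * rng.random(sigma.shape)
    right = left + w
    for _ in range(max_steps):
        grow = (_slice_logpost_sigma(left, ssq, n) > logy) & (left > lo)
        if not grow.any():
            break
        left = np.where(grow, left - w, left)
    for _ in range(max_steps):
        grow = (_slice_logpost_sigma(right, ssq, n) > logy) & (right < hi)
        if not grow.any():
            break
        right = np.where(grow, right + w, right)
    left = np.maximum(left, lo)
    right = np.minimum(right, hi)
    ls = ls0.copy()
    todo = np.ones(sigma.shape, dtype=bool)
    for _ in range(max_steps):
        prop = left + (right - left) * rng.random(sigma.shape)
        ok = _slice_logpost_sigma(prop, ssq, n) > logy
        take = todo & ok
        ls = np.where(take, prop, ls)
        todo = todo & ~ok
        if not todo.any():
            break
        # shrink the bracket toward the current point
        shrink_left = todo & (prop < ls0)
        left = np.where(shrink_left, prop, left)
        right = np.where(todo & ~shrink_left, prop, right)
    return np.exp(ls)


def _interp_ll_chains(tables: np.ndarray, logm: np.ndarray) -> np.ndarray:
    """Interpolation for (chain, cell)-shaped states against shared tables."""
    h = (_DENSE_HI - _DENSE_LO) / (_DENSE_N - 1)
    pos = np.clip((logm - _DENSE_LO) / h, 0, _DENSE_N - 1 - 1e-9)
    i = pos.astype(int)
    f = pos - i
    cols = np.arange(tables.shape[0])[None, :]
    return tables[cols, i] * (1 - f) + tables[cols, i + 1] * f


@dataclass
class HDIComparison:
    """Posterior contrast of two conditions' group log M-ratio."""

    pair: tuple
    posterior_mean_diff: float
    hdi_95: tuple
    credible: bool

    def __post_init__(self):
        lo, hi = self.hdi_95
        assert lo <= hi
        self.credible = bool(not (lo <= 0.0 <= hi))


class HierarchicalMRatioResults:
    """Posterior summaries of the joint hierarchical M-ratio model."""

    def __init__(self, posterior: PosteriorSamples, conditions, n_subjects,
                 convergence_warning: bool):
        self.posterior = posterior
        self.conditions = list(conditions)
        self.n_subjects = n_subjects
        self.convergence_warning = convergence_warning

    def group_log_mratio(self, condition) -> np.ndarray:
        return self.posterior.stacked(f"mu[{condition}]")

    def group_mratio_mean(self, condition) -> float:
        """Point estimate of the group M-ratio (exp of the posterior mean of
        the group-level log M-ratio)."""
        return float(np.exp(np.mean(self.group_log_mratio(condition))))

    def compare(self, pair) -> HDIComparison:
        return compare_conditions(self, pair)

    def compare_all_pairs(self) -> list:
        out = []
        for i, a in enumerate(self.conditions):
            for b in self.conditions[i + 1:]:
                out.append(self.compare((a, b)))
        return out

    def summary(self) -> str:
        lines = ["Hierarchical M-ratio fit",
                 "------------------------",
                 f"subjects: {self.n_subjects}   conditions: {len(self.conditions)}"]
        for cond in self.conditions:
            draws = self.group_log_mratio(cond)
            lo, hi = hdi(draws)
            rh = self.posterior.rhat[f"mu[{cond}]"]
            lines.append(
                f"  {cond}: M-ratio {np.exp(draws.mean()):.3f} "
                f"(log {draws.mean():+.3f}, 95% HDI [{lo:+.3f}, {hi:+.3f}], "
                f"R-hat {rh:.3f})")
        if self.convergence_warning:
            lines.append("  WARNING: R-hat > 1.05 on a group parameter; "
                         "credibility calls suppressed")
        return "\n".join(lines)


class HierarchicalMRatioModel:
    """Joint hierarchical model of group M-ratio over several conditions.

    Parameters
    ----------
    counts_by_subject_condition
        Mapping ``(subject, condition) -> CountTable`` (every subject must
        contribute a table for every condition), or a nested mapping
        ``condition -> {subject: CountTable}``.
    """

    def __init__(self, counts_by_subject_condition, n_ratings: int = 3):
        counts = self._normalise(counts_by_subject_condition)
        self.conditions = sorted({c for (_, c) in counts}, key=str)
        self.subjects = sorted({s for (s, _) in counts}, key=str)
        if len(self.subjects) < 5:
            raise ConfigurationError("hierarchical fit requires at least 5 subjects")
        for s in self.subjects:
            for c in self.conditions:
                if (s, c) not in counts:
                    raise ValidationError(f"subject {s!r} missing counts for condition {c!r}")
        self.n_ratings = n_ratings
        self._counts = counts
        self._tables = None  # (n_cells, dense) profile log-likelihoods

    @staticmethod
    def _normalise(obj) -> dict:
        first = next(iter(obj.values()))
        if isinstance(first, CountTable):
            return dict(obj)
        out = {}
        for cond, per_subj in obj.items():
            for subj, ct in per_subj.items():
                out[(subj, cond)] = ct
        return out

    def _prepare(self) -> None:
        if self._tables is not None:
            return
        cells = [(s, c) for c in self.conditions for s in self.subjects]
        self._cells = cells
        self._cond_index = np.array(
            [self.conditions.index(c) for (_, c) in cells])
        self._tables = np.stack([
            _profile_grid(self._counts[cell], self.n_ratings) for cell in cells])

    def fit(self, mcmc: MCMCConfig | None = None) -> HierarchicalMRatioResults:
        mcmc = mcmc or MCMCConfig()
        self._prepare()
        n_cells = len(self._cells)
        n_cond = len(self.conditions)
        cidx = self._cond_index
        tables = self._tables
        total = mcmc.burn_in + mcmc.iterations
        K = mcmc.chains
        n_per = np.bincount(cidx, minlength=n_cond).astype(float)
        # condition indicator for fast per-condition sums: (n_cells, n_cond)
        ind = np.zeros((n_cells, n_cond))
        ind[np.arange(n_cells), cidx] = 1.0

        rng = np.random.default_rng(mcmc.seed)
        dense = np.linspace(_DENSE_LO, _DENSE_HI, _DENSE_N)
        # initialise every chain at the jittered per-cell profile maximum
        logm = (dense[np.argmax(tables, axis=1)][None, :]
                + rng.normal(0, 0.15, (K, n_cells)))
        logm = np.clip(logm, _DENSE_LO + 0.1, _DENSE_HI - 0.1)
        mu = (logm @ ind) / n_per
        sigma = np.full((K, n_cond), 0.3)
        step = np.full((K, n_cells), 0.3)
        step_s = np.full((K, n_cond), 0.4)
        ll = _interp_ll_chains(tables, logm)
        keep_mu = np.empty((K, mcmc.iterations, n_cond))
        keep_sig = np.empty((K, mcmc.iterations, n_cond))

        def cell_ll(x):
            return _interp_ll_chains(tables, x)

        for it in range(total):
            adapt = mcmc.adapt and it < mcmc.burn_in
            # 1) subject-level effects: elementwise random walk
            prop = logm + step * rng.standard_normal((K, n_cells))
            inside = (prop > _DENSE_LO) & (prop < _DENSE_HI)
            prop = np.where(inside, prop, logm)
            ll_p = cell_ll(prop)
            lp = (ll_p - ll
                  - 0.5 * ((prop - mu[:, cidx]) ** 2 - (logm - mu[:, cidx]) ** 2)
                  / sigma[:, cidx] ** 2)
            acc = (np.log(rng.random((K, n_cells))) < lp) & inside
            logm = np.where(acc, prop, logm)
            ll = np.where(acc, ll_p, ll)
            if adapt:
                step = np.clip(step * np.where(acc, 1.06, 0.97), 1e-3, 2.0)

            # 2) group means: conjugate normal draw (prior N(0, 1))
            prec = n_per[None, :] / sigma ** 2 + 1.0
            mean = ((logm @ ind) / sigma ** 2) / prec
            mu = mean + rng.standard_normal((K, n_cond)) / np.sqrt(prec)

            # 3) group spreads: slice sampling on log sigma (half-Normal(1)
            # prior); tuning-free, robust to the near-zero-variance regime
            ssq = ((logm - mu[:, cidx]) ** 2) @ ind
            sigma = _slice_sigma(rng, sigma, ssq, n_per[None, :])

            # 4) non-centered translation move: shift mu_c and all its
            # subject effects together (breaks mu-logm autocorrelation)
            eps = 0.15 * rng.standard_normal((K, n_cond))
            prop = logm + eps[:, cidx]
            ok = ((prop > _DENSE_LO) & (prop < _DENSE_HI)).all(axis=1)
            ll_p = cell_ll(prop)
            dll = (ll_p - ll) @ ind
            mu_p = mu + eps
            lp_t = dll - 0.5 * (mu_p ** 2 - mu ** 2)  # mu prior N(0,1)
            acc_t = (np.log(rng.random((K, n_cond))) < lp_t) & ok[:, None]
            take = acc_t[:, cidx]
            logm = np.where(take, prop, logm)
            ll = np.where(take, ll_p, ll)
            mu = np.where(acc_t, mu_p, mu)

            # 5) non-centered scale move: expand/contract subject effects
            # about mu_c while scaling sigma_c (defeats the funnel)
            eps = 0.3 * rng.standard_normal((K, n_cond))
            s_p = sigma * np.exp(eps)
            prop = mu[:, cidx] + (logm - mu[:, cidx]) * np.exp(eps)[:, cidx]
            ok = ((prop > _DENSE_LO) & (prop < _DENSE_HI)).all(axis=1)
            ll_p = cell_ll(prop)
            dll = (ll_p - ll) @ ind
            # Gaussian layer and Jacobians cancel except for prior and +eps
            lp_sc = dll - 0.5 * (s_p ** 2 - sigma ** 2) + eps
            acc_sc = (np.log(rng.random((K, n_cond))) < lp_sc) & ok[:, None]
            take = acc_sc[:, cidx]
            logm = np.where(take, prop, logm)
            ll = np.where(take, ll_p, ll)
            sigma = np.where(acc_sc, s_p, sigma)

            if it >= mcmc.burn_in:
                keep_mu[:, it - mcmc.burn_in] = mu
                keep_sig[:, it - mcmc.burn_in] = sigma

        draws = {}
        for c, cond in enumerate(self.conditions):
            draws[f"mu[{cond}]"] = keep_mu[:, :, c]
            draws[f"sigma[{cond}]"] = keep_sig[:, :, c]
        post = PosteriorSamples(draws=draws, burn_in=mcmc.burn_in)
        max_rhat = post.max_rhat(prefix="mu[")
        warn = bool(max_rhat > 1.05)
        if warn:
            warnings.warn(f"group-level R-hat {max_rhat:.3f} > 1.05; "
                          "credibility calls suppressed", RuntimeWarning)
        return HierarchicalMRatioResults(post, self.conditions,
                                         len(self.subjects), warn)


def fit_hmeta_group(counts_by_subject_condition, mcmc: MCMCConfig | None = None,
                    n_ratings: int = 3) -> HierarchicalMRatioResults:
    """Fit the joint hierarchical group M-ratio model (module-level wrapper)."""
    model = HierarchicalMRatioModel(counts_by_subject_condition, n_ratings)
    return model.fit(mcmc)


def compare_conditions(result: HierarchicalMRatioResults, pair) -> HDIComparison:
    """Posterior difference of group log M-ratio between two conditions."""
    a, b = pair
    for cond in (a, b):
        if cond not in result.conditions:
            raise ValidationError(f"unknown condition {cond!r}")
    diff = result.group_log_mratio(a) - result.group_log_mratio(b)
    lo, hi = hdi(diff, 0.95)
    credible = not (lo <= 0.0 <= hi)
    if result.convergence_warning:
        credible = False
    return HDIComparison(pair=(a, b), posterior_mean_diff=float(diff.mean()),
                         hdi_95=(lo, hi), credible=credible)
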