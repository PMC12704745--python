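"""Group-level statistics for the psychophysical indices.

Covers the battery applied to d', meta-d', M-ratio and the diffusion
parameters: one-way repeated-measures ANOVA with Greenhouse-Geisser
correction and partial eta squared, a mixed two-factor extension with one
between-subject factor, JZS Bayes-factor one-sample t tests (Cauchy prior
on the standardised effect, default width 0.707, two-sided and directional,
with a prior-width robustness sweep), a Bayesian one-way repeated-measures
ANOVA Bayes factor under multivariate-Cauchy g-priors (r = 0.5 for the
fixed condition effect, r = 1 for random subject effects), and
Kolmogorov-Smirnov / Kruskal-Wallis nonparametric summaries for response
times.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.integrate import quad
from scipy.special import gammaln

from .design import ValidationError
from .sdt import EstimationError

__all__ = [
    "ANOVAResult", "BayesTResult", "rm_anova_gg", "mixed_anova_gg",
    "bayes_t_one_sample", "sequential_bf", "bf_oneway_rm",
    "nonparametric_tests", "t_one_sample", "cohen_d",
]


@dataclass
class ANOVAResult:
    F: float
    df_num: float
    df_den: float
    p: float
    eta_p_sq: float
    gg_epsilon: float
    corrected: bool
    effect: str = "condition"

    def summary(self) -> str:
        return (f"{self.effect}: F({self.df_num:.3f}, {self.df_den:.3f}) = "
                f"{self.F:.3f}, p = {self.p:.4g}, eta_p^2 = {self.eta_p_sq:.3f}"
                + (f" (GG epsilon = {self.gg_epsilon:.3f})" if self.corrected else ""))


@dataclass
class BayesTResult:
    t: float
    n: int
    bf10: float
    bf_plus0: float
    rscale: float
    p: float
    cohen_d: float
    robustness_curve: list = field(default_factory=list)

    def summary(self) -> str:
        return (f"t({self.n - 1}) = {self.t:.3f}, d = {self.cohen_d:.3f}, "
                f"BF10 = {self.bf10:.4g}, BF+0 = {self.bf_plus0:.4g} "
                f"(r = {self.rscale})")


def _gg_epsilon(values: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance of the
    within-subject conditions."""
    k = values.shape[1]
    if k < 3:
        return 1.0
    S = np.cov(values, rowvar=False, ddof=1)
    row = S.mean(axis=0, keepdims=True)
    M = S - row - row.T + S.mean()
    num = np.trace(M) ** 2
    den = (k - 1) * np.sum(M * M)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


def rm_anova_gg(values: np.ndarray | pd.DataFrame) -> ANOVAResult:
    """One-way repeated-measures ANOVA on a subjects x conditions matrix.

    Degrees of freedom are Greenhouse-Geisser corrected whenever the
    sphericity estimate epsilon falls below 1 (k > 2); partial eta squared
    is SS_effect / (SS_effect + SS_error).
    """
    x = np.asarray(values, float)
    if x.ndim != 2:
        raise ValidationError("expected a subjects x conditions matrix")
    if np.isnan(x).any():
        raise ValidationError("missing cells in the data matrix")
    n, k = x.shape
    if k < 2 or n < 3:
        raise ValidationError("need at least 2 conditions and 3 subjects")
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2 if ss_err > 0 else 0.0
    F = ms_cond / ms_err if ms_err > 0 else (0.0 if ss_cond == 0 else np.inf)
    eps = _gg_epsilon(x)
    corrected = eps < 1.0 - 1e-12
    d1, d2 = (df1 * eps, df2 * eps) if corrected else (df1, df2)
    p = float(sps.f.sf(F, d1, d2)) if np.isfinite(F) else 0.0
    denom = ss_cond + ss_err
    return ANOVAResult(F=float(F), df_num=float(d1), df_den=float(d2), p=p,
                       eta_p_sq=float(ss_cond / denom) if denom > 0 else 0.0,
                       gg_epsilon=eps, corrected=corrected)


def mixed_anova_gg(groups: dict) -> dict:
    """Two-factor mixed ANOVA: one between factor (the dict keys; e.g. the
    experiment) and one within factor (matrix columns).

    ``groups`` maps group label -> subjects x conditions matrix (same k).
    Returns ANOVAResult per effect: 'between', 'within', 'interaction';
    within-subject effects are GG-corrected with the pooled epsilon.
    """
    labels = list(groups)
    mats = [np.asarray(groups[g], float) for g in labels]
    k = mats[0].shape[1]
    if any(m.shape[1] != k for m in mats):
        raise ValidationError("all groups must share the condition set")
    if len(mats) < 2:
        raise ValidationError("need at least two groups")
    ns = [m.shape[0] for m in mats]
    N = sum(ns)
    allx = np.vstack(mats)
    grand = allx.mean()

    subj_means = allx.mean(axis=1)
    group_means = np.array([m.mean() for m in mats])
    cond_means = allx.mean(axis=0)
    ss_between = k * sum(n * (gm - grand) ** 2 for n, gm in zip(ns, group_means))
    ss_subj_within = k * sum(
        ((m.mean(axis=1) - m.mean()) ** 2).sum() for m in mats)
    ss_cond = N * np.sum((cond_means - grand) ** 2)
    cell_means = np.array([m.mean(axis=0) for m in mats])  # (g, k)
    ss_cells = sum(n * ((cm - grand) ** 2).sum() for n, cm in zip(ns, cell_means))
    ss_inter = ss_cells - ss_between - ss_cond
    ss_tot = np.sum((allx - grand) ** 2)
    ss_err_within = ss_tot - ss_between - ss_subj_within - ss_cond - ss_inter

    g = len(mats)
    df_b, df_sw = g - 1.0, float(N - g)
    df_c = k - 1.0
    df_i = (g - 1.0) * (k - 1.0)
    df_e = (N - g) * (k - 1.0)

    # pooled Greenhouse-Geisser epsilon over groups' covariance matrices
    if k > 2:
        pooled = sum((m.shape[0] - 1) * np.cov(m, rowvar=False, ddof=1)
                     for m in mats) / (N - g)
        row = pooled.mean(axis=0, keepdims=True)
        M = pooled - row - row.T + pooled.mean()
        den = (k - 1) * np.sum(M * M)
        eps = float(min(1.0, np.trace(M) ** 2 / den)) if den > 0 else 1.0
    else:
        eps = 1.0
    corrected = eps < 1.0 - 1e-12

    def mk(ss_eff, df_eff, ss_err, df_err, use_eps, name):
        F = (ss_eff / df_eff) / (ss_err / df_err) if ss_err > 0 else np.inf
        d1, d2 = (df_eff * eps, df_err * eps) if (use_eps and corrected) else (df_eff, df_err)
        return ANOVAResult(F=float(F), df_num=float(d1), df_den=float(d2),
                           p=float(sps.f.sf(F, d1, d2)),
                           eta_p_sq=float(ss_eff / (ss_eff + ss_err)),
                           gg_epsilon=eps if use_eps else 1.0,
                           corrected=bool(use_eps and corrected), effect=name)

    return {
        "between": mk(ss_between, df_b, ss_subj_within, df_sw, False, "between"),
        "within": mk(ss_cond, df_c, ss_err_within, df_e, True, "within"),
        "interaction": mk(ss_inter, df_i, ss_err_within, df_e, True, "interaction"),
    }


def cohen_d(values: np.ndarray) -> float:
    x = np.asarray(values, float)
    return float(x.mean() / x.std(ddof=1))


def t_one_sample(values: np.ndarray) -> tuple:
    """(t, p_two_sided) for a one-sample t test against zero."""
    x = np.asarray(values, float)
    if x.size < 2 or x.std(ddof=1) == 0:
        raise EstimationError("need n >= 2 and nonzero variance")
    t = x.mean() / (x.std(ddof=1) / np.sqrt(x.size))
    p = 2.0 * sps.t.sf(abs(t), x.size - 1)
    return float(t), float(p)


def _jzs_bf(t: float, n: int, rscale: float, directional: bool) -> float:
    """JZS Bayes factor by quadrature over the Cauchy effect-size prior."""
    nu = n - 1
    sqn = np.sqrt(n)

    def integrand(delta):
        return (sps.nct.pdf(t, nu, delta * sqn)
                * sps.cauchy.pdf(delta, scale=rscale))

    null_dens = sps.t.pdf(t, nu)
    if directional:
        num, _ = quad(integrand, 0, np.inf, limit=200)
        num *= 2.0  # half-Cauchy normalisation
    else:
        lo, _ = quad(integrand, -np.inf, 0, limit=200)
        hi, _ = quad(integrand, 0, np.inf, limit=200)
        num = lo + hi
    return float(num / null_dens)


def bayes_t_one_sample(values, direction: str = "two_sided",
                       rscale: float = 0.707,
                       robustness_grid=None) -> BayesTResult:
    """JZS Bayesian one-sample t test against zero.

    ``direction='positive'`` uses the positive half-Cauchy prior (the
    directional BF+0); the two-sided BF10 is always reported.  If
    ``robustness_grid`` is given (iterable of prior widths), a robustness
    curve of (rscale, BF) pairs for the requested direction is attached.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise EstimationError("need at least two observations")
    if x.std(ddof=1) == 0:
        raise EstimationError("zero variance")
    if direction not in ("two_sided", "positive"):
        raise ValidationError("direction must be 'two_sided' or 'positive'")
    t, p = t_one_sample(x)
    n = int(x.size)
    bf10 = _jzs_bf(t, n, rscale, directional=False)
    bf_plus0 = _jzs_bf(t, n, rscale, directional=True)
    curve = []
    if robustness_grid is not None:
        for r in robustness_grid:
            curve.append((float(r), _jzs_bf(t, n, float(r),
                                            directional=(direction == "positive"))))
    if direction == "positive":
        p = float(sps.t.sf(t, n - 1))
    return BayesTResult(t=t, n=n, bf10=bf10, bf_plus0=bf_plus0, rscale=rscale,
                        p=p, cohen_d=cohen_d(x), robustness_curve=curve)


def sequential_bf(values, direction: str = "positive",
                  rscale: float = 0.707, min_n: int = 3) -> pd.DataFrame:
    """Bayes factor as a function of accumulating subjects (in ID order);
    presentation-only summary of evidence growth."""
    x = np.asarray(values, float)
    rows = []
    for n in range(min_n, x.size + 1):
        res = bayes_t_one_sample(x[:n], direction=direction, rscale=rscale)
        rows.append({"n": n, "bf10": res.bf10, "bf_plus0": res.bf_plus0})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian one-way repeated-measures ANOVA (g-priors)


def _marginal_loglik(y: np.ndarray, X: np.ndarray | None, gvec: np.ndarray | None) -> float:
    """Log marginal likelihood of y = mu*1 + X theta + eps with
    theta ~ N(0, sigma^2 diag(gvec)), Jeffreys prior on (mu, sigma^2);
    constants common to all models are dropped."""
    N = y.size
    one = np.ones(N)
    if X is None or X.shape[1] == 0:
        Sig_inv = np.eye(N)
        logdet = 0.0
    else:
        Sig = np.eye(N) + (X * gvec) @ X.T
        sign, logdet = np.linalg.slogdet(Sig)
        Sig_inv = np.linalg.inv(Sig)
    a = one @ Sig_inv @ one
    b = one @ Sig_inv @ y
    R = y @ Sig_inv @ y - b * b / a
    return float(-0.5 * logdet - 0.5 * np.log(a)
                 - 0.5 * (N - 1) * np.log(max(R, 1e-300)))


def bf_oneway_rm(values: np.ndarray | pd.DataFrame, r_fixed: float = 0.5,
                 r_random: float = 1.0, n_mc: int = 20_000,
                 seed: int = 0) -> float:
    """BF01 for the null (subject effects only) against the condition-effect
    model in a one-way repeated-measures design.

    Both models put g-priors on the standardised effects (g drawn from
    InverseGamma(1/2, r^2/2): scale r_fixed for the orthonormalised
    condition contrasts, r_random for subject effects); marginal
    likelihoods are averaged over seeded stratified Monte-Carlo draws of g.
    In this balanced design the subject- and condition-contrast subspaces
    are orthogonal, so each draw's marginal likelihood is closed form.
    """
    x = np.asarray(values, float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValidationError("need a subjects x conditions matrix with >= 2 conditions")
    n, k = x.shape
    N = n * k
    y = x.ravel()  # subject-major order
    y = y - y.mean()
    Zs = np.kron(_orthonormal_contrasts(n), np.ones((k, 1)) / np.sqrt(k)) * np.sqrt(k)
    Zc = np.kron(np.ones((n, 1)), _orthonormal_contrasts(k))
    yy = float(y @ y)
    qs = float(np.sum((Zs.T @ y) ** 2))  # subject-subspace energy
    qc = float(np.sum((Zc.T @ y) ** 2))  # condition-contrast energy

    rng = np.random.default_rng(seed)
    # stratified (Latin-hypercube) draws sharply reduce Monte-Carlo noise
    u_s = (rng.permutation(n_mc) + rng.random(n_mc)) / n_mc
    u_c = (rng.permutation(n_mc) + rng.random(n_mc)) / n_mc
    g_s = sps.invgamma.ppf(u_s, 0.5, scale=r_random ** 2 / 2.0)
    g_c = sps.invgamma.ppf(u_c, 0.5, scale=r_fixed ** 2 / 2.0)

    # marginal log-likelihood given g (common constants dropped):
    # Sigma = I + g_s Zs Zs' + g_c Zc Zc' with Zs'Zs = k I and Zc'Zc = n I,
    # and the two contrast subspaces orthogonal to each other and to 1
    def loglik(gs, gc):
        logdet = (n - 1) * np.log1p(gs * k) + (k - 1) * np.log1p(gc * n)
        R = yy - gs / (1.0 + gs * k) * qs - gc / (1.0 + gc * n) * qc
        return -0.5 * logdet - 0.5 * (N - 1) * np.log(R / 2.0)

    ll_null = loglik(g_s, 0.0)
    ll_full = loglik(g_s, g_c)

    def logmean(v):
        m = v.max()
        return m + np.log(np.mean(np.exp(v - m)))

    return float(np.exp(logmean(ll_null) - logmean(ll_full)))


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal sum-to-zero contrast matrix (Helmert-based)."""
    H = np.zeros((k, k - 1))
    for j in range(1, k):
        H[:j, j - 1] = 1.0 / j
        H[j, j - 1] = -1.0
        H[:, j - 1] /= np.linalg.norm(H[:, j - 1])
    return H


def nonparametric_tests(samples: dict) -> pd.DataFrame:
    """Kolmogorov-Smirnov normality check per group plus a Kruskal-Wallis
    test across groups.

    ``samples`` maps group label -> 1-D array.  Returns a tidy table with
    one row per group (KS statistic/p on the z-scored values) and one
    'kruskal' row with the H statistic and its p value.
    """
    if len(samples) < 2:
        raise ValidationError("need at least two groups")
    rows = []
    groups = []
    for label, vals in samples.items():
        v = np.asarray(vals, float)
        if v.size < 2:
            raise ValidationError(f"group {label!r} has fewer than 2 observations")
        z = (v - v.mean()) / v.std(ddof=1)
        ks = sps.kstest(z, "norm")
        rows.append({"group": str(label), "test": "ks_normality",
                     "statistic": float(ks.statistic), "p": float(ks.pvalue),
                     "n": int(v.size)})
        groups.append(v)
    H, p = sps.kruskal(*groups)
    rows.append({"group": "all", "test": "kruskal_wallis",
                 "statistic": float(H), "p": float(p),
                 "n": int(sum(g.size for g in groups))})
    return pd.DataFrame(rows)
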