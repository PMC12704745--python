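"""Wiener diffusion modelling of the speeded ownership task, with v-ratio.

The decision stage is a Wiener process with drift v (signed by the stimulus:
positive when the right hand is the synchronous one), boundary separation a,
relative start point w and nondecision time t0 (diffusion scale fixed at
s = 1).  The upper boundary codes a "right" response.  First-passage-time
densities use the classic small-time / large-time series with automatic
regime switching and term counts chosen for a truncation error below 1e-7.

After the decision, evidence keeps accumulating without a boundary for the
observed post-decision interval with drift v_post (same stimulus-defined
sign); the terminal post-decisional evidence measured toward the chosen
boundary is cut into the PAS rating.  The efficiency index

    v-ratio = v_post / v

is the dynamic analogue of M-ratio: 1 means the awareness report accumulates
evidence as fast as the ownership decision itself, 0 means the rating
carries no post-decisional information.

Three fitting front-ends are provided: per-subject maximum likelihood
(:class:`DriftDiffusionModel`), a hierarchical MCMC group model
(:class:`HierarchicalDDMModel`), and the joint decision + confidence model
(:class:`VRatioModel`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .design import ConfigurationError, DDMObserverParams, ValidationError
from .mcmc import MCMCConfig, PosteriorSamples
from .sdt import EstimationError

__all__ = [
    "DDMParams", "wiener_fpt_density", "wiener_logpdf", "choice_probability",
    "DriftDiffusionModel", "DDMFitResults", "HierarchicalDDMModel",
    "HierarchicalDDMResults", "VRatioModel", "VRatioResults",
    "fit_hddm", "fit_vratio",
]

_EPS_SERIES = 1e-7  # truncation error bound of the density series


@dataclass
class DDMParams:
    """Point estimates of the diffusion parameters (scale s = 1)."""

    v: dict
    a: float
    w: float
    t0: float
    v_post: float | None = None
    vratio: float | None = None
    log_likelihood: float = np.nan
    converged: bool = True

    def __post_init__(self):
        if self.a <= 0:
            raise ConfigurationError("boundary a must be positive")
        if not 0 < self.w < 1:
            raise ConfigurationError("start point w must lie in (0, 1)")
        if self.t0 < 0:
            raise ConfigurationError("nondecision time t0 must be nonnegative")


def _ft_unit(tau: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Zero-drift unit-boundary lower first-passage density at scaled time
    tau, start w; small/large-time series with per-element regime choice."""
    tau = np.asarray(tau, float)
    w = np.broadcast_to(np.asarray(w, float), tau.shape)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]
    ww = w[pos]
    eps = _EPS_SERIES

    # required term counts (standard error bounds for each series)
    with np.errstate(divide="ignore", invalid="ignore"):
        arg_s = 2.0 * eps * np.sqrt(2.0 * np.pi * t)
        ks = np.where(arg_s < 1.0,
                      2.0 + np.sqrt(-2.0 * t * np.log(arg_s)),
                      2.0)
        ks = np.maximum(ks, np.sqrt(t) + 1.0)
        arg_l = np.pi * t * eps
        kl = np.where(arg_l < 1.0,
                      np.sqrt(-2.0 * np.log(arg_l) / (np.pi ** 2 * t)),
                      1.0 / (np.pi * np.sqrt(t)))
        kl = np.maximum(kl, 1.0 / (np.pi * np.sqrt(t)))

    use_small = ks < kl
    res = np.empty_like(t)

    if use_small.any():
        ts, ws_ = t[use_small], ww[use_small]
        K = int(np.ceil(ks[use_small].max()))
        K = min(max(K, 2), 200)
        ks_range = np.arange(-((K - 1) // 2), ((K - 1) // 2) + 1)
        wk = ws_[:, None] + 2.0 * ks_range[None, :]
        terms = wk * np.exp(-(wk ** 2) / (2.0 * ts[:, None]))
        res[use_small] = terms.sum(axis=1) / np.sqrt(
            2.0 * np.pi * ts ** 3)

    if (~use_small).any():
        tl, wl = t[~use_small], ww[~use_small]
        K = int(np.ceil(kl[~use_small].max()))
        K = min(max(K, 1), 200)
        kk = np.arange(1, K + 1)
        terms = (kk[None, :]
                 * np.exp(-(kk[None, :] ** 2) * np.pi ** 2 * tl[:, None] / 2.0)
                 * np.sin(kk[None, :] * np.pi * wl[:, None]))
        res[~use_small] = np.pi * terms.sum(axis=1)

    out[pos] = np.maximum(res, 0.0)
    return out


def wiener_fpt_density(t, boundary: str, p: DDMParams | DDMObserverParams,
                       v: float | None = None) -> np.ndarray:
    """First-passage-time density at the named boundary ("upper"/"lower").

    ``t`` is the observed response time in seconds; the density is zero for
    t <= t0.  For parameter objects with per-condition drift, pass the drift
    to use via ``v``.
    """
    if boundary not in ("upper", "lower"):
        raise ValidationError("boundary must be 'upper' or 'lower'")
    if isinstance(p, DDMObserverParams):
        a, w, t0 = p.boundary, p.start_point, p.nondecision_t0
        if v is None:
            drifts = list(dict(p.drift_by_condition).values())
            if len(drifts) != 1:
                raise ConfigurationError("pass v explicitly for multi-condition parameters")
            v = drifts[0]
    else:
        a, w, t0 = p.a, p.w, p.t0
        if v is None:
            vs = list(p.v.values())
            if len(vs) != 1:
                raise ConfigurationError("pass v explicitly for multi-condition parameters")
            v = vs[0]
    t = np.asarray(t, float)
    scalar = t.ndim == 0
    t = np.atleast_1d(t)
    tau = t - t0
    if boundary == "upper":
        v_eff, w_eff = -v, 1.0 - w
    else:
        v_eff, w_eff = v, w
    dens = np.zeros_like(tau)
    pos = tau > 0
    if pos.any():
        tt = tau[pos]
        pref = np.exp(-v_eff * a * w_eff - v_eff ** 2 * tt / 2.0)
        dens[pos] = pref * _ft_unit(tt / a ** 2, w_eff) / a ** 2
    return float(dens[0]) if scalar else dens


def wiener_logpdf(t: np.ndarray, upper: np.ndarray, v: np.ndarray,
                  a: np.ndarray, w: np.ndarray, t0: np.ndarray,
                  floor: float = 1e-29) -> np.ndarray:
    """Vectorised log first-passage density for a batch of trials.

    ``upper`` marks trials absorbed at the upper boundary; drift, boundary,
    start and nondecision time broadcast against ``t``.
    """
    t = np.asarray(t, float)
    up = np.asarray(upper, bool)
    v_eff = np.where(up, -v, v)
    w_eff = np.where(up, 1.0 - np.asarray(w, float), w)
    a = np.broadcast_to(np.asarray(a, float), t.shape)
    tau = t - t0
    dens = np.full(t.shape, floor)
    pos = tau > 1e-12
    if pos.any():
        tt = tau[pos]
        aa = a[pos]
        ve = np.broadcast_to(v_eff, t.shape)[pos]
        we = np.broadcast_to(w_eff, t.shape)[pos]
        f = _ft_unit(tt / aa ** 2, we) / aa ** 2
        logf = np.where(f > 0, np.log(np.maximum(f, floor)), np.log(floor))
        dens_log = -ve * aa * we - ve ** 2 * tt / 2.0 + logf
        out = np.full(t.shape, np.log(floor))
        out[pos] = dens_log
        return out
    return np.full(t.shape, np.log(floor))


def choice_probability(p: DDMParams | DDMObserverParams, v: float | None = None) -> float:
    """Probability of absorption at the upper boundary (closed form)."""
    if isinstance(p, DDMObserverParams):
        a, w = p.boundary, p.start_point
        if v is None:
            drifts = list(dict(p.drift_by_condition).values())
            if len(drifts) != 1:
                raise ConfigurationError("pass v explicitly for multi-condition parameters")
            v = drifts[0]
    else:
        a, w = p.a, p.w
        if v is None:
            vs = list(p.v.values())
            if len(vs) != 1:
                raise ConfigurationError("pass v explicitly for multi-condition parameters")
            v = vs[0]
    if abs(v) < 1e-12:
        return float(w)
    z = w * a
    num = -np.expm1(-2.0 * v * z)
    den = -np.expm1(-2.0 * v * a)
    return float(num / den)


# ---------------------------------------------------------------------------
# data preparation shared by the fitting front-ends


def _prep_trials(trials: pd.DataFrame, drop_censored: bool = True):
    df = trials
    if drop_censored and "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    if len(df) == 0:
        raise ValidationError("no uncensored trials")
    rt = df["rt_decision_s"].to_numpy(float)
    upper = (df["response_side"] == "right").to_numpy()
    stim = np.where(df["sync_side"] == "right", 1.0, -1.0)
    cond = df["asynchrony_ms"].to_numpy()
    return df, rt, upper, stim, cond


@dataclass
class DDMFitResults:
    """Maximum-likelihood diffusion fit for one subject."""

    params: DDMParams
    n_trials: int
    conditions: list = field(default_factory=list)

    def summary(self) -> str:
        lines = ["Diffusion maximum-likelihood fit",
                 "--------------------------------"]
        for c in self.conditions:
            lines.append(f"v[{c}]   {self.params.v[c]: .4f}")
        lines += [f"a       {self.params.a: .4f}",
                  f"w       {self.params.w: .4f}",
                  f"t0      {self.params.t0: .4f}",
                  f"log L   {self.params.log_likelihood: .2f}",
                  f"n       {self.n_trials}"]
        return "\n".join(lines)


class DriftDiffusionModel:
    """Single-subject diffusion model fitted by maximum likelihood.

    Drift is stimulus-coded (one free drift per asynchrony condition, applied
    with positive sign on right-synchronous trials and negative sign
    otherwise); boundary, start point and nondecision time are shared.
    """

    def __init__(self, trials: pd.DataFrame):
        df, rt, upper, stim, cond = _prep_trials(trials)
        if len(df) < 10:
            raise ValidationError("too few trials for a diffusion fit")
        if np.ptp(rt) < 1e-9:
            raise EstimationError("degenerate response times (zero variance)")
        if upper.all() or (~upper).all():
            raise EstimationError("both choice outcomes must be represented")
        self.conditions = sorted(pd.unique(cond))
        self._rt = rt
        self._upper = upper
        self._stim = stim
        self._cidx = np.searchsorted(self.conditions, cond)
        self._min_rt = float(rt.min())

    def _unpack(self, x):
        ncond = len(self.conditions)
        v = x[:ncond]
        a = np.exp(x[ncond])
        w = 1.0 / (1.0 + np.exp(-x[ncond + 1]))
        t0 = self._min_rt / (1.0 + np.exp(-x[ncond + 2]))
        return v, a, w, t0

    def _nll(self, x):
        v, a, w, t0 = self._unpack(x)
        drift = v[self._cidx] * self._stim
        ll = wiener_logpdf(self._rt, self._upper, drift, a, w, t0)
        return -float(ll.sum())

    def fit(self) -> DDMFitResults:
        ncond = len(self.conditions)
        starts = []
        for a0 in (1.5, 2.5):
            for t0_frac in (0.5, 0.9):
                x0 = np.concatenate([
                    np.full(ncond, 1.0),
                    [np.log(a0), 0.0, np.log(t0_frac / (1 - t0_frac))]])
                starts.append(x0)
        best = None
        for x0 in starts:
            res = minimize(self._nll, x0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-6, "fatol": 1e-6})
            if best is None or res.fun < best.fun:
                best = res
        v, a, w, t0 = self._unpack(best.x)
        params = DDMParams(v={c: float(vi) for c, vi in zip(self.conditions, v)},
                           a=float(a), w=float(w), t0=float(t0),
                           log_likelihood=float(-best.fun),
                           converged=bool(best.success))
        return DDMFitResults(params=params, n_trials=self._rt.size,
                             conditions=self.conditions)


# ---------------------------------------------------------------------------
# hierarchical MCMC group model


class HierarchicalDDMResults:
    """Posterior summaries of the hierarchical diffusion model."""

    def __init__(self, posterior: PosteriorSamples, conditions, n_subjects,
                 convergence_warning: bool):
        self.posterior = posterior
        self.conditions = list(conditions)
        self.n_subjects = n_subjects
        self.convergence_warning = convergence_warning

    def group_drift_mean(self, condition) -> float:
        return float(np.mean(self.posterior.stacked(f"mu_v[{condition}]")))

    def drift_ordering_posterior(self) -> float:
        """Posterior probability that group drift increases across the
        condition order (strictly monotone over all draws)."""
        draws = np.stack([self.posterior.stacked(f"mu_v[{c}]")
                          for c in self.conditions])
        return float(np.mean(np.all(np.diff(draws, axis=0) > 0, axis=0)))

    def summary(self) -> str:
        lines = ["Hierarchical diffusion fit",
                 "--------------------------",
                 f"subjects: {self.n_subjects}"]
        for c in self.conditions:
            d = self.posterior.stacked(f"mu_v[{c}]")
            rh = self.posterior.rhat[f"mu_v[{c}]"]
            lines.append(f"  drift v[{c}]: {d.mean():+.3f} (sd {d.std():.3f}, "
                         f"R-hat {rh:.3f})")
        for name in ("mu_log_a", "mu_logit_w", "mu_log_t0"):
            d = self.posterior.stacked(name)
            lines.append(f"  {name}: {d.mean():+.3f}")
        if self.convergence_warning:
            lines.append("  WARNING: R-hat above 1.02 on a group parameter")
        return "\n".join(lines)


class HierarchicalDDMModel:
    """Hierarchical diffusion model across subjects.

    Subject-level parameters (v per condition, log a, logit w, log t0) are
    drawn from Gaussian group distributions; the likelihood is the Wiener
    first-passage density.  Sampling: blocked adaptive Metropolis (one
    elementwise pass over the condition drifts, one joint block for
    a/w/t0 per subject), conjugate draws for the group means and slice
    sampling for the group spreads.  Chains are initialised by jittering the
    per-subject maximum-likelihood estimates.
    """

    MIN_TRIALS = 100

    def __init__(self, trials: pd.DataFrame, min_trials: int | None = None):
        min_trials = self.MIN_TRIALS if min_trials is None else min_trials
        df, rt, upper, stim, cond = _prep_trials(trials)
        self.subjects = sorted(df["subject"].unique())
        self.conditions = sorted(pd.unique(cond))
        counts = df.groupby("subject").size()
        low = counts[counts < min_trials]
        if len(low):
            raise ValidationError(
                f"subjects {list(low.index)} have fewer than {min_trials} uncensored trials")
        if np.ptp(rt) < 1e-9:
            raise EstimationError("degenerate response times (zero variance)")
        self._df = df
        self._rt = rt
        self._upper = upper
        self._stim = stim
        self._cidx = np.searchsorted(self.conditions, cond)
        self._sidx = np.searchsorted(self.subjects, df["subject"].to_numpy())
        self._min_rt_by_subj = np.array([
            rt[self._sidx == i].min() for i in range(len(self.subjects))])

    # subject parameter layout: [v_0..v_{C-1}, log a, logit w, log t0]
    def _subject_ll(self, theta: np.ndarray) -> np.ndarray:
        """Total log-likelihood per subject for parameter matrix
        theta (n_subjects, C+3)."""
        C = len(self.conditions)
        v = theta[self._sidx, self._cidx]
        a = np.exp(theta[self._sidx, C])
        w = 1.0 / (1.0 + np.exp(-theta[self._sidx, C + 1]))
        t0 = np.exp(theta[self._sidx, C + 2])
        ll = wiener_logpdf(self._rt, self._upper, v * self._stim, a, w, t0)
        return np.bincount(self._sidx, weights=ll, minlength=len(self.subjects))

    def _mle_start(self) -> np.ndarray:
        C = len(self.conditions)
        out = np.empty((len(self.subjects), C + 3))
        for i, s in enumerate(self.subjects):
            sub = self._df[self._df["subject"] == s]
            try:
                fit = DriftDiffusionModel(sub).fit()
                v = [fit.params.v.get(c, 1.0) for c in self.conditions]
                out[i] = np.concatenate([
                    v, [np.log(fit.params.a),
                        np.log(fit.params.w / (1 - fit.params.w)),
                        np.log(max(fit.params.t0, 1e-3))]])
            except (EstimationError, ValidationError):
                out[i] = np.concatenate([np.full(C, 1.0), [np.log(1.6), 0.0, np.log(0.3)]])
        return out

    def fit(self, mcmc: MCMCConfig | None = None) -> HierarchicalDDMResults:
        from .hmeta import _slice_sigma  # shared slice sampler

        mcmc = mcmc or MCMCConfig(iterations=2_000, burn_in=1_000)
        S = len(self.subjects)
        C = len(self.conditions)
        P = C + 3
        total = mcmc.burn_in + mcmc.iterations
        start = self._mle_start()
        rng = np.random.default_rng(mcmc.seed)

        keep = {f"mu_v[{c}]": [] for c in self.conditions}
        keep.update(mu_log_a=[], mu_logit_w=[], mu_log_t0=[])

        for chain in range(mcmc.chains):
            crng = np.random.default_rng((mcmc.seed, 7919, chain))
            theta = start + crng.normal(0, 0.08, start.shape)
            # keep t0 below each subject's fastest response
            theta[:, C + 2] = np.minimum(
                theta[:, C + 2], np.log(self._min_rt_by_subj * 0.95))
            mu = theta.mean(axis=0)
            sig = np.maximum(theta.std(axis=0), 0.1)
            step_v = np.full((S, C), 0.15)
            step_b = np.full(S, 0.08)
            kept = {k: np.empty(mcmc.iterations) for k in keep}

            def trial_ll(th):
                v = th[self._sidx, self._cidx]
                a = np.exp(th[self._sidx, C])
                w = 1.0 / (1.0 + np.exp(-th[self._sidx, C + 1]))
                t0 = np.exp(th[self._sidx, C + 2])
                return wiener_logpdf(self._rt, self._upper, v * self._stim,
                                     a, w, t0)

            ll_tr = trial_ll(theta)  # cached per-trial log-likelihood
            flat_sc = self._sidx * C + self._cidx

            for it in range(total):
                adapt = mcmc.adapt and it < mcmc.burn_in
                # 1) drifts: elementwise proposals (disjoint trial sets per
                # condition, so per-(subject, condition) acceptance is exact)
                prop = theta.copy()
                prop[:, :C] = theta[:, :C] + step_v * crng.standard_normal((S, C))
                ll_tr_new = trial_ll(prop)
                dll = np.bincount(flat_sc, weights=ll_tr_new - ll_tr,
                                  minlength=S * C).reshape(S, C)
                dprior = (-0.5 * ((prop[:, :C] - mu[:C]) ** 2
                                  - (theta[:, :C] - mu[:C]) ** 2) / sig[:C] ** 2)
                acc = np.log(crng.random((S, C))) < dll + dprior
                theta[:, :C] = np.where(acc, prop[:, :C], theta[:, :C])
                take = acc[self._sidx, self._cidx]
                ll_tr = np.where(take, ll_tr_new, ll_tr)
                if adapt:
                    step_v = np.clip(step_v * np.where(acc, 1.05, 0.975), 1e-3, 1.0)

                # 2) a / w / t0: joint 3-dim block per subject
                prop = theta.copy()
                prop[:, C:] = theta[:, C:] + step_b[:, None] * crng.standard_normal((S, 3))
                prop[:, C + 2] = np.minimum(prop[:, C + 2],
                                            np.log(self._min_rt_by_subj * 0.999))
                ll_tr_new = trial_ll(prop)
                dll_s = np.bincount(self._sidx, weights=ll_tr_new - ll_tr,
                                    minlength=S)
                dprior = (-0.5 * ((prop[:, C:] - mu[C:]) ** 2
                                  - (theta[:, C:] - mu[C:]) ** 2) / sig[C:] ** 2).sum(axis=1)
                acc_b = np.log(crng.random(S)) < dll_s + dprior
                theta[acc_b, C:] = prop[acc_b, C:]
                ll_tr = np.where(acc_b[self._sidx], ll_tr_new, ll_tr)
                if adapt:
                    step_b = np.clip(step_b * np.where(acc_b, 1.05, 0.975), 1e-3, 0.5)

                # 3) group means (conjugate, diffuse prior N(0, 10^2))
                prec = S / sig ** 2 + 1.0 / 100.0
                mean = theta.sum(axis=0) / sig ** 2 / prec
                mu = mean + crng.standard_normal(P) / np.sqrt(prec)

                # 4) group spreads (slice sampling, half-Normal(1) prior)
                ssq = ((theta - mu) ** 2).sum(axis=0)
                sig = _slice_sigma(crng, sig, ssq, float(S))
                sig = np.maximum(sig, 0.02)

                # 5) non-centred translation of each drift's group mean with
                # its subject effects (condition trial sets are disjoint, so
                # one likelihood pass serves all conditions)
                eps_v = 0.05 * crng.standard_normal(C)
                prop = theta.copy()
                prop[:, :C] = theta[:, :C] + eps_v[None, :]
                ll_tr_new = trial_ll(prop)
                dll_c = np.bincount(self._cidx, weights=ll_tr_new - ll_tr,
                                    minlength=C)
                mu_p = mu[:C] + eps_v
                lp_t = dll_c - 0.5 * (mu_p ** 2 - mu[:C] ** 2) / 100.0
                acc_t = np.log(crng.random(C)) < lp_t
                theta[:, :C] = np.where(acc_t[None, :], prop[:, :C], theta[:, :C])
                ll_tr = np.where(acc_t[self._cidx], ll_tr_new, ll_tr)
                mu[:C] = np.where(acc_t, mu_p, mu[:C])

                # 6) joint translation of the a/w/t0 group block
                eps_b = 0.04 * crng.standard_normal(3)
                prop = theta.copy()
                prop[:, C:] = theta[:, C:] + eps_b
                if np.all(np.exp(prop[:, C + 2]) < self._min_rt_by_subj):
                    ll_tr_new = trial_ll(prop)
                    dll = float((ll_tr_new - ll_tr).sum())
                    mu_bp = mu[C:] + eps_b
                    lp_b = dll - 0.5 * ((mu_bp ** 2 - mu[C:] ** 2) / 100.0).sum()
                    if np.log(crng.random()) < lp_b:
                        theta = prop
                        ll_tr = ll_tr_new
                        mu[C:] = mu_bp

                if it >= mcmc.burn_in:
                    j = it - mcmc.burn_in
                    for c_i, c in enumerate(self.conditions):
                        kept[f"mu_v[{c}]"][j] = mu[c_i]
                    kept["mu_log_a"][j] = mu[C]
                    kept["mu_logit_w"][j] = mu[C + 1]
                    kept["mu_log_t0"][j] = mu[C + 2]

            for k in keep:
                keep[k].append(kept[k])

        draws = {k: np.stack(v) for k, v in keep.items()}
        post = PosteriorSamples(draws=draws, burn_in=mcmc.burn_in)
        max_rhat = post.max_rhat(prefix="mu_v[")
        warn = bool(max_rhat > 1.02)
        if warn:
            warnings.warn(f"group drift R-hat {max_rhat:.3f} > 1.02",
                          RuntimeWarning)
        return HierarchicalDDMResults(post, self.conditions, S, warn)


def fit_hddm(trials: pd.DataFrame, mcmc: MCMCConfig | None = None) -> HierarchicalDDMResults:
    """Fit the hierarchical diffusion model (module-level wrapper)."""
    return HierarchicalDDMModel(trials).fit(mcmc)


# ---------------------------------------------------------------------------
# v-ratio: joint decision + post-decisional confidence model


@dataclass
class VRatioResults:
    """Joint decision/confidence fit with the v-ratio efficiency index."""

    params: DDMParams
    cutpoints: tuple
    n_trials: int
    by_condition: pd.DataFrame | None = None

    @property
    def vratio(self) -> float:
        return self.params.vratio

    def summary(self) -> str:
        lines = ["v-ratio fit (decision + post-decisional accumulation)",
                 "-----------------------------------------------------"]
        for c, vi in self.params.v.items():
            lines.append(f"v[{c}]     {vi: .4f}")
        lines += [f"a         {self.params.a: .4f}",
                  f"w         {self.params.w: .4f}",
                  f"t0        {self.params.t0: .4f}",
                  f"v_post    {self.params.v_post: .4f}",
                  f"v-ratio   {self.params.vratio: .4f}",
                  f"log L     {self.params.log_likelihood: .2f}",
                  f"n         {self.n_trials}"]
        return "\n".join(lines)


class VRatioModel:
    """Joint fit of the decision diffusion and the post-decisional
    confidence accumulator for one subject.

    The decision stage contributes the Wiener first-passage likelihood of
    (choice, decision RT); the confidence stage contributes the probability
    of the observed PAS rating given trial correctness and the observed
    post-decision interval tau (capped at the 3-s rating window): the
    post-decisional evidence toward the chosen boundary is Gaussian with
    mean +/- v_post * tau (positive after correct decisions) and variance
    tau, cut at two fitted thresholds.

    ``pooled=True`` fits a single decision drift; otherwise one drift per
    condition, with v-ratio = v_post / mean drift magnitude.
    """

    PAS_WINDOW_S = 3.0

    def __init__(self, trials: pd.DataFrame, pooled: bool = True):
        df, rt, upper, stim, cond = _prep_trials(trials)
        pas = df["pas"].to_numpy(int)
        if len(np.unique(pas)) < 2:
            raise EstimationError(
                "PAS constant across trials: post-decisional drift unidentifiable")
        if np.ptp(rt) < 1e-9:
            raise EstimationError("degenerate response times (zero variance)")
        self.pooled = pooled
        self.conditions = [0] if pooled else sorted(pd.unique(cond))
        self._cidx = (np.zeros(len(df), int) if pooled
                      else np.searchsorted(self.conditions, cond))
        self._rt = rt
        self._upper = upper
        self._stim = stim
        self._pas = pas
        self._correct = (upper == (stim > 0))
        self._tau = np.clip(df["rt_postdecision_s"].to_numpy(float),
                            1e-3, self.PAS_WINDOW_S)
        self._min_rt = float(rt.min())

    def _unpack(self, x):
        C = len(self.conditions)
        v = x[:C]
        a = np.exp(x[C])
        w = 1.0 / (1.0 + np.exp(-x[C + 1]))
        t0 = self._min_rt / (1.0 + np.exp(-x[C + 2]))
        v_post = x[C + 3]
        k1 = x[C + 4]
        k2 = k1 + np.exp(x[C + 5])
        return v, a, w, t0, v_post, k1, k2

    def _confidence_ll(self, v_post, k1, k2):
        mu = np.where(self._correct, 1.0, -1.0) * v_post * self._tau
        sd = np.sqrt(self._tau)
        p1 = ndtr((k1 - mu) / sd)
        p2 = ndtr((k2 - mu) / sd) - p1
        p3 = 1.0 - p1 - p2
        probs = np.stack([p1, p2, p3])
        p_obs = probs[self._pas - 1, np.arange(self._pas.size)]
        return np.log(np.clip(p_obs, 1e-12, None)).sum()

    def _nll(self, x):
        v, a, w, t0, v_post, k1, k2 = self._unpack(x)
        drift = v[self._cidx] * self._stim
        ll = wiener_logpdf(self._rt, self._upper, drift, a, w, t0).sum()
        ll += self._confidence_ll(v_post, k1, k2)
        return -float(ll)

    def fit(self) -> VRatioResults:
        C = len(self.conditions)
        starts = []
        for vp0 in (0.2, 1.0):
            starts.append(np.concatenate([
                np.full(C, 1.0),
                [np.log(1.6), 0.0, 0.0, vp0, -0.3, np.log(1.0)]]))
        best = None
        for x0 in starts:
            res = minimize(self._nll, x0, method="Nelder-Mead",
                           options={"maxiter": 6000, "xatol": 1e-6, "fatol": 1e-6})
            if best is None or res.fun < best.fun:
                best = res
        v, a, w, t0, v_post, k1, k2 = self._unpack(best.x)
        v_mag = float(np.mean(np.abs(v)))
        params = DDMParams(
            v={c: float(vi) for c, vi in zip(self.conditions, v)},
            a=float(a), w=float(w), t0=float(t0),
            v_post=float(v_post),
            vratio=float(v_post / v_mag) if v_mag > 1e-9 else np.nan,
            log_likelihood=float(-best.fun), converged=bool(best.success))
        return VRatioResults(params=params, cutpoints=(float(k1), float(k2)),
                             n_trials=self._rt.size)


def fit_vratio(trials: pd.DataFrame, pooled: bool = True) -> VRatioResults:
    """Fit the joint decision + confidence model and return the v-ratio."""
    return VRatioModel(trials, pooled=pooled).fit()
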