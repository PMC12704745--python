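"""Synthetic observers for the two-rubber-hand ownership paradigm.

Two generative models are provided, matching the assumptions of the
downstream analyses exactly:

* an equal-variance Gaussian SDT observer whose 2AFC choice is driven by a
  unit-variance evidence sample and whose PAS rating is driven by a second,
  noisier sample calibrated to a target metacognitive efficiency (M-ratio);
* a Wiener diffusion observer whose choice and decision time are the first
  passage of an evidence accumulator, followed by a post-decisional
  accumulation stage that is thresholded into the PAS rating (the v-ratio
  generative model).

Both are deterministic given their seed, which makes every fitting routine
in the package testable by closed-loop parameter recovery.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from .design import (
    ConfigurationError,
    DDMObserverParams,
    DesignSpec,
    QuestionnaireScores,
    SDTObserverParams,
)

__all__ = [
    "simulate_sdt_dataset",
    "simulate_ddm_trials",
    "simulate_ddm_dataset",
    "inclusion_filter",
    "TRIAL_COLUMNS",
]

#: Canonical column order of the trial table (the package's single
#: data-interchange schema).
TRIAL_COLUMNS = [
    "subject",
    "experiment",
    "asynchrony_ms",
    "n_touches",
    "sync_side",
    "response_side",
    "pas",
    "rt_decision_s",
    "rt_postdecision_s",
    "censored",
]

_SQRT2 = np.sqrt(2.0)


def _confidence_sample(rng, resp_sign, stim_sign, delta, m, theta, eps=1e-12):
    """Response-consistent metacognitive evidence sample.

    The confidence system takes a second look at the stimulus on a meta
    evidence axis with sensitivity ``m * delta`` (unit variance) and with
    the type-1 criterion mapped to its equivalent relative position
    theta_m = (theta/delta) * (m * delta).  The sample is drawn conditioned
    on falling on the side of theta_m that matches the committed response -
    the metacognitive read-out never contradicts the decision, it only
    grades it.  This is the exact generative counterpart of the meta-d'
    observer: refitting recovers meta-d' = m * d' for any m > 0.
    """
    delta_m = m * delta
    theta_m = (theta / delta) * delta_m if abs(delta) > 1e-9 else theta
    mu = stim_sign * delta_m / 2.0
    lo = norm.cdf(theta_m - mu)          # mass below the meta criterion
    u = rng.random(resp_sign.shape[0])
    right = resp_sign > 0
    q = np.where(right, lo + u * np.clip(1.0 - lo, eps, None),
                 u * np.clip(lo, eps, None))
    y = mu + norm.ppf(np.clip(q, eps, 1.0 - eps))
    return y, theta_m


def simulate_sdt_dataset(design: DesignSpec, params: SDTObserverParams,
                         seed: int | None = None, experiment: str = "exp1") -> pd.DataFrame:
    """Simulate a full trial table from the equal-variance SDT observer.

    On each trial the synchronously tapped side is drawn at random; the
    decision evidence is X ~ N(s * delta / 2, 1) with s = +1 when the right
    hand is synchronous and delta = sqrt(2) * d' (so that the 2AFC-convention
    estimate (1/sqrt2)[Z(PH) - Z(PF)] recovers the nominal d').  The observer
    responds "right" when X exceeds the criterion; the criterion equals the
    bias index C = -(1/2)[Z(PH) + Z(PF)].  The PAS rating is read from a
    second evidence sample (see :func:`_confidence_sample`) measured toward
    the chosen side and cut at ``params.type2_criteria``.

    Lapses replace both the choice and the rating with uniform draws.
    """
    dmap = dict(params.dprime_by_condition)
    for cond in design.conditions:
        if cond not in dmap:
            raise ConfigurationError(f"no d' specified for condition {cond}")
    extra = set(dmap) - set(design.conditions)
    if extra:
        raise ConfigurationError(f"conditions {sorted(extra)} absent from design")

    rng = np.random.default_rng(design.seed if seed is None else seed)
    c = params.criterion_c
    m = params.mratio_true
    t1, t2 = params.type2_criteria
    npc = design.trials_per_condition

    frames = []
    for subj in range(1, design.n_subjects + 1):
        for (a_ms, n_touch) in design.conditions:
            delta = _SQRT2 * dmap[(a_ms, n_touch)]
            stim = rng.choice([-1, 1], npc)  # +1: right hand synchronous
            x = rng.normal(stim * delta / 2.0, 1.0)
            resp = np.where(x > c, 1, -1)
            y, theta_m = _confidence_sample(rng, resp, stim, delta, m, c)
            ev = resp * (y - theta_m)
            pas = 1 + (ev > t1).astype(int) + (ev > t2).astype(int)
            if params.lapse_rate > 0:
                lapse = rng.random(npc) < params.lapse_rate
                resp = np.where(lapse, rng.choice([-1, 1], npc), resp)
                pas = np.where(lapse, rng.integers(1, 4, npc), pas)
            rt1 = np.clip(rng.lognormal(np.log(1.1), 0.35, npc), 0.15, 3.0)
            rt2 = np.clip(rng.lognormal(np.log(0.8), 0.35, npc), 0.15, 3.0)
            frames.append(pd.DataFrame({
                "subject": subj,
                "experiment": experiment,
                "asynchrony_ms": a_ms,
                "n_touches": n_touch,
                "sync_side": np.where(stim > 0, "right", "left"),
                "response_side": np.where(resp > 0, "right", "left"),
                "pas": pas,
                "rt_decision_s": np.round(rt1, 6),
                "rt_postdecision_s": np.round(rt2, 6),
                "censored": False,
            }))
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def _euler_first_passage(rng, drift, boundary, start, dt, max_t, scale=1.0):
    """Euler-Maruyama first passage through {0, boundary} for a batch of
    trials with per-trial drift.  Returns (upper_hit, rt, absorbed, x_final).

    Within-step boundary crossings are resolved with the Brownian-bridge
    correction (a step from x to x' that stays inside still crosses with
    probability exp(-2 d d'/(s^2 dt)), d and d' the distances to the
    boundary), removing the leading overshoot bias of naive Euler.
    """
    n = drift.shape[0]
    x = np.full(n, start * boundary)
    rt = np.full(n, np.nan)
    upper = np.zeros(n, dtype=bool)
    active = np.arange(n)
    s2dt = (scale ** 2) * dt
    sqdt = np.sqrt(dt) * scale
    n_steps = int(np.ceil(max_t / dt))
    for step in range(1, n_steps + 1):
        if active.size == 0:
            break
        x_prev = x[active]
        x_new = x_prev + drift[active] * dt + sqdt * rng.standard_normal(active.size)
        hit_up = x_new >= boundary
        hit_lo = x_new <= 0.0
        inside = ~(hit_up | hit_lo)
        if inside.any():
            d_up = (boundary - x_prev[inside]) * (boundary - x_new[inside])
            d_lo = x_prev[inside] * x_new[inside]
            u = rng.random(int(inside.sum()))
            bridge_up = u < np.exp(-2.0 * d_up / s2dt)
            bridge_lo = (~bridge_up) & (rng.random(int(inside.sum()))
                                        < np.exp(-2.0 * d_lo / s2dt))
            hit_up[inside] = bridge_up
            hit_lo[inside] = bridge_lo
        done = hit_up | hit_lo
        x[active] = x_new
        if done.any():
            idx = active[done]
            rt[idx] = step * dt
            upper[idx] = hit_up[done]
            x[idx] = np.where(hit_up[done], boundary, 0.0)
            active = active[~done]
    absorbed = ~np.isnan(rt)
    return upper, rt, absorbed, x


def simulate_ddm_trials(params: DDMObserverParams, n_trials: int, seed: int,
                        design: DesignSpec | None = None, dt: float = 0.001,
                        experiment: str = "exp3") -> pd.DataFrame:
    """Simulate speeded trials from the diffusion observer.

    ``n_trials`` is interpreted per condition in ``params.drift_by_condition``.
    The accumulator starts at ``start_point * boundary`` and drifts with
    ``+v`` when the right hand is the synchronous one and ``-v`` otherwise;
    the upper boundary codes a "right" response.  First passage is simulated
    by Euler-Maruyama integration (default step 1 ms).  Trials that do not
    terminate within ``max_stim_duration_s`` (design, or 30 s) are flagged
    censored with the response read from the current evidence sign.

    The post-decisional stage draws the exact Gaussian increment of a
    boundary-free accumulation of ``postdecision_duration`` seconds with
    drift ``postdecision_drift`` keeping the stimulus-defined sign; measured
    toward the chosen boundary it yields evidence that favours the choice
    after correct decisions and contradicts it after errors, which is what
    makes the PAS rating informative.
    """
    if n_trials <= 0:
        raise ConfigurationError("n_trials must be positive")
    conds = list(dict(params.drift_by_condition).items())
    if not conds:
        raise ConfigurationError("drift_by_condition is empty")
    max_t = design.max_stim_duration_s if design is not None else 30.0
    rng = np.random.default_rng(seed)
    a = params.boundary
    s = params.diffusion_scale
    tau = params.postdecision_duration
    c1, c2 = params.confidence_cutpoints

    frames = []
    for cond, v in conds:
        if isinstance(cond, tuple):
            a_ms, n_touch = cond
        else:
            a_ms, n_touch = cond, 15
        stim = rng.choice([-1, 1], n_trials)
        drift = stim * v
        upper, rt, absorbed, x_final = _euler_first_passage(
            rng, drift, a, params.start_point, dt, max_t, scale=s)
        censored = ~absorbed
        if censored.any():
            # score unfinished trials by the evidence sign at cutoff
            mid = a * params.start_point
            forced = x_final[censored] > mid
            tie = x_final[censored] == mid
            if tie.any():
                forced = forced.copy()
                forced[tie] = rng.random(int(tie.sum())) < 0.5
            upper[censored] = forced
            rt[censored] = max_t
        resp = np.where(upper, 1, -1)
        # exact post-decisional increment (no absorbing barrier)
        inc = rng.normal(stim * params.postdecision_drift * tau,
                         s * np.sqrt(tau), n_trials)
        ev = resp * inc
        pas = 1 + (ev > c1).astype(int) + (ev > c2).astype(int)
        frames.append(pd.DataFrame({
            "subject": 1,
            "experiment": experiment,
            "asynchrony_ms": a_ms,
            "n_touches": n_touch,
            "sync_side": np.where(stim > 0, "right", "left"),
            "response_side": np.where(resp > 0, "right", "left"),
            "pas": pas,
            "rt_decision_s": np.round(rt + params.nondecision_t0, 6),
            "rt_postdecision_s": np.round(np.minimum(tau, 3.0), 6),
            "censored": censored,
        }))
    out = pd.concat(frames, ignore_index=True)
    return out[TRIAL_COLUMNS]


def simulate_ddm_dataset(params: DDMObserverParams, n_subjects: int,
                         trials_per_condition: int, seed: int,
                         design: DesignSpec | None = None, dt: float = 0.001,
                         experiment: str = "exp3") -> pd.DataFrame:
    """Multi-subject trial table from the diffusion observer (independent
    streams per subject, all reproducible from the base seed)."""
    streams = np.random.SeedSequence(seed).spawn(n_subjects)
    frames = []
    for i, ss in enumerate(streams, start=1):
        sub = simulate_ddm_trials(params, trials_per_condition,
                                  seed=ss.generate_state(1)[0] % (2 ** 31),
                                  design=design, dt=dt, experiment=experiment)
        sub["subject"] = i
        frames.append(sub)
    return pd.concat(frames, ignore_index=True)


def inclusion_filter(q: QuestionnaireScores) -> bool:
    """Questionnaire-based inclusion rule for illusion responders.

    A participant is included when (a) the mean of the three ownership items
    exceeds 1 and (b) the ownership mean exceeds the control-item mean by
    more than 1.
    """
    own = float(np.mean(q.ownership_items))
    ctrl = float(np.mean(q.control_items))
    return bool(own > 1.0 and (own - ctrl) > 1.0)
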