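"""Meta-d' by maximum likelihood: type-2 sensitivity in d' units.

The meta-d' model asks what type-1 sensitivity an SDT-ideal observer would
need in order to produce the observed confidence-rating counts, holding the
type-1 criterion at its observed *relative* position c' = c/d'.  The free
parameters are meta-d' and the response-conditional type-2 criteria (a
single meta-d' shared across response sides); the fit maximises the
multinomial likelihood of the rating counts conditional on the response.
M-ratio = meta-d'/d' is the resulting efficiency index (1 = every bit of
decision information reaches the awareness report).

All sensitivities are reported in the 2AFC convention used by the rest of
the package (internal evidence separation = sqrt(2) * d'); M-ratio is
invariant to that scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .sdt import CountTable, EstimationError, dprime_2afc

__all__ = ["MetaDModel", "MetaDResults", "fit_metad", "metad_log_likelihood",
           "rating_probabilities"]

_SQRT2 = np.sqrt(2.0)
_TINY = 1e-300


def _criteria_from_theta(theta_m: float, taus: np.ndarray, n_ratings: int) -> np.ndarray:
    """Full ascending criterion vector from the meta type-1 criterion and
    positive offsets (taus = [left offsets outward, right offsets outward])."""
    k = n_ratings - 1
    left = theta_m - np.cumsum(taus[:k])
    right = theta_m + np.cumsum(taus[k:])
    return np.concatenate([left[::-1], [theta_m], right])


def rating_probabilities(meta_d_internal: float, c_prime: float, taus: np.ndarray,
                         n_ratings: int = 3) -> np.ndarray:
    """P(rating | response, stimulus) under the meta-level model.

    Returns an array of shape (stimulus: left/right-sync, response:
    left/right, rating) whose entries are the response-conditional rating
    probabilities; each (stimulus, response) slice sums to one.
    """
    theta_m = c_prime * meta_d_internal
    crit = _criteria_from_theta(theta_m, taus, n_ratings)
    mus = np.array([-0.5, 0.5]) * meta_d_internal  # stimulus left/right sync
    edges = np.concatenate([[-np.inf], crit, [np.inf]])
    cdf = ndtr(edges[None, :] - mus[:, None])          # (stim, edge)
    bins = np.diff(cdf, axis=1)                        # 2*n_ratings bins
    p_left = np.clip(ndtr(theta_m - mus), _TINY, None)
    p_right = np.clip(1.0 - ndtr(theta_m - mus), _TINY, None)
    out = np.empty((2, 2, n_ratings))
    # ascending bins below theta_m are left responses rated n..1
    out[:, 0, :] = bins[:, :n_ratings][:, ::-1] / p_left[:, None]
    out[:, 1, :] = bins[:, n_ratings:] / p_right[:, None]
    return out


def _counts_by_stim(type2: np.ndarray) -> np.ndarray:
    """Reindex (response, correctness, rating) counts to (stimulus, response,
    rating), stimulus 0 = left synchronous, 1 = right synchronous."""
    n = np.zeros_like(type2)
    n[1, 1] = type2[1, 1]   # right sync, right resp  (hits)
    n[0, 1] = type2[1, 0]   # left sync, right resp   (false alarms)
    n[0, 0] = type2[0, 1]   # left sync, left resp    (correct rejections)
    n[1, 0] = type2[0, 0]   # right sync, left resp   (misses)
    return n


def metad_log_likelihood(meta_d_internal: float, taus: np.ndarray,
                         counts_by_stim: np.ndarray, c_prime: float,
                         n_ratings: int = 3) -> float:
    """Multinomial log-likelihood of the rating counts (response-conditional)."""
    p = rating_probabilities(meta_d_internal, c_prime, taus, n_ratings)
    return float(np.sum(counts_by_stim * np.log(np.clip(p, _TINY, None))))


@dataclass
class MetaDResults:
    """Fit results of :class:`MetaDModel`.

    ``meta_dprime`` and ``dprime`` are in the 2AFC convention; the type-2
    criteria are on the internal (unscaled) evidence axis.
    """

    meta_dprime: float
    dprime: float
    mratio: float
    type1_c_prime: float
    criterion_c: float
    type2_criteria_left: tuple
    type2_criteria_right: tuple
    log_likelihood: float
    converged: bool
    n_trials: int
    n_ratings: int = 3

    def predicted_probabilities(self) -> np.ndarray:
        taus = np.concatenate([
            np.diff(np.concatenate([[self.type1_c_prime * self.meta_dprime * _SQRT2],
                                    list(self.type2_criteria_left)])) * -1,
            np.diff(np.concatenate([[self.type1_c_prime * self.meta_dprime * _SQRT2],
                                    list(self.type2_criteria_right)])),
        ])
        return rating_probabilities(self.meta_dprime * _SQRT2, self.type1_c_prime,
                                    taus, self.n_ratings)

    def summary(self) -> str:
        lines = [
            "Meta-d' maximum-likelihood fit",
            "------------------------------",
            f"d'            {self.dprime: .4f}",
            f"meta-d'       {self.meta_dprime: .4f}",
            f"M-ratio       {self.mratio: .4f}",
            f"type-1 c'     {self.type1_c_prime: .4f}",
            f"log L         {self.log_likelihood: .4f}",
            f"converged     {self.converged}",
            f"n trials      {self.n_trials}",
        ]
        return "\n".join(lines)


class MetaDModel:
    """Maximum-likelihood meta-d' model for one subject x condition cell.

    Parameters
    ----------
    counts
        :class:`~bodymeta.sdt.CountTable` with type-2 counts.
    n_ratings
        Number of confidence levels (3 for the PAS).
    pad
        Add 1/(2 * n_ratings) to every type-2 cell before fitting, keeping
        the likelihood finite when cells are empty (standard practice).
    """

    def __init__(self, counts: CountTable, n_ratings: int = 3, pad: bool = True):
        self.counts = counts
        self.n_ratings = n_ratings
        self.pad = pad
        t2 = np.asarray(counts.type2, dtype=float)
        incorrect = t2[:, 0, :].sum()
        if incorrect == 0 and not pad:
            raise EstimationError(
                "no incorrect trials: type-2 sensitivity is unidentifiable without padding")
        if pad:
            t2 = t2 + 1.0 / (2.0 * n_ratings)
        self._counts_stim = _counts_by_stim(t2)
        self._type1 = dprime_2afc(counts)
        d_internal = self._type1.dprime * _SQRT2
        if abs(d_internal) < 1e-8:
            # relative criterion undefined at d'=0; fall back to absolute c
            self._c_prime = 0.0
        else:
            self._c_prime = self._type1.criterion_c / d_internal

    def loglike(self, meta_d_2afc: float, taus) -> float:
        return metad_log_likelihood(meta_d_2afc * _SQRT2, np.asarray(taus, float),
                                    self._counts_stim, self._c_prime, self.n_ratings)

    def _nll(self, x: np.ndarray) -> float:
        meta_d = x[0]
        taus = np.exp(x[1:])
        return -metad_log_likelihood(meta_d, taus, self._counts_stim,
                                     self._c_prime, self.n_ratings)

    def fit(self) -> MetaDResults:
        d_int = self._type1.dprime * _SQRT2
        k = self.n_ratings - 1
        # deterministic multi-start: spread over plausible efficiency levels
        frac_starts = (1.0, 0.6, 0.3, 1.3, 0.05)
        base = d_int if abs(d_int) > 0.2 else 1.0
        best = None
        for frac in frac_starts:
            x0 = np.concatenate([[base * frac], np.log(np.full(2 * k, 0.5))])
            res = minimize(self._nll, x0, method="L-BFGS-B",
                           bounds=[(-10, 10)] + [(-12, 3)] * (2 * k))
            cand = (res.fun, abs(res.x[0]), res)
            if best is None or cand[:2] < best[:2]:
                best = cand
        res = best[2]
        meta_d_int = float(res.x[0])
        taus = np.exp(res.x[1:])
        theta_m = self._c_prime * meta_d_int
        left = tuple(theta_m - np.cumsum(taus[:k]))
        right = tuple(theta_m + np.cumsum(taus[k:]))
        dprime = self._type1.dprime
        meta_d = meta_d_int / _SQRT2
        return MetaDResults(
            meta_dprime=meta_d,
            dprime=dprime,
            mratio=float(meta_d / dprime) if dprime != 0 else np.nan,
            type1_c_prime=self._c_prime,
            criterion_c=self._type1.criterion_c,
            type2_criteria_left=left,
            type2_criteria_right=right,
            log_likelihood=float(-res.fun),
            converged=bool(res.success),
            n_trials=self.counts.n_trials,
            n_ratings=self.n_ratings,
        )


def fit_metad(counts: CountTable, n_ratings: int = 3, pad: bool = True) -> MetaDResults:
    """Convenience wrapper: fit the meta-d' model to one count table."""
    return MetaDModel(counts, n_ratings=n_ratings, pad=pad).fit()
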