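"""Posterior-sample container and convergence diagnostics.

Shared by the hierarchical M-ratio model and the hierarchical drift-diffusion
model.  Draws are stored per parameter as (chain, draw) arrays; R-hat and
effective sample size come from arviz (rank-normalised split R-hat).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ConfigurationError

__all__ = ["PosteriorSamples", "hdi", "MCMCConfig"]


def hdi(samples: np.ndarray, prob: float = 0.95) -> tuple:
    """Highest-density interval of a unimodal sample (shortest interval
    containing ``prob`` of the draws)."""
    x = np.sort(np.ravel(samples))
    n = x.size
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m])


@dataclass(frozen=True)
class MCMCConfig:
    """Sampler settings (defaults follow the study configuration: three
    chains of 10,000 kept iterations after 1,000 burn-in)."""

    chains: int = 3
    iterations: int = 10_000
    burn_in: int = 1_000
    seed: int = 0
    adapt: bool = True

    def __post_init__(self):
        if self.chains < 2:
            raise ConfigurationError(
                "at least two chains are required for convergence diagnostics")
        if self.iterations <= 0 or self.burn_in < 0:
            raise ConfigurationError("iterations must be positive, burn_in nonnegative")

    @classmethod
    def scaled_down(cls, seed: int = 0) -> "MCMCConfig":
        """Light configuration for iteration-heavy test runs."""
        return cls(chains=3, iterations=2_000, burn_in=500, seed=seed)


@dataclass
class PosteriorSamples:
    """Labelled MCMC draws with chain structure.

    ``draws`` maps parameter name -> array of shape (chain, draw), burn-in
    already removed.
    """

    draws: dict
    burn_in: int = 0
    _rhat: dict = field(default_factory=dict, repr=False)
    _ess: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        for name, arr in self.draws.items():
            arr = np.asarray(arr)
            if arr.ndim != 2:
                raise ConfigurationError(f"draws for {name!r} must be (chain, draw)")
            if arr.shape[0] < 2:
                raise ConfigurationError(
                    "at least two chains are required for convergence diagnostics")
            if not np.all(np.isfinite(arr)):
                raise ConfigurationError(f"non-finite draws for {name!r}")
            self.draws[name] = arr

    @property
    def parameters(self) -> list:
        return list(self.draws)

    def stacked(self, name: str) -> np.ndarray:
        return np.ravel(self.draws[name])

    def _diagnostics(self) -> None:
        if self._rhat:
            return
        import arviz as az
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for name, arr in self.draws.items():
                self._rhat[name] = float(az.rhat(arr))
                self._ess[name] = float(az.ess(arr))

    @property
    def rhat(self) -> dict:
        self._diagnostics()
        return dict(self._rhat)

    @property
    def ess(self) -> dict:
        self._diagnostics()
        return dict(self._ess)

    def max_rhat(self, prefix: str | None = None) -> float:
        r = self.rhat
        vals = [v for k, v in r.items() if prefix is None or k.startswith(prefix)]
        return float(np.nanmax(vals))

    def hdi(self, name: str, prob: float = 0.95) -> tuple:
        return hdi(self.stacked(name), prob)

    def to_dataframe(self) -> pd.DataFrame:
        """Columnar text-friendly layout with chain/iteration columns."""
        any_arr = next(iter(self.draws.values()))
        n_chain, n_draw = any_arr.shape
        out = {
            "chain": np.repeat(np.arange(n_chain), n_draw),
            "iteration": np.tile(np.arange(n_draw), n_chain),
        }
        for name, arr in self.draws.items():
            out[name] = np.ravel(arr)
        return pd.DataFrame(out)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, burn_in: int = 0) -> "PosteriorSamples":
        chains = np.sort(df["chain"].unique())
        names = [c for c in df.columns if c not in ("chain", "iteration")]
        draws = {}
        for name in names:
            draws[name] = np.stack([
                df.loc[df["chain"] == ch, name].to_numpy() for ch in chains])
        return cls(draws=draws, burn_in=burn_in)
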