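"""Basic diagnostic plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .mcmc import PosteriorSamples  # noqa: E402

__all__ = ["plot_trace", "plot_posterior", "plot_rt_distribution"]


def plot_trace(post: PosteriorSamples, name: str, path=None):
    """Per-chain trace of one posterior parameter."""
    fig, ax = plt.subplots(figsize=(7, 2.5))
    for i, chain in enumerate(post.draws[name]):
        ax.plot(chain, lw=0.5, label=f"chain {i}")
    ax.set_xlabel("iteration")
    ax.set_ylabel(name)
    ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_posterior(post: PosteriorSamples, name: str, path=None, prob=0.95):
    """Histogram of pooled draws with the HDI marked."""
    x = post.stacked(name)
    lo, hi = post.hdi(name, prob)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.hist(x, bins=60, density=True, color="steelblue", alpha=0.8)
    ax.axvspan(lo, hi, color="orange", alpha=0.25,
               label=f"{int(prob * 100)}% HDI")
    ax.set_xlabel(name)
    ax.legend(fontsize=8)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_rt_distribution(trials, path=None, by="asynchrony_ms"):
    """Decision response-time histograms per condition."""
    fig, ax = plt.subplots(figsize=(5, 3))
    for cond, sub in trials[~trials["censored"]].groupby(by):
        ax.hist(sub["rt_decision_s"], bins=np.linspace(0, 10, 60),
                histtype="step", label=f"{by}={cond}", density=True)
    ax.set_xlabel("decision RT (s)")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return fig
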