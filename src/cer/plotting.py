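"""Lag-profile plots: ER frequency against delay with the detection
threshold drawn as a dotted line. Plots are an optional convenience; no
analysis depends on them."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import BidirectionalScan, ERProfile, upper_limit

__all__ = ["plot_profile", "plot_scan"]


def plot_profile(profile: ERProfile, ax=None, title: str | None = None):
    """One-direction lag profile: frequency of joint events per lag, with
    the zero-lag-derived upper detection limit."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.bar(profile.lags, profile.frequencies, width=0.8, color="steelblue")
    ax.axhline(profile.upper_frequency, linestyle=":", color="black",
               label=f"upper limit (alpha={profile.alpha})")
    cause, effect = profile.direction
    ax.set_xlabel("delay (samples)")
    ax.set_ylabel("ER frequency")
    ax.set_title(title or f"{cause} → {effect}")
    ax.legend(fontsize=8)
    return ax


def plot_scan(scan: BidirectionalScan, ax=None, title: str | None = None):
    """Bidirectional profile over lags ``-tau_max..tau_max``; negative lags
    carry the reverse direction, so mass right of zero means the first
    channel leads."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    lags, counts = scan.combined_profile()
    n = scan.forward.n
    freqs = counts / (n - np.abs(lags))
    ax.bar(lags, freqs, width=0.8, color="steelblue")
    thr = upper_limit(scan.forward.k0, scan.forward.alpha, n_eff=n)[1]
    ax.axhline(thr, linestyle=":", color="black",
               label=f"upper limit (alpha={scan.forward.alpha})")
    cause, effect = scan.forward.direction
    ax.set_xlabel(f"delay (samples); positive = {cause} leads")
    ax.set_ylabel("ER frequency")
    ax.set_title(title or f"{cause} ⇄ {effect}")
    ax.legend(fontsize=8)
    return ax


def save_figure(ax, path: str | Path) -> None:
    ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
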