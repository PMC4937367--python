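"""Monte-Carlo evaluation of the CER test, plus stationarity diagnostics.

Each simulated replicate of a two-node scenario is scanned in both
directions and classified into one of six mutually exclusive outcomes:

- ``strongly_correct`` — detection in the true direction with every
  flagged lag inside the designed delay support;
- ``weakly_correct`` — detection in the true direction, but some flagged
  lag falls outside the support (right direction, blurred delay);
- ``missing_detection`` — causal pair, no detection either way;
- ``error_type_I`` — detection in the wrong direction (dominates any
  correct-direction finding, so the categories stay exclusive);
- ``error_type_II`` — detection on a truly non-causal pair;
- ``true_negative`` — non-causal pair, correctly silent.

The first four apply to causal ground truth, the last two to matched null
(zero-interaction) controls. Aggregating over replicates for a grid of
significance levels and interaction strengths yields the outcome-rate
report used to characterise detection power and error behaviour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import adfuller

from .core import CERResult, EventSeries, cer_test
from .simulate import (
    DelayDistribution,
    RandomWalkSpec,
    SimulationConfig,
    make_delay,
    simulate_network,
    two_node_config,
)

__all__ = [
    "OUTCOMES",
    "CAUSAL_OUTCOMES",
    "NULL_OUTCOMES",
    "classify_outcome",
    "run_experiment",
    "EvaluationReport",
    "windowed_entropy",
    "nonstationarity_check",
    "StationarityResult",
    "builtin_scenario",
    "SCENARIOS",
]

CAUSAL_OUTCOMES = (
    "strongly_correct",
    "weakly_correct",
    "missing_detection",
    "error_type_I",
)
NULL_OUTCOMES = ("error_type_II", "true_negative")
OUTCOMES = CAUSAL_OUTCOMES + NULL_OUTCOMES


def classify_outcome(
    forward: CERResult,
    reverse: CERResult,
    true_support: Iterable[int] | None,
) -> str:
    """Label one replicate given scans in the true direction (``forward``)
    and its reverse, against the ground truth.

    ``true_support`` is the designed delay support of the causal link, or
    ``None`` for a non-causal pair. Both scans must have been run with the
    same significance level and lag range.
    """
    if forward.alpha != reverse.alpha or len(forward.lags) != len(reverse.lags):
        raise ValueError("forward and reverse scans must share alpha and lag range")
    if true_support is None:
        return "error_type_II" if (forward.detected or reverse.detected) else "true_negative"
    support = set(int(t) for t in true_support)
    if not support:
        raise ValueError("causal ground truth must provide a delay support")
    if reverse.detected:
        return "error_type_I"
    if forward.detected:
        flagged = set(forward.significant_lags)
        return "strongly_correct" if flagged <= support else "weakly_correct"
    return "missing_detection"


@dataclass
class EvaluationReport:
    """Outcome rates per (alpha, interaction probability) cell.

    ``counts[(alpha, p)]`` maps outcome label -> replicate count; rates in
    every cell sum to 1 over the applicable labels. ``to_frame`` gives the
    tidy one-row-per-(alpha, interaction, outcome) form.
    """

    scenario: str
    alphas: tuple[float, ...]
    interaction_levels: tuple[float, ...]
    n_reps: int
    seed: int
    counts: dict[tuple[float, float], dict[str, int]] = field(default_factory=dict)

    def rates(self, alpha: float, interaction: float) -> dict[str, float]:
        cell = self.counts[(alpha, interaction)]
        total = sum(cell.values())
        return {label: count / total for label, count in cell.items()}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (alpha, p), cell in sorted(self.counts.items()):
            total = sum(cell.values())
            for label in OUTCOMES:
                if label in cell:
                    rows.append(
                        {
                            "alpha": alpha,
                            "interaction": p,
                            "outcome": label,
                            "count": cell[label],
                            "rate": cell[label] / total,
                            "n_reps": total,
                        }
                    )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "scenario": self.scenario,
            "alphas": list(self.alphas),
            "interaction_levels": list(self.interaction_levels),
            "n_reps": self.n_reps,
            "seed": self.seed,
            "cells": [
                {
                    "alpha": alpha,
                    "interaction": p,
                    "counts": dict(cell),
                    "rates": {k: v / sum(cell.values()) for k, v in cell.items()},
                }
                for (alpha, p), cell in sorted(self.counts.items())
            ],
        }


def run_experiment(
    scenario: SimulationConfig | str,
    interaction_levels: Iterable[float],
    alphas: Iterable[float],
    n_reps: int,
    seed: int,
    *,
    tau_max: int = 20,
    tail: str = "increase",
) -> EvaluationReport:
    """Estimate outcome rates over a grid of interaction strengths and
    significance levels.

    For each interaction level, ``n_reps`` independent replicates are
    simulated, scanned bidirectionally once (the per-lag p-values do not
    depend on alpha), and classified at every requested level. A level of
    0 makes the replicate a matched null control classified into
    ``error_type_II`` / ``true_negative``. Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    cfg = builtin_scenario(scenario) if isinstance(scenario, str) else scenario
    if len(cfg.interactions) != 1:
        raise ValueError("run_experiment expects a scenario with exactly one link")
    alphas = tuple(float(a) for a in alphas)
    levels = tuple(float(p) for p in interaction_levels)
    name = scenario if isinstance(scenario, str) else "custom"

    report = EvaluationReport(
        scenario=name,
        alphas=alphas,
        interaction_levels=levels,
        n_reps=n_reps,
        seed=seed,
    )
    link = cfg.interactions[0]
    children = np.random.SeedSequence(seed).spawn(len(levels))
    for level, child in zip(levels, children):
        rng = np.random.default_rng(child)
        cfg_level = cfg.with_interaction_probability(level)
        support = set(link.delay.support) if level > 0 else None
        cells = {
            alpha: {(lab): 0 for lab in (CAUSAL_OUTCOMES if level > 0 else NULL_OUTCOMES)}
            for alpha in alphas
        }
        for _ in range(n_reps):
            result = simulate_network(cfg_level, rng=rng)
            src, tgt = result.series[link.source], result.series[link.target]
            fwd = cer_test(tgt, src, tau_max=tau_max, alpha=alphas[0], tail=tail)
            rev = cer_test(src, tgt, tau_max=tau_max, alpha=alphas[0], tail=tail)
            for alpha in alphas:
                label = classify_outcome(
                    fwd.rethreshold(alpha), rev.rethreshold(alpha), support
                )
                cells[alpha][label] += 1
        for alpha in alphas:
            report.counts[(alpha, level)] = cells[alpha]
    return report


# ---------------------------------------------------------------------------
# built-in benchmark scenarios (all two-node, n = 5000)

def _fixed4() -> DelayDistribution:
    return make_delay("fixed", tau=4)


def _gauss5() -> DelayDistribution:
    return make_delay(
        "gaussian-discrete",
        support=(2, 3, 4, 5, 6),
        probabilities=(0.015, 0.21, 0.55, 0.21, 0.015),
    )


SCENARIOS = {
    # fixed delay tau=4 between two stationary p=0.3 nodes
    "fixed_delay": lambda: two_node_config(0.6, _fixed4()),
    # same link, non-stationary (random-walk) source, stationary target
    "fixed_delay_mixed": lambda: two_node_config(
        0.6, _fixed4(), base=RandomWalkSpec(), base_effect=0.3
    ),
    # both nodes driven by independent random-walk probabilities
    "fixed_delay_nonstationary": lambda: two_node_config(
        0.6, _fixed4(), base=RandomWalkSpec(), base_effect=RandomWalkSpec()
    ),
    # discrete-Gaussian delay {2..6}, both nodes non-stationary
    "gaussian_delay_nonstationary": lambda: two_node_config(
        0.6, _gauss5(), base=RandomWalkSpec(), base_effect=RandomWalkSpec()
    ),
}


def builtin_scenario(name: str) -> SimulationConfig:
    """A named benchmark configuration (see :data:`SCENARIOS`)."""
    try:
        return SCENARIOS[name]()
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


# ---------------------------------------------------------------------------
# diagnostics for non-stationary inputs

def windowed_entropy(series: EventSeries | np.ndarray, window: int) -> np.ndarray:
    """Sliding-window Shannon entropy (bits) of a binary series.

    For each window position (step 1 sample) the in-window event fraction
    ``q`` gives ``H = -q log2 q - (1-q) log2 (1-q)``, with ``H(0) = H(1) =
    0``. A window tracking a time-varying event probability wanders with
    it; shorter windows track faster but with larger sampling noise —
    which is why moving-window summaries are an unreliable basis for
    inference on non-stationary records.
    """
    v = series.values if isinstance(series, EventSeries) else np.asarray(series)
    if window < 1:
        raise ValueError("window must be a positive integer")
    if window > v.size:
        raise ValueError(f"window ({window}) exceeds series length ({v.size})")
    counts = np.convolve(v.astype(float), np.ones(window), mode="valid")
    q = counts / window
    h = np.zeros_like(q)
    inner = (q > 0) & (q < 1)
    qi = q[inner]
    h[inner] = -qi * np.log2(qi) - (1 - qi) * np.log2(1 - qi)
    return h


class StationarityResult(NamedTuple):
    statistic: float
    pvalue: float
    verdict: str  # "non-stationary" | "stationary" | "degenerate"


def nonstationarity_check(
    series: EventSeries | np.ndarray, alpha: float = 0.05
) -> StationarityResult:
    """Augmented Dickey–Fuller unit-root check on a probability trajectory
    or event series.

    The ADF null is a unit root, so *failing* to reject (p > alpha)
    certifies the series as non-stationary; rejection labels it
    stationary. Constant series are reported as ``degenerate`` (the
    regression is singular and the question is moot).
    """
    v = series.values if isinstance(series, EventSeries) else np.asarray(series, dtype=float)
    if v.size < 20:
        raise ValueError("series too short for a unit-root test (need >= 20 samples)")
    if np.ptp(v) == 0:
        return StationarityResult(math.nan, math.nan, "degenerate")
    statistic, pvalue, *_ = adfuller(v)
    verdict = "non-stationary" if pvalue > alpha else "stationary"
    return StationarityResult(float(statistic), float(pvalue), verdict)
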