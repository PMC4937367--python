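"""Synthetic binary event series from a neuronal-spike interaction model.

Each node fires spontaneously with a per-sample event probability — either
a constant (stationary) or a bounded random walk (non-stationary). Directed
interactions make a source firing at time ``t`` induce a target event at
``t + d`` with the interaction probability, where the delay ``d`` is drawn
independently for every source event from a discrete distribution. The
interaction graph must be acyclic; events are binary, so an induced event
landing on a spontaneous one is idempotent, and events induced past the end
of the record are discarded.

These generators define the study conditions used throughout the test and
evaluation suites: stationary nodes at event probability 0.3, interaction
probabilities in {0.2, 0.4, 0.6, 0.8}, series of 5000 samples, and the
fixed / bimodal / discrete-Gaussian / wide-uniform delay families.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter

import numpy as np

from .core import EventSeries

__all__ = [
    "DelayDistribution",
    "RandomWalkSpec",
    "NodeSpec",
    "InteractionSpec",
    "SimulationConfig",
    "SimulationResult",
    "make_delay",
    "random_walk_probability",
    "simulate_network",
    "two_node_config",
]


@dataclass(frozen=True)
class DelayDistribution:
    """Discrete distribution of cause-to-effect delays, in samples.

    All delays are >= 1: no information transfer is instantaneous, which is
    the premise that lets the zero-lag count serve as the null reference.
    """

    support: tuple[int, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self) -> None:
        support = tuple(int(s) for s in self.support)
        probs = tuple(float(p) for p in self.probabilities)
        if len(support) != len(probs) or not support:
            raise ValueError("support and probabilities must be non-empty and match")
        if any(s < 1 for s in support):
            raise ValueError("all delays must be >= 1 sample")
        if any(p < 0 for p in probs):
            raise ValueError("delay probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"delay probabilities must sum to 1; got {sum(probs)}")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "probabilities", probs)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.choice(np.array(self.support), size=size, p=self.probabilities)


def make_delay(kind: str, **params) -> DelayDistribution:
    """Build one of the standard delay families.

    - ``fixed``: single atom at ``tau``.
    - ``uniform``: equal mass on ``low..high`` (default 1..100), the
      "arbitrary delay" control where the effect may follow the cause at
      any lag.
    - ``bimodal``: two equal atoms, default ``taus=(2, 5)``.
    - ``gaussian-discrete``: explicit ``support``/``probabilities`` vectors
      approximating a discretised Gaussian, e.g. {2,3,4,5,6} with
      {0.015, 0.21, 0.55, 0.21, 0.015}.
    """
    if kind == "fixed":
        tau = int(params["tau"])
        return DelayDistribution((tau,), (1.0,))
    if kind == "uniform":
        low = int(params.get("low", 1))
        high = int(params.get("high", 100))
        if low < 1 or high < low:
            raise ValueError("uniform delay needs 1 <= low <= high")
        width = high - low + 1
        return DelayDistribution(tuple(range(low, high + 1)), (1.0 / width,) * width)
    if kind == "bimodal":
        taus = tuple(int(t) for t in params.get("taus", (2, 5)))
        return DelayDistribution(taus, (1.0 / len(taus),) * len(taus))
    if kind == "gaussian-discrete":
        return DelayDistribution(
            tuple(params["support"]), tuple(params["probabilities"])
        )
    raise ValueError(f"unknown delay kind {kind!r}")


@dataclass(frozen=True)
class RandomWalkSpec:
    """Bounded Gaussian random walk for a non-stationary event probability.

    Defaults (start 0.3, step sd 0.005 per sample, reflected at
    [0.05, 0.6]) produce slow drifts over a few thousand samples that a
    unit-root test typically fails to reject (the reflecting bounds make
    the walk only approximately unit-root), while keeping the firing
    probability well inside (0, 1).
    """

    initial: float = 0.3
    step_sd: float = 0.005
    bounds: tuple[float, float] = (0.05, 0.6)

    def __post_init__(self) -> None:
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bounds must satisfy 0 <= lo < hi <= 1; got {self.bounds}")
        if not lo <= self.initial <= hi:
            raise ValueError("initial value must lie within the bounds")
        if self.step_sd < 0:
            raise ValueError("step scale must be non-negative")


def random_walk_probability(
    n: int,
    spec: RandomWalkSpec = RandomWalkSpec(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Event-probability trajectory ``p[t]``, a reflected Gaussian walk.

    ``p[t] = reflect(p[t-1] + eps_t)`` with ``eps_t ~ N(0, step_sd^2)``,
    folded back into ``[lo, hi]`` by mirror reflection at the bounds. A
    step scale of 0 returns a constant trajectory at the initial value.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    lo, hi = spec.bounds
    steps = rng.normal(0.0, spec.step_sd, size=n - 1) if n > 1 else np.empty(0)
    raw = spec.initial + np.concatenate([[0.0], np.cumsum(steps)])
    # mirror-fold the unconstrained walk into [lo, hi]
    span = hi - lo
    if span <= 0:  # unreachable given spec validation, kept for safety
        return np.full(n, spec.initial)
    y = np.mod(raw - lo, 2.0 * span)
    return lo + np.where(y > span, 2.0 * span - y, y)


@dataclass(frozen=True)
class NodeSpec:
    """One node: a label plus its spontaneous event probability, either a
    constant in [0, 1] or a :class:`RandomWalkSpec`."""

    label: str
    base_probability: float | RandomWalkSpec = 0.3

    def __post_init__(self) -> None:
        p = self.base_probability
        if not isinstance(p, RandomWalkSpec) and not 0.0 <= float(p) <= 1.0:
            raise ValueError(f"constant event probability must lie in [0, 1]; got {p}")

    @property
    def stationary(self) -> bool:
        return not isinstance(self.base_probability, RandomWalkSpec)

    def probability_series(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if isinstance(self.base_probability, RandomWalkSpec):
            return random_walk_probability(n, self.base_probability, rng)
        return np.full(n, float(self.base_probability))


@dataclass(frozen=True)
class InteractionSpec:
    """Directed excitatory link: each source event induces a target event
    with ``probability`` after a delay drawn from ``delay``."""

    source: str
    target: str
    probability: float
    delay: DelayDistribution

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("self-interactions are not allowed")
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("interaction probability must lie in [0, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    nodes: tuple[NodeSpec, ...]
    interactions: tuple[InteractionSpec, ...] = ()
    n: int = 5000
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "interactions", tuple(self.interactions))
        if self.n < 1:
            raise ValueError("series length n must be >= 1")
        labels = [node.label for node in self.nodes]
        if len(set(labels)) != len(labels):
            raise ValueError("node labels must be unique")
        known = set(labels)
        for inter in self.interactions:
            if inter.source not in known or inter.target not in known:
                raise ValueError(
                    f"interaction {inter.source}->{inter.target} references unknown node"
                )
        self.topological_order()  # raises on cycles

    def topological_order(self) -> list[str]:
        """Node labels sorted so every source precedes its targets."""
        ts: TopologicalSorter = TopologicalSorter()
        for node in self.nodes:
            ts.add(node.label)
        for inter in self.interactions:
            ts.add(inter.target, inter.source)
        try:
            return list(ts.static_order())
        except CycleError as err:
            raise ValueError("interaction graph must be acyclic") from err

    def with_interaction_probability(self, p: float) -> "SimulationConfig":
        """Copy of the config with every interaction probability set to ``p``."""
        return dataclasses.replace(
            self,
            interactions=tuple(
                dataclasses.replace(i, probability=float(p)) for i in self.interactions
            ),
        )


@dataclass
class SimulationResult:
    """Simulated series plus the ground truth that generated them."""

    series: dict[str, EventSeries]
    probabilities: dict[str, np.ndarray]
    truth: tuple[InteractionSpec, ...]
    config: SimulationConfig

    def pair(self, a: str, b: str) -> tuple[EventSeries, EventSeries]:
        return self.series[a], self.series[b]

    def truth_for(self, source: str, target: str) -> InteractionSpec | None:
        """The direct link source -> target, if the ground truth has one
        with non-zero interaction probability."""
        for inter in self.truth:
            if inter.source == source and inter.target == target and inter.probability > 0:
                return inter
        return None


def simulate_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> SimulationResult:
    """Generate event series for every node of an acyclic interaction graph.

    Nodes are processed in topological order: a node's final series
    (spontaneous events OR events induced by its parents) is complete
    before it acts as a source itself, so chains propagate induced events
    downstream. Identical config and seed give identical output; passing an
    explicit ``rng`` instead lets Monte-Carlo drivers stream replicates
    from one generator.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n

    order = config.topological_order()
    outgoing: dict[str, list[InteractionSpec]] = {lab: [] for lab in order}
    for inter in config.interactions:
        outgoing[inter.source].append(inter)

    # spontaneous events first, in declared node order for determinism
    probs: dict[str, np.ndarray] = {}
    values: dict[str, np.ndarray] = {}
    for node in config.nodes:
        p = node.probability_series(n, rng)
        probs[node.label] = p
        values[node.label] = (rng.random(n) < p).astype(np.uint8)

    for label in order:
        for inter in outgoing[label]:
            src_times = np.nonzero(values[label])[0]
            fire = rng.random(src_times.size) < inter.probability
            delays = inter.delay.sample(rng, src_times.size)
            induced = src_times[fire] + delays[fire]
            induced = induced[induced < n]
            values[inter.target][induced] = 1

    series = {
        node.label: EventSeries(values[node.label], label=node.label)
        for node in config.nodes
    }
    return SimulationResult(
        series=series,
        probabilities=probs,
        truth=config.interactions,
        config=config,
    )


def two_node_config(
    p_yx: float,
    delay: DelayDistribution,
    *,
    n: int = 5000,
    base: float | RandomWalkSpec = 0.3,
    base_effect: float | RandomWalkSpec | None = None,
    seed: int | None = None,
    source: str = "Y",
    target: str = "X",
) -> SimulationConfig:
    """The canonical two-node benchmark: cause ``Y`` drives effect ``X``
    with interaction probability ``p_yx`` and the given delay distribution.
    ``p_yx = 0`` yields the matched non-causal control."""
    interactions: tuple[InteractionSpec, ...] = ()
    if p_yx > 0:
        interactions = (InteractionSpec(source, target, p_yx, delay),)
    return SimulationConfig(
        nodes=(
            NodeSpec(source, base),
            NodeSpec(target, base if base_effect is None else base_effect),
        ),
        interactions=interactions,
        n=n,
        seed=seed,
    )
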