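"""Readers and writers: tabular event series, simulation configs, and
JSON serialisation of results, plus the run manifest.

Series files are CSV/TSV with a header row of channel labels and one 0/1
cell per sample per channel. Missing values are disallowed — the event
logic is undefined for gaps — and any non-binary cell is an error unless a
binarisation threshold is supplied.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BidirectionalScan, CERResult, ERProfile, EventSeries
from .simulate import (
    DelayDistribution,
    InteractionSpec,
    NodeSpec,
    RandomWalkSpec,
    SimulationConfig,
    make_delay,
)

__all__ = [
    "read_series",
    "write_series",
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "profile_to_dict",
    "result_to_dict",
    "scan_to_dict",
    "RunManifest",
]


def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}[dialect]
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_series(
    path: str | Path,
    dialect: str | None = None,
    binarize: float | None = None,
) -> dict[str, EventSeries]:
    """Load aligned event channels from a delimited text file.

    One column per channel, header row with labels, one row per sample.
    Cells must parse as 0/1 integers unless ``binarize`` is given, in which
    case numeric cells are thresholded (``value >= binarize`` -> 1). The
    delimiter follows the extension (``.tsv``/``.tab``/``.txt`` -> tab,
    else comma) unless ``dialect`` ("csv"/"tsv") overrides it.
    """
    path = Path(path)
    sep = _sep_for(path, dialect)
    try:
        frame = pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as err:
        raise ValueError(f"{path}: malformed table ({err})") from err
    if frame.empty:
        raise ValueError(f"{path}: no samples found")
    if frame.isna().any().any():
        row = int(frame.isna().any(axis=1).idxmax())
        raise ValueError(f"{path}: missing value at row {row}; gaps are not allowed")
    out: dict[str, EventSeries] = {}
    for col in frame.columns:
        values = frame[col].to_numpy()
        if binarize is not None:
            values = (values.astype(float) >= binarize).astype(np.uint8)
        else:
            ok = np.isin(values, (0, 1))
            if not ok.all():
                row = int(np.argwhere(~ok)[0][0])
                raise ValueError(
                    f"{path}: non-binary value {values[row]!r} in column {col!r}, "
                    f"row {row}; pass a binarisation threshold to coerce"
                )
        out[str(col)] = EventSeries(values.astype(np.uint8), label=str(col))
    return out


def write_series(
    path: str | Path,
    series: dict[str, EventSeries],
    dialect: str | None = None,
) -> None:
    """Write aligned channels to CSV/TSV (inverse of :func:`read_series`)."""
    path = Path(path)
    lengths = {s.n for s in series.values()}
    if len(lengths) != 1:
        raise ValueError("all channels must have the same length")
    frame = pd.DataFrame({label: s.values for label, s in series.items()})
    frame.to_csv(path, sep=_sep_for(path, dialect), index=False)


# ---------------------------------------------------------------------------
# simulation configs (YAML or JSON)

def _delay_from_dict(d: dict) -> DelayDistribution:
    kind = d.get("kind")
    if kind is None:
        raise ValueError("delay spec needs a 'kind'")
    params = {k: v for k, v in d.items() if k != "kind"}
    return make_delay(kind, **params)


def _node_from_dict(d: dict) -> NodeSpec:
    label = d["label"]
    if "random_walk" in d:
        rw = d["random_walk"]
        spec = RandomWalkSpec(
            initial=float(rw.get("initial", 0.3)),
            step_sd=float(rw.get("step_sd", 0.005)),
            bounds=tuple(rw.get("bounds", (0.05, 0.6))),
        )
        return NodeSpec(label, spec)
    return NodeSpec(label, float(d.get("p", 0.3)))


def config_from_dict(d: dict) -> SimulationConfig:
    nodes = tuple(_node_from_dict(nd) for nd in d["nodes"])
    interactions = tuple(
        InteractionSpec(
            source=i["source"],
            target=i["target"],
            probability=float(i["probability"]),
            delay=_delay_from_dict(i["delay"]),
        )
        for i in d.get("interactions", ())
    )
    return SimulationConfig(
        nodes=nodes,
        interactions=interactions,
        n=int(d.get("n", 5000)),
        seed=d.get("seed"),
    )


def config_to_dict(config: SimulationConfig) -> dict:
    def node_dict(node: NodeSpec) -> dict:
        if isinstance(node.base_probability, RandomWalkSpec):
            rw = node.base_probability
            return {
                "label": node.label,
                "random_walk": {
                    "initial": rw.initial,
                    "step_sd": rw.step_sd,
                    "bounds": list(rw.bounds),
                },
            }
        return {"label": node.label, "p": node.base_probability}

    return {
        "n": config.n,
        "seed": config.seed,
        "nodes": [node_dict(nd) for nd in config.nodes],
        "interactions": [
            {
                "source": i.source,
                "target": i.target,
                "probability": i.probability,
                "delay": {
                    "kind": "gaussian-discrete",
                    "support": list(i.delay.support),
                    "probabilities": list(i.delay.probabilities),
                },
            }
            for i in config.interactions
        ],
    }


def load_config(path: str | Path) -> SimulationConfig:
    """Read a simulation config from YAML or JSON."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return config_from_dict(data)


# ---------------------------------------------------------------------------
# result serialisation

def profile_to_dict(profile: ERProfile) -> dict:
    return {
        "direction": list(profile.direction),
        "alpha": profile.alpha,
        "lags": profile.lags.tolist(),
        "counts": profile.counts.tolist(),
        "n_eff": profile.n_eff.tolist(),
        "frequencies": profile.frequencies.tolist(),
        "k0": profile.k0,
        "upper_count": profile.upper_count,
        "upper_frequency": profile.upper_frequency,
        "lower_count": profile.lower_count,
    }


def result_to_dict(result: CERResult) -> dict:
    return {
        "direction": list(result.direction),
        "alpha": result.alpha,
        "tail": result.tail,
        "status": result.status,
        "k0": result.k0,
        "n": result.n,
        "lags": result.lags.tolist(),
        "counts": result.counts.tolist(),
        "pvalues": result.pvalues.tolist(),
        "significant_lags": {str(k): v for k, v in result.significant_lags.items()},
        "overlap_correction": result.overlap_correction,
        "bonferroni": result.bonferroni,
    }


def scan_to_dict(scan: BidirectionalScan) -> dict:
    d = {
        "forward": result_to_dict(scan.forward),
        "reverse": result_to_dict(scan.reverse),
    }
    if scan.zero_lag_related is not None:
        d["zero_lag_related"] = scan.zero_lag_related
    return d


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI output."""

    command: str
    parameters: dict
    seed: int | None
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
            fh.write("\n")
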