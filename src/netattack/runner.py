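"""Replicated attack experiments: strategy x network x fraction grids.

An :class:`ExperimentSpec` describes an ensemble (generator spec or
input file, measure, strategies with parameters, removal fractions,
replicate count, base seed).  :func:`run_experiment` runs every
combination, recording per replicate the intersection distance of each
strategy's removal order against the sequential reference, the number
of centrality evaluations, and — for full-removal runs — the R and V
robustness indices.  Replicate seeds are ``base_seed + replicate``, so
a spec re-run with the same base seed reproduces its table exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import attacks, metrics, synthetic
from .errors import UsageError
from .graph_core import Network, extract_lcc, load_edgelist, load_matrix_market

logger = logging.getLogger(__name__)

__all__ = ["ExperimentSpec", "ExperimentResult", "run_experiment", "load_spec"]


@dataclass
class ExperimentSpec:
    """Declarative description of one replicated experiment.

    ``strategies`` is a list of dicts with a ``name`` key plus
    strategy-specific parameters, e.g.
    ``{"name": "threshold", "gamma": 0.01}``.  ``fractions`` are
    removal fractions in (0, 1]; a fraction of 1.0 removes every node
    and enables the R/V indices.  ``sequential_reference`` controls
    whether a sequential run is added as the isim baseline.
    """

    network: str
    strategies: list[dict] = field(
        default_factory=lambda: [{"name": "threshold", "gamma": 0.01}]
    )
    measure: str = "tc"
    fractions: list[float] = field(default_factory=lambda: [0.1])
    replicates: int = 20
    base_seed: int = 0
    sequential_reference: bool = True
    robustness: bool = False

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise UsageError("replicates must be >= 1")
        for f in self.fractions:
            if not 0 < f <= 1:
                raise UsageError(f"removal fraction {f} outside (0, 1]")
        for s in self.strategies:
            if "name" not in s:
                raise UsageError(f"strategy entry {s} lacks a 'name'")


@dataclass
class ExperimentResult:
    replicates: pd.DataFrame
    summary: pd.DataFrame

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)


def _build_network(source: str, seed) -> Network:
    p = Path(source)
    if p.suffix == ".mtx" or (p.exists() and p.is_file() and p.suffix != ""):
        if p.suffix == ".mtx":
            g = load_matrix_market(p)
        else:
            g = load_edgelist(p)
        return extract_lcc(g)
    return synthetic.from_spec(source, seed=seed)


def _strategy_label(s: dict) -> str:
    extras = {k: v for k, v in s.items() if k != "name"}
    if not extras:
        return s["name"]
    inner = ",".join(f"{k}={v}" for k, v in sorted(extras.items()))
    return f"{s['name']}({inner})"


def run_experiment(spec: ExperimentSpec) -> ExperimentResult:
    """Run the grid; returns per-replicate rows and their means."""
    rows: list[dict[str, Any]] = []
    for rep in range(spec.replicates):
        seed = spec.base_seed + rep
        g = _build_network(spec.network, seed)
        logger.info(
            "replicate %d/%d: %s (n=%d, edges=%d)",
            rep + 1, spec.replicates, spec.network, g.n_present, g.n_edges,
        )
        for frac in spec.fractions:
            m = attacks.fraction_to_count(frac, g.n_present)
            reference = None
            if spec.sequential_reference:
                reference = attacks.sequential_attack(g, spec.measure, m)
            runs = []
            if reference is not None:
                runs.append(("sequential", reference))
            for s in spec.strategies:
                kwargs = {k: v for k, v in s.items() if k != "name"}
                res = attacks.run_attack(g, s["name"], spec.measure, m, **kwargs)
                runs.append((_strategy_label(s), res))
            for label, res in runs:
                row: dict[str, Any] = {
                    "network": spec.network,
                    "n": g.n_present,
                    "replicate": rep,
                    "seed": seed,
                    "measure": spec.measure,
                    "fraction": frac,
                    "M": m,
                    "strategy": label,
                    "evaluations": res.evaluations,
                    "isim": np.nan,
                    "R": np.nan,
                    "V": np.nan,
                }
                if reference is not None and res is not reference:
                    row["isim"] = metrics.intersection_distance(
                        res.order, reference.order, k=m
                    ).value
                if spec.robustness and m == g.n_present:
                    curve = metrics.sigma_curve(g, res.order)
                    row["R"] = metrics.r_index(curve)
                    row["V"] = metrics.v_index(curve)
                rows.append(row)
    replicates = pd.DataFrame(rows)
    summary = (
        replicates.groupby(["network", "measure", "fraction", "M", "strategy"])
        .agg(
            isim=("isim", "mean"),
            evaluations=("evaluations", "mean"),
            R=("R", "mean"),
            V=("V", "mean"),
            replicates=("replicate", "count"),
        )
        .reset_index()
    )
    return ExperimentResult(replicates=replicates, summary=summary)


def load_spec(path) -> ExperimentSpec:
    """Load an :class:`ExperimentSpec` from a YAML or JSON file."""
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        import yaml

        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, dict):
        raise UsageError(f"{path}: expected a mapping of spec fields")
    try:
        return ExperimentSpec(**data)
    except TypeError as exc:
        raise UsageError(f"{path}: bad experiment spec: {exc}") from exc
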