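"""Temporal-network statistics and the aggregated-graph evaluation.

Works on contact logs -- lists of (t_start, t_end, i, j) records -- whether
simulated or read from SocioPatterns-style files.  Provides

* interduration extraction (gaps between successive interactions of a node
  or of a specific pair, measured on interaction start times and pooled
  across entities),
* the interaction-score projection: per-pair contact durations are summed,
  log-transformed and normalized by the maximum, and pairs scoring above a
  threshold (default 0.4) form a static weighted graph,
* five aggregated scalars on that graph: average clustering, Louvain
  modularity (resolution 1, averaged over partition seeds), transitivity,
  density and degree assortativity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
import numpy as np

from .engine import ParameterError

__all__ = [
    "ContactLog", "interdurations", "interaction_score_graph",
    "aggregated_metrics", "normalized_deviations",
]


@dataclass
class ContactLog:
    """A list of contacts (t_start, t_end, i, j) on ``n_nodes`` nodes."""

    events: list[tuple[float, float, int, int]]
    n_nodes: int
    horizon: float

    def __post_init__(self):
        for k, (t0, t1, i, j) in enumerate(self.events):
            if not (t0 < t1 <= self.horizon * (1 + 1e-12)):
                raise ParameterError(
                    f"contact {k}: need t_start < t_end <= horizon, "
                    f"got ({t0}, {t1})")
            if not (0 <= i < self.n_nodes and 0 <= j < self.n_nodes) or i == j:
                raise ParameterError(
                    f"contact {k}: node pair ({i}, {j}) out of range")

    def __len__(self):
        return len(self.events)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.events,
                            columns=["t_start", "t_end", "i", "j"])

    def durations(self) -> np.ndarray:
        return np.array([t1 - t0 for t0, t1, _, _ in self.events])


def interdurations(log: ContactLog, level: str = "node") -> np.ndarray:
    """Pooled gaps between successive interaction starts.

    ``level="node"``: per node, gaps between consecutive contacts involving
    it; ``level="edge"``: per unordered pair.  Entities with fewer than two
    events contribute nothing.
    """
    if level not in ("node", "edge"):
        raise ParameterError(f"level must be 'node' or 'edge', got {level!r}")
    if not log.events:
        raise ParameterError("empty contact log")
    groups: dict = {}
    for t0, _, i, j in log.events:
        if level == "node":
            groups.setdefault(i, []).append(t0)
            groups.setdefault(j, []).append(t0)
        else:
            groups.setdefault((i, j) if i < j else (j, i), []).append(t0)
    gaps: list[float] = []
    for times in groups.values():
        times.sort()
        gaps.extend(b - a for a, b in zip(times, times[1:]))
    return np.asarray(gaps)


def interaction_score_graph(log: ContactLog, threshold: float = 0.4,
                            floor: float = 1.0) -> nx.Graph:
    """Static graph of pairs whose interaction score exceeds ``threshold``.

    score_ij = ln(total contact duration of the pair) / max over pairs.
    Durations are floored at one tick before the log so sub-tick contacts
    cannot produce negative scores; with a single pair the maximal score is
    trivially 1 and the pair is always connected.  The graph contains all
    ``n_nodes`` nodes; edges carry the score as ``weight``.
    """
    if not log.events:
        raise ParameterError("empty contact log")
    totals: dict[tuple[int, int], float] = {}
    for t0, t1, i, j in log.events:
        key = (i, j) if i < j else (j, i)
        totals[key] = totals.get(key, 0.0) + (t1 - t0)
    logs = {k: math.log(max(v, floor)) for k, v in totals.items()}
    top = max(logs.values())
    if top <= 0:
        raise ParameterError(
            "all pairwise durations are at or below one tick; the "
            "max-normalized score is undefined")
    G = nx.Graph()
    G.add_nodes_from(range(log.n_nodes))
    for (i, j), v in logs.items():
        score = v / top
        if score > threshold:
            G.add_edge(i, j, weight=score)
    return G


def aggregated_metrics(G: nx.Graph, modularity_seeds: Iterable[int] = range(10),
                       resolution: float = 1.0) -> dict:
    """Clustering, modularity, transitivity, density, assortativity.

    Louvain community detection is stochastic, so modularity is reported as
    the mean over the given partition seeds.  Degenerate graphs fall back to
    density 0 with the other metrics undefined (NaN).
    """
    if G.number_of_nodes() < 2:
        raise ParameterError("need at least 2 nodes")
    if G.number_of_edges() == 0:
        return {"clustering": math.nan, "modularity": math.nan,
                "transitivity": math.nan, "density": 0.0,
                "assortativity": math.nan}
    mods = []
    for s in modularity_seeds:
        part = nx.community.louvain_communities(G, resolution=resolution,
                                                seed=int(s))
        mods.append(nx.community.modularity(G, part, resolution=resolution))
    with np.errstate(invalid="ignore"):
        try:
            assort = float(nx.degree_pearson_correlation_coefficient(G))
        except (ValueError, ZeroDivisionError):
            assort = math.nan
    return {
        "clustering": float(nx.average_clustering(G)),
        "modularity": float(np.mean(mods)),
        "transitivity": float(nx.transitivity(G)),
        "density": float(nx.density(G)),
        "assortativity": assort,
    }


def normalized_deviations(model_metrics: dict[str, dict],
                          reference: dict) -> dict[str, dict]:
    """|metric - reference| normalized by the std of the metric across models.

    Mirrors the usual cross-model deviation report: for each metric the
    spread across candidate models sets the scale on which deviations from
    the reference data are compared.
    """
    names = list(reference)
    out: dict[str, dict] = {m: {} for m in model_metrics}
    for name in names:
        vals = np.array([model_metrics[m][name] for m in model_metrics],
                        dtype=float)
        scale = float(np.nanstd(vals))
        for m in model_metrics:
            dev = abs(model_metrics[m][name] - reference[name])
            out[m][name] = dev / scale if scale > 0 else math.inf
    return out
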