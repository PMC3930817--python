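"""Enriched molecular path detection by randomized color coding.

The search looks for high-weight simple paths of a fixed length ``k``
in the weighted network.  Every node is assigned a uniform random color
from {1..k}; the greedy walk starts at the node of maximum total weight
and repeatedly extends to the highest-weight neighbor whose color is
not yet on the path, so the colors guarantee simplicity without
visited-set bookkeeping.  A fixed simple k-path is colorful — all
colors distinct — with probability k!/k^k, so repeated recoloring
recovers paths the greedy walk would otherwise miss.

Significance is assessed against a permutation null: the node weights
are shuffled, a fresh coloring is drawn, and the greedy search is rerun;
the p-value of an observed path score is its add-one exceedance rate in
the null scores.  The network is *harvested* by iterating detection
with fresh colorings until ``i`` consecutive iterations rediscover
previously seen paths, and the significant paths of one run are merged
into a combined network summarized by its PPI and metabolic edge
counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path as FilePath

import networkx as nx
import numpy as np

from .fluxes import FluxSummary
from .network import IntegratedNetwork, KIND_METABOLIC, KIND_PPI
from .weighting import ExpressionData, WeightedNetwork, WeightingConfig, assign_node_weights

__all__ = [
    "CombinedNetwork",
    "DetectionConfig",
    "DetectionResult",
    "Path",
    "combine_paths",
    "draw_coloring",
    "greedy_colorful_path",
    "harvest",
    "null_score_distribution",
    "path_pvalue",
    "run_detection",
    "write_paths_jsonl",
]

logger = logging.getLogger(__name__)


@dataclass
class DetectionConfig:
    """Search settings.

    ``k``: path length (number of nodes).  ``i``: harvest patience —
    stop after this many consecutive iterations that only rediscover
    known paths.  ``n_shuffles``: permutation count for the null score
    distribution.  ``p_cutoff``: permutation p-value below which a path
    is reported.  ``remove_found`` removes detected-path nodes between
    iterations (exploration mode; off by default so re-detection drives
    the stopping rule).  ``prefer_kind`` picks which edge kind a
    traversal records when a node pair carries both a metabolic and a
    ppi edge.
    """

    k: int = 8
    i: int = 10
    n_shuffles: int = 1000
    p_cutoff: float = 0.025
    seed: int | None = None
    remove_found: bool = False
    prefer_kind: str = KIND_METABOLIC
    max_iterations: int = 100_000

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("path length k must be >= 2")
        if self.i < 1:
            raise ValueError("harvest patience i must be >= 1")
        if self.n_shuffles < 1:
            raise ValueError("n_shuffles must be >= 1")
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must lie in (0, 1]")
        if self.prefer_kind not in (KIND_METABOLIC, KIND_PPI):
            raise ValueError("prefer_kind must be 'metabolic' or 'ppi'")


@dataclass(frozen=True)
class Path:
    """A detected simple path: ordered nodes, summed-weight score,
    permutation p-value (once assessed) and traversed edge kinds."""

    nodes: tuple[str, ...]
    score: float
    p_value: float | None = None
    edge_kinds: tuple[str, ...] = ()

    @property
    def node_set(self) -> frozenset[str]:
        return frozenset(self.nodes)

    def with_pvalue(self, p: float) -> "Path":
        return Path(self.nodes, self.score, p, self.edge_kinds)


class _GraphView:
    """Array-backed adjacency + weights for the inner search loops."""

    def __init__(self, wnet: WeightedNetwork) -> None:
        self.network = wnet.network
        self.nodes: list[str] = list(wnet.w_tot.index)
        self.index = {n: i for i, n in enumerate(self.nodes)}
        self.w = wnet.w_tot.to_numpy(dtype=float).copy()
        g = wnet.network.graph
        self.neighbors: list[np.ndarray] = [
            np.array(sorted(self.index[m] for m in g.neighbors(n)), dtype=np.int64)
            for n in self.nodes
        ]

    def n(self) -> int:
        return len(self.nodes)


def _tie_argmax(candidates: np.ndarray, values: np.ndarray, rng: np.random.Generator) -> int:
    """Index (into the full value array) of the max over candidates,
    uniform among ties."""
    vals = values[candidates]
    vmax = vals.max()
    ties = candidates[vals == vmax]
    if len(ties) == 1:
        return int(ties[0])
    return int(ties[rng.integers(len(ties))])


def _greedy_indices(
    view: _GraphView,
    w: np.ndarray,
    k: int,
    colors: np.ndarray,
    rng: np.random.Generator,
    active: np.ndarray | None = None,
) -> list[int] | None:
    """Greedy colorful walk over node indices; None on a color dead-end."""
    if active is None:
        start_pool = np.arange(view.n())
    else:
        start_pool = np.flatnonzero(active)
        if start_pool.size == 0:
            return None
    start = _tie_argmax(start_pool, w, rng)
    path = [start]
    used = {int(colors[start])}
    while len(path) < k:
        nbrs = view.neighbors[path[-1]]
        if active is not None:
            nbrs = nbrs[active[nbrs]]
        eligible = nbrs[[int(colors[v]) not in used for v in nbrs]] if nbrs.size else nbrs
        if eligible.size == 0:
            return None
        nxt = _tie_argmax(eligible, w, rng)
        path.append(nxt)
        used.add(int(colors[nxt]))
    return path


def draw_coloring(net: WeightedNetwork | IntegratedNetwork, k: int,
                  rng: np.random.Generator) -> dict[str, int]:
    """Uniform random coloring of every node with integers 1..k."""
    graph = net.network.graph if isinstance(net, WeightedNetwork) else net.graph
    nodes = list(graph.nodes)
    colors = rng.integers(1, k + 1, size=len(nodes))
    return {n: int(c) for n, c in zip(nodes, colors)}


def _edge_kinds_of(net: IntegratedNetwork, nodes: list[str], prefer: str) -> tuple[str, ...]:
    kinds = []
    other = KIND_PPI if prefer == KIND_METABOLIC else KIND_METABOLIC
    for u, v in zip(nodes, nodes[1:]):
        present = net.edge_kinds(u, v)
        kinds.append(prefer if prefer in present else other)
    return tuple(kinds)


def _path_from_indices(view: _GraphView, idxs: list[int], w: np.ndarray,
                       prefer_kind: str) -> Path:
    names = [view.nodes[i] for i in idxs]
    return Path(
        nodes=tuple(names),
        score=float(w[idxs].sum()),
        edge_kinds=_edge_kinds_of(view.network, names, prefer_kind),
    )


def greedy_colorful_path(
    net: WeightedNetwork,
    k: int,
    coloring: dict[str, int],
    rng: np.random.Generator | int | None = None,
) -> Path | None:
    """One greedy colorful search under a fixed coloring.

    Starts at the global maximum-weight node and extends to the
    maximum-weight neighbor whose color is not yet on the path; ties
    are broken uniformly at random.  Returns ``None`` when the walk
    dead-ends before reaching ``k`` nodes.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    view = _GraphView(net)
    if view.n() == 0:
        raise ValueError("network is empty")
    colors = np.array([coloring[n] for n in view.nodes], dtype=np.int64)
    idxs = _greedy_indices(view, view.w, k, colors, rng)
    if idxs is None:
        return None
    return _path_from_indices(view, idxs, view.w, KIND_METABOLIC)


def null_score_distribution(
    net: WeightedNetwork,
    k: int,
    n_shuffles: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Greedy path scores under weight shuffling.

    Each shuffle permutes the multiset of node weights uniformly, draws
    a fresh coloring and reruns the greedy search; shuffles whose walk
    dead-ends are redrawn (counted and logged).  The observed weights
    are untouched.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    view = _GraphView(net)
    scores = np.empty(n_shuffles)
    redraws = 0
    max_attempts = 1000 * n_shuffles
    attempts = 0
    got = 0
    while got < n_shuffles:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"null distribution: no length-{k} path found in {max_attempts} shuffles"
            )
        w = rng.permutation(view.w)
        colors = rng.integers(1, k + 1, size=view.n())
        idxs = _greedy_indices(view, w, k, colors, rng)
        if idxs is None:
            redraws += 1
            continue
        scores[got] = w[idxs].sum()
        got += 1
    if redraws:
        logger.info("null distribution: %d dead-end shuffle(s) redrawn", redraws)
    return scores


def path_pvalue(score: float, null_scores: np.ndarray) -> float:
    """Add-one permutation p-value: (1 + #{null >= score}) / (1 + n)."""
    null_scores = np.asarray(null_scores)
    if null_scores.size == 0:
        raise ValueError("null score distribution is empty")
    return float((1 + (null_scores >= score).sum()) / (1 + null_scores.size))


def harvest(net: WeightedNetwork, cfg: DetectionConfig) -> list[Path]:
    """Iterated detection until the network is harvested.

    Repeatedly draws a fresh coloring and runs the greedy search; a
    path is identified by its unordered node set (a path and its
    reversal are one object).  New significant paths (permutation
    p <= cfg.p_cutoff against a single null distribution computed once
    from cfg.n_shuffles weight shuffles) are collected; the loop stops
    after cfg.i consecutive iterations yielding only already-seen paths
    (color dead-ends count as seen).  Returns significant paths sorted
    by score, descending.
    """
    rng = np.random.default_rng(cfg.seed)
    view = _GraphView(net)
    if view.n() < cfg.k:
        raise ValueError(f"network has {view.n()} nodes, fewer than path length k={cfg.k}")
    null = null_score_distribution(net, cfg.k, cfg.n_shuffles, rng)

    seen: set[frozenset[int]] = set()
    results: list[Path] = []
    active = np.ones(view.n(), dtype=bool) if cfg.remove_found else None
    streak = 0
    iterations = 0
    dead_ends = 0
    while streak < cfg.i and iterations < cfg.max_iterations:
        iterations += 1
        colors = rng.integers(1, cfg.k + 1, size=view.n())
        idxs = _greedy_indices(view, view.w, cfg.k, colors, rng, active=active)
        if idxs is None:
            dead_ends += 1
            streak += 1
            continue
        key = frozenset(idxs)
        if key in seen:
            streak += 1
            continue
        seen.add(key)
        streak = 0
        path = _path_from_indices(view, idxs, view.w, cfg.prefer_kind)
        p = path_pvalue(path.score, null)
        if p <= cfg.p_cutoff:
            results.append(path.with_pvalue(p))
            if active is not None:
                active[idxs] = False
    if iterations >= cfg.max_iterations:
        logger.warning("harvest stopped at the iteration cap (%d)", cfg.max_iterations)
    logger.info(
        "harvest: %d iterations, %d distinct paths, %d significant, %d dead ends",
        iterations, len(seen), len(results), dead_ends,
    )
    return sorted(results, key=lambda p: (-p.score, p.nodes))


@dataclass
class DetectionResult:
    """Paths from one (comparison, direction, a) detection run."""

    paths: list[Path]
    weighted: WeightedNetwork
    metadata: dict = field(default_factory=dict)


def run_detection(
    net: IntegratedNetwork,
    expr: ExpressionData,
    flux: FluxSummary | None,
    case: str,
    control: str,
    a: float,
    direction: str,
    cfg: DetectionConfig | None = None,
    weighting: WeightingConfig | None = None,
) -> DetectionResult:
    """Weight the network for one comparison cell and harvest it."""
    cfg = cfg or DetectionConfig()
    wcfg = weighting or WeightingConfig()
    wcfg = WeightingConfig(
        a=a, direction=direction, zero_flux_floor=wcfg.zero_flux_floor,
        scale_flux=wcfg.scale_flux, impute_missing=wcfg.impute_missing,
    )
    wnet = assign_node_weights(net, expr, flux, case, control, wcfg)
    paths = harvest(wnet, cfg)
    metadata = {
        "case": case,
        "control": control,
        "a": a,
        "direction": direction,
        "k": cfg.k,
        "i": cfg.i,
        "n_shuffles": cfg.n_shuffles,
        "p_cutoff": cfg.p_cutoff,
        "seed": cfg.seed,
        "n_nodes": net.graph.number_of_nodes(),
        "n_edges": net.graph.number_of_edges(),
        "n_significant_paths": len(paths),
    }
    return DetectionResult(paths=paths, weighted=wnet, metadata=metadata)


# ---------------------------------------------------------------------------
# Combining paths
# ---------------------------------------------------------------------------


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class CombinedNetwork:
    """Union graph of a run's significant paths with edge-kind tallies."""

    graph: nx.Graph
    counts: dict
    paths: list[Path] = field(default_factory=list)

    @property
    def percentages(self) -> dict:
        total = self.counts["n_ppi_edges"] + self.counts["n_metabolic_edges"]
        if total == 0:
            return {"pct_ppi_edges": 0, "pct_metabolic_edges": 0}
        return {
            "pct_ppi_edges": _round_half_up(100 * self.counts["n_ppi_edges"] / total),
            "pct_metabolic_edges": _round_half_up(
                100 * self.counts["n_metabolic_edges"] / total
            ),
        }

    def summary_row(self) -> dict:
        return {**self.counts, **self.percentages}


def combine_paths(paths: list[Path], net: WeightedNetwork) -> CombinedNetwork:
    """Union of path nodes and traversed edges, with kind counts.

    Every node and edge records the indices of the contributing paths.
    An empty path list yields an empty combined network with zero
    counts.
    """
    g = nx.Graph()
    for pi, path in enumerate(paths):
        for node in path.nodes:
            if not g.has_node(node):
                data = dict(net.network.graph.nodes[node])
                g.add_node(
                    node,
                    kind=data["kind"],
                    genes=data["genes"],
                    rule=data.get("rule"),
                    tw=float(net.w_trans[node]),
                    fw=float(net.w_flux[node]),
                    w=float(net.w_tot[node]),
                    paths=[],
                )
            g.nodes[node]["paths"].append(pi)
        for (u, v), kind in zip(zip(path.nodes, path.nodes[1:]), path.edge_kinds):
            if not g.has_edge(u, v):
                mg = net.network.graph
                prov = (
                    mg[u][v][kind].get("provenance", kind)
                    if mg.has_edge(u, v) and kind in mg[u][v]
                    else ("met" if kind == KIND_METABOLIC else "S")
                )
                g.add_edge(u, v, kind=kind, provenance=prov, paths=[])
            g[u][v]["paths"].append(pi)
    n_ppi = sum(1 for _, _, d in g.edges(data=True) if d["kind"] == KIND_PPI)
    n_met = sum(1 for _, _, d in g.edges(data=True) if d["kind"] == KIND_METABOLIC)
    counts = {
        "n_ppi_edges": n_ppi,
        "n_metabolic_edges": n_met,
        "n_nodes": g.number_of_nodes(),
        "n_paths": len(paths),
    }
    return CombinedNetwork(graph=g, counts=counts, paths=list(paths))


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------


def write_paths_jsonl(paths: list[Path], path: str | FilePath) -> None:
    """One JSON object per line: nodes, score, p, edge_kinds."""
    lines = []
    for p in paths:
        lines.append(json.dumps({
            "nodes": list(p.nodes),
            "score": p.score,
            "p": p.p_value,
            "edge_kinds": list(p.edge_kinds),
        }, sort_keys=True))
    FilePath(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_paths_jsonl(path: str | FilePath) -> list[Path]:
    out = []
    for line in FilePath(path).read_text().splitlines():
        if not line.strip():
            continue
        obj = json.loads(line)
        out.append(Path(
            nodes=tuple(obj["nodes"]), score=float(obj["score"]),
            p_value=obj.get("p"), edge_kinds=tuple(obj.get("edge_kinds", [])),
        ))
    return out


def _combined_export_graph(combined: CombinedNetwork) -> nx.Graph:
    g = nx.Graph()
    for node, d in combined.graph.nodes(data=True):
        sign = "red" if d["w"] > 0 else ("blue" if d["w"] < 0 else "neutral")
        attrs = {
            "kind": d["kind"],
            "genes": ";".join(sorted(d["genes"])),
            "tw": d["tw"],
            "fw": d["fw"],
            "w": d["w"],
            "sign": sign,
            "paths": ";".join(map(str, d["paths"])),
        }
        if d.get("rule") is not None:
            attrs["rule"] = d["rule"].to_string(symbols=True)
        g.add_node(node, **attrs)
    for u, v, d in combined.graph.edges(data=True):
        g.add_edge(u, v, kind=d["kind"], provenance=d.get("provenance", d["kind"]),
                   paths=";".join(map(str, d["paths"])))
    return g


def write_combined_graphml(combined: CombinedNetwork, path: str | FilePath) -> None:
    """GraphML export with tw/fw/w node labels and red/blue/neutral sign
    classes."""
    nx.write_graphml(_combined_export_graph(combined), str(path))


def write_combined_sif(combined: CombinedNetwork, path: str | FilePath) -> None:
    lines = []
    for u, v, d in sorted(combined.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
        lines.append(f"{u}\t{d.get('provenance', d['kind'])}\t{v}")
    FilePath(path).write_text("\n".join(lines) + ("\n" if lines else ""))
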