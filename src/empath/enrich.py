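"""Functional-category enrichment of combined networks.

The genes behind a combined network's nodes (rule leaves of reaction
nodes plus the genes of signaling-protein nodes) are tested for
over-representation in user-supplied functional categories (a GMT-like
file, e.g. FunCat- or GO-style ORF annotations) with an upper-tail
hypergeometric test and Benjamini-Hochberg FDR control.  By default the
background universe is the gene set of the full weighted network — the
universe the path search actually explored — not the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .detect import CombinedNetwork
from .network import IntegratedNetwork
from .weighting import WeightedNetwork

__all__ = [
    "CategoryAnnotation",
    "EnrichmentResult",
    "genes_of",
    "hypergeom_enrich",
    "network_background",
]

logger = logging.getLogger(__name__)


@dataclass
class CategoryAnnotation:
    """Map category id -> gene set, with optional display names."""

    categories: dict[str, frozenset[str]]
    names: dict[str, str] | None = None

    def __post_init__(self) -> None:
        for cat, genes in self.categories.items():
            if not genes:
                raise ValueError(f"category {cat!r} is empty")

    def name_of(self, category: str) -> str:
        if self.names and category in self.names:
            return self.names[category]
        return category

    @staticmethod
    def read_gmt(path: str | Path) -> "CategoryAnnotation":
        """GMT format: category_id <TAB> name <TAB> gene1 <TAB> gene2 ..."""
        categories: dict[str, frozenset[str]] = {}
        names: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}: line {lineno}: GMT rows need >= 3 columns")
            cat, name, genes = cols[0], cols[1], [g for g in cols[2:] if g.strip()]
            categories[cat] = frozenset(genes)
            names[cat] = name
        return CategoryAnnotation(categories=categories, names=names)

    def to_gmt(self, path: str | Path) -> None:
        lines = []
        for cat in sorted(self.categories):
            genes = "\t".join(sorted(self.categories[cat]))
            lines.append(f"{cat}\t{self.name_of(cat)}\t{genes}")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    n_selected_in_category: int
    n_selected: int
    n_background_in_category: int
    n_background: int
    p: float
    q: float


def genes_of(combined: CombinedNetwork) -> frozenset[str]:
    """Union of gene ids over a combined network's nodes."""
    out: set[str] = set()
    for _, data in combined.graph.nodes(data=True):
        out |= set(data.get("genes", ()))
    return frozenset(out)


def network_background(net: WeightedNetwork | IntegratedNetwork) -> frozenset[str]:
    """All genes of a network: the default enrichment universe."""
    inet = net.network if isinstance(net, WeightedNetwork) else net
    out: set[str] = set()
    for node in inet.graph.nodes:
        out |= inet.genes_of_node(node)
    return frozenset(out)


def hypergeom_enrich(
    selected: frozenset[str] | set[str],
    background: frozenset[str] | set[str],
    annot: CategoryAnnotation,
    q_cutoff: float = 0.05,
    return_all: bool = False,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation with BH control.

    For each category with at least one background gene,
    ``p = P(X >= x)`` where X ~ Hypergeom(N=|background|,
    K=|background ∩ category|, n=|selected|) and x is the selected
    overlap.  q-values are Benjamini-Hochberg over the tested
    categories; results with ``q <= q_cutoff`` are returned sorted by
    (q, p, category).  ``return_all`` skips the cutoff.
    """
    selected, background = set(selected), set(background)
    if not selected <= background:
        extra = sorted(selected - background)[:5]
        raise ValueError(f"selected genes not in background, e.g. {extra}")
    if not 0 < q_cutoff <= 1:
        raise ValueError("q_cutoff must lie in (0, 1]")

    N, n = len(background), len(selected)
    rows = []
    for cat in sorted(annot.categories):
        K = len(annot.categories[cat] & background)
        if K == 0:
            logger.info("skipping category %s: no overlap with the background", cat)
            continue
        x = len(annot.categories[cat] & selected)
        p = float(hypergeom.sf(x - 1, N, K, n))
        rows.append((cat, x, K, p))
    if not rows:
        return []
    _, qvals, _, _ = multipletests([r[3] for r in rows], method="fdr_bh")
    results = [
        EnrichmentResult(
            category=cat,
            n_selected_in_category=x,
            n_selected=n,
            n_background_in_category=K,
            n_background=N,
            p=p,
            q=float(q),
        )
        for (cat, x, K, p), q in zip(rows, qvals)
    ]
    if not return_all:
        results = [r for r in results if r.q <= q_cutoff]
    return sorted(results, key=lambda r: (r.q, r.p, r.category))


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    header = ("category\tn_selected_in_category\tn_selected\t"
              "n_background_in_category\tn_background\tp\tq")
    lines = [header]
    for r in results:
        lines.append(
            f"{r.category}\t{r.n_selected_in_category}\t{r.n_selected}\t"
            f"{r.n_background_in_category}\t{r.n_background}\t{float(r.p)!r}\t{float(r.q)!r}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
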