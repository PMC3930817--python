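"""Integrated reaction-node network with protein-protein interaction edges.

Reactions of a metabolic model become nodes; two reactions are joined by
an undirected *metabolic* edge when they share a metabolite (substrate
or product on either side) that is not on a user-supplied exclusion list
of cofactors and other carrier metabolites.  Protein-protein interaction
records above an evidence-score threshold add *ppi* edges between the
reactions whose gene rules contain the interacting genes; genes with no
catalyzed reaction (signaling proteins) enter as protein-kind nodes.
Kinase-phosphatase interaction records carry no evidence score and are
always kept, tagged ``KPI``.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .model import MetabolicModel, metabolite_base_id
from .rules import GeneRule

__all__ = [
    "IntegratedNetwork",
    "PpiRecord",
    "build_reaction_graph",
    "integrate_ppi",
    "read_ppi_table",
    "write_graphml",
    "write_sif",
]

logger = logging.getLogger(__name__)

KIND_METABOLIC = "metabolic"
KIND_PPI = "ppi"

#: provenance tags, mirroring the network-export legend
_PROVENANCE = {"string-experimental": "S", "kinase-phosphatase": "KPI"}


@dataclass(frozen=True)
class PpiRecord:
    """One protein-protein interaction: a normalized gene pair with an
    integer evidence score and a source tag."""

    gene_a: str
    gene_b: str
    score: int
    source: str = "string-experimental"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-interaction record for gene {self.gene_a!r}")
        if self.score < 0:
            raise ValueError("PPI score must be >= 0")

    @property
    def provenance(self) -> str:
        return _PROVENANCE.get(self.source, self.source)


class IntegratedNetwork:
    """Undirected multigraph of reaction and protein nodes.

    Backed by :class:`networkx.MultiGraph` with edge keys ``metabolic``
    and ``ppi`` — a node pair can carry at most one edge of each kind.
    Node attributes: ``kind`` (``reaction`` | ``protein``), ``genes``
    (frozenset), ``rule`` (:class:`GeneRule` or None).  Metabolic edges
    record the shared metabolites, ppi edges their provenance tag.
    """

    def __init__(self, graph: nx.MultiGraph | None = None) -> None:
        self.graph = graph if graph is not None else nx.MultiGraph()

    # -- construction helpers -----------------------------------------
    def add_reaction_node(self, rid: str, rule: GeneRule | None) -> None:
        genes = rule.genes() if rule is not None else frozenset()
        self.graph.add_node(rid, kind="reaction", genes=genes, rule=rule)

    def add_protein_node(self, gene: str) -> str:
        node_id = gene if gene not in self.graph else f"protein:{gene}"
        self.graph.add_node(node_id, kind="protein", genes=frozenset([gene]), rule=None)
        return node_id

    def add_metabolic_edge(self, u: str, v: str, shared: set[str]) -> None:
        if u == v:
            raise ValueError("self-edges are not allowed")
        if not shared:
            raise ValueError("metabolic edge requires a non-empty shared-metabolite set")
        self.graph.add_edge(u, v, key=KIND_METABOLIC, kind=KIND_METABOLIC,
                            shared=frozenset(shared), provenance="met")

    def add_ppi_edge(self, u: str, v: str, provenance: str) -> None:
        if u == v:
            return  # no self-edges after gene->node projection
        self.graph.add_edge(u, v, key=KIND_PPI, kind=KIND_PPI, provenance=provenance)

    # -- queries ------------------------------------------------------
    @property
    def nodes(self):
        return self.graph.nodes

    def node_kind(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]

    def genes_of_node(self, node: str) -> frozenset[str]:
        return self.graph.nodes[node]["genes"]

    def reaction_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "reaction"]

    def protein_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d["kind"] == "protein"]

    def edge_kinds(self, u: str, v: str) -> set[str]:
        if not self.graph.has_edge(u, v):
            return set()
        return set(self.graph[u][v].keys())

    def edges_of_kind(self, kind: str) -> list[tuple[str, str]]:
        return [(u, v) for u, v, k in self.graph.edges(keys=True) if k == kind]

    def copy(self) -> "IntegratedNetwork":
        return IntegratedNetwork(self.graph.copy())

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def build_reaction_graph(
    model: MetabolicModel, excluded_metabolites: set[str] | frozenset[str] = frozenset()
) -> IntegratedNetwork:
    """Build the reaction-node graph of a metabolic model.

    One node per reaction; an undirected metabolic edge joins two
    reactions whenever they share at least one metabolite not on the
    exclusion list.  Exclusion entries may be compartment-qualified
    (``"atp[c]"``, matching exactly) or compartment-free (``"atp"``,
    matching the metabolite in every compartment).
    """
    net = IntegratedNetwork()
    for rxn in model.reactions:
        net.add_reaction_node(rxn.id, rxn.rule)

    excluded = set(excluded_metabolites)

    def is_excluded(mid: str) -> bool:
        return mid in excluded or metabolite_base_id(mid) in excluded

    # index: metabolite -> reactions touching it
    touching: dict[str, list[str]] = {}
    for (rid, mid) in model.stoichiometry:
        if not is_excluded(mid):
            touching.setdefault(mid, []).append(rid)

    shared: dict[tuple[str, str], set[str]] = {}
    for mid, rids in touching.items():
        rids = sorted(set(rids))
        for i, u in enumerate(rids):
            for v in rids[i + 1 :]:
                shared.setdefault((u, v), set()).add(mid)
    for (u, v), mids in shared.items():
        net.add_metabolic_edge(u, v, mids)
    return net


def integrate_ppi(
    net: IntegratedNetwork,
    ppi: list[PpiRecord],
    score_threshold: int = 900,
) -> IntegratedNetwork:
    """Attach protein-protein interaction edges to a reaction network.

    Records with ``score > score_threshold`` (strict) are kept;
    kinase-phosphatase records bypass the score filter entirely.  Each
    retained gene pair connects every node pair (u, v) with
    gene_a in genes(u) and gene_b in genes(v) — one gene pair may
    materialize many edges when enzymes catalyze several reactions.
    A gene matching no node becomes a new protein node, provided its
    partner matched something; records with both genes unmatched are
    dropped (logged).  The input network is not mutated.
    """
    out = net.copy()
    gene_index: dict[str, set[str]] = {}
    for node in out.graph.nodes:
        for g in out.genes_of_node(node):
            gene_index.setdefault(g, set()).add(node)

    def resolve(gene: str) -> set[str]:
        return gene_index.get(gene, set())

    def materialize(gene: str) -> set[str]:
        node = out.add_protein_node(gene)
        gene_index.setdefault(gene, set()).add(node)
        return {node}

    for rec in ppi:
        if rec.source != "kinase-phosphatase" and rec.score <= score_threshold:
            continue
        nodes_a, nodes_b = resolve(rec.gene_a), resolve(rec.gene_b)
        if not nodes_a and not nodes_b:
            logger.info(
                "dropping PPI record %s-%s: neither gene matches the network",
                rec.gene_a, rec.gene_b,
            )
            continue
        if not nodes_a:
            nodes_a = materialize(rec.gene_a)
        if not nodes_b:
            nodes_b = materialize(rec.gene_b)
        for u in nodes_a:
            for v in nodes_b:
                out.add_ppi_edge(u, v, rec.provenance)
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_ppi_table(path: str | Path) -> list[PpiRecord]:
    """Read a PPI TSV with columns gene_a, gene_b, score, source."""
    records: list[PpiRecord] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"gene_a", "gene_b", "score"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: PPI table needs columns {sorted(required)}")
        for row in reader:
            records.append(
                PpiRecord(
                    gene_a=row["gene_a"].strip(),
                    gene_b=row["gene_b"].strip(),
                    score=int(row["score"]),
                    source=(row.get("source") or "string-experimental").strip(),
                )
            )
    return records


def write_ppi_table(records: list[PpiRecord], path: str | Path) -> None:
    lines = ["gene_a\tgene_b\tscore\tsource"]
    for r in records:
        lines.append(f"{r.gene_a}\t{r.gene_b}\t{r.score}\t{r.source}")
    Path(path).write_text("\n".join(lines) + "\n")


def _exportable_graph(net: IntegratedNetwork) -> nx.MultiGraph:
    g = nx.MultiGraph()
    for node, data in net.graph.nodes(data=True):
        attrs = {"kind": data["kind"], "genes": ";".join(sorted(data["genes"]))}
        if data.get("rule") is not None:
            attrs["rule"] = data["rule"].to_string(symbols=True)
        for extra in ("tw", "fw", "w", "sign"):
            if extra in data:
                attrs[extra] = data[extra]
        g.add_node(node, **attrs)
    for u, v, key, data in net.graph.edges(keys=True, data=True):
        attrs = {"kind": data["kind"], "provenance": data.get("provenance", "")}
        if "shared" in data:
            attrs["shared"] = ";".join(sorted(data["shared"]))
        g.add_edge(u, v, key=key, **attrs)
    return g


def write_graphml(net: IntegratedNetwork, path: str | Path) -> None:
    """Export to GraphML with kind/genes node attrs and kind/provenance
    edge attrs."""
    nx.write_graphml(_exportable_graph(net), str(path))


def write_sif(net: IntegratedNetwork, path: str | Path) -> None:
    """Export edges in SIF; the relation column carries the provenance
    tag (``met`` for metabolic, ``S``/``KPI`` for ppi edges)."""
    lines = []
    for u, v, data in sorted(
        net.graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]), e[2]["kind"])
    ):
        lines.append(f"{u}\t{data.get('provenance', data['kind'])}\t{v}")
    Path(path).write_text("\n".join(lines) + "\n")
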