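"""Synthetic fixtures: toy models, PPI tables, omics data, annotations.

Everything the pipeline consumes can be generated here without any
download: a random sparse metabolic model whose reaction graph is
connected, cofactor metabolites shared by many reactions (to exercise
the exclusion list), STRING-style and kinase-phosphatase PPI records,
two-condition expression and flux data, and GMT-like category
annotations.  A benchmark mode plants a high-weight simple path in the
integrated network: the genes and fluxes of its nodes get a known log2
case/control shift, so recovery can be scored against ground truth.

The planted shift is applied with a mild linear taper along the path
(mean equal to the nominal shift, slightly higher at the first node),
which makes the endpoint-anchored greedy search's target well defined;
see the methods note.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrich import CategoryAnnotation
from .fluxes import FluxSummary, _feasible_point
from .model import MetabolicModel, ReactionRecord, write_tabular_model
from .network import IntegratedNetwork, PpiRecord, build_reaction_graph, integrate_ppi, write_ppi_table
from .rules import GeneRule
from .weighting import ExpressionData

__all__ = [
    "FixtureBundle",
    "FixtureError",
    "FixtureSpec",
    "generate",
    "make_annotation",
    "make_omics",
    "make_ppi",
    "make_toy_model",
    "write_fixture_dir",
]


class FixtureError(ValueError):
    """The fixture specification cannot be realized."""


@dataclass
class FixtureSpec:
    """Knobs of the synthetic-data generator.

    Defaults give a mid-sized connected network with four expression
    replicates per condition (as in the chemostat study design the
    generator emulates) and a planted length-8 path shifted by +3 log2
    units against a unit-variance background of per-gene fold changes.
    """

    n_reactions: int = 50
    n_metabolites: int = 55
    n_cofactors: int = 3
    n_proteins: int = 10
    n_ppi: int = 40
    mean_extra_metabolites: float = 1.6
    planted_path_length: int | None = 8
    planted_weight_shift: float = 3.0
    planted_taper: float = 1.0
    n_replicates: int = 4
    noise_sd: float = 0.1
    background_logfc_sd: float = 1.0
    flux_noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (self.n_reactions, self.n_metabolites, self.n_cofactors,
                  self.n_proteins, self.n_ppi, self.n_replicates)
        if any(c < 0 for c in counts):
            raise FixtureError("all counts must be >= 0")
        if self.n_reactions > 0 and self.n_metabolites < 2:
            raise FixtureError("need >= 2 metabolites to form reactions")
        if self.planted_path_length is not None:
            if self.planted_path_length > self.n_reactions + self.n_proteins:
                raise FixtureError("planted path longer than the network can hold")
            if self.planted_path_length < 2:
                raise FixtureError("planted path length must be >= 2")
        if self.noise_sd < 0 or self.flux_noise_sd < 0 or self.background_logfc_sd < 0:
            raise FixtureError("noise levels must be >= 0")
        if self.n_replicates < 1:
            raise FixtureError("need >= 1 replicate per condition")

    @staticmethod
    def from_json(path: str | Path) -> "FixtureSpec":
        data = json.loads(Path(path).read_text())
        return FixtureSpec(**data)


def _random_rule(rng: np.random.Generator, gene_counter: list[int]) -> GeneRule:
    def fresh() -> GeneRule:
        gene_counter[0] += 1
        return GeneRule.leaf(f"YG{gene_counter[0]:04d}W")

    u = rng.random()
    if u < 0.50:
        return fresh()
    if u < 0.75:
        return GeneRule.or_(fresh(), fresh())
    if u < 0.90:
        return GeneRule.and_(fresh(), fresh())
    return GeneRule.and_(fresh(), GeneRule.or_(fresh(), fresh()))


def make_toy_model(spec: FixtureSpec) -> tuple[MetabolicModel, list[str]]:
    """Random sparse model with a connected reaction graph.

    Each reaction consumes a metabolite already touched by an earlier
    reaction (guaranteeing connectivity of the shared-metabolite graph)
    and produces a fresh one while the pool lasts.  Cofactor
    metabolites are attached to roughly half of all reactions; the
    returned exclusion list holds their compartment-free ids.
    """
    rng = np.random.default_rng(spec.seed)
    comps = ["c", "m"]
    mets = [f"m{i:03d}[{comps[int(rng.integers(2))]}]" for i in range(spec.n_metabolites)]
    cof_mets = [f"cof{j}[{c}]" for j in range(spec.n_cofactors) for c in comps]
    gene_counter = [0]

    reactions: list[ReactionRecord] = []
    stoich: dict[tuple[str, str], float] = {}
    used_mets: list[str] = []
    next_new = 0

    for i in range(spec.n_reactions):
        rid = f"r{i:03d}"
        entries: dict[str, float] = {}
        if i == 0:
            sub = mets[0]
            next_new = 1
        else:
            sub = used_mets[int(rng.integers(len(used_mets)))]
        entries[sub] = entries.get(sub, 0.0) - 1.0
        if next_new < spec.n_metabolites:
            prod = mets[next_new]
            next_new += 1
        else:
            others = [m for m in mets if m not in entries]
            prod = others[int(rng.integers(len(others)))]
        entries[prod] = entries.get(prod, 0.0) + 1.0
        # extra shared metabolites set the reaction-graph density; the
        # default mean targets the edge density of genome-scale
        # metabolic + PPI networks (average degree in the low teens)
        for _ in range(int(rng.poisson(spec.mean_extra_metabolites))):
            if not used_mets:
                break
            extra = used_mets[int(rng.integers(len(used_mets)))]
            if extra not in entries:
                entries[extra] = -1.0 if rng.random() < 0.5 else 1.0
        if spec.n_cofactors and rng.random() < 0.5:
            cof = cof_mets[int(rng.integers(len(cof_mets)))]
            if cof not in entries:
                entries[cof] = -1.0 if rng.random() < 0.5 else 1.0
        for mid, coef in entries.items():
            stoich[(rid, mid)] = coef
            if mid not in used_mets and not mid.startswith("cof"):
                used_mets.append(mid)
        reversible = rng.random() < 0.3
        rule = None if rng.random() < 0.1 else _random_rule(rng, gene_counter)
        reactions.append(ReactionRecord(rid, -10.0 if reversible else 0.0, 10.0, rule))

    declared = [m for m in mets + cof_mets
                if any(mid == m for (_, mid) in stoich)]
    model = MetabolicModel(reactions=reactions, metabolites=declared, stoichiometry=stoich)
    exclusion = [f"cof{j}" for j in range(spec.n_cofactors)]
    return model, exclusion


def make_ppi(spec: FixtureSpec, model: MetabolicModel) -> list[PpiRecord]:
    """STRING-style scored records among enzyme genes plus unscored
    kinase-phosphatase records that pull in new protein nodes."""
    rng = np.random.default_rng(spec.seed + 1)
    reaction_genes = sorted({g for r in model.reactions for g in r.genes})
    records: list[PpiRecord] = []
    seen_pairs: set[frozenset[str]] = set()

    kinases = [f"YK{i:03d}W" for i in range(spec.n_proteins)]
    for kin in kinases:
        if not reaction_genes:
            break
        for _ in range(int(rng.integers(1, 3))):
            partner = reaction_genes[int(rng.integers(len(reaction_genes)))]
            pair = frozenset((kin, partner))
            if len(pair) < 2 or pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            records.append(PpiRecord(kin, partner, 0, source="kinase-phosphatase"))

    pool = reaction_genes + kinases
    attempts = 0
    added = 0
    while added < spec.n_ppi and attempts < 50 * max(spec.n_ppi, 1) and len(pool) >= 2:
        attempts += 1
        a, b = rng.choice(len(pool), size=2, replace=False)
        pair = frozenset((pool[a], pool[b]))
        if pair in seen_pairs:
            continue
        seen_pairs.add(pair)
        records.append(PpiRecord(pool[a], pool[b], int(rng.integers(600, 1000)),
                                 source="string-experimental"))
        added += 1
    return records


def _random_simple_path(net: IntegratedNetwork, length: int, rng: np.random.Generator,
                        tries: int = 5000) -> list[str]:
    # Constraints keep the planted truth well-defined as a search target:
    # only gene-bearing nodes can carry an expression shift (so the plant
    # never routes through non-enzymatic reactions), and the path is
    # induced (no chords) so the planted node sequence is the unique
    # high-weight walk through its own node set.
    graph = net.graph
    nodes = [n for n in graph.nodes if net.genes_of_node(n)]
    if not nodes:
        raise FixtureError("network has no gene-bearing nodes to plant a path on")
    for _ in range(tries):
        current = nodes[int(rng.integers(len(nodes)))]
        path = [current]
        while len(path) < length:
            nbrs = [
                n for n in graph.neighbors(path[-1])
                if n not in path and net.genes_of_node(n)
                and not any(graph.has_edge(n, p) for p in path[:-1])
            ]
            if not nbrs:
                break
            path.append(nbrs[int(rng.integers(len(nbrs)))])
        if len(path) == length:
            return path
    raise FixtureError(f"no induced simple path of length {length} found in the network")


def make_omics(
    spec: FixtureSpec, model: MetabolicModel, net: IntegratedNetwork
) -> tuple[ExpressionData, FluxSummary, list[str] | None]:
    """Two-condition expression and flux data, optionally with a
    planted high-weight path.

    Per-gene baseline log2 intensities ~ N(8, 1); per-gene true log2
    case/control fold changes ~ N(0, background_logfc_sd), replicate
    noise ~ N(0, noise_sd).  Baseline fluxes come from a random
    feasible point of the model (magnitudes clipped away from 0), with
    per-reaction background log2 flux ratios of the same spread.  If a
    path is planted, its nodes' genes and reactions get the tapered
    shift instead of a background fold change.  Returns the planted
    node list as ground truth (None when nothing is planted).
    """
    rng = np.random.default_rng(spec.seed + 2)
    genes: list[str] = sorted(
        {g for node in net.graph.nodes for g in net.genes_of_node(node)}
    )

    truth: list[str] | None = None
    gene_shift: dict[str, float] = {}
    rxn_shift: dict[str, float] = {}
    if spec.planted_path_length is not None:
        L = spec.planted_path_length
        truth = _random_simple_path(net, L, rng)
        for j, node in enumerate(truth):
            frac = 0.5 - (j / (L - 1)) if L > 1 else 0.0
            s_j = spec.planted_weight_shift + spec.planted_taper * frac
            for g in net.genes_of_node(node):
                gene_shift.setdefault(g, s_j)
            if net.node_kind(node) == "reaction":
                rxn_shift[node] = s_j

    base = 8.0 + rng.standard_normal(len(genes))
    delta = rng.standard_normal(len(genes)) * spec.background_logfc_sd
    for gi, g in enumerate(genes):
        if g in gene_shift:
            delta[gi] = gene_shift[g]

    samples: dict[str, np.ndarray] = {}
    condition_of: dict[str, str] = {}
    for cond, effect in (("control", 0.0), ("case", 1.0)):
        for rep in range(1, spec.n_replicates + 1):
            name = f"{cond}.r{rep}"
            eps = rng.standard_normal(len(genes)) * spec.noise_sd
            samples[name] = np.exp2(base + effect * delta + eps)
            condition_of[name] = cond
    expr = ExpressionData(
        intensities=pd.DataFrame(samples, index=genes), condition_of=condition_of
    )

    S, _, rxns = model.stoich_matrix()
    lb, ub = model.bounds_arrays()
    v0 = _feasible_point(S, lb, ub, c=rng.standard_normal(len(rxns)))
    baseline = np.maximum(np.abs(v0), 0.25)
    rxn_delta = rng.standard_normal(len(rxns)) * spec.background_logfc_sd
    for ri, rid in enumerate(rxns):
        if rid in rxn_shift:
            rxn_delta[ri] = rxn_shift[rid]
    eta_ctl = rng.standard_normal(len(rxns)) * spec.flux_noise_sd
    eta_case = rng.standard_normal(len(rxns)) * spec.flux_noise_sd
    control_mean = baseline * np.exp2(eta_ctl)
    case_mean = baseline * np.exp2(eta_case + rxn_delta)
    flux = FluxSummary.from_condition_means({
        "control": pd.Series(control_mean, index=rxns),
        "case": pd.Series(case_mean, index=rxns),
    })
    return expr, flux, truth


def make_annotation(
    model: MetabolicModel,
    n_categories: int,
    seed: int,
    extra_genes: list[str] | None = None,
    planted_genes: set[str] | None = None,
) -> CategoryAnnotation:
    """Random gene partition into categories, plus (when planted genes
    are given) one positive-control category concentrated on them."""
    if n_categories < 1:
        raise FixtureError("need >= 1 category")
    rng = np.random.default_rng(seed)
    genes = sorted({g for r in model.reactions for g in r.genes} | set(extra_genes or []))
    perm = [genes[i] for i in rng.permutation(len(genes))]
    chunks = np.array_split(np.arange(len(perm)), n_categories)
    categories: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for ci, chunk in enumerate(chunks):
        if len(chunk) == 0:
            continue
        cat = f"C{ci + 1:02d}"
        categories[cat] = frozenset(perm[i] for i in chunk)
        names[cat] = f"random category {ci + 1}"
    if planted_genes:
        padding = [g for g in perm if g not in planted_genes][:2]
        categories["PLANTED"] = frozenset(planted_genes) | frozenset(padding)
        names["PLANTED"] = "positive-control category on the planted path"
    return CategoryAnnotation(categories=categories, names=names)


@dataclass
class FixtureBundle:
    """Everything one synthetic study needs, generated from one spec."""

    spec: FixtureSpec
    model: MetabolicModel
    exclusion: list[str]
    ppi: list[PpiRecord]
    network: IntegratedNetwork
    expression: ExpressionData
    flux: FluxSummary
    truth: list[str] | None
    annotation: CategoryAnnotation = field(repr=False, default=None)  # type: ignore[assignment]


def generate(spec: FixtureSpec, n_categories: int = 8,
             score_threshold: int = 900) -> FixtureBundle:
    """Build a complete synthetic study from one spec (deterministic)."""
    model, exclusion = make_toy_model(spec)
    ppi = make_ppi(spec, model)
    net = integrate_ppi(build_reaction_graph(model, set(exclusion)), ppi, score_threshold)
    expr, flux, truth = make_omics(spec, model, net)
    planted_genes = None
    if truth is not None:
        planted_genes = set()
        for node in truth:
            planted_genes |= net.genes_of_node(node)
    kinase_genes = sorted(
        g for node in net.protein_nodes() for g in net.genes_of_node(node)
    )
    annotation = make_annotation(model, n_categories, spec.seed + 3,
                                 extra_genes=kinase_genes, planted_genes=planted_genes)
    return FixtureBundle(spec, model, exclusion, ppi, net, expr, flux, truth, annotation)


def write_fixture_dir(bundle: FixtureBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle as plain-text files; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": out / "model.tsv",
        "ppi": out / "ppi.tsv",
        "expression": out / "expression.tsv",
        "samples": out / "samples.tsv",
        "flux": out / "flux.tsv",
        "annotation": out / "annotation.gmt",
        "exclusion": out / "excluded_metabolites.txt",
        "truth": out / "truth.json",
    }
    write_tabular_model(bundle.model, paths["model"])
    write_ppi_table(bundle.ppi, paths["ppi"])
    bundle.expression.to_tsv(paths["expression"], paths["samples"])
    bundle.flux.to_tsv(paths["flux"])
    bundle.annotation.to_gmt(paths["annotation"])
    paths["exclusion"].write_text("\n".join(bundle.exclusion) + "\n")
    paths["truth"].write_text(json.dumps({"planted_path": bundle.truth}, indent=2) + "\n")
    return paths
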