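"""Metabolic model container and readers (tabular dialect and SBML/fbc).

A :class:`MetabolicModel` holds reactions with flux bounds, a signed
stoichiometric matrix in sparse dict form, compartment-tagged metabolite
ids (``"pyr[c]"``), and an optional gene rule per reaction.  Two input
dialects are supported: a tab-separated format designed for synthetic
fixtures, and SBML Level 3 with the fbc package for gene-product
associations.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rules import GeneRule, RuleError, parse_rule

__all__ = [
    "FormatError",
    "MetabolicModel",
    "ReactionRecord",
    "metabolite_base_id",
    "read_model",
    "read_sbml_model",
    "read_tabular_model",
    "write_tabular_model",
]


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


_COMPARTMENT_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")


def metabolite_base_id(metabolite_id: str) -> str:
    """Strip a trailing ``[compartment]`` tag, if present."""
    m = _COMPARTMENT_RE.match(metabolite_id)
    return m.group("base") if m else metabolite_id


def metabolite_compartment(metabolite_id: str) -> str | None:
    m = _COMPARTMENT_RE.match(metabolite_id)
    return m.group("comp") if m else None


@dataclass
class ReactionRecord:
    id: str
    lower: float
    upper: float
    rule: GeneRule | None = None
    name: str | None = None

    @property
    def genes(self) -> frozenset[str]:
        return self.rule.genes() if self.rule is not None else frozenset()

    @property
    def reversible(self) -> bool:
        return self.lower < 0 < self.upper


@dataclass
class MetabolicModel:
    """Reactions, metabolites and a sparse stoichiometric map.

    ``stoichiometry`` maps ``(reaction_id, metabolite_id)`` to a signed
    coefficient (negative for substrates, positive for products).
    """

    reactions: list[ReactionRecord]
    metabolites: list[str]
    stoichiometry: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({r for r in rids if rids.count(r) > 1})
            raise FormatError(f"duplicate reaction id(s): {dupes}")
        if len(set(self.metabolites)) != len(self.metabolites):
            raise FormatError("duplicate metabolite ids")
        for rxn in self.reactions:
            if not rxn.lower <= rxn.upper:
                raise FormatError(
                    f"reaction {rxn.id!r}: lower bound {rxn.lower} > upper {rxn.upper}"
                )
        rid_set, mid_set = set(rids), set(self.metabolites)
        for (rid, mid), coef in self.stoichiometry.items():
            if rid not in rid_set:
                raise FormatError(f"stoichiometry references unknown reaction {rid!r}")
            if mid not in mid_set:
                raise FormatError(f"stoichiometry references unknown metabolite {mid!r}")
            if coef == 0:
                raise FormatError(f"zero stoichiometric coefficient for ({rid}, {mid})")

    # -- views ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> ReactionRecord:
        for r in self.reactions:
            if r.id == rid:
                return r
        raise KeyError(rid)

    def metabolites_of(self, rid: str) -> set[str]:
        return {mid for (r, mid) in self.stoichiometry if r == rid}

    def stoich_matrix(self) -> tuple[np.ndarray, list[str], list[str]]:
        """Dense S matrix (metabolites x reactions) with its row/col ids."""
        mets = list(self.metabolites)
        rxns = self.reaction_ids
        midx = {m: i for i, m in enumerate(mets)}
        ridx = {r: j for j, r in enumerate(rxns)}
        S = np.zeros((len(mets), len(rxns)))
        for (rid, mid), coef in self.stoichiometry.items():
            S[midx[mid], ridx[rid]] = coef
        return S, mets, rxns

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower for r in self.reactions], dtype=float)
        ub = np.array([r.upper for r in self.reactions], dtype=float)
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reactions=[
                ReactionRecord(r.id, r.lower, r.upper, r.rule, r.name)
                for r in self.reactions
            ],
            metabolites=list(self.metabolites),
            stoichiometry=dict(self.stoichiometry),
        )

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for (rid, mid), coef in sorted(self.stoichiometry.items()):
            h.update(f"{rid}\t{mid}\t{coef!r}\n".encode())
        for r in self.reactions:
            h.update(f"{r.id}\t{r.lower!r}\t{r.upper!r}\n".encode())
        return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Tabular dialect: id <TAB> equation <TAB> lower <TAB> upper <TAB> rule
# Equation: "A[c] + 2 B[c] -> C[m]"; "<->" marks a reversible reaction.
# ---------------------------------------------------------------------------

_HEADER = ["id", "equation", "lower", "upper", "rule"]


def _parse_side(side: str, rid: str, lineno: int) -> list[tuple[str, float]]:
    out: list[tuple[str, float]] = []
    side = side.strip()
    if not side:
        return out
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise FormatError(f"line {lineno}: empty term in equation of {rid!r}")
        parts = term.split()
        if len(parts) == 1:
            coef, mid = 1.0, parts[0]
        elif len(parts) == 2:
            try:
                coef = float(parts[0])
            except ValueError as exc:
                raise FormatError(
                    f"line {lineno}: bad coefficient {parts[0]!r} in {rid!r}"
                ) from exc
            mid = parts[1]
        else:
            raise FormatError(f"line {lineno}: malformed term {term!r} in {rid!r}")
        out.append((mid, coef))
    return out


def _parse_equation(eq: str, rid: str, lineno: int) -> list[tuple[str, float]]:
    for arrow in ("<->", "<=>", "->", "=>"):
        if arrow in eq:
            left, right = eq.split(arrow, 1)
            break
    else:
        raise FormatError(f"line {lineno}: equation of {rid!r} lacks an arrow: {eq!r}")
    entries: dict[str, float] = {}
    for mid, coef in _parse_side(left, rid, lineno):
        entries[mid] = entries.get(mid, 0.0) - coef
    for mid, coef in _parse_side(right, rid, lineno):
        entries[mid] = entries.get(mid, 0.0) + coef
    return [(m, c) for m, c in entries.items() if c != 0.0]


def read_tabular_model(path: str | Path) -> MetabolicModel:
    """Read the tab-separated model dialect (see module docstring)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise FormatError(f"{path}: empty model file")
    header = [c.strip() for c in lines[0].rstrip("\n").split("\t")]
    if [h.lower() for h in header[: len(_HEADER)]] != _HEADER:
        raise FormatError(f"{path}: header must be {_HEADER}, got {header}")
    reactions: list[ReactionRecord] = []
    stoich: dict[tuple[str, str], float] = {}
    mets: list[str] = []
    seen_mets: set[str] = set()
    seen_rids: set[str] = set()
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) < 4:
            raise FormatError(f"{path}: line {lineno}: expected >=4 columns")
        rid = cols[0].strip()
        if rid in seen_rids:
            raise FormatError(f"{path}: line {lineno}: duplicate reaction id {rid!r}")
        seen_rids.add(rid)
        try:
            lower, upper = float(cols[2]), float(cols[3])
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: bad bounds for {rid!r}") from exc
        rule_text = cols[4].strip() if len(cols) > 4 else ""
        try:
            rule = parse_rule(rule_text)
        except RuleError as exc:
            raise RuleError(f"{path}: line {lineno}: {exc}") from exc
        for mid, coef in _parse_equation(cols[1].strip(), rid, lineno):
            if mid not in seen_mets:
                seen_mets.add(mid)
                mets.append(mid)
            stoich[(rid, mid)] = coef
        reactions.append(ReactionRecord(rid, lower, upper, rule))
    return MetabolicModel(reactions=reactions, metabolites=mets, stoichiometry=stoich)


def write_tabular_model(model: MetabolicModel, path: str | Path) -> None:
    """Write a model back out in the tabular dialect."""
    path = Path(path)
    rows = ["\t".join(_HEADER)]
    for rxn in model.reactions:
        subs, prods = [], []
        for mid in sorted(model.metabolites_of(rxn.id)):
            coef = model.stoichiometry[(rxn.id, mid)]
            term = mid if abs(coef) == 1.0 else f"{abs(coef):g} {mid}"
            (subs if coef < 0 else prods).append(term)
        arrow = "<->" if rxn.reversible else "->"
        eq = f"{' + '.join(subs)} {arrow} {' + '.join(prods)}".strip()
        rule = rxn.rule.to_string() if rxn.rule is not None else ""
        rows.append(f"{rxn.id}\t{eq}\t{rxn.lower:g}\t{rxn.upper:g}\t{rule}")
    path.write_text("\n".join(rows) + "\n")


# ---------------------------------------------------------------------------
# SBML Level 3 (+fbc) reader
# ---------------------------------------------------------------------------


def _association_to_rule(assoc, gene_label: dict[str, str]) -> GeneRule | None:
    import libsbml

    if assoc is None:
        return None
    if isinstance(assoc, libsbml.GeneProductRef):
        gp = assoc.getGeneProduct()
        return GeneRule.leaf(gene_label.get(gp, gp))
    if isinstance(assoc, libsbml.FbcAnd):
        children = [
            _association_to_rule(assoc.getAssociation(i), gene_label)
            for i in range(assoc.getNumAssociations())
        ]
    elif isinstance(assoc, libsbml.FbcOr):
        children = [
            _association_to_rule(assoc.getAssociation(i), gene_label)
            for i in range(assoc.getNumAssociations())
        ]
    else:  # pragma: no cover - unknown association subtype
        raise FormatError(f"unsupported gene association element {type(assoc)}")
    children = [c for c in children if c is not None]
    if not children:
        return None
    if len(children) == 1:
        return children[0]
    ctor = GeneRule.and_ if isinstance(assoc, libsbml.FbcAnd) else GeneRule.or_
    return ctor(*children)


def read_sbml_model(path: str | Path, default_bound: float = 1000.0) -> MetabolicModel:
    """Read an SBML Level 3 model, using fbc bounds and gene associations.

    Falls back to ``+/-default_bound`` (reversible) or ``[0, default_bound]``
    when a reaction carries no fbc flux bounds.
    """
    import libsbml

    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors() > 0:
        for i in range(doc.getNumErrors()):
            err = doc.getError(i)
            if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
                raise FormatError(
                    f"{path}: SBML parse error at line {err.getLine()}: "
                    f"{err.getMessage().strip()}"
                )
    sbml_model = doc.getModel()
    if sbml_model is None:
        raise FormatError(f"{path}: no <model> element")

    params = {
        sbml_model.getParameter(i).getId(): sbml_model.getParameter(i).getValue()
        for i in range(sbml_model.getNumParameters())
    }
    fbc = sbml_model.getPlugin("fbc")
    gene_label: dict[str, str] = {}
    if fbc is not None:
        for i in range(fbc.getNumGeneProducts()):
            gp = fbc.getGeneProduct(i)
            gene_label[gp.getId()] = gp.getLabel() or gp.getId()

    species_comp = {}
    mets: list[str] = []
    for i in range(sbml_model.getNumSpecies()):
        sp = sbml_model.getSpecies(i)
        if sp.getBoundaryCondition():
            continue
        comp = sp.getCompartment()
        mid = f"{sp.getId()}[{comp}]" if comp else sp.getId()
        species_comp[sp.getId()] = mid
        mets.append(mid)

    reactions: list[ReactionRecord] = []
    stoich: dict[tuple[str, str], float] = {}
    for i in range(sbml_model.getNumReactions()):
        rxn = sbml_model.getReaction(i)
        rid = rxn.getId()
        rplug = rxn.getPlugin("fbc")
        lower = upper = None
        rule = None
        if rplug is not None:
            lb_id, ub_id = rplug.getLowerFluxBound(), rplug.getUpperFluxBound()
            if lb_id and lb_id in params:
                lower = params[lb_id]
            if ub_id and ub_id in params:
                upper = params[ub_id]
            rule = _association_to_rule(
                rplug.getGeneProductAssociation().getAssociation()
                if rplug.getGeneProductAssociation() is not None
                else None,
                gene_label,
            )
        if lower is None:
            lower = -default_bound if rxn.getReversible() else 0.0
        if upper is None:
            upper = default_bound
        for j in range(rxn.getNumReactants()):
            ref = rxn.getReactant(j)
            mid = species_comp.get(ref.getSpecies())
            if mid is not None:
                stoich[(rid, mid)] = stoich.get((rid, mid), 0.0) - ref.getStoichiometry()
        for j in range(rxn.getNumProducts()):
            ref = rxn.getProduct(j)
            mid = species_comp.get(ref.getSpecies())
            if mid is not None:
                stoich[(rid, mid)] = stoich.get((rid, mid), 0.0) + ref.getStoichiometry()
        reactions.append(ReactionRecord(rid, float(lower), float(upper), rule, rxn.getName() or None))
    stoich = {k: v for k, v in stoich.items() if v != 0.0}
    return MetabolicModel(reactions=reactions, metabolites=mets, stoichiometry=stoich)


def read_model(path: str | Path, dialect: str = "tabular") -> MetabolicModel:
    """Read a metabolic model in the named dialect (``tabular`` or ``sbml``)."""
    if dialect == "tabular":
        return read_tabular_model(path)
    if dialect == "sbml":
        return read_sbml_model(path)
    raise ValueError(f"unknown model dialect {dialect!r}")
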