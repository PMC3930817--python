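"""Node weights from transcription and flux data.

Each network node gets three weights for a case-control comparison:

* ``w_trans = log2(intensity_case / intensity_control)`` where per-gene
  intensities are averaged over replicates and collapsed through the
  reaction's gene rule (OR -> mean, AND -> minimum).  Non-enzymatic
  reactions score 0; protein (signaling) nodes use their single gene.
* ``w_flux = log2(max(flux_case, floor) / max(flux_control, floor))``
  from per-reaction mean absolute fluxes, floored at the flux detection
  threshold so zero fluxes stay defined.
* ``w_tot = a * w_flux + (1 - a) * w_trans`` with mixing parameter
  ``a`` in [0, 1]; protein nodes have no flux and always score
  ``w_tot = w_trans``.

When both data types are mixed, flux weights are affinely rescaled onto
the observed transcription-weight range so neither data type dominates
the detected paths.  Down-regulated paths are detected by inverting the
ratios (control/case) rather than negating weights, so scaling is
applied to the direction actually searched.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fluxes import FluxSummary, ZERO_FLUX_THRESHOLD
from .network import IntegratedNetwork
from .rules import GeneRule

__all__ = [
    "ExpressionData",
    "MissingDataError",
    "WeightedNetwork",
    "WeightingConfig",
    "assign_node_weights",
    "flux_weight",
    "rule_intensity",
    "scale_to_range",
    "transcription_weight",
]

logger = logging.getLogger(__name__)


class MissingDataError(KeyError):
    """A gene required by the network has no expression measurement."""


@dataclass
class ExpressionData:
    """Normalized expression intensities: genes x samples, all positive,
    with a sample -> condition map."""

    intensities: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() <= 0).any():
            raise ValueError("expression intensities must be strictly positive")
        missing = set(self.intensities.columns) - set(self.condition_of)
        if missing:
            raise ValueError(f"samples without a condition label: {sorted(missing)}")
        if not self.conditions:
            raise ValueError("expression data has no conditions")

    @property
    def conditions(self) -> list[str]:
        seen: list[str] = []
        for s in self.intensities.columns:
            c = self.condition_of[s]
            if c not in seen:
                seen.append(c)
        return seen

    def samples_of(self, condition: str) -> list[str]:
        cols = [s for s in self.intensities.columns if self.condition_of[s] == condition]
        if not cols:
            raise KeyError(f"condition {condition!r} has no samples")
        return cols

    def condition_means(self, condition: str) -> pd.Series:
        """Per-gene intensity averaged over the condition's replicates."""
        return self.intensities[self.samples_of(condition)].mean(axis=1)

    # -- I/O -----------------------------------------------------------
    @staticmethod
    def read_tsv(path: str | Path, samples_path: str | Path | None = None) -> "ExpressionData":
        """Read a gene x sample TSV (first column = gene id).

        The sample -> condition map comes from a sidecar TSV with
        columns ``sample`` and ``condition`` when given; otherwise
        sample names are parsed as ``<condition>.<replicate>``.
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        if samples_path is not None:
            side = pd.read_csv(samples_path, sep="\t")
            condition_of = dict(zip(side["sample"], side["condition"]))
        else:
            condition_of = {s: s.rsplit(".", 1)[0] for s in df.columns}
        return ExpressionData(intensities=df, condition_of=condition_of)

    def to_tsv(self, path: str | Path, samples_path: str | Path | None = None) -> None:
        self.intensities.to_csv(path, sep="\t", index_label="gene")
        if samples_path is not None:
            rows = ["sample\tcondition"]
            rows += [f"{s}\t{self.condition_of[s]}" for s in self.intensities.columns]
            Path(samples_path).write_text("\n".join(rows) + "\n")


@dataclass
class WeightingConfig:
    """Mixing and direction settings for node weighting.

    ``a`` weights the flux component (0 = transcription only, 1 = flux
    only).  ``direction`` selects up- (case/control ratios) or
    down-regulated (control/case) scoring.  ``zero_flux_floor`` keeps
    flux log-ratios defined at zero flux; ``scale_flux`` rescales flux
    weights onto the transcription-weight range.  ``impute_missing``
    substitutes the condition median intensity for genes absent from
    the expression matrix instead of raising.
    """

    a: float = 0.5
    direction: str = "up"
    zero_flux_floor: float = ZERO_FLUX_THRESHOLD
    scale_flux: bool = True
    impute_missing: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.a <= 1.0:
            raise ValueError("mixing parameter a must lie in [0, 1]")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        if self.zero_flux_floor <= 0:
            raise ValueError("zero_flux_floor must be > 0")


# ---------------------------------------------------------------------------
# Elementary weight formulas
# ---------------------------------------------------------------------------


def rule_intensity(rule: GeneRule, intensities: dict[str, float] | pd.Series) -> float:
    """Collapse per-gene intensities through a gene rule.

    OR nodes take the arithmetic mean of their children, AND nodes the
    minimum, leaves their gene's intensity.  Raises
    :class:`MissingDataError` naming the first absent gene.
    """
    if rule.op == "gene":
        try:
            value = intensities[rule.gene]
        except KeyError as exc:
            raise MissingDataError(
                f"gene {rule.gene!r} has no expression measurement"
            ) from exc
        if isinstance(value, float) and math.isnan(value):
            raise MissingDataError(f"gene {rule.gene!r} has no expression measurement")
        return float(value)
    child_values = [rule_intensity(c, intensities) for c in rule.children]
    if rule.op == "and":
        return min(child_values)
    return float(np.mean(child_values))


def transcription_weight(case_intensity: float, control_intensity: float) -> float:
    """log2 ratio of replicate-averaged expression intensities."""
    if case_intensity <= 0 or control_intensity <= 0:
        raise ValueError("expression intensities must be strictly positive")
    # difference of logs keeps the antisymmetry w(a,b) = -w(b,a) exact
    return math.log2(case_intensity) - math.log2(control_intensity)


def flux_weight(case_flux: float, control_flux: float,
                floor: float = ZERO_FLUX_THRESHOLD) -> float:
    """log2 ratio of mean absolute fluxes, floored to stay defined at 0."""
    if case_flux < 0 or control_flux < 0:
        raise ValueError("mean fluxes are magnitudes and must be >= 0")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    return math.log2(max(case_flux, floor)) - math.log2(max(control_flux, floor))


def scale_to_range(values, target_min: float, target_max: float) -> np.ndarray:
    """Affine map sending min(values) -> target_min, max -> target_max.

    A constant vector maps to the target midpoint.
    """
    if target_min >= target_max:
        raise ValueError("target_min must be < target_max")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot scale an empty vector")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.full_like(values, (target_min + target_max) / 2.0)
    return target_min + (values - lo) * (target_max - target_min) / (hi - lo)


# ---------------------------------------------------------------------------
# Network-level assignment
# ---------------------------------------------------------------------------


@dataclass
class WeightedNetwork:
    """An integrated network plus per-node w_trans / w_flux / w_tot."""

    network: IntegratedNetwork
    w_trans: pd.Series
    w_flux: pd.Series
    w_tot: pd.Series
    config: WeightingConfig = field(default_factory=WeightingConfig)
    case: str = "case"
    control: str = "control"

    @property
    def nodes(self) -> list[str]:
        return list(self.w_tot.index)

    def annotate_graph(self) -> IntegratedNetwork:
        """Copy of the network with tw/fw/w node attributes and a
        red/blue/neutral sign class on every node (for export)."""
        out = self.network.copy()
        for node in out.graph.nodes:
            tw = float(self.w_trans[node])
            fw = float(self.w_flux[node])
            w = float(self.w_tot[node])
            sign = "red" if w > 0 else ("blue" if w < 0 else "neutral")
            out.graph.nodes[node].update(tw=tw, fw=fw, w=w, sign=sign)
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = ["node_id\tw_trans\tw_flux\tw_tot"]
        for node in self.nodes:
            rows.append(
                f"{node}\t{float(self.w_trans[node])!r}\t"
                f"{float(self.w_flux[node])!r}\t{float(self.w_tot[node])!r}"
            )
        Path(path).write_text("\n".join(rows) + "\n")


def _gene_intensity_table(
    expr: ExpressionData, genes: set[str], condition: str, impute: bool
) -> pd.Series:
    means = expr.condition_means(condition)
    missing = sorted(g for g in genes if g not in means.index)
    if missing and not impute:
        raise MissingDataError(
            f"gene {missing[0]!r} has no expression measurement "
            f"({len(missing)} missing in total)"
        )
    if missing:
        median = float(means.median())
        logger.info("imputing condition median intensity for %d gene(s): %s",
                    len(missing), missing[:5])
        means = pd.concat([means, pd.Series(median, index=missing)])
    return means


def assign_node_weights(
    net: IntegratedNetwork,
    expr: ExpressionData,
    flux: FluxSummary | None,
    case: str,
    control: str,
    cfg: WeightingConfig | None = None,
) -> WeightedNetwork:
    """Compute w_trans, w_flux and w_tot for every node of the network.

    Reaction nodes evaluate their gene rule on replicate-averaged
    intensities per condition and take the log2 case/control ratio
    (0 for non-enzymatic reactions); their flux weight comes from the
    flux summary through the floored log2 ratio and is optionally
    rescaled onto the transcription-weight range.  Protein nodes score
    from transcription only.  ``direction='down'`` swaps case and
    control in both ratios before any scaling.
    """
    cfg = cfg or WeightingConfig()
    if cfg.a > 0 and flux is None:
        raise ValueError("flux data is required when the mixing parameter a > 0")
    for cond in (case, control):
        expr.samples_of(cond)  # raises if absent
        if flux is not None and cond not in flux.conditions:
            raise KeyError(f"condition {cond!r} missing from the flux summary")

    num_cond, den_cond = (case, control) if cfg.direction == "up" else (control, case)

    all_genes: set[str] = set()
    for node in net.graph.nodes:
        all_genes |= net.genes_of_node(node)
    num_int = _gene_intensity_table(expr, all_genes, num_cond, cfg.impute_missing)
    den_int = _gene_intensity_table(expr, all_genes, den_cond, cfg.impute_missing)

    nodes = list(net.graph.nodes)
    w_trans = pd.Series(0.0, index=nodes)
    w_flux = pd.Series(0.0, index=nodes)
    reaction_nodes: list[str] = []
    for node in nodes:
        data = net.graph.nodes[node]
        if data["kind"] == "reaction":
            reaction_nodes.append(node)
            rule = data.get("rule")
            if rule is not None:
                w_trans[node] = transcription_weight(
                    rule_intensity(rule, num_int), rule_intensity(rule, den_int)
                )
            if flux is not None:
                w_flux[node] = flux_weight(
                    flux.mean_flux(node, num_cond),
                    flux.mean_flux(node, den_cond),
                    floor=cfg.zero_flux_floor,
                )
        else:  # protein node: single gene, transcription only
            (gene,) = data["genes"]
            w_trans[node] = transcription_weight(num_int[gene], den_int[gene])

    if flux is not None and cfg.scale_flux and reaction_nodes:
        t_lo, t_hi = float(w_trans.min()), float(w_trans.max())
        if t_lo < t_hi:
            w_flux[reaction_nodes] = scale_to_range(
                w_flux[reaction_nodes].to_numpy(), t_lo, t_hi
            )
        else:
            logger.warning("degenerate transcription-weight range; flux weights left unscaled")

    w_tot = cfg.a * w_flux + (1.0 - cfg.a) * w_trans
    for node in nodes:
        if net.graph.nodes[node]["kind"] == "protein":
            w_tot[node] = w_trans[node]

    return WeightedNetwork(
        network=net, w_trans=w_trans, w_flux=w_flux, w_tot=w_tot,
        config=cfg, case=case, control=control,
    )
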