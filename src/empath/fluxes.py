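"""Flux context: constraint expansion to feasibility and polytope sampling.

Measured extracellular rates (growth, substrate uptake, product
secretion) rarely agree exactly with the steady-state constraint
``S v = 0`` of a metabolic model.  Strict constraints (oxygen uptake and
the P/O-ratio-linked bounds) are pinned at their measured means, while
the remaining rate constraints are expanded simultaneously and
gradually — by a fixed fraction of each rate's standard error of the
mean per step — until a feasible flux solution exists.  The feasible
polytope is then sampled with an artificial-centering hit-and-run chain
and per-reaction mean absolute fluxes are summarized from a random
subset of the collected points, zeroing means below a detection
threshold (default 1e-7 mmol/(g CDW h)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import null_space
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "FluxSamples",
    "FluxSummary",
    "InfeasibleModelError",
    "RateMeasurement",
    "expand_bounds_until_feasible",
    "hit_and_run_sample",
    "summarize_fluxes",
]

logger = logging.getLogger(__name__)

ZERO_FLUX_THRESHOLD = 1e-7  # mmol/(g CDW h)


class InfeasibleModelError(RuntimeError):
    """No feasible flux distribution exists under the given constraints."""


@dataclass(frozen=True)
class RateMeasurement:
    """A measured extracellular rate with its SEM.

    ``strict`` rates are fixed at their mean and never expanded (OUR and
    P/O-linked constraints).  ``free`` rates are released entirely
    (bounds -inf..+inf), as done for the carbon evolution rate.
    """

    reaction_id: str
    mean: float
    sem: float = 0.0
    strict: bool = False
    free: bool = False

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")
        if self.strict and self.free:
            raise ValueError("a measurement cannot be both strict and free")


def _lp_feasible(S: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> bool:
    if np.any(lb > ub):
        return False
    res = linprog(
        c=np.zeros(S.shape[1]),
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    return res.status == 0


def _feasible_point(S: np.ndarray, lb: np.ndarray, ub: np.ndarray,
                    c: np.ndarray | None = None) -> np.ndarray:
    res = linprog(
        c=np.zeros(S.shape[1]) if c is None else c,
        A_eq=S if S.shape[0] else None,
        b_eq=np.zeros(S.shape[0]) if S.shape[0] else None,
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status != 0:
        raise InfeasibleModelError("LP found no feasible flux distribution")
    return np.asarray(res.x, dtype=float)


def _apply_measurements(
    model: MetabolicModel, measurements: list[RateMeasurement], m: int, step_fraction: float
) -> MetabolicModel:
    out = model.copy()
    by_id = {r.id: r for r in out.reactions}
    for meas in measurements:
        if meas.reaction_id not in by_id:
            raise KeyError(f"measured reaction {meas.reaction_id!r} not in model")
        rxn = by_id[meas.reaction_id]
        if meas.free:
            rxn.lower, rxn.upper = -np.inf, np.inf
        elif meas.strict:
            rxn.lower = rxn.upper = meas.mean
        else:
            half = m * step_fraction * meas.sem
            rxn.lower, rxn.upper = meas.mean - half, meas.mean + half
    return out


def expand_bounds_until_feasible(
    model: MetabolicModel,
    measurements: list[RateMeasurement],
    step_fraction: float = 0.1,
) -> tuple[MetabolicModel, int]:
    """Install measured rates and expand them until the model is feasible.

    Non-strict measurements get bounds
    ``[mean - m*step_fraction*sem, mean + m*step_fraction*sem]`` for the
    smallest integer ``m >= 0`` making ``{S v = 0, bounds}`` feasible;
    all non-strict measurements share the same multiplier.  Strict
    measurements are fixed at their mean, free ones are unbounded.

    Returns the constrained model and the multiplier used.  Raises
    :class:`InfeasibleModelError` if no feasible solution exists by the
    time every expanded half-width has reached 10 SEMs.
    """
    if step_fraction <= 0:
        raise ValueError("step_fraction must be > 0")
    S, _, _ = model.stoich_matrix()
    m_max = int(np.ceil(10.0 / step_fraction))
    expandable = [x for x in measurements if not x.strict and not x.free]
    for m in range(m_max + 1):
        candidate = _apply_measurements(model, measurements, m, step_fraction)
        lb, ub = candidate.bounds_arrays()
        if _lp_feasible(S, lb, ub):
            if m > 0:
                logger.info("bounds expanded %d step(s) of %.0f%% SEM to reach feasibility",
                            m, 100 * step_fraction)
            return candidate, m
        if not expandable:
            break
    blocking = sorted(x.reaction_id for x in measurements if x.strict) or \
        sorted(x.reaction_id for x in measurements)
    raise InfeasibleModelError(
        "no feasible flux distribution within 10 SEMs of the measured rates; "
        f"check constraints on {blocking}"
    )


# ---------------------------------------------------------------------------
# Artificial-centering hit-and-run sampling
# ---------------------------------------------------------------------------


@dataclass
class FluxSamples:
    """Sampled flux vectors (points x reactions) with provenance."""

    points: np.ndarray
    reaction_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=self.reaction_ids)


_CHORD_CAP = 1e6  # fallback chord bound when a direction is unbounded


def _chord(v: np.ndarray, d: np.ndarray, lb: np.ndarray, ub: np.ndarray) -> tuple[float, float]:
    """Range of t with lb <= v + t d <= ub."""
    tmin, tmax = -np.inf, np.inf
    nz = np.abs(d) > 1e-12
    if not nz.any():
        return 0.0, 0.0
    with np.errstate(invalid="ignore"):
        lo = (lb[nz] - v[nz]) / d[nz]
        hi = (ub[nz] - v[nz]) / d[nz]
    t_lo = np.minimum(lo, hi)
    t_hi = np.maximum(lo, hi)
    tmin = np.max(t_lo) if t_lo.size else -np.inf
    tmax = np.min(t_hi) if t_hi.size else np.inf
    tmin = max(tmin, -_CHORD_CAP)
    tmax = min(tmax, _CHORD_CAP)
    return float(tmin), float(tmax)


def hit_and_run_sample(
    model: MetabolicModel,
    n_points: int,
    warmup: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> FluxSamples:
    """Sample the steady-state flux polytope {S v = 0, lb <= v <= ub}.

    Runs a hit-and-run chain restricted to the null space of S (so the
    steady-state constraint holds to machine precision): ``warmup``
    uniformly-directed steps are discarded, after which directions are
    drawn through the running center of all visited points (artificial
    centering) and ``n_points`` consecutive points are collected.

    A zero-dimensional polytope (fully determined model) yields the
    unique point replicated ``n_points`` times, with a warning.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    S, _, rxns = model.stoich_matrix()
    lb, ub = model.bounds_arrays()

    # pin fully determined coordinates into the equality system so the
    # null-space basis cannot move them
    fixed = lb == ub
    rows = [S] if S.shape[0] else []
    if fixed.any():
        eye = np.eye(len(rxns))[fixed]
        rows.append(eye)
    A = np.vstack(rows) if rows else np.zeros((0, len(rxns)))

    v0 = _feasible_point(S, lb, ub, c=rng.standard_normal(len(rxns)) * 1e-3)
    if A.size:
        # refine the LP point onto the equality system (the solver only
        # guarantees feasibility to its own tolerance)
        b = np.concatenate([np.zeros(S.shape[0]), lb[fixed]]) if fixed.any() \
            else np.zeros(S.shape[0])
        correction, *_ = np.linalg.lstsq(A, b - A @ v0, rcond=None)
        v0 = np.clip(v0 + correction, lb, ub)
    N = null_space(A) if A.size else np.eye(len(rxns))
    if A.size and N.size == 0:
        N = np.zeros((len(rxns), 0))

    def pack(points: np.ndarray) -> FluxSamples:
        return FluxSamples(
            points=points,
            reaction_ids=list(rxns),
            provenance={
                "seed": "generator" if isinstance(seed, np.random.Generator) else seed,
                "n_collected": int(points.shape[0]),
                "model_hash": model.content_hash(),
            },
        )

    if N.shape[1] == 0:
        logger.warning("flux polytope is zero-dimensional; replicating its unique point")
        return pack(np.tile(v0, (n_points, 1)))

    dim = N.shape[1]
    NT = N.T
    v = v0.copy()
    center = v0.copy()
    n_seen = 1
    pool: list[np.ndarray] = [v0.copy()]
    collected = np.empty((n_points, len(rxns)))
    degenerate_streak = 0

    total = warmup + n_points
    for step in range(total):
        if step < warmup or len(pool) < 2:
            u = rng.standard_normal(dim)
            d = N @ u
        else:
            w = pool[rng.integers(len(pool))]
            d = w - center
            if np.linalg.norm(d) < 1e-10:
                d = N @ rng.standard_normal(dim)
        # re-project onto the null space every step: normalizing short
        # centering directions would otherwise amplify the tiny
        # off-subspace error that bound clipping introduces
        d = N @ (NT @ d)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            d = N @ rng.standard_normal(dim)
            norm = np.linalg.norm(d)
        d /= norm
        tmin, tmax = _chord(v, d, lb, ub)
        if tmax - tmin < 1e-12:
            degenerate_streak += 1
            if degenerate_streak > 100:
                logger.warning("polytope appears degenerate; replicating current point")
                if step >= warmup:
                    collected[step - warmup :] = v
                else:
                    collected[:] = v
                return pack(collected)
        else:
            degenerate_streak = 0
            t = rng.uniform(tmin, tmax)
            v = v0 + N @ (NT @ (v + t * d - v0))
            np.clip(v, lb, ub, out=v)
        n_seen += 1
        center += (v - center) / n_seen
        pool.append(v.copy())
        if step >= warmup:
            collected[step - warmup] = v
    return pack(collected)


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


@dataclass
class FluxSummary:
    """Per-reaction mean absolute flux per condition, with zeroed flags.

    ``means`` is a reactions x conditions DataFrame; ``zeroed`` a
    boolean DataFrame of the same shape marking means that fell below
    the detection threshold and were recorded as exactly 0.
    """

    means: pd.DataFrame
    zeroed: pd.DataFrame

    @property
    def conditions(self) -> list[str]:
        return list(self.means.columns)

    def mean_flux(self, reaction_id: str, condition: str) -> float:
        return float(self.means.at[reaction_id, condition])

    @staticmethod
    def from_condition_means(
        means: dict[str, pd.Series], zero_threshold: float = ZERO_FLUX_THRESHOLD
    ) -> "FluxSummary":
        df = pd.DataFrame(means).astype(float)
        zeroed = df < zero_threshold
        df = df.mask(zeroed, 0.0)
        return FluxSummary(means=df, zeroed=zeroed)

    def merge(self, other: "FluxSummary") -> "FluxSummary":
        return FluxSummary(
            means=pd.concat([self.means, other.means], axis=1),
            zeroed=pd.concat([self.zeroed, other.zeroed], axis=1),
        )

    def to_tsv(self, path: str | Path) -> None:
        rows = ["reaction_id\tcondition\tmean_flux\tzeroed"]
        for cond in self.means.columns:
            for rid in self.means.index:
                rows.append(
                    f"{rid}\t{cond}\t{float(self.means.at[rid, cond])!r}\t"
                    f"{int(self.zeroed.at[rid, cond])}"
                )
        Path(path).write_text("\n".join(rows) + "\n")

    @staticmethod
    def read_tsv(path: str | Path) -> "FluxSummary":
        df = pd.read_csv(path, sep="\t")
        required = {"reaction_id", "condition", "mean_flux"}
        if not required <= set(df.columns):
            raise ValueError(f"{path}: flux table needs columns {sorted(required)}")
        means = df.pivot(index="reaction_id", columns="condition", values="mean_flux")
        if "zeroed" in df.columns:
            zeroed = df.pivot(index="reaction_id", columns="condition", values="zeroed").astype(bool)
        else:
            zeroed = means == 0.0
        return FluxSummary(means=means, zeroed=zeroed)


def summarize_fluxes(
    samples: FluxSamples,
    n_select: int,
    zero_threshold: float = ZERO_FLUX_THRESHOLD,
    seed: int | np.random.Generator | None = None,
    condition: str = "case",
) -> FluxSummary:
    """Mean absolute flux per reaction over a random subset of samples.

    ``n_select`` points are drawn without replacement (seed-fixed) from
    the collected samples; per-reaction means of ``|v|`` below
    ``zero_threshold`` are recorded as exactly 0 and flagged.
    """
    n_points = samples.points.shape[0]
    if n_select > n_points:
        raise ValueError(f"n_select={n_select} exceeds collected points {n_points}")
    if zero_threshold < 0:
        raise ValueError("zero_threshold must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(n_points, size=n_select, replace=False)
    means = pd.Series(
        np.abs(samples.points[idx]).mean(axis=0), index=samples.reaction_ids
    )
    return FluxSummary.from_condition_means({condition: means}, zero_threshold)
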