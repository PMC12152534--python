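"""Transcriptomics-to-bounds integration.

An :class:`ExpressionTable` (genes x samples, normalized counts, with a
sample -> culture-phase assignment) is turned into a phase-specific,
bound-tightened model in three steps: per-phase averaging of replicate
samples, GPR evaluation (AND = min over subunits, OR = max over isozymes)
to obtain a reaction-level expression value, and reversibility-directed
bound setting — a reversible reaction with scaled value v' gets bounds
[-v', +v'], an irreversible one [0, +v'].  Reactions whose genes are not
covered by the table, or which carry no gene association at all, keep
their original bounds ("left unconstrained"), with the reason recorded.

Expression values live on a count scale, not a flux scale, so by default
they are normalized to the model's bound magnitude: v' = (v / max v over
constrained reactions) * default_bound.  Only the relative ordering
matters for the rank-based statistics downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import GPR, MetabolicModel
from .sampler import InfeasiblePolytopeError, find_feasible_point

__all__ = [
    "ExpressionTable",
    "PhaseModel",
    "DEFAULT_PHASES",
    "DEFAULT_DAY_PHASES",
    "map_gene_ids",
    "average_phase_expression",
    "evaluate_gpr",
    "reaction_expression",
    "constrain_bounds",
    "build_phase_model",
]

logger = logging.getLogger(__name__)

DEFAULT_PHASES = ("early_exponential", "late_exponential", "stationary_death")

# Default fed-batch day grouping: early exponential day 4; late exponential
# days 6-8; stationary/death days 11-14.  Day 5 is excluded (batch effect).
DEFAULT_DAY_PHASES = {
    4: "early_exponential",
    6: "late_exponential",
    7: "late_exponential",
    8: "late_exponential",
    11: "stationary_death",
    12: "stationary_death",
    14: "stationary_death",
}


@dataclass
class ExpressionTable:
    """Genes x samples matrix of non-negative normalized counts with a
    phase label per sample."""

    values: pd.DataFrame                  # index: gene ids, columns: sample ids
    phase_of: dict[str, str]

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = [s for s in self.values.columns if s not in self.phase_of]
        if missing:
            raise ValueError(f"samples without a phase label: {missing}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def phases(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(self.phase_of[s], None)
        return list(seen)

    def samples_in_phase(self, phase: str) -> list[str]:
        return [s for s in self.samples if self.phase_of[s] == phase]

    @classmethod
    def from_csv(cls, table_path: str | Path, phase_path: str | Path,
                 sep: str | None = None) -> "ExpressionTable":
        """Load a genes-in-rows table (TSV/CSV, first column = gene id) and a
        two-column (sample, phase) assignment CSV."""
        table_path = Path(table_path)
        if sep is None:
            sep = "\t" if table_path.suffix in (".tsv", ".tab", ".txt") else ","
        values = pd.read_csv(table_path, sep=sep, index_col=0)
        phases = pd.read_csv(phase_path)
        phase_of = dict(zip(phases.iloc[:, 0].astype(str), phases.iloc[:, 1].astype(str)))
        return cls(values=values, phase_of=phase_of)

    def to_csv(self, table_path: str | Path, phase_path: str | Path) -> None:
        table_path = Path(table_path)
        sep = "\t" if table_path.suffix in (".tsv", ".tab", ".txt") else ","
        self.values.to_csv(table_path, sep=sep, index_label="gene")
        pd.DataFrame(
            {"sample": self.samples, "phase": [self.phase_of[s] for s in self.samples]}
        ).to_csv(phase_path, index=False)


def map_gene_ids(
    table: ExpressionTable,
    mapping: pd.DataFrame,
    aggregate: str = "sum",
) -> ExpressionTable:
    """Rename genes to a target id namespace via a two-column mapping table.

    Genes without a mapping are dropped (count logged); several source
    genes collapsing onto one target id are aggregated (default: summed,
    matching the transcript-to-gene convention for count data).
    """
    if mapping is None or len(mapping) == 0:
        raise ValueError("empty id mapping")
    if mapping.shape[1] < 2:
        raise ValueError("mapping must have source and target columns")
    lookup = dict(zip(mapping.iloc[:, 0].astype(str), mapping.iloc[:, 1].astype(str)))

    mapped = table.values.loc[[g for g in table.genes if g in lookup]].copy()
    n_dropped = len(table.genes) - len(mapped)
    if n_dropped:
        logger.info("map_gene_ids: dropped %d gene(s) with no mapping", n_dropped)
    new_index = pd.Index([lookup[g] for g in mapped.index], name=table.values.index.name)
    mapped.index = new_index
    n_collisions = int(new_index.duplicated().sum())
    if n_collisions:
        logger.info(
            "map_gene_ids: %d many-to-one collision(s) aggregated by %s",
            n_collisions, aggregate,
        )
    grouped = mapped.groupby(level=0, sort=False).agg(aggregate)
    return ExpressionTable(values=grouped, phase_of=dict(table.phase_of))


def average_phase_expression(table: ExpressionTable, phase: str) -> pd.Series:
    """Arithmetic mean of each gene's expression over the phase's samples."""
    cols = table.samples_in_phase(phase)
    if not cols:
        raise ValueError(f"phase {phase!r} has no samples")
    return table.values[cols].mean(axis=1)


def evaluate_gpr(
    gpr: GPR, gene_values, or_mode: str = "max"
) -> float | None:
    """Reaction-level expression from a GPR rule; ``None`` means missing
    (empty rule, or a required gene absent from the table)."""
    return gpr.evaluate(dict(gene_values), or_mode=or_mode)


def reaction_expression(
    model: MetabolicModel, gene_values, or_mode: str = "max"
) -> tuple[dict[str, float], dict[str, str]]:
    """Evaluate every reaction's GPR; returns (values, reasons) where
    ``reasons`` maps unconstrained reaction ids to 'no_gpr' or
    'gene_missing'."""
    gene_values = dict(gene_values)
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for rxn in model.reactions:
        if not rxn.gpr:
            reasons[rxn.id] = "no_gpr"
            continue
        v = rxn.gpr.evaluate(gene_values, or_mode=or_mode)
        if v is None:
            reasons[rxn.id] = "gene_missing"
        else:
            values[rxn.id] = v
    return values, reasons


@dataclass
class PhaseModel:
    """A model with bounds tightened from one culture phase's expression."""

    phase: str
    model: MetabolicModel
    constrained_reactions: set[str]
    unconstrained_reason: dict[str, str]
    bounds_audit: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def constrain_bounds(
    model: MetabolicModel,
    reaction_values: dict[str, float | None],
    scaling: float | None = None,
    phase: str = "",
    check_feasible: bool = True,
) -> PhaseModel:
    """Tighten reaction bounds from reaction-level expression values.

    For a reaction with value ``v``, the scaled ceiling is
    ``v' = min(v * scaling, original upper bound)``; a reversible reaction
    gets bounds ``[max(lb, -v'), v']`` and an irreversible one ``[lb, v']``
    — bounds are never widened.  ``None`` values leave the reaction
    unconstrained with the reason recorded.  ``scaling=None`` picks the
    default normalization ``default_bound / max(v)`` with ``default_bound``
    the largest bound magnitude in the model.

    If the tightened polytope is empty the operation raises
    :class:`InfeasiblePolytopeError` instead of silently returning.
    """
    present = {
        rid: v for rid, v in reaction_values.items() if v is not None
    }
    for rid, v in present.items():
        if v < 0:
            raise ValueError(f"negative expression value for reaction {rid!r}: {v}")
    if scaling is not None and scaling <= 0:
        raise ValueError(f"scaling must be positive, got {scaling}")
    if scaling is None:
        vmax = max(present.values(), default=0.0)
        default_bound = max(
            (max(abs(r.lower_bound), abs(r.upper_bound)) for r in model.reactions),
            default=1.0,
        )
        scaling = default_bound / vmax if vmax > 0 else 1.0

    new_model = model.copy()
    constrained: set[str] = set()
    reasons = {
        rid: "gene_missing" for rid, v in reaction_values.items() if v is None
    }
    audit_rows = []
    by_id = {r.id: r for r in new_model.reactions}
    for rid, v in present.items():
        rxn = by_id.get(rid)
        if rxn is None:
            raise KeyError(f"reaction {rid!r} not in model")
        old_lb, old_ub = rxn.lower_bound, rxn.upper_bound
        v_prime = min(v * scaling, old_ub)
        if rxn.reversible:
            rxn.lower_bound = max(old_lb, -v_prime)
        rxn.upper_bound = min(old_ub, v_prime)
        # guard against inverted intervals from tiny v' on positive-lb reactions
        if rxn.upper_bound < rxn.lower_bound:
            rxn.upper_bound = rxn.lower_bound
        constrained.add(rid)
        audit_rows.append((rid, old_lb, old_ub, rxn.lower_bound, rxn.upper_bound))
    for rxn in new_model.reactions:
        if rxn.id not in constrained:
            audit_rows.append(
                (rxn.id, rxn.lower_bound, rxn.upper_bound, rxn.lower_bound, rxn.upper_bound)
            )
    audit = pd.DataFrame(
        audit_rows, columns=["reaction", "old_lb", "old_ub", "new_lb", "new_ub"]
    )

    if check_feasible:
        try:
            find_feasible_point(new_model)
        except InfeasiblePolytopeError as exc:
            raise InfeasiblePolytopeError(
                f"phase {phase or '?'}: expression constraints empty the flux "
                f"polytope ({exc})"
            ) from exc

    return PhaseModel(
        phase=phase,
        model=new_model,
        constrained_reactions=constrained,
        unconstrained_reason=reasons,
        bounds_audit=audit,
    )


def build_phase_model(
    model: MetabolicModel,
    table: ExpressionTable,
    phase: str,
    scaling: float | None = None,
    or_mode: str = "max",
    check_feasible: bool = True,
) -> PhaseModel:
    """Average the phase's samples, evaluate GPRs, and constrain bounds."""
    means = average_phase_expression(table, phase)
    values, reasons = reaction_expression(model, means, or_mode=or_mode)
    merged: dict[str, float | None] = dict(values)
    for rid in reasons:
        if reasons[rid] == "gene_missing":
            merged[rid] = None
    pm = constrain_bounds(
        model, merged, scaling=scaling, phase=phase, check_feasible=check_feasible
    )
    pm.unconstrained_reason.update(
        {rid: r for rid, r in reasons.items() if r == "no_gpr"}
    )
    return pm
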