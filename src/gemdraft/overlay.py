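"""Mapping differential gene expression onto draft-model reactions.

Given gene-level log2 fold changes with significance calls (computed
upstream by any differential-expression pipeline), each reaction is
classified from the significant genes of its GPR: ``up`` if all their
fold changes are positive, ``down`` if all negative, ``mixed``
otherwise, ``none`` when no significant measured gene occurs in the
rule.  A signed aggregate score summarises the reaction (default:
value of the largest-magnitude contributor, keeping its sign).  Route
summaries tally states over named reaction sets so that alternative
biotransformation branches — e.g. an activation route versus a
conjugation/clearance route for a toxicant — can be contrasted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .model import Model

__all__ = [
    "ExpressionRecord",
    "ReactionRegulation",
    "read_expression_table",
    "overlay_expression",
    "route_summary",
    "REGULATION_STATES",
]

REGULATION_STATES = ("up", "down", "mixed", "none")


@dataclass(frozen=True)
class ExpressionRecord:
    gene_id: str
    log2fc: float
    significant: bool


@dataclass
class ReactionRegulation:
    reaction_id: str
    state: str
    score: float
    # gene -> log2fc for the significant genes driving the call
    contributing: dict[str, float] = field(default_factory=dict)


def read_expression_table(path: str | Path) -> list[ExpressionRecord]:
    """Read a CSV/TSV with columns gene_id, log2fc, significant.

    The separator is sniffed from the extension (.tsv/.tab -> tab).
    ``significant`` accepts booleans or 0/1/true/false/yes/no strings.
    Duplicate gene ids raise.
    """
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"gene_id", "log2fc", "significant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"expression table missing column(s): {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene id(s) in expression table: {dups[:5]}")

    def to_bool(v) -> bool:
        if isinstance(v, str):
            return v.strip().lower() in ("1", "true", "yes", "y")
        return bool(v)

    return [
        ExpressionRecord(str(r.gene_id), float(r.log2fc), to_bool(r.significant))
        for r in df.itertuples(index=False)
    ]


def overlay_expression(
    model: Model,
    table: list[ExpressionRecord],
    aggregation: str = "max_abs",
) -> list[ReactionRegulation]:
    """Classify every model reaction from the significant fold changes
    of its GPR genes.

    ``aggregation`` is ``max_abs`` (signed value of the largest-magnitude
    contributor) or ``mean``.  Reactions with empty GPRs, or whose genes
    are unmeasured or non-significant, get state ``none`` and score 0.
    Output is ordered by reaction id, independent of input row order.
    """
    if aggregation not in ("max_abs", "mean"):
        raise ValueError("aggregation must be 'max_abs' or 'mean'")
    sig = {rec.gene_id: rec.log2fc for rec in table if rec.significant}
    results = []
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        contributing = {g: sig[g] for g in sorted(rxn.gpr.genes()) if g in sig}
        if not contributing:
            results.append(ReactionRegulation(rid, "none", 0.0))
            continue
        values = list(contributing.values())
        if all(v > 0 for v in values):
            state = "up"
        elif all(v < 0 for v in values):
            state = "down"
        else:
            state = "mixed"
        if aggregation == "max_abs":
            score = max(values, key=lambda v: (abs(v), v))
        else:
            score = sum(values) / len(values)
        results.append(ReactionRegulation(rid, state, score, contributing))
    return results


def unmeasured_summary(model: Model, table: list[ExpressionRecord]) -> dict[str, int]:
    """How many model genes the expression table does and does not cover."""
    measured = {rec.gene_id for rec in table}
    model_genes = set(model.genes)
    return {
        "n_model_genes": len(model_genes),
        "n_measured": len(model_genes & measured),
        "n_unmeasured": len(model_genes - measured),
    }


def route_summary(
    regulations: list[ReactionRegulation],
    reaction_sets: dict[str, list[str]],
) -> dict[str, dict[str, int]]:
    """Per named route (an ordered list of reaction ids), counts of
    reactions by regulation state.

    Unknown reaction ids warn and are skipped.  Lets the up-regulated
    activation branch of a pathway be contrasted with a down-regulated
    clearance branch.
    """
    by_id = {r.reaction_id: r for r in regulations}
    out: dict[str, dict[str, int]] = {}
    for route_name, rxn_ids in reaction_sets.items():
        counts = {state: 0 for state in REGULATION_STATES}
        for rid in rxn_ids:
            reg = by_id.get(rid)
            if reg is None:
                warnings.warn(f"route {route_name!r}: unknown reaction id {rid!r}, skipped")
                continue
            counts[reg.state] += 1
        out[route_name] = counts
    return out
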