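"""Per-subsystem gap analysis and rule-driven manual curation.

A draft built purely from homology is missing every template reaction
whose genes found no ortholog.  Inspecting one subsystem at a time
against the template surfaces these gaps; two curation criteria then
fill a subset of them reproducibly:

1. *spontaneous* — reactions known from the literature to proceed
   without enzymatic catalysis are copied into the draft with no gene
   association;
2. *family* — reactions whose chemistry clearly implicates an enzyme
   family (e.g. cytochrome P450 monooxygenases) are copied with a
   family-level placeholder gene, flagged ``putative_family_assignment``
   because no specific homolog supports them.

Curation rules are declarative data (a 3-column TSV), not code, so the
manual curation is diffable and replayable.  Reaction states export to
CSV and to an Escher-compatible "reaction data" JSON for map coloring.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from .gpr import GprExpression
from .model import Gene, Model

__all__ = [
    "CurationRules",
    "GapReport",
    "read_curation_rules",
    "subsystem_diff",
    "apply_curation",
    "export_reaction_states",
    "STATUS_AUTO",
    "STATUS_FILLED_SPONTANEOUS",
    "STATUS_FILLED_FAMILY",
    "STATUS_MISSING",
    "ESCHER_STATE_CODES",
]

STATUS_AUTO = "auto"
STATUS_FILLED_SPONTANEOUS = "filled_spontaneous"
STATUS_FILLED_FAMILY = "filled_family"
STATUS_MISSING = "missing"

# numeric codes for Escher reaction-data overlays: draft reactions (blue
# on the published maps) vs manually filled gaps (green) vs still
# missing (pink)
ESCHER_STATE_CODES = {
    STATUS_MISSING: 0,
    STATUS_AUTO: 1,
    STATUS_FILLED_SPONTANEOUS: 2,
    STATUS_FILLED_FAMILY: 3,
}


@dataclass(frozen=True)
class CurationRules:
    """Declarative gap-filling rules.

    ``spontaneous``: template reaction ids to include enzyme-free.
    ``family_assignments``: template reaction id -> placeholder gene id
    (a family token such as ``CYP1_family``).  The two sets must be
    disjoint.
    """

    spontaneous: frozenset[str] = frozenset()
    family_assignments: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.spontaneous) & set(self.family_assignments)
        if overlap:
            raise ValueError(
                f"reaction(s) listed under both rule types: {sorted(overlap)}"
            )


def read_curation_rules(path: str | Path) -> CurationRules:
    """Read a 3-column rules TSV: reaction_id, rule_type
    (``spontaneous``|``family``), placeholder_gene (or ``-``)."""
    spontaneous: set[str] = set()
    family: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 columns, got {len(fields)}")
            rid, rule_type, placeholder = fields
            if rule_type == "spontaneous":
                spontaneous.add(rid)
            elif rule_type == "family":
                if placeholder in ("", "-"):
                    raise ValueError(
                        f"{path}:{lineno}: family rule needs a placeholder gene id"
                    )
                family[rid] = placeholder
            else:
                raise ValueError(f"{path}:{lineno}: unknown rule type {rule_type!r}")
    return CurationRules(spontaneous=frozenset(spontaneous), family_assignments=family)


@dataclass
class GapReport:
    """Status of every template reaction of one subsystem.

    Statuses partition the subsystem's template reaction set:
    ``auto`` (present in the draft), ``filled_spontaneous`` /
    ``filled_family`` (added by curation), ``missing``.
    """

    subsystem: str
    statuses: dict[str, str] = field(default_factory=dict)

    def counts(self) -> dict[str, int]:
        out = {s: 0 for s in ESCHER_STATE_CODES}
        for status in self.statuses.values():
            out[status] += 1
        return out

    def with_status(self, status: str) -> set[str]:
        return {rid for rid, s in self.statuses.items() if s == status}


def subsystem_diff(template: Model, draft: Model, subsystem: str) -> GapReport:
    """Classify each template reaction of ``subsystem`` as ``auto``
    (present in the draft) or ``missing``.

    An unknown subsystem label raises, listing the available labels.
    """
    rxn_ids = [r.id for r in template.reactions.values() if r.subsystem == subsystem]
    if not rxn_ids:
        raise ValueError(
            f"subsystem {subsystem!r} not found in template; available: "
            + ", ".join(template.subsystems())
        )
    return GapReport(
        subsystem=subsystem,
        statuses={
            rid: STATUS_AUTO if rid in draft.reactions else STATUS_MISSING
            for rid in rxn_ids
        },
    )


def apply_curation(
    report: GapReport,
    rules: CurationRules,
    template: Model,
    draft: Model,
) -> tuple[GapReport, Model]:
    """Fill gaps per the curation rules; returns a new report and a new
    draft (inputs are not mutated).

    Missing reactions named as spontaneous are copied with an empty
    GPR; missing reactions with a family assignment are copied with the
    placeholder gene as GPR (the placeholder is added to the draft gene
    set flagged ``putative_family_assignment``).  Rules citing an auto
    reaction warn and are ignored; rules citing a non-template reaction
    raise.  Idempotent.
    """
    all_ruled = set(rules.spontaneous) | set(rules.family_assignments)
    bad = all_ruled - set(template.reactions)
    if bad:
        raise ValueError(f"curation rule(s) cite non-template reaction(s): {sorted(bad)}")

    new_report = GapReport(subsystem=report.subsystem, statuses=dict(report.statuses))
    new_draft = draft.copy()

    for rid in sorted(all_ruled):
        status = new_report.statuses.get(rid)
        if status is None:
            continue  # rule for another subsystem; not this report's concern
        if status == STATUS_AUTO:
            warnings.warn(f"curation rule for {rid!r} ignored: reaction already in draft")
            continue
        if status not in (STATUS_MISSING, STATUS_FILLED_SPONTANEOUS, STATUS_FILLED_FAMILY):
            continue
        template_rxn = template.reactions[rid]
        filled = template_rxn.copy()
        if rid in rules.spontaneous:
            filled.gpr = GprExpression.empty()
            new_report.statuses[rid] = STATUS_FILLED_SPONTANEOUS
        else:
            placeholder = rules.family_assignments[rid]
            filled.gpr = GprExpression.gene(placeholder)
            if placeholder not in new_draft.genes:
                new_draft.add_gene(
                    Gene(id=placeholder, flags={"putative_family_assignment"})
                )
            new_report.statuses[rid] = STATUS_FILLED_FAMILY
        if rid not in new_draft.reactions:
            new_draft.add_reaction(filled)
        for mid in filled.stoichiometry:
            if mid not in new_draft.metabolites:
                met = template.metabolites[mid]
                new_draft.add_metabolite(met)
                if met.compartment not in new_draft.compartments:
                    new_draft.compartments[met.compartment] = template.compartments.get(
                        met.compartment, met.compartment
                    )
    new_draft.validate()
    return new_report, new_draft


def export_reaction_states(report: GapReport, out_prefix: str | Path) -> tuple[Path, Path]:
    """Write ``<prefix>.csv`` (reaction_id,status) and ``<prefix>.json``
    (reaction id -> numeric state) loadable as Escher reaction data.

    Returns the two paths written.
    """
    out_prefix = Path(out_prefix)
    csv_path = out_prefix.with_suffix(".csv")
    json_path = out_prefix.with_suffix(".json")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["reaction_id", "status"])
        for rid in sorted(report.statuses):
            writer.writerow([rid, report.statuses[rid]])
    with open(json_path, "w") as fh:
        json.dump(
            {rid: ESCHER_STATE_CODES[s] for rid, s in sorted(report.statuses.items())},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")
    return csv_path, json_path
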