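"""Draft model extraction from a template GEM via an ortholog map.

A reaction is carried from the template into the draft when at least
one gene of its original GPR has a target-species ortholog — the
standard homology-drafting inclusion rule.  This deliberately keeps
enzyme complexes with only partially mapped subunits; the GPR rewrite
mode then decides how conservatively the rule itself is translated:

* ``or_of_orthologs`` (default) — the rewritten GPR is a flat OR over
  every target ortholog of every template gene in the rule.  Homology
  evidence cannot confirm complex stoichiometry, so any mapped enzyme
  is treated as sufficient.
* ``preserve_logic`` — each leaf is replaced by the OR of its
  orthologs; a leaf without orthologs is deleted, and an AND node that
  loses any child becomes empty (strict complex semantics).

Also here: comparison of mapped-gene sets across drafts built from
different genome annotations (Venn-style partition) and merging of
drafts with one chosen as baseline and the others as complementary
sources.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

from .gpr import GprExpression
from .model import Gene, Model
from .orthology import OrthologMap

__all__ = [
    "DraftOptions",
    "MappedGeneReport",
    "MergeResult",
    "rewrite_gpr",
    "extract_draft",
    "gene_partition",
    "merge_drafts",
    "OR_OF_ORTHOLOGS",
    "PRESERVE_LOGIC",
]

OR_OF_ORTHOLOGS = "or_of_orthologs"
PRESERVE_LOGIC = "preserve_logic"


@dataclass(frozen=True)
class DraftOptions:
    gpr_mode: str = OR_OF_ORTHOLOGS
    include_non_gene_reactions: bool = False

    def __post_init__(self):
        if self.gpr_mode not in (OR_OF_ORTHOLOGS, PRESERVE_LOGIC):
            raise ValueError(
                f"gpr_mode must be {OR_OF_ORTHOLOGS!r} or {PRESERVE_LOGIC!r}"
            )


@dataclass
class MappedGeneReport:
    """Which template genes carried reactions into a draft.

    ``rows`` maps each contributing template gene to its target
    orthologs and the number of included reactions whose original GPR
    contains it.  The mapped-template-gene set is what draft-vs-draft
    comparisons (Venn partitions) operate on.
    """

    name: str = "draft"
    rows: dict[str, tuple[tuple[str, ...], int]] = field(default_factory=dict)

    @property
    def template_genes(self) -> set[str]:
        return set(self.rows)

    def to_records(self) -> list[dict]:
        return [
            {
                "template_gene": g,
                "target_orthologs": ";".join(orths),
                "n_reactions": n,
            }
            for g, (orths, n) in sorted(self.rows.items())
        ]


def rewrite_gpr(expr: GprExpression, omap: OrthologMap, mode: str = OR_OF_ORTHOLOGS) -> GprExpression:
    """Translate a template-gene GPR into target-gene terms.

    See the module docstring for the two modes.  Returns the empty
    expression when nothing maps.
    """
    by_template = omap.by_template_gene()
    if mode == OR_OF_ORTHOLOGS:
        targets: set[str] = set()
        for gene_id in expr.genes():
            targets |= by_template.get(gene_id, set())
        return GprExpression.or_(*(GprExpression.gene(t) for t in sorted(targets)))
    if mode == PRESERVE_LOGIC:
        return _rewrite_preserving(expr, by_template)
    raise ValueError(f"unknown gpr_mode {mode!r}")


def _rewrite_preserving(expr: GprExpression, by_template: dict[str, set[str]]) -> GprExpression:
    if expr.is_empty:
        return expr
    if expr.op == "gene":
        orthologs = by_template.get(expr.gene_id, set())
        return GprExpression.or_(*(GprExpression.gene(t) for t in sorted(orthologs)))
    children = [_rewrite_preserving(c, by_template) for c in expr.children]
    if expr.op == "and":
        # strict complex semantics: a lost subunit voids the complex
        if any(c.is_empty for c in children):
            return GprExpression.empty()
        return GprExpression.and_(*children)
    # OR: empty children are simply dropped by the constructor
    return GprExpression.or_(*children)


def extract_draft(
    template: Model,
    omap: OrthologMap,
    options: DraftOptions = DraftOptions(),
) -> tuple[Model, MappedGeneReport]:
    """Extract the draft model for the target species.

    Inclusion tests the *original* template GPR: a reaction is kept iff
    it shares at least one gene with the mapped template-gene set
    (GPR-less reactions only with ``include_non_gene_reactions``).
    Stoichiometry, bounds, compartments and subsystem labels are copied
    verbatim; each kept reaction's GPR is rewritten per
    ``options.gpr_mode``.  Returns the draft and the mapped-gene report.
    """
    by_template = omap.by_template_gene()
    unknown = set(by_template) - set(template.genes)
    if unknown:
        warnings.warn(
            f"{len(unknown)} template gene id(s) in the ortholog map are not in "
            f"the template model and are ignored: {sorted(unknown)[:5]}..."
        )
    mapped_template_genes = set(by_template) & set(template.genes)

    if all(r.gpr.is_empty for r in template.reactions.values()):
        raise ValueError(
            "template has no gene associations at all; homology-based extraction "
            "cannot select reactions (set include_non_gene_reactions to copy "
            "GPR-less reactions)"
        )

    draft = Model(id=f"{template.id}_draft")
    draft.provenance = {
        "template": template.id,
        "gpr_mode": options.gpr_mode,
        "include_non_gene_reactions": options.include_non_gene_reactions,
    }
    if omap.params is not None:
        draft.provenance["mapping_params"] = {
            "strictness": omap.params.strictness,
            "maxE": omap.params.maxE,
            "minLen": omap.params.minLen,
            "minIde": omap.params.minIde,
        }

    report = MappedGeneReport(name=draft.id)
    reaction_count: dict[str, int] = {}

    for rxn in template.reactions.values():
        original_genes = rxn.gpr.genes()
        if rxn.gpr.is_empty:
            if not options.include_non_gene_reactions:
                continue
            new_gpr = GprExpression.empty()
        else:
            if not (original_genes & mapped_template_genes):
                continue
            new_gpr = rewrite_gpr(rxn.gpr, omap, options.gpr_mode)
        kept = rxn.copy()
        kept.gpr = new_gpr
        draft.add_reaction(kept)
        for g in original_genes & mapped_template_genes:
            reaction_count[g] = reaction_count.get(g, 0) + 1

    # metabolites and compartments restricted to those actually used
    used_mets = {mid for r in draft.reactions.values() for mid in r.stoichiometry}
    for mid in sorted(used_mets):
        met = template.metabolites[mid]
        draft.add_metabolite(met)
        if met.compartment not in draft.compartments:
            draft.compartments[met.compartment] = template.compartments.get(
                met.compartment, met.compartment
            )

    # draft gene set = target genes appearing in >=1 rewritten GPR
    draft_targets = {g for r in draft.reactions.values() for g in r.gpr.genes()}
    for t in sorted(draft_targets):
        draft.add_gene(Gene(id=t))

    for g, n in reaction_count.items():
        report.rows[g] = (tuple(sorted(by_template[g])), n)

    draft.validate()
    return draft, report


def gene_partition(reports: dict[str, MappedGeneReport | set[str]]) -> dict[str, int]:
    """Exact Venn region sizes over the drafts' mapped template genes.

    ``reports`` maps a draft name to its :class:`MappedGeneReport` (or
    directly to a gene set).  Returns region label -> size, with labels
    like ``"A"`` (exclusive to A), ``"A&B"`` (in A and B only), for all
    2^k - 1 regions; sizes sum to the union size.
    """
    if len(reports) < 2:
        raise ValueError("gene_partition needs at least 2 named drafts")
    sets = {
        name: rep.template_genes if isinstance(rep, MappedGeneReport) else set(rep)
        for name, rep in reports.items()
    }
    names = list(sets)
    universe: set[str] = set().union(*sets.values())
    regions: dict[str, int] = {}
    for k in range(1, len(names) + 1):
        for inside in combinations(names, k):
            label = "&".join(inside)
            outside = [n for n in names if n not in inside]
            region = set(universe)
            for n in inside:
                region &= sets[n]
            for n in outside:
                region -= sets[n]
            regions[label] = len(region)
    return regions


@dataclass
class MergeResult:
    model: Model
    # entity kind -> id -> source tag ("baseline" or the complement name)
    sources: dict[str, dict[str, str]] = field(default_factory=dict)


def merge_drafts(baseline: Model, complements: dict[str, Model]) -> MergeResult:
    """Merge drafts sharing the template's reaction-id namespace.

    The baseline (typically the draft from the most complete genome
    annotation) is kept in full; complements, processed in the given
    order, contribute reactions whose id is not yet present.  When a
    reaction id exists on both sides its GPRs are OR-unioned — the
    drafts come from the same template, so stoichiometry must agree
    (a mismatch raises).
    """
    merged = baseline.copy()
    merged.id = f"{baseline.id}_merged"
    merged.provenance["merge_baseline"] = baseline.id
    merged.provenance["merge_complements"] = list(complements)
    sources = {
        "reactions": {rid: "baseline" for rid in merged.reactions},
        "genes": {gid: "baseline" for gid in merged.genes},
        "metabolites": {mid: "baseline" for mid in merged.metabolites},
    }
    for name, comp in complements.items():
        for rxn in comp.reactions.values():
            if rxn.id in merged.reactions:
                mine = merged.reactions[rxn.id]
                if mine.stoichiometry != rxn.stoichiometry:
                    raise ValueError(
                        f"reaction {rxn.id!r}: conflicting stoichiometry between "
                        f"baseline and complement {name!r} — template-derived "
                        "drafts cannot disagree"
                    )
                mine.gpr = GprExpression.or_(mine.gpr, rxn.gpr)
            else:
                merged.add_reaction(rxn.copy())
                sources["reactions"][rxn.id] = name
            for mid in rxn.stoichiometry:
                if mid not in merged.metabolites:
                    merged.add_metabolite(comp.metabolites[mid])
                    sources["metabolites"][mid] = name
                    cpt = comp.metabolites[mid].compartment
                    if cpt not in merged.compartments:
                        merged.compartments[cpt] = comp.compartments.get(cpt, cpt)
        # genes introduced by new or widened GPRs
        for rxn in merged.reactions.values():
            for g in rxn.gpr.genes():
                if g not in merged.genes:
                    src = name if g in comp.genes else "baseline"
                    merged.add_gene(
                        Gene(id=g, name=comp.genes[g].name if g in comp.genes else None)
                    )
                    sources["genes"][g] = src
    merged.validate()
    return MergeResult(model=merged, sources=sources)
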