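"""Ortholog mapping from bidirectional homology tables.

The mapping follows the three strictness regimes used in
homology-based draft reconstruction:

* strictness 1 — a pair (target, template) is accepted when a
  threshold-passing alignment exists in *both* search directions
  (one-to-many mapping allowed);
* strictness 2 — a passing alignment in *at least one* direction
  suffices (the most permissive regime);
* strictness 3 — best reciprocal hits: per query only the alignment
  with the lowest E-value is retained in each direction, and a pair is
  accepted when the two retained best hits point at each other and both
  pass the thresholds.  This yields a partial matching (one-to-one).

Thresholds are a maximum E-value, a minimum alignment length and a
minimum percent identity, with defaults 1e-30, 200 residues and 40%.
All three boundaries are inclusive: the stated maximum/minimum value
itself is acceptable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .homology import TARGET_TO_TEMPLATE, TEMPLATE_TO_TARGET, HomologyHit, HomologyTable

__all__ = [
    "MappingParams",
    "OrthologMap",
    "passes_thresholds",
    "best_hits",
    "collapse_hsps",
    "map_orthologs",
    "map_summary",
]

DEFAULT_MAX_E = 1e-30
DEFAULT_MIN_LEN = 200
DEFAULT_MIN_IDE = 40.0


@dataclass(frozen=True)
class MappingParams:
    """Strictness regime plus alignment-quality thresholds.

    maxE: largest acceptable E-value (inclusive; 0 permitted).
    minLen: smallest acceptable alignment length, residues (inclusive).
    minIde: smallest acceptable percent identity, 0-100 (inclusive).
    """

    strictness: int = 1
    maxE: float = DEFAULT_MAX_E
    minLen: int = DEFAULT_MIN_LEN
    minIde: float = DEFAULT_MIN_IDE

    def __post_init__(self):
        if self.strictness not in (1, 2, 3):
            raise ValueError("strictness must be 1, 2 or 3")
        if self.maxE < 0:
            raise ValueError("maxE must be >= 0")
        if self.minLen < 1:
            raise ValueError("minLen must be >= 1")
        if not 0 <= self.minIde <= 100:
            raise ValueError("minIde must be in [0, 100]")


@dataclass
class OrthologMap:
    """Accepted (target gene, template gene) pairs with their evidence.

    ``evidence`` maps each pair to the supporting hits per direction,
    so every accepted pair can be audited against the regime that
    produced it.
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)
    evidence: dict[tuple[str, str], dict[str, HomologyHit]] = field(default_factory=dict)
    params: MappingParams | None = None

    def __len__(self):
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.pairs

    def targets_of(self, template_gene: str) -> set[str]:
        """Target orthologs of one template gene."""
        return {t for t, g in self.pairs if g == template_gene}

    def by_template_gene(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for t, g in self.pairs:
            out.setdefault(g, set()).add(t)
        return out


def passes_thresholds(hit: HomologyHit, params: MappingParams) -> bool:
    """Inclusive threshold predicate: E <= maxE, length >= minLen,
    identity >= minIde."""
    return (
        hit.e_value <= params.maxE
        and hit.alignment_length >= params.minLen
        and hit.percent_identity >= params.minIde
    )


def _better(a: HomologyHit, b: HomologyHit) -> bool:
    """True if a beats b: lower E-value, then higher bit score, then
    lexicographically smaller subject id."""
    return (a.e_value, -a.bit_score, a.subject_id) < (b.e_value, -b.bit_score, b.subject_id)


def best_hits(table: HomologyTable) -> dict[str, HomologyHit]:
    """Per query, the single hit with the lowest E-value.

    Ties break by higher bit score, then lexicographically smaller
    subject id, so the result is deterministic under row reordering.
    """
    best: dict[str, HomologyHit] = {}
    for hit in table.hits:
        cur = best.get(hit.query_id)
        if cur is None or _better(hit, cur):
            best[hit.query_id] = hit
    return best


def collapse_hsps(table: HomologyTable) -> HomologyTable:
    """One representative hit per (query, subject) pair.

    BLAST emits multiple high-scoring pairs for one sequence pair; the
    representative is the one with minimal E-value (ties as in
    :func:`best_hits`).  Idempotent.  Output ordered by first
    occurrence of each pair.
    """
    chosen: dict[tuple[str, str], HomologyHit] = {}
    for hit in table.hits:
        key = (hit.query_id, hit.subject_id)
        cur = chosen.get(key)
        if cur is None or _better(hit, cur):
            chosen[key] = hit
    return HomologyTable(direction=table.direction, hits=list(chosen.values()))


def map_orthologs(
    fwd: HomologyTable, rev: HomologyTable, params: MappingParams
) -> OrthologMap:
    """Build the ortholog map from a forward (target->template) and a
    reverse (template->target) homology table under ``params``.

    See the module docstring for the three strictness regimes.  For all
    regimes, multiple HSPs per sequence pair are first collapsed to the
    best one.
    """
    if fwd.direction == rev.direction:
        raise ValueError(
            "fwd and rev tables have the same direction flag "
            f"({fwd.direction!r}); need one table per direction"
        )
    if fwd.direction != TARGET_TO_TEMPLATE:
        fwd, rev = rev, fwd  # accept the two tables in either order

    fwd_c = collapse_hsps(fwd)
    rev_c = collapse_hsps(rev)
    result = OrthologMap(params=params)

    if params.strictness in (1, 2):
        fwd_pass = {
            (h.query_id, h.subject_id): h for h in fwd_c.hits if passes_thresholds(h, params)
        }
        rev_pass = {
            (h.subject_id, h.query_id): h for h in rev_c.hits if passes_thresholds(h, params)
        }
        if params.strictness == 1:
            accepted = set(fwd_pass) & set(rev_pass)
        else:
            accepted = set(fwd_pass) | set(rev_pass)
        for pair in accepted:
            ev = {}
            if pair in fwd_pass:
                ev["forward"] = fwd_pass[pair]
            if pair in rev_pass:
                ev["reverse"] = rev_pass[pair]
            result.pairs.add(pair)
            result.evidence[pair] = ev
    else:  # strictness 3: reciprocal best hits passing thresholds
        fwd_best = best_hits(fwd_c)
        rev_best = best_hits(rev_c)
        for target, fhit in fwd_best.items():
            template = fhit.subject_id
            rhit = rev_best.get(template)
            if rhit is None or rhit.subject_id != target:
                continue
            if passes_thresholds(fhit, params) and passes_thresholds(rhit, params):
                pair = (target, template)
                result.pairs.add(pair)
                result.evidence[pair] = {"forward": fhit, "reverse": rhit}
    return result


def map_summary(omap: OrthologMap) -> dict[str, int]:
    """Pair and gene counts, plus how many template genes have more
    than one target ortholog (one-to-many multiplicity)."""
    by_template = omap.by_template_gene()
    return {
        "n_pairs": len(omap.pairs),
        "n_target_genes": len({t for t, _ in omap.pairs}),
        "n_template_genes": len(by_template),
        "n_template_genes_multi": sum(1 for ts in by_template.values() if len(ts) > 1),
    }
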