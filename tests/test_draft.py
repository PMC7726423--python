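"""Draft extraction: GPR rewriting, inclusion rule, comparison, merging."""

import itertools

import numpy as np
import pytest

from gemdraft.draft import (
    OR_OF_ORTHOLOGS,
    PRESERVE_LOGIC,
    DraftOptions,
    extract_draft,
    gene_partition,
    merge_drafts,
    rewrite_gpr,
)
from gemdraft.gpr import GprExpression, parse_gpr
from gemdraft.model import Gene, Metabolite, Model, Reaction, model_stats
from gemdraft.orthology import OrthologMap

E = GprExpression


def omap(pairs):
    return OrthologMap(pairs=set(pairs))


class TestRewriteGpr:
    @pytest.mark.parametrize("mode", [OR_OF_ORTHOLOGS, PRESERVE_LOGIC])
    def test_or_rule_both_modes(self, mode):
        expr = parse_gpr("h1 or h3")
        result = rewrite_gpr(expr, omap([("c1", "h1"), ("c3", "h3")]), mode)
        assert result == parse_gpr("c1 or c3")

    def test_partially_mapped_complex(self):
        expr = parse_gpr("h1 and h2")
        mapping = omap([("c1", "h1")])
        assert rewrite_gpr(expr, mapping, OR_OF_ORTHOLOGS) == E.gene("c1")
        assert rewrite_gpr(expr, mapping, PRESERVE_LOGIC).is_empty

    @pytest.mark.parametrize("mode", [OR_OF_ORTHOLOGS, PRESERVE_LOGIC])
    def test_empty_map_gives_empty_expression(self, mode):
        assert rewrite_gpr(parse_gpr("h1 and (h2 or h3)"), omap([]), mode).is_empty

    def test_preserve_logic_truth_table_oracle(self):
        """preserve_logic semantics: the rewritten rule is true for a set
        of present target genes iff the original rule is true after
        marking each template leaf present when any of its orthologs is
        present — checked over all gene-presence assignments."""
        pairs = [("c1", "h1"), ("c1b", "h1"), ("c2", "h2"), ("c3", "h3")]
        mapping = omap(pairs)
        by_template = {"h1": {"c1", "c1b"}, "h2": {"c2"}, "h3": {"c3"}, "h4": set()}
        targets = sorted({t for t, _ in pairs})
        for text in ["h1 and h2", "h1 or h4", "h1 and (h2 or h4)",
                     "(h1 or h2) and h3", "h4 and h1", "h4 or h4"]:
            original = parse_gpr(text)
            rewritten = rewrite_gpr(original, mapping, PRESERVE_LOGIC)
            for presence in itertools.product([False, True], repeat=len(targets)):
                present = {t for t, p in zip(targets, presence) if p}
                template_present = {
                    g for g in original.genes() if by_template.get(g, set()) & present
                }
                assert rewritten.evaluate(present) == original.evaluate(template_present), (
                    text, present)


def small_template():
    m = Model(id="template")
    m.compartments = {"c": "cytosol"}
    for g in ("h1", "h2"):
        m.add_gene(Gene(id=g))
    for mid in ("m1", "m2", "m3", "m4"):
        m.add_metabolite(Metabolite(id=mid, compartment="c"))
    m.add_reaction(Reaction("R1", {"m1": -1, "m2": 1}, gpr=parse_gpr("h1"), subsystem="A"))
    m.add_reaction(Reaction("R2", {"m2": -1, "m3": 1}, gpr=parse_gpr("h2"), subsystem="A"))
    m.add_reaction(Reaction("R3", {"m3": -1, "m4": 1}, subsystem="B"))  # no GPR
    return m


class TestExtractDraft:
    def test_inclusion_rule(self):
        draft, report = extract_draft(small_template(), omap([("c1", "h1")]))
        assert set(draft.reactions) == {"R1"}
        assert set(draft.genes) == {"c1"}
        assert report.rows == {"h1": (("c1",), 1)}

    def test_include_non_gene_reactions(self):
        draft, _ = extract_draft(
            small_template(), omap([("c1", "h1")]),
            DraftOptions(include_non_gene_reactions=True),
        )
        assert set(draft.reactions) == {"R1", "R3"}
        assert draft.reactions["R3"].gpr.is_empty

    @pytest.mark.parametrize("mode", [OR_OF_ORTHOLOGS, PRESERVE_LOGIC])
    def test_inclusion_tests_original_gpr(self, mode):
        """A complex with one mapped subunit is included under either
        rewrite mode; only the rewritten rule differs."""
        m = small_template()
        m.reactions["R1"].gpr = parse_gpr("h1 and h2")
        draft, _ = extract_draft(m, omap([("c1", "h1")]), DraftOptions(gpr_mode=mode))
        assert "R1" in draft.reactions
        expected = E.gene("c1") if mode == OR_OF_ORTHOLOGS else E.empty()
        assert draft.reactions["R1"].gpr == expected

    def test_inclusion_matches_intersection_oracle(self, spec, template, homology):
        from gemdraft.orthology import MappingParams, map_orthologs

        fwd, rev, _ = homology
        mapping = map_orthologs(fwd, rev, MappingParams(strictness=3))
        draft, _ = extract_draft(template, mapping)
        mapped = set(mapping.by_template_gene())
        expected = {
            r.id for r in template.reactions.values() if r.gpr.genes() & mapped
        }
        assert set(draft.reactions) == expected

    def test_draft_is_subset_of_template(self, template, homology):
        from gemdraft.orthology import MappingParams, map_orthologs

        fwd, rev, _ = homology
        mapping = map_orthologs(fwd, rev, MappingParams(strictness=1))
        draft, _ = extract_draft(template, mapping)
        assert set(draft.reactions) <= set(template.reactions)
        assert set(draft.metabolites) <= set(template.metabolites)
        assert set(draft.compartments) <= set(template.compartments)
        for rid, rxn in draft.reactions.items():
            assert rxn.stoichiometry == template.reactions[rid].stoichiometry
            assert rxn.subsystem == template.reactions[rid].subsystem
        # every draft gene in >=1 GPR; every metabolite in >=1 reaction
        used_genes = set().union(*(r.gpr.genes() for r in draft.reactions.values()))
        assert set(draft.genes) == used_genes
        used_mets = {mid for r in draft.reactions.values() for mid in r.stoichiometry}
        assert set(draft.metabolites) == used_mets

    def test_larger_map_never_shrinks_draft(self, template, homology):
        fwd, rev, truth = homology
        pairs = sorted(truth.pairs)
        small = omap(pairs[: len(pairs) // 2])
        big = omap(pairs)
        d_small, _ = extract_draft(template, small)
        d_big, _ = extract_draft(template, big)
        assert set(d_small.reactions) <= set(d_big.reactions)

    def test_unknown_template_ids_warn_not_error(self):
        with pytest.warns(UserWarning, match="not in the template"):
            draft, _ = extract_draft(
                small_template(), omap([("c1", "h1"), ("cx", "ghost_gene")])
            )
        assert set(draft.reactions) == {"R1"}

    def test_gprless_template_raises_with_advice(self):
        m = Model(id="t")
        m.compartments = {"c": "c"}
        m.add_metabolite(Metabolite("m1", "c"))
        m.add_metabolite(Metabolite("m2", "c"))
        m.add_reaction(Reaction("R1", {"m1": -1, "m2": 1}))
        with pytest.raises(ValueError, match="include_non_gene_reactions"):
            extract_draft(m, omap([]))


class TestGenePartition:
    def test_hand_enumerable_regions(self):
        regions = gene_partition({"A": {"g1", "g2"}, "B": {"g2", "g3"}, "C": {"g2"}})
        assert regions["A"] == 1
        assert regions["B"] == 1
        assert regions["C"] == 0
        assert regions["A&B&C"] == 1
        assert regions["A&B"] == regions["A&C"] == regions["B&C"] == 0

    def test_identical_sets_all_in_full_intersection(self):
        s = {"g1", "g2", "g3"}
        regions = gene_partition({"A": set(s), "B": set(s)})
        assert regions == {"A": 0, "B": 0, "A&B": 3}

    def test_matches_membership_vector_oracle(self):
        rng = np.random.default_rng(4)
        universe = [f"g{i}" for i in range(60)]
        sets = {
            name: {g for g in universe if rng.random() < 0.5} for name in "ABC"
        }
        regions = gene_partition(dict(sets))
        # oracle: count per-gene membership vectors
        from collections import Counter

        vectors = Counter()
        for g in set().union(*sets.values()):
            vectors["&".join(n for n in "ABC" if g in sets[n])] += 1
        for label, size in regions.items():
            assert size == vectors.get(label, 0)
        assert sum(regions.values()) == len(set().union(*sets.values()))

    def test_fewer_than_two_drafts_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            gene_partition({"A": {"g1"}})


def draft_with(reactions, model_id="d"):
    m = Model(id=model_id)
    m.compartments = {"c": "cytosol"}
    mets = {mid for stoich, _ in reactions.values() for mid in stoich}
    for mid in sorted(mets):
        m.add_metabolite(Metabolite(mid, "c"))
    genes = set()
    for rid, (stoich, gpr_text) in reactions.items():
        gpr = parse_gpr(gpr_text)
        genes |= gpr.genes()
        m.add_reaction(Reaction(rid, dict(stoich), gpr=gpr))
    for g in sorted(genes):
        m.add_gene(Gene(g))
    return m


class TestMergeDrafts:
    def test_baseline_priority_and_new_reactions_tagged(self):
        baseline = draft_with({"R1": ({"m1": -1, "m2": 1}, "c1")})
        comp = draft_with({"R1": ({"m1": -1, "m2": 1}, "c1"),
                           "R2": ({"m2": -1, "m3": 1}, "c2")})
        result = merge_drafts(baseline, {"annotA": comp})
        assert set(result.model.reactions) == {"R1", "R2"}
        assert result.sources["reactions"]["R2"] == "annotA"
        assert result.sources["reactions"]["R1"] == "baseline"

    def test_shared_reaction_gprs_are_unioned(self):
        baseline = draft_with({"R1": ({"m1": -1, "m2": 1}, "c1")})
        comp = draft_with({"R1": ({"m1": -1, "m2": 1}, "c2")})
        result = merge_drafts(baseline, {"x": comp})
        assert result.model.reactions["R1"].gpr == parse_gpr("c1 or c2")
        assert set(result.model.genes) == {"c1", "c2"}

    def test_disjoint_drafts_union_additive_stats(self):
        baseline = draft_with({"R1": ({"m1": -1, "m2": 1}, "c1")})
        comp = draft_with({"R2": ({"m3": -1, "m4": 1}, "c2")})
        merged = merge_drafts(baseline, {"x": comp}).model
        assert set(merged.reactions) == {"R1", "R2"}
        assert model_stats(merged).n_reactions == 2
        assert model_stats(merged).n_genes == 2

    def test_conflicting_stoichiometry_raises(self):
        baseline = draft_with({"R1": ({"m1": -1, "m2": 1}, "c1")})
        comp = draft_with({"R1": ({"m1": -2, "m2": 1}, "c1")})
        with pytest.raises(ValueError, match="conflicting stoichiometry"):
            merge_drafts(baseline, {"x": comp})
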