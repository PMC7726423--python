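"""Ortholog-mapping semantics: thresholds, best hits, strictness regimes."""

import numpy as np
import pytest

from conftest import oracle_collapse, oracle_map, random_tables
from gemdraft.homology import TARGET_TO_TEMPLATE, TEMPLATE_TO_TARGET, HomologyHit, HomologyTable
from gemdraft.orthology import (
    MappingParams,
    best_hits,
    collapse_hsps,
    map_orthologs,
    map_summary,
    passes_thresholds,
)


def hit(q, s, e=1e-50, length=250, ide=80.0, bit=500.0):
    return HomologyHit(q, s, percent_identity=ide, alignment_length=length,
                       e_value=e, bit_score=bit)


def tables(fwd_hits, rev_hits):
    return (
        HomologyTable(TARGET_TO_TEMPLATE, fwd_hits),
        HomologyTable(TEMPLATE_TO_TARGET, rev_hits),
    )


class TestThresholds:
    @pytest.mark.parametrize(
        "e, length, ide, expected",
        [
            (1e-50, 250, 80.0, True),
            (1e-10, 250, 80.0, False),   # E-value too large
            (1e-50, 150, 80.0, False),   # alignment too short
            (1e-50, 250, 30.0, False),   # identity too low
            (1e-30, 200, 40.0, True),    # all three boundaries inclusive
        ],
    )
    def test_default_thresholds(self, e, length, ide, expected, default_params):
        assert passes_thresholds(hit("t", "h", e, length, ide), default_params) is expected

    def test_matches_brute_force_predicate(self, default_params):
        rng = np.random.default_rng(0)
        for _ in range(200):
            h = hit("t", "h", float(10.0 ** -rng.uniform(10, 60)),
                    int(rng.integers(100, 400)), float(rng.uniform(20, 95)))
            brute = (
                h.e_value <= default_params.maxE
                and h.alignment_length >= default_params.minLen
                and h.percent_identity >= default_params.minIde
            )
            assert passes_thresholds(h, default_params) is brute

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            MappingParams(strictness=4)
        with pytest.raises(ValueError):
            MappingParams(minIde=150)


class TestBestHits:
    def test_lowest_e_value_wins(self):
        table = HomologyTable(TARGET_TO_TEMPLATE, [hit("t1", "h1", 1e-50), hit("t1", "h2", 1e-10)])
        assert best_hits(table)["t1"].subject_id == "h1"

    def test_empty_table(self):
        assert best_hits(HomologyTable(TARGET_TO_TEMPLATE, [])) == {}

    def test_tie_breaks_by_bit_score_then_subject(self):
        table = HomologyTable(
            TARGET_TO_TEMPLATE,
            [hit("t1", "h1", 1e-50, bit=490.0), hit("t1", "h2", 1e-50, bit=500.0)],
        )
        assert best_hits(table)["t1"].subject_id == "h2"
        table2 = HomologyTable(
            TARGET_TO_TEMPLATE,
            [hit("t1", "h2", 1e-50, bit=500.0), hit("t1", "h1", 1e-50, bit=500.0)],
        )
        assert best_hits(table2)["t1"].subject_id == "h1"

    def test_exhaustive_comparison_oracle(self):
        rng = np.random.default_rng(1)
        fwd, _ = random_tables(rng, n_hits=60)
        result = best_hits(fwd)
        for query, chosen in result.items():
            rivals = [h for h in fwd.hits if h.query_id == query]
            assert all(
                (chosen.e_value, -chosen.bit_score, chosen.subject_id)
                <= (r.e_value, -r.bit_score, r.subject_id)
                for r in rivals
            )


class TestCollapseHsps:
    def test_keeps_best_hsp_per_pair(self):
        table = HomologyTable(TARGET_TO_TEMPLATE, [hit("t1", "h1", 1e-20), hit("t1", "h1", 1e-50)])
        collapsed = collapse_hsps(table)
        assert len(collapsed) == 1
        assert collapsed.hits[0].e_value == 1e-50

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        fwd, _ = random_tables(rng)
        once = collapse_hsps(fwd)
        assert collapse_hsps(once).hits == once.hits

    def test_matches_group_by_oracle(self):
        rng = np.random.default_rng(3)
        fwd, _ = random_tables(rng, n_hits=80)
        collapsed = {(h.query_id, h.subject_id): h for h in collapse_hsps(fwd).hits}
        assert collapsed == oracle_collapse(fwd.hits)


class TestMapOrthologs:
    def test_reciprocal_pair_accepted_s1(self, default_params):
        fwd, rev = tables([hit("t1", "h1", 1e-50, 250, 80.0)], [hit("h1", "t1", 1e-45, 240, 78.0)])
        omap = map_orthologs(fwd, rev, MappingParams(strictness=1))
        assert omap.pairs == {("t1", "h1")}

    def test_one_direction_evidence_s2_vs_s1(self):
        fwd, rev = tables(
            [hit("t1", "h1"), hit("t2", "h2")], [hit("h1", "t1")]
        )
        s1 = map_orthologs(fwd, rev, MappingParams(strictness=1)).pairs
        s2 = map_orthologs(fwd, rev, MappingParams(strictness=2)).pairs
        assert ("t2", "h2") in s2 and ("t2", "h2") not in s1
        assert ("t1", "h1") in s1

    def test_s3_best_reciprocal_only(self):
        fwd, rev = tables(
            [hit("t1", "h1", 1e-50), hit("t1", "h2", 1e-60)],
            [hit("h1", "t1", 1e-50), hit("h2", "t1", 1e-60)],
        )
        omap = map_orthologs(fwd, rev, MappingParams(strictness=3))
        assert omap.pairs == {("t1", "h2")}

    def test_s3_failing_best_hit_kills_pair(self):
        # the best hit fails thresholds; the second-best passing hit
        # must NOT be promoted
        fwd, rev = tables(
            [hit("t1", "h1", 1e-60, length=150), hit("t1", "h2", 1e-50)],
            [hit("h1", "t1", 1e-60), hit("h2", "t1", 1e-50)],
        )
        omap = map_orthologs(fwd, rev, MappingParams(strictness=3))
        assert omap.pairs == set()

    def test_same_direction_tables_rejected(self):
        fwd, _ = tables([], [])
        with pytest.raises(ValueError, match="direction"):
            map_orthologs(fwd, fwd, MappingParams())

    def test_evidence_recorded_per_pair(self, default_params):
        fwd, rev = tables([hit("t1", "h1")], [hit("h1", "t1")])
        omap = map_orthologs(fwd, rev, MappingParams(strictness=1))
        ev = omap.evidence[("t1", "h1")]
        assert ev["forward"].query_id == "t1" and ev["reverse"].query_id == "h1"

    @pytest.mark.parametrize("strictness", [1, 2, 3])
    def test_agrees_with_brute_force_oracle(self, strictness):
        rng = np.random.default_rng(100 + strictness)
        for _ in range(30):
            fwd, rev = random_tables(rng)
            params = MappingParams(strictness=strictness)
            assert map_orthologs(fwd, rev, params).pairs == oracle_map(fwd, rev, params)

    def test_nesting_s3_within_s1_within_s2(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            fwd, rev = random_tables(rng)
            maps = {
                s: map_orthologs(fwd, rev, MappingParams(strictness=s)).pairs
                for s in (1, 2, 3)
            }
            assert maps[3] <= maps[1] <= maps[2]

    @pytest.mark.parametrize("strictness", [1, 2])
    def test_threshold_relaxation_monotone(self, strictness):
        rng = np.random.default_rng(8)
        for _ in range(20):
            fwd, rev = random_tables(rng)
            tight = MappingParams(strictness=strictness)
            relaxed = MappingParams(strictness=strictness, maxE=1e-20, minLen=150, minIde=30.0)
            assert (
                map_orthologs(fwd, rev, tight).pairs
                <= map_orthologs(fwd, rev, relaxed).pairs
            )

    def test_s3_is_partial_matching(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            fwd, rev = random_tables(rng)
            pairs = map_orthologs(fwd, rev, MappingParams(strictness=3)).pairs
            targets = [t for t, _ in pairs]
            templates = [g for _, g in pairs]
            assert len(targets) == len(set(targets))
            assert len(templates) == len(set(templates))


class TestMapSummary:
    def test_multiplicity_count(self):
        from gemdraft.orthology import OrthologMap

        omap = OrthologMap(pairs={("t1", "h1"), ("t2", "h1")})
        summary = map_summary(omap)
        assert summary == {
            "n_pairs": 2,
            "n_target_genes": 2,
            "n_template_genes": 1,
            "n_template_genes_multi": 1,
        }

    def test_empty_map_all_zero(self):
        from gemdraft.orthology import OrthologMap

        assert all(v == 0 for v in map_summary(OrthologMap()).values())

    def test_s3_maps_have_no_multiplicity(self):
        rng = np.random.default_rng(10)
        fwd, rev = random_tables(rng, n_hits=60)
        omap = map_orthologs(fwd, rev, MappingParams(strictness=3))
        assert map_summary(omap)["n_template_genes_multi"] == 0
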