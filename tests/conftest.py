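import numpy as np
import pytest

from gemdraft.fixtures import FixtureSpec, make_homology, make_template
from gemdraft.homology import TARGET_TO_TEMPLATE, TEMPLATE_TO_TARGET, HomologyHit, HomologyTable
from gemdraft.orthology import MappingParams


@pytest.fixture
def spec():
    return FixtureSpec(seed=11)


@pytest.fixture
def template(spec):
    return make_template(spec)


@pytest.fixture
def homology(spec):
    return make_homology(spec)


@pytest.fixture
def default_params():
    return MappingParams()


def random_tables(rng: np.random.Generator, n_target=12, n_template=10, n_hits=40):
    """A random bidirectional homology-table pair for oracle comparisons.

    E-values, identities and lengths straddle the default thresholds so
    that all three predicates are exercised; a fraction of pairs get a
    second HSP.
    """
    targets = [f"t{i}" for i in range(n_target)]
    templates = [f"h{i}" for i in range(n_template)]

    def random_hits(queries, subjects, n):
        hits = []
        for _ in range(n):
            hits.append(
                HomologyHit(
                    query_id=queries[rng.integers(len(queries))],
                    subject_id=subjects[rng.integers(len(subjects))],
                    percent_identity=float(rng.uniform(20, 95)),
                    alignment_length=int(rng.integers(100, 400)),
                    e_value=float(10.0 ** -rng.uniform(5, 60)),
                    bit_score=float(rng.uniform(50, 600)),
                )
            )
        return hits

    fwd = HomologyTable(TARGET_TO_TEMPLATE, random_hits(targets, templates, n_hits))
    rev = HomologyTable(TEMPLATE_TO_TARGET, random_hits(templates, targets, n_hits))
    return fwd, rev


def oracle_collapse(hits):
    """Independent group-by-minimum: best hit per (query, subject)."""
    best = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        rank = (h.e_value, -h.bit_score, h.subject_id)
        if key not in best or rank < best[key][0]:
            best[key] = (rank, h)
    return {key: h for key, (_, h) in best.items()}


def oracle_map(fwd, rev, params):
    """Literal evaluation of the strictness predicates over every
    (target, template) pair; independent of the implementation path."""

    def ok(h):
        return (
            h.e_value <= params.maxE
            and h.alignment_length >= params.minLen
            and h.percent_identity >= params.minIde
        )

    fwd_best_per_pair = oracle_collapse(fwd.hits)
    rev_best_per_pair = oracle_collapse(rev.hits)
    targets = {h.query_id for h in fwd.hits} | {h.subject_id for h in rev.hits}
    templates = {h.subject_id for h in fwd.hits} | {h.query_id for h in rev.hits}

    if params.strictness in (1, 2):
        pairs = set()
        for t in targets:
            for g in templates:
                f = fwd_best_per_pair.get((t, g))
                r = rev_best_per_pair.get((g, t))
                f_ok = f is not None and ok(f)
                r_ok = r is not None and ok(r)
                if (params.strictness == 1 and f_ok and r_ok) or (
                    params.strictness == 2 and (f_ok or r_ok)
                ):
                    pairs.add((t, g))
        return pairs

    def best_of(per_pair, query):
        cands = [h for (q, _), h in per_pair.items() if q == query]
        return min(cands, key=lambda h: (h.e_value, -h.bit_score, h.subject_id), default=None)

    pairs = set()
    for t in targets:
        f = best_of(fwd_best_per_pair, t)
        if f is None:
            continue
        r = best_of(rev_best_per_pair, f.subject_id)
        if r is not None and r.subject_id == t and ok(f) and ok(r):
            pairs.add((t, f.subject_id))
    return pairs
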