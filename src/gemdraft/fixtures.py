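"""Deterministic synthetic fixtures for the whole reconstruction pipeline.

Real inputs to homology-based drafting are a multi-thousand-reaction
template GEM and genome-wide proteomes — far too large for tests and
not redistributable here.  This module builds scaled-down stand-ins
with *known ground truth*: a toy template model with subsystems and
mixed GPRs, a pair of proteomes, reciprocal homology tables with
planted ortholog pairs and controlled decoys, curation rules and an
expression table.  Because the mapping semantics (not sequence
alignment) are what the toolkit implements, homology tables are
generated directly with controlled E-values, identities and lengths
rather than by running an aligner.

Planted pairs always receive reciprocal best hits comfortably inside
the default acceptance thresholds (E <= 1e-40, identity >= 60, length
>= 250).  Decoys come in two flavours: hits failing at least one
default threshold, and hits passing the thresholds in one direction
only, at a worse E-value than any planted hit — these enlarge the
strictness-2 map but can never displace a planted reciprocal best hit.
Passing decoys are anchored to planted queries (emulating paralogs of
true orthologs), so a scenario with nothing planted yields empty maps
at every strictness.

Everything is a pure function of (spec, seed): identical inputs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .gpr import GprExpression
from .homology import (
    TARGET_TO_TEMPLATE,
    TEMPLATE_TO_TARGET,
    HomologyHit,
    HomologyTable,
    write_homology_table,
)
from .model import Gene, Metabolite, Model, Reaction
from .orthology import OrthologMap
from .overlay import ExpressionRecord

__all__ = [
    "FixtureSpec",
    "CYP_SUBSYSTEM",
    "make_template",
    "target_gene_ids",
    "make_homology",
    "make_expression",
    "make_proteomes",
    "write_fixture_set",
]

CYP_SUBSYSTEM = "Metabolism of xenobiotics by cytochrome P450"

_AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic reconstruction scenario.

    Defaults give a template an order of magnitude smaller than a real
    liver GEM but with the same qualitative structure: most reactions
    gene-associated, a quarter catalyzed by two-subunit complexes, a
    core of template genes with true target orthologs, and a sprinkle
    of misleading homology hits.
    """

    seed: int = 0
    n_template_genes: int = 30
    n_target_genes: int = 40
    planted_pairs: float = 0.7  # fraction of template genes with a true ortholog
    decoy_hits: int = 10
    n_reactions: int = 40
    n_subsystems: int = 4
    fraction_no_gpr: float = 0.15
    fraction_complex: float = 0.25

    def __post_init__(self):
        for name in ("planted_pairs", "fraction_no_gpr", "fraction_complex"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("n_template_genes", "n_target_genes", "decoy_hits",
                     "n_reactions", "n_subsystems"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def n_no_gpr(self) -> int:
        return round(self.fraction_no_gpr * self.n_reactions)

    def n_complex(self) -> int:
        return round(self.fraction_complex * self.n_reactions)


def _rng(spec: FixtureSpec, stream: int) -> np.random.Generator:
    # one independent substream per generated artifact
    return np.random.default_rng([spec.seed, stream])


def _template_gene_ids(spec: FixtureSpec) -> list[str]:
    return [f"HSA{i:04d}" for i in range(1, spec.n_template_genes + 1)]


def target_gene_ids(spec: FixtureSpec) -> list[str]:
    """Target-species gene identifiers used across all fixtures."""
    return [f"GMO{i:04d}" for i in range(1, spec.n_target_genes + 1)]


def make_template(spec: FixtureSpec) -> Model:
    """A connected toy template GEM.

    A linear metabolite chain guarantees connectivity; reactions are
    grouped into contiguous subsystem blocks, the first labelled
    "Metabolism of xenobiotics by cytochrome P450" for gap-analysis
    tests.  GPR assignment cycles through the gene list so every
    template gene catalyzes at least one reaction, then adds complex
    (AND) partners and isoenzyme (OR) partners at random.
    """
    if spec.n_no_gpr() + spec.n_complex() > spec.n_reactions:
        raise ValueError(
            "infeasible spec: fraction_no_gpr + fraction_complex exceed the "
            "reaction count"
        )
    if spec.n_reactions > 0 and spec.n_template_genes == 0:
        raise ValueError("infeasible spec: reactions need at least one template gene")
    rng = _rng(spec, 0)
    genes = _template_gene_ids(spec)

    model = Model(id=f"toy_template_seed{spec.seed}")
    model.provenance = {"generator": "gemdraft.fixtures", "seed": spec.seed}
    model.compartments = {"c": "cytosol", "e": "extracellular"}
    for g in genes:
        model.add_gene(Gene(id=g))

    n_mets = spec.n_reactions + 1
    for i in range(n_mets):
        comp = "e" if i in (0, n_mets - 1) else "c"
        model.add_metabolite(Metabolite(id=f"M{i:04d}", compartment=comp))

    subsystem_names = [CYP_SUBSYSTEM] + [
        f"Toy subsystem {chr(ord('B') + i)}" for i in range(max(0, spec.n_subsystems - 1))
    ]
    # which reactions are GPR-less / complex-catalyzed
    order = rng.permutation(spec.n_reactions)
    no_gpr_set = set(order[: spec.n_no_gpr()].tolist())
    complex_set = set(order[spec.n_no_gpr(): spec.n_no_gpr() + spec.n_complex()].tolist())

    gene_cycle = iter(genes * ((spec.n_reactions // max(len(genes), 1)) + 2))
    block = max(1, -(-spec.n_reactions // max(spec.n_subsystems, 1)))  # ceil division
    for i in range(spec.n_reactions):
        if i in no_gpr_set:
            gpr = GprExpression.empty()
        else:
            primary = next(gene_cycle)
            if i in complex_set:
                partner = genes[int(rng.integers(len(genes)))]
                if partner == primary:
                    partner = genes[(genes.index(primary) + 1) % len(genes)]
                gpr = GprExpression.and_(
                    GprExpression.gene(primary), GprExpression.gene(partner)
                )
            elif rng.random() < 0.3:  # isoenzyme pair
                partner = genes[int(rng.integers(len(genes)))]
                gpr = GprExpression.or_(
                    GprExpression.gene(primary), GprExpression.gene(partner)
                )
            else:
                gpr = GprExpression.gene(primary)
        model.add_reaction(
            Reaction(
                id=f"R{i + 1:04d}",
                stoichiometry={f"M{i:04d}": -1.0, f"M{i + 1:04d}": 1.0},
                lower_bound=-1000.0 if rng.random() < 0.5 else 0.0,
                upper_bound=1000.0,
                subsystem=subsystem_names[min(i // block, len(subsystem_names) - 1)],
                gpr=gpr,
            )
        )
    model.validate()
    return model


def make_homology(
    spec: FixtureSpec,
    template_genes: list[str] | None = None,
    target_genes: list[str] | None = None,
) -> tuple[HomologyTable, HomologyTable, OrthologMap]:
    """Reciprocal homology tables with planted orthologs and decoys.

    Returns (forward target->template table, reverse table, ground-truth
    ortholog map).  See the module docstring for the decoy construction
    guarantees.
    """
    rng = _rng(spec, 1)
    template_genes = list(template_genes or _template_gene_ids(spec))
    target_genes = list(target_genes or target_gene_ids(spec))

    n_planted = round(spec.planted_pairs * len(template_genes))
    n_planted = min(n_planted, len(target_genes))
    planted_templates = [
        template_genes[i]
        for i in sorted(rng.choice(len(template_genes), size=n_planted, replace=False))
    ]
    partner_targets = [
        target_genes[i] for i in rng.permutation(len(target_genes))[:n_planted]
    ]
    truth = OrthologMap()
    fwd_hits: list[HomologyHit] = []
    rev_hits: list[HomologyHit] = []

    def strong_hit(query: str, subject: str) -> HomologyHit:
        length = int(rng.integers(250, 401))
        return HomologyHit(
            query_id=query,
            subject_id=subject,
            percent_identity=float(np.round(rng.uniform(60, 95), 1)),
            alignment_length=length,
            mismatches=int(length * 0.2),
            gap_opens=int(rng.integers(0, 4)),
            q_start=1,
            q_end=length,
            s_start=1,
            s_end=length,
            e_value=float(10.0 ** -rng.uniform(50, 80)),
            bit_score=float(np.round(rng.uniform(300, 600), 1)),
        )

    for template_g, target_g in zip(planted_templates, partner_targets):
        truth.pairs.add((target_g, template_g))
        fwd_hits.append(strong_hit(target_g, template_g))
        rev_hits.append(strong_hit(template_g, target_g))

    planted_set = truth.pairs
    for k in range(spec.decoy_hits):
        target_g = target_genes[int(rng.integers(len(target_genes)))]
        template_g = template_genes[int(rng.integers(len(template_genes)))]
        if (target_g, template_g) in planted_set:
            template_g = template_genes[
                (template_genes.index(template_g) + 1) % len(template_genes)
            ]
            if (target_g, template_g) in planted_set:
                continue
        if k % 2 == 0 or not partner_targets:
            # fails thresholds outright: weak E-value and identity
            hit = HomologyHit(
                query_id=target_g,
                subject_id=template_g,
                percent_identity=float(np.round(rng.uniform(20, 35), 1)),
                alignment_length=int(rng.integers(80, 180)),
                e_value=float(10.0 ** -rng.uniform(2, 10)),
                bit_score=float(np.round(rng.uniform(30, 60), 1)),
            )
        else:
            # passes thresholds, forward direction only, worse than any
            # planted best hit — visible to strictness 2 alone; anchored
            # to a planted query, emulating a paralog of a true ortholog
            target_g = partner_targets[int(rng.integers(len(partner_targets)))]
            if (target_g, template_g) in planted_set:
                continue
            length = int(rng.integers(210, 245))
            hit = HomologyHit(
                query_id=target_g,
                subject_id=template_g,
                percent_identity=float(np.round(rng.uniform(45, 55), 1)),
                alignment_length=length,
                e_value=float(10.0 ** -rng.uniform(31, 38)),
                bit_score=float(np.round(rng.uniform(100, 180), 1)),
            )
        fwd_hits.append(hit)

    fwd = HomologyTable(direction=TARGET_TO_TEMPLATE, hits=fwd_hits)
    rev = HomologyTable(direction=TEMPLATE_TO_TARGET, hits=rev_hits)
    return fwd, rev, truth


def make_proteomes(spec: FixtureSpec) -> tuple[list[tuple[str, str]], list[tuple[str, str]]]:
    """Random peptide sequences for the target and template gene sets,
    as (id, sequence) pairs; lengths are drawn uniformly in 100-600."""
    rng = _rng(spec, 3)

    def sequences(ids: list[str]) -> list[tuple[str, str]]:
        out = []
        for pid in ids:
            length = int(rng.integers(100, 601))
            seq = "".join(_AMINO_ACIDS[rng.integers(0, 20, size=length)])
            out.append((pid, seq))
        return out

    return sequences(target_gene_ids(spec)), sequences(_template_gene_ids(spec))


def make_expression(
    spec: FixtureSpec,
    model: Model,
    up_genes: list[str],
    down_genes: list[str],
) -> list[ExpressionRecord]:
    """An expression table over the model's genes.

    Listed genes get a significant log2 fold change of the stated sign
    with magnitude drawn in [1, 3]; all other model genes get small
    non-significant noise in [-0.3, 0.3].
    """
    overlap = set(up_genes) & set(down_genes)
    if overlap:
        raise ValueError(f"gene(s) listed as both up and down: {sorted(overlap)}")
    unknown = (set(up_genes) | set(down_genes)) - set(model.genes)
    if unknown:
        raise ValueError(f"gene(s) not in model: {sorted(unknown)}")
    rng = _rng(spec, 2)
    records = []
    for gid in model.genes:
        if gid in up_genes:
            rec = ExpressionRecord(gid, float(np.round(rng.uniform(1, 3), 3)), True)
        elif gid in down_genes:
            rec = ExpressionRecord(gid, float(np.round(-rng.uniform(1, 3), 3)), True)
        else:
            rec = ExpressionRecord(gid, float(np.round(rng.uniform(-0.3, 0.3), 3)), False)
        records.append(rec)
    return records


def write_fixture_set(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory: template model (SBML + JSON),
    proteome FASTAs, homology tables, ground-truth map, an example
    curation-rules file and an expression table.  Returns the paths."""
    from .io import write_model  # local import to avoid cycle at module load

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    template = make_template(spec)
    fwd, rev, truth = make_homology(spec)
    target_seqs, template_seqs = make_proteomes(spec)

    paths = {
        "template_sbml": out / "template.xml",
        "template_json": out / "template.json",
        "target_fasta": out / "target.faa",
        "template_fasta": out / "template.faa",
        "fwd_table": out / "target_vs_template.tsv",
        "rev_table": out / "template_vs_target.tsv",
        "truth_map": out / "planted_orthologs.tsv",
        "rules": out / "curation_rules.tsv",
        "expression": out / "expression.tsv",
    }
    write_model(template, paths["template_sbml"], format="sbml")
    write_model(template, paths["template_json"], format="json")
    for key, seqs in (("target_fasta", target_seqs), ("template_fasta", template_seqs)):
        with open(paths[key], "w") as fh:
            for pid, seq in seqs:
                fh.write(f">{pid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
    write_homology_table(fwd, paths["fwd_table"])
    write_homology_table(rev, paths["rev_table"])
    with open(paths["truth_map"], "w") as fh:
        fh.write("# target_gene\ttemplate_gene\n")
        for target_g, template_g in sorted(truth.pairs):
            fh.write(f"{target_g}\t{template_g}\n")

    # example curation rules: first two reactions of the CYP subsystem
    cyp_rxns = sorted(
        r.id for r in template.reactions.values() if r.subsystem == CYP_SUBSYSTEM
    )
    with open(paths["rules"], "w") as fh:
        fh.write("# reaction_id\trule_type\tplaceholder_gene\n")
        if cyp_rxns:
            fh.write(f"{cyp_rxns[0]}\tspontaneous\t-\n")
        if len(cyp_rxns) > 1:
            fh.write(f"{cyp_rxns[1]}\tfamily\tCYP1_family\n")

    # expression over the *target* gene namespace: reuse the draft genes
    # by marking a third of planted targets up and a third down
    planted_targets = sorted(t for t, _ in truth.pairs)
    third = max(1, len(planted_targets) // 3) if planted_targets else 0
    up = planted_targets[:third]
    down = planted_targets[third: 2 * third]
    rng = _rng(spec, 4)
    with open(paths["expression"], "w") as fh:
        fh.write("gene_id\tlog2fc\tsignificant\n")
        for gid in target_gene_ids(spec):
            if gid in up:
                fh.write(f"{gid}\t{np.round(rng.uniform(1, 3), 3)}\tTrue\n")
            elif gid in down:
                fh.write(f"{gid}\t{np.round(-rng.uniform(1, 3), 3)}\tTrue\n")
            else:
                fh.write(f"{gid}\t{np.round(rng.uniform(-0.3, 0.3), 3)}\tFalse\n")
    return paths
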