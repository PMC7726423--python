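# Methods

## Scope and model

`gemdraft` reconstructs a *draft* genome-scale metabolic model (GEM)
for a target species by transferring reactions from a curated template
GEM of a related organism, using reciprocal protein-homology evidence.
The draft is a network object — compartments, metabolites, reactions
with stoichiometry, numeric flux bounds, subsystem labels, and Boolean
gene–protein–reaction (GPR) rules — not a simulation-ready model: no
biomass objective, no flux balance analysis, no mass/charge balancing.
Those belong to later curation phases and are deliberately out of
scope, as is running the aligner (the 12-column BLAST tabular file is
the interface) and optimization-based automatic gap filling.

## GPR rules

GPRs are rooted AND/OR trees over gene identifiers; AND joins complex
subunits, OR joins isoenzymes; there is no negation. The parser
accepts case-insensitive `and`/`or`, parentheses, and gene ids as
maximal runs of non-whitespace, non-parenthesis characters (so
versioned ids like `ENSG…​.5` are single tokens); `and` binds tighter
than `or`. Expressions are held in a normal form — same-operator
nesting flattened, single children collapsed, duplicate subtrees
dropped, children sorted by their serialized form — so structural
equality is insensitive to writing order and the serialized string is
canonical (deterministic diffs, deterministic tests). Normalization
never changes the Boolean function, which is property-tested by
evaluating random trees against random gene-presence sets.

## Ortholog mapping

A hit passes quality control iff `E ≤ maxE`, `length ≥ minLen`,
`identity ≥ minIde`, defaults `1e-30 / 200 / 40%`. The boundaries are
inclusive: a *maximum acceptable* E-value is itself acceptable. BLAST
may emit several HSPs per sequence pair; all are read, and mapping
first collapses each pair to its lowest-E HSP (ties: higher bit score,
then lexicographically smaller subject id — deterministic and
biologically arbitrary only between genuinely indistinguishable hits).

Strictness regimes over the collapsed tables:

* **1** — pair accepted with passing evidence in both directions;
  one template gene may collect several target orthologs (relevant
  where whole-genome duplication and splice-variant-rich annotations
  inflate target gene counts).
* **2** — passing evidence in at least one direction. The permissive
  reading of "one direction" is intentional and documented here
  because toolbox conventions differ.
* **3** — reciprocal best hits: best (lowest-E) hit per query in each
  direction, pair accepted when the two best hits point at each other
  *and both pass thresholds*. A best hit failing thresholds kills the
  pair; the second-best hit is never promoted. This yields a partial
  matching (injective both ways).

These definitions give the invariants s3 ⊆ s1 ⊆ s2 and monotonicity
under threshold relaxation (for s1/s2), both enforced by tests against
a brute-force oracle that evaluates the predicates literally over
every candidate pair.

## Draft extraction

A template reaction is included iff its *original* GPR shares at least
one gene with the mapped template-gene set. This is the standard
homology-drafting rule; it keeps complexes with partially mapped
subunits on the grounds that partial evidence still justifies
transfer. GPR-less reactions (spontaneous, transport, exchange) are
excluded by default — homology can say nothing about them — and the
gap-curation stage is the sanctioned route to re-add them; an
`include_non_gene_reactions` flag exists for users who want them
wholesale.

The kept reaction's rule is rewritten in one of two modes:

* `or_of_orthologs` (default): flat OR over all orthologs of all rule
  genes. Matches the inclusion rule's spirit (any mapped enzyme
  suffices) and avoids asserting complex stoichiometry that homology
  cannot confirm.
* `preserve_logic`: each leaf becomes the OR of its orthologs; an
  unmapped leaf is deleted; an AND node that loses any child becomes
  empty (strict complex semantics). Verified against a truth-table
  oracle: for every gene-presence assignment, the rewritten rule is
  true iff the original is true after marking a template gene present
  when any of its orthologs is present.

Both modes include the same reaction set — inclusion depends only on
the original rule. Stoichiometry, bounds, compartments and subsystem
labels are copied verbatim; metabolites are restricted to those used;
the draft gene set is exactly the genes occurring in rewritten rules.
Template gene ids in the map that the template model lacks produce
warnings, not errors, so maps built against a newer annotation remain
usable. The mapped-gene report (template gene → orthologs → number of
reactions carried) is the basis for comparing drafts built from
different genome annotations; `gene_partition` computes exact Venn
region sizes over their mapped-template-gene sets.

Merging is id-based and baseline-priority: the baseline draft
(typically from the most complete annotation) is kept in full,
complements contribute reactions with new ids in the given order, and
GPRs of shared reactions are OR-unioned. The complement order matters
only for provenance tags (which complement is credited with a new
reaction), never for the merged reaction set; stoichiometry conflicts
raise because template-derived drafts cannot disagree.

## Gap analysis and curation

`subsystem_diff` partitions one subsystem's template reactions into
`auto` (in the draft) and `missing`. Curation rules are declarative
data — a 3-column TSV — because the analogous manual work is otherwise
irreproducible; applying them is idempotent and never touches `auto`
reactions. Spontaneous fills get an empty GPR; family fills get a
placeholder gene (e.g. `CYP1_family`) flagged
`putative_family_assignment` so downstream users can distinguish
family-level assignments from homology-derived genes. The status
partition is preserved by construction and re-checked by tests over
random rule sets. Export produces a CSV and a reaction-id → numeric
state JSON consumable by Escher as reaction data; map layout is out of
scope.

## Expression overlay

Differential-expression input is gene id, log2 fold change, and a
significance flag — significance is *not* recomputed, since DE testing
is upstream of this tool. Per reaction, the significant fold changes
of its GPR genes give the state: `up` (all positive), `down` (all
negative), `mixed`, or `none` (no significant measured gene, including
every empty-GPR reaction). The default score aggregation `max_abs`
keeps the signed value of the strongest responder, matching how
pathway-level reasoning usually proceeds from the dominant enzyme;
`mean` is provided as the alternative. `mixed` is reported, not
resolved — branch-level contrasts are the job of `route_summary`,
which tallies states over named reaction sets.

## Model I/O

SBML (Level 3 with fbc gene products) is transported through
cobrapy/libsbml. Two GPR encodings are tolerated on read — fbc
`geneProductAssociation` and a `GENE_ASSOCIATION` key in reaction
notes — because template lineages derived from older human metabolic
reaction databases predate uniform fbc usage. Subsystems are read from
SBML groups or a `SUBSYSTEM` notes key and written as notes. The JSON
dialect keys entities by id with stoichiometry as id→coefficient maps,
chosen so toy fixtures are hand-writable. Reversibility is stored as
numeric bounds; a boolean `reversible` in JSON input maps to
(−1000, 1000) vs (0, 1000), the standard GEM convention. Referential
integrity is rejected, never repaired: any dangling metabolite, gene
or compartment reference raises listing all offenders.

One SBML asymmetry: genes that appear in no GPR are not serialized to
SBML (gene products attach to reactions), while the JSON dialect
preserves them. Drafts never hit this — every draft gene occurs in a
rule by construction.

## Synthetic fixtures

The generator produces the complete input suite — template model,
proteome FASTAs, reciprocal homology tables, curation rules,
expression table — as a pure function of a spec and seed, with
byte-identical reruns. Homology tables are generated directly with
controlled E-values, identities and lengths rather than by running an
aligner, because the semantics under test are the mapping rules, not
alignment. Default scenario: 30 template genes, 40 target genes, 70%
of template genes with a planted ortholog, 40 reactions in 4
subsystems (one the cytochrome-P450 xenobiotics subsystem), 15%
GPR-less reactions, 25% two-subunit complexes, 10 decoy hits — an
order of magnitude below real reconstructions but with the same
qualitative structure, sized so the whole suite and the acceptance
script run in seconds.

Planted pairs receive reciprocal best hits well inside the default
thresholds (E ≤ 1e-40, identity ≥ 60%, length ≥ 250). Decoys either
fail a threshold outright or pass in one direction only at a worse
E-value than any planted hit, anchored to planted queries (emulating
paralogs); consequently strictness 3 always recovers exactly the
planted pairs, strictness 2 is a superset, and a scenario with nothing
planted yields empty maps. What the fixtures do *not* emulate:
realistic sequence evolution, realistic network topology beyond
connectivity, fragmented or redundant annotations. Passing tests
therefore demonstrate the correctness of the mapping/extraction
semantics, not the biological quality of any real draft.

## Numerical and degenerate-input choices

* E-value 0.0 is legal (BLAST prints it) and is simply the smallest
  value under ≤ comparisons; no epsilon substitution.
* Float formatting in homology-table output uses `repr`, so
  read∘write is exact, not approximate.
* Quartiles of length distributions use linear interpolation between
  order statistics (the numpy default), cross-checked in tests by an
  explicit sort-based oracle.
* Empty protein sets are an error for summaries but a warning for
  FASTA reading (an empty file is a legitimate, if suspicious, input).
* A template with no GPRs at all cannot be drafted by homology; the
  error message points at `include_non_gene_reactions`.

## Verification of the published-template statistics

The statistics check against the published human hepatocyte template
(2322 genes, 5686 metabolites, 7930 reactions, 8 compartments) runs
whenever a locally supplied copy is present at
`data/iHepatocytes2322.xml`; the file is a ~30 MB download from its
public model repository and is not redistributed with this package.
Without it, the same code path is exercised on generated fixtures.

## Known limitations

Single template organism only; no synteny- or tree-based orthology; no
re-compartmentalization or localization prediction; merging is
restricted to drafts sharing one template's id namespace; Escher
export covers data overlays, not map layout.
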