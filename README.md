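# gemdraft

Homology-based draft reconstruction of genome-scale metabolic models
(GEMs) for non-model species, as a desk-scale Python toolkit.

## The problem

For a well-annotated organism, a draft GEM can be assembled from
biochemical databases. For a non-model species — say, a teleost fish
with a recently assembled genome — that route is closed: there is not
enough organism-specific biochemistry. The practicable alternative is
*template transfer*: take a curated GEM of a related organism (e.g. a
human liver model), find orthologs between the target and template
proteomes by reciprocal BLASTp, and carry over every template reaction
for which at least one catalyzing gene has an ortholog. The result is
a draft full of known gaps, which is then curated subsystem by
subsystem, and is already useful for qualitative work such as mapping
toxicant-exposure expression data onto pathways.

`gemdraft` implements that workflow for anyone doing it: ortholog
mapping from BLAST tabular output under three strictness regimes,
template reaction extraction with GPR (gene–protein–reaction rule)
rewriting, draft comparison and merging across genome annotations,
per-subsystem gap analysis with replayable curation rules, and
differential-expression overlay. Running BLASTp itself, automated
(optimization-based) gap filling, and flux balance analysis are out of
scope — the tool consumes homology tables and produces curated draft
networks.

## The method

Let `F` be the target→template homology table and `R` the reverse one
(12-column BLAST `-outfmt 6`). A hit passes the quality thresholds iff

    E-value ≤ maxE  ∧  alignment length ≥ minLen  ∧  %identity ≥ minIde

with defaults `maxE = 1e-30`, `minLen = 200`, `minIde = 40%` (all
boundaries inclusive). After collapsing multiple HSPs per sequence
pair to the lowest-E representative, a target–template gene pair
(t, g) is accepted at

* **strictness 1** — a passing hit t→g exists in `F` *and* g→t in `R`
  (one-to-many mapping allowed);
* **strictness 2** — a passing hit exists in *at least one* direction;
* **strictness 3** — reciprocal best hits: t's lowest-E hit is g, g's
  lowest-E hit is t, and both pass the thresholds (one-to-one).

These nest: s3 ⊆ s1 ⊆ s2. A template reaction enters the draft iff
its original GPR contains at least one mapped gene; its rule is
rewritten either as a flat OR over all orthologs (default — homology
cannot confirm complex stoichiometry) or preserving the AND/OR logic
with strict complex semantics. Gap curation then classifies each
template reaction of a subsystem as `auto` (in the draft),
`filled_spontaneous` (no enzyme needed), `filled_family` (assigned to
an enzyme family by a placeholder gene) or `missing`, and exports
Escher-compatible state overlays.

## Worked example

Generate a synthetic scenario with known ground truth (a 40-reaction
template, 21 planted ortholog pairs, decoy hits), then run the whole
pipeline:

```sh
gemdraft fixtures --seed 1 --out fx
gemdraft map --fwd fx/target_vs_template.tsv --rev fx/template_vs_target.tsv \
             --strictness 3 --out pairs.tsv
```

```json
{"n_pairs": 21, "n_target_genes": 21, "n_template_genes": 21,
 "n_template_genes_multi": 0}
```

21 pairs, one-to-one — strictness 3 recovered exactly the planted
orthologs and, by construction, no decoy. Build the draft:

```sh
gemdraft build --template fx/template.xml --map pairs.tsv \
               --out draft.xml --report report.tsv
```

```json
{"n_genes": 21, "n_reactions": 26, "n_metabolites": 34,
 "n_compartments": 2, "n_subsystems": 4}
```

26 of the 40 template reactions carried at least one mapped gene in
their GPR. Audit the cytochrome-P450 subsystem and replay the example
curation rules:

```sh
gemdraft gaps --template fx/template.xml --draft draft.xml \
              --subsystem "Metabolism of xenobiotics by cytochrome P450" \
              --rules fx/curation_rules.tsv --out-prefix states
```

```json
{"counts": {"missing": 3, "auto": 6, "filled_spontaneous": 1,
 "filled_family": 0}}
```

Of the subsystem's 10 template reactions, 6 transferred automatically,
1 gap was filled as a spontaneous reaction by the rules file, 3 remain
missing. `states.json` is loadable in Escher as reaction data for map
coloring. Finally, overlay the expression table:

```sh
gemdraft overlay --model draft.xml --expr fx/expression.tsv --out regulation.tsv
```

```json
{"n_reactions": 26, "up": 9, "down": 11, "mixed": 1, "none": 5}
```

Each draft reaction is classified from the significant log2
fold changes of its GPR genes, so up- and down-regulated pathway
branches can be contrasted (e.g. an activation route versus a
conjugation/clearance route after toxicant exposure).

Every step is equally usable as a library; see `docs/methods.md` for
the model details and `gemdraft --help` for all subcommands.

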