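"""In-memory genome-scale metabolic model (GEM) container.

A deliberately small, explicit data model: genes, metabolites with a
compartment, reactions with stoichiometry, numeric flux bounds, a
subsystem label and a GPR rule.  Referential integrity (every
stoichiometry entry resolves to a metabolite, every GPR leaf to a gene,
every metabolite compartment to a compartment) is *rejected*, never
silently repaired: :meth:`Model.validate` raises listing all offenders.

Reversibility is stored as numeric bounds following standard GEM
convention; a boolean in an input format maps to (-1000, 1000) for
reversible and (0, 1000) for irreversible, overridable via
``DEFAULT_BOUND``-style arguments in the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gpr import GprExpression

__all__ = [
    "Gene",
    "Metabolite",
    "Reaction",
    "Model",
    "ModelStats",
    "ModelIntegrityError",
    "model_stats",
    "DEFAULT_LOWER_BOUND",
    "DEFAULT_UPPER_BOUND",
]

DEFAULT_LOWER_BOUND = -1000.0
DEFAULT_UPPER_BOUND = 1000.0


class ModelIntegrityError(ValueError):
    """A model violated referential integrity or id uniqueness."""


@dataclass
class Gene:
    id: str
    name: str | None = None
    # provenance flags, e.g. "putative_family_assignment" for gap-filled
    # family placeholder genes
    flags: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.id:
            raise ValueError("gene id must be non-empty")


@dataclass
class Metabolite:
    id: str
    compartment: str
    name: str | None = None
    formula: str | None = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("metabolite id must be non-empty")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str | None = None
    lower_bound: float = DEFAULT_LOWER_BOUND
    upper_bound: float = DEFAULT_UPPER_BOUND
    subsystem: str = ""
    gpr: GprExpression = field(default_factory=GprExpression.empty)

    def __post_init__(self):
        if not self.id:
            raise ValueError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r}: stoichiometry must be non-empty")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            stoichiometry=dict(self.stoichiometry),
            name=self.name,
            lower_bound=self.lower_bound,
            upper_bound=self.upper_bound,
            subsystem=self.subsystem,
            gpr=self.gpr,
        )


@dataclass
class Model:
    """A GEM: compartments, genes, metabolites and reactions, keyed by id.

    ``provenance`` is free-form metadata (source file, build parameters,
    per-entity source tags) carried along through transformations.
    """

    id: str = "model"
    compartments: dict[str, str] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    # -- construction helpers -----------------------------------------

    def add_gene(self, gene: Gene) -> None:
        if gene.id in self.genes:
            raise ModelIntegrityError(f"duplicate gene id {gene.id!r}")
        self.genes[gene.id] = gene

    def add_metabolite(self, met: Metabolite) -> None:
        if met.id in self.metabolites:
            raise ModelIntegrityError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: Reaction) -> None:
        if rxn.id in self.reactions:
            raise ModelIntegrityError(f"duplicate reaction id {rxn.id!r}")
        self.reactions[rxn.id] = rxn

    # -- integrity ----------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ModelIntegrityError` listing every dangling
        reference; no repair is attempted."""
        problems: list[str] = []
        for met in self.metabolites.values():
            if met.compartment not in self.compartments:
                problems.append(
                    f"metabolite {met.id!r} cites unknown compartment {met.compartment!r}"
                )
        for rxn in self.reactions.values():
            for met_id in rxn.stoichiometry:
                if met_id not in self.metabolites:
                    problems.append(
                        f"reaction {rxn.id!r} cites unknown metabolite {met_id!r}"
                    )
            for gene_id in rxn.gpr.genes():
                if gene_id not in self.genes:
                    problems.append(
                        f"reaction {rxn.id!r} GPR cites unknown gene {gene_id!r}"
                    )
        if problems:
            raise ModelIntegrityError(
                "model integrity violations:\n  " + "\n  ".join(problems)
            )

    def subsystems(self) -> list[str]:
        """Sorted distinct non-empty subsystem labels."""
        return sorted({r.subsystem for r in self.reactions.values() if r.subsystem})

    def copy(self) -> "Model":
        m = Model(
            id=self.id,
            compartments=dict(self.compartments),
            genes={g.id: Gene(g.id, g.name, set(g.flags)) for g in self.genes.values()},
            metabolites={
                mt.id: Metabolite(mt.id, mt.compartment, mt.name, mt.formula)
                for mt in self.metabolites.values()
            },
            reactions={r.id: r.copy() for r in self.reactions.values()},
            provenance=dict(self.provenance),
        )
        return m


@dataclass(frozen=True)
class ModelStats:
    n_genes: int
    n_reactions: int
    n_metabolites: int
    n_compartments: int
    n_subsystems: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_genes": self.n_genes,
            "n_reactions": self.n_reactions,
            "n_metabolites": self.n_metabolites,
            "n_compartments": self.n_compartments,
            "n_subsystems": self.n_subsystems,
        }


def model_stats(model: Model) -> ModelStats:
    """Entity counts of a model; subsystems counted as distinct
    non-empty labels."""
    return ModelStats(
        n_genes=len(model.genes),
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_compartments=len(model.compartments),
        n_subsystems=len(model.subsystems()),
    )
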