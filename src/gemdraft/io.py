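"""Model I/O: SBML (Level 3, fbc gene products) and a COBRA-style JSON dialect.

SBML transport is delegated to cobrapy/libsbml; this module converts
between cobrapy's containers and :class:`gemdraft.model.Model`.  Two GPR
encodings are tolerated on read: the fbc ``geneProductAssociation``
(modern) and a ``GENE_ASSOCIATION`` key in the reaction notes (older
HMR-derived models, the lineage of common human-tissue templates).
Subsystem labels are read from SBML groups when present, otherwise from
a ``SUBSYSTEM`` notes key; writing emits the notes key.

The JSON dialect keys every entity class by id and stores stoichiometry
as metabolite-id -> coefficient maps, so toy models are hand-writable:

.. code-block:: json

    {"id": "toy",
     "compartments": {"c": "cytosol"},
     "genes": {"g1": {}},
     "metabolites": {"m1": {"compartment": "c"}},
     "reactions": {"R1": {"stoichiometry": {"m1": -1},
                          "gpr": "g1", "subsystem": "Glycolysis"}}}
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import cobra

from .gpr import GprExpression, parse_gpr, serialize_gpr
from .model import (
    DEFAULT_LOWER_BOUND,
    DEFAULT_UPPER_BOUND,
    Gene,
    Metabolite,
    Model,
    ModelIntegrityError,
    Reaction,
)

__all__ = ["read_model", "write_model"]

# cobrapy logs an error about missing objectives on every read of a
# reconstruction-stage model; drafts have no biomass objective yet, so
# that message is noise here
logging.getLogger("cobra.io.sbml").setLevel(logging.CRITICAL)

_NOTES_GPR_KEYS = ("GENE_ASSOCIATION", "GENE ASSOCIATION")
_NOTES_SUBSYSTEM_KEYS = ("SUBSYSTEM", "subsystem")


def _infer_format(path: str | Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("sbml", "json"):
            raise ValueError(f"unknown model format {fmt!r} (expected 'sbml' or 'json')")
        return fmt
    suffix = Path(path).suffix.lower()
    if suffix in (".xml", ".sbml"):
        return "sbml"
    if suffix == ".json":
        return "json"
    raise ValueError(
        f"cannot infer model format from {path!r}; pass format='sbml' or 'json'"
    )


# ---------------------------------------------------------------------
# reading


def read_model(path: str | Path, format: str | None = None) -> Model:
    """Read a model file, enforce referential integrity, return a Model.

    ``format`` may be ``"sbml"`` or ``"json"``; if omitted it is
    inferred from the file extension (.xml/.sbml vs .json).
    """
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        model = _from_cobra(cobra.io.read_sbml_model(str(path)))
    else:
        with open(path) as fh:
            model = _model_from_dict(json.load(fh))
    model.provenance.setdefault("source_file", str(path))
    model.validate()
    return model


def _from_cobra(cm: cobra.Model) -> Model:
    model = Model(id=cm.id or "model")
    model.compartments = {cid: cname or cid for cid, cname in cm.compartments.items()}
    # subsystem labels from SBML groups, if any
    group_of: dict[str, str] = {}
    for group in getattr(cm, "groups", []):
        for member in group.members:
            if isinstance(member, cobra.Reaction):
                group_of[member.id] = group.name or group.id
    for cg in cm.genes:
        model.add_gene(Gene(id=cg.id, name=cg.name or None))
    for cmet in cm.metabolites:
        if cmet.compartment and cmet.compartment not in model.compartments:
            model.compartments[cmet.compartment] = cmet.compartment
        model.add_metabolite(
            Metabolite(
                id=cmet.id,
                compartment=cmet.compartment or "",
                name=cmet.name or None,
                formula=cmet.formula or None,
            )
        )
    for crxn in cm.reactions:
        rule = crxn.gene_reaction_rule
        if not rule:
            for key in _NOTES_GPR_KEYS:  # legacy notes-field encoding
                if crxn.notes.get(key):
                    rule = str(crxn.notes[key])
                    break
        subsystem = group_of.get(crxn.id) or crxn.subsystem or ""
        if not subsystem:
            for key in _NOTES_SUBSYSTEM_KEYS:
                if crxn.notes.get(key):
                    subsystem = str(crxn.notes[key])
                    break
        gpr = parse_gpr(rule)
        for gene_id in gpr.genes():  # genes only present in notes rules
            if gene_id not in model.genes:
                model.add_gene(Gene(id=gene_id))
        model.add_reaction(
            Reaction(
                id=crxn.id,
                stoichiometry={m.id: coef for m, coef in crxn.metabolites.items()},
                name=crxn.name or None,
                lower_bound=float(crxn.lower_bound),
                upper_bound=float(crxn.upper_bound),
                subsystem=subsystem,
                gpr=gpr,
            )
        )
    return model


def _model_from_dict(data: dict) -> Model:
    model = Model(id=data.get("id", "model"))
    model.compartments = dict(data.get("compartments", {}))
    for gid, g in data.get("genes", {}).items():
        model.add_gene(Gene(id=gid, name=g.get("name"), flags=set(g.get("flags", []))))
    for mid, m in data.get("metabolites", {}).items():
        model.add_metabolite(
            Metabolite(
                id=mid,
                compartment=m.get("compartment", ""),
                name=m.get("name"),
                formula=m.get("formula"),
            )
        )
    for rid, r in data.get("reactions", {}).items():
        if "stoichiometry" in r:
            lb = float(r.get("lower_bound", DEFAULT_LOWER_BOUND))
            ub = float(r.get("upper_bound", DEFAULT_UPPER_BOUND))
            if "reversible" in r and "lower_bound" not in r:
                lb = DEFAULT_LOWER_BOUND if r["reversible"] else 0.0
            gpr = parse_gpr(r.get("gpr", ""))
            for gene_id in gpr.genes():
                if gene_id not in model.genes:
                    model.add_gene(Gene(id=gene_id))
            model.add_reaction(
                Reaction(
                    id=rid,
                    stoichiometry={k: float(v) for k, v in r["stoichiometry"].items()},
                    name=r.get("name"),
                    lower_bound=lb,
                    upper_bound=ub,
                    subsystem=r.get("subsystem", ""),
                    gpr=gpr,
                )
            )
        else:
            raise ModelIntegrityError(f"reaction {rid!r} lacks a stoichiometry map")
    model.provenance = dict(data.get("provenance", {}))
    return model


# ---------------------------------------------------------------------
# writing


def write_model(model: Model, path: str | Path, format: str | None = None) -> None:
    """Write a model as SBML L3+fbc or as the JSON dialect.

    Round trips preserve ids, stoichiometry, bounds, subsystem labels
    and canonical GPR strings.
    """
    fmt = _infer_format(path, format)
    if fmt == "sbml":
        cobra.io.write_sbml_model(_to_cobra(model), str(path))
    else:
        with open(path, "w") as fh:
            json.dump(_model_to_dict(model), fh, indent=1, sort_keys=True)
            fh.write("\n")


def _to_cobra(model: Model) -> cobra.Model:
    cm = cobra.Model(model.id)
    cmets = {}
    for met in model.metabolites.values():
        cmet = cobra.Metabolite(
            met.id,
            name=met.name or "",
            compartment=met.compartment,
            formula=met.formula or None,
        )
        cmets[met.id] = cmet
    cm.add_metabolites(list(cmets.values()))
    crxns = []
    for rxn in sorted(model.reactions.values(), key=lambda r: r.id):
        crxn = cobra.Reaction(
            rxn.id,
            name=rxn.name or "",
            lower_bound=rxn.lower_bound,
            upper_bound=rxn.upper_bound,
        )
        crxns.append((crxn, rxn))
    cm.add_reactions([c for c, _ in crxns])
    for crxn, rxn in crxns:
        crxn.add_metabolites({cmets[mid]: coef for mid, coef in rxn.stoichiometry.items()})
        crxn.gene_reaction_rule = serialize_gpr(rxn.gpr)
        if rxn.subsystem:
            crxn.subsystem = rxn.subsystem
            crxn.notes["SUBSYSTEM"] = rxn.subsystem
    # compartment names (cobra collects ids from metabolites)
    cm.compartments = dict(model.compartments)
    for gene in model.genes.values():
        if gene.id in cm.genes:
            cg = cm.genes.get_by_id(gene.id)
            if gene.name:
                cg.name = gene.name
    return cm


def _model_to_dict(model: Model) -> dict:
    return {
        "id": model.id,
        "compartments": dict(model.compartments),
        "genes": {
            g.id: {
                **({"name": g.name} if g.name else {}),
                **({"flags": sorted(g.flags)} if g.flags else {}),
            }
            for g in model.genes.values()
        },
        "metabolites": {
            m.id: {
                "compartment": m.compartment,
                **({"name": m.name} if m.name else {}),
                **({"formula": m.formula} if m.formula else {}),
            }
            for m in model.metabolites.values()
        },
        "reactions": {
            r.id: {
                "stoichiometry": dict(r.stoichiometry),
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                **({"name": r.name} if r.name else {}),
                **({"subsystem": r.subsystem} if r.subsystem else {}),
                **({"gpr": serialize_gpr(r.gpr)} if not r.gpr.is_empty else {}),
            }
            for r in model.reactions.values()
        },
        "provenance": model.provenance,
    }
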