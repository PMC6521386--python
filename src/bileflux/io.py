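"""Readers and writers: genotype tables, abundance tables, subsystem export.

Genotype TSV layout: one row per strain with columns ``strain_id``, optional
taxonomy columns (``phylum``, ``genus``, ``species``), and one 0/1 column
per enzyme class (``BSH``, ``HSDH_3A``, ``HSDH_3B``, ``HSDH_7A``,
``HSDH_7B``, ``HSDH_12A``, ``BAI``, ``CHOL_RED``).  A gene-style layout is
also accepted, with enzyme columns named after the genes/activities
(``bsh``, ``3a-HSDH``, ``3b-HSDH``, ``7a-HSDH``, ``7b-HSDH``, ``12a-HSDH``,
``bai``, ``chol_red``); the mapping is in :data:`GENE_COLUMN_ALIASES`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .builder import MetabolicModel
from .pathway import ENZYME_CLASSES, ReactionTemplate, StrainGenotype

__all__ = [
    "GENE_COLUMN_ALIASES",
    "load_genotypes",
    "write_genotypes",
    "load_abundances",
    "subsystem_to_json",
    "model_to_json",
    "model_to_sbml",
]

#: accepted gene-style column spellings per enzyme class (case-insensitive)
GENE_COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "BSH": ("bsh", "bile salt hydrolase"),
    "HSDH_3A": ("3a-hsdh", "3a_hsdh", "3alpha-hsdh"),
    "HSDH_3B": ("3b-hsdh", "3b_hsdh", "3beta-hsdh"),
    "HSDH_7A": ("7a-hsdh", "7a_hsdh", "7alpha-hsdh"),
    "HSDH_7B": ("7b-hsdh", "7b_hsdh", "7beta-hsdh"),
    "HSDH_12A": ("12a-hsdh", "12a_hsdh", "12alpha-hsdh"),
    "BAI": ("bai", "bai cluster", "baiabcdefghi"),
    "CHOL_RED": ("chol_red", "cholesterol reductase", "coprostanol"),
}

_TAX_COLUMNS = ("phylum", "genus", "species")


def _resolve_enzyme_columns(columns: Iterable[str]) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved = {}
    for enz in ENZYME_CLASSES:
        if enz.lower() in lower:
            resolved[enz] = lower[enz.lower()]
            continue
        for alias in GENE_COLUMN_ALIASES[enz]:
            if alias in lower:
                resolved[enz] = lower[alias]
                break
    return resolved


def load_genotypes(path) -> list[StrainGenotype]:
    """Read a genotype TSV (canonical or gene-style column layout)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    id_col = cols.get("strain_id") or cols.get("strain") or df.columns[0]
    enz_cols = _resolve_enzyme_columns(df.columns)
    if not enz_cols:
        raise ValueError(f"no enzyme columns recognized in {path}")
    out = []
    for _, row in df.iterrows():
        enzymes = {enz for enz, col in enz_cols.items()
                   if str(row[col]).strip() in ("1", "1.0", "True", "true")}
        tax = tuple(str(row[cols[t]]) for t in _TAX_COLUMNS if t in cols)
        out.append(StrainGenotype(str(row[id_col]), enzymes, tax))
    ids = [g.strain_id for g in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in genotype table")
    return out


def write_genotypes(genotypes: Iterable[StrainGenotype], path) -> None:
    rows = []
    for g in genotypes:
        tax = list(g.taxonomy) + [""] * (3 - len(g.taxonomy))
        row = {"strain_id": g.strain_id, "phylum": tax[0], "genus": tax[1],
               "species": tax[2]}
        row.update({enz: int(g.has(enz)) for enz in ENZYME_CLASSES})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_abundances(path) -> tuple[pd.DataFrame, pd.Series | None]:
    """Read a sample x strain table; an optional ``group`` column is split
    off and returned separately."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    groups = None
    if "group" in df.columns:
        groups = df.pop("group").astype(str)
    return df.astype(float), groups


def subsystem_to_json(templates: Iterable[ReactionTemplate], path=None) -> str:
    payload = [
        {"id": t.id, "stoichiometry": dict(t.stoichiometry),
         "reversible": t.reversible, "enzyme": t.enzyme,
         "compartment_role": t.compartment_role, "vmh_id": t.vmh_id}
        for t in templates
    ]
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_to_json(model: MetabolicModel, path=None) -> str:
    payload = {
        "id": model.id, "model_type": model.model_type, "units": model.units,
        "objective": model.objective_id, "strains": model.strains,
        "abundances": model.abundances,
        "coupling": {"c": model.coupling_c, "u": model.coupling_u,
                     "n_constraints": 2 * len(model.coupling)},
        "reactions": [
            {"id": r.id, "stoichiometry": r.stoich, "lb": r.lb, "ub": r.ub,
             "enzyme": r.enzyme, "subsystem": r.subsystem, "strain": r.strain}
            for r in model.reactions
        ],
    }
    text = json.dumps(payload, indent=1)
    if path is not None:
        Path(path).write_text(text)
    return text


def model_to_sbml(model: MetabolicModel, path) -> None:
    """Export to SBML Level 3 + FBC via cobrapy (optional dependency)."""
    import cobra
    from cobra.io import write_sbml_model

    cm = cobra.Model(model.id.replace("|", "_"))
    mets = {}

    def met(mid: str) -> "cobra.Metabolite":
        if mid not in mets:
            comp = "c"
            if "[" in mid:
                comp = mid[mid.rindex("[") + 1: -1]
            m = cobra.Metabolite(
                mid.replace("[", "_").replace("]", "").replace(":", "__"),
                compartment=comp)
            mets[mid] = m
        return mets[mid]

    for r in model.reactions:
        rxn = cobra.Reaction(r.id.replace("[", "_").replace("]", "").replace(":", "__").replace("|", "_"))
        rxn.lower_bound, rxn.upper_bound = r.lb, r.ub
        cm.add_reactions([rxn])
        rxn.add_metabolites({met(m): c for m, c in r.stoich.items()})
    if model.objective_id is not None and model.has_reaction(model.objective_id):
        oid = (model.objective_id.replace("[", "_").replace("]", "")
               .replace(":", "__").replace("|", "_"))
        cm.objective = oid
    write_sbml_model(cm, str(path))
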