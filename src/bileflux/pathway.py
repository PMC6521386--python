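"""Bile acid species registry, enzyme-specific reaction templates, and a
graph-reachability oracle for producible bile acids.

The gut microbiome deconjugates the four host-derived conjugated primary bile
acids (tauro-/glyco-cholate and tauro-/glyco-chenodeoxycholate) and transforms
the liberated cholate (CA) and chenodeoxycholate (CDCA) into 13 secondary bile
acids via position- and stereo-specific hydroxysteroid dehydrogenases (HSDHs)
and the multi-step bile-acid-inducible (bai) 7-dehydroxylation pathway.  This
module defines the 19-species registry, instantiates a mass- and
charge-balanced cytosolic reaction subsystem for any enzyme genotype, and
provides an LP-free reachability oracle used as an independent cross-check of
flux-balance results.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "BileAcid",
    "ENZYME_CLASSES",
    "StrainGenotype",
    "ReactionTemplate",
    "canonical_registry",
    "registry_by_id",
    "CONJUGATED_IDS",
    "UNCONJUGATED_IDS",
    "SECONDARY_IDS",
    "PRODUCING_ENZYME",
    "build_subsystem",
    "check_balance",
    "BalanceReport",
    "pathway_edges",
    "producible_oracle",
]

# ---------------------------------------------------------------------------
# enzyme classes

#: The eight functional enzyme classes of the bile acid subsystem.  BAI lumps
#: the full baiABCDEFGHI cluster plus the baiN/baiO terminal reductases and the
#: baiP exporter into one unit; CHOL_RED is the optional NADH-dependent
#: cholesterol -> coprostanol activity.
ENZYME_CLASSES = (
    "BSH",
    "HSDH_3A",
    "HSDH_3B",
    "HSDH_7A",
    "HSDH_7B",
    "HSDH_12A",
    "BAI",
    "CHOL_RED",
)

_ENZYME_SET = frozenset(ENZYME_CLASSES)


@dataclass(frozen=True)
class BileAcid:
    """One bile acid species with VMH-style id, elemental formula and charge."""

    id: str
    name: str
    klass: str  # primary_conjugated | primary_unconjugated | secondary
    formula: str
    charge: int


@dataclass(frozen=True)
class StrainGenotype:
    """A strain and the set of bile acid enzyme classes found in its genome."""

    strain_id: str
    enzymes: frozenset[str]
    taxonomy: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "enzymes", frozenset(self.enzymes))
        unknown = self.enzymes - _ENZYME_SET
        if unknown:
            raise ValueError(
                f"unknown enzyme tag(s) {sorted(unknown)} for strain "
                f"{self.strain_id!r}; valid tags: {sorted(_ENZYME_SET)}"
            )

    def has(self, tag: str) -> bool:
        return tag in self.enzymes


@dataclass(frozen=True)
class ReactionTemplate:
    """A single reaction of the subsystem.

    ``stoichiometry`` maps metabolite id (compartment-free) to a signed
    coefficient; negative = consumed.  ``compartment_role`` distinguishes
    cytosolic conversions from transport and boundary (exchange) templates.
    ``vmh_id`` cross-references the published reaction identifier where one
    exists.
    """

    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool
    enzyme: str  # an enzyme class tag or "gapfill" / "transport" / "exchange"
    compartment_role: str  # cytosol | transport | exchange
    vmh_id: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))
        if self.compartment_role == "exchange" and len(self.stoichiometry) != 1:
            raise ValueError(f"exchange template {self.id} must touch one metabolite")


# ---------------------------------------------------------------------------
# canonical registry (19 species)

_REGISTRY: tuple[BileAcid, ...] = (
    # 4 conjugated primary bile acids
    BileAcid("tchola", "Taurocholate (Tauro-CA)", "primary_conjugated", "C26H44NO7S", -1),
    BileAcid("gchola", "Glycocholate (Glyco-CA)", "primary_conjugated", "C26H42NO6", -1),
    BileAcid("tdchola", "Taurochenodeoxycholate (Tauro-CDCA)", "primary_conjugated", "C26H44NO6S", -1),
    BileAcid("dgchol", "Glycochenodeoxycholate (Glyco-CDCA)", "primary_conjugated", "C26H42NO5", -1),
    # 2 unconjugated primary bile acids
    BileAcid("cholate", "Cholate (CA)", "primary_unconjugated", "C24H39O5", -1),
    BileAcid("C02528", "Chenodeoxycholate (CDCA)", "primary_unconjugated", "C24H39O4", -1),
    # 13 secondary bile acids
    BileAcid("12dhchol", "12-dehydrocholate (12-dehydro-CA)", "secondary", "C24H37O5", -1),
    BileAcid("7ocholate", "7-ketodeoxycholate (7-keto-CA)", "secondary", "C24H37O5", -1),
    BileAcid("7dhcdchol", "7-dehydrochenodeoxycholate (7-dehydro-CDCA)", "secondary", "C24H37O4", -1),
    BileAcid("3dhchol", "3-dehydrocholate (3-dehydro-CA)", "secondary", "C24H37O5", -1),
    BileAcid("3dhcdchol", "3-dehydrochenodeoxycholate (3-dehydro-CDCA)", "secondary", "C24H37O4", -1),
    BileAcid("isochol", "Isocholate (Iso-CA)", "secondary", "C24H39O5", -1),
    BileAcid("icdchol", "Isochenodeoxycholate (Iso-CDCA)", "secondary", "C24H39O4", -1),
    BileAcid("HC02191", "Lithocholate (LCA)", "secondary", "C24H39O3", -1),
    BileAcid("dchac", "Deoxycholate (DCA)", "secondary", "C24H39O4", -1),
    BileAcid("alchac", "Allolithocholate (allo-LCA)", "secondary", "C24H39O3", -1),
    BileAcid("adchac", "Allodeoxycholate (allo-DCA)", "secondary", "C24H39O4", -1),
    BileAcid("uchol", "Ursocholate (UCA)", "secondary", "C24H39O5", -1),
    BileAcid("HC02194", "Ursodeoxycholate (UDCA)", "secondary", "C24H39O4", -1),
)

CONJUGATED_IDS: tuple[str, ...] = tuple(
    b.id for b in _REGISTRY if b.klass == "primary_conjugated"
)
UNCONJUGATED_IDS: tuple[str, ...] = tuple(
    b.id for b in _REGISTRY if b.klass != "primary_conjugated"
)
SECONDARY_IDS: tuple[str, ...] = tuple(b.id for b in _REGISTRY if b.klass == "secondary")

#: Enzyme class directly synthesizing each unconjugated bile acid (the
#: "producing reaction" used for reaction-abundance correlations).
PRODUCING_ENZYME: dict[str, str] = {
    "cholate": "BSH",
    "C02528": "BSH",
    "7ocholate": "HSDH_7A",
    "7dhcdchol": "HSDH_7A",
    "uchol": "HSDH_7B",
    "HC02194": "HSDH_7B",
    "12dhchol": "HSDH_12A",
    "3dhchol": "HSDH_3A",
    "3dhcdchol": "HSDH_3A",
    "isochol": "HSDH_3B",
    "icdchol": "HSDH_3B",
    "dchac": "BAI",
    "adchac": "BAI",
    "HC02191": "BAI",
    "alchac": "BAI",
}


def canonical_registry() -> list[BileAcid]:
    """Return the canonical 19-species bile acid registry.

    4 conjugated primary, 2 unconjugated primary (CA, CDCA) and 13 secondary
    species, with VMH-style ids, formulas (anionic form) and charges.
    """
    return list(_REGISTRY)


def registry_by_id() -> dict[str, BileAcid]:
    return {b.id: b for b in _REGISTRY}


# cofactors / co-substrates used by the subsystem (anionic/neutral forms)
AUX_FORMULAS: dict[str, tuple[str, int]] = {
    "gly": ("C2H5NO2", 0),
    "taur": ("C2H7NO3S", 0),
    "h2o": ("H2O", 0),
    "h": ("H", 1),
    "nad": ("C21H26N7O14P2", -1),
    "nadh": ("C21H27N7O14P2", -2),
    "nadp": ("C21H25N7O17P3", -3),
    "nadph": ("C21H26N7O17P3", -4),
    "chsterol": ("C27H46O", 0),
    "copro": ("C27H48O", 0),
    # lumped bai-pathway intermediates: 3-oxo-4,6-dien intermediates before and
    # after 7-dehydration (separate ids per substrate branch)
    "baint1ca": ("C24H35O5", -1),
    "baint2ca": ("C24H33O4", -1),
    "baint1cdca": ("C24H35O4", -1),
    "baint1udca": ("C24H35O4", -1),
    "baint2cdca": ("C24H33O3", -1),
}


def formula_table() -> dict[str, tuple[str, int]]:
    """Formulas and charges for every metabolite the subsystem can touch."""
    table = {b.id: (b.formula, b.charge) for b in _REGISTRY}
    table.update(AUX_FORMULAS)
    return table


# ---------------------------------------------------------------------------
# reaction templates per enzyme class

def _cyt(rid, stoich, reversible, enzyme, vmh=None):
    return ReactionTemplate(rid, stoich, reversible, enzyme, "cytosol", vmh)


def _enzyme_templates(tag: str) -> list[ReactionTemplate]:
    if tag == "BSH":
        return [
            _cyt("BSH_gchola", {"gchola": -1, "h2o": -1, "cholate": 1, "gly": 1}, False, "BSH", "GCHOLBHSe"),
            _cyt("BSH_tchola", {"tchola": -1, "h2o": -1, "cholate": 1, "taur": 1}, False, "BSH", "TCHOLBHSe"),
            _cyt("BSH_dgchol", {"dgchol": -1, "h2o": -1, "C02528": 1, "gly": 1}, False, "BSH", "GCDCHOLBHSe"),
            _cyt("BSH_tdchola", {"tdchola": -1, "h2o": -1, "C02528": 1, "taur": 1}, False, "BSH", "TCDCHOLBHSe"),
        ]
    if tag == "HSDH_7A":
        # NAD-linked 7alpha oxidations, reversible
        return [
            _cyt("HSDH7A_ca", {"cholate": -1, "nad": -1, "7ocholate": 1, "nadh": 1, "h": 1}, True, "HSDH_7A", "7AHSDHe"),
            _cyt("HSDH7A_cdca", {"C02528": -1, "nad": -1, "7dhcdchol": 1, "nadh": 1, "h": 1}, True, "HSDH_7A", "7AHSDH2e"),
        ]
    if tag == "HSDH_7B":
        # NADP-linked 7beta reductions, reversible
        return [
            _cyt("HSDH7B_uca", {"7ocholate": -1, "nadph": -1, "h": -1, "uchol": 1, "nadp": 1}, True, "HSDH_7B", "UCA7bHSDHe"),
            _cyt("HSDH7B_udca", {"7dhcdchol": -1, "nadph": -1, "h": -1, "HC02194": 1, "nadp": 1}, True, "HSDH_7B", "UDCA7bHSDHe"),
        ]
    if tag == "HSDH_12A":
        return [
            _cyt("HSDH12A_ca", {"cholate": -1, "nad": -1, "12dhchol": 1, "nadh": 1, "h": 1}, True, "HSDH_12A", "12AHSDHe"),
        ]
    if tag == "HSDH_3A":
        return [
            _cyt("HSDH3A_ca", {"cholate": -1, "nad": -1, "3dhchol": 1, "nadh": 1, "h": 1}, True, "HSDH_3A", "CA3aHSDHe"),
            _cyt("HSDH3A_cdca", {"C02528": -1, "nad": -1, "3dhcdchol": 1, "nadh": 1, "h": 1}, True, "HSDH_3A", "CDCA3aHSDHe"),
        ]
    if tag == "HSDH_3B":
        return [
            _cyt("HSDH3B_ica", {"3dhchol": -1, "nadph": -1, "h": -1, "isochol": 1, "nadp": 1}, True, "HSDH_3B", "ICA3bHSDHe"),
            _cyt("HSDH3B_icdca", {"3dhcdchol": -1, "nadph": -1, "h": -1, "icdchol": 1, "nadp": 1}, True, "HSDH_3B", "ICDCA3bHSDHe"),
        ]
    if tag == "BAI":
        t: list[ReactionTemplate] = []
        # CoA-activation + NAD-linked oxidations (lumped), then 7-dehydration,
        # then baiN/baiO NADH-dependent delta6/delta4 + 3-oxo reductions.
        t.append(_cyt("BAI_ox_ca", {"cholate": -1, "nad": -2, "baint1ca": 1, "nadh": 2, "h": 2}, False, "BAI"))
        t.append(_cyt("BAI_dhx_ca", {"baint1ca": -1, "baint2ca": 1, "h2o": 1}, False, "BAI"))
        t.append(_cyt("BAI_red_dca", {"baint2ca": -1, "nadh": -3, "h": -3, "dchac": 1, "nad": 3}, False, "BAI"))
        # allo (5alpha) side-branch: same cofactor stoichiometry, epimeric product
        t.append(_cyt("BAI_red_adca", {"baint2ca": -1, "nadh": -3, "h": -3, "adchac": 1, "nad": 3}, False, "gapfill"))
        t.append(_cyt("BAI_ox_cdca", {"C02528": -1, "nad": -2, "baint1cdca": 1, "nadh": 2, "h": 2}, False, "BAI"))
        t.append(_cyt("BAI_ox_udca", {"HC02194": -1, "nad": -2, "baint1udca": 1, "nadh": 2, "h": 2}, False, "BAI"))
        t.append(_cyt("BAI_dhx_cdca", {"baint1cdca": -1, "baint2cdca": 1, "h2o": 1}, False, "BAI"))
        t.append(_cyt("BAI_dhx_udca", {"baint1udca": -1, "baint2cdca": 1, "h2o": 1}, False, "BAI"))
        t.append(_cyt("BAI_red_lca", {"baint2cdca": -1, "nadh": -3, "h": -3, "HC02191": 1, "nad": 3}, False, "BAI"))
        t.append(_cyt("BAI_red_alca", {"baint2cdca": -1, "nadh": -3, "h": -3, "alchac": 1, "nad": 3}, False, "gapfill"))
        return t
    if tag == "CHOL_RED":
        return [
            _cyt("CHOLRED_c", {"chsterol": -1, "nadh": -1, "h": -1, "copro": 1, "nad": 1}, False, "CHOL_RED"),
            # extracellular activity modeled with the strain-internal NADH pool
            ReactionTemplate(
                "CHOLRED_e",
                {"chsterol[e]": -1, "nadh": -1, "h": -1, "copro[e]": 1, "nad": 1},
                False, "CHOL_RED", "cytosol",
            ),
        ]
    raise ValueError(f"unknown enzyme tag {tag!r}; valid tags: {sorted(_ENZYME_SET)}")


def build_subsystem(genotype: StrainGenotype) -> list[ReactionTemplate]:
    """Instantiate the bile acid reaction subsystem for one genotype.

    Returns the cytosolic enzyme reactions for every enzyme class the strain
    carries, plus reversible transporters for every bile acid the subsystem
    consumes or produces and exchange reactions for every extracellular
    species (conjugated substrates, CA, CDCA and the secondary products).
    An empty genotype yields an empty subsystem.
    """
    templates: list[ReactionTemplate] = []
    for tag in sorted(genotype.enzymes):
        templates.extend(_enzyme_templates(tag))
    if not templates:
        return []

    # collect bile acid species touched by the cytosolic reactions
    bas = registry_by_id()
    touched: set[str] = set()
    for t in templates:
        for met in t.stoichiometry:
            base = met.removesuffix("[e]")
            if base in bas:
                touched.add(base)
    # gapfill LCA export exists because the baiP transporter was only inferred
    need_transport = sorted(touched)
    for met in need_transport:
        enz = "gapfill" if met in ("HC02191", "alchac", "adchac") else "transport"
        templates.append(
            ReactionTemplate(f"T_{met}", {f"{met}[e]": -1, met: 1}, True, enz, "transport")
        )
        templates.append(
            ReactionTemplate(f"EX_{met}", {f"{met}[e]": -1}, True, "exchange", "exchange")
        )
    if "CHOL_RED" in genotype.enzymes:
        # predicted cholesterol uptake transporter (gapfill) + exchanges
        templates.append(ReactionTemplate("T_chsterol", {"chsterol[e]": -1, "chsterol": 1}, True, "gapfill", "transport"))
        templates.append(ReactionTemplate("T_copro", {"copro[e]": -1, "copro": 1}, True, "gapfill", "transport"))
        templates.append(ReactionTemplate("EX_chsterol", {"chsterol[e]": -1}, True, "exchange", "exchange"))
        templates.append(ReactionTemplate("EX_copro", {"copro[e]": -1}, True, "exchange", "exchange"))
    if "BSH" in genotype.enzymes:
        for met in ("gly", "taur"):
            templates.append(ReactionTemplate(f"T_{met}", {f"{met}[e]": -1, met: 1}, True, "transport", "transport"))
            templates.append(ReactionTemplate(f"EX_{met}", {f"{met}[e]": -1}, True, "exchange", "exchange"))
    return templates


# ---------------------------------------------------------------------------
# mass / charge balance checking

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    out: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_RE.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        out[m.group(1)] = out.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return out


@dataclass
class BalanceReport:
    """Per-element and charge imbalance of one reaction template."""

    reaction_id: str
    status: str  # balanced | imbalanced | boundary
    element_imbalance: dict[str, float] = field(default_factory=dict)
    charge_imbalance: float = 0.0
    missing: list[str] = field(default_factory=list)

    @property
    def balanced(self) -> bool:
        return self.status in ("balanced", "boundary")


def check_balance(
    template: ReactionTemplate,
    formulas: Mapping[str, tuple[str, int]] | None = None,
) -> BalanceReport:
    """Check elemental and charge balance of a reaction template.

    Exchange templates are boundary reactions and reported as such; transport
    templates move one species across compartments and are checked for charge
    only across identical base ids.  Metabolites missing from ``formulas`` are
    flagged, never silently skipped.
    """
    if formulas is None:
        formulas = formula_table()
    if template.compartment_role == "exchange":
        return BalanceReport(template.id, "boundary")
    elem: dict[str, float] = {}
    charge = 0.0
    missing: list[str] = []
    for met, coeff in template.stoichiometry.items():
        base = met.removesuffix("[e]")
        if base not in formulas:
            missing.append(met)
            continue
        f, q = formulas[base]
        for el, n in parse_formula(f).items():
            elem[el] = elem.get(el, 0.0) + coeff * n
        charge += coeff * q
    elem = {el: v for el, v in elem.items() if abs(v) > 1e-9}
    if missing:
        return BalanceReport(template.id, "imbalanced", elem, charge, missing)
    status = "balanced" if not elem and abs(charge) < 1e-9 else "imbalanced"
    return BalanceReport(template.id, status, elem, charge)


# ---------------------------------------------------------------------------
# reachability oracle

# (enzyme, substrate, product, reversible) pathway edges.  Mirrors the
# reaction templates above at the level of bile acid interconversion.
_EDGES: tuple[tuple[str, str, str, bool], ...] = (
    ("BSH", "gchola", "cholate", False),
    ("BSH", "tchola", "cholate", False),
    ("BSH", "dgchol", "C02528", False),
    ("BSH", "tdchola", "C02528", False),
    ("HSDH_7A", "cholate", "7ocholate", True),
    ("HSDH_7A", "C02528", "7dhcdchol", True),
    ("HSDH_7B", "7ocholate", "uchol", True),
    ("HSDH_7B", "7dhcdchol", "HC02194", True),
    ("HSDH_12A", "cholate", "12dhchol", True),
    ("HSDH_3A", "cholate", "3dhchol", True),
    ("HSDH_3A", "C02528", "3dhcdchol", True),
    ("HSDH_3B", "3dhchol", "isochol", True),
    ("HSDH_3B", "3dhcdchol", "icdchol", True),
    ("BAI", "cholate", "dchac", False),
    ("BAI", "cholate", "adchac", False),
    ("BAI", "C02528", "HC02191", False),
    ("BAI", "C02528", "alchac", False),
    ("BAI", "HC02194", "HC02191", False),
    ("BAI", "HC02194", "alchac", False),
)


def pathway_edges() -> list[tuple[str, str, str, bool]]:
    """The enzyme-labeled substrate->product edges of the pathway graph."""
    return list(_EDGES)


def producible_oracle(
    genotypes: StrainGenotype | Iterable[StrainGenotype],
    supplied: Iterable[str],
) -> set[str]:
    """Bile acids reachable from ``supplied`` given the pooled enzyme set.

    Community sharing via the lumen: an edge is usable when its enzyme is
    present in *any* genotype of the set.  Returns only newly reachable
    species (the supplied set itself is excluded from the result).
    """
    if isinstance(genotypes, StrainGenotype):
        genotypes = [genotypes]
    enzymes: set[str] = set()
    for g in genotypes:
        enzymes |= g.enzymes
    supplied = set(supplied)
    if not supplied:
        raise ValueError("supplied set must be non-empty")
    edges: list[tuple[str, str]] = []
    for enz, sub, prod, rev in _EDGES:
        if enz in enzymes:
            edges.append((sub, prod))
            if rev:
                edges.append((prod, sub))
    reach = set(supplied)
    changed = True
    while changed:
        changed = False
        for sub, prod in edges:
            if sub in reach and prod not in reach:
                reach.add(prod)
                changed = True
    return reach - supplied
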