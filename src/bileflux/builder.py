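"""Construction of growth-capable strain models, pairwise joins, and
abundance-parameterized community models with coupling constraints.

A single-strain model is a small "chassis" network (one carbon source, lumped
biomass, explicit NAD(P)/NAD(P)H regeneration) unioned with the bile acid
subsystem instantiated for the strain's genotype.  Pairwise and personalized
community models embed the member models behind per-strain compartments that
meet in a shared lumen ``[u]``, flanked by diet ``[d]`` and fecal ``[fe]``
compartments.  Community models additionally carry coupling constraints
(|v_j| <= c * v_biomass,k + u for every non-biomass reaction j of strain k)
and a community biomass reaction whose stoichiometric coefficients are the
strain relative abundances, with the community biomass export bounded to
[0.4, 1] per day (fecal emptying between once every three days and once a
day).

Units are metadata: single/pair models are labeled mmol/gDW/h, community
models mmol/person/day; no numeric conversion is applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .pathway import (
    CONJUGATED_IDS,
    ReactionTemplate,
    StrainGenotype,
    build_subsystem,
    canonical_registry,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Reaction",
    "MetabolicModel",
    "ChassisSpec",
    "DietSpec",
    "ModelBuildError",
    "build_strain_model",
    "join_pairwise",
    "enumerate_pairs",
    "count_pairs",
    "build_community",
    "apply_diet",
    "find_dead_ends",
]

BIG = 1000.0


class ModelBuildError(ValueError):
    pass


@dataclass
class Reaction:
    id: str
    stoich: dict[str, float]
    lb: float = -BIG
    ub: float = BIG
    enzyme: str | None = None
    subsystem: str = ""
    strain: str | None = None

    def copy(self) -> "Reaction":
        return Reaction(self.id, dict(self.stoich), self.lb, self.ub,
                        self.enzyme, self.subsystem, self.strain)


@dataclass
class MetabolicModel:
    """Stoichiometric model: reactions with bounds plus bookkeeping tags.

    The stoichiometric matrix is materialized on demand with rows/columns in
    sorted-id order, so assembly is deterministic for identical inputs.
    """

    id: str
    reactions: list[Reaction]
    objective_id: str | None = None
    model_type: str = "single"  # single | pair | community
    units: str = "mmol/gDW/h"
    strains: list[str] = field(default_factory=list)
    abundances: dict[str, float] | None = None
    #: (coupled reaction id, strain biomass reaction id) pairs
    coupling: list[tuple[str, str]] = field(default_factory=list)
    coupling_c: float = 400.0
    coupling_u: float = 0.01

    def __post_init__(self) -> None:
        seen = set()
        for r in self.reactions:
            if r.id in seen:
                raise ModelBuildError(f"duplicate reaction id {r.id!r}")
            seen.add(r.id)
            if r.lb > r.ub:
                raise ModelBuildError(f"reaction {r.id}: lb {r.lb} > ub {r.ub}")

    # -- lookups ---------------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def reaction(self, rid: str) -> Reaction:
        try:
            return self._index()[rid]
        except KeyError:
            raise KeyError(f"no reaction {rid!r} in model {self.id}") from None

    def has_reaction(self, rid: str) -> bool:
        return rid in self._index()

    def _index(self) -> dict[str, Reaction]:
        idx = getattr(self, "_ridx", None)
        if idx is None or len(idx) != len(self.reactions):
            idx = {r.id: r for r in self.reactions}
            self._ridx = idx
        return idx

    def metabolite_ids(self) -> list[str]:
        mets: set[str] = set()
        for r in self.reactions:
            mets.update(r.stoich)
        return sorted(mets)

    def invalidate(self) -> None:
        """Drop cached matrices after in-place modification."""
        for attr in ("_ridx", "_matrices"):
            if hasattr(self, attr):
                delattr(self, attr)

    # -- matrices --------------------------------------------------------
    def to_matrices(self):
        """Return (met_ids, rxn_ids, S (csr), lb, ub, A_couple, b_couple).

        ``A_couple``/``b_couple`` encode the one-sided coupling rows
        v_j - c*v_bio <= u and -v_j - c*v_bio <= u (empty for uncoupled
        models).
        """
        cached = getattr(self, "_matrices", None)
        if cached is not None:
            return cached
        from scipy import sparse

        met_ids = self.metabolite_ids()
        rxn_ids = sorted(r.id for r in self.reactions)
        mpos = {m: i for i, m in enumerate(met_ids)}
        rpos = {r: j for j, r in enumerate(rxn_ids)}
        rows, cols, vals = [], [], []
        lb = np.zeros(len(rxn_ids))
        ub = np.zeros(len(rxn_ids))
        for r in self.reactions:
            j = rpos[r.id]
            lb[j], ub[j] = r.lb, r.ub
            for m, coef in r.stoich.items():
                rows.append(mpos[m])
                cols.append(j)
                vals.append(coef)
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
        )
        if self.coupling:
            crows, ccols, cvals = [], [], []
            k = 0
            for rid, bio_id in self.coupling:
                j, jb = rpos[rid], rpos[bio_id]
                crows += [k, k, k + 1, k + 1]
                ccols += [j, jb, j, jb]
                cvals += [1.0, -self.coupling_c, -1.0, -self.coupling_c]
                k += 2
            A_couple = sparse.csr_matrix(
                (cvals, (crows, ccols)), shape=(k, len(rxn_ids))
            )
            b_couple = np.full(k, self.coupling_u)
        else:
            A_couple = sparse.csr_matrix((0, len(rxn_ids)))
            b_couple = np.zeros(0)
        self._matrices = (met_ids, rxn_ids, S, lb, ub, A_couple, b_couple)
        return self._matrices

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            self.id, [r.copy() for r in self.reactions], self.objective_id,
            self.model_type, self.units, list(self.strains),
            dict(self.abundances) if self.abundances else None,
            list(self.coupling), self.coupling_c, self.coupling_u,
        )


# ---------------------------------------------------------------------------
# chassis

@dataclass(frozen=True)
class ChassisSpec:
    """Minimal growth network shared by every strain.

    One carbon source (glucose) is catabolized to pyruvate with NADH
    generation, biomass is lumped into a single precursor-to-biomass step, and
    NAD(P)H pools are closed by pseudo-reactions (a lumped NADH oxidase and an
    NADPH regeneration step).  These pseudo-reactions are deliberately not
    elementally balanced — they stand in for the respiratory and anabolic
    machinery of a full reconstruction — and are tagged subsystem="chassis".
    """

    carbon_source: str = "glc_D"
    biomass_yield: float = 1.0  # biomass units per unit carbon source

    def reactions(self) -> list[Reaction]:
        g = self.carbon_source
        r = [
            Reaction(f"EX_{g}", {f"{g}[e]": -1}, 0, BIG, "exchange", "chassis"),
            Reaction(f"T_{g}", {f"{g}[e]": -1, f"{g}[c]": 1}, -BIG, BIG, "transport", "chassis"),
            Reaction("CATAB", {f"{g}[c]": -1, "nad[c]": -2, "pyr[c]": 2, "nadh[c]": 2, "h[c]": 2},
                     0, BIG, None, "chassis"),
            Reaction("T_pyr", {"pyr[e]": -1, "pyr[c]": 1}, -BIG, BIG, "transport", "chassis"),
            Reaction("EX_pyr", {"pyr[e]": -1}, 0, BIG, "exchange", "chassis"),
            Reaction("NADHOX", {"nadh[c]": -1, "h[c]": -1, "nad[c]": 1}, 0, BIG, None, "chassis"),
            Reaction("NADPHGEN", {"nadp[c]": -1, "h[c]": -1, "nadph[c]": 1}, -BIG, BIG, None, "chassis"),
            Reaction("BIOMASS", {f"{g}[c]": -1 / self.biomass_yield, "biomass[c]": 1},
                     0, BIG, None, "chassis"),
            Reaction("DM_biomass", {"biomass[c]": -1}, 0, BIG, None, "chassis"),
            Reaction("T_h2o", {"h2o[e]": -1, "h2o[c]": 1}, -BIG, BIG, "transport", "chassis"),
            Reaction("EX_h2o", {"h2o[e]": -1}, -BIG, BIG, "exchange", "chassis"),
            Reaction("T_h", {"h[e]": -1, "h[c]": 1}, -BIG, BIG, "transport", "chassis"),
            Reaction("EX_h", {"h[e]": -1}, -BIG, BIG, "exchange", "chassis"),
        ]
        return r


# ---------------------------------------------------------------------------
# diet

@dataclass
class DietSpec:
    """Exchange bounds defining the in-silico diet.

    ``entries`` maps exchange reaction base ids (e.g. ``EX_glc_D``,
    ``EX_tchola``) to (lower, upper) bounds.  Negative lower bound = allowed
    uptake.  Every exchange not named keeps lower bound 0 (no uptake).
    """

    entries: dict[str, tuple[float, float]]
    name: str = "diet"
    units: str = "mmol/person/day"

    @classmethod
    def default(cls) -> "DietSpec":
        """Synthetic average Western-style diet: chassis nutrients plus
        unlimited conjugated primary bile acids and a little cholesterol."""
        from importlib.resources import files

        path = files("bileflux.data").joinpath("average_synthetic_diet.json")
        return cls.from_json(path)

    @classmethod
    def from_json(cls, path) -> "DietSpec":
        payload = json.loads(Path(str(path)).read_text())
        entries = {k: (float(v[0]), float(v[1])) for k, v in payload["entries"].items()}
        return cls(entries, payload.get("name", "diet"), payload.get("units", "mmol/person/day"))

    @classmethod
    def empty(cls) -> "DietSpec":
        return cls({}, name="empty")

    def without(self, *exchange_ids: str) -> "DietSpec":
        entries = {k: v for k, v in self.entries.items() if k not in exchange_ids}
        return DietSpec(entries, f"{self.name}-restricted", self.units)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(
            {"name": self.name, "units": self.units, "entries": self.entries}, indent=1
        ))


def apply_diet(model: MetabolicModel, diet: DietSpec) -> MetabolicModel:
    """Apply diet bounds to the model's diet-side exchange reactions.

    Named exchanges receive the diet bounds; all other diet-side uptakes are
    closed (lower bound 0).  Unmatched diet ids are logged, not fatal.
    Returns the model (modified in place).
    """
    if model.model_type == "single":
        suffix = ""
    else:
        suffix = "[d]"
    matched = set()
    for r in model.reactions:
        if not r.id.startswith("EX_"):
            continue
        if suffix:
            if not r.id.endswith("[d]"):
                continue
            base = r.id[: -len("[d]")]
        else:
            base = r.id
        if base in diet.entries:
            r.lb, r.ub = diet.entries[base]
            matched.add(base)
        else:
            r.lb = max(r.lb, 0.0)
    unmatched = set(diet.entries) - matched
    if unmatched:
        logger.info("diet entries without matching exchange in %s: %s",
                    model.id, sorted(unmatched))
    model.invalidate()
    return model


# ---------------------------------------------------------------------------
# single-strain models

def _template_bounds(t: ReactionTemplate) -> tuple[float, float]:
    if t.compartment_role == "exchange":
        return (0.0, BIG)  # secretion only until a diet opens uptake
    return (-BIG, BIG) if t.reversible else (0.0, BIG)


def _subsystem_reactions(genotype: StrainGenotype) -> list[Reaction]:
    out = []
    for t in build_subsystem(genotype):
        lb, ub = _template_bounds(t)
        stoich = {}
        for met, coef in t.stoichiometry.items():
            if met.endswith("[e]"):
                stoich[met] = coef
            else:
                stoich[f"{met}[c]"] = coef
        out.append(Reaction(t.id, stoich, lb, ub, t.enzyme, "bile_acid"))
    return out


def build_strain_model(
    genotype: StrainGenotype, chassis: ChassisSpec | None = None
) -> MetabolicModel:
    """Chassis plus the genotype's bile acid subsystem, as one strain model.

    Raises :class:`ModelBuildError` listing any dead-end metabolite the
    subsystem would introduce.
    """
    chassis = chassis or ChassisSpec()
    reactions = [r.copy() for r in chassis.reactions()]
    sub = _subsystem_reactions(genotype)
    have = {r.id for r in reactions}
    for r in sub:
        if r.id not in have:  # BSH and CHOL_RED may both add T_/EX_ helpers
            reactions.append(r)
            have.add(r.id)
    for r in reactions:
        r.strain = genotype.strain_id
    model = MetabolicModel(
        id=genotype.strain_id, reactions=reactions, objective_id="BIOMASS",
        model_type="single", units="mmol/gDW/h", strains=[genotype.strain_id],
    )
    sub_mets = set()
    for r in sub:
        sub_mets.update(r.stoich)
    dead = [m for m in find_dead_ends(model) if m in sub_mets]
    if dead:
        raise ModelBuildError(
            f"subsystem of {genotype.strain_id} introduces dead-end "
            f"metabolite(s): {sorted(dead)}"
        )
    return model


def find_dead_ends(model: MetabolicModel) -> list[str]:
    """Metabolites that cannot be both produced and consumed at nonzero flux."""
    producible: set[str] = set()
    consumable: set[str] = set()
    for r in model.reactions:
        for m, coef in r.stoich.items():
            if (coef > 0 and r.ub > 0) or (coef < 0 and r.lb < 0):
                producible.add(m)
            if (coef < 0 and r.ub > 0) or (coef > 0 and r.lb < 0):
                consumable.add(m)
    mets = set(producible) | set(consumable)
    for r in model.reactions:
        mets.update(r.stoich)
    return sorted(m for m in mets if m not in (producible & consumable))


# ---------------------------------------------------------------------------
# joining: pairwise and community

_REGISTRY_BA_IDS = tuple(b.id for b in canonical_registry())


def _embed_member(model: MetabolicModel, sid: str) -> tuple[list[Reaction], set[str]]:
    """Prefix a member model's reactions/metabolites; replace its boundary
    exchanges by per-strain lumen exchange (IEX) reactions."""
    reactions: list[Reaction] = []
    ext_mets: set[str] = set()
    for r in model.reactions:
        if r.id.startswith("EX_") or r.id == "DM_biomass":
            continue  # boundaries re-wired through the lumen
        stoich = {}
        for m, coef in r.stoich.items():
            stoich[f"{sid}:{m}"] = coef
            if m.endswith("[e]"):
                ext_mets.add(m[:-3])
        reactions.append(Reaction(f"{sid}:{r.id}", stoich, r.lb, r.ub,
                                  r.enzyme, r.subsystem, sid))
    for met in sorted(ext_mets):
        reactions.append(Reaction(
            f"{sid}:IEX_{met}", {f"{sid}:{met}[e]": -1, f"{met}[u]": 1},
            -BIG, BIG, "transport", "lumen_exchange", sid,
        ))
    return reactions, ext_mets


def _environment_chain(met: str) -> list[Reaction]:
    return [
        Reaction(f"EX_{met}[d]", {f"{met}[d]": -1}, 0, BIG, "exchange", "diet"),
        Reaction(f"DUt_{met}", {f"{met}[d]": -1, f"{met}[u]": 1}, 0, BIG, "transport", "diet"),
        Reaction(f"UFEt_{met}", {f"{met}[u]": -1, f"{met}[fe]": 1}, 0, BIG, "transport", "fecal"),
        Reaction(f"EX_{met}[fe]", {f"{met}[fe]": -1}, 0, BIG, "exchange", "fecal"),
    ]


def _join(
    models: Sequence[MetabolicModel],
    model_id: str,
    abundances: Mapping[str, float] | None,
    couple: bool,
    c: float,
    u: float,
) -> MetabolicModel:
    sids = [m.id for m in models]
    if len(set(sids)) != len(sids):
        raise ModelBuildError(f"duplicate strain ids in join: {sids}")
    reactions: list[Reaction] = []
    coupling: list[tuple[str, str]] = []
    lumen_mets: set[str] = set(_REGISTRY_BA_IDS)
    for m in models:
        member_rxns, ext = _embed_member(m, m.id)
        reactions.extend(member_rxns)
        lumen_mets |= ext
        if couple:
            bio = f"{m.id}:BIOMASS"
            coupling.extend((r.id, bio) for r in member_rxns if r.id != bio)
    for met in sorted(lumen_mets):
        reactions.extend(_environment_chain(met))
    if abundances is None:
        # pairwise join: strain biomass drains freely
        for sid in sids:
            reactions.append(Reaction(f"{sid}:DM_biomass", {f"{sid}:biomass[c]": -1},
                                      0, BIG, None, "chassis", sid))
        objective = None
    else:
        stoich = {f"{sid}:biomass[c]": -abundances[sid] for sid in sids}
        stoich["cbiomass[u]"] = 1.0
        reactions.append(Reaction("communityBiomass", stoich, 0, BIG, None, "community"))
        reactions.append(Reaction("UFEt_cbiomass", {"cbiomass[u]": -1, "cbiomass[fe]": 1},
                                  0, BIG, "transport", "fecal"))
        reactions.append(Reaction("EX_cbiomass[fe]", {"cbiomass[fe]": -1},
                                  0.4, 1.0, "exchange", "fecal"))
        objective = "EX_cbiomass[fe]"
    return MetabolicModel(
        id=model_id, reactions=reactions, objective_id=objective,
        model_type="community" if abundances is not None else "pair",
        units="mmol/person/day",
        strains=sids,
        abundances=dict(abundances) if abundances is not None else None,
        coupling=coupling, coupling_c=c, coupling_u=u,
    )


def join_pairwise(model_a: MetabolicModel, model_b: MetabolicModel) -> MetabolicModel:
    """Join two strain models into a pair with a shared lumen and diet.

    No abundance weighting, no coupling constraints, and no community biomass
    bound: both strains' biomass reactions drain freely.
    """
    if model_a.id == model_b.id:
        raise ModelBuildError(f"cannot pair a strain with itself: {model_a.id}")
    return _join([model_a, model_b], f"{model_a.id}|{model_b.id}",
                 abundances=None, couple=False, c=400.0, u=0.01)


def count_pairs(n_models: int) -> int:
    """Number of unordered pairs from n models: n*(n-1)/2."""
    return n_models * (n_models - 1) // 2


def enumerate_pairs(models: Sequence[MetabolicModel]) -> Iterator[MetabolicModel]:
    """Lazily yield every unordered pair of distinct models, joined."""
    if len(models) < 2:
        raise ModelBuildError("need at least two models to enumerate pairs")
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            yield join_pairwise(models[i], models[j])


def build_community(
    models: Sequence[MetabolicModel],
    abundances: Sequence[float] | Mapping[str, float],
    c: float = 400.0,
    u: float = 0.01,
    model_id: str = "community",
) -> MetabolicModel:
    """Abundance-parameterized community model with coupling constraints.

    ``abundances`` must be positive and sum to 1 (tolerance 1e-8).  Each
    strain's biomass metabolite enters the community biomass reaction with its
    abundance as stoichiometric coefficient, so at steady state every strain
    grows at the measured ratio; coupling ties each member reaction's flux to
    its own biomass flux.
    """
    if not isinstance(abundances, Mapping):
        if len(abundances) != len(models):
            raise ModelBuildError("abundance vector length != number of models")
        abundances = {m.id: float(a) for m, a in zip(models, abundances)}
    vals = np.array([abundances[m.id] for m in models], dtype=float)
    if np.any(vals <= 0):
        raise ModelBuildError("abundances must all be > 0 (filter zero-abundance strains upstream)")
    if abs(vals.sum() - 1.0) > 1e-8:
        raise ModelBuildError(f"abundances must sum to 1 (got {vals.sum():.10f})")
    if c <= 0 or u < 0:
        raise ModelBuildError("coupling requires c > 0 and u >= 0")
    return _join(list(models), model_id, abundances, couple=True, c=c, u=u)
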