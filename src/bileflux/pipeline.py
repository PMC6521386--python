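"""Cohort-level analysis: abundance filtering, per-sample community
simulation, reaction abundances, bottleneck classification, and statistics.

A sample is a vector of strain relative abundances.  For each sample a
personalized community model is built, the diet applied, and the maximal
fecal secretion flux (production potential) computed for CA, CDCA and the 13
secondary bile acids.  Shadow prices from the Iso-CA maximization classify
each microbiome into one of four bottleneck scenarios; cohort statistics
compare groups (Wilcoxon rank-sum + Benjamini-Hochberg), correlate
production with producing-reaction abundance (Spearman), and ordinate
strain-level contribution profiles (Bray-Curtis PCoA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from .builder import (
    ChassisSpec,
    DietSpec,
    MetabolicModel,
    apply_diet,
    build_community,
    build_strain_model,
)
from .fba import (
    FBASolution,
    production_potential,
    shadow_price_profile,
    solve_fba,
    strain_contributions,
)
from .pathway import (
    CONJUGATED_IDS,
    ENZYME_CLASSES,
    PRODUCING_ENZYME,
    UNCONJUGATED_IDS,
    StrainGenotype,
    producible_oracle,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceTable",
    "SimulationConfig",
    "SampleResult",
    "CohortResult",
    "ScenarioLabel",
    "load_and_filter",
    "run_sample",
    "run_cohort",
    "reaction_abundance",
    "classify_bottleneck",
    "benjamini_hochberg",
    "group_compare",
    "correlate_production_abundance",
    "ordinate_contributions",
]

#: precursor of each 3beta-HSDH product (iso bile acids)
ISO_PRECURSOR = {"isochol": "3dhchol", "icdchol": "3dhcdchol"}


# ---------------------------------------------------------------------------
# abundance loading and filtering

@dataclass
class AbundanceTable:
    """Sample x strain relative abundances (rows sum to 1) with group labels."""

    data: pd.DataFrame
    groups: pd.Series | None = None
    dropped_samples: dict[str, str] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def sample_abundances(self, sample_id: str) -> pd.Series:
        row = self.data.loc[sample_id]
        return row[row > 0]


def load_and_filter(
    coverage: pd.DataFrame | AbundanceTable,
    groups: pd.Series | None = None,
    coverage_cutoff: float = 0.10,
    min_strains: int = 20,
) -> AbundanceTable:
    """Coverage table -> filtered, renormalized abundance table.

    Strains below ``coverage_cutoff`` (default 10% genome coverage) are
    dropped per sample, remaining values are renormalized to sum to 1, and
    samples retaining fewer than ``min_strains`` strains are excluded with a
    logged reason.  Passing an already-filtered :class:`AbundanceTable` is a
    no-op (filters are idempotent).
    """
    if isinstance(coverage, AbundanceTable):
        return coverage
    vals = coverage.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("coverage values must be non-negative")
    kept = coverage.where(coverage >= coverage_cutoff, 0.0)
    dropped: dict[str, str] = {}
    rows = {}
    for sid, row in kept.iterrows():
        nz = row[row > 0]
        if len(nz) == 0:
            dropped[sid] = "no strains above coverage cutoff"
            logger.info("sample %s excluded: %s", sid, dropped[sid])
            continue
        if len(nz) < min_strains:
            dropped[sid] = f"only {len(nz)} strains mapped (< {min_strains})"
            logger.info("sample %s excluded: %s", sid, dropped[sid])
            continue
        rows[sid] = nz / nz.sum()
    data = pd.DataFrame(rows).T.reindex(columns=coverage.columns).fillna(0.0)
    data.index.name = coverage.index.name or "sample"
    g = groups.loc[data.index] if groups is not None else None
    return AbundanceTable(data, g, dropped)


# ---------------------------------------------------------------------------
# per-sample simulation

@dataclass
class SimulationConfig:
    """Knobs of the per-sample community simulation."""

    coupling_c: float = 400.0
    coupling_u: float = 0.01
    bottleneck_target: str = "isochol"
    shadow_threshold: float = 1e-6
    compute_contributions: bool = False
    use_oracle_prefilter: bool = True
    bile_acids: tuple[str, ...] = UNCONJUGATED_IDS
    chassis: ChassisSpec = field(default_factory=ChassisSpec)


@dataclass
class ScenarioLabel:
    """Bottleneck scenario for one sample/target with supporting evidence."""

    label: str  # S1_no_production | S2_producer_limited | S3_precursor_limited
    #         | S4_dual_enzyme_limited | unclassified
    evidence: dict = field(default_factory=dict)


@dataclass
class SampleResult:
    sample_id: str
    production: pd.Series  # bile acid -> maximal fecal secretion flux
    reaction_abundances: pd.Series  # enzyme class -> community abundance
    scenario: ScenarioLabel | None = None
    shadow_profile: pd.DataFrame | None = None  # for the bottleneck target
    contributions: pd.DataFrame | None = None  # (strain, bile acid) -> min,max
    dropped_strains: list[str] = field(default_factory=list)


@dataclass
class CohortResult:
    production: pd.DataFrame  # samples x bile acids
    reaction_abundances: pd.DataFrame  # samples x enzyme classes
    scenarios: pd.Series  # sample -> scenario label
    groups: pd.Series | None = None
    contributions: pd.DataFrame | None = None  # samples x (strain|acid) minima
    samples: list[SampleResult] = field(default_factory=list)


def _build_sample_community(
    abundances: pd.Series,
    genotypes: Mapping[str, StrainGenotype],
    config: SimulationConfig,
    sample_id: str,
) -> tuple[MetabolicModel, list[StrainGenotype], list[str]]:
    present = abundances[abundances > 0]
    resolved, missing = [], []
    for sid in present.index:
        if sid in genotypes:
            resolved.append(sid)
        else:
            missing.append(sid)
    if missing:
        logger.info("sample %s: dropping %d unresolvable strain(s): %s",
                    sample_id, len(missing), missing[:5])
    if not resolved:
        raise ValueError(f"sample {sample_id}: no strain resolves to a genotype")
    a = present.loc[resolved]
    a = a / a.sum()
    gts = [genotypes[s] for s in resolved]
    members = [build_strain_model(g, config.chassis) for g in gts]
    community = build_community(
        members, a.to_dict(), c=config.coupling_c, u=config.coupling_u,
        model_id=str(sample_id),
    )
    return community, gts, missing


def run_sample(
    abundances: pd.Series,
    genotypes: Mapping[str, StrainGenotype],
    diet: DietSpec,
    config: SimulationConfig | None = None,
    sample_id: str = "sample",
) -> SampleResult:
    """Simulate one microbiome sample end to end.

    Builds the abundance-parameterized community, applies the diet, computes
    the 15 production potentials (graph-reachability prefilter short-circuits
    provably unreachable acids), per-strain contributions (optional), and the
    shadow-price profile + bottleneck scenario for the target bile acid.
    """
    config = config or SimulationConfig()
    community, gts, missing = _build_sample_community(
        abundances, genotypes, config, sample_id)
    apply_diet(community, diet)

    supplied = set(CONJUGATED_IDS)
    reachable = producible_oracle(gts, supplied) if config.use_oracle_prefilter else None

    production = {}
    target_solution: FBASolution | None = None
    for ba in config.bile_acids:
        if ba == config.bottleneck_target:
            # always solved: the scenario classifier needs its duals
            sol = production_potential(community, ba)
            target_solution = sol
            production[ba] = sol.objective_value
        elif reachable is not None and ba not in reachable:
            production[ba] = 0.0
        else:
            production[ba] = production_potential(community, ba).objective_value
    production = pd.Series(production, name=sample_id)

    abund = abundances[abundances > 0]
    abund = abund[[s for s in abund.index if s in genotypes]]
    abund = abund / abund.sum()
    rxn_ab = reaction_abundance(abund, genotypes)

    profile = None
    scenario = None
    if target_solution is not None and target_solution.optimal:
        profile = shadow_price_profile(target_solution, config.shadow_threshold)
        scenario = classify_bottleneck(
            production[config.bottleneck_target], profile,
            [genotypes[s] for s in abund.index], target=config.bottleneck_target,
        )

    contributions = None
    if config.compute_contributions:
        rows = []
        for ba in config.bile_acids:
            if production[ba] <= 1e-9:
                continue
            cdf = strain_contributions(community, ba, production[ba])
            for sid, row in cdf.iterrows():
                rows.append((sid, ba, max(row["min"], 0.0), max(row["max"], 0.0)))
        contributions = pd.DataFrame(
            rows, columns=["strain", "bile_acid", "min", "max"]
        )

    return SampleResult(str(sample_id), production, rxn_ab, scenario,
                        profile, contributions, missing)


def run_cohort(
    table: AbundanceTable,
    genotypes: Mapping[str, StrainGenotype],
    diet: DietSpec,
    config: SimulationConfig | None = None,
    on_error: str = "raise",
) -> CohortResult:
    """Run :func:`run_sample` over every sample of an abundance table.

    ``on_error="log"`` isolates per-sample failures (the cohort run
    continues; the sample is excluded from the result tables).
    """
    config = config or SimulationConfig()
    results: list[SampleResult] = []
    for sid in table.sample_ids:
        try:
            results.append(run_sample(table.data.loc[sid], genotypes, diet,
                                       config, sample_id=sid))
        except Exception:
            if on_error != "log":
                raise
            logger.exception("sample %s failed; continuing", sid)
    production = pd.DataFrame({r.sample_id: r.production for r in results}).T
    rxn_ab = pd.DataFrame({r.sample_id: r.reaction_abundances for r in results}).T
    scen = pd.Series(
        {r.sample_id: (r.scenario.label if r.scenario else "unclassified")
         for r in results}, name="scenario")
    groups = table.groups.loc[production.index] if table.groups is not None else None
    contrib = None
    if config.compute_contributions:
        per_sample = {}
        for r in results:
            c = r.contributions
            if c is None or c.empty:
                per_sample[r.sample_id] = pd.Series(dtype=float)
            else:
                per_sample[r.sample_id] = c.set_index(
                    c["strain"] + "|" + c["bile_acid"])["min"]
        contrib = pd.DataFrame(per_sample).T.fillna(0.0)
    return CohortResult(production, rxn_ab, scen, groups, contrib, results)


# ---------------------------------------------------------------------------
# reaction abundances

def reaction_abundance(
    abundances: pd.Series, genotypes: Mapping[str, StrainGenotype]
) -> pd.Series:
    """Community abundance of each bile acid enzyme class.

    The abundance of a reaction is the summed relative abundance of the
    member strains whose genotype carries its enzyme (all reactions of a
    class share this value).
    """
    out = {}
    for enz in ENZYME_CLASSES:
        out[enz] = float(sum(
            a for sid, a in abundances.items()
            if sid in genotypes and genotypes[sid].has(enz)
        ))
    return pd.Series(out, name="reaction_abundance")


# ---------------------------------------------------------------------------
# bottleneck classification

def classify_bottleneck(
    production: float,
    profile: pd.DataFrame,
    genotypes: Iterable[StrainGenotype],
    target: str = "isochol",
    tol: float = 1e-9,
) -> ScenarioLabel:
    """Classify the bottleneck limiting a target bile acid from shadow prices.

    Scenarios (for Iso-CA, synthesized from 3-dehydro-CA by 3beta-HSDH):

    - S1_no_production: nothing is produced and only the dietary target
      metabolite itself carries a nonzero shadow price.
    - S2_producer_limited: some strain carrying 3beta- but not 3alpha-HSDH
      has a nonzero biomass-metabolite shadow price while all
      3alpha-only strains have zero — producer abundance is limiting.
    - S3_precursor_limited: all 3beta-only strains zero, at least one
      3alpha-only strain nonzero, and dietary precursor (3-dehydro-CA)
      nonzero — precursor availability is limiting.
    - S4_dual_enzyme_limited: nonzero biomass shadow prices occur only for
      strains carrying both enzymes.

    Anything else is returned as "unclassified" with an evidence dump.
    """
    if target not in ISO_PRECURSOR:
        raise ValueError(f"no scenario definitions for target {target!r}")
    precursor = ISO_PRECURSOR[target]
    beta_only, alpha_only, dual = set(), set(), set()
    for g in genotypes:
        a, b = g.has("HSDH_3A"), g.has("HSDH_3B")
        if a and b:
            dual.add(g.strain_id)
        elif b:
            beta_only.add(g.strain_id)
        elif a:
            alpha_only.add(g.strain_id)

    nz_biomass = {
        m.split(":", 1)[0] for m in profile.index
        if profile.loc[m, "kind"] == "strain_biomass"
    }
    env = [m for m in profile.index if profile.loc[m, "kind"] == "environment"]
    target_comps = {f"{target}[d]", f"{target}[u]", f"{target}[fe]"}
    env_other = [m for m in env if m not in target_comps]
    precursor_dietary = any(
        m in (f"{precursor}[d]", f"{precursor}[u]") for m in env)

    evidence = {
        "production": production,
        "nonzero_biomass_strains": sorted(nz_biomass),
        "beta_only_nonzero": sorted(nz_biomass & beta_only),
        "alpha_only_nonzero": sorted(nz_biomass & alpha_only),
        "dual_nonzero": sorted(nz_biomass & dual),
        "dietary_precursor_nonzero": precursor_dietary,
        "environment_nonzero": env,
    }

    if production <= tol and not nz_biomass and not env_other:
        return ScenarioLabel("S1_no_production", evidence)
    if nz_biomass & beta_only and not (nz_biomass & alpha_only):
        return ScenarioLabel("S2_producer_limited", evidence)
    if (not (nz_biomass & beta_only) and (nz_biomass & alpha_only)
            and precursor_dietary):
        return ScenarioLabel("S3_precursor_limited", evidence)
    if nz_biomass and nz_biomass <= dual:
        return ScenarioLabel("S4_dual_enzyme_limited", evidence)
    return ScenarioLabel("unclassified", evidence)


# ---------------------------------------------------------------------------
# statistics

def benjamini_hochberg(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def group_compare(
    features: pd.DataFrame,
    groups: pd.Series,
    families: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum tests with BH adjustment per family.

    ``features`` is samples x features; ``groups`` assigns each sample to one
    of exactly two groups (each n >= 3).  Features constant across all
    samples are flagged and excluded from testing.  ``families`` optionally
    maps feature name -> family label; BH is applied jointly within each
    family (default: one pooled family).
    """
    groups = groups.loc[features.index]
    levels = sorted(groups.unique())
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    na, nb = (groups == levels[0]).sum(), (groups == levels[1]).sum()
    if na < 3 or nb < 3:
        raise ValueError(
            f"each group needs >= 3 samples (got {levels[0]}: {na}, {levels[1]}: {nb})")
    ga = features.loc[groups == levels[0]]
    gb = features.loc[groups == levels[1]]
    rows = []
    for feat in features.columns:
        x, y = ga[feat].to_numpy(float), gb[feat].to_numpy(float)
        if np.ptp(features[feat].to_numpy(float)) == 0:
            rows.append((feat, np.nan, np.nan, np.nan, True))
            continue
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        rows.append((feat, float(np.median(x)), float(np.median(y)), p, False))
    out = pd.DataFrame(
        rows, columns=["feature", f"median_{levels[0]}", f"median_{levels[1]}",
                       "p", "constant"]
    ).set_index("feature")
    out["q"] = np.nan
    fam = pd.Series({f: (families.get(f, "all") if families else "all")
                     for f in out.index})
    for _, idx in fam.groupby(fam).groups.items():
        mask = out.loc[idx, "p"].notna()
        tested = out.loc[idx][mask]
        if len(tested):
            out.loc[tested.index, "q"] = benjamini_hochberg(tested["p"].to_numpy())
    return out


def correlate_production_abundance(
    production: pd.DataFrame, reaction_abundances: pd.DataFrame
) -> pd.Series:
    """Spearman rho between each bile acid's production potential and the
    community abundance of its direct producing reaction, across samples.

    Zero-variance vectors yield a missing (NaN) correlation.
    """
    if len(production) < 5:
        raise ValueError("need >= 5 samples for correlation")
    out = {}
    for ba in production.columns:
        enz = PRODUCING_ENZYME.get(ba)
        if enz is None or enz not in reaction_abundances.columns:
            out[ba] = np.nan
            continue
        x = production[ba].to_numpy(float)
        y = reaction_abundances.loc[production.index, enz].to_numpy(float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            out[ba] = np.nan
            continue
        out[ba] = float(sps.spearmanr(x, y).statistic)
    return pd.Series(out, name="spearman_rho")


def contribution_dissimilarity(contributions: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between samples' contribution profiles.

    0 for identical profiles, 1 for profiles with disjoint support.
    """
    if (contributions.to_numpy(float) < 0).any():
        raise ValueError("contribution features must be non-negative")
    d = squareform(pdist(contributions.to_numpy(float), metric="braycurtis"))
    return pd.DataFrame(d, index=contributions.index, columns=contributions.index)


def ordinate_contributions(
    contributions: pd.DataFrame, n_axes: int = 2
) -> tuple[pd.DataFrame, pd.Series]:
    """Bray-Curtis dissimilarity + classical PCoA of contribution profiles.

    ``contributions`` is samples x (strain, bile acid) features,
    non-negative.  All-zero rows are excluded (logged).  Returns sample
    coordinates on the first ``n_axes`` axes and the variance-explained
    fraction per axis.  Negative eigenvalues are dropped; axis signs are
    fixed so the largest-magnitude coordinate on each axis is positive.
    """
    if (contributions.to_numpy(float) < 0).any():
        raise ValueError("contribution features must be non-negative")
    nonzero = contributions.sum(axis=1) > 0
    if (~nonzero).any():
        logger.info("excluding %d all-zero sample(s) from ordination: %s",
                    (~nonzero).sum(), list(contributions.index[~nonzero]))
    mat = contributions.loc[nonzero]
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa

    dm = DistanceMatrix(contribution_dissimilarity(mat).to_numpy(),
                        ids=[str(i) for i in mat.index])
    ord_res = pcoa(dm, method="eigh", number_of_dimensions=min(n_axes, len(mat) - 1))
    coords = ord_res.samples.iloc[:, :n_axes].copy()
    coords.columns = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coords.index = mat.index
    for col in coords.columns:
        v = coords[col].to_numpy()
        if len(v) and v[np.argmax(np.abs(v))] < 0:
            coords[col] = -v
    explained = ord_res.proportion_explained.iloc[:coords.shape[1]].clip(lower=0)
    explained.index = coords.columns
    return coords, explained
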