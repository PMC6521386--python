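# Methods

## The bile acid subsystem

The registry holds 19 species: the four conjugated primary bile acids
(tauro-/glyco-cholate `tchola`/`gchola`, tauro-/glyco-chenodeoxycholate
`tdchola`/`dgchol`), the two unconjugated primaries (cholate `cholate`,
chenodeoxycholate `C02528`), and 13 secondary bile acids (12-dehydro-CA,
7-keto-CA, 7-dehydro-CDCA, 3-dehydro-CA, 3-dehydro-CDCA, Iso-CA, Iso-CDCA,
LCA, DCA, allo-LCA, allo-DCA, UCA, UDCA) under VMH-style ids.  Formulas are
the anionic (charge −1) forms; conjugate and cofactor formulas are chosen so
that every enzymatic template closes elementally and in charge, which
`check_balance` verifies per element.

Eight enzyme classes generate reactions:

| class | reactions | cofactor |
|---|---|---|
| BSH | 4 deconjugations (conjugated BA + H₂O → BA + glycine/taurine) | — |
| 3α/7α/12α-HSDH | hydroxyl → oxo oxidations (CA/CDCA positions 3, 7, 12) | NAD⁺, reversible |
| 3β/7β-HSDH | oxo → epimeric hydroxyl reductions (iso-/urso-acids) | NADPH, reversible |
| BAI | lumped 7α/β-dehydroxylation chains CA→DCA, CDCA→LCA, UDCA→LCA | net 1 NADH per product |
| CHOL_RED | cytoplasmic + extracellular cholesterol → coprostanol | NADH |

Design choices where the underlying biochemistry is underdetermined:

- **Cytosolic placement.** All transformations run in the cytosol with
  dedicated reversible transporters and boundary exchanges, even where
  published reaction ids carry an extracellular suffix (kept in the
  `vmh_id` cross-reference field).  This keeps each strain's cofactor pools
  internal and every template mass-balanced.
- **BAI lumping.** The multi-step pathway is condensed to three internal
  steps per substrate — NAD⁺-linked CoA-activation/oxidation (2 NADH out),
  7-dehydration (H₂O out), and the NADH-dependent Δ6/Δ4 + 3-oxo terminal
  reductions (3 NADH in) — giving the net stoichiometry
  BA + NADH + H⁺ → product + H₂O + NAD⁺.  allo-DCA/allo-LCA branch off the
  dehydrated intermediate with identical cofactor stoichiometry, as
  side-products of the same pathway; their reductases and the product
  exporter are gap-fills (`enzyme="gapfill"`), i.e. reactions without a
  known gene association added to avoid dead ends.
- **Cofactor assignment.** NAD for the 3α/7α/12α oxidations and NADP for
  the 3β/7β reductions follows common oxidoreductase biochemistry; all HSDH
  reactions are reversible.
- **12α-HSDH scope.** Only CA ↔ 12-dehydro-CA is instantiated; action on
  DCA or pathway intermediates is not modeled.

A strain with every enzyme class can reach all 15 unconjugated species from
the conjugated substrates under naive reachability; reported observations
that a single organism reaches at most six secondary acids presumably hinge
on reconstruction-specific irreversibilities that are not stated anywhere we
could verify, so no artificial cap is imposed (the acceptance script reports
the maxima actually attained by the sampled genotypes).

## Chassis, diet, and units

Each strain model is the subsystem plus a deliberately minimal chassis: one
carbon source (glucose) catabolized to pyruvate with NADH generation, a
lumped biomass reaction (1 glucose → 1 biomass), and NAD(P)H-closing
pseudo-reactions (a lumped NADH oxidase and an NADPH regenerator).  The
pseudo-reactions stand in for respiration and anabolism and are exempt from
elemental balance (tagged `subsystem="chassis"`); every bile acid template
is strictly balanced.  The chassis is the smallest network in which the
cofactor-consuming bile acid reactions are actually exercised — a BAI chain
that cannot regenerate NADH would otherwise be silently dead.

The shipped diet (`average_synthetic_diet.json`) supplies glucose, water,
protons, a little cholesterol, and the four conjugated primary bile acids
with lower bound −1000 (effectively unlimited).  `apply_diet` closes every
other uptake.  Units are metadata only: single/pair models are labeled
mmol·gDW⁻¹·h⁻¹ and community models mmol·person⁻¹·day⁻¹, with no numeric
conversion — the numbers are capacity bounds, not measurements.

## Pairwise and community models

Members are embedded behind per-strain compartments; their boundary
exchanges are rewired as per-strain lumen exchanges (`IEX`), and each lumen
metabolite gets a diet-exchange → diet-transport → lumen → fecal-transport →
fecal-exchange chain.  Diet/fecal chains exist for all 19 registry acids
even when no member touches one, so dietary shadow prices are defined for
every target.  Pairwise models leave both biomass reactions free and carry
no coupling and no community biomass bound.  Community models couple every
member reaction (two one-sided rows per reaction, keeping reversible
reactions unsplit) with defaults c = 400, u = 0.01 — the published defaults
of the coupling formulation this follows — and force strains to grow at
their measured ratios through the abundance-weighted community biomass
reaction bounded to [0.4, 1] per day.  Assembly is deterministic; matrices
use sorted metabolite/reaction ids.

## Solving and shadow prices

LPs are solved with HiGHS through `scipy.optimize.linprog`; feasibility and
bound tolerances are 1e-9.  Duals vary in sign convention across solvers, so
the engine re-signs every metabolite dual to a canonical convention —
positive ⇔ one extra unit of availability (an external injection into the
mass balance) raises the maximized objective — and the test suite validates
this against finite-difference re-solves (δ = 1e-3, agreement to 1e-6;
observed error ~1e-15).  Shadow-price profiles keep entries with |sp| >
1e-6.  Strain contributions are FVA-style: with the community optimum fixed
(relative tolerance 1e-6, automatic 1e-4 fallback on numerical
infeasibility), each strain's lumen exchange is minimized and maximized; the
minimum is the guaranteed contribution.  Because reversible HSDHs plus free
cofactor cycling admit futile cross-strain shuttles, raw minima can be
negative for non-producing strains; cohort-level contribution matrices
report the positive part (secretion), which also keeps Bray–Curtis inputs
non-negative.

## Bottleneck scenarios

With Iso-CA (or Iso-CDCA) production maximized, the classifier reads the
shadow-price profile: S1 — no production and only the dietary target itself
nonzero; S2 — some 3β-only carrier's biomass metabolite nonzero while all
3α-only carriers are zero (producer-limited); S3 — the reverse pattern plus
a nonzero dietary 3-dehydro-CA (precursor-limited); S4 — nonzero biomass
entries confined to strains carrying both enzymes.  The target acid's own
diet/lumen/fecal entries are ignored outside S1, since injecting the product
trivially raises the objective in every scenario.  Profiles matching none of
the patterns return `unclassified` with an evidence dump — communities with
a 3β carrier but no 3α carrier at all, for example, are genuinely outside
the four patterns and are not forced into one.  Labels are invariant under
common rescaling of abundances (they are renormalized).

## Synthetic data

Genotypes are independent Bernoulli draws per enzyme with default
prevalences BSH 0.29, 7α 0.07, 12α 0.056, 3α 0.025, 3β 0.017, 7β 0.004,
BAI 0.010, CHOL_RED 0.007 (observed genome frequencies, documented as
defaults rather than ground truth); BAI carriers additionally receive
12α-HSDH and either 7α-HSDH or the 3α+3β pair, mirroring their observed
co-occurrence.  Cohorts draw 127 ± 38 strains per sample (truncated to
[21, 316]) with log-normal(0, 1) abundances before renormalization; group B
multiplies the abundances of depleted-enzyme carriers by the configured
factor first.  Coverage mode emits genome-coverage values in (0, 1] so the
10%-coverage and ≥20-strain filters are both exercised.  Everything is
reproducible from (config, seed), and the truth record stores parameters
plus expected effect directions.

What the generator does *not* emulate: phylogenetic correlation between
enzymes and taxa, co-abundance structure, compositional noise from read
sampling, strain-level genome variation, and any real diet beyond the
minimal chassis medium.  Passing tests therefore demonstrate that the
machinery recovers engineered effects under its own assumptions, not that it
predicts real microbiome bile acid chemistry.

## Problem sizes and numerics

Replicated experiments (the depletion power and null-calibration runs, and
the acceptance script) use compact cohorts — strain pool 250, 21–64 strains
per sample (mean 32), 25 vs 20 samples — so a 20-replicate experiment runs
in minutes on one core; the assembly and solving machinery is identical at
full scale, where a 127-strain community is a ~6,000-reaction LP with
~12,000 coupling rows.  The null-calibration arm runs 60 replicates because
the pooled rejection rate averages ~15 correlated features per cohort and
needs more replicate blocks than detection counting does; with exchangeable
groups the tie-corrected asymptotic rank-sum test calibrates at ≈0.044–0.046
empirical size at α = 0.05.  Benjamini–Hochberg is the plain step-up with a
final cumulative minimum; it matches statsmodels to <1e-12 and is applied
within feature families (productions, contributions, reaction abundances)
jointly by default.  PCoA drops negative eigenvalues and sign-fixes axes by
the largest-magnitude coordinate.  Ties in abundance draws, degenerate
alternate optima in contributions, and all-zero ordination rows are handled
explicitly (unique FVA bounds, logged exclusions).

## Known limitations

Steady-state FBA yields capacity bounds, not concentrations or dynamics; no
kinetics, regulation, or transporter saturation is modeled.  The chassis is
generic — strain-specific growth requirements, yields, and real AGORA-scale
network content are out of scope, as is the comparative genomics that
produces genotype tables.  Scenario definitions are specific to the
3α/3β-HSDH epimerization pair; other bottleneck analyses would need their
own patterns.
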