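"""Flux balance analysis on bileflux models: LP solving, canonicalized
shadow prices, production potentials, and per-strain contributions.

The LP is  max/min c'v  subject to  S v = b,  A v <= u_c  (coupling rows),
lb <= v <= ub, solved with the HiGHS backend through scipy.  Shadow prices
are re-signed to a solver-independent canonical convention: positive means
one extra unit of the metabolite's *availability* (an external injection
into its mass balance) increases the optimal objective.  The convention is
validated against finite-difference re-solves in the test suite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

from .builder import MetabolicModel
from .pathway import UNCONJUGATED_IDS

logger = logging.getLogger(__name__)

__all__ = [
    "FBASolution",
    "InfeasibleModelError",
    "solve_fba",
    "production_potential",
    "production_profile",
    "strain_contributions",
    "shadow_price_profile",
    "SOLVER_NAME",
]

SOLVER_NAME = "scipy-highs"
FEAS_TOL = 1e-9


class InfeasibleModelError(RuntimeError):
    pass


@dataclass
class FBASolution:
    """Result of one FBA solve."""

    status: str  # optimal | infeasible | unbounded
    objective_id: str
    sense: str
    objective_value: float
    fluxes: pd.Series | None = None
    shadow_prices: pd.Series | None = None
    reduced_costs: pd.Series | None = None
    solver: str = SOLVER_NAME

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _status_from_scipy(res) -> str:
    return {0: "optimal", 2: "infeasible", 3: "unbounded"}.get(res.status, "error")


def solve_fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    sense: str = "max",
    availability: Mapping[str, float] | None = None,
) -> FBASolution:
    """Solve FBA for one objective reaction.

    ``availability`` optionally injects extra units of named metabolites into
    their mass balances (used by the finite-difference shadow-price oracle).
    Infeasible/unbounded status is propagated in the returned solution, never
    silently turned into zero.
    """
    objective_id = objective_id or model.objective_id
    if objective_id is None:
        raise ValueError("no objective reaction given and model has none")
    met_ids, rxn_ids, S, lb, ub, A_c, b_c = model.to_matrices()
    try:
        j_obj = rxn_ids.index(objective_id)
    except ValueError:
        raise KeyError(f"objective reaction {objective_id!r} not in model {model.id}") from None
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    c = np.zeros(len(rxn_ids))
    c[j_obj] = -1.0 if sense == "max" else 1.0
    b_eq = np.zeros(len(met_ids))
    if availability:
        mpos = {m: i for i, m in enumerate(met_ids)}
        for met, delta in availability.items():
            # injecting delta lets the network consume delta more than it makes
            b_eq[mpos[met]] -= delta
    res = linprog(
        c, A_ub=A_c if A_c.shape[0] else None,
        b_ub=b_c if A_c.shape[0] else None,
        A_eq=S, b_eq=b_eq, bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    status = _status_from_scipy(res)
    if status != "optimal":
        return FBASolution(status, objective_id, sense, np.nan)
    obj = -res.fun if sense == "max" else res.fun
    fluxes = pd.Series(res.x, index=rxn_ids)
    # scipy marginals are d(min c'v)/d(b_eq); availability enters b_eq with a
    # minus sign, and maximization flips the internal objective sign, so the
    # canonical availability-derivative is +marginals for max, -marginals for
    # min.
    marg = np.asarray(res.eqlin.marginals, dtype=float)
    sp = marg if sense == "max" else -marg
    shadow = pd.Series(sp, index=met_ids)
    red = pd.Series(np.asarray(res.lower.marginals) + np.asarray(res.upper.marginals),
                    index=rxn_ids)
    return FBASolution(status, objective_id, sense, float(obj), fluxes, shadow, red)


# ---------------------------------------------------------------------------
# production potential

def _secretion_exchange_id(model: MetabolicModel, bile_acid: str) -> str | None:
    rid = f"EX_{bile_acid}[fe]" if model.model_type in ("pair", "community") else f"EX_{bile_acid}"
    return rid if model.has_reaction(rid) else None


def production_potential(model: MetabolicModel, bile_acid: str) -> FBASolution:
    """Maximal secretion flux of one bile acid (fecal exchange for community
    and pairwise models, boundary exchange for single-strain models).

    Returns a zero-valued optimal record when the exchange is absent.  An
    infeasible model raises with a diagnosis of the likely cause.
    """
    rid = _secretion_exchange_id(model, bile_acid)
    if rid is None:
        return FBASolution("optimal", f"EX_{bile_acid}", "max", 0.0)
    sol = solve_fba(model, rid, "max")
    if sol.status == "infeasible":
        hint = (
            "community biomass bounds [0.4, 1] unreachable under the current diet"
            if model.has_reaction("EX_cbiomass[fe]")
            else "diet constraints leave no feasible flux distribution"
        )
        raise InfeasibleModelError(
            f"model {model.id} infeasible when maximizing {rid}: {hint}"
        )
    if sol.status == "unbounded":
        raise InfeasibleModelError(f"model {model.id} unbounded for {rid}; missing bounds")
    return sol


def production_profile(
    model: MetabolicModel,
    bile_acids: Iterable[str] = UNCONJUGATED_IDS,
    prefilter: set[str] | None = None,
) -> pd.Series:
    """Production potentials for several bile acids, as a Series.

    ``prefilter``, when given (typically from the reachability oracle),
    short-circuits acids known unreachable to 0 without an LP solve.
    """
    out = {}
    for ba in bile_acids:
        if prefilter is not None and ba not in prefilter:
            out[ba] = 0.0
        else:
            out[ba] = production_potential(model, ba).objective_value
    return pd.Series(out, name=model.id)


# ---------------------------------------------------------------------------
# strain contributions

@dataclass
class ContributionRow:
    strain: str
    bile_acid: str
    min_flux: float
    max_flux: float


def strain_contributions(
    model: MetabolicModel,
    bile_acid: str,
    community_optimum: float | None = None,
    rel_tol: float = 1e-6,
) -> pd.DataFrame:
    """Per-strain secretion flux ranges at the fixed community optimum.

    With the community secretion held at its maximal value (relative
    tolerance ``rel_tol``, with an automatic 1e-4 fallback on numerical
    infeasibility), each member strain's lumen-secretion exchange is
    minimized and maximized; the minimum is the guaranteed contribution.
    Rows are indexed by strain id with ``min``/``max`` columns.
    """
    rid = _secretion_exchange_id(model, bile_acid)
    if rid is None:
        return pd.DataFrame(
            {"min": 0.0, "max": 0.0}, index=pd.Index(model.strains, name="strain")
        )
    if community_optimum is None:
        community_optimum = production_potential(model, bile_acid).objective_value
    work = model.copy()
    ex = work.reaction(rid)

    def _fix(tol: float) -> None:
        ex.lb = community_optimum * (1 - tol) if community_optimum > 0 else 0.0
        work.invalidate()

    _fix(rel_tol)
    rows = {}
    for sid in model.strains:
        iex = f"{sid}:IEX_{bile_acid}"
        if not work.has_reaction(iex):
            rows[sid] = (0.0, 0.0)
            continue
        lo = solve_fba(work, iex, "min")
        if not lo.optimal:
            logger.warning("optimum-fixing at %g infeasible for %s; retrying with 1e-4",
                           rel_tol, model.id)
            _fix(1e-4)
            lo = solve_fba(work, iex, "min")
        hi = solve_fba(work, iex, "max")
        if not (lo.optimal and hi.optimal):
            raise InfeasibleModelError(
                f"contribution LPs infeasible for strain {sid}, acid {bile_acid}")
        rows[sid] = (lo.objective_value, hi.objective_value)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=["min", "max"])
    df.index.name = "strain"
    return df


# ---------------------------------------------------------------------------
# shadow prices

def _metabolite_kind(met: str) -> str:
    if met.endswith("[d]") or met.endswith("[u]") or met.endswith("[fe]"):
        return "environment"
    if ":" in met:
        base = met.split(":", 1)[1]
        return "strain_biomass" if base == "biomass[c]" else "strain_metabolite"
    return "metabolite"


def shadow_price_profile(solution: FBASolution, threshold: float = 1e-6) -> pd.DataFrame:
    """Nonzero shadow prices of an optimal solution, annotated by kind.

    Entries with |shadow price| <= ``threshold`` (default 1e-6) are dropped.
    Kinds distinguish strain biomass metabolites, other strain-internal
    metabolites, and diet/lumen/fecal (environment) metabolites.
    """
    if not solution.optimal or solution.shadow_prices is None:
        raise ValueError("shadow_price_profile requires an optimal solution")
    sp = solution.shadow_prices
    keep = sp[np.abs(sp.values) > threshold]
    df = pd.DataFrame({"shadow_price": keep})
    df["kind"] = [_metabolite_kind(m) for m in keep.index]
    df.index.name = "metabolite"
    return df
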