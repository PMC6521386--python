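"""LP solving, canonical shadow prices, production potentials, and
per-strain contribution ranges."""

import numpy as np
import pandas as pd
import pytest

from bileflux.builder import (
    MetabolicModel,
    Reaction,
    apply_diet,
    build_community,
    build_strain_model,
)
from bileflux.fba import (
    production_potential,
    production_profile,
    shadow_price_profile,
    solve_fba,
    strain_contributions,
)
from bileflux.pathway import StrainGenotype

from conftest import single_model

TOL = 1e-6


def toy_chain():
    """EX_A(-5,0) -> A -> B -> EX_B: objective bounded by A supply."""
    return MetabolicModel("toy", [
        Reaction("EX_A", {"A": -1}, -5, 0),
        Reaction("R1", {"A": -1, "B": 1}, 0, 1000),
        Reaction("EX_B", {"B": -1}, 0, 1000),
    ])


def random_chain(rng, n=6):
    rxns = [Reaction("EX_in", {"m0": 1}, 0, rng.uniform(1, 10))]
    for i in range(n - 1):
        rxns.append(Reaction(f"R{i}", {f"m{i}": -1, f"m{i+1}": rng.uniform(0.5, 2)},
                             0, rng.uniform(1, 20)))
    rxns.append(Reaction("EX_out", {f"m{n-1}": -1}, 0, rng.uniform(1, 20)))
    return MetabolicModel("chain", rxns)


class TestSolve:
    def test_toy_chain_bottleneck(self):
        sol = solve_fba(toy_chain(), "EX_B", "max")
        assert sol.optimal
        assert sol.objective_value == pytest.approx(5.0)

    def test_toy_chain_shadow_price_canonical_sign(self):
        sol = solve_fba(toy_chain(), "EX_B", "max")
        # one extra unit of A availability yields one extra unit of product
        assert sol.shadow_prices["A"] == pytest.approx(1.0)

    def test_interior_metabolite_filtered_from_profile(self):
        m = MetabolicModel("toy2", [
            Reaction("EX_A", {"A": -1}, -5, 0),
            Reaction("R1", {"A": -1, "B": 1}, 0, 1000),
            Reaction("R2", {"B": -1, "C": 1}, 0, 2),  # bottleneck moves to R2
            Reaction("EX_C", {"C": -1}, 0, 1000),
        ])
        sol = solve_fba(m, "EX_C", "max")
        profile = shadow_price_profile(sol)
        assert "A" not in profile.index  # A is slack, sp 0

    def test_infeasible_status_propagated(self, diet):
        m = single_model(StrainGenotype("s", set()), diet)
        bio = m.reaction("BIOMASS")
        bio.lb = 1e6  # unreachable growth demand
        m.invalidate()
        sol = solve_fba(m, "BIOMASS")
        assert sol.status == "infeasible"
        assert np.isnan(sol.objective_value)

    def test_steady_state_and_bounds_respected(self, diet):
        m = single_model(StrainGenotype("s", {"BSH", "HSDH_7A"}), diet)
        sol = solve_fba(m, "EX_7ocholate", "max")
        mets, rxns, S, lb, ub, *_ = m.to_matrices()
        v = sol.fluxes.loc[rxns].to_numpy()
        assert np.abs(S @ v).max() <= 1e-9 * max(1.0, np.abs(v).max())
        assert (v >= lb - 1e-9).all() and (v <= ub + 1e-9).all()

    def test_lp_duality_gap(self):
        """Primal optimum equals the dual objective implied by the duals."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            m = random_chain(rng)
            sol = solve_fba(m, "EX_out", "max")
            mets, rxns, S, lb, ub, *_ = m.to_matrices()
            # with b_eq = 0 the dual objective is the bound term only
            red = sol.reduced_costs.loc[rxns].to_numpy()
            dual_obj = np.sum(np.where(red > 0, red * lb, red * ub))
            assert sol.objective_value == pytest.approx(-dual_obj, abs=1e-8)

    def test_objective_deterministic(self, diet):
        vals = set()
        for _ in range(3):
            m = single_model(StrainGenotype("s", {"BSH"}), diet)
            vals.add(round(production_potential(m, "cholate").objective_value, 12))
        assert len(vals) == 1


class TestFiniteDifferenceOracle:
    def test_shadow_prices_match_perturbation(self):
        """sp * delta predicts the objective change of a relaxed re-solve."""
        rng = np.random.default_rng(11)
        delta = 1e-3
        checked = 0
        for _ in range(12):
            m = random_chain(rng, n=int(rng.integers(4, 8)))
            sol = solve_fba(m, "EX_out", "max")
            for met in m.metabolite_ids():
                sp = sol.shadow_prices[met]
                pert = solve_fba(m, "EX_out", "max", availability={met: delta})
                change = pert.objective_value - sol.objective_value
                assert change == pytest.approx(sp * delta, abs=1e-6)
                checked += 1
        assert checked >= 50


class TestProductionPotential:
    def test_bsh_only_profile(self, diet):
        m = single_model(StrainGenotype("s", {"BSH"}), diet)
        prof = production_profile(m)
        assert prof["cholate"] > TOL and prof["C02528"] > TOL
        assert prof["dchac"] <= TOL

    def test_deconjugating_dehydroxylator_reaches_dca_and_lca(self, diet):
        m = single_model(
            StrainGenotype("s", {"BSH", "BAI", "HSDH_7A", "HSDH_12A"}), diet)
        prof = production_profile(m)
        assert prof["dchac"] > TOL and prof["HC02191"] > TOL

    def test_absent_exchange_reports_zero(self, diet):
        m = single_model(StrainGenotype("s", set()), diet)
        sol = production_potential(m, "dchac")
        assert sol.optimal and sol.objective_value == 0.0

    def test_monotone_in_diet_uptake(self):
        from bileflux.builder import DietSpec

        base = DietSpec.default()
        vals = []
        for lim in (1.0, 10.0, 1000.0):
            d = DietSpec(dict(base.entries), "scaled")
            d.entries["EX_gchola"] = (-lim, 1000.0)
            d.entries["EX_tchola"] = (0.0, 1000.0)
            d.entries["EX_tdchola"] = (0.0, 1000.0)
            d.entries["EX_dgchol"] = (0.0, 1000.0)
            m = single_model(StrainGenotype("s", {"BSH"}), d)
            vals.append(production_potential(m, "cholate").objective_value)
        assert vals == sorted(vals)
        assert vals[0] == pytest.approx(1.0, rel=1e-6)


class TestContributions:
    def test_single_member_equals_optimum(self, diet):
        com = apply_diet(build_community(
            [build_strain_model(StrainGenotype("a", {"BSH"}))], [1.0]), diet)
        opt = production_potential(com, "cholate").objective_value
        contr = strain_contributions(com, "cholate", opt)
        assert contr.loc["a", "min"] == pytest.approx(opt, rel=1e-4)

    def test_exclusive_terminal_producer(self, diet):
        mods = [build_strain_model(StrainGenotype("bsh", {"BSH"})),
                build_strain_model(StrainGenotype("h12", {"HSDH_12A"}))]
        com = apply_diet(build_community(mods, [0.5, 0.5]), diet)
        opt = production_potential(com, "12dhchol").objective_value
        assert opt > TOL
        contr = strain_contributions(com, "12dhchol", opt)
        assert contr.loc["h12", "min"] == pytest.approx(opt, rel=1e-3)
        assert contr.loc["bsh", "min"] == pytest.approx(0.0, abs=1e-6)

    def test_redundant_producers_have_zero_minimum(self, diet):
        """When either of two converters can carry the flux, neither is
        guaranteed: both FVA minima are ~0."""
        mods = [build_strain_model(StrainGenotype("bsh", {"BSH"})),
                build_strain_model(StrainGenotype("c1", {"HSDH_12A"})),
                build_strain_model(StrainGenotype("c2", {"HSDH_12A"}))]
        # rare deconjugator bounds the flux; converters have spare capacity
        com = apply_diet(build_community(mods, [0.02, 0.49, 0.49]), diet)
        opt = production_potential(com, "12dhchol").objective_value
        assert opt > TOL
        contr = strain_contributions(com, "12dhchol", opt)
        assert contr.loc["c1", "min"] <= 1e-6
        assert contr.loc["c2", "min"] <= 1e-6
        assert contr.loc["c1", "max"] >= opt * 0.9

    def test_min_never_exceeds_max(self, diet):
        mods = [build_strain_model(StrainGenotype("a", {"BSH", "HSDH_7A"})),
                build_strain_model(StrainGenotype("b", {"HSDH_7A"}))]
        com = apply_diet(build_community(mods, [0.6, 0.4]), diet)
        contr = strain_contributions(com, "7ocholate")
        assert (contr["min"] <= contr["max"] + 1e-9).all()
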