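"""FBA/FVA, the ATP probe, α-scans, α-selection and growth rates."""

import numpy as np
import pytest

import gensi as G
from gensi.optimize import ATP_PROBE_ID
from lp_oracle import brute_force_max, oracle_fba, oracle_fva


class TestFBA:
    def test_matches_oracles_on_mini_fixtures(self, mini_fixtures):
        for gem in mini_fixtures:
            z = G.fba(gem).objective_value
            assert z == pytest.approx(oracle_fba(gem), abs=1e-6), \
                gem.cobra_model.id

    def test_matches_brute_force_enumeration(self, mini_fixtures):
        """On the tiniest fixtures the optimum is also recovered by
        exhaustive candidate-vertex enumeration."""
        by_id = {g.cobra_model.id: g for g in mini_fixtures}
        for name in ("chain", "branch", "reversible"):
            gem = by_id[name]
            z = G.fba(gem).objective_value
            assert z == pytest.approx(brute_force_max(gem), abs=1e-6), name

    def test_min_max_bracket(self, mini_fixtures):
        gem = mini_fixtures[0]
        lo = G.fba(gem, sense="min").objective_value
        hi = G.fba(gem, sense="max").objective_value
        assert lo <= hi

    def test_no_inputs_no_growth(self, toy_gem):
        closed = toy_gem.copy()
        for rid in closed.reaction_ids("exchange"):
            rxn = closed.cobra_model.reactions.get_by_id(rid)
            rxn.lower_bound = max(rxn.lower_bound, 0.0)
        sol = G.fba(closed)
        z = sol.objective_value if sol.optimal else 0.0
        assert z == pytest.approx(0.0, abs=1e-9)

    def test_infeasible_is_status_not_exception(self, toy_gem):
        bad = toy_gem.copy()
        bad.cobra_model.reactions.BIOMASS.lower_bound = 500.0
        bad.cobra_model.reactions.EX_phe.lower_bound = 0.0
        sol = G.fba(bad)
        assert sol.status == "infeasible"
        assert np.isnan(sol.objective_value)

    def test_optimal_solution_respects_steady_state(self, gensi_models):
        gm = gensi_models["NA1"]
        sol = G.fba(gm)
        S = gm.model.stoichiometric_matrix()
        v = sol.fluxes[[r.id for r in gm.cobra_model.reactions]].values
        assert np.abs(S @ v).max() < 1e-6
        for rxn in gm.cobra_model.reactions:
            assert rxn.lower_bound - 1e-6 <= sol.fluxes[rxn.id] <= \
                rxn.upper_bound + 1e-6


class TestFVA:
    def test_matches_oracle_on_mini_fixtures(self, mini_fixtures):
        for gem in mini_fixtures:
            targets = [r.id for r in gem.cobra_model.reactions]
            result = G.fva(gem, reactions=targets, gamma=1.0)
            z0, expected = oracle_fva(gem, targets, gamma=1.0)
            assert result.z0 == pytest.approx(z0, abs=1e-6)
            for rid in targets:
                lo, hi = result.range(rid)
                elo, ehi = expected[rid]
                assert lo == pytest.approx(elo, abs=1e-6), (gem.cobra_model.id, rid)
                assert hi == pytest.approx(ehi, abs=1e-6), (gem.cobra_model.id, rid)

    def test_closed_reaction_range_is_zero(self, toy_gem, media_panel):
        constrained = G.apply_murs(
            G.block_nonmedium_uptakes(toy_gem, media_panel[0]),
            G.compute_mur(media_panel[0]))
        constrained.cobra_model.reactions.LDH.bounds = (0.0, 0.0)
        result = G.fva(constrained, reactions=["LDH"])
        assert result.range("LDH") == (pytest.approx(0.0), pytest.approx(0.0))

    def test_biomass_pinned_at_gamma_one(self, gensi_models):
        gm = gensi_models["NA3"]
        result = G.fva(gm, reactions=["BIOMASS"], gamma=1.0)
        lo, hi = result.range("BIOMASS")
        assert lo == pytest.approx(result.z0, rel=1e-6)
        assert hi == pytest.approx(result.z0, rel=1e-6)

    def test_optimal_fluxes_lie_in_envelope(self, gensi_models):
        gm = gensi_models["NA1"]
        sol = G.fba(gm)
        targets = ["EX_glc", "EX_gln", "EX_lac", "EX_o2", "OXPHOS", "GLYC"]
        result = G.fva(gm, reactions=targets)
        for rid in targets:
            lo, hi = result.range(rid)
            assert lo - 1e-6 <= sol.fluxes[rid] <= hi + 1e-6

    def test_suboptimal_gamma_widens_ranges(self, gensi_models):
        gm = gensi_models["NA1"]
        tight = G.fva(gm, reactions=["EX_lac"], gamma=1.0)
        loose = G.fva(gm, reactions=["EX_lac"], gamma=0.5)
        assert loose.range("EX_lac")[1] >= tight.range("EX_lac")[1] - 1e-9
        assert loose.range("EX_lac")[0] <= tight.range("EX_lac")[0] + 1e-9

    def test_infeasible_base_is_error(self, toy_gem):
        bad = toy_gem.copy()
        bad.cobra_model.reactions.BIOMASS.lower_bound = 500.0
        bad.cobra_model.reactions.EX_phe.lower_bound = 0.0
        with pytest.raises(RuntimeError):
            G.fva(bad, reactions=["EX_lac"])

    def test_gamma_out_of_range(self, toy_gem):
        with pytest.raises(ValueError):
            G.fva(toy_gem, gamma=1.5)


class TestATPCapacity:
    def test_surplus_capacity_at_max_biomass(self, gensi_models):
        """NA1 at the plateau: biomass needs 50 ATP of a possible
        2x25 (glycolysis) + 15x1 (oxygen-capped respiration) = 65, so
        the probe can dissipate at most 15."""
        lo, hi = G.atp_capacity(gensi_models["NA1"])
        assert lo == pytest.approx(0.0, abs=1e-6)
        assert hi == pytest.approx(15.0, abs=1e-6)

    def test_no_surplus_when_substrate_scarce(self, toy_gem, media_panel):
        """In the glutamine-only medium all producible ATP is needed
        for maximal growth: probe capacity 0."""
        na5 = media_panel[4]
        constrained = G.apply_murs(
            G.block_nonmedium_uptakes(toy_gem, na5), G.compute_mur(na5))
        lo, hi = G.atp_capacity(constrained)
        assert hi == pytest.approx(0.0, abs=1e-6)

    def test_probe_absent_after_call(self, gensi_models):
        gm = gensi_models["NA1"]
        G.atp_capacity(gm)
        assert ATP_PROBE_ID not in [r.id for r in gm.cobra_model.reactions]

    def test_missing_species_is_error(self, mini_fixtures):
        with pytest.raises(ValueError):
            G.atp_capacity(mini_fixtures[0])


class TestAlphaScan:
    @pytest.fixture(scope="class")
    def scan(self, toy_gem, toy_ras, media_panel):
        grid = sorted(np.geomspace(3e-4, 1.6, 25))
        return G.alpha_scan(toy_gem, {"toy": toy_ras}, media_panel, grid)

    def test_monotone_in_alpha(self, scan):
        for medium in scan.frame["medium"].unique():
            series = scan.frame[scan.frame["medium"] == medium] \
                .sort_values("alpha")["biomass"].values
            assert (np.diff(series) >= -1e-9).all()

    def test_high_alpha_ranks_by_carbon(self, scan):
        top = scan.frame[scan.frame["alpha"] == scan.grid[-1]] \
            .set_index("medium")["biomass"]
        assert top["NA1"] >= top["NA3"] > top["NA5"] > top["NA6"]
        assert top["NA2"] == pytest.approx(top[["NA1", "NA2"]].max())

    def test_low_alpha_converges_glucose_media(self, scan):
        low = scan.frame[scan.frame["alpha"] == scan.grid[0]] \
            .set_index("medium")["biomass"]
        glucose = low[["NA1", "NA2", "NA3", "NA4"]]
        assert glucose.max() - glucose.min() <= 1e-6
        assert low["NA5"] < glucose.min()
        assert low["NA5"] > low["NA6"]

    def test_single_point_grid_degenerates_to_fba(self, toy_gem, toy_ras,
                                                  media_panel):
        scan = G.alpha_scan(toy_gem, {"toy": toy_ras}, media_panel[:1], [10.0])
        assert len(scan.frame) == 1
        mur_only = G.apply_murs(
            G.block_nonmedium_uptakes(toy_gem, media_panel[0]),
            G.compute_mur(media_panel[0]))
        assert scan.frame["biomass"].iloc[0] == pytest.approx(
            G.fba(mur_only).objective_value, abs=1e-6)

    def test_unsorted_grid_rejected(self, toy_gem, toy_ras, media_panel):
        with pytest.raises(ValueError):
            G.alpha_scan(toy_gem, {"toy": toy_ras}, media_panel, [1.0, 0.1])


class TestSelectAlpha:
    @pytest.fixture(scope="class")
    def scan(self, toy_gem, toy_ras, media_panel):
        # grid engineered around the fixture's convergence point (the
        # glucose-containing media converge once glucose transport and
        # glycolysis bounds drop below what the poorest glucose medium
        # can supply)
        grid = [0.001, 0.01, 0.1, 0.2, 0.5, 1.0, 1.6]
        return G.alpha_scan(toy_gem, {"toy": toy_ras}, media_panel, grid)

    def test_returns_largest_converged_alpha(self, scan):
        out = G.select_alpha(scan, ["NA1", "NA2", "NA3", "NA4"],
                             ["NA5", "NA6"], tol=1e-6)
        assert out["alpha"] == pytest.approx(0.2)

    def test_infinite_tolerance_keeps_dominance_only(self, scan):
        out = G.select_alpha(scan, ["NA1", "NA2", "NA3", "NA4"],
                             ["NA5", "NA6"], tol=float("inf"))
        assert out["alpha"] == pytest.approx(1.6)

    def test_impossible_dominance_returns_none(self, scan):
        out = G.select_alpha(scan, ["NA5"], ["NA1"], tol=float("inf"))
        assert out["alpha"] is None
        assert not out["diagnostics"].empty

    def test_overlapping_sets_rejected(self, scan):
        with pytest.raises(ValueError):
            G.select_alpha(scan, ["NA1"], ["NA1", "NA5"])


class TestGrowthRate:
    def test_exact_doubling(self):
        # N(t) = 1e5 + (1e5/24)·t doubles over 24 h: rate = 1/24 per hour
        times = [0.0, 12.0, 24.0]
        counts = [1e5 + 1e5 / 24 * t for t in times]
        obs = G.growth_rate_from_counts(times, counts)
        assert obs.rate_per_h == pytest.approx(1 / 24)
        assert not obs.nongrowing

    def test_constant_counts_flagged(self):
        obs = G.growth_rate_from_counts([0.0, 24.0, 48.0], [1e5, 1e5, 1e5])
        assert obs.rate_per_h == 0.0
        assert obs.nongrowing

    def test_noisy_recovery_within_five_percent(self):
        rng = np.random.default_rng(123)
        a, b = 2e5, 8e3
        times = np.linspace(0.0, 50.0, 6)
        counts = (a + b * times) * (1 + rng.normal(0.0, 0.02, times.size))
        obs = G.growth_rate_from_counts(times, counts)
        assert obs.rate_per_h == pytest.approx(b / a, rel=0.05)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            G.growth_rate_from_counts([0.0], [1e5])
        with pytest.raises(ValueError):
            G.growth_rate_from_counts([0.0, 0.0], [1e5, 2e5])
        with pytest.raises(ValueError):
            G.growth_rate_from_counts([0.0, 1.0], [1e5, 0.0])
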