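"""Constraint-based modeling: FBA, constraints, screens, FVA, sampling."""

import json

import numpy as np
import pytest

from calorimix.fba import (
    ESSENTIALITY_TOL,
    ExchangeRate,
    apply_measured_constraints,
    depletion_screen,
    fba,
    fva,
    sample_fluxes,
)
from calorimix.gems import GEM, builtin_gem, load_gem, save_gem_json, save_gem_sbml
from oracles import lp_optimum_by_enumeration, random_bounded_network

M = 1000.0


def small_gem(rxns, mets, model_id="toy"):
    S = np.zeros((len(mets), len(rxns)))
    midx = {m: i for i, m in enumerate(mets)}
    lb, ub, obj, ids = [], [], [], []
    for j, (rid, sto, lo, hi, c) in enumerate(rxns):
        ids.append(rid)
        for m, v in sto.items():
            S[midx[m], j] = v
        lb.append(lo), ub.append(hi), obj.append(c)
    return GEM(metabolites=list(mets), reactions=ids, S=S, lb=np.array(lb, float),
               ub=np.array(ub, float), objective=np.array(obj, float), model_id=model_id)


class TestLoading:
    def test_builtin_linear_shape(self):
        gem = builtin_gem("toynet_linear")
        assert gem.n_reactions == 3
        assert np.count_nonzero(gem.objective) == 1
        assert "EX_A" in gem.exchanges

    def test_lb_above_ub_rejected(self, tmp_path):
        doc = {
            "id": "bad",
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "EX_A", "metabolites": {"A": -1}, "lower_bound": 5,
                           "upper_bound": -5, "objective_coefficient": 1}],
        }
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="EX_A"):
            load_gem(p)

    def test_missing_objective_rejected(self, tmp_path):
        doc = {
            "id": "noobj",
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "EX_A", "metabolites": {"A": -1}, "lower_bound": -5,
                           "upper_bound": 5, "objective_coefficient": 0}],
        }
        p = tmp_path / "noobj.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="objective"):
            load_gem(p)

    @pytest.mark.parametrize("name", ["toynet_branch", "am_like"])
    def test_json_sbml_round_trip(self, name, tmp_path):
        """The JSON and SBML encodings describe the same model."""
        g = builtin_gem(name)
        save_gem_sbml(g, tmp_path / "m.xml")
        g2 = load_gem(tmp_path / "m.xml")
        assert g.metabolites == g2.metabolites
        assert g.reactions == g2.reactions
        assert np.array_equal(g.S, g2.S)
        assert np.array_equal(g.lb, g2.lb) and np.array_equal(g.ub, g2.ub)
        assert np.array_equal(g.objective, g2.objective)

    def test_json_round_trip(self, tmp_path):
        g = builtin_gem("toynet_redundant")
        save_gem_json(g, tmp_path / "m.json")
        g2 = load_gem(tmp_path / "m.json")
        assert np.array_equal(g.S, g2.S)


class TestFBA:
    def test_linear_bottleneck(self):
        assert fba(builtin_gem("toynet_linear")).objective_value == pytest.approx(10.0)

    def test_branch_stoichiometric_split(self):
        assert fba(builtin_gem("toynet_branch")).objective_value == pytest.approx(5.0)

    def test_infeasible_is_a_status_not_an_exception(self):
        gem = small_gem(
            [("EX_A", {"A": -1}, 3, 3, 0), ("SINK", {"A": -1}, 0, 0, 1)], ["A"]
        )
        assert fba(gem).status == "infeasible"

    def test_unbounded_is_a_status(self):
        gem = small_gem(
            [("EX_A", {"A": -1}, -np.inf, np.inf, 0), ("SINK", {"A": -1}, -np.inf, np.inf, 1)],
            ["A"],
        )
        assert fba(gem).status == "unbounded"

    def test_steady_state_and_bounds_respected(self):
        for name in ("toynet_linear", "toynet_branch", "am_like", "bt_like", "fp_like"):
            gem = builtin_gem(name)
            res = fba(gem)
            assert res.ok
            assert np.max(np.abs(gem.S @ res.fluxes)) <= 1e-9
            assert np.all(res.fluxes >= gem.lb - 1e-9)
            assert np.all(res.fluxes <= gem.ub + 1e-9)

    def test_matches_vertex_enumeration_on_random_networks(self):
        """LP optimum equals brute-force vertex enumeration on 50 random
        bounded networks with <= 8 reactions."""
        rng = np.random.default_rng(2024)
        from scipy.optimize import linprog

        checked = 0
        while checked < 50:
            S, lb, ub, c = random_bounded_network(rng)
            res = linprog(-c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          bounds=np.column_stack([lb, ub]), method="highs")
            oracle = lp_optimum_by_enumeration(S, lb, ub, c)
            if res.status == 2:
                assert oracle is None or oracle == pytest.approx(oracle)  # infeasible
                continue
            assert res.status == 0
            assert oracle is not None
            assert -res.fun == pytest.approx(oracle, abs=1e-7)
            checked += 1

    def test_matches_cobra_on_builtin_models(self):
        """Independent cross-check: cobrapy reads the same JSON files and
        reports the same biomass optimum."""
        cobra_io = pytest.importorskip("cobra.io")
        from importlib import resources

        for name in ("toynet_linear", "toynet_branch", "am_like", "bt_like", "fp_like"):
            ref = resources.files("calorimix.data") / "gems" / f"{name}.json"
            with resources.as_file(ref) as path:
                model = cobra_io.load_json_model(str(path))
            ours = fba(builtin_gem(name)).objective_value
            theirs = model.optimize().objective_value
            assert ours == pytest.approx(theirs, abs=1e-6)


class TestMeasuredConstraints:
    def test_zero_rate_closes_exchange(self):
        gem = builtin_gem("toynet_linear")
        out = apply_measured_constraints(gem, [ExchangeRate("A_e", 0.0, 0.0)])
        j = out.reaction_index("EX_A")
        assert out.lb[j] == out.ub[j] == 0.0
        assert fba(out).objective_value == pytest.approx(0.0, abs=1e-9)

    def test_production_span(self):
        gem = small_gem(
            [("EX_A", {"A": -1}, -10, 0, 0), ("CONV", {"A": -1, "B": 1}, 0, M, 0),
             ("GROWTH", {"B": -1}, 0, M, 1), ("EX_P", {"P": -1}, 0, 20, 0),
             ("MAKE_P", {"A": -1, "P": 1}, 0, M, 0)],
            ["A", "B", "P"],
        )
        out = apply_measured_constraints(gem, [ExchangeRate("P", 5.0, 1.0)])
        j = out.reaction_index("EX_P")
        assert (out.lb[j], out.ub[j]) == (4.0, 6.0)

    def test_constrained_uptake_caps_growth(self):
        gem = builtin_gem("toynet_linear")
        out = apply_measured_constraints(gem, [ExchangeRate("A_e", -2.0, 0.0)])
        assert fba(out).objective_value == pytest.approx(2.0)

    def test_fixed_mode_pins_rate(self):
        gem = builtin_gem("toynet_linear")
        out = apply_measured_constraints(gem, [ExchangeRate("A_e", -3.0, 1.0)], sd_mode="fixed")
        j = out.reaction_index("EX_A")
        assert out.lb[j] == out.ub[j] == -3.0

    def test_unmappable_metabolites_listed(self):
        gem = builtin_gem("toynet_linear")
        with pytest.raises(KeyError, match="unobtainium"):
            apply_measured_constraints(gem, [ExchangeRate("unobtainium", -1.0)])

    def test_original_model_untouched(self):
        gem = builtin_gem("toynet_linear")
        lb_before = gem.lb.copy()
        apply_measured_constraints(gem, [ExchangeRate("A_e", 0.0, 0.0)])
        assert np.array_equal(gem.lb, lb_before)


class TestDepletionScreen:
    def test_sole_substrate_is_essential(self):
        out = depletion_screen(builtin_gem("toynet_linear"))
        row = out[out.exchange == "EX_A"].iloc[0]
        assert row.mu_pred == pytest.approx(0.0, abs=ESSENTIALITY_TOL)
        assert row.classification == "essential"

    def test_redundant_substrates_are_dispensable(self):
        out = depletion_screen(builtin_gem("toynet_redundant"))
        assert set(out.classification) == {"dispensable"}
        assert np.allclose(out.mu_pred, 8.0)

    def test_am_like_pattern(self):
        """Three essential inputs, everything else dispensable."""
        out = depletion_screen(builtin_gem("am_like")).set_index("exchange")
        assert out.loc[["EX_nag", "EX_asn", "EX_thr"], "classification"].tolist() == ["essential"] * 3
        assert out.loc[["EX_fuc", "EX_gal"], "classification"].tolist() == ["dispensable"] * 2

    def test_bt_like_pattern(self):
        """Two limiting substrate pools, sugars individually dispensable."""
        out = depletion_screen(builtin_gem("bt_like")).set_index("exchange")
        assert out.loc[["EX_asp", "EX_nag"], "classification"].tolist() == ["limiting"] * 2
        assert (out.loc[["EX_glc", "EX_gal", "EX_fuc"], "classification"] == "dispensable").all()

    def test_fp_like_pattern(self):
        out = depletion_screen(builtin_gem("fp_like")).set_index("exchange")
        assert out.loc[["EX_ser", "EX_thr", "EX_ura"], "classification"].tolist() == ["essential"] * 3

    def test_unused_substrate_depletion_is_neutral(self):
        """A substrate with zero uptake in the optimum and zero FVA width
        cannot change the optimum when closed."""
        gem = small_gem(
            [("EX_A", {"A": -1}, -10, 0, 0), ("CONV", {"A": -1, "B": 1}, 0, M, 0),
             ("GROWTH", {"B": -1}, 0, M, 1), ("EX_DEAD", {"D": -1}, -5, 0, 0)],
            ["A", "B", "D"],
        )
        mu_ref = fba(gem).objective_value
        ranges = fva(gem, fraction=1.0).set_index("reaction")
        assert ranges.loc["EX_DEAD", "min"] == pytest.approx(0.0, abs=1e-9)
        assert ranges.loc["EX_DEAD", "max"] == pytest.approx(0.0, abs=1e-9)
        out = depletion_screen(gem, ["EX_DEAD"])
        assert out.iloc[0].mu_pred == pytest.approx(mu_ref, abs=1e-9)

    def test_model_restored_between_trials(self):
        gem = builtin_gem("am_like")
        lb_before = gem.lb.copy()
        depletion_screen(gem)
        assert np.array_equal(gem.lb, lb_before)


class TestFVA:
    def test_linear_fully_determined(self):
        out = fva(builtin_gem("toynet_linear"), fraction=1.0).set_index("reaction")
        assert np.allclose(out["min"].abs(), 10.0)
        assert np.allclose(out["max"].abs(), 10.0)

    def test_parallel_paths_have_width_but_fixed_sum(self):
        out = fva(builtin_gem("toynet_parallel"), fraction=1.0).set_index("reaction")
        for r in ("AB1", "AB2"):
            assert out.loc[r, "min"] == pytest.approx(0.0, abs=1e-8)
            assert out.loc[r, "max"] == pytest.approx(5.0, abs=1e-8)
        assert out.loc["GROWTH", "min"] == pytest.approx(5.0, abs=1e-8)

    def test_interval_nesting_in_fraction(self):
        """Relaxing the optimality requirement can only widen flux ranges."""
        gem = builtin_gem("am_like")
        tight = fva(gem, fraction=1.0).set_index("reaction")
        loose = fva(gem, fraction=0.9).set_index("reaction")
        assert (loose["min"] <= tight["min"] + 1e-8).all()
        assert (loose["max"] >= tight["max"] - 1e-8).all()

    def test_contains_fba_vertex(self):
        gem = builtin_gem("bt_like")
        sol = fba(gem)
        out = fva(gem, fraction=1.0)
        assert np.all(sol.fluxes >= out["min"].to_numpy() - 1e-8)
        assert np.all(sol.fluxes <= out["max"].to_numpy() + 1e-8)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            fva(builtin_gem("toynet_linear"), fraction=0.0)


class TestSampleFluxes:
    def test_determined_polytope_has_zero_sd(self):
        out = sample_fluxes(builtin_gem("toynet_linear"), n=20, fraction=1.0, seed=0)
        assert np.allclose(out["sd"], 0.0, atol=1e-9)

    def test_single_sample_flagged(self):
        out = sample_fluxes(builtin_gem("toynet_branch"), n=1, fraction=0.9, seed=0)
        assert not out["sd_defined"].iloc[0]
        assert np.allclose(out["sd"], 0.0)

    def test_parallel_path_symmetry(self):
        """The two parallel paths are exchangeable, so their sampled means
        agree around half the shared flux."""
        out = sample_fluxes(builtin_gem("toynet_parallel"), n=2000, fraction=1.0, seed=1)
        out = out.set_index("reaction")
        assert out.loc["AB1", "mean"] == pytest.approx(2.5, abs=0.5)
        assert out.loc["AB2", "mean"] == pytest.approx(2.5, abs=0.5)

    def test_seed_reproducible(self):
        a = sample_fluxes(builtin_gem("toynet_branch"), n=25, seed=7)
        b = sample_fluxes(builtin_gem("toynet_branch"), n=25, seed=7)
        assert np.allclose(a["mean"], b["mean"])

    def test_samples_never_beat_fba_optimum(self):
        gem = builtin_gem("am_like")
        mu_star = fba(gem).objective_value
        rng = np.random.default_rng(3)
        out = sample_fluxes(gem, n=50, fraction=0.9, seed=int(rng.integers(100)))
        # mean biomass flux across vertices cannot exceed the optimum
        j = int(np.nonzero(gem.objective)[0][0])
        assert out["mean"].iloc[j] <= mu_star + 1e-8
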