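"""Consumer-resource simulator: kinetics, passaging, sampling, noise."""

import numpy as np

import pytest
from scipy import stats

from calorimix.calorimetry import HeatFlowSeries
from calorimix.params import AdaptationSchedule, CommunityParams, StrainParams
from calorimix.simulate import (
    add_measurement_noise,
    endpoint_metabolites,
    sample_reads,
    simulate_batch,
    simulate_serial_passages,
)


def strain(name="A", mu=0.5, sub="glc", K=0.01, yx=0.01, **kw):
    return StrainParams(name=name, mu_max={sub: mu}, K={sub: K}, yield_X={sub: yx}, **kw)


def community(strains, substrates, biomass, **kw):
    return CommunityParams(strains=strains, substrates=substrates, initial_biomass=biomass, **kw)


class TestBatchKinetics:
    def test_exponential_limit_heat_flow_slope(self):
        """With S >> K the Monod model reduces to exponential growth and the
        log heat-flow slope equals mu_max."""
        comm = community([strain(mu=0.5)], {"glc": 50.0}, {"A": 1e-4})
        res = simulate_batch(comm, duration=10, dt=0.01)
        mask = (res.time >= 1) & (res.time <= 8)
        slope = stats.linregress(res.time[mask], np.log(res.total_heat_flow[mask])).slope
        assert slope == pytest.approx(0.5, abs=0.01)

    def test_no_substrate_no_growth_no_heat(self):
        comm = community([strain()], {"glc": 0.0}, {"A": 1e-3})
        res = simulate_batch(comm, duration=5, dt=0.05)
        assert np.allclose(res.biomass[0], 1e-3)
        assert np.all(res.total_heat_flow == 0)

    def test_disjoint_strains_superpose(self):
        """Strains on disjoint substrates don't interact: community heat flow
        equals the sum of the two monoculture simulations."""
        a = strain("A", 0.6, "s1")
        b = strain("B", 0.3, "s2")
        # duration chosen so neither substrate is exhausted: the exhaustion
        # collapse is stiff and its exact timing is integrator-noise limited
        subs = {"s1": 5.0, "s2": 5.0}
        both = simulate_batch(community([a, b], subs, {"A": 1e-3, "B": 2e-3}), 6, 0.02, rtol=1e-11)
        only_a = simulate_batch(community([a], subs, {"A": 1e-3}), 6, 0.02, rtol=1e-11)
        only_b = simulate_batch(community([b], subs, {"B": 2e-3}), 6, 0.02, rtol=1e-11)
        expected = only_a.total_heat_flow + only_b.total_heat_flow
        assert np.allclose(both.total_heat_flow, expected, rtol=1e-8, atol=0)

    def test_mass_balance(self):
        """Substrate consumed x yield equals biomass produced (single consumer)."""
        comm = community([strain(mu=0.4, yx=0.02)], {"glc": 8.0}, {"A": 1e-3})
        res = simulate_batch(comm, duration=30, dt=0.05)
        consumed = 8.0 - res.concentration("glc")[-1]
        gained = res.biomass[0, -1] - res.biomass[0, 0]
        assert gained == pytest.approx(consumed * 0.02, rel=1e-4)

    def test_heat_biomass_linearity_exact(self):
        comm = community([strain(heat_yield=15000.0)], {"glc": 5.0}, {"A": 1e-3},
                         ampoule_volume_L=0.002)
        res = simulate_batch(comm, duration=15, dt=0.05)
        expected = 15000.0 * (res.biomass[0] - res.biomass[0, 0]) * 0.002
        assert np.allclose(res.cumulative_heat[0], expected, rtol=1e-6)

    def test_total_heat_flow_is_sum_of_strains(self):
        a, b = strain("A", 0.6, "s1"), strain("B", 0.3, "s2")
        res = simulate_batch(community([a, b], {"s1": 3.0, "s2": 3.0}, {"A": 1e-3, "B": 1e-3}), 8, 0.05)
        assert np.allclose(res.total_heat_flow, res.heat_flow.sum(axis=0))

    def test_cumulative_heat_nondecreasing(self):
        comm = community([strain()], {"glc": 5.0}, {"A": 1e-3})
        res = simulate_batch(comm, duration=20, dt=0.05)
        assert np.all(np.diff(res.total_cumulative_heat) >= -1e-12)

    def test_lag_delays_growth(self):
        comm = community([strain(lag_h=2.0)], {"glc": 5.0}, {"A": 1e-3})
        res = simulate_batch(comm, duration=8, dt=0.05)
        before = res.time < 2.0
        assert np.allclose(res.biomass[0, before], 1e-3)
        assert res.biomass[0, -1] > 1e-3

    def test_bad_arguments(self):
        comm = community([strain()], {"glc": 1.0}, {"A": 1e-3})
        with pytest.raises(ValueError):
            simulate_batch(comm, duration=0)
        with pytest.raises(ValueError):
            simulate_batch(comm, duration=5, dt=0)


class TestSerialPassages:
    def test_transfer_fraction_sets_next_inoculum(self):
        a, b = strain("A", 0.6, "s1"), strain("B", 0.3, "s2")
        comm = community([a, b], {"s1": 5.0, "s2": 10.0}, {"A": 1e-3, "B": 1e-3})
        runs = simulate_serial_passages(comm, 2, duration=30, dt=0.05)
        end = runs[0].final_biomass()
        start_next = {n: runs[1].biomass[i, 0] for i, n in enumerate(runs[1].strain_names)}
        for n in end:
            assert start_next[n] == pytest.approx(0.01 * end[n], rel=1e-9)

    def test_per_strain_dilution_applies_at_passage_one_only(self):
        a, b = strain("A", 0.6, "s1"), strain("B", 0.3, "s2")
        comm = community([a, b], {"s1": 5.0, "s2": 10.0}, {"A": 1e-3, "B": 1e-3})
        runs = simulate_serial_passages(comm, 2, per_strain_dilution={"A": 0.01}, duration=30, dt=0.05)
        assert runs[0].biomass[0, 0] == pytest.approx(1e-5)
        assert runs[0].biomass[1, 0] == pytest.approx(1e-3)
        # passage 2 inoculum follows the 1% transfer rule, not the dilution
        assert runs[1].biomass[0, 0] == pytest.approx(0.01 * runs[0].biomass[0, -1], rel=1e-9)

    def test_fixed_point_composition_without_drift(self):
        """With identical parameters each passage, the endpoint composition
        reaches a fixed point.  The 1% inoculum carry-over contracts deviations
        by x0.01 per passage, so fractions agree to 1e-6 from passage 3 on."""
        a, b = strain("A", 0.6, "s1"), strain("B", 0.3, "s2")
        comm = community([a, b], {"s1": 5.0, "s2": 10.0}, {"A": 5e-4, "B": 5e-4})
        runs = simulate_serial_passages(comm, 5, duration=40, dt=0.05)
        fracs = [r.final_fractions() for r in runs]
        for later in fracs[3:]:
            for n in later:
                assert later[n] == pytest.approx(fracs[2][n], rel=1e-6)

    def test_composition_distance_contracts(self, consortium_run):
        """Composition distance between consecutive passage endpoints is
        non-increasing after the first passage (convergence to fixed point)."""
        fracs = [np.array(list(r.final_fractions().values())) for r in consortium_run]
        dists = [np.abs(a - b).max() for a, b in zip(fracs[:-1], fracs[1:])]
        for d1, d2 in zip(dists[:-1], dists[1:]):
            assert d2 <= d1 + 1e-9

    def test_invalid_passage_count(self):
        comm = community([strain()], {"glc": 1.0}, {"A": 1e-3})
        with pytest.raises(ValueError):
            simulate_serial_passages(comm, 0)
        with pytest.raises(ValueError):
            simulate_serial_passages(comm, 2, per_strain_dilution={"nope": 0.1})


class TestAdaptation:
    def test_converges_within_one_percent_at_convergence_passage(self):
        sched = AdaptationSchedule(mu_multiplier={"A": 0.5}, convergence_passage=4)
        s = strain(mu=1.0)
        at_conv = sched.apply(s, 4).mu_max["glc"]
        assert abs(at_conv - 1.0) <= 0.01 * 0.5 + 1e-12
        # and the drift is monotone toward the asymptote
        vals = [sched.apply(s, p).mu_max["glc"] for p in range(1, 8)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(0.5)


class TestSampling:
    def test_pure_strain_gets_all_reads(self):
        reads = sample_reads([1.0, 0.0, 0.0], [3, 5, 6], 1000, seed=1)
        assert list(reads) == [1000, 0, 0]

    def test_copy_number_bias_matches_expectation(self):
        """Equal biomass with copies (3,5,6) gives read proportions 3/14, 5/14,
        6/14 in the large-depth limit."""
        reads = sample_reads([1 / 3] * 3, [3, 5, 6], 10**6, seed=2)
        props = reads / reads.sum()
        assert np.allclose(props, np.array([3, 5, 6]) / 14, atol=0.01)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sample_reads([-0.1, 1.1], [3, 5], 100, seed=0)
        with pytest.raises(ValueError):
            sample_reads([0.5, 0.4], [3, 5], 100, seed=0)  # doesn't sum to 1
        with pytest.raises(ValueError):
            sample_reads([0.5, 0.5], [0, 5], 100, seed=0)


class TestEndpointMetabolites:
    def test_noiseless_replicates_equal_trajectory_endpoints(self):
        comm = community([strain()], {"glc": 5.0}, {"A": 1e-3})
        res = simulate_batch(comm, duration=20, dt=0.05)
        tbl = endpoint_metabolites(res, noise_sd=0.0, n_replicates=3, seed=0)
        ends = tbl[(tbl.metabolite == "glc") & (tbl.timepoint == "end")]["conc_mM"]
        assert len(ends) == 3
        assert np.allclose(ends, res.concentration("glc")[-1])

    def test_product_stoichiometry(self):
        """2 mmol product per mmol substrate: consuming 5 mmol/L makes 10."""
        s = StrainParams(name="A", mu_max={"glc": 0.5}, K={"glc": 0.001},
                         yield_X={"glc": 0.01}, yield_P={"glc": {"ace": 2.0}})
        comm = community([s], {"glc": 5.0}, {"A": 1e-3})
        res = simulate_batch(comm, duration=40, dt=0.05)
        assert res.concentration("glc")[-1] == pytest.approx(0.0, abs=1e-6)
        tbl = endpoint_metabolites(res, 0.0, 1, seed=0)
        piv = tbl.pivot_table(index="metabolite", columns="timepoint", values="conc_mM")
        assert piv.loc["ace", "end"] - piv.loc["ace", "start"] == pytest.approx(10.0, rel=1e-4)

    def test_noise_truncated_at_zero(self):
        comm = community([strain()], {"glc": 0.01}, {"A": 1e-3})
        res = simulate_batch(comm, duration=5, dt=0.05)
        tbl = endpoint_metabolites(res, noise_sd=5.0, n_replicates=50, seed=3)
        assert (tbl["conc_mM"] >= 0).all()


class TestMeasurementNoise:
    def series(self):
        t = np.linspace(0, 10, 101)
        return HeatFlowSeries(time=t, power=np.exp(0.3 * t) * 1e-6)

    def test_zero_noise_identity(self):
        s = self.series()
        out = add_measurement_noise(s, sd=0.0, drift=0.0, seed=0)
        assert np.array_equal(out.power, s.power)

    def test_drift_adds_linear_baseline(self):
        s = self.series()
        out = add_measurement_noise(s, sd=0.0, drift=2e-7, seed=0)
        assert np.allclose(out.power - s.power, 2e-7 * s.time)

    def test_seed_reproducible_and_original_untouched(self):
        s = self.series()
        before = s.power.copy()
        a = add_measurement_noise(s, sd=1e-6, seed=42)
        b = add_measurement_noise(s, sd=1e-6, seed=42)
        assert np.array_equal(a.power, b.power)
        assert np.array_equal(s.power, before)
        assert not np.array_equal(a.power, s.power)


class TestParamValidation:
    def test_strain_invariants(self):
        with pytest.raises(ValueError):
            StrainParams(name="x", mu_max={"s": 0.0}, K={"s": 1}, yield_X={"s": 1})
        with pytest.raises(ValueError):
            StrainParams(name="x", mu_max={"s": 0.5}, K={}, yield_X={"s": 1})
        with pytest.raises(ValueError):
            strain(copy_number=0)
        with pytest.raises(ValueError):
            strain(lag_h=-1)

    def test_community_invariants(self):
        with pytest.raises(ValueError):
            community([strain()], {"glc": 1.0}, {"A": 1e-3}, transfer_fraction=1.5)
        with pytest.raises(ValueError):
            community([strain(), strain()], {"glc": 1.0}, {"A": 1e-3})
        with pytest.raises(ValueError):
            community([strain()], {"glc": -1.0}, {"A": 1e-3})
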