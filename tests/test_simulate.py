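"""Kinetics, steady states, time-courses and peak computation."""

import numpy as np
import pytest

from glycoforge.model import GolgiModel, default_model
from glycoforge.network import PEAK_IDS, PeakTable, generate_network
from glycoforge.rules import ENZYMES
from glycoforge.simulate import (CompiledModel, compartment_rhs, compute_peaks,
                                 reaction_rate, simulate_sequential,
                                 simulate_timecourse,
                                 solve_compartment_steady_state)

ZERO_TOTALS = {e: 0.0 for e in ENZYMES}


class TestReactionRate:
    def test_zero_substrate_gives_zero_rate(self):
        assert reaction_rate(0.0, 1.0, 5.0, 100.0, [(0.0, 100.0)]) == 0.0

    def test_single_substrate_reduces_to_michaelis_menten(self):
        # C = Km, U = 1 uM, kf = 1/min -> v = 0.5 uM/min
        v = reaction_rate(100.0, 1.0, 1.0, 100.0, [(100.0, 100.0)])
        assert v == pytest.approx(0.5, abs=0.0)
        # general MM identity to machine precision
        for c in (1.0, 37.0, 250.0, 1e4):
            v = reaction_rate(c, 2.0, 3.0, 150.0, [(c, 150.0)])
            assert v == pytest.approx(3.0 * 2.0 * c / (150.0 + c), rel=1e-15)

    def test_two_equal_competitors_split_capacity(self):
        # each at its Km: v = 1*1*1 / (1 + 1 + 1) = 1/3
        v = reaction_rate(50.0, 1.0, 1.0, 50.0, [(50.0, 50.0), (80.0, 80.0)])
        assert v == pytest.approx(1.0 / 3.0, rel=1e-15)

    def test_rejects_nonpositive_km(self):
        with pytest.raises(ValueError):
            reaction_rate(1.0, 1.0, 1.0, 0.0, [])


class TestCompartmentRhs:
    def test_transport_equilibrium_is_fixed_point(self, compiled):
        state = compiled.model.initial_condition()
        u7 = np.zeros(len(ENZYMES))
        d = compartment_rhs(compiled, state, u7, state)
        assert np.all(d == 0.0)

    def test_pure_inflow_rate(self, compiled, model):
        # empty compartment fed M5 at 1000 uM with tau = 10 min: dM5/dt = 100
        state = np.zeros(compiled.m)
        inflow = model.initial_condition()
        d = compartment_rhs(compiled, state, np.zeros(7), inflow)
        assert d[model.network.index["M5"]] == pytest.approx(100.0)
        assert d.sum() == pytest.approx(100.0)

    def test_reactions_conserve_total_mass(self, compiled, model):
        rng = np.random.default_rng(0)
        u = compiled.compartment_enzymes()
        for _ in range(20):
            c = rng.uniform(0, 50, size=compiled.m)
            nv = compiled.N @ compiled.rates(c, u[:, 2])
            assert nv.sum() == pytest.approx(0.0, abs=1e-10)

    def test_dimension_mismatch_raises(self, compiled):
        with pytest.raises(ValueError):
            compartment_rhs(compiled, np.zeros(3), np.zeros(7),
                            np.zeros(compiled.m))


class TestSteadyState:
    def test_zero_enzymes_returns_inflow_exactly(self, compiled, model):
        inflow = model.initial_condition()
        c = solve_compartment_steady_state(compiled, inflow, np.zeros(7))
        assert np.array_equal(c, inflow)

    def test_total_concentration_conserved(self, compiled):
        rng = np.random.default_rng(1)
        u = compiled.compartment_enzymes(
            {e: rng.uniform(0.05, 1.0) for e in ENZYMES})
        inflow = compiled.model.initial_condition()
        c = solve_compartment_steady_state(compiled, inflow, u[:, 0])
        assert c.sum() == pytest.approx(inflow.sum(), rel=1e-9)

    def test_two_species_toy_matches_long_time_integration(self):
        """Single GnT I reaction: algebraic root vs t -> 1e4 min ODE."""
        from scipy.integrate import solve_ivp

        net = generate_network(whitelist=["M5", "M5A1"])
        peaks = {p: () for p in PEAK_IDS}
        peaks["GP5"] = ("M5",)
        model = default_model()
        toy = GolgiModel(
            network=net, peaks=PeakTable(peaks, net),
            kinetics=model.kinetics, distribution=model.distribution,
            totals=model.totals)
        cm = CompiledModel(toy)
        u = cm.compartment_enzymes()[:, 0]
        inflow = toy.initial_condition()
        chat = solve_compartment_steady_state(cm, inflow, u)
        sol = solve_ivp(lambda t, y: cm.rhs(y, u, inflow), (0, 1e4), inflow,
                        method="BDF", rtol=1e-12, atol=1e-12)
        assert chat == pytest.approx(sol.y[:, -1], abs=1e-6)

    def test_negative_inflow_rejected(self, compiled):
        bad = np.full(compiled.m, -1.0)
        with pytest.raises(ValueError):
            solve_compartment_steady_state(compiled, bad, np.zeros(7))


class TestSequentialSimulation:
    def test_zero_enzymes_pass_input_through(self, compiled, model):
        res = simulate_sequential(compiled, ZERO_TOTALS)
        assert np.array_equal(res.c4, model.initial_condition())

    def test_every_compartment_holds_1000_um(self, median_result):
        assert median_result.compartments.sum(axis=1) == pytest.approx(
            [1000.0] * 4, rel=1e-9)

    def test_default_profile_is_realistic_igg(self, median_result):
        gp = median_result.gp_series()
        # fucosylated agalacto/mono/di-galacto peaks dominate the chromatogram
        assert gp.idxmax() in ("GP4", "GP8")
        assert gp[["GP4", "GP8", "GP14"]].sum() > 50.0
        assert 96.5 <= gp.sum() <= 100.0

    def test_galactosylation_monotonicity_at_median(self, compiled, model):
        """More GalT cannot lower the digalactosylated product peak (GP14)
        or raise its substrate peak (GP4)."""
        lo = simulate_sequential(compiled, {"GalT": model.totals["GalT"]})
        hi = simulate_sequential(compiled, {"GalT": model.totals["GalT"] * 1.5})
        ids = list(model.peaks.peak_ids)
        assert hi.gp[ids.index("GP14")] >= lo.gp[ids.index("GP14")]
        assert hi.gp[ids.index("GP4")] <= lo.gp[ids.index("GP4")]


class TestTimecourse:
    def test_zero_enzyme_relaxation_follows_closed_form(self, compiled, model):
        tc = simulate_timecourse(compiled, ZERO_TOTALS, phase_length=50.0)
        i = model.network.index["M5"]
        t = tc["t"][:101]
        # state starts at the inflow bolus, so it stays there without enzymes
        assert tc["c"][i, :101] == pytest.approx(np.full(101, 1000.0), abs=1e-6)

    def test_relaxation_efolding_from_empty_state(self, compiled, model):
        """An empty compartment fed a constant inflow fills as 1 - e^(-t/tau)."""
        from scipy.integrate import solve_ivp

        inflow = model.initial_condition()
        u7 = np.zeros(7)
        sol = solve_ivp(lambda t, y: compiled.rhs(y, u7, inflow), (0, 100),
                        np.zeros(compiled.m), method="BDF",
                        t_eval=np.linspace(0, 100, 51), rtol=1e-10, atol=1e-12)
        i = model.network.index["M5"]
        analytic = 1000.0 * (1.0 - np.exp(-sol.t / model.tau))
        assert sol.y[i] == pytest.approx(analytic, abs=1e-4)

    def test_matches_sequential_steady_states(self, compiled, median_result):
        tc = simulate_timecourse(compiled)
        diff = np.abs(tc["phase_ends"] - median_result.compartments).max()
        # 100 min = 10 e-folding times bounds phase truncation by ~e^-10
        assert diff / 1000.0 < 1e-4


class TestComputePeaks:
    def test_all_mass_in_fa2_is_pure_gp4(self, model):
        c4 = np.zeros(model.network.n_species)
        c4[model.network.index["FA2"]] = 500.0
        gp, gp_peaks, gp_all = compute_peaks(c4, model.peaks)
        ids = list(model.peaks.peak_ids)
        assert gp[ids.index("GP4")] == pytest.approx(100.0)
        assert np.delete(gp, ids.index("GP4")).sum() == 0.0
        assert gp_peaks == gp_all == 500.0

    def test_peak_sum_equals_coverage_share(self, model):
        rng = np.random.default_rng(3)
        c4 = rng.uniform(0, 10, model.network.n_species)
        gp, gp_peaks, gp_all = compute_peaks(c4, model.peaks)
        assert gp.sum() == pytest.approx(100.0 * gp_peaks / gp_all, rel=1e-12)

    def test_all_zero_state_rejected(self, model):
        with pytest.raises(ValueError):
            compute_peaks(np.zeros(model.network.n_species), model.peaks)
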