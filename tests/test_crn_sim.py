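"""Reactor-network simulator: kinetics, CSTR physics, and sampling."""

import dataclasses

import numpy as np
import pytest

from formose_dyn import io_cli, timescale_corr
from formose_dyn.crn_sim import (
    IntegrationError,
    ModelError,
    NetworkModel,
    Reaction,
    Species,
    TraceSet,
    build_formose_model,
    effective_rate,
    sample_outlet,
    simulate_cstr,
)
from formose_dyn.flow_program import sample_step_signal, program_flows

TAU = 120.0


def _flows_constant(ca=15.0, duration=9000.0):
    return program_flows(sample_step_signal(ca, 0, duration / 2, duration))


class TestEffectiveRate:
    @pytest.mark.parametrize("k,ca,s,ref,expected", [
        (1.0, 15.0, 3.0, 15.0, 1.0),    # reference point
        (2.0, 30.0, 1.0, 15.0, 4.0),    # linear doubling
        (1.0, 7.5, 2.0, 15.0, 0.25),    # power-law evaluation
        (5.0, 0.0, 2.0, 15.0, 0.0),     # zero catalyst shuts a gated step
        (5.0, 0.0, 0.0, 15.0, 5.0),     # insensitive step unaffected
    ])
    def test_power_law(self, k, ca, s, ref, expected):
        assert effective_rate(k, ca, s, ref) == pytest.approx(expected)

    def test_invalid_arguments(self):
        with pytest.raises(ModelError):
            effective_rate(1.0, -1.0, 1.0, 15.0)
        with pytest.raises(ModelError):
            effective_rate(1.0, 1.0, 1.0, 0.0)


class TestModel:
    def test_default_model_structure(self, default_model):
        labels = {s.module_label for s in default_model.species
                  if s.module_label != "none"}
        assert labels == {"core", "II", "III", "IV", "V"}
        assert len(default_model.measured_ids) == 28
        gated = [r for r in default_model.reactions if r.catalyst_sensitivity > 0]
        assert len(gated) >= 4

    def test_carbon_conservation_is_enforced(self):
        with pytest.raises(ModelError, match="carbon"):
            NetworkModel(
                species=[Species("A", 2, "core"), Species("B", 3, "II"),
                         Species("CA", 0, "none", intermediate=True)],
                reactions=[Reaction("bad", (("A", 1),), (("B", 1),), 1.0)],
            )

    def test_negative_sensitivity_rejected(self):
        with pytest.raises(ModelError):
            build_formose_model({"sensitivities": {"IV": -1.0}})
        with pytest.raises(ModelError):
            build_formose_model({"sensitivities": {"nope": 1.0}})
        with pytest.raises(ModelError):
            build_formose_model({"rates": {"nope": 1.0}})

    def test_disconnected_branches(self):
        """Zeroing the five gating rates leaves only the engine running."""
        gates = ["dim_G2", "ald_G2_G3", "ald_Pb2_G2", "dim_C1",
                 "ald_Pw1_DHA", "ald_Pw2_DHA"]
        model = build_formose_model({"rates": {g: 0.0 for g in gates}})
        flows = _flows_constant()
        sim = simulate_cstr(model, flows, (0.0, 2400.0))
        final = dict(zip([s.id for s in model.species], sim.concentrations[:, -1]))
        for sid in model.measured_ids:
            assert final[sid] < 1e-9, sid
        assert final["G2"] > 0.01 and final["G3"] > 0.01

    def test_model_round_trips_through_json(self, default_model, tmp_path):
        path = tmp_path / "model.json"
        default_model.save(path)
        loaded = NetworkModel.load(path)
        assert loaded.to_dict() == default_model.to_dict()


class TestCstrPhysics:
    def test_washout_to_steady_state_closed_form(self):
        """No reactions: C(t) = C_in (1 - exp(-t/tau))."""
        model = NetworkModel(
            species=[Species("C1", 1), Species("CA", 0, intermediate=True)],
            reactions=[],
        )
        flows = _flows_constant()
        sim = simulate_cstr(model, flows, (0.0, 400.0),
                            t_eval=np.array([0.0, 120.0, 240.0, 360.0]),
                            rtol=1e-10, atol=1e-12)
        c1 = sim.trace("C1")
        for i, t in enumerate((120.0, 240.0, 360.0), start=1):
            expected = 50.0 * (1 - np.exp(-t / TAU))
            assert abs(c1[i] - expected) < 1e-6 * expected

    def test_exponential_washout_of_initial_charge(self):
        model = NetworkModel(
            species=[Species("X", 1), Species("CA", 0, intermediate=True)],
            reactions=[],
        )
        flows = _flows_constant()
        sim = simulate_cstr(model, flows, (0.0, 400.0),
                            t_eval=np.array([120.0, 240.0]),
                            initial={"X": 5.0}, rtol=1e-10, atol=1e-12)
        np.testing.assert_allclose(
            sim.trace("X"), 5.0 * np.exp(-np.array([120.0, 240.0]) / TAU),
            rtol=1e-6)

    def test_two_species_model_matches_euler_oracle(self):
        """A -> B at k = 0.01/s with A fed; fixed-step explicit Euler oracle."""
        k = 0.01
        model = NetworkModel(
            species=[Species("C1", 1), Species("B", 1),
                     Species("CA", 0, intermediate=True)],
            reactions=[Reaction("conv", (("C1", 1),), (("B", 1),), k)],
        )
        flows = _flows_constant()
        t_eval = np.arange(60.0, 601.0, 60.0)
        sim = simulate_cstr(model, flows, (0.0, 600.0), t_eval=t_eval,
                            rtol=1e-10, atol=1e-12)

        dt = 1e-3
        a = b = 0.0
        euler_a, euler_b = [], []
        checkpoints = set(np.round(t_eval / dt).astype(int))
        for i in range(1, int(600 / dt) + 1):
            a += dt * ((50.0 - a) / TAU - k * a)
            b += dt * (-b / TAU + k * a)
            if i in checkpoints:
                euler_a.append(a)
                euler_b.append(b)
        np.testing.assert_allclose(sim.trace("C1"), euler_a, rtol=1e-4)
        np.testing.assert_allclose(sim.trace("B"), euler_b, rtol=1e-4)

    def test_constant_input_reaches_algebraic_steady_state(self, default_model):
        from formose_dyn.crn_sim import _CompiledModel

        flows = _flows_constant()
        sim = simulate_cstr(default_model, flows, (0.0, 9000.0),
                            t_eval=np.array([8990.0]), rtol=1e-10, atol=1e-13)
        compiled = _CompiledModel(default_model)
        c_in = np.zeros(len(default_model.species))
        c_in[default_model.index("C1")] = 50.0
        c_in[default_model.index("DHA")] = 50.0
        c_in[compiled.ca_idx] = 15.0
        residual = compiled.rhs(1.0 / TAU, c_in)(0.0, sim.concentrations[:, 0])
        assert np.max(np.abs(residual)) < 1e-8

    def test_flow_program_must_cover_span(self, default_model):
        flows = _flows_constant(duration=600.0)
        with pytest.raises(IntegrationError):
            simulate_cstr(default_model, flows, (0.0, 1200.0))


class TestSampleOutlet:
    def _const_traces(self, value=5.0, n=200, dt=10.0):
        times = np.arange(n) * dt
        return TraceSet(times, np.full((1, n), value), ["X"])

    def test_sampling_grid(self, default_model):
        flows = _flows_constant(duration=4000.0)
        sim = simulate_cstr(default_model, flows, (0.0, 3810.0))
        out = sample_outlet(sim, start=1800.0, interval=40.8, n_samples=50)
        assert out.times.size == 50
        assert out.times[-1] == pytest.approx(1800 + 49 * 40.8)

    def test_noiseless_sampling_interpolates(self):
        times = np.arange(0, 100.0, 1.0)
        tr = TraceSet(times, times[None, :] * 0.1, ["X"])
        out = sample_outlet(tr, start=10.0, interval=7.5, n_samples=5)
        np.testing.assert_allclose(out.trace("X"),
                                   0.1 * (10.0 + 7.5 * np.arange(5)))

    def test_noise_cv_recovered(self):
        tr = self._const_traces(n=10_000, dt=1.0)
        out = sample_outlet(tr, 0.0, 1.0, 10_000, noise_cv=0.05, seed=1)
        x = out.trace("X")
        cv = x.std() / x.mean()
        assert abs(cv - 0.05) < 0.05 * 0.05

    def test_range_error(self):
        tr = self._const_traces()
        with pytest.raises(ValueError):
            sample_outlet(tr, 1000.0, 40.8, 50)

    def test_reproducible_given_seed(self):
        tr = self._const_traces()
        a = sample_outlet(tr, 0.0, 10.0, 100, noise_cv=0.03, seed=9)
        b = sample_outlet(tr, 0.0, 10.0, 100, noise_cv=0.03, seed=9)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)


class TestTransferProperties:
    def test_low_pass_attenuation_orders_input_timescales(self, default_model):
        """Slower input steps transfer with larger relative amplitude."""
        cfg = io_cli.preset("EXP013")
        ratios = {}
        for rate in (30.0, 60.0, 120.0):
            cc = dataclasses.replace(
                cfg, step_rate_s=rate,
                sampling=io_cli.SamplingBlock(1800.0, 30.6, 100))
            flows, sampled = io_cli.simulate_condition(
                cc, seed=5, model=default_model, noise_cv=0.0)
            inp = timescale_corr.resample_to(flows.ca_inlet, sampled.times)
            for cid in ("W9", "Q4"):
                tr = sampled.trace(cid)
                ratios.setdefault(cid, {})[rate] = (
                    (tr.std() / tr.mean()) / (inp.std() / inp.mean()))
        for cid, r in ratios.items():
            assert r[30.0] <= r[60.0] <= r[120.0], (cid, r)

    def test_branch_variance_increases_with_sensitivity(self):
        cfg = io_cli.preset("EXP013")
        variances = []
        for s in (1.0, 2.0, 3.0):
            model = build_formose_model({"sensitivities": {"V": s}})
            _, sampled = io_cli.simulate_condition(cfg, seed=7, model=model,
                                                   noise_cv=0.0)
            variances.append(sampled.trace("W9").var())
        assert variances[0] < variances[1] < variances[2]

    def test_simulation_reproducible(self, default_model):
        cfg = io_cli.preset("EXP002")
        _, a = io_cli.simulate_condition(cfg, seed=4, model=default_model)
        _, b = io_cli.simulate_condition(cfg, seed=4, model=default_model)
        np.testing.assert_array_equal(a.concentrations, b.concentrations)
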