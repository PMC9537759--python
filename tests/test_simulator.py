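"""Hybrid integrator: closed-form agreement, conservation, schedules."""

import numpy as np
import pytest

import hepaflux.fixtures as fx
from hepaflux.document import MetaboliteSpec, ModelDocument, ReactionSpec
from hepaflux.ratelaws import RateLaw
from hepaflux.simulator import (
    BoundaryConditions,
    PiecewiseConstant,
    SimulationError,
    simulate,
)


class TestLinearChainAgainstMatrixExponential:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_endpoint_matches_analytic(self, seed):
        toy = fx.make_linear_chain(4, seed=seed)
        res = simulate(toy.document, horizon=3.0, step=1e-3)
        expected = toy.analytic(3.0)
        got = res.concentrations[-1]
        assert np.max(np.abs(got - expected)) < 1e-6

    def test_whole_trajectory_matches_analytic(self):
        toy = fx.make_linear_chain(3, [2.0, 0.7], x0=[1.0, 0.2, 0.0])
        res = simulate(toy.document, horizon=2.0, step=1e-3, record_interval=0.1)
        for t, x in zip(res.time, res.concentrations):
            assert np.max(np.abs(x - toy.analytic(t))) < 1e-6

    def test_step_halving_convergence(self):
        toy = fx.make_linear_chain(4, seed=7)
        end_h = simulate(toy.document, horizon=2.0, step=2e-3).concentrations[-1]
        end_h2 = simulate(toy.document, horizon=2.0, step=1e-3).concentrations[-1]
        denom = np.maximum(np.abs(end_h2), 1e-12)
        assert np.max(np.abs(end_h - end_h2) / denom) < 1e-4

    def test_mass_conservation(self):
        toy = fx.make_linear_chain(5, seed=3)
        res = simulate(toy.document, horizon=5.0, step=1e-3)
        totals = res.concentrations.sum(axis=1)
        assert np.max(np.abs(totals - totals[0])) < 1e-6


class TestHybridStaticCoupling:
    def test_branch_split_fluxes_recorded(self):
        toy = fx.make_branch_mfa(input_flux=2.0)
        res = simulate(toy.document, horizon=1.0, step=1e-3)
        assert res.flux("b1")[-1] == pytest.approx(1.0, abs=1e-9)
        assert res.flux("out")[-1] == pytest.approx(2.0, abs=1e-9)
        # consistent static system: species stay put, residual ~ 0
        assert np.max(res.residual_trace) < 1e-9

    def test_fixed_point_stays_fixed(self):
        # reversible A <-> B initialised at equilibrium (keq = 1, equal conc)
        doc = ModelDocument(
            [MetaboliteSpec("a", initial=1.0), MetaboliteSpec("b", initial=1.0)],
            [ReactionSpec(
                "r", {"a": -1, "b": 1}, "dynamic", "iso",
                RateLaw("reversible_michaelis_menten",
                        {"Vmax": 3.0, "keq": 1.0, "Km_a": 0.5, "Km_b": 0.5},
                        ("a",), ("b",)),
            )],
        )
        res = simulate(doc, horizon=2.0, step=1e-3)
        assert np.max(np.abs(res.concentrations - 1.0)) < 1e-8

    def test_conserved_moiety_drift_in_hybrid_network(self):
        # closed loop A ->(dyn) B ->(static) C ->(static) A conserves A+B+C
        doc = ModelDocument(
            [MetaboliteSpec("a", initial=2.0), MetaboliteSpec("b", initial=0.5),
             MetaboliteSpec("c", initial=0.1)],
            [
                ReactionSpec("r1", {"a": -1, "b": 1}, "dynamic", "in",
                             RateLaw("mass_action", {"k": 1.3}, ("a",))),
                ReactionSpec("r2", {"b": -1, "c": 1}, "static"),
                ReactionSpec("r3", {"c": -1, "a": 1}, "static"),
            ],
        )
        res = simulate(doc, horizon=5.0, step=1e-3)
        totals = res.concentrations.sum(axis=1)
        assert np.max(np.abs(totals - totals[0])) < 1e-6


class TestBoundariesAndSchedules:
    def test_breakpoints_hit_exactly(self, reference_doc):
        bc = BoundaryConditions(
            external_glucose=PiecewiseConstant((0.0, 1.25), (11.0, 4.0)),
        )
        res = simulate(reference_doc, "periportal", bc, horizon=2.0, step=1e-3,
                       record_interval=0.25)
        assert 1.25 in res.time
        glc_ext = res.species("glc_ext")
        assert glc_ext[res.time < 1.25].max() == 11.0
        assert glc_ext[res.time > 1.3].min() == 4.0

    def test_boundary_species_not_consumed(self, reference_doc):
        bc = BoundaryConditions(external_glucose=7.0)
        res = simulate(reference_doc, "periportal", bc, horizon=1.0, step=2e-3)
        assert np.all(res.species("glc_ext") == 7.0)
        assert np.all(res.species("lac_ext") == bc.external_lactate)

    def test_zero_horizon_returns_initial_state(self, reference_doc):
        res = simulate(reference_doc, "periportal",
                       BoundaryConditions(external_glucose=4.0), horizon=0.0)
        assert len(res.time) == 1
        assert res.time[0] == 0.0

    def test_dosing_schedule_drives_zero_order_reaction(self, reference_doc):
        bc = BoundaryConditions(
            external_glucose=4.0,
            apap_administration=PiecewiseConstant((0.0, 0.5), (0.5, 0.0)),
        )
        res = simulate(reference_doc, "periportal", bc, horizon=1.0, step=1e-3,
                       record_interval=0.05)
        dose_flux = res.flux("v_APAP_in")
        assert dose_flux[res.time < 0.5].max() == pytest.approx(0.5)
        assert dose_flux[res.time > 0.55].max() == 0.0
        # roughly 0.25 mM delivered, partially metabolised already
        assert 0.05 < res.species("apap")[-1] < 0.25

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            PiecewiseConstant((0.5, 1.0), (1.0, 2.0))  # must start at 0
        with pytest.raises(ValueError):
            PiecewiseConstant((0.0, 1.0, 0.5), (1.0, 2.0, 3.0))

    def test_step_below_minimum_rejected(self, reference_doc):
        with pytest.raises(SimulationError, match="below minimum"):
            simulate(reference_doc, "periportal", horizon=1.0, step=1e-9)


class TestNegativeClamp:
    def test_hard_negative_aborts_with_species_name(self):
        # a zero-order drain on an empty pool forces strongly negative state
        doc = ModelDocument(
            [MetaboliteSpec("a", initial=0.0), MetaboliteSpec("b", initial=0.0)],
            [ReactionSpec("r", {"a": -1, "b": 1}, "dynamic", "drain",
                          RateLaw("zero_order", {"rate": 5.0}))],
        )
        with pytest.raises(SimulationError, match="negative concentration.*a"):
            simulate(doc, horizon=1.0, step=1e-2, clamp_tolerance=1e-3)
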