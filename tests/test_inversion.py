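"""Mass-balance inversion: flow recovery, rates, aggregation, uncertainty."""

import numpy as np
import pytest

import pftrace as pt
from pftrace.inversion import DegenerateMeasurementError, design_matrix, flow_index

from conftest import single_zone_flows


def _measurement_from_flows(flows, tracers, zones, cv=0.0, seed=0):
    scen = pt.SurveyScenario(
        zones=zones, true_flows=flows, tracers=tracers,
        concentration_cv=cv, seed=seed,
    )
    return pt.simulate_survey(scen)


class TestEstimateFlows:
    def test_single_zone_inverse(self):
        zones = pt.ZoneSystem(volumes=np.array([46.0]))
        m = pt.SurveyMeasurement(
            concentrations=pt.ConcentrationMatrix(C=np.array([[20.0]])),
            tracers=(pt.TracerSpec("A", 1, 1000.0),),
            zones=zones,
        )
        est = pt.estimate_flows(m)
        assert est.flows.Q[1, 0] == pytest.approx(50.0, abs=1e-8)
        assert est.flows.Q[0, 1] == pytest.approx(50.0, abs=1e-8)
        assert est.objective == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["nnls", "bounded_quasi_newton"])
    @pytest.mark.parametrize("weighting", ["raw", "normalized"])
    def test_noiseless_round_trip(self, zones3, tracers3, flows3, method, weighting):
        m = _measurement_from_flows(flows3, tracers3, zones3)
        est = pt.estimate_flows(m, method=method, weighting=weighting)
        tol = 1e-6 if method == "nnls" else 1e-3
        assert np.abs(est.flows.Q - flows3.Q).max() < tol
        _, d = design_matrix(m, weighting)
        assert est.objective <= 1e-12 * max(float(d @ d), 1.0)

    def test_nnls_is_exact_oracle_for_quasi_newton(self, zones3, tracers3):
        """The system is linear in Q, so NNLS minimises exactly; the
        quasi-Newton route must land on the same objective."""
        for s in range(10):
            flows = pt.generate_balanced_flows(3, (1.0, 100.0), seed=200 + s)
            m = _measurement_from_flows(flows, tracers3, zones3, cv=0.05, seed=s)
            _, d = design_matrix(m)
            e1 = pt.estimate_flows(m, method="nnls")
            e2 = pt.estimate_flows(m, method="bounded_quasi_newton")
            assert e1.objective <= e2.objective + 1e-9 * max(1.0, e2.objective)
            scale = float(d @ d)
            if max(e1.objective, e2.objective) > 1e-12 * scale:
                assert abs(e1.objective - e2.objective) <= 1e-8 * max(
                    e1.objective, e2.objective
                )

    def test_nonnegativity_always(self, zones3, tracers3):
        for s in range(20):
            flows = pt.generate_balanced_flows(3, (1.0, 100.0), seed=300 + s)
            m = _measurement_from_flows(flows, tracers3, zones3, cv=0.15, seed=s)
            est = pt.estimate_flows(m)
            assert np.all(est.flows.Q >= 0)
            assert np.all(est.per_room_outdoor_ach >= 0)

    def test_objective_invariant_to_zone_permutation(self, zones3, tracers3, flows3):
        """Relabelling zones (and permuting all data consistently) must not
        change the attained objective."""
        m = _measurement_from_flows(flows3, tracers3, zones3, cv=0.08, seed=4)
        base = pt.estimate_flows(m).objective

        perm = [2, 0, 1]  # new zone k holds old zone perm[k]
        zones_p = pt.ZoneSystem(volumes=m.zones.volumes[perm])
        inv = np.argsort(perm)
        tracers_p = tuple(
            pt.TracerSpec(t.tracer_id, int(inv[t.source_zone - 1]) + 1,
                          t.dosing_rate, t.n_dosers)
            for t in m.tracers
        )
        conc_p = pt.ConcentrationMatrix(
            C=m.concentrations.C[:, perm], tracer_ids=m.concentrations.tracer_ids
        )
        m_p = pt.SurveyMeasurement(concentrations=conc_p, tracers=tracers_p,
                                   zones=zones_p)
        assert pt.estimate_flows(m_p).objective == pytest.approx(
            base, rel=1e-8, abs=1e-10
        )

    def test_all_zero_concentrations_is_degenerate(self, zones3, tracers3):
        m = pt.SurveyMeasurement(
            concentrations=pt.ConcentrationMatrix(C=np.zeros((3, 3))),
            tracers=tracers3, zones=zones3,
        )
        with pytest.raises(DegenerateMeasurementError, match="degenerate"):
            pt.estimate_flows(m)

    def test_duplicate_source_zone_rejected(self, zones3):
        tracers = tuple(pt.TracerSpec(f"T{k}", 1, 100.0) for k in range(3))
        with pytest.raises(ValueError, match="exactly one tracer"):
            pt.SurveyMeasurement(
                concentrations=pt.ConcentrationMatrix(C=np.ones((3, 3))),
                tracers=tracers, zones=zones3,
            )


class TestRoomRates:
    def test_unit_outdoor_rate(self):
        zones = pt.ZoneSystem(volumes=np.array([29.04]))
        Q = np.array([[0.0, 29.04], [29.04, 0.0]])
        outdoor, inter = pt.room_air_exchange_rates(pt.FlowMatrix(Q=Q), zones)
        assert outdoor == pytest.approx([1.0])
        assert inter == pytest.approx([0.0])

    def test_dining_kitchen_low_rate(self):
        # 13.2 m² × 2.2 m room at 5.808 m³/h fresh air → 0.2 h⁻¹
        zones = pt.ZoneSystem(volumes=np.array([13.2 * 2.2]))
        Q = np.array([[0.0, 5.808], [5.808, 0.0]])
        outdoor, _ = pt.room_air_exchange_rates(pt.FlowMatrix(Q=Q), zones)
        assert outdoor == pytest.approx([0.2])

    def test_interroom_rate_sums_inflows(self):
        zones = pt.ZoneSystem(volumes=np.array([29.04, 25.0, 25.0]))
        Q = np.zeros((4, 4))
        Q[2, 1], Q[3, 1] = 14.52, 29.04
        Q[1, 0] = Q[2, 0] = Q[3, 0] = 1.0  # keep FlowMatrix sane
        _, inter = pt.room_air_exchange_rates(pt.FlowMatrix(Q=Q), zones)
        assert inter[0] == pytest.approx(1.5)

    def test_dimension_mismatch(self, zones3):
        with pytest.raises(ValueError, match="zones"):
            pt.room_air_exchange_rates(single_zone_flows(), zones3)


class TestAggregateDaily:
    def _estimate_with_rates(self, outdoor, zones3):
        Q = np.zeros((4, 4))
        Q[0, 1:] = np.asarray(outdoor) * zones3.volumes
        Q[1:, 0] = Q[0, 1:]
        flows = pt.FlowMatrix(Q=Q)
        o, i = pt.room_air_exchange_rates(flows, zones3)
        return pt.FlowEstimate(flows=flows, objective=0.0,
                               per_room_outdoor_ach=o, per_room_interroom_ach=i)

    def test_constant_days(self, zones3):
        ests = [self._estimate_with_rates([1.0, 1.0, 1.0], zones3)] * 3
        agg = pt.aggregate_daily(ests)
        assert agg["outdoor_ach_mean"] == pytest.approx([1.0, 1.0, 1.0])
        assert agg["outdoor_ach_sd"] == pytest.approx([0.0, 0.0, 0.0])

    def test_two_days_closed_form(self, zones3):
        ests = [self._estimate_with_rates([0.5] * 3, zones3),
                self._estimate_with_rates([1.5] * 3, zones3)]
        agg = pt.aggregate_daily(ests)
        assert agg["outdoor_ach_mean"][0] == pytest.approx(1.0)
        assert agg["outdoor_ach_sd"][0] == pytest.approx(np.sqrt(0.5), rel=1e-12)

    def test_six_synthetic_days_match_independent_mean_sd(self, zones3, tracers3):
        ests = []
        for day in range(6):
            flows = pt.generate_balanced_flows(3, (1.0, 100.0), seed=500 + day)
            m = _measurement_from_flows(flows, tracers3, zones3, cv=0.05, seed=day)
            ests.append(pt.estimate_flows(m))
        agg = pt.aggregate_daily(ests)
        rates = np.array([e.per_room_outdoor_ach for e in ests])
        # spreadsheet-style oracle: Σx/n and sqrt(Σ(x−mean)²/(n−1))
        mean = rates.sum(axis=0) / 6
        sd = np.sqrt(((rates - mean) ** 2).sum(axis=0) / 5)
        np.testing.assert_allclose(agg["outdoor_ach_mean"], mean, rtol=1e-12)
        np.testing.assert_allclose(agg["outdoor_ach_sd"], sd, rtol=1e-12)

    def test_single_day_sd_is_absent_not_zero(self, zones3):
        agg = pt.aggregate_daily([self._estimate_with_rates([1.0] * 3, zones3)])
        assert agg["outdoor_ach_sd"] is None


class TestPropagateUncertainty:
    def test_zero_cv_gives_point_estimate(self, noiseless_measurement, flows3):
        out = pt.propagate_uncertainty(noiseless_measurement, 0.0, 0.0,
                                       n_draws=100, seed=1)
        lo, med, hi = out["outdoor_ach"]
        np.testing.assert_allclose(lo, hi, rtol=1e-9)
        est = pt.estimate_flows(noiseless_measurement)
        np.testing.assert_allclose(med, est.per_room_outdoor_ach, rtol=1e-6)

    def test_interval_width_grows_with_cv(self, noiseless_measurement):
        widths = []
        for cv in (0.01, 0.05, 0.10):
            out = pt.propagate_uncertainty(noiseless_measurement, cv, 0.0,
                                           n_draws=400, seed=7)
            lo, _, hi = out["outdoor_ach"]
            widths.append(float(np.sum(hi - lo)))
        assert widths[0] < widths[1] < widths[2]

    def test_fixed_seed_reproducible(self, noiseless_measurement):
        a = pt.propagate_uncertainty(noiseless_measurement, 0.05, 0.02,
                                     n_draws=150, seed=42)
        b = pt.propagate_uncertainty(noiseless_measurement, 0.05, 0.02,
                                     n_draws=150, seed=42)
        np.testing.assert_array_equal(a["flows"], b["flows"])
        assert a["n_failed"] == b["n_failed"]


def test_flow_index_covers_all_flows():
    idx = flow_index(3)
    assert len(idx) == 12 == len(set(idx))
    assert all(i != j and (i == 0) + (j == 0) < 2 for i, j in idx)
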