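"""Biomarker extraction and cost-function tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cardioinv.biomarkers import (
    BiomarkerSet, CostSpec, continuation_cost, continuation_targets,
    cost_term, dose_cost, extract_biomarkers, total_cost,
)
from cardioinv.model import Trace


def triangle_trace(t_rise=2.0, t_fall=300.0, v_rest=-80.0, v_peak=40.0,
                   dt=0.1):
    """A triangular AP-like pulse with closed-form level crossings."""
    t_up = np.arange(0.0, t_rise, dt)
    t_down = np.arange(t_rise, t_rise + t_fall, dt)
    t_tail = np.arange(t_rise + t_fall, t_rise + t_fall + 100.0, dt)
    v = np.concatenate([
        v_rest + (v_peak - v_rest) * t_up / t_rise,
        v_peak - (v_peak - v_rest) * (t_down - t_rise) / t_fall,
        np.full(len(t_tail), v_rest),
    ])
    t = np.concatenate([t_up, t_down, t_tail])
    ca = (v - v_rest) / (v_peak - v_rest) * 1e-3 + 1e-4
    return Trace(t=t, v=v, ca=ca)


class TestExtraction:
    def test_triangle_pulse_matches_closed_form(self):
        """On a triangle the p% level is crossed at (1-p/100)*t_rise on the
        way up and at t_rise + (p/100)*t_fall on the way down, so
        APDp = (p/100)*(t_rise + t_fall)."""
        t_rise, t_fall = 2.0, 300.0
        tr = triangle_trace(t_rise, t_fall)
        bm = extract_biomarkers(tr)
        for p in (30, 50, 80):
            expected = p / 100 * (t_rise + t_fall)
            assert bm[f"APD{p}"] == pytest.approx(expected, abs=0.25)

    def test_durations_invariant_to_shift_and_scale(self):
        tr = triangle_trace()
        bm0 = extract_biomarkers(tr)
        shifted = Trace(t=tr.t + 123.0, v=tr.v + 17.0, ca=tr.ca * 5.0)
        # re-zero time so window logic is comparable
        shifted = Trace(t=shifted.t - 123.0, v=shifted.v, ca=shifted.ca)
        bm1 = extract_biomarkers(shifted)
        for key in ("APD30", "APD50", "APD80", "CaD50", "CaD80"):
            assert bm1[key] == pytest.approx(bm0[key], rel=1e-9)

    def test_durations_are_nested(self, hipsc_beat):
        bm = extract_biomarkers(hipsc_beat.final_beat())
        assert bm["APD30"] <= bm["APD50"] <= bm["APD80"]
        cads = [bm[f"CaD{p}"] for p in (20, 30, 40, 50, 60, 70, 80)]
        assert all(a <= b for a, b in zip(cads, cads[1:]))
        assert bm["ca_amp"] >= 0.0

    def test_flat_trace_is_flagged_invalid(self):
        t = np.arange(0, 500.0, 1.0)
        tr = Trace(t=t, v=np.full_like(t, -80.0), ca=np.full_like(t, 1e-4))
        assert not extract_biomarkers(tr).valid


class TestCostTerm:
    def test_equal_values_cost_zero(self):
        assert cost_term(123.4, 123.4) == 0.0

    def test_double_costs_one(self):
        assert cost_term(2.0 * 7.7, 7.7) == pytest.approx(1.0)

    def test_zero_target_is_skipped(self):
        assert cost_term(1.0, 0.0) is None

    @settings(max_examples=100, deadline=None)
    @given(m=st.floats(-1e3, 1e3), t=st.floats(-1e3, 1e3))
    def test_matches_literal_transcription(self, m, t):
        got = cost_term(m, t)
        if t == 0.0:
            assert got is None
        else:
            assert got == pytest.approx(abs(m - t) / abs(t), rel=1e-12)


class TestContinuationTargets:
    def setup_method(self):
        self.r0 = BiomarkerSet({"APD80": 400.0, "ca_amp": 2e-4})
        self.r1 = BiomarkerSet({"APD80": 300.0, "ca_amp": 1e-4})

    def test_theta_zero_returns_reference(self):
        assert continuation_targets(self.r0, self.r1, 0.0).values == self.r0.values

    def test_theta_one_returns_data(self):
        assert continuation_targets(self.r0, self.r1, 1.0).values == self.r1.values

    def test_theta_half_is_the_mean(self):
        mid = continuation_targets(self.r0, self.r1, 0.5)
        assert mid["APD80"] == pytest.approx(350.0)
        assert mid["ca_amp"] == pytest.approx(1.5e-4)

    def test_theta_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            continuation_targets(self.r0, self.r1, 1.5)


class _FakeDataset:
    def __init__(self, traces):
        self.traces = traces

    def items(self):
        return iter(sorted(self.traces.items()))


class TestTotalCost:
    def _simulator(self):
        def simulate(lam, eps, dose):
            # an analytic stand-in model: APD shrinks with effective block
            block = 1.0 / (1.0 + dose * eps.get("CaL", 0.0))
            scale = (1.0 + (lam["CaL"] if lam is not None else 0.0)) * block
            return triangle_trace(t_fall=300.0 * scale)
        return simulate

    def test_self_consistency_gives_zero_cost(self):
        sim = self._simulator()
        data = _FakeDataset({0.0: sim(None, {}, 0.0), 10.0: sim(None, {}, 10.0)})
        spec = CostSpec(terms=("APD30", "APD50", "APD80", "ca_amp"))
        h = total_cost(None, {}, data, spec, sim)
        assert h == pytest.approx(0.0, abs=1e-6)

    def test_cost_scales_linearly_in_weights(self):
        sim = self._simulator()
        data = _FakeDataset({0.0: sim(None, {"CaL": 0.2}, 1.0),
                             5.0: sim(None, {"CaL": 0.2}, 5.0)})
        terms = ("APD30", "APD50", "APD80")
        h1 = total_cost(None, {}, data, CostSpec(terms=terms), sim)
        h2 = total_cost(None, {}, data,
                        CostSpec(terms=terms, weights={t: 2.0 for t in terms}),
                        sim)
        assert h1 > 0
        assert h2 == pytest.approx(2.0 * h1, rel=1e-12)

    def test_total_cost_matches_brute_force_recomputation(self):
        """Weighted squared-sum against an independent dose-by-dose,
        term-by-term recomputation on the two-current stand-in."""
        sim = self._simulator()
        data = _FakeDataset({0.0: sim(None, {}, 0.0),
                             2.0: triangle_trace(t_fall=250.0),
                             8.0: triangle_trace(t_fall=180.0)})
        spec = CostSpec(terms=("APD30", "APD80", "ca_amp"),
                        weights={"APD80": 5.0})
        h = total_cost(None, {"CaL": 0.05}, data, spec, sim)
        # brute force
        expected = 0.0
        from cardioinv.biomarkers import extract_biomarkers as ex
        for dose, trace in data.items():
            target = ex(trace)
            model = ex(sim(None, {"CaL": 0.05}, dose))
            for term in spec.terms:
                w = spec.weight(term, dose)
                tgt = target[term]
                if tgt == 0.0:
                    continue
                expected += w * (abs(model[term] - tgt) / abs(tgt)) ** 2
        assert h == pytest.approx(expected, rel=1e-12)

    def test_failed_simulation_takes_penalty(self):
        def broken(lam, eps, dose):
            from cardioinv.model import SolverError
            if dose > 0:
                raise SolverError("boom", 0.0)
            return triangle_trace()
        data = _FakeDataset({0.0: triangle_trace(), 1.0: triangle_trace()})
        spec = CostSpec(terms=("APD80",), penalty=10.0)
        h = total_cost(None, {}, data, spec, broken)
        assert h == pytest.approx(100.0)  # one dose x one term x penalty^2

    def test_continuation_cost_is_zero_at_origin(self):
        """H-bar(0, 0, 0) = 0: at theta = 0 every dose targets the default
        model's own characteristics."""
        sim = self._simulator()
        ref = extract_biomarkers(sim(None, {}, 0.0))
        data_targets = {d: extract_biomarkers(triangle_trace(t_fall=200 + 30 * d))
                        for d in (0.0, 1.0, 4.0)}
        spec = CostSpec(terms=("APD30", "APD50", "APD80"))
        h0 = continuation_cost(0.0, None, {}, ref, data_targets, spec, sim)
        assert h0 == pytest.approx(0.0, abs=1e-9)
        # and at theta = 1 it equals the plain total cost
        h1 = continuation_cost(1.0, None, {}, ref, data_targets, spec, sim)
        ht = total_cost(None, {}, _FakeDataset(
            {d: triangle_trace(t_fall=200 + 30 * d) for d in (0.0, 1.0, 4.0)}),
            spec, sim)
        assert h1 == pytest.approx(ht, rel=1e-12)

    def test_at_least_one_term_required(self):
        with pytest.raises(ValueError):
            CostSpec(terms=())

    def test_l2_regularization_adds_quadratic_lambda_penalty(self):
        from cardioinv.scaling import AdjustmentFactors
        sim = self._simulator()
        data = _FakeDataset({0.0: sim(None, {}, 0.0)})
        spec0 = CostSpec(terms=("APD80",))
        spec_reg = CostSpec(terms=("APD80",), lambda_l2=2.0)
        lam = AdjustmentFactors(CaL=0.0)
        h0 = total_cost(lam, {}, data, spec0, sim)
        h1 = total_cost(lam, {}, data, spec_reg, sim)
        assert h1 == pytest.approx(h0)            # zero factors: no penalty
        lam2 = AdjustmentFactors(CaL=0.3, Kr=-0.4)
        base = total_cost(lam2, {}, data, spec0,
                          lambda l, e, d: sim(lam2, e, d))
        reg = total_cost(lam2, {}, data, spec_reg,
                         lambda l, e, d: sim(lam2, e, d))
        assert reg - base == pytest.approx(2.0 * (0.3 ** 2 + 0.4 ** 2))


class TestOpticalRescaling:
    def test_minmax_map_matches_reference_range(self):
        from cardioinv.biomarkers import rescale_to_reference
        model = triangle_trace()
        optical = Trace(t=model.t, v=(model.v + 80.0) / 120.0,
                        ca=model.ca * 3000.0)
        mapped = rescale_to_reference(optical, model)
        assert mapped.v.min() == pytest.approx(model.v.min())
        assert mapped.v.max() == pytest.approx(model.v.max())
        assert mapped.ca.min() == pytest.approx(model.ca.min())
        # durations are invariant under the affine map
        bm_opt = extract_biomarkers(mapped)
        bm_ref = extract_biomarkers(model)
        for key in ("APD30", "APD80", "CaD50"):
            assert bm_opt[key] == pytest.approx(bm_ref[key], rel=1e-9)
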