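import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import jipflux as jf
from jipflux.exceptions import DegenerateTransientError, ExtractionError, ValidationError
from conftest import make_transient


def worked_transient():
    """Sampled exactly at the nominal landmark times."""
    times = [5e-5, 3e-4, 2e-3, 3e-2, 0.3, 1.0]
    values = [5000, 6600, 13000, 20000, 24000, 25000]
    return make_transient(times, values)


class TestCardinalPoints:
    def test_worked_example(self):
        cp = jf.extract_cardinal_points(worked_transient())
        assert cp.f0 == pytest.approx(5000)
        assert cp.f300 == pytest.approx(6600)
        assert cp.fj == pytest.approx(13000)
        assert cp.fm == pytest.approx(25000)
        assert cp.t_fm == pytest.approx(1.0)
        assert cp.vj == pytest.approx(0.4)
        assert cp.m0 == pytest.approx(4 * (6600 - 5000) / (25000 - 5000))  # 0.32
        assert not cp.degenerate

    def test_log_time_interpolation_oracle(self):
        # two points bracketing 50 µs; independent two-point interpolation in log t
        t1, t2, f1, f2 = 4e-5, 6.3e-5, 5000.0, 5400.0
        tr = make_transient([t1, t2, 2e-3, 1.0], [f1, f2, 13000, 25000])
        cp = jf.extract_cardinal_points(tr)
        frac = (math.log10(5e-5) - math.log10(t1)) / (math.log10(t2) - math.log10(t1))
        assert cp.f0 == pytest.approx(f1 + frac * (f2 - f1), rel=1e-12)

    def test_flat_transient_flagged_degenerate(self):
        cp = jf.extract_cardinal_points(make_transient([1e-5, 1e-4, 1e-2, 1.0],
                                                       [7000.0] * 4))
        assert cp.degenerate
        assert cp.fm == cp.f0 == 7000
        assert math.isnan(cp.vj) and math.isnan(cp.m0)

    def test_missing_landmark_named(self):
        tr = make_transient([1e-4, 1e-3, 1e-2, 1.0], [1, 2, 3, 4])
        with pytest.raises(ExtractionError, match="F0"):
            jf.extract_cardinal_points(tr)


class TestRelativeVariableFluorescence:
    def test_anchors_and_worked_value(self):
        assert jf.relative_variable_fluorescence(5000, 5000, 25000) == 0.0
        assert jf.relative_variable_fluorescence(25000, 5000, 25000) == 1.0
        assert jf.relative_variable_fluorescence(13000, 5000, 25000) == pytest.approx(0.4)

    def test_out_of_range_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamping"):
            assert jf.relative_variable_fluorescence(26000, 5000, 25000) == 1.0

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateTransientError):
            jf.relative_variable_fluorescence(5000, 5000, 5000)


class TestComputeArea:
    def test_constant_curve_zero(self):
        tr = make_transient([1e-5, 1e-3, 1e-2, 1.0], [100.0] * 4)
        assert jf.compute_area(tr, 100.0, 1.0) == 0.0

    def test_exponential_rise_matches_closed_form(self):
        f0, fm, k = 5000.0, 25000.0, 50.0
        t = np.logspace(-5, 0, 2000)
        tr = make_transient(t, fm - (fm - f0) * np.exp(-k * t))
        got = jf.compute_area(tr, fm, t[-1])
        expected = (fm - f0) / k * (math.exp(-k * t[0]) - math.exp(-k * t[-1]))
        assert got == pytest.approx(expected, rel=5e-3)

    def test_quadrature_converges_with_density(self):
        spec = jf.KineticSpec()
        vals = []
        for pts in (160, 480):
            tr = jf.simulate_transient(spec, jf.SamplingGrid(points=pts), noise_sd=0.0)
            cp = jf.extract_cardinal_points(tr)
            vals.append(jf.compute_area(tr, cp.fm, cp.t_fm))
        assert abs(vals[1] / vals[0] - 1) < 1e-3


class TestJipParameters:
    def test_worked_example_full_vector(self):
        cp = jf.CardinalPoints(f0=5000, f300=6600, fj=13000, fm=25000,
                               t_fm=1.0, vj=0.4, m0=1.2)
        p = jf.compute_jip_parameters(cp, area=100.0)
        assert p.phi_po == pytest.approx(0.8)
        assert p.vj == pytest.approx(0.4)
        assert p.psi_o == pytest.approx(0.6)
        assert p.abs_cs == pytest.approx(5000)
        assert p.tr0_cs == pytest.approx(4000)
        assert p.et0_cs == pytest.approx(2400)
        assert p.di0_cs == pytest.approx(1000)
        assert p.rc0_cs == pytest.approx(4000 / 3, rel=1e-12)  # 1333.33
        assert p.gamma_rc_odds == pytest.approx(1 / 3.75, rel=1e-12)  # 0.2667
        assert p.tr0_di0 == pytest.approx(4.0)
        assert p.psi_odds == pytest.approx(1.5)
        assert p.pi_abs == pytest.approx(1.6)

    def test_fully_quenched_limit(self):
        cp = jf.CardinalPoints(f0=7000, f300=7000, fj=7000, fm=7000,
                               t_fm=1.0, vj=float("nan"), m0=float("nan"),
                               degenerate=True)
        p = jf.compute_jip_parameters(cp, area=0.0)
        assert p.phi_po == 0 and p.tr0_cs == 0 and p.et0_cs == 0
        assert p.di0_cs == p.abs_cs == 7000
        assert p.pi_abs == 0

    def test_undefined_odds_marked_nan(self):
        cp = jf.CardinalPoints(f0=5000, f300=5000, fj=5000, fm=25000,
                               t_fm=1.0, vj=0.0, m0=0.5)
        p = jf.compute_jip_parameters(cp, area=1.0)
        assert p.psi_o == 1.0
        assert math.isnan(p.psi_odds) and math.isnan(p.pi_abs)
        assert p.tr0_cs == pytest.approx(4000)

    @given(c=st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        tr = worked_transient()
        scaled = make_transient(tr.times, tr.fluorescence * c)
        _, p1 = jf.analyze_transient(tr)
        _, p2 = jf.analyze_transient(scaled)
        for name in ("phi_po", "psi_o", "vj", "m0", "pi_abs", "tr0_di0", "psi_odds"):
            assert getattr(p2, name) == pytest.approx(getattr(p1, name), rel=1e-12)
        for name in ("abs_cs", "tr0_cs", "et0_cs", "di0_cs", "rc0_cs"):
            assert getattr(p2, name) == pytest.approx(c * getattr(p1, name), rel=1e-12)

    def test_monotonicity_in_fj(self):
        prev = None
        for fj in (9000.0, 13000.0, 17000.0):
            cp = jf.CardinalPoints(f0=5000, f300=6600, fj=fj, fm=25000, t_fm=1.0,
                                   vj=(fj - 5000) / 20000, m0=0.32)
            p = jf.compute_jip_parameters(cp, area=10.0)
            if prev is not None:
                assert p.vj > prev.vj
                assert p.psi_o < prev.psi_o
                assert p.et0_cs < prev.et0_cs
                assert p.pi_abs < prev.pi_abs
            prev = p


class TestAnalyzeTransients:
    def test_identity_suite_on_batch(self, default_experiment):
        *_, params, rejects = default_experiment
        assert len(params) == 80 and rejects.empty
        np.testing.assert_allclose(params["di0_cs"], params["abs_cs"] - params["tr0_cs"],
                                   rtol=1e-9)
        np.testing.assert_allclose(params["et0_cs"], params["psi_o"] * params["tr0_cs"],
                                   rtol=1e-9)
        assert ((params["phi_po"] >= 0) & (params["phi_po"] < 1)).all()
        assert ((params["vj"] >= 0) & (params["vj"] <= 1)).all()

    def test_order_invariance(self, default_experiment):
        transients, *_ , params, _ = default_experiment
        shuffled = list(transients)[::-1]
        params2, _ = jf.analyze_transients(shuffled)
        assert params2.equals(params)

    def test_flat_transient_rejected_not_dropped_silently(self):
        good = worked_transient()
        flat = make_transient([1e-5, 1e-3, 1e-2, 1.0], [7000.0] * 4, sample_id="flat")
        params, rejects = jf.analyze_transients([good, flat])
        assert len(params) == 1
        assert rejects.iloc[0]["sample_id"] == "flat"
        assert rejects.iloc[0]["reason"] == "degenerate"

    def test_empty_input_raises(self):
        with pytest.raises(ValidationError):
            jf.analyze_transients([])
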