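"""Wavefront schedules and the receptor-bound Wnt fraction."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wntclock as wc
from wntclock.errors import ConfigurationError


class TestBoundFraction:
    def test_half_saturation(self):
        assert wc.bound_fraction(wc.WntBinding(W=1.0, K_W=1.0)) == pytest.approx(0.5)

    def test_saturation_limit(self):
        assert wc.bound_fraction(wc.WntBinding(W=1e9, K_W=1.0)) == pytest.approx(1.0, abs=1e-6)

    def test_no_wnt_no_binding(self):
        assert wc.bound_fraction(wc.WntBinding(W=0.0, K_W=1.0)) == 0.0

    def test_undefined_when_both_zero(self):
        with pytest.raises(ConfigurationError):
            wc.bound_fraction(wc.WntBinding(W=0.0, K_W=0.0))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(0.0, 100.0), st.floats(0.01, 100.0), st.floats(0.001, 10.0))
    def test_monotone_in_wnt_and_affinity(self, w, k, dw):
        """Bound fraction rises with Wnt and falls with K_W."""
        f = wc.bound_fraction
        assert f(wc.WntBinding(w + dw, k)) >= f(wc.WntBinding(w, k))
        assert f(wc.WntBinding(w, k + dw)) <= f(wc.WntBinding(w, k)) or w == 0.0


class TestSchedules:
    @pytest.mark.parametrize("builder", [wc.gaussian_schedule, wc.exponential_schedule])
    def test_endpoints(self, builder):
        s = builder(fold=2.0, transit=1200.0)
        assert s.value(0.0) == pytest.approx(1.0)
        assert s.value(1200.0) == pytest.approx(0.5)

    def test_gaussian_width(self):
        s = wc.gaussian_schedule(fold=2.0, transit=1200.0)
        sigma = 1200.0 / math.sqrt(2.0 * math.log(2.0))
        assert sigma == pytest.approx(1019.2, abs=0.2)
        assert s.value(sigma) == pytest.approx(math.exp(-0.5) * s.value(0.0))

    def test_exponential_effective_halflife(self):
        s = wc.exponential_schedule(fold=2.0, transit=1200.0)
        half_life = 1200.0 / math.log2(2.0)
        assert s.value(half_life) == pytest.approx(0.5)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.floats(1.1, 10.0), st.floats(100.0, 3000.0), st.floats(0.0, 1.0))
    def test_profiles_agree_at_ends_and_decay(self, fold, transit, frac):
        """Gaussian and exponential profiles share both endpoints and are
        monotone non-increasing in between."""
        g = wc.gaussian_schedule(fold=fold, transit=transit)
        e = wc.exponential_schedule(fold=fold, transit=transit)
        assert g.value(0.0) == pytest.approx(e.value(0.0))
        assert g.value(transit) == pytest.approx(e.value(transit), rel=1e-9)
        t = frac * transit
        assert g.value(t + 1.0) <= g.value(t) + 1e-12
        assert e.value(t + 1.0) <= e.value(t) + 1e-12

    @pytest.mark.parametrize("fold", [1.0, 0.5, -2.0])
    def test_fold_must_exceed_one(self, fold):
        with pytest.raises(ConfigurationError):
            wc.gaussian_schedule(fold=fold, transit=1200.0)

    def test_scaled_start(self):
        s = wc.gaussian_schedule(fold=2.0, transit=1200.0).scaled(0.25)
        assert s.value(0.0) == pytest.approx(0.25)
        assert s.value(1200.0) == pytest.approx(0.125)

    def test_constant(self):
        s = wc.constant_schedule(0.7)
        assert s.value(0.0) == s.value(5000.0) == 0.7


class TestTailbudDrift:
    def test_endpoints_and_midpoint(self):
        d = wc.tailbud_drift(1.0, 0.5, 0.0, 1000.0)
        assert d(0.0) == 1.0
        assert d(1000.0) == 0.5
        assert d(500.0) == pytest.approx(0.75)

    def test_clamped_outside(self):
        d = wc.tailbud_drift(1.0, 0.5, 100.0, 200.0)
        assert d(-50.0) == 1.0 and d(1e6) == 0.5

    def test_shrinking_fold_range_for_late_cells(self):
        """As the tail-bud level falls toward the anterior level, the fold
        range a late-born cell traverses shrinks."""
        d = wc.tailbud_drift(1.0, 0.5, 0.0, 1000.0)
        sched = wc.gaussian_schedule(fold=2.0, transit=1200.0)
        early = sched.scaled(d(0.0))
        late = sched.scaled(d(1000.0))
        fold_early = early.value(0.0) / 0.5  # anterior level is ref/2
        fold_late = late.value(0.0) / 0.5
        assert fold_late < fold_early

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ConfigurationError):
            wc.tailbud_drift(1.0, 0.5, 100.0, 100.0)
        with pytest.raises(ConfigurationError):
            wc.tailbud_drift(0.0, 0.5, 0.0, 1.0)
        with pytest.raises(ConfigurationError):
            wc.tailbud_drift(1.0, 11.0, 0.0, 1.0)


class TestScheduleSpecs:
    @pytest.mark.parametrize(
        "spec",
        [
            "gaussian:fold=2,transit=1200,target=k_LGA",
            "exponential:fold=3,transit=900,target=S_B",
            "constant:value=0.5,target=k_LGA",
        ],
    )
    def test_roundtrip(self, spec):
        s = wc.parse_schedule(spec)
        s2 = wc.parse_schedule(s.spec)
        assert s2.kind == s.kind and s2.target == s.target
        for t in (0.0, 300.0, 1200.0):
            assert s2.value(t) == pytest.approx(s.value(t))

    @pytest.mark.parametrize("bad", ["wedge:fold=2", "gaussian:fold", "gaussian:fold=x", "gaussian:bogus=1"])
    def test_malformed_specs_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            wc.parse_schedule(bad)
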