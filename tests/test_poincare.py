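import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hrasym import (
    HRADescriptors,
    analyze_recording,
    build_poincare,
    classify_hra,
    descriptors,
    normal_pairs,
)

from conftest import make_recording


def naive_descriptors(x, y):
    """Independent per-point loop oracle for the variance decomposition."""
    n = len(x)
    ell = [(xi + yi) / math.sqrt(2) for xi, yi in zip(x, y)]
    lbar = sum(ell) / n
    sd1d2 = sd1a2 = sd2d2 = sd2a2 = 0.0
    nd = na = 0
    for xi, yi, li in zip(x, y, ell):
        d2 = ((xi - yi) / math.sqrt(2)) ** 2
        l2 = (li - lbar) ** 2
        if yi > xi:
            sd1d2 += d2
            sd2d2 += l2
            nd += 1
        elif yi < xi:
            sd1a2 += d2
            sd2a2 += l2
            na += 1
        else:
            sd2d2 += 0.5 * l2
            sd2a2 += 0.5 * l2
    out = {
        "sd1d2": sd1d2 / n, "sd1a2": sd1a2 / n,
        "sd2d2": sd2d2 / n, "sd2a2": sd2a2 / n,
        "nd": nd, "na": na,
    }
    out["sd12"] = out["sd1d2"] + out["sd1a2"]
    out["sd22"] = out["sd2d2"] + out["sd2a2"]
    return out


def rr_to_plot(rr):
    rr = np.asarray(rr, float)
    return build_poincare((rr[:-1], rr[1:]))


rr_series = st.lists(
    st.floats(min_value=300, max_value=2000, allow_nan=False, allow_infinity=False),
    min_size=3,
    max_size=200,
)


class TestBuildPoincare:
    def test_labels_follow_sign_of_y_minus_x(self):
        plot = build_poincare((np.array([1000.0, 1010, 990]), np.array([1010.0, 990, 1000])))
        assert plot.decelerations.tolist() == [True, False, True]
        assert plot.accelerations.tolist() == [False, True, False]

    def test_identity_line_point_is_nochange(self):
        plot = rr_to_plot([1000, 1000, 1001])
        assert plot.nochange.tolist() == [True, False]

    def test_monotone_ramp_is_all_deceleration(self):
        plot = rr_to_plot(np.linspace(800, 900, 30))
        assert plot.decelerations.all()

    def test_fewer_than_two_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            build_poincare((np.array([1000.0]), np.array([1010.0])))


@pytest.fixture(scope="module")
def desc():
    return descriptors(rr_to_plot([1000, 1010, 990, 1000]))


class TestWorkedExample:
    """RR = [1000, 1010, 990, 1000]: three plot points, verified by hand."""

    def test_short_term_decomposition(self, desc):
        assert desc.sd1d**2 == pytest.approx(100 / 3)
        assert desc.sd1a**2 == pytest.approx(200 / 3)
        assert desc.c1d == pytest.approx(1 / 3)

    def test_long_term_decomposition(self, desc):
        assert desc.sd2d**2 == pytest.approx(100 / 3)
        assert desc.sd2a**2 == pytest.approx(0.0, abs=1e-9)
        assert desc.c2d == pytest.approx(1.0)

    def test_total_and_counts(self, desc):
        assert desc.ctd == pytest.approx(0.5)
        assert (desc.nd_count, desc.na_count) == (2, 1)
        assert desc.nd == pytest.approx(2 / 3)


class TestDegenerateSeries:
    def test_alternating_series_is_short_term_symmetric(self):
        desc = descriptors(rr_to_plot([1000, 1010, 1000, 1010, 1000]))
        assert desc.c1d == pytest.approx(0.5)
        assert desc.nd == pytest.approx(0.5)
        assert desc.sd2 == 0.0 and not desc.c2d_defined  # all points share x + y

    def test_constant_series_has_everything_undefined(self):
        desc = descriptors(rr_to_plot([800, 800, 800, 800]))
        assert desc.sd1 == 0.0 and desc.sd2 == 0.0
        assert not (desc.c1d_defined or desc.c2d_defined or desc.ctd_defined or desc.nd_defined)
        flags = classify_hra(desc)
        assert not flags.defined


@settings(deadline=None, max_examples=200)
@given(rr_series)
def test_additive_identities(rr):
    d = descriptors(rr_to_plot(rr))
    assert d.sd1d**2 + d.sd1a**2 == pytest.approx(d.sd1**2, rel=1e-9, abs=1e-12)
    assert d.sd2d**2 + d.sd2a**2 == pytest.approx(d.sd2**2, rel=1e-9, abs=1e-12)
    assert 2 * d.sdnn**2 == pytest.approx(d.sd1**2 + d.sd2**2, rel=1e-9, abs=1e-12)
    for cd, ca, defined in [(d.c1d, d.c1a, d.c1d_defined),
                            (d.c2d, d.c2a, d.c2d_defined),
                            (d.ctd, d.cta, d.ctd_defined)]:
        if defined:
            assert 0 <= cd <= 1
            assert cd + ca == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, max_examples=200)
@given(rr_series)
def test_matches_naive_loop_oracle(rr):
    rr = np.asarray(rr, float)
    d = descriptors(rr_to_plot(rr))
    ref = naive_descriptors(rr[:-1].tolist(), rr[1:].tolist())
    assert d.sd1d**2 == pytest.approx(ref["sd1d2"], rel=1e-12, abs=1e-12)
    assert d.sd1a**2 == pytest.approx(ref["sd1a2"], rel=1e-12, abs=1e-12)
    assert d.sd2d**2 == pytest.approx(ref["sd2d2"], rel=1e-12, abs=1e-12)
    assert d.sd2a**2 == pytest.approx(ref["sd2a2"], rel=1e-12, abs=1e-12)
    assert (d.nd_count, d.na_count) == (ref["nd"], ref["na"])


@settings(deadline=None, max_examples=100)
@given(rr_series)
def test_pair_reversal_swaps_decelerations_and_accelerations(rr):
    rr = np.asarray(rr, float)
    fwd = descriptors(build_poincare((rr[:-1], rr[1:])))
    rev = descriptors(build_poincare((rr[1:], rr[:-1])))
    assert fwd.sd1d == pytest.approx(rev.sd1a, rel=1e-9, abs=1e-12)
    assert fwd.sd2d == pytest.approx(rev.sd2a, rel=1e-9, abs=1e-12)
    assert (fwd.nd_count, fwd.na_count) == (rev.na_count, rev.nd_count)
    if fwd.c1d_defined:
        assert fwd.c1d == pytest.approx(1 - rev.c1d, rel=1e-9, abs=1e-9)
    if fwd.c2d_defined:
        assert fwd.c2d == pytest.approx(1 - rev.c2d, rel=1e-9, abs=1e-9)


@settings(deadline=None, max_examples=100)
@given(rr_series, st.floats(min_value=0.1, max_value=10))
def test_scale_invariance_of_ratios(rr, k):
    rr = np.asarray(rr, float)
    base = descriptors(rr_to_plot(rr))
    scaled = descriptors(rr_to_plot(k * rr))
    assert scaled.sd1 == pytest.approx(k * base.sd1, rel=1e-9, abs=1e-9)
    assert scaled.sdnn == pytest.approx(k * base.sdnn, rel=1e-9, abs=1e-9)
    if base.c1d_defined:
        assert scaled.c1d == pytest.approx(base.c1d, rel=1e-9, abs=1e-9)
    assert (scaled.nd_count, scaled.na_count) == (base.nd_count, base.na_count)


class TestClassifyHRA:
    def _desc(self, c1d, c2d, ctd, nd):
        return HRADescriptors(
            sd1d=1, sd1a=1, sd1=1, sd2d=1, sd2a=1, sd2=1,
            sdnnd=1, sdnna=1, sdnn=1,
            c1d=c1d, c2d=c2d, ctd=ctd, nd=nd,
            nd_count=1, na_count=1, n_nochange=0, n_points=2,
        )

    def test_typical_asymmetric_profile_sets_all_flags(self):
        flags = classify_hra(self._desc(0.56, 0.48, 0.48, 0.42))
        assert (flags.hra1, flags.hra2, flags.hrat, flags.hran, flags.hracomp) == (True,) * 5

    def test_thresholds_are_strict(self):
        flags = classify_hra(self._desc(0.5, 0.5, 0.5, 0.5))
        assert not any([flags.hra1, flags.hra2, flags.hrat, flags.hran])

    def test_compensation_requires_both_short_and_long_term(self):
        flags = classify_hra(self._desc(0.51, 0.51, 0.49, 0.49))
        assert flags.hra1 and not flags.hra2 and not flags.hracomp


class TestAnalyzeRecording:
    def test_clean_recording_yields_full_result(self):
        rng = np.random.default_rng(0)
        n = int(19 * 3600)
        rec = make_recording(1000 + rng.normal(0, 30, n))
        report, desc, flags = analyze_recording(rec)
        assert report.eligible and desc is not None and flags is not None
        assert desc.n_points == n - 1

    def test_ineligible_recording_has_no_descriptors(self):
        rec = make_recording(np.full(1000, 1000.0))  # far too short
        report, desc, flags = analyze_recording(rec)
        assert not report.eligible and desc is None and flags is None

    def test_tiny_recording_fails_via_duration(self):
        report, desc, _ = analyze_recording(make_recording([800] * 10))
        assert not report.eligible and desc is None
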