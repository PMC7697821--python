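"""Unit and property tests for VPD and the membership functions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optdeg import (
    GrowthStage,
    InvalidInputError,
    LightCondition,
    MembershipParams,
    TrapezoidParams,
    audit_membership_table,
    compute_vpd,
    default_params,
    literal_printed_params,
    optdeg_humidity,
    optdeg_record,
    optdeg_temperature,
    optdeg_vpd,
)

STAGES = list(GrowthStage)
LIGHTS = list(LightCondition)


# --------------------------------------------------------------------------
# VPD
# --------------------------------------------------------------------------

@pytest.mark.parametrize("t, rh, expected", [
    (51.2, 10.2, 11.76),   # hot dry July extreme
    (19.6, 46.2, 1.23),    # July minimum-T / maximum-RH pair
    (12.3, 95.5, 0.06),    # humid pre-dawn June hour
])
def test_vpd_worked_values(t, rh, expected):
    assert round(compute_vpd(t, rh), 2) == pytest.approx(expected)


def test_vpd_zero_at_saturation():
    for t in (-5.0, 0.0, 12.3, 25.0, 51.2):
        assert compute_vpd(t, 100.0) == 0.0


@given(t=st.floats(-30, 60), rh=st.floats(0, 99.9))
@settings(deadline=None, max_examples=200, derandomize=True)
def test_vpd_monotone(t, rh):
    """Strictly increasing in T (at RH < 100), strictly decreasing in RH."""
    assert compute_vpd(t + 0.5, rh) > compute_vpd(t, rh)
    assert compute_vpd(t, min(rh + 0.5, 100.0)) < compute_vpd(t, rh)


@pytest.mark.parametrize("t, rh, fieldname", [
    (25.0, -1.0, "RH"), (25.0, 101.0, "RH"),
    (float("nan"), 50.0, "T"), (25.0, float("inf"), "RH"),
    (-240.0, 50.0, "T"),
])
def test_vpd_invalid_inputs(t, rh, fieldname):
    with pytest.raises(InvalidInputError) as err:
        compute_vpd(t, rh)
    assert err.value.fieldname == fieldname


# --------------------------------------------------------------------------
# Membership anchor examples
# --------------------------------------------------------------------------

@pytest.mark.parametrize("t, stage, light, expected", [
    (25.0, "GS2", "sun", 1.0),        # inside the [24, 27] sun plateau
    (17.0, "GS2", "night", 0.5),      # the night half-anchor
    (8.0, "GS1", "sun", 0.0),         # below the failure border
    (16.5, "GS1", "cloud", 0.5),      # ramp midpoint (16.5-9)/(24-9)
    (35.0, "GS1", "night", 0.0),      # exactly at G0_max -> failure
    (40.0, "GS2", "sun", 0.0),
    (30.0, "GS2", "night", 0.5),      # falling (40-30)/(40-20)
])
def test_temperature_anchors(t, stage, light, expected):
    assert optdeg_temperature(t, stage, light) == pytest.approx(expected)


def test_stage2_night_two_segment_rise_is_continuous():
    """0 -> 0.5 on [10, 17], 0.5 -> 1 on [17, 18], continuous at the joins."""
    assert optdeg_temperature(13.5, "GS2", "night") == pytest.approx(0.25)
    assert optdeg_temperature(17.5, "GS2", "night") == pytest.approx(0.75)
    eps = 1e-9
    for x in (10.0, 17.0, 18.0, 20.0, 40.0):
        lo = optdeg_temperature(x - eps, "GS2", "night")
        hi = optdeg_temperature(x + eps, "GS2", "night")
        assert abs(hi - lo) < 1e-6


@pytest.mark.parametrize("rh, stage, expected", [
    (80.0, "GS1", 1.0),     # above the 75 % border, one-sided form
    (100.0, "GS1", 1.0),
    (67.5, "GS1", 0.5),     # ramp midpoint
    (20.0, "GS3_5", 0.0),   # below the 30 % failure border
    (75.0, "GS2", 1.0),
    (89.5, "GS2", 0.5),     # falling (99-89.5)/(99-80)
])
def test_humidity_anchors(rh, stage, expected):
    assert optdeg_humidity(rh, stage) == pytest.approx(expected)


@pytest.mark.parametrize("v, stage, light, expected, tol", [
    (0.5, "GS1", "sun", 1.0, 0),          # GS1 plateau [0.030, 0.845]
    (0.845, "GS1", "cloud", 0.9986, 0.01),  # plateau edge ~ branch value
    (6.0, "GS3_5", "sun", 0.0, 0),        # above G0_max = 5.160
    (0.701, "GS2", "night", 0.989, 0.02),  # night G1_max endpoint
    (0.0, "GS2", "sun", 0.0, 0),
])
def test_vpd_membership_anchors(v, stage, light, expected, tol):
    got = optdeg_vpd(v, stage, light)
    assert got == pytest.approx(expected, abs=tol or 1e-12)


def test_optdeg_record_composes_vpd_before_scoring():
    r = optdeg_record(25.0, 70.0, "GS2", "sun")
    assert r.opt_t == 1.0 and r.opt_rh == 1.0
    assert r.vpd == pytest.approx(compute_vpd(25.0, 70.0))
    # saturated air: VPD = 0, below the 0.012 kPa failure border
    r2 = optdeg_record(25.0, 100.0, "GS2", "sun")
    assert r2.vpd == 0.0 and r2.opt_vpd == 0.0
    r3 = optdeg_record(16.5, 67.5, "GS1", "night")
    assert r3.opt_t == pytest.approx(0.5)
    assert r3.opt_rh == pytest.approx(0.5)


# --------------------------------------------------------------------------
# Invariants (property tests)
# --------------------------------------------------------------------------

@given(x=st.floats(-50, 150), si=st.sampled_from(STAGES),
       li=st.sampled_from(LIGHTS))
@settings(deadline=None, max_examples=300, derandomize=True)
def test_membership_outputs_in_unit_interval(x, si, li):
    assert 0.0 <= optdeg_temperature(x, si, li) <= 1.0
    assert 0.0 <= optdeg_humidity(min(max(x, 0.0), 100.0), si) <= 1.0
    assert 0.0 <= optdeg_vpd(abs(x) / 10.0, si, li) <= 1.0


@pytest.mark.parametrize("stage", STAGES)
@pytest.mark.parametrize("light", LIGHTS)
def test_plateau_support_and_monotonicity(stage, light):
    """Exactly 1 on the closed plateau, 0 at/outside the failure borders,
    monotone rise and fall in between -- for every variable and context."""
    params = default_params()
    checks = [
        (lambda x: optdeg_temperature(x, stage, light),
         params.temperature_for(stage, light)),
        (lambda x: optdeg_vpd(np.maximum(x, 0.0), stage, light),
         params.vpd_for(stage, light)),
        (lambda x: optdeg_humidity(np.clip(x, 0.0, 100.0), stage),
         params.humidity_for(stage)),
    ]
    for f, p in checks:
        plateau = np.linspace(p.g1_min, p.g1_max, 50)
        assert np.all(f(plateau) == 1.0)
        assert f(p.g0_min) == 0.0
        rise = f(np.linspace(p.g0_min, p.g1_min, 300))
        assert np.all(np.diff(rise) >= -1e-12)
        if not getattr(p, "one_sided", False) and math.isfinite(p.g0_max):
            assert f(p.g0_max) == 0.0
            fall = f(np.linspace(p.g1_max, p.g0_max, 300))
            assert np.all(np.diff(fall) <= 1e-12)


def test_gs3_5_temperature_delegates_to_gs2():
    t = np.linspace(0.0, 45.0, 901)
    for light in LIGHTS:
        a = optdeg_temperature(t, GrowthStage.GS3_5, light)
        b = optdeg_temperature(t, GrowthStage.GS2, light)
        np.testing.assert_array_equal(a, b)


# --------------------------------------------------------------------------
# Endpoint audit
# --------------------------------------------------------------------------

def test_audit_shipped_defaults_clean_at_005():
    report = audit_membership_table(tol=0.05)
    assert [e for e in report if e.flagged] == []
    # every stage/light branch pair contributes 4 endpoint checks
    assert len(report) == 4 * sum(len(t) for t in default_params().vpd.values())


def test_audit_flags_published_sign_typos():
    """With the signs exactly as published, the stage-2 sun rising branch
    evaluates near -1 at its G1 border: residual > 1, loudly flagged."""
    report = audit_membership_table(literal_printed_params(), tol=0.05)
    flagged = {(e.stage, e.light, e.branch) for e in report if e.flagged}
    assert ("GS2", "sun", "rising") in flagged
    assert ("GS3_5", "cloud", "rising") in flagged
    s2 = [e for e in report if (e.stage, e.light, e.anchor)
          == ("GS2", "sun", "G1_min")][0]
    assert s2.residual > 1.0


def test_audit_tolerance_dominates():
    assert all(not e.flagged for e in audit_membership_table(tol=10.0))


def test_audit_rejects_nonpositive_tol():
    with pytest.raises(ValueError):
        audit_membership_table(tol=0.0)


# --------------------------------------------------------------------------
# Parameters as data
# --------------------------------------------------------------------------

def test_params_yaml_round_trip(tmp_path):
    p = default_params()
    path = tmp_path / "params.yaml"
    p.save(path)
    assert MembershipParams.load(path) == p


def test_params_anchor_ordering_enforced():
    with pytest.raises(ValueError):
        TrapezoidParams(24.0, 9.0, 26.1, 35.0)
    with pytest.raises(ValueError):
        TrapezoidParams(9.0, 24.0, 26.1, 35.0, g0_5=25.0)


def test_override_params_change_scores(tmp_path):
    d = default_params().to_dict()
    d["temperature"]["GS1"]["all"]["G1_min"] = 20.0
    custom = MembershipParams.from_dict(d)
    assert optdeg_temperature(22.0, "GS1", "sun", custom) == 1.0
    assert optdeg_temperature(22.0, "GS1", "sun") < 1.0
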