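"""TIMS/TWIMS mobility calibration, Mason-Schamp CCS and cross-platform
comparison."""

import math

import numpy as np
import pytest

import oligomob as om
from oligomob.calibration import N2_MASS
from oligomob.simulate import TIMS_REFERENCE_TABLE

TUNING_MIX = list(TIMS_REFERENCE_TABLE)


# ---------------------------------------------------------------------------
# TIMS


def test_tims_identity_when_already_calibrated():
    observed = [(ik, mz) for mz, ik in TUNING_MIX]
    cal = om.fit_tims_calibration(observed, TUNING_MIX)
    for mz, ik in TUNING_MIX:
        assert cal.apply(ik) == pytest.approx(ik, abs=1e-12)


def test_tims_anchor_reproduction_under_distortion():
    """The eight Tuning Mix ions (m/z 322-2422 at 0.732-2.03 V·s/cm²) are
    reproduced exactly at the anchors of a nonlinear raw axis."""
    observed = [(100 + 400 * ik + 5 * ik**2, mz) for mz, ik in TUNING_MIX]
    cal = om.fit_tims_calibration(observed, TUNING_MIX)
    for (raw, _), (_, ik) in zip(observed, TUNING_MIX):
        assert cal.apply(raw) == pytest.approx(ik, abs=1e-12)


def test_tims_midpoint_interpolates_linearly():
    observed = [(ik, mz) for mz, ik in TUNING_MIX]
    cal = om.fit_tims_calibration(observed, TUNING_MIX)
    mid_raw = (TUNING_MIX[0][1] + TUNING_MIX[1][1]) / 2
    expected = (TUNING_MIX[0][1] + TUNING_MIX[1][1]) / 2
    assert cal.apply(mid_raw) == pytest.approx(expected)
    # strictly monotone across the whole range
    grid = np.linspace(0.6, 2.2, 200)
    assert np.all(np.diff(cal.apply(grid)) > 0)


def test_tims_rejects_non_monotone_calibrants():
    observed = [(0.9, 322.0), (0.7, 622.0), (1.2, 922.0)]
    with pytest.raises(ValueError, match="monotone"):
        om.fit_tims_calibration(observed, TUNING_MIX)


def test_tims_needs_two_matches():
    with pytest.raises(ValueError, match="at least 2"):
        om.fit_tims_calibration([(0.7, 322.0)], TUNING_MIX)


# ---------------------------------------------------------------------------
# Mason-Schamp


def test_ccs_proportional_to_charge():
    base = om.mobility_to_ccs(1.5, 1, 1000.0)
    assert om.mobility_to_ccs(1.5, 2, 1000.0) == pytest.approx(2 * base)


def test_ccs_linear_in_inv_k0():
    assert om.mobility_to_ccs(3.0, 1, 1000.0) == pytest.approx(
        2 * om.mobility_to_ccs(1.5, 1, 1000.0)
    )


def test_ccs_heavy_ion_limit():
    """As ion mass grows, mu -> gas mass and the CCS approaches the
    fixed-gas limit from below."""
    limit = om.mobility_to_ccs(1.5, 1, 1e12)
    heavy = om.mobility_to_ccs(1.5, 1, 1e6)
    light = om.mobility_to_ccs(1.5, 1, 500.0)
    assert heavy == pytest.approx(limit, rel=1e-4)
    assert light > heavy  # smaller mu -> larger sqrt(1/mu) factor


def test_ccs_heavier_of_two_equal_mobility_ions_is_smaller():
    assert om.mobility_to_ccs(1.5, 2, 5000.0) < om.mobility_to_ccs(1.5, 2, 1500.0)


def test_ccs_rejects_nonpositive_input():
    with pytest.raises(ValueError):
        om.mobility_to_ccs(-1.0, 1, 1000.0)


# ---------------------------------------------------------------------------
# TWIMS


def _synthetic_calibrants(slope, intercept, edc, noise_sd=0.0, seed=None):
    rng = np.random.default_rng(seed)
    cals = []
    for i, (mz, z, ccs) in enumerate(
        [(322.0, 1, 153.0), (622.0, 1, 202.0), (922.0, 1, 243.0),
         (1222.0, 1, 282.0), (785.0, 2, 530.0), (1047.0, 2, 610.0)]
    ):
        ion_mass = z * (mz - om.PROTON_MASS)
        mu = ion_mass * N2_MASS / (ion_mass + N2_MASS)
        ccs_red = ccs * math.sqrt(mu) / z
        dtp = math.exp((math.log(ccs_red) - intercept) / slope)
        dt = dtp + edc * math.sqrt(mz) / 1000.0
        if noise_sd:
            dt *= 1.0 + noise_sd * rng.standard_normal()
        cals.append(om.TwimsCalibrant(mz=mz, z=z, ccs_ref=ccs, drift_time=dt,
                                      name=f"synthetic_{i}"))
    return cals


def test_twims_exact_recovery_of_power_law():
    cals = _synthetic_calibrants(slope=0.52, intercept=7.1, edc=1.35)
    fit = om.fit_twims_calibration(cals, edc_coefficient=1.35)
    assert fit.slope == pytest.approx(0.52, abs=1e-9)
    assert fit.intercept == pytest.approx(7.1, abs=1e-9)
    assert fit.fit_r_squared == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("seed", range(20))
def test_twims_slope_within_2pct_at_halfpct_noise(seed):
    cals = _synthetic_calibrants(0.52, 7.1, 1.35, noise_sd=0.005, seed=seed)
    fit = om.fit_twims_calibration(cals, edc_coefficient=1.35)
    assert fit.slope == pytest.approx(0.52, rel=0.02)


def test_twims_requires_three_calibrants():
    cals = _synthetic_calibrants(0.52, 7.1, 1.35)[:2]
    with pytest.raises(ValueError, match="at least 3"):
        om.fit_twims_calibration(cals, edc_coefficient=1.35)


def test_twims_negative_corrected_drift_names_calibrant():
    cals = _synthetic_calibrants(0.52, 7.1, 1.35)
    with pytest.raises(ValueError, match="synthetic_0"):
        om.fit_twims_calibration(cals, edc_coefficient=1e6)


def test_twims_ccs_self_consistency():
    """Applying the fitted calibration to a calibrant's own drift time
    returns its reference CCS (exact fit -> zero residual)."""
    cals = _synthetic_calibrants(0.52, 7.1, 1.35)
    fit = om.fit_twims_calibration(cals, edc_coefficient=1.35)
    for cal in cals:
        ion_mass = cal.z * (cal.mz - om.PROTON_MASS)
        back = om.twims_ccs(cal.drift_time, fit, cal.z, ion_mass)
        assert back == pytest.approx(cal.ccs_ref, rel=1e-9)


def test_twims_ccs_monotone_in_drift_time():
    cals = _synthetic_calibrants(0.52, 7.1, 1.35)
    fit = om.fit_twims_calibration(cals, edc_coefficient=1.35)
    values = [om.twims_ccs(dt, fit, 2, 3000.0) for dt in (3.0, 5.0, 8.0)]
    assert values == sorted(values)


def test_twims_ccs_rejects_nonpositive_corrected_drift():
    cals = _synthetic_calibrants(0.52, 7.1, 1.35)
    fit = om.fit_twims_calibration(cals, edc_coefficient=1.35)
    with pytest.raises(ValueError):
        om.twims_ccs(1e-6, fit, 1, 800.0)


# ---------------------------------------------------------------------------
# comparison


def _ccs_list(M, values, platform):
    return [
        om.CcsValue(
            species=om.OligomerIon.from_monomer_mass(M, n, z),
            ccs=v, platform=platform,
        )
        for (n, z), v in values.items()
    ]


def test_compare_identical_lists(M):
    values = {(2, 1): 418.0, (4, 2): 702.0, (6, 3): 951.0}
    result = om.compare_platforms(
        _ccs_list(M, values, "TIMS"), _ccs_list(M, values, "TWIMS")
    )
    assert result.mean_relative_difference == 0.0
    assert result.max_relative_difference == 0.0
    assert result.r_squared == pytest.approx(1.0)


def test_compare_scaled_lists_closed_form(M):
    """b = 1.02 a gives every relative difference 100*0.02/1.01 = 1.9802%."""
    a = {(2, 1): 418.0, (4, 2): 702.0, (6, 3): 951.0, (8, 4): 1180.0}
    b = {k: 1.02 * v for k, v in a.items()}
    result = om.compare_platforms(_ccs_list(M, a, "A"), _ccs_list(M, b, "B"))
    expected = 100 * 0.02 / 1.01
    assert result.mean_relative_difference == pytest.approx(expected, abs=1e-9)
    assert result.max_relative_difference == pytest.approx(expected, abs=1e-9)
    assert result.r_squared == pytest.approx(1.0, abs=1e-12)
    assert result.n_b_larger == 4 and result.n_a_larger == 0


def test_compare_is_symmetric(M):
    a = {(2, 1): 418.0, (4, 2): 702.0}
    b = {(2, 1): 425.0, (4, 2): 690.0}
    r_ab = om.compare_platforms(_ccs_list(M, a, "A"), _ccs_list(M, b, "B"))
    r_ba = om.compare_platforms(_ccs_list(M, b, "B"), _ccs_list(M, a, "A"))
    assert r_ab.mean_relative_difference == pytest.approx(r_ba.mean_relative_difference)
    assert r_ab.max_relative_difference == pytest.approx(r_ba.max_relative_difference)


def test_compare_no_overlap_returns_none(M):
    a = _ccs_list(M, {(2, 1): 418.0}, "A")
    b = _ccs_list(M, {(4, 2): 702.0}, "B")
    assert om.compare_platforms(a, b) is None


def test_compare_matches_on_exact_nz_only(M):
    a = _ccs_list(M, {(2, 1): 418.0, (4, 2): 702.0}, "A")
    b = _ccs_list(M, {(2, 1): 420.0, (6, 3): 951.0}, "B")
    result = om.compare_platforms(a, b)
    assert result.species == [(2, 1)]
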