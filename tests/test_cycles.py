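"""Cycle-test analysis on hand-built profiles with known rates and ratios."""

import numpy as np
import pytest

from ebpr.biomass import PolymerPanel, SolidsPanel, cmol_to_mass, mass_to_cmol
from ebpr.cycles import (
    CycleProfile,
    WindowPolicy,
    analyze_cycle,
    compute_stoichiometry,
    convert_rate_basis,
    estimate_maintenance_rate,
    estimate_release_rate,
    estimate_uptake_rate,
    read_cycle_csv,
)
from ebpr.synthetic import make_fixtures

# hand-built anaerobic profile: 12.6 C-mmol/L acetate taken up at 8.4
# C-mmol/(L·h) (exhaustion at 90 min), P released at 2.0 P-mmol/(L·h) during
# uptake and 0.1 P-mmol/(L·h) maintenance afterwards; 2.0 g/L active biomass.
HAC0 = 12.6
UPTAKE_VOL = 8.4  # C-mmol/(L·h)
RELEASE_VOL = 2.0  # P-mmol/(L·h)
MAINT_VOL = 0.1  # P-mmol/(L·h)
T_EXH_H = HAC0 / UPTAKE_VOL  # 1.5 h
ACTIVE_G = 2.0
X_CMOL = mass_to_cmol(ACTIVE_G, "active_biomass")

# begin/end polymer pools in C-mmol/L: Δgly = 12.6, Δphb = 13.86, Δphv = 2.52
BEGIN_CM = {"glycogen": 30.0, "phb": 2.0, "phv": 1.0}
END_CM = {"glycogen": 17.4, "phb": 15.86, "phv": 3.52}


def _panel(cm):
    return PolymerPanel(
        phb=cmol_to_mass(cm["phb"], "phb"),
        phv=cmol_to_mass(cm["phv"], "phv"),
        glycogen=cmol_to_mass(cm["glycogen"], "glycogen"),
    )


def make_profile():
    t = np.arange(0.0, 130.0, 5.0)
    t_h = t / 60.0
    hac = np.maximum(HAC0 - UPTAKE_VOL * t_h, 0.0)
    po4 = 0.5 + RELEASE_VOL * np.minimum(t_h, T_EXH_H) + MAINT_VOL * np.maximum(
        t_h - T_EXH_H, 0.0
    )
    begin_poly = _panel(BEGIN_CM)
    end_poly = _panel(END_CM)
    vss_begin = ACTIVE_G + begin_poly.total / 1000.0
    vss_end = ACTIVE_G + end_poly.total / 1000.0
    return CycleProfile(
        t_min=t,
        po4=po4,
        hac=hac,
        anaerobic_end_min=125.0,
        begin_solids=SolidsPanel(tss=vss_begin + 0.5, vss=vss_begin, iss=0.5),
        end_solids=SolidsPanel(tss=vss_end + 0.5, vss=vss_end, iss=0.5),
        begin_polymers=begin_poly,
        end_polymers=end_poly,
    )


class TestProfileValidation:
    def test_non_increasing_time_rejected(self):
        p = make_profile()
        with pytest.raises(ValueError, match="strictly increasing"):
            CycleProfile(
                t_min=np.array([0.0, 5.0, 5.0]),
                po4=np.zeros(3), hac=np.ones(3), anaerobic_end_min=5.0,
                begin_solids=p.begin_solids, end_solids=p.end_solids,
                begin_polymers=p.begin_polymers, end_polymers=p.end_polymers,
            )

    def test_length_mismatch_rejected(self):
        p = make_profile()
        with pytest.raises(ValueError, match="equal length"):
            CycleProfile(
                t_min=np.array([0.0, 5.0]),
                po4=np.zeros(3), hac=np.ones(2), anaerobic_end_min=5.0,
                begin_solids=p.begin_solids, end_solids=p.end_solids,
                begin_polymers=p.begin_polymers, end_polymers=p.end_polymers,
            )

    def test_active_biomass_from_begin_panels(self):
        p = make_profile()
        assert p.active_biomass_g == pytest.approx(ACTIVE_G, rel=1e-12)
        assert p.active_biomass_cmol == pytest.approx(X_CMOL, rel=1e-12)


class TestUptakeRate:
    def test_exact_slope_and_window(self):
        rate = estimate_uptake_rate(make_profile())
        assert rate.per_cmol == pytest.approx(UPTAKE_VOL / X_CMOL, rel=1e-9)
        assert rate.per_gvss == pytest.approx(
            UPTAKE_VOL / make_profile().begin_solids.vss, rel=1e-9
        )
        # the window stops where acetate falls below 10% of its initial value
        assert rate.window == (0.0, 80.0)
        assert rate.r2 == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_resolution_raises(self):
        p = make_profile()
        # keep only two samples before the 10% floor
        keep = np.array([0, 10, 17, 18])  # 0, 50 min eligible; 85, 90 not
        with pytest.raises(ValueError, match="insufficient resolution"):
            estimate_uptake_rate(
                CycleProfile(
                    t_min=p.t_min[keep], po4=p.po4[keep], hac=p.hac[keep],
                    anaerobic_end_min=125.0,
                    begin_solids=p.begin_solids, end_solids=p.end_solids,
                    begin_polymers=p.begin_polymers, end_polymers=p.end_polymers,
                ),
                WindowPolicy(min_points=3),
            )


class TestReleaseRate:
    def test_exact_slope(self):
        rate = estimate_release_rate(make_profile())
        assert rate.per_cmol == pytest.approx(RELEASE_VOL / X_CMOL, rel=1e-9)
        assert rate.window == (0.0, 80.0)

    def test_flat_series_gives_zero_rate(self):
        p = make_profile()
        flat = CycleProfile(
            t_min=p.t_min, po4=np.full_like(p.po4, 0.5), hac=p.hac,
            anaerobic_end_min=125.0,
            begin_solids=p.begin_solids, end_solids=p.end_solids,
            begin_polymers=p.begin_polymers, end_polymers=p.end_polymers,
        )
        rate = estimate_release_rate(flat)
        assert rate.per_cmol == 0.0
        assert rate.r2 == 1.0


class TestMaintenanceRate:
    def test_exact_tail_slope(self):
        rate = estimate_maintenance_rate(make_profile())
        assert rate.per_cmol == pytest.approx(MAINT_VOL / X_CMOL, rel=1e-9)
        # the tail starts at the first sample with <= 5% of initial acetate
        assert rate.window[0] == pytest.approx(90.0)
        assert rate.window[1] == pytest.approx(125.0)

    def test_no_exhaustion_raises(self):
        p = make_profile()
        hac = np.maximum(p.hac, 2.0)  # never drops below the 5% threshold
        prof = CycleProfile(
            t_min=p.t_min, po4=p.po4, hac=hac, anaerobic_end_min=125.0,
            begin_solids=p.begin_solids, end_solids=p.end_solids,
            begin_polymers=p.begin_polymers, end_polymers=p.end_polymers,
        )
        with pytest.raises(ValueError, match="no maintenance window"):
            estimate_maintenance_rate(prof)
        # analyze_cycle degrades gracefully to m_p = None
        rates, _ = analyze_cycle(prof)
        assert rates.m_p is None


class TestStoichiometry:
    def test_maintenance_corrected_ratios(self):
        s = compute_stoichiometry(make_profile())
        # total release 3.0 + maintenance tail; the correction removes exactly
        # the maintenance part, leaving the uptake-coupled 3.0 P-mmol/L
        assert s.p_hac == pytest.approx(3.0 / 12.6, rel=1e-9)
        assert s.gly_hac == pytest.approx(1.0, rel=1e-9)
        assert s.phb_hac == pytest.approx(1.1, rel=1e-9)
        assert s.phv_hac == pytest.approx(0.2, rel=1e-9)
        assert s.phv_phb == pytest.approx(0.2 / 1.1, rel=1e-9)
        assert s.gly_phb == pytest.approx(1.0 / 1.1, rel=1e-9)
        assert s.flags == ()

    def test_without_correction_p_hac_is_inflated(self):
        # the raw delta includes the maintenance release
        p = make_profile()
        d_p_raw = p.po4[-1] - p.po4[0]
        assert d_p_raw > 3.0
        s = compute_stoichiometry(p)
        assert s.p_hac < d_p_raw / 12.6

    def test_no_acetate_consumed_raises(self):
        p = make_profile()
        prof = CycleProfile(
            t_min=p.t_min, po4=p.po4, hac=np.full_like(p.hac, 5.0),
            anaerobic_end_min=125.0,
            begin_solids=p.begin_solids, end_solids=p.end_solids,
            begin_polymers=p.begin_polymers, end_polymers=p.end_polymers,
        )
        with pytest.raises(ValueError, match="no acetate consumed"):
            compute_stoichiometry(prof)

    def test_negative_polymer_formation_is_flagged(self):
        p = make_profile()
        prof = CycleProfile(
            t_min=p.t_min, po4=p.po4, hac=p.hac, anaerobic_end_min=125.0,
            begin_solids=p.begin_solids, end_solids=p.end_solids,
            begin_polymers=p.end_polymers, end_polymers=p.begin_polymers,  # swapped
        )
        s = compute_stoichiometry(prof)
        assert "negative_polymer_formation" in s.flags
        assert "negative_glycogen_consumption" in s.flags
        assert s.phb_hac < 0


class TestRateBasisConversion:
    def test_round_trip(self):
        solids = make_profile().begin_solids
        poly = make_profile().begin_polymers
        per_gvss = 6.0
        per_cmol = convert_rate_basis(per_gvss, solids, poly, to="per_cmol")
        back = convert_rate_basis(per_cmol, solids, poly, to="per_gvss")
        assert back == pytest.approx(per_gvss, rel=1e-12)

    def test_matches_estimator_bases(self):
        p = make_profile()
        rate = estimate_uptake_rate(p)
        assert convert_rate_basis(
            rate.per_gvss, p.begin_solids, p.begin_polymers, to="per_cmol"
        ) == pytest.approx(rate.per_cmol, rel=1e-12)

    def test_unknown_basis_rejected(self):
        p = make_profile()
        with pytest.raises(ValueError, match="unknown basis"):
            convert_rate_basis(1.0, p.begin_solids, p.begin_polymers, to="per_litre")


def test_csv_round_trip(tmp_path):
    """A profile written by the fixture generator reloads to the same analysis."""
    paths = make_fixtures(seed=7, out_dir=tmp_path)
    prof = read_cycle_csv(tmp_path / "cycle_profile.csv", tmp_path / "cycle_panels.yaml")
    assert prof.volume_l == 2.5
    assert prof.feed_volume_l == 1.25
    rates, stoich = analyze_cycle(prof)
    assert rates.qsa_max.per_cmol > 0
    assert stoich.p_hac > 0
    assert (tmp_path / "sbr_config.yaml").exists()
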