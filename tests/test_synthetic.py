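"""Synthetic SBR generator: geometry, mass balances, noise, determinism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebpr.biomass import SolidsPanel
from ebpr.cycles import analyze_cycle
from ebpr.polyp import MASS_P, polyp_from_solids
from ebpr.synthetic import (
    NoiseModel,
    SBRConfig,
    TrueState,
    make_fixtures,
    simulate_cycle,
    simulate_to_steady_state,
    table1_schedule,
)


class TestConfig:
    def test_geometry_invariants(self, config):
        assert config.exchange_fraction == 0.5
        assert config.wastage_fraction == pytest.approx(1.0 / 32.0, rel=1e-12)
        assert config.anaerobic_react_h == pytest.approx(125.0 / 60.0, rel=1e-12)

    def test_invalid_exchange_volume(self):
        with pytest.raises(ValueError, match="exchange volume"):
            SBRConfig(exchange_volume_l=3.0)

    def test_phase_durations_must_sum(self):
        with pytest.raises(ValueError, match="sum to the cycle"):
            SBRConfig(anaerobic_h=3.0)

    def test_srt_below_hrt_rejected(self):
        with pytest.raises(ValueError, match="SRT"):
            SBRConfig(srt_d=0.25)

    def test_influent_uses_built_in_medium(self, config):
        inf = config.influent(0.64)
        assert inf.tp == pytest.approx(0.64, rel=1e-9)
        assert inf.hac == pytest.approx(12.6, abs=0.05)


class TestTrueState:
    def test_lam_half_at_anchor_ratio(self, config):
        st_ = TrueState(x_cmol=20.0, polyp_pmol=3.0, gly_cmol=10.0)
        assert st_.polyp_pmol / st_.gly_cmol == pytest.approx(config.lam_anchor)
        assert st_.lam(config) == pytest.approx(0.5, rel=1e-12)

    def test_lam_edge_cases(self, config):
        assert TrueState(x_cmol=20.0, polyp_pmol=1.0, gly_cmol=0.0).lam(config) == 1.0
        assert TrueState(x_cmol=20.0, polyp_pmol=0.0, gly_cmol=0.0).lam(config) == 0.0
        assert TrueState(x_cmol=20.0, polyp_pmol=0.0, gly_cmol=5.0).lam(config) == 0.0

    @given(p1=st.floats(0.0, 10.0), p2=st.floats(0.0, 10.0))
    def test_lam_monotone_in_polyp(self, p1, p2):
        config = SBRConfig()
        lo, hi = sorted([p1, p2])
        s_lo = TrueState(x_cmol=20.0, polyp_pmol=lo, gly_cmol=8.0)
        s_hi = TrueState(x_cmol=20.0, polyp_pmol=hi, gly_cmol=8.0)
        assert s_hi.lam(config) >= s_lo.lam(config)

    @given(polyp=st.floats(0.0, 10.0), gly=st.floats(0.1, 20.0), x=st.floats(1.0, 50.0))
    @settings(max_examples=50)
    def test_solids_panel_inverts_to_polyp(self, polyp, gly, x):
        """The emitted ash decodes back to the true poly-P pool exactly."""
        config = SBRConfig()
        state = TrueState(x_cmol=x, polyp_pmol=polyp, gly_cmol=gly)
        est = polyp_from_solids(state.solids_panel(config), config.polyp_params)
        assert est.polyp_p == pytest.approx(polyp * MASS_P, rel=1e-9, abs=1e-9)

    def test_negative_pool_rejected(self):
        with pytest.raises(ValueError):
            TrueState(x_cmol=20.0, polyp_pmol=-1.0, gly_cmol=5.0)


class TestMassBalances:
    @pytest.mark.parametrize("dose", [0.48, 0.64, 0.96, 1.44])
    def test_phosphorus_ledger_closes(self, config, dose):
        state = TrueState(x_cmol=25.0, polyp_pmol=4.0, gly_cmol=12.0, po4_mmol=0.05)
        res = simulate_cycle(state, config, phosphate_mmol=dose)
        assert abs(res.ledger["p_closure"]) < 1e-12

    def test_ledger_closes_along_a_trajectory(self, config):
        state = TrueState(x_cmol=20.0, polyp_pmol=2.0, gly_cmol=10.0, po4_mmol=0.1)
        for _ in range(25):
            res = simulate_cycle(state, config, phosphate_mmol=0.64)
            assert abs(res.ledger["p_closure"]) < 1e-12
            state = res.state

    def test_anaerobic_carbon_closure(self, config, noiseless_cycle):
        led = noiseless_cycle.ledger
        # HAc consumed + glycogen consumed = PHA formed + anaerobic CO2
        lhs = led["hac_consumed"] + led["gly_consumed_anaerobic"]
        rhs = led["pha_formed_anaerobic"] + led["co2_anaerobic"]
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestNoiselessRoundTrip:
    def test_rates_recovered_exactly(self, noiseless_cycle):
        rates, _ = analyze_cycle(noiseless_cycle.profile)
        assert rates.qsa_max.per_cmol == pytest.approx(
            noiseless_cycle.true_qsa, rel=1e-9
        )
        assert rates.qp_max.per_cmol == pytest.approx(
            noiseless_cycle.true_qp, rel=1e-9
        )

    def test_maintenance_rate_recovered_exactly(self, noiseless_cycle):
        rates, _ = analyze_cycle(noiseless_cycle.profile)
        assert rates.m_p is not None, "acetate should exhaust within the cycle"
        assert rates.m_p.per_cmol == pytest.approx(noiseless_cycle.true_m_p, rel=1e-9)

    def test_stoichiometry_recovered_exactly(self, noiseless_cycle):
        _, stoich = analyze_cycle(noiseless_cycle.profile)
        truth = noiseless_cycle.true_stoichiometry
        assert stoich.p_hac == pytest.approx(truth.p_hac, abs=1e-9)
        assert stoich.gly_hac == pytest.approx(truth.gly_hac, abs=1e-9)
        assert stoich.phb_hac == pytest.approx(truth.phb_hac, abs=1e-9)
        assert stoich.phv_hac == pytest.approx(truth.phv_hac, abs=1e-9)

    def test_profile_structure(self, config, noiseless_cycle):
        prof = noiseless_cycle.profile
        assert prof.anaerobic_end_min == pytest.approx(125.0)
        assert prof.t_min[0] == 0.0
        assert prof.t_min[-1] == pytest.approx((125.0 / 60.0 + config.aerobic_h) * 60.0)
        assert np.all(prof.po4 >= 0)
        assert np.all(prof.hac >= 0)
        assert prof.volume_l == config.working_volume_l


class TestNoise:
    def test_same_seed_reproduces_bitwise(self, config, steady_phase0):
        a = simulate_cycle(steady_phase0.state, config, noise=NoiseModel(seed=11))
        b = simulate_cycle(steady_phase0.state, config, noise=NoiseModel(seed=11))
        assert np.array_equal(a.profile.po4, b.profile.po4)
        assert np.array_equal(a.profile.hac, b.profile.hac)
        assert a.profile.begin_solids == b.profile.begin_solids

    def test_different_seeds_differ(self, config, steady_phase0):
        a = simulate_cycle(steady_phase0.state, config, noise=NoiseModel(seed=11))
        b = simulate_cycle(steady_phase0.state, config, noise=NoiseModel(seed=12))
        assert not np.array_equal(a.profile.po4, b.profile.po4)

    def test_noise_leaves_true_state_exact(self, config, steady_phase0):
        clean = simulate_cycle(steady_phase0.state, config)
        noisy = simulate_cycle(steady_phase0.state, config, noise=NoiseModel(seed=3))
        assert clean.state == noisy.state
        assert clean.true_stoichiometry == noisy.true_stoichiometry

    def test_zero_rsd_is_exact(self, config, steady_phase0):
        none_ = simulate_cycle(steady_phase0.state, config)
        zero = simulate_cycle(
            steady_phase0.state, config,
            noise=NoiseModel(rsd={k: 0.0 for k in
                                  ("po4", "hac", "tss", "vss", "phb", "phv", "gly")},
                             seed=5),
        )
        assert np.allclose(none_.profile.po4, zero.profile.po4)
        assert np.allclose(none_.profile.hac, zero.profile.hac)

    def test_truncation_keeps_values_nonnegative(self):
        nm = NoiseModel(rsd={"po4": 5.0}, seed=0)
        rng = nm.generator()
        out = nm.perturb(np.full(1000, 0.01), "po4", rng)
        assert np.all(out >= 0.0)

    def test_negative_rsd_rejected(self):
        with pytest.raises(ValueError):
            NoiseModel(rsd={"po4": -0.1})


class TestSteadyState:
    def test_phase0_converges(self, steady_phase0):
        assert steady_phase0.converged
        assert steady_phase0.cycles_run < 4000
        assert steady_phase0.state.x_cmol > 0
        assert steady_phase0.effluent_po4_mmol >= 0

    def test_start_state_is_a_fixed_point(self, config, steady_phase0):
        res = simulate_cycle(steady_phase0.state, config, phosphate_mmol=0.64)
        assert res.state.x_cmol == pytest.approx(steady_phase0.state.x_cmol, rel=1e-5)
        assert res.state.polyp_pmol == pytest.approx(
            steady_phase0.state.polyp_pmol, rel=1e-4
        )
        assert res.state.gly_cmol == pytest.approx(steady_phase0.state.gly_cmol, rel=1e-4)

    def test_table_schedule_covers_six_phases(self):
        sched = table1_schedule()
        assert [p for p, _ in sched] == [0, 1, 2, 3, 4, 5]
        assert [d for _, d in sched] == [0.64, 0.48, 0.96, 1.44, 0.48, 0.64]

    def test_washout_raises(self, config):
        dead = TrueState(x_cmol=20.0, polyp_pmol=0.0, gly_cmol=0.0)
        with pytest.raises(RuntimeError, match="washout"):
            simulate_to_steady_state(
                config, phase_schedule=[(0, 0.64)], initial_state=dead
            )

    def test_trajectory_recording(self, config):
        _, traj = simulate_to_steady_state(
            config, phase_schedule=[(0, 0.64)], record_trajectory=True
        )
        assert traj is not None
        assert set(traj.columns) >= {"phase", "cycle", "x_cmol", "polyp_pmol", "lam"}
        assert (traj["x_cmol"] > 0).all()


class TestFixtures:
    def test_identical_seeds_identical_bytes(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_fixtures(seed=42, out_dir=d1)
        make_fixtures(seed=42, out_dir=d2)
        for f in sorted(d1.iterdir()):
            assert f.read_bytes() == (d2 / f.name).read_bytes()

    def test_different_seeds_differ(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        make_fixtures(seed=1, out_dir=d1)
        make_fixtures(seed=2, out_dir=d2)
        assert (d1 / "cycle_profile.csv").read_bytes() != (
            d2 / "cycle_profile.csv"
        ).read_bytes()

    def test_fixture_files_are_small(self, tmp_path):
        paths = make_fixtures(seed=0, out_dir=tmp_path)
        assert {p.name for p in paths} == {
            "cycle_profile.csv", "cycle_panels.yaml",
            "panels_timeseries.csv", "sbr_config.yaml",
        }
        for p in paths:
            assert p.stat().st_size < 64_000
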