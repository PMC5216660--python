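"""Synthetic SBR data generator for enriched PAO cultures.

Generates per-cycle anaerobic/aerobic profiles and multi-phase long-term
trajectories with the mass-balance structure the analysis modules assume, so
every estimator in the package can be tested against known ground truth.

The model is deliberately semi-mechanistic:

* **anaerobic phase** — zero-order acetate uptake at the state's true
  specific rate, with a stoichiometry set by the culture's position on the
  poly-P/glycogen metabolic continuum (the mixing coefficient ``lam`` of
  :mod:`ebpr.shift`, tied to the poly-P/glycogen ratio by a saturating map);
  after acetate exhaustion, maintenance P release only.
* **aerobic phase** — balance closure, not kinetics: PHA is consumed,
  glycogen is replenished toward a buffer target, net growth takes a fixed
  yield on the acetate consumed, and soluble P is taken up into poly-P up to
  a capacity ceiling.  Only the anaerobic phase is analysed upstream, so
  aerobic detail would add parameters without adding testable structure.
* **wastage** — a fixed fraction of all particulate pools per cycle enforces
  the solids retention time.

All randomness enters through one seeded generator and only perturbs the
*emitted* measurements; the true state stays exact, which is what makes the
generator usable as an oracle.  The inorganic solids of emitted panels are
reconstructed as baseline ash plus poly-P ash (the inverse of the ash-route
poly-P estimator), and the organic-phosphorus ledger uses the same P-per-VSS
convention as the mass-balance estimator, so at steady state both estimators
are exact on noiseless panels by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomass import BiomassState, PolymerPanel, SolidsPanel, cmol_to_mass
from .chemistry import (
    InfluentComposition,
    PHASE_PHOSPHATE_MMOL,
    acetate_medium,
    characterize_medium,
)
from .cycles import AnaerobicStoichiometry, CycleProfile
from .polyp import MASS_P, PolyPParams
from .shift import EndMembers, default_end_members, predict_stoichiometry

__all__ = [
    "SBRConfig",
    "TrueState",
    "NoiseModel",
    "CycleResult",
    "PhaseSteadyState",
    "simulate_cycle",
    "simulate_to_steady_state",
    "make_fixtures",
    "table1_schedule",
]


@dataclass(frozen=True)
class SBRConfig:
    """Reactor geometry, cycle structure and culture parameters.

    The hydraulic retention time is never set: it emerges from the working
    volume, exchange volume and cycle length (2.5 L, 1.25 L, 6 h give 12 h).

    Culture parameters not fixed by the study design (net growth yield,
    glycogen buffer, poly-P capacity, maintenance coefficient, the lam-map
    anchor) are generator choices documented in the methods note.
    """

    working_volume_l: float = 2.5
    exchange_volume_l: float = 1.25
    cycle_h: float = 6.0
    anaerobic_h: float = 2.25
    aerobic_h: float = 2.25
    settle_h: float = 1.5
    sparge_min: float = 5.0
    feed_min: float = 5.0
    srt_d: float = 8.0
    # culture / closure parameters
    qsa_max: float = 198.0  # C-mmol HAc/(C-mol active biomass · h)
    m_p: float = 2.5  # maintenance P release, P-mmol/(C-mol · h)
    y_net: float = 0.30  # net growth yield over a full cycle, C-mol X/C-mol HAc
    gly_buffer_cycles: float = 3.0  # glycogen store, in cycles of anaerobic demand
    polyp_cap: float = 0.30  # max poly-P per active biomass, P-mol/C-mol
    lam_anchor: float = 0.3  # poly-P/glycogen ratio at which lam = 0.5
    ks_hac: float | None = None  # Monod half-saturation (C-mmol/L); None = zero-order
    end_members: EndMembers = field(default_factory=default_end_members)
    polyp_params: PolyPParams = field(default_factory=PolyPParams)

    def __post_init__(self) -> None:
        if self.exchange_volume_l <= 0 or self.exchange_volume_l > self.working_volume_l:
            raise ValueError("exchange volume must lie in (0, working volume]")
        if abs(self.anaerobic_h + self.aerobic_h + self.settle_h - self.cycle_h) > 1e-9:
            raise ValueError("phase durations must sum to the cycle length")
        if self.srt_d * 24.0 < self.hrt_h:
            raise ValueError(f"SRT ({self.srt_d} d) must be >= HRT ({self.hrt_h} h)")

    @property
    def hrt_h(self) -> float:
        """Hydraulic retention time (h), emerging from geometry and cycle."""
        return self.cycle_h * self.working_volume_l / self.exchange_volume_l

    @property
    def exchange_fraction(self) -> float:
        return self.exchange_volume_l / self.working_volume_l

    @property
    def wastage_fraction(self) -> float:
        """Fraction of particulate pools wasted per cycle (sets the SRT)."""
        return self.cycle_h / (self.srt_d * 24.0)

    @property
    def anaerobic_react_h(self) -> float:
        """Anaerobic reaction window after sparge and feed, h."""
        return self.anaerobic_h - (self.sparge_min + self.feed_min) / 60.0

    def influent(self, phosphate_mmol: float) -> InfluentComposition:
        return characterize_medium(acetate_medium(phosphate_mmol))


@dataclass(frozen=True)
class TrueState:
    """Exact reactor state, pools in mmol per litre of mixed liquor."""

    x_cmol: float  # active biomass, C-mmol/L
    polyp_pmol: float  # poly-P, P-mmol/L
    gly_cmol: float
    phb_cmol: float = 0.0
    phv_cmol: float = 0.0
    po4_mmol: float = 0.0  # soluble orthophosphate, P-mmol/L
    hac_mmol: float = 0.0  # soluble acetate, C-mmol/L

    def __post_init__(self) -> None:
        vals = [self.x_cmol, self.polyp_pmol, self.gly_cmol, self.phb_cmol,
                self.phv_cmol, self.po4_mmol, self.hac_mmol]
        if min(vals) < -1e-12:
            raise ValueError(f"pools must be >= 0, got {vals}")

    def lam(self, config: SBRConfig) -> float:
        """Metabolic mixing coefficient from the poly-P/glycogen ratio.

        Saturating map r/(r + anchor): half-way between the depleted and
        saturated metabolisms at the anchor ratio.
        """
        if self.gly_cmol <= 0:
            return 1.0 if self.polyp_pmol > 0 else 0.0
        r = self.polyp_pmol / self.gly_cmol
        return r / (r + config.lam_anchor)

    def stoichiometry(self, config: SBRConfig) -> AnaerobicStoichiometry:
        """True anaerobic stoichiometry at the state's current lam."""
        return predict_stoichiometry(self.lam(config), config.end_members)

    def vss_g(self) -> float:
        return (
            cmol_to_mass(self.x_cmol, "active_biomass")
            + cmol_to_mass(self.gly_cmol, "glycogen")
            + cmol_to_mass(self.phb_cmol, "phb")
            + cmol_to_mass(self.phv_cmol, "phv")
        ) / 1000.0

    def organic_p_mmol(self, config: SBRConfig) -> float:
        """Organically bound (non-poly-P) biomass P, P-mmol/L.

        Booked at f_P,bVSS per unit VSS — the convention the mass-balance
        poly-P estimator assumes.
        """
        return config.polyp_params.f_p_bvss * self.vss_g() * 1000.0 / MASS_P

    def solids_panel(self, config: SBRConfig) -> SolidsPanel:
        """Noiseless TSS/VSS/ISS: baseline ash plus poly-P ash."""
        p = config.polyp_params
        vss = self.vss_g()
        iss = (
            p.f_issb_tss / (1.0 - p.f_issb_tss) * vss
            + self.polyp_pmol * MASS_P / p.f_p_ppiss / 1000.0
        )
        return SolidsPanel(tss=vss + iss, vss=vss, iss=iss)

    def polymer_panel(self) -> PolymerPanel:
        return PolymerPanel(
            phb=cmol_to_mass(self.phb_cmol, "phb"),
            phv=cmol_to_mass(self.phv_cmol, "phv"),
            glycogen=cmol_to_mass(self.gly_cmol, "glycogen"),
        )

    def biomass_state(self) -> BiomassState:
        return BiomassState(
            active_cmol=self.x_cmol / 1000.0,
            polyp_pmol=self.polyp_pmol / 1000.0,
            glycogen_cmol=self.gly_cmol / 1000.0,
            phb_cmol=self.phb_cmol / 1000.0,
            phv_cmol=self.phv_cmol / 1000.0,
        )


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian measurement noise, truncated at zero.

    One relative standard deviation per analyte; a single seeded generator
    drives every draw so fixtures are reproducible bit-for-bit.
    """

    rsd: dict[str, float] = field(
        default_factory=lambda: {
            "po4": 0.02, "hac": 0.02, "tss": 0.02, "vss": 0.02,
            "phb": 0.02, "phv": 0.02, "gly": 0.02,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.rsd.values()):
            raise ValueError("relative standard deviations must be >= 0")

    def generator(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values, analyte: str, rng: np.random.Generator):
        arr = np.asarray(values, dtype=float)
        s = self.rsd.get(analyte, 0.0)
        if s == 0.0:
            return arr if arr.ndim else float(arr)
        noisy = np.maximum(arr * (1.0 + s * rng.standard_normal(arr.shape)), 0.0)
        return noisy if arr.ndim else float(noisy)


# ---------------------------------------------------------------------------
# cycle core


@dataclass(frozen=True)
class _AnaerobicRecord:
    """Exact piecewise-linear anaerobic trajectory of one cycle."""

    hac0: float
    po4_0: float
    uptake_rate_vol: float  # C-mmol/(L·h)
    release_rate_vol: float  # P-mmol/(L·h), during acetate uptake
    t_stop_h: float  # end of the uptake segment (exhaustion or window end)
    exhausted: bool  # True if acetate ran out before the window ended
    maintenance_rate_vol: float  # P-mmol/(L·h) after exhaustion
    duration_h: float
    hac_end: float
    po4_end: float


@dataclass(frozen=True)
class _CycleStep:
    state_next: TrueState  # start of next cycle (post-wastage, post-decant basis)
    state_end_anaerobic: TrueState
    state_end_aerobic: TrueState  # pre-wastage
    record: _AnaerobicRecord
    stoichiometry: AnaerobicStoichiometry
    lam: float
    ledger: dict[str, float]


def _advance_cycle(
    state: TrueState, influent: InfluentComposition, config: SBRConfig
) -> _CycleStep:
    """Advance the exact state through feed, anaerobic, aerobic, waste, decant."""
    fex = config.exchange_fraction
    w = config.wastage_fraction

    # --- feed: soluble species exchanged, solids stay in the reactor
    hac0 = state.hac_mmol * (1.0 - fex) + influent.hac * fex
    po4_0 = state.po4_mmol * (1.0 - fex) + influent.tp * fex
    p_fed = influent.tp * fex
    c_fed = influent.hac * fex

    lam = state.lam(config)
    s = state.stoichiometry(config)

    # --- anaerobic: zero-order uptake with stoichiometry s, then maintenance.
    # x_cmol is mmol/L and qsa_max is per C-mol, hence the /1000.
    t_window = config.anaerobic_react_h
    rate = config.qsa_max * state.x_cmol / 1000.0  # C-mmol/(L·h)

    d_hac = min(hac0, rate * t_window) if rate > 0 else 0.0
    if s.gly_hac > 0:
        d_hac = min(d_hac, state.gly_cmol / s.gly_hac)

    gly = state.gly_cmol
    polyp = state.polyp_pmol
    phb = state.phb_cmol
    phv = state.phv_cmol
    released = 0.0
    consumed = 0.0
    co2_ana = 0.0

    def _consume(amount: float, st: AnaerobicStoichiometry) -> None:
        nonlocal gly, polyp, phb, phv, released, consumed, co2_ana
        p_rel = min(st.p_hac * amount, polyp)
        polyp -= p_rel
        released += p_rel
        gly -= st.gly_hac * amount
        phb += st.phb_hac * amount
        phv += st.phv_hac * amount
        co2_ana += (1.0 + st.gly_hac - st.phb_hac - st.phv_hac) * amount
        consumed += amount

    if s.p_hac > 0 and polyp < s.p_hac * d_hac:
        # poly-P runs out mid-uptake: graceful shift to the depleted metabolism
        d_a = polyp / s.p_hac
        _consume(d_a, s)
        s_depl = predict_stoichiometry(0.0, config.end_members)
        d_b = d_hac - d_a
        if s_depl.gly_hac > 0:
            d_b = min(d_b, gly / s_depl.gly_hac)
        _consume(d_b, s_depl)
    else:
        _consume(d_hac, s)

    hac_end_ana = hac0 - consumed
    t_stop = consumed / rate if rate > 0 else 0.0
    exhausted = hac_end_ana <= 1e-12 and rate > 0

    maint_rate_vol = config.m_p * state.x_cmol / 1000.0
    if exhausted and t_stop < t_window:
        maint = min(maint_rate_vol * (t_window - t_stop), polyp)
        polyp -= maint
    else:
        maint = 0.0
    po4_end_ana = po4_0 + released + maint

    record = _AnaerobicRecord(
        hac0=hac0,
        po4_0=po4_0,
        uptake_rate_vol=rate,
        release_rate_vol=s.p_hac * rate,
        t_stop_h=t_stop,
        exhausted=exhausted,
        maintenance_rate_vol=maint_rate_vol,
        duration_h=t_window,
        hac_end=hac_end_ana,
        po4_end=po4_end_ana,
    )
    gly_consumed = state.gly_cmol - gly
    pha_formed = (phb - state.phb_cmol) + (phv - state.phv_cmol)
    state_ana = TrueState(
        x_cmol=state.x_cmol, polyp_pmol=polyp, gly_cmol=gly,
        phb_cmol=phb, phv_cmol=phv, po4_mmol=po4_end_ana, hac_mmol=hac_end_ana,
    )

    # --- aerobic closure: PHA consumed, glycogen toward target, net growth,
    # remainder oxidized
    c_avail = phb + phv
    gly_target = config.gly_buffer_cycles * s.gly_hac * c_fed
    d_gly = min(gly_target - gly, c_avail)
    growth = max(min(config.y_net * consumed, c_avail - d_gly), 0.0)
    co2_aer = c_avail - d_gly - growth + hac_end_ana  # residual acetate oxidized

    x_new = state.x_cmol + growth
    gly_new = gly + d_gly
    state_grown = TrueState(
        x_cmol=x_new, polyp_pmol=polyp, gly_cmol=gly_new,
        phb_cmol=0.0, phv_cmol=0.0, po4_mmol=po4_end_ana, hac_mmol=0.0,
    )

    # phosphorus: organic P follows the VSS; the rest refills poly-P to its cap
    d_org = state_grown.organic_p_mmol(config) - state.organic_p_mmol(config)
    po4_avail = po4_end_ana - d_org
    if po4_avail < 0:
        polyp = polyp + po4_avail  # growth P deficit drawn from poly-P
        po4_avail = 0.0
        if polyp < 0:
            raise RuntimeError("phosphorus-infeasible state: organic P demand unmet")
    cap_room = max(config.polyp_cap * x_new - polyp, 0.0)
    pp_uptake = min(po4_avail, cap_room)
    polyp_end = polyp + pp_uptake
    po4_final = po4_avail - pp_uptake

    state_aer = TrueState(
        x_cmol=x_new, polyp_pmol=polyp_end, gly_cmol=gly_new,
        phb_cmol=0.0, phv_cmol=0.0, po4_mmol=po4_final, hac_mmol=0.0,
    )

    # --- wastage of mixed-liquor solids, then supernatant decant
    state_next = TrueState(
        x_cmol=x_new * (1 - w), polyp_pmol=polyp_end * (1 - w),
        gly_cmol=gly_new * (1 - w), phb_cmol=0.0, phv_cmol=0.0,
        po4_mmol=po4_final, hac_mmol=0.0,
    )

    # phosphorus ledger per litre of working volume; the reactor inventory at
    # a cycle boundary holds only (1 - fex) of the soluble species (the rest
    # left with the previous decant)
    def _inventory(st: TrueState) -> float:
        return st.polyp_pmol + st.organic_p_mmol(config) + st.po4_mmol * (1 - fex)

    p_wasted = w * (polyp_end + state_aer.organic_p_mmol(config))
    p_eff = po4_final * fex
    ledger = {
        "p_in": p_fed,
        "p_eff": p_eff,
        "p_wasted": p_wasted,
        "p_reactor_start": _inventory(state),
        "p_reactor_end": _inventory(state_next),
        "c_in": c_fed,
        "hac_consumed": consumed,
        "p_released_uptake": released,
        "p_released_maintenance": maint,
        "gly_consumed_anaerobic": gly_consumed,
        "pha_formed_anaerobic": pha_formed,
        "co2_anaerobic": co2_ana,
        "co2_aerobic": co2_aer,
    }
    ledger["p_closure"] = (
        ledger["p_in"] - ledger["p_eff"] - ledger["p_wasted"]
        - (ledger["p_reactor_end"] - ledger["p_reactor_start"])
    )
    return _CycleStep(
        state_next=state_next,
        state_end_anaerobic=state_ana,
        state_end_aerobic=state_aer,
        record=record,
        stoichiometry=s,
        lam=lam,
        ledger=ledger,
    )


@dataclass(frozen=True)
class CycleResult:
    """One simulated cycle: emitted profile, new true state and bookkeeping."""

    profile: CycleProfile
    state: TrueState  # start-of-next-cycle (post-wastage) state
    state_end_aerobic: TrueState  # pre-wastage
    true_stoichiometry: AnaerobicStoichiometry
    true_lam: float
    true_qsa: float  # C-mmol/(C-mol·h)
    true_qp: float  # P-mmol/(C-mol·h), gross release during uptake
    true_m_p: float  # P-mmol/(C-mol·h)
    ledger: dict[str, float]


def _emit_profile(
    step: _CycleStep,
    begin: TrueState,
    config: SBRConfig,
    noise: NoiseModel | None,
    rng: np.random.Generator | None,
    sample_dt_min: float,
) -> CycleProfile:
    """Build the measured cycle profile (piecewise-linear truth + noise)."""
    rec = step.record
    t_an = np.arange(0.0, rec.duration_h * 60.0 + 1e-9, sample_dt_min)
    t_h = t_an / 60.0
    # uptake segment until t_stop, then either maintenance release (acetate
    # exhausted) or a flat tail (uptake stopped by a storage-pool limit)
    hac = np.maximum(rec.hac0 - rec.uptake_rate_vol * np.minimum(t_h, rec.t_stop_h),
                     rec.hac_end)
    po4 = rec.po4_0 + rec.release_rate_vol * np.minimum(t_h, rec.t_stop_h)
    if rec.exhausted:
        po4 = po4 + rec.maintenance_rate_vol * np.maximum(t_h - rec.t_stop_h, 0.0)
    # pool-limited release (depletion cycles) cannot exceed the true end value
    po4 = np.minimum(po4, rec.po4_end)

    # coarse aerobic tail: linear P uptake toward the end-of-aerobic value
    t_aer = np.arange(
        rec.duration_h * 60.0 + 15.0,
        (rec.duration_h + config.aerobic_h) * 60.0 + 1e-9,
        15.0,
    )
    frac = (t_aer - rec.duration_h * 60.0) / (config.aerobic_h * 60.0)
    po4_aer = rec.po4_end + (step.state_end_aerobic.po4_mmol - rec.po4_end) * frac
    hac_aer = rec.hac_end * (1.0 - frac)

    t_all = np.concatenate([t_an, t_aer])
    po4_all = np.concatenate([po4, po4_aer])
    hac_all = np.concatenate([hac, hac_aer])

    begin_solids = begin.solids_panel(config)
    end_solids = step.state_end_anaerobic.solids_panel(config)
    begin_poly = begin.polymer_panel()
    end_poly = step.state_end_anaerobic.polymer_panel()

    if noise is not None:
        if rng is None:
            rng = noise.generator()
        po4_all = noise.perturb(po4_all, "po4", rng)
        hac_all = noise.perturb(hac_all, "hac", rng)

        def _noisy_solids(panel: SolidsPanel) -> SolidsPanel:
            vss = noise.perturb(panel.vss, "vss", rng)
            iss = noise.perturb(panel.iss, "tss", rng)
            return SolidsPanel(tss=vss + iss, vss=vss, iss=iss)

        def _noisy_poly(panel: PolymerPanel) -> PolymerPanel:
            return PolymerPanel(
                phb=noise.perturb(panel.phb, "phb", rng),
                phv=noise.perturb(panel.phv, "phv", rng),
                glycogen=noise.perturb(panel.glycogen, "gly", rng),
            )

        begin_solids = _noisy_solids(begin_solids)
        end_solids = _noisy_solids(end_solids)
        begin_poly = _noisy_poly(begin_poly)
        end_poly = _noisy_poly(end_poly)

    return CycleProfile(
        t_min=t_all,
        po4=po4_all,
        hac=hac_all,
        anaerobic_end_min=rec.duration_h * 60.0,
        begin_solids=begin_solids,
        end_solids=end_solids,
        begin_polymers=begin_poly,
        end_polymers=end_poly,
        volume_l=config.working_volume_l,
        feed_volume_l=config.exchange_volume_l,
    )


def simulate_cycle(
    state: TrueState,
    config: SBRConfig = SBRConfig(),
    influent: InfluentComposition | None = None,
    noise: NoiseModel | None = None,
    rng: np.random.Generator | None = None,
    sample_dt_min: float = 5.0,
    phosphate_mmol: float | None = None,
) -> CycleResult:
    """Simulate one full SBR cycle and emit a measured profile.

    ``influent`` may be given directly or via ``phosphate_mmol`` (the built-in
    acetate medium at that orthophosphate dose); defaults to the phase-0 dose.
    """
    if influent is None:
        dose = PHASE_PHOSPHATE_MMOL[0] if phosphate_mmol is None else phosphate_mmol
        influent = config.influent(dose)
    step = _advance_cycle(state, influent, config)
    begin = TrueState(
        x_cmol=state.x_cmol, polyp_pmol=state.polyp_pmol, gly_cmol=state.gly_cmol,
        phb_cmol=state.phb_cmol, phv_cmol=state.phv_cmol,
        po4_mmol=step.record.po4_0, hac_mmol=step.record.hac0,
    )
    profile = _emit_profile(step, begin, config, noise, rng, sample_dt_min)
    return CycleResult(
        profile=profile,
        state=step.state_next,
        state_end_aerobic=step.state_end_aerobic,
        true_stoichiometry=step.stoichiometry,
        true_lam=step.lam,
        true_qsa=config.qsa_max,
        true_qp=step.stoichiometry.p_hac * config.qsa_max,
        true_m_p=config.m_p,
        ledger=step.ledger,
    )


@dataclass(frozen=True)
class PhaseSteadyState:
    phase: int
    phosphate_mmol: float
    pc_ratio: float
    state: TrueState  # start-of-cycle basis (post-wastage)
    state_end_aerobic: TrueState
    solids: SolidsPanel  # noiseless end-of-aerobic panel
    polymers: PolymerPanel
    iss_tss: float
    cycles_run: int
    converged: bool
    effluent_po4_mmol: float


def table1_schedule() -> list[tuple[int, float]]:
    """The six-phase influent phosphate schedule, (phase, P-mmol/L)."""
    return sorted(PHASE_PHOSPHATE_MMOL.items())


def simulate_to_steady_state(
    config: SBRConfig = SBRConfig(),
    phase_schedule: list[tuple[int, float]] | None = None,
    initial_state: TrueState | None = None,
    tol: float = 1e-6,
    max_cycles_per_phase: int = 4000,
    record_trajectory: bool = False,
) -> tuple[list[PhaseSteadyState], pd.DataFrame | None]:
    """Run the reactor through a schedule of influent phases to steady state.

    Each phase runs until the relative per-cycle change of every pool falls
    below ``tol`` (or ``max_cycles_per_phase`` is hit); the state carries over
    between phases, so an up-then-down schedule probes reversibility.  Raises
    on washout.
    """
    if phase_schedule is None:
        phase_schedule = table1_schedule()
    state = initial_state or TrueState(
        x_cmol=20.0, polyp_pmol=2.0, gly_cmol=10.0, po4_mmol=0.1, hac_mmol=0.0
    )
    results: list[PhaseSteadyState] = []
    rows: list[dict] = []
    for phase, dose in phase_schedule:
        influent = config.influent(dose)
        converged = False
        step = None
        n = 0
        for n in range(1, max_cycles_per_phase + 1):
            prev = state
            step = _advance_cycle(state, influent, config)
            state = step.state_next
            if state.x_cmol < 1e-6:
                raise RuntimeError(
                    f"washout in phase {phase}: active biomass fell to {state.x_cmol}"
                )
            if record_trajectory:
                rows.append({
                    "phase": phase, "cycle": n, "x_cmol": state.x_cmol,
                    "polyp_pmol": state.polyp_pmol, "gly_cmol": state.gly_cmol,
                    "po4_end": state.po4_mmol, "lam": step.lam,
                })
            # soluble P must be included: when poly-P sits at its capacity
            # ceiling the particulate pools pin long before the effluent does
            rel = max(
                abs(state.x_cmol - prev.x_cmol) / max(prev.x_cmol, 1e-12),
                abs(state.polyp_pmol - prev.polyp_pmol) / max(prev.polyp_pmol, 1e-9),
                abs(state.gly_cmol - prev.gly_cmol) / max(prev.gly_cmol, 1e-9),
                abs(state.po4_mmol - prev.po4_mmol) / max(prev.po4_mmol, 1e-9),
            )
            if rel < tol:
                converged = True
                break
        solids = step.state_end_aerobic.solids_panel(config)
        results.append(PhaseSteadyState(
            phase=phase,
            phosphate_mmol=dose,
            pc_ratio=influent.pc_ratio,
            state=state,
            state_end_aerobic=step.state_end_aerobic,
            solids=solids,
            polymers=step.state_end_aerobic.polymer_panel(),
            iss_tss=solids.iss_tss,
            cycles_run=n,
            converged=converged,
            effluent_po4_mmol=step.state_end_aerobic.po4_mmol,
        ))
    traj = pd.DataFrame(rows) if record_trajectory else None
    return results, traj


def make_fixtures(seed: int, out_dir: str | Path) -> list[Path]:
    """Write a deterministic fixture bundle for the test suite.

    Runs the reactor to steady state at the enrichment condition, then emits
    one noisy cycle test as CSV plus a sidecar YAML of panels and volumes, a
    panel time series in the standard schema, and the reactor configuration.
    Identical seeds give identical bytes.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = SBRConfig()
    steady, _ = simulate_to_steady_state(
        config, phase_schedule=[(0, PHASE_PHOSPHATE_MMOL[0])]
    )
    noise = NoiseModel(seed=seed)
    rng = noise.generator()
    res = simulate_cycle(
        steady[0].state, config, phosphate_mmol=PHASE_PHOSPHATE_MMOL[0],
        noise=noise, rng=rng,
    )
    prof = res.profile

    cycle_csv = out / "cycle_profile.csv"
    phase = np.where(prof.t_min <= prof.anaerobic_end_min + 1e-9, "anaerobic", "aerobic")
    pd.DataFrame({
        "t_min": prof.t_min,
        "phase": phase,
        "po4_Pmmol_L": np.round(prof.po4, 6),
        "hac_Cmmol_L": np.round(prof.hac, 6),
    }).to_csv(cycle_csv, index=False, float_format="%.6f")

    def _panel_dict(solids: SolidsPanel, poly: PolymerPanel) -> dict:
        return {
            "solids": {
                "tss_g_L": round(float(solids.tss), 6),
                "vss_g_L": round(float(solids.vss), 6),
                "iss_g_L": round(float(solids.iss), 6),
            },
            "polymers": {
                "phb_mg_L": round(float(poly.phb), 3),
                "phv_mg_L": round(float(poly.phv), 3),
                "gly_mg_L": round(float(poly.glycogen), 3),
            },
        }

    panels_yaml = out / "cycle_panels.yaml"
    with open(panels_yaml, "w") as fh:
        yaml.safe_dump(
            {
                "begin": _panel_dict(prof.begin_solids, prof.begin_polymers),
                "end": _panel_dict(prof.end_solids, prof.end_polymers),
                "volume_l": config.working_volume_l,
                "feed_volume_l": config.exchange_volume_l,
            },
            fh, sort_keys=True,
        )

    panels_csv = out / "panels_timeseries.csv"
    rows = []
    for label, solids, poly, t in [
        ("begin_anaerobic", prof.begin_solids, prof.begin_polymers, 0.0),
        ("end_anaerobic", prof.end_solids, prof.end_polymers, prof.anaerobic_end_min),
    ]:
        rows.append({
            "sample_id": label, "time_min": t,
            "tss_g_L": round(float(solids.tss), 6),
            "vss_g_L": round(float(solids.vss), 6),
            "phb_mg_L": round(float(poly.phb), 3),
            "phv_mg_L": round(float(poly.phv), 3),
            "gly_mg_L": round(float(poly.glycogen), 3),
        })
    pd.DataFrame(rows).to_csv(panels_csv, index=False)

    config_yaml = out / "sbr_config.yaml"
    with open(config_yaml, "w") as fh:
        yaml.safe_dump(
            {
                "working_volume_l": config.working_volume_l,
                "exchange_volume_l": config.exchange_volume_l,
                "cycle_h": config.cycle_h,
                "anaerobic_h": config.anaerobic_h,
                "aerobic_h": config.aerobic_h,
                "settle_h": config.settle_h,
                "srt_d": config.srt_d,
                "hrt_h": config.hrt_h,
                "seed": seed,
                "phase_phosphate_mmol": {int(k): v for k, v in PHASE_PHOSPHATE_MMOL.items()},
            },
            fh, sort_keys=True,
        )
    return [cycle_csv, panels_yaml, panels_csv, config_yaml]
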