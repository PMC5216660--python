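"""Anaerobic cycle-test analysis: kinetic rates and stoichiometric ratios.

A cycle test samples orthophosphate and acetate through one SBR cycle and
brackets the anaerobic phase with solids (TSS/VSS/ISS) and storage-polymer
(PHB/PHV/glycogen) panels.  From such a profile this module extracts

* the maximum acetate-uptake rate ``qSA`` and P-release rate ``qP`` from the
  initial linear segments of the respective series,
* the endogenous (maintenance) P-release rate ``mP`` from the substrate-free
  tail of the anaerobic phase, and
* the six anaerobic stoichiometric ratios P/HAc, gly/HAc, PHB/HAc, PHV/HAc,
  PHV/PHB and gly/PHB from the begin/end deltas.

Rates are normalized to active biomass and reported on two bases, per gVSS·h
and per C-mol active biomass·h.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .biomass import PolymerPanel, SolidsPanel, active_biomass, mass_to_cmol

__all__ = [
    "WindowPolicy",
    "CycleProfile",
    "SpecificRate",
    "KineticRates",
    "AnaerobicStoichiometry",
    "estimate_uptake_rate",
    "estimate_release_rate",
    "estimate_maintenance_rate",
    "compute_stoichiometry",
    "convert_rate_basis",
    "analyze_cycle",
    "read_cycle_csv",
]


@dataclass(frozen=True)
class WindowPolicy:
    """Rule for picking the initial linear segment of a concentration series.

    The fit window is the longest initial run of samples for which a linear
    fit keeps R^2 >= ``r2_min`` and acetate stays above ``floor_frac`` of its
    initial value (ties break toward the longer window).  Samples below
    ``exhaustion_frac`` of the initial acetate define the maintenance window.
    """

    r2_min: float = 0.98
    floor_frac: float = 0.10
    exhaustion_frac: float = 0.05
    min_points: int = 3


@dataclass(frozen=True)
class CycleProfile:
    """One cycle test: timed PO4/HAc series plus bracketing panels.

    ``t_min`` counts minutes from the end of feed; concentrations are already
    on the post-feed (fully mixed) volume basis.
    """

    t_min: np.ndarray
    po4: np.ndarray  # P-mmol/L
    hac: np.ndarray  # C-mmol/L
    anaerobic_end_min: float
    begin_solids: SolidsPanel
    end_solids: SolidsPanel
    begin_polymers: PolymerPanel
    end_polymers: PolymerPanel
    volume_l: float = 2.5
    feed_volume_l: float = 1.25

    def __post_init__(self) -> None:
        t = np.asarray(self.t_min, dtype=float)
        po4 = np.asarray(self.po4, dtype=float)
        hac = np.asarray(self.hac, dtype=float)
        if not (len(t) == len(po4) == len(hac)):
            raise ValueError("t, po4 and hac must have equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time points must be strictly increasing")
        if np.any(po4 < 0) or np.any(hac < 0):
            raise ValueError("concentrations must be >= 0")
        object.__setattr__(self, "t_min", t)
        object.__setattr__(self, "po4", po4)
        object.__setattr__(self, "hac", hac)

    def anaerobic_mask(self) -> np.ndarray:
        return self.t_min <= self.anaerobic_end_min + 1e-9

    @property
    def active_biomass_g(self) -> float:
        """Active biomass (g/L) from the begin-of-cycle panels."""
        return active_biomass(self.begin_solids.vss, self.begin_polymers)

    @property
    def active_biomass_cmol(self) -> float:
        return mass_to_cmol(self.active_biomass_g, "active_biomass")


@dataclass(frozen=True)
class SpecificRate:
    """A biomass-specific rate on both unit bases."""

    per_cmol: float  # mmol/(C-mol active biomass · h)
    per_gvss: float  # mmol/(gVSS · h)
    window: tuple[float, float] | None = None  # [t0, t1] minutes of the fit
    r2: float | None = None


@dataclass(frozen=True)
class KineticRates:
    qsa_max: SpecificRate
    qp_max: SpecificRate
    m_p: SpecificRate | None


@dataclass(frozen=True)
class AnaerobicStoichiometry:
    """Anaerobic conversion ratios per C-mol of acetate taken up."""

    p_hac: float  # P-mol/C-mol
    gly_hac: float  # C-mol/C-mol
    phb_hac: float  # C-mol/C-mol
    phv_hac: float  # C-mol/C-mol
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def phv_phb(self) -> float | None:
        return self.phv_hac / self.phb_hac if self.phb_hac > 0 else None

    @property
    def gly_phb(self) -> float | None:
        return self.gly_hac / self.phb_hac if self.phb_hac > 0 else None

    @property
    def phv_gly(self) -> float | None:
        return self.phv_hac / self.gly_hac if self.gly_hac > 0 else None

    def as_vector(self) -> np.ndarray:
        return np.array([self.p_hac, self.gly_hac, self.phb_hac, self.phv_hac])


def _linear_fit(t_h: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope (per hour) and R^2; a flat series fits exactly."""
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot < 1e-30:
        return 0.0, 1.0
    slope, intercept = np.polyfit(t_h, y, 1)
    resid = y - (slope * t_h + intercept)
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(slope), r2


def _initial_window(
    t_h: np.ndarray, y: np.ndarray, eligible: np.ndarray, policy: WindowPolicy
) -> tuple[float, float, tuple[float, float]]:
    """Fit the longest admissible initial window; returns (slope, r2, window)."""
    # the candidate run is the initial contiguous block of eligible samples
    n_run = int(np.argmin(eligible)) if not eligible.all() else len(eligible)
    if n_run < policy.min_points:
        raise ValueError(
            "insufficient resolution: fewer than "
            f"{policy.min_points} samples before acetate exhaustion"
        )
    best = None
    for k in range(policy.min_points, n_run + 1):
        slope, r2 = _linear_fit(t_h[:k], y[:k])
        if r2 >= policy.r2_min:
            best = (slope, r2, (float(t_h[0] * 60), float(t_h[k - 1] * 60)))
    if best is None:  # no window passes R^2: report the shortest fit, best effort
        k = policy.min_points
        slope, r2 = _linear_fit(t_h[:k], y[:k])
        best = (slope, r2, (float(t_h[0] * 60), float(t_h[k - 1] * 60)))
    return best


def _anaerobic_series(profile: CycleProfile):
    m = profile.anaerobic_mask()
    return profile.t_min[m] / 60.0, profile.po4[m], profile.hac[m]


def estimate_uptake_rate(
    profile: CycleProfile, policy: WindowPolicy = WindowPolicy()
) -> SpecificRate:
    """Maximum specific acetate-uptake rate from the initial linear segment.

    Returned positive, in C-mmol/(C-mol active biomass·h) and
    C-mmol/(gVSS·h).
    """
    t_h, _, hac = _anaerobic_series(profile)
    eligible = hac >= policy.floor_frac * hac[0] if hac[0] > 0 else np.ones_like(hac, bool)
    slope, r2, window = _initial_window(t_h, hac, eligible, policy)
    rate_vol = max(-slope, 0.0)  # C-mmol/(L·h)
    x_cmol = profile.active_biomass_cmol
    if x_cmol <= 0:
        raise ZeroDivisionError("zero active biomass: cannot normalize rate")
    return SpecificRate(
        per_cmol=rate_vol / x_cmol,
        per_gvss=rate_vol / profile.begin_solids.vss,
        window=window,
        r2=r2,
    )


def estimate_release_rate(
    profile: CycleProfile, policy: WindowPolicy = WindowPolicy()
) -> SpecificRate:
    """Maximum specific P-release rate during acetate uptake.

    The PO4 series is restricted to the acetate-present window so that
    maintenance release after exhaustion does not dilute the slope.
    """
    t_h, po4, hac = _anaerobic_series(profile)
    eligible = hac >= policy.floor_frac * hac[0] if hac[0] > 0 else np.ones_like(hac, bool)
    slope, r2, window = _initial_window(t_h, po4, eligible, policy)
    rate_vol = max(slope, 0.0)  # P-mmol/(L·h)
    x_cmol = profile.active_biomass_cmol
    if x_cmol <= 0:
        raise ZeroDivisionError("zero active biomass: cannot normalize rate")
    return SpecificRate(
        per_cmol=rate_vol / x_cmol,
        per_gvss=rate_vol / profile.begin_solids.vss,
        window=window,
        r2=r2,
    )


def estimate_maintenance_rate(
    profile: CycleProfile, policy: WindowPolicy = WindowPolicy()
) -> SpecificRate:
    """Endogenous P-release rate over the substrate-free anaerobic tail.

    Glycogen consumption for maintenance is deliberately not estimated: the
    per-cycle change is below the resolution of glycogen assays.
    """
    t_h, po4, hac = _anaerobic_series(profile)
    thresh = policy.exhaustion_frac * hac[0] if hac[0] > 0 else 0.0
    m = hac <= thresh
    if m.sum() < 2:
        raise ValueError("no maintenance window: acetate never exhausted in the cycle")
    slope, r2 = _linear_fit(t_h[m], po4[m])
    rate_vol = max(slope, 0.0)
    x_cmol = profile.active_biomass_cmol
    if x_cmol <= 0:
        raise ZeroDivisionError("zero active biomass: cannot normalize rate")
    return SpecificRate(
        per_cmol=rate_vol / x_cmol,
        per_gvss=rate_vol / profile.begin_solids.vss,
        window=(float(t_h[m][0] * 60), float(t_h[m][-1] * 60)),
        r2=r2,
    )


def compute_stoichiometry(
    profile: CycleProfile, policy: WindowPolicy = WindowPolicy()
) -> AnaerobicStoichiometry:
    """Anaerobic conversion ratios from begin/end deltas of one cycle.

    P release attributable to acetate uptake is the total anaerobic release
    minus the extrapolated maintenance release over the post-exhaustion
    window, so that the reported P/HAc reflects the uptake stoichiometry
    alone.  Negative polymer formation is flagged and reported as measured.
    """
    t_h, po4, hac = _anaerobic_series(profile)
    d_hac = hac[0] - hac[-1]
    if d_hac <= 0:
        raise ValueError(f"no acetate consumed in the anaerobic phase (ΔHAc={d_hac:.4f})")

    d_p = po4[-1] - po4[0]
    # maintenance correction: only if an exhausted tail exists
    thresh = policy.exhaustion_frac * hac[0] if hac[0] > 0 else 0.0
    tail = hac <= thresh
    if tail.sum() >= 2:
        uptake = estimate_uptake_rate(profile, policy)
        slope_vol = uptake.per_cmol * profile.active_biomass_cmol  # C-mmol/(L·h)
        if slope_vol > 0:
            t_exh = hac[0] / slope_vol  # h, extrapolated exhaustion time
            m_slope, _ = _linear_fit(t_h[tail], po4[tail])
            t_end = t_h[-1]
            d_p -= max(m_slope, 0.0) * max(t_end - t_exh, 0.0)

    gly = profile.begin_polymers.as_cmmol()["glycogen"] - profile.end_polymers.as_cmmol()["glycogen"]
    phb = profile.end_polymers.as_cmmol()["phb"] - profile.begin_polymers.as_cmmol()["phb"]
    phv = profile.end_polymers.as_cmmol()["phv"] - profile.begin_polymers.as_cmmol()["phv"]

    flags = []
    if phb < 0 or phv < 0:
        flags.append("negative_polymer_formation")
    if gly < 0:
        flags.append("negative_glycogen_consumption")
    return AnaerobicStoichiometry(
        p_hac=d_p / d_hac,
        gly_hac=gly / d_hac,
        phb_hac=phb / d_hac,
        phv_hac=phv / d_hac,
        flags=tuple(flags),
    )


def convert_rate_basis(
    rate: float,
    solids: SolidsPanel,
    polymers: PolymerPanel,
    to: str = "per_cmol",
) -> float:
    """Convert a specific rate between per-gVSS and per-C-mol-active-biomass.

    ``to="per_cmol"`` interprets ``rate`` as mmol/(gVSS·h); ``to="per_gvss"``
    as mmol/(C-mol·h).
    """
    x_g = active_biomass(solids.vss, polymers)
    x_cmol = mass_to_cmol(x_g, "active_biomass")
    if x_cmol <= 0:
        raise ZeroDivisionError("zero active biomass: basis conversion undefined")
    if to == "per_cmol":
        return rate * solids.vss / x_cmol
    if to == "per_gvss":
        return rate * x_cmol / solids.vss
    raise ValueError(f"unknown basis {to!r}; use 'per_cmol' or 'per_gvss'")


def analyze_cycle(
    profile: CycleProfile, policy: WindowPolicy = WindowPolicy()
) -> tuple[KineticRates, AnaerobicStoichiometry]:
    """Full anaerobic analysis of one cycle test."""
    qsa = estimate_uptake_rate(profile, policy)
    qp = estimate_release_rate(profile, policy)
    try:
        m_p = estimate_maintenance_rate(profile, policy)
    except ValueError:
        m_p = None
    stoich = compute_stoichiometry(profile, policy)
    return KineticRates(qsa_max=qsa, qp_max=qp, m_p=m_p), stoich


def read_cycle_csv(csv_path: str | Path, panels_yaml: str | Path) -> CycleProfile:
    """Load a cycle profile from the CSV/YAML pair written by the simulator.

    CSV columns: ``t_min, phase, po4_Pmmol_L, hac_Cmmol_L``; the sidecar YAML
    carries the begin/end panels and reactor volumes.
    """
    df = pd.read_csv(csv_path)
    with open(panels_yaml) as fh:
        side = yaml.safe_load(fh)
    ana = df[df["phase"] == "anaerobic"]
    anaerobic_end = float(ana["t_min"].max()) if len(ana) else float(df["t_min"].max())

    def _solids(d):
        return SolidsPanel(tss=d["tss_g_L"], vss=d["vss_g_L"], iss=d.get("iss_g_L"))

    def _poly(d):
        return PolymerPanel(phb=d["phb_mg_L"], phv=d["phv_mg_L"], glycogen=d["gly_mg_L"])

    return CycleProfile(
        t_min=df["t_min"].to_numpy(float),
        po4=df["po4_Pmmol_L"].to_numpy(float),
        hac=df["hac_Cmmol_L"].to_numpy(float),
        anaerobic_end_min=anaerobic_end,
        begin_solids=_solids(side["begin"]["solids"]),
        end_solids=_solids(side["end"]["solids"]),
        begin_polymers=_poly(side["begin"]["polymers"]),
        end_polymers=_poly(side["end"]["polymers"]),
        volume_l=side.get("volume_l", 2.5),
        feed_volume_l=side.get("feed_volume_l", 1.25),
    )
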