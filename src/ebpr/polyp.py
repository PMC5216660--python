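"""Poly-phosphate estimation by two independent routes, and their cross-check.

Intracellular poly-P cannot be assayed directly in routine SBR monitoring, but
it dominates the inorganic ("ash") fraction of the sludge and the phosphorus
mass balance of the reactor, which gives two independent estimators:

* **ash route** — the inorganic suspended solids above the baseline ash of
  non-EBPR biomass are attributed to poly-P with Mg/K counterions,

      poly-P [mg P/L] = (ISS - f_ISSb,TSS / (1 - f_ISSb,TSS) * VSS) * f_P,ppISS

* **mass-balance route** — at steady state the phosphorus retained in the
  sludge equals SRT/HRT times the influent-to-effluent P drop, of which the
  non-poly-P (organically bound) part is f_P,bVSS per unit VSS,

      poly-P [mg P/L] = SRT/HRT * (TP,in - TP,eff) - f_P,bVSS * VSS

Agreement of the two supports the assumptions behind both (negligible effluent
solids, no chemical P precipitation, the assumed counterion composition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemistry import ATOMIC_MASS, molar_mass, parse_formula

__all__ = [
    "MASS_P",
    "PolyPParams",
    "PBalanceInputs",
    "PolyPEstimate",
    "polyp_phosphorus_fraction",
    "polyp_from_solids",
    "polyp_from_pbalance",
    "cross_validate",
]

MASS_P = ATOMIC_MASS["P"]  # 30.974 g/mol


def polyp_phosphorus_fraction(formula: str) -> float:
    """Mass fraction of phosphorus (mg P/mg) in a poly-P repeating unit.

    The default unit, ``(PO3)3MgK``, is metaphosphate with the magnesium and
    potassium counterions found in PAO granules; its P fraction is ~0.31.
    """
    counts = parse_formula(formula)
    n_p = counts.get("P", 0.0)
    if n_p <= 0:
        raise ValueError(f"formula {formula!r} contains no phosphorus")
    return n_p * MASS_P / molar_mass(formula)


@dataclass(frozen=True)
class PolyPParams:
    """Constants of the two poly-P estimators.

    f_issb_tss : baseline ash fraction of non-EBPR biomass (mg ISS/mg TSS).
    f_p_ppiss  : P content of the poly-P ash (mg P/mg ISS), consistent with
                 ``polyp_formula``.
    f_p_bvss   : organically bound (non-poly-P) P per VSS (mg P/mg VSS).
    """

    f_issb_tss: float = 0.025
    f_p_ppiss: float = 0.31
    f_p_bvss: float = 0.023
    polyp_formula: str = "(PO3)3MgK"

    def __post_init__(self) -> None:
        for name in ("f_issb_tss", "f_p_ppiss", "f_p_bvss"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        implied = polyp_phosphorus_fraction(self.polyp_formula)
        if abs(implied - self.f_p_ppiss) > 0.005:
            raise ValueError(
                f"f_p_ppiss={self.f_p_ppiss} inconsistent with {self.polyp_formula!r} "
                f"(implies {implied:.4f})"
            )


@dataclass(frozen=True)
class PBalanceInputs:
    """Steady-state phosphorus balance inputs.

    tp_in/tp_eff are influent and effluent total P in P-mmol/L; srt and hrt in
    days (any common unit works as long as both match).
    """

    tp_in: float
    tp_eff: float
    srt: float
    hrt: float

    def __post_init__(self) -> None:
        if self.hrt <= 0 or self.srt < self.hrt:
            raise ValueError(f"need srt >= hrt > 0, got srt={self.srt}, hrt={self.hrt}")
        if self.tp_in < 0 or self.tp_eff < 0:
            raise ValueError("total P concentrations must be >= 0")


@dataclass(frozen=True)
class PolyPEstimate:
    """A poly-P concentration with method provenance and validity flags."""

    polyp_p: float  # mg P/L
    method: str  # "ash_based" | "mass_balance"
    flags: tuple[str, ...] = field(default_factory=tuple)

    @property
    def polyp_pmmol(self) -> float:
        """Poly-P in P-mmol/L."""
        return self.polyp_p / MASS_P


def polyp_from_solids(panel, params: PolyPParams = PolyPParams()) -> PolyPEstimate:
    """Ash-route poly-P estimate from a TSS/VSS/ISS panel.

    A panel whose ash ratio is below the non-EBPR baseline carries no
    detectable poly-P; the estimate is clamped to 0 and flagged rather than
    reported negative.
    """
    f = params.f_issb_tss
    raw = (panel.iss - f / (1.0 - f) * panel.vss) * params.f_p_ppiss * 1000.0
    flags: tuple[str, ...] = ()
    if panel.tss > 0 and panel.iss_tss < f:
        flags = ("below_ash_baseline",)
        raw = min(raw, 0.0)
    if raw < 0:
        flags = flags or ("below_ash_baseline",)
        raw = 0.0
    return PolyPEstimate(polyp_p=raw, method="ash_based", flags=flags)


def polyp_from_pbalance(
    inputs: PBalanceInputs, vss: float, params: PolyPParams = PolyPParams()
) -> PolyPEstimate:
    """Mass-balance-route poly-P estimate (mg P/L) at steady state.

    ``vss`` in g/L.  A negative balance (more P in biomass than the reactor
    retains) signals a violated steady-state assumption; it is reported as 0
    with a ``balance_inconsistent`` flag rather than raised, since transient
    panels are legitimate inputs during start-up.
    """
    if vss < 0:
        raise ValueError("VSS must be >= 0")
    retained = inputs.srt / inputs.hrt * (inputs.tp_in - inputs.tp_eff) * MASS_P
    raw = retained - params.f_p_bvss * vss * 1000.0
    flags: tuple[str, ...] = ()
    if raw < 0:
        flags = ("balance_inconsistent",)
        raw = 0.0
    return PolyPEstimate(polyp_p=raw, method="mass_balance", flags=flags)


# Assumptions whose failure would explain a disagreement between the routes.
_ASSUMPTIONS = (
    "negligible solids in the effluent",
    "no chemical phosphorus precipitation",
    "poly-P counterion composition (f_P,ppISS) as configured",
    "baseline ash and biomass P content representative of this culture",
)


def cross_validate(a: PolyPEstimate, b: PolyPEstimate, rel_tol: float = 0.1) -> dict:
    """Compare two poly-P estimates from different methods on one culture state.

    Returns the relative discrepancy (vs. the mean of the two), a pass/fail
    verdict at ``rel_tol``, and on failure the list of assumptions that are
    candidate explanations.  Two zero estimates are 'indeterminate'.
    """
    if a.method == b.method:
        raise ValueError("cross-validation needs estimates from different methods")
    mean = 0.5 * (a.polyp_p + b.polyp_p)
    if mean == 0:
        return {"status": "indeterminate", "discrepancy": None, "passed": None,
                "suspect_assumptions": ()}
    disc = abs(a.polyp_p - b.polyp_p) / mean
    passed = disc <= rel_tol
    return {
        "status": "pass" if passed else "fail",
        "discrepancy": disc,
        "passed": passed,
        "suspect_assumptions": () if passed else _ASSUMPTIONS,
    }
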