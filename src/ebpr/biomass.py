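"""Active-biomass accounting and C-mol unit conversions.

In cycle tests on enriched PAO sludge, the volatile suspended solids (VSS)
lump true cells together with their storage polymers (PHB, PHV, glycogen).
Active biomass is therefore computed by difference,

    active biomass = VSS - PHB - PHV - glycogen,

neglecting unbiodegradable endogenous residue, and expressed in C-mol using
the elemental composition CH2.09 O0.54 N0.20 P0.015 determined for enriched
PAO cultures.  All specific rates and stoichiometric ratios downstream are
normalized on this basis.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemistry import ATOMIC_MASS

__all__ = [
    "BiomassComposition",
    "ACTIVE_BIOMASS",
    "MONOMERS",
    "PolymerPanel",
    "SolidsPanel",
    "BiomassState",
    "active_biomass",
    "mass_to_cmol",
    "cmol_to_mass",
    "storage_ratios",
]


@dataclass(frozen=True)
class BiomassComposition:
    """Elemental composition per C-mol (C is fixed at 1)."""

    h: float
    o: float
    n: float = 0.0
    p: float = 0.0

    def __post_init__(self) -> None:
        if self.h < 0 or self.o < 0 or self.n < 0 or self.p < 0:
            raise ValueError("elemental coefficients must be >= 0")

    @property
    def molar_mass(self) -> float:
        """g per C-mol, recomputed from the coefficients."""
        return (
            ATOMIC_MASS["C"]
            + self.h * ATOMIC_MASS["H"]
            + self.o * ATOMIC_MASS["O"]
            + self.n * ATOMIC_MASS["N"]
            + self.p * ATOMIC_MASS["P"]
        )

    @property
    def degree_of_reduction(self) -> float:
        """Available electron equivalents per C-mol (NH3 as the N reference)."""
        return 4.0 + self.h - 2.0 * self.o - 3.0 * self.n + 5.0 * self.p


# Active PAO biomass: CH2.09 O0.54 N0.20 P0.015, ~26.0 g/C-mol.
ACTIVE_BIOMASS = BiomassComposition(h=2.09, o=0.54, n=0.20, p=0.015)

# Storage-polymer monomers on a per-carbon basis.  Glycogen uses the
# anhydroglucose unit C6H10O5 (27.02 g/C-mol): the glucan is what is weighed,
# not free glucose.  PHB (C4H6O2) and PHV (C5H8O2) are standard polyester
# monomer formulas.
MONOMERS: dict[str, BiomassComposition] = {
    "active_biomass": ACTIVE_BIOMASS,
    "glycogen": BiomassComposition(h=10.0 / 6.0, o=5.0 / 6.0),
    "phb": BiomassComposition(h=1.5, o=0.5),
    "phv": BiomassComposition(h=1.6, o=0.4),
    "acetate": BiomassComposition(h=2.0, o=1.0),
}


@dataclass(frozen=True)
class PolymerPanel:
    """Storage-polymer concentrations at one time point, mg/L."""

    phb: float = 0.0
    phv: float = 0.0
    glycogen: float = 0.0

    def __post_init__(self) -> None:
        if min(self.phb, self.phv, self.glycogen) < 0:
            raise ValueError("polymer concentrations must be >= 0")

    @property
    def total(self) -> float:
        return self.phb + self.phv + self.glycogen

    def as_cmmol(self) -> dict[str, float]:
        """Each polymer as C-mmol/L."""
        return {
            "phb": mass_to_cmol(self.phb / 1000.0, "phb") * 1000.0,
            "phv": mass_to_cmol(self.phv / 1000.0, "phv") * 1000.0,
            "glycogen": mass_to_cmol(self.glycogen / 1000.0, "glycogen") * 1000.0,
        }


@dataclass(frozen=True)
class SolidsPanel:
    """TSS/VSS/ISS at one time point, g/L.  ISS defaults to TSS - VSS."""

    tss: float
    vss: float
    iss: float | None = None

    def __post_init__(self) -> None:
        iss = self.tss - self.vss if self.iss is None else self.iss
        object.__setattr__(self, "iss", iss)
        if self.tss < 0 or self.vss < 0 or iss < -1e-9:
            raise ValueError("solids concentrations must be >= 0")
        if self.vss > self.tss + 1e-9:
            raise ValueError(f"VSS ({self.vss}) exceeds TSS ({self.tss})")
        if abs(self.tss - (self.vss + iss)) > 0.02 * max(self.tss, 1e-12):
            raise ValueError(
                f"TSS ({self.tss}) != VSS + ISS ({self.vss + iss}) beyond tolerance"
            )

    @property
    def iss_tss(self) -> float:
        """Ash fraction of the solids (mg ISS/mg TSS)."""
        if self.tss == 0:
            raise ZeroDivisionError("ISS/TSS undefined at zero TSS")
        return self.iss / self.tss


def active_biomass(vss: float, polymers: PolymerPanel) -> float:
    """Active biomass (g/L) as VSS minus storage polymers.

    Raises if the polymer masses exceed the VSS: such a panel is internally
    inconsistent and cannot be normalized on.
    """
    if vss < 0:
        raise ValueError("VSS must be >= 0")
    x = vss - polymers.total / 1000.0
    if x < -1e-12:
        raise ValueError(
            f"polymers ({polymers.total / 1000.0:.3f} g/L) exceed VSS ({vss:.3f} g/L): "
            "inconsistent panel"
        )
    return max(x, 0.0)


def mass_to_cmol(mass: float, monomer: str) -> float:
    """Convert g/L of a monomer to C-mol/L using its per-carbon molar mass."""
    comp = MONOMERS.get(monomer)
    if comp is None:
        raise KeyError(
            f"unknown monomer {monomer!r}; supported: {sorted(MONOMERS)}"
        )
    return mass / comp.molar_mass


def cmol_to_mass(cmol: float, monomer: str) -> float:
    """Inverse of :func:`mass_to_cmol`."""
    comp = MONOMERS.get(monomer)
    if comp is None:
        raise KeyError(
            f"unknown monomer {monomer!r}; supported: {sorted(MONOMERS)}"
        )
    return cmol * comp.molar_mass


@dataclass(frozen=True)
class BiomassState:
    """Composition of the sludge at one time point, on molar bases.

    ``polyp`` is the poly-phosphate pool in P-mol/L; storage pools are C-mol/L.
    """

    active_cmol: float
    polyp_pmol: float
    glycogen_cmol: float
    phb_cmol: float = 0.0
    phv_cmol: float = 0.0

    def __post_init__(self) -> None:
        if min(self.active_cmol, self.polyp_pmol, self.glycogen_cmol,
               self.phb_cmol, self.phv_cmol) < 0:
            raise ValueError("pools must be >= 0")

    @property
    def active_g(self) -> float:
        return cmol_to_mass(self.active_cmol, "active_biomass")


def storage_ratios(state: BiomassState) -> dict[str, float | None]:
    """Poly-P/active-biomass, glycogen/active-biomass and poly-P/glycogen ratios.

    Undefined ratios (zero denominator) are reported as ``None``, never as 0:
    a depleted culture has a poly-P/glycogen ratio of 0, but a glycogen-free
    panel has no such ratio at all.
    """
    polyp_per_x = state.polyp_pmol / state.active_cmol if state.active_cmol > 0 else None
    gly_per_x = state.glycogen_cmol / state.active_cmol if state.active_cmol > 0 else None
    polyp_per_gly = (
        state.polyp_pmol / state.glycogen_cmol if state.glycogen_cmol > 0 else None
    )
    return {
        "polyp_per_x": polyp_per_x,
        "gly_per_x": gly_per_x,
        "polyp_per_gly": polyp_per_gly,
    }
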