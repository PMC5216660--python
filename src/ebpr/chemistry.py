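"""Influent chemistry: medium recipes to molar carbon/nitrogen/phosphorus and COD.

An EBPR enrichment medium is specified as masses of named salts per litre of
influent.  Everything downstream of the recipe (acetate C-molarity, theoretical
oxygen demand, ammonium nitrogen, orthophosphate and the influent P/C ratio
that indexes each experimental phase) is derived here from chemical formulas
and a fixed atomic-mass table, so the characterization is reproducible to the
last digit.

Formula grammar
---------------
``Element``/``count`` tokens, one optional level of parenthesised groups with a
multiplier (e.g. ``(PO3)3MgK``), and one optional hydrate suffix ``.nH2O``
(e.g. ``MgSO4.7H2O``).  Nested parentheses are rejected: the grammar is sized
to mineral-salt recipes, not general organic nomenclature.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "ATOMIC_MASS",
    "FormulaError",
    "parse_formula",
    "molar_mass",
    "MediumComponent",
    "InfluentComposition",
    "component_mmolarity",
    "component_cmolarity",
    "nitrogen_mmolarity",
    "phosphorus_mmolarity",
    "theoretical_cod",
    "influent_pc_ratio",
    "characterize_medium",
    "acetate_medium",
    "PHASE_PHOSPHATE_MMOL",
]

# IUPAC 2021 standard atomic weights, abridged to two decimals.  Two decimals
# keeps results bit-stable across platforms while matching the precision the
# recipe is stated at (whole milligrams per litre).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "Al": 26.982,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Mn": 54.938,
    "Fe": 55.845,
    "Co": 58.933,
    "Ni": 58.693,
    "Cu": 63.546,
    "Zn": 65.38,
    "Mo": 95.95,
    "B": 10.81,
    "I": 126.90,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised when a chemical formula cannot be parsed."""


def _parse_flat(segment: str, counts: dict[str, float], mult: float) -> None:
    pos = 0
    while pos < len(segment):
        m = _TOKEN.match(segment, pos)
        if m is None or m.start() != pos:
            raise FormulaError(
                f"malformed formula near {segment[pos:]!r}: expected an element symbol"
            )
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {sym!r}")
        counts[sym] = counts.get(sym, 0.0) + mult * (int(num) if num else 1)
        pos = m.end()


def parse_formula(formula: str) -> dict[str, float]:
    """Parse a formula into an element → atom-count map.

    Supports element counts, single-level ``(...)n`` groups and one trailing
    ``.nH2O`` hydrate suffix.
    """
    if not formula or not formula.strip():
        raise FormulaError("empty formula")
    text = formula.strip()

    counts: dict[str, float] = {}

    # hydrate suffix: ".3H2O" or ".H2O"
    if "." in text:
        head, _, tail = text.partition(".")
        m = re.fullmatch(r"(\d*)H2O", tail)
        if m is None:
            raise FormulaError(
                f"unsupported suffix {('.' + tail)!r}: only a single .nH2O hydrate is allowed"
            )
        n_water = int(m.group(1)) if m.group(1) else 1
        counts["H"] = counts.get("H", 0.0) + 2.0 * n_water
        counts["O"] = counts.get("O", 0.0) + 1.0 * n_water
        text = head
        if not text:
            raise FormulaError("hydrate suffix without a parent formula")

    pos = 0
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            close = text.find(")", pos)
            if close < 0:
                raise FormulaError("unbalanced parenthesis")
            inner = text[pos + 1 : close]
            if "(" in inner:
                raise FormulaError("nested parentheses are not supported")
            m = re.match(r"\d+", text[close + 1 :])
            mult = int(m.group(0)) if m else 1
            _parse_flat(inner, counts, float(mult))
            pos = close + 1 + (m.end() if m else 0)
        elif ch == ")":
            raise FormulaError("unbalanced parenthesis")
        else:
            m = _TOKEN.match(text, pos)
            if m is None or m.start() != pos:
                raise FormulaError(
                    f"malformed formula near {text[pos:]!r}: expected an element symbol"
                )
            _parse_flat(m.group(0), counts, 1.0)
            pos = m.end()
    return counts


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a formula string (hydrates supported)."""
    counts = parse_formula(formula)
    return sum(ATOMIC_MASS[el] * n for el, n in counts.items())


# Organic components with a defined full-oxidation stoichiometry, as mol O2
# consumed per mol of the stated formula unit.  Acetate (as free acid or
# sodium salt, hydrated or not): CH3COO- + 2 O2 -> 2 CO2 + ... = 2 mol O2/mol.
_O2_PER_MOL: dict[str, float] = {
    "NaC2H3O2.3H2O": 2.0,
    "NaC2H3O2": 2.0,
    "CH3COONa.3H2O": 2.0,
    "CH3COONa": 2.0,
    "C2H4O2": 2.0,
}

_MASS_O2 = 2 * ATOMIC_MASS["O"]


@dataclass(frozen=True)
class MediumComponent:
    """One salt of a medium recipe: a formula and its mass concentration.

    Atom counts per formula unit are derived from the formula at construction,
    so C/N/P molarities cannot drift out of sync with the formula string.
    """

    formula: str
    mass_conc: float  # mg per litre
    role: str = ""
    carbon_atoms: int = field(init=False)
    nitrogen_atoms: int = field(init=False)
    phosphorus_atoms: int = field(init=False)

    def __post_init__(self) -> None:
        if self.mass_conc < 0:
            raise ValueError(f"mass_conc must be >= 0, got {self.mass_conc}")
        counts = parse_formula(self.formula)
        object.__setattr__(self, "carbon_atoms", int(counts.get("C", 0)))
        object.__setattr__(self, "nitrogen_atoms", int(counts.get("N", 0)))
        object.__setattr__(self, "phosphorus_atoms", int(counts.get("P", 0)))

    @property
    def molar_mass(self) -> float:
        return molar_mass(self.formula)


def component_mmolarity(component: MediumComponent) -> float:
    """mmol of the formula unit per litre."""
    mm = component.molar_mass
    if mm <= 0:
        raise ArithmeticError(f"non-positive molar mass for {component.formula!r}")
    return component.mass_conc / mm


def component_cmolarity(component: MediumComponent) -> float:
    """Carbon molarity of a component, C-mmol/L."""
    return component_mmolarity(component) * component.carbon_atoms


def nitrogen_mmolarity(component: MediumComponent) -> float:
    """Nitrogen molarity of a component, N-mmol/L."""
    return component_mmolarity(component) * component.nitrogen_atoms


def phosphorus_mmolarity(component: MediumComponent) -> float:
    """Phosphorus molarity of a component, P-mmol/L."""
    return component_mmolarity(component) * component.phosphorus_atoms


def theoretical_cod(component: MediumComponent, o2_per_mol: float | None = None) -> float:
    """Theoretical oxygen demand of a component's mass concentration, mg O2/L.

    Only components with a registered (or explicitly supplied) full-oxidation
    stoichiometry are supported; acetate in its common salt forms is built in.
    """
    if component.mass_conc == 0:
        return 0.0
    if o2_per_mol is None:
        o2_per_mol = _O2_PER_MOL.get(component.formula.strip())
    if o2_per_mol is None:
        raise ValueError(
            f"no oxidation stoichiometry registered for {component.formula!r}; "
            "pass o2_per_mol explicitly"
        )
    return component_mmolarity(component) * o2_per_mol * _MASS_O2


def influent_pc_ratio(tp: float, hac: float, ndigits: int | None = 3) -> float:
    """Influent P/C ratio (P-mol/C-mol) from orthophosphate and acetate molarities.

    Rounded to 3 decimals by default, the convention the phase schedule is
    tabulated at; pass ``ndigits=None`` for full precision.
    """
    if hac <= 0:
        raise ZeroDivisionError(
            f"acetate carbon molarity must be > 0 to form a P/C ratio, got {hac}"
        )
    if tp < 0:
        raise ValueError(f"total phosphorus must be >= 0, got {tp}")
    ratio = tp / hac
    return round(ratio, ndigits) if ndigits is not None else ratio


@dataclass(frozen=True)
class InfluentComposition:
    """Derived molar characterization of an influent medium."""

    hac: float  # acetate, C-mmol/L
    cod: float  # mg O2/L
    tp: float  # orthophosphate, P-mmol/L
    tn: float  # ammonium nitrogen, N-mmol/L
    pc_ratio: float  # P-mol/C-mol

    def __post_init__(self) -> None:
        for name in ("hac", "cod", "tp", "tn", "pc_ratio"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def characterize_medium(components: list[MediumComponent]) -> InfluentComposition:
    """Characterize a recipe: total acetate carbon, COD, P, N and the P/C ratio.

    Carbon and COD are summed over components flagged ``role="carbon_source"``
    (or, absent any role flags, over all components with carbon atoms and a
    registered oxidation stoichiometry).
    """
    flagged = [c for c in components if c.role == "carbon_source"]
    carbon_sources = flagged or [
        c for c in components if c.carbon_atoms > 0 and c.formula.strip() in _O2_PER_MOL
    ]
    hac = sum(component_cmolarity(c) for c in carbon_sources)
    cod = sum(theoretical_cod(c) for c in carbon_sources)
    tn = sum(nitrogen_mmolarity(c) for c in components)
    tp = sum(phosphorus_mmolarity(c) for c in components)
    pc = influent_pc_ratio(tp, hac, ndigits=None) if hac > 0 else 0.0
    return InfluentComposition(hac=hac, cod=cod, tp=tp, tn=tn, pc_ratio=pc)


# Influent orthophosphate (P-mmol/L) applied in the six experimental phases of
# the enrichment study this package models; the medium is otherwise identical
# across phases.
PHASE_PHOSPHATE_MMOL: dict[int, float] = {
    0: 0.64,
    1: 0.48,
    2: 0.96,
    3: 1.44,
    4: 0.48,
    5: 0.64,
}

_MM_NAH2PO4_H2O = None  # computed lazily so the table above stays declarative


def acetate_medium(phosphate_mmol_per_l: float) -> list[MediumComponent]:
    """The built-in acetate enrichment medium, per litre of diluted influent.

    Fixed backbone (860 mg sodium acetate trihydrate, 107 mg NH4Cl, Mg/Ca/K
    salts) plus sodium dihydrogen phosphate monohydrate dosed to the requested
    orthophosphate molarity.  The nitrification inhibitor and trace-element
    dose carry no C/N/P at recipe scale and are omitted.
    """
    global _MM_NAH2PO4_H2O
    if _MM_NAH2PO4_H2O is None:
        _MM_NAH2PO4_H2O = molar_mass("NaH2PO4.H2O")
    if phosphate_mmol_per_l < 0:
        raise ValueError("phosphate dose must be >= 0")
    recipe = [
        MediumComponent("NaC2H3O2.3H2O", 860.0, role="carbon_source"),
        MediumComponent("NH4Cl", 107.0),
        MediumComponent("MgSO4.7H2O", 120.0),
        MediumComponent("CaCl2.2H2O", 14.0),
        MediumComponent("KCl", 48.0),
        MediumComponent("NaH2PO4.H2O", phosphate_mmol_per_l * _MM_NAH2PO4_H2O),
    ]
    return recipe
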