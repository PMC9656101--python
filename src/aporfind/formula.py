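"""Elemental-composition arithmetic for singly charged positive-mode ions.

Everything downstream — formula decomposition, neutral-loss matching, library
mass self-checks — reduces to exact monoisotopic arithmetic on small CHNO
compositions.  Masses are monoisotopic (most abundant isotope), pinned to the
CODATA-2010 / IUPAC values below, and ion masses carry the electron-mass
correction: a +1 cation weighs one electron less than the same composition
at charge 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum

__all__ = [
    "ATOMIC_MASSES",
    "ELECTRON_MASS",
    "Formula",
    "FormulaError",
    "IonKind",
    "IonSpecies",
    "parse_formula",
    "monoisotopic_mz",
    "formula_add",
    "formula_subtract",
    "ppm_error",
    "round_mz",
]

# Monoisotopic atomic masses in u, >= 10 significant figures.
# Source: IUPAC/CODATA (AME2012-consistent); 12C defines the scale exactly.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

# CODATA electron mass in u.
ELECTRON_MASS: float = 0.00054857990907

# Integer (nominal) masses of the most abundant isotopes.
NOMINAL_MASSES: dict[str, int] = {"H": 1, "C": 12, "N": 14, "O": 16}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparsable formula strings or infeasible arithmetic."""


@dataclass(frozen=True)
class Formula:
    """An elemental composition plus an integer charge (0 or +1 in scope).

    ``counts`` maps element symbols to non-negative integers; at least one
    count must be positive.  Instances are immutable and hashable so they can
    key deduplication maps during candidate enumeration.
    """

    counts: tuple[tuple[str, int], ...]
    charge: int = 0

    def __post_init__(self) -> None:
        for sym, n in self.counts:
            if n < 0:
                raise FormulaError(f"negative count for element {sym!r}")
        if not any(n > 0 for _, n in self.counts):
            raise FormulaError("formula must contain at least one atom")

    @classmethod
    def from_counts(cls, counts: dict[str, int], charge: int = 0) -> "Formula":
        items = tuple(sorted((s, int(n)) for s, n in counts.items() if n != 0))
        return cls(items, charge)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def with_charge(self, charge: int) -> "Formula":
        return Formula(self.counts, charge)

    @property
    def nominal_mass(self) -> int:
        """Integer mass from the nominal mass of each most-abundant isotope."""
        d = self.as_dict()
        for sym in d:
            if sym not in NOMINAL_MASSES:
                raise FormulaError(f"unknown element symbol {sym!r}")
        return sum(NOMINAL_MASSES[s] * n for s, n in d.items())

    def hill(self) -> str:
        """Canonical serialization in Hill order (C, H, then alphabetical)."""
        d = self.as_dict()
        order = [s for s in ("C", "H") if s in d] + sorted(
            s for s in d if s not in ("C", "H")
        )
        return "".join(f"{s}{d[s] if d[s] != 1 else ''}" for s in order)

    def ion_notation(self) -> str:
        """Bracketed ion string, e.g. ``[C20H24NO4]+``."""
        sign = {0: "", 1: "+"}.get(self.charge)
        if sign is None:
            raise FormulaError(f"unsupported charge {self.charge}")
        return f"[{self.hill()}]{sign}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def parse_formula(text: str, charge: int = 0) -> Formula:
    """Parse a formula string such as ``"C20H24NO4"`` into a :class:`Formula`.

    Implicit count 1 is allowed ("N" in C20H24NO4).  Unknown element symbols
    and empty strings raise :class:`FormulaError` naming the offender.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        sym, digits = m.group(1), m.group(2)
        if sym not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element symbol {sym!r} in {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Formula.from_counts(counts, charge)


def monoisotopic_mz(formula: Formula) -> float:
    """Exact monoisotopic mass-to-charge of a neutral (charge 0) or +1 ion.

    Returns ``sum(count * atomic_mass) - charge * electron_mass``.  Display
    rounding to 4 decimals is the caller's concern (:func:`round_mz`).
    """
    if formula.charge not in (0, 1):
        raise FormulaError(f"unsupported charge {formula.charge}; only 0/+1 in scope")
    total = 0.0
    for sym, n in formula.counts:
        try:
            total += ATOMIC_MASSES[sym] * n
        except KeyError:
            raise FormulaError(f"unknown element symbol {sym!r}") from None
    return total - formula.charge * ELECTRON_MASS


def round_mz(mz: float, decimals: int = 4) -> float:
    """Round half-away-from-zero, the convention of all reported m/z values."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(mz))).quantize(q, rounding=ROUND_HALF_UP))


def formula_add(a: Formula, b: Formula) -> Formula:
    """Element-wise sum; the charge of ``a`` is preserved."""
    counts = a.as_dict()
    for sym, n in b.counts:
        counts[sym] = counts.get(sym, 0) + n
    return Formula.from_counts(counts, a.charge)


def formula_subtract(a: Formula, b: Formula) -> Formula:
    """Element-wise difference ``a - b``; negative results are infeasible."""
    counts = a.as_dict()
    for sym, n in b.counts:
        new = counts.get(sym, 0) - n
        if new < 0:
            raise FormulaError(
                f"cannot subtract {b.hill()} from {a.hill()}: "
                f"element {sym} would go negative"
            )
        counts[sym] = new
    return Formula.from_counts(counts, a.charge)


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


class IonKind(str, Enum):
    """Positive-mode species: intact cation (quaternary N) or protonated."""

    M_PLUS = "[M]+"
    M_PLUS_H = "[M+H]+"


@dataclass(frozen=True)
class IonSpecies:
    """A singly charged positive ion and, for [M+H]+, its neutral parent."""

    kind: IonKind
    ion_formula: Formula
    neutral_formula: Formula | None = field(default=None)

    def __post_init__(self) -> None:
        if self.ion_formula.charge != 1:
            raise FormulaError("ion_formula must carry charge +1")
        if self.kind is IonKind.M_PLUS_H:
            if self.neutral_formula is None:
                raise FormulaError("[M+H]+ species requires a neutral formula")
            expect = formula_add(
                self.neutral_formula, parse_formula("H")
            ).with_charge(1)
            if expect.counts != self.ion_formula.counts:
                raise FormulaError(
                    "ion formula is not neutral + H for an [M+H]+ species"
                )
        elif self.neutral_formula is not None:
            raise FormulaError("[M]+ species is the permanent cation itself")

    @classmethod
    def m_plus(cls, ion: Formula) -> "IonSpecies":
        return cls(IonKind.M_PLUS, ion.with_charge(1))

    @classmethod
    def m_plus_h(cls, neutral: Formula) -> "IonSpecies":
        ion = formula_add(neutral.with_charge(0), parse_formula("H")).with_charge(1)
        return cls(IonKind.M_PLUS_H, ion, neutral.with_charge(0))

    @property
    def mz(self) -> float:
        return monoisotopic_mz(self.ion_formula)
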