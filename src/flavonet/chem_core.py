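"""Elemental-formula arithmetic and exact m/z computation for negative-mode ESI.

All identification logic downstream reduces to three numbers computed here:
the monoisotopic mass of a neutral formula, the m/z of its deprotonated anion
[M-H]-, and the relative (ppm) deviation between an observed and a theoretical
m/z.  The anion m/z follows the physically correct convention

    m/z([M-H]-) = M - m(H) + m(e-)

i.e. the electron gained by the anion is *included*.  Omitting the electron
shifts every theoretical value by ~0.55 mDa, which at m/z 125 is a 4.4 ppm
bias -- large enough to flip tolerance decisions for small fragment ions.

Only C, H, O, N and S are supported: flavonoids and their phase I/II
conjugates need C/H/O alone; N and S are admitted so that decoy molecules in
simulations can sit off the CHO mass grid.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass, field

__all__ = [
    "ELECTRON_MASS",
    "MONOISOTOPIC_MASS",
    "SUPPORTED_ELEMENTS",
    "ElementalFormula",
    "FormulaError",
    "monoisotopic_mass",
    "deprotonated_mz",
    "ppm_error",
    "within_tolerance",
]

#: Monoisotopic atomic masses in Da (12C scale, CODATA/AME values).
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "O": 15.9949146196,
    "N": 14.0030740048,
    "S": 31.97207100,
}

#: Electron rest mass in Da.
ELECTRON_MASS: float = 0.00054857990907

SUPPORTED_ELEMENTS = frozenset(MONOISOTOPIC_MASS)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unsupported elements or impossible (negative) compositions."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> count map, the unit of all mass arithmetic.

    Immutable and hashable; addition and subtraction are element-wise, and a
    subtraction that would drive any count negative raises ``FormulaError``
    (there is no such molecule).

    Parameters
    ----------
    counts:
        Mapping of element symbol to a non-negative integer count.  Symbols
        outside ``SUPPORTED_ELEMENTS`` are rejected.
    """

    counts: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for element, count in self.counts.items():
            if element not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element {element!r}")
            if not isinstance(count, int) or count < 0:
                raise FormulaError(
                    f"count for {element} must be a non-negative integer, got {count!r}"
                )
            if count:
                clean[element] = count
        object.__setattr__(self, "counts", clean)

    @classmethod
    def parse(cls, text: str) -> "ElementalFormula":
        """Parse Hill-like notation such as ``"C21H22O12"`` (implicit count 1)."""
        if not isinstance(text, str) or not text.strip():
            raise FormulaError(f"cannot parse formula from {text!r}")
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(text.strip()):
            if not match.group(0):
                continue
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r}")
            pos = match.end()
            element = match.group(1)
            count = int(match.group(2) or 1)
            counts[element] = counts.get(element, 0) + count
        if pos != len(text.strip()):
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(counts)

    def __getitem__(self, element: str) -> int:
        return self.counts.get(element, 0)

    def __add__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            merged[element] = merged.get(element, 0) + count
        return ElementalFormula(merged)

    def __sub__(self, other: "ElementalFormula") -> "ElementalFormula":
        merged = dict(self.counts)
        for element, count in other.counts.items():
            new = merged.get(element, 0) - count
            if new < 0:
                raise FormulaError(
                    f"subtraction yields negative {element} count in {self} - {other}"
                )
            merged[element] = new
        return ElementalFormula(merged)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.counts.items())))

    def fits_within(self, cap: "ElementalFormula") -> bool:
        """True iff every element count is <= the cap's count (inclusive)."""
        return all(count <= cap[element] for element, count in self.counts.items())

    def hill(self) -> str:
        """Hill-system string: C first, then H, then the rest alphabetically."""
        order = [e for e in ("C", "H") if e in self.counts]
        order += sorted(e for e in self.counts if e not in ("C", "H"))
        return "".join(
            f"{e}{self.counts[e]}" if self.counts[e] != 1 else e for e in order
        )

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill()


def monoisotopic_mass(formula: ElementalFormula) -> float:
    """Monoisotopic mass in Da of a neutral formula (empty formula -> 0.0)."""
    return sum(MONOISOTOPIC_MASS[e] * n for e, n in formula.counts.items())


def deprotonated_mz(neutral: ElementalFormula) -> float:
    """m/z of the [M-H]- anion of ``neutral``: M - m(H) + m(e-).

    Raises ``FormulaError`` if the neutral molecule has no hydrogen to lose.
    """
    if neutral["H"] < 1:
        raise FormulaError(f"cannot deprotonate {neutral.hill() or 'empty formula'}")
    return monoisotopic_mass(neutral) - MONOISOTOPIC_MASS["H"] + ELECTRON_MASS


def ppm_error(experimental: float, theoretical: float) -> float:
    """Relative mass deviation (experimental - theoretical)/theoretical * 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (experimental - theoretical) / theoretical * 1e6


def within_tolerance(experimental: float, theoretical: float, tol_ppm: float) -> bool:
    """True iff |ppm_error| <= tol_ppm (inclusive)."""
    if tol_ppm <= 0:
        raise ValueError("tolerance must be positive")
    return abs(ppm_error(experimental, theoretical)) <= tol_ppm


def round_mz(value: float) -> float:
    """Report an m/z at 4 decimal places (round-half-even, reporting only)."""
    return round(value, 4)


def round_ppm(value: float) -> float:
    """Report a ppm error at 2 decimal places (round-half-even, reporting only)."""
    return round(value, 2)


def printed_ppm_error(experimental_printed: float, theoretical_printed: float) -> float:
    """ppm error between two already-rounded (printed) m/z values.

    Published tables compute their error column from the 4-d.p. values they
    print, not from full-precision theoreticals; this helper reproduces that
    reporting convention.
    """
    return round_ppm(ppm_error(experimental_printed, theoretical_printed))
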