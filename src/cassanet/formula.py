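"""Molecular formulas, monoisotopic mass arithmetic and formula assignment.

All mass arithmetic in the package goes through the single constants table
below.  Masses are the standard monoisotopic atomic masses of the most
abundant isotope; the proton mass is used for [M+H]+ adduct arithmetic
(positive mode, charge +1, the only adduct this package handles).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "ATOMIC_MASS",
    "PROTON_MASS",
    "MolecularFormula",
    "FormulaCandidate",
    "NeutralLoss",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "protonated_mz",
    "neutral_mass",
    "ppm_error",
    "rdbe",
    "assign_formula",
    "DEFAULT_ELEMENT_RANGES",
    "DEFAULT_RDBE_RANGE",
]

#: Monoisotopic atomic masses (Da) of the supported elements.
ATOMIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.00782503207,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "S": 31.97207100,
    "P": 30.97376163,
}

#: Mass of a proton (Da), added for the [M+H]+ ion.
PROTON_MASS: float = 1.007276467

#: Hill order for CH-containing formulas: C first, H second, rest alphabetical.
_HILL_TAIL = sorted(e for e in ATOMIC_MASS if e not in ("C", "H"))

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for unparseable or chemically empty formulas."""


@dataclass(frozen=True)
class MolecularFormula:
    """An element-count vector over C, H, N, O, S, P.

    Immutable and hashable; the canonical string representation is in
    Hill order (C, H, then remaining elements alphabetically).
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = dict(counts)
        for element, n in items.items():
            if element not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol: {element!r}")
            if n < 0:
                raise FormulaError(f"negative count for {element}: {n}")
        items = {e: n for e, n in items.items() if n > 0}
        if not items:
            raise FormulaError("formula must contain at least one atom")
        order = ["C", "H"] + _HILL_TAIL
        object.__setattr__(
            self, "counts", tuple((e, items[e]) for e in order if e in items)
        )

    def __getitem__(self, element: str) -> int:
        return dict(self.counts).get(element, 0)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def hill(self) -> str:
        """Canonical Hill-order string, e.g. ``C24H37NO5``."""
        parts = []
        for element, n in self.counts:
            parts.append(element if n == 1 else f"{element}{n}")
        return "".join(parts)

    def __str__(self) -> str:
        return self.hill()

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        merged = self.as_dict()
        for e, n in other.counts:
            merged[e] = merged.get(e, 0) + n
        return MolecularFormula(merged)


@dataclass(frozen=True)
class FormulaCandidate:
    """A candidate formula for an observed m/z with its mass deviation."""

    formula: MolecularFormula
    theoretical_mz: float
    delta_ppm: float
    rdbe: float


@dataclass(frozen=True)
class NeutralLoss:
    """A named neutral loss (departing molecule) with its exact mass."""

    name: str
    formula: MolecularFormula
    mass: float = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "mass", monoisotopic_mass(self.formula))


def parse_formula(text: str) -> MolecularFormula:
    """Parse an element-count string (any order, implicit count 1).

    Raises :class:`FormulaError` on empty input, unknown element symbols
    or explicit zero counts that leave no atoms.
    """
    if not text or not text.strip():
        raise FormulaError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for m in _TOKEN_RE.finditer(text):
        if not m.group(0):
            continue
        if m.start() != pos:
            raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
        element = m.group(1)
        if element not in ATOMIC_MASS:
            raise FormulaError(f"unknown element symbol {element!r} in {text!r}")
        n = int(m.group(2)) if m.group(2) else 1
        counts[element] = counts.get(element, 0) + n
        pos = m.end()
    if pos != len(text):
        raise FormulaError(f"cannot parse formula {text!r} at position {pos}")
    return MolecularFormula(counts)


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass of a neutral formula in Da."""
    return sum(ATOMIC_MASS[e] * n for e, n in f.counts)


def protonated_mz(f: MolecularFormula) -> float:
    """m/z of the [M+H]+ ion (charge +1)."""
    return monoisotopic_mass(f) + PROTON_MASS


def neutral_mass(mz: float) -> float:
    """Neutral monoisotopic mass corresponding to an [M+H]+ m/z."""
    return mz - PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative deviation in parts per million.

    ``1e6 * (observed - theoretical) / theoretical``; the reference
    (theoretical) mass must be positive.
    """
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (observed - theoretical) / theoretical


def rdbe(f: MolecularFormula) -> float:
    """Ring-and-double-bond equivalents, C - H/2 + N/2 + 1 for CHNOSP.

    O and S do not contribute; trivalent N and P contribute +1/2 each.
    """
    return f["C"] - f["H"] / 2 + (f["N"] + f["P"]) / 2 + 1


#: Default search box for formula assignment: bounds (lo, hi) per element.
DEFAULT_ELEMENT_RANGES: dict[str, tuple[int, int]] = {
    "C": (5, 40),
    "H": (5, 70),
    "N": (0, 2),
    "O": (0, 14),
    "S": (0, 0),
    "P": (0, 0),
}

#: Default plausibility window on ring-and-double-bond equivalents.
DEFAULT_RDBE_RANGE: tuple[float, float] = (0.0, 20.0)


def _heteroatoms(f: MolecularFormula) -> int:
    return sum(n for e, n in f.counts if e not in ("C", "H"))


def assign_formula(
    mz: float,
    tol_ppm: float = 10.0,
    element_ranges: Mapping[str, tuple[int, int]] | None = None,
    rdbe_range: tuple[float, float] = DEFAULT_RDBE_RANGE,
) -> list[FormulaCandidate]:
    """Enumerate all formulas whose [M+H]+ m/z lies within ``tol_ppm``.

    The search is an exhaustive sweep of the element box: all combinations
    of the non-hydrogen elements are enumerated and the hydrogen count is
    solved from the residual mass, so the cost is polynomial rather than
    exponential in the box width.  Candidates are filtered by the RDBE
    window and sorted by \\|delta ppm\\| ascending, ties broken by fewer
    heteroatoms and then by the Hill string.
    """
    if mz <= 0:
        raise ValueError("mz must be positive")
    ranges = dict(DEFAULT_ELEMENT_RANGES)
    if element_ranges:
        ranges.update(element_ranges)
    for e, (lo, hi) in ranges.items():
        if lo > hi or hi < 0:
            raise ValueError(f"empty constraint range for {e}: ({lo}, {hi})")
    if all(hi == 0 for lo, hi in ranges.values()):
        raise ValueError("empty constraint box")

    target = neutral_mass(mz)
    tol_da = abs(tol_ppm) * 1e-6 * mz
    h_lo, h_hi = ranges.get("H", (0, 0))
    heavy = [e for e in ("C", "N", "O", "S", "P") if ranges.get(e, (0, 0))[1] > 0]

    candidates: list[FormulaCandidate] = []
    axes = [range(ranges[e][0], ranges[e][1] + 1) for e in heavy]
    for combo in itertools.product(*axes):
        base = sum(ATOMIC_MASS[e] * n for e, n in zip(heavy, combo))
        residual = target - base
        # hydrogen count bracketing the residual mass within tolerance
        n_h_min = int((residual - tol_da) / ATOMIC_MASS["H"])
        n_h_max = int((residual + tol_da) / ATOMIC_MASS["H"]) + 1
        for n_h in range(max(h_lo, n_h_min), min(h_hi, n_h_max) + 1):
            counts = {e: n for e, n in zip(heavy, combo)}
            counts["H"] = n_h
            counts = {e: n for e, n in counts.items() if n > 0}
            if not counts:
                continue
            f = MolecularFormula(counts)
            theo = protonated_mz(f)
            delta = ppm_error(mz, theo)
            if abs(delta) > abs(tol_ppm):
                continue
            r = rdbe(f)
            if not (rdbe_range[0] <= r <= rdbe_range[1]):
                continue
            candidates.append(FormulaCandidate(f, theo, delta, r))
    candidates.sort(
        key=lambda c: (abs(c.delta_ppm), _heteroatoms(c.formula), c.formula.hill())
    )
    return candidates
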