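"""Elemental-formula algebra and exact monoisotopic mass computations.

Every downstream stage (candidate enumeration, MS1 matching, fragment
prediction) reduces to arithmetic on :class:`Composition` objects, so the
conventions are fixed here once:

* masses are monoisotopic, summed from a pinned atomic-mass table;
* a protonated molecular ion ``[M+H]+`` weighs ``M + proton``;
* an intrinsic cation (e.g. an acylium fragment) weighs its own
  composition minus one electron;
* mass deviations are expressed as signed ppm.
"""

from __future__ import annotations

import re
from collections.abc import Iterator, Mapping
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "ATOMIC_MASS",
    "ATOMIC_MASS_VERSION",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "Composition",
    "IonMode",
    "IonSpec",
    "FormulaError",
    "parse_formula",
    "monoisotopic_mass",
    "ion_mz",
    "ppm_error",
    "decompose_mz",
]

#: Monoisotopic atomic masses in Da (CODATA 2018 / AME2020 values).
ATOMIC_MASS: dict[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
    "F": 18.99840322,
    "P": 30.97376163,
    "S": 31.97207100,
    "Cl": 34.96885268,
    "Br": 78.9183371,
    "Na": 22.9897692809,
    "K": 38.96370668,
    "I": 126.904473,
}

ATOMIC_MASS_VERSION = "CODATA2018/AME2020-monoisotopic-r1"

PROTON_MASS = 1.00727646688
ELECTRON_MASS = 0.00054857990

# element symbol order used when formatting (Hill convention: C, H, rest
# alphabetical)
_HILL_TAIL = sorted(e for e in ATOMIC_MASS if e not in ("C", "H"))

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Raised for malformed formula strings or invalid compositions."""


@dataclass(frozen=True)
class Composition(Mapping):
    """Immutable multiset of element counts with exact-mass semantics.

    Behaves as a mapping ``element -> count``; zero-count elements are
    dropped on construction so equality is structural.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = dict(counts or {})
        for k, v in kw.items():
            merged[k] = merged.get(k, 0) + v
        for elem, n in merged.items():
            if elem not in ATOMIC_MASS:
                raise FormulaError(f"unknown element symbol {elem!r}")
            if n < 0:
                raise FormulaError(f"negative count for element {elem}: {n}")
        items = tuple(sorted((e, n) for e, n in merged.items() if n > 0))
        object.__setattr__(self, "counts", items)

    # -- mapping protocol -------------------------------------------------
    def __getitem__(self, elem: str) -> int:
        for e, n in self.counts:
            if e == elem:
                return n
        raise KeyError(elem)

    def get(self, elem: str, default: int = 0) -> int:
        try:
            return self[elem]
        except KeyError:
            return default

    def __iter__(self) -> Iterator[str]:
        return (e for e, _ in self.counts)

    def __len__(self) -> int:
        return len(self.counts)

    # -- algebra ----------------------------------------------------------
    def add(self, delta: Mapping[str, int]) -> "Composition":
        """Element-wise sum with a (possibly signed) delta map.

        Raises :class:`FormulaError` if any resulting count is negative.
        """
        merged = {e: n for e, n in self.counts}
        for e, d in delta.items():
            merged[e] = merged.get(e, 0) + d
        return Composition(merged)

    def can_add(self, delta: Mapping[str, int]) -> bool:
        try:
            self.add(delta)
            return True
        except FormulaError:
            return False

    def __add__(self, other: "Composition") -> "Composition":
        return self.add(dict(other.counts))

    @property
    def mass(self) -> float:
        return monoisotopic_mass(self)

    def format(self) -> str:
        """Hill-order formula string (C, H, then alphabetical)."""
        parts = []
        for e in ("C", "H", *_HILL_TAIL):
            n = self.get(e)
            if n == 1:
                parts.append(e)
            elif n > 1:
                parts.append(f"{e}{n}")
        return "".join(parts) or ""

    def __str__(self) -> str:
        return self.format()

    def __repr__(self) -> str:
        return f"Composition({self.format()!r})"


class IonMode(Enum):
    """How a composition relates to the reported ion.

    ``PROTONATED`` — composition is the neutral molecule; the ion is
    ``[M+H]+`` (add one proton).  ``CATION`` — composition already is the
    charged fragment (acylium etc.); only the electron mass is subtracted.
    """

    PROTONATED = "protonated-neutral"
    CATION = "intrinsic-cation"


@dataclass(frozen=True)
class IonSpec:
    composition: Composition
    charge: int = 1
    mode: IonMode = IonMode.PROTONATED

    def __post_init__(self):
        if self.charge == 0:
            raise FormulaError("ion charge must be non-zero")


def parse_formula(text: str) -> Composition:
    """Parse a Hill-like formula string into a :class:`Composition`.

    Underscores (as printed in some tables, ``C_19_H_28_N_4_O_3_``), unit
    counts and a trailing ``+`` are tolerated; the charge itself is *not*
    stored (see :class:`IonSpec`).
    """
    cleaned = text.replace("_", "").strip()
    if cleaned.endswith("+"):
        cleaned = cleaned[:-1]
    if not cleaned:
        raise FormulaError("empty formula string")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN_RE.match(cleaned, pos)
        if not m or not m.group(1):
            raise FormulaError(
                f"malformed formula {text!r}: unexpected token at position {pos}"
            )
        elem, digits = m.groups()
        if elem not in ATOMIC_MASS:
            raise FormulaError(
                f"malformed formula {text!r}: unknown element {elem!r} at position {pos}"
            )
        counts[elem] = counts.get(elem, 0) + (int(digits) if digits else 1)
        pos = m.end()
    return Composition(counts)


def monoisotopic_mass(c: Composition | Mapping[str, int]) -> float:
    """Exact monoisotopic mass in Da (additive over elements)."""
    if not isinstance(c, Composition):
        c = Composition(c)
    return sum(ATOMIC_MASS[e] * n for e, n in c.counts)


def ion_mz(ion: IonSpec | Composition, mode: IonMode | None = None) -> float:
    """m/z of a singly charged positive ion.

    Accepts either an :class:`IonSpec` or a bare composition plus mode.
    """
    if isinstance(ion, Composition):
        if mode is None:
            raise FormulaError("ion mode required when passing a bare composition")
        ion = IonSpec(ion, 1, mode)
    if ion.charge != 1:
        raise FormulaError(f"only +1 ions are supported, got charge {ion.charge}")
    m = monoisotopic_mass(ion.composition)
    if ion.mode is IonMode.PROTONATED:
        return m + PROTON_MASS
    return m - ELECTRON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed mass deviation in parts per million."""
    if theoretical <= 0:
        raise FormulaError(f"theoretical m/z must be positive, got {theoretical}")
    return 1e6 * (observed - theoretical) / theoretical


def decompose_mz(
    target: float,
    bounds: Composition | Mapping[str, int],
    tolerance_ppm: float = 5.0,
    mode: IonMode = IonMode.CATION,
) -> list[Composition]:
    """All compositions within ``bounds`` whose ion m/z is within tolerance.

    Exhaustive bounded search with mass pruning; results sorted by
    absolute ppm deviation (ties by formula string).
    """
    if tolerance_ppm <= 0:
        raise FormulaError("tolerance must be positive")
    if not isinstance(bounds, Composition):
        bounds = Composition(bounds)
    offset = PROTON_MASS if mode is IonMode.PROTONATED else -ELECTRON_MASS
    neutral_target = target - offset
    tol_da = target * tolerance_ppm * 1e-6
    elems = [e for e, _ in bounds.counts]
    maxima = [bounds[e] for e in elems]
    masses = [ATOMIC_MASS[e] for e in elems]
    out: list[Composition] = []

    def rec(i: int, acc_mass: float, acc: dict[str, int]) -> None:
        if acc_mass > neutral_target + tol_da:
            return
        if i == len(elems):
            if abs(acc_mass - neutral_target) <= tol_da:
                out.append(Composition(dict(acc)))
            return
        # remaining elements can only add mass, so the branch where all
        # remaining counts are zero is covered by n == 0
        for n in range(maxima[i] + 1):
            acc[elems[i]] = n
            rec(i + 1, acc_mass + n * masses[i], acc)
        del acc[elems[i]]

    rec(0, 0.0, {})
    out.sort(key=lambda c: (abs(ppm_error(ion_mz(c, mode), target)), c.format()))
    return out
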