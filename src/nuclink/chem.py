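"""Exact elemental-composition algebra and monoisotopic masses.

All chemistry in the package is expressed as integer element counts
(:class:`ElementalComposition`).  Masses are sums of per-element monoisotopic
masses, so species that are elementally identical (e.g. cytidine
monophosphate minus NH3 versus uridine monophosphate minus H2O) are *exactly*
isobaric — not merely equal to within a tolerance.  That exactness is what
lets the search engine treat such species as a single ambiguity class.
"""

from __future__ import annotations

import math
import re
from typing import Dict, Iterable, Mapping

# Monoisotopic masses of the most abundant isotope, Da.
MONOISOTOPIC: Dict[str, float] = {
    "H": 1.0078250319,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Cl": 34.96885271,
    "Na": 22.98976928,
    "K": 38.96370649,
    "Se": 79.9165218,
}

#: Mass of a proton (H+), used for all m/z conversions: mz = (M + z*p)/z.
PROTON = 1.00727646688

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(-?\d*)")


class UnknownElementError(ValueError):
    """Raised when a formula references an element absent from the table."""


class ElementalComposition(Mapping[str, int]):
    """Immutable multiset of element counts with exact monoisotopic mass.

    Counts may be negative transiently (loss algebra); ``finalize()`` checks
    that a species meant to exist physically has no negative counts.
    """

    __slots__ = ("_counts", "_mass")

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: Dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, n in src.items():
                if el not in MONOISOTOPIC:
                    raise UnknownElementError(f"unknown element symbol: {el!r}")
                if n:
                    merged[el] = merged.get(el, 0) + int(n)
        self._counts = {el: n for el, n in sorted(merged.items()) if n}
        self._mass = math.fsum(MONOISOTOPIC[el] * n for el, n in self._counts.items())

    # -- Mapping protocol ---------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, el: str, default: int = 0) -> int:
        return self._counts.get(el, default)

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: "ElementalComposition") -> "ElementalComposition":
        return combine(self, other, +1)

    def __sub__(self, other: "ElementalComposition") -> "ElementalComposition":
        return combine(self, other, -1)

    def __mul__(self, k: int) -> "ElementalComposition":
        return ElementalComposition({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ElementalComposition) and self._counts == other._counts

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"

    # -- queries ------------------------------------------------------------
    @property
    def mass(self) -> float:
        """Exact monoisotopic mass in Da (0.0 for the empty formula)."""
        return self._mass

    def is_empty(self) -> bool:
        return not self._counts

    def has_negative(self) -> bool:
        return any(n < 0 for n in self._counts.values())

    def contains(self, other: "ElementalComposition") -> bool:
        """True if ``other`` is an element-wise sub-multiset of ``self``."""
        return all(self.get(el) >= n for el, n in other.items())

    def finalize(self) -> "ElementalComposition":
        """Assert the composition describes a physical species.

        Losses may only be applied to species that actually contain them.
        """
        if self.has_negative():
            raise ValueError(f"negative element counts in finalized species: {self.formula()}")
        return self

    def formula(self) -> str:
        """Hill-like formula string (C first, then H, then alphabetical)."""
        order = sorted(self._counts, key=lambda e: (e != "C", e != "H", e))
        out = []
        for el in order:
            n = self._counts[el]
            out.append(el + ("" if n == 1 else str(n)))
        return "".join(out)

    @classmethod
    def parse(cls, formula: str) -> "ElementalComposition":
        """Parse a case-sensitive Hill-like formula such as ``"C5H7O5P"``."""
        counts: Dict[str, int] = {}
        pos = 0
        for m in _FORMULA_RE.finditer(formula):
            if not m.group(0):
                continue
            if m.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
            pos = m.end()
            el, num = m.group(1), m.group(2)
            if el not in MONOISOTOPIC:
                raise UnknownElementError(f"unknown element symbol: {el!r} in {formula!r}")
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(formula):
            raise ValueError(f"cannot parse formula {formula!r} at offset {pos}")
        return cls(counts)


EMPTY = ElementalComposition()


def combine(a: ElementalComposition, b: ElementalComposition, sign: int = +1) -> ElementalComposition:
    """Element-wise signed sum of two compositions.

    ``combine(x, EMPTY, ±1) == x``.  Negative counts are allowed in the
    result (transient loss algebra); call ``finalize()`` on the result for a
    species that must exist physically.
    """
    if sign not in (+1, -1):
        raise ValueError("sign must be +1 or -1")
    counts = dict(a.items())
    for el, n in b.items():
        counts[el] = counts.get(el, 0) + sign * n
    return ElementalComposition(counts)


def monoisotopic_mass(comp: ElementalComposition | str) -> float:
    """Exact monoisotopic mass in Da of a composition or formula string."""
    if isinstance(comp, str):
        comp = ElementalComposition.parse(comp)
    return comp.mass


def mz(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral species protonated ``charge`` times."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    return (neutral_mass + charge * PROTON) / charge


def neutral_mass(mz_value: float, charge: int) -> float:
    """Neutral mass from an observed m/z and charge."""
    return mz_value * charge - charge * PROTON


# ---------------------------------------------------------------------------
# Standard small molecules and residues
# ---------------------------------------------------------------------------

def _p(f: str) -> ElementalComposition:
    return ElementalComposition.parse(f)


WATER = _p("H2O")
AMMONIA = _p("NH3")

#: Amino-acid residue compositions (peptide-bond residues, i.e. minus water).
AA_RESIDUES: Dict[str, ElementalComposition] = {
    "G": _p("C2H3NO"), "A": _p("C3H5NO"), "S": _p("C3H5NO2"), "P": _p("C5H7NO"),
    "V": _p("C5H9NO"), "T": _p("C4H7NO2"), "C": _p("C3H5NOS"), "L": _p("C6H11NO"),
    "I": _p("C6H11NO"), "N": _p("C4H6N2O2"), "D": _p("C4H5NO3"), "Q": _p("C5H8N2O2"),
    "K": _p("C6H12N2O"), "E": _p("C5H7NO3"), "M": _p("C5H9NOS"), "H": _p("C6H7N3O"),
    "F": _p("C9H9NO"), "R": _p("C6H12N4O"), "Y": _p("C9H9NO2"), "W": _p("C11H10N2O"),
}

#: Nucleoside-monophosphate adduct compositions (free-acid NMPs); the dNMPs
#: are the ribo species minus one oxygen.  dG and A are elementally identical
#: (an ambiguity any mass measurement inherits).
NMP: Dict[str, ElementalComposition] = {
    "U": _p("C9H13N2O9P"),
    "C": _p("C9H14N3O8P"),
    "A": _p("C10H14N5O7P"),
    "G": _p("C10H14N5O8P"),
    "dC": _p("C9H14N3O7P"),
    "dA": _p("C10H14N5O6P"),
    "dG": _p("C10H14N5O7P"),
    "dT": _p("C10H15N2O8P"),
}

#: Free nucleobase compositions; primed names (U', G', ...) in marker-ion
#: labels denote these bases.
NUCLEOBASES: Dict[str, ElementalComposition] = {
    "U": _p("C4H4N2O2"),
    "C": _p("C4H5N3O"),
    "A": _p("C5H5N5"),
    "G": _p("C5H5N5O"),
    "dC": _p("C4H5N3O"),
    "dA": _p("C5H5N5"),
    "dG": _p("C5H5N5O"),
    "dT": _p("C5H6N2O2"),
}

#: Carbonyl group, subtracted from a residue to form its immonium ion.
CO = _p("CO")

PEPTIDE_MOD_MASSES = {
    "Oxidation": _p("O").mass,            # +15.994915, variable on Met
    "Carbamidomethyl": _p("C2H3NO").mass,  # +57.021464, optional fixed on Cys
}


def peptide_composition(sequence: str) -> ElementalComposition:
    """Elemental composition of an unmodified linear peptide (plus water)."""
    comp = WATER
    for aa in sequence:
        try:
            comp = comp + AA_RESIDUES[aa]
        except KeyError:
            raise ValueError(f"unknown amino acid {aa!r} in {sequence!r}") from None
    return comp


_AA_MASS = {aa: comp.mass for aa, comp in AA_RESIDUES.items()}


def peptide_mass(sequence: str, mod_masses: Iterable[float] = ()) -> float:
    """Monoisotopic mass of a peptide with optional modification deltas."""
    try:
        residues = math.fsum(_AA_MASS[aa] for aa in sequence)
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc.args[0]!r} in {sequence!r}") from None
    return WATER.mass + residues + math.fsum(mod_masses)


def immonium_mz(residue: str, extra_mass: float = 0.0) -> float:
    """m/z of the (optionally adduct-shifted) immonium ion of a residue."""
    base = AA_RESIDUES[residue].mass - CO.mass + extra_mass
    return base + PROTON
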