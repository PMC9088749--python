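"""Exact molecular-formula arithmetic for small-molecule MALDI-TOF work.

Everything mass-related in the package funnels through this module: parsing
Hill-notation formula strings, monoisotopic m/z with electron-mass
correction, cation-adduct transforms ([M+H]+, [M+Na]+, [M+K]+), aggregated
isotope patterns, ppm mass errors and double-bond equivalents.

Atomic masses and isotopic abundances are a fixed internal table (IUPAC
values, 6+ decimal places) rather than a library lookup, so that every
theoretical m/z printed by the package is reproducible independently of
third-party library versions.  The supported element set (C, H, N, O, Na,
K, S) covers all saffron and adulterant marker ions handled here; positive
single charges dominate MALDI of these analytes but charges in -2..+2 are
accepted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Tuple

__all__ = [
    "MolecularFormula",
    "AdductSpec",
    "ADDUCTS",
    "ELECTRON_MASS",
    "parse_formula",
    "render_formula",
    "monoisotopic_mass",
    "monoisotopic_mz",
    "apply_adduct",
    "isotope_pattern",
    "aggregated_isotope_distribution",
    "ppm_error",
    "dbe",
]

#: Mass of the electron in unified atomic mass units.  Subtracted once per
#: positive elementary charge; required to reproduce the 369.1333/369.1310
#: curcumin/picrocrocin-K isobar pair at 4 decimal places.
ELECTRON_MASS = 0.000548579909

#: (exact mass, abundance) per isotope, most abundant first.  IUPAC values.
ISOTOPES: Dict[str, Tuple[Tuple[float, float], ...]] = {
    "H": ((1.007825032, 0.999885), (2.014101778, 0.000115)),
    "C": ((12.0, 0.9893), (13.003354835, 0.0107)),
    "N": ((14.003074004, 0.99636), (15.000108899, 0.00364)),
    "O": (
        (15.994914620, 0.99757),
        (16.999131757, 0.00038),
        (17.999159613, 0.00205),
    ),
    "Na": ((22.989769282, 1.0),),
    "S": (
        (31.972071174, 0.9499),
        (32.971458910, 0.0075),
        (33.967867004, 0.0425),
        (35.967080710, 0.0001),
    ),
    "K": (
        (38.963706486, 0.932581),
        (39.963998166, 0.000117),
        (40.961825258, 0.067302),
    ),
}

SUPPORTED_ELEMENTS = frozenset(ISOTOPES)

#: Principal (most abundant) isotope mass per element.
MONOISOTOPIC: Dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: Elements counted as monovalent (hydrogen-like) in the DBE convention.
_MONOVALENT = ("H", "Na", "K")

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaError(ValueError):
    """Malformed formula string, unsupported element, or invalid arithmetic."""


class MolecularFormula:
    """An element-count vector with an integer charge.

    Immutable and hashable.  Supports ``+``/``-`` (element-wise, charges
    add/subtract) and ``*`` by a non-negative integer (counts scale, charge
    scales).  Counts must stay non-negative and the charge within -2..+2.
    """

    __slots__ = ("_counts", "charge")

    def __init__(self, counts: Mapping[str, int] | None = None, charge: int = 0):
        clean: Dict[str, int] = {}
        for el, n in (counts or {}).items():
            if el not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element: {el!r}")
            n = int(n)
            if n < 0:
                raise FormulaError(f"negative count for {el}: {n}")
            if n:
                clean[el] = n
        if not -2 <= charge <= 2:
            raise FormulaError(f"charge {charge} outside supported range -2..+2")
        object.__setattr__(self, "_counts", tuple(sorted(clean.items())))
        object.__setattr__(self, "charge", int(charge))

    def __setattr__(self, *_):  # pragma: no cover - immutability guard
        raise AttributeError("MolecularFormula is immutable")

    @property
    def counts(self) -> Dict[str, int]:
        return dict(self._counts)

    def __getitem__(self, element: str) -> int:
        return dict(self._counts).get(element, 0)

    def __bool__(self) -> bool:
        return bool(self._counts)

    def n_atoms(self) -> int:
        return sum(n for _, n in self._counts)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        return self._counts == other._counts and self.charge == other.charge

    def __hash__(self) -> int:
        return hash((self._counts, self.charge))

    def __add__(self, other: "MolecularFormula") -> "MolecularFormula":
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        merged = self.counts
        for el, n in other._counts:
            merged[el] = merged.get(el, 0) + n
        return MolecularFormula(merged, self.charge + other.charge)

    def __sub__(self, other: "MolecularFormula") -> "MolecularFormula":
        if not isinstance(other, MolecularFormula):
            return NotImplemented
        merged = self.counts
        for el, n in other._counts:
            new = merged.get(el, 0) - n
            if new < 0:
                raise FormulaError(
                    f"subtraction gives negative {el} count in {self} - {other}"
                )
            merged[el] = new
        return MolecularFormula(merged, self.charge - other.charge)

    def __mul__(self, k: int) -> "MolecularFormula":
        if not isinstance(k, int) or k < 0:
            return NotImplemented
        return MolecularFormula({el: n * k for el, n in self._counts}, self.charge * k)

    __rmul__ = __mul__

    def with_charge(self, charge: int) -> "MolecularFormula":
        return MolecularFormula(self.counts, charge)

    def __repr__(self) -> str:
        sign = {0: "", 1: "+", 2: "2+", -1: "-", -2: "2-"}[self.charge]
        body = render_formula(self) or "(empty)"
        return f"[{body}]{sign}" if sign else body


def parse_formula(text: str, charge: int = 0) -> MolecularFormula:
    """Parse a Hill-like formula string, e.g. ``"C20H24O4"``.

    An empty string yields the empty formula (mass 0).  Unknown elements and
    malformed tokens raise :class:`FormulaError`.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for match in _TOKEN.finditer(text):
        if match.start() != pos:
            raise FormulaError(f"malformed formula {text!r} at position {pos}")
        el, num = match.group(1), match.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaError(f"unsupported element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = match.end()
        if pos == len(text):
            break
    if pos != len(text):
        raise FormulaError(f"malformed formula {text!r} at position {pos}")
    return MolecularFormula(counts, charge)


def render_formula(f: MolecularFormula) -> str:
    """Render element counts in Hill order (C, H, then alphabetical)."""
    counts = f.counts
    ordered: List[str] = []
    if "C" in counts:
        ordered.append("C")
        if "H" in counts:
            ordered.append("H")
    ordered.extend(sorted(el for el in counts if el not in ordered))
    return "".join(
        el + (str(counts[el]) if counts[el] != 1 else "") for el in ordered
    )


def monoisotopic_mass(f: MolecularFormula) -> float:
    """Monoisotopic mass in u, including the electron-count correction."""
    mass = sum(n * MONOISOTOPIC[el] for el, n in f.counts.items())
    return mass - f.charge * ELECTRON_MASS


def monoisotopic_mz(f: MolecularFormula) -> float:
    """Monoisotopic m/z (Th) for charged species, neutral mass otherwise."""
    mass = monoisotopic_mass(f)
    return mass / abs(f.charge) if f.charge else mass


@dataclass(frozen=True)
class AdductSpec:
    """A cationization rule: formula delta plus charge delta."""

    name: str
    delta_formula: MolecularFormula
    delta_charge: int


ADDUCTS: Dict[str, AdductSpec] = {
    "M+H": AdductSpec("M+H", MolecularFormula({"H": 1}), +1),
    "M+Na": AdductSpec("M+Na", MolecularFormula({"Na": 1}), +1),
    "M+K": AdductSpec("M+K", MolecularFormula({"K": 1}), +1),
    # deprotonation: the H removal is handled explicitly in apply_adduct
    "M-H": AdductSpec("M-H", MolecularFormula({}), -1),
    # radical cation: no atoms gained, one electron lost
    "M": AdductSpec("M", MolecularFormula({}), +1),
}


def apply_adduct(f: MolecularFormula, adduct: AdductSpec | str) -> MolecularFormula:
    """Apply an adduct rule, updating element counts and charge.

    ``M-H`` on a hydrogen-free formula raises :class:`FormulaError`.
    """
    if isinstance(adduct, str):
        try:
            adduct = ADDUCTS[adduct]
        except KeyError:
            raise FormulaError(f"unknown adduct {adduct!r}") from None
    counts = f.counts
    if adduct.name == "M-H":
        if counts.get("H", 0) < 1:
            raise FormulaError("cannot deprotonate a hydrogen-free formula")
        counts["H"] -= 1
    else:
        for el, n in adduct.delta_formula.counts.items():
            counts[el] = counts.get(el, 0) + n
    return MolecularFormula(counts, f.charge + adduct.delta_charge)


# ---------------------------------------------------------------------------
# Isotope patterns
# ---------------------------------------------------------------------------

_PRUNE = 1e-15  # discard isotopologue groups below this absolute probability


def _convolve(a: Dict[int, List[float]], b: Dict[int, List[float]]) -> Dict[int, List[float]]:
    out: Dict[int, List[float]] = {}
    for ka, (pa, wa) in a.items():
        for kb, (pb, wb) in b.items():
            p = pa * pb
            if p < _PRUNE:
                continue
            w = pa * wb + pb * wa
            slot = out.setdefault(ka + kb, [0.0, 0.0])
            slot[0] += p
            slot[1] += w
    return out


def _element_distribution(element: str, n: int) -> Dict[int, List[float]]:
    """Aggregated distribution of *n* atoms of one element.

    Keyed by nucleon offset from the all-principal-isotope species; each
    value is ``[probability, probability-weighted mass]``.  Built by binary
    exponentiation of the single-atom distribution.
    """
    isotopes = ISOTOPES[element]
    base_mass = isotopes[0][0]
    single: Dict[int, List[float]] = {}
    for mass, abundance in isotopes:
        offset = round(mass - base_mass)
        slot = single.setdefault(offset, [0.0, 0.0])
        slot[0] += abundance
        slot[1] += abundance * mass
    result: Dict[int, List[float]] = {0: [1.0, 0.0]}
    power = single
    while n:
        if n & 1:
            result = _convolve(result, power)
        n >>= 1
        if n:
            power = _convolve(power, power)
    return result


def aggregated_isotope_distribution(
    f: MolecularFormula,
) -> List[Tuple[float, float]]:
    """Full isotopologue distribution aggregated by nucleon count.

    Returns ``[(m/z, probability), ...]`` sorted ascending in m/z; the
    probabilities sum to 1 (up to pruning below 1e-15).  The m/z of each
    aggregate is the abundance-weighted mean of its isotopologues, with the
    electron correction and charge division applied for ions.
    """
    if not f:
        raise FormulaError("isotope pattern of the empty formula is undefined")
    dist: Dict[int, List[float]] = {0: [1.0, 0.0]}
    for el, n in f.counts.items():
        dist = _convolve(dist, _element_distribution(el, n))
    z = abs(f.charge)
    out = []
    for offset in sorted(dist):
        p, w = dist[offset]
        if p <= 0.0:
            continue
        mass = w / p - f.charge * ELECTRON_MASS
        out.append((mass / z if z else mass, p))
    return out


def isotope_pattern(
    f: MolecularFormula,
    min_rel_abundance: float = 1e-3,
    max_peaks: int = 10,
) -> List[Tuple[float, float]]:
    """Aggregated isotope pattern normalized so the base peak is 1.

    Sorted ascending in m/z, truncated at ``min_rel_abundance`` relative to
    the base peak and at ``max_peaks`` entries.
    """
    dist = aggregated_isotope_distribution(f)
    base = max(p for _, p in dist)
    pattern = [(mz, p / base) for mz, p in dist if p / base >= min_rel_abundance]
    return pattern[:max_peaks]


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical <= 0:
        raise ValueError("theoretical m/z must be positive")
    return (observed - theoretical) / theoretical * 1e6


def dbe(f: MolecularFormula) -> float:
    """Double-bond equivalents with Na and K counted as monovalent.

    DBE = (2*C + 2 + N - H - Na - K) / 2.  This convention reproduces the
    half-integer values expected for even-electron cationized species, e.g.
    3.5 for the picrocrocin potassium adduct [C16H26O7K]+.
    """
    c = f["C"]
    n = f["N"]
    mono = sum(f[el] for el in _MONOVALENT)
    return (2 * c + 2 + n - mono) / 2
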