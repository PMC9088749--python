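"""Theoretical MS/MS product ions of glycoconjugates under high-energy CID.

Fragment labels follow the Domon-Costello convention for glycoconjugates:
B/C ions from the non-reducing end carry the ionizing cation and no
aglycone; Y/Z ions retain the aglycone (Z = Y - H2O); A/X denote cross-ring
cleavages.  Crocins carry two linear glucan chains (alpha and beta) on the
two crocetin carboxyls, so cleavages are enumerated per chain and, for
Y-type ions, over combined losses from both chains (sequential hexose
losses are routine in keV CID of oligosaccharides).

Charge-remote cross-ring cleavages of the terminal hexose are emitted as
0,2A-type (-C2H4O2, 60.0211) and 0,3A-type (-C3H6O3, 90.0317) losses from
the precursor and from Y ions, plus the 0,2X ion (precursor - 120.0423)
diagnostic of O-glycosides.  The 0,4A2 and 3,5A2 candidates are emitted
flagged ``diagnostic_absent``: their *absence* from a spectrum indicates a
linear glycosidic chain, and they never count toward match scores.

Ring cleavages of the trimethylcyclohexene (TMC) and
hexahydro-isobenzofuranone (IBF) skeletons are fixed diagnostic tables at
the 1-decimal precision they are reported with, matched at +-0.3 Th.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, List, Optional, Sequence, Tuple, Union

from .compounds import Compound, HEXOSE, HEXOSE_MASS
from .formula import (
    ADDUCTS,
    AdductSpec,
    MolecularFormula,
    apply_adduct,
    monoisotopic_mz,
    parse_formula,
)

__all__ = [
    "GlycoStructure",
    "FragmentIon",
    "MsmsMatch",
    "glycosidic_ions",
    "cross_ring_ions",
    "small_losses",
    "ring_cleavage_ions",
    "theoretical_ions",
    "match_msms",
]

WATER = monoisotopic_mz(parse_formula("H2O"))

#: Exact masses of the small neutral losses seen in high-energy CID of
#: these metabolites.  CH3 is a radical loss.
SMALL_LOSSES: Dict[str, float] = {
    "CH3": 15.023475,
    "H2O": 18.010565,
    "CO": 27.994915,
    "CH2O": 30.010565,
    "CO2": 43.989830,
    "C4H8": 56.062600,
}

_LOSS_02A = 60.021130   # C2H4O2, terminal-ring 0,2-cleavage
_LOSS_03A = 90.031694   # C3H6O3, terminal-ring 0,3-cleavage
_LOSS_02X = 120.042259  # C4H8O4, 0,2X complement

#: Ring-cleavage diagnostic tables, values at 1 d.p. as reported.
RING_CLEAVAGES: Dict[str, Dict[str, float]] = {
    "TMC": {
        "Y0": 207.1,
        "3,4TMC": 167.1,
        "3,5TMC": 149.1,
        "3,6TMC": 109.1,
        "radical": 184.1,
        "aglycone-191": 191.1,
        "aglycone-177": 177.1,
    },
    "IBF": {
        "2,3aIBF": 207.1,
        "2,3aIBF-15": 191.1,
        "3a,7aIBF": 181.1,
        "3a,7aIBF-var": 165.1,
        "3,7aIBF": 151.1,
        "3,7aIBF-var": 135.1,
        "2,7IBF": 123.1,
    },
}


@dataclass(frozen=True)
class GlycoStructure:
    """A linear glycoconjugate: aglycone plus two unbranched hexose chains."""

    aglycone: MolecularFormula
    chain_alpha: int
    chain_beta: int = 0
    skeleton: Optional[str] = None

    def __post_init__(self):
        if self.chain_alpha < 0 or self.chain_beta < 0:
            raise ValueError("chain hexose counts must be >= 0")

    @property
    def n_hexoses(self) -> int:
        return self.chain_alpha + self.chain_beta

    def neutral_formula(self) -> MolecularFormula:
        return self.aglycone + self.n_hexoses * HEXOSE

    @classmethod
    def from_compound(cls, comp: Compound) -> "GlycoStructure":
        if comp.r1 is None or comp.aglycone is None:
            raise ValueError(f"{comp.name} has no glycan topology")
        return cls(comp.aglycone, comp.r1, comp.r2 or 0, comp.skeleton)


@dataclass(frozen=True)
class FragmentIon:
    """A named theoretical product ion."""

    name: str
    mz: float
    formula: Optional[MolecularFormula] = None
    parent_adduct: str = ""
    provenance: str = ""
    diagnostic_absent: bool = False
    #: generic small-neutral-loss products carry little structural
    #: specificity; they explain peaks but are excluded from match scores
    generic: bool = False


def _adduct(adduct: Union[str, AdductSpec]) -> AdductSpec:
    return ADDUCTS[adduct] if isinstance(adduct, str) else adduct


def _precursor(s: GlycoStructure, adduct: AdductSpec) -> FragmentIon:
    ion = apply_adduct(s.neutral_formula(), adduct)
    return FragmentIon("precursor", monoisotopic_mz(ion), ion, adduct.name,
                       "precursor")


def glycosidic_ions(
    s: GlycoStructure, adduct: Union[str, AdductSpec]
) -> List[FragmentIon]:
    """B/C/Y/Z ions for every glycosidic cut of both chains.

    B_ci carries i hexose residues plus the cation; C = B + H2O.  Y ions are
    enumerated over combined removals of i residues from alpha and j from
    beta (subscripts give residues *remaining* on each chain); Z = Y - H2O.
    """
    adduct = _adduct(adduct)
    prec = _precursor(s, adduct)
    out: List[FragmentIon] = []
    for chain, length in (("a", s.chain_alpha), ("b", s.chain_beta)):
        for i in range(1, length + 1):
            b_formula = apply_adduct(i * HEXOSE, adduct)
            b = monoisotopic_mz(b_formula)
            out.append(FragmentIon(f"B_{chain}{i}", b, b_formula, adduct.name,
                                   f"glycosidic cut {i} on chain {chain}"))
            c_formula = b_formula + parse_formula("H2O")
            out.append(FragmentIon(f"C_{chain}{i}", monoisotopic_mz(c_formula),
                                   c_formula, adduct.name,
                                   f"glycosidic cut {i} on chain {chain}"))
    for i in range(s.chain_alpha + 1):
        for j in range(s.chain_beta + 1):
            removed = i + j
            if removed == 0:
                continue
            y_formula = prec.formula - removed * HEXOSE
            rem_a, rem_b = s.chain_alpha - i, s.chain_beta - j
            if j == 0:
                name = f"Y_a{rem_a}"
            elif i == 0:
                name = f"Y_b{rem_b}"
            else:
                name = f"Y_a{rem_a}/Y_b{rem_b}"
            prov = f"loss of {removed} hexose(s)"
            out.append(FragmentIon(name, monoisotopic_mz(y_formula), y_formula,
                                   adduct.name, prov))
            z_formula = y_formula - parse_formula("H2O")
            out.append(FragmentIon("Z" + name[1:], monoisotopic_mz(z_formula),
                                   z_formula, adduct.name, prov + " - H2O"))
    return out


def cross_ring_ions(
    s: GlycoStructure, adduct: Union[str, AdductSpec]
) -> List[FragmentIon]:
    """Cross-ring (A/X-type) ions of the glycan.

    Requires at least one hexose.  Emits the 0,2X ion per glycosylated
    chain, 0,2A/0,3A-type terminal-ring losses from the precursor and from
    each Y ion that still carries a hexose, and the flagged-absent 0,4A2 /
    3,5A2 candidates whose absence indicates chain linearity.
    """
    adduct = _adduct(adduct)
    if s.n_hexoses == 0:
        return []
    prec = _precursor(s, adduct)
    out: List[FragmentIon] = []
    for chain, length in (("a", s.chain_alpha), ("b", s.chain_beta)):
        if length >= 1:
            out.append(FragmentIon(f"0,2X_{chain}", prec.mz - _LOSS_02X, None,
                                   adduct.name, "0,2 cross-ring, reducing side"))
    parents: List[Tuple[str, float, int]] = [("precursor", prec.mz, s.n_hexoses)]
    for ion in glycosidic_ions(s, adduct):
        if ion.name.startswith("Y_"):
            removed = round((prec.mz - ion.mz) / HEXOSE_MASS)
            remaining = s.n_hexoses - removed
            if remaining >= 1:
                parents.append((ion.name, ion.mz, remaining))
    for pname, pmz, _ in parents:
        out.append(FragmentIon(f"0,2A[{pname}]", pmz - _LOSS_02A, None,
                               adduct.name, "terminal-ring 0,2 cleavage"))
        out.append(FragmentIon(f"0,3A[{pname}]", pmz - _LOSS_03A, None,
                               adduct.name, "terminal-ring 0,3 cleavage"))
    for chain, length in (("a", s.chain_alpha), ("b", s.chain_beta)):
        if length >= 2:
            b2 = monoisotopic_mz(apply_adduct(2 * HEXOSE, adduct))
            out.append(FragmentIon(f"0,4A_{chain}2", b2 - _LOSS_02X, None,
                                   adduct.name, "absence indicates linear chain",
                                   diagnostic_absent=True))
            out.append(FragmentIon(f"3,5A_{chain}2", b2 - 74.036779, None,
                                   adduct.name, "absence indicates linear chain",
                                   diagnostic_absent=True))
    return out


def small_losses(precursor_ion: FragmentIon, depth: int = 1) -> List[FragmentIon]:
    """Small-neutral-loss ions (CH3, H2O, CO, CH2O, CO2, C4H8).

    ``depth`` 1 gives single losses, 2 adds pairwise combinations; each
    product is labeled with its loss chain, e.g. ``[parent-H2O-CO]``.
    """
    if depth not in (1, 2):
        raise ValueError("loss depth must be 1 or 2")
    out: List[FragmentIon] = []
    names = list(SMALL_LOSSES)
    for d in range(1, depth + 1):
        for combo in combinations_with_replacement(names, d):
            mz = precursor_ion.mz - sum(SMALL_LOSSES[n] for n in combo)
            label = f"[{precursor_ion.name}-" + "-".join(combo) + "]"
            out.append(FragmentIon(label, mz, None, precursor_ion.parent_adduct,
                                   f"neutral loss from {precursor_ion.name}",
                                   generic=True))
    return out


def ring_cleavage_ions(skeleton: str, glycosylated: bool = True) -> List[FragmentIon]:
    """Diagnostic ring-cleavage table for TMC or IBF skeletons."""
    try:
        table = RING_CLEAVAGES[skeleton]
    except KeyError:
        raise ValueError(f"no ring-cleavage table for skeleton {skeleton!r}")
    ions = [
        FragmentIon(name, mz, None, "", f"{skeleton} ring cleavage")
        for name, mz in table.items()
    ]
    if not glycosylated:
        ions = [i for i in ions if i.name != "Y0"]
    return ions


def theoretical_ions(
    candidate: Union[GlycoStructure, Compound],
    adduct: Union[str, AdductSpec],
    loss_depth: int = 2,
) -> List[FragmentIon]:
    """Full scoreable ion set for a candidate under one adduct.

    Glycosidic + cross-ring ions, small-neutral losses from the precursor
    and from every B/Y ion, skeleton ring-cleavage tables, and any stored
    diagnostic ions.  Flagged-absent candidates are included but excluded
    from scoring by :func:`match_msms`.
    """
    adduct = _adduct(adduct)
    diag: Tuple[float, ...] = ()
    skeleton = None
    if isinstance(candidate, Compound):
        diag = candidate.diagnostic_ions
        skeleton = candidate.skeleton
        if candidate.r1 is not None and candidate.aglycone is not None:
            structure = GlycoStructure.from_compound(candidate)
        elif candidate.neutral_formula is not None:
            structure = GlycoStructure(candidate.neutral_formula, 0, 0,
                                       candidate.skeleton)
        else:
            raise ValueError(f"{candidate.name} is not fragmentable")
    else:
        structure = candidate
        skeleton = candidate.skeleton

    prec = _precursor(structure, adduct)
    ions: List[FragmentIon] = []
    glyco = glycosidic_ions(structure, adduct)
    ions.extend(glyco)
    ions.extend(cross_ring_ions(structure, adduct))
    ions.extend(small_losses(prec, loss_depth))
    for ion in glyco:
        if ion.name.startswith(("B_", "Y_")):
            ions.extend(small_losses(ion, loss_depth))
    if skeleton in RING_CLEAVAGES:
        ions.extend(ring_cleavage_ions(skeleton, structure.n_hexoses > 0))
    for mz in diag:
        ions.append(FragmentIon(f"diagnostic@{mz}", mz, None, adduct.name,
                                "stored diagnostic ion"))
    # drop non-physical candidates (fragments must be strictly lighter than
    # the precursor) and deduplicate by mass: structure-specific ions at
    # 1 d.p. (the precision diagnostic product ions are reported with),
    # generic loss products at 2 d.p.; specific beats generic on collision
    seen: Dict[Tuple[bool, float], FragmentIon] = {}
    specific_keys = set()
    for ion in ions:
        if not ion.diagnostic_absent and not (0.0 < ion.mz < prec.mz - 1e-9):
            continue
        if not ion.generic:
            key = (False, round(ion.mz, 1))
            if key not in seen or seen[key].diagnostic_absent:
                seen[key] = ion
            specific_keys.add(round(ion.mz, 1))
        else:
            seen.setdefault((True, round(ion.mz, 2)), ion)
    out = [
        ion for (generic, _), ion in seen.items()
        if not (generic and round(ion.mz, 1) in specific_keys)
    ]
    return sorted(out, key=lambda i: i.mz)


@dataclass
class MsmsMatch:
    """Result of scoring an observed MS/MS peak list against a candidate."""

    candidate: str
    score: float
    n_matched: int
    n_emitted: int
    matched: List[Tuple[str, float, float, float]]  # name, theo, obs, delta
    unexplained: List[float]
    sum_abs_delta: float
    #: matches of generic small-loss products (explain peaks, not scored)
    n_supporting: int = 0


def match_msms(
    observed_mz: Sequence[float],
    candidate: Union[GlycoStructure, Compound],
    adduct: Union[str, AdductSpec],
    tol: float = 0.3,
) -> MsmsMatch:
    """Score observed product ions against a candidate's theoretical set.

    score = matched structure-specific ions / emitted structure-specific
    ions (glycosidic, cross-ring, ring-cleavage and stored diagnostics);
    generic small-neutral-loss products explain observed peaks but do not
    enter the score, and flagged-absent ions are never scored.  Ties
    between candidates are broken by more matched ions, then by smaller
    summed |delta m/z| (see :func:`rank_candidates`).
    """
    peaks = sorted(float(m) for m in observed_mz)
    if not peaks:
        raise ValueError("empty MS/MS peak list")
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    ions = [i for i in theoretical_ions(candidate, adduct)
            if not i.diagnostic_absent]
    scored = [i for i in ions if not i.generic]
    matched: List[Tuple[str, float, float, float]] = []
    n_scored_matched = 0
    n_supporting = 0
    sum_abs_delta = 0.0
    explained: set = set()
    for ion in ions:
        best = None
        for obs in peaks:
            d = obs - ion.mz
            if abs(d) <= tol and (best is None or abs(d) < abs(best[1])):
                best = (obs, d)
        if best is not None:
            matched.append((ion.name, round(ion.mz, 4), best[0], round(best[1], 4)))
            explained.add(best[0])
            if ion.generic:
                n_supporting += 1
            else:
                n_scored_matched += 1
                sum_abs_delta += abs(best[1])
    name = candidate.name if isinstance(candidate, Compound) else (
        f"glyco({candidate.chain_alpha},{candidate.chain_beta})")
    return MsmsMatch(
        candidate=name,
        score=n_scored_matched / len(scored) if scored else 0.0,
        n_matched=n_scored_matched,
        n_emitted=len(scored),
        matched=matched,
        unexplained=[p for p in peaks if p not in explained],
        sum_abs_delta=sum_abs_delta,
        n_supporting=n_supporting,
    )


def rank_candidates(
    observed_mz: Sequence[float],
    candidates: Sequence[Tuple[Union[GlycoStructure, Compound], Union[str, AdductSpec]]],
    tol: float = 0.3,
) -> List[MsmsMatch]:
    """Score all candidates, best first.

    Ranked by matched-ion count (the absolute evidence), then score, then
    summed |delta|.  Count-primary ranking keeps a candidate whose ion set
    is a mass-subset of a richer isomer (e.g. crocin chain topologies) from
    winning merely by emitting fewer predictions.
    """
    matches = [match_msms(observed_mz, c, a, tol) for c, a in candidates]
    matches.sort(key=lambda m: (-m.n_matched, -m.score, m.sum_abs_delta))
    return matches
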