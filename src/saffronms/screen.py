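"""Adulterant screening verdicts from MS1 + targeted MS/MS evidence.

The decision logic mirrors the published workflow for suspicious samples:

* turmeric - the ion at m/z 369.13 is an unresolvable TOF isobar of
  protonated curcumin and the picrocrocin K adduct, so MS/MS of that
  precursor decides: picrocrocin daughters (351/337/309/225/207) exclude
  turmeric, curcuminoid daughters confirm it.  The MS1 curcuminoid triplet
  369.13/339.12/309.11 is supporting evidence.
* calendula - MS/MS of the m/z 641 di-O-glycoside precursor; the
  641 -> 478 -> 339 aglycone cascade confirms, its absence excludes.
* gardenia - the geniposide Na/K adduct pair (411.13 / 427.10, split by
  15.974 Th), optionally confirmed by geniposide MS/MS.

Missing MS/MS where it is required yields "inconclusive", never a guess.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from .compounds import Compound, default_registry, find
from .peaks import PeakList, detect_adduct_pairs

__all__ = ["Verdict", "ScreenResult", "classify_isobar_369", "screen_sample"]

#: Exclusive diagnostic daughters of the two m/z 369.13 isobars (1 d.p.).
PICROCROCIN_ONLY = (337.1, 309.1, 225.1, 207.1)
CURCUMIN_ONLY = (285.1, 245.1, 177.1, 145.0)

CURCUMINOID_TRIPLET = (369.13, 339.12, 309.11)
CALENDULA_PRECURSORS = (641.17, 649.14, 617.15)
CALENDULA_CASCADE = (478.0, 339.0)
GENIPOSIDE_NA = 411.13
GENIPOSIDE_K = 427.10


@dataclass
class Verdict:
    status: str  # "positive" | "excluded" | "inconclusive"
    evidence: List[str] = field(default_factory=list)


@dataclass
class ScreenResult:
    turmeric: Verdict
    calendula: Verdict
    gardenia: Verdict

    def as_dict(self) -> Dict[str, Dict]:
        return {
            cls: {"status": v.status, "evidence": v.evidence}
            for cls, v in (("turmeric", self.turmeric),
                           ("calendula", self.calendula),
                           ("gardenia", self.gardenia))
        }


def _hits(observed: Sequence[float], targets: Sequence[float], tol: float) -> int:
    return sum(any(abs(o - t) <= tol for o in observed) for t in targets)


def classify_isobar_369(observed_mz: Sequence[float], tol: float = 0.3) -> str:
    """Classify an MS/MS spectrum of the m/z 369.13 precursor.

    Counts hits in the exclusive diagnostic sets of each isobar (the shared
    -H2O daughter at 351.1 is ignored); at least two exclusive hits and a
    strict majority are required for a call.
    """
    pic = _hits(observed_mz, PICROCROCIN_ONLY, tol)
    cur = _hits(observed_mz, CURCUMIN_ONLY, tol)
    if pic >= 2 and pic > cur:
        return "picrocrocin"
    if cur >= 2 and cur > pic:
        return "curcumin"
    return "inconclusive"


def _nearest_msms(msms: Dict[float, Sequence[float]], precursor: float,
                  tol: float = 0.5) -> Optional[Sequence[float]]:
    for key, peaks in msms.items():
        if abs(float(key) - precursor) <= tol:
            return peaks
    return None


def screen_sample(
    ms1: PeakList,
    msms: Dict[float, Sequence[float]] | None = None,
    ms1_tol: float = 0.05,
    msms_tol: float = 0.3,
) -> ScreenResult:
    """Per-adulterant-class verdicts for one sample.

    ``msms`` maps precursor m/z to observed MS/MS fragment m/z lists.
    """
    msms = msms or {}
    mzs = ms1.mzs

    # ---- turmeric -------------------------------------------------------
    has_369 = any(abs(m - 369.13) <= ms1_tol for m in mzs)
    frag_369 = _nearest_msms(msms, 369.13)
    if frag_369 is not None:
        call = classify_isobar_369(frag_369, msms_tol)
        if call == "curcumin":
            turmeric = Verdict("positive",
                               ["m/z 369.13 MS/MS shows curcuminoid daughters"])
        elif call == "picrocrocin":
            turmeric = Verdict(
                "excluded",
                ["m/z 369.13 MS/MS daughters 351/337/309/225/207 indicate "
                 "picrocrocin; turmeric excluded"])
        else:
            turmeric = Verdict("inconclusive",
                               ["m/z 369.13 MS/MS matches neither isobar"])
    elif has_369:
        triplet = _hits(mzs, CURCUMINOID_TRIPLET, ms1_tol)
        if triplet == 3:
            turmeric = Verdict(
                "positive",
                ["curcuminoid triplet 369.13/339.12/309.11 present in MS1"])
        else:
            turmeric = Verdict(
                "inconclusive",
                ["m/z 369.13 present but no MS/MS acquired; isobar "
                 "(curcumin vs picrocrocin+K) unresolved"])
    else:
        turmeric = Verdict("excluded", ["no ion at m/z 369.13"])

    # ---- calendula ------------------------------------------------------
    markers = [t for t in CALENDULA_PRECURSORS
               if any(abs(m - t) <= ms1_tol for m in mzs)]
    frag_641 = _nearest_msms(msms, 641.17)
    if frag_641 is not None:
        if _hits(frag_641, CALENDULA_CASCADE, msms_tol) >= 1:
            calendula = Verdict(
                "positive",
                ["m/z 641 MS/MS shows the 641 -> 478 -> 339 aglycone cascade"])
        else:
            calendula = Verdict(
                "excluded",
                ["m/z 641 MS/MS lacks the di-O-glycoside cascade; "
                 "calendula excluded"])
    elif markers:
        calendula = Verdict(
            "inconclusive",
            [f"calendula marker(s) at {markers} present but no MS/MS acquired"])
    else:
        calendula = Verdict("excluded",
                            ["no calendula di-O-glycoside precursors in MS1"])

    # ---- gardenia -------------------------------------------------------
    has_na = any(abs(m - GENIPOSIDE_NA) <= ms1_tol for m in mzs)
    has_k = any(abs(m - GENIPOSIDE_K) <= ms1_tol for m in mzs)
    pair = [
        (p, q) for p, q in detect_adduct_pairs(ms1)
        if abs(p.mz - GENIPOSIDE_NA) <= ms1_tol
    ]
    if has_na and has_k and pair:
        gardenia = Verdict(
            "positive",
            ["geniposide Na/K adduct pair 411.13/427.10 detected"])
    elif has_na or has_k:
        gardenia = Verdict(
            "inconclusive",
            ["single geniposide adduct observed; Na/K pair incomplete"])
    else:
        gardenia = Verdict("excluded", ["no geniposide adducts in MS1"])

    return ScreenResult(turmeric, calendula, gardenia)
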