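"""Observed-spectrum model: centroid peak lists and MS1 annotation.

Covers the acquisition-side conventions of reflectron-positive MALDI-TOF
work on these analytes: an instrument-style S/N >= 200 discard filter,
accurate-mass matching against the theoretical fingerprint table (ppm
tolerance), detection of the 162.0528 Th hexose glycoform ladders and of
the 15.9739 Th [M+Na]+/[M+K]+ adduct pairs, and isotope-cluster area (ICA)
integration for quantitation.  All ions handled here are singly charged,
so the isotopologue spacing is fixed at 1.00336 Th.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .compounds import FingerprintEntry
from .formula import ppm_error

__all__ = [
    "Peak",
    "PeakList",
    "IsotopeCluster",
    "Assignment",
    "snr_filter",
    "match_fingerprint",
    "detect_ladder",
    "detect_adduct_pairs",
    "integrate_cluster",
    "read_peaklist_csv",
    "write_peaklist_csv",
    "read_mzml",
]

#: Averaged 13C isotopologue spacing for singly charged ions, in Th.
ISOTOPE_SPACING = 1.00336

#: Matching preference on equal |ppm|: saffron crocins first, then the
#: internal standard, then everything else; final tie-break is the name.
_ROLE_PRIORITY = {"saffron_crocin": 0}


@dataclass(frozen=True)
class Peak:
    """One centroided peak.  ``area`` falls back to intensity when absent."""

    mz: float
    intensity: float
    area: Optional[float] = None
    snr: Optional[float] = None

    def __post_init__(self):
        if not 0.0 < self.mz < 20000.0:
            raise ValueError(f"m/z {self.mz} outside (0, 20000)")
        if self.intensity < 0:
            raise ValueError("negative intensity")

    @property
    def effective_area(self) -> float:
        return self.area if self.area is not None else self.intensity


@dataclass(frozen=True)
class PeakList:
    """Centroid peaks sorted ascending in m/z, with acquisition metadata."""

    peaks: Tuple[Peak, ...]
    metadata: Tuple[Tuple[str, str], ...] = ()

    def __init__(self, peaks: Sequence[Peak], metadata: Dict[str, str] | None = None):
        ordered = tuple(sorted(peaks, key=lambda p: p.mz))
        for a, b in zip(ordered, ordered[1:]):
            if b.mz - a.mz < 1e-6:
                raise ValueError(f"duplicate m/z within 1e-6: {a.mz}")
        object.__setattr__(self, "peaks", ordered)
        object.__setattr__(self, "metadata",
                           tuple(sorted((metadata or {}).items())))

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    @property
    def mzs(self) -> List[float]:
        return [p.mz for p in self.peaks]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mz": [p.mz for p in self.peaks],
                "intensity": [p.intensity for p in self.peaks],
                "area": [p.area for p in self.peaks],
                "snr": [p.snr for p in self.peaks],
            }
        )


@dataclass
class IsotopeCluster:
    """A monoisotopic peak with its isotopologue envelope and summed area."""

    mono_mz: float
    members: List[Peak]
    ica: float
    compound: Optional[str] = None
    adduct: Optional[str] = None


@dataclass
class Assignment:
    """One peak matched to one fingerprint entry within the ppm tolerance."""

    peak: Peak
    entry: FingerprintEntry
    delta_ppm: float
    rank: int
    isobar: bool = False


def snr_filter(pl: PeakList, threshold: float = 200.0) -> PeakList:
    """Discard peaks with S/N below ``threshold``.

    Mirrors the instrument-side automatic rejection.  Peaks without an S/N
    estimate are retained with a warning; threshold 0 is the identity.
    """
    if threshold < 0:
        raise ValueError("S/N threshold must be >= 0")
    if any(p.snr is None for p in pl):
        warnings.warn("peaks without S/N retained by snr_filter", stacklevel=2)
    kept = [p for p in pl if p.snr is None or p.snr >= threshold]
    return PeakList(kept, dict(pl.metadata))


def match_fingerprint(
    pl: PeakList,
    table: Sequence[FingerprintEntry],
    ppm_tol: float = 10.0,
) -> List[Assignment]:
    """Accurate-mass assignment of peaks to fingerprint entries.

    Each peak collects every entry within ``ppm_tol`` (ranked by |ppm|), so
    unresolvable isobars - e.g. protonated curcumin vs the picrocrocin K
    adduct at m/z 369.13 - yield multiple flagged assignments on one peak.
    Ties at equal |ppm| prefer crocins, then the internal standard, then
    lexicographic compound name.
    """
    if not table:
        raise ValueError("empty fingerprint table")
    if ppm_tol <= 0:
        raise ValueError("ppm tolerance must be positive")
    out: List[Assignment] = []
    for peak in pl:
        hits = []
        for entry in table:
            dppm = ppm_error(peak.mz, entry.mz)
            if abs(dppm) <= ppm_tol:
                prio = _ROLE_PRIORITY.get(entry.role,
                                          1 if entry.internal_standard else 2)
                hits.append((abs(dppm), prio, entry.compound, dppm, entry))
        hits.sort()
        isobar = len(hits) > 1
        for rank, (_, _, _, dppm, entry) in enumerate(hits, start=1):
            out.append(Assignment(peak, entry, dppm, rank, isobar))
    return out


def detect_ladder(
    pl: PeakList,
    spacing: float = 162.052824,
    n_min: int = 3,
    tol: float = 0.05,
) -> List[List[Peak]]:
    """Maximal arithmetic peak chains with the given m/z step.

    The default step is the hexose residue mass, i.e. the crocin glycoform
    ladder.  Each peak links to its closest successor at ``mz + spacing``
    within ``tol``; chains shorter than ``n_min`` are dropped.
    """
    if spacing <= 0 or n_min < 2:
        raise ValueError("spacing must be > 0 and n_min >= 2")
    peaks = list(pl)
    successor: Dict[int, int] = {}
    has_pred = set()
    for i, p in enumerate(peaks):
        best = None
        for j in range(i + 1, len(peaks)):
            d = peaks[j].mz - (p.mz + spacing)
            if d > tol:
                break
            if abs(d) <= tol and (best is None or abs(d) < best[0]):
                best = (abs(d), j)
        if best is not None:
            successor[i] = best[1]
            has_pred.add(best[1])
    ladders = []
    for i in range(len(peaks)):
        if i in has_pred or i not in successor:
            continue
        chain = [i]
        while chain[-1] in successor:
            chain.append(successor[chain[-1]])
        if len(chain) >= n_min:
            ladders.append([peaks[k] for k in chain])
    return ladders


def detect_adduct_pairs(
    pl: PeakList,
    delta: float = 15.973895,
    tol: float = 0.02,
) -> List[Tuple[Peak, Peak]]:
    """All peak pairs separated by the K-vs-Na adduct spacing.

    Returns ordered (sodiated, potassiated) candidate pairs; the default
    delta is the exact K - Na mass difference (the nominal "16 Da" split).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    peaks = list(pl)
    pairs = []
    for i, p in enumerate(peaks):
        for q in peaks[i + 1:]:
            d = q.mz - p.mz - delta
            if d > tol:
                break
            if abs(d) <= tol:
                pairs.append((p, q))
    return pairs


def integrate_cluster(
    pl: PeakList,
    mono_mz: float,
    n_iso: int = 4,
    tol: float = 0.05,
) -> IsotopeCluster:
    """Sum the isotope-cluster area (ICA) of the ion at ``mono_mz``.

    Collects peaks at mono_mz + k * 1.00336 for k = 0..n_iso-1 within
    ``tol``; missing higher isotopologues contribute zero, but a missing
    monoisotopic peak is an error.
    """
    if n_iso < 1 or tol <= 0:
        raise ValueError("n_iso must be >= 1 and tol > 0")
    peaks = list(pl)
    members: List[Peak] = []
    for k in range(n_iso):
        target = mono_mz + k * ISOTOPE_SPACING
        best = None
        for p in peaks:
            d = abs(p.mz - target)
            if d <= tol and (best is None or d < abs(best.mz - target)):
                best = p
        if best is None:
            if k == 0:
                raise ValueError(f"monoisotopic peak not found at {mono_mz}")
            continue
        members.append(best)
    return IsotopeCluster(
        mono_mz=members[0].mz,
        members=members,
        ica=sum(p.effective_area for p in members),
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_peaklist_csv(path: str | Path) -> PeakList:
    """Read a centroid peak list CSV with header ``mz,intensity[,area][,snr]``."""
    df = pd.read_csv(path)
    if "mz" not in df.columns or "intensity" not in df.columns:
        raise ValueError(f"{path}: need at least 'mz' and 'intensity' columns")
    peaks = [
        Peak(
            mz=float(row.mz),
            intensity=float(row.intensity),
            area=float(row.area) if "area" in df.columns and pd.notna(row.area) else None,
            snr=float(row.snr) if "snr" in df.columns and pd.notna(row.snr) else None,
        )
        for row in df.itertuples()
    ]
    if not peaks:
        raise ValueError(f"{path}: empty peak list")
    return PeakList(peaks)


def write_peaklist_csv(pl: PeakList, path: str | Path) -> None:
    """Write a peak list CSV (m/z at 4 d.p., dot decimal, UTF-8)."""
    df = pl.to_dataframe()
    df["mz"] = df["mz"].map(lambda v: f"{v:.4f}")
    df.to_csv(path, index=False)


def _decode_binary(binary_text: str, accessions: set) -> "np.ndarray":
    import base64
    import zlib

    import numpy as np

    raw = base64.b64decode(binary_text)
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    return np.frombuffer(raw, dtype=dtype)


def read_mzml(path: str | Path) -> PeakList:
    """Read the first MS1 centroid spectrum from an mzML file.

    A deliberately small reader for centroided mzML as produced by common
    converters: 32/64-bit float arrays, optionally zlib-compressed.
    """
    import xml.etree.ElementTree as ET

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = ET.parse(str(path))
    for spectrum in tree.iter(ns + "spectrum"):
        level = 1
        for cv in spectrum.findall(ns + "cvParam"):
            if cv.get("accession") == "MS:1000511":
                level = int(cv.get("value", "1"))
        if level != 1:
            continue
        arrays = {}
        for bda in spectrum.iter(ns + "binaryDataArray"):
            accessions = {cv.get("accession")
                          for cv in bda.findall(ns + "cvParam")}
            binary = bda.find(ns + "binary")
            data = _decode_binary(binary.text or "", accessions)
            if "MS:1000514" in accessions:
                arrays["mz"] = data
            elif "MS:1000515" in accessions:
                arrays["intensity"] = data
        if "mz" not in arrays or "intensity" not in arrays:
            raise ValueError(f"{path}: spectrum lacks m/z or intensity array")
        peaks = [Peak(float(m), float(i))
                 for m, i in zip(arrays["mz"], arrays["intensity"])]
        return PeakList(peaks)
    raise ValueError(f"{path}: no MS1 spectrum found")
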