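"""Seeded synthetic-data generator for MALDI-like peak lists and calibrations.

Everything the other modules consume can be generated here with known
ground truth: MS1 spectra containing sodiated/potassiated marker envelopes
over a noise floor, MS/MS spectra with configurable fragment dropout, and
isotope-cluster-area calibration series across adulteration levels.

The defaults emulate the study conditions of the underlying workflow:
acquisition window m/z 200-2000, instrument-level mass accuracy of a few
ppm, an S/N >= 200 signal/noise split, Na:K adduct weights 3:1 (sodium
dominant), 8 adulteration levels spanning 0-30% (w/w) measured in
triplicate, and multiplicative area noise of a couple of percent RSD.  A
baseline picrocrocin contribution is co-integrated into the m/z 369.13
cluster, since the curcumin internal standard and the picrocrocin K adduct
are isobaric and unresolvable on a TOF analyzer.

All randomness flows from ``numpy.random.default_rng(seed)``; a fixed
config is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .compounds import Compound, default_registry, find
from .formula import isotope_pattern
from .fragments import theoretical_ions
from .peaks import Peak, PeakList
from .quantify import QUANT_CROCINS

__all__ = [
    "SimulationConfig",
    "simulate_ms1",
    "simulate_msms",
    "simulate_adulteration_series",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic spectrum generator.

    ``composition`` maps compound names to relative mole amounts.  Mass
    errors are systematic ppm bias plus Gaussian ppm jitter; peak areas are
    moles x response factor x adduct weight, spread over the truncated
    isotope envelope (total area is conserved exactly before noise).
    """

    composition: Tuple[Tuple[str, float], ...] = ()
    adduct_weights: Tuple[Tuple[str, float], ...] = (("M+Na", 3.0), ("M+K", 1.0))
    response_factors: Tuple[Tuple[str, float], ...] = ()
    ppm_bias: float = 0.0
    ppm_jitter: float = 3.0
    n_noise_peaks: int = 50
    noise_area_scale: float = 50.0
    signal_snr: float = 1000.0
    noise_snr_max: float = 150.0
    base_area: float = 1e4
    n_iso: int = 4
    mz_range: Tuple[float, float] = (200.0, 2000.0)
    msms_dropout: float = 0.0
    seed: int = 0

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)

    @staticmethod
    def for_composition(composition: Dict[str, float], **kw) -> "SimulationConfig":
        return SimulationConfig(composition=tuple(sorted(composition.items())), **kw)


def _rf(cfg: SimulationConfig, name: str) -> float:
    return dict(cfg.response_factors).get(name, 1.0)


def _curated(registry: Optional[Sequence[Compound]]) -> List[Compound]:
    return list(registry) if registry is not None else default_registry()


def simulate_ms1(
    cfg: SimulationConfig,
    registry: Optional[Sequence[Compound]] = None,
) -> PeakList:
    """Simulate one centroided MS1 spectrum.

    For each compound x weighted adduct an isotope envelope is emitted at
    the theoretical m/z perturbed by the ppm error model; spurious noise
    peaks are added below the S/N threshold.  Deterministic under seed.
    """
    comp = dict(cfg.composition)
    if not comp:
        raise ValueError("empty composition")
    registry = _curated(registry)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.mz_range
    peaks: List[Peak] = []
    for name in sorted(comp):
        moles = comp[name]
        if moles <= 0:
            continue
        records = find(registry, name)
        if not records:
            raise ValueError(f"unknown compound {name!r}")
        compound = records[0]
        if compound.neutral_formula is None:
            continue
        # curcuminoids ionize protonated; glycosides as alkali adducts
        adducts = (
            (("M+H", 1.0),) if compound.skeleton == "curcuminoid"
            else cfg.adduct_weights
        )
        total_weight = sum(w for _, w in adducts)
        for ad_name, weight in adducts:
            ion = compound.ion(ad_name)
            envelope = isotope_pattern(ion, min_rel_abundance=0.0,
                                       max_peaks=cfg.n_iso)
            rel = np.array([r for _, r in envelope])
            rel /= rel.sum()
            area_total = moles * _rf(cfg, name) * (weight / total_weight) * cfg.base_area
            shift_ppm = cfg.ppm_bias + cfg.ppm_jitter * rng.standard_normal()
            for (mz, _), frac in zip(envelope, rel):
                mz_obs = mz * (1.0 + shift_ppm * 1e-6)
                if not lo <= mz_obs <= hi:
                    continue
                area = area_total * frac
                peaks.append(Peak(mz=mz_obs, intensity=area, area=area,
                                  snr=cfg.signal_snr))
    for _ in range(cfg.n_noise_peaks):
        mz = rng.uniform(lo, hi)
        area = rng.exponential(cfg.noise_area_scale)
        snr = rng.uniform(1.0, cfg.noise_snr_max)
        peaks.append(Peak(mz=mz, intensity=area, area=area, snr=snr))
    # enforce unique m/z: nudge collisions by 1e-5 (noise only, vanishing odds)
    seen = set()
    unique: List[Peak] = []
    for p in sorted(peaks, key=lambda p: p.mz):
        mz = p.mz
        while round(mz, 6) in seen:
            mz += 1e-5
        seen.add(round(mz, 6))
        unique.append(Peak(mz, p.intensity, p.area, p.snr))
    return PeakList(unique, {"seed": str(cfg.seed), "polarity": "positive"})


def simulate_msms(
    compound_name: str,
    adduct: str,
    cfg: SimulationConfig,
    registry: Optional[Sequence[Compound]] = None,
) -> PeakList:
    """Simulate an MS/MS peak list from the theoretical fragment set.

    Each theoretical ion survives with probability 1 - dropout; surviving
    ions get lognormal intensities and ppm-jittered m/z.  Deterministic
    under seed.
    """
    registry = _curated(registry)
    records = find(registry, compound_name)
    if not records:
        raise ValueError(f"unknown compound {compound_name!r}")
    compound = records[0]
    ions = [i for i in theoretical_ions(compound, adduct)
            if not i.diagnostic_absent]
    rng = np.random.default_rng(cfg.seed)
    peaks: List[Peak] = []
    seen = set()
    for ion in ions:
        if rng.random() < cfg.msms_dropout:
            continue
        shift = (cfg.ppm_bias + cfg.ppm_jitter * rng.standard_normal()) * 1e-6
        mz = ion.mz * (1.0 + shift)
        intensity = float(rng.lognormal(mean=5.0, sigma=0.5))
        while round(mz, 6) in seen:
            mz += 1e-5
        seen.add(round(mz, 6))
        peaks.append(Peak(mz=mz, intensity=intensity, area=intensity,
                          snr=cfg.signal_snr))
    return PeakList(peaks, {"seed": str(cfg.seed), "precursor": compound_name})


# ---------------------------------------------------------------------------
# Calibration-series generator
# ---------------------------------------------------------------------------

#: Default study design: 8 adulteration levels spanning 0-30% (w/w),
#: measured in triplicate.
DEFAULT_LEVELS = (0.0, 2.0, 5.0, 9.0, 13.0, 18.0, 24.0, 30.0)
DEFAULT_REPLICATES = 3

#: Noise-free crocin cluster areas (arbitrary counts*Th) and the
#: picrocrocin baseline that co-integrates into the 369.13 internal-
#: standard cluster (the K-adduct isobar of protonated curcumin).
_AREA_CROCINS = {"C-2": 5e4, "C-3": 3e4, "C-4": 2e4}
_AREA_PICROCROCIN = 5e3
#: Curcumin response per percent adulteration.  Chosen so that the total
#: integrated signal (saffron + internal standard) is conserved across
#: adulteration levels - an ion-competition picture of MALDI in which the
#: adulterant takes over the signal share of the displaced saffron.  Under
#: this model the noise-free molar ratio is exactly linear in the level,
#: matching the good linearity the method is built on.
_AREA_CURCUMIN_PER_PCT = (sum(_AREA_CROCINS.values()) + _AREA_PICROCROCIN) / 100.0
#: Multiplicative lognormal area noise (sigma of log), ~1.5% RSD.
_AREA_SIGMA = 0.015


def simulate_adulteration_series(
    levels: Sequence[float] = DEFAULT_LEVELS,
    replicates: int = DEFAULT_REPLICATES,
    cfg: SimulationConfig = SimulationConfig(),
    area_sigma: float = _AREA_SIGMA,
    saffron_displacement: bool = True,
) -> Tuple[pd.DataFrame, Dict]:
    """Generate per-level, per-replicate isotope-cluster areas.

    The generative model: crocin areas scale with the saffron mass fraction
    (1 - x/100) when ``saffron_displacement`` is set; the 369.13 cluster
    area is the picrocrocin baseline plus a linear curcumin response in the
    adulteration level x.  All areas carry multiplicative lognormal noise.

    Returns the dataset (columns ``level_percent, replicate, ICA_C2,
    ICA_C3, ICA_C4, ICA_curcumin``) and a ground-truth sidecar holding the
    generative parameters, the noise-free responses, and the OLS line
    through those noise-free responses (the "effective" calibration that a
    zero-noise fit recovers exactly).
    """
    if not all(0.0 <= x <= 100.0 for x in levels):
        raise ValueError("levels must lie in [0, 100]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for x in levels:
        saffron_frac = (1.0 - x / 100.0) if saffron_displacement else 1.0
        for rep in range(1, replicates + 1):
            areas = {
                f"ICA_{name.replace('-', '')}": _AREA_CROCINS[name] * saffron_frac
                * float(rng.lognormal(0.0, area_sigma)) if area_sigma > 0
                else _AREA_CROCINS[name] * saffron_frac
                for name in QUANT_CROCINS
            }
            t_clean = (_AREA_PICROCROCIN * saffron_frac
                       + _AREA_CURCUMIN_PER_PCT * x)
            t = (t_clean * float(rng.lognormal(0.0, area_sigma))
                 if area_sigma > 0 else t_clean)
            rows.append({"level_percent": x, "replicate": rep, **areas,
                         "ICA_curcumin": t})
    df = pd.DataFrame(rows)

    # noise-free response curve and its OLS line
    xs = np.asarray(levels, dtype=float)
    clean_mr = []
    for x in xs:
        sf = (1.0 - x / 100.0) if saffron_displacement else 1.0
        s = sum(_AREA_CROCINS[n] for n in QUANT_CROCINS) * sf
        t = _AREA_PICROCROCIN * sf + _AREA_CURCUMIN_PER_PCT * x
        clean_mr.append(s / (s + t))
    clean_mr = np.asarray(clean_mr)
    # closed-form OLS line through the noise-free responses; with the
    # signal-conserving defaults this equals the exact generative line
    xc = xs - xs.mean()
    sxx = float(xc @ xc)
    if sxx > 0:
        slope = float(xc @ (clean_mr - clean_mr.mean())) / sxx
        intercept = float(clean_mr.mean()) - slope * float(xs.mean())
    else:  # single-level design: no line to define
        slope, intercept = float("nan"), float(clean_mr.mean())
    truth = {
        "levels": list(map(float, xs)),
        "replicates": replicates,
        "area_sigma": area_sigma,
        "crocin_areas": dict(_AREA_CROCINS),
        "picrocrocin_area": _AREA_PICROCROCIN,
        "curcumin_area_per_percent": _AREA_CURCUMIN_PER_PCT,
        "noise_free_mr": clean_mr.tolist(),
        "effective_slope": float(slope),
        "effective_intercept": float(intercept),
        "seed": cfg.seed,
    }
    return df, truth


def molar_ratios_from_series(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse an area table to (level, replicate, MR_S) rows."""
    out = df.copy()
    s = out[["ICA_C2", "ICA_C3", "ICA_C4"]].sum(axis=1)
    out["MR_S"] = s / (s + out["ICA_curcumin"])
    return out[["level_percent", "replicate", "MR_S"]]
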