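"""Registry of saffron and adulterant marker compounds.

Saffron markers: the crocins C-1..C-9 (glycosyl esters of crocetin carrying
1-9 glucose units split over the two carboxyl ends), picrocrocin and related
glycoconjugated carotenoid-breakdown metabolites (trimethylcyclohexene and
hexahydro-isobenzofuranone skeletons), and the stigma flavonols.  Adulterant
markers: the turmeric curcuminoid triplet (curcumin doubling as the
non-isotopic isobaric internal standard for quantitation), calendula
flavonol di-O-glycosides, and the gardenia iridoid geniposide.

Where a published ion formula conflicts with the compositional rule
(aglycone plus n hexose residues), the registry stores the
composition-derived formula and records the published variant in a
``discrepancy`` note together with the reported m/z, so matching against
observed spectra can still use the reported value at a configurable
tolerance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .formula import (
    ADDUCTS,
    AdductSpec,
    MolecularFormula,
    apply_adduct,
    monoisotopic_mz,
    parse_formula,
    render_formula,
)

__all__ = [
    "Compound",
    "FingerprintEntry",
    "CROCETIN",
    "HEXOSE",
    "HEXOSE_MASS",
    "REGISTRY_VERSION",
    "build_crocin",
    "default_registry",
    "find",
    "fingerprint_table",
    "registry_to_tsv",
    "registry_from_tsv",
]

REGISTRY_VERSION = "1.0"

CROCETIN = parse_formula("C20H24O4")
HEXOSE = parse_formula("C6H10O5")
#: Glycoform ladder spacing: monoisotopic mass of one hexose residue.
HEXOSE_MASS = monoisotopic_mz(HEXOSE)

ROLES = (
    "saffron_crocin",
    "saffron_metabolite",
    "saffron_flavonol",
    "adulterant_turmeric",
    "adulterant_calendula",
    "adulterant_gardenia",
)

SKELETONS = ("TMC", "IBF", "crocetin", "flavonoid", "curcuminoid", "iridoid")


@dataclass(frozen=True)
class Compound:
    """A named marker compound.

    ``r1``/``r2`` give the hexose counts of the two glycan chains for linear
    glycoconjugates (r1 >= r2); when present the neutral formula must equal
    aglycone + (r1 + r2) x C6H10O5.  Markers known only by their reported
    precursor m/z (the calendula di-O-glycosides) carry ``reported_mz``
    entries and no formula.
    """

    name: str
    neutral_formula: Optional[MolecularFormula]
    role: str
    r1: Optional[int] = None
    r2: Optional[int] = None
    aglycone: Optional[MolecularFormula] = None
    skeleton: Optional[str] = None
    internal_standard: bool = False
    #: adduct name (or "reported") -> published observed m/z
    reported_mz: Tuple[Tuple[str, float], ...] = ()
    #: published MS/MS cascade values, as printed
    cascade: Tuple[float, ...] = ()
    #: stored diagnostic MS/MS ions (1 d.p. published values)
    diagnostic_ions: Tuple[float, ...] = ()
    discrepancy: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if self.skeleton is not None and self.skeleton not in SKELETONS:
            raise ValueError(f"unknown skeleton {self.skeleton!r}")
        if self.r1 is not None:
            if self.r2 is None or self.r1 < self.r2 or self.r2 < 0:
                raise ValueError("glycan topology requires r1 >= r2 >= 0")
            if self.aglycone is not None and self.neutral_formula is not None:
                expected = self.aglycone + (self.r1 + self.r2) * HEXOSE
                if expected != self.neutral_formula:
                    raise ValueError(
                        f"{self.name}: formula {self.neutral_formula} != "
                        f"aglycone + {self.r1 + self.r2} hexoses ({expected})"
                    )

    def ion(self, adduct: str | AdductSpec) -> MolecularFormula:
        if self.neutral_formula is None:
            raise ValueError(f"{self.name} has no molecular formula")
        return apply_adduct(self.neutral_formula, adduct)

    def mz(self, adduct: str | AdductSpec) -> float:
        return monoisotopic_mz(self.ion(adduct))


@dataclass(frozen=True)
class FingerprintEntry:
    """One theoretical MS1 fingerprint row (compound x adduct)."""

    compound: str
    adduct: str
    ion_formula: Optional[MolecularFormula]
    mz: float
    role: str
    in_range: bool
    internal_standard: bool = False


def build_crocin(
    n_total: int,
    r1: int,
    r2: int,
    reported_mz: Tuple[Tuple[str, float], ...] = (),
    discrepancy: str = "",
) -> Compound:
    """Build crocin C-n: crocetin esterified with r1 + r2 = n glucoses.

    Isomeric chain topologies (e.g. C-5 as (3,2) or (4,1)) are separate
    records sharing the name "C-n".
    """
    if not 1 <= n_total <= 9:
        raise ValueError(f"crocin glucose count {n_total} outside 1..9")
    if r1 + r2 != n_total or r1 < r2 or r2 < 0:
        raise ValueError(f"invalid topology ({r1},{r2}) for C-{n_total}")
    return Compound(
        name=f"C-{n_total}",
        neutral_formula=CROCETIN + n_total * HEXOSE,
        role="saffron_crocin",
        r1=r1,
        r2=r2,
        aglycone=CROCETIN,
        skeleton="crocetin",
        reported_mz=reported_mz,
        discrepancy=discrepancy,
    )


def _glyco(name, role, aglycone, r1, r2, skeleton, **kw) -> Compound:
    ag = parse_formula(aglycone)
    return Compound(
        name=name,
        neutral_formula=ag + (r1 + r2) * HEXOSE,
        role=role,
        r1=r1,
        r2=r2,
        aglycone=ag,
        skeleton=skeleton,
        **kw,
    )


def default_registry() -> List[Compound]:
    """The built-in marker registry (30 records)."""
    reg: List[Compound] = []

    # -- crocins.  Reported sodiated m/z for the heavier glycoforms sit
    #    0.01-0.03 Th above the composition-derived theoretical values; the
    #    reported values are kept as observed references, not ground truth.
    topologies = {
        1: [(1, 0)],
        2: [(2, 0)],
        3: [(2, 1)],
        4: [(2, 2)],
        5: [(3, 2), (4, 1)],
        6: [(4, 2)],
        7: [(6, 1)],
        8: [(6, 2)],
        9: [(7, 2)],
    }
    reported_na = {
        2: 675.27, 4: 999.38, 5: 1161.45, 6: 1323.49,
        7: 1485.54, 8: 1647.59, 9: 1809.65,
    }
    for n, tops in topologies.items():
        for r1, r2 in tops:
            kw = {}
            if n in reported_na:
                theo = monoisotopic_mz(apply_adduct(CROCETIN + n * HEXOSE, "M+Na"))
                kw["reported_mz"] = (("M+Na", reported_na[n]),)
                kw["discrepancy"] = (
                    f"reported sodiated m/z {reported_na[n]} deviates from the "
                    f"composition-derived {theo:.2f}"
                )
            reg.append(build_crocin(n, r1, r2, **kw))

    # -- picrocrocin and carotenoid-derived glycoconjugates.  The published
    #    K-adduct formula shows O8 but the quoted theoretical mass 369.1310
    #    corresponds to C16H26O7K (picrocrocin is C16H26O7); treated as an
    #    O-count typo.
    reg.append(
        _glyco(
            "picrocrocin", "saffron_metabolite", "C10H16O2", 1, 0, "TMC",
            diagnostic_ions=(351.1, 337.1, 309.1, 225.1, 207.1),
            discrepancy=(
                "K-adduct formula published with O8; the quoted theoretical "
                "369.1310 corresponds to C16H26O7K"
            ),
        )
    )
    reg.append(_glyco("metabolite-1", "saffron_metabolite", "C10H16O3", 2, 0, "TMC"))
    reg.append(
        Compound(
            "metabolite-2", parse_formula("C31H38O16"), "saffron_metabolite",
            skeleton="TMC", reported_mz=(("M+Na", 693.26),),
            discrepancy=(
                "reported m/z 693.26 is inconsistent with the published ion "
                "formula [C31H38NaO16]+ (theoretical 689.20)"
            ),
        )
    )
    reg.append(_glyco("metabolite-3", "saffron_metabolite", "C10H16O2", 1, 0, "TMC"))
    reg.append(_glyco("metabolite-4", "saffron_metabolite", "C10H16O2", 2, 0, "TMC"))
    reg.append(_glyco("metabolite-5", "saffron_metabolite", "C9H16O3", 2, 0, "TMC"))
    reg.append(_glyco("metabolite-6", "saffron_metabolite", "C9H14O2", 2, 0, "TMC"))
    reg.append(
        _glyco(
            "metabolite-7", "saffron_metabolite", "C10H16O5", 2, 0, "IBF",
            discrepancy=(
                "published DBE 5.50 conflicts with the monovalent-Na/K "
                "convention (4.5) used throughout"
            ),
        )
    )
    reg.append(_glyco("metabolite-8", "saffron_metabolite", "C10H16O4", 2, 0, "IBF"))

    # -- flavonols.  Kaempferol-3-sophoroside follows the compositional rule
    #    kaempferol C15H10O6 + 2 hexoses = C27H30O16, consistent with the
    #    published sodiated ion [C27H30NaO16]+.
    reg.append(
        _glyco("kaempferol-3-sophoroside", "saffron_flavonol", "C15H10O6", 2, 0,
               "flavonoid")
    )
    reg.append(
        _glyco("kaempferol-3-sophoroside-7-glucoside", "saffron_flavonol",
               "C15H10O6", 2, 1, "flavonoid")
    )
    reg.append(
        Compound("quercetin", parse_formula("C15H10O7"), "saffron_flavonol",
                 skeleton="flavonoid")
    )
    reg.append(
        _glyco("quercetin-3-O-glucoside", "saffron_flavonol", "C15H10O7", 1, 0,
               "flavonoid")
    )

    # -- turmeric curcuminoids; curcumin is also the internal standard.
    reg.append(
        Compound(
            "curcumin", parse_formula("C21H20O6"), "adulterant_turmeric",
            skeleton="curcuminoid", internal_standard=True,
            diagnostic_ions=(351.1, 285.1, 245.1, 177.1, 145.0),
        )
    )
    reg.append(
        Compound("demethoxycurcumin", parse_formula("C20H18O5"),
                 "adulterant_turmeric", skeleton="curcuminoid")
    )
    reg.append(
        Compound("bisdemethoxycurcumin", parse_formula("C19H16O4"),
                 "adulterant_turmeric", skeleton="curcuminoid")
    )

    # -- calendula di-O-glycosides: stored by reported precursor m/z and
    #    MS/MS cascade (full formulas are not derivable consistently from
    #    the published ions).
    reg.append(
        Compound("isorhamnetin-di-O-glycoside", None, "adulterant_calendula",
                 skeleton="flavonoid", reported_mz=(("reported", 641.17),),
                 cascade=(641.0, 478.0, 339.0))
    )
    reg.append(
        Compound("quercetin-di-O-glycoside", None, "adulterant_calendula",
                 skeleton="flavonoid", reported_mz=(("reported", 649.14),),
                 cascade=(649.0, 487.0, 325.0))
    )
    reg.append(
        Compound("kaempferol-di-O-glycoside", None, "adulterant_calendula",
                 skeleton="flavonoid", reported_mz=(("reported", 617.15),),
                 cascade=(617.0, 455.0, 309.0))
    )

    # -- gardenia iridoid.  The published K adduct (427.00) deviates from the
    #    composition-derived 427.10.
    reg.append(
        _glyco(
            "geniposide", "adulterant_gardenia", "C11H14O5", 1, 0, "iridoid",
            reported_mz=(("M+K", 427.00),),
            discrepancy=(
                "reported K-adduct m/z 427.00 deviates from the "
                "composition-derived 427.10"
            ),
        )
    )
    return reg


#: Published high-energy CID product ions (1 d.p. as reported) of the
#: crocin [M+Na]+ precursors, used as the fragment-engine benchmark set.
#: Values are observed references, not theoretical ground truth; the
#: reported Z-type ions (e.g. 497.2, 335.2) follow a nonstandard Y-O rule
#: and are expected to stay unmatched by the standard Z = Y - H2O ions.
CROCIN_REFERENCE_PRODUCT_IONS: Dict[str, Tuple[float, ...]] = {
    "C-1": (335.2, 423.2, 351.2, 259.1),
    "C-2": (631.3, 585.2, 513.2, 185.0, 483.2, 461.2, 365.1, 351.2, 305.1,
            259.1, 251.1),
    "C-3": (675.1, 513.2, 509.1, 493.1, 363.1, 347.1, 351.2, 259.1, 185.0),
    "C-4": (837.3, 675.3, 347.1, 658.2, 351.2, 509.1, 689.2),
    "C-5": (347.1, 999.4, 837.3, 509.1, 675.3, 671.2, 513.2, 363.1, 819.3,
            689.2, 497.2, 1087.4, 1071.4, 895.3, 909.3, 881.3, 747.3, 733.3,
            599.2),
}


def find(registry: Iterable[Compound], name: str) -> List[Compound]:
    """All registry records with the given name (crocin isomers share one)."""
    return [c for c in registry if c.name == name]


def fingerprint_table(
    registry: Sequence[Compound],
    adducts: Sequence[str | AdductSpec] = ("M+Na", "M+K", "M+H"),
    mz_range: Tuple[float, float] = (200.0, 2000.0),
) -> List[FingerprintEntry]:
    """Theoretical MS1 table: one entry per compound x adduct, m/z sorted.

    Formula-less markers contribute their reported precursor m/z instead.
    Entries outside the acquisition range are flagged, not dropped.
    """
    if not registry:
        raise ValueError("empty compound registry")
    lo, hi = mz_range
    entries: List[FingerprintEntry] = []
    for comp in registry:
        if comp.neutral_formula is not None:
            for ad in adducts:
                spec = ADDUCTS[ad] if isinstance(ad, str) else ad
                ion = comp.ion(spec)
                mz = monoisotopic_mz(ion)
                entries.append(
                    FingerprintEntry(comp.name, spec.name, ion, mz, comp.role,
                                     lo <= mz <= hi, comp.internal_standard)
                )
        for ad_name, mz in comp.reported_mz:
            if ad_name == "reported":
                entries.append(
                    FingerprintEntry(comp.name, "reported", None, mz, comp.role,
                                     lo <= mz <= hi, comp.internal_standard)
                )
    entries.sort(key=lambda e: (e.mz, e.compound, e.adduct))
    return entries


# ---------------------------------------------------------------------------
# TSV serialization
# ---------------------------------------------------------------------------

_TSV_COLUMNS = (
    "name", "neutral_formula", "role", "r1", "r2", "aglycone", "skeleton",
    "internal_standard", "reported_mz", "cascade", "diagnostic_ions", "notes",
)


def registry_to_tsv(registry: Sequence[Compound], path: str | Path) -> None:
    lines = ["# saffronms registry v" + REGISTRY_VERSION,
             "\t".join(_TSV_COLUMNS)]
    for c in registry:
        lines.append("\t".join([
            c.name,
            render_formula(c.neutral_formula) if c.neutral_formula else "",
            c.role,
            "" if c.r1 is None else str(c.r1),
            "" if c.r2 is None else str(c.r2),
            render_formula(c.aglycone) if c.aglycone else "",
            c.skeleton or "",
            "1" if c.internal_standard else "0",
            json.dumps(list(map(list, c.reported_mz))),
            json.dumps(list(c.cascade)),
            json.dumps(list(c.diagnostic_ions)),
            c.discrepancy,
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def registry_from_tsv(path: str | Path) -> List[Compound]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows = [ln for ln in lines if ln and not ln.startswith("#")]
    header = rows[0].split("\t")
    if tuple(header) != _TSV_COLUMNS:
        raise ValueError(f"unexpected registry columns: {header}")
    out: List[Compound] = []
    for row in rows[1:]:
        vals = dict(zip(_TSV_COLUMNS, row.split("\t")))
        out.append(
            Compound(
                name=vals["name"],
                neutral_formula=(parse_formula(vals["neutral_formula"])
                                 if vals["neutral_formula"] else None),
                role=vals["role"],
                r1=int(vals["r1"]) if vals["r1"] else None,
                r2=int(vals["r2"]) if vals["r2"] else None,
                aglycone=(parse_formula(vals["aglycone"])
                          if vals["aglycone"] else None),
                skeleton=vals["skeleton"] or None,
                internal_standard=vals["internal_standard"] == "1",
                reported_mz=tuple(
                    (a, float(m)) for a, m in json.loads(vals["reported_mz"])
                ),
                cascade=tuple(json.loads(vals["cascade"])),
                diagnostic_ions=tuple(json.loads(vals["diagnostic_ions"])),
                discrepancy=vals["notes"],
            )
        )
    return out
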