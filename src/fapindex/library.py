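"""Compound reference library: descriptors, retention indices and ion sets.

The built-in library holds the 30 sterols and triterpene alcohols (plus the
5a-cholestane internal standard) observed across rapeseed, hemp, corn and
sunflower oil, with their FAP retention indices, molecular ions, published
base peaks and 4-level assignment metadata:

* level 1 - verified against an authentic reference standard,
* level 2 - unequivocally verified by GC/MS data and literature,
* level 3 - tentative assignment (a proposed structure),
* level 4 - unknown (spectrum equivocal or too weak).

Each entry also carries an expected reference spectrum over the diagnostic-ion
vocabulary (see :func:`reference_spectrum`), used both to synthesise
rule-consistent spectra and to apportion shared peak areas between co-eluting
compounds.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import pandas as pd

from . import ions as I
from .errors import FormatError, LibraryConsistencyError
from .ions import IonSet, SterolDescriptor, diagnostic_fragments, isotope_m14_ratio

#: display floor: entries below this TIC share print as "tr" (trace)
TRACE_FLOOR_PERCENT = 0.02


@dataclass(frozen=True)
class LibraryEntry:
    index: int  # table numbering; 0 = internal standard
    descriptor: SterolDescriptor
    rrt: float
    ri_fap: float
    molecular_ion: float
    base_peak: float
    level: int
    standard_available: bool = False
    proposed_structure: bool = False
    confirmed_ions: tuple[float, ...] = ()
    prominent_m15: bool = False
    source_note: str = ""

    @property
    def name(self) -> str:
        return self.descriptor.name

    @property
    def is_internal_standard(self) -> bool:
        return self.descriptor.compound_class == I.INTERNAL_STANDARD

    @property
    def ion_set(self) -> IonSet:
        return diagnostic_fragments(self.descriptor, self.molecular_ion)

    def required_ions(self) -> tuple[float, ...]:
        """Diagnostic ions whose joint presence makes the assignment complete.

        Strong class diagnostics plus any entry-specific confirmed ions.  An
        empty set means the entry cannot be fully verified from the monitored
        vocabulary (tentative and unknown entries).
        """
        ion_set = self.ion_set
        req = {mz for mz in ion_set.diagnostic.values()
               if ion_set.intensity_hints.get(mz) == "strong"}
        req.update(self.confirmed_ions)
        req.discard(self.molecular_ion)
        return tuple(sorted(req))


def reference_spectrum(entry: LibraryEntry) -> dict[float, float]:
    """Expected relative ion abundances (fractions of compound signal).

    Weights: published base peak 0.30 (0.45 when the molecular ion itself is
    the base peak), molecular ion 0.20 (0.04 for pentacyclic triterpenols,
    whose M+ is weak), strong diagnostics 0.12, weakened diagnostics 0.05,
    [M-15]+ 0.06 (0.22 for 14-methyl types with a prominent methyl loss) and
    its one-13C satellite at [M-14]+ per the binomial expectation.
    """
    ion_set = entry.ion_set
    mplus = entry.molecular_ion
    spec: dict[float, float] = {}

    if abs(entry.base_peak - mplus) <= I.MZ_TOLERANCE:
        spec[mplus] = 0.45
    else:
        spec[entry.base_peak] = 0.30
        spec[mplus] = 0.04 if entry.descriptor.compound_class == I.PENTACYCLIC else 0.20

    for mz in ion_set.diagnostic.values():
        w = 0.12 if ion_set.intensity_hints.get(mz) == "strong" else 0.05
        spec[mz] = max(spec.get(mz, 0.0), w)
    for mz in entry.confirmed_ions:
        if abs(mz - ion_set.m_minus_15) <= I.MZ_TOLERANCE:
            continue  # handled below
        spec[mz] = max(spec.get(mz, 0.0), 0.12)

    if not entry.is_internal_standard:
        m15 = ion_set.m_minus_15
        w15 = 0.22 if entry.prominent_m15 else 0.06
        spec[m15] = max(spec.get(m15, 0.0), w15)
        # one-13C satellite of the methyl-loss fragment
        n_c = entry.descriptor.carbon_number + 3 - 1
        spec[round(m15 + 1.0, 1)] = spec[m15] * isotope_m14_ratio(n_c)
    return spec


class ReferenceLibrary:
    """Ordered collection of :class:`LibraryEntry` with lookup helpers."""

    def __init__(self, entries: list[LibraryEntry]):
        self.entries = list(entries)
        self._by_name = {e.name: e for e in self.entries}
        if len(self._by_name) != len(self.entries):
            raise FormatError("duplicate compound names in library")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, name: str) -> LibraryEntry:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def compounds(self) -> list[LibraryEntry]:
        """Entries excluding the internal standard."""
        return [e for e in self.entries if not e.is_internal_standard]

    @property
    def internal_standard(self) -> LibraryEntry | None:
        for e in self.entries:
            if e.is_internal_standard:
                return e
        return None

    def ri_range(self) -> tuple[float, float]:
        ris = [e.ri_fap for e in self.compounds]
        return min(ris), max(ris)

    def candidates_by_mplus(self, mz: float, tol: float = I.MZ_TOLERANCE) -> list[LibraryEntry]:
        return [e for e in self.entries if abs(e.molecular_ion - mz) <= tol]

    def candidates_by_ri(self, ri: float, tol_ri: float) -> list[LibraryEntry]:
        out = [e for e in self.entries if abs(e.ri_fap - ri) <= tol_ri]
        return sorted(out, key=lambda e: (abs(e.ri_fap - ri), e.index))


# ---------------------------------------------------------------------------
# built-in library: the published 30-compound table (+ internal standard).
# Columns: idx, name, rrt, ri, cn, db, positions, rings, class, M+, base peak,
#          level, std, proposed, confirmed ions, prominent [M-15]+, note
# Double-bond position labels as printed, ASCII-ised ("24(241)" = Delta24(24^1)).
_D = I.DESMETHYL
_BUILTIN_ROWS = [
    (0, "5a-Cholestane", 1.00, 1868, 27, 0, "", "", I.INTERNAL_STANDARD, 372.4, 372.4, 1, True, False, "", False,
     "internal standard; saturated sterane, not silylated"),
    (1, "Cholesterol", 1.29, 2129, 27, 1, "5", "", _D, 458.4, 129.1, 1, True, False, "", False, ""),
    (2, "Brassicasterol", 1.34, 2169, 28, 2, "5;22", "", _D, 470.4, 129.1, 2, False, False, "", False,
     "characteristic for Cruciferae"),
    (3, "24-Methylenecholesterol", 1.39, 2217, 28, 2, "5;24(241)", "", _D, 470.4, 129.1, 2, False, False, "", False, ""),
    (4, "Campesterol", 1.40, 2225, 28, 1, "5", "", _D, 472.4, 129.1, 1, True, False, "", False, ""),
    (5, "Unknown 1", 1.41, 2230, 29, 2, "n/a", "", _D, 484.4, 484.4, 4, False, False, "", False, ""),
    (6, "Campestanol", 1.41, 2235, 28, 0, "", "", I.STANOL, 474.4, 215.2, 2, False, False, "", False, ""),
    (7, "Delta8-Campesterol", 1.42, 2247, 28, 1, "8", "", _D, 472.4, 472.4, 3, False, True, "", False,
     "proposed; elutes between Delta5- and Delta7-campesterol, spectrum masked by stigmasterol"),
    (8, "Stigmasterol", 1.42, 2247, 29, 2, "5;22", "", _D, 484.4, 129.1, 1, True, False, "", False, ""),
    (9, "Unknown 3", 1.45, 2274, 29, 1, "n/a", "", _D, 486.4, 129.1, 4, False, False, "", False, ""),
    (10, "Unknown 4", 1.45, 2274, 28, 2, "n/a", "", _D, 470.4, 129.1, 4, False, False, "", False,
     "co-elutes with Unknown 3"),
    (11, "Delta7-Campesterol", 1.45, 2284, 28, 1, "7", "", _D, 472.4, 255.2, 2, False, False, "", False, ""),
    (12, "Clerosterol", 1.46, 2291, 29, 2, "5;25", "", _D, 484.4, 129.1, 2, False, False, "", False, ""),
    (13, "Lanosterol", 1.48, 2306, 30, 2, "8;24", "", I.FOUR_FOUR_DIMETHYL, 498.4, 498.4, 2, False, False,
     "215.2", False, "identified by M+ only; co-elutes with beta-sitosterol"),
    (14, "beta-Sitosterol", 1.48, 2306, 29, 1, "5", "", _D, 486.4, 129.1, 1, True, False, "", False, ""),
    (15, "Sitostanol", 1.49, 2319, 29, 0, "", "", I.STANOL, 488.4, 215.2, 2, False, False, "", False, ""),
    (16, "Delta5-Avenasterol", 1.49, 2320, 29, 2, "5;24(241)", "", _D, 484.4, 129.1, 2, False, False, "", False, ""),
    (17, "beta-Amyrin", 1.50, 2327, 30, 2, "12", "6r17,18", I.PENTACYCLIC, 498.4, 218.3, 2, False, False,
     "", False, ""),
    (18, "Delta8-Sitosterol", 1.50, 2329, 29, 1, "8", "", _D, 486.4, 486.4, 3, False, True, "", False,
     "proposed; analogous to Delta8-campesterol"),
    (19, "Butyrospermol", 1.51, 2336, 30, 2, "7;24", "", I.FOUR_FOUR_DIMETHYL, 498.4, 129.1, 3, False, True,
     "", False, "tentative, literature comparison"),
    (20, "Stigmasta-5,24(25)-dienol", 1.51, 2342, 29, 2, "5;24(25)", "", _D, 484.4, 129.1, 2, False, False,
     "", False, ""),
    (21, "Unknown 7", 1.53, 2354, 31, 2, "n/a", "", _D, 512.5, 129.1, 4, False, False, "", False,
     "full co-elution with gramisterol; resolved by SIM molecular ions"),
    (22, "Gramisterol", 1.53, 2354, 29, 2, "7;24(241)", "", I.FOUR_METHYL, 484.4, 129.1, 2, False, False,
     "", False, "only 4-methylsterol below 30 carbons"),
    (23, "Delta7-Sitosterol", 1.54, 2364, 29, 1, "7", "", _D, 486.4, 255.2, 2, False, False, "", False, ""),
    (24, "alpha-Amyrin", 1.54, 2365, 30, 2, "12", "6r17,18", I.PENTACYCLIC, 498.4, 218.3, 2, False, False,
     "", False, ""),
    (25, "Cycloartenol", 1.54, 2371, 30, 2, "24", "3r9,10", I.FOUR_FOUR_DIMETHYL, 498.4, 129.1, 2, False, False,
     "215.2;255.2", False, ""),
    (26, "Lupeol", 1.54, 2371, 30, 2, "20", "5r17,18", I.PENTACYCLIC, 498.4, 189.2, 2, False, False,
     "218.3", False, "assignment requires m/z 218 next to 189"),
    (27, "Delta7-Avenasterol", 1.55, 2378, 29, 2, "7;24(241)", "", _D, 484.4, 253.2, 2, False, False,
     "", False, ""),
    (28, "24-Methylenecycloartanol", 1.60, 2423, 31, 2, "24(241)", "3r9,10", I.FOUR_FOUR_DIMETHYL, 512.5, 129.1,
     2, False, False, "497.5", True, "14-methyl type: prominent [M-15]+ at m/z 497"),
    (29, "Unknown 8", 1.63, 2442, 30, 1, "n/a", "", _D, 500.4, 500.4, 4, False, False, "", False, ""),
    (30, "Citrostadienol", 1.64, 2457, 30, 2, "7;24(241)", "", I.FOUR_METHYL, 498.4, 129.1, 2, False, False,
     "", False, ""),
]

_LIB_COLUMNS = ["index", "name", "rrt", "ri_fap", "cn", "db", "positions", "rings",
                "class", "mplus_override", "base_peak", "level", "standard",
                "proposed", "confirmed_ions", "prominent_m15", "note"]


def _clean(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    return "" if s.lower() == "nan" else s


def _row_to_entry(idx, name, rrt, ri, cn, db, positions, rings, cls, mplus, base,
                  level, std, proposed, confirmed, prom_m15, note) -> LibraryEntry:
    positions, rings, confirmed, note = (_clean(positions), _clean(rings),
                                         _clean(confirmed), _clean(note))
    positions = str(positions).strip()
    unknown = positions.lower() in ("n/a", "na", "?")
    pos = () if (unknown or not positions) else tuple(p.strip() for p in positions.split(";"))
    ring = tuple(r.strip() for r in str(rings).split(";") if str(r).strip()) if rings else ()
    desc = SterolDescriptor(name=str(name), carbon_number=int(cn), db_count=int(db),
                            db_positions=pos, ring_annotations=ring,
                            compound_class=cls, positions_known=not unknown)
    conf = tuple(float(x) for x in str(confirmed).split(";") if str(x).strip()) if confirmed else ()
    entry = LibraryEntry(index=int(idx), descriptor=desc, rrt=float(rrt), ri_fap=float(ri),
                         molecular_ion=float(mplus), base_peak=float(base), level=int(level),
                         standard_available=bool(std), proposed_structure=bool(proposed),
                         confirmed_ions=conf, prominent_m15=bool(prom_m15),
                         source_note=str(note) if note else "")
    _check_mplus(entry)
    return entry


def _check_mplus(entry: LibraryEntry) -> None:
    if entry.is_internal_standard:
        return
    expected = I.tms_molecular_mz(entry.descriptor.carbon_number, entry.descriptor.db_count)
    if abs(expected - entry.molecular_ion) > 0.05:
        raise LibraryConsistencyError(
            f"{entry.name}: molecular ion {entry.molecular_ion} inconsistent with "
            f"computed TMS mass {expected} for C{entry.descriptor.carbon_number}:"
            f"{entry.descriptor.db_count}"
        )


def builtin_library() -> ReferenceLibrary:
    """The built-in 30-compound (+ ISTD) reference library."""
    return ReferenceLibrary([_row_to_entry(*row) for row in _BUILTIN_ROWS])


def save_library(lib: ReferenceLibrary, path) -> None:
    rows = []
    for e in lib:
        d = e.descriptor
        rows.append({
            "index": e.index, "name": e.name, "rrt": e.rrt, "ri_fap": e.ri_fap,
            "cn": d.carbon_number, "db": d.db_count,
            "positions": ";".join(d.db_positions) if d.positions_known and d.db_positions
                         else ("" if d.positions_known else "n/a"),
            "rings": ";".join(d.ring_annotations),
            "class": d.compound_class, "mplus_override": e.molecular_ion,
            "base_peak": e.base_peak, "level": e.level,
            "standard": int(e.standard_available), "proposed": int(e.proposed_structure),
            "confirmed_ions": ";".join(f"{x:.1f}" for x in e.confirmed_ions),
            "prominent_m15": int(e.prominent_m15), "note": e.source_note,
        })
    pd.DataFrame(rows, columns=_LIB_COLUMNS).to_csv(path, sep="\t", index=False)


def build_compound_library(source) -> ReferenceLibrary:
    """Read a library TSV (columns as written by :func:`save_library`).

    An empty file yields an empty library with a warning; a molecular-ion
    override inconsistent with the computed TMS mass raises
    :class:`~fapindex.errors.LibraryConsistencyError`.
    """
    if isinstance(source, (str,)) and source == "builtin":
        return builtin_library()
    try:
        df = pd.read_csv(source, sep="\t")
    except pd.errors.EmptyDataError:
        warnings.warn("library file is empty; returning an empty library")
        return ReferenceLibrary([])
    missing = {"name", "cn", "db", "class", "ri_fap", "level"} - set(df.columns)
    if missing:
        raise FormatError(f"library file missing columns: {sorted(missing)}")
    entries = []
    for _, r in df.iterrows():
        mplus = r.get("mplus_override")
        if pd.isna(mplus):
            mplus = I.tms_molecular_mz(int(r["cn"]), int(r["db"]))
        entries.append(_row_to_entry(
            r.get("index", 0), r["name"], r.get("rrt", 0.0), r["ri_fap"], r["cn"], r["db"],
            r.get("positions", "n/a"), r.get("rings", ""), r["class"], mplus,
            r.get("base_peak", mplus), r["level"], r.get("standard", 0),
            r.get("proposed", 0), r.get("confirmed_ions", ""), r.get("prominent_m15", 0),
            r.get("note", ""),
        ))
    return ReferenceLibrary(entries)


def library_roundtrip_check(lib: ReferenceLibrary) -> None:
    """Assert save->load identity (used by tests and the CLI self-check)."""
    buf = io.StringIO()
    save_library(lib, buf)
    buf.seek(0)
    lib2 = build_compound_library(buf)
    assert [e.name for e in lib2] == [e.name for e in lib]
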