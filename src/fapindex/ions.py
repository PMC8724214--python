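"""Masses and diagnostic EI fragment ions of silylated sterols and triterpenols.

Phytosterols are analysed by GC/EI-MS as trimethylsilyl (TMS) ethers of the
3-OH group.  At unit (single-quadrupole) resolution the relevant structural
vocabulary is small: the molecular ion places a compound on a 5x4 grid of
carbon numbers (27-31) and double-bond equivalents (0-3), and a handful of
ring fragments encode the ring-B saturation class:

===================  =======================================================
m/z 215.2            base peak of stanols (side chain + C15-C17 + TMSOH loss)
m/z 129.1            base peak of Delta5-sterols (TMSOH + C1-C3 of ring A)
m/z 213.2 / 255.2    shared by Delta5- and Delta7-sterols
m/z 211.2 / 253.2    the analogues for Delta5,7- / Delta5,8-sterols
[M-84-TMSOH]+        verifies a second side-chain double bond on C-24
m/z 218.3 / 189.2    retro-Diels-Alder pair of pentacyclic triterpenols; the
                     218:189 abundance ratio separates Delta12 (amyrin) types
                     from Delta13 types and lupeol
===================  =======================================================

4-Methyl- and 4,4-dimethylsterols shift the ring fragments by +14 u and
weaken them, often beyond detectability, so their identification leans on the
molecular ion (and [M-15]+) instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import RuleGapError

# monoisotopic atomic masses
MASS_H = 1.0078250319
MASS_C = 12.0
MASS_O = 15.9949146221
MASS_SI = 27.9769265327

#: TMSOH = (CH3)3SiOH, the neutral lost from silylated sterol ethers
MASS_TMSOH = 3 * MASS_C + 10 * MASS_H + MASS_O + MASS_SI

#: natural 13C abundance used for the [M-14]+ satellite check
P_13C = 0.0107

#: fragment ions characteristic of fatty acid pyrrolidides (any chain length)
FAP_BASE_ION = 113.0
FAP_SECONDARY_ION = 126.0

# ring-B / skeleton diagnostic ions (1 decimal, unit-resolution quadrupole)
ION_D5_BASE = 129.1
ION_RING_213 = 213.2
ION_RING_255 = 255.2
ION_RING_211 = 211.2
ION_RING_253 = 253.2
ION_STANOL_BASE = 215.2
ION_RDA_218 = 218.3
ION_RDA_189 = 189.2

#: default m/z matching tolerance for a unit-resolution quadrupole
MZ_TOLERANCE = 0.3

CARBON_RANGE = range(27, 32)
DB_RANGE = range(0, 4)

# The published acquisition tables list the two unsaturated C31 molecular ions
# 0.1 u above their rounded monoisotopic masses (the C31 column was evidently
# stepped down by exactly 2.0 from 516.5).  Since these printed values are the
# ones a SIM method actually monitors, the grid reproduces them; the exact
# monoisotopic masses remain available via :func:`tms_monoisotopic_mass`.
_PUBLISHED_GRID_ADJUSTMENT = {(31, 2): 0.1, (31, 3): 0.1}

# compound classes
DESMETHYL = "desmethyl_sterol"
FOUR_METHYL = "4_methyl"
FOUR_FOUR_DIMETHYL = "4_4_dimethyl"
STANOL = "stanol"
PENTACYCLIC = "pentacyclic"
INTERNAL_STANDARD = "internal_standard"

COMPOUND_CLASSES = (
    DESMETHYL,
    FOUR_METHYL,
    FOUR_FOUR_DIMETHYL,
    STANOL,
    PENTACYCLIC,
    INTERNAL_STANDARD,
)

#: side-chain double-bond labels verified by the [M-84-TMSOH]+ fragment
_M84_SIDE_CHAIN_LABELS = frozenset({"24(241)", "24(25)"})


def round1(x: float) -> float:
    """Round to 1 decimal, half away from zero (reproduces printed m/z values)."""
    return math.floor(x * 10.0 + 0.5) / 10.0


def tms_monoisotopic_mass(carbon_number: int, db_equivalents: int) -> float:
    """Monoisotopic mass of a sterol TMS ether, full precision.

    The underlying sterol C(n)H(2n-6-2d)O carries four rings; ``db_equivalents``
    counts double bonds plus any extra rings (cyclopropane ring of
    cycloartanes, fifth ring of pentacyclic triterpenols), which are isobaric.
    Silylation replaces the hydroxyl H by Si(CH3)3, a net +C3H8Si.
    """
    _check_grid_domain(carbon_number, db_equivalents)
    n_c = carbon_number + 3
    n_h = 2 * carbon_number + 2 - 2 * db_equivalents
    return n_c * MASS_C + n_h * MASS_H + MASS_O + MASS_SI


def tms_molecular_mz(carbon_number: int, db_equivalents: int) -> float:
    """Molecular ion m/z of a sterol TMS ether as monitored by the SIM method.

    Monoisotopic mass rounded half-up to 1 decimal; the two unsaturated C31
    cells carry the published +0.1 u convention (see module notes).
    """
    mz = round1(tms_monoisotopic_mass(carbon_number, db_equivalents))
    return round(mz + _PUBLISHED_GRID_ADJUSTMENT.get((carbon_number, db_equivalents), 0.0), 1)


def _check_grid_domain(carbon_number: int, db_equivalents: int) -> None:
    if carbon_number not in CARBON_RANGE:
        raise ValueError(f"carbon number {carbon_number} outside 27-31")
    if db_equivalents not in DB_RANGE:
        raise ValueError(f"double-bond equivalents {db_equivalents} outside 0-3")


def molecular_ion_grid() -> dict[tuple[int, int], float]:
    """The full 5x4 molecular-ion grid {(cn, db): m/z}."""
    return {(cn, db): tms_molecular_mz(cn, db) for cn in CARBON_RANGE for db in DB_RANGE}


def mz_to_cn_db(mz: float, tol: float = MZ_TOLERANCE) -> tuple[int, int] | None:
    """Inverse grid lookup: molecular ion m/z -> (carbon number, DB equivalents)."""
    best = None
    best_err = tol
    for key, grid_mz in molecular_ion_grid().items():
        err = abs(grid_mz - mz)
        if err <= best_err:
            best, best_err = key, err
    return best


def m84_tmsoh_loss(molecular_ion: float) -> float:
    """m/z of the [M-84-TMSOH]+ fragment verifying a second DB on C-24.

    84.1 u (C6H12 chunk of the alkylidene side chain) plus 90.1 u (TMSOH),
    e.g. 470.4 -> 296.2 for a C28:2 Delta5,24(24^1) sterol.
    """
    out = molecular_ion - 84.1 - 90.1
    if out <= 0.0:
        raise ValueError(f"molecular ion {molecular_ion} too small for an [M-84-TMSOH]+ loss")
    return round(out, 1)


def isotope_m14_ratio(n_carbons_in_fragment: int) -> float:
    """Expected intensity of the one-13C isotopologue relative to the all-12C peak.

    For a fragment with n carbons the isotopologue count is binomial(n, p13C),
    so the [M-14]+/[M-15]+ intensity ratio is exactly n*p/(1-p).  Si, H and O
    isotopes are neglected (documented approximation; 13C dominates).
    """
    if n_carbons_in_fragment < 0:
        raise ValueError("carbon count must be non-negative")
    return n_carbons_in_fragment * P_13C / (1.0 - P_13C)


@dataclass(frozen=True)
class SterolDescriptor:
    """Structural description of a sterol / triterpenol analyte.

    ``db_positions`` uses plain labels ("5", "7", "22", "24(241)", "24(25)",
    "12", "20", ...); ``ring_annotations`` uses the x-ring-y notation of extra
    rings ("3r9,10" cyclopropane, "6r17,18"/"5r17,18" pentacyclic E-ring).
    ``db_count`` counts DB *equivalents* (double bonds + extra rings), which is
    what the molecular-ion grid sees.
    """

    name: str
    carbon_number: int
    db_count: int
    db_positions: tuple[str, ...] = ()
    ring_annotations: tuple[str, ...] = ()
    compound_class: str = DESMETHYL
    positions_known: bool = True

    def __post_init__(self):
        if self.compound_class not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.compound_class!r}")
        if self.positions_known and self.db_positions:
            if len(self.db_positions) + len(self.ring_annotations) != self.db_count:
                raise ValueError(
                    f"{self.name}: {self.db_count} DB equivalents inconsistent with "
                    f"positions {self.db_positions} + rings {self.ring_annotations}"
                )
        if self.ring_annotations and self.compound_class in (DESMETHYL, STANOL):
            raise ValueError(f"{self.name}: ring annotations require a cycloartane/pentacyclic class")

    @property
    def has_delta(self) -> bool:
        return bool(self.db_positions)

    def has_position(self, label: str) -> bool:
        return any(p == label or p.startswith(label + "(") for p in self.db_positions)

    @property
    def side_chain_m84(self) -> bool:
        """True when the [M-84-TMSOH]+ rule applies (DB on C-24 / C-24(25))."""
        return any(p in _M84_SIDE_CHAIN_LABELS for p in self.db_positions)


@dataclass(frozen=True)
class IonSet:
    """Expected molecular and diagnostic ions of one silylated analyte."""

    molecular_ion: float
    m_minus_15: float
    diagnostic: dict[str, float] = field(default_factory=dict)
    expected_base_peak: float = 0.0
    intensity_hints: dict[float, str] = field(default_factory=dict)

    def __post_init__(self):
        if round(self.molecular_ion - self.m_minus_15, 1) != 15.0:
            raise ValueError("m_minus_15 must equal molecular_ion - 15.0")
        for mz in self.diagnostic.values():
            if mz >= self.molecular_ion:
                raise ValueError("diagnostic ions must lie below the molecular ion")

    @property
    def all_mz(self) -> tuple[float, ...]:
        return tuple(sorted({self.molecular_ion, self.m_minus_15, *self.diagnostic.values()}))


def diagnostic_fragments(d: SterolDescriptor, molecular_ion: float | None = None) -> IonSet:
    """Apply the diagnostic-ion rule table to a descriptor.

    The rules mirror the ring-B classification used throughout the package:
    stanol -> 215 base; Delta5 -> 129 base + 213/255; Delta7 -> 213/255
    without 129; Delta5,7 / Delta5,8 -> 211/253; a second side-chain DB on
    C-24 adds [M-84-TMSOH]+; pentacyclic Delta12 -> 218 > 189, Delta13/lupeol
    -> 189 > 218 with a weak molecular ion.  4-methyl classes shift the ring
    ions by +14 u and weaken them (hinted ``weak``; they are catalogued but
    not scheduled).
    """
    if molecular_ion is None:
        if d.compound_class == INTERNAL_STANDARD:
            raise RuleGapError(
                f"{d.name}: internal standards need an explicit molecular ion",
                missing_attributes=("molecular_ion",),
            )
        molecular_ion = tms_molecular_mz(d.carbon_number, d.db_count)
    m15 = round(molecular_ion - 15.0, 1)
    diag: dict[str, float] = {}
    hints: dict[float, str] = {}
    base = molecular_ion

    cls = d.compound_class
    if cls == INTERNAL_STANDARD:
        return IonSet(molecular_ion, m15, {}, expected_base_peak=molecular_ion,
                      intensity_hints={molecular_ion: "strong"})

    if cls == PENTACYCLIC:
        diag["rda_218"] = ION_RDA_218
        diag["rda_189"] = ION_RDA_189
        hints[molecular_ion] = "weak"
        if d.has_position("12"):
            base = ION_RDA_218
            hints[ION_RDA_218] = "strong"
            hints[ION_RDA_189] = "strong"
        else:  # Delta13 types and lupeol
            base = ION_RDA_189
            hints[ION_RDA_189] = "strong"
            hints[ION_RDA_218] = "weak"
        return IonSet(molecular_ion, m15, diag, base, hints)

    if cls == STANOL:
        diag["stanol_215"] = ION_STANOL_BASE
        base = ION_STANOL_BASE
        hints[ION_STANOL_BASE] = "strong"
        return IonSet(molecular_ion, m15, diag, base, hints)

    shift = 14.0 if cls == FOUR_METHYL else 0.0
    weakened = cls in (FOUR_METHYL, FOUR_FOUR_DIMETHYL)

    if not d.positions_known:
        # unknowns: no assignable ring class; molecular ion carries the signal
        return IonSet(molecular_ion, m15, {}, molecular_ion, {molecular_ion: "strong"})

    d5, d7, d8 = d.has_position("5"), d.has_position("7"), d.has_position("8")
    if d5 and (d7 or d8):
        diag["ring_211"] = round(ION_RING_211 + shift, 1)
        diag["ring_253"] = round(ION_RING_253 + shift, 1)
        base = diag["ring_253"]
    elif d5:
        diag["d5_129"] = ION_D5_BASE
        diag["ring_213"] = round(ION_RING_213 + shift, 1)
        diag["ring_255"] = round(ION_RING_255 + shift, 1)
        base = ION_D5_BASE
    elif d7:
        diag["ring_213"] = round(ION_RING_213 + shift, 1)
        diag["ring_255"] = round(ION_RING_255 + shift, 1)
        base = diag["ring_255"]
    elif d8:
        pass  # Delta8: ring diagnostics hindered; molecular ion only
    elif not d.db_positions and not d.ring_annotations and d.db_count == 0:
        raise RuleGapError(
            f"{d.name}: saturated non-stanol descriptor cannot be classified",
            missing_attributes=("compound_class",),
        )

    if d.side_chain_m84:
        diag["m84_tmsoh"] = m84_tmsoh_loss(molecular_ion)

    for name, mz in diag.items():
        # 4-methylation hinders the ring fragments, not the side-chain loss
        if name == "m84_tmsoh":
            hints[mz] = "strong"
        else:
            hints.setdefault(mz, "weak" if weakened else "strong")
    if weakened:
        # ring diagnostics weakened until hindered; the molecular ion dominates
        base = molecular_ion
        hints[molecular_ion] = "strong"
    return IonSet(molecular_ion, m15, diag, base, hints)
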