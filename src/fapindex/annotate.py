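"""Rule-based identification of sterol/triterpenol peaks.

Identification combines three orthogonal pieces of evidence, mirroring how a
practitioner reads a SIM chromatogram:

1. the molecular ion places the compound on the carbon-number x DB grid,
2. diagnostic ring fragments assign the ring-B / skeleton class,
3. the FAP retention index selects among isomers in the reference library.

Peaks may host several compounds (full co-elutions are common in this RI
range); distinct molecular ions — or disjoint diagnostic-ion signatures on a
shared molecular ion, as for lupeol under cycloartenol — yield one annotation
each.  The one-13C satellite of a prominent [M-15]+ fragment lands exactly on
the molecular ion of a one-carbon-smaller sterol, so candidate molecular ions
are screened against the binomial isotope expectation before they are
believed ("[M-14]+ check"); an excess flags a genuine co-eluting interferent.

Assignment levels: 1 = verified by an authentic standard, 2 = unequivocally
verified by GC/MS data and literature, 3 = tentative (proposed structure),
4 = unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ions as I
from .chrom import Chromatogram, FAPAnchorSet, Peak, is_fap_peak
from .library import LibraryEntry, ReferenceLibrary
from .ri import RIValue, compute_ri_fap, compute_rrt


@dataclass(frozen=True)
class AnnotationConfig:
    """Tunable thresholds of the rule engine (documented defaults)."""

    ri_tolerance: float = 2.5          # index units; observed drift stays below this
    mplus_floor: float = 0.05          # candidate M+ must reach 5 % of the peak's top ion
    presence_floor: float = 0.01       # diagnostic 'present' above 1 % of the top ion
    isotope_rel_tolerance: float = 0.30  # +-30 % on the [M-14]+/[M-15]+ ratio
    weak_mplus_fraction: float = 0.20  # M+ below 20 % of the top ion counts as weak
    mz_tolerance: float = I.MZ_TOLERANCE


# ring-B / skeleton classes inferred from ions
RING_STANOL = "stanol"
RING_D5 = "delta5"
RING_D7 = "delta7"
RING_D5_7 = "delta5,7/5,8"
RING_PENTA_D12 = "pentacyclic_delta12"
RING_PENTA_D13 = "pentacyclic_delta13_or_lupeol"


@dataclass
class PartialClass:
    """Structure information recoverable from the ions of one peak."""

    carbon_number: int | None = None
    db_count: int | None = None
    ring_class: str | None = None
    side_chain_db: bool = False
    fired: tuple[str, ...] = ()
    ambiguities: tuple[str, ...] = ()


@dataclass
class IsotopeCheck:
    status: str  # "pass" | "fail" | "inconclusive"
    observed: float | None = None
    expected: float | None = None


@dataclass
class Annotation:
    peak: Peak
    run_id: str
    mplus: float | None
    ri: RIValue | None
    inferred: PartialClass
    entry: LibraryEntry | None
    candidates: tuple[tuple[LibraryEntry, float], ...] = ()
    level: int = 4
    evidence: tuple[str, ...] = ()
    isotope: IsotopeCheck = field(default_factory=lambda: IsotopeCheck("inconclusive"))
    rrt: float | None = None

    @property
    def name(self) -> str:
        if self.entry is not None:
            return self.entry.name
        ri = "?" if self.ri is None else self.ri.rounded
        return f"unidentified@RI{ri}"

    @property
    def interference_flag(self) -> bool:
        return self.isotope.status == "fail"


def classify_peak(peak: Peak, mplus: float | None = None,
                  config: AnnotationConfig = AnnotationConfig()) -> PartialClass:
    """Infer a partial structural class from one peak's ions.

    ``mplus`` selects the molecular-ion candidate to interpret (the strongest
    grid ion when omitted).  The ring-class precedence is total: base 215 ->
    stanol; 211 & 253 -> Delta5,7/5,8; base 129 -> Delta5; 213 & 255 without a
    129 base -> Delta7; 218/189 with a weak molecular ion -> pentacyclic
    (Delta12 when 218 > 189).  Additional rules that also fire are recorded as
    ambiguities rather than raised.
    """
    top = max(peak.ion_intensities.values())
    floor = config.presence_floor * top

    def present(mz):
        return peak.intensity_at(mz, config.mz_tolerance) > floor

    if mplus is None:
        grid_hits = [(peak.ion_intensities[mz], mz) for mz in peak.ion_intensities
                     if I.mz_to_cn_db(mz) is not None]
        mplus = max(grid_hits)[1] if grid_hits else None

    cn = db = None
    if mplus is not None:
        hit = I.mz_to_cn_db(mplus)
        if hit is not None:
            cn, db = hit

    base = peak.base_ion
    fired: list[str] = []
    matches: list[str] = []

    if abs(base - I.ION_STANOL_BASE) <= config.mz_tolerance:
        matches.append(RING_STANOL)
        fired.append("base_215_stanol")
    if present(I.ION_RING_211) and present(I.ION_RING_253):
        matches.append(RING_D5_7)
        fired.append("211_253_delta5,7")
    if abs(base - I.ION_D5_BASE) <= config.mz_tolerance:
        matches.append(RING_D5)
        fired.append("base_129_delta5")
    elif present(I.ION_RING_213) and present(I.ION_RING_255):
        matches.append(RING_D7)
        fired.append("213_255_delta7")
    mplus_weak = (mplus is None or
                  peak.intensity_at(mplus, config.mz_tolerance) < config.weak_mplus_fraction * top)
    if (present(I.ION_RDA_218) or present(I.ION_RDA_189)) and mplus_weak:
        i218 = peak.intensity_at(I.ION_RDA_218, config.mz_tolerance)
        i189 = peak.intensity_at(I.ION_RDA_189, config.mz_tolerance)
        matches.append(RING_PENTA_D12 if i218 > i189 else RING_PENTA_D13)
        fired.append("rda_218_189_pentacyclic")

    side = False
    if mplus is not None and mplus > 174.2:
        side = present(I.m84_tmsoh_loss(mplus))
        if side:
            fired.append("m84_tmsoh_side_chain_DB")

    ring = matches[0] if matches else None
    ambiguities = tuple(matches[1:])
    return PartialClass(carbon_number=cn, db_count=db, ring_class=ring,
                        side_chain_db=side, fired=tuple(fired), ambiguities=ambiguities)


def _hindered(entry: LibraryEntry) -> bool:
    """Ring diagnostics unreliable for this entry (4-methylation or unknown)."""
    cls = entry.descriptor.compound_class
    return cls in (I.FOUR_METHYL, I.FOUR_FOUR_DIMETHYL) or not entry.descriptor.positions_known


def _ring_compatible(partial: PartialClass, entry: LibraryEntry) -> bool:
    if partial.ring_class is None:
        return True
    d = entry.descriptor
    if partial.ring_class in (RING_PENTA_D12, RING_PENTA_D13):
        if d.compound_class != I.PENTACYCLIC:
            return not d.positions_known
        return d.has_position("12") if partial.ring_class == RING_PENTA_D12 \
            else not d.has_position("12")
    if _hindered(entry) or not entry.required_ions():
        # no reliable diagnostics of its own (4-methylation, Delta8, unknowns):
        # ring evidence on the peak may belong to a co-eluter
        return True
    if partial.ring_class == RING_STANOL:
        return d.compound_class == I.STANOL
    if partial.ring_class == RING_D5:
        return d.has_position("5") and not (d.has_position("7") or d.has_position("8"))
    if partial.ring_class == RING_D7:
        return d.has_position("7") and not d.has_position("5")
    if partial.ring_class == RING_D5_7:
        return d.has_position("5") and (d.has_position("7") or d.has_position("8"))
    return True


def _specificity(partial: PartialClass, entry: LibraryEntry) -> int:
    score = 0
    if partial.ring_class is not None and not _hindered(entry):
        score += 2
    if partial.side_chain_db and entry.descriptor.side_chain_m84:
        score += 1
    return score


def match_library(ri: RIValue | float, partial: PartialClass, lib: ReferenceLibrary,
                  tol_ri: float = 2.5) -> list[tuple[LibraryEntry, float]]:
    """Ranked library candidates within ``tol_ri`` index units, class-compatible.

    Candidates must agree with the inferred carbon number and DB count and
    must not contradict the inferred ring class (entries whose diagnostics
    are structurally hindered — 4-methyl types — or unknown never
    contradict).  Ties are broken by class specificity, then smaller |dRI|.
    """
    ri_val = float(ri)
    out = []
    for e in lib.candidates_by_ri(ri_val, tol_ri):
        d = e.descriptor
        if partial.carbon_number is not None and d.carbon_number != partial.carbon_number:
            continue
        if partial.db_count is not None and d.db_count != partial.db_count:
            continue
        if not _ring_compatible(partial, e):
            continue
        out.append((e, abs(e.ri_fap - ri_val)))
    out.sort(key=lambda t: (-_specificity(partial, t[0]), t[1], t[0].index))
    return out


def isotope_interference_check(peak: Peak, carbon_number: int, mplus: float,
                               config: AnnotationConfig = AnnotationConfig()) -> IsotopeCheck:
    """Compare the [M-14]+/[M-15]+ ratio with its binomial expectation.

    A ratio in excess of the expectation (beyond the relative tolerance)
    indicates a genuine molecular ion of a co-eluting sterol one carbon
    smaller hiding under the 13C satellite; an absent [M-15]+ leaves the
    check inconclusive.
    """
    m15 = round(mplus - 15.0, 1)
    m14 = round(mplus - 14.0, 1)
    i15 = peak.intensity_at(m15, 0.25)
    i14 = peak.intensity_at(m14, 0.25)
    if i15 <= 0.0 or i14 <= 0.0:
        return IsotopeCheck("inconclusive")
    n_c = carbon_number + 3 - 1  # TMS ether carbons minus the lost methyl
    expected = I.isotope_m14_ratio(n_c)
    observed = i14 / i15
    ok = abs(observed - expected) <= config.isotope_rel_tolerance * expected
    return IsotopeCheck("pass" if ok else "fail", observed=observed, expected=expected)


def assign_level(candidates, evidence_complete: bool, contradicted: bool = False,
                 standards: frozenset[str] | None = None) -> int:
    """4-level assignment from the ranked candidates and diagnostic evidence."""
    if not candidates:
        return 4
    top = candidates[0][0]
    standard = top.standard_available or (standards is not None and top.name in standards)
    if top.is_internal_standard:
        return 1
    if evidence_complete and not contradicted:
        return 1 if standard else 2
    if top.descriptor.positions_known or top.proposed_structure:
        return 3
    return 4


def _mplus_candidates(peak: Peak, config: AnnotationConfig):
    """Grid-matching ions above the floor, with 13C satellites screened out."""
    top = max(peak.ion_intensities.values())
    floor = config.mplus_floor * top
    out, checks = [], {}
    for mz, inten in sorted(peak.ion_intensities.items()):
        if inten < floor or I.mz_to_cn_db(mz) is None:
            continue
        parent = peak.intensity_at(round(mz - 1.0, 1), 0.25)
        if parent > 0.0:
            hit = I.mz_to_cn_db(round(mz + 14.0, 1))
            n_c = (hit[0] + 3 - 1) if hit else 33
            expected = I.isotope_m14_ratio(n_c)
            if inten / parent <= expected * (1.0 + config.isotope_rel_tolerance):
                # fully explained as the one-13C satellite of an [M-15]+ ion
                checks[mz] = "satellite"
                continue
            checks[mz] = "excess"  # genuine co-eluting molecular ion
        out.append(mz)
    return out, checks


def _required_present(entry: LibraryEntry, peak: Peak, config: AnnotationConfig) -> bool:
    req = entry.required_ions()
    if not req:
        return False
    top = max(peak.ion_intensities.values())
    floor = config.presence_floor * top
    return all(peak.intensity_at(mz, config.mz_tolerance) > floor for mz in req)


def _match_loose(ri: RIValue, partial: PartialClass, lib: ReferenceLibrary,
                 tol_ri: float) -> list[tuple[LibraryEntry, float]]:
    """Candidates gated by RI, carbon number and DB only.

    On a merged peak the precedence-derived ring class reflects the dominant
    co-eluter, so a minor compound's own complete signature must be allowed
    to fire even when it disagrees with the peak-level class; ring-compatible
    entries still rank first.
    """
    ri_val = float(ri)
    out = []
    for e in lib.candidates_by_ri(ri_val, tol_ri):
        d = e.descriptor
        if partial.carbon_number is not None and d.carbon_number != partial.carbon_number:
            continue
        if partial.db_count is not None and d.db_count != partial.db_count:
            continue
        out.append((e, abs(e.ri_fap - ri_val)))
    out.sort(key=lambda t: (not _ring_compatible(partial, t[0]),
                            -_specificity(partial, t[0]), t[1], t[0].index))
    return out


def _annotate_one_mplus(peak: Peak, run_id: str, ri: RIValue, mplus: float,
                        lib: ReferenceLibrary, config: AnnotationConfig) -> list[Annotation]:
    partial = classify_peak(peak, mplus, config)
    cands = match_library(ri, partial, lib, config.ri_tolerance)
    loose = _match_loose(ri, partial, lib, config.ri_tolerance)
    complete = [(e, d) for e, d in loose if _required_present(e, peak, config)]
    out = []

    def build(entry_d, is_complete):
        entry, _ = entry_d
        evidence = list(partial.fired)
        if is_complete:
            evidence += [f"required m/z {mz:g} present" for mz in entry.required_ions()]
        level = assign_level([entry_d], evidence_complete=is_complete)
        iso = isotope_interference_check(peak, entry.descriptor.carbon_number,
                                         entry.molecular_ion, config)
        return Annotation(peak=peak, run_id=run_id, mplus=mplus, ri=ri, inferred=partial,
                          entry=entry, candidates=tuple(loose), level=level,
                          evidence=tuple(evidence), isotope=iso)

    if complete:
        # compounds with disjoint diagnostic signatures on a shared molecular
        # ion (lupeol under cycloartenol) each get their own annotation
        emitted: list[tuple[LibraryEntry, float]] = []
        for e, d in complete:
            req = set(e.required_ions())
            if any(req & set(prev.required_ions()) for prev, _ in emitted):
                continue
            emitted.append((e, d))
        for ed in emitted:
            out.append(build(ed, True))
        return out

    if cands:
        out.append(build(cands[0], False))
        return out

    hit = I.mz_to_cn_db(mplus)
    iso = IsotopeCheck("inconclusive")
    if hit:
        iso = isotope_interference_check(peak, hit[0], mplus, config)
    out.append(Annotation(peak=peak, run_id=run_id, mplus=mplus, ri=ri, inferred=partial,
                          entry=None, candidates=(), level=4,
                          evidence=tuple(partial.fired), isotope=iso))
    return out


def annotate_run(chrom: Chromatogram, anchors: FAPAnchorSet, lib: ReferenceLibrary,
                 config: AnnotationConfig = AnnotationConfig()) -> list[Annotation]:
    """Annotate every non-FAP peak of a run: RI -> class -> candidates -> level.

    Co-eluting compounds are resolved per ion: several molecular ions in one
    chromatographic peak yield several annotations.  Relative retention times
    are filled in once the internal standard is located.
    """
    annotations: list[Annotation] = []
    istd = lib.internal_standard
    istd_rt = None
    for peak in chrom.peaks:
        if is_fap_peak(peak):
            continue
        try:
            ri = compute_ri_fap(peak.apex_rt, anchors)
        except Exception:
            continue  # outside the ladder: not indexable on this run
        # internal standard: matched by its own molecular ion, not the grid
        if istd is not None and peak.intensity_at(istd.molecular_ion, config.mz_tolerance) > 0 \
                and abs(float(ri) - istd.ri_fap) <= max(config.ri_tolerance, 5.0):
            istd_rt = peak.apex_rt
            annotations.append(Annotation(
                peak=peak, run_id=chrom.run_id, mplus=istd.molecular_ion, ri=ri,
                inferred=PartialClass(carbon_number=istd.descriptor.carbon_number,
                                      db_count=istd.descriptor.db_count),
                entry=istd, candidates=((istd, abs(float(ri) - istd.ri_fap)),),
                level=1, evidence=("internal_standard",)))
            continue
        mplus_ions, _checks = _mplus_candidates(peak, config)
        for mz in mplus_ions:
            annotations.extend(_annotate_one_mplus(peak, chrom.run_id, ri, mz, lib, config))
    if istd_rt is not None:
        for a in annotations:
            a.rrt = compute_rrt(a.peak.apex_rt, istd_rt)
    return annotations


def annotations_to_frame(annotations: list[Annotation]) -> pd.DataFrame:
    """Report mirroring the published table layout (one row per annotation)."""
    rows = []
    for a in annotations:
        d = a.entry.descriptor if a.entry else None
        rows.append({
            "run_id": a.run_id,
            "compound": a.name,
            "rrt": None if a.rrt is None else round(a.rrt, 2),
            "ri_fap": None if a.ri is None else a.ri.rounded,
            "cn_db": "" if d is None else f"{d.carbon_number}:{d.db_count}",
            "positions": "" if d is None or not d.positions_known else ";".join(d.db_positions),
            "class": "" if d is None else d.compound_class,
            "mplus": a.mplus,
            "level": a.level,
            "evidence": "; ".join(a.evidence),
            "interference": a.interference_flag,
            "apex_rt": a.peak.apex_rt,
            "area": a.peak.area,
        })
    return pd.DataFrame(rows)
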