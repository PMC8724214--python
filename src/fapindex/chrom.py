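"""Peak-table data model for GC/MS runs and FAP anchor extraction.

A run is represented at the peak level: each detected peak carries its apex
retention time, integrated area, height and the per-ion intensities at the
apex.  The on-disk format is a flat, diff-able TSV with one row per (peak,
ion):

    run_id  rt_min  mz  intensity  area  peak_id [asymmetry]

Rows sharing a ``peak_id`` form one peak.  Retention times are minutes,
abundances arbitrary units, m/z values carried at 1 decimal (unit-resolution
quadrupole, matched with +-0.3 u).

Fatty acid pyrrolidide (FAP) internal standards are recognised by their two
dominant fragment ions m/z 113 and 126, which are essentially absent from
silylated-sterol spectra; the ladder of their apex times defines the RI_FAP
scale (see :mod:`fapindex.ri`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import ions as I
from .errors import (AnchorConsistencyError, EmptyInputError, FormatError,
                     MissingAnchorError)
from .ri import LOCK_TARGET_MIN

#: RRT of each pyrrolidide anchor relative to 5a-cholestane, as calibrated on
#: the published 30 m 5%-phenyl column; with 24:0-P locked at 32.972 min this
#: fixes the reference anchor ladder in minutes.
ANCHOR_RRT = {18: 0.93, 19: 1.03, 20: 1.14, 21: 1.26, 22: 1.38,
              23: 1.47, 24: 1.57, 25: 1.70, 26: 1.85}

#: carbons included in the routine FAP internal-standard mix (26:0 is kept
#: out of the final mix; its RRT is retained above for late eluters)
DEFAULT_ANCHOR_CARBONS = tuple(range(18, 26))

#: FAP recognition: 113 must be the base ion and 113+126 carry this share
FAP_DOMINANCE = 0.80


def reference_anchor_times(carbons=DEFAULT_ANCHOR_CARBONS) -> dict[int, float]:
    """Reference anchor retention times (minutes) implied by the locked ladder."""
    t_ref = LOCK_TARGET_MIN / ANCHOR_RRT[24]
    return {c: ANCHOR_RRT[c] * t_ref for c in sorted(carbons)}


@dataclass(frozen=True)
class Peak:
    """One detected chromatographic peak."""

    apex_rt: float
    area: float
    height: float
    ion_intensities: dict[float, float]
    asymmetry: float | None = None

    def __post_init__(self):
        if self.apex_rt <= 0:
            raise ValueError(f"apex_rt must be positive, got {self.apex_rt}")
        if self.area < 0 or self.height < 0:
            raise ValueError("area and height must be non-negative")
        if not self.ion_intensities:
            raise ValueError("ion_intensities must be non-empty")
        if any(v < 0 for v in self.ion_intensities.values()):
            raise ValueError("ion intensities must be non-negative")

    def intensity_at(self, mz: float, tol: float = I.MZ_TOLERANCE) -> float:
        """Summed intensity of ions within ``tol`` of ``mz`` (0 when absent)."""
        return sum(v for k, v in self.ion_intensities.items() if abs(k - mz) <= tol)

    @property
    def base_ion(self) -> float:
        return max(self.ion_intensities, key=lambda k: (self.ion_intensities[k], -k))

    @property
    def total_intensity(self) -> float:
        return sum(self.ion_intensities.values())

    def sort_key(self):
        # deterministic total order: rt, then descending area, then lowest m/z
        return (self.apex_rt, -self.area, min(self.ion_intensities))


@dataclass
class Chromatogram:
    """An ordered collection of peaks from one GC/MS run."""

    run_id: str
    peaks: list[Peak] = field(default_factory=list)
    mode: str = "full_scan"
    monitored_ions: frozenset[float] = frozenset()

    def __post_init__(self):
        if self.mode not in ("full_scan", "sim"):
            raise ValueError(f"mode must be full_scan or sim, got {self.mode!r}")
        self.peaks = sorted(self.peaks, key=Peak.sort_key)
        if self.mode == "sim":
            for p in self.peaks:
                stray = [mz for mz in p.ion_intensities
                         if not any(abs(mz - m) <= I.MZ_TOLERANCE for m in self.monitored_ions)]
                if stray:
                    raise ValueError(f"sim-mode peak at {p.apex_rt} carries unmonitored ions {stray}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)


@dataclass(frozen=True)
class FAPAnchorSet:
    """Carbon-number -> retention-time ladder defining the RI_FAP scale."""

    anchors: dict[int, float]
    is_locked: bool = False

    def __post_init__(self):
        if len(self.anchors) < 2:
            raise ValueError("at least two anchors required")
        items = sorted(self.anchors.items())
        carbons = [c for c, _ in items]
        times = [t for _, t in items]
        if not all(b > a for a, b in zip(times, times[1:])):
            raise AnchorConsistencyError(
                f"anchor times must increase strictly with carbon number: {items}")
        if not any(b == a + 1 for a, b in zip(carbons, carbons[1:])):
            raise ValueError("at least two consecutive carbon numbers required")

    @property
    def carbons(self) -> tuple[int, ...]:
        return tuple(sorted(self.anchors))

    def __getitem__(self, carbon: int) -> float:
        return self.anchors[carbon]


# ---------------------------------------------------------------------------
# peak-table I/O

_REQUIRED_COLUMNS = ("run_id", "rt_min", "mz", "intensity", "area", "peak_id")


def read_peak_table(path, sep: str | None = None, rt_cluster_tol: float = 0.005) -> Chromatogram:
    """Read a peak-table TSV/CSV into a :class:`Chromatogram`.

    Separator is inferred from the file unless given.  Rows sharing a
    ``peak_id`` form one peak; when the column is missing, rows are clustered
    by apex time (gap > ``rt_cluster_tol`` minutes starts a new peak).
    Unparseable rows are collected and reported in a single warning-style
    error if *all* rows fail; otherwise they are skipped silently into the
    returned chromatogram's integrity report.
    """
    import csv as _csv
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"peak table {path} is empty") from None
    except _csv.Error:
        # separator sniffing fails on single-row/degenerate inputs
        if hasattr(path, "seek"):
            path.seek(0)
        try:
            df = pd.read_csv(path, sep="\t")
        except pd.errors.EmptyDataError:
            raise EmptyInputError(f"peak table {path} is empty") from None
    missing = set(_REQUIRED_COLUMNS[:-1]) - set(df.columns)
    missing.discard("run_id")
    if missing:
        raise FormatError(f"peak table missing mandatory columns: {sorted(missing)}")
    if df.empty:
        raise EmptyInputError(f"peak table {path} contains no rows")
    run_id = str(df["run_id"].iloc[0]) if "run_id" in df.columns else "run"
    for col in ("rt_min", "mz", "intensity", "area"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df[["rt_min", "mz", "intensity", "area"]].isna().any(axis=1)
    df = df[~bad]
    if df.empty:
        raise FormatError("no parseable rows in peak table")
    if "peak_id" not in df.columns:
        df = df.sort_values("rt_min", kind="stable").reset_index(drop=True)
        ids, current = [], 0
        last_rt = None
        for rt in df["rt_min"]:
            if last_rt is not None and rt - last_rt > rt_cluster_tol:
                current += 1
            ids.append(current)
            last_rt = rt
        df["peak_id"] = ids
    peaks = []
    for _, grp in df.groupby("peak_id", sort=False):
        ion = {}
        for _, r in grp.iterrows():
            mz = round(float(r["mz"]), 1)
            ion[mz] = ion.get(mz, 0.0) + float(r["intensity"])
        asym = float(grp["asymmetry"].iloc[0]) if "asymmetry" in grp.columns and \
            pd.notna(grp["asymmetry"].iloc[0]) else None
        height = float(grp["height"].iloc[0]) if "height" in grp.columns and \
            pd.notna(grp["height"].iloc[0]) else max(ion.values())
        peaks.append(Peak(apex_rt=float(grp["rt_min"].iloc[0]), area=float(grp["area"].iloc[0]),
                          height=height, ion_intensities=ion, asymmetry=asym))
    return Chromatogram(run_id=run_id, peaks=peaks)


def write_peak_table(chrom: Chromatogram, path) -> None:
    """Write the documented flat TSV peak table."""
    rows = []
    for pid, p in enumerate(chrom.peaks):
        for mz in sorted(p.ion_intensities):
            rows.append({"run_id": chrom.run_id, "rt_min": round(p.apex_rt, 6),
                         "mz": mz, "intensity": p.ion_intensities[mz],
                         "area": p.area, "peak_id": pid, "height": p.height,
                         "asymmetry": "" if p.asymmetry is None else p.asymmetry})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FAP anchor handling


def is_fap_peak(peak: Peak, dominance: float = FAP_DOMINANCE) -> bool:
    """A peak is FAP-flagged when m/z 113 is its base ion and 113+126 carry
    at least ``dominance`` of its summed intensity."""
    i113 = peak.intensity_at(I.FAP_BASE_ION)
    i126 = peak.intensity_at(I.FAP_SECONDARY_ION)
    if i113 <= 0:
        return False
    if abs(peak.base_ion - I.FAP_BASE_ION) > I.MZ_TOLERANCE:
        return False
    return (i113 + i126) >= dominance * peak.total_intensity


def extract_fap_anchors(chrom: Chromatogram, expected_carbons=DEFAULT_ANCHOR_CARBONS,
                        dominance: float = FAP_DOMINANCE) -> FAPAnchorSet:
    """Assign FAP-flagged peaks to anchor carbons by elution order.

    Raises :class:`~fapindex.errors.MissingAnchorError` naming the missing
    carbons when fewer FAP peaks are found than expected, and
    :class:`~fapindex.errors.AnchorConsistencyError` on a surplus (ambiguous
    assignment) or non-monotone ladder.
    """
    expected = sorted(expected_carbons)
    fap_peaks = [p for p in chrom.peaks if is_fap_peak(p, dominance)]
    if len(fap_peaks) < len(expected):
        missing = expected[len(fap_peaks):]
        raise MissingAnchorError(
            f"found {len(fap_peaks)} FAP peaks but expected {len(expected)} "
            f"(missing anchors for carbons {missing})", missing_carbons=missing)
    if len(fap_peaks) > len(expected):
        raise AnchorConsistencyError(
            f"found {len(fap_peaks)} FAP peaks for {len(expected)} expected carbons; "
            "assignment by elution order would be ambiguous")
    anchors = {c: p.apex_rt for c, p in zip(expected, fap_peaks)}
    return FAPAnchorSet(anchors=anchors)


@dataclass(frozen=True)
class AnchorQC:
    carbon: int
    apex_rt: float
    asymmetry: float | None
    height: float
    asymmetry_ok: bool
    height_ok: bool

    @property
    def passed(self) -> bool:
        return self.asymmetry_ok and self.height_ok


@dataclass(frozen=True)
class AnchorQualityReport:
    rows: tuple[AnchorQC, ...]

    @property
    def all_passed(self) -> bool:
        return all(r.passed for r in self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) | {"passed": r.passed} for r in self.rows])


def anchor_quality_report(chrom: Chromatogram, anchors: FAPAnchorSet,
                          tailing_limit: float = 1.5,
                          min_height: float = 0.0) -> AnchorQualityReport:
    """Peak-shape QC of the FAP internal standards (report-only).

    The asymmetry factor is the b/a ratio at 10 % peak height; anchors above
    ``tailing_limit`` or below ``min_height`` fail.  Routine inspection of the
    FAP peak shapes guards the quality of the locked RI scale.
    """
    mapping = anchors.anchors if hasattr(anchors, "anchors") else dict(anchors)
    by_rt = {p.apex_rt: p for p in chrom.peaks}
    rows = []
    for carbon, rt in sorted(mapping.items()):
        peak = by_rt.get(rt)
        if peak is None:  # nearest peak within matching tolerance
            candidates = [p for p in chrom.peaks if abs(p.apex_rt - rt) < 1e-6]
            if not candidates:
                continue
            peak = candidates[0]
        asym = peak.asymmetry
        rows.append(AnchorQC(
            carbon=carbon, apex_rt=rt, asymmetry=asym, height=peak.height,
            asymmetry_ok=(asym is None or asym <= tailing_limit),
            height_ok=peak.height >= min_height))
    return AnchorQualityReport(rows=tuple(rows))
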