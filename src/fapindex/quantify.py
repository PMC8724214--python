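"""Semi-quantitative composition from SIM total-ion-current shares.

Each annotated compound's percentage is its share of the summed sterol /
triterpenol peak area (internal standard and FAP ladder excluded).  Equal
response factors are assumed — the numbers describe the relevance of each
compound in the chromatogram, not a calibrated concentration.

When several compounds share one chromatographic peak, the shared area is
apportioned from the intensities of each compound's *specific* monitored
ions (ions not expected for any co-annotated compound), de-scaled by the
reference-spectrum weight of those ions.  The apportionment conserves the
peak area exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import ions as I
from .annotate import Annotation
from .errors import UndefinedCompositionError
from .library import TRACE_FLOOR_PERCENT, reference_spectrum


@dataclass
class CompositionTable:
    """Per-run TIC percentages, full precision, wide compound x run layout."""

    values: pd.DataFrame  # index: compound, columns: run_id, NaN = absent
    areas: pd.DataFrame

    def percent(self, compound: str, run_id: str) -> float:
        return float(self.values.at[compound, run_id])

    @property
    def totals(self) -> pd.Series:
        return self.values.sum(axis=0, skipna=True)

    def to_display(self, trace_floor: float = TRACE_FLOOR_PERCENT) -> pd.DataFrame:
        """Rounded table with sub-floor entries shown as ``tr`` (trace)."""
        def fmt(v):
            if pd.isna(v):
                return ""
            if v < trace_floor:
                return "tr"
            return f"{v:.1f}" if v >= 1.0 else f"{v:.2g}"
        return self.values.map(fmt)


def _apportion_peak(group: list[Annotation]) -> dict[int, float]:
    """Split one peak's area between its co-annotated compounds.

    Returns {position in group: area}.  Uses each compound's specific ions
    (absent from every co-annotation's reference spectrum); compounds without
    specific ions fall back to an even split of the then-remaining share.
    """
    peak = group[0].peak
    if len(group) == 1:
        return {0: peak.area}
    specs = []
    for a in group:
        specs.append(reference_spectrum(a.entry) if a.entry is not None
                     else {a.mplus or peak.base_ion: 0.45})
    estimates = []
    for i, a in enumerate(group):
        others = set()
        for j, s in enumerate(specs):
            if j != i:
                others.update(s.keys())
        specific = [mz for mz in specs[i]
                    if not any(abs(mz - o) <= I.MZ_TOLERANCE for o in others)]
        wsum = sum(specs[i][mz] for mz in specific)
        if wsum > 0:
            est = sum(peak.intensity_at(mz, I.MZ_TOLERANCE) for mz in specific) / wsum
        else:
            est = None
        estimates.append(est)
    known = [e for e in estimates if e is not None]
    fallback = (sum(known) / len(known)) if known else 1.0
    estimates = [fallback if e is None else e for e in estimates]
    total = sum(estimates)
    if total <= 0:
        estimates = [1.0] * len(group)
        total = float(len(group))
    return {i: peak.area * est / total for i, est in enumerate(estimates)}


def compound_areas(annotations: list[Annotation]) -> pd.DataFrame:
    """Apportioned area per (compound, run), internal standard excluded."""
    by_peak: dict[tuple[str, float], list[Annotation]] = {}
    for a in annotations:
        if a.entry is not None and a.entry.is_internal_standard:
            continue
        by_peak.setdefault((a.run_id, a.peak.apex_rt), []).append(a)
    rows = []
    for (run_id, _rt), group in by_peak.items():
        shares = _apportion_peak(group)
        for i, a in enumerate(group):
            rows.append({"run_id": run_id, "compound": a.name, "area": shares[i],
                         "level": a.level})
    if not rows:
        return pd.DataFrame(columns=["run_id", "compound", "area", "level"])
    return pd.DataFrame(rows)


def tic_percentages(annotations: list[Annotation]) -> CompositionTable:
    """Percentage contribution of each annotated compound per run.

    Raises :class:`~fapindex.errors.UndefinedCompositionError` when a run has
    zero total annotated area.
    """
    df = compound_areas(annotations)
    if df.empty:
        raise UndefinedCompositionError("no annotated compounds with area")
    areas = df.pivot_table(index="compound", columns="run_id", values="area",
                           aggfunc="sum")
    totals = areas.sum(axis=0, skipna=True)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise UndefinedCompositionError(f"zero total annotated area in runs {bad}")
    values = 100.0 * areas / totals
    return CompositionTable(values=values, areas=areas)


def trace_flagging(table: CompositionTable,
                   floor: float = TRACE_FLOOR_PERCENT) -> pd.DataFrame:
    """Display table with values below ``floor`` percent marked ``tr``."""
    return table.to_display(trace_floor=floor)
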