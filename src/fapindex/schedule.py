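"""SIM acquisition schedules under an ion-budget constraint.

A single-quadrupole SIM method can cycle over roughly 15-18 m/z values
before the per-ion dwell time (and hence the >2 cycles/s sampling of a
capillary peak) suffers.  The sterol vocabulary needs 20 molecular ions,
9-11 fragment ions and 2 FAP ions, so acquisition is split:

* two *initial* methods that tile the molecular-ion grid by carbon number
  (C28/C29 in method 1; C27/C30/C31 in method 2, time-split because C27 and
  C31 sterols cannot overlap), and
* the *merged* four-window method: RI-bounded windows snapped to whole
  hundreds, each holding the retention-independent fragment ions plus the
  molecular ions needed by the compounds eluting there, padded with adjacent
  grid ions up to the budget (the FAP confirmation ion 126.0 is the first to
  yield; 113.0 is never dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import ions as I
from .errors import SchedulingError
from .library import LibraryEntry, ReferenceLibrary
from .ri import invert_ri_fap

#: fragment ions monitored throughout (FAP pair + ring diagnostics + m/z 296)
CORE_FRAGMENT_IONS = (113.0, 126.0, 129.1, 211.2, 213.2, 215.2, 253.2, 255.2, 296.2)
#: the retro-Diels-Alder pair added where pentacyclic triterpenols elute
AMYRIN_IONS = (I.ION_RDA_189, I.ION_RDA_218)
#: full retention-independent vocabulary
RETENTION_INDEPENDENT_IONS = tuple(sorted(set(CORE_FRAGMENT_IONS) | set(AMYRIN_IONS)))

_CORE_WITHOUT_126 = tuple(mz for mz in CORE_FRAGMENT_IONS if mz != I.FAP_SECONDARY_ION)

DEFAULT_BUDGET = 17


@dataclass(frozen=True)
class TimeWindow:
    start: float
    end: float
    unit: str  # "ri" | "min"
    retention_independent_ions: frozenset[float]
    retention_dependent_ions: dict[str, frozenset[float]]
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"window start {self.start} must precede end {self.end}")

    @property
    def all_ions(self) -> frozenset[float]:
        out = set(self.retention_independent_ions)
        for ions in self.retention_dependent_ions.values():
            out.update(ions)
        return frozenset(out)

    @property
    def ion_count(self) -> int:
        return len(self.all_ions)

    def contains(self, x: float) -> bool:
        return self.start <= x < self.end

    def monitors(self, mz: float, tol: float = I.MZ_TOLERANCE) -> bool:
        return any(abs(mz - m) <= tol for m in self.all_ions)


@dataclass
class SIMMethod:
    name: str
    windows: list[TimeWindow]
    budget: int = DEFAULT_BUDGET

    def __post_init__(self):
        for a, b in zip(self.windows, self.windows[1:]):
            if a.unit == b.unit and b.start < a.end:
                raise ValueError("windows must be ordered and non-overlapping")

    def window_for(self, x: float) -> TimeWindow | None:
        for w in self.windows:
            if w.contains(x):
                return w
        if self.windows and x == self.windows[-1].end:
            return self.windows[-1]
        return None


def _grid_row(cn: int, dbs=range(0, 4)) -> frozenset[float]:
    return frozenset(I.tms_molecular_mz(cn, db) for db in dbs)


def build_initial_methods(library: ReferenceLibrary) -> tuple[SIMMethod, SIMMethod]:
    """The two development-phase methods tiling the 20-ion molecular grid.

    Method 1 (one window, 20-41.8 min): the C28 and C29 molecular ions plus
    the nine core fragment ions — 17 SIM values.  Method 2 splits the run at
    29.6 and 32.5 min so that C27 ions are only monitored early and C31 ions
    late; the amyrin pair replaces 126.0 (and the absent C31:3 ion) in the
    middle window where the pentacyclic triterpenols elute.
    """
    if not len(library):
        raise ValueError("library must be non-empty")
    m1 = SIMMethod("initial SIM 1", [TimeWindow(
        20.0, 41.8, "min", frozenset(CORE_FRAGMENT_IONS),
        {"C28": _grid_row(28), "C29": _grid_row(29)})])
    w1 = TimeWindow(20.0, 29.6, "min", frozenset(CORE_FRAGMENT_IONS),
                    {"C27": _grid_row(27), "C30": _grid_row(30)},
                    notes=("fragment-ion list inherited from the printed late window",))
    w2 = TimeWindow(29.6, 32.5, "min",
                    frozenset(_CORE_WITHOUT_126) | frozenset(AMYRIN_IONS),
                    {"C30": _grid_row(30), "C31": _grid_row(31, range(0, 3))})
    w3 = TimeWindow(32.5, 41.8, "min", frozenset(CORE_FRAGMENT_IONS),
                    {"C30": _grid_row(30), "C31": _grid_row(31)})
    m2 = SIMMethod("initial SIM 2", [w1, w2, w3])
    return m1, m2


def _carbon_groups(library: ReferenceLibrary):
    """Compound lists and RI spans per carbon number, plus the amyrin RIs."""
    groups: dict[int, list[LibraryEntry]] = {}
    amyrin_ris: list[float] = []
    for e in library.compounds:
        groups.setdefault(e.descriptor.carbon_number, []).append(e)
        if e.descriptor.compound_class == I.PENTACYCLIC:
            amyrin_ris.append(e.ri_fap)
    return groups, amyrin_ris


def build_time_windows(library: ReferenceLibrary, budget: int = DEFAULT_BUDGET,
                       snap: int = 100, boundary_margin: float = 2.0) -> SIMMethod:
    """Merge the initial methods into RI-bounded time windows.

    Windows partition the library's elution range at multiples of ``snap`` RI
    units.  Each window carries the eight always-on fragment ions, the amyrin
    pair where pentacyclic compounds elute, and the molecular ions of every
    compound eluting in the window (compounds within ``boundary_margin`` RI
    units past the end are also covered as a boundary safety).  Leftover
    budget is filled with adjacent grid ions (by DB distance from the needed
    set, lower DB first) and finally with the FAP confirmation ion 126.0.
    """
    if not library.compounds:
        raise ValueError("library must contain at least one compound")
    groups, amyrin_ris = _carbon_groups(library)
    ri_lo, ri_hi = library.ri_range()
    start = int(ri_lo // snap) * snap
    stop = (int(ri_hi // snap) + 1) * snap  # half-open windows: top boundary inside
    windows = []
    for w_start in range(start, stop, snap):
        w_end = w_start + snap
        def in_window(ri):
            return w_start <= ri < w_end + boundary_margin
        needed: dict[str, set[float]] = {}
        needed_dbs: dict[int, set[int]] = {}
        for cn, members in sorted(groups.items()):
            dbs = {e.descriptor.db_count for e in members if in_window(e.ri_fap)}
            if dbs:
                needed_dbs[cn] = dbs
                needed[f"C{cn}"] = {I.tms_molecular_mz(cn, db) for db in sorted(dbs)}
        dependent = {g: set(v) for g, v in needed.items()}
        notes = []
        amyrins_here = any(in_window(ri) for ri in amyrin_ris)
        if amyrins_here:
            dependent["Amyrins"] = set(AMYRIN_IONS)
        independent = set(_CORE_WITHOUT_126)
        count = len(independent) + sum(len(v) for v in dependent.values())
        if count > budget:
            raise SchedulingError(
                f"window {w_start}-{w_end}: {count} required ions exceed the "
                f"budget of {budget} even without padding")
        # pad with adjacent grid ions, then 126.0 if room remains
        pad_candidates = []
        for cn in sorted(needed_dbs):
            present = needed_dbs[cn]
            missing = [db for db in I.DB_RANGE if db not in present]
            missing.sort(key=lambda db: (min(abs(db - p) for p in present), db))
            for db in missing:
                pad_candidates.append((f"C{cn}", I.tms_molecular_mz(cn, db)))
        all_ions = independent | {mz for v in dependent.values() for mz in v}
        for grp, mz in pad_candidates:
            if count >= budget:
                break
            if mz in all_ions:
                continue
            dependent.setdefault(grp, set()).add(mz)
            all_ions.add(mz)
            count += 1
        if count < budget:
            independent.add(I.FAP_SECONDARY_ION)
            count += 1
        else:
            notes.append("126.0 dropped to stay within the ion budget")
        windows.append(TimeWindow(
            float(w_start), float(w_end), "ri", frozenset(independent),
            {g: frozenset(v) for g, v in sorted(dependent.items())}, tuple(notes)))
    return SIMMethod("merged time-window method", windows, budget)


@dataclass
class ScheduleReport:
    compound_rows: pd.DataFrame
    window_rows: pd.DataFrame

    @property
    def all_covered(self) -> bool:
        return bool(self.compound_rows["mplus_covered"].all())

    @property
    def within_budget(self) -> bool:
        return bool(self.window_rows["within_budget"].all())


def validate_schedule(method: SIMMethod, library: ReferenceLibrary,
                      anchors=None) -> ScheduleReport:
    """Check molecular-ion coverage, isotope-check observability and budget.

    For minute-based methods an anchor set is used to project each compound's
    RI onto the time axis.  Report-only: nothing raises.
    """
    comp_rows = []
    for e in library.compounds:
        x = e.ri_fap
        if method.windows and method.windows[0].unit == "min":
            if anchors is None:
                raise ValueError("minute-based schedules need an anchor set for validation")
            x = invert_ri_fap(e.ri_fap, anchors)
        w = method.window_for(x)
        covered = w is not None and w.monitors(e.molecular_ion)
        m15_obs = w is not None and w.monitors(e.molecular_ion - 15.0, 0.25)
        m14_obs = w is not None and w.monitors(e.molecular_ion - 14.0, 0.25)
        comp_rows.append({
            "compound": e.name, "ri_fap": e.ri_fap, "mplus": e.molecular_ion,
            "window": None if w is None else f"{w.start:g}-{w.end:g}",
            "mplus_covered": covered,
            "isotope_check_observable": m15_obs and m14_obs,
        })
    win_rows = []
    for w in method.windows:
        win_rows.append({
            "window": f"{w.start:g}-{w.end:g} {w.unit}", "ions": w.ion_count,
            "budget": method.budget, "within_budget": w.ion_count <= method.budget,
            "notes": "; ".join(w.notes),
        })
    return ScheduleReport(pd.DataFrame(comp_rows), pd.DataFrame(win_rows))


def schedule_to_frame(method: SIMMethod) -> pd.DataFrame:
    """Flat export (window, start, end, ion, group) mirroring the published layout."""
    rows = []
    for i, w in enumerate(method.windows, start=1):
        for mz in sorted(w.retention_independent_ions):
            rows.append({"window": i, "start": w.start, "end": w.end, "unit": w.unit,
                         "ion": mz, "group": "retention_independent"})
        for grp in sorted(w.retention_dependent_ions):
            for mz in sorted(w.retention_dependent_ions[grp]):
                rows.append({"window": i, "start": w.start, "end": w.end, "unit": w.unit,
                             "ion": mz, "group": grp})
    return pd.DataFrame(rows)


def schedule_in_minutes(method: SIMMethod, anchors) -> SIMMethod:
    """Project an RI-bounded schedule onto the time axis of a locked run."""
    windows = []
    for w in method.windows:
        if w.unit == "min":
            windows.append(w)
            continue
        windows.append(TimeWindow(
            invert_ri_fap(w.start, anchors), invert_ri_fap(w.end, anchors), "min",
            w.retention_independent_ions, dict(w.retention_dependent_ions), w.notes))
    return SIMMethod(method.name + " (minutes)", windows, method.budget)
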