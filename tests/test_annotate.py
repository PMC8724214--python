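"""Rule engine: classification, library matching, levels, co-elution, isotopes."""

import pytest

import fapindex as fx
from fapindex.annotate import (RING_D5, RING_D7, RING_PENTA_D12, RING_STANOL,
                               assign_level, classify_peak,
                               isotope_interference_check, match_library)
from fapindex.chrom import Peak
from fapindex.library import reference_spectrum
from fapindex.synth import DriftModel


def _peak(rt, ions, area=100.0):
    return Peak(apex_rt=rt, area=area, height=10.0, ion_intensities=dict(ions))


class TestClassifyPeak:
    def test_delta5_sitosterol_pattern(self):
        p = _peak(31.0, {129.1: 100.0, 213.2: 30.0, 255.2: 35.0, 486.4: 60.0})
        c = classify_peak(p)
        assert (c.carbon_number, c.db_count) == (29, 1)
        assert c.ring_class == RING_D5

    def test_stanol_pattern(self):
        p = _peak(31.0, {215.2: 100.0, 488.4: 60.0})
        c = classify_peak(p)
        assert (c.carbon_number, c.db_count) == (29, 0)
        assert c.ring_class == RING_STANOL

    def test_delta7_needs_213_255_without_129_base(self):
        p = _peak(31.0, {255.2: 100.0, 213.2: 40.0, 486.4: 70.0})
        assert classify_peak(p).ring_class == RING_D7

    def test_pentacyclic_weak_mplus_218_over_189(self):
        p = _peak(31.0, {218.3: 100.0, 189.2: 60.0, 498.4: 12.0})
        c = classify_peak(p)
        assert c.ring_class == RING_PENTA_D12
        assert (c.carbon_number, c.db_count) == (30, 2)

    def test_side_chain_db_via_m84_fragment(self):
        p = _peak(31.0, {129.1: 100.0, 213.2: 30.0, 255.2: 30.0,
                         470.4: 50.0, 296.2: 20.0})
        c = classify_peak(p)
        assert c.side_chain_db
        assert (c.carbon_number, c.db_count) == (28, 2)

    def test_no_grid_match_yields_unassignable(self):
        p = _peak(31.0, {129.1: 100.0})
        c = classify_peak(p)
        assert c.carbon_number is None

    def test_conflicting_rules_recorded_not_raised(self):
        # stanol base AND the 211/253 pair both fire; precedence picks stanol
        p = _peak(31.0, {215.2: 100.0, 211.2: 40.0, 253.2: 40.0, 488.4: 50.0})
        c = classify_peak(p)
        assert c.ring_class == RING_STANOL
        assert len(c.ambiguities) >= 1


class TestMatchLibrary:
    def test_sitosterol_beats_coeluting_lanosterol_by_class(self, lib):
        p = _peak(31.0, {129.1: 100.0, 213.2: 30.0, 255.2: 30.0, 486.4: 60.0})
        partial = classify_peak(p)
        ranked = match_library(2306.0, partial, lib)
        assert ranked[0][0].name == "beta-Sitosterol"
        assert all(e.name != "Lanosterol" for e, _ in ranked)  # wrong cn:db

    def test_empty_outside_library_range(self, lib):
        ranked = match_library(1500.0, classify_peak(_peak(20.0, {486.4: 10.0})), lib)
        assert ranked == []

    def test_ri_tolerance_bounds_candidates(self, lib):
        partial = classify_peak(_peak(31.0, {129.1: 50.0, 213.2: 20.0, 255.2: 20.0,
                                             484.4: 30.0}))
        names = [e.name for e, _ in match_library(2247.0, partial, lib, tol_ri=2.5)]
        assert names == ["Stigmasterol"]


class TestAssignLevel:
    def test_standard_with_complete_diagnostics_is_level1(self, lib):
        assert assign_level([(lib["Campesterol"], 0.0)], evidence_complete=True) == 1

    def test_complete_without_standard_is_level2(self, lib):
        assert assign_level([(lib["Campestanol"], 0.0)], evidence_complete=True) == 2

    def test_proposed_structure_incomplete_is_level3(self, lib):
        assert assign_level([(lib["Delta8-Campesterol"], 0.0)], evidence_complete=False) == 3

    def test_unknown_entry_is_level4(self, lib):
        assert assign_level([(lib["Unknown 7"], 0.0)], evidence_complete=False) == 4

    def test_no_candidates_is_level4(self):
        assert assign_level([], evidence_complete=False) == 4

    def test_contradicted_evidence_never_level_le2(self, lib):
        level = assign_level([(lib["Campesterol"], 0.0)], evidence_complete=True,
                             contradicted=True)
        assert level >= 3


class TestIsotopeCheck:
    def test_clean_binomial_satellite_passes(self, lib):
        entry = lib["24-Methylenecycloartanol"]
        spec = reference_spectrum(entry)
        p = _peak(33.6, {mz: w * 100 for mz, w in spec.items()})
        res = isotope_interference_check(p, 31, 512.5)
        assert res.status == "pass"
        assert res.observed == pytest.approx(res.expected, rel=1e-6)

    def test_spiked_interferent_fails(self, lib):
        spec = reference_spectrum(lib["24-Methylenecycloartanol"])
        ions = {mz: w * 100 for mz, w in spec.items()}
        ions[498.5] = ions.get(498.5, 0.0) + 10.0  # a true M+ 498 co-eluter
        res = isotope_interference_check(_peak(33.6, ions), 31, 512.5)
        assert res.status == "fail"

    def test_absent_fragment_is_inconclusive(self):
        res = isotope_interference_check(_peak(33.6, {512.5: 50.0}), 31, 512.5)
        assert res.status == "inconclusive"


class TestAnnotateRun:
    def test_noise_free_round_trip_recovers_true_identities(self, four_oils):
        """Every annotation names a compound truly present in its peak, |dRI| = 0."""
        for oil, data in four_oils.items():
            truth = data["truth"]
            rt_to_names = truth.groupby("true_rt")["compound"].apply(set)
            for a in data["annotations"]:
                assert a.entry is not None, f"{oil}: unidentified peak at {a.peak.apex_rt}"
                true_here = set()
                for rt, names in rt_to_names.items():
                    if abs(rt - a.peak.apex_rt) <= 0.006:
                        true_here |= names
                assert a.name in true_here
                if not a.entry.is_internal_standard:
                    assert float(a.ri) == pytest.approx(a.entry.ri_fap, abs=1e-6)

    def test_all_detectable_compounds_found_per_run(self, four_oils):
        # sub-floor exceptions: a 0.01% unknown under a peer and the trace
        # lanosterol fully inside the dominant sitosterol peak
        allowed_missing = {"rapeseed": {"Unknown 4"}, "hemp": {"Lanosterol"},
                           "corn": set(), "sunflower": set()}
        for oil, data in four_oils.items():
            named = {a.name for a in data["annotations"]
                     if a.entry and not a.entry.is_internal_standard}
            missing = set(data["profile"].composition) - named
            assert missing <= allowed_missing[oil], f"{oil}: {missing}"

    def test_assigned_levels_reproduce_library_levels(self, four_oils, lib):
        for oil, data in four_oils.items():
            for a in data["annotations"]:
                if a.entry and not a.entry.is_internal_standard:
                    assert a.level == lib[a.name].level, a.name

    def test_shared_molecular_ion_coelution_resolved(self, four_oils):
        """Lupeol is annotated under cycloartenol from its 189/218 signature."""
        names = {a.name for a in four_oils["sunflower"]["annotations"]}
        assert {"Cycloartenol", "Lupeol"} <= names
        peak_rts = {a.peak.apex_rt for a in four_oils["sunflower"]["annotations"]
                    if a.name in ("Cycloartenol", "Lupeol")}
        assert len(peak_rts) == 1  # both live on one chromatographic peak

    def test_distinct_molecular_ions_on_one_peak(self, four_oils):
        """Gramisterol and the co-eluting C31 unknown are separated by M+."""
        anns = [a for a in four_oils["sunflower"]["annotations"]
                if a.name in ("Gramisterol", "Unknown 7")]
        assert {a.name for a in anns} == {"Gramisterol", "Unknown 7"}
        assert len({a.peak.apex_rt for a in anns}) == 1
        assert {a.mplus for a in anns} == {484.4, 512.5}

    def test_recovery_survives_small_drift(self, profiles, lib):
        """Identity recovery is complete under sub-unit RI drift plus noise."""
        chrom, truth = fx.generate_run(profiles["sunflower"], seed=5, noise=0.02,
                                       drift=DriftModel("column_trim", 0.2))
        anchors = fx.extract_fap_anchors(chrom)
        anns = fx.annotate_run(chrom, anchors, lib)
        named = {a.name for a in anns if a.entry and not a.entry.is_internal_standard}
        assert set(profiles["sunflower"].composition) <= named

    def test_rrt_filled_from_internal_standard(self, four_oils):
        anns = four_oils["rapeseed"]["annotations"]
        istd = next(a for a in anns if a.entry and a.entry.is_internal_standard)
        assert istd.level == 1
        sito = next(a for a in anns if a.name == "beta-Sitosterol")
        assert sito.rrt == pytest.approx(sito.peak.apex_rt / istd.peak.apex_rt)
        assert 1.4 < sito.rrt < 1.6

    def test_empty_chromatogram_yields_no_annotations(self, ref_anchors, lib):
        chrom = fx.Chromatogram("empty", [])
        assert fx.annotate_run(chrom, ref_anchors, lib) == []

    def test_contradicting_evidence_is_not_identified(self, ref_anchors, lib):
        # stanol signature on sitosterol's M+/RI: no level <= 2 assignment
        p = _peak(fx.invert_ri_fap(2306.0, ref_anchors),
                  {215.2: 100.0, 486.4: 40.0})
        chrom = fx.Chromatogram("odd", [p])
        anns = fx.annotate_run(chrom, ref_anchors, lib)
        assert all(a.level >= 3 for a in anns)

    def test_annotation_report_frame(self, four_oils):
        frame = fx.annotations_to_frame(four_oils["corn"]["annotations"])
        assert {"compound", "ri_fap", "rrt", "level", "mplus"} <= set(frame.columns)
        row = frame[frame["compound"] == "Campesterol"].iloc[0]
        assert row["ri_fap"] == 2225
        assert row["level"] == 1
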