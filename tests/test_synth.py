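"""Synthetic-chromatogram generator: profiles, determinism, drift physics."""

import io

import numpy as np
import pytest

import fapindex as fx
from fapindex.errors import GenerationError
from fapindex.library import ReferenceLibrary
from fapindex.synth import (DriftModel, OilProfile, VirtualInstrument,
                            simulate_drift_series)


class TestProfiles:
    def test_four_oils_with_printed_landmarks(self, profiles):
        assert set(profiles) == {"rapeseed", "hemp", "corn", "sunflower"}
        assert profiles["rapeseed"].composition["Brassicasterol"] == 5.5
        assert profiles["rapeseed"].composition["beta-Sitosterol"] == 57.0
        assert profiles["hemp"].composition["beta-Sitosterol"] == 74.2
        assert profiles["corn"].composition["Campesterol"] == 13.3
        assert profiles["sunflower"].composition["Delta7-Sitosterol"] == 16.3

    def test_columns_sum_to_100(self, profiles):
        for prof in profiles.values():
            assert sum(prof.composition.values()) == pytest.approx(100.0, abs=1e-9)

    def test_profiles_jointly_cover_all_30_compounds(self, profiles, lib):
        union = set()
        for prof in profiles.values():
            union |= set(prof.composition)
        assert union == {e.name for e in lib.compounds}

    def test_invalid_profiles_rejected(self):
        with pytest.raises(ValueError):
            OilProfile("bad", {"a": -1.0})
        with pytest.raises(ValueError):
            OilProfile("bad", {"a": 60.0, "b": 50.0})


class TestGenerateRun:
    def test_fixed_seed_reproduces_byte_identical_table(self, profiles):
        tables = []
        for _ in range(2):
            chrom, _ = fx.generate_run(profiles["hemp"], noise=0.05, seed=42)
            buf = io.StringIO()
            fx.write_peak_table(chrom, buf)
            tables.append(buf.getvalue())
        assert tables[0] == tables[1]

    def test_different_seed_changes_noise(self, profiles):
        a, _ = fx.generate_run(profiles["hemp"], noise=0.05, seed=1)
        b, _ = fx.generate_run(profiles["hemp"], noise=0.05, seed=2)
        assert any(pa.area != pb.area for pa, pb in zip(a.peaks, b.peaks))

    def test_sidecar_is_sufficient_ground_truth(self, four_oils):
        for data in four_oils.values():
            truth = data["truth"]
            assert {"compound", "true_ri", "true_rt", "true_area", "true_class"} <= \
                set(truth.columns)
            faps = truth[truth["true_class"] == "fap_anchor"]
            assert len(faps) == 8  # 18:0-P .. 25:0-P

    def test_uniform_multiplicative_drift_leaves_ri_invariant(self, profiles, lib):
        chrom, truth = fx.generate_run(profiles["corn"], noise=0.0, seed=9,
                                       drift=DriftModel("uniform_multiplicative", 0.01))
        anchors = fx.extract_fap_anchors(chrom)
        sterols = truth[~truth["true_class"].isin(["fap_anchor"])]
        for _, row in sterols.iterrows():
            ri = fx.compute_ri_fap(row["true_rt"], anchors)
            assert float(ri) == pytest.approx(row["true_ri"], abs=1e-9)

    def test_compound_outside_ladder_raises(self, lib):
        import dataclasses
        beyond = dataclasses.replace(lib["Citrostadienol"], ri_fap=2620.0)
        small = ReferenceLibrary([beyond])
        with pytest.raises(GenerationError):
            fx.generate_run(OilProfile("x", {"Citrostadienol": 100.0}),
                            library=small, noise=0.0)

    def test_locked_run_restores_lock_target_under_trim(self, profiles):
        chrom, truth = fx.generate_run(profiles["rapeseed"], noise=0.0, seed=1,
                                       drift=DriftModel("column_trim", 1.0), locked=True)
        anchors = fx.extract_fap_anchors(chrom)
        assert anchors[24] == pytest.approx(32.972, abs=0.005)

    def test_spectra_follow_reference_templates(self, four_oils, lib):
        from fapindex.library import reference_spectrum
        truth = four_oils["corn"]["truth"]
        chrom = four_oils["corn"]["chrom"]
        row = truth[truth["compound"] == "Campesterol"].iloc[0]
        peak = next(p for p in chrom.peaks if abs(p.apex_rt - row["true_rt"]) < 1e-9)
        spec = reference_spectrum(lib["Campesterol"])
        for mz, w in spec.items():
            assert peak.intensity_at(mz, 0.05) == pytest.approx(w * row["true_area"])


class TestSimProjection:
    def test_sim_run_keeps_only_window_ions(self, four_oils, lib):
        data = four_oils["sunflower"]
        method = fx.build_time_windows(lib, budget=17)
        sim = fx.to_sim(data["chrom"], method, data["anchors"])
        assert sim.mode == "sim"
        for p in sim.peaks:
            for mz in p.ion_intensities:
                assert any(abs(mz - m) <= 0.3 for m in sim.monitored_ions)


class TestDriftStudy:
    def test_no_drift_means_no_shift(self):
        res = simulate_drift_series(n_runs=4, drift=DriftModel("none", 0.0), seed=0)
        assert np.abs(res.series["ri_unlocked"] - res.series["true_ri"]).max() < 1e-9
        # the locked arm may only carry the ageing-jitter residual
        assert np.abs(res.series["ri_locked"] - res.series["true_ri"]).max() < 0.05

    def test_seeded_stats_reproducible(self):
        a = simulate_drift_series(n_runs=10, seed=3)
        b = simulate_drift_series(n_runs=10, seed=3)
        assert a.stats.equals(b.stats)

    def test_trim_shifts_have_realistic_magnitude(self):
        res = simulate_drift_series(n_runs=25, drift=DriftModel("column_trim", 1.5), seed=7)
        worst = np.abs(res.series["ri_unlocked"] - res.series["true_ri"]).max()
        assert 1.0 < worst < 6.0  # a 1.5 m cut visibly moves the index scale

    def test_locking_tightens_dispersion_for_at_least_90pct(self):
        res = simulate_drift_series(n_runs=25, drift=DriftModel("column_trim", 1.5), seed=7)
        assert res.fraction_improved >= 0.90

    def test_n_runs_validation(self):
        with pytest.raises(ValueError):
            simulate_drift_series(n_runs=1)


class TestVirtualInstrument:
    def test_reference_conditions_reproduce_ladder(self, ref_anchors):
        inst = VirtualInstrument()
        for c, rt in ref_anchors.anchors.items():
            assert inst.elution_time(float(c)) == pytest.approx(rt, abs=1e-12)

    def test_elution_monotone_under_trim_and_lock(self):
        inst = VirtualInstrument()
        q = inst.relock(1.5)
        xs = np.linspace(18.0, 25.0, 300)
        for qq in (1.0, q):
            ts = [inst.elution_time(x, qq, 1.5) for x in xs]
            assert np.all(np.diff(ts) > 0)
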