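"""Merging, alignment, thresholds and MasterScan persistence."""

import dataclasses

import numpy as np
import pytest

from lipidquery.masterscan import (
    MasterScanSettings,
    ResolutionModel,
    align_across_samples,
    apply_thresholds,
    build_masterscan,
    load_masterscan,
    merge_scans,
    save_masterscan,
    tolerance_at,
)
from lipidquery.spectra_io import Peak, Scan

from conftest import make_cluster


def scan(peaks, sample="S1", level=1, polarity=-1, **kw):
    return Scan(
        sample_id=sample,
        ms_level=level,
        polarity=polarity,
        peaks=[Peak(m, i) for m, i in peaks],
        **kw,
    )


class TestToleranceAt:
    def test_reference_value(self):
        # resolution 7500 FWHM at m/z 750 -> 0.1 Th window
        assert tolerance_at(ResolutionModel(7500.0), 750.0) == pytest.approx(0.1)

    def test_nonpositive_resolution_guard(self):
        model = ResolutionModel(r0=7500.0, slope=-5.0, m_ref=0.0)
        with pytest.raises(ValueError):
            tolerance_at(model, 2000.0)

    def test_doubling_resolution_halves_window(self):
        assert tolerance_at(ResolutionModel(15000.0), 750.0) == pytest.approx(
            tolerance_at(ResolutionModel(7500.0), 750.0) / 2
        )


class TestMergeScans:
    def test_within_and_cross_scan_grouping(self):
        # two scans, each two peaks within the 0.05 Th window:
        # weighted mean over all four raw peaks, intensity = per-scan sum
        # averaged over the scans in which the group appears
        model = ResolutionModel(r0=2000.0, m_ref=100.0)  # 0.05 Th at m/z 100
        scans = [
            scan([(100.000, 2.0), (100.010, 6.0)]),
            scan([(100.000, 2.0), (100.010, 6.0)]),
        ]
        rep = merge_scans(scans, model)
        assert len(rep.peaks) == 1
        assert rep.peaks[0].mz == pytest.approx(100.0075, abs=1e-9)
        assert rep.peaks[0].intensity == pytest.approx(8.0)

    def test_single_scan_identity(self):
        model = ResolutionModel(r0=1_000_000.0)
        s = scan([(100.0, 2.0), (105.0, 6.0)])
        rep = merge_scans([s], model)
        assert [(p.mz, p.intensity) for p in rep.peaks] == [
            (100.0, 2.0),
            (105.0, 6.0),
        ]

    def test_distant_peaks_stay_separate(self):
        model = ResolutionModel(r0=1000.0, m_ref=100.0)  # 0.1 Th at 100
        rep = merge_scans([scan([(100.0, 1.0), (101.0, 1.0)])], model)
        assert len(rep.peaks) == 2

    def test_idempotence(self):
        model = ResolutionModel(r0=2000.0, m_ref=100.0)
        rep = merge_scans(
            [scan([(100.000, 2.0), (100.010, 6.0)]), scan([(100.002, 3.0)])], model
        )
        again = merge_scans([rep], model)
        for a, b in zip(again.peaks, rep.peaks):
            assert a.mz == pytest.approx(b.mz, abs=1e-9)
            assert a.intensity == pytest.approx(b.intensity, abs=1e-9)

    def test_mixed_metadata_rejected(self):
        model = ResolutionModel(r0=1000.0)
        with pytest.raises(ValueError):
            merge_scans([scan([]), scan([], sample="S2")], model)


class TestAlignment:
    def test_weighted_mean_example(self):
        model = ResolutionModel(r0=7025.0, m_ref=702.5)  # 0.1 Th at 702.5
        per_sample = {
            "A": scan([(702.505, 1e4)], sample="A"),
            "B": scan([(702.511, 3e4)], sample="B"),
        }
        clusters = align_across_samples(per_sample, model)
        assert len(clusters) == 1
        c = clusters[0]
        assert c.mz == pytest.approx(702.5095, abs=1e-9)
        assert c.per_sample_intensity == {"A": 1e4, "B": 3e4}
        assert c.occupancy == 1.0

    def test_single_sample(self):
        model = ResolutionModel(r0=1000.0)
        clusters = align_across_samples(
            {"A": scan([(100.0, 1.0), (200.0, 2.0)], sample="A")}, model
        )
        assert [c.mz for c in clusters] == [100.0, 200.0]
        assert all(c.occupancy == 1.0 for c in clusters)

    def test_separated_peaks_give_partial_occupancy(self):
        model = ResolutionModel(r0=1000.0, m_ref=100.0)  # 0.1 Th
        clusters = align_across_samples(
            {
                "A": scan([(100.0, 1.0)], sample="A"),
                "B": scan([(100.5, 1.0)], sample="B"),
            },
            model,
        )
        assert len(clusters) == 2
        assert [c.occupancy for c in clusters] == [0.5, 0.5]

    def test_intensity_conservation(self):
        rng = np.random.default_rng(7)
        model = ResolutionModel(r0=5000.0)
        per_sample = {}
        total_in = 0.0
        for sid in ("A", "B", "C"):
            peaks = [
                (float(rng.uniform(100, 900)), float(rng.uniform(1, 100)))
                for _ in range(50)
            ]
            total_in += sum(i for _, i in peaks)
            per_sample[sid] = scan(peaks, sample=sid)
        clusters = align_across_samples(per_sample, model)
        total_out = sum(sum(c.per_sample_intensity.values()) for c in clusters)
        assert total_out == pytest.approx(total_in, rel=1e-12)

    def test_cluster_mz_bounded_by_members(self):
        rng = np.random.default_rng(11)
        model = ResolutionModel(r0=3000.0)
        per_sample = {
            sid: scan(
                [
                    (float(rng.uniform(100, 110)), float(rng.uniform(1, 10)))
                    for _ in range(20)
                ],
                sample=sid,
            )
            for sid in ("A", "B")
        }
        all_mzs = [p.mz for s in per_sample.values() for p in s.peaks]
        for c in align_across_samples(per_sample, model):
            assert min(all_mzs) - 1e-12 <= c.mz <= max(all_mzs) + 1e-12

    def test_occupancy_invariant_under_relabeling(self):
        model = ResolutionModel(r0=5000.0)
        peaks = {"A": [(300.0, 5.0)], "B": [(300.001, 2.0)], "C": [(500.0, 1.0)]}
        base = {s: scan(p, sample=s) for s, p in peaks.items()}
        relabeled = {
            {"A": "C", "B": "A", "C": "B"}[s]: scan(
                p, sample={"A": "C", "B": "A", "C": "B"}[s]
            )
            for s, p in peaks.items()
        }
        occ1 = sorted(c.occupancy for c in align_across_samples(base, model))
        occ2 = sorted(c.occupancy for c in align_across_samples(relabeled, model))
        assert occ1 == occ2


class TestThresholds:
    def test_occupancy_one_drops_partial_clusters(self):
        c = make_cluster(700.0, {"A": 10.0}, n_samples=4)
        assert apply_thresholds([c], 0.0, 1.0) == []

    def test_zero_thresholds_keep_everything(self):
        cs = [make_cluster(700.0, {"A": 1.0}), make_cluster(710.0, {"A": 0.5})]
        assert apply_thresholds(cs, 0.0, 0.0) == cs

    def test_max_intensity_rule(self):
        c = make_cluster(700.0, {"A": 50.0, "B": 200.0})
        assert apply_thresholds([c], 100.0, 0.0) == [c]
        assert apply_thresholds([c], 300.0, 0.0) == []


class TestBuildMasterscan:
    def _dda_scans(self):
        out = []
        for sid in ("A", "B"):
            out.append(scan([(702.508, 1e5)], sample=sid, level=1))
            out.append(
                scan(
                    [(255.233, 4e4), (267.233, 3e4)],
                    sample=sid,
                    level=2,
                    precursor_mz=702.508,
                )
            )
        return out

    def test_structure_two_samples(self):
        ms = build_masterscan(self._dda_scans(), MasterScanSettings())
        assert len(ms.entries) == 1
        entry = ms.entries[0]
        assert not entry.virtual
        assert len(entry.fragments) == 2
        assert ms.samples == ["A", "B"]

    def test_orphan_ms2_becomes_virtual_precursor(self):
        scans = self._dda_scans() + [
            scan([(283.264, 1e3)], sample="A", level=2, precursor_mz=760.585)
        ]
        ms = build_masterscan(scans, MasterScanSettings())
        virtual = [e for e in ms.entries if e.virtual]
        assert len(virtual) == 1
        assert virtual[0].cluster.mz == pytest.approx(760.585)

    def test_pure_ms2_dataset_gives_virtual_only(self):
        scans = [
            scan(
                [(227.2, 5e3)],
                sample="A",
                level=2,
                precursor_mz=660.46,
                virtual=True,
            )
        ]
        ms = build_masterscan(scans, MasterScanSettings())
        assert all(e.virtual for e in ms.entries)

    def test_no_scans_is_error(self):
        with pytest.raises(ValueError):
            build_masterscan([], MasterScanSettings())

    def test_mixed_polarity_is_error(self):
        scans = [
            scan([(700.0, 1.0)], sample="A"),
            scan([(700.0, 1.0)], sample="B", polarity=1),
        ]
        with pytest.raises(ValueError):
            build_masterscan(scans, MasterScanSettings())


class TestPersistence:
    def test_round_trip(self, tmp_path):
        ms = build_masterscan(
            TestBuildMasterscan()._dda_scans(), MasterScanSettings()
        )
        path = tmp_path / "ms.json"
        save_masterscan(ms, path)
        back = load_masterscan(path)
        assert back.samples == ms.samples
        assert back.polarity == ms.polarity
        for a, b in zip(back.entries, ms.entries):
            assert a.cluster.mz == pytest.approx(b.cluster.mz, abs=1e-9)
            assert a.cluster.per_sample_intensity == b.cluster.per_sample_intensity
            for fa, fb in zip(a.fragments, b.fragments):
                assert fa.mz == pytest.approx(fb.mz, abs=1e-9)

    def test_truncated_file_is_error(self, tmp_path):
        ms = build_masterscan(
            TestBuildMasterscan()._dda_scans(), MasterScanSettings()
        )
        path = tmp_path / "ms.json"
        save_masterscan(ms, path)
        path.write_text(path.read_text()[:50])
        with pytest.raises(ValueError):
            load_masterscan(path)

    def test_future_version_refused(self, tmp_path):
        ms = build_masterscan(
            TestBuildMasterscan()._dda_scans(), MasterScanSettings()
        )
        path = tmp_path / "ms.json"
        save_masterscan(ms, path)
        path.write_text(path.read_text().replace('"version": 1', '"version": 99'))
        with pytest.raises(ValueError, match="version"):
            load_masterscan(path)
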