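"""Simulator properties: superposition, band positions, determinism,
vesicle rasterization, and benchmark bookkeeping."""

import json

import numpy as np
import pytest

import carospec as cs


class TestSimulateSpectrum:
    def test_zero_mixture_quiet_is_all_zero(self, quiet_cfg):
        spec, truth = cs.simulate_spectrum((0, 0, 0), quiet_cfg, np.random.default_rng(0))
        np.testing.assert_array_equal(spec.intensities, 0.0)
        assert not truth.informative

    def test_pure_astaxanthin_band_positions(self, quiet_cfg):
        """Local maxima fall at the published astaxanthin band positions."""
        spec, _ = cs.simulate_spectrum((1, 0, 0), quiet_cfg, np.random.default_rng(0))
        step = np.diff(quiet_cfg.grid).max()
        detected = [c for c, _ in cs.detect_peaks(spec, min_prominence=0.05)]
        for expected in (1009.0, 1160.0, 1516.0):
            assert min(abs(c - expected) for c in detected) <= step

    def test_superposition_at_zero_noise(self, quiet_cfg):
        rng = np.random.default_rng(0)
        a = np.array([0.3, 0.0, 0.2])
        b = np.array([0.1, 0.4, 0.0])
        sa, _ = cs.simulate_spectrum(a, quiet_cfg, rng)
        sb, _ = cs.simulate_spectrum(b, quiet_cfg, rng)
        sab, _ = cs.simulate_spectrum(a + b, quiet_cfg, rng)
        np.testing.assert_allclose(
            sab.intensities, sa.intensities + sb.intensities, rtol=1e-12
        )

    def test_invalid_fractions_rejected(self, quiet_cfg):
        with pytest.raises(ValueError):
            cs.simulate_spectrum((1.5, 0, 0), quiet_cfg, np.random.default_rng(0))

    def test_ground_truth_records_baseline_and_spikes(self, gen_cfg):
        rng = np.random.default_rng(5)
        from dataclasses import replace

        spiky = replace(gen_cfg, spike_rate=3.0)
        spec, truth = cs.simulate_spectrum((0.5, 0.2, 0.1), spiky, rng)
        assert truth.baseline.shape == spec.intensities.shape
        for idx in truth.spike_indices:
            assert spec.intensities[idx] > truth.baseline[idx]


class TestStandardsDataset:
    def test_deterministic_under_seed(self, gen_cfg):
        a = cs.simulate_standards_dataset((3, 3, 3), gen_cfg, seed=7)
        b = cs.simulate_standards_dataset((3, 3, 3), gen_cfg, seed=7)
        np.testing.assert_array_equal(a.intensity_matrix(), b.intensity_matrix())
        assert a.labels == b.labels

    def test_labels_one_hot(self, small_standards):
        assert sorted(small_standards.classes) == sorted(cs.COMPONENTS)
        np.testing.assert_array_equal(
            small_standards.fractions.sum(axis=1), np.ones(len(small_standards))
        )
        for label, frac in zip(small_standards.labels, small_standards.fractions):
            assert frac[cs.COMPONENTS.index(label)] == 1.0

    def test_default_count_is_34(self, gen_cfg):
        assert len(cs.simulate_standards_dataset(cfg=gen_cfg, seed=0)) == 34

    def test_classes_separate_beyond_within_class_spread(self, gen_cfg):
        """Between-class mean distance exceeds within-class spread when the
        noise is small."""
        from dataclasses import replace

        low_noise = replace(gen_cfg, noise_sigma=2.0, spike_rate=0.0)
        standards = cs.simulate_standards_dataset((4, 4, 4), low_noise, seed=11)
        mats = {
            c: np.vstack(
                [standards.spectra[k].intensities
                 for k in standards.indices_of(c)]
            )
            for c in standards.classes
        }
        means = {c: m.mean(axis=0) for c, m in mats.items()}
        spreads = [np.linalg.norm(m - means[c], axis=1).mean() for c, m in mats.items()]
        classes = list(means)
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                assert np.linalg.norm(means[a] - means[b]) > max(spreads)


class TestCellMap:
    def test_no_vesicles_mask_all_false(self, gen_cfg):
        _, truth = cs.simulate_cell_map("x", n_vesicles=0, cfg=gen_cfg, seed=0)
        assert not truth.mask.any()

    def test_zero_fractions_mask_all_false(self, gen_cfg):
        _, truth = cs.simulate_cell_map(
            "wt", n_vesicles=3, fractions=(0, 0, 0), cfg=gen_cfg, seed=0
        )
        assert not truth.mask.any()

    def test_mask_matches_disc_rasterization(self, gen_cfg):
        """The hotspot mask equals an independent brute-force rasterization
        of the drawn vesicle discs."""
        rmap, truth = cs.simulate_cell_map(
            "t", nx=20, ny=20, n_vesicles=1, vesicle_radius_px=2.0, cfg=gen_cfg, seed=3
        )
        expected = np.zeros((20, 20), dtype=bool)
        for j in range(20):
            for i in range(20):
                for cx, cy in truth.vesicle_centers:
                    if (i - cx) ** 2 + (j - cy) ** 2 <= truth.vesicle_radius_px**2:
                        expected[j, i] = True
        np.testing.assert_array_equal(truth.mask, expected)

    def test_hotspot_pixels_carry_signal(self, quiet_cfg):
        rmap, truth = cs.simulate_cell_map(
            "t", fractions=(0.2, 0.5, 0.3), cfg=quiet_cfg, seed=2
        )
        flat = truth.mask.reshape(-1)
        assert rmap.intensities[flat].max() > 0
        np.testing.assert_array_equal(rmap.intensities[~flat], 0.0)

    def test_vesicles_cannot_cover_map(self, gen_cfg):
        with pytest.raises(ValueError, match="cover"):
            cs.simulate_cell_map("x", nx=5, ny=5, n_vesicles=10,
                                 vesicle_radius_px=2.5, cfg=gen_cfg, seed=0)


class TestBenchmark:
    def test_counts_and_manifest(self, benchmark):
        assert len(benchmark.maps) == 7
        assert sum(len(v) for v in benchmark.maps.values()) == 28
        assert benchmark.manifest["n_standards"] == 34
        for line_id in benchmark.label_table.line_ids:
            np.testing.assert_allclose(
                benchmark.manifest["lines"][line_id]["fractions"],
                benchmark.label_table.fractions_for(line_id),
            )

    def test_wt_like_lines_sparse_transgenic_lines_dense(self, benchmark):
        """WT-like lines keep <5% informative pixels; transgenic-like lines
        get at least 3 vesicles."""
        for line_id in benchmark.label_table.line_ids:
            info = benchmark.manifest["lines"][line_id]
            total = sum(benchmark.label_table.fractions_for(line_id))
            for entry in info["maps"]:
                frac_informative = entry["n_true_informative"] / (entry["nx"] * entry["ny"])
                if total < 0.15:
                    assert frac_informative < 0.05
            if total >= 0.15:
                assert info["n_vesicles"] >= 3

    def test_rerun_same_seed_byte_identical_manifest(self, benchmark):
        again = cs.simulate_benchmark(seed=1)
        assert json.dumps(again.manifest, sort_keys=True) == json.dumps(
            benchmark.manifest, sort_keys=True
        )
        np.testing.assert_array_equal(
            again.standards.intensity_matrix(), benchmark.standards.intensity_matrix()
        )

    def test_written_tree_round_trips(self, tmp_path, gen_cfg):
        table = cs.LabelTable(cs.default_label_table().frame.iloc[:2])
        bench = cs.simulate_benchmark(
            label_table=table, maps_per_line=1, cfg=gen_cfg, seed=4,
            out_dir=tmp_path / "bundle", nx=6, ny=6, n_standards_per_class=(1, 1, 1),
        )
        line = table.line_ids[0]
        back = cs.read_map_dir(tmp_path / "bundle" / "lines" / line / "map_00")
        np.testing.assert_array_equal(back.intensities, bench.maps[line][0][0].intensities)
        labels = cs.read_label_table(tmp_path / "bundle" / "labels.csv")
        assert labels.line_ids == table.line_ids
        truth = json.loads((tmp_path / "bundle" / "truth.json").read_text())
        assert set(truth["lines"]) == set(table.line_ids)
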