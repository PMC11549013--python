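"""Embryo simulator: lineages, ground-truth rendering, degradations."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

import delicate as d
from delicate.lineage import COLUMNS, LineageTable
from delicate.synthetic import (BASE_INTENSITY, SimConfig, generate_lineage,
                                render_fluorescence, render_ground_truth,
                                simulate, write_fixture)

#: a small, cheap configuration for unit tests
SMALL = SimConfig(grid_shape=(20, 48, 48), spacing=(0.72, 0.36, 0.36),
                  n_timepoints=4, n_founders=3, n_debris=0, seed=7)

NOISELESS = dict(blur_sigma=0.0, texture_sd=0.0, shot_noise_scale=0.0,
                 read_noise_sd=0.0, attenuation_rate=0.0, n_debris=0,
                 intensity_jitter_sd=0.0)


class TestGenerateLineage:
    def test_two_synchronous_division_rounds(self):
        cfg = replace(SMALL, n_founders=1, n_timepoints=11,
                      cycle_length_mean=5.0, cycle_length_sd=0.0,
                      dim_fraction=0.0)
        lin = generate_lineage(cfg)
        assert lin.cell_count(10) == 4

    def test_no_divisions_when_cycle_exceeds_movie(self):
        cfg = replace(SMALL, cycle_length_mean=99.0)
        lin = generate_lineage(cfg)
        counts = [lin.cell_count(t) for t in range(cfg.n_timepoints)]
        assert counts == [cfg.n_founders] * cfg.n_timepoints

    def test_same_seed_is_byte_identical(self):
        a = generate_lineage(SMALL)
        b = generate_lineage(SMALL)
        assert a.df.equals(b.df)

    def test_cell_count_non_decreasing(self):
        cfg = replace(SMALL, n_timepoints=8, cycle_length_mean=3.0)
        lin = generate_lineage(cfg)
        counts = [lin.cell_count(t) for t in range(cfg.n_timepoints)]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_divisions_produce_binary_suffix_daughters(self):
        cfg = replace(SMALL, n_timepoints=8, cycle_length_mean=3.0,
                      cycle_length_sd=0.0)
        lin = generate_lineage(cfg)
        for parent, _, (d1, d2) in lin.divisions():
            assert {d1, d2} == {parent + "a", parent + "p"}

    def test_dim_flag_inherited_by_descendants(self):
        cfg = replace(SMALL, n_founders=4, dim_fraction=0.5, n_timepoints=8,
                      cycle_length_mean=3.0, intensity_jitter_sd=0.0)
        lin = generate_lineage(cfg)
        dim_roots = {c[:2] for c in
                     lin.df[lin.df["intensity_factor"] < 1.0]["cell"]}
        for root in dim_roots:
            members = lin.df[lin.df["cell"].str.startswith(root)]
            assert (members["intensity_factor"] == cfg.dim_factor).all()

    def test_grid_overflow_is_reported(self):
        cfg = replace(SMALL, grid_shape=(18, 34, 34),
                      spacing=(0.72, 0.36, 0.36), n_founders=6)
        with pytest.raises(Exception, match="founder|grid"):
            generate_lineage(cfg)


class TestRenderGroundTruth:
    def test_sphere_volume_matches_analytic(self):
        df = pd.DataFrame([[0, "A", "", 5.0, 5.0, 5.0, 2.0, 1.0]],
                          columns=COLUMNS)
        gt = render_ground_truth(LineageTable(df), 0, (21, 21, 21),
                                 (0.5, 0.5, 0.5))
        count = int((gt.data > 0).sum())
        expected = 4 / 3 * np.pi * 4 ** 3  # radius of 4 voxels
        assert abs(count - expected) / expected < 0.05

    def test_empty_lineage_gives_zero_volume(self):
        gt = render_ground_truth(LineageTable(), 0, (8, 8, 8), (0.5,) * 3)
        assert gt.data.sum() == 0

    def test_disjoint_nuclei_get_distinct_labels(self):
        df = pd.DataFrame([
            [0, "A", "", 3.0, 3.0, 3.0, 1.0, 1.0],
            [0, "B", "", 9.0, 9.0, 9.0, 1.0, 1.0],
        ], columns=COLUMNS)
        gt = render_ground_truth(LineageTable(df), 0, (26, 26, 26),
                                 (0.5, 0.5, 0.5))
        assert set(np.unique(gt.data)) == {0, 1, 2}

    def test_overlap_resolved_by_nearest_center(self):
        df = pd.DataFrame([
            [0, "A", "", 4.0, 5.0, 5.0, 2.0, 1.0],
            [0, "B", "", 6.0, 5.0, 5.0, 2.0, 1.0],
        ], columns=COLUMNS)
        gt = render_ground_truth(LineageTable(df), 0, (21, 21, 21),
                                 (0.5, 0.5, 0.5))
        # the contested midline voxel column goes to the nearer centre
        assert gt.data[10, 10, 7] == 1
        assert gt.data[10, 10, 13] == 2

    def test_label_count_equals_record_count(self):
        cfg = replace(SMALL, n_timepoints=6, cycle_length_mean=3.0)
        lin = generate_lineage(cfg)
        for t in range(cfg.n_timepoints):
            gt = render_ground_truth(lin, t, cfg.grid_shape, cfg.spacing)
            assert int(gt.data.max()) == lin.cell_count(t)


class TestRenderFluorescence:
    def test_identity_limit(self):
        cfg = replace(SMALL, **NOISELESS, bleach_rate=0.0, dim_fraction=0.0)
        lin = generate_lineage(cfg)
        gt = render_ground_truth(lin, 0, cfg.grid_shape, cfg.spacing)
        img = render_fluorescence(gt, lin, 0, cfg)
        inside = img.data[gt.data > 0]
        outside = img.data[gt.data == 0]
        assert np.all(inside == BASE_INTENSITY)
        assert np.all(outside == 0)

    def test_bleaching_closed_form(self):
        rate = 0.2
        cfg = replace(SMALL, **NOISELESS, bleach_rate=rate, motion_sd=0.0,
                      cycle_length_mean=99.0)
        lin = generate_lineage(cfg)
        means = []
        for t in (0, 2):
            gt = render_ground_truth(lin, t, cfg.grid_shape, cfg.spacing)
            img = render_fluorescence(gt, lin, t, cfg)
            means.append(img.data[gt.data > 0].mean())
        # tolerance reflects uint16 quantization of the stored images
        assert means[1] == pytest.approx(np.exp(-2 * rate) * means[0],
                                         rel=2e-4)

    def test_dim_cell_intensity_ratio(self):
        cfg = replace(SMALL, **NOISELESS, bleach_rate=0.0, n_founders=4,
                      dim_fraction=0.5, dim_factor=0.3)
        lin = generate_lineage(cfg)
        gt = render_ground_truth(lin, 0, cfg.grid_shape, cfg.spacing)
        img = render_fluorescence(gt, lin, 0, cfg)
        sub = lin.at_time(0)
        dim_means, bright_means = [], []
        for i, (_, row) in enumerate(sub.iterrows()):
            vals = img.data[gt.data == i + 1]
            (dim_means if row["intensity_factor"] < 1 else
             bright_means).append(vals.mean())
        ratio = np.mean(dim_means) / np.mean(bright_means)
        assert ratio == pytest.approx(0.3, rel=0.02)

    def test_deterministic_per_seed(self):
        cfg = replace(SMALL, n_timepoints=2)
        _, _, a = simulate(cfg)
        _, _, b = simulate(cfg)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.data, vb.data)

    def test_snr_non_increasing_in_bleach_rate(self):
        # noiseless apart from read noise so the SNR denominator is finite
        snrs = []
        for rate in (0.0, 0.1, 0.3):
            cfg = replace(SMALL, blur_sigma=0.0, texture_sd=0.0,
                          shot_noise_scale=0.0, read_noise_sd=50.0,
                          attenuation_rate=0.0, n_debris=0,
                          intensity_jitter_sd=0.0, bleach_rate=rate,
                          n_timepoints=4)
            lin, gts, raws = simulate(cfg)
            snrs.append(d.snr(raws[3].data, gts[3].data > 0))
        assert snrs[0] >= snrs[1] >= snrs[2]


class TestWriteFixture:
    def test_round_trip(self, tmp_path):
        cfg = replace(SMALL, n_timepoints=3)
        lin, gts, raws = simulate(cfg)
        write_fixture(lin, raws, tmp_path, name="sim")
        back = d.read_stack(tmp_path, "sim", 2)
        np.testing.assert_array_equal(back.as_array(), raws[1].data)
        lin2 = LineageTable.from_csv(tmp_path / "sim_lineage.csv")
        pd.testing.assert_frame_equal(
            lin2.df, lin.df, check_exact=False, rtol=1e-12)

    def test_file_count_and_ordering(self, tmp_path):
        cfg = replace(SMALL, grid_shape=(8, 48, 48),
                      radius_range=(0.9, 1.3), n_timepoints=3)
        lin, gts, raws = simulate(cfg)
        out = write_fixture(lin, raws, tmp_path, name="sim")
        tiffs = sorted(p.name for p in tmp_path.glob("*.tif"))
        assert len(tiffs) == 3 * 8
        assert tiffs == sorted(str(p.name) for p in out["tiffs"])


def test_simconfig_validation():
    with pytest.raises(ValueError):
        SimConfig(dim_factor=0.0)
    with pytest.raises(ValueError):
        SimConfig(bleach_rate=-0.1)
    with pytest.raises(ValueError):
        SimConfig(grid_shape=(4, 4, 4))
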