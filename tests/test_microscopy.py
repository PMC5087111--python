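"""Co-localization quantification and 3D granule morphometry."""

from __future__ import annotations

import math

import numpy as np
import pytest

import sagscope as s
from sagscope.arrayio import read_array, write_array
from sagscope.reference import CapacityError


@pytest.fixture(scope="module")
def field_and_truth():
    return s.generate_label_field(
        n_nuclei=200, n_probe_positive=60, n_protein_positive=20,
        n_host_cells=12, shape=(400, 400), seed=5,
    )


class TestColocalize:
    def test_closed_loop_counts_exact(self, field_and_truth):
        lf, truth = field_and_truth
        co = s.colocalize(lf)
        assert co.n_nuclei == 200
        assert co.n_probe_positive == 60
        assert co.positive_labels == frozenset(
            truth.loc[truth.probe_positive, "label"]
        )
        assert co.percent_positive == pytest.approx(30.0)
        assert co.n_host_cells == 12

    def test_empty_probe_mask(self):
        lf, _ = s.generate_label_field(50, 0, 0, 0, shape=(200, 200), seed=1)
        co = s.colocalize(lf)
        assert co.n_probe_positive == 0 and co.percent_positive == 0.0

    def test_probe_covering_everything(self):
        lf, _ = s.generate_label_field(50, 0, 0, 0, shape=(200, 200), seed=2)
        lf.probe_mask = np.ones_like(lf.probe_mask, dtype=bool)
        assert s.colocalize(lf).percent_positive == pytest.approx(100.0)

    def test_invariant_under_label_permutation_and_translation(self, field_and_truth):
        lf, _ = field_and_truth
        base = s.colocalize(lf)
        # permute label values
        perm = np.random.default_rng(0).permutation(np.arange(1, 201))
        lut = np.zeros(201, dtype=np.int32)
        lut[1:] = perm
        permuted = s.LabelField(
            "perm", lut[lf.nuclei_labels], lf.host_cell_labels,
            lf.probe_mask, lf.protein_mask, lf.pixel_size,
        )
        got = s.colocalize(permuted)
        assert (got.n_nuclei, got.n_probe_positive) == (base.n_nuclei, base.n_probe_positive)
        # translate everything together
        shifted = s.LabelField(
            "shift", np.roll(lf.nuclei_labels, 7, axis=1),
            np.roll(lf.host_cell_labels, 7, axis=1),
            np.roll(lf.probe_mask, 7, axis=1),
            np.roll(lf.protein_mask, 7, axis=1), lf.pixel_size,
        )
        got = s.colocalize(shifted)
        assert got.percent_positive == pytest.approx(base.percent_positive)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            s.LabelField(
                "bad", np.zeros((10, 10), int), np.zeros((10, 10), int),
                np.zeros((10, 11), bool), np.zeros((10, 10), bool), 0.2,
            )

    def test_capacity_error(self):
        with pytest.raises(CapacityError):
            s.generate_label_field(10_000, 0, 0, 0, shape=(50, 50), seed=0)

    def test_zero_objects(self):
        lf, truth = s.generate_label_field(0, 0, 0, 0, shape=(50, 50), seed=0)
        assert lf.nuclei_labels.max() == 0 and truth.empty


class TestProteinPositivity:
    def test_closed_loop_percent(self, field_and_truth):
        lf, truth = field_and_truth
        co = s.colocalize(lf)
        percent, hits, denom = s.protein_positivity(lf, co)
        assert (hits, denom) == (20, 60)
        assert percent == pytest.approx(100.0 * 20 / 60)

    def test_zero_probe_positive_flagged(self):
        lf, _ = s.generate_label_field(30, 0, 0, 0, shape=(200, 200), seed=3)
        co = s.colocalize(lf)
        percent, hits, denom = s.protein_positivity(lf, co)
        assert denom == 0 and math.isnan(percent)


class TestSummaries:
    def test_mean_and_sample_sd_across_fields(self):
        rows = [
            s.FieldColocalization(f"f{i}", 100, 20, p, 1000.0, 2.0, 10)
            for i, p in enumerate([20.0, 21.0, 22.0, 25.0])
        ]
        out = s.summarize_fields(rows)
        assert out.loc["percent_positive", "mean"] == pytest.approx(22.0)
        assert out.loc["percent_positive", "sd"] == pytest.approx(2.160, abs=1e-3)

    def test_single_field_sd_flagged(self):
        out = s.summarize_fields(
            [s.FieldColocalization("f", 10, 5, 50.0, 1.0, 1.0, 5)]
        )
        assert math.isnan(out.loc["percent_positive", "sd"])

    def test_identical_fields_sd_zero(self):
        rows = [s.FieldColocalization(f"f{i}", 10, 5, 50.0, 1.0, 1.0, 5) for i in range(3)]
        assert (s.summarize_fields(rows)["sd"] == 0).all()

    def test_density_and_ratio_unit_arithmetic(self):
        density, ratio = s.density_and_ratio(100, 0.01, 0)
        assert density == pytest.approx(1e4)
        assert math.isnan(ratio)
        _, ratio = s.density_and_ratio(792, 1.0, 154)
        assert ratio == pytest.approx(5.14, abs=5e-3)
        with pytest.raises(ValueError):
            s.density_and_ratio(1, 0.0, 1)


class TestMorphometry:
    def test_digitized_sphere_matches_analytic_within_3pc(self):
        radius = 0.084  # um -> 168 nm diameter
        mask = s.digitize_sphere(radius, 0.01)
        model = s.VoxelModel(
            np.ones_like(mask), mask.astype(np.int32), (0.01, 0.01, 0.01)
        )
        res = s.granule_morphometry(model)
        analytic = 4.0 / 3.0 * math.pi * radius**3
        assert res.granule_volumes_um3[1] == pytest.approx(analytic, rel=0.03)
        assert res.granule_diameters_nm[1] == pytest.approx(168.0, rel=0.03)

    def test_volume_error_decreases_with_resolution(self):
        radius = 0.084
        analytic = 4.0 / 3.0 * math.pi * radius**3
        errs = []
        for v in (0.04, 0.02, 0.01):
            n = int(s.digitize_sphere(radius, v).sum())
            errs.append(abs(n * v**3 - analytic) / analytic)
        assert errs[0] > errs[1] > errs[2]

    def test_bipolar_granules_score_one(self):
        model, _ = s.generate_voxel_cell(voxel_size=(0.02, 0.02, 0.02))
        res = s.granule_morphometry(model)
        assert res.granule_count == 2
        assert res.polarity == 1.0
        assert 0 < res.volume_fraction < 1

    def test_same_pole_granules_score_zero(self):
        model, _ = s.generate_voxel_cell(voxel_size=(0.02, 0.02, 0.02))
        gran = model.granule_labels
        # move granule 2 on top of granule 1's half
        half = gran.shape[0] // 2
        moved = gran.copy()
        moved[moved == 2] = 0
        src = np.argwhere(gran == 2)
        src[:, 0] -= int(src[:, 0].mean() - half // 2)
        inside = model.cell_mask[tuple(src.T)]
        moved[tuple(src[inside].T)] = 2
        res = s.granule_morphometry(
            s.VoxelModel(model.cell_mask, moved, model.voxel_size)
        )
        assert res.polarity == 0.0

    def test_no_granules_flagged(self):
        model, _ = s.generate_voxel_cell(voxel_size=(0.04, 0.04, 0.04))
        empty = s.VoxelModel(
            model.cell_mask, np.zeros_like(model.granule_labels), model.voxel_size
        )
        res = s.granule_morphometry(empty)
        assert res.volume_fraction == 0.0 and res.polarity is None

    def test_granule_outside_cell_raises(self):
        cell = np.zeros((10, 10, 10), bool)
        cell[2:8, 2:8, 2:8] = True
        gran = np.zeros((10, 10, 10), np.int32)
        gran[0, 0, 0] = 1
        with pytest.raises(ValueError):
            s.granule_morphometry(s.VoxelModel(cell, gran))

    def test_anisotropic_voxel_volume(self):
        cell = np.ones((4, 4, 4), bool)
        gran = np.zeros((4, 4, 4), np.int32)
        gran[1, 1, 1] = 1
        res = s.granule_morphometry(
            s.VoxelModel(cell, gran, voxel_size=(0.01, 0.01, 0.1))
        )
        assert res.granule_volumes_um3[1] == pytest.approx(1e-5)


class TestArrayIO:
    @pytest.mark.parametrize("shape, dtype", [((5, 7), np.int32), ((3, 4, 5), np.int64)])
    def test_round_trip(self, tmp_path, shape, dtype):
        rng = np.random.default_rng(1)
        arr = rng.integers(0, 9, size=shape).astype(dtype)
        write_array(tmp_path / "a.txt", arr)
        back = read_array(tmp_path / "a.txt")
        assert back.shape == arr.shape and back.dtype == arr.dtype
        assert (back == arr).all()

    def test_bool_round_trip(self, tmp_path):
        arr = np.random.default_rng(2).random((6, 6)) < 0.5
        write_array(tmp_path / "b.txt", arr)
        back = read_array(tmp_path / "b.txt")
        assert back.dtype == bool and (back == arr).all()
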