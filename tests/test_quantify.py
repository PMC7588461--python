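"""Per-islet statistics, size distributions, comparisons and exports."""

import numpy as np
import pandas as pd
import pytest

from aftomo import (IsletRecord, SizeDistribution, Volume, compare_to_reference,
                    export_statistics, measure_islets, mip,
                    per_object_intensity_stats, size_distribution)
from aftomo.quantify import frame_to_records, records_to_frame
from aftomo.segment import LabelVolume


def _vol(data, vs=10.0):
    return Volume(np.asarray(data, dtype=np.float32), voxel_size_um=vs)


def _record(d, volume=1000.0, label=1):
    return IsletRecord(label_id=label, voxel_count=8, volume_um3=volume,
                       extent_x_um=d, extent_y_um=d, extent_z_um=d,
                       mean_diameter_um=d, centroid_vox=(1.0, 1.0, 1.0),
                       intensity_sum=1.0)


class TestMeasureIslets:
    def test_cube_closed_form(self):
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[2:5, 2:5, 2:5] = 1
        rec = measure_islets(LabelVolume(lab, 10.0), _vol(np.ones(lab.shape)))[0]
        assert (rec.extent_x_um, rec.extent_y_um, rec.extent_z_um) == (30.0, 30.0, 30.0)
        assert rec.mean_diameter_um == 30.0
        assert rec.voxel_count == 27
        assert rec.volume_um3 == 27_000.0

    def test_mean_diameter_is_extent_average(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[1:4, 2:4, 3:4] = 1  # extents (z, y, x) = (30, 20, 10) um
        rec = measure_islets(LabelVolume(lab, 10.0), _vol(np.ones(lab.shape)))[0]
        assert rec.mean_diameter_um == 20.0

    def test_voxelized_sphere_recovery(self):
        d = 12  # voxels
        shape = (20, 20, 20)
        zz, yy, xx = np.indices(shape)
        lab = (((zz - 9.5) ** 2 + (yy - 9.5) ** 2 + (xx - 9.5) ** 2)
               <= (d / 2) ** 2).astype(np.int32)
        rec = measure_islets(LabelVolume(lab, 1.0), _vol(np.ones(shape), 1.0))[0]
        assert rec.mean_diameter_um == pytest.approx(d, abs=1.0)
        assert rec.volume_um3 == pytest.approx(np.pi / 6 * d ** 3, rel=0.15)

    def test_geometry_mismatch_rejected(self):
        lab = LabelVolume(np.zeros((4, 4, 4), dtype=np.int32), 10.0)
        with pytest.raises(ValueError, match="geometry"):
            measure_islets(lab, _vol(np.zeros((5, 5, 5))))

    def test_voxel_count_conservation(self):
        rng = np.random.default_rng(0)
        lab = rng.integers(0, 5, size=(12, 12, 12)).astype(np.int32)
        # relabel to consecutive connected pieces is not required for counts
        records = measure_islets(LabelVolume(lab, 10.0),
                                 _vol(rng.random((12, 12, 12))))
        assert sum(r.voxel_count for r in records) == int((lab > 0).sum())


class TestPerObjectIntensity:
    def test_constant_intensity_sum(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[1:3, 1:3, 1:3] = 1  # 8 voxels
        stats = per_object_intensity_stats(LabelVolume(lab, 10.0),
                                           _vol(np.full((6, 6, 6), 2.5)))
        assert stats.loc[0, "intensity_sum"] == 8 * 2.5

    def test_sums_match_brute_force_and_are_local(self):
        rng = np.random.default_rng(1)
        lab = np.zeros((10, 10, 10), dtype=np.int32)
        lab[1:4, 1:4, 1:4] = 1
        lab[6:9, 6:9, 6:9] = 2
        intensity = rng.random((10, 10, 10)).astype(np.float32)
        vol = _vol(intensity)
        stats = per_object_intensity_stats(LabelVolume(lab, 10.0), vol)
        for obj in (1, 2):
            brute = sum(float(vol.data[idx]) for idx in zip(*np.nonzero(lab == obj)))
            assert stats.loc[obj - 1, "intensity_sum"] == pytest.approx(brute, rel=1e-12)
        # editing object 1's voxels leaves object 2's sum unchanged
        intensity2 = intensity.copy()
        intensity2[lab == 1] += 5.0
        stats2 = per_object_intensity_stats(LabelVolume(lab, 10.0), _vol(intensity2))
        assert stats2.loc[1, "intensity_sum"] == stats.loc[1, "intensity_sum"]


class TestMip:
    def test_single_voxel(self):
        data = np.zeros((4, 5, 6), dtype=np.float32)
        data[2, 3, 4] = 1.0
        m = mip(_vol(data), axis="z")
        assert m.shape == (5, 6)
        assert np.argwhere(m == 1.0).tolist() == [[3, 4]]

    def test_max_semilattice(self):
        rng = np.random.default_rng(2)
        data = rng.random((4, 6, 6)).astype(np.float32)
        vol = _vol(data)
        combined = _vol(np.maximum(data, 0.5 * data))
        np.testing.assert_array_equal(mip(vol, "y"), mip(combined, "y"))

    def test_dominates_every_section(self):
        rng = np.random.default_rng(3)
        data = rng.random((5, 8, 8)).astype(np.float32)
        m = mip(_vol(data), axis="z")
        for z in range(5):
            assert np.all(m >= data[z])


class TestSizeDistribution:
    def test_simple_binning(self):
        dist = size_distribution([_record(20), _record(20), _record(70)],
                                 np.array([0.0, 50.0, 100.0]))
        np.testing.assert_array_equal(dist.counts, [2, 1])
        np.testing.assert_allclose(dist.fractions, [2 / 3, 1 / 3])
        assert dist.n_total == 3

    def test_interior_edge_goes_up(self):
        dist = size_distribution([_record(50.0)], np.array([0.0, 50.0, 100.0]))
        np.testing.assert_array_equal(dist.counts, [0, 1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            size_distribution([_record(150.0)], np.array([0.0, 50.0, 100.0]))

    def test_partition_and_permutation_invariance(self):
        rng = np.random.default_rng(4)
        records = [_record(float(d)) for d in rng.uniform(5, 395, size=100)]
        edges = np.arange(0.0, 401.0, 25.0)
        d1 = size_distribution(records, edges)
        d2 = size_distribution(list(reversed(records)), edges)
        assert d1.counts.sum() == 100
        np.testing.assert_array_equal(d1.counts, d2.counts)
        assert abs(d1.fractions.sum() - 1.0) < 1e-9

    def test_mass_weighted_variant(self):
        records = [_record(20, volume=1000.0), _record(70, volume=3000.0)]
        dist = size_distribution(records, np.array([0.0, 50.0, 100.0]))
        np.testing.assert_allclose(dist.volume_um3, [1000.0, 3000.0])
        np.testing.assert_allclose(dist.volume_fractions, [0.25, 0.75])


class TestCompareToReference:
    def test_self_comparison_is_zero(self):
        dist = size_distribution([_record(20), _record(70)],
                                 np.array([0.0, 50.0, 100.0]))
        rep = compare_to_reference(dist, dist)
        np.testing.assert_array_equal(rep.fraction_diff, [0.0, 0.0])
        assert rep.total_variation == 0.0
        assert rep.chi_square == 0.0

    def test_disjoint_distributions_tv_one(self):
        a = SizeDistribution(np.array([0.0, 50.0, 100.0]), fractions=[1.0, 0.0],
                             counts=[10, 0], n_total=10)
        b = SizeDistribution(np.array([0.0, 50.0, 100.0]), fractions=[0.0, 1.0],
                             counts=[0, 10], n_total=10)
        assert compare_to_reference(a, b).total_variation == 1.0

    def test_chi_square_closed_form(self):
        obs = SizeDistribution(np.array([0.0, 50.0, 100.0]), fractions=[0.3, 0.7],
                               counts=[30, 70], n_total=100)
        ref = SizeDistribution(np.array([0.0, 50.0, 100.0]), fractions=[0.5, 0.5])
        rep = compare_to_reference(obs, ref)
        assert rep.chi_square == pytest.approx(16.0)
        assert rep.dof == 1

    def test_mismatched_edges_rejected(self):
        a = SizeDistribution(np.array([0.0, 50.0, 100.0]), fractions=[1.0, 0.0],
                             counts=[1, 0], n_total=1)
        b = SizeDistribution(np.array([0.0, 40.0, 100.0]), fractions=[0.5, 0.5])
        with pytest.raises(ValueError, match="edges"):
            compare_to_reference(a, b)


class TestExport:
    def test_empty_records_header_only(self, tmp_path):
        paths = export_statistics([], None, None, tmp_path)
        df = pd.read_csv(paths["islets"])
        assert df.empty and len(df.columns) == 11

    def test_round_trip_exact(self, tmp_path):
        rng = np.random.default_rng(5)
        records = [
            IsletRecord(label_id=i + 1, voxel_count=int(rng.integers(27, 5000)),
                        volume_um3=float(rng.random() * 1e6),
                        extent_x_um=float(rng.random() * 300),
                        extent_y_um=float(rng.random() * 300),
                        extent_z_um=float(rng.random() * 300),
                        mean_diameter_um=float(rng.random() * 300),
                        centroid_vox=tuple(rng.random(3) * 100),
                        intensity_sum=float(rng.random() * 1e4))
            for i in range(50)
        ]
        paths = export_statistics(records, None, None, tmp_path)
        back = frame_to_records(pd.read_csv(paths["islets"], float_precision="round_trip"))
        assert back == records

    def test_large_cohort_round_trip(self, tmp_path):
        """A cohort-sized table (7034 synthetic rows) survives CSV round trip
        without loss."""
        rng = np.random.default_rng(6)
        n = 7034
        frame = records_to_frame([
            _record(float(d), volume=float(v), label=i + 1)
            for i, (d, v) in enumerate(zip(rng.uniform(10, 390, n),
                                           rng.uniform(1e3, 1e7, n)))
        ])
        path = tmp_path / "islets.csv"
        frame.to_csv(path, index=False)
        back = pd.read_csv(path, float_precision="round_trip")
        assert len(back) == n
        np.testing.assert_array_equal(back["mean_diameter_um"].to_numpy(),
                                      frame["mean_diameter_um"].to_numpy())
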