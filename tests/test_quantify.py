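"""Volumetry: voxel volume, instance labeling oracle, size classes, series."""

import numpy as np
import pytest

from lungmet.core_io import DEFAULT_SPACING_MM, LabelStack
from lungmet.phantom import PhantomSpec, generate_phantom
from lungmet.quantify import (
    VolumetryReport,
    classify_metastasis_size,
    compute_volumes,
    label_metastasis_instances,
    summarize_series,
    voxel_volume,
)

N18_OFFSETS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0) and abs(dz) + abs(dy) + abs(dx) <= 2
]


def flood_fill_components(mask):
    """Independent 18-connectivity component labeling by BFS."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=int)
    sizes = []
    for start in zip(*np.nonzero(mask)):
        if labels[start]:
            continue
        sizes.append(0)
        current = len(sizes)
        queue = [start]
        labels[start] = current
        while queue:
            z, y, x = queue.pop()
            sizes[-1] += 1
            for dz, dy, dx in N18_OFFSETS:
                n = (z + dz, y + dy, x + dx)
                if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                    if mask[n] and not labels[n]:
                        labels[n] = current
                        queue.append(n)
        # order by discovery; counts are compared as multisets
    return labels, sizes


class TestVoxelVolume:
    def test_reference_spacing_rounds_to_published_value(self):
        assert round(voxel_volume(DEFAULT_SPACING_MM), 4) == 0.0047

    def test_unit_voxel(self):
        assert voxel_volume((1.0, 1.0, 1.0)) == 1.0

    def test_product(self):
        assert voxel_volume((0.2, 0.1, 0.1)) == pytest.approx(0.002)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            voxel_volume((0.2, -0.1, 0.1))


class TestComputeVolumes:
    def test_four_voxel_metastasis(self):
        data = np.zeros((2, 4, 4), dtype=int)
        data[0, 0, 0] = data[0, 0, 1] = data[0, 1, 0] = data[0, 1, 1] = 2
        report = compute_volumes(LabelStack(data), voxel_volume_mm3=0.0047)
        assert report.met_total_volume_mm3 == pytest.approx(0.0188)
        assert report.met_count == 1

    def test_empty_mask(self):
        report = compute_volumes(LabelStack(np.zeros((2, 4, 4), dtype=int)))
        assert report.lung_volume_mm3 == 0.0
        assert report.met_total_volume_mm3 == 0.0
        assert report.met_count == 0

    def test_hundred_lung_voxels(self):
        data = np.zeros((4, 5, 5), dtype=int)
        data[:] = 1
        report = compute_volumes(LabelStack(data), voxel_volume_mm3=0.0047)
        assert report.lung_volume_mm3 == pytest.approx(100 * 0.0047)

    def test_instances_sum_to_total(self, rng):
        data = rng.integers(0, 3, size=(6, 10, 10))
        report = compute_volumes(LabelStack(data))
        assert report.met_total_volume_mm3 == pytest.approx(
            sum(report.met_instance_volumes_mm3)
        )

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError):
            VolumetryReport(1.0, 2.0, 1, [1.0], 0.0047)


class TestInstanceLabeling:
    def test_edge_adjacent_voxels_are_one_component(self):
        m = np.zeros((2, 2, 2), dtype=bool)
        m[0, 0, 0] = m[0, 1, 1] = True  # share an edge
        _, counts = label_metastasis_instances(m)
        assert counts == [2]

    def test_vertex_only_voxels_are_two_components(self):
        m = np.zeros((2, 2, 2), dtype=bool)
        m[0, 0, 0] = m[1, 1, 1] = True  # share only a vertex
        _, counts = label_metastasis_instances(m)
        assert sorted(counts) == [1, 1]

    def test_empty_mask_has_no_components(self):
        _, counts = label_metastasis_instances(np.zeros((3, 3, 3), dtype=bool))
        assert counts == []

    def test_matches_flood_fill_on_random_grids(self, rng):
        for _ in range(50):
            m = rng.random((5, 5, 5)) < rng.uniform(0.1, 0.6)
            _, counts = label_metastasis_instances(m)
            _, oracle_counts = flood_fill_components(m)
            assert sorted(counts) == sorted(oracle_counts)

    def test_connectivity_monotonicity(self, rng):
        from scipy import ndimage as ndi

        for _ in range(20):
            m = rng.random((6, 6, 6)) < 0.35
            n6 = ndi.label(m, ndi.generate_binary_structure(3, 1))[1]
            n18 = ndi.label(m, ndi.generate_binary_structure(3, 2))[1]
            n26 = ndi.label(m, ndi.generate_binary_structure(3, 3))[1]
            assert n6 >= n18 >= n26

    def test_2d_input_rejected(self):
        with pytest.raises(ValueError):
            label_metastasis_instances(np.zeros((3, 3), dtype=bool))


class TestSizeClass:
    @pytest.mark.parametrize(
        "volume,expected",
        [
            (0.0188, "small"),  # smallest detectable instance
            (0.4, "large"),  # boundary assigned to large
            (85 * 0.0047, "small"),  # 0.3995, just under the cutoff
            (6.9, "large"),
        ],
    )
    def test_cutoff(self, volume, expected):
        assert classify_metastasis_size(volume) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_metastasis_size(-0.1)


class TestSeries:
    def _report(self, volumes):
        v = 0.0047
        return VolumetryReport(
            lung_volume_mm3=1.0,
            met_total_volume_mm3=float(sum(volumes)),
            met_count=len(volumes),
            met_instance_volumes_mm3=list(volumes),
            voxel_volume_mm3=v,
        )

    def test_single_timepoint_row(self):
        table = summarize_series([self._report([0.1, 0.5])])
        assert len(table) == 1
        assert table.loc[0, "met_count"] == 2
        assert table.loc[0, "met_total_volume_mm3"] == pytest.approx(0.6)

    def test_histogram_partitions_count(self):
        table = summarize_series([self._report([0.01, 0.39, 0.4, 2.0, 30.0])])
        hist_cols = [c for c in table.columns if c.startswith("n_mets_")]
        assert table.loc[0, hist_cols].sum() == 5

    def test_growth_series_volumes_non_decreasing(self):
        from lungmet.phantom import generate_growth_series

        spec = PhantomSpec.random(dims=(12, 24, 24), n_metastases=2, seed=8,
                                  radius_range=(1.0, 1.5))
        series = generate_growth_series(spec, 3, growth="fast")
        reports = [compute_volumes(tp.labels) for tp in series]
        table = summarize_series(reports)
        vols = table["met_total_volume_mm3"].to_numpy()
        assert (np.diff(vols) >= 0).all()

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            summarize_series([self._report([])], timepoints=[0, 1])
        with pytest.raises(ValueError):
            summarize_series([])


def test_phantom_volumes_match_generator_ground_truth():
    for seed in range(8):
        spec = PhantomSpec.random(dims=(12, 24, 24), n_metastases=seed % 4,
                                  seed=seed, radius_range=(1.0, 1.5))
        _, labels = generate_phantom(spec)
        report = compute_volumes(labels)
        v = report.voxel_volume_mm3
        assert report.lung_volume_mm3 == labels.class_counts()[1] * v
        assert report.met_total_volume_mm3 == pytest.approx(
            labels.class_counts()[2] * v
        )
        assert report.met_count == (seed % 4 if seed % 4 else 0)
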