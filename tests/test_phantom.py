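"""Phantom generation, overlap resolution and label cleanup."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fingersim as fs
from fingersim.phantom import (
    AMBIENT,
    BONE,
    SUBCUTIS,
    SYNOVIAL_CAVITY,
    PhantomSizeError,
    Tissue,
    TissueLabelVolume,
    TissueTable,
    cleanup_labels,
    default_tissue_table,
    resolve_overlaps,
    validate_phantom,
)
from conftest import make_small_params


class TestTissueTable:
    def test_default_has_15_contiguous_ids_and_unique_ranks(self):
        table = default_tissue_table()
        assert sorted(t.id for t in table.entries) == list(range(1, 16))
        assert len({t.priority for t in table.entries}) == 15
        assert "joint capsule" in table.entries[5].aliases or any(
            "joint capsule" in t.aliases for t in table.entries
        )

    def test_rejects_duplicate_ids(self):
        bad = tuple(Tissue(1, f"t{i}", i) for i in range(1, 16))
        with pytest.raises(ValueError):
            TissueTable(bad)

    def test_rejects_duplicate_ranks(self):
        bad = tuple(Tissue(i, f"t{i}", 1) for i in range(1, 16))
        with pytest.raises(ValueError):
            TissueTable(bad)


class TestLabelVolume:
    def test_rejects_float_labels(self):
        with pytest.raises(ValueError):
            TissueLabelVolume(np.zeros((2, 2, 2)))

    def test_rejects_out_of_range_labels(self):
        with pytest.raises(ValueError):
            TissueLabelVolume(np.full((2, 2, 2), 16, dtype=np.int16))

    def test_rejects_nonpositive_pitch(self):
        with pytest.raises(ValueError):
            TissueLabelVolume(np.zeros((2, 2, 2), dtype=np.int16), (0.2, -1.0, 0.2))


class TestGeneratePhantom:
    def test_default_has_15_labels_and_exact_voxel_count(self, default_phantom):
        assert default_phantom.labels.size == 6_809_600
        assert default_phantom.labels.shape == (160, 320, 133)
        assert len(default_phantom.distinct_labels()) == 15

    def test_small_phantom_contains_all_tissues(self, small_phantom):
        assert small_phantom.distinct_labels() == set(range(1, 16))

    def test_deterministic_for_fixed_params(self, small_params, small_phantom):
        again = fs.generate_phantom(small_params)
        assert np.array_equal(again.labels, small_phantom.labels)

    def test_joint_toggle_removes_synovial_cavity(self):
        params = make_small_params(include_joints=False)
        vol = fs.generate_phantom(params)
        assert SYNOVIAL_CAVITY not in vol.distinct_labels()

    def test_too_small_grid_raises_sizing_error(self):
        with pytest.raises(PhantomSizeError):
            fs.generate_phantom(make_small_params(grid_shape=(20, 160, 20)))

    def test_structural_report_passes(self, small_phantom, small_params):
        report = validate_phantom(small_phantom, small_params)
        assert report.passed, report.details

    def test_injected_surface_bone_fails_adjacency_check(self, small_phantom):
        labels = small_phantom.labels.copy()
        # put a bone voxel in ambient space at a corner
        labels[0, 0, 0] = BONE
        report = validate_phantom(TissueLabelVolume(labels, small_phantom.pitch))
        assert not report.checks["bone_interior"]

    def test_counts_partition_nonambient_voxels(self, small_phantom):
        counts = small_phantom.label_counts()
        assert sum(counts.values()) == int((small_phantom.labels != AMBIENT).sum())


# --- resolve_overlaps ------------------------------------------------------

def brute_force_resolve(masks, table):
    """Exhaustive per-voxel arg-best loop (independent oracle)."""
    shape = next(iter(masks.values())).shape
    out = np.zeros(shape, dtype=np.int16)
    for idx in np.ndindex(shape):
        best, best_rank = 0, 10**9
        for tid, m in masks.items():
            if m[idx]:
                rank = table.priority_of(tid)
                if rank < best_rank:
                    best, best_rank = tid, rank
        out[idx] = best
    return out


class TestResolveOverlaps:
    def test_priority_wins_on_overlap(self):
        a = np.zeros((3, 3, 3), dtype=bool)
        b = np.zeros((3, 3, 3), dtype=bool)
        a[1, 1, 1] = b[1, 1, 1] = True
        table = default_tissue_table()
        # artery (rank 1) outranks bone (rank 12)
        vol = resolve_overlaps({5: a, 10: b}, table)
        assert vol.labels[1, 1, 1] == 5

    def test_disjoint_masks_union(self):
        a = np.zeros((4, 4, 4), dtype=bool)
        b = np.zeros((4, 4, 4), dtype=bool)
        a[:2] = True
        b[2:] = True
        vol = resolve_overlaps({1: a, 10: b})
        assert np.array_equal(vol.labels == 1, a)
        assert np.array_equal(vol.labels == 10, b)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            resolve_overlaps({1: np.ones((2, 2, 2), bool), 2: np.ones((3, 2, 2), bool)})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_grids(self, seed):
        rng = np.random.default_rng(seed)
        table = default_tissue_table()
        masks = {tid: rng.random((6, 5, 4)) < 0.4 for tid in (3, 7, 12)}
        vol = resolve_overlaps(masks, table)
        assert np.array_equal(vol.labels, brute_force_resolve(masks, table))


# --- cleanup_labels --------------------------------------------------------

def brute_force_cleanup(labels):
    """Sequential majority-filter to a fixed point (independent oracle)."""
    out = labels.astype(np.int16).copy()
    nx, ny, nz = out.shape
    changed = True
    while changed:
        changed = False
        for ix in range(nx):
            for iy in range(ny):
                for iz in range(nz):
                    lab = out[ix, iy, iz]
                    nbs = [
                        out[ix - 1, iy, iz] if ix > 0 else 0,
                        out[ix + 1, iy, iz] if ix < nx - 1 else 0,
                        out[ix, iy - 1, iz] if iy > 0 else 0,
                        out[ix, iy + 1, iz] if iy < ny - 1 else 0,
                        out[ix, iy, iz - 1] if iz > 0 else 0,
                        out[ix, iy, iz + 1] if iz < nz - 1 else 0,
                    ]
                    if lab in nbs:
                        continue
                    counts = {}
                    for v in nbs:
                        counts[v] = counts.get(v, 0) + 1
                    best = min(counts, key=lambda v: (-counts[v], v))
                    out[ix, iy, iz] = best
                    changed = True
    return out


class TestCleanupLabels:
    def test_stray_voxel_reassigned_to_surrounding_label(self):
        labels = np.ones((5, 5, 5), dtype=np.int16)
        labels[2, 2, 2] = 10
        out = cleanup_labels(TissueLabelVolume(labels, 0.2))
        assert out.labels[2, 2, 2] == 1

    def test_hole_filled_with_neighbor_label(self):
        labels = np.full((5, 5, 5), 6, dtype=np.int16)
        labels[2, 2, 2] = 0
        out = cleanup_labels(TissueLabelVolume(labels, 0.2))
        assert out.labels[2, 2, 2] == 6

    def test_clean_volume_is_fixed_point(self):
        labels = np.zeros((6, 6, 6), dtype=np.int16)
        labels[:3] = 1
        labels[3:] = 10
        vol = TissueLabelVolume(labels, 0.2)
        out = cleanup_labels(vol)
        assert np.array_equal(out.labels, labels)

    @pytest.mark.parametrize("seed", [0, 7])
    def test_matches_majority_filter_oracle_on_random_grid(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 4, (10, 10, 10)).astype(np.int16)
        out = cleanup_labels(TissueLabelVolume(labels, 0.2))
        assert np.array_equal(out.labels, brute_force_cleanup(labels))

    @given(st.integers(0, 1000))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 5, (8, 8, 8)).astype(np.int16)
        once = cleanup_labels(TissueLabelVolume(labels, 0.2))
        twice = cleanup_labels(once)
        assert np.array_equal(once.labels, twice.labels)
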