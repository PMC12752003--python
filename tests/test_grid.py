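"""Grid engine: box, spacing, classification, correction, descriptors."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import vspgrid as vg
from vspgrid.grid import (
    EXTERNAL,
    INTERNAL,
    SURFACE,
    GridTooLargeError,
    SpacingTable,
    bounding_box,
    build_grid,
    classify_grid,
    compute_psa,
    compute_surface,
    compute_volume,
    correct_isolated_points,
    select_spacing,
    surface_points,
)
from vspgrid.radii import RadiiTable


def sphere_frame(radius=2.0, center=(0.0137, 0.021, -0.0113)):
    """Lone carbon-like sphere with a custom radius; off-lattice center."""
    table = RadiiTable(entries={"C": radius})
    frame = vg.MolecularFrame.from_arrays(["C"], np.array([center]))
    return frame, table


class TestBoundingBox:
    def test_single_atom_has_zero_v_rec(self):
        frame = vg.MolecularFrame.from_arrays(["C"], np.array([[3.0, -2.0, 7.5]]))
        box = bounding_box(frame)
        assert box.v_rec == 0.0

    def test_two_corner_atoms(self):
        frame = vg.MolecularFrame.from_arrays(
            ["C", "C"], np.array([[0.0, 0.0, 0.0], [1.0, 2.0, 3.0]])
        )
        assert bounding_box(frame).v_rec == pytest.approx(6.0)

    @given(st.integers(0, 2**31 - 1))
    def test_matches_exhaustive_min_max_scan(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(-20, 20, size=(50, 3))
        frame = vg.MolecularFrame.from_arrays(["C"] * 50, coords)
        box = bounding_box(frame)
        v = 1.0
        for k in range(3):
            lo = min(c[k] for c in coords)
            hi = max(c[k] for c in coords)
            assert box.mins[k] == lo and box.maxs[k] == hi
            v *= hi - lo
        assert box.v_rec == pytest.approx(v)


class TestSelectSpacing:
    def test_universal_mode_ignores_size(self):
        for v in (0.0, 12.3, 1e6):
            assert select_spacing(v, "universal") == 0.43

    def test_degenerate_single_row_table(self):
        table = SpacingTable(bins=((math.inf, 0.3),))
        for v in (0.0, 99.0, 1e9):
            assert select_spacing(v, "size_dependent", table) == 0.3

    def test_clamps_above_largest_bound(self):
        table = SpacingTable(bins=((100.0, 0.2), (500.0, 0.3), (1000.0, 0.5)))
        assert select_spacing(50.0, "size_dependent", table) == 0.2
        assert select_spacing(600.0, "size_dependent", table) == 0.5
        assert select_spacing(5000.0, "size_dependent", table) == 0.5

    def test_size_dependent_without_table_is_a_configuration_error(self):
        with pytest.raises(ValueError, match="spacing table"):
            select_spacing(10.0, "size_dependent")

    def test_table_parses_from_text(self):
        table = SpacingTable.from_text("# bins\n100 0.2\ninf 0.43\n")
        assert table.lookup(50) == 0.2 and table.lookup(1e9) == 0.43


class TestBuildGrid:
    def test_point_box_padding_and_dims(self):
        frame, _ = sphere_frame(1.5, center=(0.0, 0.0, 0.0))
        table = RadiiTable(entries={"C": 1.5})
        grid = build_grid(bounding_box(frame), 0.5, table)
        assert grid.padding == pytest.approx(2.5)
        assert grid.dims == (11, 11, 11)

    def test_doubling_spacing_roughly_halves_dims(self):
        rng = np.random.default_rng(7)
        frame = vg.MolecularFrame.from_arrays(
            ["C"] * 10, rng.uniform(0, 9, size=(10, 3))
        )
        table = RadiiTable(entries={"C": 1.7})
        box = bounding_box(frame)
        d1 = build_grid(box, 0.25, table).dims
        d2 = build_grid(box, 0.5, table).dims
        for k, (a, b) in enumerate(zip(d1, d2)):
            # exact ceiling rule: span = extent + 2·(max radius + 2·spacing)
            for h, d in ((0.25, a), (0.5, b)):
                span = box.extents[k] + 2 * (1.7 + 2 * h)
                assert d == math.ceil(span / h) + 1
            # halving approximation, slack for the spacing-dependent padding
            assert abs(b - (math.ceil((a - 1) / 2) + 1)) <= 3

    def test_point_cap_guards_against_huge_grids(self):
        frame = vg.MolecularFrame.from_arrays(
            ["C", "C"], np.array([[0.0, 0.0, 0.0], [40.0, 40.0, 40.0]])
        )
        table = RadiiTable(entries={"C": 1.7})
        with pytest.raises(GridTooLargeError, match="coarser"):
            build_grid(bounding_box(frame), 0.05, table, point_cap=10**5)


def brute_force_labels(grid, frame, radii, surface_tol):
    """Independent all-pairs transcription of the classification rule."""
    band = 2.0 * surface_tol
    aug = radii.radii_for(frame)
    labels = np.empty(grid.dims, dtype=np.int8)
    nearest = np.full(grid.dims, -1, dtype=np.int64)
    for i in range(grid.dims[0]):
        for j in range(grid.dims[1]):
            for k in range(grid.dims[2]):
                p = grid.point((i, j, k))
                best, best_atom = math.inf, -1
                for a, (pos, r) in enumerate(zip(frame.coords, aug)):
                    s = math.dist(p, pos) - r
                    if s < best:
                        best, best_atom = s, a
                if best > 0:
                    labels[i, j, k] = EXTERNAL
                elif best < -band:
                    labels[i, j, k] = INTERNAL
                else:
                    labels[i, j, k] = SURFACE
                nearest[i, j, k] = best_atom
        # nearest identity matters only where it is retained (near atoms)
    return labels, nearest


class TestClassifyGrid:
    def test_point_at_atom_center_is_internal(self):
        frame, table = sphere_frame(1.5, center=(0.0, 0.0, 0.0))
        grid = build_grid(bounding_box(frame), 0.5, table)
        cls = classify_grid(grid, frame, table)
        center_idx = tuple(int(round(-o / 0.5)) for o in grid.origin)
        assert cls.labels[center_idx] == INTERNAL

    def test_point_at_exactly_r_vdw_is_surface(self):
        # atom on-lattice, radius an exact multiple of the spacing: the
        # lattice point 4 steps along x sits at distance exactly R
        frame, _ = sphere_frame(1.0, center=(0.0, 0.0, 0.0))
        table = RadiiTable(entries={"C": 1.0})
        grid = build_grid(bounding_box(frame), 0.25, table)
        cls = classify_grid(grid, frame, table)
        center = tuple(int(round(-o / 0.25)) for o in grid.origin)
        on_surface = (center[0] + 4, center[1], center[2])
        assert cls.labels[on_surface] == SURFACE

    @given(st.integers(0, 2**31 - 1))
    def test_labels_match_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0, 3.0, size=(5, 3))
        elements = list(rng.choice(["C", "O", "H"], size=5))
        frame = vg.MolecularFrame.from_arrays(elements, coords)
        table = vg.default_radii()
        grid = build_grid(bounding_box(frame), 0.9, table)
        cls = classify_grid(grid, frame, table, surface_tol=0.45)
        ref_labels, ref_nearest = brute_force_labels(grid, frame, table, 0.45)
        np.testing.assert_array_equal(cls.labels, ref_labels)
        # nearest-atom identity must agree wherever a label is non-external
        inside = ref_labels != EXTERNAL
        np.testing.assert_array_equal(
            cls.nearest_atom[inside], ref_nearest[inside]
        )

    def test_missing_radius_propagates(self, water):
        table = RadiiTable(entries={"O": 1.52})  # no H entry
        grid = build_grid(bounding_box(water), 0.5, table)
        with pytest.raises(KeyError):
            classify_grid(grid, water, table)

    def test_count_conservation(self, water):
        table = vg.default_radii()
        grid = build_grid(bounding_box(water), 0.3, table)
        cls = classify_grid(grid, water, table)
        external = int(np.count_nonzero(cls.labels == EXTERNAL))
        assert cls.g_v + external == grid.n_points
        assert cls.g_p <= cls.g_s <= cls.g_v


def independent_correction(labels):
    """Straightforward re-implementation of the isolated-point rule, to fixity."""
    pairs = [d for d in vg.grid.OPPOSING_PAIRS]
    labels = labels.copy()
    nx, ny, nz = labels.shape
    while True:
        changed = False
        for i in range(1, nx - 1):
            for j in range(1, ny - 1):
                for k in range(1, nz - 1):
                    c = labels[i, j, k]
                    neighbors = [
                        labels[i + di, j + dj, k + dk]
                        for di in (-1, 0, 1)
                        for dj in (-1, 0, 1)
                        for dk in (-1, 0, 1)
                        if (di, dj, dk) != (0, 0, 0)
                    ]
                    if c in neighbors:
                        continue
                    for (di, dj, dk) in pairs:
                        a = labels[i + di, j + dj, k + dk]
                        if a != c and a == labels[i - di, j - dj, k - dk]:
                            labels[i, j, k] = a
                            changed = True
                            break
        if not changed:
            return labels


class TestCorrectIsolatedPoints:
    def _cls(self, labels):
        return vg.GridClassification(
            labels=labels.astype(np.int8),
            nearest_atom=np.full(labels.shape, -1, dtype=np.int32),
        )

    def test_uniform_lattice_is_a_fixed_point(self):
        labels = np.full((5, 5, 5), INTERNAL, dtype=np.int8)
        cls = correct_isolated_points(self._cls(labels))
        assert (cls.labels == INTERNAL).all()

    def test_single_misassigned_point_is_relabeled_in_one_sweep(self):
        labels = np.full((5, 5, 5), INTERNAL, dtype=np.int8)
        labels[2, 2, 2] = EXTERNAL
        cls = correct_isolated_points(self._cls(labels), max_iters=1)
        assert cls.labels[2, 2, 2] == INTERNAL

    @given(st.integers(0, 2**31 - 1))
    def test_matches_independent_reimplementation(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(
            np.array([INTERNAL, SURFACE, EXTERNAL], dtype=np.int8), size=(6, 6, 6)
        )
        cls = correct_isolated_points(self._cls(labels.copy()))
        np.testing.assert_array_equal(cls.labels, independent_correction(labels))

    @given(st.integers(0, 2**31 - 1))
    def test_idempotent_at_its_fixed_point(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(
            np.array([INTERNAL, SURFACE, EXTERNAL], dtype=np.int8), size=(6, 6, 6)
        )
        cls = correct_isolated_points(self._cls(labels))
        once = cls.labels.copy()
        correct_isolated_points(cls)
        np.testing.assert_array_equal(cls.labels, once)


class TestDescriptorFormulas:
    def test_volume_is_count_times_voxel_volume(self):
        labels = np.full((10, 10, 10), INTERNAL, dtype=np.int8)
        cls = vg.GridClassification(
            labels=labels, nearest_atom=np.zeros((10, 10, 10), np.int32)
        )
        assert compute_volume(cls, 0.43) == pytest.approx(1000 * 0.43**3)
        assert compute_volume(cls, 0.43) == pytest.approx(79.507, abs=1e-3)

    def test_empty_counts_give_zero_volume_and_floor_surface(self):
        labels = np.full((4, 4, 4), EXTERNAL, dtype=np.int8)
        cls = vg.GridClassification(
            labels=labels, nearest_atom=np.full((4, 4, 4), -1, np.int32)
        )
        assert compute_volume(cls, 0.3) == 0.0
        assert compute_surface(cls, 0.3) == pytest.approx(13.506)

    def test_surface_formula_direct_evaluation(self):
        assert vg.surface_area_from_count(100, 0.5) == pytest.approx(45.031)

    def test_sphere_volume_converges(self):
        frame, table = sphere_frame(2.0)
        v_true, _ = vg.analytic_sphere(2.0)
        res = vg.analyze_frame(frame, radii=table, spacing=0.2)
        assert res.volume == pytest.approx(v_true, rel=0.05)

    def test_sphere_raw_shell_area(self):
        frame, table = sphere_frame(2.0)
        _, s_true = vg.analytic_sphere(2.0)
        res = vg.analyze_frame(frame, radii=table, spacing=0.2)
        assert res.g_s * 0.2**2 == pytest.approx(s_true, rel=0.15)


class TestPsa:
    def test_no_polar_atoms_means_zero_psa(self, methane):
        res = vg.analyze_frame(methane, spacing=0.3)
        assert res.psa == 0.0

    def test_all_polar_means_psa_equals_surface(self, water):
        res = vg.analyze_frame(water, spacing=0.3)
        assert res.psa == pytest.approx(res.surface)
        assert res.surface > 13.506 and res.volume > 0

    def test_symmetric_bisphere_splits_evenly(self):
        table = RadiiTable(entries={"C": 1.5, "O": 1.5})
        frame = vg.MolecularFrame.from_arrays(
            ["O", "C"], np.array([[0.0137, 0.02, -0.011], [6.0137, 0.02, -0.011]])
        )
        res = vg.analyze_frame(frame, radii=table, spacing=0.2)
        assert res.g_p / res.g_s == pytest.approx(0.5, abs=0.02)
        assert res.psa == pytest.approx(res.surface * res.g_p / res.g_s)

    def test_psa_bounds_always_hold(self):
        mol = vg.generate_molecule(vg.SyntheticSpec(n_atoms=12, seed=5))
        res = vg.analyze_frame(mol, spacing=0.3)
        assert 0.0 <= res.psa <= res.surface


class TestPipeline:
    def test_repeat_runs_are_bit_identical(self, water):
        a = vg.analyze_frame(water, spacing=0.25)
        b = vg.analyze_frame(water, spacing=0.25)
        assert (a.volume, a.surface, a.psa) == (b.volume, b.surface, b.psa)
        assert (a.g_v, a.g_s, a.g_p) == (b.g_v, b.g_s, b.g_p)

    def test_lattice_shift_preserves_counts(self, water):
        h = 0.25
        a = vg.analyze_frame(water, spacing=h)
        shifted = water.translated((3 * h, 6 * h, -9 * h))
        b = vg.analyze_frame(shifted, spacing=h)
        assert (a.g_v, a.g_s, a.g_p) == (b.g_v, b.g_s, b.g_p)

    def test_settings_are_recorded(self, water):
        res = vg.analyze_frame(water, spacing=0.3)
        assert res.settings["spacing"] == 0.3
        assert res.settings["threshold_mode"] == "iso_0001"

    def test_surface_point_export_round_trip(self, water):
        keep = {}
        vg.analyze_frame(water, spacing=0.3, _keep=keep)
        pts = surface_points(keep["classification"], keep["grid"])
        assert len(pts) == keep["classification"].g_s
        (frame,) = vg.parse_xyz(vg.write_surface_xyz(pts))
        assert len(frame) == len(pts)


class TestTrajectory:
    def test_identical_frames_give_identical_results(self, water):
        frames = [
            vg.MolecularFrame(water.atoms, frame_index=i) for i in range(10)
        ]
        results = vg.analyze_trajectory(frames, spacing=0.3)
        assert len(results) == 10
        assert len({(r.volume, r.surface, r.psa) for r in results}) == 1

    def test_stretching_dimer_volume_tracks_union_monotonically(self):
        table = RadiiTable(entries={"C": 1.5})
        seps = [0.0, 1.5, 3.0, 6.0]
        frames = [
            vg.MolecularFrame.from_arrays(
                ["C", "C"],
                np.array([[0.0137, 0.02, -0.011], [0.0137 + d, 0.02, -0.011]]),
                frame_index=i,
            )
            for i, d in enumerate(seps)
        ]
        results = vg.analyze_trajectory(frames, radii=table, spacing=0.15)
        volumes = [r.volume for r in results]
        assert volumes == sorted(volumes)
        for d, r in zip(seps, results):
            assert r.volume == pytest.approx(
                vg.two_sphere_union_volume(1.5, 1.5, d), rel=0.03
            )

    def test_corrupt_frame_is_skipped_not_fatal(self, water, caplog):
        table = RadiiTable(entries={"O": 1.52, "H": 1.2})
        bad = vg.MolecularFrame.from_arrays(
            ["N"], np.array([[0.0, 0.0, 0.0]]), frame_index=5
        )  # N has no radius in this table
        frames = [
            vg.MolecularFrame(water.atoms, frame_index=i) for i in range(9)
        ] + [bad]
        with caplog.at_level(logging.ERROR, logger="vspgrid.grid"):
            results = vg.analyze_trajectory(frames, radii=table, spacing=0.3)
        assert len(results) == 9
        assert any("frame 5" in r.message for r in caplog.records)

    def test_all_frames_failing_is_a_batch_error(self):
        table = RadiiTable(entries={"C": 1.7})
        bad = vg.MolecularFrame.from_arrays(["N"], np.array([[0.0, 0.0, 0.0]]))
        with pytest.raises(RuntimeError, match="all 1 frames failed"):
            vg.analyze_trajectory([bad], radii=table, spacing=0.3)
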