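"""Shell geometry: volumes, membership, attribution, morphometry,
rigid-motion invariance and size-independence of the density statistic."""

import numpy as np
import pytest
import trimesh

from varishell.distance import MeshDistance, brute_force_unsigned
from varishell.geometry import (
    ShellConfig,
    attribute_spot_indices,
    compute_densities,
    in_shell,
    morphometry,
    shell_volume,
    signed_distance,
)
from varishell.scene import GanglionScene, SurfaceMesh, VaricositySet
from varishell.synthetic import make_sphere_fixture

SPHERE_SHELL = 4 * np.pi / 3 * (6.0**3 - 4.0**3)  # ±1 um shell of r=5 sphere


class TestShellConfig:
    def test_pitch_invariant(self):
        with pytest.raises(ValueError, match="voxel_pitch"):
            ShellConfig(half_width=1.0, voxel_pitch=0.6)

    def test_half_width_positive(self):
        with pytest.raises(ValueError, match="half_width"):
            ShellConfig(half_width=0.0)


class TestShellVolume:
    def test_sphere_closed_form(self, sphere_cell):
        v = shell_volume(sphere_cell, ShellConfig(half_width=1.0, voxel_pitch=0.25))
        assert v == pytest.approx(SPHERE_SHELL, rel=0.02)

    def test_thin_shell_limit(self, sphere_cell):
        # area x thickness for a thin shell: t = 0.2 -> ~ 4 pi 25 * 0.4
        v = shell_volume(sphere_cell, ShellConfig(half_width=0.2, voxel_pitch=0.1))
        assert v == pytest.approx(4 * np.pi * 25 * 0.4, rel=0.05)

    def test_error_shrinks_as_pitch_halves(self, sphere_cell):
        ref = shell_volume(sphere_cell, ShellConfig(half_width=1.0, voxel_pitch=0.0625))
        errs = [
            abs(shell_volume(sphere_cell, ShellConfig(half_width=1.0, voxel_pitch=p)) - ref)
            for p in (0.5, 0.25, 0.125)
        ]
        assert errs[0] > errs[1] > errs[2]

    def test_ellipsoid_against_monte_carlo(self, ellipsoid_cell, rng):
        """Voxel-count estimate vs rejection sampling with exact distances."""
        cfg = ShellConfig(half_width=1.0, voxel_pitch=0.25)
        v_vox = shell_volume(ellipsoid_cell, cfg)
        q = MeshDistance(ellipsoid_cell.mesh)
        lo = ellipsoid_cell.vertices.min(axis=0) - 1.5
        hi = ellipsoid_cell.vertices.max(axis=0) + 1.5
        n = 1_000_000
        pts = rng.uniform(lo, hi, (n, 3))
        hits = np.isfinite(q.unsigned_within(pts, 1.0))
        box = np.prod(hi - lo)
        p_hat = hits.mean()
        v_mc = box * p_hat
        se = box * np.sqrt(p_hat * (1 - p_hat) / n)
        assert abs(v_vox - v_mc) < 3 * se + 0.01 * v_mc


class TestSignedDistanceAndShell:
    @pytest.mark.parametrize(
        "point, expected",
        [((0.0, 0.0, 0.0), -5.0), ((5.0, 0.0, 0.0), 0.0), ((7.0, 0.0, 0.0), 2.0)],
    )
    def test_sphere_distances(self, sphere_cell, point, expected):
        assert signed_distance(sphere_cell, np.array(point)) == pytest.approx(
            expected, abs=0.03
        )

    @pytest.mark.parametrize(
        "x, inside_shell",
        [(5.9, True), (6.5, False), (4.2, True), (3.8, False), (6.0, True)],
    )
    def test_shell_membership(self, sphere_cell, x, inside_shell):
        assert in_shell(sphere_cell, np.array([x, 0.0, 0.0])) == inside_shell


def _ellipsoid_at(cell_id, semi, center, subdivisions=2):
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    m.apply_scale(semi)
    m.apply_translation(center)
    return SurfaceMesh.from_trimesh(cell_id, m, repair=False)


class TestAttribution:
    def test_single_cell_inside_and_outside_shell(self, sphere_cell):
        spots = VaricositySet("TH", np.array([[5.5, 0, 0], [6.5, 0, 0]]))
        out = attribute_spot_indices([sphere_cell], spots)
        assert list(out["SPH"]) == [0]

    def test_overlapping_shells_nearest_wins(self):
        a = _ellipsoid_at("A", [3, 3, 3], [0, 0, 0], subdivisions=3)
        b = _ellipsoid_at("B", [3, 3, 3], [7.2, 0, 0], subdivisions=3)
        # spot between the two surfaces: 0.35 from A's, 0.85 from B's
        spots = VaricositySet("TH", np.array([[3.35, 0.0, 0.0]]))
        out = attribute_spot_indices([a, b], spots)
        assert list(out["A"]) == [0] and list(out["B"]) == []

    def test_empty_cell_list(self):
        with pytest.raises(ValueError, match="at least one cell"):
            attribute_spot_indices([], VaricositySet("TH", np.empty((0, 3))))

    def test_matches_brute_force_on_random_scene(self, rng):
        cells = [
            _ellipsoid_at(f"C{k}", rng.uniform(2, 5, 3), rng.uniform(0, 30, 3))
            for k in range(8)
        ]
        spots = VaricositySet("TH", rng.uniform(-2, 32, (600, 3)))
        got = attribute_spot_indices(cells, spots)
        dists = np.stack(
            [
                brute_force_unsigned(np.asarray(c.mesh.triangles), spots.points)
                for c in cells
            ]
        )
        best = np.argmin(dists, axis=0)  # argmin takes first (lowest index) on ties
        want = {
            c.cell_id: set(
                np.flatnonzero((best == k) & (dists[k] <= 1.0)).tolist()
            )
            for k, c in enumerate(cells)
        }
        assert {cid: set(v.tolist()) for cid, v in got.items()} == want

    def test_conservation(self, rng):
        cells = [
            _ellipsoid_at(f"C{k}", rng.uniform(2, 4, 3), rng.uniform(0, 20, 3))
            for k in range(5)
        ]
        spots = VaricositySet("TH", rng.uniform(-2, 22, (400, 3)))
        out = attribute_spot_indices(cells, spots)
        all_idx = np.concatenate([v for v in out.values()])
        assert len(all_idx) == len(np.unique(all_idx))
        assert len(all_idx) <= len(spots)


class TestComputeDensities:
    def test_sphere_fixture_density(self):
        scene = make_sphere_fixture(radius=5.0, n_spots_in_shell=10, seed=3)
        recs = compute_densities(scene, cfg=ShellConfig(half_width=1.0, voxel_pitch=0.25))
        th = next(r for r in recs if r.marker == "TH")
        assert th.count == 10
        assert th.density == pytest.approx(10 / SPHERE_SHELL * 1000, rel=0.02)
        enk = next(r for r in recs if r.marker == "ENK")
        assert enk.count == 0 and enk.density == 0.0

    def test_no_spots_all_zero(self, sphere_cell):
        scene = GanglionScene(
            subject_id="S01",
            ganglion_id="G1",
            cells=[sphere_cell],
            varicosities={"TH": VaricositySet("TH", np.empty((0, 3)))},
            bbox=[[-7, -7, -7], [7, 7, 7]],
        )
        recs = compute_densities(scene, cfg=ShellConfig(voxel_pitch=0.5))
        assert all(r.count == 0 and r.density == 0.0 for r in recs)

    def test_counts_equal_brute_force_recount(self, small_scenes):
        scenes, _, _ = small_scenes
        scene = scenes[0]
        cfg = ShellConfig(half_width=1.0, voxel_pitch=0.5)
        recs = compute_densities(scene, cfg=cfg)
        for marker in ("TH", "ENK"):
            pts = scene.varicosities[marker].points
            dists = np.stack(
                [
                    brute_force_unsigned(np.asarray(c.mesh.triangles), pts)
                    for c in scene.cells
                ]
            )
            best = np.argmin(dists, axis=0)
            for k, c in enumerate(scene.cells):
                want = int(np.sum((best == k) & (dists[k] <= 1.0)))
                got = next(
                    r.count for r in recs if r.cell_id == c.cell_id and r.marker == marker
                )
                assert got == want


class TestMorphometry:
    def test_sphere_closed_forms(self, sphere_cell):
        m = morphometry(sphere_cell)
        assert m.surface_area == pytest.approx(4 * np.pi * 25, rel=0.01)
        assert m.volume == pytest.approx(4 / 3 * np.pi * 125, rel=0.01)
        np.testing.assert_allclose(m.centroid, 0.0, atol=1e-6)

    def test_similarity_scaling(self, ellipsoid_cell):
        m1 = morphometry(ellipsoid_cell)
        scaled = ellipsoid_cell.mesh.copy()
        scaled.apply_scale(2.0)
        m2 = morphometry(SurfaceMesh("S2", scaled))
        assert m2.surface_area == pytest.approx(4 * m1.surface_area, rel=1e-9)
        assert m2.volume == pytest.approx(8 * m1.volume, rel=1e-9)

    def test_convex_hull_volume_oracle(self, rng):
        from scipy.spatial import ConvexHull

        pts = rng.uniform(-5, 5, (60, 3))
        hull_mesh = trimesh.convex.convex_hull(pts)
        cell = SurfaceMesh.from_trimesh("H", hull_mesh)
        hull = ConvexHull(pts)
        assert morphometry(cell).volume == pytest.approx(hull.volume, rel=1e-9)
        assert morphometry(cell).surface_area == pytest.approx(hull.area, rel=1e-9)


class TestRigidMotionInvariance:
    def test_counts_volumes_densities_invariant(self, rng):
        cell = _ellipsoid_at("E", [7.0, 5.0, 3.5], [0, 0, 0], subdivisions=3)
        spots = rng.uniform(-9, 9, (400, 3))
        cfg = ShellConfig(half_width=1.0, voxel_pitch=0.25)
        v0 = shell_volume(cell, cfg)
        att0 = attribute_spot_indices([cell], VaricositySet("TH", spots), cfg)

        theta = 0.83
        rot = trimesh.transformations.rotation_matrix(theta, [0.3, 1.0, -0.2])
        shift = np.array([13.7, -4.1, 8.9])
        moved = cell.mesh.copy()
        moved.apply_transform(rot)
        moved.apply_translation(shift)
        cell2 = SurfaceMesh.from_trimesh("E", moved, repair=False)
        spots2 = spots @ rot[:3, :3].T + shift
        v1 = shell_volume(cell2, cfg)
        att1 = attribute_spot_indices([cell2], VaricositySet("TH", spots2), cfg)

        assert v1 == pytest.approx(v0, rel=1e-6)
        assert set(att0["E"].tolist()) == set(att1["E"].tolist())


def test_density_independent_of_cell_size(rng):
    """Sampling spots at one true density around spheres of different size
    yields the same density estimate (up to sampling error)."""
    true_density = 200.0  # per 1,000 um^3, large to keep relative noise low
    cfg = ShellConfig(half_width=1.0, voxel_pitch=0.25)
    for radius in (5.0, 10.0):
        scene = make_sphere_fixture(radius=radius, n_spots_in_shell=1, seed=7)
        cell = scene.cells[0]
        vol = shell_volume(cell, cfg)
        n = rng.poisson(true_density * vol / 1000.0)
        from varishell.synthetic import _sample_in_shell

        pts = _sample_in_shell(cell, n, 1.0, rng)
        est = 1000.0 * len(pts) / vol
        se = 1000.0 * np.sqrt(true_density * vol / 1000.0) / vol
        assert abs(est - true_density) < 4 * se
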