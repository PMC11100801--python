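"""Skeletonization, Sholl ring-intersection counting, volume measures.

The Sholl implementation is cross-checked against an independent
brute-force oracle that bins every skeleton pixel by its distance from
the soma and clusters adjacent pixels with union-find — no scipy/skimage
involved on the oracle path.
"""

import numpy as np
import pytest

from mgquant.io_core import BinaryMask
from mgquant.morphometry import cell_volume, skeletonize_cell, sholl_profile
from mgquant.synthetic import generate_sholl_phantom


def brute_force_sholl(grid, center_px, radii_px, half_band_px=0.75):
    """Distance-bin every skeleton pixel and count 8-adjacent clusters
    per ring with a pure-python union-find."""
    pix = [(y, x) for y, x in np.argwhere(grid)]
    counts = []
    cy, cx = center_px
    for r in radii_px:
        on_ring = [
            (y, x)
            for (y, x) in pix
            if abs(np.hypot(y - cy, x - cx) - r) <= half_band_px
        ]
        parent = {p: p for p in on_ring}

        def find(p):
            while parent[p] != p:
                parent[p] = parent[parent[p]]
                p = parent[p]
            return p

        members = set(on_ring)
        for (y, x) in on_ring:
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    q = (y + dy, x + dx)
                    if q != (y, x) and q in members:
                        parent[find((y, x))] = find(q)
        counts.append(len({find(p) for p in on_ring}))
    return counts


def _random_walk_skeleton(seed, size=81, n_arms=3, steps=30):
    """A soma-centred bundle of random-walk processes, 1 px wide."""
    rng = np.random.default_rng(seed)
    grid = np.zeros((size, size), dtype=bool)
    c = size // 2
    for _ in range(n_arms):
        y, x = float(c), float(c)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(steps):
            ang += rng.normal(0, 0.35)
            y += np.sin(ang)
            x += np.cos(ang)
            iy, ix = int(round(y)), int(round(x))
            if not (0 <= iy < size and 0 <= ix < size):
                break
            grid[iy, ix] = True
    grid[c, c] = True
    return grid


class TestSkeletonize:
    def test_one_pixel_line_is_its_own_skeleton(self):
        grid = np.zeros((1, 9, 9), dtype=bool)
        grid[0, 4, 1:8] = True
        skel = skeletonize_cell(BinaryMask(grid, (1, 1, 1)))
        assert np.array_equal(skel.data, grid)

    def test_filled_disc_collapses_to_central_cluster(self):
        yy, xx = np.mgrid[0:41, 0:41]
        grid = ((yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2)[None]
        skel = skeletonize_cell(BinaryMask(grid, (1, 1, 1)))
        assert 0 < skel.voxel_count <= 30
        pts = np.argwhere(skel.data[0])
        assert np.all(np.hypot(pts[:, 0] - 20, pts[:, 1] - 20) <= 6)

    def test_skeleton_is_subset_of_mask(self, rng):
        grid = rng.uniform(size=(30, 30)) > 0.6
        grid[10:20, 10:20] = True
        skel = skeletonize_cell(BinaryMask(grid[None], (1, 1, 1)))
        assert not (skel.data & ~grid[None]).any()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            skeletonize_cell(BinaryMask(np.zeros((1, 5, 5), bool), (1, 1, 1)))


class TestShollProfile:
    @pytest.mark.parametrize("k", range(1, 9))
    def test_star_phantom_counts_exactly_k(self, k):
        vol, truth = generate_sholl_phantom(
            k, 25.0, 0.25, soma_radius_um=2.5, seed=k
        )
        skel = skeletonize_cell(BinaryMask(vol.data[0] > 0, vol.voxel_size))
        center = tuple(truth.soma_centers_um[0][1:])
        prof = sholl_profile(
            skel, center, ring_spacing_um=1.0, start_radius_um=4.0, max_radius_um=23.0
        )
        assert np.all(prof.intersections == k)

    def test_zero_beyond_arm_tips(self):
        vol, truth = generate_sholl_phantom(5, 12.0, 0.25, soma_radius_um=2.0)
        skel = BinaryMask(vol.data[0] > 0, vol.voxel_size)
        prof = sholl_profile(
            skel,
            tuple(truth.soma_centers_um[0][1:]),
            ring_spacing_um=1.0,
            start_radius_um=14.0,
            max_radius_um=17.0,
        )
        assert np.all(prof.intersections == 0)

    def test_matches_brute_force_oracle_on_random_phantoms(self):
        for seed in range(20):
            grid = _random_walk_skeleton(seed)
            c = grid.shape[0] // 2
            radii = np.arange(3.0, 25.0, 2.0)
            prof = sholl_profile(
                BinaryMask(grid[None], (1, 1, 1)),
                (float(c), float(c)),
                ring_spacing_um=2.0,
                start_radius_um=3.0,
                max_radius_um=24.0,
            )
            oracle = brute_force_sholl(grid, (c, c), radii)
            assert prof.intersections.tolist() == oracle, f"seed {seed}"

    def test_translation_invariance(self):
        grid = _random_walk_skeleton(99, size=61)
        shifted = np.roll(np.roll(grid, 7, axis=0), -5, axis=1)
        # roll keeps content intact here: the walk stays well inside
        kw = dict(ring_spacing_um=2.0, start_radius_um=2.0, max_radius_um=20.0)
        p1 = sholl_profile(BinaryMask(grid[None], (1, 1, 1)), (30.0, 30.0), **kw)
        p2 = sholl_profile(BinaryMask(shifted[None], (1, 1, 1)), (37.0, 25.0), **kw)
        assert np.array_equal(p1.intersections, p2.intersections)

    def test_soma_centre_outside_image_rejected(self):
        skel = BinaryMask(np.ones((1, 10, 10), bool), (1, 1, 1))
        with pytest.raises(ValueError, match="outside"):
            sholl_profile(skel, (50.0, 5.0))

    def test_clipped_rings_are_flagged_not_silent(self):
        skel = BinaryMask(np.ones((1, 21, 21), bool), (1, 1, 1))
        prof = sholl_profile(skel, (10.0, 10.0), 2.0, max_radius_um=16.0)
        assert prof.clipped[-1]
        assert not prof.clipped[0]


class TestCellVolume:
    def test_voxel_count_times_voxel_volume(self):
        grid = np.zeros((10, 10, 10), dtype=bool)
        grid.ravel()[:1000] = True
        assert cell_volume(BinaryMask(grid, (0.33, 0.1, 0.1))) == pytest.approx(3.3)

    def test_empty_mask_is_zero(self):
        assert cell_volume(BinaryMask(np.zeros((1, 5, 5), bool), (1, 1, 1))) == 0.0

    def test_digitized_sphere_within_5pct_of_analytic(self):
        r, dx = 5.0, 0.1
        n = int(2 * r / dx) + 5
        zz, yy, xx = np.mgrid[0:n, 0:n, 0:n] * dx
        c = n * dx / 2
        grid = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= r**2
        vol = cell_volume(BinaryMask(grid, (dx, dx, dx)))
        assert vol == pytest.approx(4 / 3 * np.pi * r**3, rel=0.05)
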