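from collections import deque

import numpy as np
import pytest

from nanotex import (
    HeightMap,
    connectivity_landmarks,
    make_fixture,
    minkowski_curves,
    volume_symmetry_score,
)
from nanotex.minkowski import binary_functionals


def floodfill_components(mask, eight_connected):
    """Independent BFS flood-fill component counter."""
    mask = np.asarray(mask, dtype=bool)
    rows, cols = mask.shape
    seen = np.zeros_like(mask)
    if eight_connected:
        moves = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        moves = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for sy in range(rows):
        for sx in range(cols):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            count += 1
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            while q:
                y, x = q.popleft()
                for dy, dx in moves:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < rows and 0 <= nx < cols and mask[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        q.append((ny, nx))
    return count


def pair_count_oracle(white):
    """Count 4-neighbor white/black pairs by explicit loops."""
    white = np.asarray(white, dtype=bool)
    rows, cols = white.shape
    pairs = 0
    for y in range(rows):
        for x in range(cols):
            if x + 1 < cols and white[y, x] != white[y, x + 1]:
                pairs += 1
            if y + 1 < rows and white[y, x] != white[y + 1, x]:
                pairs += 1
    return pairs


class TestBinaryFunctionals:
    def test_step_at_mid_threshold(self):
        step = make_fixture("step", 512, 4.0, h0=0.0, h1=100.0)
        curves = minkowski_curves(step, 101)
        n = step.n_points
        i = 50  # z = 50 nm
        assert curves.V[i] == 0.5
        assert curves.boundary_count[i] == step.rows  # one column of pairs
        assert curves.chi[i] == 0.0  # two half-planes: 1 white - 1 black

    def test_disk_field_connectivity(self):
        dk = make_fixture("disk_field", 256, 4.0, k=5, r=10, h0=0.0, h1=100.0)
        curves = minkowski_curves(dk, 101)
        n = dk.n_points
        i = 50
        assert curves.white_components[i] == 5
        assert curves.black_components[i] == 1
        assert curves.chi[i] == pytest.approx(4 / n)
        disk_area = (dk.heights == 100.0).sum()
        assert curves.V[i] == pytest.approx(disk_area / n)

    def test_inverted_disks_negative_connectivity(self):
        dk = make_fixture("disk_field", 256, 4.0, k=5, r=10, h0=0.0, h1=100.0)
        inv = dk.copy_with(100.0 - dk.heights)  # 5 pits in a high plain
        curves = minkowski_curves(inv, 101)
        i = 50
        assert curves.chi[i] == pytest.approx((1 - 5) / inv.n_points)
        assert curves.chi[i] < 0

    def test_matches_floodfill_oracle_on_random_images(self, rng):
        for _ in range(15):
            white = rng.random((32, 32)) > rng.uniform(0.2, 0.8)
            v, pairs, cw, cb = binary_functionals(white)
            assert cw == floodfill_components(white, eight_connected=True)
            assert cb == floodfill_components(~white, eight_connected=False)
            assert pairs == pair_count_oracle(white)
            assert v == white.mean()

    def test_complement_duality_interior_images(self, rng):
        """On black-framed images our chi equals the 8-connected Euler
        number of white minus 1, which by Jordan duality is exactly the
        negated 4-connected Euler number of the black phase."""
        from skimage.measure import euler_number

        for _ in range(10):
            inner = rng.random((24, 24)) > rng.uniform(0.3, 0.7)
            white = np.zeros((26, 26), dtype=bool)
            white[1:-1, 1:-1] = inner
            _, _, cw, cb = binary_functionals(white)
            chi_counts = cw - cb
            assert chi_counts == euler_number(white, connectivity=2) - 1
            assert chi_counts == -euler_number(~white, connectivity=1)


class TestCurves:
    def test_volume_monotone_with_exact_endpoints(self, rng):
        for _ in range(10):
            z = rng.normal(50, 20, (48, 48))
            curves = minkowski_curves(HeightMap(z, 4.0, 4.0), 64)
            assert curves.V[0] == 1.0
            assert np.all(np.diff(curves.V) <= 0)
            assert curves.S[0] == 0.0 and curves.chi[0] == 0.0
            # above the max, V would be exactly 0; at the max only the
            # argmax pixels remain
            assert curves.V[-1] == (z >= z.max()).mean()

    def test_constant_surface_degenerate(self):
        flat = HeightMap(np.full((16, 16), 5.0), 4.0, 4.0)
        curves = minkowski_curves(flat, 16)
        assert np.all(curves.V == 1.0)
        assert np.all(curves.S == 0.0)
        assert np.all(curves.chi == 0.0)

    def test_boundary_zero_at_extremes_peaks_between(self, gaussian_map):
        curves = minkowski_curves(gaussian_map, 128)
        assert curves.S[0] == 0.0
        assert curves.S[-1] <= 4 / gaussian_map.n_points
        assert curves.S.max() > 0.5  # rough mid-threshold boundary density


class TestLandmarks:
    def test_gaussian_half_volume_at_mean(self, gaussian_map):
        curves = minkowski_curves(gaussian_map, 256)
        lm = connectivity_landmarks(curves)
        step = curves.thresholds[1] - curves.thresholds[0]
        assert lm.z_half_volume == pytest.approx(50.0, abs=max(0.5 * step, 0.3))

    def test_disk_field_max_chi_between_levels(self):
        dk = make_fixture("disk_field", 256, 4.0, k=5, r=10, h0=0.0, h1=100.0)
        lm = connectivity_landmarks(minkowski_curves(dk, 101))
        assert lm.defined
        assert 0.0 < lm.z_max_chi < 100.0

    def test_step_chi_landmarks_undefined(self):
        step = make_fixture("step", 128, 4.0, h0=0.0, h1=100.0)
        lm = connectivity_landmarks(minkowski_curves(step, 64))
        assert not lm.defined
        assert lm.z_min_chi is None and lm.z_max_chi is None
        assert lm.z_half_volume is not None  # V still crosses 0.5

    def test_vanishing_threshold_after_max(self, gaussian_map):
        curves = minkowski_curves(gaussian_map, 256)
        lm = connectivity_landmarks(curves, chi_tolerance=2 / gaussian_map.n_points)
        if lm.z_chi_vanishing is not None:
            assert lm.z_chi_vanishing > lm.z_max_chi


class TestVolumeSymmetry:
    def test_analytic_point_symmetric_profile_scores_one(self):
        # odd linear ramp: V(z) is exactly linear -> point symmetric
        n = 64
        ramp = np.tile(np.linspace(0.0, 100.0, n), (n, 1))
        curves = minkowski_curves(HeightMap(ramp, 4.0, 4.0), 256)
        assert volume_symmetry_score(curves) >= 0.98

    def test_gaussian_scores_high(self, gaussian_map):
        curves = minkowski_curves(gaussian_map, 256)
        assert volume_symmetry_score(curves) >= 0.95

    def test_particle_loading_lowers_symmetry(self):
        from nanotex import ParticleFieldSpec, SceneSpec, deposit_particles, generate_fbm_surface

        spec = SceneSpec(size_px=256, hurst=0.7, rms_target=10.0, seed=5)
        bare = generate_fbm_surface(spec)
        heavy = deposit_particles(
            bare, ParticleFieldSpec(count=25, radius_mean=80.0, radius_sd=20.0, height_scale=0.8), seed=5
        )
        s_bare = volume_symmetry_score(minkowski_curves(bare))
        s_heavy = volume_symmetry_score(minkowski_curves(heavy))
        assert s_heavy < s_bare
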