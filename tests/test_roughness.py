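import math

import numpy as np
import pytest

from nanotex import (
    HeightMap,
    height_pdf,
    make_fixture,
    roughness_report,
    unimodality_check,
)
from conftest import random_heightmap


def loop_roughness_oracle(z):
    """Independent loop-based evaluation of the amplitude formulas."""
    flat = [float(v) for row in z for v in row]
    n = len(flat)
    zbar = sum(abs(v) for v in flat) / n
    ra = sum(abs(v - zbar) for v in flat) / n
    rq = math.sqrt(sum((v - zbar) ** 2 for v in flat) / n)
    rt = abs(max(flat) - min(flat))
    rmvd = abs(min(v - zbar for v in flat))
    rmph = max(v - zbar for v in flat)
    rsk = sum(abs(v - zbar) ** 3 for v in flat) / (n * rq**3) if rq > 0 else None
    rku = sum(abs(v - zbar) ** 4 for v in flat) / (n * rq**4) if rq > 0 else None
    return dict(zbar=zbar, ra=ra, rq=rq, rt=rt, rmvd=rmvd, rmph=rmph, rsk=rsk, rku=rku)


class TestAmplitudeStatistics:
    def test_hand_computed_two_by_two(self):
        hm = HeightMap(np.array([[1.0, 2.0], [3.0, 4.0]]), 1.0, 1.0)
        rep = roughness_report(hm, bins=4)
        assert rep.mean_abs_height == pytest.approx(2.5)
        assert rep.ra == pytest.approx(1.0)
        assert rep.rq == pytest.approx(math.sqrt(1.25))
        assert rep.rt == pytest.approx(3.0)
        assert rep.rmvd == pytest.approx(1.5)
        assert rep.rmph == pytest.approx(1.5)

    def test_constant_surface(self):
        hm = HeightMap(np.full((8, 8), 3.0), 1.0, 1.0)
        rep = roughness_report(hm)
        assert rep.ra == rep.rq == rep.rt == 0.0
        assert rep.mean_abs_height == 3.0
        assert not rep.moments_defined
        assert rep.rsk_abs is None and rep.rku_signed is None

    def test_negative_constant_follows_absolute_mean_reference(self):
        # the reference height is mean(|Z|), so an all-negative constant
        # sits 2|c| below it: the formulas are applied verbatim, and the
        # zero-roughness identity holds only for non-negative (zero-
        # referenced) maps
        rep = roughness_report(HeightMap(np.full((8, 8), -3.0), 1.0, 1.0))
        assert rep.mean_abs_height == 3.0
        assert rep.ra == rep.rq == 6.0
        assert rep.rt == 0.0

    def test_gaussian_moments(self, gaussian_map):
        rep = roughness_report(gaussian_map)
        assert rep.rq == pytest.approx(10.0, abs=0.5)
        assert rep.rsk_signed == pytest.approx(0.0, abs=0.05)
        assert rep.rku_signed == pytest.approx(3.0, abs=0.1)
        # absolute-moment skewness of a Gaussian: E|X|^3 / sigma^3
        assert rep.rsk_abs == pytest.approx(2 * math.sqrt(2 / math.pi), abs=0.05)

    def test_agrees_with_loop_oracle(self, rng):
        for _ in range(20):
            hm = random_heightmap(rng)
            rep = roughness_report(hm, bins=16)
            exp = loop_roughness_oracle(hm.heights)
            for got, want in [
                (rep.mean_abs_height, exp["zbar"]),
                (rep.ra, exp["ra"]),
                (rep.rq, exp["rq"]),
                (rep.rt, exp["rt"]),
                (rep.rmvd, exp["rmvd"]),
                (rep.rmph, exp["rmph"]),
                (rep.rsk_abs, exp["rsk"]),
                (rep.rku_abs, exp["rku"]),
            ]:
                assert got == pytest.approx(want, rel=1e-10)

    def test_order_and_decomposition_invariants(self, rng):
        for _ in range(30):
            rep = roughness_report(random_heightmap(rng))
            assert rep.rq >= rep.ra >= 0.0
            assert rep.rt == pytest.approx(rep.rmvd + rep.rmph, rel=1e-12)

    def test_translation_moves_only_mean(self, rng):
        hm = random_heightmap(rng, rows=32, cols=32)
        shifted = hm.copy_with(hm.heights + 50.0)
        a, b = roughness_report(hm), roughness_report(shifted)
        assert b.mean_abs_height == pytest.approx(a.mean_abs_height + 50.0, rel=1e-9)
        assert b.ra == pytest.approx(a.ra, rel=1e-9)
        assert b.rq == pytest.approx(a.rq, rel=1e-9)
        assert b.rt == pytest.approx(a.rt, rel=1e-9)
        assert b.rsk_abs == pytest.approx(a.rsk_abs, rel=1e-9)
        assert b.rku_abs == pytest.approx(a.rku_abs, rel=1e-9)


class TestHeightPDF:
    def test_uniform_density(self, rng):
        z = rng.uniform(0.0, 100.0, (512, 512))
        z.flat[0], z.flat[1] = 0.0, 100.0  # pin the range
        pdf = height_pdf(HeightMap(z, 1.0, 1.0), bins=10)
        np.testing.assert_allclose(pdf.density, 0.01, rtol=0.05)

    def test_normalization(self, rng):
        for _ in range(10):
            pdf = height_pdf(random_heightmap(rng), bins=32)
            assert np.sum(pdf.density * np.diff(pdf.bin_edges)) == pytest.approx(1.0)

    def test_step_fixture_bimodal_mode_is_taller_plateau(self):
        step = make_fixture("step", 64, 4.0, h0=0.0, h1=100.0)
        z = step.heights.copy()
        z[:, 24:] = 100.0  # make the high plateau larger
        pdf = height_pdf(HeightMap(z, 4.0, 4.0), bins=10)
        occupied = pdf.density > 0
        assert occupied.sum() == 2
        assert pdf.mode() > 50.0

    def test_pdf_median_within_one_bin_of_sample_median(self, rng):
        for _ in range(10):
            hm = random_heightmap(rng, rows=24, cols=24)
            pdf = height_pdf(hm, bins=32)
            assert abs(pdf.median() - np.median(hm.heights)) <= pdf.bin_width

    def test_constant_surface_single_bin(self):
        pdf = height_pdf(HeightMap(np.full((4, 4), 7.0), 1.0, 1.0), bins=16)
        assert pdf.n_bins == 1
        assert np.sum(pdf.density * np.diff(pdf.bin_edges)) == pytest.approx(1.0)
        assert pdf.mode() == 7.0


class TestUnimodality:
    def test_gaussian_is_unimodal(self, gaussian_map):
        rep = roughness_report(gaussian_map)
        pdf = height_pdf(gaussian_map, bins=256)
        assert bool(unimodality_check(pdf, rep))

    def test_equal_step_is_bimodal(self):
        step = make_fixture("step", 128, 4.0, h0=0.0, h1=100.0)
        rep = roughness_report(step, bins=64)
        pdf = height_pdf(step, bins=64)
        res = unimodality_check(pdf, rep)
        assert not res.unimodal
        assert res.n_local_maxima >= 2

    def test_default_particle_scenes_mostly_unimodal(self):
        from nanotex import ParticleFieldSpec, SceneSpec, generate_fbm_surface

        passed = 0
        for seed in range(10):
            m = generate_fbm_surface(SceneSpec(seed=seed, particles=ParticleFieldSpec()))
            zr = m.copy_with(m.heights - m.heights.min())
            rep = roughness_report(zr)
            pdf = height_pdf(zr, 256)
            passed += bool(unimodality_check(pdf, rep))
        assert passed >= 8
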