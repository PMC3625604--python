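"""Region growing, Chan-Vese, the TLS speed law, and the automatic pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from tlseg.errors import ParameterError, SeedRejectedError
from tlseg.levelset import LevelSetField, init_box_levelset
from tlseg.phantoms import PhantomConfig, make_phantom
from tlseg.segmenters import (
    CVParams,
    RGTParams,
    TLSParams,
    boundary_map,
    chan_vese,
    gac_speed,
    region_grow,
    segment_rgt_auto,
    segment_tls,
    tls_speed,
)
from tlseg.volumes import Volume


@pytest.fixture(scope="module")
def clean_phantom():
    cfg = PhantomConfig(
        shape=(40, 40, 40),
        tube_center_yz=(20.0, 14.0),
        tube_radius=3.0,
        sac_center=(20.0, 20.0, 22.0),
        sac_radius=6.0,
        noise_sd=0.0,
        blur_sd=0.0,
    )
    return make_phantom(cfg)


@pytest.fixture(scope="module")
def clean_tls_run(clean_phantom):
    volume, _ = clean_phantom
    return segment_tls(volume)


class TestRegionGrow:
    def test_saturated_growth_fills_volume(self, rng):
        v = Volume(rng.uniform(100, 200, (5, 5, 5)))
        m = region_grow(v, RGTParams(seed=(2, 2, 2), T1=50, T2=250))
        assert m.voxel_count == 125

    def test_growth_stays_in_seed_component(self):
        data = np.full((9, 5, 5), 0.0)
        data[:4] = 150.0   # blob A
        data[5:] = 150.0   # blob B, separated by an out-of-range wall
        v = Volume(data)
        m = region_grow(v, RGTParams(seed=(1, 2, 2), T1=100, T2=200))
        assert m.data[:4].all() and not m.data[4:].any()

    def test_out_of_range_seed_rejected(self):
        v = Volume(np.full((5, 5, 5), 300.0))
        with pytest.raises(SeedRejectedError):
            region_grow(v, RGTParams(seed=(2, 2, 2), T1=100, T2=200))

    def test_param_validation(self):
        v = Volume(np.zeros((5, 5, 5)))
        with pytest.raises(ParameterError):
            RGTParams(seed=(0, 0, 0), T1=10, T2=5)
        with pytest.raises(ParameterError):
            RGTParams(seed=(0, 0, 0), T1=0, T2=1, connectivity=18)
        with pytest.raises(ParameterError):
            region_grow(v, RGTParams(seed=(9, 0, 0), T1=-1, T2=1))

    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_connectivity_matters_on_diagonal_touch(self, connectivity):
        data = np.zeros((4, 4, 4))
        data[0, 0, 0] = data[1, 1, 1] = 150.0
        v = Volume(data)
        m = region_grow(
            v, RGTParams(seed=(0, 0, 0), T1=100, T2=200,
                         connectivity=connectivity)
        )
        assert m.voxel_count == (2 if connectivity == 26 else 1)


class TestChanVese:
    def test_two_constant_image_recovered_exactly(self):
        n = 24
        ax = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        region = (x**2 / 25 + y**2 / 49 + z**2 / 16) <= 1.0
        v = Volume(np.where(region, 200.0, 100.0))
        mask, _ = chan_vese(v, init_box_levelset(v.data.shape, 2))
        np.testing.assert_array_equal(mask.data, region)

    def test_constant_image_without_area_term_does_not_move(self):
        v = Volume(np.full((16, 16, 16), 150.0))
        phi0 = init_box_levelset(v.data.shape, 4)
        mask, _ = chan_vese(v, phi0, CVParams(beta=0.0, n_iter=40))
        np.testing.assert_array_equal(mask.data, phi0.phi < 0)

    def test_intensity_swap_gives_complementary_mask(self):
        n = 24
        ax = np.arange(n) - (n - 1) / 2
        x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
        region = x**2 + y**2 + z**2 <= 36.0
        bright_inside = Volume(np.where(region, 200.0, 100.0))
        bright_outside = Volume(np.where(region, 100.0, 200.0))
        phi0 = init_box_levelset((n, n, n), 2)
        m1, _ = chan_vese(bright_inside, phi0)
        m2, _ = chan_vese(bright_outside, LevelSetField(-phi0.phi))
        np.testing.assert_array_equal(m2.data, ~m1.data)


class TestBoundaryMap:
    def test_constant_volume_gives_unity(self):
        g = boundary_map(Volume(np.full((8, 8, 8), 42.0)), c=0.5)
        np.testing.assert_allclose(g, 1.0)

    def test_known_gradient_value(self):
        # I = x + y has |grad I|^2 = 2 away from the faces
        x, y, _ = np.meshgrid(*[np.arange(10.0)] * 3, indexing="ij")
        g = boundary_map(Volume(x + y), c=0.5, smooth_sigma=0.0)
        np.testing.assert_allclose(g[2:-2, 2:-2, 2:-2], 0.5, atol=1e-12)

    def test_monotonically_decreasing_in_c(self, rng):
        v = Volume(rng.normal(100, 20, (10, 10, 10)))
        g1 = boundary_map(v, c=0.3)
        g2 = boundary_map(v, c=0.8)
        assert (g2 <= g1 + 1e-15).all()
        assert (g1 > 0).all() and (g1 <= 1).all()

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ParameterError):
            boundary_map(Volume(np.zeros((5, 5, 5))), c=0.0)


class TestTlsSpeed:
    def test_zero_where_intensity_equals_threshold(self):
        z = np.broadcast_to(np.arange(12.0), (12, 12, 12)).copy()
        ls = LevelSetField(z - 5.5)  # planar interface
        v = Volume(np.full((12, 12, 12), 150.0))
        g = np.ones((12, 12, 12))
        f = tls_speed(v, ls, T=150.0, g=g, p=TLSParams())
        assert np.abs(f.total[2:-2, 2:-2, 2:-2]).max() < 1e-9

    def test_planar_interface_constant_g_reduces_to_alpha(self):
        z = np.broadcast_to(np.arange(12.0), (12, 12, 12)).copy()
        ls = LevelSetField(z - 5.5)
        v = Volume(np.full((12, 12, 12), 151.0))
        g = np.ones((12, 12, 12))
        f = tls_speed(v, ls, T=150.0, g=g, p=TLSParams(alpha=10.0))
        np.testing.assert_allclose(f.total[2:-2, 2:-2, 2:-2], 10.0, atol=1e-9)

    def test_beta_zero_reduces_to_threshold_sign_rule(self, rng):
        v = Volume(rng.normal(150, 40, (14, 14, 14)))
        ls = init_box_levelset(v.data.shape, 3)
        g = boundary_map(v, 0.5)
        f = tls_speed(v, ls, T=150.0, g=g, p=TLSParams(beta=0.0))
        np.testing.assert_array_equal(np.sign(f.total), np.sign(v.data - 150.0))

    def test_region_term_plus_gac_term_decomposition(self, rng):
        v = Volume(rng.normal(150, 40, (14, 14, 14)))
        ls = init_box_levelset(v.data.shape, 3)
        p = TLSParams()
        g = boundary_map(v, p.c)
        f = tls_speed(v, ls, T=140.0, g=g, p=p)
        gac = gac_speed(ls, g, p.beta)
        np.testing.assert_allclose(
            f.total - p.alpha * (v.data - 140.0), gac.total, atol=1e-12
        )


class TestSegmentTls:
    def test_clean_phantom_recovered_up_to_surface_band(self, clean_phantom,
                                                        clean_tls_run):
        _, gt = clean_phantom
        mask, est = clean_tls_run
        assert est.converged
        mismatch = mask.data ^ gt.data
        # any disagreement lies within one voxel of the truth boundary
        surface_band = ndimage.binary_dilation(gt.data) & ~ndimage.binary_erosion(
            gt.data
        )
        assert not (mismatch & ~surface_band).any()

    def test_standard_phantom_quality(self, suite_result):
        row = suite_result.table.query(
            "case == 'straight-sac' and method == 'tls'"
        ).iloc[0]
        assert row.JM >= 90.0
        assert row.VD <= 10.0

    def test_deterministic(self, clean_phantom, clean_tls_run):
        volume, _ = clean_phantom
        m1, e1 = clean_tls_run
        m2, e2 = segment_tls(volume)
        np.testing.assert_array_equal(m1.data, m2.data)
        assert e1.history == e2.history

    def test_param_validation(self):
        with pytest.raises(ParameterError):
            TLSParams(alpha=0.0)
        with pytest.raises(ParameterError):
            TLSParams(c=-0.1)
        with pytest.raises(ParameterError):
            TLSParams(beta=-1.0)


class TestSegmentRgtAuto:
    def test_equals_region_grow_with_tls_threshold(self, clean_phantom,
                                                   clean_tls_run):
        volume, _ = clean_phantom
        _, est = clean_tls_run
        seed = (20, 20, 22)
        auto = segment_rgt_auto(volume, seed, est.T)
        manual = region_grow(
            volume,
            RGTParams(seed=seed, T1=est.T, T2=float(volume.data.max())),
        )
        np.testing.assert_array_equal(auto.data, manual.data)

    def test_rgt_and_tls_differ_only_in_surface_band(self, clean_phantom,
                                                     clean_tls_run):
        volume, gt = clean_phantom
        tls_mask, est = clean_tls_run
        rgt_mask = segment_rgt_auto(volume, (20, 20, 22), est.T)
        diff = tls_mask.data ^ rgt_mask.data
        band = ndimage.binary_dilation(gt.data) & ~ndimage.binary_erosion(gt.data)
        assert not (diff & ~band).any()

    def test_threshold_above_maximum_rejected(self, clean_phantom):
        volume, _ = clean_phantom
        with pytest.raises(SeedRejectedError):
            segment_rgt_auto(volume, (20, 20, 22), volume.data.max() + 1)
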