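"""Synthetic vessel-plus-aneurysm phantoms with exact ground truth.

Contrast-enhanced CT angiography shows the vessel lumen as a bright,
roughly homogeneous structure (a few hundred HU) against darker soft
tissue.  The generator emulates exactly the features the segmentation
methods rely on:

* geometry — a tubular parent artery (straight or curved), a saccular
  aneurysm sphere attached to it, and optionally a small bleb bulging from
  the sac;
* intensity — a two-level image (I_bg outside, I_fg inside the lumen);
* partial-volume effect — Gaussian blur of the continuous indicator before
  noise, so boundary voxels take intermediate intensities;
* noise — additive white Gaussian noise.

The ground-truth mask is the voxelisation of the analytic solid (a voxel is
foreground iff its centre is inside), so segmentation quality can be
measured exactly.  Generation is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ParameterError
from .volumes import Mask, Volume


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and intensity model of one phantom.

    The tube runs along the x axis (optionally bent into a circular arc in
    the x-z plane with sagitta ``tube_bend``); the sac is a sphere, the
    optional bleb a smaller sphere protruding from the sac surface.
    Intensities are HU-scale: defaults I_fg=200, I_bg=100 with noise_sd=10
    and blur_sd=0.8 voxels give a contrast-CTA-like separation that is not
    trivially separable after blurring.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    tube_radius: float = 4.0
    tube_center_yz: tuple[float, float] = (32.0, 24.0)
    tube_bend: float = 0.0  # arc sagitta in voxels; 0 = straight
    sac_center: tuple[float, float, float] | None = (32.0, 32.0, 34.0)
    sac_radius: float = 9.0
    bleb: tuple[tuple[float, float, float], float] | None = None
    I_fg: float = 200.0
    I_bg: float = 100.0
    noise_sd: float = 10.0
    blur_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.I_fg <= self.I_bg:
            raise ParameterError("I_fg must exceed I_bg")
        if self.tube_radius < 0 or self.sac_radius <= 0:
            raise ParameterError("radii must be positive (tube_radius 0 omits the tube)")
        if self.tube_radius == 0 and self.sac_center is None:
            raise ParameterError("phantom needs a tube or a sac")
        if self.sac_center is not None:
            lo = [c - self.sac_radius for c in self.sac_center]
            hi = [c + self.sac_radius for c in self.sac_center]
            if any(a < 0 for a in lo) or any(
                b > n - 1 for b, n in zip(hi, self.shape)
            ):
                raise ParameterError("sac does not fit inside the grid")


def _tube_indicator(cfg: PhantomConfig, grids: list[np.ndarray]) -> np.ndarray:
    """Voxels within tube_radius of the (possibly bent) centreline."""
    nx = cfg.shape[0]
    y0, z0 = cfg.tube_center_yz
    xs = np.linspace(0.0, nx - 1.0, 4 * nx)
    if cfg.tube_bend == 0.0:
        path = np.column_stack(
            [xs, np.full_like(xs, y0), np.full_like(xs, z0)]
        )
    else:
        # circular-arc bend in the x-z plane: z displaced by a sagitta
        # profile peaking mid-span
        t = xs / (nx - 1.0)
        zs = z0 + cfg.tube_bend * 4.0 * t * (1.0 - t)
        path = np.column_stack([xs, np.full_like(xs, y0), zs])
    pts = np.column_stack([g.ravel() for g in grids])
    d, _ = cKDTree(path).query(pts, k=1)
    return (d <= cfg.tube_radius).reshape(cfg.shape)


def make_phantom(cfg: PhantomConfig) -> tuple[Volume, Mask]:
    """Generate the phantom volume and its exact ground-truth mask.

    The volume is I_bg + (I_fg - I_bg) * blur(indicator) + N(0, noise_sd),
    where the indicator is 1 inside the analytic tube ∪ sac ∪ bleb solid.
    """
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in cfg.shape], indexing="ij"
    )
    if cfg.tube_radius > 0:
        solid = _tube_indicator(cfg, grids)
    else:
        solid = np.zeros(cfg.shape, dtype=bool)
    if cfg.sac_center is not None:
        d2 = sum((g - c) ** 2 for g, c in zip(grids, cfg.sac_center))
        solid |= d2 <= cfg.sac_radius**2
    if cfg.bleb is not None:
        center, radius = cfg.bleb
        if radius <= 0:
            raise ParameterError("bleb radius must be positive")
        if any(c - radius < 0 or c + radius > n - 1
               for c, n in zip(center, cfg.shape)):
            raise ParameterError("bleb does not fit inside the grid")
        d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        solid |= d2 <= radius**2
    indicator = solid.astype(np.float64)
    if cfg.blur_sd > 0:
        indicator = ndimage.gaussian_filter(indicator, cfg.blur_sd)
    data = cfg.I_bg + (cfg.I_fg - cfg.I_bg) * indicator
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        data = data + rng.normal(0.0, cfg.noise_sd, size=cfg.shape)
    return Volume(data), Mask(solid)


def bleb_region(cfg: PhantomConfig) -> Mask:
    """The bleb voxels outside the sac (the protrusion a good segmentation
    must capture); empty mask if the phantom has no bleb."""
    grids = np.meshgrid(
        *[np.arange(n, dtype=np.float64) for n in cfg.shape], indexing="ij"
    )
    out = np.zeros(cfg.shape, dtype=bool)
    if cfg.bleb is not None and cfg.sac_center is not None:
        center, radius = cfg.bleb
        d2_bleb = sum((g - c) ** 2 for g, c in zip(grids, center))
        d2_sac = sum((g - c) ** 2 for g, c in zip(grids, cfg.sac_center))
        out = (d2_bleb <= radius**2) & (d2_sac > cfg.sac_radius**2)
    return Mask(out)


def case_configs(seed: int = 0) -> list[tuple[str, PhantomConfig]]:
    """The fixed four-case validation battery (each 64^3).

    1. ``straight-sac``   — straight parent artery with a medium sac.
    2. ``curved-largesac`` — curved artery hugging a large sac.
    3. ``bleb``           — sac with a small bleb at its top.
    4. ``small-lowcontrast`` — small sac at reduced contrast.
    """
    return [
        (
            "straight-sac",
            PhantomConfig(seed=seed),
        ),
        (
            "curved-largesac",
            PhantomConfig(
                tube_bend=10.0,
                tube_center_yz=(32.0, 18.0),
                sac_center=(32.0, 32.0, 38.0),
                sac_radius=11.0,
                seed=seed + 1,
            ),
        ),
        (
            "bleb",
            PhantomConfig(
                sac_radius=8.0,
                sac_center=(32.0, 32.0, 33.0),
                bleb=((32.0, 32.0, 43.5), 3.5),
                seed=seed + 2,
            ),
        ),
        (
            "small-lowcontrast",
            PhantomConfig(
                tube_radius=3.0,
                sac_center=(32.0, 32.0, 30.0),
                sac_radius=5.0,
                I_fg=160.0,
                seed=seed + 3,
            ),
        ),
    ]


def case_suite(seed: int = 0) -> list[tuple[str, Volume, Mask]]:
    """Generate the four-case battery: (name, volume, ground truth)."""
    return [
        (name, *make_phantom(cfg)) for name, cfg in case_configs(seed)
    ]
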