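"""The three segmentation algorithms: region growing, Chan-Vese, and the
threshold-based level set (TLS).

All three produce a binary mask of the vessel-plus-aneurysm lumen from a
cropped 3D angiographic volume:

* **Region Growing Threshold (RGT)** — flood fill from a seed over the
  voxels whose intensity lies in [T1, T2].  Simple and fast, but needs a
  seed and a threshold chosen by the operator.

* **Chan-Vese (CV)** — region-based active contour minimising the
  within-region intensity variance of a two-phase piecewise-constant image
  model; no edge information, no seed (a box initialisation suffices).

* **Threshold-based level set (TLS)** — a level-set evolution whose outward
  normal speed combines a region term alpha*(I - T), which expands the
  surface over voxels brighter than the threshold T and retracts it
  elsewhere, with a geodesic boundary term
  -beta * div(g * grad phi / |grad phi|) whose edge-stopping map
  g = 1/(1 + c*|grad I|^2) anchors the surface on intensity edges and
  smooths it in proportion to curvature.  T is estimated automatically from
  a Chan-Vese pre-segmentation and refined as the surface evolves
  (:func:`tlseg.threshold.iterate_threshold`), so the method needs neither
  a seed point nor a user threshold.

Setting beta = 0 reduces the TLS speed to the sign of I - T, the lower-bound
acceptance rule of region growing; setting alpha = 0 leaves the pure
geodesic-active-contour evolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    EvolutionCollapseError,
    ParameterError,
    SeedRejectedError,
)
from .levelset import (
    LevelSetField,
    SpeedField,
    cfl_dt,
    curvature,
    init_box_levelset,
    mask_from_levelset,
    reinitialize,
    step,
    weighted_curvature_term,
)
from .threshold import ThresholdEstimate, iterate_threshold
from .volumes import Mask, Volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RGTParams:
    """Region-growing parameters: seed voxel, intensity window [T1, T2],
    neighbourhood connectivity (6 = faces, 26 = faces+edges+corners)."""

    seed: tuple[int, int, int]
    T1: float
    T2: float
    connectivity: int = 26

    def __post_init__(self) -> None:
        if self.T1 > self.T2:
            raise ParameterError(f"T1={self.T1} must not exceed T2={self.T2}")
        if self.connectivity not in (6, 26):
            raise ParameterError("connectivity must be 6 or 26")


@dataclass(frozen=True)
class CVParams:
    """Chan-Vese parameters.

    lambda1/lambda2 weight the inside/outside intensity-fit terms, alpha is
    a constant area (balloon) speed and beta the curvature weight.  Defaults
    are the settings used for the aneurysm workflow:
    lambda1 = lambda2 = 0.001, alpha = 0, beta = 0.3.
    """

    lambda1: float = 0.001
    lambda2: float = 0.001
    alpha: float = 0.0
    beta: float = 0.3
    n_iter: int = 2000
    inset: int = 2
    reinit_every: int = 20
    cfl: float = 0.5
    change_tol: float = 0.001  # interface-change fraction for convergence
    clip_quantile: float = 0.9  # speed saturation quantile; 1.0 disables

    def __post_init__(self) -> None:
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise ParameterError("lambda1 and lambda2 must be >= 0")
        if self.n_iter < 1:
            raise ParameterError("n_iter must be >= 1")


@dataclass(frozen=True)
class TLSParams:
    """Threshold-based level-set parameters.

    alpha weights the region (threshold) term, beta the geodesic curvature
    term, c the slope of the edge-stopping map g = 1/(1 + c|grad I|^2)
    (stable over c in 0.5-0.7).  ``k_mode`` selects the confidence-multiplier
    estimator; ``tol_T``/``max_outer``/``inner_steps`` control the outer
    threshold-refinement loop.
    """

    alpha: float = 10.0
    beta: float = 3.0
    c: float = 0.5
    inset: int = 2
    k_mode: str = "derivation-consistent"
    tol_T: float = 0.5
    max_outer: int = 30
    inner_steps: int = 25
    smooth_sigma: float = 0.5
    stats_erosion: int = 1  # shell width excluded from region statistics
    reinit_every: int = 20
    cfl: float = 0.5
    cv: CVParams = field(default_factory=CVParams)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ParameterError("alpha must be > 0")
        if self.beta < 0:
            raise ParameterError("beta must be >= 0")
        if self.c <= 0:
            raise ParameterError("c must be > 0")


def region_grow(v: Volume, p: RGTParams) -> Mask:
    """Connected-threshold region growing from a seed voxel.

    Returns the maximal connected component, under ``p.connectivity``, of
    {x : T1 <= I(x) <= T2} that contains the seed.  Deterministic.
    """
    seed = tuple(int(s) for s in p.seed)
    if any(s < 0 or s >= n for s, n in zip(seed, v.data.shape)):
        raise ParameterError(f"seed {seed} outside volume {v.data.shape}")
    seed_val = v.data[seed]
    if not (p.T1 <= seed_val <= p.T2):
        raise SeedRejectedError(
            f"seed intensity {seed_val} outside [{p.T1}, {p.T2}]"
        )
    in_range = (v.data >= p.T1) & (v.data <= p.T2)
    structure = ndimage.generate_binary_structure(3, 1 if p.connectivity == 6 else 3)
    labels, _ = ndimage.label(in_range, structure=structure)
    return Mask(labels == labels[seed], v.spacing, v.origin)


def boundary_map(
    v: Volume, c: float, smooth_sigma: float = 0.5
) -> np.ndarray:
    """Edge-stopping map g(|grad I|) = 1 / (1 + c |grad I|^2), in (0, 1].

    g falls towards zero on strong intensity edges (the vessel wall) and is
    1 in homogeneous regions; ``c`` controls how sharply it falls.  The
    gradient is taken by central differences after an optional light
    Gaussian pre-smoothing (``smooth_sigma`` voxels, 0 to disable) that
    suppresses noise-induced spurious edges.
    """
    if c <= 0:
        raise ParameterError(f"c must be > 0, got {c}")
    data = v.data.astype(np.float64)
    if smooth_sigma > 0:
        data = ndimage.gaussian_filter(data, smooth_sigma)
    grads = np.gradient(data)
    grad_sq = sum(g * g for g in grads)
    return 1.0 / (1.0 + c * grad_sq)


def tls_speed(
    v: Volume,
    ls: LevelSetField,
    T: float,
    g: np.ndarray,
    p: TLSParams,
) -> SpeedField:
    """Outward normal speed of the TLS evolution.

    F = alpha*(I - T) - beta * div(g * grad phi / |grad phi|): positive
    (expansion) inside bright regions where I > T, negative beyond them,
    with the geodesic term smoothing the surface and pinning it to edges.
    """
    if v.data.shape != ls.phi.shape or g.shape != ls.phi.shape:
        raise ParameterError("volume, phi and g grids must be aligned")
    region = p.alpha * (v.data - T)
    if p.beta == 0:
        return SpeedField(region)
    return SpeedField(
        region, parabolic=-p.beta * weighted_curvature_term(ls, g)
    )


def gac_speed(ls: LevelSetField, g: np.ndarray, beta: float) -> SpeedField:
    """Pure geodesic-active-contour speed, -beta * div(g grad phi/|grad phi|);
    the TLS speed with its region term removed."""
    return SpeedField(
        np.zeros_like(ls.phi),
        parabolic=-beta * weighted_curvature_term(ls, g),
    )


def tls_evolve_block(
    v: Volume,
    ls: LevelSetField,
    T: float,
    g: np.ndarray,
    p: TLSParams,
    n_steps: int,
) -> LevelSetField:
    """Run ``n_steps`` explicit TLS steps at fixed threshold T, with periodic
    reinitialisation; the inner loop between threshold updates."""
    for _ in range(n_steps):
        speed = tls_speed(v, ls, T, g, p)
        ls = step(ls, speed, cfl_dt(speed, p.cfl))
        if ls.iteration % p.reinit_every == 0 and _has_both_phases(ls):
            ls = reinitialize(ls)
    return ls


def _has_both_phases(ls: LevelSetField) -> bool:
    neg = int((ls.phi < 0).sum())
    return 0 < neg < ls.phi.size


def chan_vese(
    v: Volume, phi0: LevelSetField, p: CVParams | None = None
) -> tuple[Mask, LevelSetField]:
    """Two-phase Chan-Vese evolution from an initial level-set field.

    The outward speed is
    F = lambda2*(I - mu_out)^2 - lambda1*(I - mu_in)^2 - alpha - beta*kappa,
    with mu_in / mu_out recomputed each step as the mean intensity over the
    current {phi < 0} / {phi >= 0} partition (a hard interface — no smeared
    Heaviside).  A voxel whose intensity is closer to the inside mean than
    the outside mean therefore pulls the surface outward over itself, which
    on a two-valued image drives the partition to the exact region.

    Runs ``p.n_iter`` steps or until the interface moves fewer than
    ``p.change_tol`` of all voxels between reinitialisation cycles.
    """
    if p is None:
        p = CVParams()
    ls = phi0
    if not _has_both_phases(ls):
        raise EvolutionCollapseError("initial phi must have both phases")
    prev_mask = ls.phi < 0
    n_total = ls.phi.size
    for i in range(p.n_iter):
        inside = ls.phi < 0
        n_in = int(inside.sum())
        if n_in == 0 or n_in == n_total:
            raise EvolutionCollapseError(
                f"Chan-Vese collapsed at step {i}"
            )
        mu_in = float(v.data[inside].mean())
        mu_out = float(v.data[~inside].mean())
        f = (
            p.lambda2 * (v.data - mu_out) ** 2
            - p.lambda1 * (v.data - mu_in) ** 2
            - p.alpha
        )
        if p.clip_quantile < 1.0:
            # saturate the few extreme speeds so the CFL step is not
            # throttled by them; signs (hence fixed points) are unchanged
            cap = np.quantile(np.abs(f), p.clip_quantile)
            f = np.clip(f, -cap, cap)
        speed = SpeedField(
            f, parabolic=(-p.beta * curvature(ls) if p.beta != 0 else None)
        )
        ls = step(ls, speed, cfl_dt(speed, p.cfl))
        if ls.iteration % p.reinit_every == 0:
            if _has_both_phases(ls):
                ls = reinitialize(ls)
            mask_now = ls.phi < 0
            changed = int(np.count_nonzero(mask_now != prev_mask))
            prev_mask = mask_now
            if changed < p.change_tol * n_total and i > 0:
                logger.debug("Chan-Vese converged at step %d", i)
                break
    return mask_from_levelset(ls), ls


def segment_cv(v: Volume, p: CVParams | None = None) -> Mask:
    """Chan-Vese segmentation from the standard box initialisation."""
    if p is None:
        p = CVParams()
    phi0 = init_box_levelset(v.data.shape, p.inset)
    mask, _ = chan_vese(v, phi0, p)
    return mask


def segment_tls(
    v: Volume, p: TLSParams | None = None
) -> tuple[Mask, ThresholdEstimate]:
    """Fully automatic TLS segmentation of a cropped ROI volume.

    Pipeline: (1) box-surface initialisation inset ``p.inset`` voxels from
    the ROI faces; (2) Chan-Vese pre-segmentation to obtain an initial
    foreground estimate; (3) iterative threshold refinement driving the TLS
    evolution; no seed point or manual threshold is required.

    Returns the final mask and the threshold estimate with its convergence
    history.
    """
    if p is None:
        p = TLSParams()
    phi0 = init_box_levelset(v.data.shape, p.inset)
    try:
        cv_mask, _ = chan_vese(v, phi0, p.cv)
    except EvolutionCollapseError as exc:
        raise EvolutionCollapseError(f"pre-segmentation: {exc}") from exc
    try:
        est, mask = iterate_threshold(v, cv_mask, p)
    except EvolutionCollapseError as exc:
        raise EvolutionCollapseError(f"threshold iteration: {exc}") from exc
    return mask, est


def segment_rgt_auto(
    v: Volume, seed: tuple[int, int, int], tls_T: float, connectivity: int = 26
) -> Mask:
    """Region growing with its lower threshold taken from a TLS result.

    T1 = ``tls_T`` (the converged automatic threshold) and T2 = the maximum
    intensity of the volume, so only the seed remains manual.
    """
    t2 = float(v.data.max())
    if tls_T > t2:
        raise SeedRejectedError(
            f"threshold {tls_T} exceeds maximum intensity {t2}"
        )
    return region_grow(v, RGTParams(seed=seed, T1=float(tls_T), T2=t2,
                                    connectivity=connectivity))
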