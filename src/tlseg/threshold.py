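"""Automatic intensity-threshold estimation for the threshold-based level set.

The segmentation target (the contrast-filled aneurysm and parent artery) is
assumed brighter than its background.  The lower intensity bound of the
foreground is modelled through distribution-free Chebyshev confidence
intervals: more than (1 - 1/k^2) of a population lies within k standard
deviations of its mean, so the foreground's lower bound is T = mu_a - k*sigma_a.
Requiring the foreground's lower bound to coincide with the background's upper
bound, mu_b + k*sigma_b = mu_a - k*sigma_a with a shared confidence multiplier
k, fixes

    k = (mu_a - mu_b) / (sigma_a + sigma_b).

An ``as-printed`` variant with (sigma_a - sigma_b) in the denominator is kept
behind a switch for comparison; it is singular when the two spreads are equal
and can produce out-of-band thresholds, which are then clamped.

The threshold is estimated iteratively: region statistics come from the
current segmentation (initially a Chan-Vese pre-segmentation), a block of
level-set evolution steps is run with the current T, and the statistics are
recomputed from the new mask.  As the surface settles on the vessel boundary
the statistics stop changing and T converges; iteration stops when the change
in T falls below a tolerance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import (
    AssumptionViolationError,
    DegenerateStatisticsError,
    EvolutionCollapseError,
    ParameterError,
)
from .volumes import Mask, Volume

if TYPE_CHECKING:  # pragma: no cover
    from .segmenters import TLSParams

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegionStats:
    """Foreground/background intensity statistics (HU).

    ``mu_a``/``sigma_a`` describe the aneurysm (foreground) region,
    ``mu_b``/``sigma_b`` the background; sample SDs use the n-1 denominator.
    """

    mu_a: float
    sigma_a: float
    mu_b: float
    sigma_b: float
    n_fg: int
    n_bg: int


@dataclass
class ThresholdEstimate:
    """Converged threshold with its full iteration trace."""

    k: float
    T: float
    history: list[float] = field(default_factory=list)
    trace: list[dict] = field(default_factory=list)
    converged: bool = False

    @property
    def iterations(self) -> int:
        return len(self.history)

    def history_frame(self) -> pd.DataFrame:
        """Per-iteration record (iteration, T, k, mu_a, sigma_a, mu_b,
        sigma_b) — the data behind a threshold-convergence plot."""
        return pd.DataFrame(self.trace)


def chebyshev_bounds(k: float) -> tuple[float, float]:
    """Chebyshev tail bounds for a confidence multiplier ``k``.

    Returns ``(two_sided, one_sided)``: P(|X-mu| >= k*sigma) <= 1/k^2 and the
    one-tailed P(X-mu >= k*sigma) <= 1/(1+k^2).  At k=1 the one-sided bound
    is 0.5: at least half the population lies below one SD above the mean.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    return 1.0 / k**2, 1.0 / (1.0 + k**2)


def estimate_k(stats: RegionStats, mode: str = "derivation-consistent") -> float:
    """Confidence multiplier linking foreground and background statistics.

    ``derivation-consistent`` (default) solves the balance relation
    mu_b + k*sigma_b = mu_a - k*sigma_a, giving
    k = (mu_a - mu_b)/(sigma_a + sigma_b).  ``as-printed`` uses
    (sigma_a - sigma_b) in the denominator instead.
    """
    if mode not in ("derivation-consistent", "as-printed"):
        raise ParameterError(f"unknown k mode {mode!r}")
    if stats.mu_a <= stats.mu_b:
        raise AssumptionViolationError(
            f"foreground mean {stats.mu_a:.3g} must exceed background mean "
            f"{stats.mu_b:.3g}"
        )
    if mode == "derivation-consistent":
        denom = stats.sigma_a + stats.sigma_b
    else:
        denom = stats.sigma_a - stats.sigma_b
    if abs(denom) < 1e-12:
        raise DegenerateStatisticsError(
            f"zero denominator in k estimate (mode {mode!r}): "
            f"sigma_a={stats.sigma_a:.3g}, sigma_b={stats.sigma_b:.3g}"
        )
    return (stats.mu_a - stats.mu_b) / denom


def threshold_from_stats(stats: RegionStats, k: float, clamp: bool = True) -> float:
    """Lower intensity bound of the foreground: T = mu_a - k*sigma_a.

    With the derivation-consistent k this equals mu_b + k*sigma_b, so T lies
    strictly between the two means whenever both SDs are positive.  A T at or
    outside (mu_b, mu_a) — possible in as-printed mode or with degenerate
    SDs — is clamped 5% of the band inside the violated end, with a warning,
    unless ``clamp`` is False.
    """
    if k <= 0:
        raise ParameterError(f"k must be positive, got {k}")
    t = stats.mu_a - k * stats.sigma_a
    band = stats.mu_a - stats.mu_b
    if t <= stats.mu_b or t >= stats.mu_a:
        warnings.warn(
            f"threshold {t:.3g} outside ({stats.mu_b:.3g}, {stats.mu_a:.3g})",
            stacklevel=2,
        )
        if clamp and band > 0:
            t = (
                stats.mu_b + 0.05 * band
                if t <= stats.mu_b
                else stats.mu_a - 0.05 * band
            )
    return float(t)


def stats_from_mask(v: Volume, m: Mask, background: Mask) -> RegionStats:
    """Sample means and SDs of the intensities under two disjoint masks."""
    if m.data.shape != v.data.shape or background.data.shape != v.data.shape:
        raise ParameterError("masks must match the volume grid")
    if np.any(m.data & background.data):
        raise ParameterError("foreground and background masks must be disjoint")
    fg = v.data[m.data]
    bg = v.data[background.data]
    if fg.size < 2 or bg.size < 2:
        raise DegenerateStatisticsError(
            f"need >= 2 voxels per region, got fg={fg.size}, bg={bg.size}"
        )
    return RegionStats(
        mu_a=float(fg.mean()),
        sigma_a=float(fg.std(ddof=1)),
        mu_b=float(bg.mean()),
        sigma_b=float(bg.std(ddof=1)),
        n_fg=int(fg.size),
        n_bg=int(bg.size),
    )


def _interface_excluded_stats(v: Volume, mask: Mask, erosion: int) -> RegionStats:
    """Region statistics with the partial-volume shell excluded.

    Voxels within ``erosion`` voxels of the current surface straddle the
    boundary and belong to neither intensity population (CT partial-volume
    averaging), so both the foreground and the background sample are eroded
    before computing means and SDs.  Falls back to the raw regions when an
    eroded sample would be too small.
    """
    from scipy import ndimage

    fg = mask.data
    bg = ~mask.data
    if erosion > 0:
        structure = ndimage.generate_binary_structure(3, 1)
        fg_core = ndimage.binary_erosion(fg, structure, iterations=erosion,
                                         border_value=1)
        bg_core = ndimage.binary_erosion(bg, structure, iterations=erosion,
                                         border_value=1)
        if fg_core.sum() >= 2:
            fg = fg_core
        if bg_core.sum() >= 2:
            bg = bg_core
    return stats_from_mask(
        v, Mask(fg, mask.spacing, mask.origin), Mask(bg, mask.spacing, mask.origin)
    )


def iterate_threshold(
    v: Volume, initial_mask: Mask, config: "TLSParams | None" = None
) -> tuple[ThresholdEstimate, Mask]:
    """Run the outer threshold-refinement loop of the TLS segmentation.

    Starting from ``initial_mask`` (normally a Chan-Vese pre-segmentation),
    each outer iteration (a) computes foreground statistics from the current
    mask against its complement within the ROI, (b) estimates k and
    T_i = mu_a - k*sigma_a, (c) evolves the level-set surface for a fixed
    block of PDE steps under threshold T_i, and (d) re-extracts the mask.
    Stops when |T_i - T_{i-1}| < ``config.tol_T`` or after
    ``config.max_outer`` iterations.

    When both region SDs vanish (an exactly two-valued volume) the balance
    relation degenerates; the limiting balanced threshold (mu_a + mu_b)/2 is
    used for that iteration.

    Returns the estimate (with full history) and the final mask.
    """
    from .segmenters import TLSParams, boundary_map, tls_evolve_block

    if config is None:
        config = TLSParams()
    n_total = v.data.size
    fg0 = int(initial_mask.data.sum())
    if fg0 == 0 or fg0 == n_total:
        raise DegenerateStatisticsError(
            "initial mask must contain both foreground and background"
        )

    from .levelset import mask_from_levelset, sdf_from_mask

    g = boundary_map(v, config.c, smooth_sigma=config.smooth_sigma)
    ls = sdf_from_mask(initial_mask)
    mask = initial_mask
    est = ThresholdEstimate(k=np.nan, T=np.nan)
    t_prev: float | None = None
    for i in range(config.max_outer):
        stats = _interface_excluded_stats(v, mask, config.stats_erosion)
        try:
            k = estimate_k(stats, config.k_mode)
            t_i = threshold_from_stats(stats, k)
        except DegenerateStatisticsError:
            # exactly two-valued volume: limiting balanced threshold
            k = np.nan
            t_i = 0.5 * (stats.mu_a + stats.mu_b)
        est.history.append(t_i)
        est.trace.append(
            dict(
                iteration=i,
                T=t_i,
                k=k,
                mu_a=stats.mu_a,
                sigma_a=stats.sigma_a,
                mu_b=stats.mu_b,
                sigma_b=stats.sigma_b,
                n_fg=stats.n_fg,
            )
        )
        logger.info(
            "outer %d: T=%.3f k=%.3f fg=%d", i, t_i, k, stats.n_fg
        )
        est.k, est.T = k, t_i
        if t_prev is not None and abs(t_i - t_prev) < config.tol_T:
            est.converged = True
            return est, mask
        t_prev = t_i
        ls = tls_evolve_block(v, ls, t_i, g, config, config.inner_steps)
        mask = mask_from_levelset(ls)
        n_fg = mask.voxel_count
        if n_fg == 0 or n_fg == n_total:
            raise EvolutionCollapseError(
                f"mask collapsed to {'empty' if n_fg == 0 else 'full'} "
                f"at outer iteration {i}"
            )
    return est, mask
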