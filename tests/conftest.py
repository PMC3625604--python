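"""Shared fixtures.

The phantom-battery segmentation runs are expensive (minutes), so they are
session-scoped and shared between the validation-quality, threshold-
convergence and c-stability tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from tlseg.experiment import run_experiment
from tlseg.phantoms import PhantomConfig, case_configs, make_phantom
from tlseg.segmenters import TLSParams, segment_tls

SUITE_SEED = 1


@pytest.fixture(scope="session")
def suite_result():
    """TLS/CV/RGT run over the full four-case phantom battery."""
    return run_experiment(seed=SUITE_SEED)


@pytest.fixture(scope="session")
def suite_configs():
    return dict(case_configs(SUITE_SEED))


@pytest.fixture(scope="session")
def standard_phantom():
    """The standard straight-tube + sac phantom (fg 200, bg 100, noise 10,
    blur 0.8) with its ground truth."""
    cfg = PhantomConfig(seed=SUITE_SEED)
    volume, gt = make_phantom(cfg)
    return cfg, volume, gt


@pytest.fixture(scope="session")
def c_sweep_masks(standard_phantom, suite_result):
    """TLS masks of the standard phantom for c in {0.5, 0.6, 0.7}; the
    c=0.5 run is the suite's straight-sac case (default parameters)."""
    _, volume, _ = standard_phantom
    masks = {0.5: suite_result.masks[("straight-sac", "tls")]}
    for c in (0.6, 0.7):
        masks[c], _ = segment_tls(volume, TLSParams(c=c))
    return masks


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_blob_mask(rng, shape=(12, 12, 12), density=0.5, smooth=True):
    """A random connected-ish blob mask with both phases present."""
    from scipy import ndimage

    field = ndimage.gaussian_filter(
        rng.standard_normal(shape), 1.5 if smooth else 0.0
    )
    mask = field > np.quantile(field, 1.0 - density)
    if not mask.any():
        mask[tuple(s // 2 for s in shape)] = True
    if mask.all():
        mask[0, 0, 0] = False
    return mask
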