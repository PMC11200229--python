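"""Shared fixtures: synthetic tissue/droplet datasets and small rasters."""

import warnings

import numpy as np
import pytest

import mexquant as mq
from mexquant.preprocess import median_filter, remove_hot_pixels, stack_channels
from mexquant.segmentation import (
    extract_features,
    filter_border_objects,
    filter_by_size,
    watershed_segment,
)
from mexquant.types import ImageStack


@pytest.fixture(scope="session")
def tissue():
    """Default-condition synthetic tissue (200 cells, Poisson noise, spikes)."""
    return mq.simulate_tissue(seed=0)


@pytest.fixture(scope="session")
def tissue_pipeline(tissue):
    """Tissue run through preprocess → segment → features, with truth match.

    Returns (cleaned stack, mask, cell table, detected→truth match table).
    """
    stack, truth = tissue
    metal = remove_hot_pixels(stack.channel("59Co"))
    cleaned = ImageStack(
        [metal if c.isotope == "59Co" else c for c in stack.channels],
        panel=stack.panel,
    )
    seg = stack_channels(
        median_filter(stack.channel("193Ir"), 1),
        median_filter(stack.channel("161Dy"), 1),
    )
    mask = filter_by_size(filter_border_objects(watershed_segment(seg, 10.0)), 10, 10_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cells = extract_features(mask, cleaned)
    match = mq.match_cells(mask, truth.mask)
    return cleaned, mask, cells, match


@pytest.fixture(scope="session")
def droplets_noiseless():
    """Noiseless, background-free droplet array: integrated counts are exact."""
    return mq.simulate_droplets(
        concentrations_ug_per_L=(2.5, 12.5, 25.0, 50.0, 125.0, 250.0),
        seed=0,
        poisson_noise=False,
        background_counts=0.0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def constant_image(value=10.0, shape=(5, 5), isotope="59Co"):
    return mq.ChannelImage(np.full(shape, float(value)), isotope)
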