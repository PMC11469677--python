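"""Shared fixtures: the toy atlas and small synthetic inputs.

The toy atlas is expensive enough (≈10M voxels) to build once per session;
tests must not mutate it.
"""

from __future__ import annotations

import numpy as np
import pytest

from projquant.synthetic import (
    TopographySpec,
    make_toy_atlas,
    make_tube_truth,
    simulate_axon_probability,
)


@pytest.fixture(scope="session")
def toy_atlas():
    """(AnnotationVolume, StructureGraph, CoordinateFrame) of the default toy atlas."""
    return make_toy_atlas()


@pytest.fixture(scope="session")
def noise_free_cohort(toy_atlas):
    """Seven-injection cohort with zero AP scatter (exact mirror map)."""
    from projquant.synthetic import simulate_injection_cohort

    topo = TopographySpec(ap_noise_sd_mm=0.0)
    samples, metadata, truth = simulate_injection_cohort(topo, atlas=toy_atlas, seed=11)
    return samples, metadata, truth


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free two-tube probability phantom with its ground truth."""
    shape = (50, 50, 50)
    truth = make_tube_truth(shape, n_tubes=2, n_steps=60, seed=0)
    prob = simulate_axon_probability(truth, shape, noise_sd=0.0, seed=0)
    return prob, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
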