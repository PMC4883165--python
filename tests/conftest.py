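"""Shared fixtures: phantoms are generated at test time, never stored."""

import numpy as np
import pytest

import axialseg as ax


@pytest.fixture(scope="session")
def suite20():
    """The default 20-phantom evaluation suite (512 px, seeds 1-20)."""
    return ax.default_suite(20, base_seed=1)


@pytest.fixture(scope="session")
def strip_results(suite20):
    """Skull-strip results for every phantom of the default suite."""
    return [ax.skull_strip(ph.t1) for ph in suite20]


@pytest.fixture(scope="session")
def small_phantom():
    """A fast 256 px phantom for unit tests (geometry scaled from defaults)."""
    return ax.generate(_small_spec(seed=11))


def _small_spec(seed, **overrides):
    base = dict(
        size=256,
        skull_semi_axes=(95.0, 77.0),
        skull_thickness_px=7.0,
        gap_width_px=2.0,
        tumor_radius_px=16.0,
        seed=seed,
    )
    base.update(overrides)
    return ax.PhantomSpec(**base)


@pytest.fixture
def small_spec_factory():
    return _small_spec


def random_mask(rng, shape=(16, 16), p=0.5):
    return ax.BinaryMask(rng.random(shape) < p)


def random_se(rng, max_side=5):
    """Random structuring element: arbitrary shape, support and origin."""
    h = int(rng.integers(1, max_side + 1))
    w = int(rng.integers(1, max_side + 1))
    win = rng.random((h, w)) < 0.6
    if not win.any():
        win[rng.integers(h), rng.integers(w)] = True
    origin = (int(rng.integers(h)), int(rng.integers(w)))
    return ax.StructuringElement(win, origin)
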