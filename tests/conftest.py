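"""Shared fixtures: miniature eye phantoms and random-dataset factories."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from oculims.imzml import MSIDataset, Spectrum
from oculims.phantom import EyePhantomConfig, generate_phantom
from oculims.pipeline import small_phantom_config


@pytest.fixture(scope="session")
def small_config() -> EyePhantomConfig:
    """Miniature default-structure phantom (~1.4k pixels, runs in <1 s)."""
    return small_phantom_config(seed=7)


@pytest.fixture(scope="session")
def small_phantom(small_config):
    return generate_phantom(small_config)


def make_quiet(config: EyePhantomConfig, **overrides) -> EyePhantomConfig:
    """Noise-free variant of a phantom config (no drift, no intensity noise)."""
    kwargs = dict(mass_drift_sigma_da=0.0, noise_sigma_log=0.0, noise_floor=0.0)
    kwargs.update(overrides)
    return dataclasses.replace(config, **kwargs)


def make_smooth(config: EyePhantomConfig, **overrides) -> EyePhantomConfig:
    """Hotspot-free, uniform-shell variant: the field depends only on arc length."""
    kwargs = dict(
        hotspots=(),
        epithelium_multiplier=1.0,
        stroma_multiplier=1.0,
        endothelium_multiplier=1.0,
        sclera_multiplier=1.0,
        posterior_decay_length_um=config.decay_length_um,
    )
    kwargs.update(overrides)
    return dataclasses.replace(config, **kwargs)


@pytest.fixture(scope="session")
def small_quiet_phantom(small_config):
    return generate_phantom(make_quiet(small_config))


def random_dataset(rng: np.random.Generator, mode: str = "processed") -> MSIDataset:
    """A small random but valid dataset for round-trip property tests."""
    n_pixels = int(rng.integers(1, 9))
    coords = set()
    while len(coords) < n_pixels:
        coords.add((int(rng.integers(1, 7)), int(rng.integers(1, 7))))
    shared_axis = np.sort(rng.uniform(200.0, 310.0, size=int(rng.integers(1, 8))))
    spectra = {}
    for coord in coords:
        if mode == "continuous":
            mz = shared_axis
        else:
            mz = np.sort(rng.uniform(200.0, 310.0, size=int(rng.integers(1, 8))))
            while len(np.unique(mz)) != len(mz):  # enforce strictly ascending
                mz = np.sort(rng.uniform(200.0, 310.0, size=len(mz)))
        intensity = rng.gamma(2.0, 50.0, size=len(mz))
        spectra[coord] = Spectrum(mz, intensity)
    return MSIDataset(
        spectra=spectra,
        mz_range=(200.0, 310.0),
        mode=mode,
        pitch_um=float(rng.choice([25.0, 50.0, 100.0])),
        metadata={"polarity": "positive"},
    )
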