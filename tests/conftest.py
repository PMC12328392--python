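"""Shared fixtures: the default synthetic study dataset, preprocessed once."""

from __future__ import annotations

import numpy as np
import pytest

import fpchem as f
from fpchem.preprocess import preprocess_wavelength


@pytest.fixture(scope="session")
def default_dataset() -> f.SimulatedDataset:
    """The study-shaped dataset at seed 1 (2 species x 20 extracts x 2 inj)."""
    return f.simulate_dataset(f.SimConfig(seed=1))


def _preprocess(ds: f.SimulatedDataset, wl: int):
    blank = next(b for b in ds.blanks if b.wavelength_nm == wl)
    F, rs = preprocess_wavelength(ds.chromatograms, blank, wl)
    return F, rs


@pytest.fixture(scope="session")
def fingerprints_280(default_dataset):
    return _preprocess(default_dataset, 280)


@pytest.fixture(scope="session")
def fingerprints_330(default_dataset):
    return _preprocess(default_dataset, 330)


@pytest.fixture(scope="session")
def default_index(default_dataset):
    return f.antioxidant_index(default_dataset.panel)


def response_for(F, index) -> np.ndarray:
    """RACI values aligned to fingerprint-matrix row order."""
    lookup = dict(zip(index.sample_ids, index.raci_mean))
    return np.array([lookup[s] for s in F.sample_ids])
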