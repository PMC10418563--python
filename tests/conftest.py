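"""Shared fixtures: synthetic repositories and small spectrum builders."""

from __future__ import annotations

import numpy as np
import pytest

import taxomasst as tm


def make_spectrum(precursor, peaks, source_id="s"):
    """Spectrum from a list of (mz, intensity) pairs."""
    mz = np.array([p[0] for p in peaks], dtype=float)
    inten = np.array([p[1] for p in peaks], dtype=float)
    return tm.Spectrum(precursor_mz=precursor, mz=mz, intensity=inten, source_id=source_id)


def random_spectrum(rng, n_peaks=None, precursor=None, lo=50.0, hi=1000.0, spacing=None):
    """Random spectrum; optional minimum peak spacing for unambiguous pairing."""
    n = int(n_peaks if n_peaks is not None else rng.integers(3, 11))
    if spacing:
        grid = np.arange(lo, hi, spacing)
        mz = np.sort(rng.choice(grid, size=min(n, grid.size), replace=False))
        mz = mz + rng.uniform(-0.005, 0.005, mz.size)
    else:
        mz = np.sort(rng.uniform(lo, hi, n))
    inten = rng.lognormal(3.0, 1.0, mz.size)
    pre = float(precursor if precursor is not None else rng.uniform(120, 980))
    return tm.Spectrum(precursor_mz=pre, mz=mz, intensity=inten, source_id=f"rand{rng.integers(1e9)}")


@pytest.fixture(scope="session")
def repo():
    """Default zero-noise synthetic repository with planted molecules."""
    return tm.make_repository()


@pytest.fixture(scope="session")
def index(repo):
    return repo.build_index()


@pytest.fixture(scope="session")
def tree(repo):
    return repo.build_tree()


@pytest.fixture(scope="session")
def noisy_repo():
    """Repository under the default measurement-noise model."""
    return tm.make_repository(tm.FixtureSpec(seed=11, noise=tm.NoiseSpec()))


@pytest.fixture(scope="session")
def diff_fixture():
    return tm.make_differential_fixture(seed=0)
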