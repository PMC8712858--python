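from __future__ import annotations

import numpy as np
import pytest

from cryoraman.raman import BandWindow, RamanCube
from cryoraman.synth import CalciumMovieSpec, CellPhantomSpec, make_calcium_movie, make_raman_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One default-condition phantom with dispersed ice, shared across tests."""
    spec = CellPhantomSpec(ice_fraction=0.3, partition_ratio_true=2.4, seed=11)
    return make_raman_phantom(spec)


@pytest.fixture(scope="session")
def noisefree_phantom():
    spec = CellPhantomSpec(noise_level=0.0, seed=7)
    return make_raman_phantom(spec)


@pytest.fixture(scope="session")
def default_movie():
    """Short default-condition calcium movie (full length), shared."""
    spec = CalciumMovieSpec(seed=21)
    return make_calcium_movie(spec)


def flat_cube(height: float = 1.0, n_w: int = 101, shape=(8, 8)) -> RamanCube:
    """Spectrally flat cube over wavenumbers 1000..1100."""
    w = np.linspace(1000.0, 1100.0, n_w)
    return RamanCube(np.full((n_w,) + shape, height), w, pixel_pitch=0.333)


def gaussian_cube(amplitude: float, center: float, sigma: float, shape=(4, 4)) -> RamanCube:
    w = np.linspace(center - 8 * sigma, center + 8 * sigma, 801)
    prof = amplitude * np.exp(-0.5 * ((w - center) / sigma) ** 2)
    cube = np.broadcast_to(prof[:, None, None], (len(w),) + shape).copy()
    return RamanCube(cube, w, pixel_pitch=0.333)


def window(lo: float, hi: float, baseline: str = "none") -> BandWindow:
    return BandWindow("test", lo, hi, baseline)
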