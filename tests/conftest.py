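"""Shared fixtures: expensive optical objects are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ssos import (
    GridSpec,
    ReconOptions,
    default_config,
    make_otf,
    make_psf,
    otf_support,
    ssos_reconstruct,
)
from ssos.evaluate import Scenario, default_scenario
from ssos.simulate import form_raw_pair, make_chirp_sample


@pytest.fixture(scope="session")
def cfg():
    return default_config()


@pytest.fixture(scope="session")
def small_grid():
    return GridSpec(shape=(32, 8, 64), voxel_xy=40.0, voxel_z=40.0)


@pytest.fixture(scope="session")
def small_psf(cfg, small_grid):
    return make_psf(cfg, small_grid)


@pytest.fixture(scope="session")
def small_otf(small_psf):
    return make_otf(small_psf)


@pytest.fixture(scope="session")
def small_psi(small_otf):
    return otf_support(small_otf, 1e-3)


@pytest.fixture(scope="session")
def full_scenario():
    """Standard imaging condition with the chirp phantom spanning the whole
    confocal axial band (the in-silico resolution experiment)."""
    return default_scenario(f_max_fraction=1.0)


@pytest.fixture(scope="session")
def full_setup(full_scenario):
    """Phantom, PSF and noise-free raw pair on the standard grid."""
    sc = full_scenario
    h = make_psf(sc.cfg, sc.grid)
    s = make_chirp_sample(sc.chirp)
    i_p, i_s = form_raw_pair(s, sc.pattern, h)
    return {"scenario": sc, "psf": h, "sample": s, "pair": (i_p, i_s)}


@pytest.fixture(scope="session")
def full_recon(full_setup):
    """Noise-free end-to-end reconstruction at low-bias deconvolution."""
    i_p, i_s = full_setup["pair"]
    opts = ReconOptions(wiener_w=1e-6)
    result = ssos_reconstruct(i_p, i_s, full_setup["psf"], opts)
    return {"result": result, "opts": opts, **full_setup}
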