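"""Shared fixtures: small synthetic scenes reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from boutonquant.config import RunConfig
from boutonquant.segment import Geometry
from boutonquant.stacks import DEFAULT_PIXEL_UM, DEFAULT_ZSTEP_UM, SiteMetadata
from boutonquant.synthetic import NoiseModel, StackSpec, build_filter_demo_site


@pytest.fixture(scope="session")
def default_geometry() -> Geometry:
    return Geometry(pixel_um=DEFAULT_PIXEL_UM, zstep_um=DEFAULT_ZSTEP_UM)


@pytest.fixture()
def fast_config() -> RunConfig:
    """Pipeline config for quantification tests: deconvolution skipped."""
    cfg = RunConfig()
    cfg.preprocess.deconv.skip = True
    return cfg


@pytest.fixture()
def meta_full_depth() -> SiteMetadata:
    """Unshrunk tissue: depth corrections are the identity."""
    return SiteMetadata("site0", "subj0", "monkey", "PFC", "L3", 40.0)


def quiet_spec(**kwargs) -> StackSpec:
    """Small noiseless single-channel-friendly spec for constructed scenes."""
    defaults = dict(
        nx=64, ny=64, nz=24,
        noise=NoiseModel(gain_adu_per_photon=0.0, read_noise_adu=0.0),
        bouton_cv=0.0,
        n_puncta={"vglut1": 0, "vgat": 0, "lipofuscin": 0},
    )
    defaults.update(kwargs)
    return StackSpec(**defaults)


@pytest.fixture(scope="session")
def filter_demo():
    """Constructed site where every exclusion filter fires a known number of
    times; returns (stack, metadata, expected counts, planted truth)."""
    return build_filter_demo_site()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
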