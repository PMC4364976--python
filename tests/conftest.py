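"""Shared fixtures: small deterministic phantoms and reference parameter sets."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import settings

from dcefit import AifParams, RunConfig, default_phantom, make_phantom

settings.register_profile("deterministic", derandomize=True, max_examples=50)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def aif_example() -> AifParams:
    """The reference arterial parameter set used across model tests."""
    return AifParams(
        r0_over_v1=10.0, k10=0.5, k12=0.25, k21=0.15, t0=0.0, t1=1.0, tlag=0.0
    )


def small_phantom_spec(nx: int, noise_sd: float, **kwargs):
    """Default phantom rescaled to an nx-by-nx grid (ROI scaled along)."""
    return replace(
        default_phantom(),
        nx=nx,
        ny=nx,
        noise_sd=noise_sd,
        roi_center=(0.625 * nx, 0.625 * nx),
        roi_radius=0.15 * nx,
        **kwargs,
    )


@pytest.fixture(scope="session")
def noisefree_16_run():
    """16x16 noise-free phantom plus its fitted arterial model and mask."""
    from dcefit import exclusion_mask, fit_arterial

    spec = small_phantom_spec(16, 0.0)
    data, truth = make_phantom(spec)
    cfg = RunConfig()
    aif_fit, outcome = fit_arterial(
        data.time, data.cv, cfg.aif_init_params(), cfg.aif_bounds_obj()
    )
    mask = exclusion_mask(data.ct, aif_fit, data.time)
    return spec, data, truth, aif_fit, outcome, mask


def random_valid_aif(rng: np.random.Generator) -> AifParams:
    """Sample a physically valid arterial parameter set (distinct eigenvalues)."""
    while True:
        k10, k12, k21 = rng.uniform(0.05, 2.0, 3)
        s = k10 + k12 + k21
        disc = s * s - 4 * k10 * k21
        if disc <= 1e-4 * s * s:
            continue
        t0 = rng.uniform(0.0, 0.5)
        return AifParams(
            r0_over_v1=rng.uniform(1.0, 20.0),
            k10=k10, k12=k12, k21=k21,
            t0=t0, t1=t0 + rng.uniform(0.2, 1.0),
            tlag=rng.uniform(0.0, 0.3),
        )
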