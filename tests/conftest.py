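"""Shared fixtures: small deterministic phantoms and measurement tables."""

import numpy as np
import pytest
from hypothesis import settings

import icvkit as ik

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def smooth_spec():
    """Unperturbed ellipsoid, 1 mm isotropic, small enough to be fast."""
    return ik.PhantomSpec(
        semi_axes=(30.0, 25.0, 20.0),
        grid_shape=(68, 68, 68),
        spacing=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def smooth_mask(smooth_spec):
    return ik.generate_phantom(smooth_spec, subject_seed=1)


@pytest.fixture(scope="session")
def rough_spec():
    return ik.PhantomSpec(
        semi_axes=(30.0, 25.0, 20.0),
        roughness_amplitude=4.0,
        roughness_order=10,
        grid_shape=(76, 76, 76),
        spacing=(1.0, 1.0, 1.0),
    )


@pytest.fixture(scope="session")
def rough_mask(rough_spec):
    return ik.generate_phantom(rough_spec, subject_seed=1)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six small rough phantoms with their true volumes (fast shared input)."""
    spec = ik.PhantomSpec(
        semi_axes=(24.0, 20.0, 18.0),
        roughness_amplitude=3.0,
        roughness_order=8,
        grid_shape=(68, 68, 68),
        spacing=(1.0, 1.0, 1.0),
        target_icv_mean=0.040,
        target_icv_sd=0.004,
    )
    cohort = ik.generate_cohort(spec, 6, "T", master_seed=99)
    masks = [m for _, m, _ in cohort]
    refs = [t for _, _, t in cohort]
    return masks, refs


@pytest.fixture()
def profile_mask():
    """10 consecutive slices of exactly 100 mm^2 each at 1 mm spacing."""
    occ = np.zeros((12, 12, 12), dtype=np.uint8)
    occ[1:11, 1:11, 0:10] = 1
    return ik.MaskVolume(occ, (1.0, 1.0, 1.0), slice_axis=2)


def random_mask(rng, shape=(6, 6, 40), p=0.4, spacing=(1.0, 1.0, 1.0)):
    """Random non-empty binary mask (no connectivity contract)."""
    occ = (rng.random(shape) < p).astype(np.uint8)
    if occ.sum() == 0:
        occ[tuple(s // 2 for s in shape)] = 1
    return ik.MaskVolume(occ, spacing, slice_axis=2)
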