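"""Shared fixtures: constants and phantom realisations used across suites."""

import dataclasses

import pytest

from o15pet import PhysioConstants, ReferenceAssumptions, generate_phantom, preset_scenarios

#: Seed for the single noisy phantom realisation used by the tests.
NOISY_SEED = 7


@pytest.fixture(scope="session")
def consts() -> PhysioConstants:
    return PhysioConstants()

@pytest.fixture(scope="session")
def assume() -> ReferenceAssumptions:
    return ReferenceAssumptions()


@pytest.fixture(scope="session")
def misery_bundle():
    """Noiseless misery-perfusion phantom (lesion RCBF 0.7, RCBV 1.8, ROEF 1.4)."""
    return generate_phantom(preset_scenarios()["misery_perfusion"])


@pytest.fixture(scope="session")
def noisy_bundle():
    """Same phantom with 1% multiplicative noise, fixed seed."""
    spec = dataclasses.replace(
        preset_scenarios()["misery_perfusion"], noise_cv=0.01, seed=NOISY_SEED
    )
    return generate_phantom(spec)
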