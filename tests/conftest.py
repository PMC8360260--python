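import pytest

from ricdosim import (
    get_nuclide,
    load_organ_masses,
    make_s_value_fixture,
    study_like_specs,
    simulate_biodist,
)


@pytest.fixture(scope="session")
def cu64():
    return get_nuclide("Cu-64")


@pytest.fixture(scope="session")
def lu177():
    return get_nuclide("Lu-177")


@pytest.fixture(scope="session")
def organ_masses():
    return load_organ_masses()


@pytest.fixture(scope="session")
def noiseless_biodist():
    """Zero-noise synthetic biodistribution: every animal sits exactly on
    the organ kinetic curves."""
    return simulate_biodist(study_like_specs(noise_cv=0.0), seed=7, injected_MBq=6.5)


@pytest.fixture(scope="session")
def lu_s_fixture(lu177, organ_masses):
    """Synthetic E_mean/m self-dose S-table and sphere curve for Lu-177."""
    return make_s_value_fixture(lu177, organ_masses, mean_energy_MeV_per_decay=0.147)
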