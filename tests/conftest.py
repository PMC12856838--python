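import pytest

from cannavap import (
    HELIUM,
    design_for,
    generate_series,
    get_compound,
    get_reference_correlation,
)


@pytest.fixture(scope="session")
def thc():
    return get_compound("THC")


@pytest.fixture(scope="session")
def thc_params():
    return get_reference_correlation("THC")


@pytest.fixture(scope="session")
def helium():
    return HELIUM


@pytest.fixture(scope="session")
def noiseless_thc_records():
    """Noiseless synthetic campaign: 7 temperatures x 6 series, THC truth."""
    design = design_for("THC", noise_m2_rel=0.0, noise_T_sd=0.0, seed=7)
    return generate_series(design)


@pytest.fixture()
def thc_measurements_csv(tmp_path, noiseless_thc_records):
    from cannavap.io import write_measurements

    path = tmp_path / "measurements.csv"
    write_measurements(noiseless_thc_records, path)
    return path
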