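import pytest

from ieephys import (GeneratorConfig, build_default_registry,
                     default_architecture, generate_recording, run_pipeline,
                     write_recording)


@pytest.fixture(scope="session")
def registry():
    return build_default_registry()


@pytest.fixture(scope="session")
def arch(registry):
    return default_architecture(registry)


@pytest.fixture(scope="session")
def noisy_config():
    return GeneratorConfig(seed=3, n_cells=2)


@pytest.fixture(scope="session")
def bundle(noisy_config):
    return generate_recording(noisy_config, 0)


@pytest.fixture(scope="session")
def clean_config():
    return GeneratorConfig(seed=5, n_cells=1, admittance_noise_sd=0.0,
                           capacitance_noise_sd=0.0, current_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_bundle(clean_config):
    return generate_recording(clean_config, 0)


@pytest.fixture(scope="session")
def transformed(bundle):
    return run_pipeline(bundle)


@pytest.fixture(scope="session")
def h5file(tmp_path_factory, bundle, transformed, arch):
    path = tmp_path_factory.mktemp("h5") / "cell.h5"
    write_recording(bundle, transformed, arch, path)
    return path
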