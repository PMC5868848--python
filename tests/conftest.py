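"""Shared fixtures: a default synthetic reference and mock dataset."""

import pytest

from modipkit.mockgen import (
    GeneratorConfig,
    build_background_set,
    build_mock_dataset,
    generate_reference,
    inject_modifications,
)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig()


@pytest.fixture(scope="session")
def ref(default_config):
    return generate_reference(default_config, seed=1)


@pytest.fixture(scope="session")
def dataset(ref, default_config):
    return build_mock_dataset(ref, default_config, seed=2)


@pytest.fixture(scope="session")
def modified(ref, dataset, default_config):
    return inject_modifications(dataset, default_config.n_modified, seed=3)


@pytest.fixture(scope="session")
def background(ref, dataset, default_config):
    return build_background_set(dataset, ref, default_config.n_background, seed=4)
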