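import warnings

import pytest

from coraltrade import pipeline, synth


@pytest.fixture(scope="session")
def default_config():
    return synth.SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One full synthetic study shared across test modules."""
    return synth.generate_dataset(default_config)


@pytest.fixture(scope="session")
def run(default_config, tmp_path_factory):
    """A complete pipeline run on the default synthetic study."""
    out = tmp_path_factory.mktemp("run")
    cfg = pipeline.RunConfig(output_dir=out, synth=default_config, seed=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return pipeline.run_full_analysis(cfg)


@pytest.fixture(scope="session")
def fast_config():
    """Small population without dissections/profiles, for replicate loops."""
    return synth.SyntheticConfig(
        n_colonies=20, fecundity_fraction=0.0, symbiont_fraction=0.0,
        growth_fraction=1.0, seed=11)
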