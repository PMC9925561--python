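import pytest
from hypothesis import HealthCheck, settings

from mitoplasmid.simulate import (CaptureScenario, GeneratorConfig,
                                  PlasmidScenario, generate_dataset)

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_dataset():
    """The standard 20-host study dataset (12 planted plasmids, 50 decoys/host)."""
    return generate_dataset(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A 3-host dataset: plain invertron, loss-planted capture, non-invertron."""
    cfg = GeneratorConfig(
        seed=3, n_hosts=3, n_decoys=6,
        plasmids=[
            PlasmidScenario(host=0),
            PlasmidScenario(host=1,
                            capture=CaptureScenario("Arg-TCG", loss=True,
                                                    donor_host=0)),
            PlasmidScenario(host=2, structure="non_invertron_linear"),
        ],
        tree_shape="((0,1),2);")
    return generate_dataset(cfg)
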