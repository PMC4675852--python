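import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_proteome():
    """A compact planted proteome: 6 tetraspanins, 3 decoys per class."""
    from tetmine.simulate import GeneratorSpec, make_proteome

    spec = GeneratorSpec(
        seed=11,
        n_tetraspanins=6,
        decoys={k: 3 for k in ["wrong_tm_count", "missing_motif", "ec2_smaller",
                               "long_tails", "few_cys"]},
    )
    return make_proteome(spec)


@pytest.fixture(scope="session")
def annotation_bundle():
    from tetmine.simulate import GeneratorSpec, make_annotation

    return make_annotation(GeneratorSpec(seed=11))


@pytest.fixture(scope="session")
def cq_bundle():
    from tetmine.simulate import GeneratorSpec, make_cq

    return make_cq(GeneratorSpec(seed=11))
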