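import pytest

from svforest.fixtures import FixtureSpec, generate_annotation_bundle, generate_labeled_svs, worked_feature_case


SMALL_SPEC = FixtureSpec(
    n_genes=30,
    n_chromosomes=5,
    n_pathogenic=40,
    n_benign_per_tier=(60,),
    seed=11,
)


@pytest.fixture(scope="session")
def small_spec():
    return SMALL_SPEC


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    out = tmp_path_factory.mktemp("bundle")
    return generate_annotation_bundle(SMALL_SPEC, out)


@pytest.fixture(scope="session")
def small_svs(small_bundle):
    pathogenic, tiers = generate_labeled_svs(SMALL_SPEC, small_bundle)
    return pathogenic, tiers


@pytest.fixture(scope="session")
def golden_case(tmp_path_factory):
    out = tmp_path_factory.mktemp("golden")
    return worked_feature_case(out)
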