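import pytest

from denovoprio import (AtlasConfig, QCThresholds, gen_expression_atlas,
                        gen_trio_vcf, load_mast4_events)


@pytest.fixture(scope="session")
def mast4_events():
    return load_mast4_events()


@pytest.fixture(scope="session")
def small_atlas():
    """120-gene atlas with a 30-gene latent module and 5 ramp genes."""
    return gen_expression_atlas(
        AtlasConfig(n_genes=120, n_module_genes=30, n_ramp_genes=5, seed=11)
    )


@pytest.fixture(scope="session")
def trio_vcf(tmp_path_factory):
    """A generated 200-site trio VCF together with its truth table."""
    path = tmp_path_factory.mktemp("vcf") / "trio.vcf"
    truth = gen_trio_vcf(path, n_sites=200, seed=5)
    return path, truth


@pytest.fixture
def thresholds():
    return QCThresholds()
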