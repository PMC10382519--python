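import pytest

from fbp_pheno.phenotype_stats import load_panel
from fbp_pheno.structure_context import load_context_table, load_site_annotations
from fbp_pheno.synthetic_data import index_family_trio, write_trio_ped, write_trio_vcf


@pytest.fixture(scope="session")
def panel():
    """The packaged 15-mutation measurement panel."""
    return load_panel()


@pytest.fixture(scope="session")
def sites():
    return load_site_annotations()


@pytest.fixture(scope="session")
def ctx_table():
    return load_context_table()


@pytest.fixture(scope="session")
def index_trio_files(tmp_path_factory):
    """VCF + PED for the index family's FBP1 compound het (plus filter fodder)."""
    d = tmp_path_factory.mktemp("index_trio")
    truth = index_family_trio()
    write_trio_vcf(truth, d / "trio.vcf")
    write_trio_ped(d / "trio.ped")
    return d / "trio.vcf", d / "trio.ped", truth
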