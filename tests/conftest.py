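from pathlib import Path
from types import SimpleNamespace

import pytest

from trioscreen import synthetic_cohort as sc
from trioscreen.core import GeneModel
from trioscreen.screening_pipeline import (
    ScreenConfig,
    load_screen_inputs,
    run_screen,
)

DATA_DIR = Path(__file__).parent / "data"


def load_bundle(bundle):
    """Read every file of a bundle back through the public readers."""
    inputs, region_set, genes = load_screen_inputs(
        vcf=bundle.vcf,
        ped=bundle.ped,
        cytobands=bundle.cytobands,
        gene_models=bundle.gene_models,
        expression=bundle.expression,
        annotations=bundle.annotations,
        susceptible_bands=bundle.susceptible_bands,
        gene_set=bundle.gene_set,
    )
    return inputs, region_set, genes


@pytest.fixture(scope="session")
def paper_bundle(tmp_path_factory):
    return sc.reconstruct_paper_fixture(tmp_path_factory.mktemp("paper_fixture"))


@pytest.fixture(scope="session")
def paper_run(paper_bundle):
    """Both screening arms executed on the reconstructed published cohort."""
    inputs, region_set, genes = load_bundle(paper_bundle)
    regions = run_screen(
        ScreenConfig(arm="susceptible_regions", region_set=region_set), inputs
    )
    geneset = run_screen(
        ScreenConfig(arm="gene_set", gene_set=genes, region_set=region_set),
        inputs,
    )
    return SimpleNamespace(
        bundle=paper_bundle, inputs=inputs, region_set=region_set,
        genes=genes, regions=regions, geneset=geneset,
    )


@pytest.fixture(scope="session")
def generated(tmp_path_factory):
    """One default generated cohort plus its truth table and screen run."""
    out = tmp_path_factory.mktemp("generated")
    bundle, truth = sc.generate(sc.GeneratorConfig(seed=7), out)
    inputs, region_set, _ = load_bundle(bundle)
    result = run_screen(
        ScreenConfig(arm="susceptible_regions", region_set=region_set), inputs
    )
    return SimpleNamespace(
        bundle=bundle, truth=truth, inputs=inputs, region_set=region_set,
        result=result,
    )


@pytest.fixture
def toy_gene_plus() -> GeneModel:
    """Three-exon plus-strand gene: exons [100,400) [1000,1600) [2400,3000),
    CDS [200,2700), 1 kb promoter."""
    return GeneModel(
        gene="TOY1", chrom="7", strand="+",
        tx_start=100, tx_end=3000, cds_start=200, cds_end=2700,
        exon_starts=(100, 1000, 2400), exon_ends=(400, 1600, 3000),
        promoter_len=1000,
    )


@pytest.fixture
def toy_gene_minus() -> GeneModel:
    """Mirror-image minus-strand gene with the same exon layout."""
    return GeneModel(
        gene="TOY2", chrom="7", strand="-",
        tx_start=100, tx_end=3000, cds_start=200, cds_end=2700,
        exon_starts=(100, 1000, 2400), exon_ends=(400, 1600, 3000),
        promoter_len=1000,
    )
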