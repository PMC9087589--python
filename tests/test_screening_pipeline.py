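"""Screening stages: genic-region assignment, expression filter, parent
exclusion, frequency, arm orchestration."""

import random

import pytest

from trioscreen.core import (
    CohortModel,
    GenicRegion,
    GenotypeCategory,
    RegionSet,
    Trio,
    VariantSite,
)
from trioscreen.io_formats import GenotypeMatrix, write_candidate_table
from trioscreen.screening_pipeline import (
    ScreenConfig,
    assign_genic_region,
    cohort_parent_exclusion,
    compute_cohort_frequency,
    filter_by_expression,
    overlap_matrix,
    run_screen,
)

from conftest import load_bundle


# ---------------------------------------------------------------------------
# Genic regions


@pytest.mark.parametrize(
    "pos0,expected",
    [
        (250, GenicRegion.EXON),        # inside CDS, exon1
        (1200, GenicRegion.EXON),       # exon2
        (150, GenicRegion.UTR5),        # exon1 before CDS start
        (2800, GenicRegion.UTR3),       # exon3 after CDS end
        (50, GenicRegion.PROMOTER),     # upstream of TSS (plen 1000)
        (700, GenicRegion.INTRON),      # between exon1 and exon2
        (4500, GenicRegion.INTERGENIC),
    ],
)
def test_genic_region_plus_strand(toy_gene_plus, pos0, expected):
    site = VariantSite("7", pos0 + 1, "A", "G")
    assert assign_genic_region(site, toy_gene_plus) == expected


@pytest.mark.parametrize(
    "pos0,expected",
    [
        (150, GenicRegion.UTR3),        # 5' exon end is 3' on minus strand
        (2800, GenicRegion.UTR5),
        (3200, GenicRegion.PROMOTER),   # downstream in + coords = upstream
        (50, GenicRegion.INTERGENIC),   # would be promoter on + strand
    ],
)
def test_genic_region_minus_strand(toy_gene_minus, pos0, expected):
    site = VariantSite("7", pos0 + 1, "A", "G")
    assert assign_genic_region(site, toy_gene_minus) == expected


def test_promoter_length_is_configurable(toy_gene_plus):
    site = VariantSite("7", 51, "A", "G")  # 50 bp before TSS at 100
    assert assign_genic_region(site, toy_gene_plus, promoter_len=40) == (
        GenicRegion.INTERGENIC
    )
    assert assign_genic_region(site, toy_gene_plus, promoter_len=60) == (
        GenicRegion.PROMOTER
    )


# ---------------------------------------------------------------------------
# Expression filter


def test_expression_filter_boundary_is_strict():
    """'lower than RPKM = 1' reads strictly: exactly 1.0 survives."""
    site = lambda p: VariantSite("1", p, "A", "G")  # noqa: E731
    items = [(site(1), "LOW"), (site(2), "BOUNDARY"), (site(3), "ABSENT")]
    kept, dropped = filter_by_expression(
        items, {"LOW": 0.5, "BOUNDARY": 1.0}, threshold=1.0
    )
    assert [g for _s, g in kept] == ["BOUNDARY"]
    assert dropped[site(1).key] == "low_expression"
    assert dropped[site(3).key] == "gene_missing_expression"


# ---------------------------------------------------------------------------
# Parent exclusion


def _two_trio_setup(parent_dosages):
    """Cohort of two trios; site dosages: children fixed, parents given as
    {sample: dosage}."""
    trios = [Trio("C1", "M1", "F1"), Trio("C2", "M2", "F2")]
    cohort = CohortModel(
        trios=trios,
        sample_sex={s: "female" for t in trios for s in (t.child, t.mother, t.father)},
        affected={
            **{t.child: "affected" for t in trios},
            **{p: "unaffected" for t in trios for p in (t.mother, t.father)},
        },
    )
    site = VariantSite("1", 100, "A", "G")
    dosages = {s: 0 for s in cohort.samples}
    dosages.update(parent_dosages)
    matrix = GenotypeMatrix(
        samples=list(cohort.samples),
        dosages={site: tuple(dosages[s] for s in cohort.samples)},
    )
    return site, matrix, cohort


def test_homo_candidate_dropped_when_any_parent_hom_alt():
    site, matrix, cohort = _two_trio_setup({"C1": 2, "M1": 1, "F1": 1, "M2": 2})
    keep, reason = cohort_parent_exclusion(
        site, GenotypeCategory.HOMO_INHERIT, matrix, cohort
    )
    assert not keep and reason == "parent_exclusion"


def test_homo_inherit_survives_its_own_het_parents():
    """The carrier's parents are het by definition; only a hom-alt parent
    anywhere in the cohort excludes the candidate."""
    site, matrix, cohort = _two_trio_setup({"C1": 2, "M1": 1, "F1": 1})
    keep, _ = cohort_parent_exclusion(
        site, GenotypeCategory.HOMO_INHERIT, matrix, cohort
    )
    assert keep


def test_gain_candidate_dropped_when_unrelated_parent_carries():
    site, matrix, cohort = _two_trio_setup({"C1": 1, "M2": 1})
    keep, _ = cohort_parent_exclusion(
        site, GenotypeCategory.HETERO_GAIN, matrix, cohort
    )
    assert not keep


def test_any_carrier_mode_drops_on_het_parent_regardless_of_category():
    site, matrix, cohort = _two_trio_setup({"C1": 2, "M1": 1, "F1": 1})
    keep, _ = cohort_parent_exclusion(
        site, GenotypeCategory.HOMO_INHERIT, matrix, cohort, mode="any_carrier"
    )
    assert not keep


def test_exempt_parents_are_skipped_for_compound_members():
    site, matrix, cohort = _two_trio_setup({"C1": 1, "M1": 1})
    keep, _ = cohort_parent_exclusion(
        site, GenotypeCategory.COMPOUND_HETERO_GAIN, matrix, cohort,
        exempt_parents=frozenset({"M1"}),
    )
    assert keep


# ---------------------------------------------------------------------------
# Frequency


def test_cohort_frequency_rendering():
    n, freq, ordered = compute_cohort_frequency(["100", "99"], 25)
    assert (n, freq, ordered) == (2, "2/25", ["99", "100"])


def test_zero_carriers_is_an_error():
    with pytest.raises(ValueError):
        compute_cohort_frequency([], 25)


# ---------------------------------------------------------------------------
# Orchestration on the generated cohort


def test_stage_outputs_are_monotone_nonincreasing(generated):
    counts = [s["n_out"] for s in generated.result.stage_log]
    assert all(b <= a for a, b in zip(counts, counts[1:]))


def test_frequency_conservation(generated):
    """Sum of carrier counts equals surviving (child, candidate) events."""
    total = sum(c.n_carriers for c in generated.result.candidates)
    events = sum(
        len(c.per_child_category) for c in generated.result.candidates
    )
    assert total == events


def test_order_robustness_under_vcf_permutation(tmp_path, generated):
    """Shuffling VCF record order leaves the written candidate table
    byte-identical."""
    lines = generated.bundle.vcf.read_text().splitlines(keepends=True)
    header = [l for l in lines if l.startswith("#")]
    body = [l for l in lines if not l.startswith("#")]
    random.Random(123).shuffle(body)
    shuffled = tmp_path / "shuffled.vcf"
    shuffled.write_text("".join(header + body))

    class B:  # bundle view with the shuffled VCF
        pass

    b = B()
    for attr in ("ped", "cytobands", "gene_models", "expression",
                 "annotations", "susceptible_bands", "gene_set"):
        setattr(b, attr, getattr(generated.bundle, attr))
    b.vcf = shuffled
    inputs, region_set, _ = load_bundle(b)
    result = run_screen(
        ScreenConfig(arm="susceptible_regions", region_set=region_set), inputs
    )
    t1, t2 = tmp_path / "orig.tsv", tmp_path / "shuf.tsv"
    write_candidate_table(generated.result.candidates, t1)
    write_candidate_table(result.candidates, t2)
    assert t1.read_bytes() == t2.read_bytes()


def test_empty_scope_yields_empty_result(generated):
    cfg = ScreenConfig(
        arm="susceptible_regions",
        region_set=RegionSet(bands=["none"], intervals={}),
    )
    result = run_screen(cfg, generated.inputs)
    assert result.candidates == []


def test_empty_cohort_is_fatal(generated):
    cfg = ScreenConfig(
        arm="susceptible_regions", region_set=generated.region_set
    )
    inputs = generated.inputs
    broken = type(inputs)(
        matrix=inputs.matrix,
        cohort=inputs.cohort,
        gene_models=inputs.gene_models,
        expression=inputs.expression,
    )
    broken.cohort = CohortModel.__new__(CohortModel)  # bypass validation
    broken.cohort.trios = []
    with pytest.raises(ValueError, match="empty cohort"):
        run_screen(cfg, broken)


# ---------------------------------------------------------------------------
# Arm interplay and the overlap matrix


def test_gene_set_arm_excludes_susceptible_region_genes(paper_run):
    """A dopamine-set gene inside a susceptible band contributes no
    gene-set-arm candidates (the arms partition the genome)."""
    genes_arm2 = {c.gene for c in paper_run.geneset.candidates}
    assert "CACNA1H" in paper_run.genes
    assert "CACNA1H" not in genes_arm2
    # its site is dropped with the dedicated reason
    cacna1h = [
        c for c in paper_run.regions.candidates if c.gene == "CACNA1H"
    ]
    assert cacna1h, "CACNA1H must still appear in the regions arm"
    key = cacna1h[0].site.key
    assert paper_run.geneset.drop_reasons[key] == "in_susceptible_region"


def test_overlap_matrix_membership(paper_run):
    m = overlap_matrix(
        paper_run.genes, paper_run.region_set, paper_run.inputs.gene_models
    )
    assert bool(m.loc["CACNA1H", "in_gene_set"])
    assert bool(m.loc["CACNA1H", "in_susceptible_region"])
    assert bool(m.loc["FLNA", "in_gene_set"])
    assert not bool(m.loc["FLNA", "in_susceptible_region"])
    assert not bool(m.loc["MKI67", "in_gene_set"])
    assert bool(m.loc["MKI67", "in_susceptible_region"])


def test_overlap_matrix_flags_unknown_gene(paper_run):
    m = overlap_matrix(
        ["NOSUCHGENE"], paper_run.region_set, paper_run.inputs.gene_models
    )
    assert bool(m.loc["NOSUCHGENE", "unknown"])
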