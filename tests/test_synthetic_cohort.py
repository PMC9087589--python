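"""Generator contracts: determinism, cohort arithmetic, truth consistency,
decoy isolation, and the published-table fixture."""

import hashlib
from pathlib import Path

import pytest

from trioscreen import synthetic_cohort as sc
from trioscreen.core import GenotypeCategory
from trioscreen.screening_pipeline import ScreenConfig, run_screen

from conftest import load_bundle


def bundle_digest(root: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(root.iterdir()):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def test_generated_cohort_has_75_samples(generated):
    """25 trios give 75 VCF sample columns."""
    assert generated.inputs.cohort.n_trios == 25
    assert len(generated.inputs.matrix.samples) == 75


def test_same_seed_gives_byte_identical_bundle(tmp_path):
    cfg = sc.GeneratorConfig(seed=11, n_trios=6, n_background_sites=10)
    b1, _ = sc.generate(cfg, tmp_path / "a")
    b2, _ = sc.generate(cfg, tmp_path / "b")
    assert bundle_digest(b1.root) == bundle_digest(b2.root)


def test_different_seed_changes_bundle(tmp_path):
    b1, _ = sc.generate(sc.GeneratorConfig(seed=1, n_trios=6), tmp_path / "a")
    b2, _ = sc.generate(sc.GeneratorConfig(seed=2, n_trios=6), tmp_path / "b")
    assert bundle_digest(b1.root) != bundle_digest(b2.root)


def test_every_truth_site_is_in_the_vcf(generated):
    sites = set(generated.inputs.matrix.dosages)
    for row in generated.truth.rows:
        assert row.site in sites


def test_truth_consistency_on_generated_cohort(generated):
    """The pipeline recovers exactly the expected survivors, and every
    decoy is dropped for its intended reason."""
    got = {
        (c.site.key, c.category.value): tuple(c.carriers)
        for c in generated.result.candidates
    }
    expected = {
        (t.site.key, t.expected_category): t.carriers
        for t in generated.truth.survivors
    }
    assert got == expected
    for t in generated.truth.rows:
        if not t.expected_to_survive:
            assert generated.result.drop_reasons.get(t.site.key) == (
                t.expected_drop_reason
            ), f"{t.klass} at {t.site.key}"


@pytest.mark.parametrize("decoy_class,switch", [
    ("out_of_region", "skip_scope"),
    ("parental_hom_carrier", "skip_exclusion"),
    ("low_expression_gene", "expression_off"),
])
def test_decoy_fails_exactly_its_own_filter(tmp_path, decoy_class, switch):
    """Disabling the decoy's target filter lets it through; all other
    filters leave it untouched."""
    bundle, truth = sc.generate(sc.GeneratorConfig(seed=3), tmp_path)
    inputs, region_set, _ = load_bundle(bundle)
    kwargs = dict(arm="susceptible_regions", region_set=region_set)
    if switch == "skip_scope":
        kwargs["skip_scope"] = True
    elif switch == "skip_exclusion":
        kwargs["skip_exclusion"] = True
    else:
        kwargs["apply_expression_filter"] = False
    result = run_screen(ScreenConfig(**kwargs), inputs)
    surviving_keys = {c.site.key for c in result.candidates}
    decoys = [t for t in truth.rows if t.klass == decoy_class]
    assert decoys
    for t in decoys:
        assert t.site.key in surviving_keys, (
            f"{decoy_class} should survive when its filter is disabled"
        )


def test_impossible_configs_are_fatal():
    with pytest.raises(ValueError):
        sc.GeneratorConfig(n_trios=0)
    with pytest.raises(ValueError):
        sc.GeneratorConfig(n_hetero_gain=-1)
    with pytest.raises(ValueError):
        sc.GeneratorConfig(background_rate=1.5)


def test_planted_frequency_matches_published_pattern(tmp_path):
    """Planting an inherited homozygote in one gene for three children
    yields the printed-style 3/25 frequency."""
    cfg = sc.GeneratorConfig(
        seed=5, n_trios=25, n_homo_gain=0, n_hetero_gain=0,
        n_homo_inherit=1, n_compound_hetero=0, n_x_homo_gain=0,
        n_inherited_het=0, n_parental_hom_carrier=0, n_low_expression=0,
        n_out_of_region=0, n_missing_genotype=0, n_background_sites=0,
    )
    bundle, truth = sc.generate(cfg, tmp_path)
    inputs, region_set, _ = load_bundle(bundle)
    result = run_screen(
        ScreenConfig(arm="susceptible_regions", region_set=region_set), inputs
    )
    assert len(result.candidates) == 1
    c = result.candidates[0]
    t = truth.survivors[0]
    assert c.frequency == f"{len(t.carriers)}/25"
    assert tuple(c.carriers) == t.carriers


# ---------------------------------------------------------------------------
# Published-table fixture


def test_fixture_is_deterministic(tmp_path):
    b1 = sc.reconstruct_paper_fixture(tmp_path / "a")
    b2 = sc.reconstruct_paper_fixture(tmp_path / "b")
    assert bundle_digest(b1.root) == bundle_digest(b2.root)


def test_fixture_regions_arm_recovers_every_published_row(paper_run):
    """All candidate rows of the susceptible-region tables come back with
    matching category, region and carriers."""
    expected = paper_run.bundle.expected_rows
    exp = expected[expected.table.isin([1, 2])]
    got = {c.site.site_id: c for c in paper_run.regions.candidates}
    assert len(paper_run.regions.candidates) == len(exp)
    for row in exp.itertuples():
        c = got[row.snv_id]
        assert c.gene == row.gene
        assert c.category.value == row.category
        assert c.genic_region.value == row.region
        assert c.carriers_field == row.carriers
        assert c.cytoband == row.band


def test_fixture_geneset_arm_recovers_dopamine_rows(paper_run):
    expected = paper_run.bundle.expected_rows
    exp = expected[expected.table == 3]
    got = {
        (c.site.site_id, c.gene): c for c in paper_run.geneset.candidates
    }
    assert len(paper_run.geneset.candidates) == len(exp)
    for row in exp.itertuples():
        c = got[(row.snv_id, row.gene)]
        assert c.category.value == row.category
        assert c.carriers_field == row.carriers


def test_fixture_hemizygous_x_sites_classify_as_homo_gain(paper_run):
    flna = [c for c in paper_run.geneset.candidates if c.gene == "FLNA"]
    assert len(flna) == 2
    for c in flna:
        assert c.category == GenotypeCategory.HOMO_GAIN
        sexes = {
            paper_run.inputs.cohort.sample_sex[ch] for ch in c.carriers
        }
        assert sexes == {"male"}
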