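"""Genotype-category classification: oracle agreement, invariants,
origin calls and compound-het pairing."""

import itertools

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trioscreen.core import (
    GenotypeCategory,
    Origin,
    PloidyContext,
    TrioGenotype,
    VariantSite,
)
from trioscreen.trio_classifier import (
    call_origin,
    classify_site,
    classify_site_detail,
    find_compound_het,
)

from conftest import DATA_DIR

SITE = VariantSite("1", 1000, "A", "G")
XSITE = VariantSite("X", 1000, "C", "T")


def tg(child, mother, father, sex="female", chrom_site=SITE,
       ctx=PloidyContext.AUTOSOMAL):
    return TrioGenotype(site=chrom_site, child=child, mother=mother,
                        father=father, child_sex=sex, ploidy_context=ctx)


def test_classifier_matches_committed_lookup_table():
    """Every dosage combination agrees with the hand-written oracle,
    including hemizygous male-X rows."""
    oracle = pd.read_csv(DATA_DIR / "classify_oracle.tsv", sep="\t")
    assert len(oracle) >= 27 + 9
    for row in oracle.itertuples():
        ctx = PloidyContext(row.context)
        site = XSITE if ctx == PloidyContext.X_NONPAR else SITE
        got = classify_site(
            tg(row.child, row.mother, row.father, sex=row.child_sex,
               chrom_site=site, ctx=ctx)
        )
        assert got.value == row.category, (
            f"({row.child},{row.mother},{row.father}) ctx={row.context}: "
            f"got {got.value}, oracle says {row.category}"
        )


def test_autosomal_oracle_is_exhaustive():
    oracle = pd.read_csv(DATA_DIR / "classify_oracle.tsv", sep="\t")
    auto = oracle[oracle.context == "autosomal"]
    combos = {(r.child, r.mother, r.father) for r in auto.itertuples()}
    assert combos == set(itertools.product(range(3), repeat=3))


def test_missing_dosage_disqualifies_trio():
    for pattern in [(None, 0, 0), (1, None, 0), (2, 1, None)]:
        call = classify_site_detail(tg(*pattern))
        assert call.category == GenotypeCategory.NONE
        assert call.reason == "missing"


def test_double_de_novo_is_flagged_homo_gain():
    call = classify_site_detail(tg(2, 0, 0))
    assert call.category == GenotypeCategory.HOMO_GAIN
    assert call.reason == "double_de_novo"


def test_mendelian_error_combinations_are_none_and_flagged():
    # child hom-ref with an obligate-transmitting parent
    call = classify_site_detail(tg(0, 2, 0))
    assert call.category == GenotypeCategory.NONE
    assert call.reason == "mendelian_error"
    call = classify_site_detail(tg(1, 2, 2))
    assert call.category == GenotypeCategory.NONE
    assert call.reason == "mendelian_error"


def test_invalid_dosage_is_fatal():
    with pytest.raises(ValueError):
        tg(3, 0, 0)


@given(
    child=st.sampled_from([0, 1, 2]),
    mother=st.sampled_from([0, 1, 2]),
    father=st.sampled_from([0, 1, 2]),
)
@settings(derandomize=True, max_examples=27)
def test_autosomal_symmetry_under_parent_swap(child, mother, father):
    """Swapping mother and father never changes an autosomal call."""
    assert classify_site(tg(child, mother, father)) == classify_site(
        tg(child, father, mother)
    )


def test_mendelian_sanity_over_all_combinations():
    """homo_inherit implies both parents carry; hetero_gain implies neither
    does; each combination maps to exactly one category."""
    for c, m, f in itertools.product(range(3), repeat=3):
        cat = classify_site(tg(c, m, f))
        assert isinstance(cat, GenotypeCategory)
        if cat == GenotypeCategory.HOMO_INHERIT:
            assert m >= 1 and f >= 1
        if cat == GenotypeCategory.HETERO_GAIN:
            assert m == 0 and f == 0
        if cat == GenotypeCategory.HOMO_GAIN:
            assert c == 2 and (m == 0 or f == 0)


def test_hemizygous_child_normalised_to_dosage_two():
    g = tg(1, 0, 0, sex="male", chrom_site=XSITE, ctx=PloidyContext.X_NONPAR)
    assert g.child == 2
    assert classify_site(g) == GenotypeCategory.HOMO_GAIN


def test_male_x_ignores_father_genotype():
    for father in (0, 1, 2):
        g = tg(2, 1, father, sex="male", chrom_site=XSITE,
               ctx=PloidyContext.X_NONPAR)
        assert classify_site(g) == GenotypeCategory.HOMO_INHERIT


@pytest.mark.parametrize(
    "pattern,expected",
    [
        ((1, 1, 0), Origin.MATERNAL),
        ((1, 0, 1), Origin.PATERNAL),
        ((1, 0, 0), Origin.DE_NOVO),
        ((1, 1, 1), Origin.AMBIGUOUS),
        ((1, 2, 0), Origin.MATERNAL),
    ],
)
def test_call_origin(pattern, expected):
    assert call_origin(tg(*pattern)) == expected


def test_call_origin_requires_carrier_child():
    with pytest.raises(ValueError):
        call_origin(tg(0, 1, 0))


# ---------------------------------------------------------------------------
# Compound het


def _het_site(pos, mother, father, gene):
    site = VariantSite(gene.chrom, pos, "A", "G")
    return TrioGenotype(site=site, child=1, mother=mother, father=father)


def test_compound_het_pairing_over_origin_combinations(toy_gene_plus):
    """Enumerate origin pairs: a pair needs >=1 de novo member and a
    trans-compatible configuration."""
    gene = toy_gene_plus
    origin_patterns = {
        "de_novo": (0, 0),
        "maternal": (1, 0),
        "paternal": (0, 1),
        "ambiguous": (1, 1),
    }
    expected_pair = {
        ("de_novo", "de_novo"): True,
        ("de_novo", "maternal"): True,
        ("de_novo", "paternal"): True,
        ("de_novo", "ambiguous"): True,
        ("maternal", "maternal"): False,
        ("maternal", "paternal"): False,  # no de novo member
        ("paternal", "paternal"): False,
        ("maternal", "ambiguous"): False,
        ("paternal", "ambiguous"): False,
        ("ambiguous", "ambiguous"): False,
    }
    for (oa, ob), want in expected_pair.items():
        a = _het_site(201, *origin_patterns[oa], gene=gene)
        b = _het_site(1201, *origin_patterns[ob], gene=gene)
        pairs = find_compound_het(gene, [a, b])
        assert bool(pairs) == want, f"{oa}+{ob}"
        if pairs and "ambiguous" in (oa, ob):
            assert pairs[0].flags == ("phase_uncertain",)


def test_compound_het_single_site_yields_nothing(toy_gene_plus):
    a = _het_site(201, 0, 0, gene=toy_gene_plus)
    assert find_compound_het(toy_gene_plus, [a]) == []


def test_compound_het_rejects_non_het_input(toy_gene_plus):
    site = VariantSite("7", 201, "A", "G")
    hom = TrioGenotype(site=site, child=2, mother=1, father=1)
    with pytest.raises(ValueError):
        find_compound_het(toy_gene_plus, [hom])


def test_compound_het_rejects_site_outside_gene(toy_gene_plus):
    a = _het_site(201, 0, 0, gene=toy_gene_plus)
    outside = _het_site(5000, 1, 0, gene=toy_gene_plus)
    with pytest.raises(ValueError):
        find_compound_het(toy_gene_plus, [a, outside])
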