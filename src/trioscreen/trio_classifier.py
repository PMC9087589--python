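"""Per-trio genotype-category classification and compound-het pairing.

The single-site rules, written as alt-dosage patterns (child, mother,
father):

* ``hetero_gain``   — (1, 0, 0): a de novo heterozygote.
* ``homo_inherit``  — (2, 1, 1): a homozygote assembled from two het
  carrier parents.
* ``homo_gain``     — child 2 with at least one parent at dosage 0, i.e. at
  least one child allele is not attributable to a parent.
* everything else → ``none`` (inherited heterozygotes are not candidates).

Male non-PAR X: the child is hemizygous (alt normalised to dosage 2), the
father's X genotype is irrelevant, and only the mother's dosage decides —
mother 0 → ``homo_gain``, mother 1 or 2 → ``homo_inherit``.

``compound_hetero_gain`` is a gene-level call over pairs of child het
sites; it is never assigned from a single site in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

from .core import GeneModel, GenotypeCategory, Origin, TrioGenotype


@dataclass(frozen=True)
class SiteCall:
    category: GenotypeCategory
    reason: str = ""  # {"", "missing", "mendelian_error", "double_de_novo"}


def _mendelian_possible(child: int, mother: int, father: int) -> bool:
    # possible alleles transmitted by a parent with given dosage
    opts = {0: (0,), 1: (0, 1), 2: (1,)}
    return any(
        am + af == child for am in opts[mother] for af in opts[father]
    )


def classify_site_detail(tg: TrioGenotype) -> SiteCall:
    """Classify a trio at one site, with a reason tag for non-candidates."""
    c, m, f = tg.child, tg.mother, tg.father
    if tg.hemizygous_child:
        # father's X is ignored for male children
        if c is None or m is None:
            return SiteCall(GenotypeCategory.NONE, "missing")
        if c == 0:
            return SiteCall(GenotypeCategory.NONE)
        # child carries the alt (normalised to 2)
        if m == 0:
            return SiteCall(GenotypeCategory.HOMO_GAIN)
        return SiteCall(GenotypeCategory.HOMO_INHERIT)

    if c is None or m is None or f is None:
        return SiteCall(GenotypeCategory.NONE, "missing")
    if c == 1 and m == 0 and f == 0:
        return SiteCall(GenotypeCategory.HETERO_GAIN)
    if c == 2 and m == 1 and f == 1:
        return SiteCall(GenotypeCategory.HOMO_INHERIT)
    if c == 2 and (m == 0 or f == 0):
        reason = "double_de_novo" if (m == 0 and f == 0) else ""
        return SiteCall(GenotypeCategory.HOMO_GAIN, reason)
    reason = "" if _mendelian_possible(c, m, f) else "mendelian_error"
    return SiteCall(GenotypeCategory.NONE, reason)


def classify_site(tg: TrioGenotype) -> GenotypeCategory:
    """Single-site genotype category for one trio (see module docstring)."""
    return classify_site_detail(tg).category


def call_origin(tg: TrioGenotype) -> Origin:
    """Parental origin of a child's alt allele (child dosage >= 1 required)."""
    if tg.child is None or tg.child < 1:
        raise ValueError("call_origin requires a child carrying the alt allele")
    m_carries = tg.mother is not None and tg.mother >= 1
    f_carries = tg.father is not None and tg.father >= 1
    if m_carries and f_carries:
        return Origin.AMBIGUOUS
    if m_carries:
        return Origin.MATERNAL
    if f_carries:
        return Origin.PATERNAL
    return Origin.DE_NOVO


@dataclass(frozen=True)
class CompoundPair:
    """Two child het sites in one gene forming a putative trans pair."""

    gene: str
    a: TrioGenotype
    b: TrioGenotype
    origin_a: Origin
    origin_b: Origin
    flags: tuple[str, ...] = ()


def find_compound_het(
    gene: GeneModel, child_het_sites: Sequence[TrioGenotype]
) -> list[CompoundPair]:
    """Pair child het sites within a gene into compound-het candidates.

    A pair qualifies when at least one member is de novo (the screen groups
    compound hets under de novo gains) and the origins are compatible with a
    trans configuration (not both maternal, not both paternal).  Pairs with
    an ambiguous-origin member are retained, flagged ``phase_uncertain``.
    """
    for tg in child_het_sites:
        if tg.child != 1:
            raise ValueError(
                f"compound-het input at {tg.site.chrom}:{tg.site.pos} has "
                f"child dosage {tg.child}, expected 1"
            )
        if not (gene.tx_start <= tg.site.pos0 < gene.tx_end):
            raise ValueError(
                f"site {tg.site.chrom}:{tg.site.pos} outside {gene.gene} span"
            )
    pairs: list[CompoundPair] = []
    origins = [call_origin(tg) for tg in child_het_sites]
    for (i, a), (j, b) in combinations(enumerate(child_het_sites), 2):
        oa, ob = origins[i], origins[j]
        if Origin.DE_NOVO not in (oa, ob):
            continue
        if oa == ob == Origin.MATERNAL or oa == ob == Origin.PATERNAL:
            continue
        flags: tuple[str, ...] = ()
        if Origin.AMBIGUOUS in (oa, ob):
            flags = ("phase_uncertain",)
        pairs.append(
            CompoundPair(gene=gene.gene, a=a, b=b, origin_a=oa, origin_b=ob,
                         flags=flags)
        )
    return pairs
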