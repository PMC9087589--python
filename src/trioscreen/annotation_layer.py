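"""Join upstream functional annotations onto candidates and derive
categorical impact labels.

Annotations (protein-damage predictions, TF motif hits, miRNA-site hits,
population allele frequencies) are produced upstream by tools such as
ANNOVAR/PolyPhen-2/TRANSFAC/TargetScan and consumed here as a table; this
module never recomputes them.  Two derivations are applied on top:

* when a table supplies a PolyPhen-2 HDIV score without a category, the
  published HDIV bins are used (benign <= 0.452 < possibly damaging
  <= 0.956 < probably damaging);
* a start-codon loss (``p.M1X``) overrides any score-based label, since a
  lost start abolishes or truncates translation regardless of the
  missense score.
"""

from __future__ import annotations

import logging
import re
from typing import Mapping, Optional, Sequence

from .core import (
    AnnotationRecord,
    CandidateVariant,
    GenicRegion,
    ImpactCategory,
)

logger = logging.getLogger(__name__)

HDIV_BENIGN_MAX = 0.452
HDIV_POSSIBLY_MAX = 0.956

_AA_CHANGE_RE = re.compile(r"^p\.([A-Za-z\*])(\d+)([A-Za-z\*])$")


def join_annotations(
    candidates: Sequence[CandidateVariant],
    annotation_table: Mapping[tuple[str, int, str, str], AnnotationRecord],
) -> list[CandidateVariant]:
    """Left-join annotations onto candidates in place (lossless: unmatched
    candidates keep an empty record and are retained)."""
    for c in candidates:
        rec = annotation_table.get(c.site.key)
        if rec is not None:
            c.annotations = rec
    return list(candidates)


def impact_category_from_score(score: float) -> ImpactCategory:
    """Bin a PolyPhen-2 HDIV score into its published category."""
    if not (0.0 <= score <= 1.0):
        raise ValueError(f"HDIV score {score} outside [0, 1]")
    if score <= HDIV_BENIGN_MAX:
        return ImpactCategory.BENIGN
    if score <= HDIV_POSSIBLY_MAX:
        return ImpactCategory.POSSIBLY_DAMAGING
    return ImpactCategory.PROBABLY_DAMAGING


def derive_impact_category(candidate: CandidateVariant) -> CandidateVariant:
    """Fill ``impact_category`` from the score when the table omitted it."""
    ann = candidate.annotations
    if ann.impact_category is None and ann.impact_score is not None:
        ann.impact_category = impact_category_from_score(ann.impact_score)
    return candidate


def parse_aa_change(aa_change: str) -> Optional[tuple[str, int, str]]:
    """Parse ``p.<ref><pos><alt>`` single-letter protein change strings."""
    m = _AA_CHANGE_RE.match(aa_change.strip())
    if not m:
        return None
    return (m.group(1), int(m.group(2)), m.group(3))


def apply_start_loss_override(candidate: CandidateVariant) -> CandidateVariant:
    """Relabel a variant hitting the initiator methionine as ``start_loss``.

    Triggered when the protein change is at residue 1, the reference residue
    is M and the alternate is not; the override supersedes any score-based
    category.  Unparseable strings leave the candidate unchanged (warned).
    """
    ann = candidate.annotations
    if not ann.aa_change:
        return candidate
    parsed = parse_aa_change(ann.aa_change)
    if parsed is None:
        logger.warning(
            "unparseable AA change %r at %s:%d; start-loss override skipped",
            ann.aa_change, candidate.site.chrom, candidate.site.pos,
        )
        return candidate
    ref_aa, pos, alt_aa = parsed
    if pos == 1 and ref_aa == "M" and alt_aa != "M":
        ann.impact_category = ImpactCategory.START_LOSS
    return candidate


def regulatory_impact(candidate: CandidateVariant) -> str:
    """Classify a candidate's regulatory-site hit.

    ``tf_site_hit`` requires a TF motif annotation on a promoter variant;
    ``mirna_site_hit`` requires a miRNA-site annotation on a 3'-UTR variant.
    A site annotation outside the matching region is kept but flagged
    inconsistent rather than silently dropped.
    """
    ann = candidate.annotations
    hit = "none"
    if ann.tf_site is not None:
        if candidate.genic_region == GenicRegion.PROMOTER:
            hit = "tf_site_hit"
        else:
            candidate.flags.append("tf_site_outside_promoter")
    if ann.mirna_site is not None:
        if candidate.genic_region == GenicRegion.UTR3:
            hit = "mirna_site_hit"
        else:
            candidate.flags.append("mirna_site_outside_utr3")
    candidate.regulatory_hit = hit
    return hit


def annotate_candidates(
    candidates: Sequence[CandidateVariant],
    annotation_table: Mapping[tuple[str, int, str, str], AnnotationRecord],
) -> list[CandidateVariant]:
    """Full annotation pass: join, score-derived categories, start-loss
    override, regulatory-site classification."""
    out = join_annotations(candidates, annotation_table)
    for c in out:
        derive_impact_category(c)
        apply_start_loss_override(c)
        regulatory_impact(c)
    return out
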