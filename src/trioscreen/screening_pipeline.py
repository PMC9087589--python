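"""The two-arm screening procedure, end to end.

Stage order (each stage only removes sites, never adds):

1. scope restriction — arm 1 keeps sites inside the susceptible-region
   cytoband set; arm 2 keeps sites on the configured gene set and, when a
   susceptible-region set is supplied, additionally excludes sites inside
   it (the arms are disjoint by construction);
2. gene/genic-region assignment (a site in two genes yields two rows);
3. brain-expression filter (genes below the RPKM cutoff are dropped);
4. per-trio genotype-category classification, including gene-level
   compound-het pairing;
5. cohort-wide unaffected-parent exclusion;
6. cohort-frequency computation and annotation join.

Output order is deterministic: (chromosome, position, alt, gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from .annotation_layer import annotate_candidates
from .core import (
    AnnotationRecord,
    CandidateVariant,
    CohortModel,
    GeneModel,
    GenicRegion,
    GenotypeCategory,
    Origin,
    RegionSet,
    TrioGenotype,
    VariantSite,
    ploidy_context_for,
)
from . import io_formats
from .io_formats import GenotypeMatrix, band_of_site
from .trio_classifier import classify_site_detail, find_compound_het

logger = logging.getLogger(__name__)

HOMO_CATEGORIES = frozenset(
    {GenotypeCategory.HOMO_INHERIT, GenotypeCategory.HOMO_GAIN}
)
HET_CATEGORIES = frozenset(
    {GenotypeCategory.HETERO_GAIN, GenotypeCategory.COMPOUND_HETERO_GAIN}
)


@dataclass
class ScreenConfig:
    """Configuration of one screening run (one arm active at a time)."""

    arm: str = "susceptible_regions"  # or "gene_set"
    region_set: Optional[RegionSet] = None
    gene_set: Optional[list[str]] = None
    rpkm_threshold: float = 1.0
    promoter_len: int = 1000
    cohort_exclusion_mode: str = "genotype_match"  # or "any_carrier"
    apply_expression_filter: bool = True
    # diagnostic switches (used to probe which filter removes a site)
    skip_scope: bool = False
    skip_exclusion: bool = False

    def __post_init__(self) -> None:
        if self.arm not in ("susceptible_regions", "gene_set"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.rpkm_threshold < 0:
            raise ValueError("rpkm_threshold must be >= 0")
        if self.cohort_exclusion_mode not in ("genotype_match", "any_carrier"):
            raise ValueError(
                f"unknown exclusion mode {self.cohort_exclusion_mode!r}"
            )
        if self.arm == "susceptible_regions" and self.region_set is None:
            raise ValueError("susceptible_regions arm requires a region set")
        if self.arm == "gene_set" and not self.gene_set:
            raise ValueError("gene_set arm requires a gene list")


@dataclass
class ScreenInputs:
    matrix: GenotypeMatrix
    cohort: CohortModel
    gene_models: dict[str, GeneModel]
    expression: Mapping[str, float]
    annotations: Mapping[tuple[str, int, str, str], AnnotationRecord] = field(
        default_factory=dict
    )
    cytoband_table: Optional[pd.DataFrame] = None


@dataclass
class ScreenResult:
    candidates: list[CandidateVariant]
    stage_log: list[dict]
    drop_reasons: dict[tuple[str, int, str, str], str]

    def candidate_by_id(self, site_id: str) -> CandidateVariant:
        for c in self.candidates:
            if c.site.site_id == site_id:
                return c
        raise KeyError(site_id)


# ---------------------------------------------------------------------------
# Single operations


def assign_genic_region(
    site: VariantSite, model: GeneModel, promoter_len: Optional[int] = None
) -> GenicRegion:
    """Strand-aware genic-region assignment with precedence
    exon > utr5 > utr3 > promoter > intron > intergenic."""
    if site.chrom != model.chrom:
        raise ValueError(
            f"site on {site.chrom} vs model {model.gene} on {model.chrom}"
        )
    p = site.pos0
    in_exon = any(s <= p < e for s, e in zip(model.exon_starts, model.exon_ends))
    if in_exon:
        if model.cds_start <= p < model.cds_end:
            return GenicRegion.EXON
        if p < model.cds_start:
            return GenicRegion.UTR5 if model.strand == "+" else GenicRegion.UTR3
        return GenicRegion.UTR3 if model.strand == "+" else GenicRegion.UTR5
    ps, pe = model.promoter_span(promoter_len)
    if ps <= p < pe:
        return GenicRegion.PROMOTER
    if model.tx_start <= p < model.tx_end:
        return GenicRegion.INTRON
    return GenicRegion.INTERGENIC


def filter_by_expression(
    candidates: Sequence[tuple], expression: Mapping[str, float], threshold: float,
) -> tuple[list, dict]:
    """Keep (site, gene, ...) tuples whose gene has RPKM >= threshold.

    Genes absent from the table are dropped with a distinct reason.  Returns
    (kept, {site_key: reason}).
    """
    kept, dropped = [], {}
    for item in candidates:
        site, gene = item[0], item[1]
        rpkm = expression.get(gene)
        if rpkm is None:
            dropped[site.key] = "gene_missing_expression"
            logger.warning("gene %s absent from expression table; dropped", gene)
        elif rpkm < threshold:
            dropped[site.key] = "low_expression"
        else:
            kept.append(item)
    return kept, dropped


def cohort_parent_exclusion(
    site: VariantSite,
    category: GenotypeCategory,
    matrix: GenotypeMatrix,
    cohort: CohortModel,
    mode: str = "genotype_match",
    exempt_parents: frozenset = frozenset(),
) -> tuple[bool, str]:
    """Decide whether a classified candidate survives the cohort-wide
    unaffected-parent check.  Returns (keep, reason).

    ``genotype_match`` drops a child-homozygous candidate when any cohort
    parent is hom-alt, and a child-heterozygous (gain) candidate when any
    parent carries the alt at all; ``any_carrier`` drops on any carrier
    parent regardless of category.  ``exempt_parents`` excludes the carrier
    trio's own parents for inherited alleles of compound-het members.
    """
    parents = cohort.parents
    for p in parents:
        d = matrix.dosage(site, p)
        if d is None:
            continue
        if mode == "any_carrier":
            if d >= 1 and p not in exempt_parents:
                return (False, "parent_exclusion")
        elif category in HOMO_CATEGORIES:
            if d == 2:
                return (False, "parent_exclusion")
        else:  # het/gain categories
            if d >= 1 and p not in exempt_parents:
                return (False, "parent_exclusion")
    return (True, "")


def compute_cohort_frequency(
    carriers: Sequence[str], n_children: int
) -> tuple[int, str, list[str]]:
    """Carrier count and rendered frequency string, carriers in ascending
    sample-ID order (numeric when IDs are numeric)."""
    if not carriers:
        raise ValueError("zero carriers should have been removed upstream")
    try:
        ordered = sorted(carriers, key=lambda s: int(s))
    except ValueError:
        ordered = sorted(carriers)
    return (len(ordered), f"{len(ordered)}/{n_children}", list(ordered))


def overlap_matrix(
    gene_set: Sequence[str],
    region_set: RegionSet,
    gene_models: Mapping[str, GeneModel],
) -> pd.DataFrame:
    """Gene x {in_gene_set, in_susceptible_region} membership table.

    A gene is in the susceptible region iff its transcript span intersects
    the region set; genes without a model are flagged unknown.
    """
    genes = sorted(set(gene_set) | set(gene_models))
    rows = []
    gs = set(gene_set)
    for g in genes:
        model = gene_models.get(g)
        if model is None:
            rows.append((g, g in gs, False, True))
        else:
            in_region = region_set.overlaps(model.chrom, model.tx_start, model.tx_end)
            rows.append((g, g in gs, in_region, False))
    return pd.DataFrame(
        rows, columns=["gene", "in_gene_set", "in_susceptible_region", "unknown"]
    ).set_index("gene")


# ---------------------------------------------------------------------------
# Orchestration


def _trio_genotype(
    site: VariantSite, matrix: GenotypeMatrix, cohort: CohortModel, trio
) -> TrioGenotype:
    return TrioGenotype(
        site=site,
        child=matrix.dosage(site, trio.child),
        mother=matrix.dosage(site, trio.mother),
        father=matrix.dosage(site, trio.father),
        child_sex=cohort.sample_sex.get(trio.child, "unknown"),
        ploidy_context=ploidy_context_for(site.chrom),
    )


def run_screen(config: ScreenConfig, inputs: ScreenInputs) -> ScreenResult:
    """Execute the configured screening arm over the cohort matrix."""
    matrix, cohort = inputs.matrix, inputs.cohort
    if not cohort.trios:
        raise ValueError("empty cohort")
    models = inputs.gene_models
    plen = config.promoter_len
    stage_log: list[dict] = []
    drops: dict[tuple[str, int, str, str], str] = {}

    sites = matrix.sites
    stage_log.append({"stage": "input", "n_in": len(sites), "n_out": len(sites)})

    # --- stage 1: arm scope -------------------------------------------------
    n_in = len(sites)
    if config.skip_scope:
        scoped = list(sites)
    elif config.arm == "susceptible_regions":
        scoped = []
        for s in sites:
            if config.region_set.contains(s.chrom, s.pos0):
                scoped.append(s)
            else:
                drops[s.key] = "out_of_scope"
    else:
        arm_models = [models[g] for g in config.gene_set if g in models]
        scoped = []
        for s in sites:
            in_gene = any(
                m.chrom == s.chrom
                and m.extended_span(plen)[0] <= s.pos0 < m.extended_span(plen)[1]
                for m in arm_models
            )
            if not in_gene:
                drops[s.key] = "out_of_scope"
            elif config.region_set is not None and config.region_set.contains(
                s.chrom, s.pos0
            ):
                drops[s.key] = "in_susceptible_region"
            else:
                scoped.append(s)
    stage_log.append({"stage": "scope", "n_in": n_in, "n_out": len(scoped)})

    # --- stage 2: gene / genic-region assignment ----------------------------
    if config.arm == "gene_set" and not config.skip_scope:
        assign_models = [models[g] for g in config.gene_set if g in models]
    else:
        assign_models = list(models.values())
    pairs: list[tuple[VariantSite, str, GenicRegion]] = []
    for s in scoped:
        hit = False
        for m in assign_models:
            if m.chrom != s.chrom:
                continue
            lo, hi = m.extended_span(plen)
            if not (lo <= s.pos0 < hi):
                continue
            region = assign_genic_region(s, m, plen)
            if region != GenicRegion.INTERGENIC:
                pairs.append((s, m.gene, region))
                hit = True
        if not hit:
            drops[s.key] = "intergenic"
    stage_log.append(
        {"stage": "gene_assignment", "n_in": len(scoped),
         "n_out": len({p[0] for p in pairs})}
    )

    # --- stage 3: expression filter -----------------------------------------
    if config.apply_expression_filter:
        kept_pairs, expr_drops = filter_by_expression(
            pairs, inputs.expression, config.rpkm_threshold
        )
        surviving_sites = {p[0].key for p in kept_pairs}
        for key, reason in expr_drops.items():
            if key not in surviving_sites:
                drops[key] = reason
        pairs = kept_pairs
    stage_log.append(
        {"stage": "expression", "n_in": len(scoped),
         "n_out": len({p[0] for p in pairs})}
    )

    # --- stage 4: per-trio classification + compound het --------------------
    # categories[(site, gene)][child] = category
    categories: dict[tuple[VariantSite, str], dict[str, GenotypeCategory]] = {}
    tgs: dict[tuple[VariantSite, str], dict[str, TrioGenotype]] = {}
    for site, gene, _region in pairs:
        key = (site, gene)
        categories[key] = {}
        tgs[key] = {}
        for trio in cohort.trios:
            tg = _trio_genotype(site, matrix, cohort, trio)
            call = classify_site_detail(tg)
            tgs[key][trio.child] = tg
            if call.category != GenotypeCategory.NONE:
                categories[key][trio.child] = call.category

    # compound het: per (gene, trio), pair child het sites with no
    # single-site category
    by_gene: dict[str, list[tuple[VariantSite, GenicRegion]]] = {}
    region_of: dict[tuple[VariantSite, str], GenicRegion] = {}
    for site, gene, region in pairs:
        by_gene.setdefault(gene, []).append((site, region))
        region_of[(site, gene)] = region
    compound_origin: dict[tuple[VariantSite, str, str], Origin] = {}
    for gene, site_regions in by_gene.items():
        model = models.get(gene)
        if model is None:
            continue
        for trio in cohort.trios:
            het_tgs = [
                tgs[(site, gene)][trio.child]
                for site, _r in site_regions
                if tgs[(site, gene)][trio.child].child == 1
                and model.tx_start <= site.pos0 < model.tx_end
            ]
            if len(het_tgs) < 2:
                continue
            for pair in find_compound_het(model, het_tgs):
                for tg, origin in ((pair.a, pair.origin_a), (pair.b, pair.origin_b)):
                    key = (tg.site, gene)
                    if trio.child not in categories[key]:
                        categories[key][trio.child] = (
                            GenotypeCategory.COMPOUND_HETERO_GAIN
                        )
                    compound_origin[(tg.site, gene, trio.child)] = origin

    classified = [
        (site, gene) for (site, gene) in categories if categories[(site, gene)]
    ]
    classified_sites = {s for s, _g in classified}
    for site, _gene, _r in pairs:
        if site not in classified_sites:
            drops.setdefault(site.key, "no_category")
    stage_log.append(
        {"stage": "classification", "n_in": len({p[0] for p in pairs}),
         "n_out": len({s for s, _g in classified})}
    )

    # --- stage 5: cohort parent exclusion -----------------------------------
    surviving: list[tuple[VariantSite, str, GenotypeCategory, list[str]]] = []
    for site, gene in classified:
        child_cats = categories[(site, gene)]
        for cat in sorted({c for c in child_cats.values()}, key=lambda c: c.value):
            carriers = [ch for ch, c in child_cats.items() if c == cat]
            if config.skip_exclusion:
                surviving.append((site, gene, cat, carriers))
                continue
            exempt: set[str] = set()
            if cat == GenotypeCategory.COMPOUND_HETERO_GAIN:
                for ch in carriers:
                    origin = compound_origin.get((site, gene, ch))
                    trio = cohort.trio_of_child(ch)
                    if origin in (Origin.MATERNAL, Origin.AMBIGUOUS):
                        exempt.add(trio.mother)
                    if origin in (Origin.PATERNAL, Origin.AMBIGUOUS):
                        exempt.add(trio.father)
            keep, reason = cohort_parent_exclusion(
                site, cat, matrix, cohort,
                mode=config.cohort_exclusion_mode,
                exempt_parents=frozenset(exempt),
            )
            if keep:
                surviving.append((site, gene, cat, carriers))
    surviving_sites = {s for s, *_ in surviving}
    for site, _gene in classified:
        if site not in surviving_sites:
            drops.setdefault(site.key, "parent_exclusion")
    stage_log.append(
        {"stage": "parent_exclusion", "n_in": len({s for s, _g in classified}),
         "n_out": len({s for s, _g, _c, _x in surviving})}
    )

    # --- stage 6: frequency, annotation, report rows ------------------------
    n_children = cohort.n_trios
    candidates: list[CandidateVariant] = []
    for site, gene, cat, carriers in surviving:
        _n, _freq, ordered = compute_cohort_frequency(carriers, n_children)
        cytoband = (
            band_of_site(site, inputs.cytoband_table)
            if inputs.cytoband_table is not None
            else "NA"
        )
        candidates.append(
            CandidateVariant(
                site=site,
                gene=gene,
                cytoband=cytoband,
                category=cat,
                genic_region=region_of[(site, gene)],
                carriers=ordered,
                n_children=n_children,
                per_child_category={
                    ch: categories[(site, gene)][ch] for ch in ordered
                },
            )
        )
    candidates.sort(key=lambda c: (*c.site.sort_key(), c.gene, c.category.value))
    annotate_candidates(candidates, inputs.annotations)
    stage_log.append(
        {"stage": "report", "n_in": len({s for s, *_ in surviving}),
         "n_out": len({c.site for c in candidates})}
    )
    drops = {k: v for k, v in drops.items() if v}
    return ScreenResult(candidates=candidates, stage_log=stage_log,
                        drop_reasons=drops)


# ---------------------------------------------------------------------------
# File-level convenience


def load_screen_inputs(
    vcf: str,
    ped: str,
    cytobands: str,
    gene_models: str,
    expression: str,
    annotations: Optional[str] = None,
    susceptible_bands: Optional[str] = None,
    gene_set: Optional[str] = None,
    promoter_len: int = 1000,
) -> tuple[ScreenInputs, Optional[RegionSet], Optional[list[str]]]:
    """Read every input file of a screening run.

    Returns the assembled :class:`ScreenInputs` plus the resolved
    susceptible-region set and gene list (either may be None when the
    corresponding file is not given or empty).
    """
    cohort = io_formats.read_pedigree(ped)
    matrix = io_formats.read_cohort_vcf(vcf, cohort)
    cyto = io_formats.read_cytoband_table(cytobands)
    models = io_formats.read_gene_models(gene_models, promoter_len=promoter_len)
    expr = io_formats.read_expression_table(expression)
    ann = io_formats.read_annotation_table(annotations) if annotations else {}
    region_set = None
    if susceptible_bands:
        bands = io_formats.read_band_list(susceptible_bands)
        if bands:
            region_set = io_formats.resolve_bands(bands, cyto)
    genes = io_formats.read_gene_set(gene_set) if gene_set else None
    inputs = ScreenInputs(
        matrix=matrix, cohort=cohort, gene_models=models, expression=expr,
        annotations=ann, cytoband_table=cyto,
    )
    return inputs, region_set, genes or None
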