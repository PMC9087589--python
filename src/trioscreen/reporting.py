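"""Presentation artifacts: genotype-category matrices, function-membership
matrices and machine-readable stage summaries.

Matrices are emitted as TSV (the tested surface); heatmap images are an
optional convenience on top.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from .core import CandidateVariant, CohortModel, GenicRegion, GenotypeCategory

_REGION_ORDER = [
    GenicRegion.PROMOTER, GenicRegion.UTR5, GenicRegion.EXON,
    GenicRegion.UTR3, GenicRegion.INTRON, GenicRegion.INTERGENIC,
]


def category_matrix(
    candidates: Sequence[CandidateVariant], cohort: CohortModel
) -> pd.DataFrame:
    """(candidate site x child) matrix of genotype categories.

    Cells hold the carrier child's category, ``none`` otherwise; rows are
    grouped by genic region (promoter, 5'-UTR, exon, 3'-UTR) and ordered
    deterministically within each group.
    """
    try:
        children = sorted(cohort.children, key=int)
    except ValueError:
        children = sorted(cohort.children)
    order = {r: i for i, r in enumerate(_REGION_ORDER)}
    ranked = sorted(
        candidates, key=lambda c: (order[c.genic_region], *c.site.sort_key(), c.gene)
    )
    rows = []
    index = []
    for c in ranked:
        index.append(f"{c.site.site_id}|{c.gene}|{c.genic_region.value}")
        rows.append([
            c.per_child_category.get(ch, GenotypeCategory.NONE).value
            for ch in children
        ])
    return pd.DataFrame(rows, index=index, columns=children)


def function_membership_matrix(
    genes: Sequence[str], gene_function_table: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Boolean (gene x function term) membership matrix restricted to the
    given genes.  No enrichment statistics are computed."""
    genes = sorted(set(genes))
    pairs = [(g, t) for g, t in gene_function_table if g in set(genes)]
    terms = sorted({t for _g, t in pairs})
    df = pd.DataFrame(False, index=genes, columns=terms, dtype=bool)
    for g, t in pairs:
        df.loc[g, t] = True
    return df


def summary_counts(
    stage_log: Sequence[Mapping],
    candidates: Optional[Sequence[CandidateVariant]] = None,
) -> dict:
    """JSON-ready per-stage in/out counts plus per-category and per-band
    candidate tallies."""
    summary: dict = {
        "stages": [dict(s) for s in stage_log],
    }
    if candidates is not None:
        per_category: dict[str, int] = {}
        per_region: dict[str, int] = {}
        per_band: dict[str, int] = {}
        for c in candidates:
            per_category[c.category.value] = per_category.get(c.category.value, 0) + 1
            per_region[c.genic_region.value] = (
                per_region.get(c.genic_region.value, 0) + 1
            )
            per_band[c.cytoband] = per_band.get(c.cytoband, 0) + 1
        summary["n_candidates"] = len(candidates)
        summary["per_category"] = per_category
        summary["per_genic_region"] = per_region
        summary["per_cytoband"] = per_band
    return summary


def plot_category_matrix(matrix: pd.DataFrame, path) -> None:
    """Optional heatmap rendering of a category matrix (requires
    matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = [c.value for c in GenotypeCategory]
    coded = matrix.apply(lambda col: col.map(cats.index))
    fig, ax = plt.subplots(
        figsize=(max(4, 0.3 * matrix.shape[1]), max(3, 0.3 * matrix.shape[0]))
    )
    im = ax.imshow(coded.values, aspect="auto", cmap="viridis",
                   vmin=0, vmax=len(cats) - 1)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]), matrix.index, fontsize=6)
    fig.colorbar(im, ax=ax, ticks=range(len(cats)), label="category")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
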