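"""Readers and writers for every external representation the screen touches.

Formats: multi-sample VCF 4.x (via cyvcf2), 6-column PED, UCSC-dialect
cytoband TSV (0-based half-open), refGene-style gene-model TSV, expression
TSV (gene, RPKM), annotation TSV keyed by (chrom, pos, ref, alt), and the
candidate report TSV whose columns mirror the published candidate tables.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from cyvcf2 import VCF

from .core import (
    AnnotationRecord,
    CandidateVariant,
    CohortModel,
    GeneModel,
    ImpactCategory,
    RegionSet,
    Trio,
    VariantSite,
    chrom_sort_key,
    merge_intervals,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

_SEX_CODES = {"1": "male", "2": "female"}
_PHENO_CODES = {"1": "unaffected", "2": "affected"}

_IMPACT_ALIASES = {
    "benign": ImpactCategory.BENIGN,
    "possibly damaging": ImpactCategory.POSSIBLY_DAMAGING,
    "possibly_damaging": ImpactCategory.POSSIBLY_DAMAGING,
    "probably damaging": ImpactCategory.PROBABLY_DAMAGING,
    "probably_damaging": ImpactCategory.PROBABLY_DAMAGING,
    "start_loss": ImpactCategory.START_LOSS,
    "start codon mutation": ImpactCategory.START_LOSS,
}


# ---------------------------------------------------------------------------
# Pedigree


def read_pedigree(path: PathLike) -> CohortModel:
    """Parse a 6-column PED file into a trio cohort.

    Every child must be affected with two unaffected parents present in the
    file; violations are fatal because the screen's exclusion logic depends
    on parent status.
    """
    rows: list[tuple[str, ...]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise ValueError(f"PED row with <6 columns: {line!r}")
            rows.append(tuple(parts[:6]))
    if not rows:
        raise ValueError("no trios: pedigree file is empty")

    sex: dict[str, str] = {}
    pheno: dict[str, str] = {}
    father_of: dict[str, str] = {}
    mother_of: dict[str, str] = {}
    for fam, ind, fa, mo, sx, ph in rows:
        if ind in sex:
            raise ValueError(f"duplicate individual {ind} in pedigree")
        sex[ind] = _SEX_CODES.get(sx, "unknown")
        pheno[ind] = _PHENO_CODES.get(ph, "unknown")
        if fa != "0":
            father_of[ind] = fa
        if mo != "0":
            mother_of[ind] = mo

    trios: list[Trio] = []
    for ind in sex:
        fa = father_of.get(ind)
        mo = mother_of.get(ind)
        if fa is None and mo is None:
            continue  # founder
        if fa is None or mo is None or fa not in sex or mo not in sex:
            raise ValueError(f"child {ind} lacks two genotyped parents in pedigree")
        trios.append(Trio(child=ind, mother=mo, father=fa))
    if not trios:
        raise ValueError("no trios could be assembled from pedigree")

    for t in trios:
        if pheno.get(t.child) != "affected":
            raise ValueError(f"trio child {t.child} is not marked affected")
        for p in (t.mother, t.father):
            if pheno.get(p) != "unaffected":
                raise ValueError(
                    f"parent {p} is affected; each trio must consist of an "
                    "affected child and his/her unaffected parents"
                )
    return CohortModel(trios=trios, sample_sex=sex, affected=pheno)


# ---------------------------------------------------------------------------
# VCF


@dataclass
class GenotypeMatrix:
    """Alt-allele dosages for biallelic SNVs across cohort samples.

    ``dosages[site]`` is a tuple aligned with ``samples``; ``None`` marks a
    missing genotype.
    """

    samples: list[str]
    dosages: dict[VariantSite, tuple[Optional[int], ...]]
    n_dropped_non_snv: int = 0
    n_malformed: int = 0
    n_input_records: int = 0

    _index: dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.samples)}

    def dosage(self, site: VariantSite, sample: str) -> Optional[int]:
        return self.dosages[site][self._index[sample]]

    @property
    def sites(self) -> list[VariantSite]:
        return sorted(self.dosages, key=VariantSite.sort_key)

    def __len__(self) -> int:
        return len(self.dosages)


def _allele_calls(gt_row: Sequence[int]) -> list[int]:
    # cyvcf2 genotypes: [allele0, allele1, phased] diploid, [allele, phased]
    # haploid; trailing element is the phase flag.
    return [int(a) for a in gt_row[:-1]]


def read_cohort_vcf(path: PathLike, cohort: CohortModel) -> GenotypeMatrix:
    """Read a multi-sample VCF into a dosage matrix for the cohort.

    Multi-allelic records are decomposed into biallelic SNVs; non-SNV
    alleles are dropped with a logged count.  A record with any malformed
    genotype is skipped and counted.
    """
    vcf = VCF(str(path), gts012=False)
    vcf_samples = list(vcf.samples)
    missing = [s for s in cohort.samples if s not in vcf_samples]
    if missing:
        raise ValueError(f"VCF lacks cohort sample(s): {', '.join(sorted(missing))}")
    col = [vcf_samples.index(s) for s in cohort.samples]

    dosages: dict[VariantSite, tuple[Optional[int], ...]] = {}
    n_non_snv = 0
    n_malformed = 0
    n_records = 0
    for rec in vcf:
        n_records += 1
        try:
            gts = rec.genotypes
            calls = [_allele_calls(gts[i]) for i in col]
        except Exception:
            n_malformed += 1
            continue
        emitted_snv = False
        for ai, alt in enumerate(rec.ALT, start=1):
            if len(rec.REF) != 1 or len(alt) != 1 or alt == rec.REF or alt == "*":
                continue
            row: list[Optional[int]] = []
            for alleles in calls:
                if any(a < 0 for a in alleles) or not alleles:
                    row.append(None)
                else:
                    row.append(sum(1 for a in alleles if a == ai))
            site = VariantSite(
                chrom=rec.CHROM,
                pos=rec.POS,
                ref=rec.REF,
                alt=alt,
                site_id=rec.ID or "NA",
            )
            dosages[site] = tuple(row)
            emitted_snv = True
        if not emitted_snv:
            n_non_snv += 1
    if n_non_snv:
        logger.info("dropped %d non-SNV records during VCF read", n_non_snv)
    return GenotypeMatrix(
        samples=list(cohort.samples),
        dosages=dosages,
        n_dropped_non_snv=n_non_snv,
        n_malformed=n_malformed,
        n_input_records=n_records,
    )


_DOSAGE_GT = {0: "0/0", 1: "0/1", 2: "1/1", None: "./."}


def write_vcf(
    matrix: GenotypeMatrix,
    path: PathLike,
    contig_lengths: Optional[dict[str, int]] = None,
) -> None:
    """Write a dosage matrix back out as a plain-text multi-sample VCF."""
    sites = matrix.sites
    if contig_lengths is None:
        contig_lengths = {}
        for s in sites:
            contig_lengths[s.chrom] = max(
                contig_lengths.get(s.chrom, 0), s.pos + 1000
            )
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in sorted(contig_lengths, key=chrom_sort_key):
            fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for site in sites:
            gts = "\t".join(_DOSAGE_GT[d] for d in matrix.dosages[site])
            fh.write(
                f"{site.chrom}\t{site.pos}\t{site.site_id}\t{site.ref}\t"
                f"{site.alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Cytobands


_BAND_RE = re.compile(r"^(?P<chrom>[0-9XYM]+|MT)(?P<arm>[pq])(?P<num>[\d.]+)?$")
_RANGE_RE = re.compile(
    r"^(?P<chrom>[0-9XYM]+|MT)(?P<arm>[pq])(?P<lo>\d+)-(?P<hi>\d+)$"
)


def read_cytoband_table(path: PathLike) -> pd.DataFrame:
    """Read a UCSC-style cytoband TSV (chrom, start, end, name[, stain]).

    The returned frame carries a ``band`` column with the fully qualified
    band name (chromosome prefix included, e.g. ``16p13.3``).
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "gieStain"],
        usecols=[0, 1, 2, 3],
        dtype={0: str, 1: int, 2: int, 3: str},
    )
    chrom_plain = df["chrom"].str.replace("^chr", "", regex=True)
    qualified = []
    for c, n in zip(chrom_plain, df["name"]):
        qualified.append(n if n.startswith(c) and not n[0] in "pq" else c + n)
    df["band"] = qualified
    df["chrom_plain"] = chrom_plain
    return df


def _band_matches(query: str, band: str) -> bool:
    """Hierarchical cytoband match: 16p13 covers 16p13.11; 16p13.1 covers
    16p13.11 but not 16p13.2."""
    if band == query:
        return True
    if not band.startswith(query):
        return False
    rest = band[len(query):]
    if "." in query:
        return rest.isdigit()
    return rest.startswith(".")


def resolve_bands(band_names: Iterable[str], cytoband_table: pd.DataFrame) -> RegionSet:
    """Resolve band names (including coarse names and ``5p12-13`` ranges)
    to merged genomic intervals."""
    names = list(band_names)
    spans: dict[str, list[tuple[int, int]]] = {}
    table_bands = list(
        zip(cytoband_table["chrom_plain"], cytoband_table["band"],
            cytoband_table["start"], cytoband_table["end"])
    )
    for name in names:
        queries: list[str] = []
        m = _RANGE_RE.match(name)
        if m:
            lo, hi = int(m.group("lo")), int(m.group("hi"))
            if lo > hi:
                raise ValueError(f"inverted band range: {name}")
            queries = [
                f"{m.group('chrom')}{m.group('arm')}{n}" for n in range(lo, hi + 1)
            ]
        else:
            if not _BAND_RE.match(name):
                raise ValueError(f"unparseable cytoband name: {name}")
            queries = [name]
        hits = []
        for chrom, band, start, end in table_bands:
            if any(_band_matches(q, band) for q in queries):
                hits.append((chrom, start, end))
        if not hits:
            raise ValueError(f"unknown cytoband name: {name}")
        for chrom, start, end in hits:
            spans.setdefault(chrom, []).append((int(start), int(end)))
    return RegionSet(
        bands=names,
        intervals={c: merge_intervals(v) for c, v in spans.items()},
    )


def band_of_site(site: VariantSite, cytoband_table: pd.DataFrame) -> str:
    """Fully qualified band name containing a site, or 'NA'."""
    chrom = site.chrom[3:] if site.chrom.lower().startswith("chr") else site.chrom
    sub = cytoband_table[cytoband_table["chrom_plain"] == chrom]
    hit = sub[(sub["start"] <= site.pos0) & (site.pos0 < sub["end"])]
    if hit.empty:
        return "NA"
    return str(hit.iloc[0]["band"])


# ---------------------------------------------------------------------------
# Gene models, expression, gene sets


def _int_list(cell: str) -> tuple[int, ...]:
    return tuple(int(x) for x in str(cell).rstrip(",").split(",") if x != "")


def read_gene_models(path: PathLike, promoter_len: int = 1000) -> dict[str, GeneModel]:
    """Read a refGene-style TSV of transcript models (0-based half-open)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "gene", "chrom", "strand", "txStart", "txEnd",
        "cdsStart", "cdsEnd", "exonStarts", "exonEnds",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene-model table missing columns: {sorted(missing)}")
    models: dict[str, GeneModel] = {}
    for _, row in df.iterrows():
        gm = GeneModel(
            gene=row["gene"],
            chrom=row["chrom"],
            strand=row["strand"],
            tx_start=int(row["txStart"]),
            tx_end=int(row["txEnd"]),
            cds_start=int(row["cdsStart"]),
            cds_end=int(row["cdsEnd"]),
            exon_starts=_int_list(row["exonStarts"]),
            exon_ends=_int_list(row["exonEnds"]),
            promoter_len=promoter_len,
        )
        if gm.gene in models:
            raise ValueError(f"duplicate gene model for {gm.gene}")
        models[gm.gene] = gm
    return models


def read_expression_table(path: PathLike) -> dict[str, float]:
    """Read a (gene, RPKM) TSV of brain expression levels."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError("expression table needs gene and RPKM columns")
    gene_col, rpkm_col = df.columns[0], df.columns[1]
    return {str(g): float(r) for g, r in zip(df[gene_col], df[rpkm_col])}


def read_gene_set(path: PathLike) -> list[str]:
    """Read a one-symbol-per-line gene set file."""
    genes: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                genes.append(line.split()[0])
    return genes


def read_band_list(path: PathLike) -> list[str]:
    """One cytoband name per line (e.g. the susceptible-region config)."""
    return read_gene_set(path)


# ---------------------------------------------------------------------------
# Annotations


def _opt_float(cell) -> Optional[float]:
    s = str(cell).strip()
    if s in ("", "NA", "nan", "None", "."):
        return None
    return float(s)


def _opt_str(cell) -> Optional[str]:
    s = str(cell).strip()
    return None if s in ("", "NA", "nan", "None", ".") else s


def read_annotation_table(
    path: PathLike,
) -> dict[tuple[str, int, str, str], AnnotationRecord]:
    """Read per-variant annotations keyed by (chrom, pos, ref, alt).

    Duplicate keys are fatal: the join must be unambiguous.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation table missing columns: {sorted(missing)}")
    out: dict[tuple[str, int, str, str], AnnotationRecord] = {}
    for _, row in df.iterrows():
        key = (row["chrom"], int(row["pos"]), row["ref"], row["alt"])
        if key in out:
            raise ValueError(f"duplicate annotation key: {key}")
        cat_raw = _opt_str(row.get("impact_category", ""))
        cat = None
        if cat_raw is not None:
            low = cat_raw.strip().lower()
            cat = _IMPACT_ALIASES.get(low) or _IMPACT_ALIASES.get(
                low.replace("_", " ")
            )
            if cat is None:
                raise ValueError(f"unknown impact category {cat_raw!r} at {key}")
        out[key] = AnnotationRecord(
            aa_change=str(row.get("aa_change", "")).strip(),
            impact_score=_opt_float(row.get("impact_score", "")),
            impact_category=cat,
            tf_site=_opt_str(row.get("tf_site", "")),
            mirna_site=_opt_str(row.get("mirna_site", "")),
            af_chinese=_opt_float(row.get("af_chinese", "")),
            af_east_asian=_opt_float(row.get("af_east_asian", "")),
        )
    return out


# ---------------------------------------------------------------------------
# Candidate report


_CATEGORY_LABEL = {
    ImpactCategory.BENIGN: "Benign",
    ImpactCategory.POSSIBLY_DAMAGING: "Possibly damaging",
    ImpactCategory.PROBABLY_DAMAGING: "Probably damaging",
    ImpactCategory.START_LOSS: "Start codon mutation",
}

CODING_COLUMNS = [
    "SNV_ID", "Gene", "CytoBand", "Genotype", "Ref", "Alt", "AAChange",
    "X1000g_Chinese", "X1000g_EAST", "Polyphen2_HDIV_category",
    "Frequency_in_cohort", "Sample",
]

REGULATORY_COLUMNS = [
    "SNV_ID", "Gene", "Cytoband", "Genotype", "Ref", "Alt",
    "X1000g_Chinese", "X1000g_EAST", "Region", "TF/miRNA_Sites",
    "Frequency_in_cohort", "Sample",
]


def _fmt(v) -> str:
    if v is None or v == "":
        return "NA"
    return str(v)


def candidate_row(c: CandidateVariant, style: str) -> dict[str, str]:
    ann = c.annotations
    common = {
        "SNV_ID": _fmt(c.site.site_id),
        "Gene": c.gene,
        "Genotype": c.category.value,
        "Ref": c.site.ref,
        "Alt": c.site.alt,
        "X1000g_Chinese": _fmt(ann.af_chinese),
        "X1000g_EAST": _fmt(ann.af_east_asian),
        "Frequency_in_cohort": c.frequency,
        "Sample": c.carriers_field,
    }
    if style == "coding":
        common["CytoBand"] = c.cytoband
        common["AAChange"] = _fmt(ann.aa_change)
        common["Polyphen2_HDIV_category"] = _fmt(
            _CATEGORY_LABEL.get(ann.impact_category)
            if ann.impact_category else None
        )
    else:
        common["Cytoband"] = c.cytoband
        region = {"promoter": "Promoter", "utr3": "3'-UTR", "utr5": "5'-UTR"}.get(
            c.genic_region.value, c.genic_region.value
        )
        common["Region"] = region
        common["TF/miRNA_Sites"] = _fmt(ann.tf_site or ann.mirna_site)
    return common


def write_candidate_table(
    candidates: Sequence[CandidateVariant],
    path: PathLike,
    style: str = "coding",
) -> None:
    """Write the candidate report TSV (``style`` in {coding, regulatory})."""
    if style not in ("coding", "regulatory"):
        raise ValueError(f"unknown table style {style!r}")
    cols = CODING_COLUMNS if style == "coding" else REGULATORY_COLUMNS
    rows = [candidate_row(c, style) for c in candidates]
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, sep="\t", index=False)
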