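"""Self-contained synthetic trio cohorts for exercising the screen.

Two entry points:

* :func:`generate` — a seeded generator that plants variants satisfying
  each genotype category, decoys that each violate exactly one filter, and
  background parental polymorphism, together with a machine-readable truth
  table of what the pipeline should recover;
* :func:`reconstruct_paper_fixture` — a deterministic cohort in which each
  published candidate row (gene, cytoband, category, alleles, carriers,
  annotations) is realised as planted trio genotypes, so the whole screen
  can be replayed end to end against the printed tables.

Both emit a miniature genome: every cytoband used is 1 Mb, laid out
consecutively per chromosome; gene models are small three-exon transcripts.
Real hg19 coordinates are not reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import CohortModel, GeneModel, Trio, VariantSite
from .io_formats import GenotypeMatrix, write_vcf

BASES = ("A", "C", "G", "T")

BAND_SIZE = 1_000_000

# Miniature karyotype: band order per chromosome; each band spans 1 Mb.
MINI_BANDS: dict[str, list[str]] = {
    "1": ["p13.1", "q25.3", "q32.1"],
    "2": ["q24.1", "q24.3"],
    "4": ["p16.1", "p15.2"],
    "5": ["p13.3", "p13.2", "p13.1", "p12", "q33.3"],
    "6": ["q12", "q13", "q14.1", "q22.33"],
    "7": ["p22.2", "q21.1"],
    "10": ["q25.1", "q26.2"],
    "11": ["p15.5", "q22.3", "q25"],
    "12": ["p13.32", "p13.2", "q13.12", "q23.2"],
    "16": ["p13.3", "p13.11", "q21"],
    "17": ["p11.2", "q22"],
    "19": ["p13.3", "q13.2"],
    "20": ["p12.1", "q13.13"],
    "X": ["q27.3", "q28"],
}

# The screen's susceptible-region configuration: the linkage-study bands
# plus the additional bands the published candidate tables fall in.
SUSCEPTIBLE_BANDS = [
    "4p16.1", "5p12-13", "6q12-14", "10q26", "11p15.5", "11q25",
    "12q23", "16p13", "17p11", "20q13",
    "2q24.3", "5q33.3", "11q22.3", "12p13.2", "12p13.32",
]

# Bands outside the susceptible set, used for decoys and arm-2 genes.
NONSUSCEPTIBLE_BANDS = [
    "16q21", "7q21.1", "2q24.1", "10q25.1", "1p13.1", "19q13.2",
    "20p12.1", "Xq27.3",
]


def band_interval(band: str) -> tuple[str, int, int]:
    """(chrom, start, end) of a fully qualified mini-genome band."""
    for chrom, names in MINI_BANDS.items():
        for i, name in enumerate(names):
            if chrom + name == band:
                return (chrom, i * BAND_SIZE, (i + 1) * BAND_SIZE)
    raise KeyError(f"band {band} not in miniature genome")


def mini_cytoband_frame() -> pd.DataFrame:
    rows = []
    for chrom, names in MINI_BANDS.items():
        for i, name in enumerate(names):
            rows.append((chrom, i * BAND_SIZE, (i + 1) * BAND_SIZE, name, "gneg"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "gieStain"])


def contig_lengths() -> dict[str, int]:
    return {c: len(b) * BAND_SIZE for c, b in MINI_BANDS.items()}


# Gene architecture (offsets from tx_start, + strand):
#   exon1 [0,300)  exon2 [1000,1600)  exon3 [2400,3000)
#   CDS   [100, 2700)
_EXONS = ((0, 300), (1000, 1600), (2400, 3000))
_CDS = (100, 2700)
_TX_LEN = 3000
_GENE_SLOT = 20_000
_GENE_MARGIN = 10_000


def make_gene_model(
    gene: str, band: str, slot: int, strand: str = "+", promoter_len: int = 1000
) -> GeneModel:
    """Place a small three-exon gene in the given band at a fixed slot."""
    chrom, b_start, b_end = band_interval(band)
    g = b_start + _GENE_MARGIN + slot * _GENE_SLOT
    if g + _TX_LEN + promoter_len >= b_end:
        raise ValueError(f"band {band} slot {slot} overflows the band")
    return GeneModel(
        gene=gene,
        chrom=chrom,
        strand=strand,
        tx_start=g,
        tx_end=g + _TX_LEN,
        cds_start=g + _CDS[0],
        cds_end=g + _CDS[1],
        exon_starts=tuple(g + s for s, _ in _EXONS),
        exon_ends=tuple(g + e for _, e in _EXONS),
        promoter_len=promoter_len,
    )


def site_position(model: GeneModel, region: str, index: int = 0) -> int:
    """1-based position of the index-th site of a genic region class."""
    g = model.tx_start
    fwd = model.strand == "+"
    if region == "exon":
        off = 1200 + 3 * index  # inside exon2, inside CDS
        if off >= 1600:
            raise ValueError("too many coding sites for one gene")
        return g + off + 1
    if region == "promoter":
        p0 = (model.tx_start - 500 - 3 * index) if fwd else (
            model.tx_end + 500 + 3 * index
        )
        return p0 + 1
    if region == "utr3":
        off = (2800 + 3 * index) if fwd else (50 + 3 * index)
        return g + off + 1
    if region == "utr5":
        off = (50 + 3 * index) if fwd else (2800 + 3 * index)
        return g + off + 1
    if region == "intron":
        return g + 500 + 3 * index + 1
    raise ValueError(f"unknown region {region}")


# ---------------------------------------------------------------------------
# Bundle plumbing


@dataclass
class Bundle:
    """Paths of one emitted cohort bundle (all plain-text files)."""

    root: Path
    vcf: Path
    ped: Path
    cytobands: Path
    gene_models: Path
    expression: Path
    annotations: Path
    gene_set: Path
    susceptible_bands: Path
    truth: Optional[Path] = None
    expected_rows: Optional[pd.DataFrame] = None


def _write_ped(cohort: CohortModel, path: Path) -> None:
    with open(path, "w") as fh:
        for i, t in enumerate(cohort.trios, start=1):
            fam = f"F{i:02d}"
            sx = {"male": "1", "female": "2"}.get
            fh.write(f"{fam}\t{t.father}\t0\t0\t{sx(cohort.sample_sex[t.father], '0')}\t1\n")
            fh.write(f"{fam}\t{t.mother}\t0\t0\t{sx(cohort.sample_sex[t.mother], '0')}\t1\n")
            fh.write(
                f"{fam}\t{t.child}\t{t.father}\t{t.mother}\t"
                f"{sx(cohort.sample_sex[t.child], '0')}\t2\n"
            )


def _write_gene_models(models: Sequence[GeneModel], path: Path) -> None:
    rows = []
    for m in models:
        rows.append({
            "gene": m.gene, "chrom": m.chrom, "strand": m.strand,
            "txStart": m.tx_start, "txEnd": m.tx_end,
            "cdsStart": m.cds_start, "cdsEnd": m.cds_end,
            "exonStarts": ",".join(str(s) for s in m.exon_starts),
            "exonEnds": ",".join(str(e) for e in m.exon_ends),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_expression(rpkm: dict[str, float], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tRPKM\n")
        for g in sorted(rpkm):
            fh.write(f"{g}\t{rpkm[g]:.4f}\n")


def _write_annotations(rows: Sequence[dict], path: Path) -> None:
    cols = [
        "chrom", "pos", "ref", "alt", "aa_change", "impact_score",
        "impact_category", "tf_site", "mirna_site", "af_chinese",
        "af_east_asian",
    ]
    df = pd.DataFrame(rows, columns=cols).fillna("NA")
    df.to_csv(path, sep="\t", index=False)


def _write_lines(lines: Sequence[str], path: Path) -> None:
    with open(path, "w") as fh:
        for line in lines:
            fh.write(line + "\n")


def _bundle_paths(out_dir: Path) -> Bundle:
    out_dir.mkdir(parents=True, exist_ok=True)
    return Bundle(
        root=out_dir,
        vcf=out_dir / "cohort.vcf",
        ped=out_dir / "cohort.ped",
        cytobands=out_dir / "cytobands.tsv",
        gene_models=out_dir / "gene_models.tsv",
        expression=out_dir / "expression.tsv",
        annotations=out_dir / "annotations.tsv",
        gene_set=out_dir / "gene_set.txt",
        susceptible_bands=out_dir / "susceptible_bands.txt",
    )


def _build_cohort(
    child_ids: Sequence[str],
    male_children: set[str],
    parent_pool: Sequence[str],
) -> CohortModel:
    sex: dict[str, str] = {}
    aff: dict[str, str] = {}
    trios: list[Trio] = []
    it = iter(parent_pool)
    for ch in child_ids:
        fa, mo = next(it), next(it)
        trios.append(Trio(child=ch, mother=mo, father=fa))
        sex[ch] = "male" if ch in male_children else "female"
        sex[fa] = "male"
        sex[mo] = "female"
        aff[ch] = "affected"
        aff[fa] = "unaffected"
        aff[mo] = "unaffected"
    return CohortModel(trios=trios, sample_sex=sex, affected=aff)


# ---------------------------------------------------------------------------
# The paper-table fixture


# (table, snv_id, gene, band, category, ref, alt, aa_change, af_chn, af_eas,
#  impact, carriers, region, tf_site, mirna_site)
FIXTURE_ROWS: list[dict] = [
    # --- coding SNVs in susceptible regions -------------------------------
    dict(table=1, snv_id="rs17244632", gene="COBLL1", band="2q24.3",
         category="homo_inherit", ref="G", alt="A", aa="p.T833I",
         af=("0.044851", "0.0327"), impact="Possibly damaging", carriers=["75"]),
    dict(table=1, snv_id="rs13362036", gene="CCNJL", band="5q33.3",
         category="homo_inherit", ref="G", alt="A", aa="p.H186Y",
         af=("0.164452", "0.1627"), impact="Possibly damaging",
         carriers=["6", "100"]),
    dict(table=1, snv_id="rs10764749", gene="MKI67", band="10q26.2",
         category="homo_inherit", ref="C", alt="T", aa="p.R2426Q",
         af=("0.104651", "0.1181"), impact="Probably damaging", carriers=["100"]),
    dict(table=1, snv_id="rs2071496", gene="MKI67", band="10q26.2",
         category="homo_inherit", ref="G", alt="C", aa="p.T2508S",
         af=("0.104651", "0.119"), impact="Probably damaging", carriers=["100"]),
    dict(table=1, snv_id="rs2152143", gene="MKI67", band="10q26.2",
         category="homo_inherit", ref="C", alt="T", aa="p.G682S",
         af=("0.104651", "0.1181"), impact="Probably damaging", carriers=["100"]),
    dict(table=1, snv_id="rs3740423", gene="MKI67", band="10q26.2",
         category="homo_inherit", ref="T", alt="A", aa="p.E1043V",
         af=("0.104651", "0.1181"), impact="Probably damaging", carriers=["100"]),
    dict(table=1, snv_id="rs7938342", gene="LSP1", band="11p15.5",
         category="homo_inherit", ref="T", alt="A", aa="p.H34Q",
         af=("0.767442", "0.7688"), impact="Possibly damaging", carriers=["86"]),
    dict(table=1, snv_id="rs17301182", gene="DYNC2H1", band="11q22.3",
         category="homo_inherit", ref="C", alt="T", aa="p.H341Y",
         af=("0.086379", "0.0933"), impact="Possibly damaging", carriers=["5"]),
    dict(table=1, snv_id="rs688906", gene="DYNC2H1", band="11q22.3",
         category="homo_inherit", ref="A", alt="G", aa="p.K1413R",
         af=("0.782392", "0.7827"), impact="Possibly damaging",
         carriers=["71", "79"]),
    dict(table=1, snv_id="rs2302686", gene="LRP6", band="12p13.2",
         category="hetero_gain", ref="G", alt="C", aa="p.S817C",
         af=("0.009967", "0.0109"), impact="Probably damaging", carriers=["5"]),
    dict(table=1, snv_id="rs2041290", gene="AKAP3", band="12p13.32",
         category="hetero_gain", ref="A", alt="G", aa="p.S700L",
         af=("0.126246", "0.1647"), impact="Probably damaging", carriers=["65"]),
    dict(table=1, snv_id="rs2041291", gene="AKAP3", band="12p13.32",
         category="hetero_gain", ref="G", alt="A", aa="",
         af=("0.126246", "0.1647"), impact="Probably damaging", carriers=["65"]),
    dict(table=1, snv_id="rs12227879", gene="PARPBP", band="12q23.2",
         category="homo_inherit", ref="G", alt="A", aa="p.V319M",
         af=("0.033223", "0.0327"), impact="Probably damaging", carriers=["42"]),
    dict(table=1, snv_id="rs144896967", gene="NPIPA5", band="16p13.11",
         category="hetero_gain", ref="C", alt="T", aa="p.E268K",
         af=("0.023256", "0.0268"), impact="Possibly damaging", carriers=["12"]),
    dict(table=1, snv_id="rs62038492", gene="NOMO1", band="16p13.11",
         category="hetero_gain", ref="A", alt="G", aa="p.E1153G",
         af=(None, None), impact="Possibly damaging", carriers=["74"]),
    dict(table=1, snv_id="rs10508", gene="HCFC1R1", band="16p13.3",
         category="homo_inherit", ref="G", alt="T", aa="p.P73Q",
         af=("0.109635", "0.1181"), impact="Possibly damaging", carriers=["98"]),
    dict(table=1, snv_id="rs45459806", gene="PDIA2", band="16p13.3",
         category="homo_inherit", ref="C", alt="T", aa="p.A316V",
         af=("0.018272", "0.0198"), impact="Possibly damaging", carriers=["100"]),
    dict(table=1, snv_id="rs45478794", gene="PKD1", band="16p13.3",
         category="homo_inherit", ref="G", alt="A", aa="p.T3509M",
         af=("0.068106", "0.0625"), impact="Possibly damaging", carriers=["2"]),
    dict(table=1, snv_id="rs45529833", gene="PDIA2", band="16p13.3",
         category="homo_inherit", ref="C", alt="G", aa="p.P382A",
         af=("0.021595", "0.0218"), impact="Probably damaging", carriers=["100"]),
    dict(table=1, snv_id="rs61734410", gene="CACNA1H", band="16p13.3",
         category="homo_inherit", ref="C", alt="T", aa="p.P640L",
         af=("0.835548", "0.8383"), impact="Possibly damaging",
         carriers=["99", "100"]),
    dict(table=1, snv_id="rs9806942", gene="RGS11", band="16p13.3",
         category="homo_inherit", ref="C", alt="T", aa="p.V167M",
         af=("0.325581", "0.3185"), impact="Probably damaging", carriers=["100"]),
    dict(table=1, snv_id="rs11649804", gene="RAI1", band="17p11.2",
         category="homo_inherit", ref="C", alt="A", aa="p.P165T",
         af=("0.845515", "0.8353"), impact="Probably damaging", carriers=["100"]),
    dict(table=1, snv_id="rs2272962", gene="BCAS4", band="20q13.13",
         category="homo_inherit", ref="G", alt="T", aa="p.E56D",
         af=("0.131229", "0.1329"), impact="Probably damaging", carriers=["75"]),
    # --- regulatory SNVs in susceptible regions ---------------------------
    dict(table=2, snv_id="rs67529412", gene="ZNF598", band="16p13.3",
         category="homo_gain", ref="C", alt="G", aa="",
         af=(None, None), impact=None, carriers=["8"],
         region="promoter", tf_site="ELK1_01"),
    dict(table=2, snv_id="rs866882393", gene="WFS1", band="4p16.1",
         category="hetero_gain", ref="G", alt="C", aa="",
         af=(None, None), impact=None, carriers=["42", "65", "78"],
         region="promoter", tf_site="PAX5_01"),
    dict(table=2, snv_id="rs117345841", gene="ULK2", band="17p11.2",
         category="hetero_gain", ref="T", alt="C", aa="",
         af=("0.064784", "0.0665"), impact=None, carriers=["65"],
         region="utr3", mirna_site="miR-130/301"),
    # --- coding SNVs in dopamine-related genes outside the regions --------
    dict(table=3, snv_id="rs680277", gene="RGS8", band="1q25.3",
         category="homo_inherit", ref="T", alt="C", aa="p.N3S",
         af=("0.146179", "0.1399"), impact="Benign", carriers=["99"]),
    dict(table=3, snv_id="rs61732315", gene="PPFIA4", band="1q32.1",
         category="homo_inherit", ref="G", alt="T", aa="p.A825S",
         af=("0.171096", "0.1577"), impact="Possibly damaging", carriers=["75"]),
    dict(table=3, snv_id="rs2229848", gene="LAMA2", band="6q22.33",
         category="homo_inherit", ref="C", alt="T", aa="p.A2583V",
         af=("0.621262", "0.6369"), impact="Probably damaging",
         carriers=["5", "43", "88"]),
    dict(table=3, snv_id="rs2244008", gene="LAMA2", band="6q22.33",
         category="homo_inherit", ref="A", alt="G", aa="p.T2632A",
         af=("0.124585", "0.1319"), impact="Benign", carriers=["6", "65"]),
    dict(table=3, snv_id="rs2644275", gene="GNA12", band="7p22.2",
         category="homo_inherit", ref="G", alt="A", aa="p.T23I",
         af=("0.222591", "0.2321"), impact="Benign", carriers=["43"]),
    dict(table=3, snv_id="rs798488", gene="GNA12", band="7p22.2",
         category="homo_inherit", ref="T", alt="C", aa="p.M1V",
         af=("0.219269", "0.2232"), impact="Benign", carriers=["43"]),
    dict(table=3, snv_id="NA", gene="ADCY6", band="12q13.12",
         category="hetero_gain", ref="G", alt="A", aa="p.L329F",
         af=(None, None), impact="Probably damaging", carriers=["8"]),
    dict(table=3, snv_id="rs2301868", gene="TSPOAP1", band="17q22",
         category="homo_inherit", ref="C", alt="T", aa="p.G1770E",
         af=("0.144518", "0.1161"), impact="Probably damaging", carriers=["79"]),
    dict(table=3, snv_id="rs1050457", gene="PALM", band="19p13.3",
         category="homo_gain", ref="A", alt="G", aa="p.T107A",
         af=("0.534884", "0.5446"), impact="Benign", carriers=["99"]),
    dict(table=3, snv_id="rs143873938", gene="FLNA", band="Xq28",
         category="homo_gain", ref="C", alt="T", aa="p.V528M",
         af=("0.047826", "0.0419"), impact="Probably damaging",
         carriers=["5", "65", "69"]),
    dict(table=3, snv_id="rs781798819", gene="FLNA", band="Xq28",
         category="homo_gain", ref="T", alt="C", aa="p.K676R",
         af=("0.006522", "0.0065"), impact="Benign", carriers=["78"]),
]

FIXTURE_CHILD_IDS = [
    "1", "2", "3", "4", "5", "6", "7", "8", "9", "10", "12", "42", "43",
    "65", "69", "71", "74", "75", "78", "79", "86", "88", "98", "99", "100",
]
# children carrying X-chromosome candidates must be male
FIXTURE_MALE_CHILDREN = {"5", "65", "69", "78", "2", "6", "12", "43", "75", "99"}

FIXTURE_GENE_SET = [
    "RGS8", "PPFIA4", "LAMA2", "GNA12", "ADCY6", "TSPOAP1", "PALM", "FLNA",
    "CACNA1H",  # dopamine-related but inside a susceptible region
]


def _fixture_cohort() -> CohortModel:
    used = set(FIXTURE_CHILD_IDS)
    pool = [str(i) for i in range(1, 200) if str(i) not in used]
    return _build_cohort(FIXTURE_CHILD_IDS, FIXTURE_MALE_CHILDREN, pool)


def reconstruct_paper_fixture(out_dir) -> Bundle:
    """Emit the deterministic cohort that realises every published
    candidate row, plus all side tables the screen consumes."""
    out_dir = Path(out_dir)
    bundle = _bundle_paths(out_dir)
    cohort = _fixture_cohort()

    # gene models: one slot per gene, allocated in fixture order per band
    models: dict[str, GeneModel] = {}
    slot_in_band: dict[str, int] = {}
    for row in FIXTURE_ROWS:
        gene, band = row["gene"], row["band"]
        if gene not in models:
            slot = slot_in_band.get(band, 0)
            slot_in_band[band] = slot + 1
            models[gene] = make_gene_model(gene, band, slot, strand="+")

    site_counter: dict[str, int] = {}
    dosages: dict[VariantSite, tuple] = {}
    ann_rows: list[dict] = []
    sample_index = {s: i for i, s in enumerate(cohort.samples)}
    expected = []
    for row in FIXTURE_ROWS:
        gene = row["gene"]
        model = models[gene]
        region = row.get("region", "exon")
        k = site_counter.get(gene, 0)
        site_counter[gene] = k + 1
        pos = site_position(model, region, k)
        site = VariantSite(
            chrom=model.chrom, pos=pos, ref=row["ref"], alt=row["alt"],
            site_id=row["snv_id"],
        )
        dos: list = [0] * len(cohort.samples)
        for ch in row["carriers"]:
            trio = cohort.trio_of_child(ch)
            cat = row["category"]
            if cat == "homo_inherit":
                dos[sample_index[ch]] = 2
                dos[sample_index[trio.mother]] = 1
                dos[sample_index[trio.father]] = 1
            elif cat == "hetero_gain":
                dos[sample_index[ch]] = 1
            elif cat == "homo_gain":
                dos[sample_index[ch]] = 2
                if row["snv_id"] == "rs1050457":
                    # homozygous gain with one het carrier parent
                    dos[sample_index[trio.father]] = 1
            else:
                raise ValueError(f"unexpected fixture category {cat}")
        dosages[site] = tuple(dos)
        af_chn, af_eas = row["af"]
        ann_rows.append({
            "chrom": site.chrom, "pos": site.pos, "ref": site.ref,
            "alt": site.alt, "aa_change": row["aa"] or "",
            "impact_score": None, "impact_category": row["impact"],
            "tf_site": row.get("tf_site"), "mirna_site": row.get("mirna_site"),
            "af_chinese": af_chn, "af_east_asian": af_eas,
        })
        expected.append({
            "snv_id": row["snv_id"], "gene": gene, "band": row["band"],
            "category": row["category"], "region": region,
            "table": row["table"], "carriers": "/".join(row["carriers"]),
            "n_carriers": len(row["carriers"]),
            "chrom": site.chrom, "pos": site.pos,
            "ref": site.ref, "alt": site.alt,
        })

    matrix = GenotypeMatrix(samples=list(cohort.samples), dosages=dosages)
    write_vcf(matrix, bundle.vcf, contig_lengths())
    _write_ped(cohort, bundle.ped)
    mini_cytoband_frame().to_csv(bundle.cytobands, sep="\t", index=False,
                                 header=False)
    _write_gene_models(list(models.values()), bundle.gene_models)
    rpkm = {g: 1.0 + (i % 7) * 2.5 for i, g in enumerate(sorted(models))}
    _write_expression(rpkm, bundle.expression)
    _write_annotations(ann_rows, bundle.annotations)
    _write_lines(FIXTURE_GENE_SET, bundle.gene_set)
    _write_lines(SUSCEPTIBLE_BANDS, bundle.susceptible_bands)
    bundle.expected_rows = pd.DataFrame(expected)
    return bundle


# ---------------------------------------------------------------------------
# The seeded generator


@dataclass
class GeneratorConfig:
    """Study conditions for a generated cohort: 25 trios, a handful of
    planted candidates per category, one decoy per filter class."""

    n_trios: int = 25
    n_homo_gain: int = 2
    n_hetero_gain: int = 3
    n_homo_inherit: int = 3
    n_compound_hetero: int = 2
    n_x_homo_gain: int = 1
    n_inherited_het: int = 2
    n_parental_hom_carrier: int = 2
    n_low_expression: int = 2
    n_out_of_region: int = 2
    n_missing_genotype: int = 2
    n_background_sites: int = 40
    background_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if name != "background_rate" and isinstance(v, int) and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.background_rate <= 1.0):
            raise ValueError("background_rate must be in [0, 1]")
        if self.n_trios < 1:
            raise ValueError("need at least one trio")


@dataclass
class TruthRow:
    site: VariantSite
    gene: str
    kind: str  # planted | decoy | background
    klass: str  # category name or decoy class
    expected_category: str  # pipeline-visible category, "" for non-survivors
    carriers: tuple[str, ...]
    expected_to_survive: bool
    expected_drop_reason: str  # pipeline drop-reason vocabulary


@dataclass
class TruthTable:
    rows: list[TruthRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "chrom": r.site.chrom, "pos": r.site.pos, "ref": r.site.ref,
                "alt": r.site.alt, "site_id": r.site.site_id, "gene": r.gene,
                "kind": r.kind, "class": r.klass,
                "expected_category": r.expected_category,
                "carriers": "/".join(r.carriers),
                "expected_to_survive": r.expected_to_survive,
                "expected_drop_reason": r.expected_drop_reason,
            }
            for r in self.rows
        ])

    @property
    def survivors(self) -> list[TruthRow]:
        return [r for r in self.rows if r.expected_to_survive]


# generator's region config includes Xq28 so X-linked plants are in scope
GENERATOR_BANDS = SUSCEPTIBLE_BANDS + ["Xq28"]

_IN_REGION_POOL = [
    "4p16.1", "5p12", "6q13", "10q26.2", "11p15.5", "12q23.2",
    "16p13.3", "17p11.2", "20q13.13", "2q24.3", "11q22.3", "5q33.3",
    "12p13.2", "11q25", "6q12",
]
_OUT_REGION_POOL = ["16q21", "7q21.1", "2q24.1", "10q25.1", "1p13.1", "19q13.2"]


class _GenomeAllocator:
    """Hands out gene slots and site positions deterministically."""

    def __init__(self) -> None:
        self._slot: dict[str, int] = {}
        self._n_genes = 0

    def new_gene(self, band: str, strand: str) -> GeneModel:
        self._n_genes += 1
        slot = self._slot.get(band, 0)
        self._slot[band] = slot + 1
        return make_gene_model(f"G{self._n_genes:03d}", band, slot, strand)


def generate(config: GeneratorConfig, out_dir) -> tuple[Bundle, TruthTable]:
    """Generate a cohort bundle plus its planted-variant truth table.

    All randomness derives from ``config.seed``; the same config yields a
    byte-identical bundle.
    """
    rng = np.random.default_rng(config.seed)
    out_dir = Path(out_dir)
    bundle = _bundle_paths(out_dir)

    children = [str(i) for i in range(1, config.n_trios + 1)]
    males = {c for c in children if int(c) % 2 == 1}
    parent_pool = [str(i) for i in range(config.n_trios + 1, 4 * config.n_trios + 1)]
    cohort = _build_cohort(children, males, parent_pool)
    male_children = [c for c in children if c in males]
    if config.n_x_homo_gain > 0 and not male_children:
        raise ValueError(
            "cannot plant an X-linked homo_gain without a male child"
        )

    alloc = _GenomeAllocator()
    sample_index = {s: i for i, s in enumerate(cohort.samples)}
    dosages: dict[VariantSite, tuple] = {}
    models: list[GeneModel] = []
    rpkm: dict[str, float] = {}
    ann_rows: list[dict] = []
    truth_rows: list[TruthRow] = []
    site_no = 0

    def new_site(model: GeneModel, region: str, index: int = 0) -> VariantSite:
        nonlocal site_no
        site_no += 1
        ref, alt = rng.choice(len(BASES), size=2, replace=False)
        return VariantSite(
            chrom=model.chrom, pos=site_position(model, region, index),
            ref=BASES[ref], alt=BASES[alt], site_id=f"synth{site_no}",
        )

    def pick_carriers(k_max: int = 3, pool: Optional[list[str]] = None) -> list[str]:
        pool = pool if pool is not None else children
        k = int(rng.integers(1, min(k_max, len(pool)) + 1))
        chosen = rng.choice(len(pool), size=k, replace=False)
        return sorted((pool[i] for i in chosen), key=int)

    def plant(site: VariantSite, pattern: dict[str, int]) -> None:
        dos: list = [0] * len(cohort.samples)
        for sample, d in pattern.items():
            dos[sample_index[sample]] = d
        dosages[site] = tuple(dos)

    def annotate(site: VariantSite, region: str) -> None:
        coding = region == "exon"
        cat = ["benign", "possibly_damaging", "probably_damaging"][site_no % 3]
        ann_rows.append({
            "chrom": site.chrom, "pos": site.pos, "ref": site.ref,
            "alt": site.alt,
            "aa_change": f"p.A{100 + site_no}V" if coding else "",
            "impact_score": None,
            "impact_category": cat if coding else None,
            "tf_site": "ELK1_01" if region == "promoter" else None,
            "mirna_site": "miR-130/301" if region == "utr3" else None,
            "af_chinese": f"{rng.uniform(0.001, 0.5):.6f}",
            "af_east_asian": f"{rng.uniform(0.001, 0.5):.6f}",
        })

    def new_expressed_gene(in_region: bool = True, low: bool = False) -> GeneModel:
        pool = _IN_REGION_POOL if in_region else _OUT_REGION_POOL
        band = pool[int(rng.integers(len(pool)))]
        strand = "+" if rng.integers(2) == 0 else "-"
        m = alloc.new_gene(band, strand)
        models.append(m)
        rpkm[m.gene] = (
            float(rng.uniform(0.0, 0.5)) if low else float(rng.uniform(2.0, 50.0))
        )
        return m

    # --- planted candidates -------------------------------------------------
    # each plant occupies its own gene; regions cycle over genic classes so
    # promoter/UTR plants carry matching TF/miRNA annotations
    region_cycle = ["exon", "exon", "promoter", "utr3", "utr5"]

    def planted_region(i: int) -> str:
        return region_cycle[i % len(region_cycle)]

    n_plant = 0
    for _ in range(config.n_homo_inherit):
        m = new_expressed_gene()
        region = planted_region(n_plant); n_plant += 1
        site = new_site(m, region)
        carriers = pick_carriers()
        pattern: dict[str, int] = {}
        for ch in carriers:
            t = cohort.trio_of_child(ch)
            pattern.update({ch: 2, t.mother: 1, t.father: 1})
        plant(site, pattern)
        annotate(site, region)
        truth_rows.append(TruthRow(site, m.gene, "planted", "homo_inherit",
                                   "homo_inherit", tuple(carriers), True, ""))

    for _ in range(config.n_hetero_gain):
        m = new_expressed_gene()
        region = planted_region(n_plant); n_plant += 1
        site = new_site(m, region)
        carriers = pick_carriers()
        plant(site, {ch: 1 for ch in carriers})
        annotate(site, region)
        truth_rows.append(TruthRow(site, m.gene, "planted", "hetero_gain",
                                   "hetero_gain", tuple(carriers), True, ""))

    for _ in range(config.n_homo_gain):
        m = new_expressed_gene()
        region = planted_region(n_plant); n_plant += 1
        site = new_site(m, region)
        carriers = pick_carriers(k_max=2)
        pattern = {}
        for ch in carriers:
            t = cohort.trio_of_child(ch)
            pattern[ch] = 2
            if rng.integers(2) == 1:
                pattern[t.father] = 1  # one het parent: still a gain
        plant(site, pattern)
        annotate(site, region)
        truth_rows.append(TruthRow(site, m.gene, "planted", "homo_gain",
                                   "homo_gain", tuple(carriers), True, ""))

    for _ in range(config.n_x_homo_gain):
        band = "Xq28"
        strand = "+" if rng.integers(2) == 0 else "-"
        m = alloc.new_gene(band, strand)
        models.append(m)
        rpkm[m.gene] = float(rng.uniform(2.0, 50.0))
        site = new_site(m, "exon")
        carriers = pick_carriers(k_max=2, pool=male_children)
        plant(site, {ch: 2 for ch in carriers})  # hemizygous alt, mothers 0
        annotate(site, "exon")
        truth_rows.append(TruthRow(site, m.gene, "planted", "x_homo_gain",
                                   "homo_gain", tuple(carriers), True, ""))

    for _ in range(config.n_compound_hetero):
        m = new_expressed_gene()
        ch = children[int(rng.integers(len(children)))]
        t = cohort.trio_of_child(ch)
        site_a = new_site(m, "exon", 0)  # de novo member
        site_b = new_site(m, "exon", 1)  # maternally inherited member
        plant(site_a, {ch: 1})
        plant(site_b, {ch: 1, t.mother: 1})
        annotate(site_a, "exon")
        annotate(site_b, "exon")
        truth_rows.append(TruthRow(site_a, m.gene, "planted", "compound_hetero",
                                   "hetero_gain", (ch,), True, ""))
        truth_rows.append(TruthRow(site_b, m.gene, "planted", "compound_hetero",
                                   "compound_hetero_gain", (ch,), True, ""))

    # --- decoys: each violates exactly one filter ---------------------------
    for _ in range(config.n_inherited_het):
        m = new_expressed_gene()
        site = new_site(m, "exon")
        ch = children[int(rng.integers(len(children)))]
        t = cohort.trio_of_child(ch)
        plant(site, {ch: 1, t.mother: 1})  # inherited het: not a category
        annotate(site, "exon")
        truth_rows.append(TruthRow(site, m.gene, "decoy", "inherited_het",
                                   "", (ch,), False, "no_category"))

    for _ in range(config.n_parental_hom_carrier):
        m = new_expressed_gene()
        site = new_site(m, "exon")
        carriers = pick_carriers(k_max=1)
        pattern = {}
        for ch in carriers:
            t = cohort.trio_of_child(ch)
            pattern.update({ch: 2, t.mother: 1, t.father: 1})
        others = [t for t in cohort.trios if t.child not in carriers]
        spoiler = others[int(rng.integers(len(others)))]
        pattern[spoiler.mother] = 2  # unrelated hom-alt parent
        plant(site, pattern)
        annotate(site, "exon")
        truth_rows.append(TruthRow(site, m.gene, "decoy", "parental_hom_carrier",
                                   "", tuple(carriers), False,
                                   "parent_exclusion"))

    for _ in range(config.n_low_expression):
        m = new_expressed_gene(low=True)
        site = new_site(m, "exon")
        carriers = pick_carriers(k_max=2)
        plant(site, {ch: 1 for ch in carriers})
        annotate(site, "exon")
        truth_rows.append(TruthRow(site, m.gene, "decoy", "low_expression_gene",
                                   "", tuple(carriers), False, "low_expression"))

    for _ in range(config.n_out_of_region):
        m = new_expressed_gene(in_region=False)
        site = new_site(m, "exon")
        carriers = pick_carriers(k_max=2)
        plant(site, {ch: 1 for ch in carriers})
        annotate(site, "exon")
        truth_rows.append(TruthRow(site, m.gene, "decoy", "out_of_region",
                                   "", tuple(carriers), False, "out_of_scope"))

    for _ in range(config.n_missing_genotype):
        m = new_expressed_gene()
        site = new_site(m, "exon")
        ch = children[int(rng.integers(len(children)))]
        plant(site, {ch: None})  # the would-be carrier's GT is missing
        annotate(site, "exon")
        truth_rows.append(TruthRow(site, m.gene, "decoy", "missing_genotype",
                                   "", (ch,), False, "no_category"))

    # --- background parental polymorphism -----------------------------------
    if config.n_background_sites > 0:
        n_bg_genes = max(1, config.n_background_sites // 15)
        bg_genes = [new_expressed_gene() for _ in range(n_bg_genes)]
        parents = cohort.parents
        for i in range(config.n_background_sites):
            m = bg_genes[i % len(bg_genes)]
            site = new_site(m, "intron", i // len(bg_genes))
            carry = rng.random(len(parents)) < config.background_rate
            plant(site, {p: 1 for p, hit in zip(parents, carry) if hit})
            truth_rows.append(TruthRow(site, m.gene, "background", "background",
                                       "", (), False, "no_category"))

    matrix = GenotypeMatrix(samples=list(cohort.samples), dosages=dosages)
    write_vcf(matrix, bundle.vcf, contig_lengths())
    _write_ped(cohort, bundle.ped)
    mini_cytoband_frame().to_csv(bundle.cytobands, sep="\t", index=False,
                                 header=False)
    _write_gene_models(models, bundle.gene_models)
    _write_expression(rpkm, bundle.expression)
    _write_annotations(ann_rows, bundle.annotations)
    _write_lines([], bundle.gene_set)
    _write_lines(GENERATOR_BANDS, bundle.susceptible_bands)
    truth = TruthTable(rows=truth_rows)
    bundle.truth = bundle.root / "truth.tsv"
    truth.to_frame().to_csv(bundle.truth, sep="\t", index=False)
    return bundle, truth
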