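"""Core domain types for trio-cohort SNV screening.

Coordinate conventions used throughout the package:

* VCF positions are 1-based (``VariantSite.pos``).
* All internal intervals (cytobands, gene models, promoters) are 0-based
  half-open, i.e. the UCSC/BED dialect.

Genotypes are represented as alt-allele dosages ``{0, 1, 2}`` with ``None``
for missing.  On the male X (non-pseudoautosomal), a hemizygous alternate
call is normalised to dosage 2 so that homozygous-style rules apply.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

MISSING = None  # dosage sentinel; kept as a name for readability

VALID_DOSAGES = (0, 1, 2, None)


class GenotypeCategory(str, enum.Enum):
    """Child genotype classes a trio screen nominates.

    ``homo_gain`` / ``hetero_gain`` / ``compound_hetero_gain`` are de novo
    gains (at least one child allele not attributable to a parent);
    ``homo_inherit`` is a homozygote assembled from two heterozygous carrier
    parents.  ``none`` means the trio contributes no candidate at the site.
    """

    HOMO_GAIN = "homo_gain"
    HETERO_GAIN = "hetero_gain"
    COMPOUND_HETERO_GAIN = "compound_hetero_gain"
    HOMO_INHERIT = "homo_inherit"
    NONE = "none"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class Origin(str, enum.Enum):
    """Parental origin of a child's alt allele at a single site."""

    MATERNAL = "maternal"
    PATERNAL = "paternal"
    DE_NOVO = "de_novo"
    AMBIGUOUS = "ambiguous"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class GenicRegion(str, enum.Enum):
    PROMOTER = "promoter"
    UTR5 = "utr5"
    EXON = "exon"
    UTR3 = "utr3"
    INTRON = "intron"
    INTERGENIC = "intergenic"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class ImpactCategory(str, enum.Enum):
    BENIGN = "benign"
    POSSIBLY_DAMAGING = "possibly_damaging"
    PROBABLY_DAMAGING = "probably_damaging"
    START_LOSS = "start_loss"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class PloidyContext(str, enum.Enum):
    AUTOSOMAL = "autosomal"
    X_NONPAR = "x_nonpar"
    Y = "y"
    MITO = "mito"


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: 1..22 then X, Y, MT, then others."""
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if c.isdigit():
        return (int(c), "")
    special = {"X": 100, "Y": 101, "MT": 102, "M": 102}
    return (special.get(c.upper(), 200), c)


def ploidy_context_for(chrom: str) -> PloidyContext:
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    c = c.upper()
    if c == "X":
        return PloidyContext.X_NONPAR
    if c == "Y":
        return PloidyContext.Y
    if c in ("MT", "M"):
        return PloidyContext.MITO
    return PloidyContext.AUTOSOMAL


@dataclass(frozen=True, order=True)
class VariantSite:
    """A biallelic SNV locus (1-based position, single-base alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    site_id: str = field(default="NA", compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(
                f"SNV alleles must be single bases: {self.ref}>{self.alt}"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def pos0(self) -> int:
        """0-based position."""
        return self.pos - 1

    def sort_key(self):
        return (chrom_sort_key(self.chrom), self.pos, self.alt)


@dataclass(frozen=True)
class Trio:
    child: str
    mother: str
    father: str


@dataclass
class CohortModel:
    """Pedigree-resolved trio cohort: affected children, unaffected parents."""

    trios: list[Trio]
    sample_sex: dict[str, str]  # sample -> {male, female, unknown}
    affected: dict[str, str]  # sample -> {affected, unaffected}

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.trios:
            raise ValueError("no trios in cohort")
        seen: set[str] = set()
        for t in self.trios:
            for s in (t.child, t.mother, t.father):
                if s in seen:
                    raise ValueError(f"sample {s} appears in more than one role")
                seen.add(s)
            if self.affected.get(t.child) != "affected":
                raise ValueError(f"trio child {t.child} must be affected")
            for p in (t.mother, t.father):
                if self.affected.get(p) != "unaffected":
                    raise ValueError(
                        f"parent {p} of {t.child} is not unaffected; the screen "
                        "requires each child's unaffected parents"
                    )
        if len(seen) != 3 * len(self.trios):
            raise ValueError("sample count != 3 x trio count")

    @property
    def children(self) -> list[str]:
        return [t.child for t in self.trios]

    @property
    def parents(self) -> list[str]:
        out: list[str] = []
        for t in self.trios:
            out.extend([t.mother, t.father])
        return out

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for t in self.trios:
            out.extend([t.child, t.mother, t.father])
        return out

    @property
    def n_trios(self) -> int:
        return len(self.trios)

    def trio_of_child(self, child: str) -> Trio:
        for t in self.trios:
            if t.child == child:
                return t
        raise KeyError(child)


@dataclass
class RegionSet:
    """Resolved cytoband regions: merged 0-based half-open intervals."""

    bands: list[str]
    intervals: dict[str, list[tuple[int, int]]]  # chrom -> sorted merged spans

    def contains(self, chrom: str, pos0: int) -> bool:
        for start, end in self.intervals.get(chrom, ()):
            if start <= pos0 < end:
                return True
        return False

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True if [start, end) intersects any interval on chrom."""
        for s, e in self.intervals.get(chrom, ()):
            if s < end and start < e:
                return True
        return False

    @property
    def n_intervals(self) -> int:
        return sum(len(v) for v in self.intervals.values())

    @staticmethod
    def empty() -> "RegionSet":
        return RegionSet(bands=[], intervals={})


def merge_intervals(spans: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals."""
    spans = sorted(spans)
    merged: list[tuple[int, int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


@dataclass
class GeneModel:
    """A transcript model in 0-based half-open coordinates.

    ``promoter_len`` bases upstream of the TSS (strand-aware) count as
    promoter for genic-region assignment.
    """

    gene: str
    chrom: str
    strand: str  # "+" or "-"
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exon_starts: tuple[int, ...]
    exon_ends: tuple[int, ...]
    promoter_len: int = 1000

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene}: strand must be + or -")
        if not self.tx_start < self.tx_end:
            raise ValueError(f"{self.gene}: tx_start must be < tx_end")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError(f"{self.gene}: CDS not within transcript span")
        if len(self.exon_starts) != len(self.exon_ends):
            raise ValueError(f"{self.gene}: exon start/end count mismatch")
        prev_end = -1
        for s, e in zip(self.exon_starts, self.exon_ends):
            if not (self.tx_start <= s < e <= self.tx_end):
                raise ValueError(f"{self.gene}: exon [{s},{e}) outside transcript")
            if s < prev_end:
                raise ValueError(f"{self.gene}: exons overlap or are unsorted")
            prev_end = e

    @property
    def tss(self) -> int:
        """Transcription start (0-based): tx_start on +, tx_end - 1 on -."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def promoter_span(self, promoter_len: Optional[int] = None) -> tuple[int, int]:
        plen = self.promoter_len if promoter_len is None else promoter_len
        if self.strand == "+":
            return (max(0, self.tx_start - plen), self.tx_start)
        return (self.tx_end, self.tx_end + plen)

    def extended_span(self, promoter_len: Optional[int] = None) -> tuple[int, int]:
        """Transcript span unioned with the promoter window."""
        ps, pe = self.promoter_span(promoter_len)
        return (min(ps, self.tx_start), max(pe, self.tx_end))


@dataclass
class AnnotationRecord:
    """Externally produced per-variant functional annotation (consumed, not
    computed): protein impact, TF/miRNA site hits, population AFs."""

    aa_change: str = ""
    impact_score: Optional[float] = None
    impact_category: Optional[ImpactCategory] = None
    tf_site: Optional[str] = None
    mirna_site: Optional[str] = None
    af_chinese: Optional[float] = None
    af_east_asian: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("impact_score", "af_chinese", "af_east_asian"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")

    @property
    def is_empty(self) -> bool:
        return self == AnnotationRecord()


@dataclass(frozen=True)
class TrioGenotype:
    """One site's alt-dosages for (child, mother, father).

    Hemizygous normalisation: a male child on the non-PAR X carrying the alt
    (raw dosage 1 from a haploid or het-style call) is recorded as dosage 2.
    """

    site: VariantSite
    child: Optional[int]
    mother: Optional[int]
    father: Optional[int]
    child_sex: str = "unknown"
    ploidy_context: PloidyContext = PloidyContext.AUTOSOMAL

    def __post_init__(self) -> None:
        for name in ("child", "mother", "father"):
            if getattr(self, name) not in VALID_DOSAGES:
                raise ValueError(f"invalid dosage {name}={getattr(self, name)!r}")
        if (
            self.ploidy_context == PloidyContext.X_NONPAR
            and self.child_sex == "male"
            and self.child == 1
        ):
            object.__setattr__(self, "child", 2)

    @property
    def hemizygous_child(self) -> bool:
        return (
            self.ploidy_context == PloidyContext.X_NONPAR
            and self.child_sex == "male"
        )


@dataclass
class CandidateVariant:
    """A surviving SNV: one row of the candidate report."""

    site: VariantSite
    gene: str
    cytoband: str
    category: GenotypeCategory
    genic_region: GenicRegion
    carriers: list[str]
    n_children: int
    annotations: AnnotationRecord = field(default_factory=AnnotationRecord)
    per_child_category: dict[str, GenotypeCategory] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)
    regulatory_hit: str = "none"  # {tf_site_hit, mirna_site_hit, none}

    def __post_init__(self) -> None:
        if not self.carriers:
            raise ValueError("candidate with zero carriers")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    @property
    def frequency(self) -> str:
        return f"{self.n_carriers}/{self.n_children}"

    @property
    def carriers_field(self) -> str:
        return "/".join(self.carriers)
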