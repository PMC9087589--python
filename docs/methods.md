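# Methods

## Model and assumptions

The screen treats each parent–offspring trio as an independent observation
of one affected child's genotype against the unaffected parental
background. Variants are biallelic SNVs after decomposition; genotypes are
alt-allele dosages {0, 1, 2} with missing recorded explicitly. The
single-site classification is a deterministic map over the 27 dosage
combinations (committed as a lookup-table oracle in the test suite):

* `hetero_gain` (1, 0, 0); `homo_inherit` (2, 1, 1); `homo_gain` child 2
  with at least one parent at dosage 0; everything else is not a
  candidate. Inherited heterozygotes are deliberately excluded: they are
  equally present in the unaffected generation.
* `homo_gain` is defined minimally — one unattributable allele suffices —
  so a child homozygote with one heterozygous parent still qualifies.
  A (2, 0, 0) child is classified `homo_gain` and flagged
  `double_de_novo`.
* Mendelian-impossible combinations (e.g. child 0 with a hom-alt parent)
  are classified `none` and flagged `mendelian_error`; they are counted,
  not studied.
* Missing dosage anywhere in the trio disqualifies that (trio, site); no
  imputation is attempted, which is conservative against false de novo
  calls.

### Hemizygous X

Male children on the non-PAR X are hemizygous: any alt call (haploid `1`
or diploid-style `0/1`/`1/1`, as diploid callers emit) normalises to
dosage 2. The father's X genotype is ignored for male children; the
mother's dosage alone separates `homo_gain` (mother 0) from
`homo_inherit`. The miniature genome treats the whole X as non-PAR;
pseudoautosomal regions are out of scope.

### Compound heterozygotes

Compound-het calling is gene-level: child het sites within one
transcript span are paired when at least one member is de novo (the
category is grouped under de novo gains) and the parental origins are
compatible with a trans configuration (not both maternal, not both
paternal). Pairs containing an ambiguous-origin member are retained but
flagged `phase_uncertain` — without read-backed phasing the trans
configuration cannot be confirmed, and the flag records rather than
resolves that uncertainty.

## Filters

* **Scope.** Cytoband names resolve hierarchically: `16p13` covers
  `16p13.11` … `16p13.3`; a range `5p12-13` expands over major bands 12
  and 13 inclusively. Resolved intervals are merged half-open spans;
  membership is point-in-interval. The gene-set arm takes a site as
  in-scope when it falls in a set gene's transcript span extended by the
  promoter window, minus any site inside the susceptible regions, making
  the arms disjoint.
* **Expression.** "Below RPKM 1" is strict: RPKM ≥ 1 survives. Genes
  absent from the expression table are dropped with a distinct reason
  (`gene_missing_expression`) and a warning. The filter applies in both
  arms by default and can be disabled.
* **Parent exclusion** (`genotype_match`, default): the candidate child
  genotype must not occur in any of the cohort's unaffected parents —
  hom-alt parents exclude child-homozygous candidates; any carrier parent
  excludes gain (heterozygous) candidates. The carrier trio's own parents
  are exempt for the inherited allele of a compound-het member (that
  parent carries it by construction). This is the weakest rule under
  which inherited homozygotes can exist at all, since their own parents
  are obligate het carriers. The stricter `any_carrier` alternative —
  drop on any carrier parent regardless of category — is exposed as a
  switch; it eliminates `homo_inherit` by definition and exists for
  sensitivity analysis.

## Genic regions and annotation

Genic-region assignment is strand-aware on refGene-style models with
precedence exon > 5′-UTR > 3′-UTR > promoter > intron > intergenic; the
promoter is the 1000 bp upstream of the TSS by default (configurable) —
no standard definition exists, and 1 kb is the common proximal-promoter
convention. A site inside two genes yields one candidate row per gene.

Annotations are consumed, never computed: the annotation table carries
protein changes, damage categories and/or scores, TF-motif and
miRNA-site identifiers, and population allele frequencies. When only a
score is supplied, the published PolyPhen-2 HDIV bins apply (benign
≤ 0.452 < possibly damaging ≤ 0.956 < probably damaging). A parseable
`p.M1X` change overrides any category with `start_loss`. TF hits count
only on promoter variants and miRNA hits only on 3′-UTR variants;
mismatched site annotations are flagged inconsistent, never silently
dropped.

Frequencies are rendered `n/N` over the affected children only; children
never participate in each other's exclusion.

## Synthetic cohorts

The generator emulates the study conditions: 25 trios (75 samples) by
default, a miniature genome whose cytobands are consecutive 1 Mb blocks
named after the real bands the screen references, and small three-exon
gene models. Planted variants realise exactly one category each in their
own gene; decoys violate exactly one filter each (inherited het, unrelated
hom-alt parent, low-RPKM gene, out-of-scope band, missing genotype);
background polymorphism is independent per-site per-parent Bernoulli
heterozygosity (rate 0.05 over 40 sites by default) confined to parents so
that it can never fabricate a child candidate — no population-genetic
realism (LD, frequency spectra) is claimed or needed for filter testing.
Per-category plant counts (2–3 each) are chosen for coverage of every
code path, not to mimic unpublished per-child candidate counts. All
randomness flows from one seed; identical configs produce byte-identical
bundles.

The paper-table fixture is the deterministic special case: every
published candidate row is planted with its printed gene, cytoband,
category, alleles, carrier children (male for X-linked rows), and
annotation values; all other samples are homozygous reference; every
fixture gene is given RPKM ≥ 1. Inherited homozygotes are planted with
both parents het, de novo heterozygotes with both parents hom-ref,
autosomal homozygous gains with parents (0, 0) — except one row planted
as (0, 1) to exercise the one-carrier-parent path — and X-linked gains as
hemizygous alt children of hom-ref mothers. The fixture's susceptible
band list is the ten linkage-study bands plus the five additional bands
the published candidate tables fall in, so every printed row is in scope.
Passing fixture tests shows the pipeline reproduces the published
screening arithmetic on cohorts satisfying its genotype patterns; it
cannot validate upstream calling quality, real LD structure, or the
unpublished full variant lists.

## Numerical and degenerate-input choices

* Coordinates: VCF 1-based; all internal intervals 0-based half-open.
* Multi-allelic records decompose into biallelic rows (dosage = count of
  that alt allele); non-SNV alleles are dropped and counted.
* Ties: candidates sort by (chromosome in karyotype order, position,
  alt, gene); carriers sort by numeric sample ID; a site classified into
  different categories across trios yields one row per category so
  carrier counts conserve exactly.
* Empty inputs: an empty band list is an empty region set (nothing in
  scope); an empty candidate list writes a header-only report; an empty
  pedigree is fatal.
* Problem sizes: the default test suite runs 25-trio cohorts of ~40–90
  sites; the recovery suite spans 20 generator seeds. These sizes fully
  exercise every filter while keeping the whole suite in the
  seconds range.

## Known limitations

* No statistical de novo calling from genotype likelihoods; GT fields
  are taken at face value.
* No association testing, burden statistics or multiple-testing
  correction — the screen is a deterministic funnel, and candidate lists
  are nominations, not inferences.
* Compound-het trans configurations rest on parental origin, not
  read-backed phasing.
* Enrichment analysis is out of scope; function-membership matrices are
  produced from user-supplied (gene, term) tables without statistics.
* Indels are called upstream in such studies but are out of scope here;
  the screen is SNV-only.
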