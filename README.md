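# trioscreen

Trio-based screening of single-nucleotide variants (SNVs) for
susceptibility-variant nomination in family cohorts, built around the study
design used for attention-deficit/hyperactivity disorder (ADHD): a cohort of
parent–offspring trios in which each child is affected and both parents are
unaffected, genotyped jointly by whole-genome sequencing.

## The screening model

The screen rests on the hypothesis that alleles contributing to a highly
heritable childhood disorder are enriched among child genotypes that the
unaffected parents do **not** share: de novo gains and newly assembled
homozygotes. For each trio and biallelic SNV, writing genotypes as
alt-allele dosages (child *c*, mother *m*, father *f*):

| category | rule |
|---|---|
| `hetero_gain` | *c* = 1, *m* = 0, *f* = 0 (de novo heterozygote) |
| `homo_inherit` | *c* = 2, *m* = 1, *f* = 1 (homozygote from two het carriers) |
| `homo_gain` | *c* = 2 and (*m* = 0 or *f* = 0) — at least one allele unattributable to a parent |
| `compound_hetero_gain` | gene-level: two child het sites in trans, at least one de novo |

On the male non-pseudoautosomal X the child is hemizygous (alt normalised
to dosage 2), the father's X is ignored, and the mother's dosage decides
between `homo_gain` (mother 0) and `homo_inherit` (mother carries).

Candidate sites then pass through cohort-level filters, in order:

1. **scope** — either the reported susceptible cytoband regions (e.g.
   4p16.1, 5p12-13, 6q12-14, 10q26, 11p15.5, 11q25, 12q23, 16p13, 17p11,
   20q13) or a functional gene set (dopamine-related genes) *excluding*
   those regions, so the two arms partition the genome;
2. **brain expression** — genes with RPKM < 1 in brain are dropped
   (RPKM = 1 exactly survives);
3. **per-trio classification** as above;
4. **cohort-wide unaffected-parent exclusion** — a child-homozygous
   candidate is discarded if any of the cohort's parents is hom-alt; a
   gain (heterozygous) candidate is discarded if any parent carries the
   allele at all;
5. **frequency and annotation** — carrier children are counted (`n/25`
   in a 25-trio cohort) and externally produced annotations (PolyPhen-2
   HDIV damage categories, TRANSFAC TF-motif hits for promoter variants,
   TargetScan miRNA-site hits for 3′-UTR variants, population allele
   frequencies) are joined on. A variant destroying the initiator
   methionine (`p.M1X`) is relabelled `start_loss` regardless of its
   missense score.

Because raw cohort genotypes of this kind cannot be redistributed, the
package ships a synthetic-cohort module that (a) generates seeded random
cohorts with planted variants of every category, decoys that each violate
exactly one filter, and a machine-readable truth table, and (b)
reconstructs a deterministic 25-trio cohort realising every published
candidate row (gene, cytoband, category, alleles, carrier children,
annotations) on a miniature genome, so the whole screen can be replayed
end to end.

## Worked example

```bash
# generate a synthetic 25-trio cohort (75 samples) with planted variants
trioscreen simulate --seed 5 --out demo/

# run the susceptible-regions arm
trioscreen run \
  --vcf demo/cohort.vcf --ped demo/cohort.ped \
  --cytoband demo/cytobands.tsv --gene-models demo/gene_models.tsv \
  --expression demo/expression.tsv --annotations demo/annotations.tsv \
  --regions demo/susceptible_bands.txt --arm regions --out demo_out/
```

which prints

```
13 candidate rows (9 coding, 4 regulatory) -> demo_out
```

and writes `candidates_coding.tsv` with rows such as

```
SNV_ID  Gene  CytoBand  Genotype      Ref Alt AAChange X1000g_Chinese X1000g_EAST Polyphen2_HDIV_category Frequency_in_cohort Sample
synth2  G002  4p16.1    homo_inherit  A   T   p.A102V  0.118021       0.218039    Probably damaging       1/25                17
synth7  G007  6q13      homo_gain     C   A   p.A107V  0.008254       0.466679    Possibly damaging       2/25                13/25
```

`Frequency_in_cohort` is the number of affected children carrying the
candidate genotype over the cohort size; `Sample` lists their IDs. The
run directory also contains the per-site × per-child genotype-category
matrix (`category_matrix.tsv`) and a stage-by-stage filtering summary
(`stage_summary.json`) whose counts decrease monotonically.

The same screen on the reconstructed published cohort
(`trioscreen simulate --paper-fixture --out fixture/`) returns the 26
susceptible-region candidates — among them the WFS1 promoter SNV
(`hetero_gain`, 3/25, carriers 42/65/78, PAX5 motif) and the CACNA1H
missense SNV (`homo_inherit`, 2/25, carriers 99/100) — and, on the
gene-set arm, the 11 dopamine-gene candidates including the two
hemizygous FLNA variants and the GNA12 `p.M1V` start-loss.

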