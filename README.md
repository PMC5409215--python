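# slafpop

Population-genomic analysis of amphidiploid *Brassica napus* panels
genotyped by SLAF-seq (specific-locus amplified fragment sequencing), as a
tested, reusable Python library. It covers the computational side of a
SLAF-seq diversity study end to end:

* **Library design** — in-silico double digestion (RsaI GT^AC + HaeIII
  GG^CC by default), selection of SLAF tags (restriction fragments of
  314–414 bp), per-chromosome tag spacing, and scoring of an enzyme scheme
  on the four usual criteria: few repeat-sequence tags, even chromosomal
  distribution, unique tag sequences, high tag count.
* **SNP landscape** — marker filtering at MAF > 0.05 and integrity
  (call rate) > 0.8; mutation-frequency hotspots (fraction of accessions
  with a non-reference genotype > 0.8); SNP counts in 100-kb windows; the
  top-1% windows merged into SNP-rich regions; per-ecotype (winter /
  semi-winter / spring) presence–absence contrasts of those regions.
* **Relatedness** — Loiselle marker-based kinship
  `f_ij = Σ_l (x_il − p_l)(x_jl − p_l) / Σ_l p_l(1 − p_l)` with negatives
  truncated to 0, p-distance (genotype-call mismatch proportion),
  Saitou–Nei neighbor joining, PCA of the centered dosage matrix.
* **Structure** — admixture-model EM (genotype `g_il ~ Binomial(2, Σ_k
  q_ik f_kl)`) with 5-fold genotype-masking cross-validation to choose K.
* **LD and haplotype blocks** — composite r² (squared dosage correlation),
  distance-binned decay curves anchored at (0 bp, r² = 1) with the decay
  distance at the r² = 0.1 crossing, per chromosome / subgenome / genome;
  Gabriel-style D′ confidence-interval haplotype blocks with per-chromosome
  block summaries.
* **Synthetic data** — a first-class simulator of amphidiploid genomes
  (10 "A" + 9 "C" chromosomes), structured diploid panels (Balding–Nichols
  group frequencies, founder haplotype copying with per-subgenome switch
  rates so the A subgenome shows shorter LD than C), and paired-end reads —
  so every stage is testable with no external download.

The package is aimed at crop-diversity researchers who want a transparent,
scriptable version of the usual SLAF-seq analysis stack (in-silico
digestion, PLINK/TASSEL-style LD, Haploview-style blocks, ADMIXTURE-style
structure) operating on plain FASTA/VCF inputs.

## Worked example

```python
from slafpop.digest import tag_spacing
from slafpop.tables import slaf_tag_table

per_chrom, total = slaf_tag_table()          # packaged per-chromosome table
per, overall = tag_spacing(
    dict(zip(per_chrom["chrom"], per_chrom["expected_slaf"])),
    dict(zip(per_chrom["chrom"], per_chrom["chrom_length_bp"])),
)
print(per["A01"])   # (12193, 4302)  -> 12,193 tags, one per 4,302 bp on A01
print(overall)      # 4267           -> genome-wide mean tag spacing in bp
```

A full in-silico run on synthetic data:

```sh
slafpop run --simulate --seed 1 --out demo/
```

writes, per stage, predicted tags (`tags.bed`), marker statistics and rich
regions, kinship/distance matrices and an NJ tree (`tree.nwk`), the
cross-validation curve and ancestry matrix, LD decay distances per scope
(`ld_decay.json`), haplotype blocks and their summary, plus a provenance
record of every parameter actually applied.

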