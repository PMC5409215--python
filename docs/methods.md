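# Methods

## Scope and inputs

The library analyses a diploid genotype panel (VCF with GT calls, biallelic
SNPs, missing allowed) against a chromosome-level genome (FASTA) whose
chromosomes carry subgenome labels A or C, as in amphidiploid *Brassica
napus* (A from *B. rapa*, C from *B. oleracea*). It deliberately starts
from called genotypes: demultiplexing, read clustering, alignment and
variant calling are out of scope. Read-level inputs appear only in the QC
statistics (Q30, GC content) and in the read simulator.

## In-silico digestion and tag selection

Cut positions are the union over enzymes of (site start + cut offset) for
every exact forward-strand occurrence of the recognition word; fragments
are the maximal intervals between consecutive cuts, so fragments tile each
chromosome exactly. Forward-strand scanning is exact for palindromic
enzymes (both defaults, RsaI and HaeIII, are palindromic); non-palindromic
enzymes are rejected territory — they would need double-strand scanning.
`N` never matches a recognition word. Tag selection keeps fragments with
length in the closed interval [314, 414] bp. Average spacing is
round(chromosome length / tag count) with ties rounded half away from
zero; this reproduces the printed per-chromosome table arithmetic
(52,457,410 / 12,193 → 4,302). The "repeat sequences" criterion is
operationalized as exact duplicate tag sequences, counting a tag and its
reverse complement as the same sequence, since no external repeat
annotation is assumed; "unique alignment" is likewise approximated by
tag-sequence uniqueness. Evenness is the coefficient of variation of tag
counts in fixed non-overlapping windows pooled genome-wide.

## Marker statistics

MAF is min(p, 1−p) with p the alternate-allele frequency over called
genotypes; integrity is the call rate. The filter keeps markers with
MAF > 0.05 **and** integrity > 0.8, both strict, so boundary markers are
removed. Mutation frequency is the fraction of called accessions carrying
any non-reference allele (dosage ≥ 1); hotspots are markers with mutation
frequency strictly > 0.8. The accession-level reading (rather than an
allele-frequency reading) follows from the hotspot definition being about
how many accessions differ from the reference; the denominator is called
accessions only. Windows are anchored at coordinate 0, 0-based half-open,
width 100 kb with the final window truncated — which is why rich-region
coordinates come out as multiples of 10⁵. Rich regions take the
ceil(1% × window count) highest-count windows, ties broken by genomic
order (earlier first), then merge adjacent selected windows. The
per-ecotype contrast recomputes the whole window pipeline inside each
ecotype subset using only markers polymorphic within that subset; the
reported region universe is the union of per-ecotype regions, merging
strict overlaps only (regions that merely touch stay distinct so that
ecotype-private regions remain visible).

## Relatedness

Kinship uses the Loiselle et al. (1995) estimator, which for biallelic
markers reduces to `f_ij = Σ_l (x_il − p_l)(x_jl − p_l) / Σ_l p_l(1−p_l)`
with x = dosage/2 and p the panel allele frequency; markers missing in
either accession are skipped pair-wise (the denominator is restricted to
the same markers), and negative estimates are truncated to zero after
estimation. p-distance is carried from sequence space to dosage space as
the genotype-call mismatch proportion over pairwise-complete markers.
Neighbor joining is Saitou–Nei with the Studier–Keppler Q criterion; a
negative branch length from the standard update is clamped to zero with
the deficit moved to its sister branch, preserving the pair's summed
length. PCA mean-imputes missing entries to the marker mean (so they are
neutral after centering), centers by marker, applies no variance scaling,
and reports eigenvalue fractions of the accession covariance. Kinship and
distance use pairwise deletion, PCA uses imputation: distance estimates
should not be distorted by imputed values, while PCA needs a complete
matrix.

## Structure

The admixture likelihood is `Σ_il g_il log p_il + (2−g_il) log(1−p_il)`
with `p_il = Σ_k q_ik f_kl`; missing entries are skipped. Optimization is
plain EM over the allele-origin latent variables — slower than the
quasi-Newton acceleration used by dedicated tools, but with identical
stationary points, and monotonicity of the log-likelihood is asserted at
every iteration (tolerance 1e-9 relative). Frequencies are clipped to
[1e-6, 1 − 1e-6]; q rows are renormalized each M-step. Initialization: q
from a symmetric Dirichlet(1), f from observed frequencies jittered by
seeded U(±0.05). EM is susceptible to local optima at K ≥ 3, so fits can
use `n_init` independent starts keeping the best likelihood;
cross-validation uses 3 starts per fit by default.

K is chosen by masking non-missing genotype entries (not accessions) in 5
seeded folds, refitting, predicting each masked genotype as 2·p_il, and
scoring `(g − 2p)²/2`; squared error was chosen as the held-out loss
because only an "error rate" is reported by the field-standard tool, and
the argmin rule (ties to smaller K) is fixed either way.

## LD and haplotype blocks

r² is the squared Pearson correlation of dosage vectors (composite LD) —
the comparable statistic to PLINK's default on unphased genotypes — over
pairwise-complete accessions, with pairs skipped when fewer than 4 shared
calls remain or either marker is monomorphic in the shared set.
EM-haplotype r² is deliberately *not* used for decay; haplotype-level
estimation enters only the D′/block machinery. Decay curves are 1-kb-bin
means of r² against distance with a fixed anchor at (0 bp, r² = 1); the
decay distance is the first linear-interpolated crossing of the threshold
(default 0.1), and a curve that never reaches it reports an undefined
distance rather than zero. Subgenome and genome scopes pool the pair
records of their chromosomes before binning.

D′ confidence intervals follow the Gabriel et al. (2002) likelihood
procedure: allele frequencies fixed at their sample values, double
heterozygotes resolved by EM, the multinomial likelihood of the 3×3
genotype table profiled over |D′| on a 0.001 grid (sign fixed to the EM
estimate), and the 90% interval read off the normalized likelihood mass
(5% in each tail); the point estimate is the grid maximum. Blocks use the
Gabriel defaults: strong LD iff CI low ≥ 0.70 and CI high ≥ 0.98, strong
recombination iff CI high < 0.90; a candidate interval needs a strong-LD
outermost pair and ≥ 95% strong-LD among informative pairs; candidates are
accepted greedily by descending bp span (first-to-last marker position).
Block length is that bp span. Per-chromosome summaries report block count,
total block length and its percentage of chromosome length (2 decimals);
the subgenome "frequency" aggregates as the **mean of per-chromosome
percentages**, not the pooled ratio — the aggregation that reproduces the
printed A/C subgenome figures (10.28% / 14.20%) from the printed
per-chromosome rows, whereas a pooled ratio does not — while the genome
row uses the pooled ratio (12.53%).

## Synthetic data

The generator emulates the features the analyses rely on, at desk scale:

* **Genome** — named chromosomes with subgenome labels (default 10 A at
  300 kb + 9 C at 400 kb, standing in for the ~1.2-Gb reference at ~1/180
  scale), i.i.d. background bases at a target GC (default 0.40) generated
  *free of the listed recognition words*, then recognition words planted
  at Poisson(rate × length) uniform positions — so a direct substring scan
  recovers the planted rate — plus optional exact repeat families.
* **Panel** — ancestral frequencies U(0.1, 0.9); group frequencies from
  the Balding–Nichols beta distribution with divergence F; each group
  carries two founder haplotypes per chromosome drawn from its
  frequencies; each accession draws ancestry proportions from a Dirichlet
  concentrated on one designated group (α = 9 vs 0.3, i.e. mostly-pure
  individuals with light admixture) and builds two haplotypes by Markov
  copying: at each marker the copying state (group, founder) switches with
  probability 1 − exp(−switch_rate × gap bp), the new group drawn from the
  accession's ancestry. One switch-rate per subgenome gives one-parameter
  control of LD range; the default A rate is 10× the C rate (1e-4 vs
  1e-5 per bp), reproducing the shorter-LD-in-A contrast. Genotypes are
  founder-allele sums; entries are masked i.i.d. at the missing rate
  (default 5%, matching the integrity range the filter targets). Ecotype
  labels attach to ancestral groups by largest-remainder apportionment of
  the ecotype mix (default 9% winter / 85.5% semi-winter / 5.5% spring,
  the panel composition the package emulates) and each accession takes the
  ecotype of its majority group — so ecotype tracks, but does not equal,
  genetic structure.
* **Reads** — Poisson(depth) read pairs per tag, R1 from the 5′ end and R2
  reverse-complemented from the 3′ end, Gaussian per-base Phred qualities
  clipped to [0, 41].

All randomness flows from one integer seed through named generators
(stage seeds derived by a CRC-based hash), so identical spec + seed gives
byte-identical output.

**What the simulator does not reproduce** — and hence what passing tests do
not show about real data: coalescent genealogies, selection and
demography, reference bias, sequencing-error-driven genotype errors,
non-uniform missingness, and realistic repeat landscapes. Two consequences
are worth knowing. First, with only two founders per group, realized group
allele frequencies drift beyond the nominal F (they are means of two
Bernoulli draws), so genotype-level divergence exceeds F even as F → 0;
truth-level frequency checks use the recorded `true_f`. Second, mixing
diverged groups puts a distance-independent floor under pooled r²
(stratification LD), which can dominate decay distances on strongly
structured panels; the LD-contrast experiments therefore run on
unstructured panels (k = 1) where decay reflects the copying process
alone.

## Study conditions used by the test and acceptance runs

Parameter-recovery experiments run at n = 60 accessions × 1,000 markers on
a two-chromosome genome (500 kb each): ancestry recovery with k = 3
balanced groups at F = 0.25 and near-unlinked markers (switch rates 5e-3),
K chosen over 1–5 by 5-fold CV, 10 seeded replicates. The subgenome LD
contrast runs 20 replicates of n = 50 × 250 markers per 400-kb chromosome
with switch rates 1e-4 (A) vs 1e-5 (C) on unstructured panels. Block-rule
cross-checks against exhaustive interval enumeration use 12-marker
chromosomes, where enumeration is exact and cheap.

## Numerical choices and degenerate inputs

Ties in spacing round half away from zero; densities per 100 kb round to
the nearest integer; percentages report 2 decimals. Zero-tag chromosomes
report undefined spacing (not zero); all-missing marker columns report
undefined statistics; an LD curve that never crosses the threshold reports
an undefined decay distance; accession pairs sharing no called marker get
an undefined kinship/distance entry with a warning. The EM's frequency
clipping (1e-6) bounds the likelihood away from ±∞ on monomorphic
markers. Grid resolution for D′ profiles is 0.001; making it finer changes
third-decimal CI bounds only.

## Known limitations

Digestion ignores partial digestion and methylation sensitivity. The
block finder computes all pairwise D′ CIs within a chromosome (optionally
distance-capped), which is quadratic in markers — fine at the package's
desk scale, not tuned for hundreds of thousands of markers. The
per-ecotype region contrast treats ecotypes independently and does not
test significance; it reports presence/absence only.
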