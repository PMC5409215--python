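"""Synthetic amphidiploid genomes, structured genotype panels, and reads.

The generator emulates the statistical structure the downstream analyses
assume, so the whole pipeline is testable without any external download:

* a genome of named chromosomes with subgenome labels (10 "A" + 9 "C" for a
  rapeseed-like amphidiploid), with restriction recognition words planted at
  controlled per-bp rates on an otherwise recognition-free background, plus
  optional exact repeat families;
* a structured diploid population: Balding-Nichols group allele frequencies
  around a shared ancestral frequency (divergence controlled by an F_ST-like
  parameter), per-group founder haplotypes, and a Markov haplotype-copying
  process along each chromosome whose founder-switch probability per gap is
  1 - exp(-switch_rate * gap_bp). A larger switch rate gives shorter-range
  linkage disequilibrium, so distinct A- and C-subgenome switch rates induce
  the subgenome LD contrast;
* paired-end reads from SLAF tags with a Gaussian per-base quality model,
  for read-level QC statistics (Q30, GC content).

All randomness flows from a single integer seed through named generators;
identical spec + seed reproduces outputs byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._util import BASES, revcomp, rng_for
from .digest import RestrictionEnzyme, SlafTagSet
from .genome import Chromosome, Genome
from .genotypes import ECOTYPES, GenotypeMatrix

__all__ = [
    "SimGenomeSpec",
    "SimPopSpec",
    "TruthRecord",
    "default_chrom_plan",
    "simulate_genome",
    "simulate_population",
    "simulate_reads",
]


def default_chrom_plan(
    n_a: int = 10, n_c: int = 9, a_length: int = 300_000, c_length: int = 400_000
) -> list[tuple[str, str, int]]:
    """Chromosome plan shaped like the rapeseed karyotype (10 A + 9 C).

    Lengths default to a desk-scale stand-in for the ~1.2 Gb reference
    (C chromosomes longer than A, as in the real genome).
    """
    plan = [(f"A{i + 1:02d}", "A", a_length) for i in range(n_a)]
    plan += [(f"C{i + 1:02d}", "C", c_length) for i in range(n_c)]
    return plan


@dataclass
class SimGenomeSpec:
    """Plan for a synthetic genome.

    ``site_rates`` maps each enzyme to the expected number of planted
    recognition sites per bp; the background sequence is generated free of
    all listed recognition words so a direct scan recovers the planted rate.
    ``repeat_plan`` is (family count, family length bp, copies per family).
    """

    chrom_plan: list[tuple[str, str, int]] = field(default_factory=default_chrom_plan)
    gc_target: float = 0.40
    site_rates: dict[RestrictionEnzyme, float] = field(default_factory=dict)
    repeat_plan: tuple[int, int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.chrom_plan:
            raise ValueError("chrom_plan is empty")
        for name, sub, length in self.chrom_plan:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if sub not in ("A", "C"):
                raise ValueError(f"chromosome {name!r}: subgenome must be 'A' or 'C'")
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must be in [0, 1]")
        for enz, rate in self.site_rates.items():
            if rate < 0:
                raise ValueError(f"negative site rate for {enz.name}")
        if self.repeat_plan is not None:
            n_fam, fam_len, copies = self.repeat_plan
            if copies < 1 or n_fam < 0 or fam_len <= 0:
                raise ValueError("repeat_plan requires copies >= 1 and fam_len > 0")


@dataclass
class SimPopSpec:
    """Plan for a structured diploid panel on a simulated genome.

    ``fst`` is the Balding-Nichols divergence of the ``k_true`` ancestral
    groups; ``switch_rate_a`` / ``switch_rate_c`` are per-bp founder-switch
    probabilities of the haplotype-copying process on A / C chromosomes
    (A > C yields shorter LD in the A subgenome); ``ecotype_mix`` gives the
    winter / semi-winter / spring proportions.
    """

    n_accessions: int = 60
    n_markers_per_chrom: int = 100
    k_true: int = 3
    fst: float = 0.25
    ecotype_mix: tuple[float, float, float] = (0.09, 0.855, 0.055)
    switch_rate_a: float = 1e-4
    switch_rate_c: float = 1e-5
    missing_rate: float = 0.05
    admixture_alpha: tuple[float, float] = (9.0, 0.3)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_true < 1:
            raise ValueError("k_true must be >= 1")
        if self.n_accessions < 2:
            raise ValueError("need at least two accessions")
        if self.n_markers_per_chrom < 1:
            raise ValueError("need at least one marker per chromosome")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("fst must be in (0, 1)")
        if abs(sum(self.ecotype_mix) - 1.0) > 1e-9:
            raise ValueError("ecotype_mix must sum to 1")
        for r in (self.switch_rate_a, self.switch_rate_c):
            if not 0.0 < r < 1.0:
                raise ValueError("switch rates must be in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of a simulated panel, for parameter-recovery tests."""

    true_q: np.ndarray  # accessions x groups ancestry proportions
    true_f: np.ndarray  # groups x markers allele frequencies
    true_labels: list[str]  # ecotype per accession
    group_ecotype: list[str] = field(default_factory=list)  # ecotype per group

    def __post_init__(self) -> None:
        if not np.allclose(self.true_q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("ancestry rows must sum to 1")
        if self.true_f.min() < 0 or self.true_f.max() > 1:
            raise ValueError("allele frequencies must be in [0, 1]")


# ---------------------------------------------------------------------------
# genome simulation


def _random_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _scrub_words(
    seq: list[str], words: list[str], rng: np.random.Generator, gc: float
) -> None:
    """Mutate bases in place until no listed word occurs in the sequence."""
    if not words:
        return
    for _ in range(200):  # converges in a handful of passes
        text = "".join(seq)
        hits = []
        for w in words:
            i = text.find(w)
            while i != -1:
                hits.append((i, len(w)))
                i = text.find(w, i + 1)
        if not hits:
            return
        for start, wlen in hits:
            j = start + int(rng.integers(wlen))
            old = seq[j]
            choices = [b for b in BASES if b != old]
            seq[j] = choices[int(rng.integers(3))]
    raise RuntimeError("could not scrub recognition words from sequence")


def simulate_genome(spec: SimGenomeSpec) -> Genome:
    """Generate a genome per the plan; deterministic given the seed.

    The background sequence avoids every enzyme's recognition word, repeat
    family copies are inserted as exact duplicates, and recognition words
    are then planted at Poisson(rate * length) uniform positions, so that a
    naive substring scan of the output recovers the planted site counts.
    """
    rng = rng_for(spec.seed, "genome")
    words = sorted({e.recognition for e in spec.site_rates})
    chromosomes: list[Chromosome] = []
    families: list[str] = []
    if spec.repeat_plan is not None:
        n_fam, fam_len, _ = spec.repeat_plan
        for _ in range(n_fam):
            fam = _random_bases(rng, fam_len, spec.gc_target).astype("U1").tolist()
            _scrub_words(fam, words, rng, spec.gc_target)
            families.append("".join(fam))

    copies_per_chrom: dict[str, int] = {}
    if spec.repeat_plan is not None and families:
        # spread the copies of every family uniformly over chromosomes
        total_len = sum(length for _, _, length in spec.chrom_plan)

    for name, sub, length in spec.chrom_plan:
        seq = _random_bases(rng, length, spec.gc_target).astype("U1").tolist()
        if families:
            _, fam_len, copies = spec.repeat_plan  # type: ignore[misc]
            share = length / total_len
            for fam in families:
                n_here = int(np.round(copies * share))
                for _ in range(n_here):
                    if length <= fam_len:
                        continue
                    pos = int(rng.integers(length - fam_len))
                    seq[pos : pos + fam_len] = list(fam)
        _scrub_words(seq, words, rng, spec.gc_target)
        for enz, rate in spec.site_rates.items():
            n_sites = int(rng.poisson(rate * length))
            wlen = len(enz.recognition)
            if length <= wlen:
                continue
            for pos in rng.integers(0, length - wlen, size=n_sites):
                seq[pos : pos + wlen] = list(enz.recognition)
        chromosomes.append(Chromosome(name, "".join(seq), sub))
    return Genome(chromosomes)


# ---------------------------------------------------------------------------
# population simulation


def _allocate_groups(k: int, mix: tuple[float, float, float]) -> list[str]:
    """Assign each ancestral group to an ecotype, in proportion to the mix.

    Largest-remainder apportionment; every ecotype with positive weight gets
    at least one group when k >= number of such ecotypes.
    """
    weights = np.asarray(mix, dtype=float)
    raw = weights * k
    counts = np.floor(raw).astype(int)
    active = weights > 0
    if k >= active.sum():
        counts[active & (counts == 0)] = 1
    while counts.sum() > k:
        counts[int(np.argmax(counts))] -= 1
    while counts.sum() < k:
        frac = raw - counts
        frac[~active] = -1
        counts[int(np.argmax(frac))] += 1
    out: list[str] = []
    for eco, c in zip(ECOTYPES, counts):
        out.extend([eco] * int(c))
    return out[:k]


def simulate_population(
    genome: Genome, spec: SimPopSpec
) -> tuple[GenotypeMatrix, TruthRecord]:
    """Simulate a structured diploid panel on a genome.

    Model: ancestral frequencies p_l ~ U(0.1, 0.9); group frequencies
    f_kl ~ Beta(p(1-F)/F, (1-p)(1-F)/F) (Balding-Nichols with F = fst);
    each group carries two founder haplotypes per chromosome drawn from
    Bernoulli(f_kl); each accession has ancestry proportions q_i ~ Dirichlet
    (concentrated on one designated group) and two haplotypes built by
    Markov copying: at each marker the copying state (group, founder)
    switches with probability 1 - exp(-switch_rate * gap_bp), drawing the
    new group from q_i. Genotypes are founder-allele sums; entries are then
    masked at ``missing_rate``.
    """
    for chrom in genome:
        if chrom.subgenome not in ("A", "C"):
            raise ValueError(f"chromosome {chrom.name!r} lacks a subgenome label")
    rng = rng_for(spec.seed, "population")
    k, n = spec.k_true, spec.n_accessions
    m_per = spec.n_markers_per_chrom

    chrom_names: list[str] = []
    positions: list[np.ndarray] = []
    for chrom in genome:
        upper = len(chrom)
        take = min(m_per, upper)
        pos = np.sort(rng.choice(np.arange(1, upper + 1), size=take, replace=False))
        chrom_names.append(chrom.name)
        positions.append(pos)
    m_total = sum(len(p) for p in positions)

    p_anc = rng.uniform(0.1, 0.9, size=m_total)
    a = p_anc * (1 - spec.fst) / spec.fst
    b = (1 - p_anc) * (1 - spec.fst) / spec.fst
    true_f = np.clip(rng.beta(a, b, size=(k, m_total)), 1e-4, 1 - 1e-4)

    # two founder haplotypes per group per chromosome
    founders = (rng.random(size=(k, 2, m_total)) < true_f[:, None, :]).astype(np.int8)

    group_ecotype = _allocate_groups(k, spec.ecotype_mix)
    eco_groups: dict[str, list[int]] = {}
    for g, eco in enumerate(group_ecotype):
        eco_groups.setdefault(eco, []).append(g)
    mix = np.asarray(spec.ecotype_mix, dtype=float)

    hi, lo = spec.admixture_alpha
    true_q = np.empty((n, k))
    primary = np.empty(n, dtype=int)
    for i in range(n):
        eco = ECOTYPES[int(rng.choice(3, p=mix))]
        pool = eco_groups.get(eco) or list(range(k))
        primary[i] = int(rng.choice(pool))
        alpha = np.full(k, lo)
        alpha[primary[i]] = hi
        true_q[i] = rng.dirichlet(alpha)

    # Markov haplotype copying along each chromosome
    dosages = np.zeros((n, m_total), dtype=float)
    offset = 0
    for chrom, pos in zip(genome, positions):
        mloc = len(pos)
        rate = spec.switch_rate_a if chrom.subgenome == "A" else spec.switch_rate_c
        gaps = np.diff(pos)
        p_switch = 1.0 - np.exp(-rate * gaps)
        sl = slice(offset, offset + mloc)
        fnd = founders[:, :, sl]
        for i in range(n):
            geno = np.zeros(mloc, dtype=np.int8)
            for _hap in range(2):
                g = int(rng.choice(k, p=true_q[i]))
                f = int(rng.integers(2))
                alleles = np.empty(mloc, dtype=np.int8)
                alleles[0] = fnd[g, f, 0]
                switch = rng.random(mloc - 1) < p_switch
                for j in range(1, mloc):
                    if switch[j - 1]:
                        g = int(rng.choice(k, p=true_q[i]))
                        f = int(rng.integers(2))
                    alleles[j] = fnd[g, f, j]
                geno += alleles
            dosages[i, sl] = geno
        offset += mloc

    if spec.missing_rate > 0:
        mask = rng.random(dosages.shape) < spec.missing_rate
        dosages[mask] = np.nan

    labels = [group_ecotype[int(np.argmax(true_q[i]))] for i in range(n)]
    markers = pd.DataFrame(
        {
            "chrom": np.repeat(chrom_names, [len(p) for p in positions]),
            "pos": np.concatenate(positions).astype(int),
            "ref": "A",
            "alt": "G",
        }
    )
    gm = GenotypeMatrix(
        dosages=dosages,
        markers=markers,
        accessions=[f"acc{i + 1:04d}" for i in range(n)],
        ecotype=labels,
    )
    truth = TruthRecord(true_q=true_q, true_f=true_f, true_labels=labels,
                        group_ecotype=group_ecotype)
    return gm, truth


# ---------------------------------------------------------------------------
# read simulation


def simulate_reads(
    tags: SlafTagSet,
    depth: float,
    quality_model: tuple[float, float] = (35.0, 3.0),
    seed: int = 0,
    read_length: int = 100,
) -> tuple[list[SeqRecord], list[SeqRecord]]:
    """Paired-end reads from SLAF tags: (R1 records, R2 records).

    Each tag yields Poisson(depth) read pairs; R1 is the fragment 5' end,
    R2 the reverse complement of the 3' end. Per-base Phred qualities are
    Gaussian(mean Q, sd), rounded and clipped to [0, 41].
    """
    if len(tags) == 0:
        raise ValueError("tag set is empty")
    if depth <= 0:
        raise ValueError("depth must be positive")
    mean_q, sd_q = quality_model
    rng = rng_for(seed, "reads")
    r1: list[SeqRecord] = []
    r2: list[SeqRecord] = []
    for tag in tags.tags:
        L = min(read_length, len(tag))
        fwd = tag.sequence[:L]
        rev = revcomp(tag.sequence)[:L]
        for copy in range(int(rng.poisson(depth))):
            name = f"{tag.chrom}_{tag.start}_{copy}"
            for seq, bucket in ((fwd, r1), (rev, r2)):
                if sd_q > 0:
                    quals = np.clip(np.round(rng.normal(mean_q, sd_q, len(seq))), 0, 41)
                else:
                    quals = np.full(len(seq), np.clip(round(mean_q), 0, 41))
                rec = SeqRecord(Seq(seq), id=name, description="")
                rec.letter_annotations["phred_quality"] = [int(q) for q in quals]
                bucket.append(rec)
    return r1, r2
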