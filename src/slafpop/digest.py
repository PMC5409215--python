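"""In-silico restriction digestion and SLAF tag selection.

A SLAF (specific-locus amplified fragment) library targets restriction
fragments inside a chosen size window — here 314-414 bp by default — from a
double digest. This module predicts those fragments from a genome sequence,
computes per-chromosome tag spacing, and scores an enzyme scheme against the
four usual design criteria: few repeat-sequence tags, even chromosomal
distribution, unique tag sequences, and a high tag count.

Only exact forward-strand occurrences of the recognition word are scanned.
This is exact for palindromic enzymes such as RsaI (GT^AC) and HaeIII
(GG^CC); non-palindromic enzymes would require double-strand scanning and
are not supported. Ambiguity codes (N) never match a recognition word.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._util import revcomp, round_half_away
from .genome import Genome


@dataclass(frozen=True)
class RestrictionEnzyme:
    """A blunt- or sticky-end enzyme described by its recognition word.

    ``cut_offset`` is the number of bases from the start of the recognition
    word to the cut point on the forward strand (RsaI GT^AC -> offset 2).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        word = self.recognition.upper()
        if not word or any(b not in "ACGT" for b in word):
            raise ValueError(f"{self.name}: recognition must be non-empty A/C/G/T")
        if not 0 <= self.cut_offset <= len(word):
            raise ValueError(f"{self.name}: cut_offset outside recognition word")
        object.__setattr__(self, "recognition", word)

    @property
    def is_palindromic(self) -> bool:
        return self.recognition == revcomp(self.recognition)


RSA_I = RestrictionEnzyme("RsaI", "GTAC", 2)
HAE_III = RestrictionEnzyme("HaeIII", "GGCC", 2)

ENZYMES = {"RsaI": RSA_I, "HaeIII": HAE_III}


@dataclass(frozen=True)
class Fragment:
    """A digestion fragment in 0-based half-open genomic coordinates."""

    chrom: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError("fragment requires 0 <= start < end")
        if self.end - self.start != len(self.sequence):
            raise ValueError("fragment length does not match sequence")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class SlafTagSet:
    """Fragments retained inside the tag size window, sorted and disjoint."""

    tags: list[Fragment]
    min_len: int
    max_len: int

    def __post_init__(self) -> None:
        for t in self.tags:
            if not self.min_len <= len(t) <= self.max_len:
                raise ValueError("tag length outside [min_len, max_len]")
        order = sorted(range(len(self.tags)), key=lambda i: (self.tags[i].chrom, self.tags[i].start))
        self.tags = [self.tags[i] for i in order]
        prev: Fragment | None = None
        for t in self.tags:
            if prev is not None and t.chrom == prev.chrom and t.start < prev.end:
                raise ValueError("tags overlap within a chromosome")
            prev = t

    def __len__(self) -> int:
        return len(self.tags)

    def by_chrom(self) -> dict[str, list[Fragment]]:
        out: dict[str, list[Fragment]] = {}
        for t in self.tags:
            out.setdefault(t.chrom, []).append(t)
        return out


@dataclass
class SchemeReport:
    """Metrics for the four enzyme-scheme selection criteria."""

    tag_count: int
    per_chrom: dict[str, tuple[int, int | None]]  # chrom -> (count, avg spacing bp)
    repeat_fraction: float | None
    uniqueness_fraction: float | None
    evenness_cv: float | None
    window_bp: int = 0
    genome_spacing: int | None = None


def find_sites(sequence: str, word: str) -> list[int]:
    """All start positions of exact (possibly overlapping) occurrences."""
    seq = sequence.upper()
    sites: list[int] = []
    i = seq.find(word)
    while i != -1:
        sites.append(i)
        i = seq.find(word, i + 1)
    return sites


def cut_positions(sequence: str, enzymes: list[RestrictionEnzyme]) -> list[int]:
    """Union of cut points over enzymes, restricted to the interior."""
    cuts: set[int] = set()
    for enz in enzymes:
        for s in find_sites(sequence, enz.recognition):
            c = s + enz.cut_offset
            if 0 < c < len(sequence):
                cuts.add(c)
    return sorted(cuts)


def digest(genome: Genome, enzymes: list[RestrictionEnzyme]) -> list[Fragment]:
    """Double (or multi-) digest: fragments between consecutive cut points.

    Fragments tile each chromosome exactly: the concatenation of fragment
    sequences per chromosome equals the chromosome sequence.
    """
    if not enzymes:
        raise ValueError("at least one enzyme required")
    fragments: list[Fragment] = []
    for chrom in genome:
        seq = chrom.sequence.upper()
        cuts = cut_positions(seq, enzymes)
        bounds = [0, *cuts, len(seq)]
        for a, b in zip(bounds[:-1], bounds[1:]):
            fragments.append(Fragment(chrom.name, a, b, seq[a:b]))
    return fragments


def select_tags(
    fragments: list[Fragment], min_len: int = 314, max_len: int = 414
) -> SlafTagSet:
    """Retain exactly the fragments whose length is in [min_len, max_len]."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    kept = [f for f in fragments if min_len <= len(f) <= max_len]
    return SlafTagSet(kept, min_len, max_len)


def tag_spacing(
    counts: dict[str, int], chrom_lengths: dict[str, int]
) -> tuple[dict[str, tuple[int, int | None]], int | None]:
    """Average tag spacing per chromosome and genome-wide.

    Spacing = round(chromosome length / tag count), ties rounded half away
    from zero; a chromosome with zero tags gets spacing None. Returns
    (per-chromosome {name: (count, spacing)}, genome-wide spacing).
    """
    per: dict[str, tuple[int, int | None]] = {}
    for chrom, length in chrom_lengths.items():
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length")
        n = int(counts.get(chrom, 0))
        per[chrom] = (n, round_half_away(length / n) if n > 0 else None)
    total_n = sum(counts.get(c, 0) for c in chrom_lengths)
    total_len = sum(chrom_lengths.values())
    overall = round_half_away(total_len / total_n) if total_n > 0 else None
    return per, overall


def tagset_spacing(
    tagset: SlafTagSet, chrom_lengths: dict[str, int]
) -> tuple[dict[str, tuple[int, int | None]], int | None]:
    counts = {c: len(v) for c, v in tagset.by_chrom().items()}
    return tag_spacing(counts, chrom_lengths)


def evaluate_scheme(
    tagset: SlafTagSet, genome: Genome, window_bp: int = 100_000
) -> SchemeReport:
    """Score a digestion scheme against the four selection criteria.

    ``repeat_fraction`` counts tags whose exact sequence (or its reverse
    complement) equals another tag's sequence; ``evenness_cv`` is sd/mean of
    tag counts over fixed non-overlapping windows pooled genome-wide.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    per, overall = tagset_spacing(tagset, genome.lengths)
    n = len(tagset)
    if n == 0:
        return SchemeReport(0, per, None, None, None, window_bp, overall)

    # canonical form folds a tag and its reverse complement together
    canon: dict[str, int] = {}
    for t in tagset.tags:
        key = min(t.sequence.upper(), revcomp(t.sequence.upper()))
        canon[key] = canon.get(key, 0) + 1
    dup = sum(c for c in canon.values() if c > 1)
    repeat_fraction = dup / n

    window_counts: list[int] = []
    by_chrom = tagset.by_chrom()
    for chrom in genome:
        length = len(chrom)
        n_win = -(-length // window_bp)
        counts = np.zeros(n_win, dtype=int)
        for t in by_chrom.get(chrom.name, []):
            counts[t.start // window_bp] += 1
        window_counts.extend(counts.tolist())
    wc = np.asarray(window_counts, dtype=float)
    mean = wc.mean()
    cv = float(wc.std(ddof=0) / mean) if mean > 0 else None

    return SchemeReport(
        tag_count=n,
        per_chrom=per,
        repeat_fraction=repeat_fraction,
        uniqueness_fraction=1.0 - repeat_fraction,
        evenness_cv=cv,
        window_bp=window_bp,
        genome_spacing=overall,
    )
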