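"""Readers/writers for the standard formats plus read-level QC statistics.

FASTA and FASTQ go through Biopython; VCF reading goes through cyvcf2 and
writing emits plain VCF v4.2 text. Genomic intervals are written as BED
(0-based half-open); genotype positions are VCF 1-based.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .genome import Chromosome, Genome, infer_subgenome
from .genotypes import GenotypeMatrix

log = logging.getLogger("slafpop")

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_vcf",
    "write_vcf",
    "write_fastq",
    "read_metadata",
    "write_metadata",
    "write_bed",
    "gc_content",
    "q30_fraction",
]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, subgenomes: dict[str, str] | None = None) -> Genome:
    """Load a genome; subgenome labels from the mapping or the name prefix."""
    chroms = []
    for rec in SeqIO.parse(str(path), "fasta"):
        sub = (subgenomes or {}).get(rec.id, infer_subgenome(rec.id))
        chroms.append(Chromosome(rec.id, str(rec.seq).upper(), sub))
    return Genome(chroms)


def write_fasta(genome: Genome, path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="") for c in genome]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic SNP genotypes into a dosage matrix.

    GT is mapped 0/0 -> 0, 0/1 -> 1, 1/1 -> 2, ./. -> missing; phased
    separators are accepted and treated as unphased. Multiallelic records
    are skipped with a logged count.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple[str, int, str, str]] = []
    dosage_cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        gt = np.asarray(var.gt_types, dtype=float)
        col = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
        dosage_cols.append(col)
    vcf.close()
    if n_multi:
        log.info("skipped %d multiallelic records", n_multi)
    markers = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    dosages = (
        np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0))
    )
    return GenotypeMatrix(dosages=dosages, markers=markers, accessions=samples)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(
    gm: GenotypeMatrix, path: str | Path, chrom_lengths: dict[str, int] | None = None
) -> None:
    """Write the dosage matrix as VCF v4.2 with GT fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=slafpop\n")
        for chrom, length in (chrom_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.accessions)
            + "\n"
        )
        for j in range(gm.n_markers):
            mk = gm.markers.iloc[j]
            calls = [
                _GT.get(g, "./.") if not np.isnan(g) else "./."
                for g in gm.dosages[:, j]
            ]
            fh.write(
                f"{mk['chrom']}\t{int(mk['pos'])}\t.\t{mk['ref']}\t{mk['alt']}\t.\t"
                "PASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


# ---------------------------------------------------------------------------
# FASTQ / metadata / BED


def write_fastq(records: Iterable[SeqRecord], path: str | Path) -> int:
    return SeqIO.write(list(records), str(path), "fastq")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Sample metadata: tab-separated id, ecotype, origin."""
    tab = pd.read_csv(path, sep="\t", dtype=str)
    need = {"id", "ecotype", "origin"}
    if not need <= set(tab.columns):
        raise ValueError(f"metadata must have columns {sorted(need)}")
    return tab


def write_metadata(gm: GenotypeMatrix, path: str | Path, origin: str = "simulated") -> None:
    eco = gm.ecotype or [""] * gm.n_accessions
    pd.DataFrame({"id": gm.accessions, "ecotype": eco, "origin": origin}).to_csv(
        path, sep="\t", index=False
    )


def write_bed(intervals: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write (chrom, start, end[, name]) intervals as BED (0-based half-open)."""
    cols = ["chrom", "start", "end"]
    out = intervals[cols].copy()
    if name_col is not None and name_col in intervals:
        out["name"] = intervals[name_col]
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# QC statistics


def gc_content(sequences: Iterable[str] | str) -> float:
    """(G+C) / (A+C+G+T) over the sequences; ambiguity codes excluded.

    Returns NaN when no unambiguous base is present.
    """
    if isinstance(sequences, str):
        sequences = [sequences]
    gc = at = 0
    for seq in sequences:
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    total = gc + at
    return float("nan") if total == 0 else gc / total


def q30_fraction(records: Iterable[SeqRecord] | str | Path, min_q: int = 30) -> float:
    """Fraction of bases with Phred quality >= min_q (Q30 by default)."""
    if isinstance(records, (str, Path)):
        records = SeqIO.parse(str(records), "fastq")
    n_total = n_high = 0
    for rec in records:
        quals = rec.letter_annotations.get("phred_quality")
        if quals is None or len(quals) != len(rec.seq):
            raise ValueError(f"record {rec.id}: quality/sequence length mismatch")
        n_total += len(quals)
        n_high += sum(q >= min_q for q in quals)
    if n_total == 0:
        raise ValueError("no bases")
    return n_high / n_total
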