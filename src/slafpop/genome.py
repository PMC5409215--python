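"""Genome container for amphidiploid chromosome sets.

A genome here is an ordered collection of named chromosome sequences, each
carrying a subgenome label ("A" or "C") as in amphidiploid *Brassica napus*,
whose A subgenome derives from *B. rapa* and C subgenome from *B. oleracea*.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass
class Chromosome:
    """A single named chromosome with an optional subgenome label."""

    name: str
    sequence: str
    subgenome: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"chromosome {self.name!r} has zero length")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Genome:
    """Ordered set of chromosomes keyed by name."""

    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")

    def __len__(self) -> int:
        return len(self.chromosomes)

    def __iter__(self):
        return iter(self.chromosomes)

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @property
    def lengths(self) -> dict[str, int]:
        return {c.name: len(c) for c in self.chromosomes}

    @property
    def subgenomes(self) -> dict[str, str]:
        return {c.name: c.subgenome for c in self.chromosomes}

    @property
    def total_length(self) -> int:
        return sum(len(c) for c in self.chromosomes)


def infer_subgenome(chrom_name: str) -> str:
    """Guess the subgenome label from a chromosome name like ``A01``/``C07``.

    Returns ``""`` when the name does not start with A or C.
    """
    head = chrom_name[:1].upper()
    return head if head in ("A", "C") else ""
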