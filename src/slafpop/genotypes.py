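"""Genotype matrix container: accessions x markers alternate-allele dosages.

Dosages are stored as a float array with entries in {0, 1, 2} and NaN for
missing calls. Marker metadata (chromosome, 1-based position, ref/alt
alleles) lives in a pandas DataFrame aligned with the dosage columns;
accession ids and optional ecotype labels (winter / semi-winter / spring)
align with the rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

ECOTYPES = ("winter", "semi-winter", "spring")

MARKER_COLUMNS = ["chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    dosages: np.ndarray
    markers: pd.DataFrame
    accessions: list[str]
    ecotype: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (accessions x markers)")
        n, m = self.dosages.shape
        if len(self.accessions) != n:
            raise ValueError("accession ids do not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker table does not match dosage columns")
        for col in MARKER_COLUMNS[:2]:
            if col not in self.markers.columns:
                raise ValueError(f"marker table missing column {col!r}")
        if self.ecotype is not None and len(self.ecotype) != n:
            raise ValueError("ecotype labels do not match dosage rows")
        if m and int(self.markers["pos"].min()) < 1:
            raise ValueError("marker positions must be 1-based (>= 1)")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or missing")
        self._check_sorted()
        self.markers = self.markers.reset_index(drop=True)

    def _check_sorted(self) -> None:
        chrom = self.markers["chrom"].to_numpy()
        pos = self.markers["pos"].to_numpy()
        seen: dict[str, int] = {}
        last_chrom = None
        for c, p in zip(chrom, pos):
            if c != last_chrom:
                if c in seen:
                    raise ValueError("markers not grouped by chromosome")
                seen[c] = 1
                last_chrom = c
                last_pos = p
            elif p < last_pos:
                raise ValueError("marker positions not sorted within chromosome")
            else:
                last_pos = p

    @property
    def n_accessions(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosages)

    @property
    def chroms(self) -> list[str]:
        """Chromosome names in order of first appearance."""
        return list(dict.fromkeys(self.markers["chrom"]))

    def take_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        """Subset markers by positional index, preserving order."""
        index = np.asarray(index)
        return replace(
            self,
            dosages=self.dosages[:, index],
            markers=self.markers.iloc[index].reset_index(drop=True),
        )

    def take_accessions(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        eco = None
        if self.ecotype is not None:
            eco = [self.ecotype[i] for i in index]
        return replace(
            self,
            dosages=self.dosages[index, :],
            accessions=[self.accessions[i] for i in index],
            ecotype=eco,
        )

    def markers_on(self, chrom: str) -> np.ndarray:
        """Positional indices of the markers on one chromosome."""
        return np.flatnonzero((self.markers["chrom"] == chrom).to_numpy())
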