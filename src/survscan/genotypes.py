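"""In-memory genotype container: individuals x SNPs allele-count matrix."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Allele-count matrix with per-SNP metadata.

    ``values`` is an (n_individuals, n_snps) float array of minor-allele
    counts in {0..ploidy}, with ``NaN`` for missing calls.
    """

    values: np.ndarray
    snp_ids: np.ndarray = None
    individual_ids: np.ndarray = None
    ploidy: int = 2
    chrom: np.ndarray = None
    pos: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-D (individuals x SNPs)")
        n, m = self.values.shape
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 or 2")
        v = self.values
        with np.errstate(invalid="ignore"):
            valid = np.isnan(v) | ((v >= 0) & (v <= self.ploidy) & (v == np.floor(v)))
        if not valid.all():
            raise ValueError("allele counts must be in {0..ploidy} or NaN")
        if self.snp_ids is None:
            self.snp_ids = np.array([f"snp{j}" for j in range(m)])
        else:
            self.snp_ids = np.asarray(self.snp_ids)
        if self.individual_ids is None:
            self.individual_ids = np.arange(n)
        else:
            self.individual_ids = np.asarray(self.individual_ids)
        if len(self.snp_ids) != m or len(self.individual_ids) != n:
            raise ValueError("metadata lengths do not match matrix shape")
        if self.chrom is None:
            self.chrom = np.ones(m, dtype=int)
        if self.pos is None:
            self.pos = np.arange(1, m + 1)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Per-SNP frequency of the counted allele among non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.values, axis=0) / self.ploidy

    def maf(self) -> np.ndarray:
        """Folded minor-allele frequency."""
        f = self.allele_freq()
        return np.minimum(f, 1.0 - f)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.values).mean(axis=0)

    def subset_snps(self, mask_or_index) -> "GenotypeMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.values[:, idx], self.snp_ids[idx], self.individual_ids,
            self.ploidy, np.asarray(self.chrom)[idx], np.asarray(self.pos)[idx],
        )

    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "snp_id": self.snp_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "maf": self.maf(),
                "call_rate": self.call_rate(),
            }
        )
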