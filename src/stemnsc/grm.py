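"""Genomic relationship matrix (GRM) from SNP dosages.

The additive relationship between inbred lines is estimated with the
VanRaden-style normalisation K = Zc Zc' / (2 sum_j p_j (1 - p_j)), where Zc
is the dosage matrix centred at twice the allele frequency. Monomorphic
SNPs carry no relationship information and are excluded from the
denominator (their centred column is identically zero, so they contribute
nothing to the numerator either). Missing dosages are mean-imputed before
centring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = ["GRM", "compute_grm"]


@dataclass
class GRM:
    """Symmetric lines x lines genomic relationship matrix."""

    line_ids: list[str]
    K: np.ndarray

    def __post_init__(self) -> None:
        self.K = np.asarray(self.K, dtype=float)
        n = len(self.line_ids)
        if self.K.shape != (n, n):
            raise ValueError("K must be square with one row per line id")
        if np.max(np.abs(self.K - self.K.T)) > 1e-10:
            raise ValueError("K must be symmetric (tolerance 1e-10)")
        self.line_ids = [str(s) for s in self.line_ids]

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def subset(self, ids: list[str]) -> "GRM":
        pos = {s: i for i, s in enumerate(self.line_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"lines absent from GRM: {missing}")
        idx = np.asarray([pos[s] for s in ids])
        return GRM(list(ids), self.K[np.ix_(idx, idx)])

    @classmethod
    def identity(cls, line_ids: list[str]) -> "GRM":
        """Exchangeable-lines relationship (K = I)."""
        return cls(list(line_ids), np.eye(len(line_ids)))


def compute_grm(genotypes: GenotypeMatrix) -> GRM:
    """Build the GRM from a dosage matrix.

    Raises if every SNP is monomorphic (zero denominator).
    """
    p = genotypes.allele_freqs
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    denom = 2.0 * np.sum(p[poly] * (1.0 - p[poly]))
    if denom <= 0:
        raise ValueError("all SNPs are monomorphic: GRM denominator is zero")
    z = genotypes.imputed() - 2.0 * p
    z[:, ~poly] = 0.0
    k = (z @ z.T) / denom
    k = 0.5 * (k + k.T)  # exact symmetry against float round-off
    return GRM(list(genotypes.line_ids), k)
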