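"""SNP dosage matrix container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """Lines x SNPs dosage matrix coded 0/1/2 with NaN for missing calls.

    ``allele_freqs`` holds the per-SNP alternate-allele frequency computed
    from the non-missing dosages (dosage mean / 2). It is recomputed at
    construction and must agree with any supplied value to 1e-12.
    """

    line_ids: list[str]
    dosages: np.ndarray
    snp_ids: list[str] | None = None
    allele_freqs: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D (lines x snps) matrix")
        n, p = self.dosages.shape
        if n < 2:
            raise ValueError("at least 2 lines are required")
        if len(self.line_ids) != n:
            raise ValueError("line_ids length must match number of rows")
        self.line_ids = [str(s) for s in self.line_ids]
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j:05d}" for j in range(p)]
        elif len(self.snp_ids) != p:
            raise ValueError("snp_ids length must match number of columns")
        obs = self.dosages[~np.isnan(self.dosages)]
        if obs.size and not np.all(np.isin(obs, (0.0, 1.0, 2.0))):
            raise ValueError("dosages must be in {0, 1, 2} or missing (NaN)")
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(self.dosages, axis=0) / 2.0
        if self.allele_freqs is not None:
            supplied = np.asarray(self.allele_freqs, dtype=float)
            if supplied.shape != freqs.shape or np.nanmax(np.abs(supplied - freqs)) > 1e-12:
                raise ValueError("supplied allele_freqs disagree with dosage-derived frequencies")
        self.allele_freqs = freqs

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def imputed(self) -> np.ndarray:
        """Dosages with missing entries replaced by the per-SNP mean (2p)."""
        filled = self.dosages.copy()
        idx = np.where(np.isnan(filled))
        if idx[0].size:
            filled[idx] = 2.0 * self.allele_freqs[idx[1]]
        return filled
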