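"""Readers and writers for the package's plain-text file formats.

Column dictionaries
-------------------
phenotypes (long CSV): ``line`` (str), ``replicate`` (str), ``trait``
(str; the study vocabulary is DTH, STCH_HD, SUC_HD, SEN, TIL, WT, GLC_HV,
SUC_HV, STCH_HV), ``value`` (float). One row per observation; the key
(line, replicate, trait) must be unique.

genotypes (CSV matrix): first column ``line``, one column per SNP id;
entries 0/1/2 or empty for missing. VCF input is read-only: the dosage is
the count of alternate alleles in a diploid GT; half-calls and non-diploid
genotypes raise.

spectra (wide CSV): first column ``wavenumber`` (cm^-1, increasing), one
column per sample id. Wet chemistry (CSV): ``sample_id`` plus one column
per constituent fraction, optional ``replicate`` for technical replicates.

GRM cache (CSV matrix): first column ``line``, one column per line.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .grm import GRM
from .simulate import DEFAULT_TRAITS
from .spectra import SpectraSet

__all__ = [
    "read_phenotypes", "write_phenotypes",
    "read_genotypes", "write_genotypes",
    "read_spectra", "write_spectra",
    "read_grm", "write_grm",
    "STANDARD_TRAITS",
]

STANDARD_TRAITS = DEFAULT_TRAITS

_PHENO_COLS = ("line", "replicate", "trait", "value")


def read_phenotypes(path) -> pd.DataFrame:
    """Read a long-format replicated phenotype table."""
    df = pd.read_csv(path, dtype={"line": str, "replicate": str, "trait": str})
    for col in _PHENO_COLS:
        if col not in df.columns:
            raise ValueError(f"phenotype file is missing required column {col!r}")
    df = df[list(_PHENO_COLS)]
    df["value"] = df["value"].astype(float)
    dup = df.duplicated(subset=["line", "replicate", "trait"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValueError(
            "duplicate (line, replicate, trait) row: "
            f"({first['line']}, {first['replicate']}, {first['trait']})"
        )
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df[list(_PHENO_COLS)].to_csv(path, index=False)


def read_genotypes(path, format: str = "csv") -> GenotypeMatrix:
    """Read a dosage matrix from CSV (lines x SNPs) or VCF (GT field)."""
    if format == "csv":
        df = pd.read_csv(path, index_col=0)
        return GenotypeMatrix(
            line_ids=[str(i) for i in df.index],
            dosages=df.to_numpy(dtype=float),
            snp_ids=[str(c) for c in df.columns],
        )
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    snp_ids, cols = [], []
    for variant in vcf:
        gts = variant.genotypes  # [[a1, a2, phased], ...]
        col = np.empty(len(samples))
        for i, gt in enumerate(gts):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ValueError(
                    f"non-diploid genotype for sample {samples[i]} at "
                    f"{variant.CHROM}:{variant.POS}"
                )
            if any(a < 0 for a in alleles):
                col[i] = np.nan
            else:
                col[i] = sum(1 for a in alleles if a > 0)
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        cols.append(col)
    vcf.close()
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(line_ids=samples, dosages=dosages, snp_ids=snp_ids)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    df = pd.DataFrame(geno.dosages, index=pd.Index(geno.line_ids, name="line"),
                      columns=geno.snp_ids)
    df.to_csv(path)


def read_spectra(path, wetchem_path=None) -> SpectraSet:
    """Read a wide spectra CSV and, optionally, a paired wet-chemistry CSV."""
    df = pd.read_csv(path)
    if df.columns[0] != "wavenumber":
        raise ValueError("first column of a spectra file must be 'wavenumber'")
    cons = None
    if wetchem_path is not None:
        wc = pd.read_csv(wetchem_path)
        if "sample_id" not in wc.columns:
            raise ValueError("wet-chemistry file needs a 'sample_id' column")
        cons = wc.set_index("sample_id")
    return SpectraSet(
        wavenumbers=df["wavenumber"].to_numpy(float),
        absorbance=df.drop(columns="wavenumber").to_numpy(float).T,
        sample_ids=[str(c) for c in df.columns[1:]],
        constituents=cons,
    )


def write_spectra(spectra: SpectraSet, path, wetchem_path=None) -> None:
    wide = pd.DataFrame(spectra.absorbance.T, columns=spectra.sample_ids)
    wide.insert(0, "wavenumber", spectra.wavenumbers)
    wide.to_csv(path, index=False)
    if wetchem_path is not None and spectra.constituents is not None:
        out = spectra.constituents.copy()
        out.index.name = "sample_id"
        out.to_csv(wetchem_path)


def read_grm(path) -> GRM:
    df = pd.read_csv(path, index_col=0)
    return GRM([str(i) for i in df.index], df.to_numpy(float))


def write_grm(grm: GRM, path) -> None:
    pd.DataFrame(grm.K, index=pd.Index(grm.line_ids, name="line"),
                 columns=grm.line_ids).to_csv(path)
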