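"""Core in-memory containers for mixed-ploidy variant data.

The analysis operates on biallelic SNPs scored in individuals of mixed
ploidy (diploid 2n=2x and tetraploid 2n=4x).  Two containers carry the
data between stages:

``ReadCountTable``
    per-(individual, site) total and alternate-allele read depths plus a
    per-site sequencing-error rate — the input to dosage genotyping.

``DosageMatrix``
    per-(individual, site) alternate-allele dosage in ``0..ploidy`` with a
    missingness mask — the substrate for filtering, relatedness and
    admixture estimation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SiteTable", "ReadCountTable", "DosageMatrix", "make_site_table"]


def make_site_table(
    n_sites: int,
    chrom: str | list[str] = "chr1",
    start: int = 1,
    spacing: int = 1000,
    qual: float | np.ndarray = 1000.0,
) -> pd.DataFrame:
    """Build a site table with 1-based positions (VCF convention)."""
    if isinstance(chrom, str):
        chroms = [chrom] * n_sites
    else:
        chroms = list(chrom)
        if len(chroms) != n_sites:
            raise ValueError("chrom list length must equal n_sites")
    pos = start + spacing * np.arange(n_sites, dtype=np.int64)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "ref": ["A"] * n_sites,
            "alt": ["T"] * n_sites,
            "qual": np.broadcast_to(np.asarray(qual, dtype=float), (n_sites,)).copy(),
        }
    )


# convenience alias used in type hints: a DataFrame with columns
# chrom, pos (1-based), ref, alt, qual
SiteTable = pd.DataFrame


def _check_sites(sites: pd.DataFrame, n: int) -> pd.DataFrame:
    required = {"chrom", "pos", "ref", "alt"}
    missing = required - set(sites.columns)
    if missing:
        raise ValueError(f"site table missing columns: {sorted(missing)}")
    if len(sites) != n:
        raise ValueError(f"site table has {len(sites)} rows, expected {n}")
    return sites.reset_index(drop=True)


@dataclass
class ReadCountTable:
    """Allele read counts per individual and biallelic site.

    Attributes
    ----------
    total : (N, L) int array — total reads per cell.
    alt : (N, L) int array — alternate-allele reads, ``0 <= alt <= total``.
    error : (L,) float array — per-site sequencing-error rate in [0, 0.5).
    ploidy : (N,) int array — 2 or 4 per individual.
    samples : list of sample identifiers.
    sites : site table (chrom, pos, ref, alt, qual).
    """

    total: np.ndarray
    alt: np.ndarray
    error: np.ndarray
    ploidy: np.ndarray
    samples: list[str]
    sites: pd.DataFrame

    def __post_init__(self) -> None:
        self.total = np.asarray(self.total, dtype=np.int64)
        self.alt = np.asarray(self.alt, dtype=np.int64)
        self.error = np.asarray(self.error, dtype=float)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int64)
        n, l = self.total.shape
        if self.alt.shape != (n, l):
            raise ValueError("alt and total shapes differ")
        if np.any(self.alt < 0) or np.any(self.alt > self.total):
            raise ValueError("require 0 <= alt <= total everywhere")
        if self.error.shape != (l,):
            raise ValueError("error must be per-site")
        if not np.all(np.isfinite(self.error)):
            raise ValueError("non-finite error rate")
        if np.any((self.error < 0) | (self.error >= 0.5)):
            raise ValueError("error rates must lie in [0, 0.5)")
        if self.ploidy.shape != (n,):
            raise ValueError("ploidy must be per-individual")
        if not np.all(np.isin(self.ploidy, (2, 4))):
            raise ValueError("only ploidies 2 and 4 are supported")
        if len(self.samples) != n:
            raise ValueError("sample list length mismatch")
        self.sites = _check_sites(self.sites, l)

    @property
    def n_individuals(self) -> int:
        return self.total.shape[0]

    @property
    def n_sites(self) -> int:
        return self.total.shape[1]


@dataclass
class DosageMatrix:
    """Integer alternate-allele dosages for mixed-ploidy individuals.

    ``dosage[i, l]`` counts alternate-allele copies (0..ploidy[i]); cells
    with ``missing[i, l]`` True carry no call and their dosage value is
    undefined (stored as 0).
    """

    dosage: np.ndarray
    missing: np.ndarray
    ploidy: np.ndarray
    samples: list[str]
    sites: pd.DataFrame
    posterior: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int64)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int64)
        n, l = self.dosage.shape
        if self.missing.shape != (n, l):
            raise ValueError("missing mask shape mismatch")
        if self.ploidy.shape != (n,):
            raise ValueError("ploidy must be per-individual")
        if not np.all(np.isin(self.ploidy, (2, 4))):
            raise ValueError("only ploidies 2 and 4 are supported")
        called = ~self.missing
        if np.any(self.dosage[called] < 0) or np.any(
            self.dosage[called] > self.ploidy[:, None].repeat(l, axis=1)[called]
        ):
            raise ValueError("dosage must lie in 0..ploidy for called cells")
        if len(self.samples) != n:
            raise ValueError("sample list length mismatch")
        self.sites = _check_sites(self.sites, l)

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosage.shape[1]

    def alt_allele_freq(self) -> np.ndarray:
        """Ploidy-weighted alternate-allele frequency per site.

        Sums alternate dosages over non-missing calls and divides by the
        total allele copies those calls contribute.  Sites with no calls
        return NaN.
        """
        called = ~self.missing
        alt = np.where(called, self.dosage, 0).sum(axis=0).astype(float)
        copies = (called * self.ploidy[:, None]).sum(axis=0).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(copies > 0, alt / copies, np.nan)

    def missing_fraction(self) -> np.ndarray:
        """Fraction of individuals missing per site."""
        return self.missing.mean(axis=0)

    def take_sites(self, idx: np.ndarray) -> "DosageMatrix":
        idx = np.asarray(idx)
        return DosageMatrix(
            dosage=self.dosage[:, idx],
            missing=self.missing[:, idx],
            ploidy=self.ploidy,
            samples=list(self.samples),
            sites=self.sites.iloc[idx].reset_index(drop=True),
            posterior=None if self.posterior is None else self.posterior[:, idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "DosageMatrix":
        idx = np.asarray(idx)
        return DosageMatrix(
            dosage=self.dosage[idx],
            missing=self.missing[idx],
            ploidy=self.ploidy[idx],
            samples=[self.samples[i] for i in idx],
            sites=self.sites,
            posterior=None if self.posterior is None else self.posterior[idx],
        )
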