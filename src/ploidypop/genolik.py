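"""Ploidy-aware dosage genotyping from allele read counts.

For a biallelic site read in an individual of ploidy ``v``, the alternate
read count ``a`` out of ``n`` total reads is modelled as Binomial with
success probability

    P(alt read | dosage d) = (d/v) * (1 - e) + (1 - d/v) * e,

where ``e`` is the site's sequencing-error rate, folded in symmetrically
(a true alternate read may be miscalled reference and vice versa).  With a
flat prior over the ``v + 1`` dosages the posterior is the normalized
likelihood and the call is the MAP dosage; an optional empirical-Bayes
mode iteratively replaces the flat prior with site-level genotype
frequencies estimated from the data.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats

from .containers import DosageMatrix, ReadCountTable

__all__ = [
    "dosage_likelihoods",
    "posterior_dosage",
    "estimate_site_error",
    "genotype_all",
]

ERROR_FLOOR = 1e-3
ERROR_CAP = 0.49


def dosage_likelihoods(a: int, n: int, v: int, e: float) -> np.ndarray:
    """Unnormalized likelihood of each dosage 0..v for one cell.

    Entry ``d`` is the Binomial pmf of ``a`` successes in ``n`` trials with
    success probability ``(d/v)(1-e) + (1-d/v)e``.
    """
    if not (0 <= a <= n):
        raise ValueError("require 0 <= a <= n")
    if v not in (2, 4):
        raise ValueError("ploidy must be 2 or 4")
    if not (0.0 <= e < 0.5):
        raise ValueError("error rate must lie in [0, 0.5)")
    d = np.arange(v + 1)
    p = (d / v) * (1.0 - e) + (1.0 - d / v) * e
    return stats.binom.pmf(a, n, p)


def posterior_dosage(
    likelihoods: np.ndarray, prior: np.ndarray | None = None
) -> tuple[np.ndarray, int | None]:
    """Normalize likelihoods into a posterior and take the MAP dosage.

    Ties in the posterior break toward the lower dosage.  An all-zero
    likelihood vector yields a missing call (posterior of NaNs, MAP None).
    """
    lik = np.asarray(likelihoods, dtype=float)
    if np.any(lik < 0):
        raise ValueError("likelihoods must be non-negative")
    if prior is not None:
        lik = lik * np.asarray(prior, dtype=float)
    total = lik.sum()
    if total == 0:
        return np.full_like(lik, np.nan), None
    post = lik / total
    return post, int(np.argmax(post))  # argmax takes the first (lowest) maximum


def estimate_site_error(ref: int, alt: int, other: int) -> float:
    """Per-site error rate from pileup base counts.

    ``other`` counts reads matching neither allele; the rate is floored at
    1e-3 (sequencers are never perfect) and capped at 0.49 (the model needs
    e < 0.5).  Zero-coverage sites fall back to the floor.
    """
    total = ref + alt + other
    if min(ref, alt, other) < 0:
        raise ValueError("pileup counts must be non-negative")
    if total == 0:
        return ERROR_FLOOR
    return float(np.clip(other / total, ERROR_FLOOR, ERROR_CAP))


def _cell_posterior_matrix(
    a: np.ndarray, n: np.ndarray, v: int, e: np.ndarray
) -> np.ndarray:
    """Vectorized likelihoods for all cells of one ploidy: (N, L, v+1)."""
    d = np.arange(v + 1)
    p = (d / v) * (1.0 - e[None, :, None]) + (1.0 - d / v) * e[None, :, None]
    return stats.binom.pmf(a[:, :, None], n[:, :, None], p)


def genotype_all(
    reads: ReadCountTable,
    min_depth: int = 5,
    empirical_bayes: bool = False,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> DosageMatrix:
    """Call MAP dosages for every individual x site cell.

    Cells with total depth ``n <= min_depth`` are missing (strict
    inequality: the default keeps only DP > 5).  With
    ``empirical_bayes=True`` the flat prior is replaced per site by
    genotype-class frequencies updated from the posteriors (EM over a
    site-level prior, shared across individuals of the same ploidy) until
    the prior changes by less than ``tol`` or ``max_iter`` iterations.
    """
    if min_depth < 0:
        raise ValueError("min_depth must be non-negative")
    n_ind, n_sites = reads.total.shape
    dosage = np.zeros((n_ind, n_sites), dtype=np.int64)
    missing = reads.total <= min_depth
    posterior_max = np.zeros((n_ind, n_sites))

    for v in (2, 4):
        rows = np.where(reads.ploidy == v)[0]
        if rows.size == 0:
            continue
        lik = _cell_posterior_matrix(
            reads.alt[rows], reads.total[rows], v, reads.error
        )  # (R, L, v+1)
        prior = np.full((n_sites, v + 1), 1.0 / (v + 1))
        if empirical_bayes:
            use = ~missing[rows]  # (R, L)
            for _ in range(max_iter):
                w = lik * prior[None, :, :]
                tot = w.sum(axis=2, keepdims=True)
                post = np.divide(w, tot, out=np.zeros_like(w), where=tot > 0)
                counts = (post * use[:, :, None]).sum(axis=0)  # (L, v+1)
                denom = counts.sum(axis=1, keepdims=True)
                new_prior = np.where(
                    denom > 0, counts / np.maximum(denom, 1e-300), 1.0 / (v + 1)
                )
                delta = np.abs(new_prior - prior).max()
                prior = new_prior
                if delta < tol:
                    break
        w = lik * prior[None, :, :]
        tot = w.sum(axis=2, keepdims=True)
        post = np.divide(w, tot, out=np.zeros_like(w), where=tot > 0)
        # all-zero likelihood cells become missing
        dead = tot[:, :, 0] == 0
        missing[rows] |= dead
        dosage[rows] = np.argmax(post, axis=2)
        posterior_max[rows] = post.max(axis=2)

    dosage[missing] = 0
    logging.getLogger("ploidypop").info(
        "genotyped %d x %d cells, call rate %.3f",
        n_ind, n_sites, 1.0 - missing.mean(),
    )
    return DosageMatrix(
        dosage=dosage,
        missing=missing,
        ploidy=reads.ploidy.copy(),
        samples=list(reads.samples),
        sites=reads.sites.copy(),
        posterior=posterior_max,
    )
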