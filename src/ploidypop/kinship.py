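"""Mixed-ploidy coancestry estimation, PCoA and group comparisons.

The relatedness estimator is a Ritland-type method-of-moments form on
allele-dosage fractions.  For individuals x, y at a biallelic locus with
pooled alternate frequency p (q = 1 - p) and dosage fractions
x_A = dosage/ploidy (x_a = 1 - x_A):

    theta_l = x_A * y_A / p + x_a * y_a / q - 1

averaged over pairwise-complete loci.  The reported coefficient rescales
by ploidy, r = theta * sqrt(v_x * v_y), so that a non-inbred individual
compared with itself expects 1 at any ploidy (the unscaled expectation is
1/2 for diploids and 1/4 for tetraploids), an outbred diploid
parent-offspring pair expects 1/2, and non-relatives from the same gene
pool expect 0.  Values below 0 or above 1 are possible and represent the
estimator's sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import DosageMatrix

__all__ = [
    "CoancestryMatrix",
    "PCoAResult",
    "pairwise_coancestry",
    "pcoa",
    "group_relatedness_test",
    "relatedness_linkage",
]


@dataclass
class CoancestryMatrix:
    """Symmetric N x N relatedness coefficients with per-pair locus counts."""

    values: np.ndarray
    n_loci: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("relatedness matrix must be square")
        finite = np.isfinite(v) & np.isfinite(v.T)
        if not np.allclose(v[finite], v.T[finite], atol=1e-10):
            raise ValueError("relatedness matrix must be symmetric")
        self.values = v

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.samples, columns=self.samples)


@dataclass
class PCoAResult:
    eigenvalues: np.ndarray  # descending
    coordinates: np.ndarray  # N x n_axes
    variance_explained: np.ndarray  # fraction of positive-eigenvalue mass
    samples: list[str]


def pairwise_coancestry(
    dosages: DosageMatrix, freqs: np.ndarray | None = None
) -> CoancestryMatrix:
    """Ritland-type coancestry for every pair of individuals.

    Parameters
    ----------
    dosages : mixed-ploidy dosage matrix.
    freqs : per-site pooled alternate-allele frequencies; defaults to the
        ploidy-weighted frequencies of the matrix itself.  Sites fixed at
        0 or 1 (or unscored) are excluded.

    Pairs sharing zero loci get a NaN entry.
    """
    p = dosages.alt_allele_freq() if freqs is None else np.asarray(freqs, dtype=float)
    if p.shape != (dosages.n_sites,):
        raise ValueError("freqs must be per-site")
    usable = np.isfinite(p) & (p > 0) & (p < 1)
    p = p[usable]
    q = 1.0 - p
    frac = (dosages.dosage / dosages.ploidy[:, None])[:, usable]
    valid = (~dosages.missing)[:, usable]

    # pairwise-complete sums via matrix products: theta_l decomposes into
    # two rank-1 products once masked values are zeroed
    u = np.where(valid, frac / np.sqrt(p)[None, :], 0.0)
    w = np.where(valid, (1.0 - frac) / np.sqrt(q)[None, :], 0.0)
    counts = valid.astype(float) @ valid.astype(float).T
    sums = u @ u.T + w @ w.T
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(counts > 0, sums / counts - 1.0, np.nan)
    scale = np.sqrt(np.outer(dosages.ploidy, dosages.ploidy))
    return CoancestryMatrix(
        values=theta * scale,
        n_loci=counts.astype(np.int64),
        samples=list(dosages.samples),
    )


def pcoa(matrix: CoancestryMatrix, n_axes: int = 3) -> PCoAResult:
    """Principal coordinates of the relatedness matrix.

    The matrix is symmetrized, missing entries are imputed with column
    means, and the eigendecomposition is taken directly (no distance
    conversion).  Coordinates scale eigenvectors by sqrt(max(lambda, 0));
    variance explained is each eigenvalue over the positive-eigenvalue sum.
    """
    m = np.asarray(matrix.values, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be square")
    m = (m + m.T) / 2.0
    if np.any(~np.isfinite(m)):
        col_means = np.nanmean(np.where(np.isfinite(m), m, np.nan), axis=0)
        bad = ~np.isfinite(m)
        m[bad] = np.broadcast_to(col_means, m.shape)[bad]
        m = (m + m.T) / 2.0
    evals, evecs = np.linalg.eigh(m)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos_sum = evals[evals > 0].sum()
    var = evals / pos_sum if pos_sum > 0 else np.zeros_like(evals)
    n_axes = min(n_axes, len(evals))
    coords = evecs[:, :n_axes] * np.sqrt(np.maximum(evals[:n_axes], 0.0))
    return PCoAResult(evals, coords, var, list(matrix.samples))


def group_relatedness_test(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann–Whitney U) on pair-value sets.

    Used to contrast relatedness of a tetraploid lineage with its two
    candidate diploid progenitor pools.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both pair-value sets must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def cross_group_values(
    matrix: CoancestryMatrix, group_a: np.ndarray, group_b: np.ndarray
) -> np.ndarray:
    """All pairwise relatedness values between two disjoint index sets."""
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if np.intersect1d(a, b).size:
        raise ValueError("groups must be disjoint")
    vals = matrix.values[np.ix_(a, b)].ravel()
    return vals[np.isfinite(vals)]


def relatedness_linkage(matrix: CoancestryMatrix) -> np.ndarray:
    """Average-linkage hierarchical clustering on 1 - r distances.

    Utility for ordering heatmap rows; the diagonal is ignored and
    distances are shifted non-negative if estimates exceed 1.
    """
    d = 1.0 - matrix.values
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    d -= min(0.0, d[~np.eye(len(d), dtype=bool)].min())
    np.fill_diagonal(d, 0.0)
    return hierarchy.linkage(squareform(d, checks=False), method="average")
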