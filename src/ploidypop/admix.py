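"""Dosage-aware admixture estimation, best-K selection and introgression calls.

The model is the standard admixture likelihood adapted to mixed-ploidy
dosages: individual i of ploidy v_i carries, at locus l, an alternate
dosage d_il ~ Binomial(v_i, pi_il) with pi_il = sum_k q_ik f_kl, where q_i
is the individual's ancestry vector over K clusters and f_k the cluster
allele frequencies.  Maximum-likelihood estimates of (Q, F) come from an
EM algorithm over the latent cluster of origin of each allele copy; the
log-likelihood is non-decreasing at every iteration.

Best K is chosen by the Evanno-style second-difference statistic on
replicate log-likelihoods, and individuals are classified as introgressed
when a non-home cluster's ancestry fraction exceeds a q threshold
(strictly), reported per (home cluster, donor cluster) as percentages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .containers import DosageMatrix

__all__ = [
    "AdmixtureResult",
    "AdmixtureModel",
    "KSelection",
    "fit_admixture",
    "replicate_likelihoods",
    "select_k",
    "classify_introgression",
    "align_clusters",
]

DEFAULT_THRESHOLDS = (0.05, 0.10, 0.15)


@dataclass
class AdmixtureResult:
    """Fitted ancestry proportions and cluster allele frequencies."""

    q: np.ndarray  # (N, K), rows sum to 1
    freqs: np.ndarray  # (K, L)
    log_likelihood: float
    n_iter: int
    converged: bool
    seed: int | None
    samples: list[str] = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.q.shape[1]

    def q_frame(self) -> pd.DataFrame:
        cols = [f"q{k + 1}" for k in range(self.k)]
        return pd.DataFrame(self.q, index=self.samples, columns=cols)


@dataclass
class KSelection:
    """Replicate likelihoods per K and the Evanno second-difference profile."""

    k_values: np.ndarray
    mean_ll: np.ndarray
    sd_ll: np.ndarray
    delta_k: np.ndarray  # NaN at the boundary K values and where SD = 0
    best_k: int | None  # None when no interior K has a defined delta


def _binom_const(d, v, valid):
    const = gammaln(v + 1) - gammaln(d + 1) - gammaln(v - d + 1)
    return float(const[valid].sum())


def _loglik(d, v, valid, pi, const=None):
    pi = np.clip(pi, 1e-12, 1.0 - 1e-12)
    if const is None:
        const = _binom_const(d, v, valid)
    ll = d * np.log(pi) + (v - d) * np.log1p(-pi)
    return const + float(ll[valid].sum())


def fit_admixture(
    dosages: DosageMatrix,
    k: int,
    seed: int | None = 0,
    max_iter: int = 2000,
    tol: float = 1e-8,
    restarts: int = 1,
) -> AdmixtureResult:
    """Maximum-likelihood (Q, F) for K clusters via EM.

    ``K=1`` is closed-form (q = 1, f = pooled frequencies).  With
    ``restarts > 1`` the EM runs from that many random initializations
    (seeds derived from ``seed``) and the best likelihood is kept.
    Initialization draws q rows from Dirichlet(1) and f from pooled
    frequencies plus noise.
    """
    n, l = dosages.dosage.shape
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > n:
        raise ValueError("K cannot exceed the number of individuals")
    d = dosages.dosage.astype(float)
    v = dosages.ploidy.astype(float)[:, None]
    valid = ~dosages.missing
    d = np.where(valid, d, 0.0)

    pooled = dosages.alt_allele_freq()
    pooled = np.clip(np.nan_to_num(pooled, nan=0.5), 1e-6, 1 - 1e-6)

    if k == 1:
        q = np.ones((n, 1))
        f = pooled[None, :]
        ll = _loglik(d, v, valid, q @ f)
        return AdmixtureResult(q, f, ll, 0, True, seed, list(dosages.samples))

    best: AdmixtureResult | None = None
    const = _binom_const(d, v, valid)
    seed_seq = np.random.SeedSequence(seed if seed is not None else None)
    for child in seed_seq.spawn(restarts):
        rng = np.random.default_rng(child)
        q = rng.dirichlet(np.ones(k), size=n)
        f = np.clip(
            pooled[None, :] + rng.normal(0.0, 0.1, size=(k, l)), 1e-4, 1 - 1e-4
        )
        ll_prev = -np.inf
        converged = False
        it = 0
        for it in range(1, max_iter + 1):
            pi = np.clip(q @ f, 1e-12, 1.0 - 1e-12)  # (N, L)
            # E-step responsibilities per allele copy:
            # a_ilk = q_ik f_kl / pi_il (alt), b_ilk = q_ik (1-f_kl)/(1-pi_il)
            # (ref); the M-step sums reduce to matrix products.
            alt_w = np.where(valid, d / pi, 0.0)  # (N, L)
            ref_w = np.where(valid, (v - d) / (1.0 - pi), 0.0)
            ea = f * (q.T @ alt_w)  # (K, L): expected alt copies per cluster
            er = (1.0 - f) * (q.T @ ref_w)  # expected ref copies per cluster
            copies = q * (alt_w @ f.T + ref_w @ (1.0 - f).T)  # (N, K)
            # M-step
            f = ea / np.maximum(ea + er, 1e-300)
            f = np.clip(f, 1e-6, 1.0 - 1e-6)
            q = copies / np.maximum(copies.sum(axis=1, keepdims=True), 1e-300)
            ll = _loglik(d, v, valid, q @ f, const)
            if abs(ll - ll_prev) <= tol * max(1.0, abs(ll)):
                ll_prev = ll
                converged = True
                break
            ll_prev = ll
        res = AdmixtureResult(
            q, f, ll_prev, it, converged, seed, list(dosages.samples)
        )
        if best is None or res.log_likelihood > best.log_likelihood:
            best = res
    assert best is not None
    return best


class AdmixtureModel:
    """statsmodels-flavoured front end: construct from data, then fit."""

    def __init__(self, dosages: DosageMatrix, k: int):
        self.dosages = dosages
        self.k = k

    def fit(self, seed: int | None = 0, restarts: int = 10, **kw) -> AdmixtureResult:
        return fit_admixture(self.dosages, self.k, seed=seed, restarts=restarts, **kw)


def align_clusters(
    freqs_ref: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Permutation mapping ``freqs`` clusters onto ``freqs_ref`` clusters.

    Greedy matching on the correlation of cluster allele-frequency vectors;
    resolves label switching before any cross-run comparison.  Returns
    ``perm`` such that ``freqs[perm]`` aligns with ``freqs_ref``.
    """
    k = freqs_ref.shape[0]
    if freqs.shape[0] != k:
        raise ValueError("cluster counts differ")
    if freqs.shape[1] != freqs_ref.shape[1]:
        raise ValueError(
            "frequency tables cover different loci; subset the reference "
            "to the fitted panel's sites before aligning"
        )
    corr = np.corrcoef(freqs_ref, freqs)[:k, k:]
    corr = np.nan_to_num(corr, nan=-np.inf)
    perm = np.full(k, -1)
    used_r, used_c = set(), set()
    for _ in range(k):
        best = None
        for r in range(k):
            if r in used_r:
                continue
            for c in range(k):
                if c in used_c:
                    continue
                if best is None or corr[r, c] > corr[best]:
                    best = (r, c)
        r, c = best
        perm[r] = c
        used_r.add(r)
        used_c.add(c)
    return perm


def replicate_likelihoods(
    dosages: DosageMatrix,
    k_values: range | list[int],
    n_replicates: int = 10,
    seed: int | None = 0,
    max_iter: int = 1000,
    tol: float = 1e-7,
) -> dict[int, list[float]]:
    """Replicate log-likelihoods per K for Evanno-style selection.

    A deterministic ML fit converges to (nearly) the same optimum from any
    seed whenever K under-fits the data, so raw re-runs carry no
    information in their spread — the SD in the delta-K denominator would
    measure convergence jitter.  Each replicate therefore refits on a
    bootstrap resample of loci (shared across K values, so second
    differences are paired), making the replicate SD an estimate of the
    sampling variance of L(K) — the role run-to-run MCMC noise plays for a
    Bayesian sampler.  The default convergence settings are looser than
    ``fit_admixture``'s because the bootstrap SD dominates residual
    convergence error by orders of magnitude.
    """
    l = dosages.n_sites
    rng = np.random.default_rng(seed)
    runs: dict[int, list[float]] = {int(k): [] for k in k_values}
    for r in range(n_replicates):
        idx = rng.integers(0, l, size=l)
        sub = dosages.take_sites(idx)
        for k in k_values:
            res = fit_admixture(
                sub, int(k), seed=int(rng.integers(2**31)),
                max_iter=max_iter, tol=tol,
            )
            runs[int(k)].append(res.log_likelihood)
    return runs


def select_k(runs: dict[int, list[float]]) -> KSelection:
    """Evanno-style best-K from replicate log-likelihoods per K.

    delta(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD of L(K)
    over at least 3 consecutive K values with >= 2 replicates each.  A K
    whose replicate SD is zero has no defined delta and is excluded from
    the argmax; if no interior K has one, ``best_k`` is None.
    """
    ks = np.array(sorted(runs))
    if len(ks) < 3:
        raise ValueError("need at least 3 consecutive K values")
    if np.any(np.diff(ks) != 1):
        raise ValueError("K values must be consecutive")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError("need at least 2 replicates per K")
    mean = np.array([np.mean(runs[k]) for k in ks])
    sd = np.array([np.std(runs[k], ddof=1) for k in ks])
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        if sd[i] > 0:
            delta[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1]) / sd[i]
    best = None
    if np.any(np.isfinite(delta)):
        best = int(ks[np.nanargmax(delta)])
    return KSelection(ks, mean, sd, delta, best)


def classify_introgression(
    q: np.ndarray,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    samples: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Threshold-based introgression labels and per-group percentage table.

    Each individual's home cluster is its largest ancestry fraction; for
    every other (donor) cluster j it counts as introgressed by j at
    threshold t iff q_ij > t (strict).  The percentage table has one row
    per ordered (home, donor) pair among occupied home clusters and one
    column per threshold, as percentages of the home cluster's size —
    non-increasing along each row as the threshold rises.

    Returns (per-individual label frame, percentage table).
    """
    q = np.asarray(q, dtype=float)
    if q.ndim != 2 or q.shape[0] == 0:
        raise ValueError("q matrix must be non-empty and 2-D")
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("q rows must sum to 1")
    n, k = q.shape
    ids = samples or [f"ind{i:04d}" for i in range(n)]
    home = np.argmax(q, axis=1)

    label_rows = []
    for i in range(n):
        for j in range(k):
            if j == home[i]:
                continue
            for t in thresholds:
                if q[i, j] > t:
                    label_rows.append((ids[i], home[i] + 1, j + 1, t))
    labels = pd.DataFrame(
        label_rows, columns=["sample_id", "home_cluster", "donor_cluster", "threshold"]
    )

    table_rows = []
    for h in sorted(set(home)):
        members = np.where(home == h)[0]
        for j in range(k):
            if j == h:
                continue
            row = {"home_cluster": h + 1, "donor_cluster": j + 1}
            for t in thresholds:
                count = int((q[members, j] > t).sum())
                row[f"q>{t:g} (%)"] = 100.0 * count / len(members)
            table_rows.append(row)
    return labels, pd.DataFrame(table_rows)
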