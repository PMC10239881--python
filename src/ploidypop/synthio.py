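"""Synthetic mixed-ploidy populations, read counts, fluorescence and rasters.

Generates data with the statistical structure the downstream analyses
assume: divergent gene pools under a Balding–Nichols drift model, diploid
and tetraploid individuals with tetrasomic or disomic segregation, admixed
individuals with stated ancestry fractions q, ddRAD-like read counts with
per-site sequencing error, bimodal flow-cytometry fluorescence ratios, and
presence/vote rasters with controllable overlap.

Every generator is deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import DosageMatrix, ReadCountTable, make_site_table

__all__ = [
    "SimConfig",
    "TruthSet",
    "simulate_cluster_freqs",
    "simulate_dosages",
    "simulate_reads",
    "simulate_fluorescence",
    "simulate_vote_grids",
    "simulate_truth",
    "simulate_dataset",
    "disomic_subgenome_freqs",
]

# Flow-cytometry relative-fluorescence bands (mean, SD) by ploidy.  The
# tetraploid genome is twice the diploid one, so the tetraploid band sits
# at roughly twice the diploid ratio.
DEFAULT_RF_BANDS: dict[int, tuple[float, float]] = {2: (6.73, 0.15), 4: (12.2, 0.49)}


@dataclass
class SimConfig:
    """Parameters of a synthetic mixed-ploidy study.

    Defaults emulate the sampled study system: two divergent diploid gene
    pools plus two tetraploid gene pools (tetrasomic by default), ddRAD-like
    sequencing depth, and fluorescence bands at a 2:1 tetraploid:diploid
    ratio.
    """

    n_clusters: int = 4
    cluster_ploidy: tuple[int, ...] = (2, 2, 4, 4)
    n_per_cluster: tuple[int, ...] = (50, 50, 50, 50)
    n_loci: int = 1000
    divergence_F: tuple[float, ...] | float = 0.2
    # list of (count, q-vector) specs for admixed individuals
    admixture_spec: tuple[tuple[int, tuple[float, ...]], ...] = ()
    # per-cluster inheritance mode; diploid clusters must be None
    inheritance_mode: tuple[str | None, ...] = (None, None, "tetrasomic", "tetrasomic")
    subgenome_divergence: float = 1.0
    mean_depth: float = 50.0
    error_rate: float = 0.01
    rf_bands: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_RF_BANDS)
    )
    base_freq_range: tuple[float, float] = (0.05, 0.95)
    seed: int = 0

    def __post_init__(self) -> None:
        k = self.n_clusters
        if len(self.cluster_ploidy) != k or len(self.n_per_cluster) != k:
            raise ValueError("per-cluster fields must have length n_clusters")
        if not all(p in (2, 4) for p in self.cluster_ploidy):
            raise ValueError("cluster ploidies must be 2 or 4")
        F = self.divergence_F
        self.divergence_F = tuple([float(F)] * k) if np.isscalar(F) else tuple(F)
        if len(self.divergence_F) != k:
            raise ValueError("divergence_F must be scalar or length n_clusters")
        if not all(0.0 < f < 1.0 for f in self.divergence_F):
            raise ValueError("divergence_F must lie in (0, 1)")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must lie in [0, 0.5)")
        if len(self.inheritance_mode) != k:
            raise ValueError("inheritance_mode must have length n_clusters")
        for p, m in zip(self.cluster_ploidy, self.inheritance_mode):
            if p == 2 and m is not None:
                raise ValueError("inheritance mode is only meaningful for tetraploids")
            if p == 4 and m not in ("tetrasomic", "disomic"):
                raise ValueError("tetraploid clusters need mode tetrasomic or disomic")
        for count, q in self.admixture_spec:
            q = np.asarray(q, dtype=float)
            if count < 1 or q.shape != (k,):
                raise ValueError("admixture spec entries are (count, q-vector of len K)")
            if abs(q.sum() - 1.0) > 1e-9 or np.any(q < 0):
                raise ValueError("each q-vector must be non-negative and sum to 1")


@dataclass
class TruthSet:
    """Ground truth behind a simulated dataset, for parameter-recovery tests."""

    true_q: np.ndarray  # (N, K), rows sum to 1
    true_cluster_freqs: np.ndarray  # (K, L)
    true_ploidy: np.ndarray  # (N,)
    true_mode: tuple[str | None, ...]  # per cluster
    cluster_of: np.ndarray  # (N,) home cluster index; -1 for admixed extras
    pedigree_links: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(self.true_cluster_freqs < 0) or np.any(self.true_cluster_freqs > 1):
            raise ValueError("cluster frequencies must lie in [0, 1]")
        if not np.allclose(self.true_q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("q rows must sum to 1")


def simulate_cluster_freqs(
    base_freqs: np.ndarray,
    divergence_F: float | np.ndarray,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw per-cluster allele frequencies under Balding–Nichols drift.

    Each cluster's frequency at a locus with ancestral frequency ``p`` is
    Beta-distributed with mean ``p`` and variance ``F * p * (1 - p)``, i.e.
    Beta(p(1-F)/F, (1-p)(1-F)/F).  ``F -> 0`` recovers the ancestral
    frequencies exactly.

    Parameters
    ----------
    base_freqs : (L,) ancestral frequencies in (0, 1).
    divergence_F : scalar or (K,) drift parameter per cluster in (0, 1);
        a scalar with no cluster axis yields a single cluster row.
    seed : integer seed or an existing Generator.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.asarray(base_freqs, dtype=float)
    if not np.all(np.isfinite(p)) or np.any(p <= 0) or np.any(p >= 1):
        raise ValueError("base_freqs must be finite and inside (0, 1)")
    F = np.atleast_1d(np.asarray(divergence_F, dtype=float))
    if not np.all(np.isfinite(F)) or np.any(F <= 0) or np.any(F >= 1):
        raise ValueError("divergence_F must be finite and inside (0, 1)")
    scale = (1.0 - F) / F  # a + b of the Beta
    a = p[None, :] * scale[:, None]
    b = (1.0 - p[None, :]) * scale[:, None]
    freqs = rng.beta(a, b)
    # guard against numerically degenerate draws at the open-interval edges
    return np.clip(freqs, 1e-9, 1.0 - 1e-9)


def disomic_subgenome_freqs(p: np.ndarray, divergence: float) -> tuple[np.ndarray, np.ndarray]:
    """Split mean frequency ``p`` into two subgenome frequencies.

    At ``divergence=1`` the pair is maximally divergent while preserving the
    mean: (2p, 0) for p <= 0.5 and (1, 2p-1) above; at 0 both subgenomes
    share ``p``.  With maximal divergence and p = 0.5 the pair is (1, 0),
    fixing every individual at the duplex heterozygote.
    """
    if not (0.0 <= divergence <= 1.0):
        raise ValueError("subgenome divergence must lie in [0, 1]")
    p = np.asarray(p, dtype=float)
    hi = np.where(p <= 0.5, 2.0 * p, 1.0)
    lo = np.where(p <= 0.5, 0.0, 2.0 * p - 1.0)
    f1 = (1.0 - divergence) * p + divergence * hi
    f2 = (1.0 - divergence) * p + divergence * lo
    return f1, f2


def simulate_truth(config: SimConfig, rng: np.random.Generator | None = None) -> TruthSet:
    """Draw the latent parameters (cluster frequencies, q-matrix, ploidies)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.base_freq_range
    base = rng.uniform(lo, hi, size=config.n_loci)
    freqs = simulate_cluster_freqs(base, np.asarray(config.divergence_F), rng)

    q_rows: list[np.ndarray] = []
    ploidy: list[int] = []
    cluster_of: list[int] = []
    k = config.n_clusters
    for j, (n_j, v_j) in enumerate(zip(config.n_per_cluster, config.cluster_ploidy)):
        for _ in range(n_j):
            row = np.zeros(k)
            row[j] = 1.0
            q_rows.append(row)
            ploidy.append(v_j)
            cluster_of.append(j)
    for count, q in config.admixture_spec:
        q = np.asarray(q, dtype=float)
        # admixed individuals inherit the ploidy of their largest ancestry
        v = config.cluster_ploidy[int(np.argmax(q))]
        for _ in range(count):
            q_rows.append(q.copy())
            ploidy.append(v)
            cluster_of.append(-1)
    return TruthSet(
        true_q=np.array(q_rows),
        true_cluster_freqs=freqs,
        true_ploidy=np.array(ploidy),
        true_mode=tuple(config.inheritance_mode),
        cluster_of=np.array(cluster_of),
    )


def simulate_dosages(
    config: SimConfig,
    truth: TruthSet,
    rng: np.random.Generator | None = None,
) -> DosageMatrix:
    """Draw alternate-allele dosages for every individual.

    Pure tetrasomic tetraploids and diploids draw dosage ~ Binomial(v, f_jl)
    from their cluster frequency; disomic tetraploids draw the sum of two
    Binomial(2, .) subgenome draws with divergent subgenome frequencies and
    no inter-subgenome exchange.  Admixed individuals draw each of their v
    allele copies' cluster of origin i.i.d. from q and then the allele from
    that cluster's frequency — so dosage ~ Binomial(v, sum_k q_k f_kl).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = truth.true_q.shape[0]
    l = truth.true_cluster_freqs.shape[1]
    if truth.true_q.shape[1] != config.n_clusters or truth.true_ploidy.shape != (n,):
        raise ValueError("truth inconsistent with config")
    dosage = np.zeros((n, l), dtype=np.int64)
    for i in range(n):
        v = int(truth.true_ploidy[i])
        j = int(truth.cluster_of[i])
        if j >= 0 and v == 4 and truth.true_mode[j] == "disomic":
            f1, f2 = disomic_subgenome_freqs(
                truth.true_cluster_freqs[j], config.subgenome_divergence
            )
            dosage[i] = rng.binomial(2, f1) + rng.binomial(2, f2)
        else:
            pi = truth.true_q[i] @ truth.true_cluster_freqs
            dosage[i] = rng.binomial(v, pi)
    samples = [f"ind{i:04d}" for i in range(n)]
    return DosageMatrix(
        dosage=dosage,
        missing=np.zeros((n, l), dtype=bool),
        ploidy=truth.true_ploidy.copy(),
        samples=samples,
        sites=make_site_table(l),
    )


def simulate_reads(
    dosages: DosageMatrix,
    mean_depth: float,
    error_rate: float,
    seed: int | np.random.Generator,
    error_jitter_shape: float = 4.0,
    ploidy_depth_scaling: bool = True,
) -> ReadCountTable:
    """Simulate allele read counts from true dosages.

    Per cell, total reads ~ Poisson(individual mean depth) and alternate
    reads ~ Binomial(n, (d/v)(1-e) + (1-d/v)e) with the per-site error
    rate ``e`` drawn from a Gamma with mean ``error_rate`` (clipped to
    [1e-4, 0.49]) so that error varies across loci as it does across
    sequencing positions.  ``error_rate=0`` disables error entirely.

    ``mean_depth`` is the diploid mean; with ``ploidy_depth_scaling``
    (default) tetraploids receive twice that, emulating libraries pooled
    with twice the PCR product for tetraploids so that per-allele-copy
    coverage is comparable across ploidies.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    if not (0.0 <= error_rate < 0.5):
        raise ValueError("error_rate must lie in [0, 0.5)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n, l = dosages.dosage.shape
    if error_rate == 0.0:
        err = np.zeros(l)
    else:
        err = rng.gamma(error_jitter_shape, error_rate / error_jitter_shape, size=l)
        err = np.clip(err, 1e-4, 0.49)
    depth_i = mean_depth * (
        dosages.ploidy / 2.0 if ploidy_depth_scaling else np.ones(n)
    )
    total = rng.poisson(depth_i[:, None], size=(n, l))
    frac = dosages.dosage / dosages.ploidy[:, None]
    p_alt = frac * (1.0 - err[None, :]) + (1.0 - frac) * err[None, :]
    alt = rng.binomial(total, p_alt)
    return ReadCountTable(
        total=total,
        alt=alt,
        error=err,
        ploidy=dosages.ploidy.copy(),
        samples=list(dosages.samples),
        sites=dosages.sites.copy(),
    )


def simulate_fluorescence(
    ploidy_vector: np.ndarray,
    rf_bands: dict[int, tuple[float, float]] | None = None,
    replicates: int = 2,
    seed: int | np.random.Generator = 0,
    sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Simulate replicated relative-fluorescence (RF) measurements.

    Each individual yields ``replicates`` RF values ~ Normal(band mean,
    band SD) truncated positive, with the band keyed by true ploidy.
    Instruments measure each sample at least twice, hence replicates >= 2.

    Returns a long-format frame with columns sample_id, replicate, rf.
    """
    if replicates < 2:
        raise ValueError("at least two replicate measurements are required")
    bands = dict(DEFAULT_RF_BANDS) if rf_bands is None else rf_bands
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ploidy_vector = np.asarray(ploidy_vector, dtype=int)
    for v in np.unique(ploidy_vector):
        if int(v) not in bands:
            raise KeyError(f"no fluorescence band for ploidy {v}")
    ids = sample_ids or [f"ind{i:04d}" for i in range(len(ploidy_vector))]
    rows = []
    for sid, v in zip(ids, ploidy_vector):
        mu, sd = bands[int(v)]
        vals = rng.normal(mu, sd, size=replicates)
        while np.any(vals <= 0):  # truncate positive by redraw
            bad = vals <= 0
            vals[bad] = rng.normal(mu, sd, size=bad.sum())
        for r, x in enumerate(vals):
            rows.append((sid, r, float(x)))
    return pd.DataFrame(rows, columns=["sample_id", "replicate", "rf"])


def simulate_vote_grids(
    shape: tuple[int, int],
    cell_area: float,
    pattern: str = "overlap",
    overlap_fraction: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> tuple["np.ndarray", "np.ndarray", float]:
    """Build a pair of vote rasters with a designed presence overlap.

    Patterns
    --------
    ``disjoint``   : two non-overlapping presence blocks.
    ``identical``  : both models vote on the same block.
    ``overlap``    : blocks arranged so the co-occurring area is
                     ``overlap_fraction`` of the union, exactly, on the
                     boolean grid thresholded at 0.6.

    Returns (votes_a, votes_b, cell_area).  Presence cells carry votes in
    (0.6, 1], absence cells in [0, 0.6].
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive")
    if cell_area <= 0:
        raise ValueError("cell_area must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows, cols = shape
    a = np.zeros(shape, dtype=bool)
    b = np.zeros(shape, dtype=bool)
    half = cols // 2
    if pattern == "disjoint":
        a[:, :half] = True
        b[:, half:] = True
    elif pattern == "identical":
        a[:, :half] = True
        b[:, :half] = True
    elif pattern == "overlap":
        if not (0.0 < overlap_fraction < 1.0):
            raise ValueError("overlap_fraction must lie in (0, 1)")
        # union of u cells with o shared: pick o = round(f * u) on a row
        u = cols
        o = int(round(overlap_fraction * u))
        if o < 1:
            raise ValueError("grid too small for requested overlap")
        # a covers [0, s), b covers [s - o, u) with s chosen so both blocks fit
        s = (u + o) // 2
        a[:, :s] = True
        b[:, s - o : u] = True
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    # presence votes strictly above the 0.6 cutoff; absence at or below
    votes_a = np.where(a, rng.uniform(0.61, 1.0, size=shape), rng.uniform(0.0, 0.6, size=shape))
    votes_b = np.where(b, rng.uniform(0.61, 1.0, size=shape), rng.uniform(0.0, 0.6, size=shape))
    return votes_a, votes_b, float(cell_area)


def simulate_dataset(config: SimConfig) -> tuple[TruthSet, DosageMatrix, ReadCountTable]:
    """Full generative chain: truth -> dosages -> read counts."""
    rng = np.random.default_rng(config.seed)
    truth = simulate_truth(config, rng)
    dosages = simulate_dosages(config, truth, rng)
    reads = simulate_reads(dosages, config.mean_depth, config.error_rate, rng)
    return truth, dosages, reads
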