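"""Inheritance-mode inference for tetraploid gene pools.

Auto- and allopolyploids differ in how chromosomes pair at meiosis, which
leaves a signature in genotype-frequency versus allele-frequency spectra.
Under tetrasomic (autopolyploid) segregation all five dosage classes
(AAAA..TTTT) appear at allele frequency 0.5 with Binomial(4, 0.5)
proportions (1,4,6,4,1)/16; under strictly disomic (allopolyploid)
segregation with maximally divergent subgenomes every individual is the
duplex heterozygote AATT at frequency 0.5.  The classifier sums a per-locus
log-likelihood ratio between those two reference models over loci near
allele frequency 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import DosageMatrix
from .synthio import disomic_subgenome_freqs

__all__ = [
    "GenotypeSpectrum",
    "ModeCall",
    "build_spectrum",
    "expected_spectrum",
    "classify_mode",
]

BIN_WIDTH = 0.05
CENTRAL_RANGE = (0.4, 0.6)
DEFAULT_LLR_THRESHOLD = 10.0  # nats
#: floor for zero-probability classes of the disomic-extreme model;
#: keeps the LLR finite when a stray non-duplex genotype appears
PROB_FLOOR = 1e-6


def bin_centers() -> np.ndarray:
    """Allele-frequency bin centers at multiples of 0.05 over [0, 1]."""
    return np.round(np.arange(0.0, 1.0 + BIN_WIDTH / 2, BIN_WIDTH), 10)


def assign_bin(af: np.ndarray) -> np.ndarray:
    """Index of the half-open bin [c - 0.025, c + 0.025) holding each AF."""
    centers = bin_centers()
    idx = np.floor((np.asarray(af, dtype=float) + BIN_WIDTH / 2) / BIN_WIDTH)
    return np.clip(idx.astype(int), 0, len(centers) - 1)


@dataclass
class GenotypeSpectrum:
    """Dosage-class proportions per allele-frequency bin (tetraploids).

    ``class_counts[b, d]`` counts genotype calls of dosage d among loci in
    bin b; ``locus_af`` and ``locus_counts`` keep the per-locus detail the
    classifier consumes.
    """

    centers: np.ndarray  # (B,)
    class_counts: np.ndarray  # (B, 5)
    n_loci: np.ndarray  # (B,)
    locus_af: np.ndarray  # (L,)
    locus_counts: np.ndarray  # (L, 5) per-locus dosage-class counts
    n_individuals: int

    def proportions(self) -> np.ndarray:
        tot = self.class_counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(tot > 0, self.class_counts / tot, np.nan)

    def as_frame(self) -> pd.DataFrame:
        props = self.proportions()
        df = pd.DataFrame(props, columns=[f"class_{d}" for d in range(5)])
        df.insert(0, "bin_center", self.centers)
        df["n_loci"] = self.n_loci
        return df


@dataclass
class ModeCall:
    mode: str  # tetrasomic | disomic | indeterminate
    llr: float  # sum over central-bin loci, tetrasomic minus disomic
    n_loci: int  # central-bin loci used
    n_classes_at_half: int  # distinct dosage classes observed near AF 0.5
    threshold: float


def build_spectrum(
    dosages: DosageMatrix,
    q: np.ndarray | None = None,
    purity: float = 0.9,
) -> GenotypeSpectrum:
    """Genotype-frequency spectrum of non-introgressed tetraploids.

    Keeps tetraploid individuals whose largest ancestry fraction is at
    least ``purity`` (all tetraploids when ``q`` is None), computes each
    site's allele frequency from the retained individuals, and accumulates
    dosage-class counts into allele-frequency bins.
    """
    tet = dosages.ploidy == 4
    if q is not None:
        q = np.asarray(q, dtype=float)
        if q.shape[0] != dosages.n_individuals:
            raise ValueError("q rows must match individuals")
        tet &= q.max(axis=1) >= purity
    if not np.any(tet):
        raise ValueError("no tetraploid individual passes the purity filter")
    sub = dosages.take_individuals(np.where(tet)[0])

    valid = ~sub.missing
    called = valid.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.where(
            called > 0,
            np.where(valid, sub.dosage, 0).sum(axis=0) / (4.0 * called),
            np.nan,
        )
    scored = called > 0
    counts = np.zeros((sub.n_sites, 5), dtype=np.int64)
    for d in range(5):
        counts[:, d] = ((sub.dosage == d) & valid).sum(axis=0)

    centers = bin_centers()
    class_counts = np.zeros((len(centers), 5), dtype=np.int64)
    n_loci = np.zeros(len(centers), dtype=np.int64)
    bins = assign_bin(af[scored])
    np.add.at(class_counts, bins, counts[scored])
    np.add.at(n_loci, bins, 1)
    return GenotypeSpectrum(
        centers=centers,
        class_counts=class_counts,
        n_loci=n_loci,
        locus_af=af[scored],
        locus_counts=counts[scored],
        n_individuals=sub.n_individuals,
    )


def expected_spectrum(mode: str, p: float) -> np.ndarray:
    """Expected dosage-class probabilities at allele frequency ``p``.

    ``tetrasomic``: Binomial(4, p).  ``disomic``: the maximal-divergence
    extreme — the convolution of Binomial(2, p1) and Binomial(2, p2) with
    (p1, p2) the most divergent subgenome pair whose mean is p; at p = 0.5
    that is (1, 0), i.e. every individual duplex heterozygous,
    (0, 0, 1, 0, 0).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie inside (0, 1)")
    if mode == "tetrasomic":
        return stats.binom.pmf(np.arange(5), 4, p)
    if mode == "disomic":
        p1, p2 = disomic_subgenome_freqs(np.array([p]), 1.0)
        a = stats.binom.pmf(np.arange(3), 2, float(p1[0]))
        b = stats.binom.pmf(np.arange(3), 2, float(p2[0]))
        return np.convolve(a, b)
    raise ValueError(f"unknown mode {mode!r}")


def classify_mode(
    spectrum: GenotypeSpectrum,
    llr_threshold: float = DEFAULT_LLR_THRESHOLD,
    central_range: tuple[float, float] = CENTRAL_RANGE,
) -> ModeCall:
    """Call tetrasomic vs disomic inheritance from central-bin loci.

    For every locus whose allele frequency falls in a bin intersecting
    ``central_range``, the observed dosage-class counts are scored under
    the tetrasomic and disomic-extreme expected spectra at the locus's own
    allele frequency (probabilities floored at 1e-6 so structurally-zero
    classes stay finite).  The summed log-likelihood ratio calls
    tetrasomic above +threshold, disomic below -threshold, else
    indeterminate.  Also reports how many distinct genotype classes were
    observed in the central bins — five is the autopolyploid hallmark.
    """
    lo, hi = central_range
    centers = bin_centers()
    central_bins = np.where(
        (centers + BIN_WIDTH / 2 > lo) & (centers - BIN_WIDTH / 2 < hi)
    )[0]
    locus_bins = assign_bin(spectrum.locus_af)
    central = np.isin(locus_bins, central_bins)
    n_central = int(central.sum())
    observed = spectrum.locus_counts[central]
    n_classes = int((observed.sum(axis=0) > 0).sum())
    if n_central == 0:
        return ModeCall("indeterminate", 0.0, 0, 0, llr_threshold)

    llr = 0.0
    for af, counts in zip(spectrum.locus_af[central], observed):
        af = float(np.clip(af, 1e-6, 1 - 1e-6))
        pt = np.maximum(expected_spectrum("tetrasomic", af), PROB_FLOOR)
        pd_ = np.maximum(expected_spectrum("disomic", af), PROB_FLOOR)
        llr += float(counts @ (np.log(pt) - np.log(pd_)))

    if llr > llr_threshold:
        mode = "tetrasomic"
    elif llr < -llr_threshold:
        mode = "disomic"
    else:
        mode = "indeterminate"
    return ModeCall(mode, llr, n_central, n_classes, llr_threshold)


def plot_spectrum(spectrum: GenotypeSpectrum, path: str) -> None:
    """Genotype-frequency vs allele-frequency scatter, one series per class."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    props = spectrum.proportions()
    fig, ax = plt.subplots(figsize=(6, 4))
    for d in range(5):
        ax.plot(spectrum.centers, props[:, d], "o-", label=f"dosage {d}", ms=4)
    ax.set_xlabel("alternate-allele frequency")
    ax.set_ylabel("genotype-class proportion")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
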