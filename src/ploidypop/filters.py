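"""Variant-filter cascade and linkage thinning for ddRAD dosage data.

The cascade keeps biallelic sites with quality above 100, at most 10%
missing individuals, and alternate-allele frequency above 0.04 (computed
on ploidy-weighted allele copies among non-missing calls); depth filtering
(DP > 5 per cell) happens upstream at genotyping.  Thinning keeps a single
SNP per 139-bp window — the ddRAD read length — to reduce linkage between
markers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd

from .containers import DosageMatrix

__all__ = ["FilterConfig", "FilterLog", "filter_sites", "intersect_ploidy_sets", "thin_one_per_window"]


@dataclass
class FilterConfig:
    max_missing_frac: float = 0.10
    min_qual: float = 100.0  # strict >
    min_depth: int = 5  # strict >, applied at genotyping
    min_alt_freq: float = 0.04  # strict >
    window_bp: int = 139
    biallelic_only: bool = True

    def __post_init__(self) -> None:
        if min(self.max_missing_frac, self.min_qual, self.min_depth, self.min_alt_freq) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")


@dataclass
class FilterLog:
    """Sites dropped per rule, in cascade order."""

    n_input: int = 0
    dropped: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0

    def as_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input)]
        rows += [(f"dropped_{k}", v) for k, v in self.dropped.items()]
        rows.append(("retained", self.n_retained))
        return pd.DataFrame(rows, columns=["rule", "sites"])


def _is_biallelic(sites: pd.DataFrame) -> np.ndarray:
    ref = sites["ref"].astype(str)
    alt = sites["alt"].astype(str)
    single = (ref.str.len() == 1) & (alt.str.len() == 1)
    return (single & ~alt.str.contains(",")).to_numpy()


def filter_sites(
    matrix: DosageMatrix, config: FilterConfig | None = None
) -> tuple[DosageMatrix, FilterLog]:
    """Apply the site-filter cascade; returns the retained matrix and a log.

    Rules, in order: biallelic; QUAL > min_qual; missing fraction <=
    max_missing_frac; alternate-allele frequency > min_alt_freq.  The
    frequency is alt-dosage sum over ploidy-weighted allele copies among
    non-missing calls, computed jointly over all individuals.
    """
    config = config or FilterConfig()
    log = FilterLog(n_input=matrix.n_sites)
    if matrix.n_sites == 0:
        warnings.warn("filter_sites received an empty matrix")
        log.n_retained = 0
        return matrix, log

    keep = np.ones(matrix.n_sites, dtype=bool)
    if config.biallelic_only:
        ok = _is_biallelic(matrix.sites)
        log.dropped["not_biallelic"] = int((keep & ~ok).sum())
        keep &= ok
    qual = matrix.sites["qual"].to_numpy(dtype=float)
    ok = qual > config.min_qual
    log.dropped["low_qual"] = int((keep & ~ok).sum())
    keep &= ok
    ok = matrix.missing_fraction() <= config.max_missing_frac
    log.dropped["missingness"] = int((keep & ~ok).sum())
    keep &= ok
    freq = matrix.alt_allele_freq()
    ok = np.nan_to_num(freq, nan=0.0) > config.min_alt_freq
    log.dropped["low_alt_freq"] = int((keep & ~ok).sum())
    keep &= ok

    log.n_retained = int(keep.sum())
    return matrix.take_sites(np.where(keep)[0]), log


def intersect_ploidy_sets(
    diploid_sites: pd.DataFrame, tetraploid_sites: pd.DataFrame
) -> pd.DataFrame:
    """Shared variants between the diploid and tetraploid callsets.

    Sites are keyed by (chrom, pos, ref, alt); the intersection preserves
    the diploid set's original order.
    """
    key_cols = ["chrom", "pos", "ref", "alt"]
    tet_keys = set(map(tuple, tetraploid_sites[key_cols].itertuples(index=False)))
    mask = [
        tuple(row) in tet_keys
        for row in diploid_sites[key_cols].itertuples(index=False)
    ]
    return diploid_sites.loc[mask].reset_index(drop=True)


def thin_one_per_window(
    matrix: DosageMatrix, window_bp: int = 139
) -> DosageMatrix:
    """Keep one SNP per window of ``window_bp`` bases, per chromosome.

    Greedy left-to-right: the window starts at the first unconsumed SNP;
    among SNPs within [start, start + window_bp - 1] the one with least
    missingness is kept (ties to the lowest position), then the scan
    advances past the window.  Already-thinned input passes unchanged
    (idempotent).
    """
    sites = matrix.sites
    pos = sites["pos"].to_numpy()
    chrom = sites["chrom"].to_numpy()
    order = np.lexsort((pos, chrom))
    if not np.array_equal(order, np.arange(len(order))):
        warnings.warn("sites were not coordinate-sorted; sorting internally")
    miss = matrix.missing_fraction()

    kept: list[int] = []
    i = 0
    while i < len(order):
        j0 = order[i]
        c, start = chrom[j0], pos[j0]
        window = [j0]
        j = i + 1
        while j < len(order):
            jj = order[j]
            if chrom[jj] != c or pos[jj] > start + window_bp - 1:
                break
            window.append(jj)
            j += 1
        # least missingness, tie -> lowest position
        best = min(window, key=lambda k: (miss[k], pos[k]))
        kept.append(best)
        i = j
    kept_sorted = sorted(kept)
    return matrix.take_sites(np.array(kept_sorted, dtype=int))
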