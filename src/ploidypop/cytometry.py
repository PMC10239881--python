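"""Ploidy inference from flow-cytometry relative fluorescence.

A sample's relative fluorescence (RF) is the ratio of its mean
fluorescence to that of an internal reference standard; RF is proportional
to genome size, so tetraploids sit at roughly twice the diploid ratio.
Replicated RF measurements are reduced to a ploidy call — diploid,
tetraploid, or ambiguous when the mean RF falls outside both accepted
bands (ambiguous samples are excluded downstream).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FluorescenceRecord",
    "PloidyCall",
    "compute_rf",
    "call_ploidy",
    "calibrate_band",
    "call_ploidy_table",
]

#: replicate coefficient of variation above which a record is flagged noisy
CV_FLAG_THRESHOLD = 0.05


@dataclass
class FluorescenceRecord:
    """Replicated RF measurements for one individual."""

    sample_id: str
    rf_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.rf_values) < 1:
            raise ValueError("at least one replicate RF value is required")
        if any(not np.isfinite(v) or v <= 0 for v in self.rf_values):
            raise ValueError("RF values must be positive and finite")


@dataclass
class PloidyCall:
    sample_id: str
    call: str  # diploid | tetraploid | ambiguous
    mean_rf: float
    replicate_cv: float
    flagged: bool  # replicate CV above CV_FLAG_THRESHOLD


def compute_rf(sample_mean: float, reference_mean: float) -> float:
    """Relative fluorescence: sample channel mean over reference mean."""
    if sample_mean <= 0 or reference_mean <= 0:
        raise ValueError("channel means must be positive")
    return sample_mean / reference_mean


def call_ploidy(
    record: FluorescenceRecord,
    band_2x_center: float,
    tolerance: float = 0.15,
) -> PloidyCall:
    """Call ploidy from a record's mean RF against doubling bands.

    The diploid band is ``band_2x_center * (1 ± tolerance)`` and the
    tetraploid band twice that; a mean RF outside both is ambiguous.
    The replicate coefficient of variation is reported, and records with
    CV above 5% are flagged but not automatically ambiguated.
    """
    if band_2x_center <= 0:
        raise ValueError("band center must be positive")
    if not (0.0 < tolerance < 0.5):
        raise ValueError("tolerance must lie in (0, 0.5)")
    vals = np.asarray(record.rf_values, dtype=float)
    mean_rf = float(vals.mean())
    cv = float(vals.std(ddof=0) / mean_rf) if len(vals) > 1 else 0.0
    lo2, hi2 = band_2x_center * (1 - tolerance), band_2x_center * (1 + tolerance)
    lo4, hi4 = 2 * lo2, 2 * hi2
    if lo2 <= mean_rf <= hi2:
        call = "diploid"
    elif lo4 <= mean_rf <= hi4:
        call = "tetraploid"
    else:
        call = "ambiguous"
    return PloidyCall(record.sample_id, call, mean_rf, cv, cv > CV_FLAG_THRESHOLD)


def calibrate_band(known_diploid_rfs: np.ndarray) -> float:
    """Robust diploid band center: the median of known-diploid RF values.

    The median keeps the center stable when an occasional mis-labelled
    tetraploid slips into the calibration set.
    """
    vals = np.asarray(known_diploid_rfs, dtype=float)
    if vals.size < 3:
        raise ValueError("band calibration needs at least 3 known-diploid values")
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ValueError("RF values must be positive and finite")
    return float(np.median(vals))


def call_ploidy_table(
    fluorescence: pd.DataFrame,
    band_2x_center: float,
    tolerance: float = 0.15,
) -> pd.DataFrame:
    """Vectorized calls over a long-format fluorescence table.

    Expects columns sample_id, rf (one row per replicate); returns one row
    per sample with call, mean_rf, replicate_cv, flagged.
    """
    calls = []
    for sid, grp in fluorescence.groupby("sample_id", sort=True):
        rec = FluorescenceRecord(str(sid), tuple(grp["rf"]))
        c = call_ploidy(rec, band_2x_center, tolerance)
        calls.append((c.sample_id, c.call, c.mean_rf, c.replicate_cv, c.flagged))
    return pd.DataFrame(
        calls, columns=["sample_id", "call", "mean_rf", "replicate_cv", "flagged"]
    )
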