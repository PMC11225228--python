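"""Robust per-sample quality flagging.

Low-quality MS runs show up as columns with an excess of missing values
and/or a shifted median intensity relative to the rest of the cohort.  Both
diagnostics are scored with a robust z-rule: a sample is flagged when its
statistic deviates from the cohort median by more than ``k`` scaled median
absolute deviations (MAD x 1.4826, the consistency constant for normal
data).  The comparison is strict, so a cohort of identical samples never
flags anything even though its MAD is zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import FeatureMatrix

MAD_SCALE = 1.4826


@dataclass
class QCReport:
    """Per-sample QC statistics with flags and the rules that fired."""

    table: pd.DataFrame  # sample_id, missing_fraction, median_intensity, flagged, flag_reason

    @property
    def flagged_samples(self) -> list:
        return list(self.table.loc[self.table["flagged"], "sample_id"])


def _robust_outliers(x: np.ndarray, k: float) -> np.ndarray:
    """True where |x - median| strictly exceeds k * 1.4826 * MAD."""
    med = np.median(x)
    mad = MAD_SCALE * np.median(np.abs(x - med))
    return np.abs(x - med) > k * mad


def qc_flag_samples(m: FeatureMatrix, k: float = 3.0) -> QCReport:
    """Flag samples with outlying missingness or median intensity.

    Requires at least 4 samples; with fewer, the cohort median and MAD carry
    no information about what is typical.
    """
    if m.n_samples < 4:
        raise ValueError("qc_flag_samples needs at least 4 samples")
    vals = m.values.to_numpy(dtype=float)
    miss_frac = np.isnan(vals).mean(axis=0)
    medians = np.nanmedian(vals, axis=0)
    miss_out = _robust_outliers(miss_frac, k)
    med_out = _robust_outliers(medians, k)
    reasons = []
    for a, b in zip(miss_out, med_out):
        fired = []
        if a:
            fired.append("missing_fraction")
        if b:
            fired.append("median_intensity")
        reasons.append(";".join(fired))
    table = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "missing_fraction": miss_frac,
            "median_intensity": medians,
            "flagged": miss_out | med_out,
            "flag_reason": reasons,
        }
    )
    return QCReport(table=table)
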