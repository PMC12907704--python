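"""Longitudinal treatment monitoring of predicted tumor fractions.

For each patient the baseline visit (smallest timepoint) is paired with the
first follow-up (next smallest); the per-patient change in tumor fraction is
tested against zero with a two-sided paired t-test. A therapy that clears
tumor cells should show a significant negative mean change in sensitive
patients and none in resistant ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from cfdeconv.errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MonitorResult:
    """Summary of the baseline vs first-follow-up paired comparison."""

    n_patients: int
    mean_delta: float
    sd_delta: float
    t_statistic: float
    p_value: float

    def __str__(self) -> str:  # report-style "mean ± SD, p" summary
        return (
            f"n={self.n_patients}, mean change {self.mean_delta:+.3f} "
            f"± {self.sd_delta:.3f} (SD); paired t-test p = {self.p_value:.4f}"
        )


def pair_baseline_followup(
    estimates: pd.DataFrame,
    meta: pd.DataFrame,
    fraction_column: str = "tumor_fraction",
) -> pd.DataFrame:
    """Pair each patient's baseline with the first follow-up tumor fraction.

    ``estimates`` needs columns ``sample_id`` and ``fraction_column``;
    ``meta`` maps sample_id to patient_id and timepoint. Technical replicates
    (several samples of one patient at one timepoint) are averaged before
    pairing; patients with fewer than two distinct timepoints are skipped
    with a warning.

    Returns a DataFrame with columns patient_id, baseline_fraction,
    followup_fraction, delta (follow-up minus baseline).
    """
    for col in ("sample_id", fraction_column):
        if col not in estimates.columns:
            raise ValidationError(f"estimates table lacks column '{col}'")
    merged = estimates.merge(meta[["sample_id", "patient_id", "timepoint"]],
                             on="sample_id", how="left")
    if merged["patient_id"].isna().any():
        missing = merged.loc[merged["patient_id"].isna(), "sample_id"].tolist()
        raise ValidationError(
            f"metadata does not cover sample(s): {missing[:10]}"
        )
    per_visit = (
        merged.groupby(["patient_id", "timepoint"], sort=True)[fraction_column]
        .mean()
        .reset_index()
    )
    replicated = merged.groupby(["patient_id", "timepoint"]).size()
    n_reps = int((replicated > 1).sum())
    if n_reps:
        logger.info("averaged technical replicates at %d patient-visits", n_reps)

    rows = []
    skipped = []
    for patient, visits in per_visit.groupby("patient_id", sort=True):
        if len(visits) < 2:
            skipped.append(patient)
            continue
        visits = visits.sort_values("timepoint")
        baseline = float(visits[fraction_column].iloc[0])
        followup = float(visits[fraction_column].iloc[1])
        rows.append(
            {
                "patient_id": patient,
                "baseline_fraction": baseline,
                "followup_fraction": followup,
                "delta": followup - baseline,
            }
        )
    if skipped:
        warnings.warn(
            f"skipped {len(skipped)} patient(s) with a single timepoint: "
            f"{skipped[:10]}",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=[
        "patient_id", "baseline_fraction", "followup_fraction", "delta"
    ])


def paired_t_test(deltas: np.ndarray | pd.Series | list[float]) -> MonitorResult:
    """Two-sided one-sample t-test of the per-patient changes against zero.

    ``t = mean(delta) / (sd(delta) / sqrt(n))`` with ``n - 1`` degrees of
    freedom. Identical nonzero deltas give sd = 0; that degenerate case is
    reported as p = 0 with a warning.
    """
    deltas = np.asarray(deltas, dtype=float)
    n = deltas.size
    if n < 2:
        raise ValidationError("need at least two patients for a paired t-test")
    mean = float(deltas.mean())
    sd = float(deltas.std(ddof=1))
    # identical deltas can leave a femto-scale sd from float summation
    if sd <= 1e-12 * max(float(np.abs(deltas).max()), 1.0):
        sd = 0.0
    if sd == 0.0:
        if mean == 0.0:
            return MonitorResult(n, 0.0, 0.0, 0.0, 1.0)
        warnings.warn(
            "all deltas identical and nonzero: sd = 0, p reported as 0",
            stacklevel=2,
        )
        return MonitorResult(n, mean, 0.0, float(np.sign(mean)) * np.inf, 0.0)
    t = mean / (sd / np.sqrt(n))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return MonitorResult(n, mean, sd, float(t), p)


def monitor_cohort(
    estimates: pd.DataFrame,
    meta: pd.DataFrame,
) -> tuple[pd.DataFrame, MonitorResult]:
    """Convenience wrapper: pairing plus the paired t-test."""
    pairs = pair_baseline_followup(estimates, meta)
    result = paired_t_test(pairs["delta"].to_numpy())
    return pairs, result
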