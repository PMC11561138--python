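"""Balanced test-set construction and accuracy metrics.

The test set is balanced so no participant or walking configuration
dominates: a participant is kept only if every one of the six walking
configurations (3 instructed velocities x 2 directions) has at least five
valid trials, and exactly the first five valid trials per configuration are
used — 30 trials per kept participant.

Metrics: RMSE pooled over trials, NRMSE (RMSE normalized to the mean of the
reference values), Pearson R, and MAE. Predictor accuracy is aggregated
per participant first (inter-subject mean of intra-subject RMSE/R, spread
as the population SD of the per-subject values).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError

REQUIRED_COLUMNS = ("subject_id", "velocity_class", "direction",
                    "trial_index", "valid")
N_CONFIGURATIONS = 6
TRIALS_PER_CONFIGURATION = 5


@dataclass
class PeakMetrics:
    """Pooled-trial accuracy of one response variable."""

    rmse: float
    nrmse: float
    r: float  # NaN when the references have zero variance
    mae: float
    n: int

    @property
    def r_defined(self) -> bool:
        return np.isfinite(self.r)


def build_balanced_test_set(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Apply the validity/balancing filter to a trial table.

    Returns the kept records (first five valid trials of each configuration
    for each surviving subject, 30 rows per subject) and the list of
    excluded subject ids. Idempotent: re-filtering the output is a no-op.
    """
    missing = set(REQUIRED_COLUMNS) - set(records.columns)
    if missing:
        raise InvalidArgumentError(f"records lack columns {sorted(missing)}")
    valid = records[records["valid"].astype(bool)]
    excluded: list[str] = []
    kept = []
    for sid, group in records.groupby("subject_id", sort=True):
        vgroup = valid[valid["subject_id"] == sid]
        counts = vgroup.groupby(["velocity_class", "direction"]).size()
        if len(counts) < N_CONFIGURATIONS or (counts < TRIALS_PER_CONFIGURATION).any():
            excluded.append(str(sid))
            continue
        first5 = (
            vgroup.sort_values("trial_index", kind="stable")
            .groupby(["velocity_class", "direction"], sort=True)
            .head(TRIALS_PER_CONFIGURATION)
        )
        kept.append(first5)
    if not kept:
        return records.iloc[0:0].copy(), excluded
    out = pd.concat(kept).sort_index()
    return out, excluded


def compute_peak_metrics(
    predictions: np.ndarray, references: np.ndarray
) -> PeakMetrics:
    """Pooled RMSE / NRMSE / Pearson R / MAE over aligned trial pairs."""
    p = np.asarray(predictions, dtype=float)
    r = np.asarray(references, dtype=float)
    if p.shape != r.shape or p.ndim != 1:
        raise InvalidArgumentError("predictions/references must align 1-d")
    if len(p) == 0:
        raise InvalidArgumentError("empty metric input")
    err = p - r
    rmse = float(np.sqrt(np.mean(err**2)))
    mean_ref = float(np.mean(r))
    nrmse = rmse / mean_ref if mean_ref != 0 else np.inf
    if np.std(r) == 0 or np.std(p) == 0:
        pearson = np.nan  # undefined on constant series
    else:
        pearson = float(stats.pearsonr(p, r).statistic)
    return PeakMetrics(rmse=rmse, nrmse=float(nrmse), r=pearson,
                       mae=float(np.mean(np.abs(err))), n=len(p))


def compute_predictor_metrics(
    df: pd.DataFrame,
    estimate_col: str,
    reference_col: str,
    subject_col: str = "subject_id",
) -> dict[str, float]:
    """Per-predictor accuracy with equal participant weighting.

    RMSE and Pearson R are computed within each subject and then averaged
    across subjects; the SDs are population SDs of the per-subject values.
    Subjects with zero-variance series contribute no R value.
    """
    rmses, rs = [], []
    for _, g in df.groupby(subject_col, sort=True):
        est = g[estimate_col].to_numpy(dtype=float)
        ref = g[reference_col].to_numpy(dtype=float)
        rmses.append(float(np.sqrt(np.mean((est - ref) ** 2))))
        if len(g) > 1 and np.std(est) > 0 and np.std(ref) > 0:
            rs.append(float(stats.pearsonr(est, ref).statistic))
    return {
        "rmse_mean": float(np.mean(rmses)),
        "rmse_sd": float(np.std(rmses)),  # population SD
        "r_mean": float(np.mean(rs)) if rs else np.nan,
        "r_sd": float(np.std(rs)) if rs else np.nan,
        "n_subjects": len(rmses),
    }


def mae_change_from_baseline(
    df: pd.DataFrame,
    modality_col: str,
    baseline_col: str,
    reference_col: str,
    subject_col: str = "subject_id",
    direction_col: str = "direction",
) -> pd.DataFrame:
    """Relative change of per-subject MAE versus the baseline predictions,
    tabulated by subject and walking direction.

    change = (MAE_modality - MAE_baseline) / MAE_baseline; 0 means the
    portable modality predicts exactly as well as the baseline.
    """
    rows = []
    for (sid, direction), g in df.groupby([subject_col, direction_col], sort=True):
        mae_mod = float(np.mean(np.abs(g[modality_col] - g[reference_col])))
        mae_base = float(np.mean(np.abs(g[baseline_col] - g[reference_col])))
        change = (mae_mod - mae_base) / mae_base if mae_base > 0 else np.nan
        rows.append({subject_col: sid, direction_col: direction,
                     "mae_modality": mae_mod, "mae_baseline": mae_base,
                     "relative_change": change})
    return pd.DataFrame(rows)
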