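"""Accuracy metrics: 3D distance errors, detection rates, summary tables.

The headline numbers of a landmark-detection system are the per-landmark
3D mean distance error (Euclidean, world mm, mean ± SD over subjects) and
the detection rate: the percentage of predictions whose error falls
strictly below a threshold (2 / 2.5 / 3 / 4 mm by convention).  Rates are
non-decreasing in the threshold.  Standard deviations use the n-1 sample
denominator; a single-observation group reports SD 0 with a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_THRESHOLDS = (2.0, 2.5, 3.0, 4.0)


def error_3d(pred, truth) -> float:
    """Euclidean distance between predicted and reference points, in mm."""
    return float(np.linalg.norm(np.asarray(pred, float) - np.asarray(truth, float)))


def detection_rates(errors, thresholds=DEFAULT_THRESHOLDS) -> dict[float, float]:
    """Percentage of errors strictly below each threshold."""
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("empty error list")
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    return {float(t): float(100.0 * np.mean(errors < t)) for t in thresholds}


@dataclass
class ErrorTable:
    """Per-landmark rows plus per-landmark / per-type / overall summaries."""

    rows: pd.DataFrame  # columns: landmark, type, subject, error_mm
    per_landmark: pd.DataFrame
    per_type: pd.DataFrame
    overall: dict

    def to_csv(self, path) -> None:
        self.per_landmark.to_csv(path, index=False)

    def summary_json(self) -> dict:
        return {
            "overall": self.overall,
            "per_landmark": self.per_landmark.to_dict(orient="records"),
            "per_type": self.per_type.to_dict(orient="records"),
        }


def _group_stats(g: pd.DataFrame, thresholds) -> dict:
    errs = g["error_mm"].to_numpy()
    single = len(errs) == 1
    out = {
        "n": int(len(errs)),
        "mean_mm": float(errs.mean()),
        "sd_mm": 0.0 if single else float(errs.std(ddof=1)),
        "sd_undefined": bool(single),
    }
    for t, r in detection_rates(errs, thresholds).items():
        out[f"rate_lt_{t:g}mm"] = r
    return out


def summarize(rows, thresholds=DEFAULT_THRESHOLDS) -> ErrorTable:
    """Summarise (landmark, type, subject, error) records.

    ``rows`` is any iterable of dicts/tuples with fields
    (landmark, type, subject, error_mm), or a DataFrame with those columns.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        rows = list(rows)
        if not rows:
            raise ValueError("need at least one row")
        if isinstance(rows[0], dict):
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(rows, columns=["landmark", "type", "subject", "error_mm"])
    if df.empty:
        raise ValueError("need at least one row")

    per_landmark = pd.DataFrame(
        [
            {"landmark": lm, "type": g["type"].iloc[0], **_group_stats(g, thresholds)}
            for lm, g in df.groupby("landmark", sort=True)
        ]
    )
    per_type = pd.DataFrame(
        [
            {"type": t, **_group_stats(g, thresholds)}
            for t, g in df.groupby("type", sort=True)
        ]
    )
    overall = _group_stats(df, thresholds)
    return ErrorTable(rows=df, per_landmark=per_landmark, per_type=per_type, overall=overall)
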