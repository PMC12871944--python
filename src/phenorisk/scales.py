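"""Outcome scales, score ranges, and high-risk binarization thresholds.

Four self-report instruments define the classification targets:

* **SDQ** (Strengths and Difficulties Questionnaire), total 0-40; a total of
  16 or more flags high internalizing/externalizing risk.
* **SCI** (Sleep Condition Indicator), total 0-32; *lower* scores mean worse
  sleep, and a total of 16 or less flags probable insomnia.
* **ED-15** (brief eating-disorder scale), a continuous 0-6 mean-style score;
  values strictly above 2.69 (nonclinical mean + 1 SD) flag elevated risk.
* **Suicidal-ideation frequency**, a single 0-4 item over two weeks; any
  nonzero response defines the high-risk class.

The SCI cut is stated both as "<=16" and "<17" in different places; with
integer SCI totals these coincide, and the implementation uses <=16. The
ED-15 cut is strict (">2.69") on the continuous score.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SCALE_RANGES = {
    "sdq_total": (0, 40),
    "sci_total": (0, 32),
    "ed15_total": (0.0, 6.0),
    "si_frequency": (0, 4),
}

OUTCOMES = ("sdq", "insomnia", "si", "ed")

#: outcome key -> column of the score table it is derived from
OUTCOME_SCORE_COLUMN = {
    "sdq": "sdq_total",
    "insomnia": "sci_total",
    "si": "si_frequency",
    "ed": "ed15_total",
}

LABEL_COLUMNS = {
    "sdq": "sdq_high",
    "insomnia": "insomnia_high",
    "si": "si_high",
    "ed": "ed_high",
}


@dataclass(frozen=True)
class ThresholdConfig:
    """High-risk cut points; defaults are the validated published cuts."""

    sdq_high_min: float = 16.0
    sci_high_max: float = 16.0
    ed15_high_exclusive_min: float = 2.69
    si_high_min: float = 1.0

    def validate(self) -> None:
        if not (SCALE_RANGES["sdq_total"][0] <= self.sdq_high_min <= SCALE_RANGES["sdq_total"][1]):
            raise ValueError("sdq_high_min outside the 0-40 SDQ range")
        if not (SCALE_RANGES["sci_total"][0] <= self.sci_high_max <= SCALE_RANGES["sci_total"][1]):
            raise ValueError("sci_high_max outside the 0-32 SCI range")
        if not (SCALE_RANGES["ed15_total"][0] <= self.ed15_high_exclusive_min <= SCALE_RANGES["ed15_total"][1]):
            raise ValueError("ed15_high_exclusive_min outside the 0-6 ED-15 range")
        if not (SCALE_RANGES["si_frequency"][0] <= self.si_high_min <= SCALE_RANGES["si_frequency"][1]):
            raise ValueError("si_high_min outside the 0-4 ideation range")


def _check_ranges(scores: pd.DataFrame) -> None:
    for col, (lo, hi) in SCALE_RANGES.items():
        if col not in scores.columns:
            raise ValueError(f"score table is missing column {col!r}")
        vals = scores[col].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite values in {col}")
        if vals.min() < lo or vals.max() > hi:
            raise ValueError(f"{col} outside its {lo}-{hi} range")


def binarize_outcomes(scores: pd.DataFrame, thresholds: ThresholdConfig | None = None) -> pd.DataFrame:
    """Map a per-user score table to four boolean high-risk labels.

    Parameters
    ----------
    scores
        One row per user with columns ``user_id``, ``sdq_total``,
        ``sci_total``, ``ed15_total``, ``si_frequency``.
    thresholds
        Cut points; defaults to the published cuts.

    Returns
    -------
    DataFrame with ``user_id`` and boolean columns ``sdq_high``,
    ``insomnia_high``, ``si_high``, ``ed_high``.
    """
    thresholds = thresholds or ThresholdConfig()
    thresholds.validate()
    _check_ranges(scores)
    out = pd.DataFrame({"user_id": scores["user_id"].to_numpy()})
    out["sdq_high"] = scores["sdq_total"].to_numpy(dtype=float) >= thresholds.sdq_high_min
    out["insomnia_high"] = scores["sci_total"].to_numpy(dtype=float) <= thresholds.sci_high_max
    out["si_high"] = scores["si_frequency"].to_numpy(dtype=float) >= thresholds.si_high_min
    out["ed_high"] = scores["ed15_total"].to_numpy(dtype=float) > thresholds.ed15_high_exclusive_min
    return out


def prevalence_summary(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-outcome high-risk counts and percentages (1-decimal rounding)."""
    if len(labels) == 0:
        raise ValueError("empty label table")
    n = len(labels)
    rows = []
    for outcome, col in LABEL_COLUMNS.items():
        count = int(labels[col].sum())
        rows.append({
            "outcome": outcome,
            "n_high": count,
            "n_total": n,
            "percent_high": round(100.0 * count / n, 1),
        })
    return pd.DataFrame(rows)
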