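"""Interval growth outcomes: day-normalised z-score change, age-window
exclusions, anthropometric flags and winsorization.

The change in a z-score over a visit interval is normalised by the actual
number of days between the two measurements and rescaled to a standard
6-month interval of 182.625 days (365.25 / 2), so children measured a few
weeks early or late are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "STANDARD_DAYS",
    "DAYS_PER_MONTH",
    "AGE_WINDOW_MONTHS",
    "delta_z",
    "apply_age_windows",
    "flag_malnutrition",
    "winsorize",
    "build_interval_outcomes",
    "IntervalOutcome",
]

STANDARD_DAYS = 182.625
DAYS_PER_MONTH = 30.4375

#: Upper age limit (months) per scheduled visit; children strictly older are
#: excluded from that visit's analyses.
AGE_WINDOW_MONTHS = {"6mo": 8.0, "12mo": 15.0, "18mo": 21.0}

MALNUTRITION_CUTOFF = -2.0
_FLAG_NAMES = {
    "waz": "underweight",
    "laz": "stunting",
    "wlz": "wasting",
    "hcz": "small_head",
}


@dataclass
class IntervalOutcome:
    """Day-normalised z-score change over one 6-month interval."""

    child_id: str
    interval: str  # "6-12" or "12-18"
    index: str  # laz | waz | wlz | hcz
    delta_z: float
    baseline_z: float
    predictor_at_start: float
    days_between: int


def delta_z(z_start, z_end, date_start, date_end, standard_days: float = STANDARD_DAYS):
    """Change in z-score per standard interval.

    delta = (z_end - z_start) / days_between * standard_days, where
    days_between is the actual span between the two measurement dates.
    """
    d0 = pd.to_datetime(date_start)
    d1 = pd.to_datetime(date_end)
    days = (d1 - d0).days if np.isscalar(z_start) else (d1 - d0).dt.days  # type: ignore[union-attr]
    days = np.asarray(days, dtype=float)
    if (days <= 0).any():
        raise ValueError("date_end must be strictly after date_start")
    out = (np.asarray(z_end, dtype=float) - np.asarray(z_start, dtype=float)) / days * standard_days
    return float(out) if out.ndim == 0 else out


def apply_age_windows(
    visits: pd.DataFrame, windows: dict[str, float] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop visits where the child was strictly older than the visit's window.

    Months are age_days / 30.4375; the comparison is strict ("older than"),
    so a child at exactly the limit is kept. Returns (included, exclusion log).
    """
    windows = AGE_WINDOW_MONTHS if windows is None else windows
    age_months = visits["age_days"].to_numpy(dtype=float) / DAYS_PER_MONTH
    limits = visits["visit_label"].map(windows).to_numpy(dtype=float)
    excluded = age_months > limits
    log = pd.DataFrame(
        {
            "child_id": visits.loc[excluded, "child_id"],
            "visit_label": visits.loc[excluded, "visit_label"],
            "age_months": age_months[excluded],
            "reason": [
                f"age {a:.2f} mo exceeds {l:.0f} mo window"
                for a, l in zip(age_months[excluded], limits[excluded])
            ],
        }
    )
    return visits.loc[~excluded].reset_index(drop=True), log.reset_index(drop=True)


def flag_malnutrition(z: float, index: str) -> dict[str, bool]:
    """Anthropometric status flags; true iff z < -2.0 (strictly below).

    ``index`` selects which flag can fire: waz -> underweight, laz -> stunting,
    wlz -> wasting, hcz -> small_head.
    """
    index = index.lower()
    if index not in _FLAG_NAMES:
        raise ValueError(f"unknown anthropometric index {index!r}")
    flags = {name: False for name in _FLAG_NAMES.values()}
    flags[_FLAG_NAMES[index]] = bool(np.isfinite(z) and z < MALNUTRITION_CUTOFF)
    return flags


def winsorize(values, lower_pct: float = 2.5, upper_pct: float = 97.5) -> np.ndarray:
    """Clamp values beyond the given percentiles to those percentiles.

    The clamping bounds are nearest-rank (inclusive) order statistics — the
    smallest data value at or above the lower percentile and the largest at
    or below the upper one — so winsorizing an already-winsorized vector is a
    no-op. (Interpolated percentiles would shift slightly on each pass; the
    two definitions coincide up to one order-statistic gap and converge at
    cohort sample sizes.) NaNs are ignored for the percentile computation and
    passed through unchanged. The caller keeps the original vector for the
    non-winsorized sensitivity refit.
    """
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if finite.size < 2:
        raise ValueError("winsorize needs at least 2 finite values")
    lo = np.percentile(finite, lower_pct, method="higher")
    hi = np.percentile(finite, upper_pct, method="lower")
    return np.clip(arr, lo, hi)


def build_interval_outcomes(
    visits: pd.DataFrame,
    predictor: str,
    indices: tuple[str, ...] = ("laz", "waz", "wlz", "hcz"),
    standard_days: float = STANDARD_DAYS,
) -> pd.DataFrame:
    """Stack per-child interval outcomes for the repeated-measures models.

    For each consecutive visit pair (6->12, 12->18) and anthropometric index,
    emits the day-normalised delta-z, the baseline z at interval start and the
    named predictor measured at interval start. A child contributes an
    interval whenever both of its endpoint visits are present with complete
    data; missing one interval does not exclude the other.
    """
    pairs = [("6mo", "12mo", "6-12"), ("12mo", "18mo", "12-18")]
    cols = ["child_id", "visit_label", "stool_date", predictor, *indices]
    missing = [c for c in cols if c not in visits.columns]
    if missing:
        raise ValueError(f"visits frame lacks columns: {missing}")
    if visits.duplicated(["child_id", "visit_label"]).any():
        dupes = visits[visits.duplicated(["child_id", "visit_label"], keep=False)]
        raise ValueError(
            "duplicate child-visit rows: "
            + ", ".join(map(str, dupes["child_id"].unique()[:5]))
        )
    wide = {
        lab: visits[visits["visit_label"] == lab].set_index("child_id")
        for lab in ("6mo", "12mo", "18mo")
    }
    rows = []
    for lab0, lab1, name in pairs:
        common = wide[lab0].index.intersection(wide[lab1].index)
        a, b = wide[lab0].loc[common], wide[lab1].loc[common]
        days = (
            pd.to_datetime(b["stool_date"]) - pd.to_datetime(a["stool_date"])
        ).dt.days
        for idx in indices:
            dz = (b[idx] - a[idx]) / days * standard_days
            rows.append(
                pd.DataFrame(
                    {
                        "child_id": common,
                        "interval": name,
                        "index": idx,
                        "delta_z": dz.to_numpy(),
                        "baseline_z": a[idx].to_numpy(),
                        "predictor_at_start": a[predictor].to_numpy(),
                        "days_between": days.to_numpy(),
                    }
                )
            )
    out = pd.concat(rows, ignore_index=True)
    return out.dropna(subset=["delta_z", "baseline_z", "predictor_at_start"])
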