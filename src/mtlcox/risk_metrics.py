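"""Personalized risk layer on top of a fitted multitask Cox model.

Turns per-subject absolute risks into the quantities a screening program
reports: basis (age-group average) risk, relative absolute risk
RAR = AR / basis, excess absolute risk EAR = AR - basis, three-level risk
strata cut at configurable quantiles of the cohort's absolute risks, and a
per-subject ranking of diseases by absolute risk.

All tables are tidy pandas DataFrames with columns
``subject, disease, horizon, ...`` so they serialize directly to delimited
text.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_HORIZONS",
    "DEFAULT_AGE_BINS",
    "DEFAULT_QUANTILES",
    "risk_table",
    "assign_age_groups",
    "basis_risk",
    "relative_and_excess",
    "compute_strata",
    "stratify",
    "rank_diseases",
]

DEFAULT_HORIZONS: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0)
DEFAULT_AGE_BINS: tuple[tuple[float, float], ...] = (
    (40.0, 50.0),
    (50.0, 60.0),
    (60.0, 70.0),
    (70.0, np.inf),
)
DEFAULT_QUANTILES: tuple[float, float, float] = (0.33, 0.50, 0.66)


def risk_table(
    model,
    features: np.ndarray,
    subject_ids: Sequence,
    horizons: Sequence[float] = DEFAULT_HORIZONS,
) -> pd.DataFrame:
    """Absolute risk per subject x disease x horizon.

    ``features`` is the shared design matrix (already on the model's
    standardized scale); every disease model scores the same subjects.
    Diseases are separate proportional-hazards models, so nothing constrains
    a subject's risks to sum to anything.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    rows = []
    for disease in model.task_names:
        for h in horizons:
            ar = model.predict_absolute_risk(disease, features, float(h))
            rows.append(
                pd.DataFrame(
                    {
                        "subject": list(subject_ids),
                        "disease": disease,
                        "horizon": float(h),
                        "AR": np.asarray(ar, dtype=float),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def assign_age_groups(
    age: np.ndarray, age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS
) -> np.ndarray:
    """Label each subject's age bin; half-open [lo, hi) intervals, the last
    bin open-ended.  Ages outside every bin get the label ``"other"``."""
    age = np.asarray(age, dtype=float)
    labels = np.full(age.shape, "other", dtype=object)
    for lo, hi in age_bins:
        name = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">={lo:g}"
        labels[(age >= lo) & (age < hi)] = name
    return labels


def basis_risk(
    risk_df: pd.DataFrame,
    age: np.ndarray,
    subject_ids: Sequence,
    age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Age-group mean absolute risk per disease x age group x horizon.

    The basis risk is the average incidence of the subject's own age group
    over the horizon — the reference level that RAR and EAR compare against.
    Bins with no subjects are absent from the result (downstream RAR/EAR for
    such a bin are undefined).
    """
    groups = assign_age_groups(age, age_bins)
    age_map = pd.DataFrame({"subject": list(subject_ids), "age_group": groups})
    df = risk_df.merge(age_map, on="subject", how="left")
    out = (
        df.groupby(["disease", "age_group", "horizon"], as_index=False)["AR"]
        .mean()
        .rename(columns={"AR": "basis_AR"})
    )
    return out


def relative_and_excess(
    risk_df: pd.DataFrame,
    basis_df: pd.DataFrame,
    age: np.ndarray,
    subject_ids: Sequence,
    age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Per-record relative and excess absolute risk.

    RAR = AR / basis_AR (a multiple of the age-group average); EAR =
    AR - basis_AR, also provided in percentage points (``EAR_pct``).  When the
    basis risk is exactly zero, RAR is reported as NaN (undefined) rather than
    infinity.
    """
    groups = assign_age_groups(age, age_bins)
    age_map = pd.DataFrame({"subject": list(subject_ids), "age_group": groups})
    df = risk_df.merge(age_map, on="subject", how="left").merge(
        basis_df, on=["disease", "age_group", "horizon"], how="left"
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        rar = np.where(df["basis_AR"] > 0, df["AR"] / df["basis_AR"], np.nan)
    df["RAR"] = rar
    df["EAR"] = df["AR"] - df["basis_AR"]
    df["EAR_pct"] = 100.0 * df["EAR"]
    return df


@dataclass
class RiskStrata:
    """Quantile boundaries of the three-level stratification.

    ``table`` has one row per disease (x age group when ``by_age``) x horizon
    with columns ``low_upper`` (the low-risk upper bound), ``average_mid``
    (the median of the cohort) and ``high_lower`` (the high-risk lower bound).
    """

    table: pd.DataFrame
    quantiles: tuple[float, float, float]
    by_age: bool


def compute_strata(
    risk_df: pd.DataFrame,
    age: np.ndarray | None = None,
    subject_ids: Sequence | None = None,
    *,
    quantiles: tuple[float, float, float] = DEFAULT_QUANTILES,
    age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
    by_age: bool = True,
) -> RiskStrata:
    """Quantile cut-points of the absolute-risk distribution.

    Quantiles use linear interpolation between order statistics (the common
    "type 7" convention).  ``by_age=True`` computes the boundaries within
    each disease x age group x horizon cell; ``by_age=False`` pools ages.
    """
    q_low, q_mid, q_high = quantiles
    if not (q_low <= q_mid <= q_high):
        raise ValueError("quantiles must be nondecreasing")
    df = risk_df
    keys = ["disease", "horizon"]
    if by_age:
        if age is None or subject_ids is None:
            raise ValueError("by_age strata need age and subject_ids")
        groups = assign_age_groups(age, age_bins)
        age_map = pd.DataFrame({"subject": list(subject_ids), "age_group": groups})
        df = risk_df.merge(age_map, on="subject", how="left")
        keys = ["disease", "age_group", "horizon"]

    def _cuts(s: pd.Series) -> pd.Series:
        return pd.Series(
            {
                "low_upper": s.quantile(q_low, interpolation="linear"),
                "average_mid": s.quantile(q_mid, interpolation="linear"),
                "high_lower": s.quantile(q_high, interpolation="linear"),
            }
        )

    table = df.groupby(keys)["AR"].apply(_cuts).unstack().reset_index()
    return RiskStrata(table=table, quantiles=quantiles, by_age=by_age)


def stratify(
    risk_df: pd.DataFrame,
    strata: RiskStrata,
    age: np.ndarray | None = None,
    subject_ids: Sequence | None = None,
    age_bins: Sequence[tuple[float, float]] = DEFAULT_AGE_BINS,
) -> pd.DataFrame:
    """Attach a low / average / high stratum label to each risk record.

    AR <= low_upper -> "low" (the boundary itself is inclusive downward);
    AR >= high_lower -> "high"; everything between -> "average".  When the
    boundaries coincide (degenerate risk distribution) a record can satisfy
    both rules at once; such records are labeled "average".
    """
    df = risk_df
    keys = ["disease", "horizon"]
    if strata.by_age:
        if age is None or subject_ids is None:
            raise ValueError("by_age strata need age and subject_ids")
        groups = assign_age_groups(age, age_bins)
        age_map = pd.DataFrame({"subject": list(subject_ids), "age_group": groups})
        df = risk_df.merge(age_map, on="subject", how="left")
        keys = ["disease", "age_group", "horizon"]
    df = df.merge(strata.table, on=keys, how="left")
    is_low = df["AR"] <= df["low_upper"]
    is_high = df["AR"] >= df["high_lower"]
    label = np.select(
        [is_low & ~is_high, is_high & ~is_low], ["low", "high"], default="average"
    )
    df["stratum"] = label
    return df


def rank_diseases(risk_df: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Per-subject ranking of diseases by absolute risk at one horizon.

    Rank 1 is the highest-risk disease; ties break by disease name
    (alphabetical), so the ordering is deterministic and invariant to the
    input column order.
    """
    df = risk_df[risk_df["horizon"] == float(horizon)].copy()
    if df.empty:
        raise ValueError(f"no records at horizon {horizon}")
    df = df.sort_values(["subject", "AR", "disease"], ascending=[True, False, True])
    df["rank"] = df.groupby("subject").cumcount() + 1
    return df[["subject", "disease", "horizon", "AR", "rank"]].reset_index(drop=True)
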