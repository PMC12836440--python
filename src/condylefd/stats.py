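"""Cohort-level statistics: descriptives, normality-gated two-group
tests, pooled-SD effect sizes, Bonferroni correction, and ICC(2,1)
inter-observer agreement.

The comparison rule mirrors standard practice for FD cohort studies:
Shapiro-Wilk on each arm at alpha = 0.05; if both arms are normal, an
equal-variance independent t-test (consistent with the pooled-SD
Cohen's d reported alongside), otherwise a two-sided Mann-Whitney U.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .synthetic import AGE_BANDS, AGE_GROUPS

__all__ = [
    "GroupComparison",
    "AgreementResult",
    "DegenerateDataError",
    "age_group_of",
    "descriptive_stats",
    "shapiro_wilk",
    "cohens_d",
    "cohens_d_from_samples",
    "compare_groups",
    "bonferroni",
    "icc_2_1",
    "combined_condyle_table",
]

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Raised for samples without the variation a test requires."""


@dataclass(frozen=True)
class GroupComparison:
    """One patient-vs-control comparison within a stratum."""

    stratum: str
    test_name: str  # "independent t-test" or "Mann-Whitney U"
    statistic: float
    p_value: float
    cohens_d: float
    mean_patient: float
    mean_control: float
    sd_patient: float
    sd_control: float
    n_patient: int
    n_control: int

    @property
    def significant(self) -> bool:
        """Pre-correction flag at alpha = 0.05."""
        return self.p_value < ALPHA


@dataclass(frozen=True)
class AgreementResult:
    """ICC(2,1) with its F-based 95% confidence interval."""

    icc: float
    ci_low: float
    ci_high: float


def age_group_of(age: int) -> str:
    """Map an age in years onto the study's four bands."""
    for name, (lo, hi) in AGE_BANDS.items():
        if lo <= age <= hi:
            return name
    raise ValueError(f"age {age} outside the study range 18-75")


def descriptive_stats(
    cohort: pd.DataFrame,
    strata: tuple[str, ...] = ("group", "age_group", "gender"),
    value_cols: tuple[str, ...] = ("lc_fd", "rc_fd"),
) -> pd.DataFrame:
    """Per-cell n / mean / sample SD (n-1 denominator) for each condyle.

    Every stratum combination present in the categorical cross-product
    appears in the output; empty cells are kept with n = 0 and NaN
    moments, single-subject cells keep the mean but flag the SD as
    undefined (NaN).
    """
    if cohort.empty:
        raise ValueError("cohort is empty")
    df = cohort.copy()
    if "age_group" in strata and "age_group" not in df.columns:
        df["age_group"] = df["age"].map(age_group_of)
    levels = []
    for col in strata:
        if col == "age_group":
            levels.append(list(AGE_GROUPS))
        else:
            levels.append(sorted(df[col].unique()))
    index = pd.MultiIndex.from_product(levels, names=list(strata))
    rows = []
    for key in index:
        sel = np.ones(len(df), dtype=bool)
        for col, val in zip(strata, key):
            sel &= (df[col] == val).to_numpy()
        cell = df[sel]
        row = dict(zip(strata, key))
        row["n"] = len(cell)
        for vc in value_cols:
            vals = cell[vc].to_numpy(dtype=float)
            row[f"{vc}_mean"] = float(vals.mean()) if len(vals) else math.nan
            row[f"{vc}_sd"] = float(vals.std(ddof=1)) if len(vals) >= 2 else math.nan
        rows.append(row)
    return pd.DataFrame(rows)


def shapiro_wilk(values) -> tuple[float, float, bool]:
    """Shapiro-Wilk W, p, and the p >= 0.05 normality verdict."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {vals.size}")
    if np.ptp(vals) == 0:
        raise DegenerateDataError("all values identical; normality undefined")
    w, p = sps.shapiro(vals)
    return float(w), float(p), bool(p >= ALPHA)


def cohens_d(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int) -> float:
    """Pooled-SD standardized mean difference (group 1 minus group 2).

    d = (m1 - m2) / sqrt(((n1-1) s1^2 + (n2-1) s2^2) / (n1 + n2 - 2)).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    pooled_var = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if pooled_var <= 0:
        raise DegenerateDataError("zero pooled SD; effect size undefined")
    return (m1 - m2) / math.sqrt(pooled_var)


def cohens_d_from_samples(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(
        x.mean(), x.std(ddof=1), x.size, y.mean(), y.std(ddof=1), y.size
    )


def compare_groups(patient_values, control_values, stratum: str = "") -> GroupComparison:
    """Normality-gated two-sided patient-vs-control comparison.

    Both arms normal by Shapiro-Wilk -> equal-variance independent
    t-test; otherwise Mann-Whitney U.  Cohen's d (patient - control,
    pooled SD) is always reported from the sample moments.
    """
    x = np.asarray(patient_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("each arm needs n >= 3")
    _, _, x_normal = shapiro_wilk(x)
    _, _, y_normal = shapiro_wilk(y)
    if x_normal and y_normal:
        test_name = "independent t-test"
        stat, p = sps.ttest_ind(x, y, equal_var=True)
    else:
        test_name = "Mann-Whitney U"
        stat, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    return GroupComparison(
        stratum=stratum,
        test_name=test_name,
        statistic=float(stat),
        p_value=float(p),
        cohens_d=cohens_d_from_samples(x, y),
        mean_patient=float(x.mean()),
        mean_control=float(y.mean()),
        sd_patient=float(x.std(ddof=1)),
        sd_control=float(y.std(ddof=1)),
        n_patient=int(x.size),
        n_control=int(y.size),
    )


def bonferroni(p_values, m: int | None = None) -> list[float]:
    """Multiply each p by the comparison count m, capping at 1."""
    ps = [float(p) for p in p_values]
    if m is None:
        m = len(ps)
    if m < len(ps):
        raise ValueError(f"m={m} smaller than the number of p-values ({len(ps)})")
    return [min(1.0, p * m) for p in ps]


def icc_2_1(ratings: np.ndarray) -> AgreementResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a subjects x raters matrix with no missing cells.
    """
    mat = np.asarray(ratings, dtype=float)
    if mat.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters matrix")
    n_subj, n_raters = mat.shape
    if n_subj < 5 or n_raters < 2:
        raise ValueError("need >= 5 subjects and >= 2 raters")
    if not np.isfinite(mat).all():
        raise ValueError("ratings matrix contains missing/non-finite cells")
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_raters),
            "rater": np.tile(np.arange(n_raters), n_subj),
            "score": mat.ravel(),
        }
    )
    import warnings as _warnings

    with _warnings.catch_warnings(), np.errstate(divide="ignore", invalid="ignore"):
        _warnings.simplefilter("ignore", RuntimeWarning)
        res = pg.intraclass_corr(
            data=long, targets="subject", raters="rater", ratings="score"
        )
    # Two-way random, absolute agreement, single measure: labelled
    # "ICC2" or "ICC(A,1)" depending on pingouin version.
    mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res.loc[mask].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    ci_low, ci_high = (float(v) for v in row[ci_col])
    icc = float(row["ICC"])
    # The F-based interval degenerates (0/0) under perfect agreement and
    # its endpoints can numerically undershoot the point estimate; fall
    # back to the estimate so ci_low <= icc <= ci_high always holds.
    if not math.isfinite(ci_low):
        ci_low = icc
    if not math.isfinite(ci_high):
        ci_high = icc
    return AgreementResult(icc=icc, ci_low=min(ci_low, icc), ci_high=max(ci_high, icc))


def _tier(p_corrected: float) -> str:
    if p_corrected < 0.005:
        return "Highly Significant (***)"
    if p_corrected < ALPHA:
        return "Significant (**)"
    return "Not Significant"


def combined_condyle_table(cohort: pd.DataFrame, m: int = 8) -> pd.DataFrame:
    """Gender-wise comparison of pooled left+right condyle FD per age band.

    For each of the 8 (age_group, gender) strata, each subject's LC and
    RC values are pooled into one arm per group, compared patient vs
    control, then Bonferroni-corrected over the ``m`` comparisons.
    Significance tiers: corrected p < 0.05 "Significant (**)",
    < 0.005 "Highly Significant (***)".
    """
    df = cohort.copy()
    if "age_group" not in df.columns:
        df["age_group"] = df["age"].map(age_group_of)
    rows = []
    for age_group in AGE_GROUPS:
        for gender in ("male", "female"):
            sel = (df["age_group"] == age_group) & (df["gender"] == gender)
            pat = df[sel & (df["group"] == "patient")]
            ctl = df[sel & (df["group"] == "control")]
            pat_vals = np.concatenate([pat["lc_fd"], pat["rc_fd"]])
            ctl_vals = np.concatenate([ctl["lc_fd"], ctl["rc_fd"]])
            comp = compare_groups(pat_vals, ctl_vals, stratum=f"{age_group}/{gender}")
            rows.append(
                {
                    "age_group": age_group,
                    "gender": gender,
                    "mean_patient": comp.mean_patient,
                    "sd_patient": comp.sd_patient,
                    "mean_control": comp.mean_control,
                    "sd_control": comp.sd_control,
                    "difference": comp.mean_control - comp.mean_patient,
                    "test_name": comp.test_name,
                    "p_value": comp.p_value,
                    "cohens_d": comp.cohens_d,
                }
            )
    out = pd.DataFrame(rows)
    out["p_corrected"] = bonferroni(out["p_value"], m=m)
    out["significance"] = out["p_corrected"].map(_tier)
    return out
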