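"""Two-group cohort comparison battery with Bonferroni control.

For every measure in the family (per tract: the two normalized volumes
and the eight microstructural means; plus TBV and WMV) the comparison
records Shapiro-Wilk normality per group and Levene's homogeneity of
variance as QC, then reports the classic pooled-variance two-sample
Student's t (two-sided), Cohen's d with the df-weighted pooled SD, the
standard effect-size bins at |d| = 0.2 / 0.5 / 0.8, and the relative
difference with the men-mean denominator.  The family-wise threshold is
alpha divided by the family size; with a 77-tract atlas the family is
77 x 10 + 2 = 772 comparisons and the alpha = 0.05 threshold prints as
0.000064767.

Sign convention throughout: positive d or relative difference means the
measure is larger in men.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "RegressionResult",
    "bonferroni_threshold",
    "cohens_d",
    "effect_bin",
    "relative_difference",
    "group_compare",
    "family_size",
    "run_full_comparison",
    "volume_vs_tbv_regression",
]

EFFECT_BINS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"), (np.inf, "large"))
MEASURES_PER_TRACT = 10  # 2 normalized volumes + 8 microstructural means


@dataclass
class ComparisonResult:
    measure: str
    mean_m: float
    sd_m: float
    n_m: int
    mean_f: float
    sd_f: float
    n_f: int
    shapiro_p_m: float
    shapiro_p_f: float
    levene_p: float
    t_stat: float
    p_value: float
    bonferroni_alpha: float
    significant: bool
    cohens_d: float
    effect_bin: str
    relative_difference_pct: float


@dataclass
class RegressionResult:
    slope_m: float
    intercept_m: float
    r2_m: float
    slope_f: float
    intercept_f: float
    r2_f: float
    interaction_f_stat: float
    interaction_p: float


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("family size must be >= 1")
    return alpha / m


def cohens_d(
    mean_m: float, sd_m: float, n_m: int, mean_f: float, sd_f: float, n_f: int
) -> float:
    """Standardized mean difference with the df-weighted pooled SD.

    Positive values mean the measure is larger in men.
    """
    if sd_m <= 0 or sd_f <= 0:
        raise ValueError("standard deviations must be positive")
    if n_m < 2 or n_f < 2:
        raise ValueError("need n >= 2 per group")
    pooled = np.sqrt(((n_m - 1) * sd_m**2 + (n_f - 1) * sd_f**2) / (n_m + n_f - 2))
    if pooled == 0:
        raise ZeroDivisionError("pooled standard deviation is zero; effect size undefined")
    return (mean_m - mean_f) / pooled


def effect_bin(d: float) -> str:
    """Bin |d| at 0.2 / 0.5 / 0.8; boundary values go to the higher bin."""
    if not np.isfinite(d):
        raise ValueError("effect size must be finite")
    a = abs(d)
    for cut, name in EFFECT_BINS:
        if a < cut:
            return name
    return "large"


def relative_difference(mean_m: float, mean_f: float) -> float:
    """100 * (mean_m - mean_f) / mean_m (men-mean denominator), percent."""
    if mean_m == 0:
        raise ZeroDivisionError("men mean is zero; relative difference undefined")
    return 100.0 * (mean_m - mean_f) / mean_m


def group_compare(
    values_m: np.ndarray,
    values_f: np.ndarray,
    bonferroni_alpha: float = 0.05,
    measure: str = "",
) -> ComparisonResult:
    """Full two-group comparison of one measure from raw samples."""
    values_m = np.asarray(values_m, dtype=float)
    values_f = np.asarray(values_f, dtype=float)
    if len(values_m) < 3 or len(values_f) < 3:
        raise ValueError("need at least 3 observations per group")

    def _shapiro(v):
        if np.ptp(v) == 0:
            return float("nan")
        import warnings

        with warnings.catch_warnings():
            # near-identical samples trigger a harmless precision warning
            warnings.simplefilter("ignore", RuntimeWarning)
            return float(sps.shapiro(v).pvalue)

    sh_m, sh_f = _shapiro(values_m), _shapiro(values_f)
    if np.ptp(values_m) > 0 or np.ptp(values_f) > 0:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            lev = float(sps.levene(values_m, values_f, center="mean").pvalue)
    else:
        lev = float("nan")
    import warnings

    with warnings.catch_warnings():
        # near-identical samples trigger a harmless precision warning
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = sps.ttest_ind(values_m, values_f, equal_var=True)
    mean_m, mean_f = values_m.mean(), values_f.mean()
    sd_m, sd_f = values_m.std(ddof=1), values_f.std(ddof=1)
    if sd_m > 0 and sd_f > 0:
        d = cohens_d(mean_m, sd_m, len(values_m), mean_f, sd_f, len(values_f))
    else:
        d = 0.0 if mean_m == mean_f else float("inf") * np.sign(mean_m - mean_f)
    rel = relative_difference(mean_m, mean_f) if mean_m != 0 else float("nan")
    if np.isnan(p):  # identical constant samples
        t, p = 0.0, 1.0
    return ComparisonResult(
        measure=measure,
        mean_m=float(mean_m),
        sd_m=float(sd_m),
        n_m=len(values_m),
        mean_f=float(mean_f),
        sd_f=float(sd_f),
        n_f=len(values_f),
        shapiro_p_m=sh_m,
        shapiro_p_f=sh_f,
        levene_p=lev,
        t_stat=float(t),
        p_value=float(p),
        bonferroni_alpha=bonferroni_alpha,
        significant=bool(p < bonferroni_alpha),
        cohens_d=float(d) if np.isfinite(d) else float(d),
        effect_bin=effect_bin(d) if np.isfinite(d) else "large",
        relative_difference_pct=float(rel),
    )


def family_size(n_tracts: int) -> int:
    """Comparisons in the family: n_tracts x 10 + TBV + WMV."""
    if n_tracts < 1:
        raise ValueError("need at least one tract")
    return n_tracts * MEASURES_PER_TRACT + 2


def run_full_comparison(
    cohort: pd.DataFrame,
    alpha: float = 0.05,
    metric_names: tuple = ("fa", "md", "ad", "rd", "gfa", "ndi", "iwvf", "odi"),
) -> pd.DataFrame:
    """Compare every measure of a tidy cohort table between the sexes.

    ``cohort`` has one row per (subject, tract) with columns ``subject_id``,
    ``sex`` (M/F), ``tract``, ``vol_pct_tbv``, ``vol_pct_wmv``, the metric
    columns, and per-subject ``tbv_cm3`` / ``wmv_cm3``.  Returns one row
    per measure, in stable (tract-sorted) order, with the Bonferroni
    threshold computed from the family size.
    """
    sexes = set(cohort["sex"].unique())
    if not {"M", "F"} <= sexes:
        raise ValueError("cohort must contain both sexes (M and F)")
    tracts = sorted(cohort["tract"].dropna().unique())
    m = family_size(len(tracts))
    thr = bonferroni_threshold(alpha, m)

    subj = cohort.drop_duplicates("subject_id").sort_values("subject_id")
    results = []
    for name, col in (("tbv_cm3", "tbv_cm3"), ("wmv_cm3", "wmv_cm3")):
        vm = subj.loc[subj.sex == "M", col].to_numpy()
        vf = subj.loc[subj.sex == "F", col].to_numpy()
        results.append(group_compare(vm, vf, thr, measure=name))
    measure_cols = ["vol_pct_tbv", "vol_pct_wmv", *metric_names]
    for tract in tracts:
        sub = cohort[cohort.tract == tract].sort_values("subject_id")
        for col in measure_cols:
            vm = sub.loc[sub.sex == "M", col].dropna().to_numpy()
            vf = sub.loc[sub.sex == "F", col].dropna().to_numpy()
            results.append(group_compare(vm, vf, thr, measure=f"{tract}:{col}"))
    df = pd.DataFrame([asdict(r) for r in results])
    df.attrs["family_size"] = m
    df.attrs["bonferroni_threshold"] = thr
    return df


def volume_vs_tbv_regression(
    cohort: pd.DataFrame, tract: str, volume_col: str = "vol_pct_tbv"
) -> RegressionResult:
    """Per-sex OLS of normalized tract volume on TBV, plus the ANCOVA
    sex x TBV interaction (statsmodels OLS, F and p of the interaction)."""
    import statsmodels.formula.api as smf

    sub = cohort[cohort.tract == tract][["subject_id", "sex", "tbv_cm3", volume_col]].dropna()
    if (sub.sex == "M").sum() < 3 or (sub.sex == "F").sum() < 3:
        raise ValueError("need at least 3 subjects per sex")
    fits = {}
    for sex in ("M", "F"):
        g = sub[sub.sex == sex]
        res = sps.linregress(g["tbv_cm3"], g[volume_col])
        fits[sex] = (res.slope, res.intercept, res.rvalue**2)
    data = sub.rename(columns={volume_col: "vol"})
    model = smf.ols("vol ~ tbv_cm3 * C(sex)", data=data).fit()
    name = [c for c in model.params.index if ":" in c][0]
    t_int = model.tvalues[name]
    return RegressionResult(
        slope_m=fits["M"][0],
        intercept_m=fits["M"][1],
        r2_m=fits["M"][2],
        slope_f=fits["F"][0],
        intercept_f=fits["F"][1],
        r2_f=fits["F"][2],
        interaction_f_stat=float(t_int**2),
        interaction_p=float(model.pvalues[name]),
    )
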