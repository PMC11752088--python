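"""Group-level statistical battery for regional microstructure tables.

Covers the analyses of the target study design: independent-samples t-tests
with Hedges' g for MS-vs-HC comparisons, Greenhouse-Geisser-corrected
repeated-measures ANOVA with paired post-hoc t-tests for the within-subject
lesional -> normal-appearing gradient, z-scoring against the healthy-control
distribution, covariate-adjusted linear regression, Benjamini-Hochberg FDR
per analysis family, and cognitive domain-score aggregation.

Sign conventions follow the reporting style of the tables this package
reproduces: mean differences are group B minus group A (MS minus HC) while
Hedges' g is positive when group A (HC) exceeds group B.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["StatResult", "independent_t", "hedges_g_from_summary", "paired_t",
           "rm_anova_gg", "zscore_vs_hc", "adjusted_regression", "bh_fdr",
           "cognition_scores", "group_comparison_table", "within_subject_battery"]


@dataclass
class StatResult:
    label: str
    mean_diff: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    hedges_g: float = np.nan
    statistic: float = np.nan       # t or F
    df: tuple = ()
    p: float = np.nan
    p_corr: float = np.nan
    family: str = ""
    extra: dict = field(default_factory=dict)
    degenerate: bool = False


def _hedges_j(df: float) -> float:
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def hedges_g_from_summary(mean_a: float, sd_a: float, n_a: int,
                          mean_b: float, sd_b: float, n_b: int) -> float:
    """Hedges' g from summary statistics (positive when A exceeds B)."""
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least two observations per group")
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    df = n_a + n_b - 2
    s_pooled = np.sqrt(((n_a - 1) * sd_a ** 2 + (n_b - 1) * sd_b ** 2) / df)
    return _hedges_j(df) * (mean_a - mean_b) / s_pooled


def independent_t(group_a, group_b, label: str = "", family: str = "") -> StatResult:
    """Two-sided pooled-variance t-test of B vs A with Hedges' g.

    Mean difference and CI refer to mean(B) - mean(A); g is positive when
    A exceeds B (the HC-minus-MS convention of the reference tables when
    A is the control group).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per group")
    df = a.size + b.size - 2
    diff = b.mean() - a.mean()
    sp2 = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)) / df
    degenerate = sp2 <= 0
    if degenerate:
        t_stat = np.inf if diff != 0 else 0.0
        p = 0.0 if diff != 0 else 1.0
        half = 0.0
        g = np.nan
    else:
        se = np.sqrt(sp2 * (1.0 / a.size + 1.0 / b.size))
        t_stat = diff / se
        p = 2.0 * sps.t.sf(abs(t_stat), df)
        half = sps.t.ppf(0.975, df) * se
        g = _hedges_j(df) * (a.mean() - b.mean()) / np.sqrt(sp2)
    return StatResult(label=label, mean_diff=float(diff),
                      ci_low=float(diff - half), ci_high=float(diff + half),
                      hedges_g=float(g), statistic=float(t_stat), df=(df,),
                      p=float(p), family=family, degenerate=bool(degenerate))


def paired_t(values_a, values_b, label: str = "", family: str = "") -> StatResult:
    """Two-sided paired t-test on within-subject differences (B - A)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = b - a
    n = d.size
    sd = d.std(ddof=1)
    degenerate = sd <= 0
    if degenerate:
        t_stat = np.inf if d.mean() != 0 else 0.0
        p = 0.0 if d.mean() != 0 else 1.0
        half = 0.0
        g = np.nan
    else:
        se = sd / np.sqrt(n)
        t_stat = d.mean() / se
        p = 2.0 * sps.t.sf(abs(t_stat), n - 1)
        half = sps.t.ppf(0.975, n - 1) * se
        g = _hedges_j(n - 1) * d.mean() / sd
    return StatResult(label=label, mean_diff=float(d.mean()),
                      ci_low=float(d.mean() - half), ci_high=float(d.mean() + half),
                      hedges_g=float(g), statistic=float(t_stat), df=(n - 1,),
                      p=float(p), family=family, degenerate=bool(degenerate))


def rm_anova_gg(matrix, label: str = "", family: str = "") -> StatResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is (subjects x conditions), complete (no missing values).
    The correction is applied unconditionally; the corrected p-value is
    reported as ``p`` and epsilon in ``extra``.
    """
    import pingouin as pg

    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError("need a complete (>=3 subjects) x (>=2 conditions) matrix")
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must be complete")
    n, k = x.shape
    grand = x.mean()
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    if ss_cond <= 1e-15 * max(1.0, abs(grand)):
        # no between-condition variation at all: F = 0 by construction
        return StatResult(label=label, statistic=0.0, df=(float(k - 1),
                                                          float((k - 1) * (n - 1))),
                          p=1.0, family=family,
                          extra={"eps": 1.0, "p_uncorrected_df": 1.0})
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "condition": np.tile(np.arange(k), n),
        "value": x.ravel(),
    })
    aov = pg.rm_anova(data=long, dv="value", within="condition",
                      subject="subject", correction=True, detailed=True)
    row = aov.iloc[0]
    eps = float(row["eps"])
    f_stat = float(row["F"])
    p_gg = float(row["p_GG_corr"]) if "p_GG_corr" in row and np.isfinite(
        row["p_GG_corr"]) else float(row["p_unc"])
    df1 = eps * (k - 1)
    df2 = eps * (k - 1) * (n - 1)
    return StatResult(label=label, statistic=f_stat, df=(df1, df2),
                      p=p_gg, family=family,
                      extra={"eps": eps, "p_uncorrected_df": float(row["p_unc"])})


def zscore_vs_hc(value, hc_mean: float, hc_sd: float):
    """Z-score of a value (or array) against the healthy-control distribution."""
    if hc_sd <= 0:
        raise ValueError("reference SD must be positive")
    return (np.asarray(value, dtype=float) - hc_mean) / hc_sd


def adjusted_regression(outcome, predictor, age, sex, label: str = "",
                        family: str = "") -> StatResult:
    """OLS of outcome on predictor adjusting for age and sex.

    ``sex`` may be numeric or "M"/"F" strings.  Returns the predictor
    coefficient B with its 95% CI and p-value.
    """
    import statsmodels.api as sm

    y = np.asarray(outcome, dtype=float)
    x = np.asarray(predictor, dtype=float)
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "SUO":
        sex = (sex == "M").astype(float)
    sex = sex.astype(float)
    if not (y.size == x.size == age.size == sex.size):
        raise ValueError("unequal lengths")
    if y.size <= 4:
        raise ValueError("need more observations than parameters")
    if np.any(~np.isfinite(np.c_[y, x, age, sex])):
        raise ValueError("missing values")
    design = sm.add_constant(np.column_stack([x, age, sex]),
                             has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient design (constant predictor?)")
    fit = sm.OLS(y, design).fit()
    ci = fit.conf_int()[1]
    return StatResult(label=label, mean_diff=float(fit.params[1]),
                      ci_low=float(ci[0]), ci_high=float(ci[1]),
                      statistic=float(fit.tvalues[1]),
                      df=(float(fit.df_resid),), p=float(fit.pvalues[1]),
                      family=family,
                      extra={"r2": float(fit.rsquared)})


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one analysis family)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def apply_fdr(results: list[StatResult]) -> list[StatResult]:
    """Fill ``p_corr`` within each family of a list of results."""
    families: dict[str, list[int]] = {}
    for i, r in enumerate(results):
        families.setdefault(r.family, []).append(i)
    for idxs in families.values():
        adj = bh_fdr([results[i].p for i in idxs])
        for i, a in zip(idxs, adj):
            results[i].p_corr = float(a)
    return results


def cognition_scores(domain_z: dict | pd.DataFrame,
                     threshold: float = -1.5) -> pd.DataFrame:
    """Average cognition z-score and impairment flags per subject.

    A domain is impaired at z <= threshold (inclusive); a subject is
    impaired when at least one domain is.
    """
    df = pd.DataFrame(domain_z)
    if df.shape[1] == 0:
        raise ValueError("no cognitive domains provided")
    out = pd.DataFrame(index=df.index)
    out["average_z"] = df.mean(axis=1)
    impaired = df.le(threshold)
    out["n_impaired_domains"] = impaired.sum(axis=1)
    out["impaired"] = impaired.any(axis=1)
    return out


# ---------------------------------------------------------------------------
# batteries over RegionTable data frames
# ---------------------------------------------------------------------------

def _region_values(table: pd.DataFrame, group: str, region: str,
                   measure: str) -> pd.Series:
    sel = table[(table.group == group) & (table.region == region)
                & (table.measure == measure) & table["valid"]]
    return sel.set_index("subject_id")["mean"]


def group_comparison_table(table: pd.DataFrame,
                           measures=("f_is", "f_in", "f_ec", "r_s"),
                           regions=("na_cortex", "outer_layer", "inner_layer",
                                    "lesion"),
                           hc_region: str = "cortex",
                           family: str = "group") -> pd.DataFrame:
    """MS regional means vs the HC whole-cortex reference, with FDR.

    Each MS region x measure is compared against the healthy-control
    whole-cortex values by a pooled-variance t-test; one FDR family.
    """
    results = []
    for region in regions:
        for measure in measures:
            hc = _region_values(table, "HC", hc_region, measure).dropna()
            ms = _region_values(table, "MS", region, measure).dropna()
            if hc.size < 2 or ms.size < 2:
                continue
            r = independent_t(hc.values, ms.values,
                              label=f"{region}:{measure}", family=family)
            r.extra.update({"region": region, "measure": measure,
                            "hc_mean": hc.mean(), "hc_sd": hc.std(ddof=1),
                            "ms_mean": ms.mean(), "ms_sd": ms.std(ddof=1),
                            "n_hc": int(hc.size), "n_ms": int(ms.size)})
            results.append(r)
    apply_fdr(results)
    rows = [{"region": r.extra["region"], "measure": r.extra["measure"],
             "hc_mean": r.extra["hc_mean"], "hc_sd": r.extra["hc_sd"],
             "ms_mean": r.extra["ms_mean"], "ms_sd": r.extra["ms_sd"],
             "n_hc": r.extra["n_hc"], "n_ms": r.extra["n_ms"],
             "mean_diff": r.mean_diff, "ci_low": r.ci_low, "ci_high": r.ci_high,
             "hedges_g": r.hedges_g, "t": r.statistic, "p": r.p,
             "p_corr": r.p_corr} for r in results]
    return pd.DataFrame(rows)


def regression_battery(table: pd.DataFrame, lesion_volumes: pd.Series,
                       measures=("f_is", "f_in", "f_ec", "r_s"),
                       family: str = "regression") -> pd.DataFrame:
    """Adjusted regressions of cortical measures on lesion burden.

    For each measure, the MS subjects' whole-cortex value is z-scored
    against the healthy-control distribution and regressed on the
    log10-transformed total cortical-lesion volume, adjusting for age and
    sex; one FDR family.  ``lesion_volumes`` maps subject_id to total
    lesion volume in mL.
    """
    results = []
    for measure in measures:
        hc = _region_values(table, "HC", "cortex", measure).dropna()
        ms = _region_values(table, "MS", "cortex", measure).dropna()
        if hc.size < 3 or ms.size < 5 or hc.std(ddof=1) <= 0:
            continue
        meta = table[(table.group == "MS") & (table.region == "cortex")
                     & (table.measure == measure)].set_index("subject_id")
        ids = [i for i in ms.index if i in lesion_volumes.index
               and lesion_volumes[i] > 0]
        if len(ids) < 5:
            continue
        z = zscore_vs_hc(ms[ids].values, hc.mean(), hc.std(ddof=1))
        logvol = np.log10(lesion_volumes[ids].values)
        r = adjusted_regression(z, logvol, meta.loc[ids, "age"].values,
                                meta.loc[ids, "sex"].values,
                                label=f"z({measure})~log10(CL volume)",
                                family=family)
        r.extra["measure"] = measure
        results.append(r)
    apply_fdr(results)
    rows = [{"measure": r.extra["measure"], "B": r.mean_diff,
             "ci_low": r.ci_low, "ci_high": r.ci_high, "t": r.statistic,
             "p": r.p, "p_corr": r.p_corr} for r in results]
    return pd.DataFrame(rows)


def within_subject_battery(table: pd.DataFrame,
                           measures=("f_is", "f_in", "f_ec", "r_s"),
                           regions=("lesion", "inner_layer", "outer_layer",
                                    "na_cortex"),
                           family: str = "within") -> dict:
    """RM-ANOVA (GG) across regions per measure plus paired post-hocs.

    Subjects missing any region row are excluded listwise.  Returns
    ``{"anova": DataFrame, "posthoc": DataFrame}`` with a single FDR family
    covering the ANOVAs and post-hoc contrasts together.
    """
    results: list[StatResult] = []
    anova_rows, post_rows = [], []
    for measure in measures:
        wide = pd.DataFrame({region: _region_values(table, "MS", region, measure)
                             for region in regions}).dropna()
        if wide.shape[0] < 3:
            continue
        r = rm_anova_gg(wide.values, label=f"rm:{measure}", family=family)
        r.extra.update({"measure": measure, "n": wide.shape[0]})
        results.append(r)
        for i in range(len(regions)):
            for j in range(i + 1, len(regions)):
                pr = paired_t(wide[regions[i]].values, wide[regions[j]].values,
                              label=f"{measure}:{regions[j]}-{regions[i]}",
                              family=family)
                pr.extra.update({"measure": measure, "region_a": regions[i],
                                 "region_b": regions[j], "n": wide.shape[0]})
                results.append(pr)
    apply_fdr(results)
    for r in results:
        if r.label.startswith("rm:"):
            anova_rows.append({"measure": r.extra["measure"], "n": r.extra["n"],
                               "F": r.statistic, "df1": r.df[0], "df2": r.df[1],
                               "eps": r.extra["eps"], "p": r.p,
                               "p_corr": r.p_corr})
        else:
            post_rows.append({"measure": r.extra["measure"],
                              "region_a": r.extra["region_a"],
                              "region_b": r.extra["region_b"],
                              "n": r.extra["n"], "mean_diff": r.mean_diff,
                              "t": r.statistic, "p": r.p, "p_corr": r.p_corr})
    return {"anova": pd.DataFrame(anova_rows), "posthoc": pd.DataFrame(post_rows)}
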