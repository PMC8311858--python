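"""The statistical battery applied to the node metrics.

Four model families mirror the study's analyses of the target node:

* pre-treatment: patient-vs-control group comparison and a severity
  regression, each an OLS fit with age, education, gender and in-scanner
  motion as covariates;
* treatment: an OLS fit of the pre-to-post metric change on treatment arm
  (plus severity and the same covariates), followed by per-arm paired
  t-tests and per-timepoint independent t-tests against controls;
* brain-behavior: behavioral gain regressed on the metric change, arm and
  their interaction (plus severity, age, education, gender), with per-arm
  simple correlations;
* per-module comparisons corrected with the Benjamini-Hochberg FDR
  step-up within one analysis family.

Factor coding is fixed for reproducibility: gender reference F, arm
reference sham, cohort reference HC.  Independent t-tests default to the
pooled-variance (Student) form so df = n1 + n2 - 2; Welch is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps


@dataclass
class StatResult:
    """One fitted model or test: per-term estimates and the test summary."""

    model_id: str
    terms: pd.DataFrame  # index term, columns estimate/se/t/p
    df_resid: float
    n: int
    extra: dict = field(default_factory=dict)

    def term(self, name: str) -> pd.Series:
        for idx in self.terms.index:
            if idx == name or name in idx:
                return self.terms.loc[idx]
        raise KeyError(f"term {name!r} not in model {self.model_id}: "
                       f"{self.terms.index.tolist()}")

    def __repr__(self) -> str:  # compact, log-friendly
        lines = [f"StatResult({self.model_id}, n={self.n}, df={self.df_resid:g})"]
        for idx, row in self.terms.iterrows():
            lines.append(
                f"  {idx}: est={row['estimate']:.4g} t={row['t']:.3g} p={row['p']:.3g}"
            )
        return "\n".join(lines)


_GENDER = "C(gender, Treatment('F'))"
_ARM = "C(arm, Treatment('sham'))"
_COHORT = "C(cohort, Treatment('HC'))"


def _check_covariates(df: pd.DataFrame, cols: list[str]) -> None:
    for col in cols:
        if col not in df.columns:
            raise ValueError(f"missing covariate column: {col}")
        bad = df.loc[df[col].isna()]
        if not bad.empty:
            subjects = bad.get("subject_id", bad.index).tolist()
            raise ValueError(f"missing {col} for subject(s): {subjects}")


def _fit_ols(model_id: str, formula: str, data: pd.DataFrame) -> StatResult:
    fit = smf.ols(formula, data=data).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError(f"rank-deficient design in model {model_id}")
    terms = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    return StatResult(
        model_id=model_id,
        terms=terms,
        df_resid=float(fit.df_resid),
        n=int(fit.nobs),
    )


def pretreatment_model(
    metrics: pd.DataFrame, covariates: pd.DataFrame
) -> tuple[StatResult, StatResult]:
    """Pre-treatment analyses of one node's threshold-averaged metric.

    ``metrics`` needs columns subject_id and value (one row per subject at
    the pre/single timepoint).  Returns two OLS fits:

    (a) ``value ~ cohort + age + education + gender + motion`` over
        controls and patients pooled (cohort term = disease effect);
    (b) ``value ~ severity + age + education + gender + motion`` over
        patients only (severity term = severity association).
    """
    covar_cols = ["age", "education", "gender", "motion_rms"]
    data = metrics.merge(covariates, on="subject_id", how="left")
    _check_covariates(data, covar_cols + ["cohort"])
    fit_cohort = _fit_ols(
        "pretreatment_cohort",
        f"value ~ {_COHORT} + age + education + {_GENDER} + motion_rms",
        data,
    )
    ppa = data[data["cohort"] == "PPA"]
    _check_covariates(ppa, ["severity"])
    fit_severity = _fit_ols(
        "pretreatment_severity",
        f"value ~ severity + age + education + {_GENDER} + motion_rms",
        ppa,
    )
    return fit_cohort, fit_severity


def change_model(delta: pd.DataFrame, covariates: pd.DataFrame) -> StatResult:
    """Arm effect on the pre-to-post change of one node's metric.

    ``delta`` needs columns subject_id and value (post minus pre, one row
    per patient).  Fits ``delta ~ arm + severity + age + education + gender
    + motion``; the arm term is the headline treatment contrast.
    """
    data = delta.merge(covariates, on="subject_id", how="left")
    if (data["arm"] == "none").any() or data["arm"].isna().any():
        bad = data.loc[
            data["arm"].isna() | (data["arm"] == "none"), "subject_id"
        ].tolist()
        raise ValueError(f"change model is patients-only; bad subject(s): {bad}")
    _check_covariates(
        data, ["severity", "age", "education", "gender", "motion_rms"]
    )
    return _fit_ols(
        "change_arm",
        f"value ~ {_ARM} + severity + age + education + {_GENDER} + motion_rms",
        data,
    )


def paired_change_test(pre: np.ndarray, post: np.ndarray) -> StatResult:
    """Classical paired t-test of post vs pre (two-sided).

    A zero within-pair variance with a nonzero mean difference yields an
    infinite t, flagged via a non-finite statistic rather than an error.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    n = pre.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = post - pre
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        t = 0.0 if md == 0 else np.inf * np.sign(md)
        p = 1.0 if md == 0 else 0.0
    else:
        t = md / (sd / np.sqrt(n))
        p = 2 * sps.t.sf(abs(t), df)
    terms = pd.DataFrame(
        {"estimate": [md], "se": [sd / np.sqrt(n) if sd else 0.0],
         "t": [t], "p": [p]},
        index=["mean_change"],
    )
    return StatResult("paired_t", terms, float(df), n)


def independent_group_test(
    a: np.ndarray, b: np.ndarray, welch: bool = False
) -> StatResult:
    """Two-sample t-test of group a vs group b (two-sided).

    Pooled-variance Student form by default (df = n1 + n2 - 2); set
    ``welch=True`` for the unequal-variance form.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    diff = a.mean() - b.mean()
    if welch:
        res = sps.ttest_ind(a, b, equal_var=False)
        t, p, df = float(res.statistic), float(res.pvalue), float(res.df)
        se = diff / t if t != 0 else np.nan
    else:
        n1, n2 = a.size, b.size
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        if se == 0:
            t = 0.0 if diff == 0 else np.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = 2 * sps.t.sf(abs(t), df)
    terms = pd.DataFrame(
        {"estimate": [diff], "se": [se], "t": [t], "p": [p]},
        index=["mean_difference"],
    )
    return StatResult(
        "independent_t" + ("_welch" if welch else ""),
        terms, float(df), int(a.size + b.size),
    )


def brain_behavior_model(
    data: pd.DataFrame, covariates: pd.DataFrame
) -> StatResult:
    """Interaction between metric change and arm in predicting behavioral gain.

    ``data`` needs columns subject_id, delta_pc, behavior_gain (patients
    only, gain on the 0-100 percent-of-maximal-gain scale).  Fits
    ``gain ~ delta_pc * arm + severity + age + education + gender`` and
    reports the interaction term plus per-arm simple Pearson correlations
    in ``extra["simple_slopes"]``.
    """
    covs = covariates.drop(columns=["behavior_gain"], errors="ignore")
    merged = data.merge(covs, on="subject_id", how="left")
    if (merged["arm"] == "none").any() or merged["arm"].isna().any():
        raise ValueError("brain-behavior model is patients-only")
    _check_covariates(merged, ["severity", "age", "education", "gender"])
    if merged["behavior_gain"].isna().any():
        bad = merged.loc[merged["behavior_gain"].isna(), "subject_id"].tolist()
        raise ValueError(f"missing behavior_gain for subject(s): {bad}")
    result = _fit_ols(
        "brain_behavior",
        f"behavior_gain ~ delta_pc * {_ARM} + severity + age + education + {_GENDER}",
        merged,
    )
    slopes = {}
    for arm_name, grp in merged.groupby("arm"):
        if grp["delta_pc"].std(ddof=1) == 0 or grp["behavior_gain"].std(ddof=1) == 0:
            slopes[arm_name] = {"r": 0.0, "p": 1.0, "n": len(grp)}
        else:
            r, p = sps.pearsonr(grp["delta_pc"], grp["behavior_gain"])
            slopes[arm_name] = {"r": float(r), "p": float(p), "n": len(grp)}
    result.extra["simple_slopes"] = slopes
    return result


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    Adjusted p for the i-th smallest of m p-values is
    ``min_{j >= i} (m / j) * p_(j)``, capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    # enforce monotonicity from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def per_module_comparisons(
    patient_counts: pd.DataFrame,
    hc_counts: pd.DataFrame,
    welch: bool = False,
) -> pd.DataFrame:
    """Patient-vs-control comparison of a node's connection counts, module by
    module, FDR-corrected within the family of between-module tests.

    Both inputs need columns module_name, is_own and one count column per
    subject row (long format: subject_id, module_name, is_own, value).
    Returns one row per module with t, raw p and BH-adjusted p (the
    own-module row is reported uncorrected, mirroring an analysis where the
    FDR family is the set of between-module comparisons).
    """
    rows = []
    for mod, grp in patient_counts.groupby("module_name", sort=False):
        hc = hc_counts[hc_counts["module_name"] == mod]
        res = independent_group_test(
            grp["value"].to_numpy(), hc["value"].to_numpy(), welch=welch
        )
        rows.append(
            {
                "module_name": mod,
                "is_own": bool(grp["is_own"].iloc[0]),
                "t": float(res.terms.loc["mean_difference", "t"]),
                "p": float(res.terms.loc["mean_difference", "p"]),
                "df": res.df_resid,
            }
        )
    out = pd.DataFrame(rows)
    between = ~out["is_own"]
    out["p_fdr"] = np.nan
    out.loc[between, "p_fdr"] = bh_fdr(out.loc[between, "p"].to_numpy())
    return out
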