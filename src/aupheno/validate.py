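"""Clinical validation of the AU metrics against clinician ratings.

The primary analysis correlates the three headline metrics (intensity>1
proportion, mean intensity, switch proportion) of each AU with the
clinician-rated facial-affect item, over all participants.  AU28 has no
intensity channel, so the family holds 3 x 18 - 1 = 53 Pearson tests,
corrected two ways: Benjamini-Hochberg q-values and a Bonferroni
threshold of 0.05/53 ~= 0.000943.  Exploratory analyses repeat the family
against social-skill factor scores (all participants) and symptom scores
(cases only), each outcome corrected as its own BH family.  Group
univariate Welch tests, optional covariate adjustment, and the two-stage
antipsychotic-exposure sensitivity analysis complete the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import catalog
from .features import FeatureMatrix

PRIMARY_OUTCOME = "hisoc_item1"
EXPLORATORY_OUTCOMES = (
    "hisoc_f1",
    "hisoc_f2",
    "hisoc_f3",
    "hisoc_f4",
    "hisoc_total",
    "caarms",
    "sans",
)
#: symptom scores measured/interpreted within cases only
CASE_ONLY_OUTCOMES = ("caarms", "sans")


@dataclass(frozen=True)
class ClinicalRecord:
    """One participant's clinician ratings and symptom scores."""

    id: str
    group: str
    sex: str
    ap_status: str
    hisoc_item1: float
    hisoc_f1: float
    hisoc_f2: float
    hisoc_f3: float
    hisoc_f4: float
    hisoc_total: float
    caarms: float
    sans: float | None

    def __post_init__(self) -> None:
        if self.group == "control" and self.sans is not None and not np.isnan(self.sans):
            raise ValueError("controls carry no SANS score")
        if not 1 <= self.hisoc_item1 <= 5:
            raise ValueError("hisoc_item1 is a 1-5 Likert rating")


def read_clinical_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"id", "group", "sex", "ap_status", PRIMARY_OUTCOME}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return df


def pearson_with_p(x, y) -> tuple[int, float, float]:
    """Pearson r with the exact two-sided p (t transform, n-2 df).

    Pairwise complete-case; constant input is an error, not r = 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = stats.pearsonr(x, y)
    return len(x), float(r), float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, in [0, 1])."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def _correlation_family(
    features: FeatureMatrix, clinical: pd.DataFrame, outcome: str, subset: pd.Index | None = None
) -> pd.DataFrame:
    """The 53 metric x AU Pearson tests against one outcome, BH-corrected
    within the family, with the Bonferroni flag at 0.05/m."""
    cl = clinical.set_index("id") if "id" in clinical.columns else clinical
    if outcome not in cl.columns:
        raise ValueError(f"outcome {outcome!r} absent from clinical table")
    ids = features.X.index.intersection(cl.index)
    if subset is not None:
        ids = ids.intersection(subset)
    y = cl.loc[ids, outcome].to_numpy(float)
    if np.mean(~np.isfinite(y)) > 0.5:
        raise ValueError(f"outcome {outcome!r} missing for more than half of participants")
    rows = []
    for metric, au, column in catalog.metric_variables():
        x = features.X.loc[ids, column].to_numpy(float)
        n, r, p = pearson_with_p(x, y)
        rows.append(
            {"metric": metric, "au": catalog.au_label(au), "outcome": outcome, "n": n, "r": r, "p": p}
        )
    out = pd.DataFrame(rows)
    m = len(out)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["bonferroni_significant"] = out["p"] < 0.05 / m
    out.attrs["family_size"] = m
    out.attrs["bonferroni_alpha"] = 0.05 / m
    return out


def primary_validation(features: FeatureMatrix, clinical: pd.DataFrame) -> pd.DataFrame:
    """Headline metric x AU correlations with clinician-rated facial
    affect over all participants (53-test family)."""
    return _correlation_family(features, clinical, PRIMARY_OUTCOME)


def correlation_table_wide(results: pd.DataFrame, value: str = "r") -> pd.DataFrame:
    """Rows = AUs, columns = metrics (presentation layout)."""
    wide = results.pivot(index="au", columns="metric", values=value)
    order = [catalog.au_label(a) for a in catalog.AU_IDS]
    return wide.reindex(order)[[m for m in catalog.METRICS if m in wide.columns]]


def exploratory_correlations(
    features: FeatureMatrix,
    clinical: pd.DataFrame,
    outcomes: tuple[str, ...] = EXPLORATORY_OUTCOMES,
) -> dict[str, pd.DataFrame]:
    """One BH family per outcome; symptom scores restricted to cases."""
    cl = clinical.set_index("id") if "id" in clinical.columns else clinical
    out: dict[str, pd.DataFrame] = {}
    for outcome in outcomes:
        subset = None
        if outcome in CASE_ONLY_OUTCOMES:
            subset = cl.index[cl["group"] == "case"]
            if len(subset) == 0:
                raise ValueError(f"outcome {outcome!r} requires case participants")
        out[outcome] = _correlation_family(features, clinical, outcome, subset=subset)
    return out


def group_univariate_tests(
    features: FeatureMatrix,
    clinical: pd.DataFrame | None = None,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Welch test per feature (case vs control), BH over the family.

    With covariates, a linear model ``feature ~ group + covariates`` adds
    a covariate-adjusted p for the group coefficient.  Constant features
    are reported with an undefined (NaN) statistic.
    """
    y_case = (features.labels == "case").to_numpy()
    if y_case.sum() < 2 or (~y_case).sum() < 2:
        raise ValueError("both groups need at least 2 members")
    X = features.X
    rows = []
    for col in X.columns:
        v = X[col].to_numpy(float)
        a, b = v[y_case], v[~y_case]
        if v.std() == 0:
            t = p = np.nan
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "feature": col,
                "case_mean": a.mean(),
                "case_sd": a.std(ddof=1),
                "control_mean": b.mean(),
                "control_sd": b.std(ddof=1),
                "t": t,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    defined = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[defined.to_numpy()] = bh_adjust(out.loc[defined, "p"].to_numpy())
    out["q"] = q

    if covariates:
        if clinical is None:
            raise ValueError("covariate adjustment needs the clinical table")
        cl = clinical.set_index("id") if "id" in clinical.columns else clinical
        cl = cl.loc[X.index]
        design = pd.DataFrame({"group": y_case.astype(float)}, index=X.index)
        for cov in covariates:
            col = cl[cov]
            design[cov] = pd.factorize(col)[0].astype(float) if col.dtype == object else col.astype(float)
        design = sm.add_constant(design)
        adj = []
        for col in X.columns:
            if X[col].std() == 0:
                adj.append(np.nan)
                continue
            fit = sm.OLS(X[col].to_numpy(float), design).fit()
            adj.append(float(fit.pvalues["group"]))
        out["p_adjusted"] = adj
    return out


def ap_sensitivity(
    features: FeatureMatrix, clinical: pd.DataFrame, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Two-stage antipsychotic-exposure sensitivity analysis.

    Stage 1: AP-naive vs AP-exposed cases, Welch test on every headline
    metric variable.  Stage 2, gated on stage-1 significance (p < alpha,
    uncorrected): each case subgroup vs controls on the flagged variables.
    """
    cl = clinical.set_index("id") if "id" in clinical.columns else clinical
    cl = cl.loc[features.X.index]
    is_case = (cl["group"] == "case").to_numpy()
    naive = is_case & (cl["ap_status"] == "naive").to_numpy()
    exposed = is_case & (cl["ap_status"] == "exposed").to_numpy()
    control = ~is_case
    for name, mask in (("AP-naive", naive), ("AP-exposed", exposed)):
        if mask.sum() < 2:
            raise ValueError(
                f"{name} subgroup has {int(mask.sum())} member(s); "
                "the sensitivity analysis needs both case subgroups"
            )

    def welch(mask_a, mask_b, col):
        va = features.X.loc[mask_a, col].to_numpy(float)
        vb = features.X.loc[mask_b, col].to_numpy(float)
        if np.concatenate([va, vb]).std() == 0:
            return np.nan, np.nan
        t, p = stats.ttest_ind(va, vb, equal_var=False)
        return float(t), float(p)

    stage1 = []
    for metric, au, column in catalog.metric_variables():
        t, p = welch(naive, exposed, column)
        stage1.append(
            {
                "metric": metric,
                "au": catalog.au_label(au),
                "variable": column,
                "t_naive_vs_exposed": t,
                "p": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    s1 = pd.DataFrame(stage1)
    s1.attrs["gate_alpha"] = alpha

    stage2 = []
    for _, row in s1[s1["significant"]].iterrows():
        for label, mask in (("naive_vs_control", naive), ("exposed_vs_control", exposed)):
            t, p = welch(mask, control, row["variable"])
            stage2.append(
                {
                    "variable": row["variable"],
                    "comparison": label,
                    "t": t,
                    "p": p,
                    "significant": bool(p < alpha) if np.isfinite(p) else False,
                }
            )
    s2 = pd.DataFrame(stage2, columns=["variable", "comparison", "t", "p", "significant"])
    return {"stage1": s1, "stage2": s2}


@dataclass
class ValidationResults:
    """Results bundle for :class:`ExpressivityValidation`."""

    primary: pd.DataFrame
    exploratory: dict[str, pd.DataFrame]
    group_tests: pd.DataFrame
    ap: dict[str, pd.DataFrame] | None

    def summary(self) -> str:
        prim = self.primary
        m = prim.attrs["family_size"]
        lines = [
            "Clinical validation of AU metrics",
            "=" * 50,
            f"primary family: {m} Pearson tests vs {PRIMARY_OUTCOME}",
            f"Bonferroni per-test alpha: {prim.attrs['bonferroni_alpha']:.6f}",
            f"FDR-significant (q < 0.05): {int((prim['q'] < 0.05).sum())}",
            f"Bonferroni-significant:     {int(prim['bonferroni_significant'].sum())}",
            "-" * 50,
            "group Welch tests with q < 0.05: "
            f"{int((self.group_tests['q'] < 0.05).sum())} of {len(self.group_tests)}",
        ]
        if self.ap is not None:
            n_gate = int(self.ap["stage1"]["significant"].sum())
            lines.append(f"AP sensitivity: {n_gate} variable(s) passed stage 1")
        return "\n".join(lines)


class ExpressivityValidation:
    """Model object joining the feature matrix with the clinical table.

    ``fit()`` runs the primary, exploratory, group-difference and (when
    both case subgroups exist) antipsychotic-sensitivity analyses.
    """

    def __init__(self, features: FeatureMatrix, clinical: pd.DataFrame):
        self.features = features
        self.clinical = clinical

    def fit(self, covariates: list[str] | None = None) -> ValidationResults:
        ap = None
        cl = self.clinical.set_index("id") if "id" in self.clinical.columns else self.clinical
        status = cl.loc[cl["group"] == "case", "ap_status"]
        if (status == "naive").sum() >= 2 and (status == "exposed").sum() >= 2:
            ap = ap_sensitivity(self.features, self.clinical)
        return ValidationResults(
            primary=primary_validation(self.features, self.clinical),
            exploratory=exploratory_correlations(self.features, self.clinical),
            group_tests=group_univariate_tests(self.features, self.clinical, covariates),
            ap=ap,
        )
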