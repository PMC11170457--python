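"""Descriptive group comparisons and JIVE-score logistic regressions.

Two deliverables mirror the standard reporting layout for this kind of
cohort analysis:

* a descriptive table of features/covariates by diagnostic group, with
  chi-square tests for categorical rows and one-way ANOVA for continuous
  ones; plus pooling helpers that recombine per-group counts and means into
  whole-cohort summaries;
* logistic regressions of an MDD contrast (lifetime / current / remitted,
  each against the no-MDD group as a separate fit) on the nine standardized
  JIVE scores simultaneously, adjusted for age, sex, BMI, current anxiety
  and current substance use disorder (optionally current medication).
  Scores enter per 1 SD, so ``exp(coef)`` is the odds ratio per SD.  Wald
  95% CIs and p-values are reported; a Benjamini-Hochberg adjusted column
  is emitted alongside for transparency but the headline p-values are
  unadjusted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

DEFAULT_COVARIATES = ("age", "sex", "bmi", "anxiety", "sud")
CONTRASTS = {"lifetime": ("current", "remitted"),
             "current": ("current",),
             "remitted": ("remitted",)}


def pooled_percent(counts: dict[str, float], ns: dict[str, float]) -> float:
    """Overall percentage of a category from per-group counts and sizes."""
    groups = list(ns)
    return 100.0 * sum(counts[g] for g in groups) / sum(ns[g] for g in groups)


def pooled_mean(means: dict[str, float], ns: dict[str, float]) -> float:
    """Size-weighted overall mean from per-group means."""
    groups = list(ns)
    return sum(ns[g] * means[g] for g in groups) / sum(ns[g] for g in groups)


@dataclass
class DescriptiveRow:
    variable: str
    kind: str  # "categorical" or "continuous"
    per_group: dict[str, tuple[float, float]]  # mean/sd or count/pct
    statistic: float
    p_value: float


def descriptive_table(
    data: pd.DataFrame,
    group_col: str = "group",
    *,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
) -> pd.DataFrame:
    """Group comparison table: chi-square for categorical variables, one-way
    ANOVA for continuous ones.  Percentages use group denominators.  A
    continuous row with any group of n < 2 gets a missing p-value."""
    groups = list(pd.unique(data[group_col]))
    if len(groups) < 2 or data[group_col].value_counts().min() == 0:
        raise ValueError("need at least 2 non-empty groups")
    categorical = categorical or []
    continuous = continuous or []
    rows = []
    for var in categorical:
        tab = pd.crosstab(data[var], data[group_col])
        if tab.shape[0] > 1:
            chi2, p, _, _ = stats.chi2_contingency(tab.to_numpy(), correction=False)
        else:
            chi2, p = 0.0, 1.0
        per_group = {}
        for g in groups:
            n_g = int((data[group_col] == g).sum())
            top = tab[g].iloc[-1] if g in tab.columns else 0
            per_group[g] = (float(top), 100.0 * float(top) / n_g)
        rows.append(DescriptiveRow(var, "categorical", per_group, float(chi2), float(p)))
    for var in continuous:
        samples = [data.loc[data[group_col] == g, var].dropna().to_numpy()
                   for g in groups]
        per_group = {g: (float(np.mean(s)) if s.size else np.nan,
                         float(np.std(s, ddof=1)) if s.size > 1 else np.nan)
                     for g, s in zip(groups, samples)}
        if min(s.size for s in samples) < 2:
            f, p = np.nan, np.nan
        elif all(np.allclose(s, samples[0].mean()) for s in samples):
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*samples)
        rows.append(DescriptiveRow(var, "continuous", per_group, float(f), float(p)))
    out = []
    for r in rows:
        rec = {"variable": r.variable, "kind": r.kind,
               "statistic": r.statistic, "p_value": r.p_value}
        for g, (a, b) in r.per_group.items():
            rec[f"{g}_1"] = a  # mean or count
            rec[f"{g}_2"] = b  # sd or percent
        out.append(rec)
    return pd.DataFrame(out)


@dataclass
class AssociationResult:
    """Odds ratios for one MDD contrast on the JIVE scores."""

    contrast: str
    table: pd.DataFrame  # predictor, OR, ci_low, ci_high, p, p_bh
    n_case: int
    n_control: int
    covariates: list[str]
    converged: bool
    warnings: list[str] = field(default_factory=list)


def _design_from_covariates(cov: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    X = pd.DataFrame(index=cov.index)
    for c in covariates:
        col = cov[c]
        if c == "sex":
            X["sex"] = (col == "male").astype(float)
        elif col.dtype == bool:
            X[c] = col.astype(float)
        else:
            X[c] = col.astype(float)
    return X


def logistic_table(
    X: pd.DataFrame, y: np.ndarray, *, score_cols: list[str] | None = None
) -> tuple[pd.DataFrame, bool, list[str]]:
    """Maximum-likelihood logistic fit; returns (per-predictor table,
    converged flag, warnings).  Separation or non-convergence is flagged,
    never silently dropped."""
    warnings: list[str] = []
    Xc = sm.add_constant(X, has_constant="add")
    model = sm.Logit(np.asarray(y, dtype=float), Xc)
    try:
        res = model.fit(disp=0, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", False))
    except Exception:
        # singular Hessian (e.g. a near-empty binary covariate): quasi-Newton
        # is slower but does not invert the Hessian at every step
        try:
            res = model.fit(disp=0, method="bfgs", maxiter=500)
            converged = bool(res.mle_retvals.get("converged", False))
            warnings.append("Newton failed; fell back to BFGS")
        except Exception as exc:  # perfect separation, ...
            warnings.append(f"logistic fit failed: {exc}")
            empty = pd.DataFrame(columns=["predictor", "OR", "ci_low",
                                          "ci_high", "p", "p_bh"])
            return empty, False, warnings
    if not converged:
        warnings.append("maximum-likelihood iteration did not converge")
    if np.any(np.abs(res.params.drop("const")) > 15):
        warnings.append("extreme coefficients suggest separation")
        converged = False
    keep = score_cols if score_cols is not None else [c for c in X.columns]
    coef = res.params[keep]
    se = res.bse[keep]
    tab = pd.DataFrame({
        "predictor": keep,
        "OR": np.exp(coef.to_numpy()),
        "ci_low": np.exp(coef.to_numpy() - 1.959963984540054 * se.to_numpy()),
        "ci_high": np.exp(coef.to_numpy() + 1.959963984540054 * se.to_numpy()),
        "p": res.pvalues[keep].to_numpy(),
    })
    tab["p_bh"] = multipletests(tab["p"].to_numpy(), method="fdr_bh")[1]
    return tab, converged, warnings


def jive_logistic(
    scores: pd.DataFrame,
    covariate_table: pd.DataFrame,
    contrast: str = "lifetime",
    *,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    with_medication: bool = False,
) -> AssociationResult:
    """Fit one MDD contrast (vs the no-MDD group) on all JIVE scores at once.

    ``scores`` rows must be indexed by subject like ``covariate_table``.
    Only subjects in the contrast's case group or the ``none`` group enter
    the fit; odds ratios are per 1 SD of each score.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    cov_list = list(covariates) + (["medication"] if with_medication else [])
    case_groups = CONTRASTS[contrast]
    cov = covariate_table.loc[scores.index]
    mask = cov["group"].isin(case_groups) | (cov["group"] == "none")
    cov = cov[mask]
    sc = scores.loc[cov.index]
    y = cov["group"].isin(case_groups).to_numpy()
    X = pd.concat([sc, _design_from_covariates(cov, cov_list)], axis=1)
    tab, converged, warn = logistic_table(X, y, score_cols=list(scores.columns))
    return AssociationResult(
        contrast=contrast, table=tab,
        n_case=int(y.sum()), n_control=int((~y).sum()),
        covariates=cov_list, converged=converged, warnings=warn,
    )
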