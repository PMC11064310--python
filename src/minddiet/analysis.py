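"""Statistical workflow: score grouping, descriptives, group comparisons,
correlations, per-component contrasts, hierarchical logistic regression,
imputation, and normality checks.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ScoreGroupAssignment",
    "ModelSpec",
    "RegressionResult",
    "SeparationError",
    "assign_score_groups",
    "describe_groups",
    "compare_continuous",
    "compare_categorical",
    "correlate_score_cognition",
    "fit_hierarchical_logistic",
    "default_model_specs",
    "compare_components",
    "impute_missing",
    "pool_rubin",
    "normality_check",
]


class SeparationError(RuntimeError):
    """Perfect (or quasi-perfect) separation in a logistic fit."""


# ---------------------------------------------------------------------------
# score groups


@dataclass(frozen=True)
class ScoreGroupAssignment:
    labels: np.ndarray  # "T1".."Tk" per observation
    boundaries: tuple[float, ...]  # k-1 sample quantiles
    k: int

    def sizes(self) -> dict[str, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def assign_score_groups(scores, k: int = 4) -> ScoreGroupAssignment:
    """Quantile groups T1..Tk; a score tied with a boundary goes low.

    Boundaries are the 1/k .. (k-1)/k empirical quantiles (linear
    interpolation); group j collects scores in (q_{j-1}, q_j].
    """
    scores = np.asarray(scores, dtype=float)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if np.isnan(scores).any():
        raise ValueError("scores contain missing values")
    if np.unique(scores).size < k:
        raise ValueError(f"need at least {k} distinct score values, got {np.unique(scores).size}")
    boundaries = np.quantile(scores, [i / k for i in range(1, k)])
    idx = np.searchsorted(boundaries, scores, side="left")
    labels = np.array([f"T{i + 1}" for i in idx])
    return ScoreGroupAssignment(labels=labels, boundaries=tuple(boundaries.tolist()), k=k)


# ---------------------------------------------------------------------------
# descriptives and univariate comparisons


def _groups_of(df: pd.DataFrame, group_col: str, var: str) -> list[np.ndarray]:
    out = []
    for _, sub in df.groupby(group_col, sort=True, observed=True):
        out.append(pd.to_numeric(sub[var], errors="coerce").dropna().to_numpy())
    return out


def describe_groups(
    df: pd.DataFrame,
    group_col: str,
    continuous: Sequence[str] = (),
    categorical: Sequence[str] = (),
) -> pd.DataFrame:
    """Tidy per-group summaries: mean/sd for continuous, n (%) for categorical."""
    if df.empty:
        raise ValueError("empty cohort")
    group_levels = sorted(df[group_col].dropna().unique().tolist())
    for g in group_levels:
        if (df[group_col] == g).sum() == 0:  # pragma: no cover
            raise ValueError(f"empty group {g!r}")
    rows = []
    for var in continuous:
        for g in group_levels:
            vals = pd.to_numeric(df.loc[df[group_col] == g, var], errors="coerce").dropna()
            if len(vals) == 0:
                raise ValueError(f"group {g!r} has no observations for {var!r}")
            rows.append(
                dict(variable=var, level="", group=str(g), n=len(vals),
                     mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                     pct=np.nan)
            )
    for var in categorical:
        sub = df[[group_col, var]].dropna()
        for g in group_levels:
            gsub = sub.loc[sub[group_col] == g, var]
            denom = len(gsub)
            for level in sorted(sub[var].unique().tolist()):
                n = int((gsub == level).sum())
                rows.append(
                    dict(variable=var, level=str(level), group=str(g), n=n,
                         mean=np.nan, sd=np.nan,
                         pct=100.0 * n / denom if denom else np.nan)
                )
    return pd.DataFrame(rows)


def compare_continuous(
    df: pd.DataFrame, group_col: str, var: str, test: str = "anova"
) -> tuple[float, float]:
    """One-way ANOVA across >=2 groups, or two-sided Mann-Whitney for 2."""
    groups = [g for g in _groups_of(df, group_col, var)]
    if test == "anova":
        if len(groups) < 2:
            raise ValueError("anova needs at least 2 groups")
        if any(len(g) < 2 for g in groups):
            raise ValueError("anova needs >= 2 observations per group")
        res = stats.f_oneway(*groups)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        if len(groups) != 2:
            raise ValueError(f"mann_whitney needs exactly 2 groups, got {len(groups)}")
        a, b = groups
        pooled = np.concatenate([a, b])
        exact = max(len(a), len(b)) <= 20 and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if exact else "asymptotic",
            use_continuity=False,
        )
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


def compare_categorical(df: pd.DataFrame, group_col: str, var: str) -> tuple[float, float]:
    """Pearson chi-square on the crosstab, no continuity correction."""
    sub = df[[group_col, var]].dropna()
    table = pd.crosstab(sub[var], sub[group_col])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"contingency table for {var!r} has an empty/degenerate margin")
    res = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(res[0]), float(res[1])


def correlate_score_cognition(
    df: pd.DataFrame, score_col: str, test_cols: Sequence[str]
) -> pd.DataFrame:
    """Pearson r (two-sided t-test p) of the diet score against each test."""
    rows = []
    for col in test_cols:
        sub = df[[score_col, col]].dropna()
        if len(sub) < 3:
            raise ValueError(f"need >= 3 paired observations for {col!r}")
        x, y = sub[score_col].to_numpy(float), sub[col].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"constant input for correlation with {col!r}")
        r, p = stats.pearsonr(x, y)
        rows.append(dict(test=col, n=len(sub), r=float(r), p=float(p)))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# hierarchical logistic regression


@dataclass(frozen=True)
class ModelSpec:
    """One block of the hierarchical regression."""

    label: str
    covariates: tuple[str, ...]


def default_model_specs() -> tuple[ModelSpec, ...]:
    """The three nested adjustment blocks."""
    m1 = ("age", "education_years", "household_income", "smoking")
    m2 = m1 + ("iadl", "gds15", "hypertension", "diabetes")
    m3 = m2 + ("bmi",)
    return (ModelSpec("Model1", m1), ModelSpec("Model2", m2), ModelSpec("Model3", m3))


@dataclass
class RegressionResult:
    label: str
    table: pd.DataFrame  # term, coef, se, or_, ci_low, ci_high, p
    llf: float
    n: int

    def term(self, name: str) -> pd.Series:
        hit = self.table.loc[self.table["term"] == name]
        if hit.empty:
            raise KeyError(name)
        return hit.iloc[0]


def _check_nested(specs: Sequence[ModelSpec]) -> None:
    for prev, nxt in zip(specs, specs[1:]):
        if not set(prev.covariates) <= set(nxt.covariates):
            raise ValueError(f"model specs not nested: {prev.label} not within {nxt.label}")


def _level_key(label) -> tuple:
    s = str(label)
    m = re.fullmatch(r"([A-Za-z]*)(\d+)", s)
    return (m.group(1), int(m.group(2))) if m else (s, -1)


def fit_hierarchical_logistic(
    df: pd.DataFrame,
    specs: Optional[Sequence[ModelSpec]] = None,
    outcome: str = "true_mci",
    group_col: Optional[str] = "score_group",
) -> list[RegressionResult]:
    """Fit each nested block by ML on the common complete-case subsample.

    Score-group indicators (reference = lowest label) enter every block;
    pass ``group_col=None`` to fit covariate-only blocks.  Wald 95% CIs
    (z = 1.96) and two-sided Wald p-values per term.
    """
    specs = list(specs) if specs is not None else list(default_model_specs())
    _check_nested(specs)
    all_cols = [outcome] + ([group_col] if group_col else [])
    all_cols += sorted({c for s in specs for c in s.covariates})
    all_cols = list(dict.fromkeys(all_cols))
    data = df[all_cols].copy()
    for col in all_cols:
        if col != group_col:
            data[col] = pd.to_numeric(data[col], errors="coerce")
    data = data.dropna()
    y = data[outcome].astype(float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    if group_col:
        levels = sorted(data[group_col].unique().tolist(), key=_level_key)
        dummies = pd.get_dummies(data[group_col], prefix="group", prefix_sep=":")[
            [f"group:{lv}" for lv in levels[1:]]
        ].astype(float)
    else:
        dummies = pd.DataFrame(index=data.index)

    results = []
    for spec in specs:
        X = pd.concat([dummies, data[list(spec.covariates)].astype(float)], axis=1)
        X = sm.add_constant(X, has_constant="add")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # statsmodels raises on hard separation
            raise SeparationError(f"{spec.label}: logistic fit failed ({exc})") from exc
        params = fit.params.drop("const")
        if (params.abs() > 30).any() or fit.bse.drop("const").gt(1e3).any():
            worst = params.abs().idxmax()
            raise SeparationError(f"{spec.label}: separation suspected on term {worst!r}")
        coef = fit.params
        se = fit.bse
        terms = [t for t in coef.index if t != "const"]
        table = pd.DataFrame(
            dict(
                term=terms,
                coef=[coef[t] for t in terms],
                se=[se[t] for t in terms],
                or_=[math.exp(coef[t]) for t in terms],
                ci_low=[math.exp(coef[t] - 1.96 * se[t]) for t in terms],
                ci_high=[math.exp(coef[t] + 1.96 * se[t]) for t in terms],
                p=[float(fit.pvalues[t]) for t in terms],
            )
        )
        results.append(RegressionResult(label=spec.label, table=table, llf=float(fit.llf), n=len(y)))
    return results


# ---------------------------------------------------------------------------
# per-component contrasts


def compare_components(
    df: pd.DataFrame,
    component_ids: Sequence[str],
    status_col: str = "true_mci",
    total_col: str = "diet_total",
) -> pd.DataFrame:
    """Mean +/- sd of each component score (and the total) by outcome group,
    with two-sided Mann-Whitney p-values."""
    rows = []
    for cid in list(component_ids) + [None]:
        col = total_col if cid is None else f"score_{cid}"
        sub = df[[status_col, col]].dropna()
        non = sub.loc[sub[status_col] == 0, col].to_numpy(float)
        mci = sub.loc[sub[status_col] == 1, col].to_numpy(float)
        _, p = compare_continuous(sub, status_col, col, test="mann_whitney")
        rows.append(
            dict(
                component="total" if cid is None else cid,
                mean_all=float(sub[col].mean()), sd_all=float(sub[col].std(ddof=1)),
                mean_non_mci=float(non.mean()), sd_non_mci=float(non.std(ddof=1)),
                mean_mci=float(mci.mean()), sd_mci=float(mci.std(ddof=1)),
                p=p,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# missing data


def impute_missing(
    df: pd.DataFrame,
    method: str = "complete_case",
    variables: Optional[Sequence[str]] = None,
    m: int = 5,
    seed: int = 0,
    n_iter: int = 5,
):
    """Return an analysis-ready cohort (or a list of m cohorts).

    complete_case   drop rows missing any analysis variable
    single_mean_mode fill continuous with the mean, categorical with the mode
    multiple_imputation(m) Gaussian chained-equations draws; pool downstream
    estimates with :func:`pool_rubin`
    """
    if variables is None:
        variables = [c for c in df.columns if df[c].isna().any()]
    variables = list(variables)
    for v in variables:
        if df[v].isna().all():
            raise ValueError(f"variable {v!r} is entirely missing")
    if method == "complete_case":
        out = df.dropna(subset=variables).copy() if variables else df.copy()
        out.attrs["dropped_rows"] = len(df) - len(out)
        return out
    if method == "single_mean_mode":
        out = df.copy()
        for v in variables:
            col = out[v]
            if pd.api.types.is_numeric_dtype(col):
                out[v] = col.fillna(float(col.mean()))
            else:
                out[v] = col.fillna(col.mode(dropna=True).iloc[0])
        return out
    if method == "multiple_imputation":
        return _mice_gaussian(df, variables, m=m, seed=seed, n_iter=n_iter)
    raise ValueError(f"unknown imputation method {method!r}")


def _mice_gaussian(df, variables, m: int, seed: int, n_iter: int) -> list[pd.DataFrame]:
    """Chained-equations draws with Gaussian conditionals.

    Each target variable is regressed on the other (currently completed)
    numeric variables; coefficients are drawn from their sampling normal and
    missing cells from the resulting predictive distribution.  Non-numeric
    variables are left untouched.
    """
    num_vars = [v for v in variables if pd.api.types.is_numeric_dtype(
        pd.to_numeric(df[v], errors="coerce"))]
    work_base = df[num_vars].apply(pd.to_numeric, errors="coerce")
    masks = {v: work_base[v].isna().to_numpy() for v in num_vars}
    preds = {v: [w for w in num_vars if w != v] for v in num_vars}
    out = []
    for imp in range(m):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x4D494345, imp]))
        work = work_base.copy()
        for v in num_vars:  # initial fill: random draws from observed values
            obs = work[v].dropna().to_numpy()
            work.loc[masks[v], v] = rng.choice(obs, size=masks[v].sum(), replace=True)
        for _ in range(n_iter):
            for v in num_vars:
                if not masks[v].any():
                    continue
                X = np.column_stack([np.ones(len(work))] + [work[w].to_numpy() for w in preds[v]])
                yv = work[v].to_numpy()
                obs = ~masks[v]
                beta, *_ = np.linalg.lstsq(X[obs], yv[obs], rcond=None)
                resid = yv[obs] - X[obs] @ beta
                dof = max(obs.sum() - X.shape[1], 1)
                sigma = float(np.sqrt(resid @ resid / dof))
                try:
                    cov = sigma**2 * np.linalg.inv(X[obs].T @ X[obs])
                    bdraw = rng.multivariate_normal(beta, cov, method="cholesky")
                except np.linalg.LinAlgError:
                    bdraw = beta
                draw = X[masks[v]] @ bdraw + sigma * rng.standard_normal(masks[v].sum())
                work.loc[masks[v], v] = draw
        completed = df.copy()
        for v in num_vars:
            completed[v] = work[v]
        out.append(completed)
    return out


def pool_rubin(estimates: Sequence[float], variances: Sequence[float]) -> dict:
    """Rubin's rules: pooled point estimate and total variance."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    m = len(q)
    if m < 2:
        raise ValueError("need at least 2 imputations to pool")
    qbar = float(q.mean())
    within = float(u.mean())
    between = float(q.var(ddof=1))
    total = within + (1 + 1 / m) * between
    return dict(estimate=qbar, within=within, between=between, variance=total)


# ---------------------------------------------------------------------------
# normality


def normality_check(values) -> tuple[float, float]:
    """One-sample KS statistic against N(sample mean, sample sd)."""
    v = pd.to_numeric(pd.Series(values), errors="coerce").dropna().to_numpy(float)
    if len(v) < 5:
        raise ValueError("need at least 5 observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant input")
    res = stats.kstest(v, "norm", args=(v.mean(), sd))
    return float(res.statistic), float(res.pvalue)
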