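"""Linear models linking feather deuterium to ancestry class, date and sex.

Fits ordinary least squares of d2H_f on genetic class (categorical, pure wild
as the reference level), harvest day (4 October = day 0) and sex, with type-II
F-tests per term; sex is dropped and the model refitted when its F-test is
non-significant. Pairwise class differences use a Tukey HSD test on
least-squares (model-adjusted) class means via the studentized-range
distribution. The date effect is summarized as the model-predicted change in
d2H_f across the harvest season.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

DEFAULT_CLASSES = ("WILD", "FX_WMA", "F3_WMA")
SEASON_DAY_SPAN = 76  # 4 October (day 0) to 19 December


@dataclass
class ModelFit:
    """OLS fit of d2H_f on class (+ day, + sex when significant)."""

    params: pd.DataFrame  # term, estimate, se, ci_low, ci_high
    anova: pd.DataFrame  # term-level type-II F tests
    resid_df: int
    classes: list[str]
    sex_included: bool
    sex_pvalue: float | None
    result: object = field(repr=False)  # statsmodels results object
    data: pd.DataFrame = field(repr=False, default=None)

    def coefficient(self, term: str) -> float:
        row = self.params.loc[self.params["term"] == term]
        if row.empty:
            raise KeyError(f"term {term!r} not in model")
        return float(row["estimate"].iloc[0])


@dataclass
class TukeyResult:
    table: pd.DataFrame  # group1, group2, estimate, se, q, p_adj

    def p_adjusted(self, a: str, b: str) -> float:
        t = self.table
        hit = t[((t.group1 == a) & (t.group2 == b)) | ((t.group1 == b) & (t.group2 == a))]
        if hit.empty:
            raise KeyError(f"no contrast {a} vs {b}")
        return float(hit["p_adj"].iloc[0])


def _class_term(ref: str = "WILD") -> str:
    return f'C(klass, Treatment("{ref}"))'


def fit_model(
    samples: pd.DataFrame,
    classes_included: tuple[str, ...] = DEFAULT_CLASSES,
    alpha: float = 0.05,
    reference: str = "WILD",
    drop_nonsig_sex: bool = True,
    include_day: bool = True,
) -> ModelFit:
    """OLS of d2hf ~ class + day (+ sex); sex dropped if its F-test p > alpha.

    ``samples`` needs columns sample_id, d2hf, day, sex, klass. Classes not in
    ``classes_included`` are excluded (report them descriptively instead; see
    :func:`descriptive_stats`). ``include_day=False`` fits the one-way
    class-only model (useful when harvest date is constant).
    """
    data = samples[samples["klass"].isin(classes_included)].copy()
    present = sorted(data["klass"].unique())
    if len(present) < 2:
        raise ValueError("need >= 2 classes with data")
    if reference not in present:
        raise ValueError(f"reference class {reference!r} absent from data")
    cls = _class_term(reference)
    has_sex = data["sex"].nunique() > 1
    day_term = " + day" if include_day else ""
    formula = f"d2hf ~ {cls}{day_term}" + (" + C(sex)" if has_sex else "")
    res = smf.ols(formula, data=data).fit()
    _check_rank(res)
    anova = sm.stats.anova_lm(res, typ=2)
    sex_p = None
    if has_sex:
        sex_p = float(anova.loc["C(sex)", "PR(>F)"])
        if drop_nonsig_sex and sex_p > alpha:
            res = smf.ols(f"d2hf ~ {cls}{day_term}", data=data).fit()
            _check_rank(res)
            anova = sm.stats.anova_lm(res, typ=2)
    params = _tidy_params(res, reference)
    return ModelFit(
        params=params,
        anova=anova,
        resid_df=int(res.df_resid),
        classes=present,
        sex_included="C(sex)" in res.model.formula,
        sex_pvalue=sex_p,
        result=res,
        data=data,
    )


def _check_rank(res) -> None:
    X = res.model.exog
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix rank deficient ({rank} < {X.shape[1]}): "
            f"confounded terms among {list(res.model.exog_names)}"
        )


def _tidy_params(res, reference: str) -> pd.DataFrame:
    ci = res.conf_int(alpha=0.05)
    rows = []
    for name in res.params.index:
        term = _pretty_term(name)
        rows.append(
            {
                "term": term,
                "estimate": float(res.params[name]),
                "se": float(res.bse[name]),
                "ci_low": float(ci.loc[name, 0]),
                "ci_high": float(ci.loc[name, 1]),
            }
        )
    # the reference class carries coefficient 0 by construction
    rows.append({"term": reference, "estimate": 0.0, "se": 0.0,
                 "ci_low": 0.0, "ci_high": 0.0})
    return pd.DataFrame(rows)


def _pretty_term(name: str) -> str:
    if name == "Intercept":
        return "Intercept"
    if name.startswith("C(klass"):
        return name.split("[T.")[1].rstrip("]")
    if name.startswith("C(sex"):
        return "sex:" + name.split("[T.")[1].rstrip("]")
    return name


def tukey_contrasts(fit: ModelFit, alpha: float = 0.05) -> TukeyResult:
    """Tukey HSD on least-squares class means from the fitted model.

    Adjusted means are model predictions for each class with covariates held
    at their sample means; pairwise differences are tested against the
    studentized-range distribution with k = number of classes and the model's
    residual df (Tukey-Kramer for unequal n).
    """
    res = fit.result
    groups = fit.classes
    if len(groups) < 2:
        raise ValueError("need >= 2 groups for contrasts")
    exog_names = list(res.model.exog_names)
    X = res.model.exog
    base = X.mean(axis=0)  # covariates at sample means
    rows_by_class = {}
    for g in groups:
        row = base.copy()
        for j, name in enumerate(exog_names):
            if name.startswith("C(klass"):
                level = name.split("[T.")[1].rstrip("]")
                row[j] = 1.0 if level == g else 0.0
        rows_by_class[g] = row
    cov = res.cov_params().to_numpy() if hasattr(res.cov_params(), "to_numpy") else res.cov_params()
    beta = res.params.to_numpy()
    k = len(groups)
    df = int(res.df_resid)
    recs = []
    for a, b in combinations(groups, 2):
        L = rows_by_class[a] - rows_by_class[b]
        est = float(L @ beta)
        se = float(np.sqrt(L @ cov @ L))
        q = abs(est) / (se / np.sqrt(2.0))
        p = float(studentized_range.sf(q, k, df))
        recs.append({"group1": a, "group2": b, "estimate": est,
                     "se": se, "q": q, "p_adj": min(p, 1.0),
                     "significant": p < alpha})
    return TukeyResult(pd.DataFrame(recs))


def seasonal_change(fit: ModelFit, day_span: int = SEASON_DAY_SPAN) -> float:
    """Model-predicted change in d2H_f over the harvest season (permil)."""
    try:
        beta = fit.coefficient("day")
    except KeyError as e:
        raise ValueError("model has no date term") from e
    return beta * day_span


def descriptive_stats(samples: pd.DataFrame, classes: list[str]) -> pd.DataFrame:
    """mean/min/max d2H_f per class, for classes too small to model."""
    sub = samples[samples["klass"].isin(classes)]
    out = (
        sub.groupby("klass")["d2hf"]
        .agg(n="count", mean="mean", min="min", max="max")
        .reset_index()
    )
    return out


def group_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-class n, mean and standard error of d2H_f (raw means)."""
    g = samples.groupby("klass")["d2hf"]
    out = g.agg(n="count", mean="mean", sd="std").reset_index()
    out["se"] = out["sd"] / np.sqrt(out["n"])
    return out


def load_s1_table(path: str) -> pd.DataFrame:
    """Load a per-bird metadata CSV (id, d2hf, day, sex, class columns).

    Accepts the canonical column names used throughout this package
    (sample_id, d2hf, day, sex, klass) or common aliases. Harvest day must be
    days since 4 October (day 0).
    """
    df = pd.read_csv(path)
    aliases = {
        "id": "sample_id", "sample": "sample_id",
        "d2h": "d2hf", "d2h_f": "d2hf", "dd2h": "d2hf",
        "harvest_day": "day", "date": "day",
        "class": "klass", "genetic_class": "klass", "assignment": "klass",
    }
    df = df.rename(columns={c: aliases.get(c.lower(), c.lower()) for c in df.columns})
    required = {"sample_id", "d2hf", "day", "klass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table missing columns: {sorted(missing)}")
    if "sex" not in df.columns:
        df["sex"] = "unknown"
    return df
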