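"""Model battery for the aggregate tables.

The battery mirrors the study's analysis: linear mixed-effects models
(REML, random intercept per duo) for nested fixed-effect structures such
as ``power ~ phrase_level/take``, with an automatic ordinary-least-squares
fallback when the between-duo variance is negligible or the mixed fit is
singular; Tukey post-hoc contrasts; and a Bonferroni-corrected p-value
threshold for the battery of empathy models.

The R-style nesting ``A/B`` is expanded as ``A + A:B`` (main effect of A
plus B-within-A dummies).  Marginal and conditional R-squared follow the
Nakagawa variance decomposition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import studentized_range

__all__ = [
    "ModelSpec",
    "ModelFit",
    "fit_model",
    "tukey_contrasts",
    "bonferroni_threshold",
]

log = logging.getLogger("duosync.stats")

#: Between-group variance below this fraction of residual variance triggers
#: the OLS fallback, mirroring "variance negligible (<0.001)".
RE_VARIANCE_FRACTION = 1e-3


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one model in the battery.

    ``fixed`` terms are column names; ``"A/B"`` denotes B nested within A.
    ``categorical`` lists numeric columns to be treated as factors (e.g.
    take numbers); ``baselines`` sets the reference level of a factor.
    """

    response: str
    fixed: tuple[str, ...]
    random_intercept: str | None = None
    categorical: tuple[str, ...] = ()
    baselines: dict = field(default_factory=dict)

    def formula(self, table: pd.DataFrame) -> str:
        terms = []
        for term in self.fixed:
            if "/" in term:
                outer, inner = term.split("/")
                terms.append(self._factor(outer, table))
                terms.append(f"{self._factor(outer, table)}:{self._factor(inner, table)}")
            else:
                terms.append(self._factor(term, table))
        return f"{self.response} ~ " + " + ".join(terms)

    def _factor(self, col: str, table: pd.DataFrame) -> str:
        if col not in table.columns:
            raise ValueError(f"column {col!r} not in table")
        is_cat = col in self.categorical or table[col].dtype == object
        if not is_cat:
            return col
        if col in self.baselines:
            return f"C({col}, Treatment({self.baselines[col]!r}))"
        return f"C({col})"


@dataclass(frozen=True)
class ModelFit:
    """Coefficients, intervals, tests, and fit diagnostics of one model."""

    spec: ModelSpec
    formula: str
    params: pd.Series
    conf_int: pd.DataFrame
    tvalues: pd.Series
    pvalues: pd.Series
    marginal_r2: float
    conditional_r2: float
    used_ols_fallback: bool
    converged: bool
    table: pd.DataFrame

    def __post_init__(self) -> None:
        lo, hi = self.conf_int.iloc[:, 0], self.conf_int.iloc[:, 1]
        finite = np.isfinite(lo) & np.isfinite(hi) & np.isfinite(self.params)
        inside = (lo[finite] <= self.params[finite]) & (self.params[finite] <= hi[finite])
        if not inside.all():
            raise ValueError("confidence interval does not bracket coefficient")

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "ci_low": self.conf_int.iloc[:, 0],
                "ci_high": self.conf_int.iloc[:, 1],
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def _check_full_rank(formula: str, table: pd.DataFrame) -> None:
    import patsy

    _, X = patsy.dmatrices(formula, table, return_type="dataframe")
    rank = np.linalg.matrix_rank(X.values)
    if rank < X.shape[1]:
        # name aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(X.values, pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        aliased += [X.columns[p] for p in piv[len(diag):]]
        raise ValueError(f"rank-deficient design; aliased terms: {aliased}")


def _ols_fit(
    spec: ModelSpec, formula: str, table: pd.DataFrame, *, fallback: bool
) -> ModelFit:
    res = smf.ols(formula, data=table).fit()
    r2 = float(res.rsquared) if res.model.df_model > 0 else 0.0
    if not np.isfinite(r2):
        r2 = 0.0
    return ModelFit(
        spec=spec,
        formula=formula,
        params=res.params,
        conf_int=res.conf_int(alpha=0.05),
        tvalues=res.tvalues,
        pvalues=res.pvalues,
        marginal_r2=r2,
        conditional_r2=r2,
        used_ols_fallback=fallback,
        converged=True,
        table=table,
    )


def _nakagawa_r2(res) -> tuple[float, float]:
    """Marginal/conditional R2 for a Gaussian random-intercept model."""
    fixed = res.model.exog @ res.fe_params.values
    var_f = float(np.var(fixed))
    var_re = float(res.cov_re.values[0, 0])
    var_e = float(res.scale)
    total = var_f + var_re + var_e
    return var_f / total, (var_f + var_re) / total


def fit_model(spec: ModelSpec, table: pd.DataFrame) -> ModelFit:
    """Fit one model of the battery on an aggregate table.

    With a random intercept the model is estimated by REML; if the
    random-effect variance is below ``RE_VARIANCE_FRACTION`` of the
    residual variance, or the fit is singular or fails to converge, the
    model is refit by OLS and the fallback is flagged.
    """
    if spec.response not in table.columns:
        raise ValueError(f"response {spec.response!r} not in table")
    formula = spec.formula(table)
    _check_full_rank(formula, table)
    if spec.random_intercept is None:
        return _ols_fit(spec, formula, table, fallback=False)
    groups = table[spec.random_intercept]
    if groups.nunique() < 2:
        raise ValueError("random intercept requires >= 2 groups")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = smf.mixedlm(formula, data=table, groups=groups).fit(reml=True)
        singular = not res.converged or np.isnan(res.cov_re.values[0, 0])
        re_var = float(res.cov_re.values[0, 0])
        negligible = re_var < RE_VARIANCE_FRACTION * float(res.scale)
    except (np.linalg.LinAlgError, ValueError):
        singular, negligible = True, False
    if singular or negligible:
        log.info(
            "random intercept %s dropped (%s); refitting by OLS",
            spec.random_intercept,
            "singular fit" if singular else "negligible variance",
        )
        return _ols_fit(spec, formula, table, fallback=True)
    marg, cond = _nakagawa_r2(res)
    keep = [ix for ix in res.params.index if ix != "Group Var"]
    return ModelFit(
        spec=spec,
        formula=formula,
        params=res.params[keep],
        conf_int=res.conf_int(alpha=0.05).loc[keep],
        tvalues=res.tvalues[keep],
        pvalues=res.pvalues[keep],
        marginal_r2=marg,
        conditional_r2=cond,
        used_ols_fallback=False,
        converged=bool(res.converged),
        table=table,
    )


def tukey_contrasts(fit: ModelFit, factor: str) -> pd.DataFrame:
    """All pairwise mean differences of a factor with Tukey-adjusted p.

    Uses the Tukey-Kramer statistic on the factor's group means with the
    pooled within-group variance, and the studentized-range distribution
    for the adjusted p-values.
    """
    table = fit.table
    if factor not in table.columns:
        raise ValueError(f"factor {factor!r} not in table")
    groups = table.groupby(factor)[fit.spec.response]
    levels = list(groups.groups)
    if len(levels) < 2:
        raise ValueError("factor must have at least 2 levels")
    means = groups.mean()
    ns = groups.size()
    df = int((ns - 1).sum())
    if df < 1:
        raise ValueError("no residual degrees of freedom for Tukey contrasts")
    mse = float(
        sum(((table.loc[g_idx, fit.spec.response] - means[g]) ** 2).sum()
            for g, g_idx in groups.groups.items())
        / df
    )
    rows = []
    k = len(levels)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = levels[i], levels[j]
            diff = float(means[b] - means[a])
            se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            if se == 0.0:
                p_adj = 1.0 if diff == 0.0 else 0.0
                q = np.inf if diff != 0.0 else 0.0
            else:
                q = abs(diff) / se
                p_adj = float(studentized_range.sf(q, k, df))
            rows.append(
                {"group_a": a, "group_b": b, "diff": diff, "q": float(q),
                 "p_adj": min(max(p_adj, 0.0), 1.0)}
            )
    return pd.DataFrame(rows)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-comparison p-value threshold alpha / m."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m
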