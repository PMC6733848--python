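"""Covariate-adjusted association models.

Implements the study's regression machinery:

* ordinary least squares (optionally on a natural-log outcome, with
  back-transformed ratios) and maximum-likelihood logistic fits, both with
  Wald 95% intervals consistent with the reported p-value;
* Spearman-based collinearity pruning of covariates against the predictor;
* the two-interval repeated-measures ANCOVA with the interaction decision
  rule: the interval x predictor interaction is tested first, the pooled
  predictor coefficient is reported from the model without the interaction,
  and per-interval cross-sectional models are fitted only when the
  interaction is significant;
* concurrent and predictive inflammation models for AGP/CRP (continuous on
  the log scale, binary from the >1.0 g/L and >5.0 mg/L cutoffs).

Within-child correlation across the two stacked intervals is handled with
cluster-robust (sandwich) standard errors grouped by child.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .growth import build_interval_outcomes, winsorize

__all__ = [
    "AssociationResult",
    "GrowthAnalysisResult",
    "RankDeficientError",
    "SeparationError",
    "prune_collinear",
    "fit_linear",
    "fit_logistic",
    "percent_change_from_ratio",
    "describe_percent_change",
    "run_growth_analysis",
    "run_inflammation_analysis",
    "HIGH_AGP_CUTOFF",
    "HIGH_CRP_CUTOFF",
]

HIGH_AGP_CUTOFF = 1.0  # g/L, strictly greater
HIGH_CRP_CUTOFF = 5.0  # mg/L, strictly greater


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; the message lists aliased columns."""


class SeparationError(ValueError):
    """Logistic fit met complete separation; a penalized fallback must be an
    explicit caller choice, never applied silently."""


@dataclass
class AssociationResult:
    """One predictor-outcome association: coefficient, Wald 95% CI, p-value
    and, for log/binary outcomes, the back-transformed ratio scale."""

    beta: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    back_transformed: float | None = None
    bt_ci_low: float | None = None
    bt_ci_high: float | None = None

    def as_dict(self) -> dict:
        return {
            "beta": self.beta,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_value": self.p_value,
            "n_used": self.n_used,
            "back_transformed": self.back_transformed,
            "bt_ci_low": self.bt_ci_low,
            "bt_ci_high": self.bt_ci_high,
        }


@dataclass
class GrowthAnalysisResult:
    """Outcome of the two-interval repeated-measures analysis for one
    anthropometric index and predictor."""

    interaction_p: float
    pooled: AssociationResult
    per_interval: dict[str, AssociationResult] | None = None
    dropped_covariates: list[str] = field(default_factory=list)
    sensitivity_pooled: AssociationResult | None = None

    @property
    def stratified(self) -> bool:
        return self.per_interval is not None


def _spearman_abs(x: np.ndarray, col: pd.Series) -> float:
    """Max |Spearman rho| between x and a covariate (over dummy levels if
    the covariate is categorical)."""
    if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
        best = 0.0
        for _, d in pd.get_dummies(col).items():
            ok = np.isfinite(x) & d.notna().to_numpy()
            if ok.sum() >= 3 and d[ok].nunique() > 1:
                r = stats.spearmanr(x[ok], d.to_numpy()[ok]).statistic
                if np.isfinite(r):
                    best = max(best, abs(r))
        return best
    v = col.to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(v)
    if ok.sum() < 3 or len(np.unique(v[ok])) < 2:
        return 0.0
    r = stats.spearmanr(x[ok], v[ok]).statistic
    return abs(r) if np.isfinite(r) else 0.0


def prune_collinear(
    predictor_values,
    covariate_table: pd.DataFrame,
    rho_max: float = 0.7,
) -> tuple[list[str], pd.DataFrame]:
    """Drop covariates too collinear with the predictor.

    A covariate is removed when |Spearman rho| with the predictor exceeds
    ``rho_max``. Returns (retained covariate names, drop log with the rho of
    each dropped covariate).
    """
    x = np.asarray(predictor_values, dtype=float)
    retained, dropped = [], []
    for name in covariate_table.columns:
        rho = _spearman_abs(x, covariate_table[name])
        if rho > rho_max:
            dropped.append({"covariate": name, "abs_spearman_rho": rho})
        else:
            retained.append(name)
    return retained, pd.DataFrame(dropped, columns=["covariate", "abs_spearman_rho"])


def _design_matrix(data: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    """Numeric design matrix with an intercept; categorical columns expand to
    treatment-coded indicators."""
    parts = [pd.Series(1.0, index=data.index, name="const")]
    for c in columns:
        col = data[c]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            parts.append(pd.get_dummies(col, prefix=c, drop_first=True, dtype=float))
        else:
            parts.append(col.astype(float))
    return pd.concat(parts, axis=1)


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify aliased columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(arr, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(arr.shape) * np.finfo(float).eps
        aliased = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        aliased += [X.columns[j] for j in piv[len(diag):]]
        raise RankDeficientError(f"design matrix rank deficient; aliased: {aliased}")


def _extract(result, term: str, n: int, exponentiate: bool) -> AssociationResult:
    beta = float(result.params[term])
    ci = result.conf_int()
    lo, hi = float(ci.loc[term, 0]), float(ci.loc[term, 1])
    p = float(result.pvalues[term])
    out = AssociationResult(beta=beta, ci_low=lo, ci_high=hi, p_value=p, n_used=n)
    if exponentiate:
        out.back_transformed = float(np.exp(beta))
        out.bt_ci_low = float(np.exp(lo))
        out.bt_ci_high = float(np.exp(hi))
    return out


def fit_linear(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | None = None,
    log_outcome: bool = False,
    cluster: str | None = None,
) -> AssociationResult:
    """OLS of *outcome* on *predictor* plus covariates (complete cases).

    With ``log_outcome``, the outcome is natural-log transformed and the
    result carries exp(beta) with the exponentiated CI for ratio-scale
    reporting. With ``cluster``, standard errors are cluster-robust by that
    grouping column.
    """
    covariates = covariates or []
    use_cols = [outcome, predictor, *covariates] + ([cluster] if cluster else [])
    sub = data[use_cols].dropna()
    y = sub[outcome].astype(float)
    if log_outcome:
        if (y <= 0).any():
            raise ValueError("log outcome requires positive values")
        y = np.log(y)
    X = _design_matrix(sub, [predictor, *covariates])
    _check_rank(X)
    model = sm.OLS(y, X)
    if cluster:
        res = model.fit(
            cov_type="cluster", cov_kwds={"groups": sub[cluster]}, use_t=True
        )
    else:
        res = model.fit()
    return _extract(res, predictor, len(sub), exponentiate=log_outcome)


def fit_logistic(
    data: pd.DataFrame,
    outcome: str,
    predictor: str,
    covariates: list[str] | None = None,
    cluster: str | None = None,
) -> AssociationResult:
    """Maximum-likelihood logit fit; the result carries OR = exp(coef) with
    the exponentiated Wald CI. Complete separation raises
    :class:`SeparationError` rather than silently penalizing."""
    covariates = covariates or []
    use_cols = [outcome, predictor, *covariates] + ([cluster] if cluster else [])
    sub = data[use_cols].dropna()
    y = sub[outcome].astype(float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("binary outcome needs both classes present")
    X = _design_matrix(sub, [predictor, *covariates])
    _check_rank(X)
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        model = sm.Logit(y, X)
        if cluster:
            res = model.fit(
                disp=False,
                cov_type="cluster",
                cov_kwds={"groups": sub[cluster]},
            )
        else:
            res = model.fit(disp=False)
        # (quasi-)complete separation: the MLE diverges, coefficients blow up
        # and the sample is perfectly classified
        fitted = np.asarray(res.predict())
    perfectly_classified = np.all(np.abs(fitted - np.asarray(y)) < 1e-6)
    if perfectly_classified or np.abs(res.params.drop("const")).max() > 50:
        raise SeparationError(
            "complete separation detected; consider an explicit penalized "
            "(Firth-style) refit"
        )
    return _extract(res, predictor, len(sub), exponentiate=True)


def percent_change_from_ratio(ratio: float) -> float:
    """Signed percent change implied by a back-transformed ratio:
    (ratio - 1) x 100. Negative values read as a percent *decrease*."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return (ratio - 1.0) * 100.0


def describe_percent_change(ratio: float, decimals: int = 0) -> str:
    """Human-readable translation of a ratio: 0.88 -> '12% decrease'."""
    pct = percent_change_from_ratio(ratio)
    mag = round(abs(pct), decimals)
    if decimals == 0:
        mag = int(mag)
    if pct < 0:
        return f"{mag}% decrease"
    if pct > 0:
        return f"{mag}% increase"
    return "0% change"


def _interval_design(
    intervals: pd.DataFrame,
    covariates: list[str],
    include_interaction: bool,
) -> pd.DataFrame:
    df = intervals.copy()
    df["interval_late"] = (df["interval"] == "12-18").astype(float)
    cols = ["predictor_at_start", "interval_late", "baseline_z", *covariates]
    X = _design_matrix(df, cols)
    if include_interaction:
        X["interval_late:predictor"] = (
            df["interval_late"] * df["predictor_at_start"]
        )
    return X


def _fit_ols(y, X, groups=None):
    _check_rank(X)
    model = sm.OLS(np.asarray(y, dtype=float), X)
    if groups is not None:
        return model.fit(
            cov_type="cluster", cov_kwds={"groups": np.asarray(groups)}, use_t=True
        )
    return model.fit()


def run_growth_analysis(
    visits: pd.DataFrame,
    predictor: str,
    index: str,
    covariates: list[str] | None = None,
    alpha: float = 0.05,
    rho_max: float = 0.7,
    winsorize_outcome: bool = True,
    winsor_pcts: tuple[float, float] = (2.5, 97.5),
) -> GrowthAnalysisResult:
    """Two-interval repeated-measures ANCOVA for one anthropometric index.

    The stacked data hold one row per child x interval (6->12 with the
    predictor at 6 months, 12->18 with the predictor at 12 months), with the
    baseline z at interval start as a covariate; a child missing one interval
    still contributes the other. The interaction model yields
    ``interaction_p``; the pooled predictor coefficient comes from the model
    without the interaction; when the interaction is significant at ``alpha``
    each interval is additionally analysed cross-sectionally.
    """
    covariates = list(covariates or [])
    stacked = build_interval_outcomes(visits, predictor, indices=(index,))
    if stacked.duplicated(["child_id", "interval"]).any():
        raise ValueError("duplicate child rows within an interval")

    if covariates:
        start_lab = {"6-12": "6mo", "12-18": "12mo"}
        cov_rows = visits.set_index(["child_id", "visit_label"])[covariates]
        key = pd.MultiIndex.from_arrays(
            [stacked["child_id"], stacked["interval"].map(start_lab)]
        )
        stacked = pd.concat(
            [stacked.reset_index(drop=True), cov_rows.reindex(key).reset_index(drop=True)],
            axis=1,
        )
        retained, drop_log = prune_collinear(
            stacked["predictor_at_start"], stacked[covariates], rho_max=rho_max
        )
        dropped = list(drop_log["covariate"]) if len(drop_log) else []
        covariates = retained
        stacked = stacked.dropna(subset=["delta_z", *covariates])
    else:
        dropped = []

    raw = stacked["delta_z"].to_numpy(dtype=float)
    y = winsorize(raw, *winsor_pcts) if winsorize_outcome else raw

    X_int = _interval_design(stacked, covariates, include_interaction=True)
    res_int = _fit_ols(y, X_int, groups=stacked["child_id"])
    interaction_p = float(res_int.pvalues["interval_late:predictor"])

    X_pool = _interval_design(stacked, covariates, include_interaction=False)
    res_pool = _fit_ols(y, X_pool, groups=stacked["child_id"])
    pooled = _extract(res_pool, "predictor_at_start", len(stacked), False)

    sensitivity = None
    if winsorize_outcome:
        res_sens = _fit_ols(raw, X_pool, groups=stacked["child_id"])
        sensitivity = _extract(res_sens, "predictor_at_start", len(stacked), False)

    per_interval = None
    if interaction_p < alpha:
        per_interval = {}
        for name in ("6-12", "12-18"):
            sub = stacked[stacked["interval"] == name]
            y_sub = (
                winsorize(sub["delta_z"].to_numpy(dtype=float), *winsor_pcts)
                if winsorize_outcome
                else sub["delta_z"].to_numpy(dtype=float)
            )
            X_sub = _design_matrix(
                sub, ["predictor_at_start", "baseline_z", *covariates]
            )
            res_sub = _fit_ols(y_sub, X_sub)
            per_interval[name] = _extract(
                res_sub, "predictor_at_start", len(sub), False
            )

    return GrowthAnalysisResult(
        interaction_p=interaction_p,
        pooled=pooled,
        per_interval=per_interval,
        dropped_covariates=dropped,
        sensitivity_pooled=sensitivity,
    )


def run_inflammation_analysis(
    visits: pd.DataFrame,
    predictor: str,
    predictor_visit: str,
    outcome_visit: str,
    covariates: list[str] | None = None,
    rho_max: float = 0.7,
    winsorize_outcome: bool = True,
    strict: bool = True,
) -> dict[str, AssociationResult | None]:
    """Associate a predictor at one visit with inflammation at another.

    Concurrent configurations use the same visit twice (6->6, 18->18);
    predictive ones use an earlier predictor (6->18, 12->18). Continuous AGP
    and CRP are modelled on the natural-log scale and back-transformed; the
    binary outcomes use the >1.0 g/L (AGP) and >5.0 mg/L (CRP) cutoffs.
    Rows with non-positive biomarker values are excluded.

    With ``strict=False`` a failing model (separation, singular information
    matrix at small n) is recorded as ``None`` instead of aborting the other
    outcomes.
    """
    covariates = list(covariates or [])
    pred_rows = visits[visits["visit_label"] == predictor_visit].set_index("child_id")
    out_rows = visits[visits["visit_label"] == outcome_visit].set_index("child_id")
    common = pred_rows.index.intersection(out_rows.index)
    df = pd.DataFrame(
        {
            "child_id": common,
            "x": pred_rows.loc[common, predictor].to_numpy(dtype=float),
            "agp": out_rows.loc[common, "agp"].to_numpy(dtype=float),
            "crp": out_rows.loc[common, "crp"].to_numpy(dtype=float),
        }
    )
    for c in covariates:
        df[c] = pred_rows.loc[common, c].to_numpy()

    bad = (df["agp"] <= 0) | (df["crp"] <= 0)
    if bad.any():
        df = df.loc[~bad]
    df = df.reset_index(drop=True)

    if covariates:
        covariates, _ = prune_collinear(df["x"], df[covariates], rho_max=rho_max)

    results: dict[str, AssociationResult | None] = {}

    def attempt(key, fit):
        try:
            results[key] = fit()
        except (ValueError, np.linalg.LinAlgError):
            if strict:
                raise
            results[key] = None

    for marker in ("agp", "crp"):
        ln = np.log(df[marker].to_numpy(dtype=float))
        d = df.copy()
        d["_ln"] = winsorize(ln) if winsorize_outcome else ln

        def fit_ln(d=d):
            res = fit_linear(d, "_ln", "x", covariates, log_outcome=False)
            # outcome already on the log scale: report the ratio per predictor
            res.back_transformed = float(np.exp(res.beta))
            res.bt_ci_low = float(np.exp(res.ci_low))
            res.bt_ci_high = float(np.exp(res.ci_high))
            return res

        attempt(f"ln_{marker}", fit_ln)

    df["high_agp"] = (df["agp"] > HIGH_AGP_CUTOFF).astype(int)
    df["high_crp"] = (df["crp"] > HIGH_CRP_CUTOFF).astype(int)
    for marker in ("agp", "crp"):
        attempt(
            f"high_{marker}",
            lambda m=marker: fit_logistic(df, f"high_{m}", "x", covariates),
        )
    return results
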