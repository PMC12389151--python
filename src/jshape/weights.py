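"""Inverse-probability weights for a four-level time-varying exposure.

Treatment weights come from multinomial (default) or one-vs-rest logistic
models of the current exposure category given the time-updated confounders,
the previous category, and baseline covariates; censoring weights from
logistic models of continued follow-up. Weights multiply, are optionally
stabilized and cumulated over waves, and are trimmed at percentile cuts of
the combined distribution. Balance of each confounder across exposure
contrasts is summarised by standardized mean differences, with |SMD| < 0.10
the conventional adequacy rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohort import CATEGORIES, REFERENCE, CohortTable

logger = logging.getLogger(__name__)

_CODE = {c: i for i, c in enumerate(CATEGORIES)}


class WeightEstimationError(RuntimeError):
    """Propensity / censoring model failed to produce usable probabilities."""


@dataclass
class PropensityModelSpec:
    """What enters the exposure model and how weights are formed."""

    covariates: Sequence[str] = ("L", "age", "female")
    method: str = "multinomial"  # or "one_vs_rest"
    stabilized: bool = False
    cumulative: bool = True
    include_previous_category: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("multinomial", "one_vs_rest"):
            raise ValueError(f"unknown estimation method {self.method!r}")


@dataclass
class WeightSet:
    """Per-observation weights keyed by (participant_id, wave)."""

    table: pd.DataFrame  # participant_id, wave, iptw, ipcw, combined, trimmed
    lower_cut: float
    upper_cut: float
    n_excluded: int

    @property
    def retained(self) -> pd.DataFrame:
        return self.table.loc[~self.table["trimmed"]]

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class BalanceReport:
    """Standardized mean differences per covariate and contrast."""

    table: pd.DataFrame  # covariate, contrast, smd_unweighted, smd_weighted, flagged
    threshold: float = 0.10

    @property
    def any_flagged_weighted(self) -> bool:
        return bool(self.table["flag_weighted"].any())

    def to_markdown(self) -> str:
        """Love-plot-style text table, largest unweighted imbalance first."""
        t = (
            self.table.assign(_a=self.table["smd_unweighted"].abs())
            .sort_values("_a", ascending=False)
            .drop(columns="_a")
        )
        lines = ["| covariate | contrast | SMD unweighted | SMD weighted | flag |",
                 "|---|---|---|---|---|"]
        for _, r in t.iterrows():
            flag = "*" if r["flag_weighted"] else ""
            lines.append(
                f"| {r['covariate']} | {r['contrast']} | {r['smd_unweighted']:.3f} "
                f"| {r['smd_weighted']:.3f} | {flag} |"
            )
        return "\n".join(lines)


def _design(df: pd.DataFrame, covariates: Sequence[str], prev_col: str | None) -> pd.DataFrame:
    X = df[list(covariates)].astype(float).copy()
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        # absorbed by the intercept; keeping them makes the fit singular
        logger.info("dropping constant covariates from exposure model: %s", constant)
        X = X.drop(columns=constant)
    if prev_col is not None:
        prev = df[prev_col].astype(str)
        for cat in CATEGORIES:
            if cat == REFERENCE:
                continue
            X[f"prev_{cat}"] = (prev == cat).astype(float)
    X.insert(0, "const", 1.0)
    return X


def _fit_multinomial(X: pd.DataFrame, y_codes: np.ndarray) -> np.ndarray:
    try:
        fit = sm.MNLogit(y_codes, X).fit(method="newton", maxiter=200, disp=0)
    except Exception as exc:  # pragma: no cover - rare numerical failure
        raise WeightEstimationError(f"multinomial exposure model failed: {exc}") from exc
    if not fit.mle_retvals.get("converged", True):
        raise WeightEstimationError(
            "multinomial exposure model did not converge; check for separation "
            f"among covariates {list(X.columns)}"
        )
    probs = np.asarray(fit.predict(X))
    return probs


def _fit_one_vs_rest(X: pd.DataFrame, y_codes: np.ndarray) -> np.ndarray:
    cols = []
    for k in range(len(CATEGORIES)):
        yk = (y_codes == k).astype(float)
        fit = sm.GLM(yk, X, family=sm.families.Binomial()).fit()
        cols.append(np.asarray(fit.predict(X)))
    raw = np.column_stack(cols)
    total = raw.sum(axis=1)
    logger.info(
        "one_vs_rest probability sums before renormalization: mean=%.4f, range=(%.4f, %.4f)",
        total.mean(), total.min(), total.max(),
    )
    return raw / total[:, None]


def fit_exposure_model(
    table: pd.DataFrame, spec: PropensityModelSpec, category_col: str = "alcohol_category"
) -> pd.DataFrame:
    """Per-row probabilities of each exposure category.

    Waves with a previous observed category are modeled separately from
    wave 0 (which has none), both on the covariates in ``spec``. Returns a
    frame aligned with ``table`` holding ``prob_<category>`` columns and
    ``prob_observed``, the probability of the category actually reported.
    """
    fitter = _fit_multinomial if spec.method == "multinomial" else _fit_one_vs_rest
    df = table.sort_values(["participant_id", "wave"])
    cov_missing = [c for c in spec.covariates if c not in df.columns]
    if cov_missing:
        raise KeyError(f"exposure-model covariates missing from table: {cov_missing}")
    if df[list(spec.covariates)].isna().any().any():
        raise WeightEstimationError("missing covariate values among analysis rows")

    work = df.copy()
    work["_prev"] = work.groupby("participant_id")[category_col].shift()
    y = work[category_col].astype(str).map(_CODE).to_numpy()

    probs = np.full((len(work), len(CATEGORIES)), np.nan)
    first = work["_prev"].isna().to_numpy()
    if spec.include_previous_category:
        segments = [(first, None), (~first, "_prev")]
    else:
        segments = [(np.ones(len(work), bool), None)]
    for mask, prev_col in segments:
        if mask.sum() == 0:
            continue
        X = _design(work.loc[mask], spec.covariates, prev_col)
        probs[mask] = fitter(X, y[mask])

    out = pd.DataFrame(
        probs, columns=[f"prob_{c}" for c in CATEGORIES], index=work.index
    )
    out["prob_observed"] = probs[np.arange(len(work)), y]
    return out.reindex(table.index)


def compute_iptw(
    probabilities: pd.DataFrame,
    table: pd.DataFrame,
    stabilized: bool = False,
    cumulative: bool = True,
    category_col: str = "alcohol_category",
    numerator: str = "marginal",
) -> pd.Series:
    """Inverse-probability-of-treatment weights.

    Base weight is ``1 / P(A_t = observed | covariates)``. Stabilization
    multiplies by a numerator free of the time-varying confounders: the
    empirical per-wave marginal share of the observed category
    (``numerator="marginal"``) or the empirical transition probability
    given the previous wave's category (``numerator="transition"``, the
    usual choice for cumulated weights because it cancels the persistence
    part of the denominator and keeps the products short-tailed). The
    cumulative form takes the running product over a participant's waves.
    """
    p = probabilities["prob_observed"]
    floor = np.finfo(float).tiny * 1e4
    if (p <= floor).any():
        bad = list(table.index[p <= floor])[:10]
        raise WeightEstimationError(f"treatment probabilities at machine floor, rows {bad}")
    w = 1.0 / p
    if stabilized:
        if numerator not in ("marginal", "transition"):
            raise ValueError(f"unknown stabilization numerator {numerator!r}")
        obs = table[category_col].astype(str)
        if numerator == "marginal":
            keys = ["wave"]
        else:
            prev = (
                table.sort_values(["participant_id", "wave"])
                .groupby("participant_id")[category_col]
                .shift()
                .reindex(table.index)
                .astype(str)
            )
            keys = ["wave", "_prev"]
            table = table.assign(_prev=prev.fillna("<baseline>"))
        num = (
            table.assign(_c=obs)
            .groupby(keys + ["_c"], observed=True)["_c"]
            .transform("size")
            / table.groupby(keys, observed=True)["wave"].transform("size")
        )
        w = w * num
    if cumulative:
        w = w.groupby(table["participant_id"]).cumprod()
    return w.rename("iptw")


def fit_censoring_model(
    cohort: CohortTable,
    covariates: Sequence[str],
    time_updated: bool = True,
    pooled: bool = True,
    include_previous_category: bool = True,
    category_col: str = "alcohol_category",
) -> pd.DataFrame:
    """Probability of remaining under follow-up at each observed wave.

    For every wave t >= 1 the risk set is everyone observed at t-1; the
    model regresses participation at t on covariates measured at the last
    observed wave (``time_updated=True``) or at baseline, plus indicators
    of the exposure category at that wave (dropout is typically
    exposure-dependent). ``pooled`` fits one logistic model with wave
    indicators, otherwise one model per wave. Waves with no dropout get
    retention probability 1. Returns rows (participant_id, wave,
    p_retained) for observed waves; wave 0 has probability 1 by convention.
    """
    df = cohort.data.sort_values(["participant_id", "wave"])
    last = df.groupby("participant_id")["wave"].max()
    horizon = cohort.n_waves

    cat_cols: list[str] = []
    if include_previous_category:
        cat_cols = [f"lastcat_{c}" for c in CATEGORIES if c != REFERENCE]

    risk_rows = []
    for t in range(1, horizon):
        at_risk = last.index[last >= t - 1]
        cov_wave = (t - 1) if time_updated else 0
        covs = df.loc[df["wave"] == cov_wave].set_index("participant_id")
        covs = covs.loc[covs.index.intersection(at_risk)]
        block = covs[list(covariates)].astype(float)
        if include_previous_category:
            # exposure as reported at the last observed wave before t
            lastcat = (
                df.loc[df["wave"] == t - 1]
                .set_index("participant_id")[category_col]
                .reindex(covs.index)
                .astype(str)
            )
            for c in CATEGORIES:
                if c != REFERENCE:
                    block[f"lastcat_{c}"] = (lastcat == c).astype(float)
        block["_retained"] = (last >= t).reindex(covs.index).astype(float)
        block["_wave"] = t
        risk_rows.append(block.reset_index())
    risk = pd.concat(risk_rows, ignore_index=True)

    def _fit(block: pd.DataFrame) -> pd.Series:
        if block["_retained"].nunique() == 1:
            logger.info("no dropout events in censoring block; retention prob = 1")
            return pd.Series(np.ones(len(block)), index=block.index)
        X = block[list(covariates) + cat_cols].astype(float).copy()
        if pooled and block["_wave"].nunique() > 1:
            for t in sorted(block["_wave"].unique())[1:]:
                X[f"wave_{t}"] = (block["_wave"] == t).astype(float)
        X.insert(0, "const", 1.0)
        fit = sm.GLM(block["_retained"], X, family=sm.families.Binomial()).fit()
        return pd.Series(np.asarray(fit.predict(X)), index=block.index)

    if pooled:
        risk["p_retained"] = _fit(risk)
    else:
        risk["p_retained"] = (
            risk.groupby("_wave", group_keys=False).apply(_fit).sort_index()
        )
    risk = risk.rename(columns={"_wave": "wave"})[["participant_id", "wave", "p_retained"]]

    base = pd.DataFrame(
        {"participant_id": last.index, "wave": 0, "p_retained": 1.0}
    )
    out = pd.concat([base, risk], ignore_index=True)
    # keep only waves the participant actually attended
    obs = df[["participant_id", "wave"]]
    out = obs.merge(out, on=["participant_id", "wave"], how="left")
    return out


def compute_ipcw(retention: pd.DataFrame, cumulative: bool = True) -> pd.Series:
    """Inverse-probability-of-censoring weights from retention probabilities.

    Reciprocal of the per-wave retention probability, by default cumulated
    over waves within participant; always >= 1.
    """
    p = retention["p_retained"]
    if ((p <= 0) | (p > 1)).any():
        raise WeightEstimationError("retention probabilities must lie in (0, 1]")
    w = 1.0 / p
    if cumulative:
        w = w.groupby(retention["participant_id"]).cumprod()
    return w.rename("ipcw")


def combine_and_trim(
    iptw: pd.Series,
    ipcw: pd.Series,
    keys: pd.DataFrame,
    lower_pct: float = 2.0,
    upper_pct: float = 98.0,
    mode: str = "exclude",
) -> WeightSet:
    """Combined weight = IPTW x IPCW, trimmed at percentile cuts.

    Percentile cuts use the nearest-rank order statistics of the combined
    weights of the analysis rows, computed once for the whole analysis
    dataset. ``exclude`` flags rows outside the cuts for removal (pre-trim
    values retained); ``cap`` winsorizes at the cuts, preserving row count.
    A degenerate all-equal distribution excludes nothing.
    """
    if mode not in ("exclude", "cap"):
        raise ValueError(f"unknown trim mode {mode!r}")
    combined = (iptw * ipcw).to_numpy()
    n = len(combined)
    srt = np.sort(combined)
    k_low = int(np.floor(n * lower_pct / 100.0))
    k_high = int(np.floor(n * (100.0 - upper_pct) / 100.0))
    lower_cut = srt[min(k_low, n - 1)]
    upper_cut = srt[max(n - 1 - k_high, 0)]

    table = keys[["participant_id", "wave"]].copy()
    table["iptw"] = iptw.to_numpy()
    table["ipcw"] = ipcw.to_numpy()
    table["combined"] = combined
    if mode == "exclude":
        table["trimmed"] = (combined < lower_cut) | (combined > upper_cut)
    else:
        table["combined"] = np.clip(combined, lower_cut, upper_cut)
        table["trimmed"] = False
    n_excluded = int(table["trimmed"].sum())
    if n_excluded == 0 and lower_pct > 0:
        logger.info("weight trimming excluded no rows (degenerate or tight distribution)")
    return WeightSet(table, float(lower_cut), float(upper_cut), n_excluded)


def standardized_mean_difference(
    values: np.ndarray,
    group: np.ndarray,
    weights: np.ndarray | None = None,
    binary: bool | None = None,
) -> float:
    """SMD between two groups: difference in (weighted) means over the
    pooled standard deviation sqrt((v1 + v2) / 2).

    Binary covariates use the proportion variance p(1-p). Identical-mean
    degenerate groups return 0; unequal means with zero pooled variance
    raise.
    """
    values = np.asarray(values, float)
    group = np.asarray(group, bool)
    w = np.ones_like(values) if weights is None else np.asarray(weights, float)
    if group.sum() == 0 or (~group).sum() == 0:
        raise ValueError("both groups must be nonempty")
    if binary is None:
        binary = set(np.unique(values)) <= {0.0, 1.0}

    def moments(mask):
        ww, xx = w[mask], values[mask]
        m = np.average(xx, weights=ww)
        if binary:
            v = m * (1 - m)
        else:
            v = np.average((xx - m) ** 2, weights=ww)
        return m, v

    m1, v1 = moments(group)
    m2, v2 = moments(~group)
    pooled = np.sqrt((v1 + v2) / 2.0)
    if pooled == 0:
        if np.isclose(m1, m2):
            return 0.0
        raise ValueError("zero pooled variance with unequal means")
    return float((m1 - m2) / pooled)


def balance_report(
    table: pd.DataFrame,
    weights: WeightSet,
    covariates: Sequence[str],
    category_col: str = "alcohol_category",
    threshold: float = 0.10,
) -> BalanceReport:
    """SMD of each covariate for every category-vs-moderate contrast,
    before and after weighting (weighted SMDs use retained rows only)."""
    merged = table.merge(
        weights.table[["participant_id", "wave", "combined", "trimmed"]],
        on=["participant_id", "wave"],
        how="inner",
    )
    rows = []
    cat = merged[category_col].astype(str)
    for contrast in CATEGORIES:
        if contrast == REFERENCE:
            continue
        pair = merged.loc[cat.isin([contrast, REFERENCE])]
        g = (pair[category_col].astype(str) == contrast).to_numpy()
        kept = ~pair["trimmed"].to_numpy()
        for cov in covariates:
            x = pair[cov].astype(float).to_numpy()
            smd_u = standardized_mean_difference(x, g)
            smd_w = standardized_mean_difference(
                x[kept], g[kept], pair["combined"].to_numpy()[kept]
            )
            rows.append(
                {
                    "covariate": cov,
                    "contrast": f"{contrast} vs {REFERENCE}",
                    "smd_unweighted": smd_u,
                    "smd_weighted": smd_w,
                    "flag_unweighted": abs(smd_u) >= threshold,
                    "flag_weighted": abs(smd_w) >= threshold,
                }
            )
    return BalanceReport(pd.DataFrame(rows), threshold)
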