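"""Adjusted prognostic models: per-SD logistic and Cox fits with subgroups.

The analysis design: each microarchitectural feature (possibly
log-transformed, then standardized to unit SD on the analysis subset) is
entered into

* a logistic regression of nodal status, adjusted for age at diagnosis,
  grade (numeric 1-3) and tumour size (cm) — all patients by default;
* a Cox proportional-hazards model of breast cancer-specific survival
  (BCSS) or time to distant metastasis (TTDM) with the same adjustment —
  restricted to patients who received no chemotherapy, so the association
  is not confounded by treatment response.

Effects are reported as OR/HR per 1 SD with Wald 95% CIs.  Analyses repeat
across ER/HER2 subgroups, grade subgroups, and their crossings.  Missing
data are handled complete-case per fit, with the exclusion count logged.
Ties in the Cox partial likelihood use the Breslow approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .spot_io import logger

ADJUSTMENT = ["age", "grade", "tumour_size"]

FEATURE_NAMES = [
    "n_nests",
    "total_area",
    "mean_area",
    "total_perimeter",
    "mean_perimeter",
    "mean_circularity",
    "mean_roundness",
]

ER_HER2_SUBGROUPS = ["ER+/HER2-", "ER+/HER2+", "ER-/HER2+", "ER-/HER2-"]
GRADE_SUBGROUPS = ["grade1", "grade2", "grade3"]
CROSSED_SUBGROUPS = [f"{e}:{g}" for e in ER_HER2_SUBGROUPS for g in GRADE_SUBGROUPS]
ALL_SUBGROUPS = ["all"] + ER_HER2_SUBGROUPS + GRADE_SUBGROUPS + CROSSED_SUBGROUPS

ENDPOINTS = ("node", "bcss", "ttdm")


class DegenerateFeatureError(ValueError):
    """Feature has zero variance on the analysis subset."""


class FeatureValidationError(ValueError):
    """Feature violates a transform precondition (e.g. log of non-positive)."""


@dataclass(frozen=True)
class FeatureSpec:
    """How a feature enters the model.

    transform 'log' requires strictly positive values; scaling 'per_sd'
    standardizes to unit SD on the analysis subset, 'per_unit' leaves the
    (transformed) scale untouched, 'tertiles' codes the tertile group 0/1/2
    (entered linearly, effect per tertile step).
    """

    name: str
    transform: Literal["identity", "log"] = "identity"
    scaling: Literal["per_sd", "per_unit", "tertiles"] = "per_sd"


# Size-like features are right-skewed and enter on the log scale; counts and
# shape indices enter untransformed.
DEFAULT_FEATURES = [
    FeatureSpec("n_nests"),
    FeatureSpec("total_area", transform="log"),
    FeatureSpec("mean_area", transform="log"),
    FeatureSpec("total_perimeter", transform="log"),
    FeatureSpec("mean_perimeter", transform="log"),
    FeatureSpec("mean_circularity"),
    FeatureSpec("mean_roundness"),
]


@dataclass
class AssociationResult:
    """One fitted cell of the analysis grid.

    ``status`` is 'ok', 'non_converged', or 'refused: <reason>'; effect and
    CI are NaN unless status is 'ok'.
    """

    feature: FeatureSpec
    endpoint: str
    subgroup: str
    effect: float = float("nan")
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    p: float = float("nan")
    n_used: int = 0
    n_events: int = 0
    sd_used: float = float("nan")
    adjustment: list[str] = field(default_factory=lambda: list(ADJUSTMENT))
    status: str = "ok"


def subgroup_mask(df: pd.DataFrame, subgroup: str) -> pd.Series:
    """Boolean row mask for a named subgroup ('all', 'ER+/HER2-', 'grade2',
    or a crossing like 'ER+/HER2-:grade2')."""
    mask = pd.Series(True, index=df.index)
    for part in subgroup.split(":"):
        if part == "all":
            continue
        elif part.startswith("grade"):
            mask &= df["grade"] == int(part[len("grade"):])
        elif part.startswith("ER"):
            er_part, her2_part = part.split("/")
            mask &= (df["er"] == (1 if er_part == "ER+" else 0)) & (
                df["her2"] == (1 if her2_part == "HER2+" else 0)
            )
        else:
            raise ValueError(f"unknown subgroup: {subgroup!r}")
    return mask.fillna(False).astype(bool)


def prepare_feature(
    df: pd.DataFrame, spec: FeatureSpec
) -> tuple[pd.Series, float]:
    """Transform and scale a feature column on the (already filtered)
    analysis subset.

    Returns the prepared column and the SD used (sample SD of the
    transformed values; NaN for tertile coding).  Tertile cut points sit at
    the 1/3 and 2/3 quantiles (linear-interpolation convention).
    """
    if spec.name not in df.columns:
        raise KeyError(f"feature {spec.name!r} not in cohort table")
    x = df[spec.name].astype(float)
    if spec.transform == "log":
        bad = df.index[(x <= 0) | x.isna()]
        if (x <= 0).any():
            raise FeatureValidationError(
                f"log transform of {spec.name} undefined for rows: {list(bad[:10])}"
            )
        x = np.log(x)
    sd = float(x.std(ddof=1))
    if not np.isfinite(sd) or sd == 0.0:
        raise DegenerateFeatureError(f"{spec.name} has zero variance in this subset")
    if spec.scaling == "per_sd":
        return (x - x.mean()) / sd, sd
    if spec.scaling == "per_unit":
        return x, sd
    if spec.scaling == "tertiles":
        cuts = x.quantile([1 / 3, 2 / 3]).to_numpy()
        codes = pd.Series(np.searchsorted(cuts, x, side="right"), index=x.index)
        return codes.astype(float), float("nan")
    raise ValueError(f"unknown scaling: {spec.scaling!r}")


def _analysis_subset(
    cohort: pd.DataFrame,
    spec: FeatureSpec,
    subgroup: str,
    outcome_cols: list[str],
    no_chemo: bool,
) -> pd.DataFrame:
    df = cohort.loc[subgroup_mask(cohort, subgroup)]
    if no_chemo:
        df = df.loc[df["chemo"].fillna(1).astype(int) == 0]
    needed = [spec.name, *ADJUSTMENT, *outcome_cols]
    complete = df.dropna(subset=needed)
    dropped = len(df) - len(complete)
    if dropped:
        logger.info(
            "%s/%s: dropped %d of %d rows with missing data (complete-case)",
            spec.name,
            subgroup,
            dropped,
            len(df),
        )
    return complete


def _usable_adjustment(df: pd.DataFrame, spec: FeatureSpec, subgroup: str) -> list[str]:
    """Adjustment covariates with variance in this subset (grade is constant
    within grade subgroups and must not enter the design matrix there)."""
    usable = [c for c in ADJUSTMENT if df[c].nunique() > 1]
    dropped = sorted(set(ADJUSTMENT) - set(usable))
    if dropped:
        logger.info(
            "%s/%s: adjustment covariates %s constant in subset, dropped",
            spec.name,
            subgroup,
            dropped,
        )
    return usable


def fit_node_logistic(
    cohort: pd.DataFrame,
    spec: FeatureSpec,
    subgroup: str = "all",
    min_n: int = 30,
) -> AssociationResult:
    """Adjusted logistic regression of nodal status on one feature.

    Returns the OR per stated scale with Wald 95% CI and two-sided p.
    Complete separation or a failed Newton iteration yields a result with
    status 'non_converged'; fewer than ``min_n`` usable rows yields a
    refusal — neither crashes, so the grid stays complete.
    """
    res = AssociationResult(feature=spec, endpoint="node", subgroup=subgroup)
    df = _analysis_subset(cohort, spec, subgroup, ["node_positive"], no_chemo=False)
    res.n_used = len(df)
    if len(df) < min_n:
        res.status = f"refused: n={len(df)} below floor {min_n}"
        return res
    try:
        feat, sd = prepare_feature(df, spec)
    except (DegenerateFeatureError, FeatureValidationError) as exc:
        res.status = f"refused: {exc}"
        return res
    res.sd_used = sd
    y = df["node_positive"].astype(int).to_numpy()
    res.n_events = int(y.sum())
    if y.min() == y.max():
        res.status = "refused: outcome constant in subset"
        return res
    res.adjustment = _usable_adjustment(df, spec, subgroup)
    X = sm.add_constant(
        pd.DataFrame(
            {"feature": feat.to_numpy(), **{c: df[c].astype(float).to_numpy() for c in res.adjustment}}
        )
    )
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
        converged = bool(fit.mle_retvals.get("converged", False))
        bse = float(fit.bse["feature"])
        if not converged or not np.isfinite(bse) or bse > 50:
            res.status = "non_converged"
            return res
    except Exception:
        res.status = "non_converged"
        return res
    beta = float(fit.params["feature"])
    res.effect = float(np.exp(beta))
    res.ci_low = float(np.exp(beta - 1.959963984540054 * bse))
    res.ci_high = float(np.exp(beta + 1.959963984540054 * bse))
    res.p = float(fit.pvalues["feature"])
    return res


def fit_cox(
    cohort: pd.DataFrame,
    spec: FeatureSpec,
    endpoint: Literal["bcss", "ttdm"],
    subgroup: str = "all",
    min_n: int = 30,
    min_events: int = 5,
) -> AssociationResult:
    """Adjusted Cox model of BCSS or TTDM on one feature (no-chemo patients).

    BCSS events are breast-cancer deaths; deaths from other causes censor.
    TTDM events are distant metastases; patients are censored at the latest
    time known alive and metastasis-free.  Breslow tie handling.
    """
    if endpoint not in ("bcss", "ttdm"):
        raise ValueError(f"unknown endpoint: {endpoint!r}")
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    res = AssociationResult(feature=spec, endpoint=endpoint, subgroup=subgroup)
    df = _analysis_subset(cohort, spec, subgroup, [time_col, event_col], no_chemo=True)
    res.n_used = len(df)
    res.n_events = int(df[event_col].astype(float).sum()) if len(df) else 0
    if len(df) < min_n:
        res.status = f"refused: n={len(df)} below floor {min_n}"
        return res
    if res.n_events < min_events:
        res.status = f"refused: {res.n_events} events below floor {min_events}"
        return res
    try:
        feat, sd = prepare_feature(df, spec)
    except (DegenerateFeatureError, FeatureValidationError) as exc:
        res.status = f"refused: {exc}"
        return res
    res.sd_used = sd
    res.adjustment = _usable_adjustment(df, spec, subgroup)
    frame = pd.DataFrame(
        {
            "T": df[time_col].astype(float).to_numpy(),
            "E": df[event_col].astype(int).to_numpy(),
            "feature": feat.to_numpy(),
            **{c: df[c].astype(float).to_numpy() for c in res.adjustment},
        }
    )
    cph = CoxPHFitter()
    try:
        cph.fit(frame, duration_col="T", event_col="E")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        res.status = "non_converged"
        return res
    row = cph.summary.loc["feature"]
    res.effect = float(row["exp(coef)"])
    res.ci_low = float(row["exp(coef) lower 95%"])
    res.ci_high = float(row["exp(coef) upper 95%"])
    res.p = float(row["p"])
    return res


def run_analysis_grid(
    cohort: pd.DataFrame,
    features: list[FeatureSpec] | None = None,
    subgroups: list[str] | None = None,
    endpoints: tuple[str, ...] = ENDPOINTS,
    min_n: int = 30,
) -> pd.DataFrame:
    """Fit the full feature x endpoint x subgroup grid; one tidy row per cell.

    Unestimable cells are present with their refusal reason in ``status`` —
    no silent omissions.
    """
    features = features if features is not None else DEFAULT_FEATURES
    subgroups = subgroups if subgroups is not None else ALL_SUBGROUPS
    rows = []
    for spec in features:
        for endpoint in endpoints:
            for subgroup in subgroups:
                if endpoint == "node":
                    r = fit_node_logistic(cohort, spec, subgroup, min_n=min_n)
                else:
                    r = fit_cox(cohort, spec, endpoint, subgroup, min_n=min_n)
                rows.append(
                    {
                        "feature": spec.name,
                        "transform": spec.transform,
                        "scale": spec.scaling,
                        "endpoint": endpoint,
                        "subgroup": subgroup,
                        "n": r.n_used,
                        "events": r.n_events,
                        "effect": r.effect,
                        "ci_low": r.ci_low,
                        "ci_high": r.ci_high,
                        "p": r.p,
                        "status": r.status,
                    }
                )
    return pd.DataFrame(rows)


def km_summary(
    cohort: pd.DataFrame,
    spec: FeatureSpec,
    endpoint: Literal["bcss", "ttdm"] = "bcss",
) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimates per feature tertile.

    Rows: tertile (0 = lowest), event time, survival estimate, number at
    risk, number of events.  Same inclusion rules as :func:`fit_cox`;
    plotting is a thin layer the caller supplies over this table.
    """
    time_col, event_col = f"{endpoint}_time", f"{endpoint}_event"
    df = _analysis_subset(cohort, spec, "all", [time_col, event_col], no_chemo=True)
    if df.empty:
        raise ValueError("no usable rows for Kaplan-Meier summary")
    tert_spec = FeatureSpec(spec.name, spec.transform, "tertiles")
    groups, _ = prepare_feature(df, tert_spec)
    out = []
    for g in sorted(groups.unique()):
        sub = df.loc[groups == g]
        kmf = KaplanMeierFitter()
        kmf.fit(sub[time_col].astype(float), sub[event_col].astype(int))
        table = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        for t, row in table.iterrows():
            out.append(
                {
                    "tertile": int(g),
                    "time": float(t),
                    "survival": float(surv.loc[t]),
                    "n_risk": int(row["at_risk"]),
                    "n_events": int(row["observed"]),
                }
            )
    return pd.DataFrame(out)
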