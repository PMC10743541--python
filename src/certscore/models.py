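"""Association models for prevalent and new-onset hypertension.

* Prevalent hypertension (present at baseline: BP-lowering treatment, or
  SBP >= 140 mmHg, or DBP >= 90 mmHg) is modelled by logistic regression;
  effects are reported as odds ratios (OR) with Wald 95% CIs.
* New-onset hypertension (among the prevalent-free) is modelled by Cox
  proportional hazards with *attained age* as the timescale: subjects enter
  the risk set at their baseline age (left truncation) and exit at the age of
  onset or censoring.  Sex enters as a stratum, never as a covariate, and the
  age+sex adjustment model is not fitted — age is already the time axis.

Nested covariate-adjustment sets:
  M1 = age + sex; M2 = M1 + TC + HDL + LDL;
  M3 = M2 + BMI + smoking + diabetes + lipid-lowering treatment.

Predictors: CERT totals enter as raw points (effects per score point); lipid
species and ratios are standardized to zero mean / unit SD, so their effects
are per SD.  No multiple-testing correction is applied; ``significant`` flags
raw p < 0.05.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter
from scipy import stats

from . import scoring
from .errors import (
    ConfigurationError,
    ConvergenceError,
    DataError,
    DegeneratePredictorError,
)

logger = logging.getLogger(__name__)

_Z95 = float(stats.norm.ppf(0.975))

#: Covariate sets for the nested adjustment models (logistic setting).
ADJUSTMENT_SETS: dict[str, tuple[str, ...]] = {
    "unadjusted": (),
    "M1": ("age_baseline", "sex"),
    "M2": ("age_baseline", "sex", "tc", "hdl", "ldl"),
    "M3": (
        "age_baseline", "sex", "tc", "hdl", "ldl",
        "bmi", "smoking", "diabetes", "lipid_lowering_tx",
    ),
}

#: The 13 lipid predictors: seven species plus six ratios.
LIPID_PREDICTORS: tuple[str, ...] = (
    "cer_16_0",
    "cer_18_0",
    "cer_24_0",
    "cer_24_1",
    "pc_14_0_22_6",
    "pc_16_0_16_0",
    "pc_16_0_22_5",
    "cer_16_0_over_cer_24_0",
    "cer_18_0_over_cer_24_0",
    "cer_24_1_over_cer_24_0",
    "cer_16_0_over_pc_16_0_22_5",
    "cer_18_0_over_pc_14_0_22_6",
    "cer_18_0_over_cer_16_0",
)

_RATIO_PARTS: dict[str, tuple[str, str]] = {
    "cer_16_0_over_cer_24_0": ("cer_16_0", "cer_24_0"),
    "cer_18_0_over_cer_24_0": ("cer_18_0", "cer_24_0"),
    "cer_24_1_over_cer_24_0": ("cer_24_1", "cer_24_0"),
    "cer_16_0_over_pc_16_0_22_5": ("cer_16_0", "pc_16_0_22_5"),
    "cer_18_0_over_pc_14_0_22_6": ("cer_18_0", "pc_14_0_22_6"),
    "cer_18_0_over_cer_16_0": ("cer_18_0", "cer_16_0"),
}

SCORE_PREDICTORS: tuple[str, ...] = ("cert1", "cert2")


@dataclass(frozen=True)
class AdjustmentModel:
    """A labelled, ordered covariate set."""

    label: str
    covariates: tuple[str, ...]

    @classmethod
    def named(cls, label: str) -> "AdjustmentModel":
        if label not in ADJUSTMENT_SETS:
            raise ConfigurationError(
                f"unknown adjustment model {label!r}; known: {sorted(ADJUSTMENT_SETS)}"
            )
        return cls(label, ADJUSTMENT_SETS[label])


@dataclass(frozen=True)
class AssociationResult:
    """One fitted effect: OR or HR with Wald 95% CI."""

    predictor: str
    outcome: str          # "prevalent" | "new_onset"
    model_label: str
    effect_type: str      # "OR" | "HR"
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_used: int
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("confidence interval does not bracket the estimate")

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def classify_prevalent(sbp, dbp, bp_tx):
    """Prevalent hypertension: on BP-lowering treatment, or SBP >= 140 mmHg,
    or DBP >= 90 mmHg.  Vectorised over array inputs."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    bp_tx = np.asarray(bp_tx, dtype=bool)
    out = bp_tx | (sbp >= 140.0) | (dbp >= 90.0)
    return bool(out) if out.ndim == 0 else out


def standardize_predictor(values) -> np.ndarray:
    """Center and scale to zero mean / unit SD (sample SD, ddof=1)."""
    arr = np.asarray(values, dtype=float)
    finite = arr[np.isfinite(arr)]
    if np.unique(finite).size < 2:
        raise DegeneratePredictorError("predictor is constant; cannot standardize")
    sd = float(np.std(finite, ddof=1))
    return (arr - float(np.mean(finite))) / sd


def _is_lipid_predictor(name: str) -> bool:
    return name in LIPID_PREDICTORS or name in scoring.LIPID_SPECIES or name in _RATIO_PARTS


def prepare_predictors(
    cohort: pd.DataFrame,
    predictors: Sequence[str],
    standardize_lipids: bool = True,
    log_transform_lipids: bool = False,
) -> pd.DataFrame:
    """Return a copy of ``cohort`` with all requested predictor columns
    materialised: CERT totals (``cert1``/``cert2``, raw points, cohort-internal
    quartiles), lipid ratio columns, and per-SD standardization of lipid
    predictors."""
    df = cohort.copy()
    for name in predictors:
        if name in SCORE_PREDICTORS:
            if name not in df.columns:
                scores, _ = scoring.score_cohort(df, name.upper())
                df[name] = scores["total"].reindex(df.index)
        elif name in _RATIO_PARTS:
            if name not in df.columns:
                num, den = _RATIO_PARTS[name]
                df[name] = df[num] / df[den]
        elif name not in df.columns:
            raise ConfigurationError(
                f"unknown predictor {name!r}; valid: {sorted(set(SCORE_PREDICTORS) | set(LIPID_PREDICTORS))}"
            )
        if _is_lipid_predictor(name):
            vals = df[name].astype(float)
            if log_transform_lipids:
                vals = np.log(vals)
            if standardize_lipids:
                df[name] = standardize_predictor(vals)
            else:
                df[name] = vals
    return df


def _design_columns(df: pd.DataFrame, names: Iterable[str]) -> pd.DataFrame:
    """Numeric design block; 'sex' becomes a male indicator, booleans 0/1."""
    out = {}
    for name in names:
        if name == "sex":
            out["sex_male"] = (df["sex"] == "male").astype(float)
        else:
            if name not in df.columns:
                raise ConfigurationError(f"covariate column {name!r} missing from cohort")
            out[name] = df[name].astype(float)
    return pd.DataFrame(out, index=df.index)


def fit_prevalent(
    cohort: pd.DataFrame,
    predictor: str,
    model: AdjustmentModel | str = "unadjusted",
) -> AssociationResult:
    """Logistic regression of prevalent hypertension on one predictor.

    The outcome is the ``prevalent_htn`` column if present, else derived from
    SBP/DBP/treatment via :func:`classify_prevalent`.  Complete-case on the
    used columns; returns the Wald OR per unit predictor.
    """
    if isinstance(model, str):
        model = AdjustmentModel.named(model)
    if "prevalent_htn" in cohort.columns:
        y = cohort["prevalent_htn"].astype(bool)
    else:
        y = pd.Series(
            classify_prevalent(cohort["sbp"], cohort["dbp"], cohort["bp_lowering_tx"]),
            index=cohort.index,
        )
    X = _design_columns(cohort, (predictor, *model.covariates))
    mask = X.notna().all(axis=1) & y.notna()
    n_total = len(cohort)
    X, y = X.loc[mask], y.loc[mask].astype(float)
    n_used = int(len(X))
    if n_used < len(X.columns) + 2:
        raise DataError(f"too few complete cases ({n_used}) to fit {model.label}")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y.to_numpy(), Xc).fit(disp=0, maxiter=200)
    except Exception as exc:  # statsmodels raises PerfectSeparationError etc.
        raise ConvergenceError(
            f"logistic fit failed for predictor {predictor!r} ({model.label}): {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise ConvergenceError(
            f"logistic fit did not converge for predictor {predictor!r} "
            f"({model.label}); possible complete separation"
        )
    key = predictor if predictor != "sex" else "sex_male"
    beta = float(fit.params[key])
    se = float(fit.bse[key])
    return AssociationResult(
        predictor=predictor,
        outcome="prevalent",
        model_label=model.label,
        effect_type="OR",
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(fit.pvalues[key]),
        n_used=n_used,
        n_excluded=n_total - n_used,
    )


def _cox_covariates(model: AdjustmentModel) -> tuple[str, ...]:
    """Cox models drop age (it is the timescale) and sex (a stratum)."""
    return tuple(c for c in model.covariates if c not in ("age_baseline", "sex"))


def fit_new_onset(
    cohort: pd.DataFrame,
    predictor: str,
    model: AdjustmentModel | str = "unadjusted",
) -> AssociationResult:
    """Cox regression of new-onset hypertension with age as the timescale.

    Prevalent subjects are excluded; entry is baseline age, exit the age at
    onset or censoring (left truncation), sex is a stratifying variable and
    ties are handled by the Efron approximation.  The M1 (age + sex) model is
    not fitted: age is the time axis and sex the stratum.
    """
    if isinstance(model, str):
        model = AdjustmentModel.named(model)
    if model.label == "M1":
        raise ConfigurationError(
            "M1 (age + sex) is not fitted for new-onset hypertension: "
            "age is the timescale and sex a stratum"
        )
    n_total = len(cohort)
    if "prevalent_htn" in cohort.columns:
        at_risk = cohort.loc[~cohort["prevalent_htn"].astype(bool)]
    else:
        prev = classify_prevalent(
            cohort["sbp"], cohort["dbp"], cohort["bp_lowering_tx"]
        )
        at_risk = cohort.loc[~prev]

    bad = at_risk["age_at_event_or_censor"] <= at_risk["age_baseline"]
    if bad.any():
        sid = at_risk.loc[bad, "subject_id"].iloc[0] if "subject_id" in at_risk else "?"
        raise DataError(
            f"subject {sid}: age at event/censor does not exceed baseline age"
        )

    X = _design_columns(at_risk, (predictor, *_cox_covariates(model)))
    frame = X.copy()
    frame["_entry"] = at_risk["age_baseline"].astype(float)
    frame["_exit"] = at_risk["age_at_event_or_censor"].astype(float)
    frame["_event"] = at_risk["event_new_onset"].astype(bool)
    frame["_sex"] = at_risk["sex"].astype(str)
    frame = frame.dropna()
    n_used = int(len(frame))

    events_per_stratum = frame.groupby("_sex", observed=True)["_event"].sum()
    empty = events_per_stratum[events_per_stratum == 0]
    if len(empty) or n_used == 0:
        name = empty.index[0] if len(empty) else "<all>"
        raise DataError(f"no new-onset events in stratum {name!r}; cannot fit Cox model")

    cph = CoxPHFitter()  # lifelines uses the Efron tie approximation
    try:
        cph.fit(
            frame,
            duration_col="_exit",
            event_col="_event",
            entry_col="_entry",
            strata=["_sex"],
            show_progress=False,
        )
    except Exception as exc:
        raise ConvergenceError(
            f"Cox fit failed for predictor {predictor!r} ({model.label}): {exc}"
        ) from exc
    key = predictor if predictor != "sex" else "sex_male"
    beta = float(cph.params_[key])
    se = float(cph.standard_errors_[key])
    return AssociationResult(
        predictor=predictor,
        outcome="new_onset",
        model_label=model.label,
        effect_type="HR",
        estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        p_value=float(cph.summary.loc[key, "p"]),
        n_used=n_used,
        n_excluded=n_total - n_used,
    )


def fit_sex_interaction(
    cohort: pd.DataFrame,
    predictor: str,
    outcome: str,
    model: AdjustmentModel | str = "unadjusted",
) -> float:
    """Wald p-value for a sex x predictor interaction term.

    For the prevalent outcome the interaction enters a pooled logistic model
    alongside a main sex effect; for new-onset it enters the sex-stratified
    Cox model (the sex main effect lives in the stratum baselines).
    """
    if isinstance(model, str):
        model = AdjustmentModel.named(model)
    df = cohort.copy()
    inter = f"{predictor}_x_male"
    df[inter] = df[predictor].astype(float) * (df["sex"] == "male").astype(float)
    if outcome == "prevalent":
        covs = tuple(dict.fromkeys((*model.covariates, "sex", inter)))
        X = _design_columns(df, (predictor, *covs))
        y = df["prevalent_htn"].astype(float)
        mask = X.notna().all(axis=1)
        fit = sm.Logit(y.loc[mask].to_numpy(), sm.add_constant(X.loc[mask])).fit(
            disp=0, maxiter=200
        )
        return float(fit.pvalues[inter])
    elif outcome == "new_onset":
        covs = (*_cox_covariates(model), inter)
        at_risk = df.loc[~df["prevalent_htn"].astype(bool)]
        frame = _design_columns(at_risk, (predictor, *covs))
        frame["_entry"] = at_risk["age_baseline"].astype(float)
        frame["_exit"] = at_risk["age_at_event_or_censor"].astype(float)
        frame["_event"] = at_risk["event_new_onset"].astype(bool)
        frame["_sex"] = at_risk["sex"].astype(str)
        cph = CoxPHFitter()
        cph.fit(
            frame.dropna(), duration_col="_exit", event_col="_event",
            entry_col="_entry", strata=["_sex"],
        )
        return float(cph.summary.loc[inter, "p"])
    raise ConfigurationError(f"unknown outcome {outcome!r}")


def run_association_suite(
    cohort: pd.DataFrame,
    predictors: Sequence[str] | None = None,
    outcomes: Sequence[str] = ("prevalent", "new_onset"),
    models: Sequence[str] | None = None,
    standardize_lipids: bool = True,
    log_transform_lipids: bool = False,
    sex_stratified: bool = False,
) -> pd.DataFrame:
    """Fit every predictor x outcome x adjustment-model combination.

    Default predictors are the two CERT totals plus the 13 lipid
    species/ratios; default models are unadjusted, M1, M2 and M3, with the
    M1 Cox fits skipped (age is the timescale).  Returns a tidy DataFrame in
    a stable order with a ``significant`` flag at raw p < 0.05.  With
    ``sex_stratified=True``, per-sex refits (models without the sex term) are
    appended with model labels suffixed ``:male`` / ``:female``.
    """
    if predictors is None:
        predictors = (*SCORE_PREDICTORS, *LIPID_PREDICTORS)
    for p in predictors:
        if p not in SCORE_PREDICTORS and p not in LIPID_PREDICTORS and p not in cohort.columns:
            raise ConfigurationError(
                f"unknown predictor {p!r}; valid: "
                f"{sorted(set(SCORE_PREDICTORS) | set(LIPID_PREDICTORS))}"
            )
    if models is None:
        models = ("unadjusted", "M1", "M2", "M3")
    for o in outcomes:
        if o not in ("prevalent", "new_onset"):
            raise ConfigurationError(f"unknown outcome {o!r}")

    df = prepare_predictors(
        cohort, predictors,
        standardize_lipids=standardize_lipids,
        log_transform_lipids=log_transform_lipids,
    )

    results: list[AssociationResult] = []
    for outcome in outcomes:
        for predictor in predictors:
            for label in models:
                if outcome == "new_onset" and label == "M1":
                    continue  # age is the timescale; sex a stratum
                fit = fit_prevalent if outcome == "prevalent" else fit_new_onset
                results.append(fit(df, predictor, label))
    rows = [
        {
            "predictor": r.predictor,
            "outcome": r.outcome,
            "model": r.model_label,
            "effect_type": r.effect_type,
            "estimate": r.estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "n_used": r.n_used,
            "significant": r.significant,
        }
        for r in results
    ]

    if sex_stratified:
        for sex in ("male", "female"):
            sub = df.loc[df["sex"] == sex]
            for outcome in outcomes:
                for predictor in predictors:
                    for label in models:
                        if outcome == "new_onset" and label == "M1":
                            continue
                        base = AdjustmentModel.named(label)
                        covs = tuple(c for c in base.covariates if c != "sex")
                        m = AdjustmentModel(label, covs)
                        fit = fit_prevalent if outcome == "prevalent" else fit_new_onset
                        r = fit(sub, predictor, m)
                        rows.append({
                            "predictor": r.predictor,
                            "outcome": r.outcome,
                            "model": f"{label}:{sex}",
                            "effect_type": r.effect_type,
                            "estimate": r.estimate,
                            "ci_low": r.ci_low,
                            "ci_high": r.ci_high,
                            "p_value": r.p_value,
                            "n_used": r.n_used,
                            "significant": r.significant,
                        })
    return pd.DataFrame(rows)
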