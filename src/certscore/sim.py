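"""Synthetic FINRISK-like cohort generator.

Simulates a population survey cohort of adults aged 25-74 with the seven
lipid species used by the CERT scores, clinical covariates, baseline blood
pressure, prevalent-hypertension status and new-onset hypertension over a
10-year follow-up.  Marginal means/SDs/prevalences default to the observed
baseline characteristics of the hypertension-free FINRISK 2002 stratum; joint
structure (lipid correlations, outcome models) is configurable.

Generative model
----------------
* lipids: multivariate log-normal — a 7-dimensional Gaussian on the log scale
  with configurable per-species location/scale and correlation matrix;
* prevalent hypertension: Bernoulli from a logistic model whose linear
  predictor may include covariates and the subject's CERT total (computed
  from the simulated lipids with cohort-internal quartiles);
* blood pressure and treatment flag are drawn *conditionally on* prevalent
  status so that the clinical threshold rule (treated, or SBP >= 140, or
  DBP >= 90) reproduces the simulated indicator exactly;
* new-onset hypertension (among the prevalent-free): onset age from a
  Weibull proportional-hazards model on the attained-age timescale, censored
  at baseline age + follow-up or at a competing exponential death time.

Reproducibility: one master seed; independent sub-streams are derived per
variable block via ``numpy.random.SeedSequence.spawn``, so adding a block
never perturbs earlier ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import scoring
from .errors import ConfigurationError

__all__ = ["SimulationConfig", "default_finrisk_config", "simulate_cohort"]


def _default_lipid_correlation() -> np.ndarray:
    """0.4 within lipid class (ceramide/PC), 0.2 across classes."""
    n = len(scoring.LIPID_SPECIES)
    is_cer = np.array([s.startswith("cer") for s in scoring.LIPID_SPECIES])
    corr = np.where(is_cer[:, None] == is_cer[None, :], 0.4, 0.2)
    np.fill_diagonal(corr, 1.0)
    assert corr.shape == (n, n)
    return corr


# Typical plasma concentrations (micromol/L-ish; common fixed unit, arbitrary
# scale): geometric means per species.
_DEFAULT_LIPID_GEOMETRIC_MEANS: Mapping[str, float] = {
    "cer_16_0": 0.22,
    "cer_18_0": 0.055,
    "cer_24_0": 2.6,
    "cer_24_1": 1.0,
    "pc_14_0_22_6": 2.2,
    "pc_16_0_22_5": 4.5,
    "pc_16_0_16_0": 13.0,
}


@dataclass
class SimulationConfig:
    """Full parameterisation of one simulated cohort.

    Effect-size dictionaries (``prevalent_logit_coefs``,
    ``incident_log_hr_coefs``) map covariate names to coefficients; valid
    names are any numeric cohort column, ``male`` (1 for men) and the score
    totals ``cert1`` / ``cert2``.  ``prevalent_logit_coefs`` additionally
    takes an ``intercept`` key (log-odds); the incident model's baseline is
    carried by the Weibull hazard, so it has no intercept.
    """

    n_subjects: int = 7722
    seed: int = 0
    age_mean: float = 46.7
    age_sd: float = 12.9
    age_range: tuple[float, float] = (25.0, 74.0)
    male_fraction: float = 0.462
    lipid_log_means: dict[str, float] = field(
        default_factory=lambda: {
            k: float(np.log(v)) for k, v in _DEFAULT_LIPID_GEOMETRIC_MEANS.items()
        }
    )
    lipid_log_sds: dict[str, float] = field(
        default_factory=lambda: {k: 0.35 for k in scoring.LIPID_SPECIES}
    )
    lipid_correlation: np.ndarray = field(default_factory=_default_lipid_correlation)
    covariate_params: dict[str, tuple] = field(
        default_factory=lambda: {
            # continuous: (mean, sd) — hypertension-free FINRISK stratum
            "bmi": (26.5, 4.5),
            "waist": (88.2, 13.1),
            "tg": (1.4, 0.9),        # log-normal (right-skewed)
            "tc": (5.6, 1.1),
            "hdl": (1.5, 0.4),
            "ldl": (3.4, 0.9),       # not tabulated; Friedewald-consistent
            "crp": (2.4, 4.9),       # log-normal (right-skewed)
            # binary: (prevalence,)
            "smoking": (0.269,),
            "diabetes": (0.042,),
            "lipid_lowering_tx": (0.052,),
        }
    )
    # Calibrated so that overall prevalence ~= 11.3% (875/7722) under the
    # default marginals; cert2 enters at 0.10 log-odds per point.
    prevalent_logit_coefs: dict[str, float] = field(
        default_factory=lambda: {
            "intercept": -9.26,
            "age": 0.075,
            "male": 0.20,
            "bmi": 0.10,
            "cert2": 0.10,
        }
    )
    # Per-point/per-unit log hazard ratios for onset; baseline Weibull below.
    incident_log_hr_coefs: dict[str, float] = field(
        default_factory=lambda: {"bmi": 0.06, "smoking": 0.15, "cert2": 0.08}
    )
    # Weibull hazard on the age axis: H0(a) = (a / scale)^shape.  Shape > 1
    # makes onset risk rise with age; scale calibrated so ~18% of the
    # prevalent-free develop hypertension within the 10-year follow-up.
    baseline_hazard_params: dict[str, float] = field(
        default_factory=lambda: {"shape": 5.0, "scale": 109.5}
    )
    followup_years: float = 10.0
    death_rate: float = 0.0097  # per person-year, independent censoring
    # BP-generation parameters, conditional on prevalent status (mmHg).
    bp_params: dict[str, float] = field(
        default_factory=lambda: {
            "sbp_mean_normo": 133.0, "sbp_sd_normo": 19.5,
            "dbp_mean_normo": 78.0, "dbp_sd_normo": 11.1,
            "sbp_mean_hyper": 162.0, "sbp_sd_hyper": 19.7,
            "dbp_mean_hyper": 84.0, "dbp_sd_hyper": 10.4,
            "treated_fraction_hyper": 0.906,
        }
    )

    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ConfigurationError(f"age_range inverted: ({lo}, {hi})")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigurationError("male_fraction must be in [0, 1]")
        if self.followup_years <= 0:
            raise ConfigurationError("followup_years must be > 0")
        corr = np.asarray(self.lipid_correlation, dtype=float)
        k = len(scoring.LIPID_SPECIES)
        if corr.shape != (k, k):
            raise ConfigurationError(f"lipid_correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-10):
            raise ConfigurationError("lipid_correlation is not symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-10):
            raise ConfigurationError("lipid_correlation diagonal must be 1")
        if np.linalg.eigvalsh(corr).min() < -1e-8:
            raise ConfigurationError(
                "lipid_correlation is not positive semi-definite"
            )
        for name in scoring.LIPID_SPECIES:
            if name not in self.lipid_log_means or name not in self.lipid_log_sds:
                raise ConfigurationError(f"missing lipid parameters for {name!r}")
        shape = self.baseline_hazard_params.get("shape", 0)
        scale = self.baseline_hazard_params.get("scale", 0)
        if shape <= 0 or scale <= 0:
            raise ConfigurationError("baseline_hazard_params shape/scale must be > 0")

    # ------------------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["lipid_correlation"] = np.asarray(self.lipid_correlation).tolist()
        d["age_range"] = list(self.age_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "lipid_correlation" in d:
            d["lipid_correlation"] = np.asarray(d["lipid_correlation"], dtype=float)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "covariate_params" in d:
            d["covariate_params"] = {
                k: tuple(v) for k, v in dict(d["covariate_params"]).items()
            }
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_finrisk_config(n_subjects: int = 7722, seed: int = 0) -> SimulationConfig:
    """Config whose marginals match the hypertension-free survey stratum
    (age 46.7 +- 12.9, 46.2% men, BMI 26.5 +- 4.5, diabetes 4.2%, ...)."""
    return SimulationConfig(n_subjects=n_subjects, seed=seed)


# ----------------------------------------------------------------------
def _truncated_normal(rng, mean, sd, lo, hi, size=None):
    """Vectorised truncated normal; ``mean``/``lo``/``hi`` may be arrays."""
    mean = np.asarray(mean, dtype=float)
    a = (np.asarray(lo, dtype=float) - mean) / sd
    b = (np.asarray(hi, dtype=float) - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _truncated_normal_matched(rng, mean, sd, lo, hi, size):
    """Truncated normal whose *post-truncation* mean equals ``mean``.

    Truncation shifts the mean of a plain truncated normal (for age on
    [25, 74] by ~+0.7 y), so the location parameter is solved for instead;
    this keeps the generator calibrated to the configured marginal means.
    """
    from scipy.optimize import brentq

    def shifted_mean(loc):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean

    if shifted_mean(mean) == 0.0:
        loc = float(mean)
    else:
        loc = brentq(shifted_mean, mean - 3 * sd, mean + 3 * sd, xtol=1e-8)
    return _truncated_normal(rng, loc, sd, lo, hi, size=size)


def _lognormal_from_moments(rng, mean, sd, size):
    """Log-normal draws with the requested arithmetic mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - s2 / 2.0
    return rng.lognormal(mu, np.sqrt(s2), size=size)


def _linear_predictor(coefs: Mapping[str, float], frame: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(frame), float(coefs.get("intercept", 0.0)))
    for name, beta in coefs.items():
        if name == "intercept":
            continue
        if name == "age":
            name = "age_baseline"
        if name not in frame.columns:
            raise ConfigurationError(
                f"effect coefficient refers to unknown column {name!r}"
            )
        lp += float(beta) * frame[name].to_numpy(dtype=float)
    return lp


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Generate a cohort DataFrame of exactly ``config.n_subjects`` records.

    Deterministic given ``(config, config.seed)``.  Columns follow the cohort
    table dialect (see :mod:`certscore.io`).
    """
    config.validate()
    n = config.n_subjects
    ss = np.random.SeedSequence(config.seed)
    (s_demo, s_lip, s_cov, s_prev, s_bp, s_inc, s_death) = ss.spawn(7)
    rng_demo = np.random.default_rng(s_demo)
    rng_lip = np.random.default_rng(s_lip)
    rng_cov = np.random.default_rng(s_cov)
    rng_prev = np.random.default_rng(s_prev)
    rng_bp = np.random.default_rng(s_bp)
    rng_inc = np.random.default_rng(s_inc)
    rng_death = np.random.default_rng(s_death)

    df = pd.DataFrame(
        {"subject_id": [f"S{i + 1:06d}" for i in range(n)]}
    )

    # demographics ---------------------------------------------------
    lo, hi = config.age_range
    df["age_baseline"] = _truncated_normal_matched(
        rng_demo, config.age_mean, config.age_sd, lo, hi, size=n
    )
    male = rng_demo.random(n) < config.male_fraction
    df["sex"] = np.where(male, "male", "female")
    df["male"] = male.astype(int)

    # lipids: multivariate log-normal --------------------------------
    corr = np.asarray(config.lipid_correlation, dtype=float)
    evals, evecs = np.linalg.eigh(corr)
    root = evecs @ np.diag(np.sqrt(np.clip(evals, 0.0, None)))
    z = rng_lip.standard_normal((n, len(scoring.LIPID_SPECIES))) @ root.T
    for j, name in enumerate(scoring.LIPID_SPECIES):
        df[name] = np.exp(
            config.lipid_log_means[name] + config.lipid_log_sds[name] * z[:, j]
        )

    # clinical covariates --------------------------------------------
    cp = config.covariate_params
    df["bmi"] = _truncated_normal_matched(rng_cov, *cp["bmi"], 14.0, 60.0, size=n)
    df["waist"] = _truncated_normal_matched(rng_cov, *cp["waist"], 50.0, 180.0, size=n)
    df["tg"] = _lognormal_from_moments(rng_cov, *cp["tg"], size=n)
    df["tc"] = _truncated_normal_matched(rng_cov, *cp["tc"], 2.0, 12.0, size=n)
    df["hdl"] = _truncated_normal_matched(rng_cov, *cp["hdl"], 0.4, 4.0, size=n)
    df["ldl"] = _truncated_normal_matched(rng_cov, *cp["ldl"], 0.5, 10.0, size=n)
    df["crp"] = _lognormal_from_moments(rng_cov, *cp["crp"], size=n)
    df["smoking"] = rng_cov.random(n) < cp["smoking"][0]
    df["diabetes"] = rng_cov.random(n) < cp["diabetes"][0]
    df["lipid_lowering_tx"] = rng_cov.random(n) < cp["lipid_lowering_tx"][0]

    # CERT totals (cohort-internal quartiles) drive the outcome models
    work = df.copy()
    if n >= 4:
        for score in ("CERT1", "CERT2"):
            scores, _ = scoring.score_cohort(df, score)
            work[score.lower()] = scores["total"].to_numpy()
    else:  # too few subjects for quartiles; score contributes nothing
        work["cert1"] = 0.0
        work["cert2"] = 0.0

    # prevalent hypertension -----------------------------------------
    lp_prev = _linear_predictor(config.prevalent_logit_coefs, work)
    p_prev = 1.0 / (1.0 + np.exp(-lp_prev))
    prevalent = rng_prev.random(n) < p_prev
    df["prevalent_htn"] = prevalent

    # blood pressure, consistent with prevalent status ---------------
    bp = config.bp_params
    sbp = np.empty(n)
    dbp = np.empty(n)
    bp_tx = np.zeros(n, dtype=bool)
    normo = ~prevalent
    sbp[normo] = _truncated_normal(
        rng_bp, bp["sbp_mean_normo"], bp["sbp_sd_normo"], 85.0, 139.9,
        size=int(normo.sum()),
    )
    dbp[normo] = _truncated_normal(
        rng_bp, bp["dbp_mean_normo"], bp["dbp_sd_normo"],
        40.0, np.minimum(89.9, sbp[normo] - 5.0),
    )
    n_hyp = int(prevalent.sum())
    if n_hyp:
        treated = rng_bp.random(n_hyp) < bp["treated_fraction_hyper"]
        bp_tx[prevalent] = treated
        sbp_h = np.empty(n_hyp)
        # untreated prevalent cases must exceed a BP threshold
        sbp_h[~treated] = _truncated_normal(
            rng_bp, bp["sbp_mean_hyper"], bp["sbp_sd_hyper"], 140.0, 250.0,
            size=int((~treated).sum()),
        )
        sbp_h[treated] = _truncated_normal(
            rng_bp, bp["sbp_mean_hyper"] - 8.0, bp["sbp_sd_hyper"], 95.0, 250.0,
            size=int(treated.sum()),
        )
        sbp[prevalent] = sbp_h
        dbp[prevalent] = _truncated_normal(
            rng_bp, bp["dbp_mean_hyper"], bp["dbp_sd_hyper"],
            40.0, sbp_h - 5.0,
        )
    df["sbp"] = sbp
    df["dbp"] = dbp
    df["bp_lowering_tx"] = bp_tx

    # new-onset hypertension on the age timescale --------------------
    shape = float(config.baseline_hazard_params["shape"])
    scale = float(config.baseline_hazard_params["scale"])
    lp_inc = _linear_predictor(config.incident_log_hr_coefs, work)
    a0 = df["age_baseline"].to_numpy()
    u = rng_inc.random(n)
    # conditional on being onset-free at a0: (T/scale)^shape =
    # (a0/scale)^shape - ln(U)/exp(lp)
    t_onset = scale * (
        (a0 / scale) ** shape - np.log(u) / np.exp(lp_inc)
    ) ** (1.0 / shape)
    if config.death_rate > 0:
        t_death = a0 + rng_death.exponential(1.0 / config.death_rate, size=n)
    else:
        t_death = np.full(n, np.inf)
    t_admin = a0 + config.followup_years

    onset_first = (~prevalent) & (t_onset <= t_death) & (t_onset <= t_admin)
    exit_age = np.minimum(t_death, t_admin)
    exit_age[onset_first] = t_onset[onset_first]
    died = (~onset_first) & (t_death <= t_admin)
    df["event_new_onset"] = onset_first
    df["age_at_event_or_censor"] = exit_age
    df["died"] = died

    from .io import COHORT_COLUMNS

    df = df[list(COHORT_COLUMNS)]
    assert len(df) == n
    assert (df["age_at_event_or_censor"] > df["age_baseline"]).all()
    assert (df["sbp"] > df["dbp"]).all() and (df["dbp"] > 0).all()
    return df
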