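"""Baseline-characteristics ("Table 1"-style) reports and wide result tables.

Continuous variables are summarised as mean (SD) with a Welch two-sample
t-test between groups; categorical variables as count (percentage, one
decimal) with a Pearson chi-square test (no continuity correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DataError

__all__ = ["BaselineTable", "baseline_table", "percentage", "format_cert_table"]

CONTINUOUS_VARS: tuple[str, ...] = (
    "age_baseline", "bmi", "waist", "tg", "tc", "hdl", "crp", "sbp", "dbp",
)
CATEGORICAL_VARS: tuple[str, ...] = (
    "male", "smoking", "diabetes", "lipid_lowering_tx", "bp_lowering_tx", "died",
)


def percentage(count: int, n: int) -> float:
    """count / n as a percentage rounded to one decimal (Table-1 convention)."""
    if n <= 0:
        raise DataError("group size must be positive")
    return round(count / n * 100.0, 1)


@dataclass
class BaselineTable:
    """Per-group baseline characteristics with between-group p-values."""

    grouping: str
    group_labels: tuple[str, str]
    group_ns: tuple[int, int]
    rows: list[dict] = field(default_factory=list)

    @property
    def n_total(self) -> int:
        return sum(self.group_ns)

    def to_frame(self) -> pd.DataFrame:
        cols = ["variable", "type"]
        for lab in self.group_labels:
            cols += [f"{lab}_display", f"{lab}_stat1", f"{lab}_stat2"]
        cols.append("p_value")
        return pd.DataFrame(self.rows, columns=cols)


def _groups(cohort: pd.DataFrame, grouping: str):
    if grouping == "prevalent_status":
        g = cohort["prevalent_htn"].astype(bool)
        return (
            ("without_hypertension", cohort.loc[~g]),
            ("with_hypertension", cohort.loc[g]),
        )
    if grouping == "new_onset_status":
        base = cohort.loc[~cohort["prevalent_htn"].astype(bool)]
        e = base["event_new_onset"].astype(bool)
        return (
            ("no_new_onset", base.loc[~e]),
            ("new_onset", base.loc[e]),
        )
    if grouping == "sex":
        return (
            ("male", cohort.loc[cohort["sex"] == "male"]),
            ("female", cohort.loc[cohort["sex"] == "female"]),
        )
    raise ConfigurationError(
        f"unknown grouping {grouping!r}; valid: prevalent_status, new_onset_status, sex"
    )


def baseline_table(
    cohort: pd.DataFrame,
    grouping: str = "prevalent_status",
    continuous: Sequence[str] | None = None,
    categorical: Sequence[str] | None = None,
) -> BaselineTable:
    """Two-group baseline table in the survey-report style.

    Continuous rows show ``mean (sd)`` (one decimal) with a Welch t-test;
    categorical rows show ``n (pct%)`` with a Pearson chi-square test.  The
    ``male`` pseudo-variable is derived from ``sex``.
    """
    df = cohort.copy()
    df["male"] = (df["sex"] == "male").astype(bool)
    pairs = _groups(df, grouping)
    for lab, sub in pairs:
        if len(sub) == 0:
            raise DataError(f"group {lab!r} is empty")
    if continuous is None:
        continuous = [c for c in CONTINUOUS_VARS if c in df.columns]
        continuous += [c for c in ("cert1", "cert2") if c in df.columns]
    if categorical is None:
        categorical = [c for c in CATEGORICAL_VARS if c in df.columns]
        if grouping == "sex":
            categorical = [c for c in categorical if c != "male"]

    labels = tuple(lab for lab, _ in pairs)
    ns = tuple(len(sub) for _, sub in pairs)
    table = BaselineTable(grouping=grouping, group_labels=labels, group_ns=ns)

    for var in continuous:
        row = {"variable": var, "type": "continuous"}
        samples = []
        for lab, sub in pairs:
            vals = sub[var].astype(float).dropna()
            m, s = float(vals.mean()), float(vals.std(ddof=1))
            row[f"{lab}_display"] = f"{m:.1f} ({s:.1f})"
            row[f"{lab}_stat1"] = m
            row[f"{lab}_stat2"] = s
            samples.append(vals.to_numpy())
        try:
            _, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
            row["p_value"] = float(p)
        except Exception:
            row["p_value"] = float("nan")
        table.rows.append(row)

    for var in categorical:
        row = {"variable": var, "type": "categorical"}
        counts = []
        for lab, sub in pairs:
            k = int(sub[var].astype(bool).sum())
            n = len(sub)
            pct = percentage(k, n)
            row[f"{lab}_display"] = f"{k} ({pct}%)"
            row[f"{lab}_stat1"] = k
            row[f"{lab}_stat2"] = pct
            counts.append((k, n - k))
        tab = np.array(counts)
        if (tab.sum(axis=0) > 0).all():
            _, p, _, _ = stats.chi2_contingency(tab, correction=False)
            row["p_value"] = float(p)
        else:
            row["p_value"] = float("nan")
        table.rows.append(row)

    return table


def format_cert_table(results: pd.DataFrame) -> pd.DataFrame:
    """Wide OR/HR table for the CERT scores across adjustment models.

    One row per score x model (unadjusted, M1, M2, M3) with paired
    prevalent-hypertension OR and new-onset HR columns; the new-onset M1
    cells are dashes (that model is not fitted — age is the timescale).
    """
    rows = []
    for model in ("unadjusted", "M1", "M2", "M3"):
        for score in ("cert1", "cert2"):
            sub = results[(results["predictor"] == score) & (results["model"] == model)]
            row = {"score": score.upper(), "model": model}
            for outcome, eff in (("prevalent", "OR"), ("new_onset", "HR")):
                hit = sub[sub["outcome"] == outcome]
                if len(hit):
                    r = hit.iloc[0]
                    row[f"{eff} (95% CI)"] = (
                        f"{r['estimate']:.2f} ({r['ci_low']:.2f}-{r['ci_high']:.2f})"
                    )
                    row[f"{eff}_p"] = float(r["p_value"])
                else:
                    row[f"{eff} (95% CI)"] = "-"
                    row[f"{eff}_p"] = float("nan")
            rows.append(row)
    wide = pd.DataFrame(rows)
    # keep only rows where at least one outcome was fitted
    fitted = (wide["OR (95% CI)"] != "-") | (wide["HR (95% CI)"] != "-")
    return wide.loc[fitted].reset_index(drop=True)
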