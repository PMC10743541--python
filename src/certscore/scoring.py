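"""CERT1 / CERT2 ceramide- and phosphatidylcholine-based risk scores.

Both scores sum quartile points over a small panel of lipid components.  A
component is either a single species concentration or a ratio of two species.
For each component the cohort (or an external reference) defines quartile
cut-points; a subject receives points according to the quartile their
component value falls in.

* CERT1 uses six ceramide components — the concentrations of Cer(d18:1/16:0),
  Cer(d18:1/18:0) and Cer(d18:1/24:1), and their ratios to Cer(d18:1/24:0) —
  with point map (0, 0, 1, 2) per quartile, so the total spans 0-12.
* CERT2 uses four components — Cer(d18:1/24:1)/Cer(d18:1/24:0),
  Cer(d18:1/16:0)/PC(16:0/22:5), Cer(d18:1/18:0)/PC(14:0/22:6) and the
  PC(16:0/16:0) concentration — with point map (0, 1, 2, 3), again 0-12.

The cohort is a pandas DataFrame with one row per subject and one column per
lipid species (see :data:`LIPID_SPECIES`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, InsufficientDataError

logger = logging.getLogger(__name__)

#: Canonical column names for the seven measured lipid species.
LIPID_SPECIES: tuple[str, ...] = (
    "cer_16_0",       # Cer(d18:1/16:0)
    "cer_18_0",       # Cer(d18:1/18:0)
    "cer_24_0",       # Cer(d18:1/24:0)
    "cer_24_1",       # Cer(d18:1/24:1)
    "pc_14_0_22_6",   # PC(14:0/22:6)
    "pc_16_0_22_5",   # PC(16:0/22:5)
    "pc_16_0_16_0",   # PC(16:0/16:0)
)

#: Human-readable labels for reports.
LIPID_LABELS: Mapping[str, str] = {
    "cer_16_0": "Cer(d18:1/16:0)",
    "cer_18_0": "Cer(d18:1/18:0)",
    "cer_24_0": "Cer(d18:1/24:0)",
    "cer_24_1": "Cer(d18:1/24:1)",
    "pc_14_0_22_6": "PC(14:0/22:6)",
    "pc_16_0_22_5": "PC(16:0/22:5)",
    "pc_16_0_16_0": "PC(16:0/16:0)",
}


@dataclass(frozen=True)
class ScoreComponentSpec:
    """One score component: a species (or species ratio) plus its quartile point map.

    ``denominator is None`` means the raw numerator concentration is used.
    ``point_map`` gives the points awarded in quartiles Q1..Q4 and must be
    non-decreasing.
    """

    name: str
    numerator: str
    denominator: str | None = None
    point_map: tuple[int, int, int, int] = (0, 0, 1, 2)

    def __post_init__(self) -> None:
        if self.numerator == self.denominator:
            raise ConfigurationError(
                f"component {self.name!r}: numerator equals denominator"
            )
        if len(self.point_map) != 4:
            raise ConfigurationError(
                f"component {self.name!r}: point_map must have 4 entries"
            )
        if any(p < 0 for p in self.point_map):
            raise ConfigurationError(f"component {self.name!r}: negative points")
        if any(a > b for a, b in zip(self.point_map, self.point_map[1:])):
            raise ConfigurationError(
                f"component {self.name!r}: point_map must be non-decreasing Q1..Q4"
            )

    @property
    def max_points(self) -> int:
        return self.point_map[3]


@dataclass(frozen=True)
class QuartileBoundaries:
    """25th/50th/75th percentile cut-points for one score component."""

    component_name: str
    cuts: tuple[float, float, float]
    source: str = "cohort_internal"  # or "external_reference"
    degenerate: bool = False

    def __post_init__(self) -> None:
        c = self.cuts
        if not all(np.isfinite(c)):
            raise ConfigurationError(f"{self.component_name}: non-finite cut-points")
        if not self.degenerate and not (c[0] < c[1] < c[2]):
            raise ConfigurationError(
                f"{self.component_name}: cut-points must be strictly increasing"
            )


@dataclass(frozen=True)
class CategoryScheme:
    """Partition of the 0-12 total into four CVD risk bands.

    ``boundaries`` are the inclusive upper bounds of the first three bands,
    e.g. (2, 6, 9) puts totals 0-2 in *low*, 3-6 in *moderate*, 7-9 in
    *increased* and 10-12 in *high*.
    """

    score_name: str
    boundaries: tuple[int, int, int]
    labels: tuple[str, str, str, str] = ("low", "moderate", "increased", "high")

    def __post_init__(self) -> None:
        b = self.boundaries
        if not (0 <= b[0] < b[1] < b[2] <= 12):
            raise ConfigurationError(
                f"{self.score_name}: category bounds must be strictly increasing in [0, 12]"
            )

    def categorize(self, total: int | np.ndarray) -> np.ndarray:
        idx = np.searchsorted(np.asarray(self.boundaries), np.asarray(total), side="left")
        return np.asarray(self.labels, dtype=object)[idx]


@dataclass(frozen=True)
class CertScoreResult:
    """Scored subject: per-component points, 0-12 total and risk category."""

    subject_id: str
    score_name: str
    component_points: Mapping[str, int]
    total: int
    category: str


def _cert1_components() -> tuple[ScoreComponentSpec, ...]:
    m = (0, 0, 1, 2)
    return (
        ScoreComponentSpec("cer_16_0", "cer_16_0", None, m),
        ScoreComponentSpec("cer_18_0", "cer_18_0", None, m),
        ScoreComponentSpec("cer_24_1", "cer_24_1", None, m),
        ScoreComponentSpec("cer_16_0_over_cer_24_0", "cer_16_0", "cer_24_0", m),
        ScoreComponentSpec("cer_18_0_over_cer_24_0", "cer_18_0", "cer_24_0", m),
        ScoreComponentSpec("cer_24_1_over_cer_24_0", "cer_24_1", "cer_24_0", m),
    )


def _cert2_components() -> tuple[ScoreComponentSpec, ...]:
    m = (0, 1, 2, 3)
    return (
        ScoreComponentSpec("cer_24_1_over_cer_24_0", "cer_24_1", "cer_24_0", m),
        ScoreComponentSpec("cer_16_0_over_pc_16_0_22_5", "cer_16_0", "pc_16_0_22_5", m),
        ScoreComponentSpec("cer_18_0_over_pc_14_0_22_6", "cer_18_0", "pc_14_0_22_6", m),
        ScoreComponentSpec("pc_16_0_16_0", "pc_16_0_16_0", None, m),
    )


CERT1_COMPONENTS: tuple[ScoreComponentSpec, ...] = _cert1_components()
CERT2_COMPONENTS: tuple[ScoreComponentSpec, ...] = _cert2_components()

SCORE_COMPONENTS: Mapping[str, tuple[ScoreComponentSpec, ...]] = {
    "CERT1": CERT1_COMPONENTS,
    "CERT2": CERT2_COMPONENTS,
}

#: Default risk-band schemes (configurable; totals 0-12 in four bands).
DEFAULT_CATEGORY_SCHEMES: Mapping[str, CategoryScheme] = {
    "CERT1": CategoryScheme("CERT1", (2, 6, 9)),
    "CERT2": CategoryScheme("CERT2", (3, 6, 8)),
}


def component_value(
    profile: Mapping[str, float] | pd.Series, spec: ScoreComponentSpec
) -> float:
    """Component value for one subject: ratio if a denominator is set, else the
    raw concentration."""
    num = float(profile[spec.numerator])
    if spec.denominator is None:
        return num
    den = float(profile[spec.denominator])
    if den <= 0:
        sid = profile.get("subject_id", "<unknown>") if hasattr(profile, "get") else "<unknown>"
        raise DataError(
            f"subject {sid}: non-positive denominator {spec.denominator}={den} "
            f"in component {spec.name}"
        )
    return num / den


def component_values(cohort: pd.DataFrame, spec: ScoreComponentSpec) -> pd.Series:
    """Vectorised :func:`component_value` over a cohort DataFrame."""
    num = cohort[spec.numerator].astype(float)
    if spec.denominator is None:
        return num.rename(spec.name)
    den = cohort[spec.denominator].astype(float)
    bad = den <= 0
    if bad.any():
        i = cohort.index[bad][0]
        sid = cohort["subject_id"].loc[i] if "subject_id" in cohort else i
        raise DataError(
            f"subject {sid}: non-positive denominator {spec.denominator} "
            f"in component {spec.name}"
        )
    return (num / den).rename(spec.name)


def fit_quartiles(
    values: Iterable[float],
    component_name: str,
    method: str = "linear",
) -> QuartileBoundaries:
    """Quartile cut-points (25th/50th/75th percentiles) of ``values``.

    ``method`` is a numpy percentile method name; the default linearly
    interpolates between order statistics.  All-tied input yields degenerate
    (flagged) boundaries.
    """
    arr = np.asarray(list(values), dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 4:
        raise InsufficientDataError(
            f"{component_name}: need at least 4 finite values to fit quartiles, "
            f"got {arr.size}"
        )
    cuts = tuple(float(c) for c in np.percentile(arr, [25, 50, 75], method=method))
    degenerate = not (cuts[0] < cuts[1] < cuts[2])
    if degenerate:
        logger.warning("quartiles for %s are degenerate (ties): %s", component_name, cuts)
    return QuartileBoundaries(component_name, cuts, "cohort_internal", degenerate)


def assign_points(
    value: float, bounds: QuartileBoundaries, spec: ScoreComponentSpec
) -> int:
    """Points for one component value.

    Quartile membership uses half-open intervals (-inf, c1], (c1, c2],
    (c2, c3], (c3, inf): a value exactly at a cut falls in the lower quartile.
    """
    if not np.isfinite(value):
        raise DataError(f"component {spec.name}: non-finite value {value!r}")
    q = int(np.searchsorted(np.asarray(bounds.cuts), value, side="left"))
    return spec.point_map[q]


def assign_points_vector(
    values: np.ndarray | pd.Series, bounds: QuartileBoundaries, spec: ScoreComponentSpec
) -> np.ndarray:
    vals = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DataError(f"component {spec.name}: non-finite component values")
    q = np.searchsorted(np.asarray(bounds.cuts), vals, side="left")
    return np.asarray(spec.point_map, dtype=int)[q]


def score_cohort(
    cohort: pd.DataFrame,
    score_name: str = "CERT2",
    specs: Sequence[ScoreComponentSpec] | None = None,
    bounds_source: str = "cohort_internal",
    external_bounds: Mapping[str, QuartileBoundaries] | None = None,
    category_scheme: CategoryScheme | None = None,
    quantile_method: str = "linear",
) -> tuple[pd.DataFrame, dict[str, QuartileBoundaries]]:
    """Score every subject of a cohort.

    Returns ``(scores, boundaries)``.  ``scores`` has one row per scored
    subject with per-component values (``value_*``), per-component points
    (``points_*``), the 0-12 ``total`` and the risk ``category``; its
    ``attrs["n_excluded"]`` records subjects dropped for missing lipids
    (complete-case).  Quartiles are fitted once on the whole input cohort when
    ``bounds_source="cohort_internal"``; ``"external_reference"`` applies
    frozen cut-points from ``external_bounds`` instead.
    """
    if score_name not in SCORE_COMPONENTS and specs is None:
        raise ConfigurationError(
            f"unknown score {score_name!r}; known: {sorted(SCORE_COMPONENTS)}"
        )
    if specs is None:
        specs = SCORE_COMPONENTS[score_name]
    if category_scheme is None:
        category_scheme = DEFAULT_CATEGORY_SCHEMES.get(
            score_name, CategoryScheme(score_name, (2, 6, 9))
        )

    needed = sorted({s.numerator for s in specs} | {s.denominator for s in specs if s.denominator})
    missing_cols = [c for c in needed if c not in cohort.columns]
    if missing_cols:
        raise ConfigurationError(f"cohort is missing lipid columns: {missing_cols}")

    complete = cohort[needed].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info(
            "score_cohort(%s): excluded %d subject(s) with missing lipids "
            "(complete-case)", score_name, n_excluded,
        )
    data = cohort.loc[complete]

    out = pd.DataFrame(index=data.index)
    if "subject_id" in data.columns:
        out["subject_id"] = data["subject_id"]
    boundaries: dict[str, QuartileBoundaries] = {}
    total = np.zeros(len(data), dtype=int)
    for spec in specs:
        vals = component_values(data, spec)
        if bounds_source == "cohort_internal":
            b = fit_quartiles(vals, spec.name, method=quantile_method)
        elif bounds_source == "external_reference":
            if external_bounds is None or spec.name not in external_bounds:
                raise ConfigurationError(
                    f"external_reference bounds missing for component {spec.name!r}"
                )
            b = external_bounds[spec.name]
        else:
            raise ConfigurationError(f"unknown bounds_source {bounds_source!r}")
        pts = assign_points_vector(vals, b, spec)
        boundaries[spec.name] = b
        out[f"value_{spec.name}"] = vals.to_numpy()
        out[f"points_{spec.name}"] = pts
        total += pts

    out["total"] = total
    out["category"] = category_scheme.categorize(total)
    out.attrs["n_excluded"] = n_excluded
    out.attrs["score_name"] = score_name
    max_total = sum(s.max_points for s in specs)
    assert (0 <= total).all() and (total <= max_total).all()
    return out, boundaries


def max_total(score_name: str) -> int:
    """Maximum attainable total for a score (12 for both CERT1 and CERT2)."""
    return sum(s.max_points for s in SCORE_COMPONENTS[score_name])


def iter_results(
    scores: pd.DataFrame, score_name: str | None = None
) -> Iterable[CertScoreResult]:
    """Yield one :class:`CertScoreResult` per scored subject."""
    name = score_name or scores.attrs.get("score_name", "CERT")
    pt_cols = [c for c in scores.columns if c.startswith("points_")]
    for _, row in scores.iterrows():
        yield CertScoreResult(
            subject_id=str(row.get("subject_id", "")),
            score_name=name,
            component_points={c[len("points_"):]: int(row[c]) for c in pt_cols},
            total=int(row["total"]),
            category=str(row["category"]),
        )
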