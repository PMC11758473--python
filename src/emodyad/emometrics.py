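"""Emotion composites, Gini emodiversity, and reliability coefficients.

Per-valence scoring of a person's diary proceeds in three steps:

1. *daily composite* — the mean of that day's available items of one
   valence (7 negative, 9 positive items, each rated 0-4);
2. *person mean* — the unweighted mean of daily composites across the
   person's available days;
3. *emodiversity* — one minus the classical Gini inequality of the
   per-emotion totals ``c_j`` (the 0-4 ratings of item ``j`` summed over
   days), computed on the totals sorted in non-decreasing order::

       Gini = 1 - [ 2 * sum_j j * c_(j) / (m * sum_j c_(j)) - (m + 1) / m ]

   so 1 means all ``m`` emotions of the valence were felt equally often
   and the minimum 1/m means all mass fell on a single emotion.  Summed
   0-4 intensities (rather than binary daily endorsements) preserve the
   relative-abundance component of diversity alongside richness.

Reliability of the person-level means is the between-person reliability
for multi-item diary data from a generalizability-theory decomposition
(person, person-by-item, residual variance after removing fixed item
effects); Cronbach's alpha covers the single-occasion symptom scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .diary import ADOLESCENT, CAREGIVER, DailyReport, DyadRecord
from .items import ITEM_NAMES, items_for

logger = logging.getLogger(__name__)

_ITEM_INDEX = {name: i for i, name in enumerate(ITEM_NAMES)}


@dataclass
class GiniInput:
    """Aggregated per-emotion totals for one person and one valence."""

    totals: np.ndarray
    items: tuple[str, ...]

    def __post_init__(self) -> None:
        self.totals = np.asarray(self.totals, dtype=float)
        if self.totals.ndim != 1 or len(self.totals) != len(self.items):
            raise ValueError("totals must be 1-D with one entry per item")
        if np.any(self.totals < 0):
            raise ValueError("totals must be non-negative")


@dataclass
class EmotionSummary:
    dyad_id: str
    role: str
    mean_neg: float
    mean_pos: float
    gini_neg: float
    gini_pos: float
    n_days: int


@dataclass
class VarianceComponents:
    sigma2_person: float
    sigma2_person_item: float
    sigma2_residual: float
    k_items: int
    mean_days: float
    reliability: float


def _ratings_array(report: DailyReport) -> np.ndarray:
    row = np.full(len(ITEM_NAMES), np.nan)
    for name, value in report.ratings.items():
        row[_ITEM_INDEX[name]] = value
    return row


def reports_to_frame(reports: list[DailyReport]) -> pd.DataFrame:
    """Long reports -> wide frame (dyad_id, role, day, one column per item)."""
    data = {
        "dyad_id": [r.dyad_id for r in reports],
        "role": [r.role for r in reports],
        "day": [r.day for r in reports],
    }
    mat = np.vstack([_ratings_array(r) for r in reports]) if reports else \
        np.empty((0, len(ITEM_NAMES)))
    for j, name in enumerate(ITEM_NAMES):
        data[name] = mat[:, j]
    return pd.DataFrame(data)


def daily_composite(report: DailyReport, valence: str) -> float:
    """Mean of the day's available items of one valence; NaN if none rated."""
    values = [report.ratings[name] for name in items_for(valence)
              if name in report.ratings]
    if not values:
        return float("nan")
    return float(np.mean(values))


def person_mean(diary: list[DailyReport], valence: str) -> float:
    """Unweighted mean of daily composites over the person's usable days."""
    comps = [c for c in (daily_composite(r, valence) for r in diary)
             if not np.isnan(c)]
    if not comps:
        logger.warning("no usable days for %s mean; returning NaN", valence)
        return float("nan")
    return float(np.mean(comps))


def emotion_totals(diary: list[DailyReport], valence: str) -> GiniInput:
    """Per-emotion totals c_j: 0-4 ratings summed over days (missing = 0)."""
    names = items_for(valence)
    totals = np.zeros(len(names))
    for rep in diary:
        for j, name in enumerate(names):
            totals[j] += rep.ratings.get(name, 0)
    return GiniInput(totals, names)


def gini_emodiversity(gini_input: GiniInput | np.ndarray) -> float:
    """Gini-based diversity of the per-emotion totals (1 = maximally even).

    Returns NaN with a logged reason when all totals are zero (no emotion
    of the valence was ever endorsed, so diversity is undefined).
    """
    totals = gini_input.totals if isinstance(gini_input, GiniInput) else \
        np.asarray(gini_input, dtype=float)
    if np.any(totals < 0):
        raise ValueError("totals must be non-negative")
    m = len(totals)
    total = totals.sum()
    if total == 0:
        logger.warning("all-zero totals: emodiversity undefined")
        return float("nan")
    c = np.sort(totals, kind="stable")
    ranks = np.arange(1, m + 1)
    return float(1.0 - (2.0 * np.dot(ranks, c) / (m * total) - (m + 1) / m))


def summarize_person(dyad_id: str, role: str, diary: list[DailyReport]) -> EmotionSummary:
    return EmotionSummary(
        dyad_id=dyad_id,
        role=role,
        mean_neg=person_mean(diary, "negative"),
        mean_pos=person_mean(diary, "positive"),
        gini_neg=gini_emodiversity(emotion_totals(diary, "negative")),
        gini_pos=gini_emodiversity(emotion_totals(diary, "positive")),
        n_days=sum(1 for r in diary if r.n_rated > 0),
    )


def summarize_dyads(dyads: list[DyadRecord]) -> pd.DataFrame:
    """Per-person EmotionSummary table (one row per dyad member)."""
    rows = []
    for dyad in dyads:
        for role in (ADOLESCENT, CAREGIVER):
            s = summarize_person(dyad.dyad_id, role, dyad.diary(role))
            rows.append(vars(s))
    return pd.DataFrame(rows, columns=[
        "dyad_id", "role", "mean_neg", "mean_pos", "gini_neg", "gini_pos", "n_days"])


def _long_ratings(reports: list[DailyReport], valence: str) -> pd.DataFrame:
    names = items_for(valence)
    rows = []
    for rep in reports:
        for name in names:
            if name in rep.ratings:
                rows.append((f"{rep.dyad_id}/{rep.role}", rep.day, name,
                             float(rep.ratings[name])))
    return pd.DataFrame(rows, columns=["person", "day", "item", "rating"])


def between_person_reliability(data: list[DailyReport] | pd.DataFrame,
                               valence: str = "negative") -> VarianceComponents:
    """Between-person reliability of the person-mean composite.

    Method-of-moments decomposition of item-centered ratings into person,
    person-by-item and residual variance on the (possibly unbalanced)
    person x day x item layout; person-specific day counts enter through
    a harmonic-mean number of days.  The reliability of a k-item,
    d-day person mean is::

        R = (s2_p + s2_pi / k) / (s2_p + s2_pi / k + s2_e / (k * d))

    Negative moment estimates are truncated at zero.
    """
    if isinstance(data, pd.DataFrame):
        long = data.copy()
    else:
        long = _long_ratings(data, valence)
    if long.empty:
        raise ValueError("no ratings available")
    # fixed item effects removed before decomposition
    long["rating"] = long["rating"] - long.groupby("item")["rating"].transform("mean")

    persons = long["person"].unique()
    k = long["item"].nunique()
    day_counts = long.groupby("person")["day"].nunique()
    if len(persons) < 2 or k < 2 or (day_counts < 2).all():
        raise ValueError("need >=2 persons, >=2 items and >=2 days for decomposition")
    d_harm = float(len(day_counts) / (1.0 / day_counts).sum())

    # residual: variation across days within person x item cells
    cell = long.groupby(["person", "item"])["rating"]
    ss_within = ((long["rating"] - cell.transform("mean")) ** 2).sum()
    df_within = (cell.count() - 1).clip(lower=0).sum()
    s2_e = float(ss_within / df_within) if df_within > 0 else 0.0

    # person x item: variance across items of cell means, within person
    cell_means = cell.mean().reset_index()
    ms_pi = float(cell_means.groupby("person")["rating"].var(ddof=1).mean())
    s2_pi = max(0.0, ms_pi - s2_e / d_harm)

    # person: variance across persons of the person grand mean
    person_means = long.groupby("person")["rating"].mean()
    var_p = float(person_means.var(ddof=1))
    s2_p = max(0.0, var_p - s2_pi / k - s2_e / (k * d_harm))

    denom = s2_p + s2_pi / k + s2_e / (k * d_harm)
    if denom <= 0:
        logger.warning("all-constant ratings: reliability undefined")
        rel = float("nan")
    else:
        rel = float(s2_p + s2_pi / k) / denom
    return VarianceComponents(s2_p, s2_pi, s2_e, int(k), d_harm, rel)


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha on complete-case rows of a person x item matrix."""
    mat = np.asarray(item_matrix, dtype=float)
    mat = mat[~np.isnan(mat).any(axis=1)]
    n, k = mat.shape
    if k < 2 or n < 3:
        raise ValueError("need >=2 items and >=3 complete persons")
    total_var = mat.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        logger.warning("zero total-score variance: alpha undefined")
        return float("nan")
    item_vars = mat.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_vars / total_var))
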