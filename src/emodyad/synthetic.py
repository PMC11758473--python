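"""Synthetic dyadic daily-diary cohorts with known generating structure.

The generator emulates a 14-day evening-diary study of adolescent -
caregiver dyads: each person has latent trait positive and negative
affect, daily latent affect is trait plus an independent normal daily
deviation, and each 0-4 item rating is latent affect times an item
discrimination plus item noise, rounded and clamped to the scale.  Days
are dropped completely at random per role-specific compliance, mirroring
the ~84% (adolescent) / ~88% (caregiver) prompt completion of such
studies.  Baseline symptom means are then generated by a linear
actor-partner model in each person's *realized* mean emotion and Gini
emodiversity (grand-mean centered, products of centered factors), with
correlated bivariate-normal residuals across the two dyad members, so
every downstream estimator can be validated against exact truth.

Emodiversity is emergent — item-discrimination spread and item noise,
not a direct dial, move its distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .diary import ADOLESCENT, CAREGIVER, BaselineRecord, DailyReport, DyadRecord
from .items import ITEM_NAMES, NEGATIVE_ITEMS, POSITIVE_ITEMS

PATH_NAMES = ("a_mean", "a_div", "a_mean_x_div", "c_mean", "c_div", "c_mean_x_div")

_NEG_IDX = np.array([ITEM_NAMES.index(n) for n in NEGATIVE_ITEMS])
_POS_IDX = np.array([ITEM_NAMES.index(n) for n in POSITIVE_ITEMS])


@dataclass
class OutcomeModel:
    """True actor-partner structure for one symptom outcome pair."""

    valence: str
    intercept_adol: float
    intercept_cg: float
    b_adol: dict[str, float]
    b_cg: dict[str, float]
    resid_sd_adol: float
    resid_sd_cg: float
    resid_corr: float

    def __post_init__(self) -> None:
        for b in (self.b_adol, self.b_cg):
            for key in b:
                if key not in PATH_NAMES:
                    raise ValueError(f"unknown path {key!r}")
        if not (self.resid_sd_adol > 0 and self.resid_sd_cg > 0):
            raise ValueError("residual SDs must be positive")
        if not -1 < self.resid_corr < 1:
            raise ValueError("residual correlation must be in (-1, 1)")


def _default_outcomes() -> dict[str, OutcomeModel]:
    return {
        "anxious": OutcomeModel(
            valence="negative", intercept_adol=0.88, intercept_cg=0.40,
            b_adol={"a_mean": 0.5, "a_div": 0.1, "a_mean_x_div": 0.1,
                    "c_mean": 0.0, "c_div": 0.0, "c_mean_x_div": 0.0},
            b_cg={"c_mean": 0.55, "c_div": 0.1, "c_mean_x_div": 0.1,
                  "a_mean": 0.0, "a_div": 0.0, "a_mean_x_div": 0.0},
            resid_sd_adol=0.45, resid_sd_cg=0.30, resid_corr=0.25,
        ),
        "depressive": OutcomeModel(
            valence="positive", intercept_adol=1.47, intercept_cg=0.49,
            b_adol={"a_mean": -0.25, "a_div": -0.05, "a_mean_x_div": 0.0,
                    "c_mean": 0.0, "c_div": 0.0, "c_mean_x_div": 0.0},
            b_cg={"c_mean": -0.30, "c_div": 0.15, "c_mean_x_div": 0.0,
                  "a_mean": 0.0, "a_div": 0.0, "a_mean_x_div": 0.0},
            resid_sd_adol=0.22, resid_sd_cg=0.33, resid_corr=0.20,
        ),
    }


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the diary-study design the package targets: 175
    dyads over 14 days, 84%/88% compliance, trait affect levels and
    spreads matching published descriptives of caregiver-adolescent
    evening diaries.
    """

    n_dyads: int = 175
    n_days: int = 14
    seed: int = 0
    trait_mean: dict[tuple[str, str], float] = field(default_factory=lambda: {
        (ADOLESCENT, "negative"): 0.90, (CAREGIVER, "negative"): 0.67,
        (ADOLESCENT, "positive"): 2.04, (CAREGIVER, "positive"): 2.15,
    })
    trait_sd: dict[tuple[str, str], float] = field(default_factory=lambda: {
        (ADOLESCENT, "negative"): 0.35, (CAREGIVER, "negative"): 0.30,
        (ADOLESCENT, "positive"): 0.55, (CAREGIVER, "positive"): 0.48,
    })
    daily_sd: float = 0.5
    item_disc_spread: float = 0.45
    person_item_sd: float = 0.35
    item_noise_sd: float = 0.4
    compliance: dict[str, float] = field(default_factory=lambda: {
        ADOLESCENT: 0.84, CAREGIVER: 0.88})
    outcomes: dict[str, OutcomeModel] = field(default_factory=_default_outcomes)
    baseline_missing_rate: float = 0.05
    gender_probs: dict[str, float] = field(default_factory=lambda: {
        "boy": 0.44, "girl": 0.49, "other": 0.04, "unreported": 0.03})
    store_latents: bool = False

    def __post_init__(self) -> None:
        if self.n_dyads < 1 or self.n_days < 1:
            raise ValueError("n_dyads and n_days must be positive")
        if len(ITEM_NAMES) == 0:
            raise ValueError("degenerate config: no emotion items")
        for p in list(self.compliance.values()) + [self.baseline_missing_rate]:
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for sd in list(self.trait_sd.values()) + [self.daily_sd, self.item_noise_sd]:
            if sd <= 0:
                raise ValueError("SDs must be positive")


def _discretize(latent: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(latent), 0, 4)


def _rate_items(rng: np.random.Generator, latent_neg: np.ndarray,
                latent_pos: np.ndarray, disc: np.ndarray,
                affinity: np.ndarray, noise_sd: float) -> np.ndarray:
    """(n, days) latents -> (n, days, 16) integer ratings.

    ``affinity`` (n x 16) is each person's stable item profile — the
    person-by-item component that concentrates reports on idiosyncratic
    favourite emotions and lowers emergent emodiversity.
    """
    n, days = latent_neg.shape
    lat = np.empty((n, days, len(ITEM_NAMES)))
    lat[:, :, _NEG_IDX] = latent_neg[:, :, None]
    lat[:, :, _POS_IDX] = latent_pos[:, :, None]
    noise = rng.normal(0.0, noise_sd, size=lat.shape)
    out = _discretize(lat * disc[None, None, :] + affinity[:, None, :] + noise)
    return out.astype(int)


def _realized_predictors(ratings: np.ndarray, kept: np.ndarray,
                         idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Person mean and Gini diversity for one valence from kept days.

    Mirrors the scoring rules in :mod:`emodyad.emometrics` exactly
    (daily composite = mean of the valence items; person mean = mean of
    composites over kept days; totals = ratings summed over kept days).
    """
    n = ratings.shape[0]
    means = np.full(n, np.nan)
    ginis = np.full(n, np.nan)
    m = len(idx)
    ranks = np.arange(1, m + 1)
    for i in range(n):
        days = np.flatnonzero(kept[i])
        if days.size == 0:
            continue
        sub = ratings[i][days][:, idx]
        means[i] = sub.mean(axis=1).mean()
        totals = sub.sum(axis=0).astype(float)
        tot = totals.sum()
        if tot > 0:
            c = np.sort(totals)
            ginis[i] = 1.0 - (2.0 * np.dot(ranks, c) / (m * tot) - (m + 1) / m)
    return means, ginis


def generate_dyads(config: SyntheticConfig) -> tuple[list[DyadRecord], dict[str, Any]]:
    """Draw one cohort; returns dyad records and the full truth record."""
    rng = np.random.default_rng(config.seed)
    n, days = config.n_dyads, config.n_days

    disc = np.clip(rng.normal(1.0, config.item_disc_spread, len(ITEM_NAMES)), 0.2, None)

    ratings: dict[str, np.ndarray] = {}
    kept: dict[str, np.ndarray] = {}
    latents: dict[str, dict[str, list]] = {}
    for role in (ADOLESCENT, CAREGIVER):
        t_neg = rng.normal(config.trait_mean[(role, "negative")],
                           config.trait_sd[(role, "negative")], n)
        t_pos = rng.normal(config.trait_mean[(role, "positive")],
                           config.trait_sd[(role, "positive")], n)
        l_neg = t_neg[:, None] + rng.normal(0.0, config.daily_sd, (n, days))
        l_pos = t_pos[:, None] + rng.normal(0.0, config.daily_sd, (n, days))
        affinity = rng.normal(0.0, config.person_item_sd, (n, len(ITEM_NAMES)))
        ratings[role] = _rate_items(rng, l_neg, l_pos, disc, affinity,
                                    config.item_noise_sd)
        kept[role] = rng.random((n, days)) < config.compliance[role]
        if config.store_latents:
            latents.setdefault(role, {})["negative"] = l_neg.tolist()
            latents[role]["positive"] = l_pos.tolist()

    predictors: dict[str, dict[str, np.ndarray]] = {}
    for valence, idx in (("negative", _NEG_IDX), ("positive", _POS_IDX)):
        a_mean, a_div = _realized_predictors(ratings[ADOLESCENT], kept[ADOLESCENT], idx)
        c_mean, c_div = _realized_predictors(ratings[CAREGIVER], kept[CAREGIVER], idx)
        predictors[valence] = {"a_mean": a_mean, "a_div": a_div,
                               "c_mean": c_mean, "c_div": c_div}

    truth: dict[str, Any] = {
        "seed": config.seed, "n_dyads": n, "n_days": days,
        "item_discriminations": {name: float(d) for name, d in zip(ITEM_NAMES, disc)},
        "predictor_means": {}, "coefficients": {},
    }

    symptoms: dict[str, dict[str, np.ndarray]] = {}
    for symptom, model in config.outcomes.items():
        cols = predictors[model.valence]
        centers = {k: float(np.nanmean(v)) for k, v in cols.items()}
        xc = {k: v - centers[k] for k, v in cols.items()}
        design = {
            "a_mean": xc["a_mean"], "a_div": xc["a_div"],
            "a_mean_x_div": xc["a_mean"] * xc["a_div"],
            "c_mean": xc["c_mean"], "c_div": xc["c_div"],
            "c_mean_x_div": xc["c_mean"] * xc["c_div"],
        }
        cov = np.array([
            [model.resid_sd_adol ** 2,
             model.resid_corr * model.resid_sd_adol * model.resid_sd_cg],
            [model.resid_corr * model.resid_sd_adol * model.resid_sd_cg,
             model.resid_sd_cg ** 2]])
        resid = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        y_a = model.intercept_adol + sum(
            model.b_adol.get(p, 0.0) * design[p] for p in PATH_NAMES) + resid[:, 0]
        y_c = model.intercept_cg + sum(
            model.b_cg.get(p, 0.0) * design[p] for p in PATH_NAMES) + resid[:, 1]
        miss_a = rng.random(n) < config.baseline_missing_rate
        miss_c = rng.random(n) < config.baseline_missing_rate
        symptoms[symptom] = {
            ADOLESCENT: np.where(miss_a, np.nan, y_a),
            CAREGIVER: np.where(miss_c, np.nan, y_c),
        }
        truth["predictor_means"].setdefault(model.valence, centers)
        truth["coefficients"][symptom] = {
            "valence": model.valence,
            "y_adol": {p: model.b_adol.get(p, 0.0) for p in PATH_NAMES},
            "y_cg": {p: model.b_cg.get(p, 0.0) for p in PATH_NAMES},
            "intercepts": {"y_adol": model.intercept_adol, "y_cg": model.intercept_cg},
            "resid_sd": {"y_adol": model.resid_sd_adol, "y_cg": model.resid_sd_cg},
            "resid_corr": model.resid_corr,
        }

    genders = rng.choice(list(config.gender_probs), size=n,
                         p=list(config.gender_probs.values()))

    dyads: list[DyadRecord] = []
    for i in range(n):
        dyad_id = f"d{i + 1:04d}"
        rec = DyadRecord(dyad_id)
        for role in (ADOLESCENT, CAREGIVER):
            diary = rec.diary(role)
            for d in range(days):
                if not kept[role][i, d]:
                    continue
                vals = ratings[role][i, d]
                diary.append(DailyReport(
                    dyad_id, role, d + 1,
                    {name: int(vals[j]) for j, name in enumerate(ITEM_NAMES)}))

            def _sym(symptom: str) -> float | None:
                v = symptoms[symptom][role][i]
                return None if np.isnan(v) else float(v)

            base = BaselineRecord(
                dyad_id=dyad_id, role=role,
                anxious_mean=_sym("anxious"), depressive_mean=_sym("depressive"),
                gender_group=str(genders[i]) if role == ADOLESCENT else "unreported",
            )
            if role == ADOLESCENT:
                rec.adolescent_baseline = base
            else:
                rec.caregiver_baseline = base
        dyads.append(rec)

    if config.store_latents:
        truth["latents"] = latents
    truth["realized_predictors"] = {
        val: {k: v.tolist() for k, v in cols.items()}
        for val, cols in predictors.items()
    }
    return dyads, truth


def compliance_summary(dyads: list[DyadRecord], n_scheduled: int = 14) -> pd.DataFrame:
    """Per-role completion rate and mean number of daily responses."""
    if not dyads:
        raise ValueError("dyads must be nonempty")
    rows = []
    for role in (ADOLESCENT, CAREGIVER):
        counts = [sum(1 for r in d.diary(role) if r.n_rated > 0) for d in dyads]
        completed = float(np.sum(counts))
        rows.append({
            "role": role,
            "completion_rate": completed / (n_scheduled * len(dyads)),
            "mean_daily_responses": completed / len(dyads),
        })
    return pd.DataFrame(rows)


def write_truth(truth: dict[str, Any], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
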