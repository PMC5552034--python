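"""Normative feedback: z-scores against a model cohort, 0-100 score, comments.

The user's narrative features are compared with a cohort of model speakers
(people with good narrative skills) as z-scores, z = (x - mean) / sd with the
cohort sd taken with the n-1 denominator.  An overall score on a 0-100 scale
comes from an identity-link Gaussian GLM (ordinary least squares) over four
features (words per minute, amplitude, long-word count, smiling ratio), with
the linear prediction clipped to [0, 100].

Comment policy: the *positive* comment praises the feature whose |z| is
smallest (closest to the models); the *improvement* comment targets the
feature at the median rank of |z| — not the farthest, because asking a user
to fix their single worst behavior first is counterproductive.  For an even
feature count the lower middle rank is used; distance ties break by the
canonical feature order.  With exactly two features the median rank coincides
with the closest feature, so the improvement target is bumped to the next
rank to keep the two comments distinct.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import (
    ASD5_FEATURES,
    COMMENT_TEMPLATES_EN,
    FULL_FEATURES,
    SCORE_FEATURES,
)

__all__ = [
    "ModelCohort",
    "ScoreModel",
    "FeedbackReport",
    "zscores",
    "predict_overall_score",
    "fit_score_model",
    "select_comments",
    "build_report",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelCohort:
    """Model speakers' feature matrix with per-feature mean and sd (ddof=1)."""

    table: pd.DataFrame

    def __post_init__(self):
        if len(self.table) < 2:
            raise ValueError("cohort needs at least 2 model speakers")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(self.table.columns)

    def mean(self, feature: str) -> float:
        return float(self.table[feature].mean())

    def sd(self, feature: str) -> float:
        return float(self.table[feature].std(ddof=1))

    @classmethod
    def from_csv(cls, path) -> "ModelCohort":
        return cls(pd.read_csv(path))


@dataclass
class ScoreModel:
    """Linear overall-score model, prediction clipped to [0, 100]."""

    intercept: float
    coef: dict[str, float]
    clip: tuple[float, float] = (0.0, 100.0)
    loo_r: float | None = None  # leave-one-out predicted-vs-true correlation
    standardized: bool = False

    def __post_init__(self):
        vals = [self.intercept, *self.coef.values()]
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite score-model parameters")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "intercept": self.intercept,
                    "coef": self.coef,
                    "clip": list(self.clip),
                    "loo_r": self.loo_r,
                    "standardized": self.standardized,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "ScoreModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            intercept=d["intercept"],
            coef=d["coef"],
            clip=tuple(d.get("clip", (0.0, 100.0))),
            loo_r=d.get("loo_r"),
            standardized=d.get("standardized", False),
        )


@dataclass(frozen=True)
class FeedbackReport:
    """Everything the feedback screen shows for one role-play."""

    overall_score: float
    zscores: dict[str, float]
    positive_feature: str
    positive_comment: str
    improve_feature: str
    improve_comment: str
    radar_features: tuple[str, ...]
    radar_user: tuple[float, ...]
    radar_model: tuple[float, ...]  # cohort baseline, all zeros

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "overall_score": self.overall_score,
                    "zscores": self.zscores,
                    "positive": {
                        "feature": self.positive_feature,
                        "comment": self.positive_comment,
                    },
                    "improve": {
                        "feature": self.improve_feature,
                        "comment": self.improve_comment,
                    },
                    "radar": {
                        "features": list(self.radar_features),
                        "user": list(self.radar_user),
                        "model": list(self.radar_model),
                    },
                },
                fh,
                indent=1,
            )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def zscores(
    user: Mapping[str, float],
    cohort: ModelCohort,
    features: Sequence[str] | None = None,
) -> dict[str, float]:
    """z-score each feature of ``user`` against the cohort (sd with ddof=1)."""
    feats = tuple(features) if features is not None else cohort.features
    out = {}
    for f in feats:
        if f not in user:
            raise KeyError(f"user features missing {f!r}")
        sd = cohort.sd(f)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"cohort sd is zero for feature {f!r}")
        out[f] = (float(user[f]) - cohort.mean(f)) / sd
    return out


def predict_overall_score(user: Mapping[str, float], model: ScoreModel) -> float:
    """Clipped linear score: clip(intercept + sum coef_f * x_f, 0, 100)."""
    total = model.intercept
    for f, c in model.coef.items():
        if f not in user:
            raise KeyError(f"score model requires feature {f!r}")
        total += c * float(user[f])
    lo, hi = model.clip
    return float(np.clip(total, lo, hi))


def fit_score_model(
    rows: Sequence[Mapping[str, float]] | pd.DataFrame,
    ratings: Sequence[float],
    features: Sequence[str] = SCORE_FEATURES,
    rating_scale: tuple[float, float] | None = None,
    standardize: bool = False,
) -> ScoreModel:
    """Ordinary-least-squares fit of ratings on the score features.

    ``rating_scale=(lo, hi)`` linearly rescales ratings from [lo, hi] onto
    [0, 100] before fitting (e.g. ``(1, 7)`` for Likert scores).  With
    ``standardize`` the design columns are z-scored first and the returned
    coefficients are mapped back to the raw-feature scale, so predictions are
    identical either way; which mode was used is recorded on the model.

    Also computes the leave-one-out predicted-vs-true Pearson correlation,
    stored as ``loo_r``.

    Raises
    ------
    ValueError
        On a rank-deficient design or fewer than two distinct rows.
    """
    df = pd.DataFrame(rows)[list(features)] if not isinstance(rows, pd.DataFrame) else rows[list(features)]
    X = df.to_numpy(float)
    y = np.asarray(ratings, dtype=float)
    if len(X) != len(y):
        raise ValueError("rows and ratings must have equal length")
    if len(X) < 2 or len(np.unique(X, axis=0)) < 2:
        raise ValueError("need at least 2 distinct feature rows")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite inputs")
    if rating_scale is not None:
        lo, hi = rating_scale
        y = (y - lo) / (hi - lo) * 100.0

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if standardize:
        if np.any(sd == 0):
            raise ValueError("cannot standardize a constant feature column")
        Xd = (X - mu) / sd
    else:
        Xd = X
    A = np.column_stack([np.ones(len(Xd)), Xd])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("rank-deficient design matrix")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)

    if standardize:  # map back to raw-feature scale
        coefs = beta[1:] / sd
        intercept = float(beta[0] - np.sum(beta[1:] * mu / sd))
    else:
        coefs = beta[1:]
        intercept = float(beta[0])

    loo_r = _loo_correlation(A, y)
    return ScoreModel(
        intercept=intercept,
        coef={f: float(c) for f, c in zip(features, coefs)},
        loo_r=loo_r,
        standardized=standardize,
    )


def _loo_correlation(A: np.ndarray, y: np.ndarray) -> float | None:
    """Leave-one-out predicted-vs-true Pearson r; None if undefined."""
    n = len(y)
    if n < 3:
        return None
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        Ai, yi = A[mask], y[mask]
        if np.linalg.matrix_rank(Ai) < A.shape[1]:
            return None
        b, *_ = np.linalg.lstsq(Ai, yi, rcond=None)
        preds[i] = A[i] @ b
    if np.std(preds) == 0 or np.std(y) == 0:
        return None
    # exact-fit residuals can leave numerically constant predictions
    r = np.corrcoef(preds, y)[0, 1]
    return float(r)


def select_comments(
    z: Mapping[str, float], feature_order: Sequence[str] | None = None
) -> tuple[str, str]:
    """Pick (positive_feature, improve_feature) from the |z| distances.

    positive = argmin |z|; improve = feature at the median rank of |z| sorted
    ascending (odd count: middle; even count: lower middle).  Ties break by
    the canonical feature order.  See the module docstring for the two-feature
    corner case.
    """
    if len(z) < 2:
        raise ValueError("comment selection needs at least 2 features")
    order = list(feature_order) if feature_order is not None else [
        f for f in FULL_FEATURES if f in z
    ] + [f for f in z if f not in FULL_FEATURES]
    rank = {f: i for i, f in enumerate(order)}
    ranked = sorted(z, key=lambda f: (abs(z[f]), rank.get(f, len(rank))))
    positive = ranked[0]
    k = len(ranked)
    med = (k - 1) // 2
    if med == 0:  # only when k == 2: keep positive and improve distinct
        med = 1
    return positive, ranked[med]


def build_report(
    user: Mapping[str, float],
    cohort: ModelCohort,
    score_model: ScoreModel,
    comment_templates: Mapping[str, Mapping[str, str]] = COMMENT_TEMPLATES_EN,
    features: Sequence[str] = ASD5_FEATURES,
) -> FeedbackReport:
    """Assemble the full feedback report for one narrative."""
    z = zscores(user, cohort, features)
    score = predict_overall_score(user, score_model)
    positive, improve = select_comments(z, feature_order=features)
    direction = "high" if z[improve] >= 0 else "low"
    pos_text = comment_templates.get(positive, {}).get(
        "positive", f"Your {positive} was close to the model speakers."
    )
    imp_text = comment_templates.get(improve, {}).get(
        direction, f"Try adjusting your {improve} toward the model speakers."
    )
    feats = tuple(features)
    return FeedbackReport(
        overall_score=score,
        zscores=dict(z),
        positive_feature=positive,
        positive_comment=pos_text,
        improve_feature=improve,
        improve_comment=imp_text,
        radar_features=feats,
        radar_user=tuple(z[f] for f in feats),
        radar_model=tuple(0.0 for _ in feats),
    )


def plot_radar(report: FeedbackReport, path) -> None:
    """Render the report's radar chart (user vs cohort baseline) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    feats = list(report.radar_features)
    k = len(feats)
    angles = np.linspace(0, 2 * np.pi, k, endpoint=False).tolist()
    angles += angles[:1]
    user = list(report.radar_user) + [report.radar_user[0]]
    model = list(report.radar_model) + [report.radar_model[0]]
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"})
    ax.plot(angles, user, label="you")
    ax.plot(angles, model, label="models", linestyle="--")
    ax.set_xticks(angles[:-1])
    ax.set_xticklabels(feats, fontsize=8)
    ax.set_title(f"Overall score: {report.overall_score:.0f}/100")
    ax.legend(loc="lower right", fontsize=8)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
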