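"""Pre/post evaluation statistics for training-effect analyses.

Implements the statistics used to evaluate narrative-skill training: paired
and two-sample (pooled-variance Student's) t-tests with explicit one- and
two-tailed p-values, Cohen's d with the pooled-sd-of-two-groups convention,
Pearson correlation, and an above/below-own-mean rater-agreement fraction.

Sign convention: the paired t statistic is computed on the differences
``pre - post``, so an improvement (post > pre) yields a *negative* t.  Both
one- and two-tailed p-values are always reported; the caller chooses the tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "EffectSize",
    "paired_t",
    "two_sample_t",
    "cohens_d_pooled",
    "pearson_r",
    "rater_agreement",
    "load_rating_table",
    "load_asd_rating_table",
    "summarize_pre_post",
]


@dataclass(frozen=True)
class TTestResult:
    """t statistic with df and both tail p-values.

    ``p_one`` is the probability in the requested tail direction:
    ``"less"`` = P(T <= t), ``"greater"`` = P(T >= t).
    """

    t: float
    df: int
    p_one: float
    p_two: float
    tail: str


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d, pooled-sd convention: (mean2 - mean1) / sqrt((v1 + v2) / 2)."""

    cohens_d: float


def _tail_p(t: float, df: int, tail: str) -> tuple[float, float]:
    p_two = 2.0 * stats.t.sf(abs(t), df)
    if tail == "less":
        p_one = stats.t.cdf(t, df)
    elif tail == "greater":
        p_one = stats.t.sf(t, df)
    else:
        raise ValueError("tail must be 'less' or 'greater'")
    return float(p_one), float(p_two)


def paired_t(pre, post, tail: str = "less") -> TTestResult:
    """Paired t-test on the differences pre - post, df = n - 1.

    ``tail="less"`` tests for improvement (post greater than pre, hence
    negative mean difference).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length (paired design)")
    n = len(pre)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = pre - post
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    t = d.mean() / (sd / np.sqrt(n))
    p_one, p_two = _tail_p(t, n - 1, tail)
    return TTestResult(t=float(t), df=n - 1, p_one=p_one, p_two=p_two, tail=tail)


def two_sample_t(a, b, tail: str = "less") -> TTestResult:
    """Pooled-variance Student's t-test, df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("both groups need at least 2 observations")
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    p_one, p_two = _tail_p(t, na + nb - 2, tail)
    return TTestResult(t=float(t), df=na + nb - 2, p_one=p_one, p_two=p_two, tail=tail)


def cohens_d_pooled(pre, post) -> EffectSize:
    """Cohen's d between two groups, pooled-sd convention.

    d = (mean(post) - mean(pre)) / sqrt((var(pre) + var(post)) / 2), with n-1
    variances; positive d means the post scores are higher.  Invariant under
    adding a common constant and under common positive rescaling.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if len(pre) < 2 or len(post) < 2:
        raise ValueError("both groups need at least 2 observations")
    pooled = np.sqrt((pre.var(ddof=1) + post.var(ddof=1)) / 2.0)
    if pooled == 0:
        raise ValueError("zero pooled standard deviation")
    return EffectSize(cohens_d=float((post.mean() - pre.mean()) / pooled))


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input: correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def rater_agreement(reference, rater) -> float:
    """Above/below-own-mean class agreement between two raters' scores.

    Each score vector is binarized against its own mean (>= mean counts as
    the high class); the result is the fraction of positions assigned to the
    same class by both raters.
    """
    reference = np.asarray(reference, dtype=float)
    rater = np.asarray(rater, dtype=float)
    if reference.shape != rater.shape or len(reference) < 2:
        raise ValueError("need two equal-length vectors of at least 2 scores")
    ref_cls = reference >= reference.mean()
    rat_cls = rater >= rater.mean()
    return float(np.mean(ref_cls == rat_cls))


# ---------------------------------------------------------------------------
# Rating tables
# ---------------------------------------------------------------------------


def load_rating_table(path, scale: tuple[int, int] = (1, 7)) -> pd.DataFrame:
    """Read a rating table CSV (columns id, age, pre, post[, followup]).

    Scores are validated against the declared Likert scale bounds and ids
    must be unique.
    """
    df = pd.read_csv(path)
    required = {"id", "pre", "post"}
    if not required.issubset(df.columns):
        raise ValueError(f"rating table must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        raise ValueError("participant ids must be unique")
    lo, hi = scale
    for col in ("pre", "post", "followup"):
        if col in df.columns:
            vals = df[col].dropna()
            if ((vals < lo) | (vals > hi)).any():
                raise ValueError(f"{col} scores outside the declared scale [{lo}, {hi}]")
    return df


def load_asd_rating_table() -> pd.DataFrame:
    """The bundled pre/post narrative-skill ratings of the ten ASD participants."""
    with resources.as_file(
        resources.files("sstcoach.data").joinpath("asd_pre_post_ratings.csv")
    ) as p:
        return load_rating_table(p)


def summarize_pre_post(table: pd.DataFrame, tail: str = "less") -> dict:
    """Run the full pre/post analysis on a rating table.

    Returns the paired t-test (on pre - post), pooled Cohen's d, the mean
    improvement, and the per-participant post - pre differences.
    """
    tt = paired_t(table["pre"], table["post"], tail=tail)
    d = cohens_d_pooled(table["pre"], table["post"])
    diffs = (table["post"] - table["pre"]).tolist()
    return {
        "n": int(len(table)),
        "t": tt.t,
        "df": tt.df,
        "p_one": tt.p_one,
        "p_two": tt.p_two,
        "cohens_d": d.cohens_d,
        "mean_improvement": float(np.mean(diffs)),
        "differences": {str(i): v for i, v in zip(table["id"], diffs)},
    }
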