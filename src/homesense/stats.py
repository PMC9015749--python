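"""Inferential layer: Levene, one-/two-way ANOVA, Tukey-Kramer post hoc.

Every test is computable both from raw per-household values and from
published group summaries ``(n, mean, sd)``.  The two routes agree to
floating-point precision whenever the raw groups realize the summaries
exactly, which is what makes printed descriptive tables a sufficient
input for reproducing F statistics and studentized-range q values.

All response values are in minutes unless noted; F and q are invariant
to affine changes of unit, so the choice does not matter for the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import scipy.stats as sps

from .errors import DataError

__all__ = [
    "GroupSummary",
    "AnovaResult",
    "TukeyPair",
    "LeveneResult",
    "summarize",
    "levene",
    "anova_oneway",
    "anova_oneway_from_summary",
    "anova_twoway_additive",
    "tukey_kramer",
    "tukey_kramer_raw",
    "grand_weighted_mean",
]


@dataclass(frozen=True)
class GroupSummary:
    """Descriptive summary of one group: size, mean, sample SD."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise DataError(f"group {self.label!r}: n must be >= 2, got {self.n}")
        if self.sd < 0:
            raise DataError(f"group {self.label!r}: sd must be >= 0")


@dataclass(frozen=True)
class AnovaResult:
    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    F: float
    p: float

    @property
    def ms_between(self) -> float:
        return self.ss_between / self.df_between

    @property
    def ms_within(self) -> float:
        return self.ss_within / self.df_within


@dataclass(frozen=True)
class TukeyPair:
    group1: str
    group2: str
    diff: float
    se: float
    q: float
    ci_low: float
    ci_high: float
    p_adj: float


@dataclass(frozen=True)
class LeveneResult:
    W: float
    p: float


def summarize(label: str, values: Sequence[float]) -> GroupSummary:
    """Summary statistics with the sample (ddof=1) standard deviation."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise DataError(f"group {label!r}: need >= 2 values")
    return GroupSummary(label, int(arr.size), float(arr.mean()), float(arr.std(ddof=1)))


def _check_groups(groups: Sequence[Sequence[float]]) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise DataError("need at least 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 2:
            raise DataError(f"group {i}: need >= 2 values")
    return arrs


def levene(groups: Sequence[Sequence[float]], center: str = "mean") -> LeveneResult:
    """Levene's homogeneity-of-variance test.

    ``center='mean'`` is the classic statistic on absolute deviations from
    the group mean; ``center='median'`` gives the Brown-Forsythe variant.
    """
    arrs = _check_groups(groups)
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    with np.errstate(invalid="ignore"):  # degenerate groups yield 0/0
        W, p = sps.levene(*arrs, center=center)
    if not np.isfinite(W):
        raise DataError("degenerate groups: Levene statistic undefined")
    return LeveneResult(float(W), float(p))


def anova_oneway(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classic one-way fixed-effects ANOVA on raw group values."""
    arrs = _check_groups(groups)
    k = len(arrs)
    ns = np.array([g.size for g in arrs])
    means = np.array([g.mean() for g in arrs])
    total_n = int(ns.sum())
    grand = float((ns * means).sum() / total_n)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in arrs))
    return _finish_anova(ss_between, ss_within, k - 1, total_n - k)


def anova_oneway_from_summary(summaries: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA reconstructed from group (n, mean, sd) summaries.

    Uses the identities SS_between = sum n_i (m_i - grand_mean)^2 and
    SS_within = sum (n_i - 1) s_i^2; exactly equal to :func:`anova_oneway`
    on any raw data realizing the summaries.
    """
    if len(summaries) < 2:
        raise DataError("need at least 2 group summaries")
    ns = np.array([s.n for s in summaries], dtype=float)
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    total_n = ns.sum()
    grand = float((ns * means).sum() / total_n)
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(((ns - 1.0) * sds**2).sum())
    return _finish_anova(ss_between, ss_within, len(summaries) - 1, int(total_n) - len(summaries))


def _finish_anova(ss_b: float, ss_w: float, df_b: int, df_w: int) -> AnovaResult:
    if df_w <= 0:
        raise DataError("non-positive residual degrees of freedom")
    if ss_w <= 0:
        raise DataError("zero within-group variation: F undefined")
    F = (ss_b / df_b) / (ss_w / df_w)
    p = float(sps.f.sf(F, df_b, df_w))
    return AnovaResult(ss_b, ss_w, df_b, df_w, float(F), p)


def _dummies(labels: Sequence) -> tuple[np.ndarray, int]:
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise DataError("factor needs >= 2 levels")
    idx = {lev: j for j, lev in enumerate(levels)}
    mat = np.zeros((len(labels), len(levels) - 1))
    for i, lab in enumerate(labels):
        j = idx[lab]
        if j > 0:  # first level is the reference
            mat[i, j - 1] = 1.0
    return mat, len(levels)


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def anova_twoway_additive(
    values: Sequence[float],
    factor_a: Sequence,
    factor_b: Sequence,
    names: tuple[str, str] = ("A", "B"),
) -> dict[str, AnovaResult]:
    """Two-way additive (no interaction) ANOVA with Type II sums of squares.

    Handles unbalanced designs; empty cells are fine because no
    interaction term is fit.  SS for each factor is the RSS drop when
    adding that factor to a model already containing the other one, and
    both factors share the residual of the full additive model.
    """
    y = np.asarray(values, dtype=float)
    if not (len(y) == len(factor_a) == len(factor_b)):
        raise DataError("values and factors must have equal length")
    da, a_levels = _dummies(factor_a)
    db, b_levels = _dummies(factor_b)
    ones = np.ones((len(y), 1))
    X_full = np.hstack([ones, da, db])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise DataError("rank-deficient design: factors are confounded")
    rss_full = _rss(X_full, y)
    rss_b_only = _rss(np.hstack([ones, db]), y)
    rss_a_only = _rss(np.hstack([ones, da]), y)
    df_resid = len(y) - 1 - (a_levels - 1) - (b_levels - 1)
    out = {}
    for name, ss, df in (
        (names[0], rss_b_only - rss_full, a_levels - 1),
        (names[1], rss_a_only - rss_full, b_levels - 1),
    ):
        out[name] = _finish_anova(max(ss, 0.0), rss_full, df, df_resid)
    return out


@lru_cache(maxsize=256)
def _q_crit(alpha: float, k: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, k, df))


def tukey_kramer(
    summaries: Sequence[GroupSummary],
    ms_within: float | None = None,
    df_within: int | None = None,
    alpha: float = 0.05,
    with_p: bool = True,
) -> list[TukeyPair]:
    """All-pairs Tukey-Kramer comparisons from group summaries.

    For each pair, ``se = sqrt((ms_within / 2) (1/n1 + 1/n2))`` and
    ``q = |m1 - m2| / se``; the adjusted p-value is the studentized-range
    upper tail with parameters (k, df_within) and the CI half-width is
    the alpha-level critical q times se.  If ``ms_within`` is omitted it
    is taken from the one-way ANOVA on the same summaries.
    """
    if len(summaries) < 2:
        raise DataError("need at least 2 groups")
    if ms_within is None or df_within is None:
        an = anova_oneway_from_summary(summaries)
        ms_within = an.ms_within if ms_within is None else ms_within
        df_within = an.df_within if df_within is None else df_within
    if ms_within <= 0:
        raise DataError("ms_within must be positive")
    k = len(summaries)
    pairs = list(combinations(summaries, 2))
    qs = np.empty(len(pairs))
    ses = np.empty(len(pairs))
    diffs = np.empty(len(pairs))
    for i, (g1, g2) in enumerate(pairs):
        se = math.sqrt((ms_within / 2.0) * (1.0 / g1.n + 1.0 / g2.n))
        diff = g1.mean - g2.mean
        ses[i] = se
        diffs[i] = diff
        qs[i] = abs(diff) / se
    if with_p:
        p_adj = np.clip(sps.studentized_range.sf(qs, k, df_within), 0.0, 1.0)
    else:
        p_adj = np.full(len(pairs), np.nan)
    qc = _q_crit(alpha, k, int(df_within)) if with_p else np.nan
    out = []
    for i, (g1, g2) in enumerate(pairs):
        half = qc * ses[i] if with_p else np.nan
        out.append(
            TukeyPair(
                group1=g1.label,
                group2=g2.label,
                diff=float(diffs[i]),
                se=float(ses[i]),
                q=float(qs[i]),
                ci_low=float(diffs[i] - half),
                ci_high=float(diffs[i] + half),
                p_adj=float(p_adj[i]),
            )
        )
    return out


def tukey_kramer_raw(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05, with_p: bool = True
) -> list[TukeyPair]:
    """Tukey-Kramer from raw per-group values (MS_within from their ANOVA)."""
    summaries = [summarize(lab, vals) for lab, vals in groups.items()]
    an = anova_oneway(list(groups.values()))
    return tukey_kramer(summaries, an.ms_within, an.df_within, alpha=alpha, with_p=with_p)


def grand_weighted_mean(summaries: Iterable[GroupSummary]) -> float:
    """Size-weighted grand mean across group summaries."""
    summaries = list(summaries)
    if not summaries:
        raise DataError("need at least 1 summary")
    n_total = sum(s.n for s in summaries)
    return sum(s.n * s.mean for s in summaries) / n_total
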