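"""Site-level differential methylation and combined-rank aggregation.

Every CpG is scored on three criteria between two sample groups:

(a) the difference in mean beta value, ``diff = mean_g1 − mean_g2``;
(b) the (regularized, log2) quotient of mean beta values;
(c) an empirical-Bayes moderated t-test of the two groups (a plain pooled
    t-test is the ``d0 = 0`` special case).

Each criterion yields a rank over the testable probes (1 = strongest
evidence, ties averaged) and the *combined rank* of a probe is the maximum
— i.e. worst — of its three ranks, so a small combined rank requires the
probe to score well on all three criteria simultaneously. Signatures are
the K probes with the smallest combined rank; threshold filtering keeps
probes with ``p < alpha`` and ``|diff| > min_abs_diff``.

The variance moderation follows the standard empirical-Bayes hierarchy:
true probe variances σ² are drawn from a scaled inverse-chi-square prior
with ``d0`` degrees of freedom and scale ``s0²``; the posterior variance
``(d0·s0² + df·s²)/(d0 + df)`` replaces ``s²`` in the t statistic and the
null distribution gains ``d0`` degrees of freedom. The hyperparameters are
fitted by moment-matching the log sample variances against the implied
log-F distribution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import digamma, polygamma

from cpgrank.core_io import BetaMatrix, ValidationError

#: default regularizer added to both group means before forming the quotient
DEFAULT_EPSILON = 0.01

STATS_COLUMNS = [
    "mean_g1",
    "mean_g2",
    "diff",
    "log_quotient",
    "n_g1",
    "n_g2",
    "s2",
    "t_stat",
    "df_total",
    "p_value",
    "rank_diff",
    "rank_quot",
    "rank_p",
    "combined_rank",
]


@dataclass(frozen=True)
class ShrinkageParams:
    """Empirical-Bayes variance prior: ``d0`` prior df (may be inf), ``s0_sq`` prior variance."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.d0 < 0:
            raise ValidationError("d0 must be >= 0")
        if not self.s0_sq > 0:
            raise ValidationError("s0_sq must be > 0")


def _split_groups(
    m: BetaMatrix,
    labels: Mapping[str, str] | pd.Series,
    groups: tuple[str, str] | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[str, str]]:
    """Split matrix columns by a two-level label mapping.

    ``groups`` fixes which label is g1 (its mean enters ``diff`` with a
    positive sign); when omitted the two labels are taken in sorted order.
    """
    labels = pd.Series(dict(labels) if not isinstance(labels, pd.Series) else labels)
    labels = labels[labels.index.isin(m.sample_ids)]
    levels = sorted(labels.dropna().unique())
    if groups is None:
        if len(levels) != 2:
            raise ValidationError(f"need exactly two group labels, got {levels}")
        groups = (levels[0], levels[1])
    g1 = labels.index[labels == groups[0]]
    g2 = labels.index[labels == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError(
            f"each group needs >=2 samples (got {len(g1)} {groups[0]!r}, "
            f"{len(g2)} {groups[1]!r})"
        )
    return m.values[g1].to_numpy(), m.values[g2].to_numpy(), groups


def _group_moments(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise-complete per-row (n, mean, sum of squared deviations)."""
    ok = ~np.isnan(x)
    n = ok.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(x, axis=1)
        ss = np.nansum((x - mean[:, None]) ** 2, axis=1)
    return n, mean, ss


def group_mean_difference(
    m: BetaMatrix,
    labels: Mapping[str, str] | pd.Series,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-probe group means and their difference (pairwise-complete)."""
    x1, x2, _ = _split_groups(m, labels, groups)
    n1, m1, _ = _group_moments(x1)
    n2, m2, _ = _group_moments(x2)
    df = pd.DataFrame(
        {"mean_g1": m1, "mean_g2": m2, "diff": m1 - m2, "n_g1": n1, "n_g2": n2},
        index=m.probe_ids,
    )
    df.loc[(n1 < 2) | (n2 < 2), ["mean_g1", "mean_g2", "diff"]] = np.nan
    return df


def group_mean_quotient(
    m: BetaMatrix,
    labels: Mapping[str, str] | pd.Series,
    epsilon: float = DEFAULT_EPSILON,
    groups: tuple[str, str] | None = None,
) -> pd.Series:
    """log2((mean_g1 + ε) / (mean_g2 + ε)) per probe.

    The regularizer ε keeps the quotient finite at fully unmethylated
    probes; the log makes the metric symmetric under group exchange
    (swapping groups negates it) so |log_quotient| is a direction-free
    evidence magnitude.
    """
    d = group_mean_difference(m, labels, groups)
    return pd.Series(
        np.log2((d["mean_g1"] + epsilon) / (d["mean_g2"] + epsilon)),
        index=d.index,
        name="log_quotient",
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes variance shrinkage


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_shrinkage(s2: Sequence[float] | np.ndarray, df: float) -> ShrinkageParams:
    """Fit the variance prior (d0, s0²) from per-probe sample variances.

    Under the hierarchy, ``log(s²)`` is a shifted log-F variable; matching
    its mean and excess variance (beyond the chi-square sampling noise
    ``trigamma(df/2)``) identifies the prior. When the observed dispersion
    does not exceed the sampling noise the prior is degenerate:
    ``d0 = inf`` with ``s0²`` the average sample variance.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[~np.isnan(s2)]
    if df < 1:
        raise ValidationError("residual df must be >= 1")
    if s2.size == 0 or np.all(s2 == 0):
        raise ValidationError("all sample variances are zero or missing")
    if s2.size < 2:
        return ShrinkageParams(d0=math.inf, s0_sq=float(s2.mean()))

    # Offset zero variances as limma does, to keep logs finite.
    floor = np.min(s2[s2 > 0]) * 1e-6 if np.any(s2 > 0) else 1e-12
    z = np.log(np.maximum(s2, floor))
    e = z - float(digamma(df / 2.0)) + math.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, df / 2.0))
    if e_var <= 0:
        return ShrinkageParams(d0=math.inf, s0_sq=float(s2.mean()))
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    s0_sq = math.exp(e_mean + float(digamma(half_d0)) - math.log(half_d0))
    return ShrinkageParams(d0=d0, s0_sq=s0_sq)


def moderated_t(
    m: BetaMatrix,
    labels: Mapping[str, str] | pd.Series,
    shrink: ShrinkageParams,
    groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Moderated two-sample t-test per probe.

    ``t = diff / (s̃·√(1/n1 + 1/n2))`` with posterior variance
    ``s̃² = (d0·s0² + df·s²)/(d0 + df)``; two-sided p from a t distribution
    with ``df + d0`` degrees of freedom (normal limit when d0 = inf).
    ``d0 = 0`` recovers the classical pooled t-test exactly.
    """
    x1, x2, _ = _split_groups(m, labels, groups)
    n1, m1, ss1 = _group_moments(x1)
    n2, m2, ss2 = _group_moments(x2)
    testable = (n1 >= 2) & (n2 >= 2)

    with np.errstate(divide="ignore", invalid="ignore"):
        df_resid = (n1 + n2 - 2).astype(float)
        s2 = (ss1 + ss2) / df_resid
        if math.isinf(shrink.d0):
            s2_post = np.full_like(s2, shrink.s0_sq)
            df_total = np.full_like(s2, math.inf)
        else:
            s2_post = (shrink.d0 * shrink.s0_sq + df_resid * s2) / (shrink.d0 + df_resid)
            df_total = df_resid + shrink.d0
        se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        t = (m1 - m2) / se

    with np.errstate(invalid="ignore"):
        if math.isinf(shrink.d0):
            p = 2.0 * sps.norm.sf(np.abs(t))
        else:
            p = 2.0 * sps.t.sf(np.abs(t), df_total)
    testable &= np.isfinite(t)

    out = pd.DataFrame(
        {"s2": s2, "t_stat": t, "df_total": df_total, "p_value": p},
        index=m.probe_ids,
    )
    out.loc[~testable, ["t_stat", "df_total", "p_value"]] = np.nan
    return out


# ---------------------------------------------------------------------------
# Ranks, combined rank, selection


def site_statistics(
    m: BetaMatrix,
    labels: Mapping[str, str] | pd.Series,
    groups: tuple[str, str] | None = None,
    epsilon: float = DEFAULT_EPSILON,
    test: str = "moderated",
    shrink: ShrinkageParams | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Full per-probe statistics table with ranks and combined rank.

    Returns ``(stats, untestable)``: a DataFrame over the testable probes
    (columns per :data:`STATS_COLUMNS`) and the list of probes excluded
    because a group had fewer than two non-missing values or the test was
    degenerate. ``test='plain'`` forces the classical pooled t-test
    (d0 = 0); otherwise the prior is estimated from the data unless
    ``shrink`` is supplied.
    """
    if test not in ("moderated", "plain"):
        raise ValidationError(f"unknown test {test!r}")
    x1, x2, groups = _split_groups(m, labels, groups)

    d = group_mean_difference(m, labels, groups)
    q = group_mean_quotient(m, labels, epsilon, groups)

    n1, n2 = d["n_g1"].to_numpy(), d["n_g2"].to_numpy()
    testable0 = (n1 >= 2) & (n2 >= 2)
    df_resid = float(np.median((n1 + n2 - 2)[testable0])) if testable0.any() else 0.0

    if shrink is None:
        if test == "plain":
            shrink = ShrinkageParams(d0=0.0, s0_sq=1.0)
        else:
            _, _, ss1 = _group_moments(x1)
            _, _, ss2 = _group_moments(x2)
            with np.errstate(divide="ignore", invalid="ignore"):
                s2_all = (ss1 + ss2) / (n1 + n2 - 2)
            shrink = estimate_shrinkage(s2_all[testable0], df_resid)

    tt = moderated_t(m, labels, shrink, groups)

    stats = pd.concat([d, q, tt], axis=1)
    testable = stats[["diff", "log_quotient", "p_value"]].notna().all(axis=1)
    untestable = list(stats.index[~testable])
    stats = stats.loc[testable].copy()
    stats = rank_sites(stats)
    stats = combined_rank(stats)
    stats.attrs["shrinkage"] = shrink
    stats.attrs["groups"] = groups
    return stats[STATS_COLUMNS], untestable


def rank_sites(stats: pd.DataFrame) -> pd.DataFrame:
    """Assign the three per-criterion ranks (1 = strongest, ties averaged).

    ``rank_diff`` orders by descending |diff|, ``rank_quot`` by descending
    |log_quotient|, ``rank_p`` by ascending p-value.
    """
    out = stats.copy()
    out["rank_diff"] = sps.rankdata(-np.abs(out["diff"]), method="average")
    out["rank_quot"] = sps.rankdata(-np.abs(out["log_quotient"]), method="average")
    out["rank_p"] = sps.rankdata(out["p_value"], method="average")
    return out


def combined_rank(stats: pd.DataFrame) -> pd.DataFrame:
    """Combined rank = max (worst) of the three criterion ranks."""
    out = stats.copy()
    out["combined_rank"] = out[["rank_diff", "rank_quot", "rank_p"]].max(axis=1)
    return out


def select_top_k(stats: pd.DataFrame, k: int = 200) -> pd.DataFrame:
    """The k probes with smallest combined rank, ascending.

    Boundary ties are broken by smaller ``rank_p``, then probe id, so the
    selection is deterministic. If fewer than k probes are testable, all
    are returned with a warning.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    if len(stats) < k:
        warnings.warn(
            f"only {len(stats)} testable probes available for a top-{k} signature",
            stacklevel=2,
        )
        k = len(stats)
    order = stats.assign(_pid=stats.index.astype(str)).sort_values(
        ["combined_rank", "rank_p", "_pid"], kind="mergesort"
    )
    return order.drop(columns="_pid").head(k)


def threshold_filter(
    stats: pd.DataFrame, min_abs_diff: float = 0.2, alpha: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split probes passing ``p < alpha`` and ``|diff| > min_abs_diff``.

    Both inequalities are strict. Returns ``(hyper, hypo)``: probes more
    methylated in group 1 (diff > 0) and less methylated (diff < 0).
    """
    keep = (stats["p_value"] < alpha) & (stats["diff"].abs() > min_abs_diff)
    kept = stats.loc[keep]
    return kept.loc[kept["diff"] > 0], kept.loc[kept["diff"] < 0]
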