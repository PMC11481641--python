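"""Statistical stage: summaries, correlation, paired tests, discriminants.

Covers the comparison of pre- and post-sewerage monitoring periods:
descriptive summary tables, Spearman rank correlation between the two
indices, the Wilcoxon signed-rank test on paired per-well index values
(exact enumeration for small effective n, tie-corrected normal
approximation otherwise), Fisher's two-group linear discriminant with
Wilks' lambda, Bartlett's chi-square and leave-one-out cross-validation,
plus the rank-agreement and per-year rank-count tables.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .indices import IndexResult

__all__ = [
    "CorrelationResult",
    "WilcoxonResult",
    "DiscriminantResult",
    "RankAgreementTable",
    "descriptive_summary",
    "spearman",
    "wilcoxon_signed_rank",
    "lda_two_group",
    "rank_agreement",
    "count_by_rank",
    "paired_period_means",
]


# ---------------------------------------------------------------- summaries


def descriptive_summary(
    frame: pd.DataFrame,
    value_columns: list[str],
    group_by: str = "year",
) -> pd.DataFrame:
    """Per-group n / mean / min / max / lower & upper quartile table.

    Quartiles use linear interpolation between order statistics (the
    inclusive convention shared by spreadsheet software and most statistics
    packages). Groups with no finite values are omitted.
    """
    rows = []
    for key, grp in frame.groupby(group_by):
        for col in value_columns:
            v = grp[col].dropna().to_numpy(dtype=float)
            if len(v) == 0:
                continue
            rows.append(
                {
                    group_by: key,
                    "parameter": col,
                    "n": len(v),
                    "mean": float(np.mean(v)),
                    "min": float(np.min(v)),
                    "max": float(np.max(v)),
                    "q25": float(np.quantile(v, 0.25)),
                    "q75": float(np.quantile(v, 0.75)),
                }
            )
    return pd.DataFrame(rows)


# -------------------------------------------------------------- correlation


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    method: str  # 't-approximation' | 'exact-permutation'


def spearman(x, y, *, exact: bool | None = None) -> CorrelationResult:
    """Spearman rank correlation with average ranks for ties.

    The p-value comes from the t-approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))``; for n <= 8 an exact permutation
    p-value (full enumeration of the n! orderings) is available and is the
    default there.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    n = len(x)
    if exact is None:
        exact = n <= 8
    rho, p = sps.spearmanr(x, y)
    if not exact:
        return CorrelationResult(float(rho), float(p), n, "t-approximation")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    obs = _rank_corr(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _rank_corr(rx, ry[list(perm)])
        if abs(r) >= abs(obs) - 1e-12:
            count += 1
        total += 1
    return CorrelationResult(float(rho), count / total, n, "exact-permutation")


def _rank_corr(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two rank vectors (handles ties)."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / math.sqrt((rx @ rx) * (ry @ ry)))


# ------------------------------------------------------------ Wilcoxon test


@dataclass(frozen=True)
class WilcoxonResult:
    w: float  # min of the signed-rank sums
    z: float  # signed: negative when the second sample is lower
    p_value: float
    n_effective: int
    method: str  # 'exact' | 'normal-approximation'


def wilcoxon_signed_rank(
    pre,
    post,
    *,
    exact_limit: int = 15,
    zero_method: str = "wilcox",
) -> WilcoxonResult:
    """Paired Wilcoxon signed-rank test of ``post`` against ``pre``.

    Differences ``d = post - pre`` equal to zero are dropped
    (``zero_method='wilcox'``, the classic convention; ``'pratt'`` keeps
    them in the ranking and then discards their ranks). Absolute
    differences are ranked with average ranks for ties; the statistic is
    ``W = min(W+, W-)``. For effective n <= ``exact_limit`` the two-tailed
    p-value is exact, from full enumeration of the 2^n sign assignments of
    the observed ranks; beyond that the tie-corrected normal approximation

        Z = (W+ - n(n+1)/4) / sqrt(n(n+1)(2n+1)/24 - tie_correction)

    is used. Z is reported signed, negative when the post values are lower.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("paired vectors must have equal length")
    d = post - pre
    if zero_method == "wilcox":
        d = d[d != 0]
    elif zero_method != "pratt":
        raise ValueError(f"unknown zero_method {zero_method!r}")
    if len(d) == 0 or np.all(d == 0):
        raise ValueError("degenerate test: all paired differences are zero")

    ranks = sps.rankdata(np.abs(d))
    if zero_method == "pratt":
        ranks = ranks[d != 0]
        d = d[d != 0]
    n = len(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)

    mu = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_corr = float((counts**3 - counts).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_corr
    z = (w_plus - mu) / math.sqrt(var) if var > 0 else 0.0

    if n <= exact_limit:
        # Distribution of W+ over all sign assignments of the observed ranks.
        p = _exact_two_tailed_p(ranks, w)
        method = "exact"
    else:
        p = 2.0 * sps.norm.sf(abs(z)) if var > 0 else 1.0
        method = "normal-approximation"
    return WilcoxonResult(w, float(z), min(p, 1.0), n, method)


def _exact_two_tailed_p(ranks: np.ndarray, w: float) -> float:
    """P(min(W+, W-) <= w) over all 2^n sign assignments of the ranks.

    Equals 2*P(W+ <= w) because W+ and W- are exchangeable under the null.
    Average ranks from ties are half-integers, so the convolution runs on
    doubled ranks.
    """
    r2 = np.rint(2.0 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:  # convolve in the sign of each rank
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    w2 = int(math.floor(2.0 * w + 1e-9))
    p_le = dist[: w2 + 1].sum() / 2 ** len(ranks)
    return min(1.0, 2.0 * p_le)


# -------------------------------------------------- Fisher two-group LDA


@dataclass
class DiscriminantResult:
    coefficients: np.ndarray  # discriminant direction w
    wilks_lambda: float
    chi2: float
    p_value: float
    group_means_axis: tuple[float, float]  # projected group means (g1, g2)
    cut: float
    confusion_original: np.ndarray  # rows true group, cols predicted
    confusion_loo: np.ndarray
    pct_correct_original: float
    pct_correct_loo: float
    group_labels: tuple[str, str]


def _fisher_fit(x1: np.ndarray, x2: np.ndarray, ridge: float = 0.0):
    """Fisher direction and midpoint cut for two groups."""
    m1, m2 = x1.mean(axis=0), x2.mean(axis=0)
    s1 = (x1 - m1).T @ (x1 - m1)
    s2 = (x2 - m2).T @ (x2 - m2)
    sw = s1 + s2
    if ridge > 0:
        sw = sw + ridge * np.trace(sw) / sw.shape[0] * np.eye(sw.shape[0])
    w = np.linalg.solve(sw, m1 - m2)
    c1, c2 = float(w @ m1), float(w @ m2)
    return w, (c1 + c2) / 2.0, c1, c2


def _classify_axis(scores, cut, g1_high: bool) -> np.ndarray:
    """0 = group 1, 1 = group 2; boundary ties go to group 1."""
    if g1_high:
        return np.where(scores >= cut, 0, 1)
    return np.where(scores <= cut, 0, 1)


def lda_two_group(features, labels, *, group_order=None) -> DiscriminantResult:
    """Fisher's two-group linear discriminant with LOO cross-validation.

    The direction ``w`` solves ``Sw w = m1 - m2`` (pooled within-group
    scatter); samples are classified by nearest projected group mean with
    the midpoint cut (equal priors). Wilks' lambda is ``1/(1 + lambda_B)``
    with ``lambda_B`` the between/within scatter ratio along ``w``;
    significance uses Bartlett's chi-square. Leave-one-out refits the
    discriminant n times. A singular within-group scatter is ridged by
    ``1e-8 * trace``.
    """
    x = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if group_order is None:
        group_order = tuple(pd.unique(labels))
    if len(group_order) != 2:
        raise ValueError("exactly two groups required")
    g1, g2 = group_order
    x1, x2 = x[labels == g1], x[labels == g2]
    n1, n2 = len(x1), len(x2)
    p = x.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    if n1 + n2 <= p:
        raise ValueError("need more samples than features")

    try:
        w, cut, c1, c2 = _fisher_fit(x1, x2)
    except np.linalg.LinAlgError:
        w, cut, c1, c2 = _fisher_fit(x1, x2, ridge=1e-8)

    n = n1 + n2
    scores = x @ w
    proj1, proj2 = scores[labels == g1], scores[labels == g2]
    ss_within = float(((proj1 - proj1.mean()) ** 2).sum() + ((proj2 - proj2.mean()) ** 2).sum())
    ss_between = float(n1 * (proj1.mean() - scores.mean()) ** 2 + n2 * (proj2.mean() - scores.mean()) ** 2)
    lam_b = ss_between / ss_within if ss_within > 0 else math.inf
    wilks = 1.0 / (1.0 + lam_b)
    chi2 = -(n - 1 - (p + 2) / 2.0) * math.log(wilks) if wilks > 0 else math.inf
    p_value = float(sps.chi2.sf(chi2, p))

    g1_high = c1 >= c2
    pred = _classify_axis(scores, cut, g1_high)
    truth = np.where(labels == g1, 0, 1)
    conf = _confusion(truth, pred)

    # Leave-one-out: refit without each sample, classify it.
    pred_loo = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        xi1 = x[keep & (labels == g1)]
        xi2 = x[keep & (labels == g2)]
        try:
            wi, cuti, ci1, ci2 = _fisher_fit(xi1, xi2)
        except np.linalg.LinAlgError:
            wi, cuti, ci1, ci2 = _fisher_fit(xi1, xi2, ridge=1e-8)
        s = float(x[i] @ wi)
        pred_loo[i] = _classify_axis(np.array([s]), cuti, ci1 >= ci2)[0]
    conf_loo = _confusion(truth, pred_loo)

    return DiscriminantResult(
        coefficients=w,
        wilks_lambda=wilks,
        chi2=float(chi2),
        p_value=p_value,
        group_means_axis=(c1, c2),
        cut=cut,
        confusion_original=conf,
        confusion_loo=conf_loo,
        pct_correct_original=100.0 * np.trace(conf) / n,
        pct_correct_loo=100.0 * np.trace(conf_loo) / n,
        group_labels=(str(g1), str(g2)),
    )


def _confusion(truth: np.ndarray, pred: np.ndarray) -> np.ndarray:
    conf = np.zeros((2, 2), dtype=int)
    for t, pr in zip(truth, pred):
        conf[t, pr] += 1
    return conf


# --------------------------------------------------- rank tables


@dataclass(frozen=True)
class RankAgreementTable:
    """Distribution of rank_wqs - rank_cds over a result set."""

    counts: dict[int, int]  # difference -4..+4 -> count
    percentages: dict[int, float]
    n: int
    share_within_2: float  # percent with |difference| <= 2

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"difference": d, "count": self.counts[d], "percent": self.percentages[d]}
            for d in sorted(self.counts)
        ]
        return pd.DataFrame(rows)


def rank_agreement(results: list[IndexResult]) -> RankAgreementTable:
    """Tabulate the per-sample difference between the two rank assignments."""
    if not results:
        raise ValueError("no index results to tabulate")
    n = len(results)
    counts = {d: 0 for d in range(-4, 5)}
    for r in results:
        counts[r.rank_wqs - r.rank_cds] += 1
    pct = {d: 100.0 * c / n for d, c in counts.items()}
    within = 100.0 * sum(c for d, c in counts.items() if abs(d) <= 2) / n
    return RankAgreementTable(counts, pct, n, within)


def count_by_rank(
    results: list[IndexResult], index: str = "wqs", years: list[int] | None = None
) -> pd.DataFrame:
    """Per-year counts of samples in each of the five ranks.

    ``index`` selects which rank assignment to tabulate (``'wqs'`` or
    ``'cds'``); row sums equal the per-year sample counts. An explicit
    ``years`` list may include years without samples (all-zero rows).
    """
    if index not in ("wqs", "cds"):
        raise ValueError("index must be 'wqs' or 'cds'")
    attr = "rank_wqs" if index == "wqs" else "rank_cds"
    if years is None:
        years = sorted({r.year for r in results})
    table = pd.DataFrame(
        0, index=years, columns=[f"rank_{k}" for k in range(1, 6)]
    )
    for r in results:
        table.loc[r.year, f"rank_{getattr(r, attr)}"] += 1
    table.insert(0, "n", table.sum(axis=1))
    table.index.name = "year"
    return table


def paired_period_means(
    results: list[IndexResult], value: str = "wqi"
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Per-well paired (pre, post) index means for the signed-rank test.

    Each well contributes its mean pre-sewerage value paired with its mean
    post-sewerage value; wells observed in only one period are dropped.
    """
    if value not in ("wqi", "cd"):
        raise ValueError("value must be 'wqi' or 'cd'")
    pre: dict[str, list[float]] = {}
    post: dict[str, list[float]] = {}
    for r in results:
        bucket = pre if r.period == "pre_sewerage" else post
        bucket.setdefault(r.well_id, []).append(getattr(r, value))
    wells = sorted(set(pre) & set(post))
    a = np.array([np.mean(pre[w]) for w in wells])
    b = np.array([np.mean(post[w]) for w in wells])
    return a, b, wells
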