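"""Between-cluster comparisons and cross-band partition agreement.

Continuous variables are compared with a two-sided Mann–Whitney U test and
the rank-biserial correlation r_rb = 2 U1 / (n1 n2) - 1 as effect size;
categorical 2x2 associations use Fisher's exact test with the phi
coefficient; paired pre/post contrasts use the Wilcoxon signed-rank test.
Effect-size confidence intervals are percentile bootstrap.  Partition
agreement between two cluster assignments is summarized by the contingency
table, the Rand Index, and the Hubert-Arabie Adjusted Rand Index.

No multiple-comparison correction is applied anywhere; every table these
functions emit says so in its header metadata.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ComparisonResult",
    "PartitionAgreement",
    "mann_whitney_rb",
    "fisher_phi",
    "wilcoxon_prepost",
    "partition_agreement",
    "agreement_from_contingency",
    "cluster_comparison_table",
    "prepost_comparison_table",
    "NO_CORRECTION_NOTE",
]

NO_CORRECTION_NOTE = (
    "significance threshold p < 0.05; NO multiple-comparison correction applied"
)


@dataclass
class ComparisonResult:
    variable: str
    group_summaries: dict
    test: str
    statistic: float
    p_value: float
    effect_size: float
    effect_ci_low: float
    effect_ci_high: float
    degenerate: bool = False


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney_rb(
    x,
    y,
    n_boot: int = 2000,
    seed: int = 0,
    variable: str = "",
) -> ComparisonResult:
    """Two-sided Mann–Whitney U with rank-biserial effect size.

    The exact null distribution is used when n1*n2 <= 400 and there are no
    ties; otherwise the tie-corrected normal approximation with continuity
    correction.  r_rb = 2 U1 / (n1 n2) - 1, where U1 counts wins of the
    first sample (midranks split ties).  The 95% CI is a percentile
    bootstrap over ``n_boot`` resamples of both groups; pass ``n_boot=0``
    to skip it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    method = (
        "exact" if (x.size * y.size <= 400 and not _has_ties(x, y)) else "asymptotic"
    )
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)

    def rb(a: np.ndarray, b: np.ndarray) -> float:
        u = float(sps.mannwhitneyu(a, b, alternative="two-sided").statistic)
        return 2.0 * u / (a.size * b.size) - 1.0

    r = 2.0 * u1 / (x.size * y.size) - 1.0
    ci_lo = ci_hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for i in range(n_boot):
            boots[i] = rb(
                rng.choice(x, size=x.size, replace=True),
                rng.choice(y, size=y.size, replace=True),
            )
        ci_lo, ci_hi = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    return ComparisonResult(
        variable=variable,
        group_summaries={
            "group1": (float(np.mean(x)), float(np.std(x, ddof=1)) if x.size > 1 else 0.0),
            "group2": (float(np.mean(y)), float(np.std(y, ddof=1)) if y.size > 1 else 0.0),
        },
        test="mann_whitney",
        statistic=u1,
        p_value=float(res.pvalue),
        effect_size=float(r),
        effect_ci_low=ci_lo,
        effect_ci_high=ci_hi,
    )


def fisher_phi(
    table,
    n_boot: int = 2000,
    seed: int = 0,
    variable: str = "",
) -> ComparisonResult:
    """Fisher's exact test (two-sided, probability ordering) with phi.

    phi = (ad - bc) / sqrt((a+b)(c+d)(a+c)(b+d)), reported signed.  A zero
    margin makes the table degenerate: p = 1, phi = 0, flagged.  The CI is a
    percentile bootstrap over multinomial resamples of the table.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a nonnegative 2x2 count table")
    n = int(t.sum())
    if n < 1:
        raise ValueError("empty table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    margins = [a + b, c + d, a + c, b + d]
    if 0 in margins:
        return ComparisonResult(
            variable=variable,
            group_summaries={"counts": t.tolist()},
            test="fisher_exact",
            statistic=float("nan"),
            p_value=1.0,
            effect_size=0.0,
            effect_ci_low=float("nan"),
            effect_ci_high=float("nan"),
            degenerate=True,
        )

    def phi_of(tt: np.ndarray) -> float:
        aa, bb, cc, dd = tt.ravel().astype(float)
        denom = (aa + bb) * (cc + dd) * (aa + cc) * (bb + dd)
        return float((aa * dd - bb * cc) / np.sqrt(denom)) if denom > 0 else 0.0

    _, p = sps.fisher_exact(t, alternative="two-sided")
    phi = phi_of(t)
    ci_lo = ci_hi = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        probs = t.ravel() / n
        draws = rng.multinomial(n, probs, size=n_boot).reshape(n_boot, 2, 2)
        boots = np.array([phi_of(dd) for dd in draws])
        ci_lo, ci_hi = (float(q) for q in np.percentile(boots, [2.5, 97.5]))
    return ComparisonResult(
        variable=variable,
        group_summaries={"counts": t.tolist()},
        test="fisher_exact",
        statistic=phi,
        p_value=float(p),
        effect_size=phi,
        effect_ci_low=ci_lo,
        effect_ci_high=ci_hi,
    )


def _signed_rank_exact_p(ranks: np.ndarray, w_obs: float) -> float:
    """Exact two-sided signed-rank p over all sign flips, midranks allowed.

    Doubling the (mid)ranks makes them integers; a subset-sum count then
    gives the full permutation distribution of W+, which is symmetric about
    half the total, so the |deviation| rule equals twice the smaller tail.
    """
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        counts[r:] += counts[: total + 1 - r].copy()
    center = total / 2.0
    dev = abs(2 * w_obs - center) - 1e-9
    ks = np.arange(total + 1)
    p = counts[np.abs(ks - center) >= dev].sum() / counts.sum()
    return float(min(p, 1.0))


def wilcoxon_prepost(pre, post, variable: str = "") -> ComparisonResult:
    """Two-sided Wilcoxon signed-rank test on paired pre/post samples.

    Zero differences are dropped; the exact distribution is used for
    n (nonzero pairs) <= 25, the normal approximation with continuity
    correction otherwise.  All-zero differences give p = 1, flagged.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must be paired (equal length)")
    diff = post - pre
    nz = diff[diff != 0]
    if nz.size == 0:
        return ComparisonResult(
            variable=variable,
            group_summaries={
                "pre": (float(np.mean(pre)), float(np.std(pre, ddof=1)) if pre.size > 1 else 0.0),
                "post": (float(np.mean(post)), float(np.std(post, ddof=1)) if post.size > 1 else 0.0),
            },
            test="wilcoxon_signed_rank",
            statistic=float("nan"),
            p_value=1.0,
            effect_size=0.0,
            effect_ci_low=float("nan"),
            effect_ci_high=float("nan"),
            degenerate=True,
        )
    ranks = sps.rankdata(np.abs(nz))
    if nz.size <= 25:
        stat = float(ranks[nz > 0].sum())
        pval = _signed_rank_exact_p(ranks, stat)
    else:
        res = sps.wilcoxon(
            pre, post, zero_method="wilcox", alternative="two-sided",
            correction=True, method="approx",
        )
        stat, pval = float(res.statistic), float(res.pvalue)
    # matched-pairs rank-biserial: (favorable - unfavorable rank sums) / total
    r_rb = float((ranks[nz > 0].sum() - ranks[nz < 0].sum()) / ranks.sum())
    return ComparisonResult(
        variable=variable,
        group_summaries={
            "pre": (float(np.mean(pre)), float(np.std(pre, ddof=1)) if pre.size > 1 else 0.0),
            "post": (float(np.mean(post)), float(np.std(post, ddof=1)) if post.size > 1 else 0.0),
        },
        test="wilcoxon_signed_rank",
        statistic=stat,
        p_value=pval,
        effect_size=r_rb,
        effect_ci_low=float("nan"),
        effect_ci_high=float("nan"),
    )


@dataclass
class PartitionAgreement:
    contingency: np.ndarray
    rand_index: float
    adjusted_rand_index: float
    n_concordant: int

    @property
    def n(self) -> int:
        return int(self.contingency.sum())


def agreement_from_contingency(table) -> PartitionAgreement:
    """RI / ARI / concordant count from a k1 x k2 contingency table.

    RI = (a + b) / C(n, 2) with a = pairs co-clustered in both partitions
    and b = pairs separated in both.  ARI is the Hubert-Arabie form
    (Index - Expected) / (Max - Expected) under the permutation model.
    ``n_concordant`` sums the contingency cells after matching clusters
    across partitions by maximal overlap (Hungarian assignment).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("contingency must be a nonnegative 2-D count table")
    n = int(t.sum())
    if n < 2:
        raise ValueError("need at least 2 participants")
    pairs = comb(n, 2)
    index = sum(comb(int(v), 2) for v in t.ravel())
    row_pairs = sum(comb(int(v), 2) for v in t.sum(axis=1))
    col_pairs = sum(comb(int(v), 2) for v in t.sum(axis=0))
    a = index
    b = pairs - row_pairs - col_pairs + index
    ri = (a + b) / pairs
    expected = row_pairs * col_pairs / pairs
    maximum = 0.5 * (row_pairs + col_pairs)
    ari = 0.0 if maximum == expected else (index - expected) / (maximum - expected)
    from scipy.optimize import linear_sum_assignment

    r, c = linear_sum_assignment(-t)
    n_concordant = int(t[r, c].sum())
    return PartitionAgreement(
        contingency=t,
        rand_index=float(ri),
        adjusted_rand_index=float(ari),
        n_concordant=n_concordant,
    )


def partition_agreement(labels_a, labels_b) -> PartitionAgreement:
    """Agreement between two partitions of the same participant set."""
    la = np.asarray(labels_a)
    lb = np.asarray(labels_b)
    if la.shape != lb.shape or la.ndim != 1:
        raise ValueError("partitions must label the same participants")
    ua, ub = np.unique(la), np.unique(lb)
    table = np.zeros((ua.size, ub.size), dtype=np.int64)
    for i, ca in enumerate(ua):
        for j, cb in enumerate(ub):
            table[i, j] = int(((la == ca) & (lb == cb)).sum())
    return agreement_from_contingency(table)


def cluster_comparison_table(
    data: pd.DataFrame,
    labels: np.ndarray,
    continuous: list[str],
    categorical: list[str],
    seed: int = 0,
    n_boot: int = 2000,
) -> pd.DataFrame:
    """Long-format cluster comparison table (two clusters).

    Continuous variables: Mann–Whitney + r_rb (group 1 = cluster 1).
    Categorical (binary) variables: Fisher exact + phi on the
    level x cluster table.  Output mirrors the published table layout:
    per-group mean ± SD (or counts), effect size with CI, p-value.
    """
    labels = np.asarray(labels)
    ids = np.unique(labels)
    if ids.size != 2:
        raise ValueError("comparison table expects exactly 2 clusters")
    g1, g2 = labels == ids[0], labels == ids[1]
    rng = np.random.default_rng(seed)
    rows = []
    for var in continuous:
        x, y = data.loc[g1, var].to_numpy(float), data.loc[g2, var].to_numpy(float)
        res = mann_whitney_rb(
            x, y, n_boot=n_boot, seed=int(rng.integers(2**31)), variable=var
        )
        rows.append(
            {
                "variable": var,
                "test": res.test,
                "cluster1_summary": f"{np.mean(x):.2f} ± {np.std(x, ddof=1):.2f}",
                "cluster2_summary": f"{np.mean(y):.2f} ± {np.std(y, ddof=1):.2f}",
                "statistic": res.statistic,
                "effect_size": res.effect_size,
                "ci_low": res.effect_ci_low,
                "ci_high": res.effect_ci_high,
                "p_value": res.p_value,
                "note": NO_CORRECTION_NOTE,
            }
        )
    for var in categorical:
        col = data[var]
        levels = sorted(col.unique())
        if len(levels) != 2:
            raise ValueError(f"categorical variable {var!r} must be binary")
        tab = [
            [int((col[g] == lv).sum()) for g in (g1, g2)] for lv in levels
        ]
        res = fisher_phi(
            tab, n_boot=n_boot, seed=int(rng.integers(2**31)), variable=var
        )
        rows.append(
            {
                "variable": var,
                "test": res.test,
                "cluster1_summary": f"{levels[0]}={tab[0][0]}, {levels[1]}={tab[1][0]}",
                "cluster2_summary": f"{levels[0]}={tab[0][1]}, {levels[1]}={tab[1][1]}",
                "statistic": res.statistic,
                "effect_size": res.effect_size,
                "ci_low": res.effect_ci_low,
                "ci_high": res.effect_ci_high,
                "p_value": res.p_value,
                "note": NO_CORRECTION_NOTE,
            }
        )
    return pd.DataFrame(rows)


def prepost_comparison_table(
    metrics: pd.DataFrame, variables: list[str]
) -> pd.DataFrame:
    """Paired pre/post Wilcoxon tests over cohort-level metric columns.

    ``metrics`` must be wide with ``<var>_before`` / ``<var>_after`` columns.
    """
    rows = []
    for var in variables:
        res = wilcoxon_prepost(
            metrics[f"{var}_before"], metrics[f"{var}_after"], variable=var
        )
        rows.append(
            {
                "variable": var,
                "test": res.test,
                "pre_mean": res.group_summaries["pre"][0],
                "pre_sd": res.group_summaries["pre"][1],
                "post_mean": res.group_summaries["post"][0],
                "post_sd": res.group_summaries["post"][1],
                "statistic": res.statistic,
                "effect_size": res.effect_size,
                "p_value": res.p_value,
                "note": NO_CORRECTION_NOTE,
            }
        )
    return pd.DataFrame(rows)
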