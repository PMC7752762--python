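"""Descriptive statistics for baseline and intake tables.

The trial's descriptive tables use distribution-free tests throughout:
Kruskal-Wallis across the four diet-sex groups for continuous variables,
Dunn's rank-based post-hoc test with Bonferroni adjustment for pairwise
follow-up (reported as shared-superscript letter codes), and Fisher's exact
test — generalized to r x c tables by Freeman-Halton enumeration — for
categorical variables.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def kruskal_wallis(values, group_labels) -> tuple[float, int, float]:
    """Kruskal-Wallis H with tie correction; p from chi-square on k-1 df.

    Identical values across all groups yield H = 0, p = 1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    samples = [values[labels == g] for g in uniq]
    if any(len(s) == 0 for s in samples):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return 0.0, len(uniq) - 1, 1.0
    H, p = stats.kruskal(*samples)
    return float(H), len(uniq) - 1, float(p)


@dataclass
class DunnResult:
    pairs: pd.DataFrame  # group_a, group_b, z, p_unadjusted, p_bonferroni, significant
    letters: dict[str, str]  # shared-superscript code per group


def dunn_bonferroni(values, group_labels) -> DunnResult:
    """Dunn's pairwise rank test after Kruskal-Wallis, Bonferroni adjusted.

    z_ij = (Rbar_i - Rbar_j) / sqrt[(N(N+1)/12 - T) (1/n_i + 1/n_j)] with the
    tie term T = sum(t^3 - t) / (12 (N - 1)); each two-sided p is multiplied
    by the number of pairs and capped at 1.  Pairs with adjusted p < 0.05
    receive a shared letter in the per-group codes, mirroring the
    shared-superscript convention of trial baseline tables.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    uniq = list(pd.unique(labels))
    if len(uniq) < 3:
        raise ValueError("Dunn's post-hoc test needs at least three groups")
    sizes = {g: int((labels == g).sum()) for g in uniq}
    if any(n == 0 for n in sizes.values()):
        raise ValueError("every group must be non-empty")
    N = len(values)
    ranks = stats.rankdata(values)
    mean_rank = {g: float(ranks[labels == g].mean()) for g in uniq}
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(uniq, 2))
    m = len(pairs)
    rows = []
    sig_pairs = []
    for a, b in pairs:
        se = math.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p_un = 2.0 * float(stats.norm.sf(abs(z)))
        p_adj = min(1.0, m * p_un)
        sig = p_adj < 0.05
        if sig:
            sig_pairs.append((a, b))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": z,
                "p_unadjusted": p_un,
                "p_bonferroni": p_adj,
                "significant": sig,
            }
        )
    letters = {g: "" for g in uniq}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    for code, (a, b) in zip(alphabet, sig_pairs):
        letters[a] += code
        letters[b] += code
    return DunnResult(pairs=pd.DataFrame(rows), letters=letters)


def _table_log_prob(table: np.ndarray, lognum: float) -> float:
    """log P(table | margins) under the multiple hypergeometric distribution."""
    return lognum - sum(math.lgamma(x + 1) for x in table.ravel())


def _enumerate_tables(row_sums, col_sums):
    """Yield all non-negative integer tables with the given margins."""
    r, c = len(row_sums), len(col_sums)

    def rec(row_idx, remaining_cols, current):
        if row_idx == r - 1:
            last = np.asarray(remaining_cols)
            if (last >= 0).all():
                yield current + [list(last)]
            return
        target = row_sums[row_idx]

        def fill(col_idx, left, row_acc):
            if col_idx == c - 1:
                if 0 <= left <= remaining_cols[col_idx]:
                    yield row_acc + [left]
                return
            hi = min(left, remaining_cols[col_idx])
            for v in range(hi + 1):
                yield from fill(col_idx + 1, left - v, row_acc + [v])

        for row in fill(0, target, []):
            rem = [remaining_cols[j] - row[j] for j in range(c)]
            yield from rec(row_idx + 1, rem, current + [row])

    yield from rec(0, list(col_sums), [])


def _count_tables_upper_bound(row_sums, col_sums) -> float:
    """Cheap upper bound on the number of margin-fixed tables."""
    r, c = len(row_sums), len(col_sums)
    bound = 1.0
    for i in range(r - 1):
        for j in range(c - 1):
            bound *= min(row_sums[i], col_sums[j]) + 1
    return bound


def fisher_exact_rxc(
    table,
    max_enumeration: float = 1e7,
    n_monte_carlo: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float | None]:
    """Two-sided exact test of independence for an r x c count table.

    Freeman-Halton rule: the p-value is the total probability, under the
    multiple hypergeometric distribution with the observed margins, of all
    tables no more probable than the observed one.  Tables are enumerated
    exactly while the (bounded) enumeration count stays below
    ``max_enumeration``; beyond that a Monte-Carlo estimate over
    margin-preserving random tables is returned together with its binomial
    standard error (``None`` for the exact path).

    Rows or columns with a zero margin are dropped (with a warning); they
    carry no information about association.
    """
    T = np.asarray(table)
    if T.ndim != 2:
        raise ValueError("table must be two-dimensional")
    if np.any(T < 0) or not np.issubdtype(T.dtype, np.integer):
        T = T.astype(float)
        if np.any(T < 0) or np.any(T != np.round(T)):
            raise ValueError("table entries must be non-negative integers")
        T = T.astype(int)
    row_ok = T.sum(axis=1) > 0
    col_ok = T.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        logger.warning("dropping %d zero-margin row(s)/column(s)", int((~row_ok).sum() + (~col_ok).sum()))
        T = T[row_ok][:, col_ok]
    if T.shape[0] < 2 or T.shape[1] < 2:
        return 1.0, None
    row_sums = T.sum(axis=1)
    col_sums = T.sum(axis=0)
    n = int(T.sum())
    lognum = (
        sum(math.lgamma(x + 1) for x in row_sums)
        + sum(math.lgamma(x + 1) for x in col_sums)
        - math.lgamma(n + 1)
    )
    logp_obs = _table_log_prob(T, lognum)

    if _count_tables_upper_bound(row_sums, col_sums) <= max_enumeration:
        tol = 1e-10  # counts "as probable" tables despite float round-off
        total = 0.0
        for tab in _enumerate_tables(list(row_sums), list(col_sums)):
            lp = _table_log_prob(np.asarray(tab), lognum)
            if lp <= logp_obs + tol:
                total += math.exp(lp)
        return min(total, 1.0), None

    rng = rng or np.random.default_rng(0)
    dist = stats.random_table(row_sums, col_sums)
    draws = dist.rvs(n_monte_carlo, method="patefield", random_state=rng)
    lps = np.array([_table_log_prob(d, lognum) for d in draws])
    hits = float(np.mean(lps <= logp_obs + 1e-10))
    se = math.sqrt(hits * (1.0 - hits) / n_monte_carlo)
    return hits, se


def proportion_endorsing(
    counts_by_category: dict[str, int],
    categories_of_interest,
    denominator: int | None = None,
) -> tuple[float, int]:
    """Percentage of a group endorsing the given categories.

    The denominator defaults to the sum over all categories (all randomized,
    with missing responses kept as their own category).  Returns the
    unrounded percentage and its nearest-integer display value.
    """
    for cat in categories_of_interest:
        if cat not in counts_by_category:
            raise ValueError(f"unknown category label {cat!r}")
    total = denominator if denominator is not None else sum(counts_by_category.values())
    if total <= 0:
        raise ValueError("denominator must be positive")
    hits = sum(counts_by_category[c] for c in categories_of_interest)
    pct = 100.0 * hits / total
    return pct, int(round(pct))


def group_summary_continuous(values: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Mean (SD) per group with missing counts, plus the omnibus p-value."""
    df = pd.DataFrame({"value": values, "group": groups})
    out = []
    for g, sub in df.groupby("group", sort=False):
        v = sub["value"].dropna()
        out.append(
            {
                "group": g,
                "n": len(sub),
                "mean": v.mean(),
                "sd": v.std(ddof=1),
                "missing": int(sub["value"].isna().sum()),
                "display": f"{v.mean():.1f} (±{v.std(ddof=1):.1f})",
            }
        )
    res = pd.DataFrame(out)
    complete = df.dropna()
    if complete["group"].nunique() >= 2:
        _, _, p = kruskal_wallis(complete["value"].to_numpy(), complete["group"].to_numpy())
        res["omnibus_p"] = p
    return res
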