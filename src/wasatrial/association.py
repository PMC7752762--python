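"""Adherence-outcome association and the descriptive mediation check.

Covers three questions about the WASA adherence score:

* does adherence differ by diet-sex group? (one-way OLS regression with an
  omnibus F and the four pairwise t contrasts, no multiplicity adjustment);
* does adherence track 12-month percent change in each body measure?
  (Spearman rank correlation within each diet-sex group);
* does adjusting the longitudinal mixed model for WASA move the group
  contrasts? (a descriptive mediation check: if group differences operate
  through adherence, adding WASA as a covariate should shrink them).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from wasatrial.lmm import (
    ContrastResult,
    LMMFit,
    ModelSpec,
    OmnibusResult,
    fit_lmm,
    pairwise_12mo_contrasts,
)

logger = logging.getLogger(__name__)

GROUP_ORDER = ("HLC-F", "HLC-M", "HLF-F", "HLF-M")

#: (label, plus, minus) — same comparisons of interest as the outcome models.
PAIRWISE = (
    ("HLC vs HLF, women", "HLC-F", "HLF-F"),
    ("HLC vs HLF, men", "HLC-M", "HLF-M"),
    ("Men vs women, HLC", "HLC-M", "HLC-F"),
    ("Men vs women, HLF", "HLF-M", "HLF-F"),
)


@dataclass
class AdherenceGroupResult:
    omnibus: OmnibusResult
    contrasts: list[ContrastResult]
    group_means: pd.Series
    n_with_wasa: int


@dataclass
class CorrelationResult:
    group: str
    measure: str
    rs: float
    p: float
    n: int
    flagged: bool = False


def percent_change_12mo(outcomes: pd.DataFrame, measure: str) -> pd.Series:
    """Observed 12-month percent change per participant, 100*(v12 - v0)/v0.

    Participants missing either endpoint are excluded (their count is
    logged); a non-positive baseline value is a data error.
    """
    meas = outcomes[outcomes["measure"] == measure]
    wide = meas.pivot_table(index="participant_id", columns="month", values="value_kg")
    for month in (0, 12):
        if month not in wide.columns:
            wide[month] = np.nan
    complete = wide[[0, 12]].dropna()
    n_excl = len(wide) - len(complete)
    if n_excl:
        logger.info("%s: %d participant(s) lack baseline or month-12 value", measure, n_excl)
    if (complete[0] <= 0).any():
        raise ValueError(f"non-positive baseline {measure} value encountered")
    pct = 100.0 * (complete[12] - complete[0]) / complete[0]
    pct.name = f"pct_change_{measure}"
    return pct


def adherence_group_regression(wasa_table: pd.DataFrame) -> AdherenceGroupResult:
    """OLS of WASA on the 4-level diet-sex group factor.

    One-way ANOVA algebra: the omnibus F has (k-1, n-k) degrees of freedom;
    pairwise contrasts use the pooled residual variance with n-k df.
    """
    df = wasa_table.dropna(subset=["wasa"]).copy()
    df["group"] = df["diet"] + "-" + df["sex"]
    present = [g for g in GROUP_ORDER if g in set(df["group"])]
    present += [g for g in df["group"].unique() if g not in present]
    counts = df.groupby("group")["wasa"].count()
    for g in present:
        if counts.get(g, 0) < 2:
            raise ValueError(f"group {g} has fewer than 2 participants with a WASA score")
    n = len(df)
    k = len(present)
    if k < 2:
        raise ValueError("need at least two diet-sex groups with WASA scores")
    means = df.groupby("group")["wasa"].mean().reindex(present)
    grand = df["wasa"].mean()
    ss_between = float((counts.reindex(present) * (means - grand) ** 2).sum())
    ss_within = float(
        df.groupby("group")["wasa"].apply(lambda v: ((v - v.mean()) ** 2).sum()).sum()
    )
    df2 = n - k
    ms_within = ss_within / df2
    scale = n * (abs(grand) + 1.0) ** 2
    if ss_between < 1e-12 * scale:
        ss_between = 0.0
    if ms_within > 0:
        F = (ss_between / (k - 1)) / ms_within
    else:
        F = 0.0 if ss_between == 0 else float("inf")
    p = float(stats.f.sf(F, k - 1, df2))
    omnibus = OmnibusResult(F=float(F), df1=k - 1, df2=float(df2), p=p)

    contrasts = []
    tcrit = stats.t.ppf(0.975, df2)
    if set(present) >= set(GROUP_ORDER):
        comparisons = PAIRWISE
    else:
        comparisons = [
            (f"{a} vs {b}", a, b)
            for i, a in enumerate(present)
            for b in present[i + 1 :]
        ]
    for label, plus, minus in comparisons:
        est = float(means[plus] - means[minus])
        se = float(np.sqrt(ms_within * (1.0 / counts[plus] + 1.0 / counts[minus])))
        t = est / se if se > 0 else 0.0
        pc = 2.0 * float(stats.t.sf(abs(t), df2)) if se > 0 else 1.0
        contrasts.append(
            ContrastResult(label, est, se, float(df2), t, pc, est - tcrit * se, est + tcrit * se)
        )
    return AdherenceGroupResult(omnibus, contrasts, means, n)


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for Spearman's rs (n <= 10)."""
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p supported only for n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = abs(np.corrcoef(rx, ry[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def spearman_by_group(
    wasa_table: pd.DataFrame,
    pct_change: pd.Series,
    measure: str,
    exact: bool = False,
) -> list[CorrelationResult]:
    """Spearman rank correlation of WASA with percent change, per group.

    Average ranks for ties; p from the t approximation (or exact
    permutation when ``exact`` and n <= 10).  Groups with fewer than three
    pairs are flagged and get no p-value.
    """
    merged = wasa_table.dropna(subset=["wasa"]).merge(
        pct_change.rename("pct"), left_on="participant_id", right_index=True
    )
    merged["group"] = merged["diet"] + "-" + merged["sex"]
    results = []
    for g in GROUP_ORDER:
        sub = merged[merged["group"] == g]
        n = len(sub)
        if n < 3:
            results.append(CorrelationResult(g, measure, float("nan"), float("nan"), n, True))
            continue
        rs, p = stats.spearmanr(sub["wasa"], sub["pct"])
        if exact and n <= 10:
            p = _exact_spearman_p(sub["wasa"].to_numpy(), sub["pct"].to_numpy())
        results.append(CorrelationResult(g, measure, float(rs), float(p), n))
    return results


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"group": r.group, "measure": r.measure, "rs": r.rs, "p": r.p, "n": r.n}
            for r in results
        ]
    )


def mediation_check(
    outcomes: pd.DataFrame,
    participants: pd.DataFrame,
    wasa_table: pd.DataFrame,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Compare group contrasts with and without adjustment for WASA.

    Both models are fit on the same participants (those with a WASA score)
    so any difference is attributable to the adjustment, not to the sample.
    Returns one row per pairwise comparison with unadjusted and adjusted
    estimates and their absolute and relative differences.
    """
    spec = spec or ModelSpec()
    scored = wasa_table.dropna(subset=["wasa"])
    keep = set(scored["participant_id"])
    outcomes_w = outcomes[outcomes["participant_id"].isin(keep)]
    participants_w = participants[participants["participant_id"].isin(keep)]

    base_spec = ModelSpec(
        measure=spec.measure, months=spec.months, analysis_set=spec.analysis_set
    )
    fit_unadj = fit_lmm(outcomes_w, participants_w, base_spec)
    adj_spec = ModelSpec(
        measure=spec.measure,
        months=spec.months,
        analysis_set=spec.analysis_set,
        extra_covariates=("wasa",),
    )
    fit_adj = fit_lmm(outcomes_w, participants_w, adj_spec, wasa_table=scored)

    rows = []
    for unadj, adj in zip(pairwise_12mo_contrasts(fit_unadj), pairwise_12mo_contrasts(fit_adj)):
        delta = adj.estimate - unadj.estimate
        rel = delta / abs(unadj.estimate) if unadj.estimate != 0 else np.nan
        rows.append(
            {
                "label": unadj.label,
                "measure": spec.measure,
                "estimate_unadjusted": unadj.estimate,
                "estimate_wasa_adjusted": adj.estimate,
                "abs_change": abs(delta),
                "rel_change": rel,
            }
        )
    return pd.DataFrame(rows)
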