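"""Weight-adjusted standardized adherence (WASA) scoring.

Both arms of the trial share a 20 g/day prescription for their restricted
macronutrient (carbohydrate on the low-carb arm, fat on the low-fat arm)
during the initial "limbo" phase, which makes a single adherence scale
possible across arms of very different absolute intake.  For each
participant and post-randomization timepoint (months 3, 6, 12):

1. average the available 24-h recall days' restricted-macronutrient grams;
2. deviation = 20 g - averaged grams (sign preserved; intake below target
   gives a positive deviation);
3. deviation score DS = deviation / baseline body weight (g per kg), so a
   30 g overshoot counts for more in a lighter person;
4. z-score the DS within each diet x month stratum (both sexes pooled, so
   scores are comparable across sex);
5. WASA = mean of the available z-scores over months 3, 6 and 12.

A WASA of 0 is average adherence relative to everyone on the same diet;
positive is better than average, negative worse.
"""

from __future__ import annotations

import logging
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from wasatrial.config import POST_MONTHS
from wasatrial.synthetic import RESTRICTED

logger = logging.getLogger(__name__)

TARGET_G = 20.0

SdConvention = Literal["sample", "population"]


def average_recalls(recalls_at_month: pd.DataFrame | Iterable[float], restricted: str = "carb") -> float:
    """Mean reported grams of the restricted macronutrient over 1-3 recall days.

    Accepts either a recalls DataFrame slice (one participant-month) or a
    bare sequence of gram values.  An empty input yields ``nan`` (missing),
    not an error: a participant simply has no dietary data at that visit.
    """
    if isinstance(recalls_at_month, pd.DataFrame):
        if restricted not in ("carb", "fat"):
            raise ValueError(f"restricted macronutrient must be 'carb' or 'fat', got {restricted!r}")
        values = recalls_at_month[f"{restricted}_g"].to_numpy(dtype=float)
    else:
        values = np.asarray(list(recalls_at_month), dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan")
    if values.size > 3:
        raise ValueError("at most three recall days per participant-month")
    return float(values.mean())


def deviation_from_target(mean_g: float, target_g: float = TARGET_G) -> float:
    """Signed deviation ``target - mean`` in grams (no capping, no absolute value)."""
    if np.isnan(mean_g):
        return float("nan")
    if mean_g < 0:
        raise ValueError(f"mean intake must be non-negative, got {mean_g}")
    return float(target_g - mean_g)


def deviation_score(deviation_g: float, baseline_weight_kg: float) -> float:
    """DS = deviation (g) per kg of baseline body weight."""
    if baseline_weight_kg is None or not baseline_weight_kg > 0:
        raise ValueError(f"baseline weight must be positive, got {baseline_weight_kg}")
    return float(deviation_g) / float(baseline_weight_kg)


def zscore_within_strata(
    ds_table: pd.DataFrame, sd_convention: SdConvention = "sample"
) -> pd.DataFrame:
    """Z-score the ``ds`` column within each (diet, month) stratum.

    Strata pool both sexes; that is what makes cross-sex adherence
    comparisons on the z scale meaningful.  A stratum with fewer than two
    non-missing scores, or zero spread, cannot be normalized: its z-scores
    are set missing and a warning is logged.

    Parameters
    ----------
    ds_table
        Long table with columns ``participant_id, diet, month, ds`` (extra
        columns pass through).
    sd_convention
        ``"sample"`` (n-1 denominator, default) or ``"population"`` (n).
    """
    if sd_convention not in ("sample", "population"):
        raise ValueError(f"sd_convention must be 'sample' or 'population', got {sd_convention!r}")
    ddof = 1 if sd_convention == "sample" else 0
    out = ds_table.copy()
    orig_index = out.index
    out.index = pd.RangeIndex(len(out))  # guard against duplicate labels
    out["z"] = np.nan
    for (diet, month), idx in out.groupby(["diet", "month"]).groups.items():
        ds = out.loc[idx, "ds"]
        valid = ds.dropna()
        if len(valid) < 2:
            logger.warning(
                "stratum (%s, month %s) has %d score(s); z set missing", diet, month, len(valid)
            )
            continue
        sd = valid.std(ddof=ddof)
        if sd == 0 or np.isnan(sd):
            logger.warning("stratum (%s, month %s) has zero spread; z set missing", diet, month)
            continue
        out.loc[idx, "z"] = (ds - valid.mean()) / sd
    out.index = orig_index
    return out


def wasa(z_by_month: Iterable[float]) -> float:
    """Average of the available z-scores; ``nan`` when none are available."""
    values = np.asarray(list(z_by_month), dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan")
    if values.size > len(POST_MONTHS):
        raise ValueError("at most one z-score per post-randomization month")
    return float(values.mean())


def compute_wasa_table(
    recalls: pd.DataFrame,
    participants: pd.DataFrame,
    sd_convention: SdConvention = "sample",
) -> pd.DataFrame:
    """Full scoring pipeline: recalls + participants -> one WASA row each.

    Returns a table with columns ``participant_id, diet, sex, ds_3, ds_6,
    ds_12, z_3, z_6, z_12, wasa, n_months_available``.  Participants with
    no post-randomization recalls get ``wasa = nan`` and are excluded from
    adherence analyses downstream.  Baseline (month 0) recalls never enter.
    """
    part = participants.set_index("participant_id")
    missing_weight = part["baseline_weight_kg"].isna()
    if missing_weight.any():
        logger.warning(
            "%d participant(s) lack baseline weight; excluded from DS", int(missing_weight.sum())
        )
        part = part[~missing_weight]

    post = recalls[recalls["month"].isin(POST_MONTHS)]
    rows = []
    for (pid, month), grp in post.groupby(["participant_id", "month"]):
        if pid not in part.index:
            continue
        diet = part.at[pid, "diet"]
        mean_g = average_recalls(grp, RESTRICTED[diet])
        dev = deviation_from_target(mean_g)
        rows.append(
            {
                "participant_id": pid,
                "diet": diet,
                "month": int(month),
                "mean_restricted_g": mean_g,
                "deviation_g": dev,
                "ds": deviation_score(dev, part.at[pid, "baseline_weight_kg"]),
            }
        )
    ds_long = pd.DataFrame(rows, columns=["participant_id", "diet", "month", "mean_restricted_g", "deviation_g", "ds"])
    ds_long = zscore_within_strata(ds_long, sd_convention=sd_convention)

    ds_wide = ds_long.pivot_table(index="participant_id", columns="month", values="ds")
    z_wide = ds_long.pivot_table(index="participant_id", columns="month", values="z")
    out = pd.DataFrame(index=part.index)
    for month in POST_MONTHS:
        out[f"ds_{month}"] = ds_wide[month] if month in ds_wide else np.nan
        out[f"z_{month}"] = z_wide[month] if month in z_wide else np.nan
    zcols = [f"z_{m}" for m in POST_MONTHS]
    out["n_months_available"] = out[zcols].notna().sum(axis=1)
    out["wasa"] = out[zcols].mean(axis=1)  # pandas mean skips NaN
    out.loc[out["n_months_available"] == 0, "wasa"] = np.nan
    out = out.reset_index().rename(columns={"index": "participant_id"})
    out.insert(1, "diet", part["diet"].to_numpy())
    out.insert(2, "sex", part["sex"].to_numpy())
    n_excluded = int(out["wasa"].isna().sum())
    if n_excluded:
        logger.info("%d participant(s) have no post-randomization recalls (WASA missing)", n_excluded)
    return out
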