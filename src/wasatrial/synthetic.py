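"""Synthetic trial-cohort generator.

Emulates the data structure of a two-arm macronutrient-restriction trial:
a participants table, a longitudinal outcomes table (weight at months
0/3/6/12; DEXA fat and lean mass at months 0/6/12), and a 24-h dietary
recall table (up to three recall days per participant per timepoint).

Generating model for each outcome measure::

    value(t) = baseline + f(t) * (delta_group + effect * a_i) + b_i + eps_it

with f(0) = 0, f(12) = 1 and f(3), f(6) from ``time_fraction``;
``a_i ~ N(group shift, 1)`` the latent adherence trait, ``b_i`` a subject
random intercept and ``eps`` visit-level noise.  Reported
restricted-macronutrient intake decreases smoothly with ``a_i``::

    grams = 20 + softplus(location - scale * a_i + noise)

so the 20 g/day prescription is a floor approached but rarely met.
Post-baseline visits are dropped independently (missing at random given
arm and sex), and the earliest-enrolled fraction of participants lacks all
DEXA records, including the baseline body-fat percentage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from wasatrial.config import (
    DEXA_MONTHS,
    GROUPS,
    POST_MONTHS,
    RECALL_MONTHS,
    WEIGHT_MONTHS,
    CohortConfig,
)

logger = logging.getLogger(__name__)

#: Share of the adherence-driven weight change attributed to fat / lean mass.
FAT_ADHERENCE_SHARE = 0.7
LEAN_ADHERENCE_SHARE = 0.3

#: Noise scale factors for DEXA measures relative to the weight SDs
#: (DEXA repeatability is better than day-to-day weight fluctuation).
FAT_NOISE_SCALE = 0.5
LEAN_NOISE_SCALE = 0.4

#: Lean mass at baseline is this fraction of fat-free mass; the remainder
#: (bone mineral etc.) keeps fat + lean strictly below total weight.
LEAN_FRACTION_OF_FAT_FREE = 0.85

#: Baseline (pre-randomization) macronutrient intake moments (g): mean, SD.
_BASELINE_INTAKE = {"carb": (240.0, 80.0), "fat": (90.0, 33.0), "protein": (95.0, 28.0)}

#: Post-randomization moments for the *unrestricted* macronutrients (g).
_POST_UNRESTRICTED = {"carb": (200.0, 70.0), "fat": (90.0, 30.0), "protein": (95.0, 28.0)}

#: Restricted macronutrient by arm.
RESTRICTED = {"HLC": "carb", "HLF": "fat"}

_RECALL_DAY_PROBS = ((1, 0.05), (2, 0.15), (3, 0.80))


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(x))
    return np.logaddexp(0.0, x)


def generate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate one synthetic cohort.

    Returns
    -------
    participants : DataFrame
        Columns ``participant_id, sex, diet, baseline_weight_kg,
        baseline_bodyfat_pct, latent_adherence``.  The latent trait exists
        only in memory; :func:`write_cohort` never exports it.
    outcomes : DataFrame
        Columns ``participant_id, measure, month, value_kg`` (long format).
    recalls : DataFrame
        Columns ``participant_id, month, day_index, carb_g, fat_g,
        protein_g, energy_kcal``.
    """
    config.validate()
    root = np.random.SeedSequence(int(config.seed))
    (ss_part, ss_out, ss_rec, ss_ret) = root.spawn(4)
    rng_part = np.random.default_rng(ss_part)
    rng_out = np.random.default_rng(ss_out)
    rng_rec = np.random.default_rng(ss_rec)
    rng_ret = np.random.default_rng(ss_ret)

    participants = _draw_participants(config, rng_part)
    attended = _draw_attendance(config, participants, rng_ret)
    outcomes = _draw_outcomes(config, participants, attended, rng_out)
    recalls = _draw_recalls(config, participants, attended, rng_rec)
    return participants, outcomes, recalls


def _draw_participants(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    for diet, sex in GROUPS:
        n = config.n_per_group[(diet, sex)]
        w = rng.normal(config.baseline_weight_mean_kg[sex], config.baseline_weight_sd_kg[sex], n)
        w = np.clip(w, 45.0, None)
        bf = rng.normal(
            config.baseline_bodyfat_mean_pct[sex], config.baseline_bodyfat_sd_pct[sex], n
        )
        bf = np.clip(bf, 5.0, 60.0)
        a = rng.normal(config.adherence_mean_by_group.get((diet, sex), 0.0), 1.0, n)
        rows.append(
            pd.DataFrame(
                {
                    "sex": sex,
                    "diet": diet,
                    "baseline_weight_kg": w,
                    "baseline_bodyfat_pct": bf,
                    "latent_adherence": a,
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    # enrollment order is a seeded interleaving of the four groups; the
    # DEXA-missing rule applies to the earliest enrollees
    order = rng.permutation(len(df))
    df = df.iloc[np.argsort(order)].reset_index(drop=True)
    df.insert(0, "participant_id", [f"P{i + 1:04d}" for i in range(len(df))])
    n_missing_dexa = int(np.floor(config.dexa_missing_fraction * len(df)))
    df["has_dexa"] = True
    df.loc[: n_missing_dexa - 1, "has_dexa"] = False
    df.loc[~df["has_dexa"], "baseline_bodyfat_pct"] = np.nan
    return df


def _draw_attendance(
    config: CohortConfig, participants: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Visit-attendance indicator per participant x post-baseline month."""
    n = len(participants)
    cols = {}
    for month in POST_MONTHS:
        cols[month] = rng.random(n) < config.retention_at(month)
    out = pd.DataFrame(cols, index=participants["participant_id"])
    out[0] = True  # baseline visit always attended
    return out


def _time_fractions(config: CohortConfig) -> dict[int, float]:
    return {0: 0.0, 3: config.time_fraction[3], 6: config.time_fraction[6], 12: 1.0}


def _draw_outcomes(
    config: CohortConfig,
    participants: pd.DataFrame,
    attended: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    f = _time_fractions(config)
    n = len(participants)
    w0 = participants["baseline_weight_kg"].to_numpy()
    bf = participants["baseline_bodyfat_pct"].to_numpy()
    a = participants["latent_adherence"].to_numpy()
    has_dexa = participants["has_dexa"].to_numpy()
    diet = participants["diet"].to_numpy()
    sex = participants["sex"].to_numpy()

    fat0 = np.where(has_dexa, w0 * bf / 100.0, np.nan)
    lean0 = LEAN_FRACTION_OF_FAT_FREE * (w0 - fat0)
    b = rng.normal(0.0, config.subject_sd_kg, n)

    delta = {
        m: np.array(
            [config.true_change_12mo[(m, d, s)] for d, s in zip(diet, sex)]
        )
        for m in ("weight", "fat_mass", "lean_mass")
    }
    adh = {
        "weight": config.adherence_effect_kg * a,
        "fat_mass": FAT_ADHERENCE_SHARE * config.adherence_effect_kg * a,
        "lean_mass": LEAN_ADHERENCE_SHARE * config.adherence_effect_kg * a,
    }
    base = {"weight": w0 + b, "fat_mass": fat0 + 0.6 * b, "lean_mass": lean0 + 0.4 * b}
    res_sd = {
        "weight": config.residual_sd_kg,
        "fat_mass": FAT_NOISE_SCALE * config.residual_sd_kg,
        "lean_mass": LEAN_NOISE_SCALE * config.residual_sd_kg,
    }
    months_for = {"weight": WEIGHT_MONTHS, "fat_mass": DEXA_MONTHS, "lean_mass": DEXA_MONTHS}

    frames = []
    for measure in ("weight", "fat_mass", "lean_mass"):
        for month in months_for[measure]:
            eps = rng.normal(0.0, res_sd[measure], n) if res_sd[measure] > 0 else np.zeros(n)
            value = base[measure] + f[month] * (delta[measure] + adh[measure]) + eps
            ok = attended[month].to_numpy()
            if measure != "weight":
                ok = ok & has_dexa
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": participants["participant_id"],
                        "measure": measure,
                        "month": month,
                        "value_kg": value,
                    }
                )[ok]
            )
    out = pd.concat(frames, ignore_index=True)
    out = _enforce_composition(out)
    out["value_kg"] = out["value_kg"].clip(lower=1.0)
    return out.sort_values(["participant_id", "measure", "month"]).reset_index(drop=True)


def _enforce_composition(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Clamp lean mass so fat + lean stays below weight at each visit.

    Visit-level noise is drawn independently per measure; this physical
    consistency clamp fires only in rare tail draws (the noise-free model
    keeps an explicit bone-mineral margin).
    """
    wide = outcomes.pivot_table(
        index=["participant_id", "month"], columns="measure", values="value_kg"
    )
    if not {"weight", "fat_mass", "lean_mass"} <= set(wide.columns):
        return outcomes
    full = wide.dropna(subset=["weight", "fat_mass", "lean_mass"])
    cap = full["weight"] - full["fat_mass"] - 0.1
    bad = full["lean_mass"] > cap
    if bad.any():
        logger.debug("composition clamp applied to %d visit records", int(bad.sum()))
        fixes = cap[bad]
        idx = outcomes.set_index(["participant_id", "month", "measure"]).index
        outcomes = outcomes.copy()
        for (pid, month), newval in fixes.items():
            mask = (
                (outcomes["participant_id"] == pid)
                & (outcomes["month"] == month)
                & (outcomes["measure"] == "lean_mass")
            )
            outcomes.loc[mask, "value_kg"] = newval
        del idx
    return outcomes


def _draw_recalls(
    config: CohortConfig,
    participants: pd.DataFrame,
    attended: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    a = participants["latent_adherence"].to_numpy()
    diet = participants["diet"].to_numpy()
    pid = participants["participant_id"].to_numpy()
    n = len(participants)

    day_counts_choices = np.array([c for c, _ in _RECALL_DAY_PROBS])
    day_counts_probs = np.array([p for _, p in _RECALL_DAY_PROBS])

    frames = []
    for month in RECALL_MONTHS:
        ok = attended[month].to_numpy()
        n_days = rng.choice(day_counts_choices, size=n, p=day_counts_probs)
        for day in (1, 2, 3):
            present = ok & (n_days >= day)
            macros = {}
            if month == 0:
                for macro, (mu, sd) in _BASELINE_INTAKE.items():
                    macros[macro] = np.clip(rng.normal(mu, sd, n), 0.0, None)
            else:
                noise = rng.normal(0.0, config.recall_noise_sd_g, n)
                restricted_g = 20.0 + _softplus(
                    config.intake_location - config.intake_scale * a + noise
                )
                for macro, (mu, sd) in _POST_UNRESTRICTED.items():
                    macros[macro] = np.clip(rng.normal(mu, sd, n), 0.0, None)
                for arm, macro in RESTRICTED.items():
                    macros[macro] = np.where(diet == arm, restricted_g, macros[macro])
            energy = (
                4.0 * macros["carb"]
                + 9.0 * macros["fat"]
                + 4.0 * macros["protein"]
                + rng.normal(0.0, 50.0, n)
            )
            frames.append(
                pd.DataFrame(
                    {
                        "participant_id": pid,
                        "month": month,
                        "day_index": day,
                        "carb_g": macros["carb"],
                        "fat_g": macros["fat"],
                        "protein_g": macros["protein"],
                        "energy_kcal": np.clip(energy, 0.0, None),
                    }
                )[present]
            )
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["participant_id", "month", "day_index"]).reset_index(drop=True)


def write_cohort(
    participants: pd.DataFrame,
    outcomes: pd.DataFrame,
    recalls: pd.DataFrame,
    out_dir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write the three analysis-facing CSV files.

    The latent adherence trait and the internal ``has_dexa`` flag are
    excluded from ``participants.csv``: downstream analysis must only see
    what a real trial would record.
    """
    from wasatrial.io import write_csv_with_metadata

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    public = participants[
        ["participant_id", "sex", "diet", "baseline_weight_kg", "baseline_bodyfat_pct"]
    ]
    paths = {}
    for name, df in (
        ("participants", public),
        ("outcomes", outcomes),
        ("recalls", recalls),
    ):
        paths[name] = write_csv_with_metadata(df, out_dir / f"{name}.csv", metadata)
    return paths
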