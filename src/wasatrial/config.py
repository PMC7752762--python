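"""Configuration for the synthetic trial-cohort generator.

:class:`CohortConfig` holds every knob of the generating model.  The defaults
describe a 609-participant, two-arm (healthy low-carbohydrate, HLC, vs.
healthy low-fat, HLF), 12-month weight-loss trial with four diet-sex analysis
cells, ~79% retention at each post-baseline visit, a subset of early
enrollees without DEXA body-composition measurements, and a latent adherence
trait that both lowers reported restricted-macronutrient intake and
amplifies weight loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: Analysis cells in enrollment-table order: (diet, sex).
GROUPS: tuple[tuple[str, str], ...] = (
    ("HLC", "F"),
    ("HLC", "M"),
    ("HLF", "F"),
    ("HLF", "M"),
)

MEASURES: tuple[str, ...] = ("weight", "fat_mass", "lean_mass")

WEIGHT_MONTHS: tuple[int, ...] = (0, 3, 6, 12)
DEXA_MONTHS: tuple[int, ...] = (0, 6, 12)
RECALL_MONTHS: tuple[int, ...] = (0, 3, 6, 12)
POST_MONTHS: tuple[int, ...] = (3, 6, 12)


class CohortConfigError(ValueError):
    """Raised when a cohort configuration field is invalid; names the field."""


def _default_n_per_group() -> dict[tuple[str, str], int]:
    return {("HLC", "F"): 179, ("HLC", "M"): 125, ("HLF", "F"): 167, ("HLF", "M"): 138}


def _default_true_change() -> dict[tuple[str, str, str], float]:
    # 12-month mean changes (kg) per (measure, diet, sex), chosen so that the
    # implied pairwise differences match the scale of published sex-stratified
    # diet-trial contrasts: men HLC-HLF = -2.98 kg weight, -1.51 kg fat,
    # -1.33 kg lean; HLC men vs HLC women = -2.32 kg weight, -1.42 kg lean.
    return {
        ("weight", "HLC", "F"): -5.36,
        ("weight", "HLC", "M"): -7.68,
        ("weight", "HLF", "F"): -5.36,
        ("weight", "HLF", "M"): -4.70,
        ("fat_mass", "HLC", "F"): -4.20,
        ("fat_mass", "HLC", "M"): -5.50,
        ("fat_mass", "HLF", "F"): -4.20,
        ("fat_mass", "HLF", "M"): -3.99,
        ("lean_mass", "HLC", "F"): -0.78,
        ("lean_mass", "HLC", "M"): -2.20,
        ("lean_mass", "HLF", "F"): -0.78,
        ("lean_mass", "HLF", "M"): -0.87,
    }


@dataclass
class CohortConfig:
    """Generating-model parameters for one synthetic cohort.

    Attributes
    ----------
    n_per_group
        Randomized count per (diet, sex) cell.
    baseline_weight_mean_kg, baseline_weight_sd_kg
        Baseline body-weight moments by sex.
    baseline_bodyfat_mean_pct, baseline_bodyfat_sd_pct
        Baseline DEXA body-fat percentage moments by sex.
    true_change_12mo
        Mean 12-month change in kg per (measure, diet, sex).
    time_fraction
        Fraction of the 12-month change realized at months 3 and 6
        (f(0) = 0 and f(12) = 1 are fixed).
    adherence_effect_kg
        Shift in 12-month weight change per SD of the latent adherence
        trait; negative means more adherent participants lose more.
    intake_location, intake_scale
        Location/scale (g) of reported restricted-macronutrient intake above
        the 20 g target: grams = 20 + softplus(location - scale * a + noise).
    recall_noise_sd_g
        Day-to-day reporting noise SD (g) in the restricted macronutrient.
    retention_prob
        Probability that a post-baseline visit is attended; scalar or
        mapping month -> probability.  Visits are dropped independently.
    dexa_missing_fraction
        Fraction of earliest-enrolled participants with no DEXA records
        (and hence missing baseline body-fat percentage).
    subject_sd_kg, residual_sd_kg
        Random-intercept and visit-level residual SDs of body weight.
    adherence_mean_by_group
        Optional mean shift of the latent adherence trait per (diet, sex);
        all zero by default.
    seed
        Master seed; every random substream is derived from it.
    """

    n_per_group: dict[tuple[str, str], int] = field(default_factory=_default_n_per_group)
    baseline_weight_mean_kg: dict[str, float] = field(
        default_factory=lambda: {"F": 89.8, "M": 106.2}
    )
    baseline_weight_sd_kg: dict[str, float] = field(
        default_factory=lambda: {"F": 12.0, "M": 13.8}
    )
    baseline_bodyfat_mean_pct: dict[str, float] = field(
        default_factory=lambda: {"F": 40.7, "M": 30.1}
    )
    baseline_bodyfat_sd_pct: dict[str, float] = field(
        default_factory=lambda: {"F": 4.0, "M": 4.6}
    )
    true_change_12mo: dict[tuple[str, str, str], float] = field(
        default_factory=_default_true_change
    )
    time_fraction: dict[int, float] = field(default_factory=lambda: {3: 0.6, 6: 0.85})
    adherence_effect_kg: float = -2.0
    intake_location: float = 80.0
    intake_scale: float = 25.0
    recall_noise_sd_g: float = 30.0
    retention_prob: float | dict[int, float] = 0.79
    dexa_missing_fraction: float = 0.128
    subject_sd_kg: float = 3.0
    residual_sd_kg: float = 2.5
    adherence_mean_by_group: dict[tuple[str, str], float] = field(
        default_factory=lambda: {g: 0.0 for g in GROUPS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def retention_at(self, month: int) -> float:
        if isinstance(self.retention_prob, Mapping):
            return float(self.retention_prob[month])
        return float(self.retention_prob)

    def validate(self) -> None:
        for g in GROUPS:
            n = self.n_per_group.get(g)
            if n is None or int(n) != n or n <= 0:
                raise CohortConfigError(f"n_per_group[{g}] must be a positive integer, got {n!r}")
        for sex in ("F", "M"):
            for name in ("baseline_weight_sd_kg", "baseline_bodyfat_sd_pct"):
                if getattr(self, name)[sex] <= 0:
                    raise CohortConfigError(f"{name}[{sex!r}] must be > 0")
            if not 0 < self.baseline_bodyfat_mean_pct[sex] < 100:
                raise CohortConfigError(
                    f"baseline_bodyfat_mean_pct[{sex!r}] must lie in (0, 100)"
                )
            if self.baseline_weight_mean_kg[sex] <= 0:
                raise CohortConfigError(f"baseline_weight_mean_kg[{sex!r}] must be > 0")
        for m, d, s in [(m, d, s) for m in MEASURES for d, s in GROUPS]:
            if (m, d, s) not in self.true_change_12mo:
                raise CohortConfigError(f"true_change_12mo missing entry {(m, d, s)}")
        for month in (3, 6):
            f = self.time_fraction.get(month)
            if f is None or not 0 <= f <= 1:
                raise CohortConfigError(f"time_fraction[{month}] must lie in [0, 1]")
        for month in POST_MONTHS:
            p = self.retention_at(month)
            if not 0 < p <= 1:
                raise CohortConfigError(f"retention_prob at month {month} must lie in (0, 1]")
        if not 0 <= self.dexa_missing_fraction < 1:
            raise CohortConfigError("dexa_missing_fraction must lie in [0, 1)")
        for name in ("recall_noise_sd_g", "subject_sd_kg", "residual_sd_kg"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        if self.intake_scale < 0:
            raise CohortConfigError("intake_scale must be >= 0")
        if int(self.seed) != self.seed:
            raise CohortConfigError("seed must be an integer")

    # -- (de)serialization --------------------------------------------------

    def total_n(self) -> int:
        return sum(self.n_per_group[g] for g in GROUPS)

    @classmethod
    def from_dict(cls, raw: dict) -> "CohortConfig":
        """Build a config from a plain-key dictionary (YAML-friendly).

        Tuple-keyed fields use ``"HLC-F"`` / ``"weight:HLC-F"`` string keys.
        """
        kwargs: dict = {}
        for key, value in raw.items():
            if key == "n_per_group" or key == "adherence_mean_by_group":
                kwargs[key] = {_parse_group(k): v for k, v in value.items()}
            elif key == "true_change_12mo":
                kwargs[key] = {}
                for k, v in value.items():
                    measure, grp = k.split(":")
                    diet, sex = _parse_group(grp)
                    kwargs[key][(measure, diet, sex)] = float(v)
            elif key in ("time_fraction", "retention_prob") and isinstance(value, Mapping):
                kwargs[key] = {int(k): float(v) for k, v in value.items()}
            else:
                kwargs[key] = value
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)


def _parse_group(token: str) -> tuple[str, str]:
    diet, sex = token.split("-")
    if (diet, sex) not in GROUPS:
        raise CohortConfigError(f"unknown diet-sex group {token!r}")
    return diet, sex
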