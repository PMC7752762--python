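import pytest

from wasatrial.config import GROUPS, CohortConfig
from wasatrial.synthetic import generate_cohort


def small_config(seed: int = 0, n: int = 40, **overrides) -> CohortConfig:
    """Reduced cohort (n per group) for fast tests; defaults otherwise."""
    kwargs = dict(n_per_group={g: n for g in GROUPS}, seed=seed)
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort at default (trial-like) settings, generated once."""
    cfg = CohortConfig(seed=42)
    participants, outcomes, recalls = generate_cohort(cfg)
    return cfg, participants, outcomes, recalls


@pytest.fixture(scope="session")
def public_participants(default_cohort):
    _, participants, _, _ = default_cohort
    return participants[
        ["participant_id", "sex", "diet", "baseline_weight_kg", "baseline_bodyfat_pct"]
    ]
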