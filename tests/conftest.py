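"""Shared fixtures: small synthetic cohorts and planted feature matrices."""

import numpy as np
import pytest

from nirspd.synthetic_data import CohortSpec, SignalModel, generate_cohort, generate_record


@pytest.fixture(scope="session")
def tiny_spec() -> CohortSpec:
    """Six subjects, six channels, 40 s — fast but structurally complete."""
    return CohortSpec(
        n_per_class=3, n_long_channels=4, n_short_channels=2,
        duration_s=40.0, effect_channels=(0, 1), effect_size=2.0, seed=123,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return generate_cohort(tiny_spec)


@pytest.fixture(scope="session")
def clean_record():
    """One full-geometry (22-channel) control recording, 120 s."""
    spec = CohortSpec(n_per_class=1, duration_s=120.0, seed=7)
    return generate_record(spec, SignalModel(), "control", np.random.default_rng(7))


def make_planted(
    n: int = 40,
    d: int = 100,
    n_informative: int = 5,
    effect: float = 2.0,
    seed: int = 0,
    standardized: bool = False,
):
    """Gaussian noise matrix with a class-mean shift planted in the first
    ``n_informative`` columns; returns (X, y, informative_indices)."""
    rng = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[: n // 2] = 1
    X = rng.normal(size=(n, d))
    shift = effect / 2.0
    X[:, :n_informative] += np.where(y[:, None] == 1, shift, -shift)
    if standardized:
        X = (X - X.mean(axis=0)) / X.std(axis=0)
    return X, y, np.arange(n_informative)
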