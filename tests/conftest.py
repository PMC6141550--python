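"""Shared fixtures and helpers for the icalink test suite.

All fixtures build data programmatically from the synthetic generator so
the suite needs no stored files.  ``effective_profile_mixing`` maps the
planted raw-score mixing onto the standardized-score scale on which the
profile ICA actually operates (per-factor standardization rescales the
rows of the mixing matrix), which is the correct ground truth for
recovery comparisons.
"""

from __future__ import annotations

import numpy as np
import pytest

from icalink import (
    SimulationConfig,
    random_ground_truth,
    simulate_families,
    simulate_personality,
    simulate_roi_timeseries,
)


def effective_profile_mixing(truth, config) -> np.ndarray:
    """Planted profile mixing on the standardized-score scale."""
    raw_sd = np.sqrt(
        (truth.profile_mixing**2).sum(axis=1) + config.noise_sd_personality**2
    )
    return truth.profile_mixing / raw_sd[:, None]


def linear_config(n_subjects: int, n_timepoints: int = 10, seed: int = 0, **kw):
    """Generator configured as the pure linear model: continuous scores,
    independent subjects.  Used for parameter-recovery experiments, where
    the planted mixing must remain the exact ground truth."""
    return SimulationConfig(
        n_subjects=n_subjects,
        n_timepoints=n_timepoints,
        seed=seed,
        neo_scale=False,
        singleton_fraction=1.0,
        mz_fraction=0.0,
        dz_fraction=0.0,
        **kw,
    )


@pytest.fixture(scope="session")
def ground_truth():
    return random_ground_truth(seed=42)


@pytest.fixture(scope="session")
def coupled_truth():
    # planted coupling: profile 5 (index 4) drives mode 2 (index 1), rho=0.4
    return random_ground_truth(seed=42, coupling_pairs=[(4, 1, 0.4)])


@pytest.fixture(scope="session")
def small_table(ground_truth):
    cfg = SimulationConfig(n_subjects=100, n_timepoints=10, seed=1)
    return simulate_personality(cfg, ground_truth)


@pytest.fixture(scope="session")
def small_study(coupled_truth):
    """40 subjects x 80 timepoints with families — fast end-to-end input."""
    cfg = SimulationConfig(n_subjects=40, n_timepoints=80, seed=5)
    families = simulate_families(cfg)
    table, latent = simulate_personality(
        cfg, coupled_truth, families, return_latent=True
    )
    ts = simulate_roi_timeseries(cfg, coupled_truth, latent)
    return cfg, table, ts, families, latent
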