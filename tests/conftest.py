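"""Shared fixtures: small synthetic cohorts and corpora.

Heavy corpora are session-scoped so the classification tests share one
simulation + feature extraction pass.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitmark.corpus import prepare_corpus
from gaitmark.simulate import SimConfig, simulate_cohort, simulate_recording


@pytest.fixture(scope="session")
def clean_config():
    """Noise- and jitter-free simulation settings (deterministic templates)."""
    return SimConfig(
        n_subjects=1,
        speeds=(1.2,),
        conditions=("none",),
        duration=20.0,
        noise_sd=0.0,
        jitter_cv=0.0,
        amp_jitter_cv=0.0,
        seed=1,
    )


@pytest.fixture(scope="session")
def clean_recording(clean_config):
    """One noise-free land recording with its exact ground-truth events."""
    return simulate_recording("S01", 1.2, "none", clean_config)


@pytest.fixture(scope="session")
def small_land_corpus():
    """3 subjects x 2 speeds x 3 land conditions, 30 s — enough cycles for
    cycle-level splits and cross-validation at test speed."""
    cfg = SimConfig(
        n_subjects=3,
        speeds=(0.8, 1.6),
        conditions=("none", "bws30", "bws50"),
        duration=30.0,
        seed=9,
    )
    recs = [rec for rec, _ in simulate_cohort(cfg)]
    return prepare_corpus(recs)


@pytest.fixture(scope="session")
def mixed_corpus():
    """3 subjects, land + water conditions at 1.2/1.6 m/s, 30 s."""
    cfg = SimConfig(
        n_subjects=3,
        speeds=(1.2, 1.6),
        conditions=("none", "bws30", "bws50", "waist", "chest"),
        duration=30.0,
        seed=5,
    )
    recs = [rec for rec, _ in simulate_cohort(cfg)]
    return prepare_corpus(recs)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
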