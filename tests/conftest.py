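"""Shared fixtures: synthetic bundles and labeled candidate sets.

The heavy bundles are session-scoped so the end-to-end tests reuse them.
"""

from __future__ import annotations

import numpy as np
import pytest

from methbind import (
    SimConfig,
    label_candidates,
    make_null_dataset,
    pfm_to_pwm,
    scan_genome,
    simulate_dataset,
)
from methbind.scan import genome_background


def scan_and_label(bundle, relative_threshold: float = 0.8):
    """Scan a bundle's genome with its own PFM and label against its peaks."""
    ds = bundle.dataset
    pwm = pfm_to_pwm(ds.pfm, background=genome_background(ds.genome))
    sites = scan_genome(ds.genome, pwm, relative_threshold, relative=True)
    return label_candidates(sites, ds.peaks)


@pytest.fixture(scope="session")
def strong_bundle():
    """Standard strong-signal conditions: 500 sites, 30% bound, dip 0.8 -> 0.2."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def null_bundle():
    """Same construction with the methylation signal removed."""
    return make_null_dataset(SimConfig(seed=11))


@pytest.fixture(scope="session")
def strong_candidates(strong_bundle):
    return scan_and_label(strong_bundle)


@pytest.fixture(scope="session")
def null_candidates(null_bundle):
    return scan_and_label(null_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
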