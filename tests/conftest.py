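"""Shared fixtures: small simulated loci used across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from retrotandem import simarray

# pairwise divergence d corresponds to an array age of d / (2 mu)
def years_for_divergence(d: float, mu: float = 6.5e-9) -> float:
    return d / (2.0 * mu)


@pytest.fixture(scope="session")
def parent_pair():
    return simarray.make_parent_pair(np.random.default_rng(2024))


@pytest.fixture(scope="session")
def small_locus():
    """A 20-monomer locus at ~5% pairwise divergence with one nested element."""
    cfg = simarray.SimConfig(
        seed=1,
        n_monomers_target=20,
        array_age_years=years_for_divergence(0.05),
        nested_insertions=((0.94e6, 4000, 5),),
    )
    return simarray.simulate(cfg)


@pytest.fixture(scope="session")
def clean_locus():
    """A noise-free 12-monomer locus: no divergence, no tracts, single IR."""
    cfg = simarray.SimConfig(
        seed=3,
        n_monomers_target=12,
        array_age_years=0.0,
        donor_tract_prob=0.0,
        ir_copy_distribution={1: 1.0},
    )
    return simarray.simulate(cfg)
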