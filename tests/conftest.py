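"""Shared fixtures: synthetic libraries at the study conditions.

The heavyweight fixtures (10 kb genome pair, 60,000 fragments) are session
scoped and cached per contamination level so that the consensus-accuracy and
contamination-estimate tests share one pipeline run per level.
"""

import numpy as np
import pytest

import paleomt as p
from paleomt.model import SubstitutionErrorModel

GENOME_LENGTH = 10_000
N_SUBSTITUTIONS = 50
N_FRAGMENTS = 60_000
GENOME_SEED = 1


@pytest.fixture(scope="session")
def err():
    return SubstitutionErrorModel.uniform()


@pytest.fixture(scope="session")
def genome_pair_10k():
    return p.make_genome_pair(GENOME_LENGTH, N_SUBSTITUTIONS, GENOME_SEED)


@pytest.fixture(scope="session")
def pipeline_10k(genome_pair_10k):
    """Factory: full iterative run on the 10 kb / 60 k-fragment fixture.

    Results are cached per contamination level; returns
    (SimulationResult, RunResult).
    """
    endo, cont = genome_pair_10k
    cache = {}

    def run(c, n_fragments=N_FRAGMENTS, seed=3):
        key = (c, n_fragments, seed)
        if key not in cache:
            cfg = p.SimulationConfig(
                endo_genome=endo,
                cont_genomes=[(cont, c)],
                n_fragments=n_fragments,
                seed=seed,
            )
            res = p.simulate_dataset(cfg)
            result = p.run_pipeline(
                res.to_fragments(), res.reference,
                db=[("true_contaminant", cont)], protocol="single",
            )
            cache[key] = (res, result)
        return cache[key]

    return run


@pytest.fixture(scope="session")
def small_sim():
    """A modest 2 kb / 6,000-fragment library at 30 % contamination, with its
    fragments and pileup, for unit-level tests."""
    endo, cont = p.make_genome_pair(2000, 20, GENOME_SEED)
    cfg = p.SimulationConfig(
        endo_genome=endo, cont_genomes=[(cont, 0.3)], n_fragments=6000, seed=2
    )
    res = p.simulate_dataset(cfg)
    frags = res.to_fragments()
    pile = p.Pileup(frags, res.reference)
    return res, frags, pile


def random_profile(rng, depth=4):
    """A random but valid deamination profile (row sums <= 1)."""
    end5 = rng.uniform(0, 0.2, size=(depth, 4, 4))
    end3 = rng.uniform(0, 0.2, size=(depth, 4, 4))
    for end in (end5, end3):
        idx = np.arange(4)
        end[:, idx, idx] = 0.0
    return p.DeaminationProfile(end5, end3)
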