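"""Shared fixtures: small fitness tables and a full synthetic study dataset."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import epiland as ep

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow], deadline=None
)
settings.load_profile("ci")


def fitness_frame(cells, antibiotic=0.0, temperature=37.0, se=0.0, n=3):
    """Build a fitness table from {(abr, ko): w_mean}."""
    rows = [
        {
            "abr_allele": a,
            "ko_allele": k,
            "antibiotic": antibiotic,
            "temperature": temperature,
            "w_mean": w,
            "w_se": se,
            "n": n,
        }
        for (a, k), w in cells.items()
    ]
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def paper_like_sim():
    return ep.simulate_competitions(ep.scenario("paper_like", seed=11))


@pytest.fixture(scope="session")
def paper_like_fits(paper_like_sim):
    return ep.summarize_fitness(paper_like_sim.records)


@pytest.fixture()
def env0():
    return ep.Environment(0.0, 37.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_slice(rng, scale=1.0):
    w = rng.normal(0.0, scale, size=4)
    return ep.slice_from_means(*w)
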