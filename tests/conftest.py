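"""Shared fixtures.

The expensive synthetic tables and campaign batteries are session-scoped so
every test (and the per-criterion acceptance checks) reuses one generation
pass and one fingerprint cache per library.
"""

import numpy as np
import pytest

from dockboost.campaign import Campaign
from dockboost.fingerprints import MorganFeaturizer
from dockboost.records import CampaignConfig, Drop, ScoreTable, Substitute
from dockboost.synthetic import make_scenario


@pytest.fixture()
def tiny_table() -> ScoreTable:
    """Hand-built 6-compound table with one failed entry."""
    return ScoreTable(
        ids=["A", "B", "C", "D", "E", "F"],
        smiles=["CCO", "c1ccccc1", "CCN", "CCC", "CCCl", "CC=O"],
        scores=[-9.0, np.nan, -8.0, -7.0, -6.5, -7.5],
        provenance="tiny",
    )


@pytest.fixture(scope="session")
def sura_50k():
    """sura-like benchmark: 50k compounds, ~3% feature-independent failures."""
    library, table, spec = make_scenario("sura-like", 50_000, seed=11)
    return library, table, spec


@pytest.fixture(scope="session")
def gak_100k():
    """gak-like benchmark: 100k compounds, ~45% mostly constraint failures."""
    library, table, spec = make_scenario("gak-like", 100_000, seed=11)
    return library, table, spec


@pytest.fixture(scope="session")
def shared_featurizer():
    return MorganFeaturizer()


def _policy_config(policy, n, seed):
    return CampaignConfig(
        library_size=n,
        fraction=0.01,
        n_iterations=10,
        failed_policy=policy,
        seed=seed,
    )


@pytest.fixture(scope="session")
def policy_runs_100k(gak_100k, shared_featurizer):
    """Drop vs Substitute(+5.0) campaigns on the gak-like 100k table.

    Five seeds per policy with the default fingerprint-ridge surrogate;
    shared by the failed-policy, attrition and learning-signal checks.
    """
    _, table, _ = gak_100k
    seeds = [101, 102, 103, 104, 105]
    runs = {"drop": [], "substitute": []}
    for seed in seeds:
        for key, policy in [("drop", Drop()), ("substitute", Substitute(5.0))]:
            config = _policy_config(policy, len(table), seed)
            runs[key].append(Campaign(table, config, shared_featurizer).run())
    return runs


@pytest.fixture(scope="session")
def null_runs_50k(sura_50k):
    """Twenty random-surrogate campaigns (L=50k, f=0.01, N=10)."""
    _, table, _ = sura_50k
    results = []
    for seed in range(20):
        config = CampaignConfig(
            library_size=len(table),
            fraction=0.01,
            n_iterations=10,
            failed_policy=Drop(),
            seed=seed,
            surrogate_spec={"name": "random", "params": {}},
        )
        results.append(Campaign(table, config).run())
    return results
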