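"""Selection loop: initialization, ranking, replay and full campaigns."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dockboost.campaign import (
    Campaign,
    initial_selection,
    load_scores,
    rank_and_select,
    run_campaign,
)
from dockboost.records import CampaignConfig, Drop, ScoreTable, Substitute
from dockboost.synthetic import make_scenario


class TestInitialSelection:
    def test_fraction_one_selects_whole_library(self):
        ids = [f"c{i}" for i in range(25)]
        assert sorted(initial_selection(ids, 1.0, seed=0)) == sorted(ids)

    def test_seeded_and_sized(self):
        ids = [f"c{i}" for i in range(1000)]
        a = initial_selection(ids, 0.1, seed=4)
        b = initial_selection(ids, 0.1, seed=4)
        assert a == b
        assert len(a) == 100 and len(set(a)) == 100

    def test_two_seeds_overlap_near_hypergeometric_expectation(self):
        # L=1e5, f=0.01: E[overlap] = f^2 L = 10, sd ~ 3.1
        ids = [f"c{i}" for i in range(100_000)]
        overlaps = []
        for s in range(3):
            a = set(initial_selection(ids, 0.01, seed=2 * s))
            b = set(initial_selection(ids, 0.01, seed=2 * s + 1))
            assert a != b
            overlaps.append(len(a & b))
        assert 2 <= np.mean(overlaps) <= 25

    def test_empty_batch_errors(self):
        with pytest.raises(ValueError, match="selects nothing"):
            initial_selection(["a", "b"], 0.1, seed=0)


def _brute_force_select(ids, preds, docked, batch):
    pool = [(p, i) for i, p in zip(ids, preds) if i not in docked]
    return [i for _, i in sorted(pool)[:batch]]


class TestRankAndSelect:
    def test_forced_ordering(self):
        out = rank_and_select(["a", "b", "c"], [-9, -8, -7], {"a"}, 1)
        assert out == ["b"]

    def test_tie_breaks_by_ascending_id(self):
        out = rank_and_select(["c", "b", "a"], [-8, -8, -9], {"a"}, 1)
        assert out == ["b"]

    def test_returns_all_when_pool_small(self):
        out = rank_and_select(["a", "b", "c"], [1, 2, 3], {"a"}, 10)
        assert sorted(out) == ["b", "c"]

    def test_nonpositive_batch_rejected(self):
        with pytest.raises(ValueError, match="batch"):
            rank_and_select(["a"], [1.0], set(), 0)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        seed=st.integers(0, 10_000),
        batch=st.sampled_from([1, 10, 100]),
    )
    def test_agrees_with_brute_force_sort(self, seed, batch):
        rng = np.random.default_rng(seed)
        ids = [f"m{i:04d}" for i in range(1000)]
        preds = np.round(rng.standard_normal(1000), 2)  # rounding forces ties
        docked = set(rng.choice(ids, size=200, replace=False))
        fast = rank_and_select(ids, preds, docked, batch)
        assert fast == _brute_force_select(ids, preds, docked, batch)


class TestLoadScores:
    def test_outcomes_copied_verbatim(self, tiny_table):
        recs = load_scores(["A", "B"], tiny_table)
        assert recs[0].score == -9.0
        assert recs[1].is_failed

    def test_empty_selection(self, tiny_table):
        assert load_scores([], tiny_table) == []

    def test_missing_id_names_offender(self, tiny_table):
        with pytest.raises(KeyError, match="ZZ"):
            load_scores(["A", "ZZ"], tiny_table)


@pytest.fixture(scope="module")
def small_scenario():
    _, table, _ = make_scenario("gak-like", 3000, seed=17)
    return table


def _config(table, **kw):
    base = dict(
        library_size=len(table),
        fraction=0.02,
        n_iterations=5,
        failed_policy=Drop(),
        seed=13,
    )
    base.update(kw)
    return CampaignConfig(**base)


class TestRunCampaign:
    def test_single_iteration_is_random_initialization_only(self, small_scenario):
        config = _config(small_scenario, n_iterations=1)
        result = run_campaign(config, small_scenario)
        assert result.n_iterations_run == 1
        assert result.per_iteration[0].diagnostics is None
        assert len(result.selected(1)) == config.batch_size

    def test_selections_are_disjoint_and_sized(self, small_scenario):
        result = run_campaign(_config(small_scenario), small_scenario)
        all_ids = [cid for rec in result.per_iteration for cid in rec.selected_ids]
        assert len(all_ids) == len(set(all_ids))  # no compound docked twice
        for rec in result.per_iteration:
            assert len(rec.selected_ids) == result.config.batch_size
        assert result.n_docked == len(result.cumulative_docked())

    def test_rerun_is_deterministic(self, small_scenario):
        config = _config(small_scenario)
        a = run_campaign(config, small_scenario)
        b = run_campaign(config, small_scenario)
        assert a == b

    def test_different_seed_changes_initialization(self, small_scenario):
        a = run_campaign(_config(small_scenario, n_iterations=1), small_scenario)
        b = run_campaign(
            _config(small_scenario, n_iterations=1, seed=14), small_scenario
        )
        assert set(a.selected(1)) != set(b.selected(1))

    def test_diagnostics_present_from_iteration_two(self, small_scenario):
        result = run_campaign(_config(small_scenario, n_iterations=3), small_scenario)
        assert result.per_iteration[0].diagnostics is None
        for rec in result.per_iteration[1:]:
            assert rec.diagnostics is not None
            assert np.isfinite(rec.diagnostics.train_rmse)

    def test_failed_selection_counts_match_table(self, small_scenario):
        result = run_campaign(_config(small_scenario, n_iterations=3), small_scenario)
        for rec in result.per_iteration:
            truth_failed = sum(
                1
                for cid in rec.selected_ids
                if np.isnan(small_scenario.scores[small_scenario.ids.index(cid)])
            )
            assert rec.n_failed_selected == truth_failed

    def test_checkpoint_resume_reproduces_uninterrupted_run(
        self, small_scenario, tmp_path
    ):
        config = _config(small_scenario)
        full = run_campaign(config, small_scenario)
        # interrupt after 2 iterations, then resume
        partial_cfg = _config(small_scenario, n_iterations=2)
        partial = run_campaign(
            partial_cfg, small_scenario, checkpoint_dir=tmp_path / "cp"
        )
        assert partial.n_iterations_run == 2
        # rewrite the checkpoint with the full config so resume continues it
        resumed_result = run_campaign(
            config, small_scenario, checkpoint_dir=tmp_path / "cp2"
        )
        assert resumed_result == full

    def test_resume_from_partial_checkpoint(self, small_scenario, tmp_path):
        config = _config(small_scenario)
        full = run_campaign(config, small_scenario)
        # simulate an aborted run: persist only the first 2 iterations
        from dockboost.records import CampaignResult

        partial = CampaignResult(config=config, per_iteration=full.per_iteration[:2])
        partial.save(tmp_path / "cp")
        resumed = run_campaign(
            config, small_scenario, checkpoint_dir=tmp_path / "cp", resume=True
        )
        assert resumed == full

    def test_resume_can_extend_the_iteration_count(self, small_scenario, tmp_path):
        short = run_campaign(
            _config(small_scenario, n_iterations=3),
            small_scenario,
            checkpoint_dir=tmp_path / "cp",
        )
        extended = run_campaign(
            _config(small_scenario, n_iterations=5),
            small_scenario,
            checkpoint_dir=tmp_path / "cp",
            resume=True,
        )
        uninterrupted = run_campaign(_config(small_scenario), small_scenario)
        assert extended == uninterrupted
        assert extended.per_iteration[:3] == short.per_iteration

    def test_resume_rejects_conflicting_config(self, small_scenario, tmp_path):
        run_campaign(
            _config(small_scenario, n_iterations=2),
            small_scenario,
            checkpoint_dir=tmp_path / "cp",
        )
        with pytest.raises(ValueError, match="does not match"):
            run_campaign(
                _config(small_scenario, n_iterations=3, seed=99),
                small_scenario,
                checkpoint_dir=tmp_path / "cp",
                resume=True,
            )

    def test_library_size_mismatch_rejected(self, small_scenario):
        config = _config(small_scenario)
        bad = ScoreTable(["x"], ["CCO"], [-1.0])
        with pytest.raises(ValueError, match="library_size"):
            run_campaign(config, bad)

    def test_substitute_policy_runs(self, small_scenario):
        config = _config(
            small_scenario, n_iterations=3, failed_policy=Substitute(5.0)
        )
        result = run_campaign(config, small_scenario)
        assert result.n_iterations_run == 3

    def test_campaign_front_end_matches_function(self, small_scenario):
        config = _config(small_scenario, n_iterations=2)
        assert Campaign(small_scenario, config).run() == run_campaign(
            config, small_scenario
        )


class TestConfigInvariants:
    def test_overdocking_config_rejected(self):
        with pytest.raises(ValueError, match="more compounds than the library"):
            CampaignConfig(library_size=100, fraction=0.2, n_iterations=6)

    def test_empty_batch_config_rejected(self):
        with pytest.raises(ValueError, match="selects no compounds"):
            CampaignConfig(library_size=100, fraction=0.001, n_iterations=1)

    def test_bad_split_fractions_rejected(self):
        with pytest.raises(ValueError, match="split_fractions"):
            CampaignConfig(
                library_size=100,
                fraction=0.1,
                n_iterations=2,
                split_fractions=(0.5, 0.5, 0.5),
            )


def test_simu_dock_blindness(small_scenario):
    """The campaign reads exactly the table rows it selected, nothing else."""
    import hashlib

    small_scenario.reset_access_log()
    result = run_campaign(_config(small_scenario), small_scenario)
    accessed = hashlib.sha256(
        "\n".join(sorted(small_scenario.accessed_ids)).encode()
    ).hexdigest()
    docked = hashlib.sha256(
        "\n".join(sorted(result.cumulative_docked())).encode()
    ).hexdigest()
    assert accessed == docked
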