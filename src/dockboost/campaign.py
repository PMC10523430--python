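"""The iterative surrogate-guided selection loop.

Iteration 1 docks a uniform random batch of ``floor(fraction * L)``
compounds.  Every later iteration (i) applies the failed-compound policy to
everything docked so far, (ii) redraws an 80/10/10 train/val/test split,
(iii) trains the surrogate from scratch, (iv) predicts the whole library,
and (v) docks the best-predicted batch among never-docked compounds.  Scores
are replayed from a pre-generated table, and the loop only ever reads the
rows it selected (the replay-blindness contract, auditable through
``ScoreTable.accessed_ids``).

All randomness derives from ``config.seed`` via context-tagged sub-seeds, so
reruns — including resumes from a checkpoint — are bit-identical.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np

from .fingerprints import MorganFeaturizer
from .records import (
    CampaignConfig,
    CampaignResult,
    CompoundRecord,
    IterationRecord,
    ScoreTable,
    derive_seed,
)
from .surrogate import (
    WORST_PREDICTION,
    apply_failed_policy,
    split_train_val_test,
    train_surrogate,
)

__all__ = [
    "initial_selection",
    "rank_and_select",
    "load_scores",
    "run_campaign",
    "Campaign",
]

logger = logging.getLogger(__name__)


def initial_selection(ids: Sequence[str], fraction: float, seed: int = 0) -> list[str]:
    """Uniform random sample (without replacement) of floor(fraction * L) ids."""
    batch = int(np.floor(fraction * len(ids)))
    if batch < 1:
        raise ValueError(
            f"fraction {fraction} of a {len(ids)}-compound library selects nothing"
        )
    rng = np.random.default_rng(int(seed))
    chosen = rng.choice(len(ids), size=batch, replace=False)
    return [ids[i] for i in chosen]


def rank_and_select(
    ids: Sequence[str],
    predictions: Sequence[float],
    docked: set[str] | frozenset[str],
    batch: int,
) -> list[str]:
    """The ``batch`` never-docked ids with the best (lowest) predictions.

    Ties break by ascending id, so reruns are order-independent.  If fewer
    than ``batch`` undocked compounds remain, all of them are returned.
    """
    if batch <= 0:
        raise ValueError("batch must be positive")
    if len(ids) != len(predictions):
        raise ValueError("ids and predictions must have equal length")
    pred = np.asarray(predictions, dtype=float)
    undocked = np.array([cid not in docked for cid in ids], dtype=bool)
    idx = np.where(undocked)[0]
    # lowest predicted score first; ties by ascending id
    id_arr = np.array([ids[i] for i in idx], dtype=object)
    order = np.lexsort((id_arr, pred[idx]))
    chosen = idx[order[: min(batch, idx.size)]]
    return [ids[i] for i in chosen]


def load_scores(ids: Sequence[str], table: ScoreTable) -> list[CompoundRecord]:
    """Replay pre-generated outcomes for the selected ids (and only those)."""
    return table.lookup(ids)


def run_campaign(
    config: CampaignConfig,
    table: ScoreTable,
    featurizer: MorganFeaturizer | None = None,
    checkpoint_dir=None,
    resume: bool = False,
) -> CampaignResult:
    """Run (or resume) a full surrogate-guided campaign against a score table."""
    if config.library_size != len(table):
        raise ValueError(
            f"config.library_size={config.library_size} but score table has "
            f"{len(table)} records"
        )
    featurizer = featurizer or MorganFeaturizer()
    ids = list(table.ids)
    smiles = list(table.smiles)

    result = CampaignResult(config=config)
    docked_records: list[CompoundRecord] = []
    if resume:
        if checkpoint_dir is None:
            raise ValueError("resume requires checkpoint_dir")
        cp = Path(checkpoint_dir) / "summary.json"
        if cp.exists():
            loaded = CampaignResult.load(checkpoint_dir)
            # a resume may extend n_iterations (e.g. 10 -> 25); everything
            # else must match, or the replayed seeds would be meaningless
            ours = {k: v for k, v in config.to_dict().items() if k != "n_iterations"}
            theirs = {
                k: v for k, v in loaded.config.to_dict().items() if k != "n_iterations"
            }
            if ours != theirs or loaded.n_iterations_run > config.n_iterations:
                raise ValueError("checkpoint config does not match")
            result = CampaignResult(config=config, per_iteration=loaded.per_iteration)
            for rec in result.per_iteration:
                docked_records.extend(load_scores(rec.selected_ids, table))

    start_iter = result.n_iterations_run + 1
    docked_ids = set(r.id for r in docked_records)
    for iteration in range(start_iter, config.n_iterations + 1):
        t0 = time.monotonic()
        diagnostics = None
        if iteration == 1:
            selected = initial_selection(
                ids, config.fraction, seed=derive_seed(config.seed, "init")
            )
        else:
            regression = apply_failed_policy(docked_records, config.failed_policy)
            ts = split_train_val_test(
                regression,
                config.split_fractions,
                seed=derive_seed(config.seed, "split", iteration),
                mode=config.split_mode,
            )
            model, diagnostics = train_surrogate(
                ts,
                config.surrogate_spec,
                seed=derive_seed(config.seed, "model", iteration),
                featurizer=featurizer,
                table=table if config.surrogate_spec.get("name") == "oracle" else None,
            )
            predictions = model.predict(smiles)
            selected = rank_and_select(ids, predictions, docked_ids, config.batch_size)
        new_records = load_scores(selected, table)
        docked_records.extend(new_records)
        docked_ids.update(selected)
        n_failed = sum(r.is_failed for r in new_records)
        result.per_iteration.append(
            IterationRecord(
                iteration=iteration,
                selected_ids=tuple(selected),
                n_failed_selected=n_failed,
                diagnostics=diagnostics,
            )
        )
        logger.info(
            "iteration %d: selected %d (failed %d, cumulative %d) in %.1fs",
            iteration,
            len(selected),
            n_failed,
            len(docked_ids),
            time.monotonic() - t0,
        )
        if checkpoint_dir is not None:
            result.save(checkpoint_dir, force=True)
    return result


class Campaign:
    """Model-style front end: configure once, ``run()`` to get the results.

    A shared featurizer may be passed so replicate runs over the same table
    featurize the library only once.
    """

    def __init__(
        self,
        table: ScoreTable,
        config: CampaignConfig,
        featurizer: MorganFeaturizer | None = None,
    ):
        self.table = table
        self.config = config
        self.featurizer = featurizer or MorganFeaturizer()

    def run(self, checkpoint_dir=None, resume: bool = False) -> CampaignResult:
        return run_campaign(
            self.config,
            self.table,
            featurizer=self.featurizer,
            checkpoint_dir=checkpoint_dir,
            resume=resume,
        )
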