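"""Evaluation of campaigns against the brute-force truth.

Recall@k is the fraction of the true top-k compounds — ranked by the
brute-force table, failed compounds excluded — that the campaign had
selected for docking up to a given iteration.  Replicate overlap partitions
the true top-k by how many of three independent runs recalled each compound.
Hit-to-training-set similarity uses binary radius-2, 2048-bit Morgan
fingerprints and Tanimoto similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from rdkit import DataStructs

from .fingerprints import MorganFeaturizer
from .records import CampaignResult, ScoreTable

__all__ = [
    "true_top_k",
    "RecallReport",
    "recall_at_k",
    "OverlapReport",
    "replicate_overlap",
    "tanimoto_nearest_training",
    "export_prediction_scatter",
]


def true_top_k(table: ScoreTable, k: int) -> list[str]:
    """The k best-scoring ids in the truth table, failed compounds excluded.

    Ties at the boundary break by ascending id, the same rule the campaign
    uses, so recall is well-defined and reproducible.
    """
    scored = ~np.isnan(table.scores)
    n_scored = int(scored.sum())
    if k > n_scored:
        raise ValueError(f"k={k} exceeds the {n_scored} scored compounds")
    idx = np.where(scored)[0]
    id_arr = np.array([table.ids[i] for i in idx], dtype=object)
    order = np.lexsort((id_arr, table.scores[idx]))
    return [table.ids[i] for i in idx[order[:k]]]


def _check_same_library(result: CampaignResult, table: ScoreTable) -> None:
    if result.config.library_size != len(table):
        raise ValueError(
            "campaign result and score table cover different libraries "
            f"({result.config.library_size} vs {len(table)} compounds)"
        )
    docked = result.cumulative_docked()
    missing = next((cid for cid in docked if cid not in table), None)
    if missing is not None:
        raise ValueError(f"selected id {missing!r} is not in the score table")


@dataclass(frozen=True)
class RecallReport:
    """Recall per (iteration, k), plus the cumulative docked count."""

    frame: pd.DataFrame  # columns: iteration, k, recall, n_docked

    def recall(self, iteration: int, k: int) -> float:
        row = self.frame[
            (self.frame.iteration == iteration) & (self.frame.k == k)
        ]
        if row.empty:
            raise KeyError(f"no recall entry for iteration={iteration}, k={k}")
        return float(row.recall.iloc[0])

    def final(self, k: int) -> float:
        sub = self.frame[self.frame.k == k]
        return float(sub.recall.iloc[-1])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def to_json(self, path) -> None:
        self.frame.to_json(path, orient="records", indent=1)


def recall_at_k(
    result: CampaignResult,
    table: ScoreTable,
    k_list: Sequence[int] | None = None,
) -> RecallReport:
    """Recall of the true top-k per iteration.

    recall(i, k) = |cumulative_docked(i) ∩ true_top_k| / k.  Recall counts
    selection, not docking success: a true hit docked in any iteration counts
    from that iteration on.
    """
    _check_same_library(result, table)
    k_list = list(k_list if k_list is not None else result.config.top_k_list)
    truth = {k: set(true_top_k(table, k)) for k in k_list}
    rows = []
    docked: set[str] = set()
    for rec in result.per_iteration:
        docked.update(rec.selected_ids)
        for k in k_list:
            rows.append(
                {
                    "iteration": rec.iteration,
                    "k": k,
                    "recall": len(docked & truth[k]) / k,
                    "n_docked": len(docked),
                }
            )
    return RecallReport(pd.DataFrame(rows, columns=["iteration", "k", "recall", "n_docked"]))


@dataclass(frozen=True)
class OverlapReport:
    """Counts of true top-k compounds recalled by exactly 3/2/1/0 replicates."""

    frame: pd.DataFrame  # columns: iteration, k, by_3, by_2, by_1, by_0

    def counts(self, iteration: int, k: int) -> tuple[int, int, int, int]:
        row = self.frame[
            (self.frame.iteration == iteration) & (self.frame.k == k)
        ]
        if row.empty:
            raise KeyError(f"no overlap entry for iteration={iteration}, k={k}")
        r = row.iloc[0]
        return (int(r.by_3), int(r.by_2), int(r.by_1), int(r.by_0))

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def replicate_overlap(
    results: Sequence[CampaignResult],
    table: ScoreTable,
    k_list: Sequence[int] | None = None,
) -> OverlapReport:
    """Partition the true top-k by the number of recalling replicates.

    Expects exactly three results over the same table, differing only in
    their random seed.
    """
    if len(results) != 3:
        raise ValueError(f"replicate overlap needs exactly 3 results, got {len(results)}")
    for result in results:
        _check_same_library(result, table)
    n_iter = {r.n_iterations_run for r in results}
    if len(n_iter) != 1:
        raise ValueError("replicates ran different numbers of iterations")
    k_list = list(k_list if k_list is not None else results[0].config.top_k_list)
    truth = {k: true_top_k(table, k) for k in k_list}
    rows = []
    docked = [set() for _ in results]
    for it in range(1, n_iter.pop() + 1):
        for d, result in zip(docked, results):
            d.update(result.selected(it))
        for k in k_list:
            hits = np.array([sum(cid in d for d in docked) for cid in truth[k]])
            rows.append(
                {
                    "iteration": it,
                    "k": k,
                    "by_3": int((hits == 3).sum()),
                    "by_2": int((hits == 2).sum()),
                    "by_1": int((hits == 1).sum()),
                    "by_0": int((hits == 0).sum()),
                }
            )
    return OverlapReport(
        pd.DataFrame(rows, columns=["iteration", "k", "by_3", "by_2", "by_1", "by_0"])
    )


def tanimoto_nearest_training(
    hits: Sequence[str], training: Sequence[str]
) -> pd.DataFrame:
    """Per-hit maximum Tanimoto similarity to any training compound.

    Uses binary radius-2, 2048-bit Morgan fingerprints.  An invalid SMILES
    produces a per-item error entry (NaN similarity), never a global failure.
    """
    if not len(hits) or not len(training):
        raise ValueError("hits and training lists must be non-empty")
    feat = MorganFeaturizer(counts=False)
    train_fps = []
    for smi in training:
        fp = feat.bitvector(smi)
        if fp is not None:
            train_fps.append(fp)
    if not train_fps:
        raise ValueError("no valid SMILES in the training list")
    rows = []
    for smi in hits:
        fp = feat.bitvector(smi)
        if fp is None:
            rows.append(
                {"hit_smiles": smi, "max_similarity": np.nan, "error": "invalid SMILES"}
            )
            continue
        sims = DataStructs.BulkTanimotoSimilarity(fp, train_fps)
        rows.append(
            {"hit_smiles": smi, "max_similarity": float(max(sims)), "error": ""}
        )
    return pd.DataFrame(rows, columns=["hit_smiles", "max_similarity", "error"])


def export_prediction_scatter(
    model, table: ScoreTable, path, chunk_size: int = 65536
) -> pd.DataFrame:
    """TSV export of predicted vs. true score for all scored compounds."""
    scored = ~np.isnan(table.scores)
    smiles = [s for s, ok in zip(table.smiles, scored) if ok]
    ids = [i for i, ok in zip(table.ids, scored) if ok]
    pred = model.predict(smiles, chunk_size=chunk_size)
    frame = pd.DataFrame(
        {"id": ids, "smiles": smiles, "true_score": table.scores[scored], "predicted": pred}
    )
    frame.to_csv(path, sep="\t", index=False)
    return frame
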