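"""Readers and writers for SMILES libraries, score tables and campaign results.

Formats are deliberately plain text:

* library: ``.smi`` lines of ``SMILES<whitespace>ID``;
* score table: header CSV ``id,smiles,score`` with an empty field (or the
  sentinel ``FAILED``) marking a failed docking;
* campaign result: a directory with ``summary.json`` plus one plain-text
  selected-id list per iteration.

SMILES are never canonicalized here — canonicalization is a fingerprint
concern — and scores round-trip at full precision (``repr``/``float``).
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .records import CampaignResult, CampaignConfig, IterationRecord, ScoreTable

__all__ = [
    "read_score_table",
    "write_score_table",
    "read_smiles_library",
    "write_smiles_library",
    "write_campaign_result",
    "read_campaign_result",
]

_FAILED_TOKEN = "FAILED"


def read_score_table(path) -> ScoreTable:
    """Read a ``id,smiles,score`` CSV into a :class:`ScoreTable`.

    An empty score field or the token ``FAILED`` marks a failed docking.
    Duplicate ids and non-numeric scores are hard errors naming the offender.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, dtype=str, keep_default_na=False, skipinitialspace=False
    )
    required = {"id", "smiles", "score"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"{path}: score table must have columns id,smiles,score "
            f"(found {list(frame.columns)})"
        )
    ids = frame["id"].str.strip()
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate id {dup.iloc[0]!r}")
    scores = np.empty(len(frame), dtype=float)
    raw = frame["score"].str.strip()
    for row, text in enumerate(raw):
        if text == "" or text.upper() == _FAILED_TOKEN:
            scores[row] = np.nan
        else:
            try:
                scores[row] = float(text)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric score {text!r} at data row {row + 1}"
                ) from None
    return ScoreTable(
        list(ids), [s.strip() for s in frame["smiles"]], scores, provenance=str(path)
    )


def write_score_table(table: ScoreTable, path) -> None:
    """Write a score table as ``id,smiles,score`` CSV (failed -> empty field)."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("id,smiles,score\n")
        for cid, smi, value in zip(table.ids, table.smiles, table.scores):
            score = "" if math.isnan(value) else repr(float(value))
            fh.write(f"{cid},{smi},{score}\n")


def read_smiles_library(path) -> list[tuple[str, str]]:
    """Read a ``.smi`` file of ``SMILES<whitespace>ID`` lines, order preserved."""
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 'SMILES ID', got {line!r}"
                )
            smiles, cid = parts[0], parts[1]
            if cid in seen:
                raise ValueError(f"{path}:{lineno}: duplicate id {cid!r}")
            seen.add(cid)
            out.append((smiles, cid))
    return out


def write_smiles_library(library: Sequence[tuple[str, str]], path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        for smiles, cid in library:
            fh.write(f"{smiles}\t{cid}\n")


def _selected_filename(iteration: int) -> str:
    return f"iteration_{iteration:03d}_selected.txt"


def write_campaign_result(result: CampaignResult, directory, force: bool = False) -> None:
    """Persist a campaign result as ``summary.json`` + per-iteration id lists.

    Refuses to overwrite an existing result unless ``force`` is set.
    """
    directory = Path(directory)
    summary_path = directory / "summary.json"
    if summary_path.exists() and not force:
        raise FileExistsError(
            f"{summary_path} exists; pass force=True to overwrite"
        )
    directory.mkdir(parents=True, exist_ok=True)
    summary = {
        "config": result.config.to_dict(),
        "per_iteration": [
            {k: v for k, v in rec.to_dict().items() if k != "selected_ids"}
            for rec in result.per_iteration
        ],
    }
    with summary_path.open("w") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")
    for rec in result.per_iteration:
        with (directory / _selected_filename(rec.iteration)).open("w") as fh:
            for cid in rec.selected_ids:
                fh.write(cid + "\n")


def read_campaign_result(directory) -> CampaignResult:
    directory = Path(directory)
    with (directory / "summary.json").open() as fh:
        summary = json.load(fh)
    config = CampaignConfig.from_dict(summary["config"])
    per_iteration = []
    for meta in summary["per_iteration"]:
        iteration = int(meta["iteration"])
        path = directory / _selected_filename(iteration)
        selected = tuple(
            line.strip() for line in path.read_text().splitlines() if line.strip()
        )
        per_iteration.append(
            IterationRecord.from_dict({**meta, "selected_ids": selected})
        )
    return CampaignResult(config=config, per_iteration=per_iteration)
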