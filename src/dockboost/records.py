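"""Core domain types for replayed docking campaigns.

Scores follow the Glide convention throughout: lower (more negative) is more
favorable.  The sign convention is fixed, not configurable, so a ranking can
never be silently inverted.  A compound's outcome is exactly one of

* a finite docking score (``float``),
* :data:`FAILED` — docking produced no score, or
* ``None`` — not yet docked (unknown).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "FAILED",
    "CompoundRecord",
    "ScoreTable",
    "Substitute",
    "Drop",
    "parse_failed_policy",
    "CampaignConfig",
    "Diagnostics",
    "IterationRecord",
    "CampaignResult",
    "derive_seed",
]


class _FailedType:
    """Singleton marker for a docking run that produced no score."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "FAILED"


FAILED = _FailedType()


def derive_seed(base: int, *tags: object) -> int:
    """Derive a stable sub-seed (< 2**31) from a base seed and context tags.

    Every source of randomness in a campaign pulls its seed through this
    function, so reruns and checkpoint resumes are bit-identical and never
    depend on shared RNG stream state.
    """
    key = "|".join([str(int(base))] + [str(t) for t in tags])
    digest = hashlib.blake2b(key.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass(frozen=True, slots=True)
class CompoundRecord:
    """One library member: identifier, SMILES, and its docking outcome."""

    id: str
    smiles: str
    outcome: object = None  # float score | FAILED | None (= not yet docked)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("compound id must be a non-empty string")
        if isinstance(self.outcome, (int, float)):
            value = float(self.outcome)
            if not math.isfinite(value):
                raise ValueError(
                    f"docking score for {self.id!r} must be finite, got {value!r}"
                )
            object.__setattr__(self, "outcome", value)
        elif self.outcome is not None and self.outcome is not FAILED:
            raise ValueError(f"invalid outcome for {self.id!r}: {self.outcome!r}")

    @property
    def is_scored(self) -> bool:
        return isinstance(self.outcome, float)

    @property
    def is_failed(self) -> bool:
        return self.outcome is FAILED

    @property
    def is_unknown(self) -> bool:
        return self.outcome is None

    @property
    def score(self) -> float:
        if not self.is_scored:
            raise ValueError(f"compound {self.id!r} has no score ({self.outcome!r})")
        return self.outcome  # type: ignore[return-value]


class ScoreTable:
    """Replayable ground truth: the brute-force docking outcome per library id.

    Internally scores are a float array with NaN marking failed compounds; a
    table never contains undocked (unknown) entries.  Access through
    :meth:`lookup` is recorded so the simu-dock blindness contract — a campaign
    touches exactly the rows it selected — can be audited after a run.
    """

    def __init__(
        self,
        ids: Sequence[str],
        smiles: Sequence[str],
        scores: Sequence[float],
        provenance: str = "",
    ) -> None:
        self.ids: tuple[str, ...] = tuple(str(i) for i in ids)
        self.smiles: tuple[str, ...] = tuple(str(s) for s in smiles)
        self.scores: np.ndarray = np.asarray(scores, dtype=float)
        self.provenance = provenance
        if not (len(self.ids) == len(self.smiles) == len(self.scores)):
            raise ValueError("ids, smiles and scores must have equal length")
        if any(not i for i in self.ids):
            raise ValueError("empty compound id in score table")
        self._index: dict[str, int] = {}
        for pos, cid in enumerate(self.ids):
            if cid in self._index:
                raise ValueError(f"duplicate id in score table: {cid!r}")
            self._index[cid] = pos
        finite = self.scores[~np.isnan(self.scores)]
        if finite.size and not np.all(np.isfinite(finite)):
            raise ValueError("docking scores must be finite or NaN (failed)")
        self._accessed: set[str] = set()

    @classmethod
    def from_records(
        cls, records: Iterable[CompoundRecord], provenance: str = ""
    ) -> "ScoreTable":
        ids, smiles, scores = [], [], []
        for rec in records:
            if rec.is_unknown:
                raise ValueError(f"score table entry {rec.id!r} has unknown outcome")
            ids.append(rec.id)
            smiles.append(rec.smiles)
            scores.append(rec.score if rec.is_scored else np.nan)
        return cls(ids, smiles, scores, provenance)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, cid: str) -> bool:
        return cid in self._index

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScoreTable):
            return NotImplemented
        return (
            self.ids == other.ids
            and self.smiles == other.smiles
            and np.array_equal(self.scores, other.scores, equal_nan=True)
            and self.provenance == other.provenance
        )

    def record(self, cid: str) -> CompoundRecord:
        """Fetch one record; the access is logged (see :attr:`accessed_ids`)."""
        try:
            pos = self._index[cid]
        except KeyError:
            raise KeyError(f"id not present in score table: {cid!r}") from None
        self._accessed.add(cid)
        value = self.scores[pos]
        outcome = FAILED if np.isnan(value) else float(value)
        return CompoundRecord(cid, self.smiles[pos], outcome)

    def lookup(self, ids: Iterable[str]) -> list[CompoundRecord]:
        return [self.record(cid) for cid in ids]

    def records(self) -> Iterator[CompoundRecord]:
        """Iterate all records (does not count as campaign access)."""
        for pos, cid in enumerate(self.ids):
            value = self.scores[pos]
            outcome = FAILED if np.isnan(value) else float(value)
            yield CompoundRecord(cid, self.smiles[pos], outcome)

    @property
    def accessed_ids(self) -> frozenset[str]:
        return frozenset(self._accessed)

    def reset_access_log(self) -> None:
        self._accessed = set()

    @property
    def n_failed(self) -> int:
        return int(np.isnan(self.scores).sum())

    @property
    def failure_fraction(self) -> float:
        return self.n_failed / len(self) if len(self) else 0.0

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"id": self.ids, "smiles": self.smiles, "score": self.scores}
        )


# ---------------------------------------------------------------------------
# Failed-compound policies


@dataclass(frozen=True, slots=True)
class Substitute:
    """Replace a failed outcome with an arbitrary unfavorable score."""

    failed_score: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.failed_score):
            raise ValueError("substituted failed score must be finite")

    def __str__(self) -> str:
        return f"substitute:{self.failed_score}"


@dataclass(frozen=True, slots=True)
class Drop:
    """Exclude failed compounds from the training data entirely."""

    def __str__(self) -> str:
        return "drop"


def parse_failed_policy(text: str) -> Substitute | Drop:
    """Parse ``"drop"`` or ``"substitute:<score>"`` (e.g. ``substitute:5.0``)."""
    text = text.strip().lower()
    if text == "drop":
        return Drop()
    if text.startswith("substitute:"):
        return Substitute(float(text.split(":", 1)[1]))
    raise ValueError(f"unknown failed policy: {text!r}")


# ---------------------------------------------------------------------------
# Campaign configuration and results


def _default_surrogate_spec() -> dict:
    return {"name": "fingerprint_ridge", "params": {}}


@dataclass(frozen=True)
class CampaignConfig:
    """All knobs of a campaign run.

    ``fraction`` is the per-iteration docking fraction: both the initial random
    batch and every subsequent selection batch contain ``floor(fraction *
    library_size)`` compounds.
    """

    library_size: int
    fraction: float
    n_iterations: int
    failed_policy: Substitute | Drop = Drop()
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    top_k_list: tuple[int, ...] = (100, 1000, 10000)
    surrogate_spec: dict = field(default_factory=_default_surrogate_spec)
    split_mode: str = "redraw"  # "redraw" | "frozen"

    def __post_init__(self) -> None:
        if self.library_size < 1:
            raise ValueError("library_size must be positive")
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError("fraction must be in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")
        if self.batch_size < 1:
            raise ValueError(
                f"fraction {self.fraction} of library {self.library_size} "
                "selects no compounds"
            )
        if self.n_iterations * self.batch_size > self.library_size:
            raise ValueError(
                "campaign would dock more compounds than the library holds: "
                f"{self.n_iterations} x {self.batch_size} > {self.library_size}"
            )
        fr = self.split_fractions
        if len(fr) != 3 or any(f < 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ValueError("split_fractions must be 3 nonnegative values summing to 1")
        if any(k < 1 for k in self.top_k_list):
            raise ValueError("top-k values must be positive")
        if self.split_mode not in ("redraw", "frozen"):
            raise ValueError("split_mode must be 'redraw' or 'frozen'")
        object.__setattr__(self, "split_fractions", tuple(float(f) for f in fr))
        object.__setattr__(self, "top_k_list", tuple(int(k) for k in self.top_k_list))

    @property
    def batch_size(self) -> int:
        """Compounds docked per iteration: floor(fraction x library size)."""
        return int(math.floor(self.fraction * self.library_size))

    @property
    def total_budget(self) -> int:
        """Total compounds docked over the whole campaign."""
        return self.n_iterations * self.batch_size

    @property
    def docked_fraction(self) -> float:
        """Share of the library docked after the final iteration."""
        return self.total_budget / self.library_size

    def with_seed(self, seed: int) -> "CampaignConfig":
        return replace(self, seed=int(seed))

    def to_dict(self) -> dict:
        return {
            "library_size": self.library_size,
            "fraction": self.fraction,
            "n_iterations": self.n_iterations,
            "failed_policy": str(self.failed_policy),
            "split_fractions": list(self.split_fractions),
            "seed": self.seed,
            "top_k_list": list(self.top_k_list),
            "surrogate_spec": self.surrogate_spec,
            "split_mode": self.split_mode,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CampaignConfig":
        data = dict(data)
        if "failed_policy" in data:
            data["failed_policy"] = parse_failed_policy(data["failed_policy"])
        for key in ("split_fractions", "top_k_list"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


@dataclass(frozen=True, slots=True)
class Diagnostics:
    """Per-iteration surrogate RMSE on the three splits, in score units."""

    train_rmse: float
    val_rmse: float
    test_rmse: float

    def to_dict(self) -> dict:
        return {
            "train_rmse": self.train_rmse,
            "val_rmse": self.val_rmse,
            "test_rmse": self.test_rmse,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "Diagnostics":
        return cls(**{k: float(v) for k, v in data.items()})


@dataclass(frozen=True)
class IterationRecord:
    """Bookkeeping for one campaign iteration (1-based index).

    Iteration 1 is the random initialization and carries no model
    diagnostics; iterations >= 2 record the RMSE of the surrogate trained on
    everything docked before the iteration's selection.
    """

    iteration: int
    selected_ids: tuple[str, ...]
    n_failed_selected: int
    diagnostics: Diagnostics | None = None

    def to_dict(self) -> dict:
        return {
            "iteration": self.iteration,
            "selected_ids": list(self.selected_ids),
            "n_failed_selected": self.n_failed_selected,
            "diagnostics": None if self.diagnostics is None else self.diagnostics.to_dict(),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "IterationRecord":
        diag = data.get("diagnostics")
        return cls(
            iteration=int(data["iteration"]),
            selected_ids=tuple(data["selected_ids"]),
            n_failed_selected=int(data["n_failed_selected"]),
            diagnostics=None if diag is None else Diagnostics.from_dict(diag),
        )


@dataclass
class CampaignResult:
    """Results object of a campaign run.

    Carries the configuration and one :class:`IterationRecord` per completed
    iteration; selection sets are pairwise disjoint and their union is the
    cumulative docked set.
    """

    config: CampaignConfig
    per_iteration: list[IterationRecord] = field(default_factory=list)

    @property
    def n_iterations_run(self) -> int:
        return len(self.per_iteration)

    def selected(self, iteration: int) -> tuple[str, ...]:
        """Ids newly sent to docking at a given (1-based) iteration."""
        return self.per_iteration[iteration - 1].selected_ids

    def cumulative_docked(self, iteration: int | None = None) -> frozenset[str]:
        """All ids docked up to and including ``iteration`` (default: all)."""
        upto = self.n_iterations_run if iteration is None else iteration
        out: set[str] = set()
        for rec in self.per_iteration[:upto]:
            out.update(rec.selected_ids)
        return frozenset(out)

    @property
    def n_docked(self) -> int:
        return sum(len(rec.selected_ids) for rec in self.per_iteration)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CampaignResult):
            return NotImplemented
        return self.config == other.config and self.per_iteration == other.per_iteration

    def summary(self) -> str:
        """Human-readable per-iteration table."""
        lines = [
            "Campaign summary",
            f"  library size   : {self.config.library_size}",
            f"  batch/iteration: {self.config.batch_size} "
            f"({100 * self.config.fraction:g}% of library)",
            f"  failed policy  : {self.config.failed_policy}",
            f"  surrogate      : {self.config.surrogate_spec.get('name')}",
            f"  seed           : {self.config.seed}",
            "",
            f"{'iter':>4} {'selected':>9} {'failed':>7} {'cum.docked':>11} "
            f"{'train_rmse':>11} {'val_rmse':>9} {'test_rmse':>10}",
        ]
        cum = 0
        for rec in self.per_iteration:
            cum += len(rec.selected_ids)
            d = rec.diagnostics
            fmt = lambda x: f"{x:.4f}" if x is not None and math.isfinite(x) else "-"
            lines.append(
                f"{rec.iteration:>4} {len(rec.selected_ids):>9} "
                f"{rec.n_failed_selected:>7} {cum:>11} "
                f"{fmt(d.train_rmse if d else None):>11} "
                f"{fmt(d.val_rmse if d else None):>9} "
                f"{fmt(d.test_rmse if d else None):>10}"
            )
        return "\n".join(lines)

    def save(self, directory, force: bool = False) -> None:
        from . import io

        io.write_campaign_result(self, directory, force=force)

    @classmethod
    def load(cls, directory) -> "CampaignResult":
        from . import io

        return io.read_campaign_result(directory)
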