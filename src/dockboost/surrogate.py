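"""Surrogate regressors that predict docking scores from SMILES.

The default engine is ridge regression on 2048-bit radius-2 Morgan count
fingerprints: it preserves the campaign protocol's logic (train from scratch
each iteration, predict the whole library, rank greedily) at desk scale while
remaining deterministic and cheap.  A histogram gradient-boosting variant and
two diagnostic doubles (an oracle that returns the true score, and a seeded
random predictor) satisfy the same interface; a message-passing network could
be plugged in through :data:`SURROGATES` without touching the campaign loop.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import norm

from .fingerprints import MorganFeaturizer
from .records import (
    CompoundRecord,
    Diagnostics,
    Drop,
    ScoreTable,
    Substitute,
    derive_seed,
)

__all__ = [
    "WORST_PREDICTION",
    "TrainingSet",
    "apply_failed_policy",
    "split_train_val_test",
    "Surrogate",
    "FingerprintRidge",
    "FingerprintGBR",
    "OracleSurrogate",
    "RandomSurrogate",
    "SURROGATES",
    "make_surrogate",
    "train_surrogate",
]

logger = logging.getLogger(__name__)

#: Sentinel prediction for SMILES the featurizer cannot process: worse than
#: any real score, so such compounds are never selected.  A featurization
#: failure is a surrogate artifact, not a docking outcome.
WORST_PREDICTION = 1.0e9

Record = tuple[str, str, float]  # (id, smiles, target score)


@dataclass(frozen=True)
class TrainingSet:
    """Disjoint train/val/test collections of (id, smiles, score) records."""

    train: tuple[Record, ...]
    val: tuple[Record, ...]
    test: tuple[Record, ...]

    def __post_init__(self) -> None:
        ids = [r[0] for part in (self.train, self.val, self.test) for r in part]
        if len(ids) != len(set(ids)):
            raise ValueError("train/val/test sets share compound ids")

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.val), len(self.test))


def apply_failed_policy(
    records: Iterable[CompoundRecord], policy: Substitute | Drop
) -> list[Record]:
    """Turn docked records into regression records under a failed policy.

    ``Substitute(v)``: failed outcomes become score ``v``; ``Drop``: failed
    records are removed.  Scored records always pass through unchanged.
    """
    out: list[Record] = []
    for rec in records:
        if rec.is_scored:
            out.append((rec.id, rec.smiles, rec.score))
        elif rec.is_failed:
            if isinstance(policy, Substitute):
                out.append((rec.id, rec.smiles, policy.failed_score))
        else:
            raise ValueError(f"record {rec.id!r} has not been docked")
    return out


def split_train_val_test(
    records: Sequence[Record],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    mode: str = "redraw",
) -> TrainingSet:
    """Split records into train/val/test by a seeded permutation.

    Val and test sizes are floored; the remainder goes to train.  In
    ``"frozen"`` mode each compound's assignment is a hash of its id and the
    seed, so a compound keeps its split across growing iterations.
    """
    f_tr, f_va, f_te = fractions
    if abs(f_tr + f_va + f_te - 1.0) > 1e-9 or min(fractions) < 0:
        raise ValueError("split fractions must be nonnegative and sum to 1")
    n = len(records)
    if mode == "frozen":
        train, val, test = [], [], []
        for rec in records:
            u = (zlib.crc32(f"{rec[0]}|{seed}".encode()) & 0xFFFFFFFF) / 2**32
            if u < f_tr:
                train.append(rec)
            elif u < f_tr + f_va:
                val.append(rec)
            else:
                test.append(rec)
        parts = (train, val, test)
    else:
        n_va = int(np.floor(n * f_va))
        n_te = int(np.floor(n * f_te))
        n_tr = n - n_va - n_te
        order = np.random.default_rng(int(seed)).permutation(n)
        train = [records[i] for i in order[:n_tr]]
        val = [records[i] for i in order[n_tr : n_tr + n_va]]
        test = [records[i] for i in order[n_tr + n_va :]]
        parts = (train, val, test)
    for frac, part, name in zip(fractions, parts, ("train", "val", "test")):
        if frac > 0 and not part:
            raise ValueError(
                f"too few records ({n}) to populate the {name} set "
                f"(fraction {frac})"
            )
    return TrainingSet(tuple(parts[0]), tuple(parts[1]), tuple(parts[2]))


# ---------------------------------------------------------------------------
# Surrogate engines


class Surrogate:
    """Interface: fit on (smiles, score) pairs, predict scores for SMILES."""

    def fit(self, smiles: Sequence[str], y: Sequence[float], seed: int = 0) -> "Surrogate":
        raise NotImplementedError

    def _predict_batch(self, smiles: Sequence[str]) -> np.ndarray:
        raise NotImplementedError

    def predict(self, smiles: Sequence[str], chunk_size: int = 65536) -> np.ndarray:
        """Predict one finite score per input SMILES, in input order.

        Evaluation is chunked; results are independent of ``chunk_size``.
        """
        if len(smiles) == 0:
            return np.empty(0)
        parts = [
            self._predict_batch(smiles[start : start + chunk_size])
            for start in range(0, len(smiles), chunk_size)
        ]
        return np.concatenate(parts)


class _FingerprintRegressor(Surrogate):
    """Shared featurize-then-regress scaffolding for fingerprint engines."""

    #: abort training when more than this share of SMILES cannot be featurized
    max_skip_fraction = 0.10

    def __init__(self, featurizer: MorganFeaturizer | None = None):
        self.featurizer = featurizer or MorganFeaturizer()
        self.n_skipped_ = 0

    def _design_matrix(self, smiles, y):
        X, valid = self.featurizer.transform(smiles)
        self.n_skipped_ = int((~valid).sum())
        if self.n_skipped_:
            skipped = [s for s, ok in zip(smiles, valid) if not ok]
            logger.warning(
                "skipping %d unfeaturizable SMILES during training (e.g. %r)",
                self.n_skipped_,
                skipped[0],
            )
            if self.n_skipped_ > self.max_skip_fraction * len(smiles):
                raise ValueError(
                    f"{self.n_skipped_}/{len(smiles)} training SMILES could "
                    "not be featurized (>10%)"
                )
        y = np.asarray(y, dtype=float)
        return X[valid], y[valid]

    def _predict_valid(self, X) -> np.ndarray:
        raise NotImplementedError

    def _predict_batch(self, smiles):
        X, valid = self.featurizer.transform(smiles)
        out = np.full(len(smiles), WORST_PREDICTION)
        if valid.any():
            out[valid] = self._predict_valid(X[valid])
        if not valid.all():
            logger.warning(
                "%d unfeaturizable SMILES assigned worst-rank sentinel",
                int((~valid).sum()),
            )
        return out


class FingerprintRidge(_FingerprintRegressor):
    """Ridge regression on Morgan count fingerprints (the default engine).

    The default penalty is deliberately strong: with 2048 correlated count
    features and training sets of a few thousand compounds, light shrinkage
    overfits while heavy shrinkage barely costs ranking quality.
    """

    def __init__(self, alpha: float = 30.0, featurizer: MorganFeaturizer | None = None):
        super().__init__(featurizer)
        self.alpha = float(alpha)
        self._model = None

    def fit(self, smiles, y, seed: int = 0):
        from sklearn.linear_model import Ridge

        X, y = self._design_matrix(smiles, y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self._model = Ridge(alpha=self.alpha, solver="sparse_cg", tol=1e-8)
        self._model.fit(X, y)
        return self

    def _predict_valid(self, X):
        if self._model is None:
            raise RuntimeError("surrogate is not fitted")
        return self._model.predict(X)


class FingerprintGBR(_FingerprintRegressor):
    """Histogram gradient boosting on Morgan count fingerprints."""

    def __init__(
        self,
        featurizer: MorganFeaturizer | None = None,
        **params,
    ):
        super().__init__(featurizer)
        self.params = params
        self._model = None

    def fit(self, smiles, y, seed: int = 0):
        from sklearn.ensemble import HistGradientBoostingRegressor

        X, y = self._design_matrix(smiles, y)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        self._model = HistGradientBoostingRegressor(
            random_state=int(seed) % (2**31), **self.params
        )
        self._model.fit(X.toarray(), y)
        return self

    def _predict_valid(self, X):
        if self._model is None:
            raise RuntimeError("surrogate is not fitted")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return self._model.predict(X.toarray())


class OracleSurrogate(Surrogate):
    """Diagnostic double whose predictions are the true docking scores.

    It is deliberately clairvoyant — built directly from the ground-truth
    table, outside the replay-blindness contract — and exists to verify that
    with perfect predictions the campaign selects exactly the true top
    compounds.  Failed compounds predict far above any real score.
    """

    FAILED_PREDICTION = 1.0e6

    def __init__(self, truth: dict[str, float]):
        self._truth = truth

    @classmethod
    def from_table(cls, table: ScoreTable) -> "OracleSurrogate":
        truth = {
            smi: (cls.FAILED_PREDICTION if np.isnan(score) else float(score))
            for smi, score in zip(table.smiles, table.scores)
        }
        return cls(truth)

    def fit(self, smiles, y, seed: int = 0):
        return self

    def _predict_batch(self, smiles):
        return np.array(
            [self._truth.get(s, WORST_PREDICTION) for s in smiles], dtype=float
        )


class RandomSurrogate(Surrogate):
    """Null model: a seeded, per-compound pseudo-random prediction.

    The value is a deterministic hash of (SMILES, seed) mapped through the
    normal quantile function, so predictions are independent of query order
    and chunking, and a fresh seed gives fresh noise.
    """

    def __init__(self, seed: int = 0):
        self.seed = int(seed)

    def fit(self, smiles, y, seed: int = 0):
        self.seed = int(seed)
        return self

    def _predict_batch(self, smiles):
        raw = np.array(
            [zlib.crc32(f"{s}|{self.seed}".encode()) & 0xFFFFFFFF for s in smiles],
            dtype=np.float64,
        )
        u = (raw + 0.5) / 2**32
        return norm.ppf(u)


SURROGATES = {
    "fingerprint_ridge": FingerprintRidge,
    "fingerprint_gbr": FingerprintGBR,
    "oracle": OracleSurrogate,
    "random": RandomSurrogate,
}


def make_surrogate(
    spec: dict,
    featurizer: MorganFeaturizer | None = None,
    table: ScoreTable | None = None,
) -> Surrogate:
    """Instantiate a surrogate from ``{"name": ..., "params": {...}}``."""
    name = spec.get("name", "fingerprint_ridge")
    params = dict(spec.get("params", {}))
    if name not in SURROGATES:
        raise ValueError(f"unknown surrogate {name!r}; choose from {sorted(SURROGATES)}")
    if name == "oracle":
        if table is None:
            raise ValueError("the oracle surrogate needs the ground-truth table")
        return OracleSurrogate.from_table(table)
    if name == "random":
        return RandomSurrogate(**params)
    return SURROGATES[name](featurizer=featurizer, **params)


def _rmse(model: Surrogate, part: Sequence[Record]) -> float:
    if not part:
        return float("nan")
    smiles = [r[1] for r in part]
    y = np.array([r[2] for r in part])
    pred = model.predict(smiles)
    ok = pred < WORST_PREDICTION
    if not ok.any():
        return float("nan")
    return float(np.sqrt(np.mean((pred[ok] - y[ok]) ** 2)))


def train_surrogate(
    ts: TrainingSet,
    spec: dict,
    seed: int = 0,
    featurizer: MorganFeaturizer | None = None,
    table: ScoreTable | None = None,
) -> tuple[Surrogate, Diagnostics]:
    """Train a fresh surrogate (no warm start) and report split RMSEs."""
    if not ts.train:
        raise ValueError("training set is empty")
    model = make_surrogate(spec, featurizer=featurizer, table=table)
    model.fit([r[1] for r in ts.train], [r[2] for r in ts.train], seed=seed)
    diagnostics = Diagnostics(
        train_rmse=_rmse(model, ts.train),
        val_rmse=_rmse(model, ts.val),
        test_rmse=_rmse(model, ts.test),
    )
    return model, diagnostics
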