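"""Morgan-fingerprint featurization shared by the surrogate and the oracle.

A single :class:`MorganFeaturizer` instance caches per-SMILES sparse rows, so
a campaign featurizes its library once no matter how many iterations (or
replicate runs) reuse it.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy import sparse

from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")

__all__ = ["MorganFeaturizer", "mol_from_smiles"]


def mol_from_smiles(smiles: str):
    """Parse a SMILES, returning None when RDKit rejects it."""
    return Chem.MolFromSmiles(smiles)


class MorganFeaturizer:
    """Radius-2 Morgan fingerprints (2048 bits), count or binary valued."""

    def __init__(self, radius: int = 2, n_bits: int = 2048, counts: bool = True):
        self.radius = int(radius)
        self.n_bits = int(n_bits)
        self.counts = bool(counts)
        self._generator = rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius, fpSize=self.n_bits
        )
        # smiles -> (bit indices, values) or None for unfeaturizable input
        self._cache: dict[str, tuple[np.ndarray, np.ndarray] | None] = {}

    def _row(self, smiles: str):
        try:
            return self._cache[smiles]
        except KeyError:
            pass
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            row = None
        else:
            if self.counts:
                fp = self._generator.GetCountFingerprint(mol)
                elems = fp.GetNonzeroElements()
                idx = np.fromiter(elems.keys(), dtype=np.int32, count=len(elems))
                val = np.fromiter(elems.values(), dtype=np.float32, count=len(elems))
            else:
                fp = self._generator.GetFingerprint(mol)
                idx = np.asarray(list(fp.GetOnBits()), dtype=np.int32)
                val = np.ones(len(idx), dtype=np.float32)
            order = np.argsort(idx)
            row = (idx[order], val[order])
        self._cache[smiles] = row
        return row

    def transform(
        self, smiles: Sequence[str]
    ) -> tuple[sparse.csr_matrix, np.ndarray]:
        """Featurize a SMILES batch.

        Returns ``(X, valid)`` where ``X`` is CSR of shape ``(n, n_bits)`` and
        ``valid`` flags rows whose SMILES parsed; invalid rows are all-zero.
        """
        n = len(smiles)
        indptr = np.zeros(n + 1, dtype=np.int64)
        chunks_idx: list[np.ndarray] = []
        chunks_val: list[np.ndarray] = []
        valid = np.ones(n, dtype=bool)
        for pos, smi in enumerate(smiles):
            row = self._row(smi)
            if row is None:
                valid[pos] = False
                indptr[pos + 1] = indptr[pos]
                continue
            idx, val = row
            chunks_idx.append(idx)
            chunks_val.append(val)
            indptr[pos + 1] = indptr[pos] + len(idx)
        indices = (
            np.concatenate(chunks_idx) if chunks_idx else np.empty(0, dtype=np.int32)
        )
        data = (
            np.concatenate(chunks_val) if chunks_val else np.empty(0, dtype=np.float32)
        )
        X = sparse.csr_matrix(
            (data, indices, indptr), shape=(n, self.n_bits), dtype=np.float32
        )
        return X, valid

    def bitvector(self, smiles: str):
        """RDKit ExplicitBitVect for Tanimoto arithmetic (binary, any mode)."""
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return None
        return self._generator.GetFingerprint(mol)
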