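"""HDF5-backed store for per-residue and pooled protein embeddings.

Search over a large target set must never re-run the encoder or re-pool, so
the store keeps one named per-residue matrix (m × d) and one pooled vector
(1 × d) per protein. Roundtrips are bit-exact (float64 arrays).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

_RESIDUE = "residue"
_POOLED = "pooled"


class EmbeddingStore:
    """Named-array container keyed by protein id.

    Parameters
    ----------
    path:
        HDF5 file location.
    mode:
        ``"r"`` read-only, ``"w"`` truncate, ``"a"`` append.
    """

    def __init__(self, path: str | Path, mode: str = "r") -> None:
        self._file = h5py.File(str(path), mode)
        for group in (_RESIDUE, _POOLED):
            if group not in self._file and mode in ("w", "a"):
                self._file.create_group(group)

    # -- context manager -----------------------------------------------------
    def __enter__(self) -> "EmbeddingStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._file.close()

    # -- writing -------------------------------------------------------------
    @property
    def dim(self) -> int | None:
        """Embedding dimension d, fixed across the dataset."""
        return self._file.attrs.get("dim")

    def _check_dim(self, d: int) -> None:
        current = self.dim
        if current is None:
            self._file.attrs["dim"] = int(d)
        elif int(current) != int(d):
            raise ValueError(
                f"dimension mismatch: store has d={current}, got d={d}"
            )

    def put_residue(self, protein_id: str, matrix: np.ndarray) -> None:
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2:
            raise ValueError(f"per-residue embedding for {protein_id} must be 2-D")
        if not np.all(np.isfinite(matrix)):
            raise ValueError(f"non-finite values in embedding for {protein_id}")
        self._check_dim(matrix.shape[1])
        grp = self._file[_RESIDUE]
        if protein_id in grp:
            del grp[protein_id]
        grp.create_dataset(protein_id, data=matrix)

    def put_pooled(self, protein_id: str, vector: np.ndarray) -> None:
        vector = np.asarray(vector, dtype=np.float64)
        if vector.ndim != 1:
            raise ValueError(f"pooled embedding for {protein_id} must be 1-D")
        if not np.all(np.isfinite(vector)):
            raise ValueError(f"non-finite values in embedding for {protein_id}")
        self._check_dim(vector.shape[0])
        grp = self._file[_POOLED]
        if protein_id in grp:
            del grp[protein_id]
        grp.create_dataset(protein_id, data=vector)

    # -- reading -------------------------------------------------------------
    def residue(self, protein_id: str) -> np.ndarray:
        grp = self._file[_RESIDUE]
        if protein_id not in grp:
            raise KeyError(f"missing embedding for {protein_id}")
        return np.asarray(grp[protein_id])

    def pooled(self, protein_id: str) -> np.ndarray:
        grp = self._file[_POOLED]
        if protein_id not in grp:
            raise KeyError(f"missing embedding for {protein_id}")
        return np.asarray(grp[protein_id])

    def residue_ids(self) -> list[str]:
        return sorted(self._file[_RESIDUE].keys())

    def pooled_ids(self) -> list[str]:
        return sorted(self._file[_POOLED].keys())

    def pooled_dict(self) -> dict[str, np.ndarray]:
        grp = self._file[_POOLED]
        return {pid: np.asarray(grp[pid]) for pid in grp.keys()}


def write_store(
    path: str | Path,
    residue: dict[str, np.ndarray] | None = None,
    pooled: dict[str, np.ndarray] | None = None,
) -> None:
    """Create a store file from in-memory embedding dictionaries."""
    with EmbeddingStore(path, "w") as store:
        for pid, mat in (residue or {}).items():
            store.put_residue(pid, mat)
        for pid, vec in (pooled or {}).items():
            store.put_pooled(pid, vec)
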