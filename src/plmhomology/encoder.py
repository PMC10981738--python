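"""Pluggable embedding providers and mean pooling.

A protein language model maps a length-m sequence to an m × d per-residue
embedding matrix; average pooling over residues yields the 1 × d per-protein
embedding used for search. Real encoders (ESM, ProtT5, ...) plug in through
the same interface; this module ships a deterministic mock encoder so the
whole pipeline runs without any pretrained model:

``context_free``
    each residue letter has a fixed profile — a one-hot vector over the
    amino-acid alphabet plus optional Gaussian jitter. With zero jitter and
    d >= 21 the dot product of two rows is exactly 1 for identical residues
    and 0 otherwise, which reduces embedding alignment to classic
    match/mismatch alignment.

``planted``
    the whole matrix is a planted per-protein vector (e.g. a fold centroid
    plus noise) broadcast over residues, so pooling returns the planted
    vector exactly; used to drive end-to-end search benchmarks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .records import ALPHABET, ProteinRecord


@dataclass(frozen=True)
class EncoderSpec:
    """Configuration of an embedding backend.

    ``dimension`` is d, fixed per run; ``deterministic_seed`` makes the mock
    encoder a pure function of (sequence, seed).
    """

    name: str = "mock"
    dimension: int = 32
    deterministic_seed: int = 0
    mode: str = "context_free"
    noise: float = 0.0

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("embedding dimension must be positive")


def _letter_rng(seed: int, letter: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, ord(letter)])
    )


def _id_rng(seed: int, protein_id: str) -> np.random.Generator:
    crc = zlib.crc32(protein_id.encode())
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, crc]))


class MockEncoder:
    """Deterministic stand-in encoder; see module docstring for modes."""

    def __init__(
        self,
        spec: EncoderSpec,
        planted: Mapping[str, np.ndarray] | None = None,
        planted_noise: float = 0.0,
    ) -> None:
        self.spec = spec
        self._profiles: dict[str, np.ndarray] = {}
        self._planted = planted
        self._planted_noise = planted_noise
        if spec.mode not in ("context_free", "planted"):
            raise ValueError(f"unknown mock mode {spec.mode!r}")
        if spec.mode == "planted" and planted is None:
            raise ValueError("planted mode requires a planted-vector mapping")

    def _profile(self, letter: str) -> np.ndarray:
        prof = self._profiles.get(letter)
        if prof is None:
            d = self.spec.dimension
            prof = np.zeros(d)
            idx = ALPHABET.find(letter)
            if idx < 0:
                idx = ord(letter) % len(ALPHABET)
            prof[idx % d] = 1.0
            if self.spec.noise > 0:
                rng = _letter_rng(self.spec.deterministic_seed, letter)
                prof = prof + self.spec.noise * rng.standard_normal(d)
            self._profiles[letter] = prof
        return prof

    def encode(self, record: ProteinRecord) -> np.ndarray:
        """Return the m × d per-residue embedding matrix for ``record``."""
        if len(record.sequence) == 0:
            raise ValueError("cannot encode an empty sequence")
        if self.spec.mode == "planted":
            base = np.asarray(self._planted[record.id], dtype=float)
            vec = base
            if self._planted_noise > 0:
                rng = _id_rng(self.spec.deterministic_seed, record.id)
                vec = base + self._planted_noise * rng.standard_normal(base.shape)
            return np.tile(vec, (len(record.sequence), 1))
        rows = [self._profile(letter) for letter in record.sequence]
        return np.stack(rows, axis=0)


def get_encoder(
    spec: EncoderSpec, planted: Mapping[str, np.ndarray] | None = None
) -> MockEncoder:
    """Factory for embedding backends; only the mock backend ships."""
    if spec.name == "mock":
        return MockEncoder(spec, planted=planted)
    raise RuntimeError("encoder backend unavailable")


def pool(matrix: np.ndarray) -> np.ndarray:
    """Average pooling: column-wise mean of an m × d matrix (m >= 1)."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 1:
        raise ValueError("pooling requires an m x d matrix with m >= 1")
    return matrix.mean(axis=0)
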