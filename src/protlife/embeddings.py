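"""Residue- and sequence-level protein representations.

The classifier consumes, per protein, a residue-level matrix of shape
(d_local x L_padded) — a single-channel "image" the convolutional head
projects to a fixed-length vector — and a sequence-level vector of length
d_global. Any object satisfying the small ``Embedder`` contract can
provide them. The package ships a deterministic synthetic embedder (a
hash-seeded function of sequence content, optionally carrying a planted
class signal) so the whole pipeline runs without model downloads, and an
adapter hook for a pretrained protein language model whose weights the
user supplies.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np

from .io import ProteinRecord

DEFAULT_L_PADDED = 1655


@dataclass(frozen=True)
class EmbedderSpec:
    name: str
    d_local: int
    d_global: int
    L_padded: int = DEFAULT_L_PADDED

    def __post_init__(self) -> None:
        if min(self.d_local, self.d_global, self.L_padded) < 1:
            raise ValueError("embedding dimensions must be >= 1")


@dataclass
class EmbeddingBundle:
    residue_matrix: np.ndarray  # (d_local, L_padded), zero beyond true_length
    sequence_vector: np.ndarray  # (d_global,)
    true_length: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.residue_matrix)) or not np.all(
            np.isfinite(self.sequence_vector)
        ):
            raise ValueError("non-finite embedding values")
        if self.true_length > self.residue_matrix.shape[1]:
            raise ValueError("true_length exceeds padded length")
        if self.true_length < self.residue_matrix.shape[1]:
            pad = self.residue_matrix[:, self.true_length :]
            if np.any(pad != 0):
                raise ValueError("padding columns must be zero")


class Embedder(Protocol):
    spec: EmbedderSpec

    def embed_one(self, sequence: str) -> EmbeddingBundle: ...


def _sequence_digest(sequence: str) -> int:
    """Stable content hash of a sequence, as a non-negative 31-bit int."""
    h = hashlib.blake2b(sequence.encode(), digest_size=8).digest()
    return int.from_bytes(h, "big") % (2**31)


class SyntheticEmbedder:
    """Deterministic stand-in embedder for testing and simulation.

    Embeddings are Gaussian noise seeded by (seed, content hash), so the
    same sequence always maps to the same bundle regardless of its id.
    ``signal_map`` ({motif: effect_size}) shifts the first coordinate of
    the sequence-level vector by ``effect_size`` whenever the motif occurs
    in the sequence, giving classifiers a provable signal to learn.
    """

    def __init__(
        self,
        seed: int,
        d_local: int = 128,
        d_global: int = 512,
        L_padded: int = DEFAULT_L_PADDED,
        signal_map: Mapping[str, float] | None = None,
    ) -> None:
        self.spec = EmbedderSpec("synthetic", d_local, d_global, L_padded)
        self.seed = int(seed)
        self.signal_map = dict(signal_map or {})
        self._cache: dict[int, EmbeddingBundle] = {}

    def embed_one(self, sequence: str) -> EmbeddingBundle:
        L = len(sequence)
        if L > self.spec.L_padded:
            raise ValueError(
                f"sequence length {L} exceeds padded length {self.spec.L_padded}"
            )
        key = _sequence_digest(sequence)
        if key in self._cache:
            return self._cache[key]
        rng = np.random.default_rng([self.seed, key])
        residue = np.zeros((self.spec.d_local, self.spec.L_padded), dtype=np.float32)
        residue[:, :L] = rng.standard_normal((self.spec.d_local, L)).astype(np.float32)
        seq_vec = rng.standard_normal(self.spec.d_global).astype(np.float32)
        for motif, effect in self.signal_map.items():
            if motif in sequence:
                seq_vec[0] += effect
        bundle = EmbeddingBundle(residue, seq_vec, L)
        self._cache[key] = bundle
        return bundle


class PretrainedAdapter:
    """Hook for a pretrained protein language model.

    Construction fails with an actionable message when the weights are not
    available; nothing in the package requires them.
    """

    def __init__(self, model_path: str) -> None:
        from pathlib import Path

        if not Path(model_path).exists():
            raise FileNotFoundError(
                f"pretrained weights not found at {model_path!r}; download the "
                "language-model weights and pass their path, or use the "
                "synthetic embedder (--embedder synthetic)"
            )
        raise NotImplementedError(
            "loading pretrained weights requires a deep-learning runtime; "
            "provide a custom Embedder implementing embed_one()"
        )


def embed(
    records: Sequence[ProteinRecord], embedder: Embedder
) -> list[EmbeddingBundle]:
    """One bundle per record; deterministic for a fixed embedder."""
    return [embedder.embed_one(r.sequence) for r in records]


def sequence_matrix(bundles: Sequence[EmbeddingBundle]) -> np.ndarray:
    """Stack sequence-level vectors into an (n, d_global) matrix."""
    return np.stack([b.sequence_vector for b in bundles]).astype(np.float64)


def residue_tensor(bundles: Sequence[EmbeddingBundle]) -> np.ndarray:
    """Stack residue matrices into an (n, 1, d_local, L_padded) tensor."""
    return np.stack([b.residue_matrix for b in bundles])[:, None, :, :].astype(
        np.float32
    )
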