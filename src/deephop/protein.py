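"""Protein sequence encoding: a fixed k-dimensional conditioning vector.

The default backend is a hashed k-mer composition (k = 1..3) that requires no
pretrained weights: every k-mer of the sequence is hashed into one of ``k``
buckets and the bucket counts are L2-normalized.  It is deterministic,
invariant to the sequence id and sensitive to point substitutions.

Any pretrained per-residue encoder (e.g. a transformer protein language
model) can be plugged in through :class:`ResidueEncoderAdapter`, which
mean-pools the residue matrix into the fixed-length vector.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol

import numpy as np
from Bio import SeqIO

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinSequence:
    seq_id: str
    residues: str

    def __post_init__(self):
        if not self.residues:
            raise ValueError("empty protein sequence")
        bad = set(self.residues) - AMINO_ACIDS - {"X"}
        if bad:
            raise ValueError(f"non-amino-acid characters in {self.seq_id}: {sorted(bad)}")


@dataclass(frozen=True)
class ProteinEmbedding:
    H_p: np.ndarray   # shape (k,)

    def __post_init__(self):
        arr = np.asarray(self.H_p, dtype=np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("protein embedding must be finite")
        object.__setattr__(self, "H_p", arr)

    @property
    def k(self) -> int:
        return self.H_p.shape[0]


class ProteinBackend(Protocol):
    dim: int

    def __call__(self, seq: ProteinSequence) -> np.ndarray: ...


def _bucket(kmer: str, dim: int) -> int:
    # md5 rather than hash() so bucket assignment is stable across processes
    return int.from_bytes(hashlib.md5(kmer.encode()).digest()[:8], "big") % dim


class KmerCompositionBackend:
    """Hashed 1-3-mer composition, L2-normalized. Default, fully offline."""

    def __init__(self, dim: int = 128, kmax: int = 3):
        self.dim = dim
        self.kmax = kmax

    def __call__(self, seq: ProteinSequence) -> np.ndarray:
        v = np.zeros(self.dim, dtype=np.float64)
        s = seq.residues
        for k in range(1, self.kmax + 1):
            for i in range(len(s) - k + 1):
                v[_bucket(s[i:i + k], self.dim)] += 1.0
        norm = np.linalg.norm(v)
        return (v / norm if norm > 0 else v).astype(np.float32)


class ResidueEncoderAdapter:
    """Adapter for any encoder producing a per-residue (l × k) matrix.

    The matrix is mean-pooled over residues to the fixed vector H_p.
    """

    def __init__(self, residue_encoder: Callable[[str], np.ndarray], dim: int):
        self._enc = residue_encoder
        self.dim = dim

    def __call__(self, seq: ProteinSequence) -> np.ndarray:
        mat = np.asarray(self._enc(seq.residues), dtype=np.float32)
        if mat.ndim != 2 or mat.shape[0] != len(seq.residues) or mat.shape[1] != self.dim:
            raise ValueError(
                f"residue encoder must return ({len(seq.residues)}, {self.dim}), "
                f"got {mat.shape}")
        return mat.mean(axis=0)


def embed_protein(seq: ProteinSequence,
                  backend: ProteinBackend | None = None) -> ProteinEmbedding:
    """Encode a protein sequence into its fixed k-dimensional vector."""
    backend = backend or KmerCompositionBackend()
    return ProteinEmbedding(H_p=backend(seq))


def read_fasta(path) -> list[ProteinSequence]:
    return [ProteinSequence(seq_id=rec.id, residues=str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(seqs: list[ProteinSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.seq_id}\n{s.residues}\n")


class EmbeddingCache:
    """On-disk JSON cache of embeddings keyed by sequence hash."""

    def __init__(self, path):
        self.path = Path(path)
        self._store: dict[str, list] = {}
        if self.path.exists():
            self._store = json.loads(self.path.read_text())

    @staticmethod
    def _key(seq: ProteinSequence) -> str:
        return hashlib.sha1(seq.residues.encode()).hexdigest()

    def get_or_compute(self, seq: ProteinSequence,
                       backend: ProteinBackend | None = None) -> ProteinEmbedding:
        key = self._key(seq)
        if key not in self._store:
            self._store[key] = embed_protein(seq, backend).H_p.tolist()
            self.path.write_text(json.dumps(self._store))
        return ProteinEmbedding(H_p=np.array(self._store[key], dtype=np.float32))
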