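"""Pluggable per-protein embedding backends.

A backend maps an amino-acid sequence to an L x dim matrix of per-residue
vectors; :func:`mean_pool` averages them into one protein-level vector. The
default testing backend (:func:`mock_backend`) is a deterministic hashed
3-mer embedder; a real protein-language-model backend can be supplied
through the same interface (it is loaded lazily and is never required by the
rest of the pipeline).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: default embedding width, matching the per-residue width of the 150M-scale
#: ESM2 family of protein language models.
DEFAULT_DIM = 640


@dataclass(frozen=True)
class ProteinEmbedding:
    gene_id: str
    vector: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"{self.gene_id}: non-finite embedding")


@dataclass
class EmbeddingBackend:
    """A deterministic map from protein sequence to per-residue vectors.

    ``per_residue(seq)`` must return an (L, dim) array and must be a pure
    function of the sequence: identical inputs yield identical outputs.
    """

    name: str
    dim: int
    per_residue: Callable[[str], np.ndarray] = field(repr=False)

    def __call__(self, aa_seq: str) -> np.ndarray:
        return self.per_residue(aa_seq)


def mean_pool(per_residue: np.ndarray) -> np.ndarray:
    """Average per-residue vectors into a single protein-level vector."""
    per_residue = np.asarray(per_residue, dtype=float)
    if per_residue.ndim != 2 or per_residue.shape[0] < 1:
        raise ValueError("per-residue matrix must be (L, dim) with L >= 1")
    return per_residue.mean(axis=0)


def sanitize_sequence(aa_seq: str) -> str:
    """Uppercase and map any non-standard residue character to X."""
    return "".join(c if c in AA_ALPHABET else "X" for c in aa_seq.upper())


def embed_protein(backend: EmbeddingBackend, aa_seq: str, gene_id: str = "") -> ProteinEmbedding:
    """Embed one protein: per-residue vectors from ``backend``, mean-pooled.

    Unknown characters are mapped to X before embedding. Raises
    ``ValueError`` on an empty sequence.
    """
    if not aa_seq:
        raise ValueError("cannot embed an empty protein sequence")
    mat = backend(sanitize_sequence(aa_seq))
    if mat.shape != (len(aa_seq), backend.dim):
        raise ValueError(
            f"backend {backend.name} returned shape {mat.shape}, expected "
            f"({len(aa_seq)}, {backend.dim})"
        )
    return ProteinEmbedding(gene_id=gene_id, vector=mean_pool(mat))


def _stable_bucket(token: str, n_buckets: int) -> int:
    digest = hashlib.blake2b(token.encode(), digest_size=8).digest()
    return int.from_bytes(digest, "little") % n_buckets


def mock_backend(dim: int = DEFAULT_DIM, seed: int = 0, n_buckets: int = 4096) -> EmbeddingBackend:
    """Deterministic hashed-3-mer embedding backend for desk-scale runs.

    Residue ``i`` is represented by the 3-mer centred on it (clipped at the
    sequence ends, so proteins shorter than three residues still embed).
    Each distinct 3-mer hashes to one row of a seeded Gaussian projection
    matrix, making the pooled vector a linear image of the protein's 3-mer
    composition: composition-sensitive, so a planted sequence motif shifts
    the pooled vectors of the proteins that carry it.
    """
    if dim < 8:
        raise ValueError("mock backend requires dim >= 8")
    rng = np.random.default_rng(seed)
    table = rng.standard_normal((n_buckets, dim))

    def per_residue(seq: str) -> np.ndarray:
        L = len(seq)
        idx = np.empty(L, dtype=np.int64)
        for i in range(L):
            token = seq[max(0, i - 1) : i + 2]
            idx[i] = _stable_bucket(token, n_buckets)
        return table[idx]

    return EmbeddingBackend(name=f"mock3mer-d{dim}-s{seed}", dim=dim, per_residue=per_residue)


def esm2_backend(model_name: str = "esm2_t30_150M_UR50D", max_length: int = 1022) -> EmbeddingBackend:
    """Real protein-language-model backend (optional, loaded lazily).

    Requires the ``fair-esm`` package and model weights; sequences longer
    than ``max_length`` are truncated with a logged warning and pooled over
    the retained prefix. Special begin/end tokens are excluded from pooling.
    """
    try:
        import esm  # type: ignore
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "the real protein-language-model backend requires the 'fair-esm' "
            "package; use mock_backend() for a dependency-free embedder"
        ) from exc

    import logging

    logger = logging.getLogger(__name__)
    model, alphabet = esm.pretrained.load_model_and_alphabet(model_name)  # pragma: no cover
    model.eval()  # pragma: no cover
    converter = alphabet.get_batch_converter()  # pragma: no cover
    dim = model.embed_dim  # pragma: no cover

    def per_residue(seq: str) -> np.ndarray:  # pragma: no cover
        import torch

        if len(seq) > max_length:
            logger.warning("truncating %d-residue protein to %d", len(seq), max_length)
            seq = seq[:max_length]
        _, _, toks = converter([("q", seq)])
        with torch.no_grad():
            out = model(toks, repr_layers=[model.num_layers])
        rep = out["representations"][model.num_layers][0, 1 : len(seq) + 1]
        return rep.numpy()

    return EmbeddingBackend(name=model_name, dim=dim, per_residue=per_residue)  # pragma: no cover


def embed_genes(backend: EmbeddingBackend, genes) -> dict[str, ProteinEmbedding]:
    """Embed every gene record in an iterable; returns gene_id -> embedding."""
    return {g.gene_id: embed_protein(backend, g.aa_seq, g.gene_id) for g in genes}
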