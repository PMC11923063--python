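"""Featurization of enzyme-substrate pairs.

An enzyme-substrate reaction is represented by the concatenation of a
protein embedding (default 1024-d, the width of ProtT5-class protein
language models), a molecule embedding (default 768-d, MolT5-class), and
the 167-bit MACCS structural-key fingerprint — 1959 dimensions in total
with the defaults.  Embedding providers are pluggable: any deterministic
map from a string to a fixed-length vector satisfies the contract, so
precomputed language-model matrices and the synthetic desk-scale providers
below are interchangeable.

Synthetic providers:

``iid_hash``
    An independent pseudo-random unit-scale vector per distinct input
    string (no similarity structure; categorical identity only).
``kmer_composition``
    A fixed seeded random vector per k-mer; a string embeds as the mean
    over its k-mers, so similar sequences receive similar embeddings —
    the property that makes homology leakage demonstrable at desk scale.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import MACCSkeys

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "EmbeddingProvider", "FeatureBundle", "maccs_keys", "featurize",
    "average_molecule_features", "synthetic_provider", "feature_matrix",
]

MACCS_DIM = 167


@dataclass(frozen=True)
class EmbeddingProvider:
    """A deterministic map from an input string to a vector of length dim."""

    name: str
    dim: int
    embed: Callable[[str], np.ndarray]

    def __call__(self, text: str) -> np.ndarray:
        vec = np.asarray(self.embed(text), dtype=np.float64)
        if vec.shape != (self.dim,):
            raise ValueError(
                f"provider {self.name!r} returned shape {vec.shape}, "
                f"declared dim {self.dim}"
            )
        return vec


@dataclass(frozen=True)
class FeatureBundle:
    """Protein embedding + molecule embedding + MACCS keys, concatenated."""

    protein_vec: np.ndarray
    molecule_vec: np.ndarray
    maccs: np.ndarray

    @property
    def concat(self) -> np.ndarray:
        return np.concatenate([self.protein_vec, self.molecule_vec,
                               self.maccs.astype(np.float64)])


def maccs_keys(smiles: str) -> np.ndarray:
    """The standard 167-position MACCS keys bit vector of a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    fp = MACCSkeys.GenMACCSKeys(mol)
    arr = np.zeros(MACCS_DIM, dtype=np.uint8)
    for bit in fp.GetOnBits():
        arr[bit] = 1
    return arr


def featurize(
    sequence: str,
    smiles: str,
    protein_provider: EmbeddingProvider,
    molecule_provider: EmbeddingProvider,
) -> FeatureBundle:
    """Build the concatenated feature bundle for one enzyme-substrate pair.

    Concatenation order is fixed: (protein, molecule embedding, MACCS);
    with the default 1024/768-d providers the result is 1959-d.
    """
    return FeatureBundle(
        protein_vec=protein_provider(sequence),
        molecule_vec=molecule_provider(smiles),
        maccs=maccs_keys(smiles),
    )


def average_molecule_features(
    smiles_list: Sequence[str],
    molecule_provider: EmbeddingProvider,
) -> np.ndarray:
    """Multi-substrate reactions: elementwise mean of per-substrate features.

    Embedding and MACCS parts are averaged alike; the result has length
    ``molecule_provider.dim + 167`` and is permutation-invariant in the
    substrate list.
    """
    if len(smiles_list) == 0:
        raise ValueError("average_molecule_features requires ≥ 1 substrate")
    stacked = np.stack([
        np.concatenate([molecule_provider(s),
                        maccs_keys(s).astype(np.float64)])
        for s in smiles_list
    ])
    return stacked.mean(axis=0)


def _string_seed(seed: int, text: str) -> int:
    digest = hashlib.blake2b(
        text.encode(), digest_size=8, key=str(seed).encode()
    ).digest()
    return int.from_bytes(digest, "little") % (2**63)


def synthetic_provider(
    dim: int,
    seed: int = 0,
    mode: str = "iid_hash",
    k: int = 3,
    name: str | None = None,
) -> EmbeddingProvider:
    """Deterministic stand-in for language-model embedding providers.

    ``iid_hash`` draws an independent N(0, 1/dim) vector per distinct input
    string; distinct inputs are near-orthogonal at large dim.
    ``kmer_composition`` assigns a fixed seeded vector to every k-mer and
    embeds a string as the mean over its k-mers, so embedding similarity
    tracks sequence similarity.
    """
    if dim < 1:
        raise ValueError(f"dim must be ≥ 1, got {dim}")
    if mode not in ("iid_hash", "kmer_composition"):
        raise ValueError(f"unknown provider mode {mode!r}")

    if mode == "iid_hash":
        cache: dict[str, np.ndarray] = {}

        def embed(text: str) -> np.ndarray:
            vec = cache.get(text)
            if vec is None:
                rng = np.random.default_rng(_string_seed(seed, text))
                vec = rng.standard_normal(dim) / np.sqrt(dim)
                cache[text] = vec
            return vec

    else:
        kmer_vecs: dict[str, np.ndarray] = {}
        emb_cache: dict[str, np.ndarray] = {}

        def kmer_vec(kmer: str) -> np.ndarray:
            vec = kmer_vecs.get(kmer)
            if vec is None:
                rng = np.random.default_rng(_string_seed(seed, "k:" + kmer))
                vec = rng.standard_normal(dim) / np.sqrt(dim)
                kmer_vecs[kmer] = vec
            return vec

        def embed(text: str) -> np.ndarray:
            vec = emb_cache.get(text)
            if vec is None:
                if len(text) < k:
                    raise ValueError(
                        f"input of length {len(text)} shorter than k={k}"
                    )
                kmers = [text[i:i + k] for i in range(len(text) - k + 1)]
                vec = np.mean([kmer_vec(km) for km in kmers], axis=0)
                emb_cache[text] = vec
            return vec

    return EmbeddingProvider(
        name=name or f"synthetic_{mode}_d{dim}_s{seed}", dim=dim, embed=embed
    )


def default_providers(seed: int = 0) -> tuple[EmbeddingProvider,
                                              EmbeddingProvider]:
    """Default-dimension synthetic providers: 1024-d protein (ProtT5-style
    width), 768-d molecule (MolT5-style width)."""
    return (
        synthetic_provider(1024, seed=seed, mode="kmer_composition",
                           name="protein_kmer_1024"),
        synthetic_provider(768, seed=seed + 1, mode="kmer_composition",
                           name="molecule_kmer_768"),
    )


def feature_matrix(
    pairs: Iterable[tuple[str, str]],
    protein_provider: EmbeddingProvider,
    molecule_provider: EmbeddingProvider,
) -> np.ndarray:
    """Stack featurize() over (sequence, smiles) pairs into an (n, d) matrix.

    Protein and molecule parts are cached per distinct string, so datasets
    with repeated sequences or substrates featurize in O(distinct) embedding
    calls.
    """
    seq_cache: dict[str, np.ndarray] = {}
    mol_cache: dict[str, np.ndarray] = {}
    rows = []
    for sequence, smiles in pairs:
        if sequence not in seq_cache:
            seq_cache[sequence] = protein_provider(sequence)
        if smiles not in mol_cache:
            mol_cache[smiles] = np.concatenate([
                molecule_provider(smiles),
                maccs_keys(smiles).astype(np.float64),
            ])
        rows.append(np.concatenate([seq_cache[sequence], mol_cache[smiles]]))
    return np.asarray(rows)
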