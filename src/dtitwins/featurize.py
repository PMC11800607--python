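"""Molecule and protein featurization.

Molecules become binary circular (Morgan/ECFP-style) fingerprints, folded to a
configurable bit width (default 1024 bits, radius 2).  Proteins become either
a fixed-length one-hot encoding over the 20 standard amino acids or a
precomputed embedding vector looked up from a table keyed by sequence
(language-model embeddings are consumed, never computed, here).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .data import AMINO_ACIDS, DTIDataset

AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

FingerprintKind = Literal["ecfp", "atom_pair", "rdkit", "maccs"]


class FeaturizationError(ValueError):
    pass


def compute_fingerprint(smiles: str, kind: FingerprintKind = "ecfp",
                        n_bits: int = 1024, radius: int = 2) -> np.ndarray:
    """Binary fingerprint of a molecule, folded to ``n_bits``.

    Canonicalisation happens inside RDKit's graph hashing, so any SMILES
    spelling of the same molecule yields the same vector.  ``radius`` only
    applies to the circular (``ecfp``) family; MACCS has a fixed 167-bit size.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    if kind == "ecfp":
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
        fp = gen.GetFingerprint(mol)
    elif kind == "atom_pair":
        gen = rdFingerprintGenerator.GetAtomPairGenerator(fpSize=n_bits)
        fp = gen.GetFingerprint(mol)
    elif kind == "rdkit":
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=n_bits)
        fp = gen.GetFingerprint(mol)
    elif kind == "maccs":
        fp = MACCSkeys.GenMACCSKeys(mol)
    else:
        raise ValueError(f"unknown fingerprint kind {kind!r}")
    arr = np.zeros(fp.GetNumBits(), dtype=np.float64)
    arr[list(fp.GetOnBits())] = 1.0
    return arr


def one_hot_encode(sequence: str, l_max: int) -> np.ndarray:
    """One-hot encode a sanitised protein sequence to length ``20 * l_max``.

    Residue ``j`` occupies the 20-wide block starting at ``20*j`` with a
    single 1 at the alphabetical index of its amino acid; the placeholder
    ``X`` and padding positions are all-zero blocks.  Sequences longer than
    ``l_max`` keep their N-terminal prefix.
    """
    if l_max <= 0:
        raise ValueError("l_max must be positive")
    vec = np.zeros(20 * l_max, dtype=np.float64)
    for j, aa in enumerate(sequence[:l_max]):
        if aa == "X":
            continue
        try:
            vec[20 * j + AA_INDEX[aa]] = 1.0
        except KeyError:
            raise ValueError(f"unsanitised residue {aa!r}") from None
    return vec


@dataclass
class ProteinEmbeddingTable:
    """Precomputed per-sequence embedding vectors of one shared dimension."""

    vectors: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        dims = {v.shape[-1] for v in self.vectors.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent embedding dimensions: {sorted(dims)}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[-1]

    def __contains__(self, sequence: str) -> bool:
        return sequence in self.vectors

    def __getitem__(self, sequence: str) -> np.ndarray:
        return self.vectors[sequence]

    @classmethod
    def read(cls, path: str | Path, sep: str = ",") -> "ProteinEmbeddingTable":
        """Read a delimited matrix whose first column is the sequence key."""
        df = pd.read_csv(path, sep=sep)
        key_col = df.columns[0]
        mat = df.drop(columns=[key_col]).to_numpy(dtype=np.float64)
        return cls({str(k): mat[i] for i, k in enumerate(df[key_col])})

    def write(self, path: str | Path, sep: str = ",") -> None:
        keys = list(self.vectors)
        mat = np.stack([self.vectors[k] for k in keys])
        df = pd.DataFrame(mat, columns=[f"e{i}" for i in range(mat.shape[1])])
        df.insert(0, "sequence", keys)
        df.to_csv(path, sep=sep, index=False)


def attach_embeddings(dataset: DTIDataset,
                      table: ProteinEmbeddingTable) -> np.ndarray:
    """Per-record protein vectors from an embedding table.

    The table must cover every distinct sequence in the dataset; the error
    enumerates all absent sequences.
    """
    missing = sorted({r.protein_sequence for r in dataset.records
                      if r.protein_sequence not in table})
    if missing:
        raise KeyError(f"embedding table missing {len(missing)} sequences: {missing}")
    return np.stack([table[r.protein_sequence] for r in dataset.records])


@dataclass
class FeatureBundle:
    """Aligned per-record feature matrices for one dataset.

    ``molecule`` has shape (n_records, n_bits); ``protein`` has shape
    (n_records, 20*l_max) for one-hot or (n_records, emb_dim) for table
    embeddings.  All records of one bundle share one representation per
    modality.
    """

    molecule: np.ndarray
    protein: np.ndarray
    record_ids: list[str]
    protein_kind: Literal["one_hot", "embedding"] = "one_hot"

    def __post_init__(self) -> None:
        if not (len(self.molecule) == len(self.protein) == len(self.record_ids)):
            raise ValueError("misaligned feature matrices")

    def subset(self, indices: np.ndarray) -> "FeatureBundle":
        return FeatureBundle(self.molecule[indices], self.protein[indices],
                             [self.record_ids[i] for i in indices],
                             self.protein_kind)


def featurize_dataset(dataset: DTIDataset, kind: FingerprintKind = "ecfp",
                      n_bits: int = 1024, radius: int = 2, l_max: int = 64,
                      embedding_table: ProteinEmbeddingTable | None = None,
                      ) -> FeatureBundle:
    """Compute the full feature bundle for a dataset.

    Distinct molecules and proteins are featurized once and broadcast to
    records.  With ``embedding_table`` the protein side uses table lookups
    instead of one-hot encoding.
    """
    mol_cache: dict[str, np.ndarray] = {}
    for smi in dataset.molecules():
        if smi not in mol_cache:
            try:
                mol_cache[smi] = compute_fingerprint(smi, kind, n_bits, radius)
            except FeaturizationError as exc:
                raise FeaturizationError(f"record with SMILES {smi!r}: {exc}") from exc
    molecule = np.stack([mol_cache[s] for s in dataset.molecules()]) \
        if len(dataset) else np.zeros((0, n_bits))
    if embedding_table is not None:
        protein = attach_embeddings(dataset, embedding_table)
        pkind = "embedding"
    else:
        prot_cache = {seq: one_hot_encode(seq, l_max)
                      for seq in set(dataset.proteins())}
        protein = np.stack([prot_cache[s] for s in dataset.proteins()]) \
            if len(dataset) else np.zeros((0, 20 * l_max))
        pkind = "one_hot"
    return FeatureBundle(molecule, protein,
                         [r.record_id for r in dataset.records], pkind)
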