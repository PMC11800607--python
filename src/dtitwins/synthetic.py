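"""Synthetic drug-target interaction benchmarks with planted structure.

Molecules are sampled from a small grammar of alkyl chains and benzene
rings with simple decorations; a configured fraction carries a
pharmacophore fragment (default: a carboxylic acid).  Proteins are uniform
random sequences over the 20 standard residues; a configured fraction
contains a fixed motif at a random position.  A pair interacts exactly
when the molecule carries the pharmacophore AND the protein contains the
motif — a conjunctive rule, so neither modality alone can predict — and
each label is then flipped independently with probability ``label_noise``.
The flip-free rule labels are returned alongside as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .data import AMINO_ACIDS, DTIDataset, DTIRecord


@dataclass(frozen=True)
class SyntheticConfig:
    n_molecules: int = 200
    n_proteins: int = 50
    n_pairs: int = 2000
    protein_length: tuple[int, int] = (40, 60)
    pharmacophore: str = "C(=O)[OX2H1]"  # SMARTS used for ground truth
    motif: str = "HKWW"
    pharmacophore_fraction: float = 0.7
    motif_fraction: float = 0.7
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_molecules, self.n_proteins, self.n_pairs) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        if self.protein_length[0] < len(self.motif):
            raise ValueError("motif longer than minimum protein length")


_PREFIXES = ["", "O", "N", "F", "Cl"]
_RING_SUBS = ["C", "CC", "O", "N", "F", "Cl"]


def _random_chain(rng: np.random.Generator) -> str:
    k = int(rng.integers(2, 10))
    atoms = ["C"] * k
    # up to two methyl branches on interior carbons
    for pos in range(1, k - 1):
        if rng.random() < 0.25:
            atoms[pos] = "C(C)"
    return str(rng.choice(_PREFIXES)) + "".join(atoms)


def _random_ring(rng: np.random.Generator) -> str:
    s1 = str(rng.choice(_RING_SUBS))
    if rng.random() < 0.5:
        s2 = str(rng.choice(_RING_SUBS))
        return f"{s1}c1ccc({s2})cc1"
    return f"{s1}c1ccccc1"


def _random_skeleton(rng: np.random.Generator) -> str:
    return _random_chain(rng) if rng.random() < 0.6 else _random_ring(rng)


def molecule_matches(smiles: str, smarts: str) -> bool:
    mol = Chem.MolFromSmiles(smiles)
    pattern = Chem.MolFromSmarts(smarts)
    if mol is None or pattern is None:
        raise ValueError(f"bad SMILES/SMARTS: {smiles!r} / {smarts!r}")
    return mol.HasSubstructMatch(pattern)


def _stratified_flags(n: int, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Exactly ``round(fraction * n)`` True flags at random positions, so the
    observed carrier fraction matches the configured one without
    small-pool binomial fluctuation."""
    flags = np.zeros(n, dtype=bool)
    flags[: int(round(fraction * n))] = True
    rng.shuffle(flags)
    return flags


def generate_molecules(n: int, seed: int,
                       pharmacophore_fraction: float = 0.7,
                       pharmacophore_smarts: str = "C(=O)[OX2H1]",
                       ) -> list[str]:
    """``n`` distinct, valid, canonical SMILES; a stratified fraction
    carries the pharmacophore (a carboxylic-acid cap on the skeleton)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    carry = _stratified_flags(n, pharmacophore_fraction, rng)
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 1000 * n:
            raise RuntimeError("molecule grammar exhausted; lower n")
        skeleton = _random_skeleton(rng)
        smiles = "OC(=O)" + skeleton if carry[len(out)] else skeleton
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:  # pragma: no cover - grammar guarantees validity
            continue
        canonical = Chem.MolToSmiles(mol)
        if canonical in seen:
            continue
        seen.add(canonical)
        out.append(canonical)
    return out


def generate_proteins(n: int, length_range: tuple[int, int] = (40, 60),
                      motif_fraction: float = 0.7, motif: str = "HKWW",
                      seed: int = 0) -> list[str]:
    """``n`` distinct random sequences; a stratified fraction contains the
    motif at one uniformly random position, the rest are guaranteed
    motif-free."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if length_range[0] < len(motif):
        raise ValueError("motif longer than minimum sequence length")
    rng = np.random.default_rng(seed)
    carry = _stratified_flags(n, motif_fraction, rng)
    alphabet = list(AMINO_ACIDS)
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        seq = "".join(rng.choice(alphabet, size=length))
        if carry[len(out)]:
            pos = int(rng.integers(0, length - len(motif) + 1))
            seq = seq[:pos] + motif + seq[pos + len(motif):]
        elif motif in seq:
            continue  # resample the rare accidental motif carrier
        if seq in seen:
            continue
        seen.add(seq)
        out.append(seq)
    return out


def plant_interactions(molecules: list[str], proteins: list[str],
                       config: SyntheticConfig
                       ) -> tuple[DTIDataset, pd.DataFrame]:
    """Sample pairs without replacement and label them by the planted rule.

    Returns the dataset and a ground-truth sidecar with one row per record:
    ``record_id``, ``rule_label`` (flip-free) and ``flipped``.
    """
    if not molecules or not proteins:
        raise ValueError("molecule and protein pools must be non-empty")
    n_total = len(molecules) * len(proteins)
    if config.n_pairs > n_total:
        raise ValueError(
            f"n_pairs={config.n_pairs} exceeds {n_total} distinct pairs")
    rng = np.random.default_rng(config.seed + 17)
    flat = rng.choice(n_total, size=config.n_pairs, replace=False)
    has_pharm = {m: molecule_matches(m, config.pharmacophore) for m in molecules}
    records: list[DTIRecord] = []
    truth_rows = []
    for i, idx in enumerate(flat):
        mol = molecules[idx // len(proteins)]
        prot = proteins[idx % len(proteins)]
        rule = int(has_pharm[mol] and config.motif in prot)
        flip = rng.random() < config.label_noise
        label = rule ^ flip
        rid = f"r{i:06d}"
        records.append(DTIRecord(rid, mol, prot, float(label)))
        truth_rows.append({"record_id": rid, "rule_label": rule,
                           "flipped": int(flip)})
    return (DTIDataset(records, task="classification"),
            pd.DataFrame(truth_rows))


def generate_dataset(config: SyntheticConfig | None = None
                     ) -> tuple[DTIDataset, pd.DataFrame]:
    """One-call generator: molecule pool, protein pool, planted pairs."""
    config = config or SyntheticConfig()
    molecules = generate_molecules(config.n_molecules, config.seed,
                                   config.pharmacophore_fraction,
                                   config.pharmacophore)
    proteins = generate_proteins(config.n_proteins, config.protein_length,
                                 config.motif_fraction, config.motif,
                                 config.seed + 1)
    return plant_interactions(molecules, proteins, config)


def write_ground_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False)
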