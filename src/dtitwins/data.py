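"""Dataset model and I/O for drug-target interaction (DTI) tables.

A dataset is an ordered collection of (molecule, protein, label) records with
an optional train/valid/test split assignment.  Molecules are SMILES strings,
proteins are amino-acid sequences over the 20 standard residues plus the
placeholder ``X``.  Labels are either binary interaction flags
(``task="classification"``) or real-valued affinities (``task="regression"``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Optional

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: The 20 standard amino acids in alphabetical one-letter order.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)
#: Non-standard residue codes collapsed to the placeholder X.
_NONSTANDARD = set("BJOUZ")

Task = Literal["classification", "regression"]
SplitName = Literal["train", "valid", "test"]


class MoleculeRejected(ValueError):
    """Raised when a SMILES string cannot be parsed or curated."""


class SplitSizingError(ValueError):
    """Raised when a requested split cannot be realised on the given data."""


def sanitize_sequence(sequence: str) -> str:
    """Upper-case a protein sequence and map non-standard residues to ``X``.

    Raises ``ValueError`` for characters outside the amino-acid alphabet,
    placeholder and whitespace.
    """
    seq = sequence.strip().upper()
    out = []
    for ch in seq:
        if ch in _AA_SET or ch == "X":
            out.append(ch)
        elif ch in _NONSTANDARD:
            out.append("X")
        else:
            raise ValueError(f"invalid residue {ch!r} in sequence")
    if not out:
        raise ValueError("empty protein sequence")
    return "".join(out)


_LARGEST_FRAGMENT = rdMolStandardize.LargestFragmentChooser()
_UNCHARGER = rdMolStandardize.Uncharger()


def clean_molecule(smiles: str) -> str:
    """Curate a SMILES string into a canonical form.

    The cascade is: parse, keep the largest organic fragment, neutralise
    simple charges, canonicalise.  This approximates the published ChEMBL
    structure-curation pipeline with deterministic RDKit primitives.

    Raises :class:`MoleculeRejected` for unparseable input.  Cleaning is
    idempotent: ``clean_molecule(clean_molecule(s)) == clean_molecule(s)``.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise MoleculeRejected("empty SMILES")
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        raise MoleculeRejected(f"unparseable SMILES: {smiles!r}")
    try:
        mol = _LARGEST_FRAGMENT.choose(mol)
        mol = _UNCHARGER.uncharge(mol)
        Chem.SanitizeMol(mol)
    except Exception as exc:  # pragma: no cover - standardiser edge cases
        raise MoleculeRejected(f"curation failed for {smiles!r}: {exc}") from exc
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class DTIRecord:
    """One molecule/protein pair with an interaction label."""

    record_id: str
    molecule_smiles: str
    protein_sequence: str
    label: float

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "protein_sequence", sanitize_sequence(self.protein_sequence)
        )


@dataclass(frozen=True)
class SplitScheme:
    """How to partition a dataset into train/valid/test.

    ``kind`` is ``random`` (over records), ``unseen_ligand`` (molecules are
    partitioned; no test molecule appears in train or valid) or
    ``unseen_protein`` (likewise over protein sequences).
    """

    kind: Literal["random", "unseen_ligand", "unseen_protein"] = "random"
    fractions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if any(f < 0 for f in self.fractions):
            raise ValueError("split fractions must be non-negative")


@dataclass
class DTIDataset:
    """Ordered DTI records with a task and an optional split assignment."""

    records: list[DTIRecord]
    task: Task = "classification"
    split_assignment: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([r.label for r in self.records], dtype=float)

    def subset(self, split: SplitName) -> "DTIDataset":
        """Records assigned to one split, original order preserved."""
        recs = [r for r in self.records if self.split_assignment.get(r.record_id) == split]
        assignment = {r.record_id: split for r in recs}
        return DTIDataset(recs, task=self.task, split_assignment=assignment)

    def molecules(self) -> list[str]:
        return [r.molecule_smiles for r in self.records]

    def proteins(self) -> list[str]:
        return [r.protein_sequence for r in self.records]


def clean_dataset(dataset: DTIDataset) -> tuple[DTIDataset, int]:
    """Run :func:`clean_molecule` over every record, dropping rejections.

    Returns the cleaned dataset and the number of dropped records.
    """
    kept: list[DTIRecord] = []
    dropped = 0
    for rec in dataset.records:
        try:
            smiles = clean_molecule(rec.molecule_smiles)
        except MoleculeRejected:
            dropped += 1
            continue
        kept.append(replace(rec, molecule_smiles=smiles))
    if dropped:
        logger.info("clean_dataset dropped %d unparseable records", dropped)
    kept_ids = {r.record_id for r in kept}
    assignment = {rid: s for rid, s in dataset.split_assignment.items()
                  if rid in kept_ids}
    return DTIDataset(kept, task=dataset.task, split_assignment=assignment), dropped


def deduplicate(dataset: DTIDataset) -> tuple[DTIDataset, int]:
    """Keep the first occurrence of each (canonical molecule, sequence) pair.

    Returns the deduplicated dataset and the number of label conflicts seen
    among duplicates (duplicates whose label differs from the kept record's).
    """
    seen: dict[tuple[str, str], float] = {}
    kept: list[DTIRecord] = []
    conflicts = 0
    for rec in dataset.records:
        key = (rec.molecule_smiles, rec.protein_sequence)
        if key in seen:
            if rec.label != seen[key]:
                conflicts += 1
            continue
        seen[key] = rec.label
        kept.append(rec)
    if conflicts:
        logger.info("deduplicate found %d label conflicts", conflicts)
    assignment = {r.record_id: dataset.split_assignment[r.record_id]
                  for r in kept if r.record_id in dataset.split_assignment}
    return DTIDataset(kept, task=dataset.task, split_assignment=assignment), conflicts


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    n_train = int(round(n * fractions[0]))
    n_valid = int(round(n * fractions[1]))
    n_train = min(n_train, n)
    n_valid = min(n_valid, n - n_train)
    return n_train, n_valid, n - n_train - n_valid


def make_splits(dataset: DTIDataset, scheme: SplitScheme) -> DTIDataset:
    """Assign every record to train/valid/test according to ``scheme``.

    Cold splits (``unseen_ligand`` / ``unseen_protein``) partition the unique
    entities and map the assignment back to records, which is the only
    construction guaranteeing that no test entity occurs in train or valid.
    Deterministic for a fixed seed.
    """
    if len(dataset) == 0:
        raise SplitSizingError("cannot split an empty dataset")
    rng = np.random.default_rng(scheme.seed)
    if scheme.kind == "random":
        order = rng.permutation(len(dataset))
        n_train, n_valid, _ = _partition_sizes(len(dataset), scheme.fractions)
        names = np.empty(len(dataset), dtype=object)
        names[order[:n_train]] = "train"
        names[order[n_train:n_train + n_valid]] = "valid"
        names[order[n_train + n_valid:]] = "test"
        assignment = {rec.record_id: names[i] for i, rec in enumerate(dataset.records)}
    else:
        key = (lambda r: r.molecule_smiles) if scheme.kind == "unseen_ligand" \
            else (lambda r: r.protein_sequence)
        entities = sorted({key(r) for r in dataset.records})
        if len(entities) < 3:
            raise SplitSizingError(
                f"{scheme.kind} split needs >=3 unique entities, got {len(entities)}"
            )
        order = rng.permutation(len(entities))
        n_train, n_valid, _ = _partition_sizes(len(entities), scheme.fractions)
        entity_split: dict[str, str] = {}
        for pos, idx in enumerate(order):
            name = "train" if pos < n_train else (
                "valid" if pos < n_train + n_valid else "test")
            entity_split[entities[idx]] = name
        assignment = {rec.record_id: entity_split[key(rec)] for rec in dataset.records}
    return DTIDataset(list(dataset.records), task=dataset.task,
                      split_assignment=assignment)


def random_undersample(dataset: DTIDataset, ratio_neg_to_pos: float,
                       seed: int) -> DTIDataset:
    """Subsample negatives so that ``#neg <= ratio * #pos``.

    Positives are untouched; retained negatives are drawn uniformly without
    replacement.  Record order is preserved.
    """
    if ratio_neg_to_pos <= 0:
        raise ValueError("ratio_neg_to_pos must be positive")
    if dataset.task != "classification":
        raise ValueError("undersampling requires a classification task")
    labels = dataset.labels
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if len(pos_idx) == 0 or len(neg_idx) == 0:
        raise ValueError("both classes must be present")
    n_keep = int(ratio_neg_to_pos * len(pos_idx))
    if len(neg_idx) <= n_keep:
        return dataset
    rng = np.random.default_rng(seed)
    kept_neg = set(rng.choice(neg_idx, size=n_keep, replace=False).tolist())
    keep = sorted(set(pos_idx.tolist()) | kept_neg)
    recs = [dataset.records[i] for i in keep]
    assignment = {r.record_id: dataset.split_assignment[r.record_id]
                  for r in recs if r.record_id in dataset.split_assignment}
    return DTIDataset(recs, task=dataset.task, split_assignment=assignment)


# ---------------------------------------------------------------------------
# Delimited-text I/O


def write_dti_table(dataset: DTIDataset, path: str | Path, sep: str = ",") -> None:
    """Write a dataset as a delimited table (columns: record_id, smiles,
    sequence, label and, when assigned, split)."""
    rows = {
        "record_id": [r.record_id for r in dataset.records],
        "smiles": [r.molecule_smiles for r in dataset.records],
        "sequence": [r.protein_sequence for r in dataset.records],
        "label": [r.label for r in dataset.records],
    }
    df = pd.DataFrame(rows)
    if dataset.split_assignment:
        df["split"] = [dataset.split_assignment.get(r.record_id, "")
                       for r in dataset.records]
    df.to_csv(path, sep=sep, index=False)


def read_dti_table(path: str | Path, task: Task = "classification",
                   sep: Optional[str] = None) -> DTIDataset:
    """Read a delimited DTI table (comma or tab, auto-detected by default).

    Required columns: ``smiles``, ``sequence``, ``label``; optional
    ``record_id`` (generated as row numbers when absent) and ``split``.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = {"smiles", "sequence", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"DTI table missing columns: {sorted(missing)}")
    if "record_id" not in df.columns:
        df["record_id"] = [f"r{i:06d}" for i in range(len(df))]
    records = [
        DTIRecord(str(row.record_id), str(row.smiles), str(row.sequence),
                  float(row.label))
        for row in df.itertuples()
    ]
    assignment = {}
    if "split" in df.columns:
        assignment = {
            str(rid): str(s) for rid, s in zip(df["record_id"], df["split"])
            if isinstance(s, str) and s in ("train", "valid", "test")
        }
    return DTIDataset(records, task=task, split_assignment=assignment)


def write_split_file(dataset: DTIDataset, path: str | Path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {"record_id": list(dataset.split_assignment),
         "split": list(dataset.split_assignment.values())}
    )
    df.to_csv(path, sep=sep, index=False)


def read_split_file(path: str | Path, sep: str = "\t") -> dict[str, str]:
    df = pd.read_csv(path, sep=sep)
    return {str(r): str(s) for r, s in zip(df["record_id"], df["split"])}


def attach_split(dataset: DTIDataset, assignment: dict[str, str]) -> DTIDataset:
    """Attach an externally defined split assignment."""
    known = {r.record_id for r in dataset.records}
    unknown = set(assignment) - known
    if unknown:
        raise ValueError(f"split file names unknown records: {sorted(unknown)[:5]}")
    return DTIDataset(list(dataset.records), task=dataset.task,
                      split_assignment=dict(assignment))
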