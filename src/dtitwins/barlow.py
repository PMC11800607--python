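"""Cross-modal Barlow Twins network for drug-target pairs.

Two MLP encoders (one per modality: molecule fingerprint, protein vector)
feed a shared projector.  Training drives the batch cross-correlation matrix
between the two projections toward the identity:

    L_BT = sum_i (1 - C_ii)^2  +  lambda * sum_{i != j} C_ij^2

with

    C_ij = sum_b zA[b,i] zB[b,j] / (||zA[:,i]|| * ||zB[:,j]||)

an *uncentered* cosine similarity along the batch axis.  The diagonal term
makes the two modalities' projections of one interaction agree
(invariance); the off-diagonal term decorrelates feature dimensions
(redundancy reduction).  After training, the projector is discarded for
inference: a record's joint embedding is the concatenation of the two
encoder outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .featurize import FeatureBundle
from .nn import AdamW, Sequential, StepLR, mlp_stack


class DegenerateBatchError(ValueError):
    """A projection column has zero norm; the correlation is undefined."""


@dataclass
class BTConfig:
    """Network and training configuration.

    Defaults are the selected full-scale values; tests and the synthetic
    pipeline pass reduced sizes.  ``loss_weight`` is the lambda trading off
    invariance against redundancy reduction.  ``batch_size`` is capped at
    the training-set size; trailing batches of size 1 are dropped because
    the batch-axis normaliser needs at least two rows.
    """

    enc_n_neurons: int = 4096
    enc_n_layers: int = 3
    proj_n_neurons: int = 2048
    proj_n_layers: int = 1
    embedding_dim: int = 512
    loss_weight: float = 0.005
    batch_size: int = 4096
    epochs: int = 250
    learning_rate: float = 3e-4
    betas: tuple[float, float] = (0.9, 0.999)
    weight_decay: float = 5e-5
    step_size: int = 10
    gamma: float = 0.1
    val_fraction: float = 0.15
    patience: int = 10
    seed: int = 0
    center_projections: bool = False
    corr_eps: float = 1e-12

    def __post_init__(self) -> None:
        if self.loss_weight <= 0:
            raise ValueError("loss_weight must be positive")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")
        for name in ("enc_n_neurons", "enc_n_layers", "proj_n_neurons",
                     "proj_n_layers", "embedding_dim", "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


def cross_correlation(zA: np.ndarray, zB: np.ndarray, eps: float = 0.0,
                      center: bool = False) -> np.ndarray:
    """Batch cross-correlation matrix C between two projection batches.

    ``C[i, j]`` is the uncentered cosine similarity between column ``i`` of
    ``zA`` and column ``j`` of ``zB`` along the batch axis.  Every entry lies
    in [-1, 1] by Cauchy-Schwarz.  ``center=True`` opts into subtracting the
    per-column batch mean first (the original Barlow Twins normalisation);
    the default matches the uncentered definition used here.

    Raises :class:`DegenerateBatchError` when a column norm vanishes and
    ``eps`` is 0.
    """
    zA = np.asarray(zA, dtype=np.float64)
    zB = np.asarray(zB, dtype=np.float64)
    if zA.shape != zB.shape:
        raise ValueError(f"shape mismatch: {zA.shape} vs {zB.shape}")
    if zA.ndim != 2 or zA.shape[0] < 2:
        raise ValueError("projection batches must be 2-d with batch >= 2")
    if center:
        zA = zA - zA.mean(axis=0)
        zB = zB - zB.mean(axis=0)
    na = np.sqrt((zA ** 2).sum(axis=0))
    nb = np.sqrt((zB ** 2).sum(axis=0))
    if eps == 0.0 and (np.any(na == 0) or np.any(nb == 0)):
        raise DegenerateBatchError("zero-norm projection column in batch")
    return (zA.T @ zB) / np.outer(na + eps, nb + eps)


def bt_loss(C: np.ndarray, loss_weight: float) -> float:
    """Barlow Twins loss of a cross-correlation matrix.

    Invariance term: squared deviation of the diagonal from 1.  Redundancy
    reduction term: ``loss_weight`` times the sum of squared off-diagonal
    entries.  Zero exactly when C is the identity.
    """
    C = np.asarray(C, dtype=np.float64)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("C must be square")
    diag = np.diagonal(C)
    off = C - np.diag(diag)
    return float(((1.0 - diag) ** 2).sum() + loss_weight * (off ** 2).sum())


def _bt_loss_and_grads(zA: np.ndarray, zB: np.ndarray, loss_weight: float,
                       eps: float) -> tuple[float, np.ndarray, np.ndarray]:
    """Loss plus analytic gradients with respect to both projection batches."""
    na = np.sqrt((zA ** 2).sum(axis=0))
    nb = np.sqrt((zB ** 2).sum(axis=0))
    if eps == 0.0 and (np.any(na == 0) or np.any(nb == 0)):
        raise DegenerateBatchError("zero-norm projection column in batch")
    a_hat = zA / (na + eps)
    b_hat = zB / (nb + eps)
    C = a_hat.T @ b_hat
    diag = np.diagonal(C)
    loss = float(((1.0 - diag) ** 2).sum()
                 + loss_weight * ((C - np.diag(diag)) ** 2).sum())
    # dL/dC: diagonal -2(1-C_ii), off-diagonal 2*lambda*C_ij
    S = 2.0 * loss_weight * C
    np.fill_diagonal(S, -2.0 * (1.0 - diag))
    g_a_hat = b_hat @ S.T
    g_b_hat = a_hat @ S
    # back through the column normalisation x_hat = x / ||x||
    gA = (g_a_hat - a_hat * (a_hat * g_a_hat).sum(axis=0)) / (na + eps)
    gB = (g_b_hat - b_hat * (b_hat * g_b_hat).sum(axis=0)) / (nb + eps)
    return loss, gA, gB


@dataclass
class BTModel:
    """Twin encoders plus the shared projector, with training history."""

    mol_encoder: Sequential
    prot_encoder: Sequential
    projector: Sequential
    config: BTConfig
    mol_dim: int
    prot_dim: int
    history: dict[str, list[float]] = field(
        default_factory=lambda: {"train_loss": [], "valid_loss": []})

    # -- parameter plumbing -------------------------------------------------
    @property
    def params(self) -> list[np.ndarray]:
        return (self.mol_encoder.params + self.prot_encoder.params
                + self.projector.params)

    def set_params(self, values: list[np.ndarray]) -> None:
        n1 = len(self.mol_encoder.params)
        n2 = len(self.prot_encoder.params)
        self.mol_encoder.set_params(values[:n1])
        self.prot_encoder.set_params(values[n1:n1 + n2])
        self.projector.set_params(values[n1 + n2:])

    @property
    def buffers(self) -> list[np.ndarray]:
        return (self.mol_encoder.buffers + self.prot_encoder.buffers
                + self.projector.buffers)

    def set_buffers(self, values: list[np.ndarray]) -> None:
        n1 = len(self.mol_encoder.buffers)
        n2 = len(self.prot_encoder.buffers)
        self.mol_encoder.set_buffers(values[:n1])
        self.prot_encoder.set_buffers(values[n1:n1 + n2])
        self.projector.set_buffers(values[n1 + n2:])

    def snapshot(self) -> tuple[list[np.ndarray], list[np.ndarray]]:
        return ([p.copy() for p in self.params], [b.copy() for b in self.buffers])

    def restore(self, snap: tuple[list[np.ndarray], list[np.ndarray]]) -> None:
        self.set_params([p.copy() for p in snap[0]])
        self.set_buffers([b.copy() for b in snap[1]])

    # -- inference ----------------------------------------------------------
    def encode(self, bundle: FeatureBundle) -> np.ndarray:
        """Joint embeddings: ``[drug embedding || target embedding]`` rows.

        Inference mode (batch-norm running statistics), so the output for a
        record does not depend on what else is in the batch.
        """
        if bundle.molecule.shape[1] != self.mol_dim:
            raise ValueError(
                f"molecule dim {bundle.molecule.shape[1]} != model {self.mol_dim}")
        if bundle.protein.shape[1] != self.prot_dim:
            raise ValueError(
                f"protein dim {bundle.protein.shape[1]} != model {self.prot_dim}")
        em, _ = self.mol_encoder.forward(bundle.molecule, training=False)
        ep, _ = self.prot_encoder.forward(bundle.protein, training=False)
        return np.concatenate([em, ep], axis=1)

    def project(self, bundle: FeatureBundle, training: bool = False
                ) -> tuple[np.ndarray, np.ndarray]:
        """Projector outputs for both pathways (loss-side view)."""
        em, _ = self.mol_encoder.forward(bundle.molecule, training)
        ep, _ = self.prot_encoder.forward(bundle.protein, training)
        zA, _ = self.projector.forward(em, training)
        zB, _ = self.projector.forward(ep, training)
        return zA, zB

    # -- persistence ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        lines = []
        for key, value in asdict(self.config).items():
            if isinstance(value, tuple):
                value = ",".join(str(v) for v in value)
            lines.append(f"{key} = {value}")
        lines.append(f"mol_dim = {self.mol_dim}")
        lines.append(f"prot_dim = {self.prot_dim}")
        (directory / "config.txt").write_text("\n".join(lines) + "\n")
        arrays = {f"param_{i:04d}": p for i, p in enumerate(self.params)}
        arrays.update({f"buffer_{i:04d}": b for i, b in enumerate(self.buffers)})
        np.savez(directory / "params.npz", **arrays)

    @classmethod
    def load(cls, directory: str | Path) -> "BTModel":
        directory = Path(directory)
        kv: dict[str, str] = {}
        for line in (directory / "config.txt").read_text().splitlines():
            if "=" in line:
                key, _, value = line.partition("=")
                kv[key.strip()] = value.strip()
        mol_dim = int(kv.pop("mol_dim"))
        prot_dim = int(kv.pop("prot_dim"))
        kwargs: dict = {}
        for f_ in BTConfig.__dataclass_fields__.values():
            raw = kv.get(f_.name)
            if raw is None:
                continue
            if f_.name == "betas":
                kwargs["betas"] = tuple(float(v) for v in raw.split(","))
            elif f_.type == "bool" or isinstance(f_.default, bool):
                kwargs[f_.name] = raw == "True"
            elif isinstance(f_.default, int):
                kwargs[f_.name] = int(raw)
            else:
                kwargs[f_.name] = float(raw)
        model = build_model(mol_dim, prot_dim, BTConfig(**kwargs))
        with np.load(directory / "params.npz") as data:
            params = [data[k] for k in sorted(k for k in data.files
                                              if k.startswith("param_"))]
            buffers = [data[k] for k in sorted(k for k in data.files
                                               if k.startswith("buffer_"))]
        model.set_params(params)
        model.set_buffers(buffers)
        return model


def build_model(mol_dim: int, prot_dim: int, config: BTConfig) -> BTModel:
    """Construct the twin network with seeded parameter initialisation."""
    if mol_dim < 1 or prot_dim < 1:
        raise ValueError("input dimensions must be >= 1")
    rng = np.random.default_rng(config.seed)
    mol_enc = mlp_stack(mol_dim, config.enc_n_neurons, config.enc_n_layers,
                        config.embedding_dim, rng)
    prot_enc = mlp_stack(prot_dim, config.enc_n_neurons, config.enc_n_layers,
                         config.embedding_dim, rng)
    projector = mlp_stack(config.embedding_dim, config.proj_n_neurons,
                          config.proj_n_layers, config.proj_n_neurons, rng)
    return BTModel(mol_enc, prot_enc, projector, config, mol_dim, prot_dim)


def _forward_backward(model: BTModel, mol: np.ndarray, prot: np.ndarray
                      ) -> tuple[float, list[np.ndarray]]:
    """One training-mode forward/backward pass; grads aligned with params."""
    cfg = model.config
    em, cache_m = model.mol_encoder.forward(mol, training=True)
    ep, cache_p = model.prot_encoder.forward(prot, training=True)
    zA, cache_projA = model.projector.forward(em, training=True)
    zB, cache_projB = model.projector.forward(ep, training=True)
    if cfg.center_projections:
        zA = zA - zA.mean(axis=0)
        zB = zB - zB.mean(axis=0)
    loss, gA, gB = _bt_loss_and_grads(zA, zB, cfg.loss_weight, cfg.corr_eps)
    if cfg.center_projections:
        gA = gA - gA.mean(axis=0)
        gB = gB - gB.mean(axis=0)
    g_em, gradsA = model.projector.backward(gA, cache_projA)
    g_ep, gradsB = model.projector.backward(gB, cache_projB)
    proj_grads = [a + b for a, b in zip(gradsA, gradsB)]
    _, mol_grads = model.mol_encoder.backward(g_em, cache_m)
    _, prot_grads = model.prot_encoder.backward(g_ep, cache_p)
    return loss, mol_grads + prot_grads + proj_grads


def validation_loss(model: BTModel, bundle: FeatureBundle) -> float:
    """L_BT of the projections in inference mode over one full batch."""
    zA, zB = model.project(bundle, training=False)
    C = cross_correlation(zA, zB, eps=model.config.corr_eps,
                          center=model.config.center_projections)
    return bt_loss(C, model.config.loss_weight)


def train(model: BTModel, bundle: FeatureBundle) -> BTModel:
    """Self-supervised pretraining on paired features (labels unused).

    The record set is split into train/validation by the configured
    fraction; minibatches minimise L_BT with AdamW and a step learning-rate
    decay.  Training stops at the epoch limit or once the validation loss
    has not improved for ``patience`` epochs, and the best-validation
    parameters are restored.  Fully deterministic for a fixed config seed.
    """
    cfg = model.config
    n = len(bundle.record_ids)
    if n < 4:
        raise ValueError("need at least 4 records for a train/validation split")
    rng = np.random.default_rng(cfg.seed + 1)
    order = rng.permutation(n)
    n_valid = max(2, int(round(cfg.val_fraction * n)))
    if n - n_valid < 2:
        raise ValueError("training split too small after validation holdout")
    valid_idx = order[:n_valid]
    train_idx = order[n_valid:]
    train_bundle = bundle.subset(train_idx)
    valid_bundle = bundle.subset(valid_idx)

    optimizer = AdamW(model.params, lr=cfg.learning_rate, betas=cfg.betas,
                      weight_decay=cfg.weight_decay)
    scheduler = StepLR(optimizer, cfg.step_size, cfg.gamma)
    batch_size = min(cfg.batch_size, len(train_idx))

    best_loss = np.inf
    best_snap = model.snapshot()
    epochs_since_improve = 0
    for epoch in range(cfg.epochs):
        scheduler.set_epoch(epoch)
        perm = rng.permutation(len(train_idx))
        epoch_losses = []
        for start in range(0, len(perm), batch_size):
            batch = perm[start:start + batch_size]
            if len(batch) < 2:
                continue  # correlation undefined for a single row
            loss, grads = _forward_backward(
                model, train_bundle.molecule[batch], train_bundle.protein[batch])
            optimizer.step(grads)
            epoch_losses.append(loss)
        val_loss = validation_loss(model, valid_bundle)
        model.history["train_loss"].append(float(np.mean(epoch_losses)))
        model.history["valid_loss"].append(val_loss)
        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_snap = model.snapshot()
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
            if epochs_since_improve > cfg.patience:
                break
    model.restore(best_snap)
    return model


def encode(model: BTModel, bundle: FeatureBundle) -> np.ndarray:
    """Functional alias for :meth:`BTModel.encode`."""
    return model.encode(bundle)
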