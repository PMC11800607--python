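"""End-to-end pipeline: synthetic data -> features -> twin network ->
boosted head -> metrics and influence.

This is the orchestration layer the command-line interface, the replicate
benchmark and the acceptance checks share.  One master seed drives data
generation, splitting, network initialisation and shuffling, the
hyperparameter sampler and the tree ensemble, which makes whole-pipeline
reruns bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import stats
from .barlow import BTConfig, BTModel, build_model, train
from .data import DTIDataset, SplitScheme, make_splits
from .featurize import FeatureBundle, featurize_dataset
from .gbm import FeatureRecipe, HybridModel, OptimizationResult, fit_hybrid
from .influence import rank_influential
from .synthetic import SyntheticConfig, generate_dataset


def desk_bt_config(seed: int = 0, **overrides) -> BTConfig:
    """Reduced twin-network configuration for desk-scale experiments."""
    defaults = dict(enc_n_neurons=256, enc_n_layers=2, proj_n_neurons=256,
                    proj_n_layers=1, embedding_dim=64, batch_size=256,
                    epochs=50, patience=5, seed=seed)
    defaults.update(overrides)
    return BTConfig(**defaults)


@dataclass
class PipelineResult:
    dataset: DTIDataset
    truth: pd.DataFrame
    bundle: FeatureBundle
    bt_model: BTModel | None
    hybrid: HybridModel
    optimization: OptimizationResult | None
    test_labels: np.ndarray
    test_scores: np.ndarray
    metrics: dict[str, float]


def _split_indices(dataset: DTIDataset) -> dict[str, np.ndarray]:
    names = [dataset.split_assignment[r.record_id] for r in dataset.records]
    arr = np.asarray(names)
    return {s: np.flatnonzero(arr == s) for s in ("train", "valid", "test")}


def run_pipeline(seed: int,
                 synthetic_config: SyntheticConfig | None = None,
                 split_scheme: SplitScheme | None = None,
                 bt_config: BTConfig | None = None,
                 recipe: FeatureRecipe = "embeddings",
                 optimize: bool = True,
                 n_trials: int = 25,
                 l_max: int = 64,
                 fingerprint_bits: int = 1024,
                 fingerprint_radius: int = 2) -> PipelineResult:
    """Run the whole method once on a synthetic benchmark.

    ``recipe`` and ``optimize`` select one of the four ablation variants:
    the full model (embeddings + optimised head), embeddings with the
    default head, raw concatenation with the optimised head, and raw
    concatenation with the default head.
    """
    syn = synthetic_config or SyntheticConfig(seed=seed)
    if syn.seed != seed:
        syn = replace(syn, seed=seed)
    dataset, truth = generate_dataset(syn)
    scheme = split_scheme or SplitScheme(kind="random", seed=seed)
    dataset = make_splits(dataset, scheme)
    bundle = featurize_dataset(dataset, n_bits=fingerprint_bits,
                               radius=fingerprint_radius, l_max=l_max)
    idx = _split_indices(dataset)
    labels = dataset.labels
    train_bundle = bundle.subset(idx["train"])
    valid_bundle = bundle.subset(idx["valid"])
    test_bundle = bundle.subset(idx["test"])

    bt_model = None
    if recipe == "embeddings":
        cfg = bt_config or desk_bt_config(seed)
        if cfg.seed != seed:
            cfg = replace(cfg, seed=seed)
        bt_model = build_model(bundle.molecule.shape[1],
                               bundle.protein.shape[1], cfg)
        bt_model = train(bt_model, train_bundle)

    hybrid, opt = fit_hybrid(bt_model, train_bundle, labels[idx["train"]],
                             task=dataset.task, recipe=recipe,
                             valid_bundle=valid_bundle,
                             valid_labels=labels[idx["valid"]],
                             optimize=optimize, n_trials=n_trials, seed=seed)
    test_labels = labels[idx["test"]]
    test_scores = hybrid.predict(test_bundle)
    metrics = {"roc_auc": stats.roc_auc(test_labels, test_scores),
               "pr_auc": stats.pr_auc(test_labels, test_scores)}
    return PipelineResult(dataset, truth, bundle, bt_model, hybrid, opt,
                          test_labels, test_scores, metrics)


ABLATION_VARIANTS: dict[str, tuple[FeatureRecipe, bool]] = {
    "full": ("embeddings", True),
    "embeddings_default": ("embeddings", False),
    "concat_optimized": ("concat", True),
    "concat_default": ("concat", False),
}


def run_ablation_lattice(seed: int, n_trials: int = 10,
                         synthetic_config: SyntheticConfig | None = None,
                         bt_config: BTConfig | None = None,
                         ) -> dict[str, PipelineResult]:
    """All four ablation variants on the same seed and fixture."""
    return {
        name: run_pipeline(seed, synthetic_config=synthetic_config,
                           bt_config=bt_config, recipe=recipe,
                           optimize=optimize, n_trials=n_trials)
        for name, (recipe, optimize) in ABLATION_VARIANTS.items()
    }


def benchmark_replicates(seeds: list[int], variants: list[str] | None = None,
                         n_trials: int = 10,
                         alpha: float = 0.001) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate runs of selected variants plus the comparison table.

    Returns (per-replicate metric table, Welch/BH comparison table).
    """
    variants = variants or list(ABLATION_VARIANTS)
    reports = []
    rows = []
    for variant in variants:
        recipe, optimize = ABLATION_VARIANTS[variant]
        for rep, seed in enumerate(seeds):
            result = run_pipeline(seed, recipe=recipe, optimize=optimize,
                                  n_trials=n_trials)
            reports.append(stats.classification_report(
                variant, rep, result.test_labels, result.test_scores))
            for metric, value in result.metrics.items():
                rows.append({"model": variant, "replicate": rep,
                             "seed": seed, "metric": metric, "value": value})
    comparison = stats.compare_models(reports, alpha=alpha)
    return pd.DataFrame(rows), comparison


def influence_for_query(result: PipelineResult, query_index: int,
                        top_k: int = 10):
    """Rank training records by influence on one test-set query."""
    idx = _split_indices(result.dataset)
    train_feats = result.hybrid.features(result.bundle.subset(idx["train"]))
    query_feats = result.hybrid.features(
        result.bundle.subset(idx["test"][[query_index]]))
    train_ids = [result.bundle.record_ids[i] for i in idx["train"]]
    return rank_influential(result.hybrid.ensemble, train_feats, train_ids,
                            query_feats, top_k=top_k)
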