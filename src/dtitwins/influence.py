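"""Training-sample influence via leaf-index Jaccard similarity.

Every sample routed through a trained tree ensemble lands in one leaf per
tree; the vector of those leaf identifiers characterises how the ensemble
"sees" the sample.  A query's most influential training samples are the
ones whose leaf-index vectors are most similar, measured by Jaccard
similarity of the vectors read as sets of (tree position, leaf id) pairs:
with m matching positions out of T trees,

    J(A, B) = |A n B| / |A u B| = m / (2T - m),

so J = 1 exactly for identical vectors and raw leaf ids from different
trees can never collide spuriously.  An alternative "matching fraction"
m / T is exposed via ``method="fraction"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def leaf_indices(ensemble, features: np.ndarray) -> np.ndarray:
    """Leaf-index matrix: one row per sample, one column per tree."""
    features = np.asarray(features)
    if features.ndim != 2:
        raise ValueError("features must be 2-d")
    if features.shape[1] != ensemble.n_features_in_:
        raise ValueError(
            f"feature dim {features.shape[1]} != ensemble {ensemble.n_features_in_}")
    return np.asarray(ensemble.apply(features))


def jaccard_similarity(A: np.ndarray, B: np.ndarray,
                       method: Literal["pairs", "fraction"] = "pairs") -> float:
    """Jaccard similarity of two leaf-index vectors of equal length T."""
    A = np.asarray(A).ravel()
    B = np.asarray(B).ravel()
    if A.shape != B.shape:
        raise ValueError(f"length mismatch: {A.shape} vs {B.shape}")
    T = len(A)
    m = int((A == B).sum())
    if method == "fraction":
        return m / T
    return m / (2 * T - m)


@dataclass(frozen=True)
class InfluenceScore:
    record_id: str
    similarity: float


def rank_influential(ensemble, train_features: np.ndarray,
                     train_ids: list[str], query_features: np.ndarray,
                     top_k: int = 10,
                     method: Literal["pairs", "fraction"] = "pairs",
                     block_size: int = 8192,
                     ) -> tuple[list[InfluenceScore], np.ndarray]:
    """Rank the training set by leaf-index similarity to one query.

    Similarities are computed in blocks over the training set so only one
    block of leaf indices is materialised at a time.  Returns the top-k list
    (descending similarity, ties broken by ascending training position) and
    the full similarity distribution for histogramming.
    """
    query_features = np.atleast_2d(np.asarray(query_features))
    if query_features.shape[0] != 1:
        raise ValueError("rank_influential takes a single query row")
    n_train = len(train_ids)
    if len(train_features) != n_train:
        raise ValueError("train_features and train_ids length mismatch")
    if top_k > n_train:
        logger.warning("top_k=%d exceeds training size %d; capping",
                       top_k, n_train)
        top_k = n_train
    query_leaves = leaf_indices(ensemble, query_features)[0]
    T = len(query_leaves)
    sims = np.empty(n_train, dtype=np.float64)
    for start in range(0, n_train, block_size):
        block = leaf_indices(ensemble, train_features[start:start + block_size])
        m = (block == query_leaves).sum(axis=1)
        if method == "fraction":
            sims[start:start + len(block)] = m / T
        else:
            sims[start:start + len(block)] = m / (2 * T - m)
    order = np.lexsort((np.arange(n_train), -sims))[:top_k]
    ranking = [InfluenceScore(train_ids[i], float(sims[i])) for i in order]
    return ranking, sims


def ranking_table(ranking: list[InfluenceScore]) -> pd.DataFrame:
    return pd.DataFrame({"record_id": [s.record_id for s in ranking],
                         "jaccard": [s.similarity for s in ranking]})
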