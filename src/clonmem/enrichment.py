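"""Condition enrichment in k-NN neighborhoods of a latent embedding.

For each cell, the k nearest neighbors (Euclidean, self excluded) are found
in an externally produced low-dimensional space (topic weights or PCs), the
observed fraction of neighbors from each condition is compared with the
expected fraction under random assignment — which is simply each condition's
global cell fraction — and enrichment is reported as observed minus
expected.  Enrichments are exactly zero-sum per cell and bounded in [-1, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_condition_enrichment", "KNNConditionEnrichment"]


def knn_condition_enrichment(embedding, labels, k: int = 100) -> dict:
    """k-NN condition enrichment per cell.

    Returns a dict with DataFrames ``observed``, ``expected`` and
    ``enrichment`` (cells x conditions) plus the neighbor index array.
    Duplicate points are handled deterministically (ties by index).
    """
    X = np.asarray(embedding, dtype=float)
    labels = np.asarray(labels)
    n = X.shape[0]
    if not 0 < k < n:
        raise ValueError("k must satisfy 0 < k < n_cells")
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("embedding must be 2-D with >= 2 dimensions")

    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    # drop self: remove the own index where present, else the farthest
    neighbors = np.empty((n, k), dtype=int)
    for i in range(n):
        row = idx[i]
        row = row[row != i]
        neighbors[i] = row[:k]

    conditions = np.unique(labels)
    code = {c: j for j, c in enumerate(conditions)}
    lab_codes = np.vectorize(code.get)(labels)
    neigh_codes = lab_codes[neighbors]
    observed = np.stack([(neigh_codes == j).mean(axis=1)
                         for j in range(len(conditions))], axis=1)
    expected = np.bincount(lab_codes, minlength=len(conditions)) / n
    enrichment = observed - expected[None, :]
    return {
        "observed": pd.DataFrame(observed, columns=conditions),
        "expected": pd.Series(expected, index=conditions),
        "enrichment": pd.DataFrame(enrichment, columns=conditions),
        "neighbors": neighbors,
    }


class KNNConditionEnrichment(BaseEstimator):
    """Estimator form of :func:`knn_condition_enrichment`.

    ``fit(embedding, labels)`` computes neighborhoods once;
    ``enrichment_``, ``observed_`` and ``expected_`` hold the results.
    """

    def __init__(self, k: int = 100):
        self.k = k

    def fit(self, embedding, labels):
        res = knn_condition_enrichment(embedding, labels, k=self.k)
        self.observed_ = res["observed"]
        self.expected_ = res["expected"]
        self.enrichment_ = res["enrichment"]
        self.neighbors_ = res["neighbors"]
        return self

    def fit_transform(self, embedding, labels) -> pd.DataFrame:
        return self.fit(embedding, labels).enrichment_
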