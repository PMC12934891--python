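"""Cross-modality label transfer in a shared embedding.

The joint embedding itself is an input (any per-cell coordinate matrix of
fixed dimension); labels move from the reference modality to query cells
by k-nearest-neighbor majority vote (k = 30 by default, Euclidean
distance), and the transfer is diagnosed by the row-normalized
contingency of predicted vs original labels (the match rate). A small
shared-feature PCA utility is provided for building embeddings in
synthetic tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

__all__ = ["knn_transfer", "match_rate", "shared_feature_pca"]


def knn_transfer(reference: np.ndarray, reference_labels, query: np.ndarray,
                 k: int = 30) -> pd.DataFrame:
    """Label query points by majority vote among k nearest reference points.

    Vote ties are broken by the smallest mean distance to the tied
    classes, then lexicographic label order, so the assignment is
    deterministic and invariant to reference ordering. Returns a frame
    with the assigned label and the winning vote count per query point.
    """
    reference = np.asarray(reference, dtype=float)
    query = np.asarray(query, dtype=float)
    labels = np.asarray(reference_labels)
    if reference.ndim != 2 or query.ndim != 2:
        raise ValueError("embeddings must be 2-D")
    if reference.shape[1] != query.shape[1]:
        raise ValueError("reference and query dimensionality differ")
    if k > len(reference):
        raise ValueError(f"k={k} exceeds reference size {len(reference)}")
    if len(labels) != len(reference):
        raise ValueError("one label per reference point required")

    nn = NearestNeighbors(n_neighbors=k).fit(reference)
    dist, idx = nn.kneighbors(query)
    assigned, votes = [], []
    for d_row, i_row in zip(dist, idx):
        neigh = labels[i_row]
        classes, counts = np.unique(neigh, return_counts=True)
        top = counts.max()
        tied = classes[counts == top]
        if len(tied) > 1:
            mean_d = {c: d_row[neigh == c].mean() for c in tied}
            best_d = min(mean_d.values())
            winner = sorted(c for c in tied
                            if np.isclose(mean_d[c], best_d))[0]
        else:
            winner = tied[0]
        assigned.append(winner)
        votes.append(int(top))
    return pd.DataFrame({"label": assigned, "votes": votes})


def match_rate(predicted, original) -> pd.DataFrame:
    """Row-normalized contingency of predicted (rows) x original (columns).

    Each row of the contingency table is divided by its sum; predicted
    classes with no cells are absent from the result rather than
    zero-filled.
    """
    predicted = np.asarray(predicted)
    original = np.asarray(original)
    if len(predicted) != len(original):
        raise ValueError("label vectors must have equal length")
    table = pd.crosstab(pd.Series(predicted, name="predicted"),
                        pd.Series(original, name="original"))
    return table.div(table.sum(axis=1), axis=0)


def shared_feature_pca(reference_features: pd.DataFrame,
                       query_features: pd.DataFrame,
                       n_components: int = 20) -> tuple:
    """Project both modalities onto PCs of their shared feature columns.

    Fits PCA on the z-scored reference restricted to the intersection of
    feature names and applies the same transform to the query; a
    convenience for constructing the joint embedding input.
    """
    shared = sorted(set(reference_features.columns)
                    & set(query_features.columns))
    if not shared:
        raise ValueError("no shared features between modalities")
    ref = reference_features[shared].to_numpy(float)
    qry = query_features[shared].to_numpy(float)
    mean, sd = ref.mean(axis=0), ref.std(axis=0)
    sd[sd == 0] = 1.0
    n_components = min(n_components, len(shared))
    pca = PCA(n_components=n_components, random_state=0)
    ref_emb = pca.fit_transform((ref - mean) / sd)
    qry_emb = pca.transform((qry - mean) / sd)
    return ref_emb, qry_emb
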