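"""Sliding-window trajectory supervectors and the shared manifold embedding.

A cell history of length T yields T - n_tau + 1 snippets of length n_tau in
a sliding-window manner (a 12-frame track gives 5 snippets of length 8:
frames 1-8, 2-9, 3-10, 4-11, 5-12).  The per-frame reduced features (PCs) of
the snippet's cells are concatenated time-ordered into a supervector of
length n_pc * n_tau.  Supervectors pooled over all treatments are embedded
with a nonlinear neighborhood-graph reducer (UMAP by default) into d
dimensions, producing the shared cell-state landscape; the same fitted model
transforms held-out supervectors for validation.

The scrambled null permutes per-cell feature rows across all (cell, frame)
slots within each treatment before snippets are rebuilt on the original
tracks, so temporal ordering carries no information while marginal feature
distributions are preserved exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SnippetSet",
    "EmbeddingModel",
    "extract_snippets",
    "build_supervectors",
    "sliding_windows",
    "fit_embedding",
    "scramble_null",
    "scramble_trajectories",
]


@dataclass
class SnippetSet:
    """All sliding-window snippets of one history collection."""

    n_tau: int
    nodes: list[tuple[tuple[int, int], ...]]  # each snippet: n_tau (frame, label) nodes
    index: pd.DataFrame  # stack_id, treatment, terminal_label, end_frame

    def __len__(self) -> int:
        return len(self.nodes)


def extract_snippets(
    histories,
    n_tau: int,
    stack_id: str = "",
    treatment: str = "",
) -> SnippetSet:
    """Extract every length-``n_tau`` sliding window from each history.

    ``histories`` is a list of time-ordered (frame, label) node lists (or
    objects with a ``trace`` attribute).  A history of length T contributes
    max(0, T - n_tau + 1) snippets; duplicated parental prefixes across
    sibling histories are kept as-is.
    """
    if n_tau < 1:
        raise ValueError("n_tau must be >= 1")
    nodes: list[tuple[tuple[int, int], ...]] = []
    rows = []
    for hist in histories:
        trace = list(getattr(hist, "trace", hist))
        T = len(trace)
        for start in range(T - n_tau + 1):
            snip = tuple(trace[start : start + n_tau])
            nodes.append(snip)
            rows.append(
                {
                    "stack_id": stack_id,
                    "treatment": treatment,
                    "terminal_label": trace[-1][1],
                    "end_frame": snip[-1][0],
                }
            )
    index = pd.DataFrame(rows, columns=["stack_id", "treatment", "terminal_label", "end_frame"])
    return SnippetSet(n_tau=n_tau, nodes=nodes, index=index)


def build_supervectors(
    sset: SnippetSet,
    features: dict[tuple[int, int], np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-frame feature vectors into snippet supervectors.

    ``features`` maps (frame, label) to the reduced feature vector of that
    cell observation.  Snippets with any missing frame are dropped (the count
    is logged).  Returns ``(X, kept)`` with ``X`` of shape
    (n_kept, n_features * n_tau) and ``kept`` the boolean keep-mask over the
    snippet set.
    """
    rows = []
    kept = np.zeros(len(sset.nodes), dtype=bool)
    for i, snip in enumerate(sset.nodes):
        try:
            vecs = [np.asarray(features[node], dtype=float) for node in snip]
        except KeyError:
            continue
        rows.append(np.concatenate(vecs))
        kept[i] = True
    dropped = int((~kept).sum())
    if dropped:
        logger.info("dropped %d snippets with missing features", dropped)
    X = np.vstack(rows) if rows else np.empty((0, 0))
    return X, kept


def sliding_windows(trajectories: np.ndarray, n_tau: int) -> np.ndarray:
    """Supervectors of dense per-cell trajectories.

    ``trajectories`` has shape (n_cells, n_frames, n_dims); the result has
    shape (n_cells, n_frames - n_tau + 1, n_dims * n_tau), the supervector of
    every sliding window, time-ordered.  This is the fast path for simulated
    feature trajectories where every cell spans every frame.
    """
    if n_tau < 1:
        raise ValueError("n_tau must be >= 1")
    n_c, n_f, n_d = trajectories.shape
    if n_f < n_tau:
        return np.empty((n_c, 0, n_d * n_tau))
    n_w = n_f - n_tau + 1
    out = np.empty((n_c, n_w, n_d * n_tau))
    for w in range(n_w):
        out[:, w, :] = trajectories[:, w : w + n_tau, :].reshape(n_c, n_d * n_tau)
    return out


class EmbeddingModel:
    """Pluggable nonlinear reducer over supervectors (UMAP by default).

    Parameters
    ----------
    d : embedding dimension (2 for landscape analyses).
    reducer : "umap", "pca", or any object with fit_transform/transform.
        PCA is a fast linear fallback useful for smoke tests; UMAP is the
        default nonlinear choice.
    seed : random state for the reducer; fixed seed gives deterministic
        coordinates for identical input.
    """

    def __init__(self, d: int = 2, reducer: str | object = "umap", seed: int = 0, **kwargs):
        self.d = d
        self.seed = seed
        self.reducer_kind = reducer if isinstance(reducer, str) else "custom"
        if reducer == "umap":
            import umap

            kwargs.setdefault("n_neighbors", 15)
            kwargs.setdefault("min_dist", 0.1)
            self._reducer = umap.UMAP(n_components=d, random_state=seed, **kwargs)
        elif reducer == "pca":
            from sklearn.decomposition import PCA

            self._reducer = PCA(n_components=d, random_state=seed)
        else:
            self._reducer = reducer
        self.embedding_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "EmbeddingModel":
        X = np.asarray(X, dtype=float)
        if X.shape[0] < self.d + 2:
            raise ValueError("need at least d + 2 supervectors to fit an embedding")
        self.embedding_ = np.asarray(self._reducer.fit_transform(X), dtype=float)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.embedding_ is None:
            raise RuntimeError("embedding not fitted")
        return np.asarray(self._reducer.transform(np.asarray(X, dtype=float)), dtype=float)


def fit_embedding(
    supervectors: np.ndarray, d: int = 2, seed: int = 0, reducer: str | object = "umap", **kwargs
) -> EmbeddingModel:
    """Fit the shared embedding on pooled supervectors."""
    return EmbeddingModel(d=d, reducer=reducer, seed=seed, **kwargs).fit(supervectors)


def scramble_null(
    features: pd.DataFrame,
    seed: int = 0,
    group_col: str = "treatment",
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Scrambled-time null: permute feature rows within each treatment.

    Feature vectors are randomly reassigned across all (cell, frame) slots of
    the same treatment; the index structure (and hence the tracks on which
    snippets are rebuilt) is untouched, so any temporal signal is destroyed
    while the per-treatment marginal feature distribution is preserved as a
    multiset.
    """
    rng = np.random.default_rng(seed)
    out = features.copy()
    if feature_cols is None:
        feature_cols = [c for c in features.columns if c.startswith("PC") or c.startswith("f")]
    for _, idx in features.groupby(group_col, sort=True).groups.items():
        perm = rng.permutation(len(idx))
        out.loc[idx, feature_cols] = features.loc[idx, feature_cols].to_numpy()[perm]
    return out


def scramble_trajectories(trajectories: np.ndarray, seed: int = 0) -> np.ndarray:
    """Scrambled null for dense (n_cells, n_frames, n_dims) trajectories.

    All (cell, frame) feature rows of the array (one treatment) are permuted
    as a single pool and reshaped back onto the original slots.
    """
    rng = np.random.default_rng(seed)
    n_c, n_f, n_d = trajectories.shape
    flat = trajectories.reshape(n_c * n_f, n_d)
    return flat[rng.permutation(n_c * n_f)].reshape(n_c, n_f, n_d)
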