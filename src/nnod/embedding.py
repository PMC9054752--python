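"""Dictionary projection: from standardized maps to low-dimensional loadings.

Each map's in-mask voxel vector is projected onto a component dictionary by
ordinary least squares — the loading vector x solves

    min_x || v - B^T x ||^2

for the K x V component matrix B.  Because the components are non-negative,
clipping the loadings at zero amounts to keeping only the positive part of
the map, which suppresses control-condition (baseline) artifacts.  Loadings
from several resolutions can be stacked (convention: descending component
count, 1024 then 512 then 128) into a multi-resolution representation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .volumes import ComponentDictionary, StatMap

STACKED_TAG = "stacked"


@dataclass
class Embedding:
    """Per-map loading vector over one dictionary (or a stack of them)."""

    loadings: np.ndarray
    resolution_tag: str  # e.g. "128", "512", "1024", or "stacked"
    positive_only: bool
    map_id: str

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 1:
            raise ValueError("loadings must be a vector")
        if self.positive_only and np.any(self.loadings < 0):
            raise ValueError("positive_only embedding has negative loadings")

    def __len__(self) -> int:
        return self.loadings.size


def project(sm: StatMap, dictionary: ComponentDictionary) -> Embedding:
    """OLS projection of one standardized map onto a dictionary.

    Minimum-norm least squares, so rank-deficient dictionaries are handled
    by the pseudoinverse contract.
    """
    if not sm.volume.same_geometry(dictionary.grid):
        raise ValueError("map is not on the dictionary grid")
    v = sm.volume.masked_values()
    x, *_ = scipy.linalg.lstsq(dictionary.components.T, v, lapack_driver="gelsd")
    return Embedding(
        loadings=x,
        resolution_tag=str(dictionary.n_components),
        positive_only=False,
        map_id=sm.map_id,
    )


def project_many(maps: list[StatMap], dictionary: ComponentDictionary) -> pd.DataFrame:
    """Batched projection; rows indexed by map_id, K loading columns."""
    for sm in maps:
        if not sm.volume.same_geometry(dictionary.grid):
            raise ValueError(f"map {sm.map_id} is not on the dictionary grid")
    if not maps:
        return pd.DataFrame()
    V = np.stack([sm.volume.masked_values() for sm in maps], axis=1)
    X, *_ = scipy.linalg.lstsq(dictionary.components.T, V, lapack_driver="gelsd")
    tag = str(dictionary.n_components)
    return pd.DataFrame(
        X.T,
        index=pd.Index([sm.map_id for sm in maps], name="map_id"),
        columns=[f"{tag}_{j}" for j in range(dictionary.n_components)],
    )


def positive_part(e: Embedding) -> Embedding:
    """Clip loadings at zero (idempotent)."""
    return replace(e, loadings=np.maximum(e.loadings, 0.0), positive_only=True)


def stack(parts: list[Embedding]) -> Embedding:
    """Concatenate embeddings of one map, in the order given."""
    if not parts:
        raise ValueError("nothing to stack")
    map_ids = {p.map_id for p in parts}
    if len(map_ids) != 1:
        raise ValueError("cannot stack embeddings of different maps")
    signs = {p.positive_only for p in parts}
    if len(signs) != 1:
        raise ValueError("cannot mix positive-only and signed parts")
    return Embedding(
        loadings=np.concatenate([p.loadings for p in parts]),
        resolution_tag=STACKED_TAG,
        positive_only=parts[0].positive_only,
        map_id=parts[0].map_id,
    )


def embed_repository(
    maps: list[StatMap],
    dictionaries: list[ComponentDictionary],
    positive: bool = True,
    stacked: bool = True,
) -> pd.DataFrame:
    """Project all maps on all dictionaries and (optionally) stack.

    Dictionaries are used in the order given; the stacking convention is
    descending component count (1024 || 512 || 128), which callers should
    follow for serialization stability.
    """
    frames = [project_many(maps, d) for d in dictionaries]
    if stacked:
        out = pd.concat(frames, axis=1)
    else:
        out = frames[0]
    if positive:
        out = out.clip(lower=0.0)
    return out


def representation_grid(
    maps: list[StatMap],
    dictionaries: list[ComponentDictionary],
) -> dict[tuple[str, bool], pd.DataFrame]:
    """All single-resolution and stacked feature tables, signed and positive."""
    frames = {str(d.n_components): project_many(maps, d) for d in dictionaries}
    if len(dictionaries) > 1:
        frames[STACKED_TAG] = pd.concat(list(frames.values()), axis=1)
    grid: dict[tuple[str, bool], pd.DataFrame] = {}
    for tag, df in frames.items():
        grid[(tag, False)] = df
        grid[(tag, True)] = df.clip(lower=0.0)
    return grid


def compare_representations(
    maps: list[StatMap],
    dictionaries: list[ComponentDictionary],
    labels,
    test_collections: set[str],
    k: int = 10,
    epochs: int = 150,
    learning_rate: float = 1e-2,
    seed: int = 0,
) -> pd.DataFrame:
    """Decoding performance of every representation in the grid.

    Trains one baseline logistic model (0 hidden layers, binary mode, light
    ridge penalty) per representation on the training collections and scores
    macro AUC and WR@k on the held-out collections.  `labels` is a
    LabelMatrix from the labeling module.
    """
    from .labeling import LabelMatrix
    from .metrics import evaluate_scores, leave_collections_out_split
    from .model import ModelConfig, train

    if not isinstance(labels, LabelMatrix):
        raise TypeError("labels must be a LabelMatrix")
    if len(dictionaries) * 2 < 2:
        raise ValueError("at least two representations are required")
    manifest = pd.Series({sm.map_id: sm.collection_id for sm in maps})
    train_ids, test_ids, evaluable = leave_collections_out_split(
        labels, manifest, test_collections
    )
    grid = representation_grid(maps, dictionaries)
    rows = []
    for (tag, positive), feats in grid.items():
        X_train = feats.loc[train_ids].to_numpy()
        X_test = feats.loc[test_ids].to_numpy()
        Y_train = labels.frame.loc[train_ids].to_numpy()
        cfg = ModelConfig(
            n_hidden=0,
            activation="identity",
            output_mode="binary",
            l1_weight=0.0,
            l2_weight=1e-4,
            dropout_rate=0.0,
            input_dim=X_train.shape[1],
            n_labels=labels.frame.shape[1],
            seed=seed,
        )
        fitted = train(cfg, X_train, Y_train, epochs=epochs, learning_rate=learning_rate)
        scores = fitted.decision_function(X_test)
        Y_test = labels.frame.loc[test_ids]
        eval_cols = [labels.frame.columns.get_loc(c) for c in evaluable]
        report = evaluate_scores(
            Y_test.to_numpy()[:, eval_cols],
            scores[:, eval_cols],
            label_names=list(evaluable),
            k=min(k, len(evaluable)),
        )
        rows.append(
            {
                "representation": tag,
                "positive_only": positive,
                "macro_auc": report.macro_auc,
                "wr_at_k": report.wr_at_k,
            }
        )
    return pd.DataFrame(rows)
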