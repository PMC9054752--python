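"""Concept decoding (sensitivity) and encoding maps in voxel space.

Decoding maps ask "what input pattern drives this concept's score?": the
gradient of the concept's pre-activation score with respect to the input
loadings, averaged over maps, back-projected through the dictionaries to
voxels.  Gradients are taken on the logit rather than the post-sigmoid
probability to avoid saturation flattening.

Encoding maps ask the converse question "how does each component respond to
the concept?": an intercept-included OLS regression of every component
loading on the full binary concept matrix; the concept's coefficient vector
is back-projected to voxels.

Because the decoder learns to discard responses shared across conditions
(e.g. collection baselines), decoding maps are typically sparser than the
corresponding encoding maps.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.linalg

from .model import DecoderResults
from .volumes import ComponentDictionary, Volume

KINDS = ("decoding", "encoding")


@dataclass
class ConceptMap:
    """One concept's spatial map on the common grid."""

    concept: str
    volume: Volume
    kind: str
    threshold_percentile: float | None = None
    flagged_rank_deficient: bool = False

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")


def back_project_stacked(
    gradient: np.ndarray,
    dictionaries: list[ComponentDictionary],
) -> np.ndarray:
    """Back-project a (stacked) loading-space vector to in-mask voxels.

    The vector is split by dictionary sizes in the given (stack) order; each
    segment weights its dictionary's components and the voxel maps sum.
    """
    sizes = [d.n_components for d in dictionaries]
    if gradient.shape != (sum(sizes),):
        raise ValueError("gradient length does not match the dictionary stack")
    vox = np.zeros(dictionaries[0].n_voxels)
    start = 0
    for d, k in zip(dictionaries, sizes):
        vox += d.back_project(gradient[start:start + k])
        start += k
    return vox


def sensitivity_map(
    model: DecoderResults,
    X,
    dictionaries: list[ComponentDictionary],
    concept: str,
    positives_only: bool = False,
    Y=None,
) -> ConceptMap:
    """Gradient-based decoding map for one concept.

    Averages d score / d input over the rows of X (optionally only over the
    concept's positive maps when `positives_only` and Y are given), then
    back-projects the averaged gradient to voxels.
    """
    label_index = model.label_index(concept)
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy()
    X = np.asarray(X, dtype=float)
    if positives_only:
        if Y is None:
            raise ValueError("positives_only requires Y")
        frame = Y.frame if hasattr(Y, "frame") else Y
        yv = frame[concept].to_numpy() if isinstance(frame, pd.DataFrame) else np.asarray(frame)
        X = X[yv == 1]
        if X.shape[0] == 0:
            raise ValueError(f"concept {concept!r} has no positive map")
    grad = model.input_gradient(X, label_index).mean(axis=0)
    vox = back_project_stacked(grad, dictionaries)
    return ConceptMap(
        concept=concept,
        volume=dictionaries[0].grid.with_masked_values(vox),
        kind="decoding",
    )


def encoding_map(
    X,
    Y,
    dictionaries: list[ComponentDictionary],
    concept: str,
) -> ConceptMap:
    """OLS encoding map for one concept.

    Each component loading is regressed on [1, Y] (all concepts jointly);
    the queried concept's coefficients across components are back-projected.
    A rank-deficient concept matrix falls back to the minimum-norm fit and
    is flagged on the returned map.
    """
    frame = Y.frame if hasattr(Y, "frame") else Y
    if not isinstance(frame, pd.DataFrame):
        raise TypeError("Y must be a LabelMatrix or DataFrame")
    if concept not in frame.columns:
        raise ValueError(f"concept {concept!r} not in the label matrix")
    if frame[concept].sum() < 1:
        raise ValueError(f"concept {concept!r} has no positive map")
    if isinstance(X, pd.DataFrame):
        X = X.loc[frame.index].to_numpy()
    X = np.asarray(X, dtype=float)
    design = np.column_stack([np.ones(len(frame)), frame.to_numpy(dtype=float)])
    coefs, _, rank, _ = scipy.linalg.lstsq(design, X, lapack_driver="gelsd")
    flagged = rank < design.shape[1]
    concept_row = 1 + list(frame.columns).index(concept)
    vox = back_project_stacked(coefs[concept_row], dictionaries)
    return ConceptMap(
        concept=concept,
        volume=dictionaries[0].grid.with_masked_values(vox),
        kind="encoding",
        flagged_rank_deficient=bool(flagged),
    )


def threshold_for_display(cmap: ConceptMap, q: float = 0.95) -> ConceptMap:
    """Zero in-mask absolute values below the q-quantile (for visualization)."""
    if not (0.0 < q < 1.0):
        raise ValueError("q must be in (0, 1)")
    values = cmap.volume.masked_values()
    cut = np.quantile(np.abs(values), q)
    kept = np.where(np.abs(values) >= cut, values, 0.0)
    return replace(
        cmap,
        volume=cmap.volume.with_masked_values(kept),
        threshold_percentile=q,
    )
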