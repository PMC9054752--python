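"""Per-label evaluation metrics and cross-study validation splits.

Both metrics average over labels with uniform weights, so they are
insensitive to label prevalence:

* WR@k (weighted recall at k) — for each label, the fraction of maps truly
  carrying it whose predicted ranking places it among the map's top-k
  labels; averaged over labels with at least one positive map.
* macro AUC — for each label with both classes present, the probability
  that a random positive map scores higher than a random negative one
  (ties count one half, computed via midranks); averaged over those labels.

Generalization is measured by holding out whole collections (studies): the
evaluable vocabulary is then restricted to concepts positive in both splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class EvalConfig:
    k: int = 10
    test_collections: set[str] = field(default_factory=set)


@dataclass
class EvalReport:
    per_label_auc: dict[str, float]
    macro_auc: float
    wr_at_k: float
    k: int
    evaluated_labels: list[str]
    excluded_labels: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"label": list(self.per_label_auc), "auc": list(self.per_label_auc.values())}
        )

    def to_dict(self) -> dict:
        return {
            "macro_auc": self.macro_auc,
            "wr_at_k": self.wr_at_k,
            "k": self.k,
            "per_label_auc": dict(self.per_label_auc),
            "evaluated_labels": list(self.evaluated_labels),
            "excluded_labels": dict(self.excluded_labels),
        }


def _coerce_matrix(Y, scores) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(Y, "frame"):
        Y = Y.frame
    if isinstance(Y, pd.DataFrame):
        Y = Y.to_numpy()
    Y = np.asarray(Y, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if Y.shape != scores.shape:
        raise ValueError("label and score matrices must have the same shape")
    if Y.ndim != 2:
        raise ValueError("expected 2-D maps x labels matrices")
    return Y, scores


def top_k_mask(scores: np.ndarray, k: int) -> np.ndarray:
    """Boolean maps x labels matrix marking each map's top-k labels.

    Boundary ties break by ascending label index (stable sort on -score).
    """
    order = np.argsort(-scores, axis=1, kind="stable")
    mask = np.zeros(scores.shape, dtype=bool)
    rows = np.arange(scores.shape[0])[:, None]
    mask[rows, order[:, :k]] = True
    return mask


def wr_at_k(Y, scores, k: int) -> float:
    """Weighted recall at k, averaged uniformly over labels with positives."""
    Y, scores = _coerce_matrix(Y, scores)
    n_labels = Y.shape[1]
    if not (1 <= k <= n_labels):
        raise ValueError(f"k must be in [1, {n_labels}]")
    mask = top_k_mask(scores, k)
    recalls = []
    for l in range(n_labels):
        pos = Y[:, l] == 1
        if not pos.any():
            continue
        recalls.append(float(mask[pos, l].mean()))
    if not recalls:
        raise ValueError("no label has a positive map")
    return float(np.mean(recalls))


def per_label_auc(Y, scores) -> tuple[dict[int, float], dict[int, str]]:
    """ROC AUC per label column via midrank statistics.

    Labels with one class absent are excluded with a reason rather than
    scored 0.5.  Returns ({column -> auc}, {column -> exclusion reason}).
    """
    Y, scores = _coerce_matrix(Y, scores)
    aucs: dict[int, float] = {}
    excluded: dict[int, str] = {}
    for l in range(Y.shape[1]):
        y = Y[:, l]
        n_pos = int((y == 1).sum())
        n_neg = int((y == 0).sum())
        if n_pos == 0:
            excluded[l] = "no_positives"
            continue
        if n_neg == 0:
            excluded[l] = "no_negatives"
            continue
        ranks = rankdata(scores[:, l])  # midranks: ties count one half
        auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
        aucs[l] = float(auc)
    if not aucs:
        raise ValueError("no evaluable label (need both classes somewhere)")
    return aucs, excluded


def evaluate_scores(
    Y,
    scores,
    label_names: list[str] | None = None,
    k: int = 10,
) -> EvalReport:
    """Full evaluation report: per-label AUCs, macro AUC and WR@k."""
    Ym, Sm = _coerce_matrix(Y, scores)
    if label_names is None:
        label_names = [f"label_{l}" for l in range(Ym.shape[1])]
    aucs, excluded = per_label_auc(Ym, Sm)
    per_label = {label_names[l]: a for l, a in aucs.items()}
    return EvalReport(
        per_label_auc=per_label,
        macro_auc=float(np.mean(list(aucs.values()))),
        wr_at_k=wr_at_k(Ym, Sm, k),
        k=k,
        evaluated_labels=[label_names[l] for l in aucs],
        excluded_labels={label_names[l]: r for l, r in excluded.items()},
    )


def leave_collections_out_split(
    labels,
    manifest,
    test_collections: set[str],
) -> tuple[list[str], list[str], list[str]]:
    """Hold out whole collections for testing.

    `manifest` maps map_id -> collection_id (Series or dict).  Returns
    (train map_ids, test map_ids, evaluable vocabulary): the evaluable
    concepts are those positive in both splits.
    """
    frame = labels.frame if hasattr(labels, "frame") else labels
    manifest = pd.Series(manifest)
    test_collections = set(test_collections)
    if not test_collections:
        raise ValueError("test_collections must be nonempty")
    known = set(manifest.values)
    unknown = test_collections - known
    if unknown:
        raise ValueError(f"unknown collections: {sorted(unknown)}")
    train_ids, test_ids = [], []
    for map_id in frame.index:
        if manifest.get(map_id) in test_collections:
            test_ids.append(map_id)
        else:
            train_ids.append(map_id)
    train_pos = frame.loc[train_ids].sum(axis=0)
    test_pos = frame.loc[test_ids].sum(axis=0)
    evaluable = [c for c in frame.columns if train_pos[c] > 0 and test_pos[c] > 0]
    return train_ids, test_ids, evaluable
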