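"""Concept label extraction from uncurated free-text annotations.

Labels are obtained by exact (word-boundary, case-insensitive) matching of
ontology concept names and registered synonyms inside the annotation fields,
then enriched: hypernym closure adds every ancestor of a matched concept, and
an optional rule set corrects common errors/abbreviations, fires
collection-specific labels, and merges synonymous concepts.  Rules are meant
for training collections only — the evaluation split keeps raw extraction
plus closure so metrics are not biased by hand-tuned rules.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ontology import Ontology
from .volumes import StatMap


@dataclass
class Vocabulary:
    """Ordered concept-id list defining the label indexing."""

    concepts: list[str]

    def __post_init__(self) -> None:
        if len(set(self.concepts)) != len(self.concepts):
            raise ValueError("duplicate concepts in vocabulary")

    def __len__(self) -> int:
        return len(self.concepts)

    def __iter__(self):
        return iter(self.concepts)

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts


@dataclass
class LabelMatrix:
    """maps x concepts binary supervision; rows are labeled maps only."""

    frame: pd.DataFrame  # index map_id, columns concept ids, values {0,1}

    def __post_init__(self) -> None:
        values = self.frame.to_numpy()
        if values.size and not np.isin(values, (0, 1)).all():
            raise ValueError("label matrix must be binary")
        self.frame = self.frame.astype(np.int8)

    @property
    def map_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def vocabulary(self) -> Vocabulary:
        return Vocabulary(list(self.frame.columns))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "LabelMatrix":
        return cls(pd.read_csv(path, index_col=0))


@dataclass
class RuleSet:
    """Curation rules tailored to a repository's annotation habits.

    synonym_merges    (survivor, merged) concept-id pairs; a concept may be
                      merged into at most one survivor, and a survivor may
                      not itself be merged away
    collection_rules  collection id -> {annotation pattern -> concept ids};
                      a pattern is a case-insensitive substring that, when
                      found in any annotation field, fires the listed labels
    correction_map    token -> replacement rewriting common errors and
                      abbreviations before matching (e.g. "wm" -> "working
                      memory")
    """

    synonym_merges: list[tuple[str, str]] = field(default_factory=list)
    collection_rules: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    correction_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        survivor_of: dict[str, str] = {}
        survivors = set()
        for survivor, merged in self.synonym_merges:
            if merged in survivor_of and survivor_of[merged] != survivor:
                raise ValueError(f"{merged} merged into two distinct survivors")
            survivor_of[merged] = survivor
            survivors.add(survivor)
        if survivors & set(survivor_of):
            raise ValueError("a merge survivor is itself merged away")


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


def _concept_patterns(ontology: Ontology, vocabulary: Vocabulary) -> dict[str, re.Pattern]:
    patterns = {}
    for cid in vocabulary:
        forms = [_normalize(f) for f in ontology.surface_forms(cid)]
        alternation = "|".join(re.escape(f) for f in sorted(forms, key=len, reverse=True))
        patterns[cid] = re.compile(rf"\b(?:{alternation})\b")
    return patterns


def _map_text(sm: StatMap) -> str:
    # fields joined with a hard separator so phrases cannot span fields
    return _normalize(" ; ".join(str(v) for v in sm.annotations.values()))


def extract_exact_labels(
    maps: list[StatMap],
    ontology: Ontology,
    vocabulary: Vocabulary,
) -> LabelMatrix:
    """y_i^l = 1 iff concept l's canonical name or a registered synonym occurs
    (word-boundary, case-insensitive) in any annotation field of map i.

    Maps with no matched label are dropped from the matrix.
    """
    unknown = [c for c in vocabulary if c not in set(ontology.concept_ids)]
    if unknown:
        raise ValueError(f"vocabulary concepts missing from ontology: {unknown}")
    patterns = _concept_patterns(ontology, vocabulary)
    rows, index = [], []
    for sm in maps:
        text = _map_text(sm)
        row = [1 if patterns[cid].search(text) else 0 for cid in vocabulary]
        if any(row):
            rows.append(row)
            index.append(sm.map_id)
    frame = pd.DataFrame(rows, index=pd.Index(index, name="map_id"), columns=list(vocabulary))
    return LabelMatrix(frame)


def _closure_matrix(ontology: Ontology, concepts: list[str]) -> np.ndarray:
    """C[i, j] = 1 iff concept j is concept i or one of its ancestors."""
    pos = {cid: k for k, cid in enumerate(concepts)}
    C = np.eye(len(concepts), dtype=np.int8)
    for cid in concepts:
        for anc in ontology.ancestors(cid):
            if anc in pos:
                C[pos[cid], pos[anc]] = 1
    return C


def hypernym_close(labels: LabelMatrix, ontology: Ontology) -> LabelMatrix:
    """Add every in-vocabulary ancestor of each positive label (idempotent)."""
    concepts = list(labels.frame.columns)
    C = _closure_matrix(ontology, concepts)
    closed = (labels.frame.to_numpy() @ C > 0).astype(np.int8)
    return LabelMatrix(pd.DataFrame(closed, index=labels.frame.index, columns=concepts))


def _rewrite_tokens(text: str, correction_map: dict[str, str]) -> str:
    out = []
    for token in text.split():
        core = token.strip(string.punctuation)
        key = core.lower()
        if core and key in correction_map:
            token = token.replace(core, correction_map[key], 1)
        out.append(token)
    return " ".join(out)


def apply_ruleset(
    maps: list[StatMap],
    ontology: Ontology,
    vocabulary: Vocabulary,
    rules: RuleSet,
) -> LabelMatrix:
    """Extraction with curation rules.

    Annotations are first rewritten through the correction map, exact
    matching runs on the corrected text, collection rules fire additional
    labels, and synonym merges OR the merged concept's column into its
    survivor.  An empty RuleSet reproduces extract_exact_labels exactly.
    """
    rewritten = [
        sm.replace(
            annotations={k: _rewrite_tokens(v, rules.correction_map) for k, v in sm.annotations.items()}
        )
        if rules.correction_map
        else sm
        for sm in maps
    ]
    lm = extract_exact_labels(rewritten, ontology, vocabulary)
    frame = lm.frame
    if rules.collection_rules:
        extra_rows: dict[str, set[str]] = {}
        for sm in rewritten:
            coll = rules.collection_rules.get(sm.collection_id)
            if not coll:
                continue
            text = _map_text(sm)
            fired = {
                cid
                for pattern, cids in coll.items()
                for cid in cids
                if cid in vocabulary and _normalize(pattern) in text
            }
            if fired:
                extra_rows[sm.map_id] = fired
        new_ids = [m for m in extra_rows if m not in frame.index]
        if new_ids:
            add = pd.DataFrame(0, index=pd.Index(new_ids, name="map_id"), columns=frame.columns)
            frame = pd.concat([frame, add])
            order = [sm.map_id for sm in maps if sm.map_id in set(frame.index)]
            frame = frame.loc[order]
        for map_id, fired in extra_rows.items():
            for cid in fired:
                frame.loc[map_id, cid] = 1
    for survivor, merged in rules.synonym_merges:
        if merged not in frame.columns:
            continue
        if survivor in frame.columns:
            frame[survivor] = ((frame[survivor] | frame[merged]) > 0).astype(np.int8)
            frame = frame.drop(columns=[merged])
        else:
            frame = frame.rename(columns={merged: survivor})
    frame = frame.loc[frame.sum(axis=1) > 0]
    return LabelMatrix(frame)


def prune_vocabulary(
    labels: LabelMatrix,
    min_count: int = 10,
    max_abs_corr: float = 0.95,
) -> tuple[Vocabulary, LabelMatrix]:
    """Drop concepts that are too rare or too correlated with another.

    Iterates to a fixed point: remove all columns with fewer than `min_count`
    positives; then, for the most-correlated pair with |phi| above
    `max_abs_corr`, remove the rarer member (tie: the later column), and
    repeat.  Constant columns have undefined phi and are treated as
    uncorrelated.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if not (0.0 < max_abs_corr <= 1.0):
        raise ValueError("max_abs_corr must be in (0, 1]")
    frame = labels.frame.copy()
    while True:
        counts = frame.sum(axis=0)
        rare = counts[counts < min_count].index
        if len(rare):
            frame = frame.drop(columns=list(rare))
            if frame.shape[1] == 0:
                raise ValueError("all concepts pruned")
            continue
        if frame.shape[1] < 2:
            break
        with np.errstate(invalid="ignore", divide="ignore"):
            phi = np.corrcoef(frame.to_numpy(dtype=float), rowvar=False)
        phi = np.nan_to_num(phi, nan=0.0)
        np.fill_diagonal(phi, 0.0)
        absphi = np.abs(phi)
        if absphi.max() <= max_abs_corr:
            break
        i, j = np.unravel_index(int(absphi.argmax()), absphi.shape)
        i, j = min(i, j), max(i, j)
        counts = frame.sum(axis=0).to_numpy()
        drop = i if counts[i] < counts[j] else j  # tie -> later column j
        frame = frame.drop(columns=[frame.columns[drop]])
        if frame.shape[1] == 0:
            raise ValueError("all concepts pruned")
    return Vocabulary(list(frame.columns)), LabelMatrix(frame)
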