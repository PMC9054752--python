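"""Label extraction, hypernym closure, rulesets and vocabulary pruning."""

import numpy as np
import pandas as pd
import pytest

from nnod.labeling import (
    LabelMatrix,
    RuleSet,
    Vocabulary,
    apply_ruleset,
    extract_exact_labels,
    hypernym_close,
    prune_vocabulary,
)
from nnod.ontology import Ontology
from nnod.volumes import StatMap, make_grid


@pytest.fixture(scope="module")
def grid():
    return make_grid((4, 4, 4), border=0)


def _annotated(grid, map_id, text, collection_id="c0"):
    return StatMap(
        volume=grid.with_masked_values(np.ones(grid.n_voxels_in_mask)),
        map_type="z", collection_id=collection_id, map_id=map_id,
        annotations={"name": text},
    )


@pytest.fixture
def flat_ontology():
    concepts = [(n, n) for n in ("working memory", "visual perception", "reward")]
    return Ontology(concepts=concepts, synonyms={"wm": "working memory"})


class TestExtractExactLabels:
    def test_word_boundary_substring_matching(self, grid, flat_ontology):
        maps = [_annotated(grid, "m0", "Visual Working Memory 2-back task")]
        vocab = Vocabulary(["working memory", "visual perception"])
        lm = extract_exact_labels(maps, flat_ontology, vocab)
        assert lm.frame.loc["m0"].to_dict() == {"working memory": 1, "visual perception": 0}

    def test_partial_words_do_not_match(self, grid):
        onto = Ontology(concepts=[("art", "art")])
        maps = [_annotated(grid, "m0", "startle response")]
        lm = extract_exact_labels(maps, onto, Vocabulary(["art"]))
        assert "m0" not in lm.frame.index

    def test_synonyms_match(self, grid, flat_ontology):
        maps = [_annotated(grid, "m0", "wm load contrast")]
        lm = extract_exact_labels(maps, flat_ontology, Vocabulary(["working memory"]))
        assert lm.frame.loc["m0", "working memory"] == 1

    def test_unmatched_maps_dropped(self, grid, flat_ontology):
        maps = [
            _annotated(grid, "m0", "reward anticipation"),
            _annotated(grid, "m1", "nothing relevant here"),
        ]
        lm = extract_exact_labels(maps, flat_ontology, Vocabulary(["reward"]))
        assert list(lm.frame.index) == ["m0"]

    def test_field_order_does_not_matter(self, grid, flat_ontology):
        a = _annotated(grid, "m0", "")
        a.annotations = {"x": "reward", "y": "working memory"}
        b = _annotated(grid, "m0", "")
        b.annotations = {"y": "working memory", "x": "reward"}
        vocab = Vocabulary(["working memory", "reward"])
        la = extract_exact_labels([a], flat_ontology, vocab)
        lb = extract_exact_labels([b], flat_ontology, vocab)
        pd.testing.assert_frame_equal(la.frame, lb.frame)


class TestHypernymClose:
    def test_auditory_sentence_comprehension_chain(self, grid, auditory_chain_ontology):
        maps = [_annotated(grid, "m0", "story listening: auditory sentence comprehension")]
        vocab = Vocabulary([c for c, _ in auditory_chain_ontology.concepts])
        lm = hypernym_close(
            extract_exact_labels(maps, auditory_chain_ontology, vocab),
            auditory_chain_ontology,
        )
        positives = {c for c in lm.frame.columns if lm.frame.loc["m0", c]}
        assert positives == {
            "auditory sentence comprehension",
            "auditory sentence perception",
            "auditory perception",
            "perception",
            "language comprehension",
            "language",
        }

    def test_root_labels_unchanged(self, grid, auditory_chain_ontology):
        maps = [_annotated(grid, "m0", "basic perception test")]
        vocab = Vocabulary([c for c, _ in auditory_chain_ontology.concepts])
        lm = extract_exact_labels(maps, auditory_chain_ontology, vocab)
        closed = hypernym_close(lm, auditory_chain_ontology)
        pd.testing.assert_frame_equal(lm.frame, closed.frame)

    def test_closure_is_idempotent_and_monotone(self, grid, auditory_chain_ontology):
        maps = [_annotated(grid, "m0", "auditory sentence perception during stories")]
        vocab = Vocabulary([c for c, _ in auditory_chain_ontology.concepts])
        lm = extract_exact_labels(maps, auditory_chain_ontology, vocab)
        once = hypernym_close(lm, auditory_chain_ontology)
        twice = hypernym_close(once, auditory_chain_ontology)
        pd.testing.assert_frame_equal(once.frame, twice.frame)
        assert (once.frame.to_numpy() >= lm.frame.to_numpy()).all()


class TestApplyRuleset:
    def test_correction_map_rewrites_then_matches(self, grid, flat_ontology):
        maps = [_annotated(grid, "m0", "wm 2-back")]
        rules = RuleSet(correction_map={"wm": "working memory"})
        onto = Ontology(concepts=[("working memory", "working memory")])
        lm = apply_ruleset(maps, onto, Vocabulary(["working memory"]), rules)
        assert lm.frame.loc["m0", "working memory"] == 1

    def test_merge_relabels_to_survivor(self, grid):
        onto = Ontology(concepts=[("A", "alpha task"), ("B", "beta task")])
        maps = [_annotated(grid, "m0", "a beta task run")]
        rules = RuleSet(synonym_merges=[("A", "B")])
        lm = apply_ruleset(maps, onto, Vocabulary(["A", "B"]), rules)
        assert list(lm.frame.columns) == ["A"]
        assert lm.frame.loc["m0", "A"] == 1

    def test_collection_rules_fire_for_matching_collection_only(self, grid, flat_ontology):
        maps = [
            _annotated(grid, "m0", "run 1", collection_id="c0"),
            _annotated(grid, "m1", "run 1", collection_id="c1"),
        ]
        rules = RuleSet(collection_rules={"c0": {"run": ["reward"]}})
        lm = apply_ruleset(maps, flat_ontology, Vocabulary(["reward"]), rules)
        assert list(lm.frame.index) == ["m0"]

    def test_empty_ruleset_is_neutral(self, grid, flat_ontology):
        maps = [_annotated(grid, "m0", "reward and working memory")]
        vocab = Vocabulary(["working memory", "reward"])
        a = apply_ruleset(maps, flat_ontology, vocab, RuleSet())
        b = extract_exact_labels(maps, flat_ontology, vocab)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_conflicting_merges_rejected(self):
        with pytest.raises(ValueError):
            RuleSet(synonym_merges=[("A", "C"), ("B", "C")])


def _brute_force_prune(frame: pd.DataFrame, min_count: int, max_abs_corr: float):
    """Independent reimplementation with explicit loops for cross-checking."""
    frame = frame.copy()
    while True:
        dropped = False
        for col in list(frame.columns):
            if frame[col].sum() < min_count:
                frame = frame.drop(columns=[col])
                dropped = True
        if frame.shape[1] == 0:
            raise ValueError("empty")
        if dropped:
            continue
        best = None
        cols = list(frame.columns)
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                x = frame[cols[i]].to_numpy(dtype=float)
                y = frame[cols[j]].to_numpy(dtype=float)
                if x.std() == 0 or y.std() == 0:
                    continue
                phi = abs(np.corrcoef(x, y)[0, 1])
                if phi > max_abs_corr and (best is None or phi > best[0] + 1e-12):
                    best = (phi, i, j)
        if best is None:
            return frame
        _, i, j = best
        ci, cj = cols[i], cols[j]
        drop = ci if frame[ci].sum() < frame[cj].sum() else cj
        frame = frame.drop(columns=[drop])


class TestPruneVocabulary:
    def test_rare_concept_dropped(self):
        frame = pd.DataFrame({"a": [1, 1, 1, 1, 1], "b": [0, 0, 0, 0, 0]})
        vocab, lm = prune_vocabulary(LabelMatrix(frame), min_count=5, max_abs_corr=0.95)
        assert list(vocab) == ["a"]

    def test_identical_columns_keep_one(self):
        col = [1, 0, 1, 1, 0, 1]
        frame = pd.DataFrame({"a": col, "b": col})
        vocab, _ = prune_vocabulary(LabelMatrix(frame), min_count=1, max_abs_corr=0.95)
        assert len(vocab) == 1

    def test_matches_brute_force_oracle(self, rng):
        frame = pd.DataFrame(
            (rng.random((200, 30)) < 0.2).astype(int),
            columns=[f"c{i:02d}" for i in range(30)],
        )
        # plant correlated and rare columns
        frame["c01"] = frame["c00"]
        frame["c02"] = (frame["c00"] | (rng.random(200) < 0.02)).astype(int)
        frame["c03"] = 0
        vocab, lm = prune_vocabulary(LabelMatrix(frame), min_count=10, max_abs_corr=0.8)
        expected = _brute_force_prune(frame, 10, 0.8)
        assert list(vocab) == list(expected.columns)
        pd.testing.assert_frame_equal(lm.frame.astype(int), expected.astype(int))

    def test_postconditions_hold(self, rng):
        frame = pd.DataFrame(
            (rng.random((120, 12)) < 0.3).astype(int),
            columns=[f"c{i}" for i in range(12)],
        )
        vocab, lm = prune_vocabulary(LabelMatrix(frame), min_count=5, max_abs_corr=0.9)
        counts = lm.frame.sum(axis=0)
        assert (counts >= 5).all()
        phi = np.corrcoef(lm.frame.to_numpy(dtype=float), rowvar=False)
        np.fill_diagonal(phi, 0.0)
        assert np.nanmax(np.abs(phi)) <= 0.9 + 1e-12

    def test_everything_pruned_raises(self):
        frame = pd.DataFrame({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ValueError):
            prune_vocabulary(LabelMatrix(frame), min_count=5, max_abs_corr=0.95)
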