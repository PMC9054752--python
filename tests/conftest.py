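import numpy as np
import pytest

import nnod.io as nio
from nnod.embedding import embed_repository
from nnod.labeling import Vocabulary, extract_exact_labels, hypernym_close
from nnod.ontology import Ontology
from nnod.qc import deduplicate, qc_filter
from nnod.synth import standard_fixture


@pytest.fixture(scope="session")
def study():
    """The standard synthetic study (3 collections x 170 maps, 20 concepts)."""
    return standard_fixture(seed=1)


@pytest.fixture(scope="session")
def study_data(study):
    """Prepared study: QC'd maps, positive stacked features, closed labels."""
    kept, _ = qc_filter(study.maps)
    kept = deduplicate(kept)
    feats = embed_repository(kept, study.analysis_dictionaries, positive=True)
    vocab = Vocabulary(study.ontology.concept_ids)
    labels = hypernym_close(extract_exact_labels(kept, study.ontology, vocab), study.ontology)
    return {
        "kept": kept,
        "features": feats,
        "labels": labels,
        "manifest": nio.collection_of(kept),
    }


@pytest.fixture
def auditory_chain_ontology():
    """Hand-built ontology around the auditory-sentence-comprehension chain:
    comprehension is-a (sentence perception, language comprehension), with
    chains up to perception and language."""
    names = [
        "perception",
        "auditory perception",
        "auditory sentence perception",
        "language",
        "language comprehension",
        "auditory sentence comprehension",
        "visual perception",
    ]
    concepts = [(n, n) for n in names]
    edges = [
        ("auditory perception", "perception"),
        ("auditory sentence perception", "auditory perception"),
        ("language comprehension", "language"),
        ("auditory sentence comprehension", "auditory sentence perception"),
        ("auditory sentence comprehension", "language comprehension"),
        ("visual perception", "perception"),
    ]
    return Ontology(concepts=concepts, synonyms={"asc": "auditory sentence comprehension"},
                    hypernym_edges=edges)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
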