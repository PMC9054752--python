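"""Concept ontology: canonical names, synonyms and hypernym (is-a) structure.

A label implies all of its hypernym ancestors: a map probing *auditory
sentence comprehension* also involves *auditory sentence perception*,
*auditory perception*, *perception*, *language comprehension* and
*language*.  The closure operation below materializes that implication in a
label set.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from pathlib import Path


@dataclass
class Ontology:
    """Cognitive concepts with synonym and hypernymy structure.

    concepts       ordered list of (concept id, canonical name)
    synonyms       surface name -> concept id (each synonym resolves uniquely)
    hypernym_edges (child id, parent id) pairs; the relation must be acyclic
                   and may give a concept several parents (a DAG, not a tree)
    """

    concepts: list[tuple[str, str]]
    synonyms: dict[str, str] = field(default_factory=dict)
    hypernym_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.concepts]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate concept ids")
        self._ids = set(ids)
        names = [name for _, name in self.concepts]
        if len(set(names)) != len(names):
            raise ValueError("duplicate canonical names")
        for child, parent in self.hypernym_edges:
            if child not in self._ids or parent not in self._ids:
                raise ValueError(f"edge ({child}, {parent}) references unknown concept")
        for syn, cid in self.synonyms.items():
            if cid not in self._ids:
                raise ValueError(f"synonym {syn!r} resolves to unknown concept {cid}")
        self._parents: dict[str, set[str]] = {cid: set() for cid in ids}
        for child, parent in self.hypernym_edges:
            self._parents[child].add(parent)
        try:  # acyclicity is an invariant, enforced at construction
            list(TopologicalSorter({c: set(p) for c, p in self._parents.items()}).static_order())
        except CycleError as err:
            raise ValueError("hypernym relation contains a cycle") from err

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def concept_ids(self) -> list[str]:
        return [cid for cid, _ in self.concepts]

    def name_of(self, concept_id: str) -> str:
        for cid, name in self.concepts:
            if cid == concept_id:
                return name
        raise KeyError(concept_id)

    def parents_of(self, concept_id: str) -> set[str]:
        return set(self._parents[concept_id])

    def ancestors(self, concept_id: str) -> set[str]:
        """All strict hypernym ancestors of a concept."""
        seen: set[str] = set()
        stack = list(self._parents[concept_id])
        while stack:
            cid = stack.pop()
            if cid not in seen:
                seen.add(cid)
                stack.extend(self._parents[cid])
        return seen

    def hypernym_closure(self, labels: set[str]) -> set[str]:
        """Close a label set under hypernymy (add every ancestor)."""
        closed = set(labels)
        for cid in labels:
            closed |= self.ancestors(cid)
        return closed

    def surface_forms(self, concept_id: str) -> list[str]:
        """Canonical name plus all registered synonyms of a concept."""
        forms = [self.name_of(concept_id)]
        forms += [s for s, cid in self.synonyms.items() if cid == concept_id]
        return forms

    # --- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "concepts": [[cid, name] for cid, name in self.concepts],
            "synonyms": dict(self.synonyms),
            "hypernym_edges": [[c, p] for c, p in self.hypernym_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ontology":
        return cls(
            concepts=[tuple(c) for c in d["concepts"]],
            synonyms=dict(d.get("synonyms", {})),
            hypernym_edges=[tuple(e) for e in d.get("hypernym_edges", [])],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "Ontology":
        return cls.from_dict(json.loads(Path(path).read_text()))
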