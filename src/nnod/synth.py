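"""Synthetic repository generator with known ground truth.

Emulates the statistical structure of an open fMRI-map repository: maps are
grouped in collections, each collection carries its own control-condition
baseline pattern, map values mix z/t/beta conventions, free-text annotations
contain (possibly corrupted) ontology concept names, and a configurable
fraction of maps are contaminants (thresholded, low-coverage, or
wrong-modality uploads).

The forward model for a clean map mirrors the subtractive logic of
contrast-based fMRI (target condition minus an ill-specified control):

    voxels = sum_{c active} effect * B^T s_c  -  u * B^T c_coll  +  noise

where B is the generating component dictionary, s_c is the fixed sparse
non-negative loading signature of concept c, c_coll is a non-negative
per-collection control-condition pattern of scale `baseline_shift_sd`,
u ~ Uniform(0.5, 1.5) is the per-map control intensity (studies subtract
"more or less" of their control response), and noise is i.i.d. Gaussian.
Because the control enters negatively, most of its effect lives in the
negative part of the map — which is why positive-part loadings mitigate it.
Ground-truth labels are the hypernym closure of the active concept set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ontology import Ontology
from .volumes import ComponentDictionary, StatMap, Volume, make_grid

# Root nouns and modifiers are disjoint word sets; a child concept's name is
# built as "<modifier> <parent name>", so word-boundary containment between
# canonical names coincides exactly with hypernym ancestry.
ROOT_NOUNS = [
    "perception", "memory", "language", "attention",
    "emotion", "reasoning", "action", "learning",
]
MODIFIERS = [
    "visual", "auditory", "motor", "spatial", "verbal", "episodic",
    "semantic", "social", "working", "sentence", "face", "reward",
    "numerical", "tactile", "affective", "sustained", "selective",
    "abstract", "implicit", "explicit", "covert", "overt", "rapid",
    "divided",
]

_VOWELS = set("aeiou")


# ---------------------------------------------------------------------------
# dictionaries
# ---------------------------------------------------------------------------

def generate_dictionary(
    n_components: int,
    grid: Volume,
    sparsity: float = 0.95,
    overlap: float = 0.5,
    seed: int = 0,
) -> ComponentDictionary:
    """Draw K sparse non-negative spatial components on `grid`.

    Components are contiguous blobs (in the style of probabilistic-atlas
    dictionaries): each grows from a random center over the nearest in-mask
    voxels to a support of ~(1 - sparsity) * V voxels, with a Gaussian
    radial profile.  While growing, a voxel already claimed by an earlier
    component is entered only with probability `overlap`; at overlap 0 the
    supports are therefore disjoint (an error if infeasible).
    """
    if n_components < 1:
        raise ValueError("need at least one component")
    if not (0.0 < sparsity < 1.0):
        raise ValueError("sparsity must be in (0, 1)")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    n_vox = grid.n_voxels_in_mask
    if n_vox == 0:
        raise ValueError("grid mask is empty")
    if n_components > n_vox:
        raise ValueError("more components than in-mask voxels")
    support = max(1, int(round((1.0 - sparsity) * n_vox)))
    if overlap == 0.0 and n_components * support > n_vox:
        raise ValueError("disjoint supports infeasible at this sparsity")
    rng = np.random.default_rng(seed)
    coords = np.argwhere(grid.mask).astype(float)
    claimed = np.zeros(n_vox, dtype=bool)
    components = np.zeros((n_components, n_vox))
    for j in range(n_components):
        free = np.flatnonzero(~claimed)
        pool = free if free.size else np.arange(n_vox)
        center = coords[pool[int(rng.integers(pool.size))]]
        d2 = ((coords - center) ** 2).sum(axis=1)
        order = np.argsort(d2, kind="stable")
        taken: list[int] = []
        for v in order:
            if claimed[v] and rng.random() >= overlap:
                continue
            taken.append(int(v))
            if len(taken) == support:
                break
        if len(taken) < support and overlap == 0.0:
            raise ValueError("disjoint supports infeasible at this sparsity")
        idx = np.asarray(taken)
        r2 = max(float(d2[idx].max()), 1.0)
        components[j, idx] = np.exp(-1.5 * d2[idx] / r2) * rng.uniform(0.8, 1.2)
        claimed[idx] = True
    return ComponentDictionary(components=components, grid=grid)


# ---------------------------------------------------------------------------
# ontology
# ---------------------------------------------------------------------------

def _abbreviate(name: str) -> str:
    words = name.split()
    if len(words) >= 2:
        return "".join(w[0] for w in words)
    return name[:4]


def generate_ontology(
    n_concepts: int,
    n_synonym_pairs: int = 0,
    max_depth: int = 3,
    seed: int = 0,
) -> Ontology:
    """A hypernym forest of synthetic cognitive concepts with synonyms.

    Concept names compose hierarchically (child = modifier + parent name),
    mirroring how real ontology terms specialize (*auditory perception* is-a
    *perception*).  Depth of every ancestor chain is at most `max_depth`.
    """
    if n_concepts < 1:
        raise ValueError("need at least one concept")
    if n_synonym_pairs > n_concepts:
        raise ValueError("more synonym pairs than concepts")
    rng = np.random.default_rng(seed)
    n_roots = max(1, min(len(ROOT_NOUNS), int(np.ceil(n_concepts / 6))))
    names: list[str] = []
    depths: list[int] = []
    parents: list[int | None] = []
    child_modifiers: dict[int, set[str]] = {}
    for i in range(n_concepts):
        if i < n_roots:
            names.append(ROOT_NOUNS[i])
            depths.append(0)
            parents.append(None)
        else:
            eligible = [j for j in range(i) if depths[j] < max_depth]
            parent = int(rng.choice(eligible))
            used = child_modifiers.setdefault(parent, set())
            free = [m for m in MODIFIERS if m not in used]
            modifier = free[int(rng.integers(len(free)))] if free else f"type{len(used)}"
            used.add(modifier)
            names.append(f"{modifier} {names[parent]}")
            depths.append(depths[parent] + 1)
            parents.append(parent)
    concepts = [(f"c{i:03d}", names[i]) for i in range(n_concepts)]
    edges = [
        (f"c{i:03d}", f"c{parents[i]:03d}")
        for i in range(n_concepts)
        if parents[i] is not None
    ]
    synonyms: dict[str, str] = {}
    if n_synonym_pairs:
        chosen = rng.choice(n_concepts, size=n_synonym_pairs, replace=False)
        taken = set(names)
        for i in sorted(int(c) for c in chosen):
            syn = _abbreviate(names[i])
            if syn in taken or syn in synonyms:
                syn = "".join(
                    ch for k, ch in enumerate(names[i])
                    if k == 0 or ch not in _VOWELS
                )
            if syn in taken or syn in synonyms:
                syn = f"{syn}{i}"
            synonyms[syn] = f"c{i:03d}"
    return Ontology(concepts=concepts, synonyms=synonyms, hypernym_edges=edges)


# ---------------------------------------------------------------------------
# concept signatures and repository config
# ---------------------------------------------------------------------------

def concept_signatures(
    ontology: Ontology,
    dictionary: ComponentDictionary,
    seed: int,
    support: int = 4,
) -> dict[str, np.ndarray]:
    """Fixed sparse non-negative loading signature per concept.

    Deterministic in (ontology concept order, dictionary size, seed); this is
    the stable, learnable decoding target — each concept maps to a small set
    of "brain systems" (dictionary components).
    """
    k = dictionary.n_components
    s = min(support, k)
    rng = np.random.default_rng([int(seed), 0x51D])
    out: dict[str, np.ndarray] = {}
    for cid in ontology.concept_ids:
        sig = np.zeros(k)
        idx = rng.choice(k, size=s, replace=False)
        sig[idx] = rng.uniform(0.5, 1.5, size=s)
        out[cid] = sig
    return out


@dataclass
class AnnotationNoise:
    """Per-label-mention corruption probabilities (independent Bernoullis)."""

    synonym: float = 0.05
    abbreviation: float = 0.05
    typo: float = 0.05
    omission: float = 0.05

    def __post_init__(self) -> None:
        for name in ("synonym", "abbreviation", "typo", "omission"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} probability must be in [0, 1]")

    @classmethod
    def none(cls) -> "AnnotationNoise":
        return cls(0.0, 0.0, 0.0, 0.0)


@dataclass
class ContaminantRates:
    """Per-map probabilities of each contamination (independent Bernoullis)."""

    thresholded: float = 0.05
    low_coverage: float = 0.05
    wrong_modality: float = 0.05

    def __post_init__(self) -> None:
        for name in ("thresholded", "low_coverage", "wrong_modality"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} probability must be in [0, 1]")

    @classmethod
    def none(cls) -> "ContaminantRates":
        return cls(0.0, 0.0, 0.0)


@dataclass
class SynthConfig:
    """Study conditions for one synthetic repository.

    Defaults define the standard high-signal regime used throughout the
    test-bed: three collections of 170 maps, concept effects well above the
    voxel noise floor, a per-collection baseline artifact of comparable
    magnitude to the signal (the confound that positive-part loadings
    mitigate), mild annotation corruption and a 5% rate of each contaminant.
    """

    n_collections: int = 3
    maps_per_collection: int = 170
    concept_effect_size: float = 3.0
    noise_sd: float = 0.5
    baseline_shift_sd: float = 2.0
    annotation_noise: AnnotationNoise = field(default_factory=AnnotationNoise)
    contaminant_rates: ContaminantRates = field(default_factory=ContaminantRates)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_collections < 1 or self.maps_per_collection < 1:
            raise ValueError("counts must be positive")
        if self.noise_sd < 0 or self.baseline_shift_sd < 0:
            raise ValueError("noise scales must be non-negative")
        if self.concept_effect_size < 0:
            raise ValueError("effect size must be non-negative")


# ---------------------------------------------------------------------------
# repository generation
# ---------------------------------------------------------------------------

def _corrupt_name(
    name: str,
    concept_id: str,
    ontology: Ontology,
    noise: AnnotationNoise,
    rng: np.random.Generator,
) -> str | None:
    """Apply the corruption operators to one label mention; None = omitted."""
    if rng.random() < noise.omission:
        return None
    out = name
    if rng.random() < noise.synonym:
        syns = [s for s, cid in ontology.synonyms.items() if cid == concept_id]
        if syns:
            out = syns[int(rng.integers(len(syns)))]
    if rng.random() < noise.abbreviation:
        out = " ".join(
            "".join(ch for k, ch in enumerate(w) if k == 0 or ch not in _VOWELS)
            for w in out.split()
        )
    if rng.random() < noise.typo and len(out) >= 3:
        i = int(rng.integers(len(out) - 1))
        out = out[:i] + out[i + 1] + out[i] + out[i + 2:]
    return out


def generate_repository(
    ontology: Ontology,
    dictionary: ComponentDictionary,
    config: SynthConfig,
) -> list[StatMap]:
    """Generate collections of annotated statistical maps with ground truth.

    Deterministic given config.seed.  Contaminated maps keep their annotations
    and truth labels but carry an internal `contaminant` flag ("+"-joined when
    several corruptions fire) and, for wrong-modality maps, a non-statistical
    `modality` metadata value.
    """
    if len(ontology) == 0:
        raise ValueError("ontology is empty")
    rng = np.random.default_rng(config.seed)
    signatures = concept_signatures(ontology, dictionary, config.seed)
    concept_ids = ontology.concept_ids
    n_vox = dictionary.n_voxels
    grid = dictionary.grid
    noise = config.annotation_noise
    rates = config.contaminant_rates
    maps: list[StatMap] = []
    for coll in range(config.n_collections):
        collection_id = f"coll{coll:02d}"
        # sparse non-negative control-condition pattern (a control task
        # engages a few systems), subtracted map-wise below
        k = dictionary.n_components
        control_loading = np.zeros(k)
        support = rng.choice(k, size=max(1, k // 10), replace=False)
        control_loading[support] = np.abs(
            rng.normal(0.0, config.baseline_shift_sd, size=support.size)
        )
        control_vox = dictionary.back_project(control_loading)
        for m in range(config.maps_per_collection):
            map_id = f"{collection_id}_map{m:03d}"
            n_active = int(rng.integers(1, 4))  # 1..3 concepts per map
            active = [
                concept_ids[i]
                for i in rng.choice(len(concept_ids), size=n_active, replace=False)
            ]
            signal = np.zeros(n_vox)
            for cid in active:
                signal += config.concept_effect_size * dictionary.back_project(signatures[cid])
            vox = signal - rng.uniform(0.5, 1.5) * control_vox
            if config.noise_sd > 0:
                vox = vox + rng.normal(0.0, config.noise_sd, size=n_vox)
            map_type = str(rng.choice(["z", "t", "beta"], p=[0.6, 0.25, 0.15]))
            if map_type == "t":
                vox = vox * rng.uniform(0.8, 1.25)
            elif map_type == "beta":
                vox = vox + rng.standard_t(3, size=n_vox) * config.noise_sd
            truth = ontology.hypernym_closure(set(active))
            mentions = []
            for cid in sorted(truth):
                corrupted = _corrupt_name(ontology.name_of(cid), cid, ontology, noise, rng)
                if corrupted is not None:
                    mentions.append(corrupted)
            annotations = {
                "name": f"statistical contrast {map_id}",
                "contrast_definition": "; ".join(mentions) + " vs. control baseline",
                "description": f"synthetic upload, batch {coll}",
            }
            flags: list[str] = []
            modality = "statistical"
            if rng.random() < rates.thresholded:
                flags.append("thresholded")
                cut = np.quantile(np.abs(vox), 0.6)
                vox = np.where(np.abs(vox) <= cut, 0.0, vox)
            if rng.random() < rates.low_coverage:
                flags.append("low_coverage")
                keep = rng.choice(n_vox, size=max(1, int(0.35 * n_vox)), replace=False)
                covered = np.zeros(n_vox, dtype=bool)
                covered[keep] = True
                vox = np.where(covered, vox, 0.0)
            if rng.random() < rates.wrong_modality:
                flags.append("wrong_modality")
                modality = "anatomical"
            maps.append(
                StatMap(
                    volume=grid.with_masked_values(vox),
                    map_type=map_type,
                    collection_id=collection_id,
                    map_id=map_id,
                    annotations=annotations,
                    truth_labels=frozenset(truth),
                    modality=modality,
                    contaminant="+".join(flags) if flags else None,
                )
            )
    return maps


# ---------------------------------------------------------------------------
# the standard study fixture
# ---------------------------------------------------------------------------

@dataclass
class StudyFixture:
    """A complete synthetic study: repository + ontology + dictionaries.

    The generating dictionary (the true basis of the signal) is distinct from
    the three analysis dictionaries, just as real maps are not generated by
    any reduction dictionary; the multi-resolution stack of analysis
    projections then has to recover the signal from misaligned bases.
    """

    ontology: Ontology
    generating_dictionary: ComponentDictionary
    analysis_dictionaries: list[ComponentDictionary]  # descending K: 1024, 512, 128
    config: SynthConfig
    maps: list[StatMap]

    @property
    def grid(self) -> Volume:
        return self.generating_dictionary.grid

    def signatures(self) -> dict[str, np.ndarray]:
        return concept_signatures(self.ontology, self.generating_dictionary, self.config.seed)


def standard_fixture(
    seed: int = 0,
    annotation_noise: AnnotationNoise | None = None,
    contaminant_rates: ContaminantRates | None = None,
    maps_per_collection: int = 170,
    n_collections: int = 3,
) -> StudyFixture:
    """The standard synthetic study: 3 collections x 170 maps, 20 concepts.

    High signal-to-noise regime on a 1200-voxel grid with a 256-component
    generating dictionary and 1024/512/128-component analysis dictionaries.
    """
    base = int(seed)
    grid = make_grid((12, 14, 12), voxel_size=4.0, border=1)
    ontology = generate_ontology(20, n_synonym_pairs=5, max_depth=3, seed=base + 1)
    gen_dict = generate_dictionary(256, grid, sparsity=0.99, overlap=0.3, seed=base + 2)
    dict_1024 = generate_dictionary(1024, grid, sparsity=0.995, overlap=0.3, seed=base + 3)
    dict_512 = generate_dictionary(512, grid, sparsity=0.99, overlap=0.3, seed=base + 4)
    dict_128 = generate_dictionary(128, grid, sparsity=0.975, overlap=0.3, seed=base + 5)
    config = SynthConfig(
        n_collections=n_collections,
        maps_per_collection=maps_per_collection,
        annotation_noise=annotation_noise or AnnotationNoise(),
        contaminant_rates=contaminant_rates or ContaminantRates(),
        seed=base + 6,
    )
    maps = generate_repository(ontology, gen_dict, config)
    return StudyFixture(
        ontology=ontology,
        generating_dictionary=gen_dict,
        analysis_dictionaries=[dict_1024, dict_512, dict_128],
        config=config,
        maps=maps,
    )


def representation_fixture(
    seed: int = 0,
    n_collections: int = 12,
    maps_per_collection: int = 60,
    noise_sd: float = 2.0,
    baseline_shift_sd: float = 4.0,
) -> StudyFixture:
    """A many-collection study for comparing signal representations.

    Differs from the standard fixture where it matters for representation
    choice: a larger grid (4096 voxels) so that no single dictionary spans
    the signal, many small collections so that control-condition baselines
    vary across the training set, a strong control amplitude, and voxel
    noise high enough to keep decoding off the ceiling.
    """
    base = int(seed)
    grid = make_grid((18, 18, 18), voxel_size=4.0, border=1)
    ontology = generate_ontology(20, n_synonym_pairs=5, max_depth=3, seed=base + 1)
    gen_dict = generate_dictionary(256, grid, sparsity=0.994, overlap=0.3, seed=base + 2)
    dict_1024 = generate_dictionary(1024, grid, sparsity=0.998, overlap=0.3, seed=base + 3)
    dict_512 = generate_dictionary(512, grid, sparsity=0.996, overlap=0.3, seed=base + 4)
    dict_128 = generate_dictionary(128, grid, sparsity=0.988, overlap=0.3, seed=base + 5)
    config = SynthConfig(
        n_collections=n_collections,
        maps_per_collection=maps_per_collection,
        noise_sd=noise_sd,
        baseline_shift_sd=baseline_shift_sd,
        annotation_noise=AnnotationNoise.none(),
        contaminant_rates=ContaminantRates.none(),
        seed=base + 6,
    )
    maps = generate_repository(ontology, gen_dict, config)
    return StudyFixture(
        ontology=ontology,
        generating_dictionary=gen_dict,
        analysis_dictionaries=[dict_1024, dict_512, dict_128],
        config=config,
        maps=maps,
    )
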