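"""End-to-end pipeline binding all stages of the decoding workflow.

Stages (in order): simulate -> prepare -> embed -> label -> train ->
evaluate -> interpret.  Each stage reads the artifacts of the previous one
from the workspace directory, writes its own artifacts plus a structured log
entry (inputs, parameters, in/out counts, seed) into ``state.json``, and is
skipped on re-run when its input hash is unchanged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from . import qc as nqc
from .embedding import compare_representations, embed_repository
from .interpret import encoding_map, sensitivity_map, threshold_for_display
from .labeling import LabelMatrix, RuleSet, Vocabulary, extract_exact_labels, hypernym_close, prune_vocabulary
from .metrics import evaluate_scores, leave_collections_out_split
from .model import ConceptDecoder, DecoderResults, ModelConfig, reference_config
from .ontology import Ontology
from .synth import standard_fixture
from .volumes import ComponentDictionary, Volume

logger = logging.getLogger("nnod")

STAGES = ("simulate", "prepare", "embed", "label", "train", "evaluate", "interpret")


@dataclass
class PipelineConfig:
    """Declarative configuration for a full run.

    Defaults reproduce the selected setting: stacked positive-part
    representation, one rectifier hidden layer of width 300, dropout 0.2,
    l1 = l2 = 0.001, WR@k at k = 10; the last collection is held out.
    """

    output_dir: str = "nnod_run"
    seed: int = 0
    synth: dict = field(default_factory=dict)      # overrides for the fixture
    qc: dict = field(default_factory=dict)         # qc_filter keyword overrides
    labeling: dict = field(default_factory=dict)   # min_count, max_abs_corr, rules
    representation: dict = field(default_factory=lambda: {"positive": True, "stacked": True})
    model: dict = field(default_factory=dict)      # ModelConfig field overrides
    training: dict = field(default_factory=dict)   # epochs, batch_size, learning_rate
    eval: dict = field(default_factory=lambda: {"k": 10})
    interpret: dict = field(default_factory=lambda: {"n_concepts": 3, "threshold": 0.95})
    compare_representations: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=str)


# ---------------------------------------------------------------------------
# workspace state and hashing
# ---------------------------------------------------------------------------

def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_state(outdir: Path) -> dict:
    path = outdir / "state.json"
    if path.exists():
        return json.loads(path.read_text())
    return {}


def _save_state(outdir: Path, state: dict) -> None:
    (outdir / "state.json").write_text(json.dumps(state, indent=1, default=str))


# stage -> stages whose outputs it consumes (hash-chained for staleness)
_UPSTREAM_STAGES = {
    "simulate": [],
    "prepare": ["simulate"],
    "embed": ["simulate", "prepare"],
    "label": ["simulate", "prepare"],
    "train": ["embed", "label"],
    "evaluate": ["train", "embed", "label"],
    "interpret": ["evaluate", "train", "embed", "label"],
}


def _stage_inputs_hash(
    config: PipelineConfig,
    section: dict,
    upstream: list[Path],
    upstream_records: list[dict],
) -> str:
    h = hashlib.sha256()
    h.update(json.dumps(section, sort_keys=True, default=str).encode())
    h.update(str(config.seed).encode())
    for path in upstream:
        if path.exists():
            h.update(path.name.encode())
            h.update(_file_hash(path).encode())
    for record in upstream_records:
        h.update(record.get("input_hash", "").encode())
        h.update(json.dumps(record.get("artifact_hashes", {}), sort_keys=True).encode())
    return h.hexdigest()


def _require(path: Path, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}; run the '{produced_by}' stage first"
        )
    return path


def save_dictionary(d: ComponentDictionary, path: Path) -> None:
    np.savez_compressed(
        path,
        components=d.components,
        mask=d.grid.mask,
        affine=d.grid.affine,
    )


def load_dictionary(path: Path) -> ComponentDictionary:
    data = np.load(path)
    grid = Volume(
        data=np.zeros(data["mask"].shape),
        affine=data["affine"],
        mask=data["mask"],
    )
    return ComponentDictionary(components=data["components"], grid=grid)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_stage(stage: str, config: PipelineConfig, force: bool = False) -> dict:
    """Execute one pipeline stage; returns its structured log entry.

    Stages are re-runnable: when the hash of the stage's configuration and
    upstream artifacts matches the recorded state and the artifacts exist,
    the stage is skipped.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    state = _load_state(outdir)
    runner = globals()[f"_stage_{stage}"]
    consumed = {
        "simulate": ["synth"],
        "prepare": ["qc"],
        "embed": ["representation"],
        "label": ["labeling", "eval"],
        "train": ["model", "training", "eval"],
        "evaluate": ["eval", "compare_representations"],
        "interpret": ["interpret", "representation"],
    }[stage]
    section = {name: getattr(config, name) for name in consumed}
    upstream = _stage_upstream(stage, outdir)
    for path in upstream:
        _require(path, _producer_of(path, outdir))
    upstream_records = [state.get(us, {}) for us in _UPSTREAM_STAGES[stage]]
    input_hash = _stage_inputs_hash(config, section, upstream, upstream_records)
    record = state.get(stage)
    if (
        not force
        and record
        and record.get("input_hash") == input_hash
        and all(Path(p).exists() for p in record.get("artifacts", []))
    ):
        logger.info("stage %s up to date; skipped", stage)
        record["skipped"] = True
        return record
    t0 = time.time()
    entry = runner(config, outdir)
    entry.update(
        {
            "stage": stage,
            "seed": config.seed,
            "input_hash": input_hash,
            "elapsed_s": round(time.time() - t0, 3),
            "skipped": False,
        }
    )
    entry["artifact_hashes"] = {
        p: _file_hash(Path(p)) for p in entry.get("artifacts", []) if Path(p).is_file()
    }
    state[stage] = entry
    _save_state(outdir, state)
    logger.info("stage %s done in %.1fs", stage, entry["elapsed_s"])
    return entry


def run_all(config: PipelineConfig, force: bool = False) -> dict:
    return {stage: run_stage(stage, config, force=force) for stage in STAGES}


def _producer_of(path: Path, outdir: Path) -> str:
    rel = path.relative_to(outdir)
    head = rel.parts[0]
    by_artifact = {
        "repository": "simulate",
        "dictionaries": "simulate",
        "kept_manifest.json": "prepare",
        "qc_report.csv": "prepare",
        "embeddings.csv": "embed",
        "labels.csv": "label",
        "model": "train",
        "eval.json": "evaluate",
    }
    return by_artifact.get(head, "an earlier stage")


def _stage_upstream(stage: str, outdir: Path) -> list[Path]:
    deps = {
        "simulate": [],
        "prepare": [outdir / "repository" / "mask.nii.gz"],
        "embed": [outdir / "kept_manifest.json"],
        "label": [outdir / "kept_manifest.json"],
        "train": [outdir / "embeddings.csv", outdir / "labels.csv"],
        "evaluate": [outdir / "embeddings.csv", outdir / "labels.csv",
                     outdir / "model" / "config.json"],
        "interpret": [outdir / "embeddings.csv", outdir / "labels.csv",
                      outdir / "model" / "config.json"],
    }
    return deps[stage]


def _fixture_for(config: PipelineConfig):
    from .synth import AnnotationNoise, ContaminantRates

    kw = dict(config.synth)
    noise = kw.pop("annotation_noise", None)
    rates = kw.pop("contaminant_rates", None)
    return standard_fixture(
        seed=config.seed,
        annotation_noise=AnnotationNoise(**noise) if isinstance(noise, dict) else noise,
        contaminant_rates=ContaminantRates(**rates) if isinstance(rates, dict) else rates,
        **kw,
    )


def _stage_simulate(config: PipelineConfig, outdir: Path) -> dict:
    fixture = _fixture_for(config)
    repo_dir = outdir / "repository"
    nio.write_repository(fixture.maps, repo_dir)
    fixture.ontology.save(repo_dir / "ontology.json")
    dict_dir = outdir / "dictionaries"
    dict_dir.mkdir(exist_ok=True)
    save_dictionary(fixture.generating_dictionary, dict_dir / "generating.npz")
    for d in fixture.analysis_dictionaries:
        save_dictionary(d, dict_dir / f"analysis_{d.n_components}.npz")
    return {
        "counts": {"maps": len(fixture.maps), "concepts": len(fixture.ontology)},
        "artifacts": [str(repo_dir / "mask.nii.gz"), str(repo_dir / "ontology.json"),
                      str(dict_dir / "generating.npz")],
    }


def _load_common(outdir: Path):
    maps = nio.read_repository(outdir / "repository")
    ontology = Ontology.load(outdir / "repository" / "ontology.json")
    dict_paths = sorted(
        (outdir / "dictionaries").glob("analysis_*.npz"),
        key=lambda p: -int(p.stem.split("_")[1]),
    )
    dictionaries = [load_dictionary(p) for p in dict_paths]
    return maps, ontology, dictionaries


def _stage_prepare(config: PipelineConfig, outdir: Path) -> dict:
    maps, _, dictionaries = _load_common(outdir)
    target = dictionaries[0].grid
    maps = [nqc.resample_to_common(sm, target) for sm in maps]
    kept, reports = nqc.qc_filter(maps, **config.qc)
    kept, dedup_reports = nqc.deduplicate(kept, return_reports=True)
    all_reports = reports + [r for r in dedup_reports if r.decision == "rejected"]
    nqc.reports_to_frame(all_reports).to_csv(outdir / "qc_report.csv", index=False)
    (outdir / "kept_manifest.json").write_text(
        json.dumps([sm.map_id for sm in kept])
    )
    return {
        "counts": {"input": len(maps), "kept": len(kept),
                   "rejected": len(maps) - len(kept)},
        "artifacts": [str(outdir / "qc_report.csv"), str(outdir / "kept_manifest.json")],
    }


def _kept_maps(config: PipelineConfig, outdir: Path):
    maps, ontology, dictionaries = _load_common(outdir)
    kept_ids = set(json.loads((outdir / "kept_manifest.json").read_text()))
    target = dictionaries[0].grid
    kept = [nqc.resample_to_common(sm, target) for sm in maps if sm.map_id in kept_ids]
    return kept, ontology, dictionaries


def _stage_embed(config: PipelineConfig, outdir: Path) -> dict:
    kept, _, dictionaries = _kept_maps(config, outdir)
    rep = config.representation
    dicts = dictionaries if rep.get("stacked", True) else dictionaries[:1]
    feats = embed_repository(kept, dicts, positive=rep.get("positive", True))
    feats.to_csv(outdir / "embeddings.csv")
    return {
        "counts": {"maps": feats.shape[0], "features": feats.shape[1]},
        "artifacts": [str(outdir / "embeddings.csv")],
    }


def _test_collections(config: PipelineConfig, maps) -> set[str]:
    explicit = config.eval.get("test_collections")
    if explicit:
        return set(explicit)
    return {sorted({sm.collection_id for sm in maps})[-1]}


def _stage_label(config: PipelineConfig, outdir: Path) -> dict:
    kept, ontology, _ = _kept_maps(config, outdir)
    vocabulary = Vocabulary(ontology.concept_ids)
    rules_path = config.labeling.get("rules")
    test_colls = _test_collections(config, kept)
    if rules_path:
        # curation rules apply to training collections only
        from .labeling import apply_ruleset

        rules = RuleSet(**json.loads(Path(rules_path).read_text()))
        train_maps = [sm for sm in kept if sm.collection_id not in test_colls]
        test_maps = [sm for sm in kept if sm.collection_id in test_colls]
        lm_train = apply_ruleset(train_maps, ontology, vocabulary, rules)
        lm_test = extract_exact_labels(test_maps, ontology, vocabulary)
        common = [c for c in lm_train.frame.columns if c in lm_test.frame.columns]
        frame = pd.concat([lm_train.frame[common], lm_test.frame[common]])
        lm = LabelMatrix(frame)
    else:
        lm = extract_exact_labels(kept, ontology, vocabulary)
    lm = hypernym_close(lm, ontology)
    min_count = config.labeling.get("min_count", 10)
    max_corr = config.labeling.get("max_abs_corr", 0.95)
    manifest = nio.collection_of(kept)
    train_rows = [m for m in lm.map_ids if manifest[m] not in test_colls]
    _, pruned_train = prune_vocabulary(
        LabelMatrix(lm.frame.loc[train_rows]), min_count=min_count, max_abs_corr=max_corr
    )
    lm = LabelMatrix(lm.frame[list(pruned_train.frame.columns)])
    lm = LabelMatrix(lm.frame.loc[lm.frame.sum(axis=1) > 0])
    lm.to_csv(outdir / "labels.csv")
    return {
        "counts": {"labeled_maps": lm.frame.shape[0], "vocabulary": lm.frame.shape[1]},
        "artifacts": [str(outdir / "labels.csv")],
    }


def _load_xy(outdir: Path):
    feats = pd.read_csv(outdir / "embeddings.csv", index_col="map_id")
    lm = LabelMatrix.from_csv(outdir / "labels.csv")
    common = [m for m in lm.map_ids if m in set(feats.index)]
    return feats.loc[common], LabelMatrix(lm.frame.loc[common])


def _stage_train(config: PipelineConfig, outdir: Path) -> dict:
    feats, lm = _load_xy(outdir)
    maps = nio.read_repository(outdir / "repository")
    test_colls = _test_collections(config, maps)
    manifest = nio.collection_of(maps)
    train_ids, _, _ = leave_collections_out_split(lm, manifest, test_colls)
    cfg = reference_config(feats.shape[1], lm.frame.shape[1], seed=config.seed)
    for k, v in config.model.items():
        cfg = ModelConfig(**{**{f: getattr(cfg, f) for f in cfg.__dataclass_fields__}, k: v})
    decoder = ConceptDecoder(feats.loc[train_ids], lm.frame.loc[train_ids], cfg)
    results = decoder.fit(**config.training)
    results.save(outdir / "model")
    (outdir / "train_summary.txt").write_text(results.summary() + "\n")
    return {
        "counts": {"train_maps": len(train_ids), "parameters": results.n_parameters},
        "test_collections": sorted(test_colls),
        "artifacts": [str(outdir / "model" / "config.json"),
                      str(outdir / "model" / "weights.npz")],
    }


def _stage_evaluate(config: PipelineConfig, outdir: Path) -> dict:
    feats, lm = _load_xy(outdir)
    results = DecoderResults.load(outdir / "model")
    maps = nio.read_repository(outdir / "repository")
    test_colls = _test_collections(config, maps)
    manifest = nio.collection_of(maps)
    train_ids, test_ids, evaluable = leave_collections_out_split(lm, manifest, test_colls)
    cols = [lm.frame.columns.get_loc(c) for c in evaluable]
    scores = results.decision_function(feats.loc[test_ids].to_numpy())
    k = min(config.eval.get("k", 10), len(evaluable))
    report = evaluate_scores(
        lm.frame.loc[test_ids].to_numpy()[:, cols], scores[:, cols],
        label_names=evaluable, k=k,
    )
    (outdir / "eval.json").write_text(json.dumps(report.to_dict(), indent=1))
    report.to_frame().to_csv(outdir / "per_label_auc.csv", index=False)
    entry = {
        "counts": {"test_maps": len(test_ids), "evaluable_labels": len(evaluable)},
        "macro_auc": report.macro_auc,
        "wr_at_k": report.wr_at_k,
        "artifacts": [str(outdir / "eval.json"), str(outdir / "per_label_auc.csv")],
    }
    if config.compare_representations:
        kept, _, dictionaries = _kept_maps(config, outdir)
        labeled = [sm for sm in kept if sm.map_id in set(lm.map_ids)]
        grid = compare_representations(labeled, dictionaries, lm, test_colls, k=k)
        grid.to_csv(outdir / "representation_grid.csv", index=False)
        entry["artifacts"].append(str(outdir / "representation_grid.csv"))
    return entry


def _stage_interpret(config: PipelineConfig, outdir: Path) -> dict:
    import nibabel as nib

    feats, lm = _load_xy(outdir)
    results = DecoderResults.load(outdir / "model")
    _, _, dictionaries = _load_common(outdir)
    rep = config.representation
    dicts = dictionaries if rep.get("stacked", True) else dictionaries[:1]
    report = json.loads((outdir / "eval.json").read_text())
    ranked = sorted(report["per_label_auc"].items(), key=lambda kv: -kv[1])
    chosen = [c for c, _ in ranked[: config.interpret.get("n_concepts", 3)]]
    q = config.interpret.get("threshold", 0.95)
    map_dir = outdir / "concept_maps"
    map_dir.mkdir(exist_ok=True)
    index = []
    X = feats.to_numpy()
    for concept in chosen:
        for kind, cmap in (
            ("decoding", sensitivity_map(results, X, dicts, concept)),
            ("encoding", encoding_map(feats, lm, dicts, concept)),
        ):
            cmap = threshold_for_display(cmap, q)
            fname = f"{concept}_{kind}.nii.gz"
            nib.save(nio.volume_to_image(cmap.volume), map_dir / fname)
            index.append({"concept": concept, "kind": kind, "file": fname,
                          "threshold_percentile": q})
    (map_dir / "index.json").write_text(json.dumps(index, indent=1))
    return {
        "counts": {"concept_maps": len(index)},
        "artifacts": [str(map_dir / "index.json")],
    }


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def report(config: PipelineConfig) -> str:
    """Human-readable summary of a completed run (twin of eval.json)."""
    outdir = Path(config.output_dir)
    _require(outdir / "eval.json", "evaluate")
    data = json.loads((outdir / "eval.json").read_text())
    lines = [
        "Decoding evaluation (held-out collections)",
        "=" * 46,
        f"macro AUC : {data['macro_auc']:.3f}",
        f"WR@{data['k']:<3d}    : {data['wr_at_k']:.3f}",
        "",
        f"{'label':<32s} AUC",
    ]
    for label, auc in sorted(data["per_label_auc"].items(), key=lambda kv: -kv[1]):
        lines.append(f"{label:<32s} {auc:.3f}")
    if data.get("excluded_labels"):
        lines.append("")
        lines.append("excluded labels:")
        for label, reason in data["excluded_labels"].items():
            lines.append(f"  {label}: {reason}")
    grid_path = outdir / "representation_grid.csv"
    if grid_path.exists():
        lines.append("")
        lines.append("representation comparison:")
        lines.append(pd.read_csv(grid_path).to_string(index=False))
    return "\n".join(lines)
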