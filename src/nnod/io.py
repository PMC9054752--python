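"""Reading and writing repository artifacts.

On disk a repository is: one NIfTI-1 file per map, a shared brain mask
(`mask.nii.gz`), one JSON manifest per collection (map_id, file, map_type,
modality, annotations, collection_id), an ontology JSON, and an optional
ground-truth CSV (map_id rows x concept-id columns, 0/1).  Real exports that
follow the same manifest schema are read identically.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .ontology import Ontology
from .volumes import StatMap, Volume


def volume_to_image(volume: Volume) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(volume.data, dtype=np.float32), volume.affine)


def image_to_volume(img: nib.Nifti1Image, mask: np.ndarray) -> Volume:
    data = np.asarray(img.get_fdata(), dtype=float)
    return Volume(data=data, affine=np.asarray(img.affine), mask=mask)


def write_repository(maps: list[StatMap], outdir: str | Path) -> Path:
    """Write maps, per-collection manifests, the shared mask and ground truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if not maps:
        raise ValueError("no maps to write")
    grid = maps[0].volume
    nib.save(
        nib.Nifti1Image(grid.mask.astype(np.uint8), grid.affine),
        outdir / "mask.nii.gz",
    )
    by_collection: dict[str, list[dict]] = {}
    truth_rows: dict[str, frozenset[str]] = {}
    for sm in maps:
        fname = f"{sm.map_id}.nii.gz"
        nib.save(volume_to_image(sm.volume), outdir / fname)
        by_collection.setdefault(sm.collection_id, []).append(
            {
                "map_id": sm.map_id,
                "file": fname,
                "map_type": sm.map_type,
                "modality": sm.modality,
                "annotations": sm.annotations,
                "collection_id": sm.collection_id,
            }
        )
        if sm.truth_labels is not None:
            truth_rows[sm.map_id] = sm.truth_labels
    for cid, entries in by_collection.items():
        (outdir / f"collection_{cid}.json").write_text(json.dumps(entries, indent=1))
    if truth_rows:
        concepts = sorted(set().union(*truth_rows.values()))
        df = pd.DataFrame(
            [[int(c in labels) for c in concepts] for labels in truth_rows.values()],
            index=list(truth_rows.keys()),
            columns=concepts,
        )
        df.index.name = "map_id"
        df.to_csv(outdir / "truth_labels.csv")
    return outdir


def read_repository(directory: str | Path) -> list[StatMap]:
    """Load a repository written by `write_repository` (or the same schema)."""
    directory = Path(directory)
    mask_img = nib.load(directory / "mask.nii.gz")
    mask = np.asarray(mask_img.get_fdata()) > 0.5
    truth_path = directory / "truth_labels.csv"
    truth: dict[str, frozenset[str]] = {}
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, index_col="map_id")
        for map_id, row in tdf.iterrows():
            truth[str(map_id)] = frozenset(c for c, v in row.items() if v)
    maps: list[StatMap] = []
    for manifest in sorted(directory.glob("collection_*.json")):
        for entry in json.loads(manifest.read_text()):
            img = nib.load(directory / entry["file"])
            maps.append(
                StatMap(
                    volume=image_to_volume(img, mask),
                    map_type=entry["map_type"],
                    collection_id=entry["collection_id"],
                    map_id=entry["map_id"],
                    annotations=dict(entry.get("annotations", {})),
                    truth_labels=truth.get(entry["map_id"]),
                    modality=entry.get("modality", "statistical"),
                )
            )
    return maps


def write_ontology(ontology: Ontology, path: str | Path) -> None:
    ontology.save(path)


def read_ontology(path: str | Path) -> Ontology:
    return Ontology.load(path)


def collection_of(maps: list[StatMap]) -> pd.Series:
    """map_id -> collection_id lookup used by split construction."""
    return pd.Series({sm.map_id: sm.collection_id for sm in maps})
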