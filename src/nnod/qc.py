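"""Map selection, standardization to a common grid, and deduplication.

Repository uploads are heterogeneous: some are not statistical maps at all,
some are thresholded (mostly exact zeros), some barely cover the brain, and
some carry values implausible for contrast-effect statistics.  This module
keeps the usable maps, resamples everything to one grid and mask, and
collapses exact duplicates.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from nilearn.image import resample_img

from .io import volume_to_image
from .volumes import StatMap, Volume

REASONS = ("wrong_modality", "low_coverage", "thresholded", "extreme_values", "duplicate")


@dataclass
class QCReport:
    map_id: str
    decision: str  # "kept" | "rejected"
    reasons: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.decision not in ("kept", "rejected"):
            raise ValueError("decision must be kept or rejected")
        if not self.reasons <= set(REASONS):
            raise ValueError(f"unknown reasons {self.reasons - set(REASONS)}")
        if (self.decision == "rejected") != bool(self.reasons):
            raise ValueError("rejected iff reasons nonempty")


def qc_filter(
    maps: list[StatMap],
    coverage_min: float = 0.5,
    zero_fraction_max: float = 0.5,
    value_cap: float = 50.0,
    beta_value_cap: float = 500.0,
) -> tuple[list[StatMap], list[QCReport]]:
    """Select usable statistical maps; one QCReport per input map.

    Rules: non-statistical modality metadata; in-mask nonzero coverage below
    `coverage_min`; in-mask exact-zero fraction above `zero_fraction_max` (a
    thresholding proxy); |value| above `value_cap` for z/t maps.  Beta maps
    have arbitrary units and are exempt from `value_cap`, but wildly extreme
    values (above `beta_value_cap`) are still excluded.
    """
    for name, v in (("coverage_min", coverage_min), ("zero_fraction_max", zero_fraction_max)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1]")
    if value_cap <= 0 or beta_value_cap <= 0:
        raise ValueError("value caps must be positive")
    kept: list[StatMap] = []
    reports: list[QCReport] = []
    for sm in maps:
        reasons: set[str] = set()
        if sm.modality != "statistical":
            reasons.add("wrong_modality")
        values = sm.volume.masked_values()
        n = values.size
        nonzero = float(np.count_nonzero(values)) / n if n else 0.0
        if nonzero < coverage_min:
            reasons.add("low_coverage")
        if (1.0 - nonzero) > zero_fraction_max:
            reasons.add("thresholded")
        vmax = float(np.max(np.abs(values))) if n else 0.0
        cap = beta_value_cap if sm.map_type == "beta" else value_cap
        if vmax > cap:
            reasons.add("extreme_values")
        if reasons:
            reports.append(QCReport(sm.map_id, "rejected", reasons))
        else:
            reports.append(QCReport(sm.map_id, "kept", set()))
            kept.append(sm)
    return kept, reports


def resample_to_common(sm: StatMap, target: Volume) -> StatMap:
    """Resample a map onto the target grid and mask.

    Trilinear (continuous) interpolation for the data; values outside the
    target mask are set to zero.  A map already on the target geometry is
    returned with its values untouched apart from out-of-mask zeroing.
    """
    if sm.volume.same_geometry(target):
        data = np.where(target.mask, sm.volume.data, 0.0)
    else:
        resampled = resample_img(
            volume_to_image(sm.volume),
            target_affine=target.affine,
            target_shape=target.shape,
            interpolation="continuous",
            force_resample=True,
            copy_header=True,
        )
        data = np.where(target.mask, np.asarray(resampled.get_fdata(), dtype=float), 0.0)
    volume = Volume(data=data, affine=target.affine.copy(), mask=target.mask.copy())
    return sm.replace(volume=volume)


def content_hash(sm: StatMap) -> str:
    """Hash of the standardized in-mask values (exact duplicate detection)."""
    return hashlib.sha256(np.ascontiguousarray(sm.volume.masked_values()).tobytes()).hexdigest()


def deduplicate(
    maps: list[StatMap],
    return_reports: bool = False,
) -> list[StatMap] | tuple[list[StatMap], list[QCReport]]:
    """Collapse exact-duplicate volumes; the first occurrence survives."""
    seen: set[str] = set()
    kept: list[StatMap] = []
    reports: list[QCReport] = []
    for sm in maps:
        h = content_hash(sm)
        if h in seen:
            reports.append(QCReport(sm.map_id, "rejected", {"duplicate"}))
        else:
            seen.add(h)
            kept.append(sm)
            reports.append(QCReport(sm.map_id, "kept", set()))
    if return_reports:
        return kept, reports
    return kept


def reports_to_frame(reports: list[QCReport]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "map_id": [r.map_id for r in reports],
            "decision": [r.decision for r in reports],
            "reasons": ["|".join(sorted(r.reasons)) for r in reports],
        }
    )
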