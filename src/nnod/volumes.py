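"""Core spatial containers: brain volumes, statistical maps, component dictionaries.

A statistical map is a 3-D grid of per-voxel statistics (z, t or beta values)
from a task-vs-control contrast.  All analysis happens on the voxels inside a
binary brain mask shared across maps; a component dictionary is a set of
sparse non-negative spatial modes over those in-mask voxels, used for
dimension reduction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

MAP_TYPES = ("z", "t", "beta")


@dataclass
class Volume:
    """A 3-D real-valued grid with an affine voxel-to-world transform and a mask.

    Out-of-mask values carry no signal meaning and are ignored by every
    downstream computation.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if self.data.shape != self.mask.shape:
            raise ValueError("data and mask shapes differ")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels_in_mask(self) -> int:
        return int(self.mask.sum())

    def masked_values(self) -> np.ndarray:
        """In-mask voxel values as a flat vector (fixed C-order convention)."""
        return self.data[self.mask]

    def with_masked_values(self, values: np.ndarray) -> "Volume":
        """New volume with `values` placed at in-mask voxels, zero elsewhere."""
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_voxels_in_mask,):
            raise ValueError("value vector length does not match mask size")
        data = np.zeros(self.shape)
        data[self.mask] = values
        return Volume(data=data, affine=self.affine.copy(), mask=self.mask.copy())

    def same_geometry(self, other: "Volume", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.affine, other.affine, atol=atol)
            and bool(np.array_equal(self.mask, other.mask))
        )


def make_grid(
    shape: tuple[int, int, int] = (12, 14, 12),
    voxel_size: float = 4.0,
    border: int = 1,
) -> Volume:
    """A zero-valued volume whose mask is the grid interior.

    The `border`-voxel shell is out of mask, mimicking the out-of-brain
    margin of a standardized template grid.
    """
    mask = np.zeros(shape, dtype=bool)
    sl = tuple(slice(border, s - border) for s in shape)
    mask[sl] = True
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return Volume(data=np.zeros(shape), affine=affine, mask=mask)


@dataclass
class StatMap:
    """One statistical brain volume plus its repository metadata.

    `annotations` are free-text fields in the style of repository uploads
    (name, contrast definition, task description...); they are the only
    source of supervision for label extraction.  `truth_labels` exists only
    for synthetic maps and holds the hypernym-closed set of generating
    concept ids.  `contaminant` is an internal generator flag naming the
    corruption applied (thresholded / low_coverage / wrong_modality), unset
    for clean maps.
    """

    volume: Volume
    map_type: str
    collection_id: str
    map_id: str
    annotations: dict[str, str] = field(default_factory=dict)
    truth_labels: frozenset[str] | None = None
    modality: str = "statistical"
    contaminant: str | None = None

    def __post_init__(self) -> None:
        if self.map_type not in MAP_TYPES:
            raise ValueError(f"map_type must be one of {MAP_TYPES}")

    def replace(self, **kw) -> "StatMap":
        return dataclasses.replace(self, **kw)


@dataclass
class ComponentDictionary:
    """K sparse non-negative spatial components over the in-mask voxels.

    `components` is K x V where V is the in-mask voxel count of `grid`
    (order given by Volume.masked_values).  Components may overlap but each
    has at least one nonzero voxel and a strictly positive fraction of zeros.
    """

    components: np.ndarray
    grid: Volume

    def __post_init__(self) -> None:
        self.components = np.asarray(self.components, dtype=float)
        if self.components.ndim != 2:
            raise ValueError("components must be a K x V matrix")
        if self.components.shape[1] != self.grid.n_voxels_in_mask:
            raise ValueError("component length does not match grid mask size")
        if np.any(self.components < 0):
            raise ValueError("components must be non-negative")
        nonzero = (self.components != 0).sum(axis=1)
        if np.any(nonzero == 0):
            raise ValueError("every component needs at least one nonzero voxel")
        if np.any(nonzero == self.components.shape[1]):
            raise ValueError("every component must have positive sparsity")

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.components.shape[1]

    def back_project(self, loadings: np.ndarray) -> np.ndarray:
        """Map component loadings back to an in-mask voxel vector.

        Accepts a (K,) vector or an (n, K) batch; returns (V,) or (n, V).
        """
        loadings = np.asarray(loadings, dtype=float)
        return loadings @ self.components

    def component_volume(self, j: int) -> Volume:
        return self.grid.with_masked_values(self.components[j])
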