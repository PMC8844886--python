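"""Core data containers shared across the pipeline stages.

Conventions: voxel arrays are indexed (Z, Y, X) (channel-first (C, Z, Y, X)
for multi-channel fields); voxel sizes and centroids follow the same axis
order; physical units are micrometers unless a name says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CHANNEL_ROLES = ("FISH_probe", "IF_TH", "IF_HA")


@dataclass
class ImageField:
    """A calibrated multi-channel 3D image.

    Parameters
    ----------
    voxels : ndarray, shape (C, Z, Y, X)
        Non-negative intensities.
    voxel_size : (float, float, float)
        Physical voxel edge lengths in μm, ordered (z, y, x).
    channel_roles : dict[int, str]
        Maps channel index to one of ``FISH_probe``, ``IF_TH``, ``IF_HA``.
    """

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_roles: dict[int, str]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValueError("voxels must be a (C, Z, Y, X) array")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError("voxel_size must be three positive values (z, y, x)")
        self.voxel_size = vs
        for c, role in self.channel_roles.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r} for channel {c}")
            if not (0 <= int(c) < self.voxels.shape[0]):
                raise ValueError(f"channel index {c} out of range")
        if not self.channel_roles:
            raise ValueError("at least one channel role required")

    @property
    def shape(self) -> tuple[int, int, int]:
        """Spatial shape (Z, Y, X)."""
        return self.voxels.shape[1:]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in μm³."""
        return float(np.prod(self.voxel_size))

    def channel(self, role_or_index) -> np.ndarray:
        """Return one channel's (Z, Y, X) array by role name or index."""
        if isinstance(role_or_index, str):
            hits = [c for c, r in self.channel_roles.items() if r == role_or_index]
            if not hits:
                raise KeyError(f"no channel with role {role_or_index!r}")
            return self.voxels[hits[0]]
        return self.voxels[int(role_or_index)]


@dataclass
class NeuriteMask:
    """Binary mask of marker-positive voxels with its provenance."""

    mask: np.ndarray
    threshold_used: float
    source_channel: int | str

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.threshold_used < 0:
            raise ValueError("threshold_used must be non-negative")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class Punctum:
    """A detected diffraction-limited spot."""

    centroid: tuple[float, float, float]  # (z, y, x), voxel units, 0-based
    diameter: float  # μm
    quality: float
    contrast: float
    total_intensity: float


@dataclass
class PunctaSet:
    """Detected spots plus the detection settings that produced them."""

    puncta: list[Punctum] = field(default_factory=list)
    diameter_range: tuple[float, float] = (0.5, 1.0)
    image_shape: tuple[int, int, int] | None = None  # (Z, Y, X) of the source field

    def __len__(self) -> int:
        return len(self.puncta)

    def __iter__(self):
        return iter(self.puncta)

    @property
    def centroids(self) -> np.ndarray:
        """(N, 3) array of (z, y, x) centroids in voxel units."""
        if not self.puncta:
            return np.zeros((0, 3))
        return np.array([p.centroid for p in self.puncta], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z": [p.centroid[0] for p in self.puncta],
                "y": [p.centroid[1] for p in self.puncta],
                "x": [p.centroid[2] for p in self.puncta],
                "diameter_um": [p.diameter for p in self.puncta],
                "quality": [p.quality for p in self.puncta],
                "contrast": [p.contrast for p in self.puncta],
                "total_intensity": [p.total_intensity for p in self.puncta],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, diameter_range=(0.5, 1.0)) -> "PunctaSet":
        puncta = [
            Punctum(
                centroid=(float(r.z), float(r.y), float(r.x)),
                diameter=float(r.diameter_um),
                quality=float(r.quality),
                contrast=float(r.contrast),
                total_intensity=float(r.total_intensity),
            )
            for r in df.itertuples()
        ]
        return cls(puncta=puncta, diameter_range=tuple(diameter_range))


@dataclass
class DendriteTrace:
    """An ordered voxel path (a traced dendrite) plus its 3D fill.

    ``path`` is an (N, 3) integer array of (z, y, x) voxel coordinates in
    traversal order; ``filled_mask`` is the binary 3D fill used for the
    puncta-overlap rule; ``path_length`` is the polyline length in μm.
    """

    path: np.ndarray
    filled_mask: np.ndarray
    path_length: float
    voxel_size: tuple[float, float, float]
    distance_class: str = "none"  # proximal_50_200 | distal_gt200 | none

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=int)
        self.filled_mask = np.asarray(self.filled_mask, dtype=bool)
        if self.path_length < 0:
            raise ValueError("path_length must be non-negative")
        if self.path.size and not self.filled_mask[tuple(self.path.T)].all():
            raise ValueError("filled_mask must contain every path voxel")


@dataclass
class SomaROI:
    """A 2D region of interest on a maximum projection."""

    mask: np.ndarray  # boolean (Y, X)
    label: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("SomaROI mask is empty")


@dataclass
class ColocalizationReport:
    """Per-punctum neighborhood/mask overlap and its summary."""

    per_punctum: pd.DataFrame  # overlap_fraction, colocalized, n_neighborhood_voxels
    n_puncta: int
    n_colocalized: int
    percent_colocalized: float
    density_per_volume: float | None = None  # puncta / μm³, filled in later


@dataclass
class CountMatrix:
    """Gene × sample integer counts with per-sample factor metadata."""

    counts: pd.DataFrame  # genes in rows, samples in columns
    metadata: pd.DataFrame  # indexed by sample id

    def __post_init__(self) -> None:
        missing = [s for s in self.counts.columns if s not in self.metadata.index]
        if missing:
            raise ValueError(f"metadata missing for samples: {missing}")
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def genes(self) -> Sequence[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> Sequence[str]:
        return list(self.counts.columns)
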