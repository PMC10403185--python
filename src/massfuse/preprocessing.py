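"""Lesion ROI extraction and model-input assembly.

Pipeline per case: minimum bounding box of the mask's nonzero voxels,
symmetric expansion to a cube, physical-extent crop + trilinear resample of
every modality to a fixed isotropic side, per-cube min-max normalization,
optional Sobel gradient-magnitude channels, and channel-dimension fusion.

Gradient channels are computed AFTER intensity normalization and are
themselves min-max re-normalized so all channels share the [0, 1] scale.
Gradient direction is computed but never fused (only magnitude images are
model inputs).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .data_io import ModalityVolume, SegmentationMask

logger = logging.getLogger(__name__)

#: the printed horizontal-derivative kernel; the vertical one is below
SOBEL_KX = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_KY = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], dtype=float)


@dataclass
class BoundingCube:
    """Inclusive voxel-index extents on the reference grid, plus physical extent."""

    min_index: tuple[int, int, int]
    max_index: tuple[int, int, int]
    cube_side: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if any(a > b for a, b in zip(self.min_index, self.max_index)):
            raise ValueError("min_index must be <= max_index per axis")
        extents = [b - a + 1 for a, b in zip(self.min_index, self.max_index)]
        if self.cube_side < max(extents):
            raise ValueError("cube_side smaller than the box extent")

    @property
    def min_phys(self) -> tuple[float, float, float]:
        return tuple(i * s for i, s in zip(self.min_index, self.spacing))

    @property
    def max_phys(self) -> tuple[float, float, float]:
        return tuple(i * s for i, s in zip(self.max_index, self.spacing))

    def to_dict(self) -> dict:
        return {"min_index": list(self.min_index), "max_index": list(self.max_index),
                "cube_side": self.cube_side, "spacing": list(self.spacing)}


@dataclass
class NormalizedCube:
    voxels: np.ndarray
    source_modality: str
    case_id: str = ""
    x_min: float = 0.0
    x_max: float = 1.0


@dataclass
class GradientChannels:
    magnitude: np.ndarray
    direction: np.ndarray | None = None


@dataclass
class ModelInputTensor:
    channels: np.ndarray            # (C, side, side, side)
    channel_labels: list[str]
    case_id: str
    label: str

    def __post_init__(self) -> None:
        if self.channels.ndim != 4:
            raise ValueError("channels must be a 4D (C, D, H, W) array")
        if self.channels.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel required")

    def save(self, path: str | Path, cube: BoundingCube | None = None,
             norm_ranges: dict | None = None) -> Path:
        path = Path(path)
        np.savez(path, channels=self.channels,
                 channel_labels=np.array(self.channel_labels),
                 case_id=self.case_id, label=self.label)
        sidecar = {"case_id": self.case_id, "label": self.label,
                   "channel_labels": self.channel_labels}
        if cube is not None:
            sidecar["bounding_cube"] = cube.to_dict()
        if norm_ranges is not None:
            sidecar["normalization"] = norm_ranges
        out = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
        out.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
        return out

    @classmethod
    def load(cls, path: str | Path) -> "ModelInputTensor":
        with np.load(path, allow_pickle=False) as data:
            return cls(channels=data["channels"],
                       channel_labels=[str(s) for s in data["channel_labels"]],
                       case_id=str(data["case_id"]), label=str(data["label"]))


def compute_bounding_cube(mask: SegmentationMask, make_cube: bool = True,
                          spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
                          ) -> BoundingCube:
    """Min/max voxel indices of the mask support, optionally expanded to a cube.

    Expansion is symmetric to side = longest extent, shifted back inside the
    grid when it overhangs; if the grid itself is smaller than the cube side
    the cube stays centered and the crop step zero-pads the overhang.
    """
    coords = np.nonzero(mask.voxels)
    if coords[0].size == 0:
        raise ValueError("empty mask")
    mins = [int(c.min()) for c in coords]
    maxs = [int(c.max()) for c in coords]
    side = max(b - a + 1 for a, b in zip(mins, maxs))
    if not make_cube:
        return BoundingCube(tuple(mins), tuple(maxs), side, spacing)
    shape = mask.voxels.shape
    lo, hi = [], []
    for a, b, dim in zip(mins, maxs, shape):
        extent = b - a + 1
        pad = side - extent
        low = a - pad // 2
        high = b + (pad - pad // 2)
        if low < 0:
            high += -low
            low = 0
        if high > dim - 1:
            low -= high - (dim - 1)
            high = dim - 1
        if low < 0:  # grid smaller than the cube: center with overhang
            low = (dim - side) // 2
            high = low + side - 1
        lo.append(low)
        hi.append(high)
    return BoundingCube(tuple(lo), tuple(hi), side, spacing)


def crop_and_resample(volume: ModalityVolume, cube: BoundingCube,
                      target_side: int = 64) -> np.ndarray:
    """Map the cube's physical extent onto this modality's grid and resample.

    Trilinear interpolation; sample points outside the volume are exactly 0.
    """
    lo_phys = np.asarray(cube.min_phys, dtype=float)
    hi_phys = np.asarray(cube.max_phys, dtype=float)
    spacing = np.asarray(volume.spacing, dtype=float)
    lo_idx = lo_phys / spacing
    hi_idx = hi_phys / spacing
    shape = volume.voxels.shape
    if np.any(hi_idx < 0) or np.any(lo_idx > np.asarray(shape) - 1):
        raise ValueError("bounding cube lies entirely outside the volume")
    axes = [np.linspace(lo_idx[d], hi_idx[d], target_side) for d in range(3)]
    grid = np.meshgrid(*axes, indexing="ij")
    out = ndimage.map_coordinates(np.asarray(volume.voxels, dtype=float),
                                  np.stack([g.ravel() for g in grid]),
                                  order=1, mode="constant", cval=0.0)
    return out.reshape(target_side, target_side, target_side)


def minmax_normalize(cube: np.ndarray, modality: str = "",
                     case_id: str = "") -> NormalizedCube:
    """x = (X - X_min) / (X_max - X_min); a constant cube maps to all zeros."""
    cube = np.asarray(cube, dtype=float)
    if cube.size == 0:
        raise ValueError("empty cube")
    x_min, x_max = float(cube.min()), float(cube.max())
    if x_max == x_min:
        logger.warning("constant cube for case %r modality %r; normalized to zeros",
                       case_id, modality)
        return NormalizedCube(np.zeros_like(cube), modality, case_id, x_min, x_max)
    return NormalizedCube((cube - x_min) / (x_max - x_min), modality, case_id,
                          x_min, x_max)


def _sobel_pair(padded: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gx/Gy correlations of a 1-voxel-padded 2D array.

    Written as paired differences so locally constant regions cancel to an
    exact 0.0 rather than float residue.
    """
    p = padded
    gx = (p[:-2, 2:] - p[:-2, :-2]) + 2.0 * (p[1:-1, 2:] - p[1:-1, :-2]) \
        + (p[2:, 2:] - p[2:, :-2])
    gy = (p[:-2, :-2] - p[2:, :-2]) + 2.0 * (p[:-2, 1:-1] - p[2:, 1:-1]) \
        + (p[:-2, 2:] - p[2:, 2:])
    return gx, gy


def sobel_gradient_2d(image: np.ndarray) -> tuple[np.ndarray, np.ndarray,
                                                  np.ndarray, np.ndarray]:
    """Apply the printed 3x3 kernels (reflect-padded); returns (Gx, Gy, G, theta)."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("image must be 2D and at least 3x3")
    gx, gy = _sobel_pair(np.pad(image, 1, mode="reflect"))
    g = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)
    return gx, gy, g, theta


def sobel_channel(cube: NormalizedCube | np.ndarray, mode: str = "slicewise_2d",
                  renormalize: bool = True) -> GradientChannels:
    """Gradient-magnitude channel of a cube, slicewise 2D or separable 3D."""
    voxels = cube.voxels if isinstance(cube, NormalizedCube) else np.asarray(cube)
    voxels = voxels.astype(float)
    if voxels.ndim != 3:
        raise ValueError("cube must be 3D")
    if mode == "slicewise_2d":
        padded = np.pad(voxels, ((1, 1), (1, 1), (0, 0)), mode="reflect")
        gx = np.empty_like(voxels)
        gy = np.empty_like(voxels)
        for k in range(voxels.shape[2]):
            gx[:, :, k], gy[:, :, k] = _sobel_pair(padded[:, :, k])
        magnitude = np.hypot(gx, gy)
        direction = np.arctan2(gy, gx)
    elif mode == "full_3d":
        grads = [ndimage.sobel(voxels, axis=ax, mode="reflect") for ax in range(3)]
        magnitude = np.sqrt(sum(g ** 2 for g in grads))
        direction = None
    else:
        raise ValueError(f"unknown sobel mode {mode!r}")
    if renormalize:
        mmax = magnitude.max()
        if mmax > 0:
            magnitude = magnitude / mmax
    return GradientChannels(magnitude=magnitude, direction=direction)


def fuse_channels(cubes: list[NormalizedCube], include_sobel: bool = True,
                  sobel_mode: str = "slicewise_2d", label: str = "") -> ModelInputTensor:
    """Stack modalities (and their gradient channels) along the channel axis.

    Channel order: [mod_1, ..., mod_M, mod_1_sobel, ..., mod_M_sobel].
    """
    if not cubes:
        raise ValueError("no cubes to fuse")
    case_ids = {c.case_id for c in cubes}
    if len(case_ids) > 1:
        raise ValueError(f"mixed case_ids in fusion: {sorted(case_ids)}")
    shapes = {c.voxels.shape for c in cubes}
    if len(shapes) > 1:
        raise ValueError(f"shape mismatch across cubes: {sorted(shapes)}")
    channels = [c.voxels for c in cubes]
    labels = [c.source_modality for c in cubes]
    if include_sobel:
        for c in cubes:
            channels.append(sobel_channel(c, mode=sobel_mode).magnitude)
            labels.append(f"{c.source_modality}_sobel")
    return ModelInputTensor(channels=np.stack(channels).astype(np.float32),
                            channel_labels=labels, case_id=cubes[0].case_id,
                            label=label)


def preprocess_case(reference: ModalityVolume, mask: SegmentationMask,
                    volumes: list[ModalityVolume], label: str = "",
                    target_side: int = 64, include_sobel: bool = True,
                    sobel_mode: str = "slicewise_2d",
                    ) -> tuple[ModelInputTensor, BoundingCube, dict]:
    """Full per-case preprocessing; returns the tensor, cube and norm ranges."""
    cube = compute_bounding_cube(mask, make_cube=True, spacing=reference.spacing)
    cubes, ranges = [], {}
    for vol in volumes:
        cropped = crop_and_resample(vol, cube, target_side=target_side)
        norm = minmax_normalize(cropped, modality=vol.modality, case_id=vol.case_id)
        ranges[vol.modality] = {"x_min": norm.x_min, "x_max": norm.x_max}
        cubes.append(norm)
    tensor = fuse_channels(cubes, include_sobel=include_sobel,
                           sobel_mode=sobel_mode, label=label)
    return tensor, cube, ranges
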