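"""Punctum segmentation of single fluorescence channels.

The processing chain mirrors a standard FIJI particle-analysis macro for
punctate immunofluorescence: background subtraction (grey-scale opening),
Gaussian smoothing, binarization, watershed splitting of merged structures,
removal of structures smaller than 8 pixels, and measurement of particle
number, size and intensity with the intensity read from the *raw* image
("redirect" measurement), not the processed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops_table
from skimage.morphology import disk
from skimage.segmentation import watershed

__all__ = [
    "MultiChannelScene",
    "SegmentationParams",
    "subtract_background",
    "gaussian_smooth",
    "binarize",
    "watershed_split",
    "filter_small",
    "measure_particles",
    "segment_channel",
]

#: 8-connectivity structuring element used throughout.
_STRUCT8 = np.ones((3, 3), dtype=bool)


@dataclass
class MultiChannelScene:
    """Registered 2D intensity planes keyed by marker role.

    Parameters
    ----------
    planes
        Mapping of marker role (e.g. ``"vacht"``, ``"psd95"``, ``"dapi"``)
        to a 2D array of non-negative intensities. All planes must share
        one shape.
    pixel_size_um
        Lateral pixel size in micrometres (default 0.04).
    """

    planes: dict[str, np.ndarray]
    pixel_size_um: float = 0.04

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        shapes = {role: np.asarray(p).shape for role, p in self.planes.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"planes must share one shape, got {shapes}")
        for role, plane in self.planes.items():
            arr = np.asarray(plane, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"plane {role!r} contains non-finite values")
            if arr.min() < 0:
                raise ValueError(f"plane {role!r} contains negative intensities")
            self.planes[role] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.planes.values())).shape

    @property
    def area_um2(self) -> float:
        h, w = self.shape
        return h * w * self.pixel_size_um**2

    def __getitem__(self, role: str) -> np.ndarray:
        if role not in self.planes:
            raise KeyError(f"role {role!r} not in scene (have {sorted(self.planes)})")
        return self.planes[role]

    def __contains__(self, role: str) -> bool:
        return role in self.planes


@dataclass
class SegmentationParams:
    """Parameters of the punctum-segmentation chain for one channel.

    ``min_size_px`` defaults to 8: structures of fewer than eight pixels
    are discarded. ``threshold_method`` is ``"otsu"`` (between-class
    variance maximisation) or ``"manual"`` with ``manual_threshold`` set.
    """

    background_radius_px: float = 20.0
    gaussian_sigma_px: float = 1.0
    threshold_method: str = "otsu"
    manual_threshold: float | None = None
    min_size_px: int = 8
    connectivity: int = 8
    watershed_min_distance_px: int = 3

    def __post_init__(self) -> None:
        if self.background_radius_px < 0:
            raise ValueError("background_radius_px must be >= 0")
        if self.gaussian_sigma_px < 0:
            raise ValueError("gaussian_sigma_px must be >= 0")
        if self.min_size_px < 1:
            raise ValueError("min_size_px must be >= 1")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method == "manual" and self.manual_threshold is None:
            raise ValueError("manual threshold_method requires manual_threshold")


def subtract_background(plane: np.ndarray, radius_px: float) -> np.ndarray:
    """Remove smooth background by grey-scale morphological opening.

    The background estimate is the opening of the image with a disc of the
    given radius (rolling-ball-like); it is subtracted and the result
    clipped at zero. ``radius_px == 0`` returns the input unchanged.
    """
    plane = np.asarray(plane, dtype=float)
    if radius_px < 0:
        raise ValueError("radius_px must be >= 0")
    if radius_px == 0:
        return plane.copy()
    footprint = disk(int(round(radius_px)))
    background = ndi.grey_opening(plane, footprint=footprint)
    return np.clip(plane - background, 0, None)


def gaussian_smooth(plane: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing with reflective borders; ``sigma 0`` is identity."""
    plane = np.asarray(plane, dtype=float)
    if sigma_px < 0:
        raise ValueError("sigma_px must be >= 0")
    if sigma_px == 0:
        return plane.copy()
    return ndi.gaussian_filter(plane, sigma=sigma_px, mode="mirror")


def binarize(
    plane: np.ndarray,
    method: str = "otsu",
    manual_threshold: float | None = None,
) -> np.ndarray:
    """Threshold a plane to a boolean foreground mask (pixel > T).

    ``"otsu"`` maximises between-class variance; a constant plane yields an
    empty mask (no object is distinguishable). ``"manual"`` uses the given
    threshold value.
    """
    plane = np.asarray(plane, dtype=float)
    if not np.all(np.isfinite(plane)):
        raise ValueError("plane contains non-finite values")
    if method == "manual":
        if manual_threshold is None:
            raise ValueError("manual method requires manual_threshold")
        return plane > manual_threshold
    if method == "otsu":
        if plane.min() == plane.max():
            return np.zeros(plane.shape, dtype=bool)
        return plane > threshold_otsu(plane)
    raise ValueError(f"unknown threshold method {method!r}")


def watershed_split(mask: np.ndarray, min_distance_px: int = 3) -> np.ndarray:
    """Split touching structures by distance-transform watershed.

    Seeds are local maxima of the Euclidean distance transform separated by
    at least ``min_distance_px``; 8-connectivity. Every foreground pixel is
    assigned exactly one label and no foreground pixel is created or lost.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(mask)
    peaks = peak_local_max(
        distance, min_distance=min_distance_px, labels=mask, exclude_border=False
    )
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    # components with no detected peak (e.g. 1-px wide) fall back to their own seed
    comp, n_comp = ndi.label(mask, structure=_STRUCT8)
    seeded = set(np.unique(comp[markers > 0]))
    next_label = len(peaks) + 1
    for lab in range(1, n_comp + 1):
        if lab not in seeded:
            ys, xs = np.nonzero(comp == lab)
            markers[ys[0], xs[0]] = next_label
            next_label += 1
    labels = watershed(-distance, markers=markers, mask=mask, connectivity=2)
    return _relabel_contiguous(labels)


def filter_small(labels: np.ndarray, min_size_px: int = 8) -> np.ndarray:
    """Drop particles of area < ``min_size_px`` and relabel contiguously.

    The default keeps structures of 8 pixels and larger.
    """
    labels = np.asarray(labels)
    if min_size_px < 1:
        raise ValueError("min_size_px must be >= 1")
    if labels.max() == 0:
        return labels.astype(np.int32)
    counts = np.bincount(labels.ravel())
    keep = counts >= min_size_px
    keep[0] = False
    out = np.where(keep[labels], labels, 0)
    return _relabel_contiguous(out)


def measure_particles(
    labels: np.ndarray, raw_plane: np.ndarray, pixel_size_um: float
) -> pd.DataFrame:
    """Measure particle area, centroid and mean raw intensity per label.

    Intensity is averaged over the *raw* plane under each particle mask —
    the binarized image only selects which pixels to measure.

    Returns a table with columns ``label``, ``area_px``, ``area_um2``,
    ``centroid_y``, ``centroid_x``, ``mean_raw_intensity``.
    """
    labels = np.asarray(labels)
    raw_plane = np.asarray(raw_plane, dtype=float)
    if labels.shape != raw_plane.shape:
        raise ValueError("labels and raw_plane shapes differ")
    if labels.max() == 0:
        return pd.DataFrame(
            columns=[
                "label",
                "area_px",
                "area_um2",
                "centroid_y",
                "centroid_x",
                "mean_raw_intensity",
            ]
        ).astype({"label": int, "area_px": int})
    props = regionprops_table(
        labels,
        intensity_image=raw_plane,
        properties=("label", "area", "centroid", "intensity_mean"),
    )
    table = pd.DataFrame(props).rename(
        columns={
            "area": "area_px",
            "centroid-0": "centroid_y",
            "centroid-1": "centroid_x",
            "intensity_mean": "mean_raw_intensity",
        }
    )
    table["area_px"] = table["area_px"].astype(int)
    table["area_um2"] = table["area_px"] * pixel_size_um**2
    return table[
        ["label", "area_px", "area_um2", "centroid_y", "centroid_x", "mean_raw_intensity"]
    ]


def segment_channel(
    scene: MultiChannelScene,
    role: str,
    params: SegmentationParams | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Run the full segmentation chain on one channel of a scene.

    Composition: background subtraction -> Gaussian smoothing -> threshold
    -> watershed split -> size filter -> raw-intensity measurement.

    Returns ``(particle_table, label_map)``; the label map feeds the
    colocalization stage.
    """
    if params is None:
        params = SegmentationParams()
    raw = scene[role]
    processed = subtract_background(raw, params.background_radius_px)
    processed = gaussian_smooth(processed, params.gaussian_sigma_px)
    mask = binarize(processed, params.threshold_method, params.manual_threshold)
    labels = watershed_split(mask, params.watershed_min_distance_px)
    labels = filter_small(labels, params.min_size_px)
    table = measure_particles(labels, raw, scene.pixel_size_um)
    return table, labels


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    """Relabel to 1..K preserving original label order."""
    labels = np.asarray(labels)
    present = np.unique(labels)
    present = present[present > 0]
    lut = np.zeros(labels.max() + 1 if labels.size else 1, dtype=np.int32)
    lut[present] = np.arange(1, len(present) + 1, dtype=np.int32)
    return lut[labels]
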