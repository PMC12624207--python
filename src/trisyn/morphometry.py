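"""Cell-scale morphometry.

Nuclear versus cytoplasmic pTDP-43 partition (per DAPI nucleus with a
fixed-width cytoplasmic annulus), cell densities per 10,000 um^2, soma
sizes, GFAP coverage/intensity/cell density and skeleton-based astrocyte
branching analysis.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk, skeletonize

from trisyn.segmentation import MultiChannelScene

__all__ = [
    "nuclear_cyto_partition",
    "cell_density",
    "soma_metrics",
    "gfap_summary",
    "skeleton_branching",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def nuclear_cyto_partition(
    ptdp_plane: np.ndarray,
    nuclei_labels: np.ndarray,
    pixel_size_um: float,
    shell_width_um: float = 1.0,
    mode: str = "intensity",
    ptdp_labels: np.ndarray | None = None,
    signal_mask: np.ndarray | None = None,
    exclude_border: bool = True,
) -> pd.DataFrame:
    """Partition pTDP-43 signal between each nucleus and its cell body.

    The "surrounding cell body" is approximated by an annulus of
    ``shell_width_um`` around each nucleus, minus every nucleus. In
    ``"intensity"`` mode (default) the nuclear and cytoplasmic signals are
    summed intensities of ``ptdp_plane`` (pass a background-subtracted
    plane); in ``"count"`` mode they are counts of segmented pTDP-43
    particles (``ptdp_labels`` required) whose centroids fall in each
    compartment. With ``signal_mask`` set (e.g. the segmented pTDP-43
    foreground) intensity sums are restricted to masked pixels, which
    removes the residual noise floor that otherwise accumulates over the
    larger cytoplasmic compartment.

    Returns one row per nucleus: ``nucleus_label``, ``nucleus_area_um2``,
    ``ptdp43_nuclear_signal``, ``ptdp43_cytoplasmic_signal``,
    ``nuclear_ratio`` (inf when cytoplasmic signal is zero),
    ``nuclear_fraction`` in [0, 1], ``touches_border`` and ``excluded``.
    """
    ptdp_plane = np.asarray(ptdp_plane, dtype=float)
    nuclei_labels = np.asarray(nuclei_labels)
    if ptdp_plane.shape != nuclei_labels.shape:
        raise ValueError("ptdp_plane and nuclei_labels shapes differ")
    if shell_width_um <= 0:
        raise ValueError("shell_width_um must be > 0")
    if mode not in ("intensity", "count"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "count" and ptdp_labels is None:
        raise ValueError("count mode requires ptdp_labels")

    shell_px = max(1, int(round(shell_width_um / pixel_size_um)))
    all_nuclei = nuclei_labels > 0
    h, w = nuclei_labels.shape

    if mode == "count":
        # particle centroids, rounded to pixel, assign per compartment
        centroid_map = np.zeros_like(nuclei_labels, dtype=bool)
        labs = np.asarray(ptdp_labels)
        coords = ndi.center_of_mass(labs > 0, labs, np.arange(1, labs.max() + 1)) if labs.max() else []
        for cy, cx in coords:
            centroid_map[int(round(cy)), int(round(cx))] = True
        signal_plane = centroid_map.astype(float)
    else:
        signal_plane = ptdp_plane
        if signal_mask is not None:
            signal_mask = np.asarray(signal_mask, dtype=bool)
            if signal_mask.shape != ptdp_plane.shape:
                raise ValueError("signal_mask shape differs from ptdp_plane")
            signal_plane = np.where(signal_mask, ptdp_plane, 0.0)

    rows = []
    selem = disk(shell_px)
    for lab in range(1, int(nuclei_labels.max()) + 1):
        nuc = nuclei_labels == lab
        if not nuc.any():
            continue
        ys, xs = np.nonzero(nuc)
        touches = bool(
            ys.min() == 0 or xs.min() == 0 or ys.max() == h - 1 or xs.max() == w - 1
        )
        shell = ndi.binary_dilation(nuc, structure=selem) & ~all_nuclei
        nuc_sig = float(signal_plane[nuc].sum())
        cyt_sig = float(signal_plane[shell].sum())
        total = nuc_sig + cyt_sig
        frac = nuc_sig / total if total > 0 else float("nan")
        ratio = nuc_sig / cyt_sig if cyt_sig > 0 else float("inf")
        rows.append(
            {
                "nucleus_label": lab,
                "nucleus_area_um2": int(nuc.sum()) * pixel_size_um**2,
                "ptdp43_nuclear_signal": nuc_sig,
                "ptdp43_cytoplasmic_signal": cyt_sig,
                "nuclear_ratio": ratio,
                "nuclear_fraction": frac,
                "touches_border": touches,
                "excluded": touches and exclude_border,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "nucleus_label", "nucleus_area_um2", "ptdp43_nuclear_signal",
            "ptdp43_cytoplasmic_signal", "nuclear_ratio", "nuclear_fraction",
            "touches_border", "excluded",
        ],
    )


def cell_density(n_cells: int, scene: MultiChannelScene | None = None, area_um2: float | None = None) -> float:
    """Cell count normalised to 10,000 um^2 of field area."""
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if area_um2 is None:
        if scene is None:
            raise ValueError("provide a scene or an explicit area_um2")
        area_um2 = scene.area_um2
    if area_um2 <= 0:
        raise ValueError("area_um2 must be > 0")
    return n_cells / area_um2 * 1e4


def soma_metrics(soma_labels: np.ndarray, pixel_size_um: float) -> dict:
    """Count and per-soma areas (um^2) from a labelled soma map."""
    soma_labels = np.asarray(soma_labels)
    n = int(soma_labels.max())
    if n == 0:
        return {"count": 0, "areas_um2": [], "mean_area_um2": float("nan")}
    counts = np.bincount(soma_labels.ravel())[1 : n + 1]
    areas = (counts * pixel_size_um**2).tolist()
    return {"count": n, "areas_um2": areas, "mean_area_um2": float(np.mean(areas))}


def gfap_summary(
    gfap_plane: np.ndarray,
    gfap_mask: np.ndarray,
    nuclei_labels: np.ndarray | None,
    pixel_size_um: float,
) -> dict:
    """GFAP coverage, intensity and astrocyte density.

    ``gfap_area_fraction`` = foreground / total pixels; mean intensity is
    read from the raw plane over the mask (0 with ``intensity_undefined``
    flag if the mask is empty). Astrocyte density counts DAPI nuclei
    overlapping the GFAP mask by >= 1 px, per 10,000 um^2 — GFAP fragments
    are not cells.
    """
    gfap_plane = np.asarray(gfap_plane, dtype=float)
    gfap_mask = np.asarray(gfap_mask, dtype=bool)
    if gfap_plane.shape != gfap_mask.shape:
        raise ValueError("plane and mask shapes differ")
    total_px = gfap_mask.size
    fg = int(gfap_mask.sum())
    area_fraction = fg / total_px
    if fg == 0:
        mean_intensity, undefined = 0.0, True
    else:
        mean_intensity, undefined = float(gfap_plane[gfap_mask].mean()), False
    area_um2 = total_px * pixel_size_um**2
    n_astro = 0
    if nuclei_labels is not None and fg > 0:
        labs = np.unique(np.asarray(nuclei_labels)[gfap_mask])
        n_astro = int((labs > 0).sum())
    return {
        "gfap_area_fraction": area_fraction,
        "gfap_mean_intensity": mean_intensity,
        "intensity_undefined": undefined,
        "gfap_positive_cell_density": n_astro / area_um2 * 1e4,
        "n_gfap_positive_cells": n_astro,
    }


def skeleton_branching(
    gfap_mask: np.ndarray,
    pixel_size_um: float,
    prune_spurs_px: float = 3.0,
) -> dict:
    """Branch points and branch lengths of the skeletonized mask.

    The mask is thinned to a 1-px skeleton; a branch point is a skeleton
    pixel with >= 3 skeleton neighbours (adjacent such pixels merge into
    one junction), branches are the skeleton segments between junctions
    and endpoints, and lengths count diagonal steps as sqrt(2) pixels,
    scaled by ``pixel_size_um``. Terminal spurs shorter than
    ``prune_spurs_px`` are discarded.

    Returns ``n_branch_points`` and ``branch_lengths_um``.
    """
    gfap_mask = np.asarray(gfap_mask, dtype=bool)
    skel = skeletonize(gfap_mask)
    if not skel.any():
        return {"n_branch_points": 0, "branch_lengths_um": []}

    # neighbour count per skeleton pixel (8-connectivity)
    nb = ndi.convolve(skel.astype(int), np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]]), mode="constant")
    degree = np.where(skel, nb, 0)
    junction = skel & (degree >= 3)
    junction_lbl, n_junctions = ndi.label(junction, structure=_STRUCT8)

    # branch segments: skeleton minus junction pixels
    segments = skel & ~junction
    seg_lbl, n_seg = ndi.label(segments, structure=_STRUCT8)
    lengths_um: list[float] = []
    for s in range(1, n_seg + 1):
        coords = np.argwhere(seg_lbl == s)
        length_px = _path_length(coords)
        # connections from segment ends to adjacent junctions add one step each
        n_touch = _touching_junctions(coords, junction_lbl)
        length_px += n_touch  # approximate 1-px connector per junction contact
        is_spur = n_touch <= 1 and n_junctions > 0
        if is_spur and length_px < prune_spurs_px:
            continue
        if length_px <= 0:
            continue
        lengths_um.append(length_px * pixel_size_um)
    return {"n_branch_points": int(n_junctions), "branch_lengths_um": lengths_um}


def _path_length(coords: np.ndarray) -> float:
    """Length of a (near-)path pixel set: sum of nearest-neighbour steps.

    Pixels are ordered by walking from an end; diagonal steps count
    sqrt(2). Falls back to n-1 steps if the component is not a simple
    path."""
    n = len(coords)
    if n <= 1:
        return 0.0
    pts = {tuple(c) for c in coords}
    # degree within the segment
    def nbrs(p):
        y, x = p
        return [
            (y + dy, x + dx)
            for dy in (-1, 0, 1)
            for dx in (-1, 0, 1)
            if (dy or dx) and (y + dy, x + dx) in pts
        ]

    ends = [p for p in pts if len(nbrs(p)) == 1]
    start = ends[0] if ends else next(iter(pts))
    visited = {start}
    total = 0.0
    cur = start
    while True:
        nxt = [p for p in nbrs(cur) if p not in visited]
        if not nxt:
            break
        # prefer 4-connected steps to avoid double-counting corners
        nxt.sort(key=lambda p: (abs(p[0] - cur[0]) + abs(p[1] - cur[1])))
        p = nxt[0]
        total += math.sqrt((p[0] - cur[0]) ** 2 + (p[1] - cur[1]) ** 2)
        visited.add(p)
        cur = p
    if len(visited) < n:  # not a simple path; approximate remaining
        total += n - len(visited)
    return total


def _touching_junctions(coords: np.ndarray, junction_lbl: np.ndarray) -> int:
    """Number of distinct junction clusters 8-adjacent to the segment."""
    h, w = junction_lbl.shape
    touched = set()
    for y, x in coords:
        y0, y1 = max(0, y - 1), min(h, y + 2)
        x0, x1 = max(0, x - 1), min(w, x + 2)
        labs = np.unique(junction_lbl[y0:y1, x0:x1])
        touched.update(labs[labs > 0].tolist())
    return len(touched)
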