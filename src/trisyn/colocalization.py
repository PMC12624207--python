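"""Object-based colocalization and synapse typing.

Two particles from different channels are deemed to colocalize when their
masks overlap by a minimum of one pixel. On that rule this module defines
bona fide synapses (presynaptic bouton partially colocalised with PSD95),
classifies them as tripartite or non-tripartite by contact with a
perisynaptic-astrocytic-process (PAP) particle, detects C-bouton apposition
to motor-neuron somata, and counts pTDP-43 clusters per bouton.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.morphology import disk

__all__ = [
    "pixel_overlap",
    "coloc_fraction",
    "define_synapses",
    "classify_tripartite",
    "c_bouton_apposition",
    "ptdp43_content",
]


def pixel_overlap(labels_a: np.ndarray, labels_b: np.ndarray) -> pd.DataFrame:
    """Table of particle pairs sharing at least one pixel.

    Returns columns ``label_a``, ``label_b``, ``overlap_px`` (>= 1), one
    row per pair.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label maps must share one shape")
    both = (labels_a > 0) & (labels_b > 0)
    if not both.any():
        return pd.DataFrame(columns=["label_a", "label_b", "overlap_px"]).astype(int)
    pairs = np.stack([labels_a[both], labels_b[both]], axis=1)
    uniq, counts = np.unique(pairs, axis=0, return_counts=True)
    out = pd.DataFrame(
        {"label_a": uniq[:, 0], "label_b": uniq[:, 1], "overlap_px": counts}
    )
    return out.sort_values(["label_a", "label_b"], ignore_index=True)


def coloc_fraction(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Fraction of A-particles overlapping at least one B-particle."""
    labels_a = np.asarray(labels_a)
    n_a = int(labels_a.max())
    if n_a == 0:
        raise ValueError("coloc_fraction undefined: no particles in A")
    ov = pixel_overlap(labels_a, labels_b)
    return ov["label_a"].nunique() / n_a


def define_synapses(
    pre_table: pd.DataFrame,
    pre_labels: np.ndarray,
    psd_table: pd.DataFrame,
    psd_labels: np.ndarray,
) -> pd.DataFrame:
    """One synapse record per presynaptic particle.

    ``has_psd`` marks bona fide synapses (>= 1 px overlap with a PSD95
    particle); ``psd_area_um2`` is the area of the largest overlapping PSD
    particle (ties broken by lowest PSD label).
    """
    ov = pixel_overlap(pre_labels, psd_labels)
    records = pre_table.rename(columns={"area_um2": "bouton_area_um2"}).copy()
    records["has_psd"] = False
    records["psd_area_um2"] = np.nan
    if len(ov):
        psd_area = psd_table.set_index("label")["area_um2"]
        ov = ov.assign(psd_area_um2=ov["label_b"].map(psd_area))
        # largest partner; ties -> lowest label (stable sort after label order)
        ov = ov.sort_values(
            ["label_a", "psd_area_um2", "label_b"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        best = ov.drop_duplicates("label_a")
        best_map = best.set_index("label_a")["psd_area_um2"]
        hit = records["label"].isin(best_map.index)
        records.loc[hit, "has_psd"] = True
        records.loc[hit, "psd_area_um2"] = records.loc[hit, "label"].map(best_map)
    return records


def classify_tripartite(
    records: pd.DataFrame, pre_labels: np.ndarray, pap_labels: np.ndarray
) -> pd.DataFrame:
    """Set ``is_tripartite`` on synapse records by PAP contact.

    A bouton is tripartite when it overlaps any PAP particle by >= 1 px.
    The tripartite fraction is reported over bona fide synapses only.
    """
    ov = pixel_overlap(pre_labels, pap_labels)
    contacted = set(ov["label_a"]) if len(ov) else set()
    records = records.copy()
    records["is_tripartite"] = records["label"].isin(contacted)
    return records


def tripartite_fraction(records: pd.DataFrame) -> float:
    """Share of bona fide synapses classified tripartite."""
    bona = records[records["has_psd"]]
    if len(bona) == 0:
        return float("nan")
    return float(bona["is_tripartite"].mean())


def c_bouton_apposition(
    records: pd.DataFrame,
    vacht_labels: np.ndarray,
    soma_mask: np.ndarray,
    dilation_px: int = 2,
) -> pd.DataFrame:
    """Flag boutons apposed to the (dilated) soma mask.

    "Opposed to" soma labelling implies membrane contact rather than
    containment, so the soma mask is dilated by ``dilation_px`` (default
    2 px = 0.08 um at 0.04 um/px) before the >= 1 px overlap test.
    """
    soma_mask = np.asarray(soma_mask, dtype=bool)
    if dilation_px < 0:
        raise ValueError("dilation_px must be >= 0")
    if dilation_px > 0 and soma_mask.any():
        soma_mask = ndi.binary_dilation(soma_mask, structure=disk(dilation_px))
    records = records.copy()
    if not soma_mask.any():
        records["apposed"] = False
        return records
    hit_labels = np.unique(np.asarray(vacht_labels)[soma_mask])
    hit_labels = set(hit_labels[hit_labels > 0])
    records["apposed"] = records["label"].isin(hit_labels)
    return records


def ptdp43_content(
    records: pd.DataFrame,
    pre_labels: np.ndarray,
    ptdp_table: pd.DataFrame,
    ptdp_labels: np.ndarray,
) -> pd.DataFrame:
    """Count pTDP-43 clusters per bouton and record their sizes.

    A cluster overlapping k boutons increments each bouton's count — the
    metric is per-bouton content, not an exclusive assignment. Adds
    ``n_ptdp43_clusters`` and ``ptdp43_cluster_areas_um2`` (list) columns.
    """
    ov = pixel_overlap(pre_labels, ptdp_labels)
    records = records.copy()
    counts = {}
    areas = {}
    if len(ov):
        size_map = ptdp_table.set_index("label")["area_um2"]
        for lab_a, grp in ov.groupby("label_a"):
            counts[lab_a] = len(grp)
            areas[lab_a] = [float(size_map[b]) for b in grp["label_b"]]
    records["n_ptdp43_clusters"] = records["label"].map(counts).fillna(0).astype(int)
    records["ptdp43_cluster_areas_um2"] = records["label"].map(areas).apply(
        lambda v: v if isinstance(v, list) else []
    )
    return records


def ptdp43_image_metrics(records: pd.DataFrame) -> dict[str, float]:
    """Per-image pTDP-43 content summary over boutons.

    Returns the fraction of boutons containing any cluster, mean clusters
    per containing bouton, mean clusters per bouton (all boutons) and mean
    cluster area.
    """
    n = len(records)
    if n == 0:
        return {
            "ptdp_containing_fraction": float("nan"),
            "ptdp_clusters_per_containing_bouton": float("nan"),
            "ptdp_clusters_per_bouton": float("nan"),
            "ptdp_mean_cluster_area_um2": float("nan"),
        }
    containing = records[records["n_ptdp43_clusters"] > 0]
    all_areas = [a for lst in records["ptdp43_cluster_areas_um2"] for a in lst]
    return {
        "ptdp_containing_fraction": len(containing) / n,
        "ptdp_clusters_per_containing_bouton": (
            float(containing["n_ptdp43_clusters"].mean()) if len(containing) else float("nan")
        ),
        "ptdp_clusters_per_bouton": float(records["n_ptdp43_clusters"].mean()),
        "ptdp_mean_cluster_area_um2": (
            float(np.mean(all_areas)) if all_areas else float("nan")
        ),
    }
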