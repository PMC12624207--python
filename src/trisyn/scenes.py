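"""Synthetic multi-channel microscopy scenes with known ground truth.

Emulates super-resolution confocal fields of spinal-cord ventral horn:
punctate synaptic markers as spatial Poisson point processes of isotropic
Gaussian spots, PSD95 appositions and perisynaptic-astrocyte contacts placed
with set probabilities, nuclei and motor-neuron somata as filled discs, and
phospho-TDP-43 split between nuclear and cytoplasmic compartments by a
mislocalisation parameter. Photon shot noise and Gaussian read noise follow
the standard fluorescence camera model.

Every scene carries a :class:`SceneGroundTruth` listing the true objects and
summary values, so downstream measurements can be validated by parameter
recovery.
"""

from __future__ import annotations

import copy
import csv
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from trisyn.segmentation import MultiChannelScene

__all__ = [
    "MarkerParams",
    "SceneConfig",
    "SceneGroundTruth",
    "generate_scene",
    "generate_cohort",
    "control_config",
    "nls_config",
]

#: object mask = pixels above half the spot's peak (full width at half max)
FWHM_FACTOR = math.sqrt(2.0 * math.log(2.0))


@dataclass
class MarkerParams:
    """Punctum statistics for one marker channel.

    density_per_10k_um2
        Expected punctum count per 10,000 um^2 of field.
    radius_median_px, radius_dispersion
        Log-normal distribution of the spot Gaussian sigma (px): median and
        sigma of log.
    amp_mean, amp_sd
        Normal distribution (truncated > 0) of spot peak amplitude.
    """

    density_per_10k_um2: float = 100.0
    radius_median_px: float = 4.0
    radius_dispersion: float = 0.25
    amp_mean: float = 100.0
    amp_sd: float = 15.0

    def __post_init__(self) -> None:
        if self.density_per_10k_um2 < 0:
            raise ValueError("density_per_10k_um2 must be >= 0")
        if self.radius_median_px <= 0:
            raise ValueError("radius_median_px must be > 0")
        if self.radius_dispersion < 0:
            raise ValueError("radius_dispersion must be >= 0")


@dataclass
class SceneConfig:
    """Full description of one synthetic field.

    Defaults reproduce a 78 x 78 um field at 0.04 um/px with marker
    densities, effect parameters and noise typical of punctate
    immunofluorescence in ventral-horn grey matter.
    """

    field_size_px: tuple[int, int] = (1950, 1950)
    pixel_size_um: float = 0.04
    markers: dict[str, MarkerParams] = field(default_factory=dict)
    presyn_roles: tuple[str, ...] = ("vacht",)
    psd_role: str = "psd95"
    pap_role: str = "pezrin"
    ptdp_role: str = "ptdp43"
    nuclear_role: str = "dapi"
    soma_role: str = "smi32"
    psd_apposition_prob: float = 0.8
    tripartite_prob: float = 0.75
    soma_count: int = 3
    soma_radius_range_px: tuple[float, float] = (150.0, 250.0)
    nucleus_count: int = 3
    nucleus_radius_range_px: tuple[float, float] = (60.0, 90.0)
    ptdp43_clusters_per_bouton_rate: float = 2.0
    ptdp43_cluster_sigma_px: float = 2.5
    ptdp43_cell_signal: float = 4000.0
    ptdp43_spots_per_compartment: int = 8
    nuclear_fraction: float = 0.8
    cell_shell_width_px: float = 25.0
    exclude_cell_regions: bool = True
    min_separation_px: float = 0.0
    shot_noise_scale: float = 2.0
    read_noise_sd: float = 2.0
    background_level: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.field_size_px
        if h < 64 or w < 64:
            raise ValueError(f"field_size_px must be >= 64 per side, got {self.field_size_px}")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        for name in ("psd_apposition_prob", "tripartite_prob", "nuclear_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in (
            "ptdp43_clusters_per_bouton_rate",
            "shot_noise_scale",
            "read_noise_sd",
            "background_level",
            "min_separation_px",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.soma_count < 0 or self.nucleus_count < 0:
            raise ValueError("soma_count and nucleus_count must be >= 0")

    @property
    def area_um2(self) -> float:
        h, w = self.field_size_px
        return h * w * self.pixel_size_um**2

    def expected_count(self, role: str) -> float:
        """Expected punctum count for a marker role in this field."""
        return self.markers[role].density_per_10k_um2 * self.area_um2 / 1e4


@dataclass
class SceneGroundTruth:
    """True object lists and summary values of one generated scene.

    ``puncta``: every rendered spot (role, y, x, sigma_px, amplitude).
    ``presyn``: one row per presynaptic bouton with has_psd, is_tripartite
    (defined for bona fide boutons) and n_ptdp43_clusters.
    ``nuclei`` / ``somata``: centre and radius (px).
    ``summary``: true density per 10,000 um^2 per role, true PSD-apposition
    and tripartite fractions, clusters-per-bouton mean, nuclear fraction.
    """

    puncta: pd.DataFrame
    presyn: pd.DataFrame
    nuclei: pd.DataFrame
    somata: pd.DataFrame
    summary: dict[str, float]


def default_markers() -> dict[str, MarkerParams]:
    """Marker statistics for a control-like ventral-horn field."""
    return {
        "vacht": MarkerParams(15.0, 10.0, 0.20, 120.0, 20.0),
        "glyt2": MarkerParams(120.0, 4.0, 0.25, 100.0, 15.0),
        "vglut1": MarkerParams(80.0, 5.0, 0.25, 100.0, 15.0),
        "vglut2": MarkerParams(150.0, 4.0, 0.25, 100.0, 15.0),
        "psd95": MarkerParams(50.0, 3.0, 0.25, 90.0, 12.0),
        "pezrin": MarkerParams(60.0, 3.0, 0.25, 90.0, 12.0),
    }


def control_config(**overrides) -> SceneConfig:
    """Scene configuration for the control-like phenotype."""
    cfg = SceneConfig(
        markers=default_markers(),
        presyn_roles=("vacht", "glyt2", "vglut1", "vglut2"),
        psd_apposition_prob=0.8,
        tripartite_prob=0.75,
        ptdp43_clusters_per_bouton_rate=3.0,
        nuclear_fraction=0.8,
    )
    return replace(cfg, **overrides)


def nls_config(**overrides) -> SceneConfig:
    """NLS-like phenotype: cytoplasmic TDP-43 mislocalisation, smaller
    cholinergic boutons, fewer VGLUT1 boutons, fewer pTDP-43 clusters per
    bouton."""
    markers = default_markers()
    markers["vacht"] = replace(markers["vacht"], radius_median_px=7.5)
    markers["vglut1"] = replace(markers["vglut1"], density_per_10k_um2=60.0)
    cfg = SceneConfig(
        markers=markers,
        presyn_roles=("vacht", "glyt2", "vglut1", "vglut2"),
        psd_apposition_prob=0.8,
        tripartite_prob=0.75,
        ptdp43_clusters_per_bouton_rate=2.0,
        nuclear_fraction=0.4,
    )
    return replace(cfg, **overrides)


def _add_spot(plane: np.ndarray, y: float, x: float, sigma: float, amp: float) -> None:
    """Render an isotropic Gaussian spot truncated at 3 sigma, in place."""
    h, w = plane.shape
    r = 3.0 * sigma
    y0, y1 = max(0, int(math.floor(y - r))), min(h, int(math.ceil(y + r)) + 1)
    x0, x1 = max(0, int(math.floor(x - r))), min(w, int(math.ceil(x + r)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - y) ** 2 + (xx - x) ** 2
    spot = amp * np.exp(-d2 / (2.0 * sigma**2))
    spot[d2 > r * r] = 0.0
    plane[y0:y1, x0:x1] += spot


def _add_disc(plane: np.ndarray, y: float, x: float, radius: float, amp: float, edge_sigma: float = 2.0) -> None:
    """Render a filled disc with a soft (Gaussian-blurred) edge, in place."""
    h, w = plane.shape
    r = radius + 3 * edge_sigma
    y0, y1 = max(0, int(math.floor(y - r))), min(h, int(math.ceil(y + r)) + 1)
    x0, x1 = max(0, int(math.floor(x - r))), min(w, int(math.ceil(x + r)) + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d = np.sqrt((yy - y) ** 2 + (xx - x) ** 2)
    # logistic edge profile approximating a blurred disc
    prof = amp / (1.0 + np.exp((d - radius) / max(edge_sigma, 1e-6)))
    plane[y0:y1, x0:x1] += prof


def _sample_positions(
    rng: np.random.Generator,
    n: int,
    shape: tuple[int, int],
    min_separation: float = 0.0,
    forbidden: list[tuple[float, float, float]] | None = None,
    max_tries: int = 200,
) -> np.ndarray:
    """Uniform positions, optionally with a hard-core separation and
    exclusion discs (cy, cx, radius). Falls back to accepting a point after
    ``max_tries`` rejections so the count stays Poisson-exact."""
    pts: list[tuple[float, float]] = []
    h, w = shape
    for _ in range(n):
        for attempt in range(max_tries):
            y, x = rng.uniform(0, h), rng.uniform(0, w)
            ok = True
            if forbidden:
                for cy, cx, r in forbidden:
                    if (y - cy) ** 2 + (x - cx) ** 2 < r * r:
                        ok = False
                        break
            if ok and min_separation > 0:
                for py, px in pts:
                    if (y - py) ** 2 + (x - px) ** 2 < min_separation**2:
                        ok = False
                        break
            if ok:
                break
        pts.append((y, x))
    return np.asarray(pts, dtype=float).reshape(n, 2)


def generate_scene(config: SceneConfig) -> tuple[MultiChannelScene, SceneGroundTruth]:
    """Generate one multi-channel scene and its ground truth.

    The same ``config`` (including its ``seed``) always produces
    bit-identical pixel arrays and tables.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.field_size_px
    shape = (h, w)
    planes: dict[str, np.ndarray] = {}
    puncta_rows: list[dict] = []
    presyn_rows: list[dict] = []

    # --- nuclei and somata -------------------------------------------------
    nuc_rows, soma_rows = [], []
    margin_extra = config.cell_shell_width_px + 10
    n_cells = max(config.soma_count, config.nucleus_count)
    # cells (nucleus + cytoplasmic shell, soma) must not overlap each other
    cell_extent = 0.0
    if config.soma_count > 0:
        cell_extent = max(cell_extent, config.soma_radius_range_px[1])
    if config.nucleus_count > 0:
        cell_extent = max(cell_extent, config.nucleus_radius_range_px[1] + margin_extra)
    placed: list[tuple[float, float]] = []
    for i in range(n_cells):
        sr = rng.uniform(*config.soma_radius_range_px) if i < config.soma_count else 0.0
        nr = rng.uniform(*config.nucleus_radius_range_px) if i < config.nucleus_count else 0.0
        margin = max(sr, nr + margin_extra)
        if 2 * margin >= min(h, w):
            margin = min(h, w) / 2.0 - 1
        for _ in range(300):
            cy = rng.uniform(margin, h - margin)
            cx = rng.uniform(margin, w - margin)
            if all((cy - py) ** 2 + (cx - px) ** 2 >= (2 * cell_extent) ** 2 for py, px in placed):
                break
        placed.append((cy, cx))
        if i < config.soma_count:
            soma_rows.append({"y": cy, "x": cx, "radius_px": sr})
        if i < config.nucleus_count:
            nuc_rows.append({"y": cy, "x": cx, "radius_px": nr})
    nuclei = pd.DataFrame(nuc_rows, columns=["y", "x", "radius_px"])
    somata = pd.DataFrame(soma_rows, columns=["y", "x", "radius_px"])

    if config.soma_count > 0:
        soma_plane = np.zeros(shape)
        for r in soma_rows:
            _add_disc(soma_plane, r["y"], r["x"], r["radius_px"], 80.0)
        planes[config.soma_role] = soma_plane
    if config.nucleus_count > 0:
        dapi_plane = np.zeros(shape)
        for r in nuc_rows:
            _add_disc(dapi_plane, r["y"], r["x"], r["radius_px"], 120.0)
        planes[config.nuclear_role] = dapi_plane

    # exclusion zones keep synaptic puncta out of the cell-body compartments
    forbidden = None
    if config.exclude_cell_regions and nuc_rows:
        forbidden = [
            (r["y"], r["x"], r["radius_px"] + config.cell_shell_width_px + 15)
            for r in nuc_rows
        ]

    # --- punctate channels -------------------------------------------------
    ptdp_plane = np.zeros(shape)
    n_bouton_clusters = 0
    for role, mp in config.markers.items():
        if role not in planes:
            planes[role] = np.zeros(shape)
        plane = planes[role]
        n = rng.poisson(config.expected_count(role))
        is_presyn = role in config.presyn_roles
        pos = _sample_positions(
            rng, n, shape, config.min_separation_px,
            forbidden if is_presyn else None,
        )
        sigmas = mp.radius_median_px * np.exp(
            rng.normal(0.0, mp.radius_dispersion, size=n)
        )
        amps = np.abs(rng.normal(mp.amp_mean, mp.amp_sd, size=n))
        for i in range(n):
            y, x = pos[i]
            _add_spot(plane, y, x, sigmas[i], amps[i])
            puncta_rows.append(
                {"role": role, "y": y, "x": x, "sigma_px": sigmas[i], "amplitude": amps[i]}
            )
        if not is_presyn:
            continue
        # partner spots and pTDP-43 content per bouton
        for i in range(n):
            y, x, sig = pos[i][0], pos[i][1], sigmas[i]
            has_psd = bool(rng.random() < config.psd_apposition_prob)
            is_tri = bool(has_psd and rng.random() < config.tripartite_prob)
            if has_psd:
                _place_partner(rng, planes, config, config.psd_role, y, x, sig, puncta_rows)
            if is_tri:
                _place_partner(rng, planes, config, config.pap_role, y, x, sig, puncta_rows)
            k = int(rng.poisson(config.ptdp43_clusters_per_bouton_rate))
            placed_clusters: list[tuple[float, float]] = []
            min_sep = 4.0 * config.ptdp43_cluster_sigma_px
            for _ in range(k):
                # hard-core separation keeps clusters of one bouton resolvable
                for _try in range(60):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = sig * math.sqrt(rng.uniform())
                    cy, cx = y + rad * math.sin(ang), x + rad * math.cos(ang)
                    if all(
                        (cy - qy) ** 2 + (cx - qx) ** 2 >= min_sep**2
                        for qy, qx in placed_clusters
                    ):
                        break
                placed_clusters.append((cy, cx))
                camp = abs(rng.normal(80.0, 12.0))
                _add_spot(ptdp_plane, cy, cx, config.ptdp43_cluster_sigma_px, camp)
                puncta_rows.append(
                    {
                        "role": config.ptdp_role,
                        "y": cy,
                        "x": cx,
                        "sigma_px": config.ptdp43_cluster_sigma_px,
                        "amplitude": camp,
                    }
                )
            n_bouton_clusters += k
            presyn_rows.append(
                {
                    "role": role,
                    "y": y,
                    "x": x,
                    "sigma_px": sig,
                    "amplitude": amps[i],
                    "has_psd": has_psd,
                    "is_tripartite": is_tri,
                    "n_ptdp43_clusters": k,
                }
            )

    # --- somatic pTDP-43 split nucleus vs cytoplasm ------------------------
    csig = config.ptdp43_cluster_sigma_px
    nspots = config.ptdp43_spots_per_compartment
    # spot counts per compartment chosen so per-spot amplitudes are nearly
    # equal across compartments (keeps threshold truncation unbiased) while
    # the compartment amplitude sums hit nuclear_fraction exactly
    n_total = 2 * nspots
    k_nuc = int(round(config.nuclear_fraction * n_total))
    for r in nuc_rows:
        cy, cx, nr = r["y"], r["x"], r["radius_px"]
        amp_total = config.ptdp43_cell_signal
        for inside, share, k in (
            (True, config.nuclear_fraction, k_nuc),
            (False, 1.0 - config.nuclear_fraction, n_total - k_nuc),
        ):
            if share <= 0 or amp_total <= 0 or k == 0:
                continue
            amp = share * amp_total / k
            for _ in range(k):
                ang = rng.uniform(0, 2 * math.pi)
                if inside:
                    rad = (nr - 3 * csig) * math.sqrt(rng.uniform()) if nr > 3 * csig else 0.0
                else:
                    lo = nr + 3 * csig
                    hi = nr + config.cell_shell_width_px - 3 * csig
                    hi = max(hi, lo + 1e-6)
                    rad = math.sqrt(rng.uniform(lo * lo, hi * hi))
                sy, sx = cy + rad * math.sin(ang), cx + rad * math.cos(ang)
                _add_spot(ptdp_plane, sy, sx, csig, amp)
                puncta_rows.append(
                    {"role": config.ptdp_role, "y": sy, "x": sx, "sigma_px": csig, "amplitude": amp}
                )
    if config.ptdp43_clusters_per_bouton_rate > 0 or (
        config.nucleus_count > 0 and config.ptdp43_cell_signal > 0
    ):
        planes[config.ptdp_role] = ptdp_plane

    # --- noise -------------------------------------------------------------
    for role in planes:
        clean = planes[role] + config.background_level
        if config.shot_noise_scale > 0:
            noisy = rng.poisson(clean * config.shot_noise_scale) / config.shot_noise_scale
        else:
            noisy = clean
        if config.read_noise_sd > 0:
            noisy = noisy + rng.normal(0.0, config.read_noise_sd, size=shape)
        planes[role] = np.clip(noisy, 0.0, None)

    presyn = pd.DataFrame(
        presyn_rows,
        columns=[
            "role", "y", "x", "sigma_px", "amplitude",
            "has_psd", "is_tripartite", "n_ptdp43_clusters",
        ],
    )
    puncta = pd.DataFrame(puncta_rows, columns=["role", "y", "x", "sigma_px", "amplitude"])
    summary: dict[str, float] = {"true_nuclear_fraction": config.nuclear_fraction}
    for role in config.markers:
        cnt = int((puncta["role"] == role).sum()) if len(puncta) else 0
        if role in config.presyn_roles:
            cnt = int((presyn["role"] == role).sum())
        summary[f"true_count_{role}"] = cnt
        summary[f"true_density_{role}"] = cnt / (config.area_um2 / 1e4)
    for role in config.presyn_roles:
        sub = presyn[presyn["role"] == role]
        summary[f"true_median_sigma_{role}"] = float(sub["sigma_px"].median()) if len(sub) else float("nan")
    if len(presyn):
        summary["true_psd_fraction"] = float(presyn["has_psd"].mean())
        bona = presyn[presyn["has_psd"]]
        summary["true_tripartite_fraction"] = (
            float(bona["is_tripartite"].mean()) if len(bona) else float("nan")
        )
        summary["true_clusters_per_bouton"] = float(presyn["n_ptdp43_clusters"].mean())
    gt = SceneGroundTruth(puncta=puncta, presyn=presyn, nuclei=nuclei, somata=somata, summary=summary)
    scene = MultiChannelScene(planes=planes, pixel_size_um=config.pixel_size_um)
    return scene, gt


def _place_partner(
    rng: np.random.Generator,
    planes: dict[str, np.ndarray],
    config: SceneConfig,
    role: str,
    y: float,
    x: float,
    bouton_sigma: float,
    puncta_rows: list[dict],
) -> None:
    """Render an apposed partner spot offset by one bouton sigma.

    The offset guarantees partial (>= 1 px), not concentric, overlap of the
    two half-maximum object masks for any partner size."""
    mp = config.markers.get(role, MarkerParams(0.0, 3.0, 0.25, 90.0, 12.0))
    if role not in planes:
        planes[role] = np.zeros(planes[next(iter(planes))].shape if planes else config.field_size_px)
    ang = rng.uniform(0, 2 * math.pi)
    py, px = y + bouton_sigma * math.sin(ang), x + bouton_sigma * math.cos(ang)
    sig = mp.radius_median_px * math.exp(rng.normal(0.0, mp.radius_dispersion))
    amp = abs(rng.normal(mp.amp_mean, mp.amp_sd))
    _add_spot(planes[role], py, px, sig, amp)
    puncta_rows.append({"role": role, "y": py, "x": px, "sigma_px": sig, "amplitude": amp})


def generate_cohort(
    n_control: int,
    n_nls: int,
    images_per_animal: int,
    out_dir: str | Path,
    base_config_pair: tuple[SceneConfig, SceneConfig] | None = None,
    seed: int = 0,
    animal_cv: float = 0.05,
) -> pd.DataFrame:
    """Write a synthetic two-group cohort to disk and return the sample sheet.

    One multi-page TIFF per image (channel order recorded in the sample
    sheet), a ``sample_sheet.csv`` with image path, section, animal and
    genotype, and a ``ground_truth.csv`` of per-image true summary values.
    Animals within a group share the group configuration up to a small
    log-normal animal effect (``animal_cv``) on marker density and size;
    the two groups differ only by their stated effect parameters.
    """
    if n_control < 1 or n_nls < 1:
        raise ValueError("group sizes must be >= 1")
    if images_per_animal < 2:
        raise ValueError("images_per_animal must be >= 2 (at least two tissue sections)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if base_config_pair is None:
        base_config_pair = (control_config(), nls_config())
    ctrl_cfg, nls_cfg = base_config_pair

    rng = np.random.default_rng(seed)
    sheet_rows, gt_rows = [], []
    animals = [("control", ctrl_cfg, f"ctrl{i + 1:02d}") for i in range(n_control)]
    animals += [("nls", nls_cfg, f"nls{i + 1:02d}") for i in range(n_nls)]
    for genotype, base_cfg, animal in animals:
        cfg = copy.deepcopy(base_cfg)
        dens_eff = math.exp(rng.normal(0.0, animal_cv))
        size_eff = math.exp(rng.normal(0.0, animal_cv))
        for role, mp in cfg.markers.items():
            cfg.markers[role] = replace(
                mp,
                density_per_10k_um2=mp.density_per_10k_um2 * dens_eff,
                radius_median_px=mp.radius_median_px * size_eff,
            )
        for img_idx in range(images_per_animal):
            section = img_idx % 2 + 1
            img_seed = int(rng.integers(0, 2**31 - 1))
            scene_cfg = replace(cfg, seed=img_seed)
            scene, gt = generate_scene(scene_cfg)
            roles = sorted(scene.planes)
            stack = np.stack([scene.planes[r] for r in roles]).astype(np.float32)
            fname = f"{animal}_s{section}_i{img_idx + 1}.tif"
            tifffile.imwrite(out_dir / fname, stack, photometric="minisblack")
            sheet_rows.append(
                {
                    "image": fname,
                    "section": section,
                    "animal": animal,
                    "genotype": genotype,
                    "channels": ";".join(roles),
                    "pixel_size_um": cfg.pixel_size_um,
                }
            )
            gt_rows.append({"image": fname, "animal": animal, "genotype": genotype, **gt.summary})
    sheet = pd.DataFrame(sheet_rows)
    sheet.to_csv(out_dir / "sample_sheet.csv", index=False)
    pd.DataFrame(gt_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    return sheet
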