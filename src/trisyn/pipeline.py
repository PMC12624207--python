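"""End-to-end orchestration.

Reads a sample sheet (image -> section -> animal -> genotype) and a run
config, executes segmentation -> colocalization/typing -> morphometry on
every image, aggregates per-image metrics to per-animal medians and runs
the two-group statistics. Analysis stages see blinded rows (no genotype
string appears in any intermediate file); genotype is joined only at the
statistics stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from trisyn import colocalization as coloc
from trisyn import morphometry as morpho
from trisyn.segmentation import (
    MultiChannelScene,
    SegmentationParams,
    segment_channel,
    subtract_background,
)
from trisyn.stats import aggregate_animal, summarize_groups, two_sample_t

__all__ = [
    "RunConfig",
    "read_scene",
    "run_pipeline",
    "image_metrics",
    "simulated_cohort_comparison",
]

logger = logging.getLogger("trisyn")

PRESYN_ROLES = ("vacht", "glyt2", "vglut1", "vglut2")


@dataclass
class RunConfig:
    """All pipeline parameters; round-trips losslessly through YAML."""

    presyn_roles: tuple[str, ...] = PRESYN_ROLES
    psd_role: str = "psd95"
    pap_role: str = "pezrin"
    ptdp_role: str = "ptdp43"
    nuclear_role: str = "dapi"
    soma_role: str = "smi32"
    gfap_role: str = "gfap"
    seg_params: dict[str, SegmentationParams] = field(default_factory=dict)
    default_seg: SegmentationParams = field(default_factory=SegmentationParams)
    nucleus_min_size_px: int = 200
    soma_min_size_px: int = 500
    c_bouton_dilation_px: int = 2
    shell_width_um: float = 1.0
    nuclear_mode: str = "intensity"
    pixel_size_um: float | None = None
    control_label: str = "control"
    case_label: str = "nls"
    bh_adjust: bool = False
    output_dir: str = "trisyn_out"
    seed: int = 0
    log_level: str = "INFO"

    def params_for(self, role: str) -> SegmentationParams:
        if role in self.seg_params:
            return self.seg_params[role]
        if role == self.nuclear_role:
            return SegmentationParams(
                background_radius_px=0,
                gaussian_sigma_px=2.0,
                min_size_px=self.nucleus_min_size_px,
                watershed_min_distance_px=15,
            )
        if role in (self.soma_role, "mmp9"):
            return SegmentationParams(
                background_radius_px=0,
                gaussian_sigma_px=2.0,
                min_size_px=self.soma_min_size_px,
                watershed_min_distance_px=25,
            )
        return self.default_seg

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["presyn_roles"] = list(self.presyn_roles)
        data["seg_params"] = {k: asdict(v) for k, v in self.seg_params.items()}
        data["default_seg"] = asdict(self.default_seg)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["presyn_roles"] = tuple(data.get("presyn_roles", PRESYN_ROLES))
        data["seg_params"] = {
            k: SegmentationParams(**v) for k, v in data.get("seg_params", {}).items()
        }
        data["default_seg"] = SegmentationParams(**data.get("default_seg", {}))
        return cls(**data)

    def digest(self) -> str:
        data = asdict(self)
        data["presyn_roles"] = list(self.presyn_roles)
        return hashlib.sha256(
            json.dumps(data, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def read_scene(
    path: str | Path,
    channel_role_map: dict[str, int] | list[str] | str,
    pixel_size_um: float | None = None,
) -> MultiChannelScene:
    """Read a multi-channel TIFF into a scene.

    ``channel_role_map`` maps role -> channel index, or is a list (or
    ``";"``-joined string) of roles in channel order. An explicitly given
    ``pixel_size_um`` wins over file metadata (a warning is logged when
    they disagree); with neither, an error is raised.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_px = _pixel_size_from_tiff(tif)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected 2D or 3D (C,H,W) image, got shape {arr.shape}")
    if isinstance(channel_role_map, str):
        channel_role_map = channel_role_map.split(";")
    if isinstance(channel_role_map, (list, tuple)):
        channel_role_map = {role: i for i, role in enumerate(channel_role_map)}
    planes = {}
    for role, idx in channel_role_map.items():
        if idx >= arr.shape[0]:
            raise ValueError(
                f"role {role!r} maps to channel {idx} but image has {arr.shape[0]} channels"
            )
        planes[role] = np.clip(arr[idx].astype(float), 0, None)
    if pixel_size_um is not None:
        if meta_px is not None and not np.isclose(meta_px, pixel_size_um):
            logger.warning(
                "pixel size: config %s um overrides metadata %s um for %s",
                pixel_size_um, meta_px, path.name,
            )
        px = pixel_size_um
    elif meta_px is not None:
        px = meta_px
    else:
        raise ValueError(f"missing pixel size for {path}: none in metadata or config")
    return MultiChannelScene(planes=planes, pixel_size_um=px)


def _pixel_size_from_tiff(tif: "tifffile.TiffFile") -> float | None:
    try:
        page = tif.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None or unit is None:
            return None
        num, den = res.value
        if num == 0:
            return None
        # unit 3 = cm -> um
        scale = {2: 25400.0, 3: 10000.0}.get(int(getattr(unit.value, "value", unit.value)))
        if scale is None:
            return None
        return den / num * scale
    except Exception:
        return None


def image_metrics(scene: MultiChannelScene, config: RunConfig) -> tuple[dict, dict]:
    """All per-image metrics for one scene.

    Returns ``(metrics, skipped)`` where ``skipped`` maps analysis name to
    the reason it was not run (missing channels)."""
    metrics: dict[str, float] = {}
    skipped: dict[str, str] = {}
    area_10k = scene.area_um2 / 1e4
    labels_cache: dict[str, tuple[pd.DataFrame, np.ndarray]] = {}

    def seg(role):
        if role not in labels_cache:
            labels_cache[role] = segment_channel(scene, role, config.params_for(role))
        return labels_cache[role]

    ptdp_available = config.ptdp_role in scene
    psd_available = config.psd_role in scene
    pap_available = config.pap_role in scene

    for role in config.presyn_roles:
        if role not in scene:
            continue
        table, labels = seg(role)
        metrics[f"{role}_density_per_10k_um2"] = len(table) / area_10k
        metrics[f"{role}_total_area_um2"] = float(table["area_um2"].sum())
        metrics[f"{role}_mean_size_um2"] = (
            float(table["area_um2"].mean()) if len(table) else float("nan")
        )

        records = None
        if psd_available:
            psd_table, psd_labels = seg(config.psd_role)
            records = coloc.define_synapses(table, labels, psd_table, psd_labels)
            bona = records[records["has_psd"]]
            metrics[f"{role}_bona_fide_fraction"] = (
                float(records["has_psd"].mean()) if len(records) else float("nan")
            )
            metrics[f"{role}_synapse_bouton_size_um2"] = (
                float(bona["bouton_area_um2"].mean()) if len(bona) else float("nan")
            )
            metrics[f"{role}_psd_size_um2"] = (
                float(bona["psd_area_um2"].mean()) if len(bona) else float("nan")
            )
            if pap_available:
                _, pap_labels = seg(config.pap_role)
                records = coloc.classify_tripartite(records, labels, pap_labels)
                metrics[f"{role}_tripartite_fraction"] = coloc.tripartite_fraction(records)
                tri = bona_tri = records[records["has_psd"] & records["is_tripartite"]]
                non = records[records["has_psd"] & ~records["is_tripartite"]]
                metrics[f"{role}_tripartite_bouton_size_um2"] = (
                    float(tri["bouton_area_um2"].mean()) if len(tri) else float("nan")
                )
                metrics[f"{role}_nontripartite_bouton_size_um2"] = (
                    float(non["bouton_area_um2"].mean()) if len(non) else float("nan")
                )
        elif pap_available:
            skipped[f"{role}_tripartite"] = f"missing channel {config.psd_role}"

        if ptdp_available:
            base = records if records is not None else table.rename(
                columns={"area_um2": "bouton_area_um2"}
            )
            ptdp_table, ptdp_labels = seg(config.ptdp_role)
            with_content = coloc.ptdp43_content(base, labels, ptdp_table, ptdp_labels)
            for k, v in coloc.ptdp43_image_metrics(with_content).items():
                metrics[f"{role}_{k}"] = v

        if role == "vacht" and config.soma_role in scene:
            _, soma_labels = seg(config.soma_role)
            base = records if records is not None else table.rename(
                columns={"area_um2": "bouton_area_um2"}
            )
            apposed = coloc.c_bouton_apposition(
                base, labels, soma_labels > 0, config.c_bouton_dilation_px
            )
            metrics["vacht_apposed_fraction"] = (
                float(apposed["apposed"].mean()) if len(apposed) else float("nan")
            )

    if config.nuclear_role in scene and ptdp_available:
        _, nuc_labels = seg(config.nuclear_role)
        ptdp_params = config.params_for(config.ptdp_role)
        ptdp_bgsub = subtract_background(
            scene[config.ptdp_role], ptdp_params.background_radius_px
        )
        ptdp_seg_labels = seg(config.ptdp_role)[1]
        cells = morpho.nuclear_cyto_partition(
            ptdp_bgsub,
            nuc_labels,
            scene.pixel_size_um,
            shell_width_um=config.shell_width_um,
            mode=config.nuclear_mode,
            ptdp_labels=ptdp_seg_labels if config.nuclear_mode == "count" else None,
            signal_mask=ptdp_seg_labels > 0,
        )
        usable = cells[~cells["excluded"]]
        metrics["ptdp_nuclear_fraction"] = (
            float(usable["nuclear_fraction"].mean()) if len(usable) else float("nan")
        )
        metrics["n_nuclei"] = int(len(cells))
    elif config.nuclear_role in scene:
        skipped["nuclear_fraction"] = f"missing channel {config.ptdp_role}"

    for soma_role in (config.soma_role, "mmp9"):
        if soma_role not in scene:
            continue
        _, soma_labels = seg(soma_role)
        sm = morpho.soma_metrics(soma_labels, scene.pixel_size_um)
        metrics[f"{soma_role}_density_per_10k_um2"] = morpho.cell_density(
            sm["count"], scene
        )
        metrics[f"{soma_role}_mean_soma_area_um2"] = sm["mean_area_um2"]

    if config.gfap_role in scene:
        gfap_table, gfap_labels = seg(config.gfap_role)
        nuc_labels = seg(config.nuclear_role)[1] if config.nuclear_role in scene else None
        gs = morpho.gfap_summary(
            scene[config.gfap_role], gfap_labels > 0, nuc_labels, scene.pixel_size_um
        )
        metrics["gfap_area_fraction"] = gs["gfap_area_fraction"]
        metrics["gfap_mean_intensity"] = gs["gfap_mean_intensity"]
        metrics["gfap_cell_density_per_10k_um2"] = gs["gfap_positive_cell_density"]
        sk = morpho.skeleton_branching(gfap_labels > 0, scene.pixel_size_um)
        metrics["gfap_branch_points"] = sk["n_branch_points"]
        metrics["gfap_mean_branch_length_um"] = (
            float(np.mean(sk["branch_lengths_um"]))
            if sk["branch_lengths_um"]
            else float("nan")
        )
    return metrics, skipped


def simulated_cohort_comparison(
    base_config_pair,
    n_control: int,
    n_nls: int,
    images_per_animal: int,
    config: RunConfig,
    seed: int = 0,
    animal_cv: float = 0.05,
) -> pd.DataFrame:
    """Simulation-study path: generate a cohort in memory and compare groups.

    Mirrors :func:`run_pipeline` (same per-image metrics, per-animal median
    aggregation and pooled t-test) without touching disk; used for power
    and type-I-error studies. Animal-level log-normal effects of coefficient
    of variation ``animal_cv`` are applied to marker density and size, as in
    :func:`trisyn.scenes.generate_cohort`.
    """
    import copy
    import math as _math
    from dataclasses import replace as _replace

    from trisyn.scenes import generate_scene

    ctrl_cfg, nls_cfg = base_config_pair
    rng = np.random.default_rng(seed)
    rows = []
    genotype = {}
    animals = [("control", ctrl_cfg, f"c{i}") for i in range(n_control)]
    animals += [("nls", nls_cfg, f"n{i}") for i in range(n_nls)]
    for geno, base_cfg, animal in animals:
        genotype[animal] = geno
        cfg = copy.deepcopy(base_cfg)
        dens_eff = _math.exp(rng.normal(0.0, animal_cv))
        size_eff = _math.exp(rng.normal(0.0, animal_cv))
        for role, mp in cfg.markers.items():
            cfg.markers[role] = _replace(
                mp,
                density_per_10k_um2=mp.density_per_10k_um2 * dens_eff,
                radius_median_px=mp.radius_median_px * size_eff,
            )
        for img in range(images_per_animal):
            scene_cfg = _replace(cfg, seed=int(rng.integers(0, 2**31 - 1)))
            scene, _ = generate_scene(scene_cfg)
            metrics, _skipped = image_metrics(scene, config)
            rows.append({"animal": animal, **metrics})
    per_image = pd.DataFrame(rows)
    metric_cols = [c for c in per_image.columns if c != "animal"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_animal = (
            per_image.groupby("animal")[metric_cols]
            .agg(lambda v: aggregate_animal(v.dropna()) if v.notna().any() else float("nan"))
            .reset_index()
        )
        joined = per_animal.assign(genotype=per_animal["animal"].map(genotype))
        comparisons = []
        for col in metric_cols:
            a = joined.loc[joined["genotype"] == "control", col].dropna()
            b = joined.loc[joined["genotype"] == "nls", col].dropna()
            if len(a) >= 2 and len(b) >= 2:
                comparisons.append(two_sample_t(a, b, metric=col))
    return summarize_groups(comparisons)


def run_pipeline(
    sample_sheet: pd.DataFrame | str | Path,
    config: RunConfig,
    image_dir: str | Path | None = None,
) -> dict:
    """Run the full analysis and write all result tables.

    Writes ``per_image_metrics.csv`` and ``per_animal_metrics.csv``
    (blinded: no genotype column), ``group_comparisons.csv`` (genotype
    joined at the statistics stage), and ``run_manifest.json``. Returns a
    dict with the three tables and the manifest.
    """
    logging.basicConfig(level=getattr(logging, config.log_level, logging.INFO))
    if not isinstance(sample_sheet, pd.DataFrame):
        sheet_path = Path(sample_sheet)
        sample_sheet = pd.read_csv(sheet_path)
        if image_dir is None:
            image_dir = sheet_path.parent
    image_dir = Path(image_dir) if image_dir is not None else Path(".")
    required = {"image", "section", "animal", "genotype", "channels"}
    missing = required - set(sample_sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    declared = {config.control_label, config.case_label}
    bad = set(sample_sheet["genotype"]) - declared
    if bad:
        raise ValueError(f"undeclared genotypes in sample sheet: {sorted(bad)}")
    for fname in sample_sheet["image"]:
        if not (image_dir / fname).exists():
            raise FileNotFoundError(image_dir / fname)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    all_skipped: dict[str, str] = {}
    rows = []
    for rec in sample_sheet.to_dict("records"):
        px = config.pixel_size_um if config.pixel_size_um is not None else rec.get("pixel_size_um")
        scene = read_scene(image_dir / rec["image"], rec["channels"], px)
        metrics, skipped = image_metrics(scene, config)
        all_skipped.update(skipped)
        rows.append(
            {"image": rec["image"], "section": rec["section"], "animal": rec["animal"], **metrics}
        )
    per_image = pd.DataFrame(rows)
    per_image.to_csv(out_dir / "per_image_metrics.csv", index=False)

    metric_cols = [c for c in per_image.columns if c not in ("image", "section", "animal")]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_animal = per_image.groupby("animal")[metric_cols].agg(
            lambda v: aggregate_animal(v.dropna()) if v.notna().any() else float("nan")
        )
    per_animal = per_animal.reset_index()
    per_animal.to_csv(out_dir / "per_animal_metrics.csv", index=False)

    # genotype joined only here, at the statistics stage
    genotype_map = sample_sheet.drop_duplicates("animal").set_index("animal")["genotype"]
    joined = per_animal.assign(genotype=per_animal["animal"].map(genotype_map))
    comparisons = []
    for col in metric_cols:
        grp_a = joined.loc[joined["genotype"] == config.control_label, col].dropna()
        grp_b = joined.loc[joined["genotype"] == config.case_label, col].dropna()
        if len(grp_a) < 2 or len(grp_b) < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            comparisons.append(two_sample_t(grp_a, grp_b, metric=col))
    group_table = summarize_groups(comparisons, adjust="bh" if config.bh_adjust else None)
    group_table.to_csv(out_dir / "group_comparisons.csv", index=False)

    manifest = {
        "software": "trisyn",
        "version": __import__("trisyn").__version__,
        "config_hash": config.digest(),
        "n_images": int(len(sample_sheet)),
        "n_animals": int(sample_sheet["animal"].nunique()),
        "skipped_analyses": all_skipped,
        "status_flag": 1 if all_skipped else 0,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    for name, reason in all_skipped.items():
        logger.warning("skipped %s: %s", name, reason)
    return {
        "per_image": per_image,
        "per_animal": per_animal,
        "group_comparisons": group_table,
        "manifest": manifest,
    }
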