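"""End-to-end orchestration: simulate -> ground -> heights -> traits ->
cluster -> dominance, from one YAML-able config, with a hashed run manifest.

Every stage writes its outputs under ``output_dir`` and can equally be run
from the serialized outputs of the previous stage, so partial pipelines
(e.g. cluster-only on an existing profiles CSV) behave identically to a
fused run.  All randomness flows from the config seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import traits as traits_mod
from .design import FieldDesign, make_field_design
from .dominance import dominant_background, hard_assign, intersections, typical_profiles
from .fcm import scan_cluster_sizes
from .ground import AtinParams, build_dem, classify_ground_atin
from .growth import DEFAULT_DAYS, GrowthModel, simulate_growth_profiles
from .heights import (aggregate_local_maxima, binarize_vegetation, compute_csm,
                      compute_ngrdi, validate_heights, zonal_mean_height)
from .pointcloud import PointCloud
from .raster import RasterGrid
from .scene import (CanopyParams, SpectralParams, SyntheticScene, TerrainParams,
                    render_scene, sample_point_cloud)

__all__ = ["RunConfig", "run_pipeline", "validate_run", "default_config", "StageError"]

log = logging.getLogger("phenoprofiles")

ALL_STAGES = ("simulate", "ground", "heights", "traits", "cluster", "dominance")

# Workflow defaults in one block: ATIN 0.20 m / 0.03 m / 1.5 deg, NGRDI
# threshold 0, 0.25 m aggregation window, fuzzifier m = 2, C scanned 2-15,
# 500 iterations, winsorization at the 2nd/98th percentiles.
DEFAULTS = {
    "seed": 0,
    "stages": list(ALL_STAGES),
    "output_dir": "phenoprofiles_run",
    "simulate": {
        "n_plots": 24,
        "plot_width_m": 2.0,
        "plot_length_m": 2.4,
        "cell_size_m": 0.025,
        "observation_days": list(DEFAULT_DAYS),
        "height_noise_sd": 2.0,
        "lodging_fraction": 0.194,
        "spectral_noise_sd": 0.0,
        "point_density_per_cm2": 0.05,
        "point_noise_sd_cm": 0.0,
        "relief_amplitude_m": 0.08,
    },
    "ground": {"cell_size": 0.20, "max_distance": 0.03, "max_angle": 1.5},
    "heights": {"ngrdi_threshold": 0.0, "window_m": 0.25},
    "traits": {"lower_pct": 2.0, "upper_pct": 98.0},
    "cluster": {"traits": ["PH", "AGRPH", "CRPH"], "c_min": 2, "c_max": 15,
                "fuzzifier": 2.0, "max_iter": 500, "tol": 1e-6, "restarts": 5},
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def default_config() -> dict:
    return json.loads(json.dumps(DEFAULTS))


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``DEFAULTS`` for the schema)."""

    raw: dict

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        merged = _merge(default_config(), cfg or {})
        unknown = set(merged) - set(DEFAULTS) - {"inputs"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad = set(merged["stages"]) - set(ALL_STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return cls(merged)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def __getitem__(self, key: str):
        return self.raw[key]

    @property
    def stages(self) -> list[str]:
        return list(self.raw["stages"])

    @property
    def output_dir(self) -> Path:
        return Path(self.raw["output_dir"])


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class PipelineState:
    """In-memory carry between stages plus the file registry."""

    outdir: Path
    scene: SyntheticScene | None = None
    cloud: PointCloud | None = None
    dem: RasterGrid | None = None
    heights: pd.DataFrame | None = None
    profiles: dict = field(default_factory=dict)       # trait -> list[TemporalProfile]
    scans: dict = field(default_factory=dict)          # trait -> ClusterScanResults
    dominance: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)

    def register(self, name: str, path: Path) -> None:
        self.files[name] = str(path.relative_to(self.outdir))


def run_pipeline(config: RunConfig | dict, return_state: bool = False):
    """Execute the enabled stages in order; return the run manifest
    (and the in-memory :class:`PipelineState` when ``return_state``)."""
    if isinstance(config, dict):
        config = RunConfig.from_dict(config)
    outdir = config.output_dir
    outdir.mkdir(parents=True, exist_ok=True)
    state = PipelineState(outdir=outdir)
    manifest: dict = {"config": config.raw, "stages": [], "timings_s": {}}

    runners = {
        "simulate": _stage_simulate,
        "ground": _stage_ground,
        "heights": _stage_heights,
        "traits": _stage_traits,
        "cluster": _stage_cluster,
        "dominance": _stage_dominance,
    }
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        log.info("stage %s: start", stage)
        t0 = time.perf_counter()
        try:
            runners[stage](config, state)
        except Exception as exc:
            _write_manifest(manifest, state, outdir, failed_stage=stage)
            raise StageError(stage, exc) from exc
        manifest["stages"].append(stage)
        manifest["timings_s"][stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", stage, manifest["timings_s"][stage])

    _write_manifest(manifest, state, outdir)
    return (manifest, state) if return_state else manifest


def _write_manifest(manifest: dict, state: PipelineState, outdir: Path,
                    failed_stage: str | None = None) -> None:
    manifest["files"] = {k: {"path": v, "sha256": _sha256(outdir / v)}
                         for k, v in sorted(state.files.items())}
    if failed_stage:
        manifest["failed_stage"] = failed_stage
    manifest.pop("timings_s_out", None)
    path = outdir / "run_manifest.json"
    hashable = {k: v for k, v in manifest.items() if k != "timings_s"}
    manifest["manifest_sha256"] = hashlib.sha256(
        json.dumps(hashable, sort_keys=True).encode()).hexdigest()
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


# -- stages ----------------------------------------------------------------
def _stage_simulate(config: RunConfig, state: PipelineState) -> None:
    cfg = config["simulate"]
    seed = int(config["seed"])
    design = make_field_design(
        n_plots=int(cfg["n_plots"]), plot_width_m=cfg["plot_width_m"],
        plot_length_m=cfg["plot_length_m"], seed=seed)
    model = GrowthModel(observation_days=tuple(cfg["observation_days"]),
                        height_noise_sd=cfg["height_noise_sd"],
                        lodging_fraction=cfg["lodging_fraction"])
    heights, abnormal = simulate_growth_profiles(design, model, seed=seed + 1)
    scene = render_scene(
        design, heights,
        terrain=TerrainParams(relief_amplitude_m=cfg["relief_amplitude_m"]),
        spectral=SpectralParams(noise_sd=cfg["spectral_noise_sd"]),
        cell_size_m=cfg["cell_size_m"], seed=seed + 2, abnormal=abnormal)
    scene_dir = state.outdir / "scene"
    scene.write(scene_dir)
    for p in scene_dir.iterdir():
        state.register(f"scene/{p.name}", p)
    # dense cloud for the first (low-cover) campaign, used for the DEM
    cloud = sample_point_cloud(scene, scene.days[0],
                               density_per_cm2=cfg["point_density_per_cm2"],
                               vertical_noise_sd_cm=cfg["point_noise_sd_cm"],
                               seed=seed + 3)
    cloud_path = state.outdir / "cloud_first_date.xyz"
    PointCloud(cloud.xyz).to_xyz(cloud_path)   # unlabeled: truth stays separate
    np.savetxt(state.outdir / "cloud_first_date_truth.txt", cloud.labels, fmt="%d")
    state.register("cloud_first_date", cloud_path)
    state.register("cloud_first_date_truth", state.outdir / "cloud_first_date_truth.txt")
    state.scene = scene
    state.cloud = PointCloud(cloud.xyz)


def _stage_ground(config: RunConfig, state: PipelineState) -> None:
    cfg = config["ground"]
    params = AtinParams(cell_size=cfg["cell_size"], max_distance=cfg["max_distance"],
                        max_angle=cfg["max_angle"])
    if state.cloud is None:
        cloud_path = config.raw.get("inputs", {}).get(
            "cloud", state.outdir / "cloud_first_date.xyz")
        state.cloud = PointCloud.from_xyz(cloud_path)
    labeled = classify_ground_atin(state.cloud, params)
    labeled.to_xyz(state.outdir / "cloud_classified.xyz")
    state.register("cloud_classified", state.outdir / "cloud_classified.xyz")

    if state.scene is not None:
        grid = state.scene.dem_truth
    else:
        grid = RasterGrid.from_geotiff(config.raw["inputs"]["dsm_grid"])
    dem = build_dem(labeled, grid)
    dem.to_geotiff(state.outdir / "dem.tif")
    state.register("dem", state.outdir / "dem.tif")
    state.dem = dem
    state.cloud = labeled


def _stage_heights(config: RunConfig, state: PipelineState) -> None:
    cfg = config["heights"]
    if state.scene is None:
        raise ValueError("heights stage requires a scene (run simulate first or "
                         "provide rasters via the canopy_height API directly)")
    scene = state.scene
    dem = state.dem
    if dem is None:
        dem_path = state.outdir / "dem.tif"
        dem = RasterGrid.from_geotiff(dem_path) if dem_path.exists() else scene.dem_truth
    window = max(1, int(round(cfg["window_m"] / scene.dem_truth.cell_size)))
    frames = []
    for d in scene.days:
        csm = compute_csm(scene.dsm[d], dem)
        ngrdi = compute_ngrdi(scene.green_band[d], scene.red_band[d])
        mask = binarize_vegetation(ngrdi, cfg["ngrdi_threshold"])
        blocks = aggregate_local_maxima(csm, window, mask=mask)
        frames.append(zonal_mean_height(blocks, scene.design, d))
    heights = pd.concat(frames, ignore_index=True)
    heights.to_csv(state.outdir / "plot_heights.csv", index=False)
    state.register("plot_heights", state.outdir / "plot_heights.csv")
    state.heights = heights


def _stage_traits(config: RunConfig, state: PipelineState) -> None:
    cfg = config["traits"]
    if state.heights is None:
        path = config.raw.get("inputs", {}).get(
            "heights", state.outdir / "plot_heights.csv")
        state.heights = pd.read_csv(path)
    if state.scene is not None:
        backgrounds = state.scene.design.background_map()
        flags = (state.scene.abnormal.to_dict() if state.scene.abnormal is not None
                 else {p: False for p in backgrounds})
    else:
        plots = pd.read_csv(config.raw["inputs"]["plots"])
        backgrounds = dict(zip(plots["plot_id"].astype(str), plots["background"]))
        flags = {p: False for p in backgrounds}

    ph, incomplete = traits_mod.build_profiles(state.heights, backgrounds)
    flags = {p.plot_id: bool(flags.get(p.plot_id, False)) for p in ph}
    ph, removal = traits_mod.remove_abnormal(ph, flags)
    derived = {"PH": ph,
               "AGRPH": [traits_mod.agrph(p) for p in ph],
               "CRPH": [traits_mod.crph(p) for p in ph]}
    reports = {"incomplete_plots": incomplete, "removal": removal.to_dict(), "winsor": {}}
    for name in derived:
        derived[name], rep = traits_mod.winsorize(derived[name], cfg["lower_pct"],
                                                  cfg["upper_pct"])
        reports["winsor"][name] = rep.to_dict()
    long_df = pd.concat([traits_mod.profiles_to_frame(ps) for ps in derived.values()],
                        ignore_index=True)
    long_df.to_csv(state.outdir / "trait_profiles.csv", index=False)
    with open(state.outdir / "cleaning_report.json", "w") as fh:
        json.dump(reports, fh, indent=2)
    state.register("trait_profiles", state.outdir / "trait_profiles.csv")
    state.register("cleaning_report", state.outdir / "cleaning_report.json")
    state.profiles = derived


def _profiles_matrix(profiles: list) -> tuple[np.ndarray, list[str], list[str]]:
    mat = np.vstack([p.values for p in profiles])
    return mat, [p.plot_id for p in profiles], [p.background for p in profiles]


def _stage_cluster(config: RunConfig, state: PipelineState) -> None:
    cfg = config["cluster"]
    if not state.profiles:
        path = config.raw.get("inputs", {}).get(
            "profiles", state.outdir / "trait_profiles.csv")
        df = pd.read_csv(path)
        state.profiles = {t: traits_mod.frame_to_profiles(df, t)
                          for t in cfg["traits"] if t in set(df["trait"])}
    seed = int(config["seed"])
    selection = {}
    for t_i, trait in enumerate(cfg["traits"]):
        profs = state.profiles.get(trait)
        if not profs:
            continue
        mat, pids, _ = _profiles_matrix(profs)
        scan = scan_cluster_sizes(
            mat, c_range=range(int(cfg["c_min"]), int(cfg["c_max"]) + 1),
            m=cfg["fuzzifier"], seed=seed + 10 + 100 * t_i,
            max_iter=int(cfg["max_iter"]), tol=cfg["tol"],
            n_restarts=int(cfg["restarts"]))
        state.scans[trait] = scan
        scan.table.to_csv(state.outdir / f"validity_{trait}.csv")
        best = scan.best_fit()
        pd.DataFrame(best.memberships, index=pd.Index(pids, name="plot_id")
                     ).to_csv(state.outdir / f"memberships_{trait}.csv")
        pd.DataFrame(best.centroids).to_csv(state.outdir / f"centroids_{trait}.csv",
                                            index_label="cluster")
        for name in ("validity", "memberships", "centroids"):
            state.register(f"{name}_{trait}", state.outdir / f"{name}_{trait}.csv")
        selection[trait] = {"selected_c": scan.selected_c,
                            "has_majority": scan.selection.has_majority,
                            "proposals": scan.proposals}
    with open(state.outdir / "cluster_selection.json", "w") as fh:
        json.dump(selection, fh, indent=2)
    state.register("cluster_selection", state.outdir / "cluster_selection.json")


def _stage_dominance(config: RunConfig, state: PipelineState) -> None:
    if not state.scans:
        raise ValueError("dominance stage requires the cluster stage")
    report = {}
    for trait, scan in state.scans.items():
        profs = state.profiles[trait]
        _, pids, bgs = _profiles_matrix(profs)
        best = scan.best_fit()
        assignments, _ = hard_assign(best, pids)
        table = intersections(assignments, dict(zip(pids, bgs)))
        dom = dominant_background(table)
        days = profs[0].days if trait == "PH" else profs[0].days[:-1]
        typ = typical_profiles(best, dom, days, trait_name=trait)
        table.to_frame().to_csv(state.outdir / f"intersections_{trait}.csv", index=False)
        state.register(f"intersections_{trait}", state.outdir / f"intersections_{trait}.csv")
        typ_df = pd.DataFrame(
            [{"cluster": t.cluster_id, "dominant_background": t.dominant_background,
              **{f"d{d}": v for d, v in zip(t.days, t.centroid)}} for t in typ])
        typ_df.to_csv(state.outdir / f"typical_profiles_{trait}.csv", index=False)
        state.register(f"typical_profiles_{trait}", state.outdir / f"typical_profiles_{trait}.csv")
        report[trait] = {str(cl): info for cl, info in dom.items()}
    with open(state.outdir / "dominance_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    state.register("dominance_report", state.outdir / "dominance_report.json")
    state.dominance = report


# -- validation against synthetic truth ------------------------------------
def validate_run(state_or_dir, scene: SyntheticScene | None = None) -> dict:
    """Regression of estimated vs true plot heights plus clustering recovery.

    Accepts the :class:`PipelineState` of a fused run, or an output
    directory (with ``scene`` supplied for the truth).  Returns height R²
    and RMSE (cm), the adjusted Rand index of hard assignments against the
    true background groups, and the selected C per trait.
    """
    from sklearn.metrics import adjusted_rand_score

    if isinstance(state_or_dir, PipelineState):
        state = state_or_dir
        scene = scene or state.scene
        heights = state.heights
        scans = state.scans
        profiles = state.profiles
    else:
        outdir = Path(state_or_dir)
        heights = pd.read_csv(outdir / "plot_heights.csv")
        scans, profiles = {}, {}
    if scene is None:
        return {"status": "not-applicable: no synthetic truth available"}

    truth_long = scene.true_plot_heights.reset_index().melt(
        id_vars="plot_id", var_name="das", value_name="height_cm")
    truth_long["das"] = truth_long["das"].astype(int)
    est = heights.rename(columns={"height_cm": "height_cm"})
    metrics = validate_heights(est[["plot_id", "das", "height_cm"]], truth_long)

    out = {"height_r2": metrics["r2"], "height_rmse_cm": metrics["rmse_cm"],
           "height_slope": metrics["slope"], "height_intercept": metrics["intercept"],
           "n_pairs": metrics["n"], "selected_c": {}, "ari": {}}
    for trait, scan in scans.items():
        profs = profiles[trait]
        _, pids, bgs = _profiles_matrix(profs)
        labels, _ = scan.best_fit().hard_labels()
        out["selected_c"][trait] = scan.selected_c
        out["ari"][trait] = float(adjusted_rand_score(bgs, labels))
    return out
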