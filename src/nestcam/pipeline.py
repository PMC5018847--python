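"""End-to-end orchestration: scene -> regions -> edges -> metrics ->
species comparison -> survival model selection.

A run is driven by a RunConfig (constructable from a YAML file), writes
every stage output into a fresh run directory and records a manifest with
parameters and per-stage row counts.  Inputs are never mutated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .color import LabScene, RgbScene, crop_roi, rgb_to_lab
from .comparison import DEFAULT_LOG_VARS, compare_groups, quadratic_deviation
from .edges import canny
from .metrics import METRIC_COLUMNS, measure_clutch, records_to_frame
from .regions import ClutchMask, derive_regions
from .survival import (
    code_fates,
    enumerate_models,
    fit_model_suite,
    km_curve,
    model_average,
    plot_km,
    vif_prune,
)

logger = logging.getLogger(__name__)

#: Candidate survival predictors before collinearity pruning.
CANDIDATE_PREDICTORS = [
    "DisRat",
    "VisRat",
    "CompRat^2",
    "DeltaE",
    "BgEdge",
    "EggEdge",
    "ContEdge",
    "PropBgToEggColorMatch",
]

#: The model suite of the original study design: the ratio and color
#: metrics, with the raw edge densities excluded as collinear components
#: of the ratios.  Enumerated over two-metric significant sets this gives
#: the 19-model candidate suite.
STUDY_SUITE_METRICS = ["DisRat", "VisRat", "CompRat^2", "DeltaE", "PropBgToEggColorMatch"]


@dataclass
class RunConfig:
    """Every knob of the pipeline, with the study's defaults."""

    # detector
    canny_sigma: float = 3.0
    canny_high: float = 0.2
    canny_low: float | None = None  # None -> 0.4 * high
    # regions
    erode_px: int = 4
    dilate_px: int = 8
    se_shape: str = "disk"
    # cropping
    side_cm: float = 13.3
    # maculation segmentation
    maculation_method: str = "otsu"
    fixed_threshold: float | None = None
    # statistics
    adjust_method: str = "bh"
    alpha: float = 0.05
    vif_threshold: float = 5.0
    delta_max: float = 2.0
    # None -> derive the suite from VIF pruning instead of the fixed
    # study design (see survival_stage)
    suite_metrics: list | None = field(default_factory=lambda: list(STUDY_SUITE_METRICS))
    log_vars: list = field(default_factory=lambda: list(DEFAULT_LOG_VARS))
    # reproducibility / paths
    seed: int = 0
    metadata_csv: str | None = None
    visits_csv: str | None = None
    out_dir: str = "nestcam_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def crop_scene_and_mask(lab: LabScene, mask: ClutchMask, side_cm: float) -> tuple[LabScene, ClutchMask]:
    """Crop the analysis window around the clutch centroid, scene and mask
    together so they stay aligned."""
    rr, cc = np.nonzero(mask.mask)
    centroid = (float(rr.mean()), float(cc.mean()))
    cropped = crop_roi(lab, centroid, side_cm=side_cm)
    (r0, r1) = cropped.provenance["crop"]["rows"]
    (c0, c1) = cropped.provenance["crop"]["cols"]
    return cropped, ClutchMask(mask.mask[r0:r1, c0:c1])


def analyze_scene(
    scene: RgbScene,
    mask: ClutchMask,
    config: RunConfig | None = None,
    nest_id: str = "",
    species: str = "",
    crop: bool = True,
):
    """Measure one clutch photograph: returns (CamouflageRecord, artifacts).

    artifacts carries the cropped LabScene, RegionSet and EdgeMap for
    audit export.
    """
    config = config or RunConfig()
    lab = rgb_to_lab(scene)
    if crop:
        lab, mask = crop_scene_and_mask(lab, mask, config.side_cm)
    regions = derive_regions(mask, config.erode_px, config.dilate_px, config.se_shape)
    edge_map = canny(lab.L, sigma=config.canny_sigma, high=config.canny_high, low=config.canny_low)
    record = measure_clutch(
        lab,
        regions,
        edge_map,
        nest_id=nest_id,
        species=species,
        maculation_method=config.maculation_method,
        fixed_threshold=config.fixed_threshold,
    )
    return record, {"lab": lab, "mask": mask, "regions": regions, "edge_map": edge_map}


def add_quadratic_complexity(metrics: pd.DataFrame) -> pd.DataFrame:
    """Append the CompRat^2 covariate ((log CompRat)^2) to a metrics table."""
    out = metrics.copy()
    out["CompRat^2"] = quadratic_deviation(out["CompRat"].to_numpy(dtype=float))
    return out


def metrics_stage(metadata: pd.DataFrame, config: RunConfig, base_dir: Path | None = None) -> pd.DataFrame:
    """Measure every nest listed in the metadata table.

    Image/mask paths are resolved relative to ``base_dir``; a missing file
    aborts the run naming the offending nest.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")
    records = []
    for _, row in metadata.iterrows():
        img = base / row["image"]
        msk = base / row["mask"]
        if not img.exists():
            raise FileNotFoundError(f"nest {row['nest_id']}: image file {img} not found")
        if not msk.exists():
            raise FileNotFoundError(f"nest {row['nest_id']}: mask file {msk} not found")
        scene = nio.read_scene(img, row["colorspace"], float(row["pixels_per_cm"]))
        mask = nio.read_mask(msk)
        rec, _ = analyze_scene(scene, mask, config, nest_id=str(row["nest_id"]), species=str(row["species"]))
        records.append(rec)
    return records_to_frame(records)


def comparison_stage(metrics: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    variables = [c for c in METRIC_COLUMNS if c in metrics.columns]
    for extra in ("egg_L", "egg_a", "egg_b", "eggbg_L", "eggbg_a", "eggbg_b",
                  "macul_L", "macul_a", "macul_b", "substrate_L", "substrate_a", "substrate_b"):
        if extra in metrics.columns:
            variables.append(extra)
    return compare_groups(
        metrics, variables, log_vars=config.log_vars, adjust=config.adjust_method, alpha=config.alpha
    )


def survival_stage(
    fates: pd.DataFrame,
    metrics: pd.DataFrame,
    config: RunConfig,
    comparison: pd.DataFrame | None = None,
):
    """Model selection over the camouflage candidate suite.

    Joins fate records to the metrics table, runs VIF pruning over the
    full candidate pool (the ratio metrics plus their raw edge-density
    components, which are strongly collinear by construction), then
    enumerates the suite, ranks it by AICc and averages the
    well-supported models.  By default the suite is the study design's
    fixed five ratio/color metrics (``config.suite_metrics``); set it to
    None to enumerate over whatever survives pruning instead.  Returns a
    dict of stage outputs.
    """
    data = fates.merge(add_quadratic_complexity(metrics), on="nest_id", suffixes=("", "_m"))
    if "species_m" in data.columns:
        data = data.drop(columns=["species_m"])
    candidates = [c for c in CANDIDATE_PREDICTORS if c in data.columns]
    usable = data.dropna(subset=candidates)
    if len(usable) < len(data):
        logger.warning("dropped %d nests with missing covariates", len(data) - len(usable))
    retained, prune_log = vif_prune(usable, candidates, threshold=config.vif_threshold)
    suite = list(config.suite_metrics) if config.suite_metrics is not None else retained
    suite = [m for m in suite if m in data.columns]

    significant: list[str] = []
    if comparison is not None:
        sig_rows = comparison[(comparison["p_adjusted"] < config.alpha)]
        significant = [v for v in sig_rows["variable"] if v in suite]

    specs = enumerate_models(suite, significant_set=significant)
    ranking, fits = fit_model_suite(usable, specs)
    averaged = model_average(ranking, fits, delta_max=config.delta_max)
    curves = km_curve(usable)
    return {
        "data": usable,
        "suite_metrics": suite,
        "pruned_predictors": retained,
        "prune_log": prune_log,
        "significant_set": significant,
        "ranking": ranking,
        "fits": fits,
        "averaged": averaged,
        "km": curves,
    }


def run_pipeline(config: RunConfig, base_dir=None) -> Path:
    """Full run: metrics -> comparison -> survival, written to a run directory.

    Deterministic given the config; returns the run directory path.  The
    manifest records parameters and per-stage row counts.
    """
    if config.metadata_csv is None:
        raise ValueError("config.metadata_csv is required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir) if base_dir is not None else Path(config.metadata_csv).parent

    metadata = nio.read_metadata(config.metadata_csv)
    metrics = metrics_stage(metadata, config, base_dir=base)
    metrics.to_csv(out / "metrics.csv", index=False)

    comparison = comparison_stage(metrics, config)
    comparison.to_csv(out / "comparison.csv", index=False)

    manifest = {
        "config": {k: v for k, v in asdict(config).items()},
        "n_nests": int(len(metadata)),
        "stages": {"metrics": int(len(metrics)), "comparison": int(len(comparison))},
    }

    if config.visits_csv is not None:
        visits = pd.read_csv(config.visits_csv)
        fates = code_fates(visits)
        fates.to_csv(out / "fates.csv", index=False)
        surv = survival_stage(fates, metrics, config, comparison)
        surv["ranking"].to_csv(out / "model_ranking.csv", index=False)
        surv["averaged"].to_csv(out / "model_averaged.csv", index=False)
        surv["km"].to_csv(out / "km_curves.csv", index=False)
        plot_km(surv["km"], out / "km_curves.png")
        manifest["stages"].update(
            {
                "fates": int(len(fates)),
                "models_ranked": int(len(surv["ranking"])),
                "pruned_predictors": surv["pruned_predictors"],
                "significant_set": surv["significant_set"],
            }
        )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    logger.info("run complete: %s", out)
    return out
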