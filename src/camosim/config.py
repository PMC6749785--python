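"""TOML pipeline configuration: parsing, defaults, validation.

A single plain-text config drives every stage; the master ``seed`` fully
determines all downstream randomness (stage seeds are spawned from it). Any
block or key omitted from the file falls back to the default study
configuration.
"""

from __future__ import annotations

import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .geometry import DisplayCalibration, calibration_from_extent
from .leaves import LeafSpec
from .observers import CohortSpec
from .snakes import SnakeSpec
from .staircase import ExperimentDesign
from .textures import EdgeEnhancementSpec, FilterSpec

__all__ = ["PipelineConfig", "load_config", "default_config"]

SCHEMA_VERSION = 1


@dataclass
class PipelineConfig:
    """Validated configuration for the full stimulus + study + analysis chain."""

    calibration: DisplayCalibration
    filter_spec: FilterSpec
    ee_spec: EdgeEnhancementSpec
    leaf_spec: LeafSpec
    snake_spec: SnakeSpec
    design: ExperimentDesign
    cohort: CohortSpec
    prior_scale: float = 0.7071067811865476
    bootstrap_resamples: int = 10_000
    one_sided_baseline: bool = False
    n_backgrounds: int = 10
    n_textures_per_type: int = 10
    seed: int = 0
    out_dir: str = "camosim_out"
    scene_size: int = 1024
    grey: tuple[int, int, int] = (128, 128, 128)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.prior_scale <= 0:
            raise ValueError("prior_scale must be positive")
        if self.bootstrap_resamples < 1000:
            raise ValueError("bootstrap_resamples must be >= 1000")
        if self.n_backgrounds < 1 or self.n_textures_per_type < 1:
            raise ValueError("need at least one background and one texture per type")


def default_config() -> PipelineConfig:
    """The default study configuration (all printed design constants)."""
    return PipelineConfig(
        calibration=calibration_from_extent(1024, 29.86, 600.0),
        filter_spec=FilterSpec(),
        ee_spec=EdgeEnhancementSpec(),
        leaf_spec=LeafSpec(),
        snake_spec=SnakeSpec(),
        design=ExperimentDesign(),
        cohort=CohortSpec(),
        metadata={
            "display": "CRT 1280x1024 @ 60 Hz, mid-grey 65.3 cd/m2, CIE xy (0.28, 0.30)",
            "timing": {"min_presentation_ms": 1000, "isi_ms": 2000},
            "schema_version": SCHEMA_VERSION,
        },
    )


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a TOML config, filling unspecified values from the defaults.

    All blocks are validated through their dataclass invariants before any
    pipeline stage runs; an invalid value raises before any file is written.
    """
    cfg = default_config()
    if path is None:
        return cfg
    raw = tomllib.loads(Path(path).read_text())

    cal = raw.get("calibration", {})
    if cal:
        cfg.calibration = calibration_from_extent(
            cal.get("extent_px", 1024),
            cal.get("extent_deg", 29.86),
            cal.get("distance_mm", 600.0),
        )
    tex = raw.get("texture", {})
    cfg.filter_spec = FilterSpec(
        mu=tex.get("mu", cfg.filter_spec.mu),
        sigma=tex.get("sigma", cfg.filter_spec.sigma),
        size=tex.get("size", cfg.filter_spec.size),
    )
    cfg.ee_spec = EdgeEnhancementSpec(
        total_width_deg=tex.get("ee_width_deg", cfg.ee_spec.total_width_deg),
        offset_L=tex.get("ee_offset", cfg.ee_spec.offset_L),
        profile=tex.get("ee_profile", cfg.ee_spec.profile),
    )
    leaf = raw.get("leaf", {})
    cfg.leaf_spec = LeafSpec(
        n_leaves=leaf.get("n_leaves", cfg.leaf_spec.n_leaves),
        mean_height_deg=leaf.get("mean_height_deg", cfg.leaf_spec.mean_height_deg),
        height_jitter=leaf.get("height_jitter", cfg.leaf_spec.height_jitter),
        aspect_ratio=leaf.get("aspect_ratio", cfg.leaf_spec.aspect_ratio),
        shadow_fraction=leaf.get("shadow_fraction", cfg.leaf_spec.shadow_fraction),
        shadow_shift_deg=leaf.get("shadow_shift_deg", cfg.leaf_spec.shadow_shift_deg),
    )
    cfg.n_backgrounds = leaf.get("n_backgrounds", cfg.n_backgrounds)
    snake = raw.get("snake", {})
    cfg.snake_spec = SnakeSpec(
        baseline_width_px=snake.get("baseline_width_px", cfg.snake_spec.baseline_width_px),
        height_deg=snake.get("height_deg", cfg.snake_spec.height_deg),
        thickness_deg=snake.get("thickness_deg", cfg.snake_spec.thickness_deg),
        periods=snake.get("periods", cfg.snake_spec.periods),
        separation_deg=snake.get("separation_deg", cfg.snake_spec.separation_deg),
        y_offset_max_deg=snake.get("y_offset_max_deg", cfg.snake_spec.y_offset_max_deg),
    )
    design = raw.get("design", {})
    cfg.design = ExperimentDesign(
        start_levels=tuple(design.get("start_levels", cfg.design.start_levels)),
        trials_per_staircase=design.get(
            "trials_per_staircase", cfg.design.trials_per_staircase
        ),
        initial_step=design.get("initial_step", cfg.design.initial_step),
        min_step=design.get("min_step", cfg.design.min_step),
        pedestal_max=design.get("pedestal_max", cfg.design.pedestal_max),
        pedestal_step=design.get("pedestal_step", cfg.design.pedestal_step),
    )
    cohort = raw.get("cohort", {})
    base = CohortSpec()
    cfg.cohort = CohortSpec(
        n_observers=cohort.get("n_observers", base.n_observers),
        mean_thresholds=cohort.get("mean_thresholds", base.mean_thresholds),
        observer_sd=cohort.get("observer_sd", base.observer_sd),
        condition_sd=cohort.get("condition_sd", base.condition_sd),
        slope_mean=cohort.get("slope_mean", base.slope_mean),
        slope_sd=cohort.get("slope_sd", base.slope_sd),
        lapse=cohort.get("lapse", base.lapse),
    )
    analysis = raw.get("analysis", {})
    cfg.prior_scale = analysis.get("prior_scale", cfg.prior_scale)
    cfg.bootstrap_resamples = analysis.get(
        "bootstrap_resamples", cfg.bootstrap_resamples
    )
    cfg.one_sided_baseline = analysis.get("one_sided_baseline", cfg.one_sided_baseline)
    cfg.seed = raw.get("seed", cfg.seed)
    cfg.out_dir = raw.get("out_dir", cfg.out_dir)
    cfg.n_textures_per_type = tex.get("n_per_type", cfg.n_textures_per_type)
    # re-run validation after overrides
    cfg.__post_init__()
    return cfg


def config_summary(cfg: PipelineConfig) -> dict:
    """JSON-serialisable snapshot of the configuration for run logs."""
    return {
        "calibration": asdict(cfg.calibration),
        "filter": asdict(cfg.filter_spec),
        "edge_enhancement": asdict(cfg.ee_spec),
        "leaf": {
            k: v for k, v in asdict(cfg.leaf_spec).items() if k != "colour_population"
        },
        "snake": asdict(cfg.snake_spec),
        "design": asdict(cfg.design),
        "cohort": asdict(cfg.cohort),
        "analysis": {
            "prior_scale": cfg.prior_scale,
            "bootstrap_resamples": cfg.bootstrap_resamples,
            "one_sided_baseline": cfg.one_sided_baseline,
        },
        "seed": cfg.seed,
        "metadata": cfg.metadata,
    }
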