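"""End-to-end experiment orchestration.

One configuration drives the whole comparison: generate the synthetic
landscape, build three input data sets —

* ``coarse``        4 species-group indices from the degraded inventory, with
                    per-species diameters recovered by stand segmentation;
* ``coarseClass``   the same indices split into 20 forest types by fertility;
* ``detailClass``   a composite of the detailed truth (where detailed coverage
                    exists, default 45 % of the land) and the coarse data
                    elsewhere, split into 20 forest types, with the planned-
                    operations condition layer;

— then run each data set through the greedy ranker with and without matrix
connectivity (the default six-run grid) and assemble the comparison report.
Everything is deterministic under a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import raster_io
from .evaluation_suite import experiment_report
from .inventory_indices import (
    BenefitFunctionParams,
    apply_weight_scheme,
    build_condition_layer,
    classify_by_fertility,
    conservation_index,
)
from .prioritization_engine import (
    ConnectivityConfig,
    PrioritizationConfig,
    cross_load_evaluation,
    matrix_connectivity_transform,
    rank_landscape,
)
from .stand_segmentation import (
    SegmentationConfig,
    segment_directed_trees,
    segment_species_attributes,
)
from .synthetic_landscape import (
    LandscapeConfig,
    gaussian_random_field,
    generate_landscape,
)

logger = logging.getLogger("forestprio")

DATASETS = ("coarse", "coarseClass", "detailClass")

#: The six-run grid: each input data set with and without connectivity.
DEFAULT_RUN_GRID = (
    ("coarse", False),
    ("coarse", True),
    ("coarseClass", False),
    ("coarseClass", True),
    ("detailClass", False),
    ("detailClass", True),
)


def run_label(dataset, connectivity):
    return dataset + ("Con" if connectivity else "")


@dataclass
class ExperimentConfig:
    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    benefit: BenefitFunctionParams = field(default_factory=BenefitFunctionParams)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    prioritization: PrioritizationConfig = field(default_factory=PrioritizationConfig)
    run_grid: tuple = DEFAULT_RUN_GRID
    detailed_coverage_fraction: float = 0.45
    fertile_weight_factor: float = 2.0
    deciduous_weight_factor: float = 1.5
    effect_table: dict | None = None
    min_segment_area_ha: float = 1.0
    segment_max_heterogeneity: float = 15.0
    top_fraction: float = 0.10

    def __post_init__(self):
        grid = tuple((str(d), bool(c)) for d, c in self.run_grid)
        if len(set(grid)) != len(grid):
            raise ValueError("run_grid entries must be unique")
        for dataset, _ in grid:
            if dataset not in DATASETS:
                raise ValueError(f"unknown dataset {dataset!r}")
        self.run_grid = grid
        if not (0.0 < self.detailed_coverage_fraction <= 1.0):
            raise ValueError("detailed_coverage_fraction must lie in (0, 1]")

    def config_hash(self):
        """Stable hash of the full configuration (stamps all artifacts)."""
        payload = _as_jsonable(self)
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _as_jsonable(getattr(obj, f.name))
            for f in dataclasses.fields(obj)
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _as_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    detailed: "object"
    coarse: "object"
    validation: "object"
    stacks: dict
    condition: "object"
    runs: dict
    report: dict


def build_input_stacks(config, detailed, coarse, validation=None, rng=None):
    """Construct the three weighted input feature stacks and the condition layer.

    Coarse per-species diameters come from directed-trees segmentation of the
    coarse data (structure band = overall mean diameter, plus the four
    per-group volume bands).  The detailClass composite takes detailed-based
    indices inside a spatially coherent coverage mask and coarse-based indices
    elsewhere.
    """
    cell_ha = config.landscape.cell_area_ha
    min_px = max(1, int(round(config.min_segment_area_ha / cell_ha)))
    bands = np.stack(
        [coarse.diameter_overall]
        + [coarse.volumes[g] for g in coarse.species_groups],
        axis=-1,
    )
    seg_cfg = SegmentationConfig(
        min_segment_px=min_px, max_heterogeneity=config.segment_max_heterogeneity
    )
    t0 = time.perf_counter()
    segments = segment_directed_trees(bands, coarse.valid_mask, seg_cfg)
    seg_diameters, _seg_volumes = segment_species_attributes(
        segments, coarse.diameter_overall, coarse.volumes
    )
    logger.info(
        "segmentation: %d segments in %.1fs", segments.n_segments, time.perf_counter() - t0
    )

    coarse4 = conservation_index(coarse, config.benefit, species_diameters=seg_diameters)
    coarse4 = apply_weight_scheme(
        coarse4, config.fertile_weight_factor, config.deciduous_weight_factor
    )
    coarse20 = classify_by_fertility(coarse4, coarse.fertility_class)
    coarse20 = apply_weight_scheme(
        coarse20, config.fertile_weight_factor, config.deciduous_weight_factor
    )

    detail4 = conservation_index(detailed, config.benefit)
    # composite: detailed indices where detailed coverage exists, coarse elsewhere
    rng = np.random.default_rng(config.landscape.seed + 202_305) if rng is None else rng
    cover_field = gaussian_random_field(
        detailed.valid_mask.shape,
        config.landscape.autocorrelation_range * 2,
        config.landscape.cell_size,
        rng,
    )
    threshold = np.quantile(
        cover_field[detailed.valid_mask], 1.0 - config.detailed_coverage_fraction
    )
    coverage = (cover_field >= threshold) & detailed.valid_mask
    composite = detail4.copy()
    composite.data = np.where(coverage[None], detail4.data, coarse4.data)
    composite.weights = detail4.weights.copy()
    detail20 = classify_by_fertility(composite, detailed.fertility_class)
    detail20 = apply_weight_scheme(
        detail20, config.fertile_weight_factor, config.deciduous_weight_factor
    )

    # planned operations are known from the detailed inventory only: the
    # condition discounts value inside the coverage area, 1.0 elsewhere
    condition = build_condition_layer(detailed.operations, config.effect_table)
    condition.multiplier = np.where(coverage, condition.multiplier, 1.0)

    stacks = {"coarse": coarse4, "coarseClass": coarse20, "detailClass": detail20}
    return stacks, condition, coverage, segments


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResult:
    """Execute the configured run grid end to end.

    With ``out_dir`` set, rank rasters, curves, the report and a config echo
    are written there; a rerun against an existing directory resumes (cached
    rank results are reused) only if the stored config hash matches.
    """
    cfg_hash = config.config_hash()
    out = None
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest_path = out / "manifest.json"
        if manifest_path.exists():
            stored = json.loads(manifest_path.read_text())
            if stored.get("config_hash") != cfg_hash:
                raise ValueError(
                    "output directory holds results for a different configuration"
                )
        else:
            manifest_path.write_text(
                json.dumps({"config_hash": cfg_hash, "seed": config.landscape.seed})
            )
        (out / "config_echo.yml").write_text(yaml.safe_dump(_as_jsonable(config)))

    t0 = time.perf_counter()
    detailed, coarse, validation = generate_landscape(config.landscape)
    logger.info("landscape generated in %.1fs", time.perf_counter() - t0)
    stacks, condition, coverage, segments = build_input_stacks(
        config, detailed, coarse, validation
    )

    runs = {}
    for dataset, use_conn in config.run_grid:
        label = run_label(dataset, use_conn)
        cached = _load_cached_run(out, label) if out is not None else None
        if cached is not None:
            runs[label] = cached
            logger.info("run %s: resumed from cache", label)
            continue
        stack = stacks[dataset]
        if use_conn:
            stack = matrix_connectivity_transform(stack, config.connectivity)
        run_cfg = dataclasses.replace(
            config.prioritization,
            use_connectivity=use_conn,
            condition=condition if dataset == "detailClass" else None,
        )
        t0 = time.perf_counter()
        runs[label] = rank_landscape(stack, run_cfg)
        logger.info(
            "run %s: ranked %d cells in %.1fs",
            label, runs[label].n_cells, time.perf_counter() - t0,
        )
        if out is not None:
            _save_run(out, label, runs[label], config.landscape.cell_size)

    cross_loads = {}
    if "detailClass" in stacks:
        detail_stack = stacks["detailClass"]
        for label, result in runs.items():
            cross_loads[f"{label}_order_on_detailClass"] = cross_load_evaluation(
                result, detail_stack, config.top_fraction
            )
    report = experiment_report(
        runs,
        validation=validation,
        cross_loads=cross_loads,
        out_dir=out,
        metadata={"config_hash": cfg_hash, "seed": config.landscape.seed,
                  "n_runs": len(runs)},
    )
    return ExperimentResult(
        config=config,
        detailed=detailed,
        coarse=coarse,
        validation=validation,
        stacks=stacks,
        condition=condition,
        runs=runs,
        report=report,
    )


def _save_run(out, label, result, cell_size):
    raster_io.write_raster(out / f"rank_{label}.tif", result.rank, cell_size)
    np.savez_compressed(
        out / f"run_{label}.npz",
        rank=result.rank,
        removal_order=result.removal_order,
        curves=result.curves,
        valid_mask=result.valid_mask,
        adjusted_totals=result.adjusted_totals,
        feature_names=np.array(result.feature_names, dtype=str),
    )


def _load_cached_run(out, label):
    from .prioritization_engine import RankResult

    path = out / f"run_{label}.npz"
    if not path.exists():
        return None
    with np.load(path) as z:
        return RankResult(
            rank=z["rank"],
            removal_order=z["removal_order"],
            curves=z["curves"],
            feature_names=[str(n) for n in z["feature_names"]],
            valid_mask=z["valid_mask"],
            adjusted_totals=z["adjusted_totals"],
        )


# ---------------------------------------------------------------------------
# YAML configuration


def config_from_yaml(path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML file (missing keys -> defaults)."""
    from .inventory_indices import LogisticBenefit
    from .synthetic_landscape import PatchSpec

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    if "landscape" in raw:
        land = dict(raw["landscape"])
        if "patch_specs" in land:
            land["patch_specs"] = tuple(PatchSpec(**p) for p in land["patch_specs"])
        if "fertility_prevalence" in land:
            land["fertility_prevalence"] = tuple(land["fertility_prevalence"])
        kwargs["landscape"] = LandscapeConfig(**land)
    if "benefit" in raw:
        kwargs["benefit"] = BenefitFunctionParams(
            per_group={g: LogisticBenefit(**p) for g, p in raw["benefit"].items()}
        )
    if "connectivity" in raw:
        kwargs["connectivity"] = ConnectivityConfig(**raw["connectivity"])
    if "prioritization" in raw:
        kwargs["prioritization"] = PrioritizationConfig(**raw["prioritization"])
    if "run_grid" in raw:
        kwargs["run_grid"] = tuple((d, bool(c)) for d, c in raw["run_grid"])
    for key in (
        "detailed_coverage_fraction",
        "fertile_weight_factor",
        "deciduous_weight_factor",
        "min_segment_area_ha",
        "segment_max_heterogeneity",
        "top_fraction",
    ):
        if key in raw:
            kwargs[key] = raw[key]
    if "effect_table" in raw:
        kwargs["effect_table"] = {int(k): float(v) for k, v in raw["effect_table"].items()}
    return ExperimentConfig(**kwargs)
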