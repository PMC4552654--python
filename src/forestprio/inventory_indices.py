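"""Conservation-value index rasters from forest inventory layers.

The index for a tree-species group is a sigmoidal benefit of the group's mean
stem diameter multiplied by the group's growing-stock volume:

    index_s = B_s(D_s) * V_s      [unitless-in-[0,1] * m^3/ha]

where ``B_s`` is a four-parameter logistic reflecting that older, larger-
diameter stands carry most of the structural features (dead wood, microhabitat
diversity) valuable for boreal forest biodiversity.  Crossing the four
species-group indices with the five site-fertility classes yields the 20
"forest type" features used in classified prioritization runs.  A condition
layer in [0, 1] discounts value where forestry operations are planned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic_landscape import (
    FERTILITY_CLASSES,
    OPERATION_CODES,
    SPECIES_GROUPS,
    InventoryLayerSet,
)


@dataclass(frozen=True)
class LogisticBenefit:
    """Four-parameter logistic benefit of diameter (cm):
    ``floor + (ceiling - floor) / (1 + exp(-steepness * (d - midpoint_cm)))``.
    """

    midpoint_cm: float
    steepness: float
    floor: float = 0.0
    ceiling: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.floor < self.ceiling <= 1.0):
            raise ValueError("require 0 <= floor < ceiling <= 1")
        if self.midpoint_cm <= 0 or self.steepness <= 0:
            raise ValueError("midpoint_cm and steepness must be positive")

    def __call__(self, diameter):
        return benefit_transform(diameter, self)


@dataclass(frozen=True)
class BenefitFunctionParams:
    """Per-species-group benefit curves.

    Default midpoints put half-benefit at 30 cm for the conifers, 25 cm for
    birch and 20 cm for other broadleaved trees (deciduous stands mature at
    smaller diameters); steepness 0.3/cm, full 0..1 range.  All stand-in
    values, fully configurable.
    """

    per_group: dict = field(
        default_factory=lambda: {
            "pine": LogisticBenefit(30.0, 0.3),
            "spruce": LogisticBenefit(30.0, 0.3),
            "birch": LogisticBenefit(25.0, 0.3),
            "other_broadleaved": LogisticBenefit(20.0, 0.3),
        }
    )

    def __getitem__(self, group):
        return self.per_group[group]


def benefit_transform(diameter, params: LogisticBenefit):
    """Sigmoid benefit of mean stem diameter, monotone, in [floor, ceiling]."""
    d = np.asarray(diameter, dtype=float)
    if np.any(d < 0):
        raise ValueError("diameter must be non-negative")
    value = params.floor + (params.ceiling - params.floor) / (
        1.0 + np.exp(-params.steepness * (d - params.midpoint_cm))
    )
    return value if value.ndim else float(value)


@dataclass
class FeatureStack:
    """Named, aligned, non-negative biodiversity-feature rasters with weights.

    ``group_labels[i]`` is ``(species_group, fertility_code or None)`` for
    layer i; classified stacks have 20 layers (4 groups x 5 classes) whose
    fertility layers partition each pixel's value.
    """

    names: list
    data: np.ndarray  # (n_features, H, W)
    weights: np.ndarray
    group_labels: list
    valid_mask: np.ndarray
    cell_size: float = 60.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.data.shape[0] != len(self.names):
            raise ValueError("one name per layer required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        if self.weights.shape != (self.data.shape[0],):
            raise ValueError("one weight per layer required")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")
        if self.data.shape[1:] != self.valid_mask.shape:
            raise ValueError("layers must align with valid_mask")
        if np.any(self.data[:, self.valid_mask] < 0):
            raise ValueError("feature values must be >= 0 on the valid mask")

    @property
    def n_features(self):
        return self.data.shape[0]

    def totals(self):
        """Per-feature landscape totals over the valid mask."""
        return self.data[:, self.valid_mask].sum(axis=1)

    def copy(self):
        return FeatureStack(
            names=list(self.names),
            data=self.data.copy(),
            weights=self.weights.copy(),
            group_labels=list(self.group_labels),
            valid_mask=self.valid_mask.copy(),
            cell_size=self.cell_size,
        )


@dataclass
class ConditionLayer:
    """Per-pixel multiplier in [0, 1]; code 0 (no operation) keeps value 1."""

    multiplier: np.ndarray
    effect_table: dict

    def __post_init__(self):
        if np.any((self.multiplier < 0) | (self.multiplier > 1)):
            raise ValueError("condition multipliers must lie in [0, 1]")


#: Default discounts for planned operations: a clear-cut removes all standing
#: conservation value, thinnings part of it.  The 0..1 semantics is fixed, the
#: numbers are configurable stand-ins.
DEFAULT_EFFECT_TABLE = {
    OPERATION_CODES["light_thinning"]: 0.6,
    OPERATION_CODES["heavy_thinning"]: 0.3,
    OPERATION_CODES["clear_cut"]: 0.0,
}


def build_condition_layer(operations, effect_table=None) -> ConditionLayer:
    """Map a planned-operation code raster to a [0, 1] condition multiplier."""
    effect_table = DEFAULT_EFFECT_TABLE if effect_table is None else effect_table
    codes = np.unique(operations)
    unknown = [c for c in codes if c != 0 and c not in effect_table]
    if unknown:
        raise ValueError(f"operation codes without effect entries: {unknown}")
    multiplier = np.ones(operations.shape, dtype=float)
    for code, effect in effect_table.items():
        multiplier[operations == code] = effect
    return ConditionLayer(multiplier=multiplier, effect_table=dict(effect_table))


def conservation_index(
    layers: InventoryLayerSet,
    params: BenefitFunctionParams | None = None,
    species_diameters: dict | None = None,
) -> FeatureStack:
    """Per-species conservation-value index stack (4 layers).

    Detailed inventories supply per-species diameters directly.  Coarse
    inventories carry only an overall mean diameter; pass segment-derived
    per-species diameters via ``species_diameters`` when available, otherwise
    the overall diameter is reused for every group.
    """
    params = params or BenefitFunctionParams()
    if species_diameters is not None:
        diameters = species_diameters
    elif layers.is_detailed:
        diameters = layers.diameters
    elif layers.diameter_overall is not None:
        diameters = {g: layers.diameter_overall for g in layers.species_groups}
    else:
        raise ValueError("no diameter information available")
    data = []
    for group in layers.species_groups:
        if group not in diameters:
            raise ValueError(f"missing diameter layer for group {group!r}")
        index = benefit_transform(diameters[group], params[group]) * layers.volumes[group]
        index = np.where(layers.valid_mask, index, 0.0)
        data.append(index)
    return FeatureStack(
        names=list(layers.species_groups),
        data=np.stack(data),
        weights=np.ones(len(layers.species_groups)),
        group_labels=[(g, None) for g in layers.species_groups],
        valid_mask=layers.valid_mask.copy(),
        cell_size=layers.cell_size,
    )


def classify_by_fertility(stack: FeatureStack, fertility_class) -> FeatureStack:
    """Split each species index into five site-fertility layers (20 features).

    Layer (s, c) equals index_s where fertility == c and 0 elsewhere, so the
    per-pixel sum over the 20 output layers equals the sum over the 4 inputs.
    """
    fert = np.asarray(fertility_class)
    on_mask = fert[stack.valid_mask]
    if on_mask.size and (on_mask.min() < 1 or on_mask.max() > 5):
        raise ValueError("fertility codes must be 1..5 on the valid mask")
    names, data, labels, weights = [], [], [], []
    for i, group in enumerate(n for n, _ in stack.group_labels):
        for code, cls_name in enumerate(FERTILITY_CLASSES, start=1):
            layer = np.where(fert == code, stack.data[i], 0.0)
            names.append(f"{group}__{cls_name}")
            data.append(layer)
            labels.append((group, code))
            weights.append(stack.weights[i])
    return FeatureStack(
        names=names,
        data=np.stack(data),
        weights=np.asarray(weights),
        group_labels=labels,
        valid_mask=stack.valid_mask.copy(),
        cell_size=stack.cell_size,
    )


#: Deciduous species groups emphasised by the default weighting scheme.
DECIDUOUS_GROUPS = ("birch", "other_broadleaved")


def apply_weight_scheme(
    stack: FeatureStack, fertile_factor=2.0, deciduous_factor=1.5
) -> FeatureStack:
    """Default expert-style weighting: forest types on the two most fertile
    classes (herb-rich, herb-rich heath) x2 and deciduous groups x1.5,
    multiplicatively; everything else weight 1."""
    out = stack.copy()
    for i, (group, fert_code) in enumerate(out.group_labels):
        w = 1.0
        if fert_code is not None and fert_code in (1, 2):
            w *= fertile_factor
        if group in DECIDUOUS_GROUPS:
            w *= deciduous_factor
        out.weights[i] = w
    return out


def aggregate_raster(fine, factor, nodata=np.nan):
    """Block-mean aggregation (e.g. 20 m -> 60 m with ``factor=3``).

    Input is padded with nodata to a multiple of ``factor``; each coarse pixel
    is the mean of its valid fine pixels, nodata when the block is empty.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    factor = int(factor)
    fine = np.asarray(fine, dtype=float)
    if np.isnan(nodata):
        invalid = np.isnan(fine)
    else:
        invalid = fine == nodata
    h, w = fine.shape
    ph = (-h) % factor
    pw = (-w) % factor
    fine = np.pad(fine, ((0, ph), (0, pw)), constant_values=np.nan)
    invalid = np.pad(invalid, ((0, ph), (0, pw)), constant_values=True)
    vals = np.where(invalid, 0.0, fine)
    H, W = fine.shape
    blocks = vals.reshape(H // factor, factor, W // factor, factor)
    counts = (~invalid).reshape(H // factor, factor, W // factor, factor).sum(axis=(1, 3))
    sums = blocks.sum(axis=(1, 3))
    out = np.full(counts.shape, np.nan)
    np.divide(sums, counts, out=out, where=counts > 0)
    if not np.isnan(nodata):
        out[counts == 0] = nodata
    return out
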