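"""Synthetic boreal forest inventory landscapes.

Generates a *detailed* stand-level inventory truth (per-species growing-stock
volumes and mean diameters, site fertility classes, planned forestry
operations) together with a *coarse* satellite-inventory style degradation of
it, plus validation polygons emulating protected areas, woodland key-habitats
and recently acquired conservation sites.

The generator mimics the statistical structure of Finnish inventory data that
the downstream prioritization comparison assumes:

* four tree-species groups (pine, spruce, birch, other broadleaved) dominated
  by the conifers;
* five site-fertility classes with unequal prevalence — the herb-rich and
  xeric extremes are rare;
* spatially autocorrelated volume/diameter mosaics (stationary Gaussian random
  fields with an exponential correlogram);
* small high-value patches (woodland key-habitat analogues, mean ~0.61 ha)
  and larger reserve analogues (mean ~13.54 ha protected areas, ~5.36 ha
  acquisition sites);
* a coarse variant produced by disk-mean smoothing plus truncated Gaussian
  per-pixel noise that carries only one overall mean diameter instead of
  per-species diameters — the degradation that erases small-feature contrast.

All randomness flows through a single integer seed; equal (config, seed)
yields bit-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely.ops import unary_union

SPECIES_GROUPS = ("pine", "spruce", "birch", "other_broadleaved")

#: Finnish 5-level site fertility typology, code 1..5.
FERTILITY_CLASSES = ("herb_rich", "herb_rich_heath", "mesic", "sub_xeric", "xeric")

#: Planned-operation codes (0 = no operation planned).
OPERATION_CODES = {"none": 0, "light_thinning": 1, "heavy_thinning": 2, "clear_cut": 3}


@dataclass(frozen=True)
class PatchSpec:
    """One validation-patch class: ``count`` patches of mean ``mean_area_ha``,
    with within-patch diameters and volumes multiplied by ``1 + value_boost``."""

    name: str
    count: int
    mean_area_ha: float
    value_boost: float


# Default patch classes scale Table-1-like coverage shares (PA 1.87 %, WKH
# 0.50 %, acquisitions 0.13 %) down to the 144 km^2 default landscape.
DEFAULT_PATCH_SPECS = (
    PatchSpec("pa_analogue", count=20, mean_area_ha=13.54, value_boost=0.5),
    PatchSpec("metso_analogue", count=4, mean_area_ha=5.36, value_boost=0.6),
    PatchSpec("wkh_analogue", count=110, mean_area_ha=0.61, value_boost=0.8),
)

#: Species-group volume means (m^3/ha) and diameter means/sds (cm) typical of
#: managed south-boreal forest; conifers dominate the growing stock.
_VOLUME_MEAN = {"pine": 60.0, "spruce": 50.0, "birch": 20.0, "other_broadleaved": 10.0}
_DIAMETER_MEAN = {"pine": 20.0, "spruce": 18.0, "birch": 16.0, "other_broadleaved": 14.0}
_DIAMETER_SD = {"pine": 6.0, "spruce": 6.0, "birch": 5.0, "other_broadleaved": 5.0}
_VOLUME_LOG_SD = 0.6  # lognormal shape of the volume fields


@dataclass(frozen=True)
class LandscapeConfig:
    grid_height: int = 200
    grid_width: int = 200
    cell_size: float = 60.0
    fertility_prevalence: tuple = (0.05, 0.15, 0.50, 0.20, 0.10)
    species_groups: tuple = SPECIES_GROUPS
    autocorrelation_range: float = 600.0
    patch_specs: tuple = DEFAULT_PATCH_SPECS
    coarse_smoothing_radius: float = 180.0
    coarse_noise_sd: dict = field(
        default_factory=lambda: {"volume": 12.0, "diameter": 2.0}
    )
    water_fraction: float = 0.12
    operation_fractions: dict = field(
        default_factory=lambda: {"light_thinning": 0.08, "heavy_thinning": 0.05, "clear_cut": 0.02}
    )
    seed: int = 0

    def __post_init__(self):
        prev = np.asarray(self.fertility_prevalence, dtype=float)
        if prev.size != 5 or np.any(prev < 0) or abs(prev.sum() - 1.0) > 1e-9:
            raise ValueError(
                "fertility_prevalence must be 5 non-negative proportions summing to 1"
            )
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.grid_height < 3 or self.grid_width < 3:
            raise ValueError("grid dimensions must be >= 3")
        if len(self.species_groups) != 4:
            raise ValueError("exactly 4 tree-species groups are supported")
        cell_ha = (self.cell_size**2) / 1e4
        landscape_ha = self.grid_height * self.grid_width * cell_ha
        for spec in self.patch_specs:
            if spec.mean_area_ha > landscape_ha:
                raise ValueError(f"patch class {spec.name!r} exceeds landscape area")

    @property
    def cell_area_ha(self):
        return (self.cell_size**2) / 1e4


@dataclass
class InventoryLayerSet:
    """Aligned per-pixel forest attribute rasters.

    ``diameters`` holds one raster per species group (detailed variant) or is
    None, in which case ``diameter_overall`` carries the single stand mean
    diameter (coarse variant).  Values are undefined (zero-filled) outside
    ``valid_mask``.
    """

    volumes: dict
    diameters: dict | None
    diameter_overall: np.ndarray | None
    fertility_class: np.ndarray
    operations: np.ndarray
    valid_mask: np.ndarray
    cell_size: float

    def __post_init__(self):
        shape = self.valid_mask.shape
        rasters = list(self.volumes.values()) + [self.fertility_class, self.operations]
        if self.diameters is not None:
            rasters += list(self.diameters.values())
        if self.diameter_overall is not None:
            rasters.append(self.diameter_overall)
        for r in rasters:
            if r.shape != shape:
                raise ValueError("all rasters must share the grid shape")
        m = self.valid_mask
        for v in self.volumes.values():
            if np.any(v[m] < 0):
                raise ValueError("volumes must be non-negative on the valid mask")
        fert = self.fertility_class[m]
        if fert.size and (fert.min() < 1 or fert.max() > 5):
            raise ValueError("fertility_class must be in 1..5 on the valid mask")

    @property
    def is_detailed(self):
        return self.diameters is not None

    @property
    def species_groups(self):
        return tuple(self.volumes)


@dataclass
class ValidationSet:
    """Named boolean validation masks plus their source polygons (areas in ha)."""

    masks: dict
    provenance: dict

    def mean_area_ha(self, name):
        areas = [p["area_ha"] for p in self.provenance[name]]
        return float(np.mean(areas)) if areas else 0.0


# ---------------------------------------------------------------------------
# Random field machinery


def gaussian_random_field(shape, correlation_range, cell_size, rng):
    """Stationary unit-variance Gaussian field with correlogram
    ``exp(-d / correlation_range)`` via circulant embedding on a doubled grid.

    Negative embedding eigenvalues (the exponential correlogram is not exactly
    embeddable on a torus) are clipped to zero; the approximation error is
    negligible at the ranges used here.
    """
    h, w = shape
    bh, bw = 2 * h, 2 * w
    dy = np.minimum(np.arange(bh), bh - np.arange(bh))[:, None]
    dx = np.minimum(np.arange(bw), bw - np.arange(bw))[None, :]
    d = np.hypot(dy, dx) * cell_size
    cov = np.exp(-d / correlation_range)
    lam = np.fft.fft2(cov).real
    lam = np.clip(lam, 0.0, None)
    noise = rng.standard_normal((bh, bw))
    field = np.fft.ifft2(np.sqrt(lam) * np.fft.fft2(noise)).real
    # mean eigenvalue equals C(0) = 1, so the field is already ~unit variance
    return field[:h, :w]


def _classify_by_quantiles(field, mask, proportions):
    """Threshold ``field`` at empirical quantiles so masked cells split into
    classes 1..k with shares ``proportions`` (class 1 = highest field values)."""
    out = np.zeros(field.shape, dtype=np.uint8)
    vals = field[mask]
    # class 1 gets the top proportions[0] of values, etc.
    cum = np.cumsum(proportions)[:-1]
    # thresholds from above: quantiles of (1 - cum)
    thresholds = np.quantile(vals, 1.0 - np.asarray(cum))
    codes = np.ones(vals.shape, dtype=np.uint8)
    for t in thresholds:
        codes += (vals < t).astype(np.uint8)
    out[mask] = codes
    return out


# ---------------------------------------------------------------------------
# Landscape generation


def _place_patches(config, valid, occupied, spec, rng):
    """Rejection-sample disjoint roughly circular patches inside the mask.

    Patch areas are lognormal around ``spec.mean_area_ha`` (cv ~0.3) and are
    realised as the ``n`` nearest valid unoccupied cells to a random centre.
    """
    h, w = valid.shape
    cell_ha = config.cell_area_ha
    sigma = 0.3
    mu = np.log(spec.mean_area_ha) - sigma**2 / 2
    patches = []
    rows, cols = np.indices((h, w))
    for _ in range(spec.count):
        area = float(np.exp(rng.normal(mu, sigma)))
        n_px = max(1, int(round(area / cell_ha)))
        placed = None
        for _attempt in range(200):
            r0 = int(rng.integers(h))
            c0 = int(rng.integers(w))
            if not valid[r0, c0] or occupied[r0, c0]:
                continue
            # candidate cells: nearest free valid cells within a generous window
            rad = int(np.ceil(np.sqrt(n_px / np.pi))) + 2
            r_lo, r_hi = max(0, r0 - rad), min(h, r0 + rad + 1)
            c_lo, c_hi = max(0, c0 - rad), min(w, c0 + rad + 1)
            sub_valid = valid[r_lo:r_hi, c_lo:c_hi] & ~occupied[r_lo:r_hi, c_lo:c_hi]
            if sub_valid.sum() < n_px:
                continue
            rr = rows[r_lo:r_hi, c_lo:c_hi][sub_valid]
            cc = cols[r_lo:r_hi, c_lo:c_hi][sub_valid]
            dist2 = (rr - r0) ** 2 + (cc - c0) ** 2
            order = np.lexsort((cc, rr, dist2))[:n_px]
            placed = (rr[order], cc[order])
            break
        if placed is None:
            raise RuntimeError(
                f"could not place patch of {n_px} px for class {spec.name!r}"
            )
        occupied[placed] = True
        patches.append(placed)
    return patches


def _patch_polygon(rows, cols, cell_size, grid_height):
    """Union of cell squares, in a y-up metric frame with origin at the
    grid's south-west corner (row 0 = north)."""
    cells = [
        box(c * cell_size, (grid_height - 1 - r) * cell_size,
            (c + 1) * cell_size, (grid_height - r) * cell_size)
        for r, c in zip(rows, cols)
    ]
    return unary_union(cells)


def generate_landscape(config: LandscapeConfig):
    """Generate ``(detailed, coarse, validation)`` for one seeded landscape.

    The detailed set carries per-species diameters; the coarse set is produced
    from it via :func:`degrade_to_coarse`; validation patches sit inside the
    valid mask, are mutually disjoint, and have their attribute boosts already
    applied to the detailed truth (and hence, attenuated, to the coarse data).
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_height, config.grid_width)
    rng_fields = np.random.default_rng(rng.integers(2**31))
    rng_patches = np.random.default_rng(rng.integers(2**31))
    rng_coarse = int(rng.integers(2**31))

    def grf():
        return gaussian_random_field(
            shape, config.autocorrelation_range, config.cell_size, rng_fields
        )

    # land / water
    water_field = grf()
    if config.water_fraction > 0:
        threshold = np.quantile(water_field, config.water_fraction)
        valid = water_field > threshold
    else:
        valid = np.ones(shape, dtype=bool)

    # fertility classes: class 1 (herb-rich) on the most fertile tail
    fertility = _classify_by_quantiles(grf(), valid, config.fertility_prevalence)

    # per-species volumes (lognormal) and diameters (truncated normal), partly
    # sharing a field so big-timber stands are also high-volume stands
    volumes, diameters = {}, {}
    for group in config.species_groups:
        g_vol = grf()
        g_dia = 0.6 * g_vol + 0.8 * grf()
        vol = _VOLUME_MEAN[group] * np.exp(
            _VOLUME_LOG_SD * g_vol - _VOLUME_LOG_SD**2 / 2
        )
        dia = np.clip(_DIAMETER_MEAN[group] + _DIAMETER_SD[group] * g_dia, 0.0, None)
        vol[~valid] = 0.0
        dia[~valid] = 0.0
        volumes[group] = vol
        diameters[group] = dia

    # validation patches: disjoint, inside the mask, high-value
    occupied = np.zeros(shape, dtype=bool)
    masks, provenance = {}, {}
    for spec in config.patch_specs:
        patches = _place_patches(config, valid, occupied, spec, rng_patches)
        mask = np.zeros(shape, dtype=bool)
        prov = []
        for rr, cc in patches:
            mask[rr, cc] = True
            poly = _patch_polygon(rr, cc, config.cell_size, config.grid_height)
            prov.append({"polygon": poly, "area_ha": poly.area / 1e4})
        masks[spec.name] = mask
        provenance[spec.name] = prov
        boost = 1.0 + spec.value_boost
        for group in config.species_groups:
            volumes[group][mask] *= boost
            diameters[group][mask] *= boost

    # planned operations on managed land only (not inside validation patches)
    op_field = grf()
    operations = np.zeros(shape, dtype=np.uint8)
    managed = valid & ~occupied
    op_vals = op_field[managed]
    frac = config.operation_fractions
    total_frac = sum(frac.values())
    if total_frac > 0 and op_vals.size:
        # stack operations into the lowest tail of an independent field:
        # clear-cuts at the very bottom, then heavy and light thinning
        order = ("clear_cut", "heavy_thinning", "light_thinning")
        cum = 0.0
        prev_t = -np.inf
        for name in order:
            cum += frac.get(name, 0.0)
            t = np.quantile(op_vals, min(cum, 1.0))
            sel = managed & (op_field > prev_t) & (op_field <= t)
            operations[sel] = OPERATION_CODES[name]
            prev_t = t

    fertility_out = fertility.copy()
    fertility_out[~valid] = 0
    detailed = InventoryLayerSet(
        volumes=volumes,
        diameters=diameters,
        diameter_overall=None,
        fertility_class=fertility_out,
        operations=operations,
        valid_mask=valid,
        cell_size=config.cell_size,
    )
    coarse = degrade_to_coarse(
        detailed,
        smoothing_radius=config.coarse_smoothing_radius,
        noise_sd=config.coarse_noise_sd,
        seed=rng_coarse,
    )
    validation = ValidationSet(masks=masks, provenance=provenance)
    return detailed, coarse, validation


# ---------------------------------------------------------------------------
# Coarse degradation


def _disk_offsets(radius, cell_size):
    """Cell offsets whose centre distance is strictly below ``radius``; at
    radius == cell_size this is the identity kernel."""
    r_cells = int(np.ceil(radius / cell_size))
    dy, dx = np.mgrid[-r_cells : r_cells + 1, -r_cells : r_cells + 1]
    inside = np.hypot(dy, dx) * cell_size < radius
    return inside


def _masked_disk_mean(raster, mask, kernel):
    """Normalized (mask-aware) disk-mean filter."""
    from scipy.ndimage import convolve

    k = kernel.astype(float)
    num = convolve(np.where(mask, raster, 0.0), k, mode="constant", cval=0.0)
    den = convolve(mask.astype(float), k, mode="constant", cval=0.0)
    out = np.zeros_like(raster, dtype=float)
    np.divide(num, den, out=out, where=den > 0)
    out[~mask] = 0.0
    return out


def degrade_to_coarse(detailed: InventoryLayerSet, smoothing_radius, noise_sd, seed):
    """Degrade a detailed inventory into its coarse satellite-estimate analogue.

    Per-species volumes are disk-mean low-pass filtered (mask-aware, so water
    does not dilute shoreline stands) and perturbed with additive Gaussian
    noise truncated at zero.  The four per-species diameters collapse into one
    volume-weighted overall mean diameter, which is then smoothed and
    perturbed the same way.  Fertility, operations and the valid mask pass
    through unchanged.
    """
    if not detailed.is_detailed:
        raise ValueError("degrade_to_coarse requires a detailed layer set")
    if smoothing_radius < detailed.cell_size:
        raise ValueError("smoothing_radius must be >= cell_size")
    rng = np.random.default_rng(seed)
    mask = detailed.valid_mask
    kernel = _disk_offsets(smoothing_radius, detailed.cell_size)
    sd_vol = noise_sd.get("volume", 0.0) if isinstance(noise_sd, dict) else noise_sd
    sd_dia = noise_sd.get("diameter", 0.0) if isinstance(noise_sd, dict) else noise_sd

    # overall diameter from the *pixel-level* species mix, before smoothing
    vol_total = sum(detailed.volumes.values())
    weighted = sum(
        detailed.diameters[g] * detailed.volumes[g] for g in detailed.species_groups
    )
    overall = np.zeros_like(vol_total)
    np.divide(weighted, vol_total, out=overall, where=vol_total > 0)

    coarse_volumes = {}
    for group in detailed.species_groups:
        smooth = _masked_disk_mean(detailed.volumes[group], mask, kernel)
        if sd_vol > 0:
            smooth = smooth + rng.normal(0.0, sd_vol, smooth.shape)
        smooth = np.clip(smooth, 0.0, None)
        smooth[~mask] = 0.0
        coarse_volumes[group] = smooth

    overall_smooth = _masked_disk_mean(overall, mask, kernel)
    if sd_dia > 0:
        overall_smooth = overall_smooth + rng.normal(0.0, sd_dia, overall_smooth.shape)
    overall_smooth = np.clip(overall_smooth, 0.0, None)
    overall_smooth[~mask] = 0.0

    return InventoryLayerSet(
        volumes=coarse_volumes,
        diameters=None,
        diameter_overall=overall_smooth,
        fertility_class=detailed.fertility_class.copy(),
        operations=detailed.operations.copy(),
        valid_mask=mask.copy(),
        cell_size=detailed.cell_size,
    )


# ---------------------------------------------------------------------------
# Serialization


def write_landscape(out_dir, detailed, coarse, validation, config):
    """Write all layers as TIFF rasters + GeoJSON validation polygons."""
    from pathlib import Path

    from . import raster_io

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for tag, ls in (("detailed", detailed), ("coarse", coarse)):
        for g, v in ls.volumes.items():
            raster_io.write_raster(out / f"{tag}_volume_{g}.tif", v, ls.cell_size)
        if ls.diameters is not None:
            for g, d in ls.diameters.items():
                raster_io.write_raster(out / f"{tag}_diameter_{g}.tif", d, ls.cell_size)
        if ls.diameter_overall is not None:
            raster_io.write_raster(
                out / f"{tag}_diameter_overall.tif", ls.diameter_overall, ls.cell_size
            )
        raster_io.write_raster(
            out / f"{tag}_fertility.tif", ls.fertility_class, ls.cell_size, categorical=True
        )
        raster_io.write_raster(
            out / f"{tag}_operations.tif", ls.operations, ls.cell_size, categorical=True
        )
        raster_io.write_raster(
            out / f"{tag}_valid_mask.tif", ls.valid_mask, ls.cell_size, categorical=True
        )
    for name, prov in validation.provenance.items():
        raster_io.write_geojson(
            out / f"validation_{name}.geojson",
            [p["polygon"] for p in prov],
            [{"class": name, "area_ha": p["area_ha"]} for p in prov],
        )
        raster_io.write_raster(
            out / f"validation_{name}.tif",
            validation.masks[name],
            config.cell_size,
            categorical=True,
        )


def landscape_checksum(layer_set: InventoryLayerSet):
    """Deterministic content hash of every raster in the set."""
    import hashlib

    h = hashlib.sha256()
    for g in layer_set.species_groups:
        h.update(np.ascontiguousarray(layer_set.volumes[g]).tobytes())
        if layer_set.diameters is not None:
            h.update(np.ascontiguousarray(layer_set.diameters[g]).tobytes())
    if layer_set.diameter_overall is not None:
        h.update(np.ascontiguousarray(layer_set.diameter_overall).tobytes())
    h.update(np.ascontiguousarray(layer_set.fertility_class).tobytes())
    h.update(np.ascontiguousarray(layer_set.operations).tobytes())
    h.update(np.ascontiguousarray(layer_set.valid_mask).tobytes())
    return h.hexdigest()
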