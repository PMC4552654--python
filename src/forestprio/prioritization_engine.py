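"""Greedy complementarity ranking of a landscape (additive benefit function).

The ranker iteratively removes the cell whose removal loses the least summed
feature benefit, producing a priority rank raster in [0, 1] (1 = removed last
= highest priority).  With ``p_j`` the remaining proportion of feature *j*'s
(condition-adjusted) landscape total and ``q_ij`` cell *i*'s fixed share of
that total, the marginal loss of removing cell *i* is

    delta_i = sum_j  w_j * ( p_j**z - (p_j - q_ij)**z ),      0 < z <= 1.

The concave power (default z = 0.25) makes losses from already-depleted
features loom larger: repeated range-size normalization, so rarity raises a
feature's relative significance as removal proceeds.  Connectivity enters by
replacing the feature layers with kernel-smoothed combinations of all layers
("matrix connectivity"): layer r becomes

    sum_c M[r][c] * sum_j exp(-alpha * d(i, j)) * layer_c(j) * cell_area,

with ``alpha = 2 / mean dispersal distance`` of the negative-exponential
dispersal kernel, followed by a rescaling that conserves each layer's
landscape total (connectivity redistributes value, it does not create it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .inventory_indices import ConditionLayer, FeatureStack


def connectivity_alpha(mean_dispersal_km):
    """Decay rate (1/m) of the negative-exponential dispersal kernel:
    ``alpha = 2 / (mean dispersal distance in metres)``; 2.0 km -> 0.001."""
    d = np.asarray(mean_dispersal_km, dtype=float)
    if np.any(d <= 0):
        raise ValueError("mean dispersal distance must be positive")
    alpha = 2.0 / (d * 1000.0)
    return float(alpha) if alpha.ndim == 0 else alpha


@dataclass
class ConnectivityConfig:
    """Kernel scale and feature-similarity multipliers.

    ``mean_dispersal_km`` is a scalar or per-feature array; ``multiplier_matrix``
    M (features x features, non-negative, positive diagonal, asymmetry allowed)
    gives the contribution of feature c (column) to the connectivity-smoothed
    value of feature r (row).  Kernel contributions below ``kernel_truncation``
    (relative to the kernel peak) are dropped.
    """

    mean_dispersal_km: float | np.ndarray = 2.0
    multiplier_matrix: np.ndarray | None = None
    kernel_truncation: float = 1e-6

    def __post_init__(self):
        if not (0.0 < self.kernel_truncation < 1.0):
            raise ValueError("kernel_truncation must lie in (0, 1)")
        if self.multiplier_matrix is not None:
            M = np.asarray(self.multiplier_matrix, dtype=float)
            if np.any(M < 0) or np.any(np.diag(M) <= 0):
                raise ValueError("multipliers must be >= 0 with positive diagonal")
            self.multiplier_matrix = M

    def alphas(self, n_features):
        alpha = connectivity_alpha(self.mean_dispersal_km)
        return np.broadcast_to(np.asarray(alpha, dtype=float), (n_features,)).copy()


def default_multiplier_matrix(group_labels):
    """Similarity multipliers from layer labels: 1 on the diagonal, 0.5 for the
    same species group on a different fertility class, 0.2 across species
    groups (every forest type aids every other's connectivity a little)."""
    n = len(group_labels)
    M = np.full((n, n), 0.2)
    for r, (gr, _) in enumerate(group_labels):
        for c, (gc, _) in enumerate(group_labels):
            if r == c:
                M[r, c] = 1.0
            elif gr == gc:
                M[r, c] = 0.5
    return M


def _exponential_kernel(alpha, cell_size, truncation):
    """Truncated negative-exponential kernel sampled on the cell grid."""
    max_d = -np.log(truncation) / alpha
    r = int(np.floor(max_d / cell_size))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    d = np.hypot(dy, dx) * cell_size
    k = np.exp(-alpha * d)
    k[k < truncation] = 0.0
    return k


def matrix_connectivity_transform(
    stack: FeatureStack, config: ConnectivityConfig, cell_size=None
) -> FeatureStack:
    """Connectivity-smoothed feature stack (original stack untouched).

    Each layer is convolved with its negative-exponential kernel (times the
    cell area), the smoothed layers are mixed through the multiplier matrix,
    values outside the valid mask are dropped, and every output layer is
    rescaled to its pre-transform landscape total.
    """
    cell_size = stack.cell_size if cell_size is None else cell_size
    F = stack.n_features
    M = (
        default_multiplier_matrix(stack.group_labels)
        if config.multiplier_matrix is None
        else config.multiplier_matrix
    )
    if M.shape != (F, F):
        raise ValueError("multiplier matrix dimension must equal the layer count")
    alphas = config.alphas(F)
    cell_area = cell_size**2
    mask = stack.valid_mask
    n_valid = int(mask.sum())

    smoothed = np.empty_like(stack.data)
    if n_valid <= 4096:
        # exact pairwise evaluation on small grids
        rows, cols = np.nonzero(mask)
        d = np.hypot(
            rows[:, None] - rows[None, :], cols[:, None] - cols[None, :]
        ) * cell_size
        vals = stack.data[:, mask]
        for c in range(F):
            k = np.exp(-alphas[c] * d)
            k[k < config.kernel_truncation] = 0.0
            layer = np.zeros(mask.shape)
            layer[mask] = k @ (vals[c] * cell_area)
            smoothed[c] = layer
    else:
        from scipy.signal import fftconvolve

        masked = np.where(mask, stack.data, 0.0)
        for c in range(F):
            k = _exponential_kernel(alphas[c], cell_size, config.kernel_truncation)
            smoothed[c] = fftconvolve(masked[c], k, mode="same") * cell_area

    mixed = np.tensordot(M, smoothed, axes=(1, 0))
    mixed = np.where(mask, mixed, 0.0)
    mixed = np.clip(mixed, 0.0, None)

    out = stack.copy()
    totals_before = stack.totals()
    totals_after = mixed[:, mask].sum(axis=1)
    scale = np.ones(F)
    np.divide(totals_before, totals_after, out=scale, where=totals_after > 0)
    out.data = mixed * scale[:, None, None]
    return out


@dataclass
class PrioritizationConfig:
    """Additive-benefit-function removal settings.

    ``z_exponent`` is the benefit curvature (0 < z <= 1; 0.25 by convention),
    ``removal_batch`` the number of cells removed per iteration (1 = exact),
    tie-break is the lowest row-major cell index.
    """

    z_exponent: float = 0.25
    removal_batch: int = 1
    use_connectivity: bool = False
    condition: ConditionLayer | None = None

    def __post_init__(self):
        if not (0.0 < self.z_exponent <= 1.0):
            raise ValueError("z_exponent must lie in (0, 1]")
        if self.removal_batch < 1:
            raise ValueError("removal_batch must be >= 1")


@dataclass
class RankResult:
    """Priority ranking of the valid cells.

    ``rank`` is NaN outside the mask and in (0, 1] on it (1 = highest
    priority); ``removal_order`` lists flat row-major cell indices in removal
    order; ``curves[k, j]`` is the proportion of feature j's (condition-
    adjusted) total remaining after k removals — every curve starts at 1, is
    non-increasing, and ends at 0.
    """

    rank: np.ndarray
    removal_order: np.ndarray
    curves: np.ndarray
    feature_names: list
    valid_mask: np.ndarray
    adjusted_totals: np.ndarray

    @property
    def n_cells(self):
        return len(self.removal_order)

    def top_fraction_mask(self, top_fraction):
        """Boolean raster of the ``round(f * N)`` highest-priority cells."""
        if not (0.0 <= top_fraction <= 1.0):
            raise ValueError("top_fraction must lie in [0, 1]")
        k = int(round(top_fraction * self.n_cells))
        mask = np.zeros(self.rank.shape, dtype=bool)
        if k > 0:
            top = self.removal_order[self.n_cells - k :]
            mask.ravel()[top] = True
        return mask


def _pow_z(x, z):
    if z == 1.0:
        return x
    if z == 0.5:
        return np.sqrt(x)
    if z == 0.25:
        return np.sqrt(np.sqrt(x))
    return np.power(x, z)


def rank_landscape(stack: FeatureStack, config: PrioritizationConfig) -> RankResult:
    """Rank every valid cell by iterative worst-cell removal.

    The condition layer (if any) is applied multiplicatively to all layers
    first.  Cell shares ``q_ij`` are fixed at the start; remaining proportions
    ``p_j`` shrink as cells are removed.  Ties in the marginal loss break
    toward the lowest row-major cell index.
    """
    mask = stack.valid_mask
    flat_idx = np.nonzero(mask.ravel())[0]
    n = flat_idx.size
    if n == 0:
        raise ValueError("valid mask is empty")
    F = stack.n_features
    v = stack.data[:, mask].T.astype(float).copy()  # (n, F)
    if config.condition is not None:
        cond = config.condition.multiplier
        if cond.shape != mask.shape:
            raise ValueError("condition layer must align with the stack")
        v *= cond[mask][:, None]

    totals = v.sum(axis=0)
    if np.all(totals == 0):
        warnings.warn("all features are zero everywhere; ranking by tie-break order")
    safe_totals = np.where(totals > 0, totals, 1.0)
    q = v / safe_totals  # (n, F) fixed shares of the adjusted totals
    w = stack.weights
    z = config.z_exponent
    batch = config.removal_batch

    # sparse CSR-like layout of the nonzero shares
    rows_full, cols_full = np.nonzero(q)
    data_full = q[rows_full, cols_full]
    wcols_full = w[cols_full]

    p = np.ones(F)
    alive = np.ones(n, dtype=bool)
    active = np.arange(n)  # ascending -> argmin picks lowest index on ties
    rows, cols, data, wcols = rows_full, cols_full, data_full, wcols_full
    row_map = np.arange(n)  # maps row ids in the compacted arrays -> cell ids
    removal_positions = np.empty(n, dtype=np.int64)
    order = np.empty(n, dtype=np.int64)
    n_removed = 0

    while n_removed < n:
        # compact the sparse arrays once most entries are dead
        if active.size and active.size < 0.5 * row_map.size:
            keep = alive[row_map[rows]]
            rows_cells = row_map[rows[keep]]
            row_map = active.copy()
            renumber = np.full(n, -1, dtype=np.int64)
            renumber[row_map] = np.arange(row_map.size)
            rows = renumber[rows_cells]
            cols = cols[keep]
            data = data[keep]
            wcols = wcols[keep]

        live_rows = alive[row_map[rows]]
        pz = _pow_z(p, z)
        shrunk = np.clip(p[cols] - data, 0.0, None)
        contrib = wcols * (pz[cols] - _pow_z(shrunk, z))
        contrib = np.where(live_rows, contrib, 0.0)
        delta_rows = np.bincount(rows, weights=contrib, minlength=row_map.size)
        delta = np.full(n, np.inf)
        delta[row_map] = delta_rows
        delta[~alive] = np.inf

        k = min(batch, n - n_removed)
        if k == 1:
            picks = np.array([int(np.argmin(delta))])
        else:
            picks = np.lexsort((np.arange(n), delta))[:k]
        for cell in picks:
            order[n_removed] = cell
            removal_positions[cell] = n_removed
            n_removed += 1
        alive[picks] = False
        active = active[alive[active]]
        p = np.clip(p - q[picks].sum(axis=0), 0.0, None)

    # rank: removal position -> (0, 1]; batch removals share the batch-end rank
    positions = removal_positions + 1
    if batch > 1:
        positions = (np.ceil(positions / batch) * batch).astype(np.int64)
        positions = np.minimum(positions, n)
    rank = np.full(mask.shape, np.nan)
    rank.ravel()[flat_idx] = positions / n

    # performance curves from suffix sums of the adjusted values in removal
    # order: exactly 1 at the start, exactly 0 at the end
    v_ordered = v[order]
    suffix = np.zeros((n + 1, F))
    suffix[:-1] = np.cumsum(v_ordered[::-1], axis=0)[::-1]
    denom = suffix[0].copy()
    curves = np.full((n + 1, F), np.nan)
    np.divide(suffix, denom, out=curves, where=denom > 0)

    return RankResult(
        rank=rank,
        removal_order=flat_idx[order],
        curves=curves,
        feature_names=list(stack.names),
        valid_mask=mask.copy(),
        adjusted_totals=totals,
    )


def performance_at(result: RankResult, top_fraction):
    """Per-feature share of the (condition-adjusted) landscape total retained
    inside the best ``top_fraction`` of the landscape."""
    if not (0.0 <= top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in [0, 1]")
    k = int(round(top_fraction * result.n_cells))
    # the top k cells are exactly those still remaining after n - k removals
    return result.curves[result.n_cells - k]


def cross_load_evaluation(order_from: RankResult, stack_of: FeatureStack, top_fraction):
    """Representation of ``stack_of``'s features inside the top fraction of a
    (possibly foreign) ranking, with fertility-class and overall means.

    Quantifies the cost of ranking with coarser data: how much of the detailed
    features' distributions the coarse-derived priority order actually covers.
    """
    import pandas as pd

    if order_from.rank.shape != stack_of.valid_mask.shape:
        raise ValueError("ranking and stack must share the grid")
    top = order_from.top_fraction_mask(top_fraction)
    vals = stack_of.data[:, stack_of.valid_mask]
    totals = vals.sum(axis=1)
    inside = stack_of.data[:, top & stack_of.valid_mask].sum(axis=1)
    rep = np.full(stack_of.n_features, np.nan)
    np.divide(inside, totals, out=rep, where=totals > 0)
    per_feature = pd.Series(rep, index=stack_of.names, name="representation")
    fert = pd.Series(
        [code for _, code in stack_of.group_labels], index=stack_of.names
    )
    by_class = per_feature.groupby(fert).mean() if fert.notna().any() else pd.Series(dtype=float)
    return {
        "per_feature": per_feature,
        "by_fertility_class": by_class,
        "mean": float(np.nanmean(rep)),
    }
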