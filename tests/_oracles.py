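"""Independent brute-force references used to validate the fast implementations.

These deliberately use naive Python loops and from-scratch recomputation each
iteration, sharing nothing with the library code paths they check.
"""

import numpy as np


def brute_force_removal_order(values, weights, z):
    """Greedy additive-benefit removal order by exhaustive recomputation.

    ``values``: (n_cells, n_features) non-negative array.  Every iteration
    recomputes all remaining totals and every cell's marginal loss from
    scratch; ties break toward the lowest cell index.
    """
    values = np.asarray(values, dtype=float)
    n, n_feat = values.shape
    totals = [values[:, j].sum() for j in range(n_feat)]
    safe = [t if t > 0 else 1.0 for t in totals]
    remaining = list(range(n))
    order = []
    while remaining:
        p = []
        for j in range(n_feat):
            rem_total = sum(values[i, j] for i in remaining)
            p.append(rem_total / safe[j])
        best_i, best_d = None, None
        for i in remaining:
            delta = 0.0
            for j in range(n_feat):
                q = values[i, j] / safe[j]
                delta += weights[j] * (p[j] ** z - max(p[j] - q, 0.0) ** z)
            if best_d is None or delta < best_d:
                best_i, best_d = i, delta
        order.append(best_i)
        remaining.remove(best_i)
    return order


def direct_kernel_transform(data, mask, M, alphas, cell_size, truncation):
    """Double-loop evaluation of the matrix connectivity transform, including
    the landscape-total rescaling and masking."""
    n_feat, h, w = data.shape
    smoothed = np.zeros_like(data, dtype=float)
    cell_area = cell_size**2
    for c in range(n_feat):
        for r0 in range(h):
            for c0 in range(w):
                if not mask[r0, c0]:
                    continue
                acc = 0.0
                for r1 in range(h):
                    for c1 in range(w):
                        if not mask[r1, c1]:
                            continue
                        d = np.hypot(r0 - r1, c0 - c1) * cell_size
                        k = np.exp(-alphas[c] * d)
                        if k < truncation:
                            continue
                        acc += k * data[c, r1, c1] * cell_area
                smoothed[c, r0, c0] = acc
    mixed = np.zeros_like(data, dtype=float)
    for r in range(n_feat):
        for c in range(n_feat):
            mixed[r] += M[r, c] * smoothed[c]
    mixed[:, ~mask] = 0.0
    out = np.zeros_like(mixed)
    for r in range(n_feat):
        before = data[r, mask].sum()
        after = mixed[r, mask].sum()
        out[r] = mixed[r] * (before / after if after > 0 else 1.0)
    return out
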