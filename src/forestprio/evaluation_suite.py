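"""Comparison and validation battery for priority rank rasters.

Three instruments, mirroring how competing prioritizations are usually
compared: (1) decile-interval Jaccard matrices measuring the spatial overlap
of priority bands between two rankings, (2) the distribution of priority
ranks inside validation masks of known conservation value, and (3) a
machine-readable report bundling everything for a grid of analysis runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .prioritization_engine import RankResult
from .synthetic_landscape import ValidationSet

N_INTERVALS = 10


def jaccard(a, b):
    """Jaccard coefficient of two boolean masks: |A ∩ B| / |A ∪ B| (0 when the
    union is empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def _interval_bins(rank, mask):
    """Half-open rank bins [0, 0.1), ..., [0.9, 1.0] as indices 0..9."""
    bins = np.floor(np.asarray(rank)[mask] * N_INTERVALS).astype(int)
    return np.clip(bins, 0, N_INTERVALS - 1)


def decile_jaccard_matrix(rank_a, rank_b, valid_mask):
    """10x10 Jaccard matrix between the priority deciles of two rank rasters.

    Entry (a, b) compares interval a of the first ranking with interval b of
    the second; a self-comparison yields the identity-like matrix because the
    intervals partition the landscape.
    """
    rank_a = np.asarray(rank_a)
    rank_b = np.asarray(rank_b)
    if rank_a.shape != rank_b.shape or rank_a.shape != valid_mask.shape:
        raise ValueError("rank rasters and mask must share the grid")
    ia = _interval_bins(rank_a, valid_mask)
    ib = _interval_bins(rank_b, valid_mask)
    counts = np.zeros((N_INTERVALS, N_INTERVALS), dtype=np.int64)
    np.add.at(counts, (ia, ib), 1)
    na = counts.sum(axis=1)
    nb = counts.sum(axis=0)
    union = na[:, None] + nb[None, :] - counts
    out = np.zeros((N_INTERVALS, N_INTERVALS))
    np.divide(counts, union, out=out, where=union > 0)
    return out


def validation_overlay(result: RankResult, validation: ValidationSet) -> pd.DataFrame:
    """Distribution of priority ranks inside each validation mask.

    One row per mask with cell count, median and quartiles; an empty mask is
    flagged absent (``present == False``) rather than reported as zeros.
    """
    rows = []
    for name, mask in validation.masks.items():
        inside = mask & result.valid_mask
        vals = result.rank[inside]
        if vals.size == 0:
            rows.append(
                {"mask": name, "present": False, "n_cells": 0,
                 "median": np.nan, "q25": np.nan, "q75": np.nan}
            )
        else:
            rows.append(
                {
                    "mask": name,
                    "present": True,
                    "n_cells": int(vals.size),
                    "median": float(np.median(vals)),
                    "q25": float(np.quantile(vals, 0.25)),
                    "q75": float(np.quantile(vals, 0.75)),
                }
            )
    return pd.DataFrame(rows).set_index("mask")


def experiment_report(
    runs: dict,
    validation: ValidationSet | None = None,
    cross_loads: dict | None = None,
    out_dir=None,
    metadata: dict | None = None,
):
    """Bundle run metadata, pairwise decile Jaccard matrices, validation
    overlays and cross-load summaries into one deterministic JSON structure
    (optionally written to ``out_dir`` as JSON + CSV matrices).

    ``runs`` maps run label -> RankResult; all unordered pairs including the
    self-comparisons are reported, so a single run yields exactly one matrix.
    """
    if not runs:
        raise ValueError("at least one run is required")
    labels = sorted(runs)
    report = {
        "metadata": dict(metadata or {}),
        "runs": {
            lab: {
                "n_cells": int(runs[lab].n_cells),
                "n_features": len(runs[lab].feature_names),
            }
            for lab in labels
        },
        "jaccard": {},
        "overlay": {},
        "cross_load_top10": {},
    }
    for i, la in enumerate(labels):
        for lb in labels[i:]:
            mask = runs[la].valid_mask & runs[lb].valid_mask
            mat = decile_jaccard_matrix(runs[la].rank, runs[lb].rank, mask)
            report["jaccard"][f"{la}__vs__{lb}"] = np.round(mat, 10).tolist()
    if validation is not None:
        for lab in labels:
            df = validation_overlay(runs[lab], validation)
            report["overlay"][lab] = {}
            for name, row in df.to_dict(orient="index").items():
                stats = {"present": bool(row["present"]), "n_cells": int(row["n_cells"])}
                for k in ("median", "q25", "q75"):
                    val = float(row[k])
                    stats[k] = None if np.isnan(val) else round(val, 10)
                report["overlay"][lab][name] = stats
    for key, summary in (cross_loads or {}).items():
        report["cross_load_top10"][key] = {
            "mean": round(float(summary["mean"]), 10),
            "by_fertility_class": {
                str(int(k)): round(float(v), 10)
                for k, v in summary["by_fertility_class"].items()
                if not np.isnan(v)
            },
            "per_feature": {
                str(name): round(float(v), 10)
                for name, v in summary["per_feature"].items()
                if not np.isnan(v)
            },
        }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, sort_keys=True, indent=1))
        for pair, mat in report["jaccard"].items():
            pd.DataFrame(mat).to_csv(out / f"jaccard_{pair}.csv", index=False)
    return report
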