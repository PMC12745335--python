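"""Region-level sampling of structured-surface fields.

Fields living on the 200x50 structured grid (stress, WSS, pressure,
growth rate, thrombus presence) are averaged over the 38 descending
regions per patient, producing the pooled region table the mixed-effects
models consume.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

from .meshmodel import RegionPartition, StructuredSurface, node_radii

__all__ = [
    "region_average",
    "thrombus_presence",
    "thrombus_region_indicator",
    "pearson_by_patient",
    "build_region_table",
]


def region_average(values: np.ndarray, partition: RegionPartition,
                   valid: np.ndarray | None = None) -> np.ndarray:
    """Mean of a structured-node field over each descending region.

    ``values`` has shape (n_layers, n_circ); invalid nodes (mask False)
    are excluded from the averages.  A region with no valid node yields
    NaN and is dropped pairwise downstream.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    out = np.empty(partition.n_descending)
    for k, reg in enumerate(partition.descending_regions):
        lay = partition.layers(reg)
        v = values[lay]
        m = valid[lay]
        out[k] = v[m].mean() if m.any() else np.nan
    return out


def thrombus_presence(structured: StructuredSurface,
                      thrombus_points: np.ndarray | None) -> np.ndarray:
    """Binary thrombus map on the structured surface.

    A node is thrombus-covered when its distance to the nearest thrombus
    point is smaller than the node's local radius (its distance to the
    layer center).  With no thrombus points the map is all-absent.
    """
    shape = (structured.n_layers, structured.n_circ)
    if thrombus_points is None or len(thrombus_points) == 0:
        return np.zeros(shape, dtype=int)
    tree = cKDTree(np.asarray(thrombus_points, dtype=float))
    d, _ = tree.query(structured.points())
    radius = node_radii(structured).ravel()
    return (d < radius).astype(int).reshape(shape)


def thrombus_region_indicator(binary_map: np.ndarray,
                              partition: RegionPartition) -> np.ndarray:
    """Region indicator Tb: 1 where the regional mean exceeds 0.5
    (strictly), else 0."""
    avg = region_average(np.asarray(binary_map, dtype=float), partition)
    return (avg > 0.5).astype(int)


def pearson_by_patient(table: pd.DataFrame, x: str, y: str,
                       groups: str = "patient_id") -> pd.DataFrame:
    """Per-patient Pearson correlation with two-sided t-based p values.

    Patients with fewer than 3 complete pairs, or zero variance in
    either variable, are flagged (NaN r) rather than dropped silently.
    """
    rows = []
    for pid, sub in table.groupby(groups, sort=False):
        sub = sub[[x, y]].dropna()
        if len(sub) < 3 or sub[x].nunique() < 2 or sub[y].nunique() < 2:
            rows.append({groups: pid, "n": len(sub), "r": np.nan, "p": np.nan,
                         "flag": "degenerate"})
            continue
        r, p = sps.pearsonr(sub[x], sub[y])
        rows.append({groups: pid, "n": len(sub), "r": float(r), "p": float(p),
                     "flag": ""})
    return pd.DataFrame(rows)


def build_region_table(patient_id: str, partition: RegionPartition,
                       fields: dict[str, np.ndarray],
                       valid: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
    """Assemble one patient's 38-region rows from structured fields.

    ``fields`` maps column names to (n_layers, n_circ) arrays; the
    special key ``thrombus`` is passed through the > 0.5 indicator rule
    instead of plain averaging.
    """
    valid = valid or {}
    data = {"patient_id": patient_id,
            "region": list(partition.descending_regions)}
    for name, arr in fields.items():
        if name == "thrombus":
            data[name] = thrombus_region_indicator(arr, partition)
        else:
            data[name] = region_average(arr, partition, valid.get(name))
    return pd.DataFrame(data)
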