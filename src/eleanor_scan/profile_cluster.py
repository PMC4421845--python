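"""FPKM quantification, variance/abundance filtering and k-means patterns.

Gene profiles are FPKM per condition; genes pass the filter when the
interquartile range of their condition values exceeds ``iqr_min`` (strict)
and their maximum exceeds ``fpkm_min`` (strict).  Rows are z-scored before
k-means so clusters capture expression *patterns* rather than magnitudes,
and pattern extraction is centroid-shape based (cluster numbering is
arbitrary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans


def compute_fpkm(
    counts: pd.DataFrame,
    exonic_length: pd.Series,
    mapped_reads: pd.Series,
) -> pd.DataFrame:
    """FPKM = count / (length/1e3 * mapped/1e6), per gene per sample."""
    lengths = exonic_length.reindex(counts.index).to_numpy(dtype=float)
    if np.isnan(lengths).any() or (lengths <= 0).any():
        raise ValueError("every gene needs a positive exonic length")
    mapped = mapped_reads.reindex(counts.columns).to_numpy(dtype=float)
    if np.isnan(mapped).any() or (mapped <= 0).any():
        raise ValueError("every sample needs a positive mapped-read total")
    fpkm = counts.to_numpy(dtype=float) / (
        lengths[:, None] / 1e3 * mapped[None, :] / 1e6
    )
    return pd.DataFrame(fpkm, index=counts.index, columns=counts.columns)


def condition_means(
    values: pd.DataFrame, sample_sheet: pd.DataFrame, conditions: list[str]
) -> pd.DataFrame:
    """Average replicate columns into one column per condition, in order."""
    sheet = sample_sheet.set_index("sample")["condition"]
    out = {}
    for cond in conditions:
        cols = [s for s in values.columns if sheet.get(s) == cond]
        if not cols:
            raise ValueError(f"no samples for condition {cond!r}")
        out[cond] = values[cols].mean(axis=1)
    return pd.DataFrame(out)


def filter_genes(
    profiles: pd.DataFrame,
    iqr_min: float = 10.0,
    fpkm_min: float = 5.0,
) -> pd.DataFrame:
    """Keep genes with IQR(values) > iqr_min and max(values) > fpkm_min.

    Quartiles use linear interpolation (the common scientific-stack
    default); both inequalities are strict.
    """
    if profiles.shape[1] < 2:
        raise ValueError("need >= 2 condition values per profile")
    vals = profiles.to_numpy(dtype=float)
    q1 = np.percentile(vals, 25, axis=1)
    q3 = np.percentile(vals, 75, axis=1)
    keep = ((q3 - q1) > iqr_min) & (vals.max(axis=1) > fpkm_min)
    return profiles.loc[keep]


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels (1..k) plus z-scored centroids per cluster."""

    labels: pd.Series
    centroids: pd.DataFrame  # k rows, condition columns
    k: int
    seed: int
    inertia: float


def zscore_rows(profiles: pd.DataFrame) -> pd.DataFrame:
    vals = profiles.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0  # constant rows map to all-zero profiles
    return pd.DataFrame((vals - mu) / sd, index=profiles.index,
                        columns=profiles.columns)


def kmeans_cluster(
    profiles: pd.DataFrame,
    k: int = 14,
    seed: int = 0,
    restarts: int = 50,
) -> ClusterAssignment:
    """k-means over z-scored profiles: k-means++ init, best of ``restarts``.

    Deterministic under ``seed``.  Raises when there are fewer genes than
    clusters, suggesting a smaller k.
    """
    n = len(profiles)
    if n < k:
        raise ValueError(
            f"{n} profiles cannot form {k} clusters; use k <= {n}"
        )
    z = zscore_rows(profiles)
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    labels = km.fit_predict(z.to_numpy())
    return ClusterAssignment(
        labels=pd.Series(labels + 1, index=profiles.index, name="cluster"),
        centroids=pd.DataFrame(km.cluster_centers_, columns=profiles.columns,
                               index=pd.RangeIndex(1, k + 1, name="cluster")),
        k=k,
        seed=seed,
        inertia=float(km.inertia_),
    )


def extract_pattern(
    assignment: ClusterAssignment, pattern: str = "up_then_down"
) -> set:
    """Genes in clusters whose centroid shows the requested 3-point shape.

    ``up_then_down``: the middle condition is the maximum (induction then
    repression); ``down_then_up`` is the mirror image.
    """
    cents = assignment.centroids.to_numpy()
    if cents.shape[1] != 3:
        raise ValueError("pattern extraction expects 3-condition profiles")
    a, b, c = cents[:, 0], cents[:, 1], cents[:, 2]
    if pattern == "up_then_down":
        sel = (b > a) & (b > c)
    elif pattern == "down_then_up":
        sel = (b < a) & (b < c)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    chosen = set(assignment.centroids.index[sel])
    return set(assignment.labels.index[assignment.labels.isin(chosen)])
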