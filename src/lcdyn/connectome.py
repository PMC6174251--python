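"""Parcellation, ROI time courses, and fiber-length-derived conduction lags.

The connectome stage turns vertex-level source estimates into the variables of
the lagged linear dynamics model: source vertices are clustered into regions
of interest (ROIs) by spatial proximity, each ROI's time course is the mean of
its member dipole moments, and every tractography edge gets an integer sample
lag from its mean fiber length at a fixed axonal conduction velocity
(default 6 m/s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .data import FiberNetwork, Parcellation, SourceActivity


def parcellate(
    source_positions: np.ndarray, n_rois: int, seed: int = 0
) -> Parcellation:
    """Cluster source vertices into ``n_rois`` balanced, spatially compact ROIs.

    K-means centroids seed the clustering; vertices are then assigned greedily
    (nearest-first) under a per-ROI capacity of ``ceil(n_sources/n_rois)``,
    which keeps ROI sizes within one vertex of each other ("equally
    distributed"). Hemisphere labels follow the sign of the medio-lateral
    centroid coordinate, with exact midline broken toward left.
    """
    pos = np.asarray(source_positions, dtype=float)
    n_sources = pos.shape[0]
    if n_rois > n_sources:
        raise ValueError(f"n_rois={n_rois} exceeds n_sources={n_sources}")

    km = KMeans(n_clusters=n_rois, n_init=4, random_state=seed)
    km.fit(pos)
    centroids = km.cluster_centers_

    # capacity-constrained assignment: globally nearest (vertex, roi) first
    cap = int(np.ceil(n_sources / n_rois))
    d = np.linalg.norm(pos[:, None, :] - centroids[None, :, :], axis=2)
    order = np.argsort(d, axis=None, kind="stable")
    assignment = np.full(n_sources, -1, dtype=int)
    fill = np.zeros(n_rois, dtype=int)
    assigned = 0
    for flat in order:
        v, r = divmod(int(flat), n_rois)
        if assignment[v] >= 0 or fill[r] >= cap:
            continue
        assignment[v] = r
        fill[r] += 1
        assigned += 1
        if assigned == n_sources:
            break

    # recompute centroids from final membership
    for r in range(n_rois):
        centroids[r] = pos[assignment == r].mean(axis=0)
    hemi = np.where(centroids[:, 0] > 0, "right", "left")
    return Parcellation(assignment, centroids, hemi, n_rois)


def roi_timecourses(src: SourceActivity, parc: Parcellation) -> SourceActivity:
    """ROI x time matrix: each ROI is the mean of its member dipole moments."""
    if src.n_units != parc.n_sources:
        raise ValueError(
            f"source count {src.n_units} != parcellation size {parc.n_sources}"
        )
    sizes = parc.roi_sizes().astype(float)
    sums = np.zeros((parc.n_rois, src.n_times))
    np.add.at(sums, parc.assignment, src.currents)
    return SourceActivity(sums / sizes[:, None], src.fs, src.time_zero, kind="roi")


def lag_from_length(length_mm: float, velocity_mps: float, fs: float) -> int:
    """Integer sample lag for one fiber: round half-up, clamp to >= 1.

    The clamp means no instantaneous inter-ROI term exists — inter-regional
    interactions are strictly lagged (order one at the edge's own delay).
    """
    if velocity_mps <= 0:
        raise ValueError("conduction velocity must be positive")
    if fs <= 0 or length_mm <= 0:
        raise ValueError("length and sampling rate must be positive")
    lag = int(np.floor(length_mm / 1000.0 / velocity_mps * fs + 0.5))
    return max(1, lag)


def lags_from_lengths(
    net: FiberNetwork, velocity_mps: float = 6.0, fs: float = 512.0
) -> FiberNetwork:
    """Fill ``lag_samples`` for every edge from its mean fiber length."""
    edges = net.edges.copy()
    edges["lag_samples"] = [
        lag_from_length(l, velocity_mps, fs) for l in edges["mean_length_mm"]
    ]
    return FiberNetwork(edges, velocity_mps=velocity_mps, fs=fs)


# ---------------------------------------------------------------------------
# TSV interchange


def read_fiber_table(path, velocity_mps: float = 6.0, fs: float = 512.0) -> FiberNetwork:
    """Read a tractography edge table (TSV: roi_a, roi_b, n_fibers, mean_length_mm).

    Duplicate undirected edges — repeated (a, b) rows or reversed (b, a)
    rows — are merged into one edge whose length is the fiber-count-weighted
    mean and whose fiber count is the sum. Self-loops and non-positive
    lengths are rejected with the offending row number.
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("roi_a", "roi_b", "n_fibers", "mean_length_mm"):
        if col not in df.columns:
            raise ValueError(f"fiber table missing column {col!r}")
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1 = header line
        if int(row.roi_a) == int(row.roi_b):
            raise ValueError(f"row {i}: self-loop edge {row.roi_a}->{row.roi_b}")
        if row.mean_length_mm <= 0:
            raise ValueError(f"row {i}: non-positive fiber length {row.mean_length_mm}")
        if row.n_fibers <= 0:
            raise ValueError(f"row {i}: non-positive fiber count {row.n_fibers}")

    a = np.minimum(df["roi_a"], df["roi_b"])
    b = np.maximum(df["roi_a"], df["roi_b"])
    canon = pd.DataFrame(
        {
            "roi_a": a.astype(int),
            "roi_b": b.astype(int),
            "n_fibers": df["n_fibers"].astype(int),
            "mean_length_mm": df["mean_length_mm"].astype(float),
        }
    )
    canon["_wl"] = canon["n_fibers"] * canon["mean_length_mm"]
    merged = canon.groupby(["roi_a", "roi_b"], as_index=False).agg(
        n_fibers=("n_fibers", "sum"), _wl=("_wl", "sum")
    )
    merged["mean_length_mm"] = merged["_wl"] / merged["n_fibers"]
    merged = merged.drop(columns="_wl").sort_values(
        ["roi_a", "roi_b"], ignore_index=True
    )
    return FiberNetwork(merged, velocity_mps=velocity_mps, fs=fs)


def write_fiber_table(net: FiberNetwork, path) -> None:
    cols = ["roi_a", "roi_b", "n_fibers", "mean_length_mm"]
    if net.has_lags:
        cols.append("lag_samples")
    net.edges[cols].to_csv(path, sep="\t", index=False)


def read_parcellation(path) -> Parcellation:
    """Read a source->ROI table (TSV: source_id, roi_id, hemisphere[, x, y, z])."""
    df = pd.read_csv(path, sep="\t")
    for col in ("source_id", "roi_id", "hemisphere"):
        if col not in df.columns:
            raise ValueError(f"parcellation table missing column {col!r}")
    df = df.sort_values("source_id", ignore_index=True)
    if not np.array_equal(df["source_id"].to_numpy(), np.arange(len(df))):
        raise ValueError("source_id must cover 0..n_sources-1 exactly once")
    assignment = df["roi_id"].to_numpy(dtype=int)
    n_rois = int(assignment.max()) + 1
    hemi = np.empty(n_rois, dtype=object)
    for roi, lab in zip(df["roi_id"], df["hemisphere"]):
        hemi[int(roi)] = str(lab)
    if {"x", "y", "z"} <= set(df.columns):
        pos = df[["x", "y", "z"]].to_numpy(dtype=float)
        centroids = np.zeros((n_rois, 3))
        for r in range(n_rois):
            centroids[r] = pos[assignment == r].mean(axis=0)
    else:
        centroids = np.zeros((n_rois, 3))
    return Parcellation(assignment, centroids, hemi.astype(str), n_rois)


def write_parcellation(
    parc: Parcellation, path, source_positions: np.ndarray | None = None
) -> None:
    df = pd.DataFrame(
        {
            "source_id": np.arange(parc.n_sources),
            "roi_id": parc.assignment,
            "hemisphere": parc.hemisphere[parc.assignment],
        }
    )
    if source_positions is not None:
        df[["x", "y", "z"]] = np.asarray(source_positions, dtype=float)
    df.to_csv(path, sep="\t", index=False)
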