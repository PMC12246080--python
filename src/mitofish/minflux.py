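"""MINFLUX / DNA-PAINT localization processing.

Stages, in the order they are applied to a region of interest (ROI):

1. :func:`align_datasets` — rigid per-dataset translation from fiducial
   gold-bead positions (sequential imaging rounds drift, they do not rotate).
2. :func:`combine_events` — raw localizations of each binding event (trace)
   with more than four localizations are combined into one position with
   per-axis standard-error precisions: radial s_r and axial s_z.
3. :func:`filter_by_precision` — per dataset, the axis with the worst mean
   precision is found and combined localizations beyond twice that mean are
   discarded (single pass).
4. :func:`dbscan_filter` — DBSCAN (epsilon 120 nm, minimum 8 points) over
   the concatenated datasets of the ROI rejects background localizations.
5. :func:`cross_dataset_min_distances` — nearest-neighbour distances between
   combined localizations of different datasets.
6. :func:`export_sphere_model` — sphere-model table (default diameter 10 nm)
   for 3D rendering, as CSV and an ASCII PLY point cloud.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .sted import nearest_neighbor_distances, summarize_distances
from .types import DistanceSummary

XYZ = ["x_nm", "y_nm", "z_nm"]

COMBINED_COLUMNS = ["dataset_id", "trace_id", "x_nm", "y_nm", "z_nm",
                    "n_locs", "s_x", "s_y", "s_z", "s_r"]


@dataclass
class DbscanParams:
    """DBSCAN parameters for background rejection (defaults: 120 nm, 8 points)."""

    epsilon: float = 120.0
    min_points: int = 8

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class PrecisionSummary:
    """Median localization precisions, pooled and per dataset."""

    median_s_r: float
    median_s_z: float
    per_dataset: pd.DataFrame          # dataset_id, median_s_r, median_s_z, n
    histograms: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "median_s_r": float(self.median_s_r),
            "median_s_z": float(self.median_s_z),
            "per_dataset": self.per_dataset.to_dict(orient="records"),
        }


def _dataset_order(df: pd.DataFrame) -> list:
    return list(dict.fromkeys(df["dataset_id"]))


def align_datasets(raw: pd.DataFrame, beads: pd.DataFrame,
                   reference: str | None = None
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Rigidly align sequential imaging rounds on shared fiducial beads.

    For each dataset the translation is the difference between its mean
    position of the shared beads and that of the reference dataset (the
    first one by default); the translation is subtracted from all
    localizations and bead tracks of that dataset.

    Returns ``(aligned_raw, aligned_beads, translations)`` where
    ``translations`` maps dataset id to the applied (dx, dy, dz).
    """
    datasets = _dataset_order(beads)
    if reference is None:
        reference = datasets[0]
    shared = None
    for ds in datasets:
        ids = set(beads.loc[beads["dataset_id"] == ds, "bead_id"])
        shared = ids if shared is None else shared & ids
    if not shared:
        raise ValueError("no fiducial bead shared across all datasets")
    shared = sorted(shared)

    def bead_centroid(ds):
        sub = beads[(beads["dataset_id"] == ds) & beads["bead_id"].isin(shared)]
        # mean per bead first, then across beads, so uneven track lengths
        # cannot weight one bead more than another
        return sub.groupby("bead_id")[XYZ].mean().loc[shared].to_numpy().mean(axis=0)

    ref_centroid = bead_centroid(reference)
    raw = raw.copy()
    beads = beads.copy()
    raw[XYZ] = raw[XYZ].astype(float)
    beads[XYZ] = beads[XYZ].astype(float)
    translations: dict = {}
    for ds in datasets:
        shift = bead_centroid(ds) - ref_centroid
        translations[ds] = tuple(float(v) for v in shift)
        raw.loc[raw["dataset_id"] == ds, XYZ] -= shift
        beads.loc[beads["dataset_id"] == ds, XYZ] -= shift
    return raw, beads, translations


def combine_events(raw: pd.DataFrame, s_r_convention: str = "rms"
                   ) -> pd.DataFrame:
    """Combine each binding event's raw localizations into one position.

    Traces with four or fewer localizations are dropped.  The combined
    position is the per-axis arithmetic mean; per-axis precision is the
    standard error, sample SD / sqrt(n).  The radial precision pools x and
    y: ``"rms"`` (default) gives sqrt((s_x^2 + s_y^2) / 2), commensurate
    with a single-axis value; ``"quadrature"`` gives sqrt(s_x^2 + s_y^2).
    """
    if s_r_convention not in ("rms", "quadrature"):
        raise ValueError(f"unknown s_r convention {s_r_convention!r}")
    if raw.empty:
        return pd.DataFrame(columns=COMBINED_COLUMNS)
    g = raw.groupby(["dataset_id", "trace_id"], sort=False)
    agg = g[XYZ].agg(["mean", "std", "count"])
    n = agg[("x_nm", "count")].to_numpy()
    keep = n > 4
    out = pd.DataFrame({
        "dataset_id": [k[0] for k in agg.index],
        "trace_id": [k[1] for k in agg.index],
        "x_nm": agg[("x_nm", "mean")].to_numpy(),
        "y_nm": agg[("y_nm", "mean")].to_numpy(),
        "z_nm": agg[("z_nm", "mean")].to_numpy(),
        "n_locs": n.astype(int),
    })
    se = {ax: agg[(ax, "std")].to_numpy() / np.sqrt(n) for ax in XYZ}
    out["s_x"] = se["x_nm"]
    out["s_y"] = se["y_nm"]
    out["s_z"] = se["z_nm"]
    if s_r_convention == "rms":
        out["s_r"] = np.sqrt((out["s_x"] ** 2 + out["s_y"] ** 2) / 2.0)
    else:
        out["s_r"] = np.sqrt(out["s_x"] ** 2 + out["s_y"] ** 2)
    return out.loc[keep].reset_index(drop=True)


def precision_summary(combined: pd.DataFrame) -> PrecisionSummary:
    """Median s_r and s_z over combined localizations, pooled and per dataset."""
    if combined.empty:
        raise ValueError("no combined localizations to summarize")
    rows = []
    hists = {}
    for ds, sub in combined.groupby("dataset_id", sort=False):
        rows.append({
            "dataset_id": ds,
            "median_s_r": float(sub["s_r"].median()),
            "median_s_z": float(sub["s_z"].median()),
            "n": int(len(sub)),
        })
        hists[ds] = {
            "s_r": np.histogram(sub["s_r"], bins=30),
            "s_z": np.histogram(sub["s_z"], bins=30),
        }
    return PrecisionSummary(
        median_s_r=float(combined["s_r"].median()),
        median_s_z=float(combined["s_z"].median()),
        per_dataset=pd.DataFrame(rows),
        histograms=hists,
    )


def filter_by_precision(combined: pd.DataFrame) -> pd.DataFrame:
    """Discard poorly localized events on each dataset's worst axis.

    Per dataset, the worst axis is the one of {s_r, s_z} with the larger
    mean precision value; combined localizations whose precision on that
    axis exceeds twice the (pre-filter) mean are discarded.  Applied once —
    the threshold is not re-estimated after removal.
    """
    if combined.empty:
        return combined.copy()
    parts = []
    for ds, sub in combined.groupby("dataset_id", sort=False):
        means = {"s_r": sub["s_r"].mean(), "s_z": sub["s_z"].mean()}
        worst = max(means, key=means.get)
        parts.append(sub[sub[worst] <= 2.0 * means[worst]])
    return pd.concat(parts).sort_index().reset_index(drop=True)


def dbscan_labels(points: np.ndarray, epsilon: float, min_points: int
                  ) -> np.ndarray:
    """DBSCAN labels from the original definition.

    A core point has at least ``min_points`` neighbours within ``epsilon``
    (itself included); clusters grow by density-reachability from core
    points; non-reached points are labelled noise (-1).  Border points join
    the first cluster that reaches them.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    tree = cKDTree(points)
    neighborhoods = tree.query_ball_point(points, r=epsilon)
    core = np.array([len(nb) >= min_points for nb in neighborhoods])
    cluster = 0
    visited = np.zeros(n, dtype=bool)
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # expand a new cluster from this core point
        stack = [i]
        visited[i] = True
        labels[i] = cluster
        while stack:
            j = stack.pop()
            for k in neighborhoods[j]:
                if labels[k] == -1:
                    labels[k] = cluster
                if not visited[k] and core[k]:
                    visited[k] = True
                    stack.append(k)
        cluster += 1
    return labels


def dbscan_filter(combined: pd.DataFrame, p: DbscanParams | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split concatenated combined localizations into clustered and noise.

    The combined localizations of all datasets of one ROI are clustered
    jointly; points labelled noise are excluded from downstream analysis.
    Returns ``(clustered, noise)``; ``clustered`` carries a ``cluster``
    column.
    """
    p = p or DbscanParams()
    if combined.empty:
        empty = combined.copy()
        empty["cluster"] = pd.Series(dtype=int)
        return empty, combined.copy()
    labels = dbscan_labels(combined[XYZ].to_numpy(), p.epsilon, p.min_points)
    out = combined.copy()
    out["cluster"] = labels
    clustered = out[labels >= 0].reset_index(drop=True)
    noise = out[labels < 0].drop(columns="cluster").reset_index(drop=True)
    return clustered, noise


def cross_dataset_min_distances(filtered: pd.DataFrame, pooled: bool = True,
                                datasets: list | None = None
                                ) -> dict[tuple, DistanceSummary]:
    """Minimum 3D distances between combined localizations of different
    datasets of one ROI, per dataset pair.

    Both directions of each pair are pooled by default.  ``datasets`` may
    name the expected datasets of the ROI (a dataset can lose all its
    localizations to filtering); pairs with an empty side are skipped with
    a warning.
    """
    if datasets is None:
        datasets = _dataset_order(filtered)
    if len(datasets) < 2:
        raise ValueError("need at least two datasets for cross distances")
    groups = {ds: filtered.loc[filtered["dataset_id"] == ds, XYZ].to_numpy()
              for ds in datasets}
    out: dict[tuple, DistanceSummary] = {}
    for a, b in combinations(datasets, 2):
        pa, pb = groups[a], groups[b]
        if len(pa) == 0 or len(pb) == 0:
            warnings.warn(f"dataset pair ({a}, {b}) skipped: empty after "
                          "filtering", stacklevel=2)
            continue
        d = nearest_neighbor_distances(pa, pb)
        if pooled:
            d = np.concatenate([d, nearest_neighbor_distances(pb, pa)])
        out[(a, b)] = summarize_distances(d)
    return out


def export_sphere_model(positions: pd.DataFrame, diameter: float = 10.0,
                        csv_path: str | Path | None = None,
                        ply_path: str | Path | None = None) -> pd.DataFrame:
    """Sphere-model table for rendering combined localizations.

    One record per combined localization: center (nm), sphere diameter
    (default 10 nm) and dataset label.  Optionally written as CSV and as an
    ASCII PLY point cloud.
    """
    table = pd.DataFrame({
        "x_nm": positions["x_nm"].to_numpy(dtype=float),
        "y_nm": positions["y_nm"].to_numpy(dtype=float),
        "z_nm": positions["z_nm"].to_numpy(dtype=float),
        "diameter_nm": float(diameter),
        "dataset_id": positions["dataset_id"].to_numpy()
        if "dataset_id" in positions else "",
    }) if len(positions) else pd.DataFrame(
        columns=["x_nm", "y_nm", "z_nm", "diameter_nm", "dataset_id"])
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    if ply_path is not None:
        with open(ply_path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {len(table)}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("property float radius\nend_header\n")
            for row in table.itertuples(index=False):
                fh.write(f"{row.x_nm!r} {row.y_nm!r} {row.z_nm!r} "
                         f"{float(row.diameter_nm) / 2.0!r}\n")
    return table


def read_sphere_model(csv_path: str | Path) -> pd.DataFrame:
    """Read back a sphere-model CSV written by :func:`export_sphere_model`."""
    return pd.read_csv(csv_path, float_precision="round_trip")
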