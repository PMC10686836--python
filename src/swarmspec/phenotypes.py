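"""Microscopy-derived phenotype metrics from per-frame cell tables.

Works downstream of segmentation / optical flow: the input is one table
per video with per-cell centroid (µm), axial orientation (rad, mod pi),
speed (µm/s) and area (µm²) per frame.  Metrics follow the swarm
conventions: non-motile means speed strictly below 8 µm/s, motile means
speed of 10 µm/s or more, and all neighbourhood distances are inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

# Centralized threshold conventions (strictness is part of the contract).
NON_MOTILE_SPEED = 8.0      # µm/s, strict: speed < 8 is non-motile
MOTILE_SPEED = 10.0         # µm/s, inclusive: speed >= 10 is motile
NEIGHBOR_RADIUS_NEMATIC = 10.0   # µm, inclusive
NEIGHBOR_RADIUS_RAFT = 30.0      # µm, inclusive
RAFT_ANGLE_TOL = np.deg2rad(15.0)
CLUSTER_LINK = 2.0          # µm single-linkage cutoff
CLUSTER_MIN_SIZE = 10


@dataclass
class CellTable:
    """Per-frame cell records for one video."""

    frames: pd.DataFrame      # columns: frame, x, y, orientation, speed, area
    field_of_view: tuple[float, float]

    REQUIRED = ("frame", "x", "y", "orientation", "speed", "area")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.frames.columns)
        if missing:
            raise ValueError(f"cell table missing columns: {sorted(missing)}")
        if len(self.frames) and (self.frames["speed"] < 0).any():
            raise ValueError("negative speeds")

    def frame(self, index: int) -> pd.DataFrame:
        return self.frames[self.frames["frame"] == index]

    @property
    def frame_indices(self) -> np.ndarray:
        return np.sort(self.frames["frame"].unique())


def pair_nematic_order(theta: np.ndarray) -> np.ndarray:
    """2-D nematic order parameter S = 1.5 cos^2(theta) - 0.5.

    S = 1 for parallel axes, -0.5 for perpendicular; pi-periodic in the
    relative angle theta.
    """
    return 1.5 * np.cos(np.asarray(theta, float)) ** 2 - 0.5


def axial_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Smallest angle between two axial (head-tail symmetric) orientations."""
    d = np.abs(np.asarray(a, float) - np.asarray(b, float)) % np.pi
    return np.minimum(d, np.pi - d)


def local_nematic_order(cells: pd.DataFrame,
                        radius: float = NEIGHBOR_RADIUS_NEMATIC) -> np.ndarray:
    """Mean pairwise nematic order of each cell with its neighbours.

    Neighbours are cells within a centroid-centroid distance <= radius
    (self excluded).  Cells without neighbours get NaN and are excluded
    from downstream aggregation.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    xy = cells[["x", "y"]].to_numpy(float)
    theta = cells["orientation"].to_numpy(float)
    n = len(cells)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    tree = cKDTree(xy)
    for i, nbrs in enumerate(tree.query_ball_point(xy, radius)):
        nbrs = [j for j in nbrs if j != i]
        if nbrs:
            out[i] = pair_nematic_order(axial_difference(theta[i], theta[nbrs])).mean()
    return out


def non_motile_clusters(cells: pd.DataFrame,
                        speed_cutoff: float = NON_MOTILE_SPEED,
                        link_cutoff: float = CLUSTER_LINK,
                        min_size: int = CLUSTER_MIN_SIZE) -> list[np.ndarray]:
    """Single-linkage clusters of non-motile cells.

    Cells with speed strictly below ``speed_cutoff`` are linked when their
    centroid distance is <= ``link_cutoff``; connected components with at
    least ``min_size`` members are returned as index arrays into
    ``cells``.
    """
    if speed_cutoff <= 0 or link_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    slow = np.flatnonzero(cells["speed"].to_numpy(float) < speed_cutoff)
    if slow.size == 0:
        return []
    xy = cells.iloc[slow][["x", "y"]].to_numpy(float)
    tree = cKDTree(xy)
    adj = tree.sparse_distance_matrix(tree, link_cutoff, output_type="coo_matrix")
    _n, labels = connected_components(adj.tocsr(), directed=False)
    clusters = []
    for lab in np.unique(labels):
        members = slow[labels == lab]
        if members.size >= min_size:
            clusters.append(members)
    return clusters


def local_rafting_ratio(cells: pd.DataFrame,
                        radius: float = NEIGHBOR_RADIUS_RAFT,
                        motile_speed: float = MOTILE_SPEED,
                        angle_tol: float = RAFT_ANGLE_TOL) -> np.ndarray:
    """Fraction of each cell's neighbourhood that rafts with it.

    For every cell, count motile neighbours (speed >= motile_speed)
    aligned with it within angle_tol, divided by the total neighbour
    count.  Empty neighbourhoods give NaN.
    """
    xy = cells[["x", "y"]].to_numpy(float)
    theta = cells["orientation"].to_numpy(float)
    speed = cells["speed"].to_numpy(float)
    n = len(cells)
    out = np.full(n, np.nan)
    if n < 2:
        return out
    tree = cKDTree(xy)
    for i, nbrs in enumerate(tree.query_ball_point(xy, radius)):
        nbrs = np.array([j for j in nbrs if j != i])
        if nbrs.size == 0:
            continue
        aligned = axial_difference(theta[i], theta[nbrs]) <= angle_tol
        motile = speed[nbrs] >= motile_speed
        out[i] = np.sum(aligned & motile) / nbrs.size
    return out


def density_fluctuations(table: CellTable, tile: float = 48.0) -> float:
    """Mean over frames of the spatial SD of local coverage fractions.

    Each frame's field of view is split into complete tile x tile µm
    sub-images; the coverage fraction of each is approximated from cell
    areas assigned to the tile containing the centroid.  The SD uses the
    population (divide-by-N) convention.  Partial edge tiles are dropped.
    """
    w, h = table.field_of_view
    nx, ny = int(w // tile), int(h // tile)
    if nx < 1 or ny < 1:
        raise ValueError("field of view smaller than one tile")
    frame_sds = []
    for f in table.frame_indices:
        cells = table.frame(f)
        cover = np.zeros((nx, ny))
        if len(cells):
            ix = (cells["x"].to_numpy(float) // tile).astype(int)
            iy = (cells["y"].to_numpy(float) // tile).astype(int)
            ok = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
            np.add.at(cover, (ix[ok], iy[ok]), cells["area"].to_numpy(float)[ok])
            cover /= tile**2
        frame_sds.append(float(np.std(cover)))
    return float(np.mean(frame_sds)) if frame_sds else 0.0


def biomass_density(cells: pd.DataFrame, radius: float = 30.0) -> np.ndarray:
    """Fraction of area covered by cells in a circle around each centroid."""
    xy = cells[["x", "y"]].to_numpy(float)
    area = cells["area"].to_numpy(float)
    n = len(cells)
    out = np.zeros(n)
    if n == 0:
        return out
    tree = cKDTree(xy)
    circle = np.pi * radius**2
    for i, nbrs in enumerate(tree.query_ball_point(xy, radius)):
        out[i] = area[nbrs].sum() / circle
    return np.clip(out, 0.0, 1.0)


def simple_properties(table: CellTable,
                      biomass_radius: float = 30.0) -> dict[str, float]:
    """Per-video scalar properties with median-then-mean aggregation.

    Per-cell quantities are reduced to a frame value by the median over
    the field of view, then to a video value by the mean over frames.
    The non-motile fraction and nematic order use the same scheme on
    their natural per-frame values.  Empty frames are skipped.
    """
    per_frame: dict[str, list[float]] = {
        "non_motile_fraction": [], "mean_speed": [], "mean_cell_area": [],
        "local_biomass_density": [], "nematic_order": [], "rafting": [],
    }
    for f in table.frame_indices:
        cells = table.frame(f)
        if len(cells) == 0:
            continue
        speed = cells["speed"].to_numpy(float)
        per_frame["non_motile_fraction"].append(float(np.mean(speed < NON_MOTILE_SPEED)))
        per_frame["mean_speed"].append(float(np.median(speed)))
        per_frame["mean_cell_area"].append(float(np.median(cells["area"])))
        per_frame["local_biomass_density"].append(
            float(np.median(biomass_density(cells, biomass_radius))))
        s = local_nematic_order(cells)
        per_frame["nematic_order"].append(
            float(np.median(s[np.isfinite(s)])) if np.isfinite(s).any() else np.nan)
        r = local_rafting_ratio(cells)
        per_frame["rafting"].append(
            float(np.median(r[np.isfinite(r)])) if np.isfinite(r).any() else np.nan)
    return {k: float(np.nanmean(v)) if v else np.nan for k, v in per_frame.items()}


def phenotype_kymograph(video_scalars: dict[str, float], annotations,
                        property_name: str) -> pd.DataFrame:
    """Tile grid for one property, same contract as the gene kymograph.

    ``video_scalars`` maps sample_id (one video per sampling location) to
    the property value; missing videos yield missing tiles flagged NaN.
    """
    from .counts import assemble_kymograph
    sample_ids = [a.sample_id for a in annotations]
    values = np.array([video_scalars.get(s, np.nan) for s in sample_ids])
    df = assemble_kymograph(values, annotations, sample_ids)
    df["property"] = property_name
    df["missing"] = ~np.isfinite(df["value"].to_numpy())
    return df
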