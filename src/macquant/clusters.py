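"""Actomyosin cluster detection and Delaunay neighbor distances.

Myosin activity contracts the actin layer into bright aster-like foci.
These are detected in the actin channel with the multiscale
Laplacian-of-Gaussian blob detector, and each cluster is assigned its
neighbors through the Delaunay triangulation of the centroid set; the
distribution of Delaunay edge lengths is the per-frame neighbor-distance
statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError
from skimage import feature

__all__ = ["ClusterGraph", "detect_clusters", "neighbor_distances", "cluster_sequence"]


@dataclass
class ClusterGraph:
    """Cluster centroids plus their Delaunay neighbor edges for one frame.

    centroids_um
        (n, 2) array of (x, y) positions in micrometers.
    edges
        Sorted (i, j) centroid index pairs; symmetric by construction.
    edge_lengths_um
        Euclidean length of each edge.
    degenerate
        True when fewer than 3 non-collinear points were available and the
        nearest-neighbor chain fallback was used instead of a triangulation.
    """

    frame_index: int
    centroids_um: np.ndarray
    edges: np.ndarray  # (m, 2) int
    edge_lengths_um: np.ndarray
    sigmas_px: np.ndarray = field(default_factory=lambda: np.zeros(0))
    responses: np.ndarray = field(default_factory=lambda: np.zeros(0))
    degenerate: bool = False

    def summary(self) -> dict:
        if len(self.edge_lengths_um) == 0:
            return {"n_clusters": len(self.centroids_um), "n_edges": 0,
                    "mean_um": np.nan, "sd_um": np.nan}
        return {"n_clusters": len(self.centroids_um),
                "n_edges": len(self.edges),
                "mean_um": float(self.edge_lengths_um.mean()),
                "sd_um": float(self.edge_lengths_um.std(ddof=1))
                if len(self.edge_lengths_um) > 1 else 0.0}


def detect_clusters(frame: np.ndarray, min_sigma: float = 2.0,
                    max_sigma: float = 6.0, threshold: float = 0.1,
                    pixel_size_um: float = 1.0) -> pd.DataFrame:
    """Detect bright diffraction-limited spots with the LoG method.

    The frame is min-max normalized and scale-space LoG maxima above
    ``threshold`` are returned; overlapping detections are merged keeping
    the stronger response.

    Returns
    -------
    DataFrame with columns x_um, y_um, sigma_px, response, sorted by
    descending response.
    """
    if min_sigma > max_sigma:
        raise ValueError("min_sigma must be <= max_sigma")
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("frame must be a single 2-D channel")
    rng = np.ptp(frame)
    cols = ["x_um", "y_um", "sigma_px", "response"]
    if rng == 0:
        return pd.DataFrame(columns=cols)
    norm = (frame - frame.min()) / rng
    blobs = feature.blob_log(norm, min_sigma=min_sigma, max_sigma=max_sigma,
                             num_sigma=8, threshold=threshold, overlap=0.5)
    if len(blobs) == 0:
        return pd.DataFrame(columns=cols)
    rows_px, cols_px, sigmas = blobs.T
    # peak response = normalized intensity at the detection site
    resp = norm[rows_px.astype(int), cols_px.astype(int)]
    rows_px, cols_px = _refine_subpixel(norm, rows_px, cols_px, sigmas)
    df = pd.DataFrame({"x_um": cols_px * pixel_size_um,
                       "y_um": rows_px * pixel_size_um,
                       "sigma_px": sigmas, "response": resp})
    return df.sort_values("response", ascending=False, ignore_index=True)


def _refine_subpixel(img: np.ndarray, rows, cols, sigmas):
    """Refine integer LoG maxima to the intensity-weighted centroid of a
    window of +-sigma around each detection (background-subtracted)."""
    h, w = img.shape
    r_out, c_out = rows.copy(), cols.copy()
    for i, (r, c, s) in enumerate(zip(rows, cols, sigmas)):
        half = max(int(round(s)), 1)
        r0, r1 = int(r) - half, int(r) + half + 1
        c0, c1 = int(c) - half, int(c) + half + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            continue
        win = img[r0:r1, c0:c1] - img[r0:r1, c0:c1].min()
        tot = win.sum()
        if tot <= 0:
            continue
        yy, xx = np.mgrid[r0:r1, c0:c1]
        r_out[i] = float((win * yy).sum() / tot)
        c_out[i] = float((win * xx).sum() / tot)
    return r_out, c_out


def _collinear(points: np.ndarray, tol: float = 1e-9) -> bool:
    if len(points) < 3:
        return True
    d = points - points.mean(axis=0)
    sv = np.linalg.svd(d, compute_uv=False)
    return sv[1] <= tol * max(sv[0], 1.0)


def _nn_chain_edges(points: np.ndarray) -> np.ndarray:
    """Fallback for degenerate sets: chain consecutive points along the
    dominant axis (for collinear sets this is the nearest-neighbor chain)."""
    if len(points) < 2:
        return np.zeros((0, 2), dtype=int)
    d = points - points.mean(axis=0)
    axis = np.linalg.svd(d)[2][0]
    order = np.argsort(d @ axis, kind="stable")
    return np.sort(np.column_stack([order[:-1], order[1:]]), axis=1)


def neighbor_distances(centroids_um, frame_index: int = 0,
                       sigmas_px=None, responses=None) -> ClusterGraph:
    """Delaunay neighbor graph and edge lengths of a centroid set.

    With at least 3 non-collinear points the edge set is exactly that of
    the Delaunay triangulation (each point's neighbors are its triangulation
    vertex neighbors).  Fewer or collinear points cannot be triangulated;
    the result then falls back to the nearest-neighbor chain and is flagged
    ``degenerate``.
    """
    pts = np.asarray(centroids_um, dtype=float).reshape(-1, 2)
    degenerate = _collinear(pts)
    if degenerate:
        edges = _nn_chain_edges(pts)
    else:
        try:
            tri = Delaunay(pts)
        except QhullError:
            degenerate, edges = True, _nn_chain_edges(pts)
        else:
            pairs = set()
            for simplex in tri.simplices:
                for i in range(3):
                    a, b = simplex[i], simplex[(i + 1) % 3]
                    pairs.add((min(a, b), max(a, b)))
            edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
    lengths = (np.hypot(*(pts[edges[:, 0]] - pts[edges[:, 1]]).T)
               if len(edges) else np.zeros(0))
    return ClusterGraph(
        frame_index=frame_index, centroids_um=pts, edges=edges,
        edge_lengths_um=lengths,
        sigmas_px=np.asarray(sigmas_px) if sigmas_px is not None else np.zeros(0),
        responses=np.asarray(responses) if responses is not None else np.zeros(0),
        degenerate=degenerate)


def cluster_sequence(frames: np.ndarray, pixel_size_um: float = 1.0,
                     min_sigma: float = 2.0, max_sigma: float = 6.0,
                     threshold: float = 0.1):
    """Detect clusters and build neighbor graphs for every frame of a stack.

    Returns (graphs, cluster_table, edge_table); frames with fewer than 3
    clusters produce degenerate graphs that are excluded from the edge
    table (they carry no triangulation distances).
    """
    graphs, cl_rows, edge_rows = [], [], []
    for i, frame in enumerate(np.asarray(frames, dtype=float)):
        det = detect_clusters(frame, min_sigma, max_sigma, threshold, pixel_size_um)
        g = neighbor_distances(det[["x_um", "y_um"]].to_numpy(), frame_index=i,
                               sigmas_px=det["sigma_px"].to_numpy(),
                               responses=det["response"].to_numpy())
        graphs.append(g)
        for _, r in det.iterrows():
            cl_rows.append({"frame": i, **r.to_dict()})
        if not g.degenerate:
            for (a, b), length in zip(g.edges, g.edge_lengths_um):
                edge_rows.append({"frame": i, "i": int(a), "j": int(b),
                                  "distance_um": float(length)})
    cluster_table = pd.DataFrame(cl_rows, columns=["frame", "x_um", "y_um",
                                                   "sigma_px", "response"])
    edge_table = pd.DataFrame(edge_rows, columns=["frame", "i", "j", "distance_um"])
    return graphs, cluster_table, edge_table
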