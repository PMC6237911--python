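"""Density-based ligand-pose clustering with frame sieving and reweighted
cluster free energies.

Trajectory frames are sieved at a fixed stride, DBSCAN (scikit-learn) is run
on the sieved poses, and every remaining frame is assigned to the cluster of
its nearest clustered sieved frame — provided that frame lies within ``eps``,
otherwise it is labelled noise (force-assigning distant frames would break
DBSCAN's density semantics).  Equidistant ties go to the lowest cluster id.
With stride 1 the procedure reduces exactly to plain DBSCAN.

Cluster free energies treat each cluster as one histogram bin and delegate to
the second-order cumulant reweighting: F_c = −k_B T ln p_c − (C1 + β C2/2),
min-shifted to zero over clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

__all__ = ["PoseCluster", "PoseClusterSet", "cluster_poses",
           "cluster_free_energies", "occupancy_series"]


@dataclass
class PoseCluster:
    id: int
    members: np.ndarray              # frame indices (0-based)
    representative: np.ndarray       # medoid pose over the sieved members
    population: float                # fraction of all frames
    free_energy: float | None = None  # k_B T, min-shifted over clusters
    low_count: bool = False          # fewer than 2 members: C2 forced to 0

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class PoseClusterSet:
    clusters: list[PoseCluster]
    noise: np.ndarray                # frame indices in no cluster
    n_frames: int
    params: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def labels(self) -> np.ndarray:
        """Per-frame cluster id (−1 for noise)."""
        lab = np.full(self.n_frames, -1, dtype=int)
        for c in self.clusters:
            lab[c.members] = c.id
        return lab


def cluster_poses(pose_coords, eps: float, min_samples: int = 4,
                  sieve_stride: int = 1) -> PoseClusterSet:
    """Sieved DBSCAN clustering of per-frame ligand poses.

    Parameters
    ----------
    pose_coords:
        Array (n_frames, n_dims) of pose coordinates (a point ligand's
        position, or concatenated atom coordinates).
    eps, min_samples:
        DBSCAN radius and core-point neighbour count (Euclidean metric).
    sieve_stride:
        Cluster every ``sieve_stride``-th frame only; remaining frames are
        assigned to the nearest clustered sieved frame if within ``eps``,
        else to noise.
    """
    coords = np.asarray(pose_coords, dtype=float)
    if coords.ndim == 1:
        coords = coords[:, None]
    n = len(coords)
    if n == 0:
        raise ValueError("empty input: no poses to cluster")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if sieve_stride < 1:
        raise ValueError("sieve_stride must be >= 1")
    sieved_idx = np.arange(0, n, sieve_stride)
    if len(sieved_idx) < min_samples:
        raise ValueError(
            f"only {len(sieved_idx)} sieved frames for min_samples={min_samples}")

    db = DBSCAN(eps=eps, min_samples=min_samples).fit(coords[sieved_idx])
    sieved_labels = db.labels_

    labels = np.full(n, -1, dtype=int)
    labels[sieved_idx] = sieved_labels

    clustered = sieved_idx[sieved_labels >= 0]
    rest = np.setdiff1d(np.arange(n), sieved_idx, assume_unique=False)
    if len(clustered) and len(rest):
        tree = cKDTree(coords[clustered])
        k = min(8, len(clustered))
        dist, nn = tree.query(coords[rest], k=k)
        dist = np.atleast_2d(dist.T).T if k == 1 else dist
        nn = np.atleast_2d(nn.T).T if k == 1 else nn
        cand_labels = labels[clustered[nn]]
        for row in range(len(rest)):
            d0 = dist[row, 0]
            if d0 > eps:
                continue
            ties = np.isclose(dist[row], d0, rtol=0.0, atol=1e-12)
            labels[rest[row]] = int(cand_labels[row][ties].min())

    unique = sorted(set(sieved_labels) - {-1})
    clusters = []
    for cid in unique:
        members = np.flatnonzero(labels == cid)
        smem = sieved_idx[sieved_labels == cid]
        rep = _medoid(coords[smem])
        clusters.append(PoseCluster(
            id=int(cid),
            members=members,
            representative=rep,
            population=len(members) / n,
        ))
    noise = np.flatnonzero(labels == -1)
    return PoseClusterSet(
        clusters=clusters,
        noise=noise,
        n_frames=n,
        params={"eps": eps, "min_samples": min_samples,
                "sieve_stride": sieve_stride},
    )


def _medoid(points: np.ndarray) -> np.ndarray:
    """Point minimizing the summed Euclidean distance to the others.

    Computed over the sieved members only, which bounds the pairwise cost."""
    if len(points) == 1:
        return points[0].copy()
    from scipy.spatial.distance import cdist
    d = cdist(points, points)
    return points[int(d.sum(axis=1).argmin())].copy()


def cluster_free_energies(clusterset: PoseClusterSet, dv,
                          temperature: float = 1.0) -> PoseClusterSet:
    """Reweighted free energy per cluster (cluster = one histogram bin).

    Uses the order-2 cumulant factor on each cluster's member ΔV values:
    F*_c = −k_B T ln(size_c / n_frames), F_c = F*_c − (C1 + β C2 / 2),
    then min-shifts over clusters.  Clusters with fewer than two members get
    C2 = 0 and are flagged ``low_count``.
    """
    dv = np.asarray(dv, dtype=float)
    if len(dv) != clusterset.n_frames:
        raise ValueError("dV array must align with the clustered frames")
    if np.any(dv < 0):
        raise ValueError("boost potential values must be non-negative")
    beta = 1.0 / temperature
    raw = []
    flags = []
    for c in clusterset.clusters:
        vals = dv[c.members]
        c1 = float(vals.mean()) if len(vals) else 0.0
        if len(vals) >= 2:
            c2 = float(vals.var())
            flags.append(False)
        else:
            c2 = 0.0
            flags.append(True)
        f_star = -temperature * np.log(len(c.members) / clusterset.n_frames)
        raw.append(f_star - (c1 + 0.5 * beta * c2))
    raw = np.asarray(raw)
    raw -= raw.min()
    new_clusters = [replace(c, free_energy=float(f), low_count=fl)
                    for c, f, fl in zip(clusterset.clusters, raw, flags)]
    return PoseClusterSet(clusters=new_clusters, noise=clusterset.noise,
                          n_frames=clusterset.n_frames,
                          params=dict(clusterset.params,
                                      temperature=temperature))


def occupancy_series(pam_coords, site_center, site_radius: float) -> np.ndarray:
    """Per-frame 0/1 occupancy of an allosteric site.

    1 iff the PAM lies within ``site_radius`` of ``site_center`` (inclusive).
    """
    if site_radius <= 0:
        raise ValueError("site_radius must be positive")
    coords = np.atleast_2d(np.asarray(pam_coords, dtype=float))
    center = np.asarray(site_center, dtype=float)
    d = np.linalg.norm(coords - center, axis=1)
    return (d <= site_radius).astype(int)
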