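"""Chain-level condensate analytics for bead trajectories.

Two chains belong to the same cluster in a frame when any inter-chain bead
pair lies within a cutoff (default 7.5 A = 1.5x the nucleic bond length)
under the minimum-image convention; clusters are the connected components of
that chain graph.  Exchange dynamics are counted through migration matrices:
M_f = A_{f+1} - A_f, where A is the symmetric same-cluster adjacency matrix.
Positive entries mark arrivals, negative entries departures; to avoid
counting one chain's move once per partner, at most one arrival and one
departure are kept per row/column of M (deterministic greedy scan in
ascending row-then-column order over the upper triangle).

Shape analytics: per-chain gyration tensor metrics (Rg, end-to-end distance,
relative shape anisotropy kappa^2 in [0, 1]) and convex-hull Jaccard overlap
between frames of a tracked cluster, estimated by seeded Monte-Carlo
point-in-hull sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Delaunay

from .cgsim import Trajectory

__all__ = [
    "ClusterTimeline",
    "MigrationEvents",
    "ChainShape",
    "find_clusters",
    "build_timeline",
    "unwrap_clusters",
    "migration_events",
    "hull_jaccard",
    "chain_shape",
    "cluster_growth_series",
]

DEFAULT_CUTOFF = 7.5  # A, 1.5 x the 5.00 A nucleic bond length


def _min_image(d: np.ndarray, box: float) -> np.ndarray:
    if box > 0:
        d = d - box * np.round(d / box)
    return d


def find_clusters(positions: np.ndarray, chain_ids: np.ndarray, box: float,
                  cutoff: float = DEFAULT_CUTOFF,
                  include: np.ndarray | None = None) -> np.ndarray:
    """Per-chain cluster labels for one frame.

    `include` optionally masks beads (e.g. RNA-only analysis ignoring peptide
    beads); excluded chains get label -1.  Labels are canonical: clusters are
    numbered 0.. in order of their lowest chain id.
    """
    chain_ids = np.asarray(chain_ids)
    n_chains = int(chain_ids.max()) + 1
    mask = np.ones(len(chain_ids), bool) if include is None else np.asarray(include, bool)
    pos = positions[mask]
    cid = chain_ids[mask]
    chains = np.unique(cid)
    rows, cols = [], []
    groups = {c: pos[cid == c] for c in chains}
    for a_i, a in enumerate(chains):
        pa = groups[a]
        for b in chains[a_i + 1:]:
            d = _min_image(pa[:, None, :] - groups[b][None, :, :], box)
            if np.min(np.einsum("ijk,ijk->ij", d, d)) <= cutoff * cutoff:
                rows.append(a)
                cols.append(b)
    m = len(chains)
    lut = {c: i for i, c in enumerate(chains)}
    graph = csr_matrix((np.ones(len(rows)), ([lut[r] for r in rows],
                                             [lut[c] for c in cols])), shape=(m, m))
    _, comp = connected_components(graph, directed=False)
    # canonical renumbering by lowest chain id
    labels = np.full(n_chains, -1, dtype=int)
    order: dict[int, int] = {}
    for c in chains:
        k = comp[lut[c]]
        if k not in order:
            order[k] = len(order)
        labels[c] = order[k]
    return labels


@dataclass
class ClusterTimeline:
    """Per-frame chain-to-cluster partition of a trajectory."""

    labels: np.ndarray          # (n_frames, n_chains), -1 = excluded chain
    cutoff: float = DEFAULT_CUTOFF

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def cluster_sizes(self, frame: int) -> dict[int, int]:
        lab = self.labels[frame]
        vals, counts = np.unique(lab[lab >= 0], return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def n_clusters(self, frame: int) -> int:
        lab = self.labels[frame]
        return int(np.unique(lab[lab >= 0]).size)


def build_timeline(traj: Trajectory, cutoff: float = DEFAULT_CUTOFF,
                   rna_only: bool = False,
                   rna_types: tuple[str, ...] = ("A", "U", "C")) -> ClusterTimeline:
    """Cluster every frame of a trajectory.

    rna_only=True restricts the analysis to RNA beads, the computational
    analogue of contrast-matching away the peptide signal.
    """
    include = None
    if rna_only:
        include = np.array([t in rna_types for t in traj.bead_types])
    labels = np.stack([
        find_clusters(traj.frames[f], traj.chain_ids, traj.box_edge, cutoff, include)
        for f in range(traj.n_frames)])
    return ClusterTimeline(labels=labels, cutoff=cutoff)


def restrict_chains(timeline: ClusterTimeline, chains) -> ClusterTimeline:
    """Project a timeline onto a subset of chains (e.g. RNA strands within
    condensates that were identified from all chains): exchange counting then
    sees only those chains' same-cluster partnerships."""
    chains = np.asarray(chains, dtype=int)
    return ClusterTimeline(labels=timeline.labels[:, chains],
                           cutoff=timeline.cutoff)


# ---------------------------------------------------------------------------
# periodic unwrapping
# ---------------------------------------------------------------------------


def unwrap_clusters(traj: Trajectory, timeline: ClusterTimeline,
                    frame: int) -> dict[int, np.ndarray]:
    """Unwrap each cluster of one frame into contiguous coordinates.

    Chains are first made internally contiguous (consecutive-bead jumps folded
    by minimum image), then shifted by whole box lengths so each chain joins
    the cluster through its nearest periodic image.  A cluster whose extent
    reaches half the box (percolation) is flagged with a ValueError.
    """
    box = traj.box_edge
    pos = traj.frames[frame]
    chain_ids = traj.chain_ids
    labels = timeline.labels[frame]
    out: dict[int, np.ndarray] = {}
    for lab in np.unique(labels[labels >= 0]):
        chains = np.where(labels == lab)[0]
        unwrapped: dict[int, np.ndarray] = {}
        for c in chains:
            p = pos[chain_ids == c].copy()
            steps = _min_image(np.diff(p, axis=0), box)
            p[1:] = p[0] + np.cumsum(steps, axis=0)
            unwrapped[c] = p
        done = {chains[0]}
        pending = set(chains[1:])
        coords = [unwrapped[chains[0]]]
        while pending:
            best = None
            anchor = np.vstack([unwrapped[c] for c in done])
            for c in pending:
                d = unwrapped[c][:, None, :] - anchor[None, :, :]
                dmi = _min_image(d, box)
                r2 = np.einsum("ijk,ijk->ij", dmi, dmi)
                i, j = np.unravel_index(np.argmin(r2), r2.shape)
                if best is None or r2[i, j] < best[0]:
                    shift = dmi[i, j] - d[i, j]
                    best = (r2[i, j], c, shift)
            _, c, shift = best
            unwrapped[c] = unwrapped[c] + shift
            coords.append(unwrapped[c])
            done.add(c)
            pending.remove(c)
        allc = np.vstack(coords)
        if np.any(allc.max(0) - allc.min(0) >= box):
            import warnings

            warnings.warn(f"cluster {lab} spans the box (percolation); "
                          "unwrapped coordinates are not unique", RuntimeWarning)
        out[int(lab)] = allc
    return out


# ---------------------------------------------------------------------------
# exchange events
# ---------------------------------------------------------------------------


@dataclass
class MigrationEvents:
    """Deduplicated arrival/departure events between consecutive frames."""

    arrivals: list[tuple[int, int, int]]    # (frame, chain, partner chain)
    departures: list[tuple[int, int, int]]
    total_arrivals: int
    total_departures: int


def _adjacency(labels_frame: np.ndarray) -> np.ndarray:
    lab = labels_frame
    n = lab.size
    a = (lab[:, None] == lab[None, :]) & (lab[:, None] >= 0)
    a = a.astype(np.int8)
    a[np.arange(n), np.arange(n)] = 1
    return a


def migration_events(timeline: ClusterTimeline) -> MigrationEvents:
    """Arrival/departure counting through migration matrices M = A_{f+1} - A_f.

    A positive entry marks an arrival, a negative one a departure.  At most one
    arrival and one departure are counted per row/column of each M (greedy
    ascending scan of the upper triangle), so a chain joining a k-chain cluster
    scores one arrival, not k.
    """
    if timeline.n_frames < 2:
        raise ValueError("need at least 2 frames")
    arrivals, departures = [], []
    for f in range(timeline.n_frames - 1):
        m = _adjacency(timeline.labels[f + 1]).astype(np.int8) - \
            _adjacency(timeline.labels[f]).astype(np.int8)
        for sign, store in ((1, arrivals), (-1, departures)):
            used_r, used_c = set(), set()
            ii, jj = np.nonzero(np.triu(m, 1) == sign)
            for i, j in zip(ii.tolist(), jj.tolist()):
                if i in used_r or j in used_c or j in used_r or i in used_c:
                    continue
                store.append((f, i, j))
                used_r.add(i)
                used_c.add(j)
    return MigrationEvents(arrivals=arrivals, departures=departures,
                           total_arrivals=len(arrivals),
                           total_departures=len(departures))


# ---------------------------------------------------------------------------
# shape metrics
# ---------------------------------------------------------------------------


@dataclass
class ChainShape:
    Rg: float
    REE: float
    kappa2: float
    eigenvalues: np.ndarray


def chain_shape(coords: np.ndarray) -> ChainShape:
    """Gyration-tensor size and shape metrics of one (unwrapped) chain.

    kappa^2 = 1 - 3 (l1 l2 + l2 l3 + l3 l1) / (l1 + l2 + l3)^2 is the relative
    shape anisotropy: 0 for isotropic mass distributions, 1 for a rod.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 beads")
    centered = coords - coords.mean(axis=0)
    s = centered.T @ centered / coords.shape[0]
    lam = np.sort(np.linalg.eigvalsh(s))[::-1]
    tr = lam.sum()
    kappa2 = 0.0 if tr == 0 else 1.0 - 3.0 * (lam[0] * lam[1] + lam[1] * lam[2]
                                              + lam[2] * lam[0]) / (tr * tr)
    return ChainShape(Rg=float(np.sqrt(tr)),
                      REE=float(np.linalg.norm(coords[-1] - coords[0])),
                      kappa2=float(np.clip(kappa2, 0.0, 1.0)),
                      eigenvalues=lam)


def hull_jaccard(points_a: np.ndarray, points_b: np.ndarray,
                 n_samples: int = 100_000, seed: int = 0,
                 align_com: bool = False) -> float:
    """Convex-hull volume overlap |A ∩ B| / |A ∪ B| of two point clouds.

    Estimated by uniform Monte-Carlo sampling over the joint bounding box with
    point-in-hull tests (Delaunay).  align_com=True superposes the centers of
    mass first (shape-only comparison); the default compares hulls in place.
    """
    a = np.asarray(points_a, dtype=float)
    b = np.asarray(points_b, dtype=float)
    if align_com:
        b = b - b.mean(0) + a.mean(0)
    for pts in (a, b):
        if pts.shape[0] < 4:
            raise ValueError("need at least 4 points per hull")
    try:
        ConvexHull(a), ConvexHull(b)
        da, db = Delaunay(a), Delaunay(b)
    except Exception as exc:  # qhull degeneracy
        raise ValueError(f"degenerate hull: {exc}") from exc
    lo = np.minimum(a.min(0), b.min(0))
    hi = np.maximum(a.max(0), b.max(0))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, 3))
    in_a = da.find_simplex(pts) >= 0
    in_b = db.find_simplex(pts) >= 0
    union = np.count_nonzero(in_a | in_b)
    if union == 0:
        return 0.0
    return float(np.count_nonzero(in_a & in_b) / union)


# ---------------------------------------------------------------------------
# growth series with identity tracking
# ---------------------------------------------------------------------------


def cluster_growth_series(timeline: ClusterTimeline, return_labels: bool = False):
    """Per-cluster size vs time with identity tracked by maximal overlap.

    Cluster identity across frames follows the greatest membership overlap
    with the previous frame (ties to the lower previous id); clusters without
    an overlap start a new track.  Returns (tracks, n_clusters_per_frame)
    where tracks maps track id -> {frame: size}; with return_labels=True a
    third mapping track id -> {frame: cluster label} is appended.
    """
    labels = timeline.labels
    n_frames = labels.shape[0]
    tracks: dict[int, dict[int, int]] = {}
    track_labels: dict[int, dict[int, int]] = {}
    next_track = 0
    prev_track_of: dict[int, int] = {}
    for f in range(n_frames):
        lab = labels[f]
        cur_ids = np.unique(lab[lab >= 0])
        cur_track_of: dict[int, int] = {}
        claimed: set[int] = set()
        for cid in cur_ids:
            members = set(np.where(lab == cid)[0].tolist())
            best_t, best_ov = None, 0
            if f > 0:
                prev = labels[f - 1]
                ov: dict[int, int] = {}
                for ch in members:
                    p = prev[ch]
                    if p >= 0:
                        ov[p] = ov.get(p, 0) + 1
                for pid in sorted(ov):
                    t = prev_track_of.get(int(pid))
                    if t is None or t in claimed:
                        continue
                    if ov[pid] > best_ov:
                        best_ov, best_t = ov[pid], t
            if best_t is None:
                best_t = next_track
                next_track += 1
            claimed.add(best_t)
            cur_track_of[int(cid)] = best_t
            tracks.setdefault(best_t, {})[f] = len(members)
            track_labels.setdefault(best_t, {})[f] = int(cid)
        prev_track_of = cur_track_of
    n_per_frame = np.array([timeline.n_clusters(f) for f in range(n_frames)])
    if return_labels:
        return tracks, n_per_frame, track_labels
    return tracks, n_per_frame
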