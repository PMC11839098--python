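"""Synthetic ground-truth generators.

Everything downstream of the experimental inputs (scattering profiles of
disordered 30-mers, bead trajectories of clustering chains) can be exercised
against data whose truth is known exactly: parametric helices and freely
jointed chains with closed-form orientation statistics, noise-perturbed
profiles with a known error law, and scripted trajectories whose cluster
membership at every frame is prescribed, so migration analytics can be checked
event-for-event.

Synthetic chains carry a single pseudo-atom per residue labelled as phosphorus,
so the order-parameter code paths are shared with all-atom structures.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chains import Conformer
from .saxs import ScatteringProfile

__all__ = [
    "NoiseModel",
    "TrajectoryScript",
    "ScriptEvent",
    "gen_ideal_helix",
    "gen_random_coil",
    "gen_noisy_profile",
    "gen_scripted_trajectory",
    "helix_ocf_closed_form",
]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------


def _p_chain(coords: np.ndarray) -> Conformer:
    n = coords.shape[0]
    return Conformer(elements=np.full(n, "P"), res_idx=np.arange(n),
                     atom_names=np.full(n, "P"), coords=coords)


def gen_ideal_helix(n_residues: int, rise: float, twist: float,
                    radius: float) -> Conformer:
    """Backbone pseudo-atoms on an exact circular helix.

    residue k sits at (radius*cos(k*twist), radius*sin(k*twist), k*rise);
    twist in degrees per residue, rise and radius in Angstrom.  twist = 0 with
    radius = 0 degenerates to a straight rod of spacing `rise`.
    """
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    if rise <= 0:
        raise ValueError("rise must be positive")
    if radius < 0:
        raise ValueError("radius must be nonnegative")
    k = np.arange(n_residues)
    phi = np.radians(twist) * k
    coords = np.column_stack([radius * np.cos(phi), radius * np.sin(phi), rise * k])
    return _p_chain(coords)


def helix_ocf_closed_form(s: np.ndarray, rise: float, twist: float,
                          radius: float) -> np.ndarray:
    """Analytic bond-orientation correlation of the parametric helix.

    cos(theta(s)) = [2 R^2 (1-cos(phi)) cos(s*phi) + h^2] /
                    [2 R^2 (1-cos(phi)) + h^2]  with phi the twist per residue.
    """
    phi = np.radians(twist)
    a = 2.0 * radius * radius * (1.0 - np.cos(phi))
    return (a * np.cos(np.asarray(s) * phi) + rise * rise) / (a + rise * rise)


def gen_random_coil(n_residues: int, bond_length: float = 5.9,
                    seed: int = 0) -> Conformer:
    """Freely jointed chain: fixed bond length, isotropic random directions."""
    if n_residues < 2:
        raise ValueError("need at least 2 residues")
    rng = np.random.default_rng(seed)
    v = rng.normal(size=(n_residues - 1, 3))
    v *= bond_length / np.linalg.norm(v, axis=1)[:, None]
    coords = np.vstack([np.zeros(3), np.cumsum(v, axis=0)])
    return _p_chain(coords)


# ---------------------------------------------------------------------------
# noisy profiles
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise law for synthetic profiles.

    kind="gaussian-proportional": sigma is a relative fraction of I(q)
    (2% is a typical synchrotron-like relative error and the default).
    kind="gaussian-constant": sigma is an absolute intensity.
    """

    kind: str = "gaussian-proportional"
    sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("gaussian-constant", "gaussian-proportional"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")


def gen_noisy_profile(true_profile: ScatteringProfile,
                      noise: NoiseModel) -> ScatteringProfile:
    """Perturb a noise-free profile according to the noise model.

    The sigma column of the output is filled with the model's per-point
    standard deviation, so chi-square statistics against the truth are
    calibrated by construction.  Identical seeds give identical draws.
    """
    if np.any(true_profile.I <= 0):
        raise ValueError("true profile must have positive intensities")
    rng = np.random.default_rng(noise.seed)
    if noise.kind == "gaussian-proportional":
        sig = noise.sigma * true_profile.I
    else:
        sig = np.full_like(true_profile.I, noise.sigma)
    I = true_profile.I + rng.standard_normal(true_profile.I.size) * sig
    return ScatteringProfile(q=true_profile.q.copy(), I=I, sigma=sig.copy())


# ---------------------------------------------------------------------------
# scripted trajectories
# ---------------------------------------------------------------------------

SOLUTION = "solution"


@dataclass(frozen=True)
class ScriptEvent:
    """One scripted membership change: at `frame`, `chain` leaves `source`
    (a cluster id or "solution") and joins `dest`."""

    frame: int
    chain: int
    source: int | str
    dest: int | str


@dataclass
class TrajectoryScript:
    """Prescribed chain-to-cluster membership history.

    `initial` maps each chain to a cluster id or "solution"; events are applied
    in frame order.  A chain occupies exactly one cluster or solution at every
    frame; event frames must lie strictly inside the trajectory.
    """

    n_chains: int
    n_frames: int
    box_edge: float
    initial: dict[int, int | str] = field(default_factory=dict)
    events: list[ScriptEvent] = field(default_factory=list)

    def __post_init__(self):
        for c in range(self.n_chains):
            self.initial.setdefault(c, SOLUTION)
        if set(self.initial) != set(range(self.n_chains)):
            raise ValueError("initial membership must cover chains 0..n_chains-1")
        state = dict(self.initial)
        for ev in sorted(self.events, key=lambda e: e.frame):
            if not (0 < ev.frame < self.n_frames):
                raise ValueError(f"event frame {ev.frame} outside (0, {self.n_frames})")
            if state[ev.chain] != ev.source:
                raise ValueError(
                    f"event at frame {ev.frame}: chain {ev.chain} is in "
                    f"{state[ev.chain]}, not {ev.source}")
            if ev.source == ev.dest:
                raise ValueError("event source and destination coincide")
            state[ev.chain] = ev.dest

    def membership(self) -> list[dict[int, int | str]]:
        """Per-frame chain -> cluster-or-solution mapping."""
        state = dict(self.initial)
        by_frame: dict[int, list[ScriptEvent]] = {}
        for ev in self.events:
            by_frame.setdefault(ev.frame, []).append(ev)
        frames = []
        for f in range(self.n_frames):
            for ev in by_frame.get(f, []):
                state[ev.chain] = ev.dest
            frames.append(dict(state))
        return frames

    def to_json(self, path: str | Path) -> None:
        doc = {
            "n_chains": self.n_chains, "n_frames": self.n_frames,
            "box_edge": self.box_edge,
            "initial": {str(k): v for k, v in self.initial.items()},
            "events": [[e.frame, e.chain, e.source, e.dest] for e in self.events],
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrajectoryScript":
        doc = json.loads(Path(path).read_text())
        return cls(n_chains=doc["n_chains"], n_frames=doc["n_frames"],
                   box_edge=doc["box_edge"],
                   initial={int(k): v for k, v in doc["initial"].items()},
                   events=[ScriptEvent(*e) for e in doc["events"]])

    @classmethod
    def random(cls, n_chains: int, n_frames: int, n_events: int,
               n_clusters: int, box_edge: float, seed: int = 0,
               min_cluster_size: int = 2) -> "TrajectoryScript":
        """Random feasible script: one event per frame, clusters never drop
        below `min_cluster_size` members (so a membership change is a genuine
        migration, not a cluster death)."""
        if n_events > n_frames - 2:
            raise ValueError("at most one event per interior frame")
        rng = np.random.default_rng(seed)
        sites: list[int | str] = list(range(n_clusters)) + [SOLUTION]
        initial: dict[int, int | str] = {}
        # seed every cluster above the floor, put the rest in solution
        c = 0
        for cl in range(n_clusters):
            for _ in range(min_cluster_size + 1):
                initial[c] = cl
                c += 1
        if c > n_chains:
            raise ValueError("not enough chains to populate the clusters")
        for rest in range(c, n_chains):
            initial[rest] = SOLUTION
        state = dict(initial)
        frames = rng.choice(np.arange(1, n_frames - 1), size=n_events, replace=False)
        events = []
        for f in sorted(int(x) for x in frames):
            for _ in range(1000):
                ch = int(rng.integers(n_chains))
                src = state[ch]
                if src != SOLUTION:
                    members = sum(1 for v in state.values() if v == src)
                    if members <= min_cluster_size:
                        continue
                dest = sites[int(rng.integers(len(sites)))]
                if dest == src:
                    continue
                events.append(ScriptEvent(f, ch, src, dest))
                state[ch] = dest
                break
            else:  # pragma: no cover - generator safeguard
                raise RuntimeError("could not draw a feasible event")
        return cls(n_chains=n_chains, n_frames=n_frames, box_edge=box_edge,
                   initial=initial, events=events)

    def count_events(self) -> tuple[int, int]:
        """(arrivals, departures) implied by the script.

        Joining a cluster is an arrival; leaving one is a departure; moves to
        or from solution contribute only their cluster-side event."""
        arr = sum(1 for e in self.events if e.dest != SOLUTION)
        dep = sum(1 for e in self.events if e.source != SOLUTION)
        return arr, dep


def gen_scripted_trajectory(script: TrajectoryScript, beads_per_chain: int = 4,
                            cluster_spacing: float | None = None,
                            cutoff: float = 7.5):
    """Deterministic bead trajectory realizing the scripted memberships.

    Cluster centres sit on a cubic grid separated by much more than `cutoff`;
    chains inside a cluster sit on a sub-grid with spacing 0.8*cutoff, and each
    chain is a compact bead blob of ~1 A extent, so chain-level clustering at
    `cutoff` reproduces the scripted membership exactly at every frame.
    Solution chains occupy their own widely spaced grid.

    Raises ValueError when the requested geometry cannot honour the cutoff
    inside the scripted box.
    """
    from .cgsim import Trajectory

    sub = 0.8 * cutoff if cluster_spacing is None else cluster_spacing
    if sub >= cutoff:
        raise ValueError(
            f"intra-cluster chain spacing {sub} must be below the cutoff {cutoff}")
    membership = script.membership()
    sites = sorted({v for fr in membership for v in fr.values()},
                   key=lambda s: (s == SOLUTION, s))
    # worst-case site: all chains on one sub-grid (solution sites are sparser)
    m = int(np.ceil(script.n_chains ** (1 / 3)))
    extent = (m - 1) * max(sub, 3.0 * cutoff) + 4.0
    pitch = extent + 4.0 * cutoff
    g = int(np.ceil(len(sites) ** (1 / 3)))
    if g * pitch > script.box_edge:
        raise ValueError(
            f"cannot place {len(sites)} sites with pitch {pitch:.1f} A in a "
            f"{script.box_edge:.1f} A box without violating the cutoff")
    site_center = {}
    for i, s in enumerate(sites):
        iz, rem = divmod(i, g * g)
        iy, ix = divmod(rem, g)
        site_center[s] = np.array([ix, iy, iz]) * pitch + pitch / 2.0

    # compact blob offsets for one chain (~1 A extent)
    bb = int(np.ceil(beads_per_chain ** (1 / 3)))
    offs = []
    for i in range(beads_per_chain):
        iz, rem = divmod(i, bb * bb)
        iy, ix = divmod(rem, bb)
        offs.append([ix, iy, iz])
    blob = (np.array(offs, dtype=float) - np.mean(offs, axis=0)) * (1.0 / max(bb - 1, 1))

    n_beads = script.n_chains * beads_per_chain
    chain_ids = np.repeat(np.arange(script.n_chains), beads_per_chain)
    frames = np.empty((script.n_frames, n_beads, 3))
    for f, state in enumerate(membership):
        # deterministic packing: chains at a site sorted by id onto the sub-grid
        by_site: dict[object, list[int]] = {}
        for ch in range(script.n_chains):
            by_site.setdefault(state[ch], []).append(ch)
        for s, members in by_site.items():
            spacing = sub if s != SOLUTION else 3.0 * cutoff
            for rank, ch in enumerate(sorted(members)):
                iz, rem = divmod(rank, m * m)
                iy, ix = divmod(rem, m)
                center = site_center[s] + np.array([ix, iy, iz]) * spacing
                frames[f, chain_ids == ch] = center + blob
    times = np.arange(script.n_frames, dtype=float)
    return Trajectory(frames=frames, chain_ids=chain_ids,
                      box_edge=script.box_edge, times=times)
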