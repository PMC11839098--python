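"""Residue-level coarse-grained Langevin dynamics of RNA + peptide chains.

One bead per nucleotide or amino acid.  Consecutive beads are joined by a
harmonic bond E = sum K (r - r_ref)^2 (note: no 1/2 factor) with
K = 9.6 kJ/(mol A^2) and r_ref = 5.00 A for nucleic chains, 3.81 A for amino
chains.  Electrostatics are screened Coulomb (Debye-Hueckel),
E = sum q_i q_j e^2/(4 pi eps_r eps_0 r) * exp(-kappa r), with the inverse
screening length kappa = sqrt(c_Na)/3.06 1/A for a monovalent salt
concentration c_Na in mol/L.  Base/sidechain "sticker" contacts use the
Wang-Frenkel potential, a finite-range well that is exactly zero at its
cutoff and reaches -eps at its analytic minimum.

Internal units: Angstrom, amu, kJ/mol; the derived time unit is 0.1 ps.
Integration is BAOAB Langevin with friction 1/tau (tau = the stated
relaxation time); with zero friction it reduces to velocity Verlet.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit

__all__ = [
    "ForceField",
    "CGSystem",
    "SimConfig",
    "Trajectory",
    "kappa_from_salt",
    "bonded_energy",
    "dh_energy",
    "wang_frenkel_energy",
    "wf_potential",
    "wf_minimum_location",
    "init_lattice",
    "make_system",
    "run_langevin",
    "desk_preset",
]

KB = 0.00831446  # kJ/(mol K)
COULOMB = 1389.35  # e^2/(4 pi eps0) * N_A, in kJ A / mol
TIME_UNIT_PS = 0.1  # one internal time unit in ps
FORCE_BLOWUP = 1.0e5  # kJ/(mol A); any larger |F| aborts the run


def kappa_from_salt(c_na: float) -> float:
    """Inverse Debye screening length kappa = sqrt(c_Na)/3.06 in 1/A.

    c_Na is the monovalent salt concentration in mol/L; c_Na = 0 recovers the
    unscreened Coulomb limit.
    """
    if c_na < 0:
        raise ValueError("salt concentration must be nonnegative")
    return float(np.sqrt(c_na) / 3.06)


# ---------------------------------------------------------------------------
# force field
# ---------------------------------------------------------------------------


@dataclass
class ForceField:
    """Parameter tables resolved to dense per-type arrays."""

    type_names: list[str]
    masses: np.ndarray          # (T,)
    charges: np.ndarray         # (T,)
    classes: list[str]          # per type: "nucleic" | "amino"
    K: float
    rref: dict[str, float]
    epsilon_r: float
    coulomb_cutoff: float
    kappa: float                # 1/A, set from the salt concentration
    wf_eps: np.ndarray          # (T, T) well depths, kJ/mol
    wf_sigma: np.ndarray        # (T, T)
    wf_mu: float
    wf_nu: float
    wf_rc: np.ndarray           # (T, T)

    def scaled_stickers(self, factor: float) -> "ForceField":
        """Copy of the force field with all Wang-Frenkel well depths scaled."""
        import copy

        out = copy.copy(self)
        out.wf_eps = self.wf_eps * float(factor)
        return out

    def type_index(self, names) -> np.ndarray:
        lut = {n: i for i, n in enumerate(self.type_names)}
        return np.array([lut[n] for n in names], dtype=np.int64)

    @classmethod
    def load(cls, source: str | Path = "default", kappa: float = 0.0) -> "ForceField":
        """Load the bead/pair tables from JSON (or the shipped synthetic default)."""
        if source == "default":
            ref = importlib.resources.files("condensaxs.data") / "forcefield_synthetic.json"
            doc = json.loads(ref.read_text())
        else:
            doc = json.loads(Path(source).read_text())
        beads = doc["beads"]
        names = list(beads)
        t = len(names)
        masses = np.array([beads[n]["mass"] for n in names], dtype=float)
        charges = np.array([beads[n]["charge"] for n in names], dtype=float)
        classes = [beads[n]["class"] for n in names]
        wf = doc["wang_frenkel"]
        sig1 = np.array([wf["sigma"][n] for n in names], dtype=float)
        sigma = 0.5 * (sig1[:, None] + sig1[None, :])
        eps = np.zeros((t, t))
        for key, val in wf["epsilon_pairs"].items():
            a, b = key.split("-")
            i, j = names.index(a), names.index(b)
            eps[i, j] = eps[j, i] = float(val)
        if np.any(eps == 0):
            missing = [(names[i], names[j]) for i in range(t) for j in range(i, t)
                       if eps[i, j] == 0]
            raise ValueError(f"missing Wang-Frenkel pair parameters for {missing}")
        rc = wf["rc_over_sigma"] * sigma
        return cls(type_names=names, masses=masses, charges=charges, classes=classes,
                   K=float(doc["harmonic"]["K"]), rref=dict(doc["harmonic"]["rref"]),
                   epsilon_r=float(doc["electrostatics"]["epsilon_r"]),
                   coulomb_cutoff=float(doc["electrostatics"]["cutoff"]),
                   kappa=float(kappa), wf_eps=eps, wf_sigma=sigma,
                   wf_mu=float(wf["mu"]), wf_nu=float(wf["nu"]), wf_rc=rc)


def _wf_alpha(sigma, rc, mu, nu):
    x = (rc / sigma) ** (2 * mu)
    return 2 * nu * x * ((1 + 2 * nu) / (2 * nu * (x - 1))) ** (2 * nu + 1)


def wf_potential(r, eps, sigma, mu=2.0, nu=1.0, rc=None):
    """Wang-Frenkel pair potential; exactly zero at and beyond rc (default 3*sigma)."""
    rc = 3.0 * sigma if rc is None else rc
    r = np.asarray(r, dtype=float)
    alpha = _wf_alpha(sigma, rc, mu, nu)
    x = (sigma / r) ** (2 * mu)
    y = (rc / r) ** (2 * mu)
    u = eps * alpha * (x - 1.0) * (y - 1.0) ** (2 * nu)
    return np.where(r >= rc, 0.0, u)


def wf_minimum_location(sigma, mu=2.0, nu=1.0, rc=None) -> float:
    """Analytic location of the Wang-Frenkel minimum (where U = -eps)."""
    rc = 3.0 * sigma if rc is None else rc
    x = (rc / sigma) ** (2 * mu)
    return float(rc * ((1 + 2 * nu) / (1 + 2 * nu * x)) ** (1 / (2 * mu)))


# ---------------------------------------------------------------------------
# system and trajectory containers
# ---------------------------------------------------------------------------


@dataclass
class CGSystem:
    """Bead chains with constant topology in a periodic cubic box."""

    positions: np.ndarray       # (n, 3)
    bead_types: list[str]       # per bead
    chain_ids: np.ndarray       # (n,)
    box_edge: float

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def bonds(self) -> np.ndarray:
        """(nb, 2) indices of consecutive beads within each chain."""
        idx = np.arange(self.n_beads - 1)
        same = self.chain_ids[idx] == self.chain_ids[idx + 1]
        return np.column_stack([idx[same], idx[same] + 1])


@dataclass
class SimConfig:
    """Integration settings.  Times: dt in fs, relaxation time in ps."""

    box_edge: float
    n_steps: int
    dt_fs: float = 10.0
    temperature: float = 298.0
    relaxation_ps: float = 100.0
    c_na: float = 0.15
    seed: int = 0
    save_stride: int = 100


@dataclass
class Trajectory:
    """Frame-wise bead coordinates (wrapped into the box)."""

    frames: np.ndarray          # (nf, n, 3)
    chain_ids: np.ndarray       # (n,)
    box_edge: float
    times: np.ndarray           # (nf,) in ps
    bead_types: list[str] = field(default_factory=list)
    temperatures: np.ndarray | None = None  # kinetic T at each saved frame

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_chains(self) -> int:
        return int(self.chain_ids.max()) + 1

    def write_xyz(self, path: str | Path) -> None:
        """Multi-frame extended XYZ: name x y z chain_id, box edge in the comment."""
        n = self.frames.shape[1]
        names = self.bead_types or ["X"] * n
        with open(path, "w") as fh:
            for f in range(self.n_frames):
                fh.write(f"{n}\n")
                fh.write(f"box_edge={self.box_edge} time_ps={self.times[f]}\n")
                for i in range(n):
                    x, y, z = self.frames[f, i]
                    fh.write(f"{names[i]} {x:.6f} {y:.6f} {z:.6f} {self.chain_ids[i]}\n")

    @classmethod
    def read_xyz(cls, path: str | Path) -> "Trajectory":
        frames, times, chain_ids, names = [], [], None, None
        with open(path) as fh:
            while True:
                header = fh.readline()
                if not header.strip():
                    break
                n = int(header)
                comment = fh.readline().split()
                meta = dict(kv.split("=") for kv in comment if "=" in kv)
                box = float(meta.get("box_edge", 0.0))
                times.append(float(meta.get("time_ps", len(times))))
                rows = [fh.readline().split() for _ in range(n)]
                frames.append([[float(r[1]), float(r[2]), float(r[3])] for r in rows])
                if chain_ids is None:
                    names = [r[0] for r in rows]
                    chain_ids = np.array([int(r[4]) for r in rows])
        return cls(frames=np.array(frames), chain_ids=chain_ids, box_edge=box,
                   times=np.array(times), bead_types=names)

    def write_hdf5(self, path: str | Path) -> None:
        import h5py

        with h5py.File(path, "w") as h5:
            h5.create_dataset("frames", data=self.frames)
            h5.create_dataset("chain_ids", data=self.chain_ids)
            h5.create_dataset("times", data=self.times)
            h5.attrs["box_edge"] = self.box_edge
            h5.create_dataset("bead_types",
                              data=np.array(self.bead_types, dtype="S4"))

    @classmethod
    def read_hdf5(cls, path: str | Path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as h5:
            return cls(frames=h5["frames"][...], chain_ids=h5["chain_ids"][...],
                       box_edge=float(h5.attrs["box_edge"]), times=h5["times"][...],
                       bead_types=[b.decode() for b in h5["bead_types"][...]])


# ---------------------------------------------------------------------------
# energies and forces (numba kernels + thin wrappers)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _min_image(d, box):  # pragma: no cover - jitted
    if box > 0.0:
        for k in range(3):
            d[k] -= box * np.round(d[k] / box)
    return d


@njit(cache=True)
def _energy_forces(pos, box, charges, tidx, chain_ids, bonds, bond_rref, K,
                   coul_pref, kappa, coul_cut, wf_eps, wf_sigma, wf_mu, wf_nu,
                   wf_rc, wf_alpha, forces):  # pragma: no cover - jitted
    n = pos.shape[0]
    e_bond = 0.0
    e_dh = 0.0
    e_wf = 0.0
    d = np.empty(3)
    for b in range(bonds.shape[0]):
        i, j = bonds[b, 0], bonds[b, 1]
        for k in range(3):
            d[k] = pos[i, k] - pos[j, k]
        _min_image(d, box)
        r = np.sqrt(d[0] * d[0] + d[1] * d[1] + d[2] * d[2])
        dr = r - bond_rref[b]
        e_bond += K * dr * dr
        fs = -2.0 * K * dr / r
        for k in range(3):
            forces[i, k] += fs * d[k]
            forces[j, k] -= fs * d[k]
    max_cut2 = max(coul_cut, np.max(wf_rc)) ** 2
    for i in range(n):
        for j in range(i + 1, n):
            if chain_ids[i] == chain_ids[j] and j == i + 1:
                continue  # bonded pair: excluded from nonbonded terms
            for k in range(3):
                d[k] = pos[i, k] - pos[j, k]
            _min_image(d, box)
            r2 = d[0] * d[0] + d[1] * d[1] + d[2] * d[2]
            if r2 > max_cut2:
                continue
            r = np.sqrt(r2)
            if r < 1e-6:
                return 1.0e30, e_dh, e_wf  # overlapping beads: poisoned energy
            fs = 0.0
            qq = charges[i] * charges[j]
            if qq != 0.0 and r < coul_cut:
                e = coul_pref * qq / r * np.exp(-kappa * r)
                e_dh += e
                fs += e * (1.0 / r + kappa) / r
            ti, tj = tidx[i], tidx[j]
            rc = wf_rc[ti, tj]
            if r < rc:
                eps = wf_eps[ti, tj]
                if eps != 0.0:
                    sig = wf_sigma[ti, tj]
                    al = wf_alpha[ti, tj]
                    if wf_mu == 2.0 and wf_nu == 1.0:
                        s2 = sig * sig / r2
                        x = s2 * s2
                        c2 = rc * rc / r2
                        y = c2 * c2
                        ym1 = y - 1.0
                        e_wf += eps * al * (x - 1.0) * ym1 * ym1
                        dx = -4.0 * x / r
                        dy = -4.0 * y / r
                        du = eps * al * (dx * ym1 * ym1 +
                                         (x - 1.0) * 2.0 * ym1 * dy)
                    else:
                        x = (sig / r) ** (2.0 * wf_mu)
                        y = (rc / r) ** (2.0 * wf_mu)
                        ym = (y - 1.0) ** (2.0 * wf_nu)
                        e_wf += eps * al * (x - 1.0) * ym
                        dx = -2.0 * wf_mu * x / r
                        dy = -2.0 * wf_mu * y / r
                        du = eps * al * (dx * ym + (x - 1.0) * 2.0 * wf_nu *
                                         (y - 1.0) ** (2.0 * wf_nu - 1.0) * dy)
                    fs += -du / r
            for k in range(3):
                forces[i, k] += fs * d[k]
                forces[j, k] -= fs * d[k]
    return e_bond, e_dh, e_wf


def _kernel_args(system: CGSystem, ff: ForceField):
    tidx = ff.type_index(system.bead_types)
    charges = ff.charges[tidx]
    bonds = system.bonds()
    rref = np.array([ff.rref[ff.classes[tidx[i]]] for i, _ in bonds])
    alpha = _wf_alpha(ff.wf_sigma, ff.wf_rc, ff.wf_mu, ff.wf_nu)
    return tidx, charges, bonds, rref, alpha


def compute_energy_forces(system: CGSystem, ff: ForceField):
    """Total potential terms and per-bead forces.

    Returns (energies dict with 'bond', 'dh', 'wf', and forces (n, 3))."""
    tidx, charges, bonds, rref, alpha = _kernel_args(system, ff)
    forces = np.zeros_like(system.positions)
    eb, ed, ew = _energy_forces(
        np.ascontiguousarray(system.positions), float(system.box_edge), charges,
        tidx, system.chain_ids, bonds, rref, ff.K, COULOMB / ff.epsilon_r,
        ff.kappa, ff.coulomb_cutoff, ff.wf_eps, ff.wf_sigma, ff.wf_mu,
        ff.wf_nu, ff.wf_rc, alpha, forces)
    if eb >= 1.0e30:
        raise FloatingPointError("overlapping beads (r < 1e-6 A)")
    return {"bond": eb, "dh": ed, "wf": ew}, forces


def bonded_energy(system: CGSystem, ff: ForceField) -> float:
    """Harmonic bond energy sum K (r - r_ref)^2 over consecutive beads."""
    return compute_energy_forces(system, ff)[0]["bond"]


def dh_energy(system: CGSystem, ff: ForceField) -> float:
    """Screened-Coulomb pair energy (minimum image, spherical cutoff)."""
    return compute_energy_forces(system, ff)[0]["dh"]


def wang_frenkel_energy(system: CGSystem, ff: ForceField) -> float:
    """Wang-Frenkel sticker pair energy (minimum image, per-pair cutoff)."""
    return compute_energy_forces(system, ff)[0]["wf"]


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


def init_lattice(n_rna: int, n_peptide: int, beads_per_chain: int, box: float,
                 rna_type: str = "U", peptide_types: tuple[str, str] = ("P", "R"),
                 conformation: str = "straight",
                 rref: dict[str, float] | None = None) -> CGSystem:
    """Chains equally spaced on a cubic lattice, deterministic order (RNA first).

    conformation="straight": each chain is a straight segment along z through
    its lattice site; layers are staggered laterally by 2.5 A per z-level when
    chains are longer than the lattice spacing so that no inter-chain bead
    pair starts closer than 2 A.  Chains longer than half the box are rejected
    (they would self-overlap through the periodic boundary).
    conformation="coil": a compact deterministic helix around the site (used by
    the desk-scale preset where the box is much smaller than a straight chain).
    """
    rref = rref or {"nucleic": 5.0, "amino": 3.81}
    n_chains = n_rna + n_peptide
    side = int(np.ceil(n_chains ** (1 / 3)))
    spacing = box / side
    if spacing <= 4.0:
        raise ValueError("overfilled box: lattice spacing below bead size")
    positions = []
    bead_types: list[str] = []
    chain_ids = []
    for c in range(n_chains):
        is_rna = c < n_rna
        b = rref["nucleic"] if is_rna else rref["amino"]
        iz, rem = divmod(c, side * side)
        iy, ix = divmod(rem, side)
        center = (np.array([ix, iy, iz]) + 0.5) * spacing
        if conformation == "straight":
            extent = (beads_per_chain - 1) * b
            if extent >= box / 2:
                raise ValueError(
                    f"straight chain of extent {extent:.0f} A does not fit in "
                    f"box {box:.0f} A; use conformation='coil'")
            if extent >= spacing - 2.0:
                center = center + np.array([2.5 * iz, 2.5 * iz, 0.0])
            k = np.arange(beads_per_chain) - (beads_per_chain - 1) / 2
            xyz = center + np.outer(k * b, np.array([0.0, 0.0, 1.0]))
        elif conformation == "coil":
            # compact serpentine walk on a k^3 grid of pitch b: consecutive
            # beads exactly one bond apart, chain extent ~ (k-1)*b
            side3 = int(np.ceil(beads_per_chain ** (1 / 3)))
            pts = []
            for gz in range(side3):
                ys = range(side3) if gz % 2 == 0 else range(side3 - 1, -1, -1)
                for gy in ys:
                    xs = (range(side3) if (gy + gz) % 2 == 0
                          else range(side3 - 1, -1, -1))
                    for gx in xs:
                        pts.append((gx, gy, gz))
                        if len(pts) == beads_per_chain:
                            break
                    if len(pts) == beads_per_chain:
                        break
                if len(pts) == beads_per_chain:
                    break
            grid = np.array(pts, dtype=float)
            extent = (side3 - 1) * b
            if extent >= spacing - 2.0:
                raise ValueError("overfilled box: compact chains overlap")
            xyz = center + (grid - grid.mean(axis=0)) * b
        else:
            raise ValueError(f"unknown conformation {conformation!r}")
        positions.append(xyz)
        if is_rna:
            bead_types += [rna_type] * beads_per_chain
        else:
            # PR repeat peptide: alternating proline / arginine
            bead_types += [peptide_types[i % 2] for i in range(beads_per_chain)]
        chain_ids += [c] * beads_per_chain
    pos = np.vstack(positions) % box
    return CGSystem(positions=pos, bead_types=bead_types,
                    chain_ids=np.array(chain_ids), box_edge=box)


def make_system(n_rna: int, n_peptide: int, beads_per_chain: int,
                cfg: SimConfig, **kw) -> CGSystem:
    return init_lattice(n_rna, n_peptide, beads_per_chain, cfg.box_edge, **kw)


def desk_preset(salt: float = 0.15, n_steps: int = 30_000, seed: int = 0,
                box: float = 120.0) -> SimConfig:
    """Scaled-down condensation run: small box, 10 fs steps, 100 ps relaxation
    (the condensate setting; weaker friction lets chains meet within the run)."""
    return SimConfig(box_edge=box, n_steps=n_steps, dt_fs=10.0, temperature=298.0,
                     relaxation_ps=100.0, c_na=salt, seed=seed, save_stride=500)


# ---------------------------------------------------------------------------
# integrator
# ---------------------------------------------------------------------------


def run_langevin(system: CGSystem, ff: ForceField, cfg: SimConfig,
                 velocities: np.ndarray | None = None) -> Trajectory:
    """BAOAB Langevin integration; friction = 1/relaxation-time.

    Thermal noise is seeded from cfg.seed; frames (wrapped into the box) are
    stored every cfg.save_stride steps, the initial frame included.  A force
    blow-up (any |F| component above 1e5 kJ/(mol A)) aborts with the offending
    step in the message.
    """
    ff = ForceField(**{**ff.__dict__})
    ff.kappa = kappa_from_salt(cfg.c_na)
    tidx = ff.type_index(system.bead_types)
    m = ff.masses[tidx][:, None]
    dt = cfg.dt_fs * 1e-3 / TIME_UNIT_PS  # internal time units
    kt = KB * cfg.temperature
    gamma = 0.0 if cfg.relaxation_ps <= 0 else 1.0 / (cfg.relaxation_ps / TIME_UNIT_PS)
    c1 = np.exp(-gamma * dt)
    c2 = np.sqrt(max(1.0 - c1 * c1, 0.0))
    rng = np.random.default_rng(cfg.seed)

    x = system.positions.copy()
    v = (velocities.copy() if velocities is not None
         else rng.standard_normal(x.shape) * np.sqrt(kt / m))
    sys_now = CGSystem(x, system.bead_types, system.chain_ids, system.box_edge)
    _, f = compute_energy_forces(sys_now, ff)

    frames = [x % system.box_edge]
    times = [0.0]
    temps = [kinetic_temperature(v, ff.masses[tidx])]
    for step in range(1, cfg.n_steps + 1):
        v += 0.5 * dt * f / m
        x += 0.5 * dt * v
        if gamma > 0:
            v = c1 * v + c2 * np.sqrt(kt / m) * rng.standard_normal(x.shape)
        x += 0.5 * dt * v
        sys_now.positions = x
        _, f = compute_energy_forces(sys_now, ff)
        if np.max(np.abs(f)) > FORCE_BLOWUP:
            raise FloatingPointError(
                f"force blow-up at step {step}: max |F| = {np.max(np.abs(f)):.3g}")
        v += 0.5 * dt * f / m
        if step % cfg.save_stride == 0:
            frames.append(x % system.box_edge)
            times.append(step * cfg.dt_fs * 1e-3)
            temps.append(kinetic_temperature(v, ff.masses[tidx]))
    return Trajectory(frames=np.array(frames), chain_ids=system.chain_ids.copy(),
                      box_edge=system.box_edge, times=np.array(times),
                      bead_types=list(system.bead_types),
                      temperatures=np.array(temps))


def kinetic_temperature(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Instantaneous kinetic temperature from equipartition (K)."""
    ke = 0.5 * float(np.sum(masses[:, None] * velocities ** 2))
    return 2.0 * ke / (3.0 * velocities.shape[0] * KB)
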