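"""All-atom single-stranded RNA conformers from dinucleotide backbone suites.

Single-stranded RNA backbones populate a finite alphabet of dinucleotide
"suites": discrete combinations of the five inter-residue backbone torsions
(epsilon, zeta of the 5' residue; alpha, beta, gamma of the 3' residue), the
two sugar puckers (delta and delta of the preceding residue) and the two
glycosidic angles (chi).  A 30-mer is assembled from 29 consecutive suites;
drawing suites from a probability vector and rejecting steric clashes yields
conformer pools whose suite statistics are known exactly.

Atoms are placed sequentially with the natural-extension reference frame
(NeRF) using idealized bond lengths and angles, so the requested torsions are
reproduced exactly by construction.  Sugar-ring closure is approximate: the
two ring torsions that position C1' and O4' are derived from the pucker
pseudorotation phase, leaving a small (<0.15 A) closure error on the
O4'-C4' ring bond that is irrelevant for scattering or order-parameter work.

The shipped suite library uses the community suite nomenclature with
approximate consensus torsion means and is fully user-replaceable (CSV with
name + 11 angle columns).
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._geometry import dihedral, place_atom

__all__ = [
    "Suite",
    "SuiteLibrary",
    "SuiteWeights",
    "Conformer",
    "ConformerPool",
    "load_suite_library",
    "build_chain",
    "has_clash",
    "sample_pool",
    "measure_suite_torsions",
]

ANGLE_COLUMNS = [
    "delta_prev", "epsilon", "zeta", "alpha", "beta", "gamma", "delta",
    "chi_prev", "chi", "pucker_prev", "pucker",
]

# ---------------------------------------------------------------------------
# idealized covalent geometry (bond lengths in A, angles in degrees)
# ---------------------------------------------------------------------------

BOND = {
    ("P", "O5'"): 1.593, ("O5'", "C5'"): 1.440, ("C5'", "C4'"): 1.510,
    ("C4'", "C3'"): 1.524, ("C3'", "O3'"): 1.423, ("O3'", "P"): 1.607,
    ("C3'", "C2'"): 1.525, ("C2'", "C1'"): 1.528, ("C1'", "O4'"): 1.414,
    ("C2'", "O2'"): 1.413, ("C1'", "N"): 1.473, ("P", "OP"): 1.485,
}
ANGLE = {
    "O3'-P-O5'": 104.0, "P-O5'-C5'": 120.9, "O5'-C5'-C4'": 111.5,
    "C5'-C4'-C3'": 115.5, "C4'-C3'-O3'": 110.5, "C3'-O3'-P": 119.7,
    "C4'-C3'-C2'": 102.6, "C3'-C2'-C1'": 101.5, "C2'-C1'-O4'": 106.4,
    "C3'-C2'-O2'": 113.0, "C2'-C1'-N": 113.4, "O3'-P-OP": 108.0,
}
# exocyclic torsion offsets (calibrated so a C3'-endo nucleotide closes its ring
# and places O2'/N on the correct ribose face)
C2P_OFFSET = -122.0   # dihedral(C5',C4',C3',C2') = delta + C2P_OFFSET
O2P_OFFSET = -121.0   # dihedral(C4',C3',C2',O2') = nu2 + O2P_OFFSET
N_OFFSET = -119.0     # dihedral(C3',C2',C1',N)  = nu1 + N_OFFSET
PUCKER_AMPLITUDE = 38.0  # degrees, nu_max of the pseudorotation wheel
GAMMA_5PRIME = 54.0   # gamma of residue 1 (not covered by any suite)

PURINES = {"A"}
PYRIMIDINES = {"U", "C"}
CHI_REF = {"A": "C4", "U": "C2", "C": "C2"}  # chi = O4'-C1'-N-CHI_REF
GLYCOSIDIC_N = {"A": "N9", "U": "N1", "C": "N1"}


def _pyrimidine_template(exo4: str, d_exo4: float) -> dict[str, np.ndarray]:
    """Planar six-ring template; origin N1, x toward C2, ring at negative y."""
    s = 1.38
    center = np.array([s / 2, -s * np.sqrt(3) / 2])
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    ring = {}
    # N1 sits at angle 120 deg from the ring center; vertices every -60 deg
    for k, nm in enumerate(names):
        ang = np.radians(120 - 60 * k)
        ring[nm] = center + s * np.array([np.cos(ang), np.sin(ang)])
    out = dict(ring)
    out["O2"] = ring["C2"] + 1.23 * (ring["C2"] - center) / s
    out[exo4] = ring["C4"] + d_exo4 * (ring["C4"] - center) / s
    return out


def _purine_template() -> dict[str, np.ndarray]:
    """Fused 5-6 ring template for adenine; origin N9, x toward C4."""
    s5 = 1.37
    r5 = s5 / (2 * np.sin(np.radians(36)))
    c5 = np.array([s5 / 2, -r5 * np.cos(np.radians(36))])
    penta = {}
    for nm, ang in [("N9", 126), ("C4", 54), ("C5", -18), ("N7", -90), ("C8", -162)]:
        penta[nm] = c5 + r5 * np.array([np.cos(np.radians(ang)), np.sin(np.radians(ang))])
    s6 = 1.37
    mid = (penta["C4"] + penta["C5"]) / 2
    u = (penta["C5"] - penta["C4"]) / s5
    n = np.array([-u[1], u[0]])
    if np.dot(n, c5 - mid) > 0:  # hexagon center on the far side from the pentagon
        n = -n
    c6 = mid + s6 * np.sqrt(3) / 2 * n
    hexa = {}
    a0 = np.degrees(np.arctan2(*(penta["C4"] - c6)[::-1]))
    a1 = np.degrees(np.arctan2(*(penta["C5"] - c6)[::-1]))
    step = -60 if (a0 - a1) % 360 < 180 else 60
    for k, nm in enumerate(["C4", "N3", "C2", "N1", "C6", "C5"]):
        ang = np.radians(a0 + step * k)
        hexa[nm] = c6 + s6 * np.array([np.cos(ang), np.sin(ang)])
    out = {**hexa, **penta}
    out["N6"] = hexa["C6"] + 1.34 * (hexa["C6"] - c6) / s6
    return out


BASE_TEMPLATES = {
    "A": _purine_template(),
    "U": _pyrimidine_template("O4", 1.23),
    "C": _pyrimidine_template("N4", 1.34),
}
BASE_RING_ATOMS = {
    "A": ["N9", "C8", "N7", "C5", "C4", "N3", "C2", "N1", "C6"],
    "U": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Suite:
    """One dinucleotide backbone suite: 11 defining angles (degrees)."""

    name: str
    delta_prev: float
    epsilon: float
    zeta: float
    alpha: float
    beta: float
    gamma: float
    delta: float
    chi_prev: float
    chi: float
    pucker_prev: float
    pucker: float

    def __post_init__(self):
        for col in ANGLE_COLUMNS:
            v = getattr(self, col)
            if not (-180.0 < v <= 180.0):
                raise ValueError(f"suite {self.name}: angle {col}={v} outside (-180, 180]")


@dataclass
class SuiteLibrary:
    """Ordered library of dinucleotide suites (34 by default)."""

    suites: list[Suite]
    provenance: str = ""

    def __post_init__(self):
        names = [s.name for s in self.suites]
        if len(set(names)) != len(names):
            raise ValueError("suite names must be unique")

    def __len__(self) -> int:
        return len(self.suites)

    def __getitem__(self, key: int | str) -> Suite:
        if isinstance(key, str):
            return self.suites[self.index(key)]
        return self.suites[key]

    def index(self, name: str) -> int:
        for i, s in self.suites_enum():
            if s.name == name:
                return i
        raise KeyError(f"unknown suite name {name!r}")

    def suites_enum(self):
        return enumerate(self.suites)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.suites]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"name": s.name, **{c: getattr(s, c) for c in ANGLE_COLUMNS}}
                for s in self.suites]
        return pd.DataFrame(rows)

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def subset(self, names: list[str]) -> "SuiteLibrary":
        return SuiteLibrary([self[n] for n in names],
                            provenance=self.provenance + " (subset)")


def load_suite_library(source: str | Path = "default",
                       expected_size: int | None = 34) -> SuiteLibrary:
    """Load and validate a suite library from CSV (or the shipped default).

    The default table must contain exactly 34 suites; a user-supplied file may
    opt out of the size check with ``expected_size=None``.
    """
    if source == "default":
        ref = importlib.resources.files("condensaxs.data") / "suite_library.csv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p)
        provenance = ("community RNA suite nomenclature, approximate consensus "
                      "torsion means; user-replaceable")
    else:
        df = pd.read_csv(source)
        provenance = str(source)
    missing = {"name", *ANGLE_COLUMNS} - set(df.columns)
    if missing:
        raise ValueError(f"suite table missing columns: {sorted(missing)}")
    if expected_size is not None and len(df) != expected_size:
        raise ValueError(f"suite table has {len(df)} rows, expected {expected_size}")
    suites = [Suite(name=str(r["name"]), **{c: float(r[c]) for c in ANGLE_COLUMNS})
              for _, r in df.iterrows()]
    return SuiteLibrary(suites, provenance=provenance)


@dataclass
class SuiteWeights:
    """Probability vector over the suite library plus reference frequencies."""

    w: np.ndarray
    h_pool: np.ndarray | None = None
    h_ens: np.ndarray | None = None

    def __post_init__(self):
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("suite weights must be nonnegative")
        if abs(self.w.sum() - 1.0) > 1e-9:
            raise ValueError("suite weights must sum to 1 (within 1e-9)")

    @classmethod
    def uniform(cls, n: int = 34) -> "SuiteWeights":
        return cls(np.full(n, 1.0 / n))

    @property
    def n(self) -> int:
        return self.w.size


@dataclass
class Conformer:
    """All-atom structure: parallel arrays of element / residue / name / xyz."""

    elements: np.ndarray
    res_idx: np.ndarray
    atom_names: np.ndarray
    coords: np.ndarray
    sequence: str = ""
    suite_assignment: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype="U2")
        self.res_idx = np.asarray(self.res_idx, dtype=int)
        self.atom_names = np.asarray(self.atom_names, dtype="U4")
        self.coords = np.asarray(self.coords, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return int(self.res_idx.max()) + 1 if self.n_atoms else 0

    def atom(self, res: int, name: str) -> np.ndarray:
        m = (self.res_idx == res) & (self.atom_names == name)
        idx = np.where(m)[0]
        if idx.size != 1:
            raise KeyError(f"atom {name} of residue {res}: {idx.size} matches")
        return self.coords[idx[0]]

    def backbone_points(self, atom_name: str = "P") -> np.ndarray:
        """Coordinates of one reference atom per residue (in residue order)."""
        m = self.atom_names == atom_name
        order = np.argsort(self.res_idx[m], kind="stable")
        return self.coords[m][order]

    def transformed(self, R: np.ndarray | None = None,
                    t: np.ndarray | None = None) -> "Conformer":
        xyz = self.coords
        if R is not None:
            xyz = xyz @ np.asarray(R).T
        if t is not None:
            xyz = xyz + np.asarray(t)
        return Conformer(self.elements.copy(), self.res_idx.copy(),
                         self.atom_names.copy(), xyz, self.sequence,
                         list(self.suite_assignment))

    def write_pdb(self, path: str | Path) -> None:
        import biotite.structure as struc
        from biotite.structure.io.pdb import PDBFile

        arr = struc.AtomArray(self.n_atoms)
        arr.coord = self.coords.astype(np.float32)
        arr.chain_id = np.full(self.n_atoms, "A")
        arr.res_id = self.res_idx + 1
        arr.res_name = np.array([self.sequence[i] if self.sequence else "N"
                                 for i in self.res_idx])
        arr.atom_name = self.atom_names
        arr.element = self.elements
        arr.hetero = np.zeros(self.n_atoms, dtype=bool)
        f = PDBFile()
        f.set_structure(arr)
        f.write(str(path))

    @classmethod
    def read_pdb(cls, path: str | Path) -> "Conformer":
        from biotite.structure.io.pdb import PDBFile

        arr = PDBFile.read(str(path)).get_structure(model=1)
        res_ids = arr.res_id - arr.res_id.min()
        seq = ""
        for rid in np.unique(arr.res_id):
            seq += str(arr.res_name[arr.res_id == rid][0]).strip()[:1]
        return cls(elements=arr.element, res_idx=res_ids,
                   atom_names=arr.atom_name, coords=np.asarray(arr.coord, dtype=float),
                   sequence=seq)


# ---------------------------------------------------------------------------
# builder
# ---------------------------------------------------------------------------


def _ring_nus(pucker_phase: float) -> tuple[float, float]:
    """Ring torsions nu1, nu2 from the pseudorotation phase (degrees)."""
    p = np.radians(pucker_phase)
    nu2 = PUCKER_AMPLITUDE * np.cos(p)
    nu1 = PUCKER_AMPLITUDE * np.cos(p - np.radians(144.0))
    return float(nu1), float(nu2)


def _append_base(atoms: list, res: int, base: str, c1p, n_pos, cref_pos) -> None:
    """Place the planar base template in the frame (origin N, x->Cref, C1' side +y)."""
    tpl = BASE_TEMPLATES[base]
    n_name = GLYCOSIDIC_N[base]
    ref_name = CHI_REF[base]
    xhat = cref_pos - n_pos
    xhat /= np.linalg.norm(xhat)
    c = c1p - n_pos
    zhat = np.cross(xhat, c)
    zhat /= np.linalg.norm(zhat)
    yhat = np.cross(zhat, xhat)
    for nm, xy in tpl.items():
        if nm in (n_name, ref_name):
            continue
        pos = n_pos + xy[0] * xhat + xy[1] * yhat
        atoms.append((nm[0], res, nm, pos))


def build_chain(sequence: str, suite_assignment: list[str],
                library: SuiteLibrary) -> Conformer:
    """Deterministic all-atom conformer from a sequence and a suite assignment.

    Linkage k (between residues k and k+1, 0-based) contributes epsilon/zeta to
    residue k and alpha/beta/gamma/delta/chi (and pucker) to residue k+1; the
    first suite's *_prev entries set delta/chi/pucker of residue 1.  Measured
    backbone torsions of the output reproduce the assigned suite angles to
    numerical precision.
    """
    sequence = sequence.upper()
    n = len(sequence)
    if n < 2:
        raise ValueError("need at least 2 residues")
    bad = set(sequence) - (PURINES | PYRIMIDINES)
    if bad:
        raise ValueError(f"unsupported nucleotides {sorted(bad)}; only A, U, C are built")
    if len(suite_assignment) != n - 1:
        raise ValueError("suite assignment length must be len(sequence) - 1")
    suites = [library[name] for name in suite_assignment]

    # per-residue torsion schedule
    delta = np.empty(n)
    chi = np.empty(n)
    pucker = np.empty(n)
    delta[0], chi[0], pucker[0] = suites[0].delta_prev, suites[0].chi_prev, suites[0].pucker_prev
    for k, s in enumerate(suites):
        delta[k + 1], chi[k + 1], pucker[k + 1] = s.delta, s.chi, s.pucker

    atoms: list[tuple[str, int, str, np.ndarray]] = []

    def add(res, name, pos):
        atoms.append((name[0], res, name, pos))

    # residue 0 seed: O5'-C5'-C4' in the xy-plane
    o5 = np.array([0.0, 0.0, 0.0])
    c5 = np.array([BOND[("O5'", "C5'")], 0.0, 0.0])
    ang = np.radians(ANGLE["O5'-C5'-C4'"])
    c4 = c5 + BOND[("C5'", "C4'")] * np.array([-np.cos(ang), np.sin(ang), 0.0])
    add(0, "O5'", o5)
    add(0, "C5'", c5)
    add(0, "C4'", c4)
    gamma_seed = GAMMA_5PRIME  # torsion O5'-C5'-C4'-C3' of the 5' residue

    prev = {"O5'": o5, "C5'": c5, "C4'": c4}

    def place_residue_tail(res, frame, gamma_val, delta_val, chi_val, pucker_val):
        """Place C3', O3', sugar ring and base of residue `res`.

        `frame` holds the already-placed O5', C5', C4' (and P for res > 0).
        Returns positions needed to continue the chain (C4', C3', O3')."""
        o5_, c5_, c4_ = frame["O5'"], frame["C5'"], frame["C4'"]
        c3 = place_atom(o5_, c5_, c4_, BOND[("C4'", "C3'")],
                        ANGLE["C5'-C4'-C3'"], gamma_val)
        o3 = place_atom(c5_, c4_, c3, BOND[("C3'", "O3'")],
                        ANGLE["C4'-C3'-O3'"], delta_val)
        nu1, nu2 = _ring_nus(pucker_val)
        c2 = place_atom(c5_, c4_, c3, BOND[("C3'", "C2'")],
                        ANGLE["C4'-C3'-C2'"], delta_val + C2P_OFFSET)
        c1 = place_atom(c4_, c3, c2, BOND[("C2'", "C1'")],
                        ANGLE["C3'-C2'-C1'"], nu2)
        o4 = place_atom(c3, c2, c1, BOND[("C1'", "O4'")],
                        ANGLE["C2'-C1'-O4'"], nu1)
        o2 = place_atom(c4_, c3, c2, BOND[("C2'", "O2'")],
                        ANGLE["C3'-C2'-O2'"], nu2 + O2P_OFFSET)
        base = sequence[res]
        npos = place_atom(c3, c2, c1, BOND[("C1'", "N")],
                          ANGLE["C2'-C1'-N"], nu1 + N_OFFSET)
        cref = place_atom(o4, c1, npos, 1.37,
                          126.3 if base in PURINES else 117.8, chi_val)
        add(res, "C3'", c3)
        add(res, "C2'", c2)
        add(res, "C1'", c1)
        add(res, "O4'", o4)
        add(res, "O2'", o2)
        add(res, "O3'", o3)
        add(res, GLYCOSIDIC_N[base], npos)
        add(res, CHI_REF[base], cref)
        _append_base(atoms, res, base, c1, npos, cref)
        return c4_, c3, o3

    c4p, c3p, o3p = place_residue_tail(0, prev, gamma_seed, delta[0], chi[0], pucker[0])

    for k, s in enumerate(suites):
        res = k + 1
        p = place_atom(c4p, c3p, o3p, BOND[("O3'", "P")],
                       ANGLE["C3'-O3'-P"], s.epsilon)
        o5_ = place_atom(c3p, o3p, p, BOND[("P", "O5'")],
                         ANGLE["O3'-P-O5'"], s.zeta)
        op1 = place_atom(c3p, o3p, p, BOND[("P", "OP")], ANGLE["O3'-P-OP"],
                         s.zeta + 120.0)
        op2 = place_atom(c3p, o3p, p, BOND[("P", "OP")], ANGLE["O3'-P-OP"],
                         s.zeta - 120.0)
        c5_ = place_atom(o3p, p, o5_, BOND[("O5'", "C5'")],
                         ANGLE["P-O5'-C5'"], s.alpha)
        c4_ = place_atom(p, o5_, c5_, BOND[("C5'", "C4'")],
                         ANGLE["O5'-C5'-C4'"], s.beta)
        add(res, "P", p)
        add(res, "OP1", op1)
        add(res, "OP2", op2)
        add(res, "O5'", o5_)
        add(res, "C5'", c5_)
        add(res, "C4'", c4_)
        frame = {"O5'": o5_, "C5'": c5_, "C4'": c4_}
        c4p, c3p, o3p = place_residue_tail(res, frame, s.gamma, delta[res],
                                           chi[res], pucker[res])

    elements = np.array([a[0] for a in atoms])
    res_idx = np.array([a[1] for a in atoms])
    names = np.array([a[2] for a in atoms])
    coords = np.array([a[3] for a in atoms])
    return Conformer(elements=elements, res_idx=res_idx, atom_names=names,
                     coords=coords, sequence=sequence,
                     suite_assignment=list(suite_assignment))


def measure_suite_torsions(conf: Conformer, linkage: int) -> dict[str, float]:
    """Measure the suite angles of linkage k (residues k, k+1) from coordinates."""
    k = linkage
    g = conf.atom

    def base_atoms(res):
        b = conf.sequence[res]
        return g(res, "O4'"), g(res, "C1'"), g(res, GLYCOSIDIC_N[b]), g(res, CHI_REF[b])

    out = {
        "delta_prev": dihedral(g(k, "C5'"), g(k, "C4'"), g(k, "C3'"), g(k, "O3'")),
        "epsilon": dihedral(g(k, "C4'"), g(k, "C3'"), g(k, "O3'"), g(k + 1, "P")),
        "zeta": dihedral(g(k, "C3'"), g(k, "O3'"), g(k + 1, "P"), g(k + 1, "O5'")),
        "alpha": dihedral(g(k, "O3'"), g(k + 1, "P"), g(k + 1, "O5'"), g(k + 1, "C5'")),
        "beta": dihedral(g(k + 1, "P"), g(k + 1, "O5'"), g(k + 1, "C5'"), g(k + 1, "C4'")),
        "gamma": dihedral(g(k + 1, "O5'"), g(k + 1, "C5'"), g(k + 1, "C4'"), g(k + 1, "C3'")),
        "delta": dihedral(g(k + 1, "C5'"), g(k + 1, "C4'"), g(k + 1, "C3'"), g(k + 1, "O3'")),
        "chi_prev": dihedral(*base_atoms(k)),
        "chi": dihedral(*base_atoms(k + 1)),
    }
    return out


# ---------------------------------------------------------------------------
# steric screening and pool sampling
# ---------------------------------------------------------------------------


def has_clash(conformer: Conformer, min_distance: float = 2.0,
              residue_exclusion: int = 1):
    """Check for non-bonded heavy-atom pairs closer than `min_distance` A.

    Pairs within the same residue or within `residue_exclusion` residues of
    each other are treated as bonded context and skipped.  Returns
    (flag, offending pair) where the pair is (atom index, atom index) or None.
    """
    heavy = conformer.elements != "H"
    idx = np.where(heavy)[0]
    if idx.size < 2:
        raise ValueError("need at least 2 atoms")
    coords = conformer.coords[idx]
    res = conformer.res_idx[idx]
    tree = cKDTree(coords)
    for i, j in tree.query_pairs(min_distance):
        if abs(int(res[i]) - int(res[j])) > residue_exclusion:
            return True, (int(idx[i]), int(idx[j]))
    return False, None


@dataclass
class ConformerPool:
    """Pool of conformers with optional theoretical profiles and selection weights."""

    conformers: list[Conformer]
    profiles: list = field(default_factory=list)
    selection_weights: np.ndarray | None = None
    h_pool: np.ndarray | None = None
    suite_names: list[str] = field(default_factory=list)
    seed: int | None = None

    def __post_init__(self):
        if self.profiles and len(self.profiles) != len(self.conformers):
            raise ValueError("profiles and conformers must be parallel lists")
        if self.selection_weights is not None:
            self.selection_weights = np.asarray(self.selection_weights, dtype=float)
            if self.selection_weights.size != len(self.conformers):
                raise ValueError("selection_weights length mismatch")
            if np.any(self.selection_weights < 0):
                raise ValueError("selection weights must be nonnegative")

    def __len__(self) -> int:
        return len(self.conformers)

    def compute_profiles(self, q_grid=None, atoms: str = "heavy") -> None:
        """Attach a theoretical scattering profile to every conformer.

        atoms="heavy" uses all non-hydrogen atoms; atoms="phosphorus" restricts
        the Debye sum to backbone P (a fast coarse mode for reduced-size runs).
        """
        from . import saxs

        self.profiles = []
        for c in self.conformers:
            if atoms == "phosphorus":
                m = c.atom_names == "P"
                sub = Conformer(c.elements[m], c.res_idx[m], c.atom_names[m],
                                c.coords[m], c.sequence)
                self.profiles.append(saxs.debye_intensity(sub, q_grid))
            else:
                self.profiles.append(saxs.debye_intensity(c, q_grid))

    def suite_frequencies(self, library: SuiteLibrary,
                          weights: np.ndarray | None = None) -> np.ndarray:
        """(Weighted) empirical frequency of each library suite over the pool."""
        h = np.zeros(len(library))
        wts = np.ones(len(self)) if weights is None else np.asarray(weights, float)
        for c, wc in zip(self.conformers, wts):
            for name in c.suite_assignment:
                h[library.index(name)] += wc
        tot = h.sum()
        return h / tot if tot > 0 else h

    def save(self, directory: str | Path) -> None:
        """Directory of PDBs plus a JSON manifest (weights, seed, h_pool)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, c in enumerate(self.conformers):
            c.write_pdb(d / f"conformer_{i:05d}.pdb")
        manifest = {
            "n_conformers": len(self),
            "seed": self.seed,
            "suite_names": self.suite_names,
            "h_pool": None if self.h_pool is None else self.h_pool.tolist(),
            "selection_weights": (None if self.selection_weights is None
                                  else self.selection_weights.tolist()),
            "suite_assignments": [c.suite_assignment for c in self.conformers],
            "sequences": [c.sequence for c in self.conformers],
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))


def sample_pool(sequence: str, weights: SuiteWeights, library: SuiteLibrary,
                n_conformers: int = 2000, seed: int = 0, max_retries: int = 500,
                clash_cutoff: float | None = 2.0) -> ConformerPool:
    """Draw a conformer pool with per-linkage suites sampled from `weights`.

    Clash handling is local: when a built chain contains a steric violation the
    suite of the linkage nearest the offending pair is resampled (a Gibbs-style
    single-site move), up to `max_retries` per conformer.  Set
    ``clash_cutoff=None`` to disable steric rejection.
    """
    if n_conformers < 1:
        raise ValueError("n_conformers must be >= 1")
    if weights.n != len(library):
        raise ValueError("weights length must match library size")
    rng = np.random.default_rng(seed)
    names = library.names
    n_link = len(sequence) - 1
    conformers = []
    for _ in range(n_conformers):
        assign = list(rng.choice(names, size=n_link, p=weights.w))
        conf = build_chain(sequence, assign, library)
        if clash_cutoff is not None:
            retries = 0
            clash, pair = has_clash(conf, clash_cutoff)
            while clash:
                res_lo = int(min(conf.res_idx[pair[0]], conf.res_idx[pair[1]]))
                res_hi = int(max(conf.res_idx[pair[0]], conf.res_idx[pair[1]]))
                if retries >= max_retries:
                    raise RuntimeError(
                        f"clash rejection stuck around linkage {res_hi - 1} "
                        f"after {max_retries} retries")
                # any linkage between the clashing residues moves them apart
                link = int(rng.integers(res_lo, res_hi))
                link = min(max(link, 0), n_link - 1)
                assign[link] = str(rng.choice(names, p=weights.w))
                conf = build_chain(sequence, assign, library)
                retries += 1
                clash, pair = has_clash(conf, clash_cutoff)
        conformers.append(conf)
    pool = ConformerPool(conformers=conformers, suite_names=names, seed=seed)
    pool.h_pool = pool.suite_frequencies(library)
    return pool
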