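"""Genetic sub-ensemble selection against a scattering target, with iterative
suite reweighting.

A pool of conformers (each with a theoretical profile) is searched for
sub-ensembles of M members whose averaged profile fits the target: N ensembles
are evolved by an elitist genetic algorithm (tournament selection, single-point
crossover of member lists, single-member resampling mutations) minimizing the
reduced chi-square with an analytically fitted scale factor.  Repeat member
selections are allowed; additive intensity offsets are not.

The outer loop alternates pool sampling with reweighting of the dinucleotide
suite probabilities so that the suite frequencies observed in the selected
ensembles become the expected frequencies of the next pool.  Convergence of
the weight vector is tracked with the Jensen-Shannon divergence (natural log,
so JSD is bounded by ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .chains import ConformerPool, SuiteLibrary, SuiteWeights, sample_pool
from .saxs import ScatteringProfile

__all__ = [
    "GAConfig",
    "EnsembleSelection",
    "IterationTrace",
    "ensemble_average",
    "genetic_select",
    "reweight_suites",
    "suite_chi2",
    "jsd",
    "iterate_eom",
]


@dataclass
class GAConfig:
    """Genetic-algorithm settings (defaults follow the production protocol:
    1000 generations, 50 ensembles of 20 curves, 10 mutations per ensemble,
    100 independent restarts)."""

    n_generations: int = 1000
    n_ensembles: int = 50
    curves_per_ensemble: int = 20
    mutations_per_ensemble: int = 10
    inner_iterations: int = 100
    allow_repeats: bool = True
    allow_offsets: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.allow_offsets:
            raise NotImplementedError("additive I(q) offsets are deliberately not supported")


def ensemble_average(profiles: list[ScatteringProfile],
                     a: np.ndarray) -> ScatteringProfile:
    """Pointwise weighted sum I(q) = sum_k a_k I_k(q) on a common grid."""
    a = np.asarray(a, dtype=float)
    if len(profiles) != a.size:
        raise ValueError("weights must be parallel to profiles")
    if np.any(a < 0):
        raise ValueError("weights must be nonnegative")
    q = profiles[0].q
    for p in profiles[1:]:
        if p.q.shape != q.shape or not np.allclose(p.q, q):
            raise ValueError("profiles must share one q grid")
    I = np.zeros_like(q)
    for w, p in zip(a, profiles):
        I = I + w * p.I
    return ScatteringProfile(q=q.copy(), I=I)


@dataclass
class EnsembleSelection:
    members: np.ndarray          # (N, M) pool indices
    chi2: np.ndarray             # per-ensemble reduced chi-square
    chi2_red: float              # mean over the N ensembles
    mu: np.ndarray               # per-ensemble fitted scale
    frequency: np.ndarray        # per-conformer selection frequency over all N*M slots
    top_frequency: np.ndarray    # frequency within the best quartile of ensembles
    best_index: int              # ensemble with lowest chi2
    best_history: np.ndarray     # best chi2 per generation (winning restart)

    def weights_of(self, ensemble: int) -> np.ndarray:
        """Implied member weights a_k = multiplicity / M for one ensemble."""
        n_pool = self.frequency.size
        a = np.bincount(self.members[ensemble], minlength=n_pool).astype(float)
        return a / self.members.shape[1]


def _pool_matrix(pool: ConformerPool, target: ScatteringProfile) -> np.ndarray:
    if not pool.profiles:
        raise ValueError("pool has no theoretical profiles; call compute_profiles first")
    rows = []
    for p in pool.profiles:
        if p.q.shape == target.q.shape and np.allclose(p.q, target.q):
            rows.append(p.I)
        else:
            rows.append(np.interp(target.q, p.q, p.I))
    return np.array(rows)


def _population_chi2(idx: np.ndarray, profs: np.ndarray, Ie: np.ndarray,
                     w: np.ndarray):
    """Vectorized reduced chi-square of each ensemble in a population."""
    model = profs[idx].mean(axis=1)                      # (N, Q)
    denom = (w * model * model).sum(axis=1)
    mu = (w * model * Ie).sum(axis=1) / np.maximum(denom, 1e-300)
    resid2 = w * (mu[:, None] * model - Ie) ** 2
    chi2 = resid2.sum(axis=1) / max(Ie.size - 1, 1)
    return chi2, mu


def genetic_select(pool: ConformerPool, target: ScatteringProfile,
                   cfg: GAConfig = GAConfig()) -> EnsembleSelection:
    """Evolve N ensembles of M pool members against the target profile.

    Elitism keeps the best ensemble each generation, so the best fitness is
    non-increasing across generations.  The inner iterations are independent
    restarts; the restart with the lowest global chi2_red is returned.
    """
    if target.sigma is None or np.any(target.sigma <= 0):
        raise ValueError("target profile needs strictly positive sigma")
    profs = _pool_matrix(pool, target)
    n_pool = profs.shape[0]
    N, M = cfg.n_ensembles, cfg.curves_per_ensemble
    if not cfg.allow_repeats and n_pool < M:
        raise ValueError("pool smaller than ensemble size with repeats disabled")
    Ie = target.I
    w = 1.0 / target.sigma**2
    rng = np.random.default_rng(cfg.seed)

    best_run = None
    for _restart in range(cfg.inner_iterations):
        idx = rng.integers(n_pool, size=(N, M))
        chi2, mu = _population_chi2(idx, profs, Ie, w)
        history = []
        for _gen in range(cfg.n_generations):
            order = np.argsort(chi2)
            history.append(chi2[order[0]])
            elite = idx[order[0]].copy()
            # tournament selection (k = 2)
            cand = rng.integers(N, size=(N - 1, 2))
            winners = np.where(chi2[cand[:, 0]] <= chi2[cand[:, 1]],
                               cand[:, 0], cand[:, 1])
            partners = rng.integers(N, size=N - 1)
            new_idx = np.empty((N, M), dtype=np.int64)
            new_idx[0] = elite
            cut = rng.integers(1, M, size=N - 1)
            for k in range(N - 1):
                child = np.concatenate([idx[winners[k], :cut[k]],
                                        idx[partners[k], cut[k]:]])
                slots = rng.integers(M, size=cfg.mutations_per_ensemble)
                child[slots] = rng.integers(n_pool, size=cfg.mutations_per_ensemble)
                new_idx[k + 1] = child
            idx = new_idx
            chi2, mu = _population_chi2(idx, profs, Ie, w)
        history.append(chi2.min())
        chi2_red = float(chi2.mean())
        if best_run is None or chi2_red < best_run[0]:
            best_run = (chi2_red, idx, chi2, mu, np.array(history))

    chi2_red, idx, chi2, mu, history = best_run
    freq = np.bincount(idx.ravel(), minlength=n_pool).astype(float) / idx.size
    order = np.argsort(chi2)
    top = idx[order[:max(1, N // 4)]]
    top_freq = np.bincount(top.ravel(), minlength=n_pool).astype(float) / top.size
    return EnsembleSelection(members=idx, chi2=chi2, chi2_red=chi2_red, mu=mu,
                             frequency=freq, top_frequency=top_freq,
                             best_index=int(np.argmin(chi2)),
                             best_history=history)


# ---------------------------------------------------------------------------
# suite reweighting
# ---------------------------------------------------------------------------


def _predicted(h_pool: np.ndarray, w: np.ndarray, w_old: np.ndarray) -> np.ndarray:
    ratio = w / np.maximum(w_old, 1e-12)
    t = h_pool * ratio
    s = t.sum()
    return t / s if s > 0 else t


def suite_chi2(h_ens: np.ndarray, h_pool: np.ndarray, w: np.ndarray,
               w_old: np.ndarray) -> float:
    """Discrepancy between observed ensemble suite frequencies and the
    frequencies the reweighted pool would produce."""
    p = _predicted(h_pool, w, w_old)
    return float(np.sum((h_ens - p) ** 2))


def reweight_suites(h_ens: np.ndarray, h_pool: np.ndarray,
                    w_old: SuiteWeights | np.ndarray,
                    tol: float = 1e-10) -> SuiteWeights:
    """New suite weights minimizing the frequency discrepancy on the simplex.

    Constrained minimization (SLSQP) started from the old weights; the
    closed-form candidate w_m ∝ w_old_m * h_ens_m / h_pool_m is also evaluated
    and the lower-objective solution kept, so the result never scores worse
    than the starting point.
    """
    w0 = w_old.w if isinstance(w_old, SuiteWeights) else np.asarray(w_old, float)
    h_ens = np.asarray(h_ens, dtype=float)
    h_pool = np.asarray(h_pool, dtype=float)
    if h_ens.shape != h_pool.shape or h_ens.shape != w0.shape:
        raise ValueError("frequency vectors and weights must have equal length")
    if np.any((h_ens > 0) & (h_pool <= 0)):
        raise ValueError("h_pool must be positive wherever h_ens is positive")

    def obj(w):
        return suite_chi2(h_ens, h_pool, w, w0)

    candidates = [w0]
    with np.errstate(divide="ignore", invalid="ignore"):
        closed = np.where(h_pool > 0, w0 * h_ens / np.maximum(h_pool, 1e-300), 0.0)
    if closed.sum() > 0:
        candidates.append(closed / closed.sum())
    res = optimize.minimize(
        obj, x0=w0, method="SLSQP",
        bounds=[(0.0, 1.0)] * w0.size,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0}],
        options={"maxiter": 300, "ftol": tol})
    if res.success and res.x.min() > -1e-12:
        candidates.append(np.clip(res.x, 0.0, None))
    best = min(candidates, key=obj)
    if obj(best) > obj(w0) + 1e-12:  # pragma: no cover - defensive
        raise RuntimeError(f"reweighting failed to improve; chi_h^2 = {obj(best):.3g}")
    best = best / best.sum()
    return SuiteWeights(w=best, h_pool=h_pool, h_ens=h_ens)


# ---------------------------------------------------------------------------
# Jensen-Shannon divergence
# ---------------------------------------------------------------------------


def _entropy(w: np.ndarray) -> float:
    nz = w > 0
    return float(-np.sum(w[nz] * np.log(w[nz])))


def jsd(W1, W2) -> float:
    """Jensen-Shannon divergence between two discrete weight distributions
    (natural log; bounded by ln 2; 0*ln 0 := 0)."""
    w1 = W1.w if isinstance(W1, SuiteWeights) else np.asarray(W1, float)
    w2 = W2.w if isinstance(W2, SuiteWeights) else np.asarray(W2, float)
    if w1.shape != w2.shape:
        raise ValueError("distributions must have equal support size")
    for w in (w1, w2):
        if abs(w.sum() - 1.0) > 1e-6 or np.any(w < 0):
            raise ValueError("inputs must be normalized probability vectors")
    m = 0.5 * (w1 + w2)
    return _entropy(m) - 0.5 * _entropy(w1) - 0.5 * _entropy(w2)


# ---------------------------------------------------------------------------
# outer iteration
# ---------------------------------------------------------------------------


@dataclass
class IterationTrace:
    chi2_red: list[float] = field(default_factory=list)
    jsd: list[float] = field(default_factory=list)
    weights: list[np.ndarray] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.chi2_red)


def iterate_eom(sequence: str, target: ScatteringProfile, library: SuiteLibrary,
                cfg: GAConfig = GAConfig(), n_outer: int = 10, seed: int = 0,
                pool_size: int = 2000, jsd_tol: float = 0.01,
                atoms: str = "heavy", initial_weights: SuiteWeights | None = None,
                clash_cutoff: float | None = 2.0):
    """Iterative loop: sample pool -> theoretical profiles -> genetic selection
    -> suite reweighting, until the weight vector stops moving (JSD below
    `jsd_tol` nats) or `n_outer` iterations.

    Returns (final pool, final EnsembleSelection, IterationTrace).  The
    reported trace contains one chi2_red per iteration and one JSD per
    completed reweighting step (none for n_outer = 1).
    """
    rng = np.random.default_rng(seed)
    w = initial_weights or SuiteWeights.uniform(len(library))
    trace = IterationTrace()
    pool = sel = None
    for it in range(n_outer):
        sub_seed = int(rng.integers(2**31 - 1))
        pool = sample_pool(sequence, w, library, n_conformers=pool_size,
                           seed=sub_seed, clash_cutoff=clash_cutoff)
        pool.compute_profiles(q_grid=target.q, atoms=atoms)
        ga_cfg = GAConfig(**{**cfg.__dict__, "seed": int(rng.integers(2**31 - 1))})
        sel = genetic_select(pool, target, ga_cfg)
        pool.selection_weights = sel.frequency
        trace.chi2_red.append(sel.chi2_red)
        trace.weights.append(w.w.copy())
        if it == n_outer - 1:
            break
        # reweight from the best-fitting quartile of ensembles: the selected
        # sub-ensembles carry the signal, the unconverged remainder is noise
        h_ens = pool.suite_frequencies(library, weights=sel.top_frequency)
        w_new = reweight_suites(h_ens, pool.h_pool, w)
        step = jsd(w, w_new)
        trace.jsd.append(step)
        w = w_new
        if step < jsd_tol:
            break
    return pool, sel, trace
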