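"""Solution small-angle X-ray scattering: theoretical profiles and profile-level analyses.

The central object is the :class:`ScatteringProfile` — a q grid with intensities
and (optional) uncertainties.  Theoretical intensities of atomic structures are
computed with the Debye double sum over tabulated atomic form factors; the
analyses cover Guinier fitting, the swollen-polymer molecular form factor
(Flory exponent), reduced chi-square with analytic scale factor, Kratky
transforms, linear I(0) extrapolation, contrast match-point extrapolation and
the diffuse-peak lengthscale conversion d = 2*pi/q.

Form factors are the in-vacuo Cromer–Mann (IT92) coefficients as tabulated by
gemmi; no hydration shell or excluded-volume correction is applied, so absolute
profiles carry a systematic offset against programs that model the solvent.
Hydrogens are omitted from the scattering sum by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numba import njit
from scipy import optimize, special

__all__ = [
    "ScatteringProfile",
    "GuinierResult",
    "FloryFitResult",
    "ChiSquareResult",
    "MatchPointResult",
    "debye_intensity",
    "debye_sum",
    "form_factor_table",
    "guinier_fit",
    "mff_fit",
    "mff_curve",
    "chi_square",
    "kratky_transforms",
    "extrapolate_I0_linear",
    "i0_fold_change",
    "match_point",
    "peak_lengthscale",
    "default_q_grid",
]

# electron-density map for the sucrose contrast series, rho(c) = RHO_WATER + RHO_PER_WV * c
RHO_WATER = 0.3344  # e/A^3, pure buffer
RHO_PER_WV = 0.0021  # e/A^3 per % w/v sucrose (linearized over the working range)


def default_q_grid(q_max: float = 0.3, n_points: int = 61) -> np.ndarray:
    """Default computation grid: `n_points` values from 0 to `q_max` (1/A)."""
    return np.linspace(0.0, q_max, n_points)


@dataclass
class ScatteringProfile:
    """One-dimensional scattering profile I(q) with optional uncertainties."""

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if self.q.ndim != 1 or self.q.shape != self.I.shape:
            raise ValueError("q and I must be 1-D arrays of equal length")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        if self.q[0] < 0:
            raise ValueError("q values must be nonnegative")
        if self.sigma is not None and self.sigma.shape != self.q.shape:
            raise ValueError("sigma must match the q grid")

    @property
    def n_points(self) -> int:
        return self.q.size

    def write(self, path: str | Path) -> None:
        """Write as 3-column whitespace text (q [1/A], I, sigma)."""
        sig = self.sigma if self.sigma is not None else np.zeros_like(self.q)
        np.savetxt(path, np.column_stack([self.q, self.I, sig]),
                   header="q[1/A]  I  sigma")

    @classmethod
    def read(cls, path: str | Path) -> "ScatteringProfile":
        data = np.loadtxt(path)
        if data.ndim == 1:
            data = data[None, :]
        sigma = data[:, 2] if data.shape[1] >= 3 else None
        return cls(q=data[:, 0], I=data[:, 1], sigma=sigma)


# ---------------------------------------------------------------------------
# Debye scattering
# ---------------------------------------------------------------------------


def form_factor_table(elements: Sequence[str], q: np.ndarray) -> np.ndarray:
    """Cromer–Mann in-vacuo X-ray form factors f_e(q), shape (n_elements, n_q).

    q is the momentum transfer 4*pi*sin(theta)/lambda; gemmi's tables are
    parameterized in (sin(theta)/lambda)^2 = (q/(4*pi))^2.
    """
    import gemmi

    stol2 = (np.asarray(q, dtype=float) / (4.0 * np.pi)) ** 2
    out = np.empty((len(elements), stol2.size))
    for i, el in enumerate(elements):
        it92 = gemmi.Element(el).it92
        out[i] = [it92.calculate_sf(s) for s in stol2]
    return out


@njit(cache=True)
def _debye_kernel(pos: np.ndarray, elem_idx: np.ndarray, f: np.ndarray,
                  q: np.ndarray) -> np.ndarray:  # pragma: no cover - jitted
    n = pos.shape[0]
    nq = q.shape[0]
    intensity = np.zeros(nq)
    for i in range(n):
        ei = elem_idx[i]
        for k in range(nq):
            intensity[k] += f[ei, k] * f[ei, k]
    for i in range(n):
        ei = elem_idx[i]
        for j in range(i + 1, n):
            ej = elem_idx[j]
            dx = pos[i, 0] - pos[j, 0]
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            for k in range(nq):
                x = q[k] * r
                s = 1.0 if x == 0.0 else np.sin(x) / x
                intensity[k] += 2.0 * f[ei, k] * f[ej, k] * s
    return intensity


def debye_sum(positions: np.ndarray, f_table: np.ndarray,
              elem_idx: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Exact Debye double sum I(q) = sum_ij f_i f_j sin(q r_ij)/(q r_ij)."""
    positions = np.ascontiguousarray(positions, dtype=float)
    q = np.ascontiguousarray(q, dtype=float)
    return _debye_kernel(positions, np.ascontiguousarray(elem_idx, dtype=np.int64),
                         np.ascontiguousarray(f_table, dtype=float), q)


def debye_intensity(conformer, q_grid: np.ndarray | None = None,
                    include_hydrogens: bool = False) -> ScatteringProfile:
    """Theoretical scattering profile of an atomic structure via the Debye formula.

    At q = 0 the sum reduces to (sum_i f_i(0))^2.  The sigma column of the
    returned profile is zero (a theoretical curve carries no counting error).
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    elements = np.asarray(conformer.elements)
    pos = np.asarray(conformer.coords, dtype=float)
    if pos.shape[0] == 0:
        raise ValueError("conformer has no atoms")
    if not include_hydrogens:
        keep = elements != "H"
        elements, pos = elements[keep], pos[keep]
    uniq, elem_idx = np.unique(elements, return_inverse=True)
    f = form_factor_table(list(uniq), q_grid)
    intensity = debye_sum(pos, f, elem_idx, q_grid)
    return ScatteringProfile(q=q_grid, I=intensity, sigma=np.zeros_like(q_grid))


# ---------------------------------------------------------------------------
# Guinier analysis
# ---------------------------------------------------------------------------


@dataclass
class GuinierResult:
    Rg: float
    I0: float
    Rg_err: float
    I0_err: float
    q_min: float
    q_max: float
    n_points: int


class GuinierError(ValueError):
    """Raised when no self-consistent Guinier window exists."""


def _linfit_with_errors(x: np.ndarray, y: np.ndarray):
    A = np.column_stack([x, np.ones_like(x)])
    coef, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    dof = max(x.size - 2, 1)
    resid = y - A @ coef
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    return coef, np.sqrt(np.diag(cov))


def guinier_fit(profile: ScatteringProfile, qRg_limit: float = 1.3,
                min_points: int = 5) -> GuinierResult:
    """Guinier fit log I = log I0 - (q Rg)^2/3 on a self-consistent low-q window.

    The window is the largest low-q stretch satisfying max(q)*Rg <= qRg_limit,
    found by iterating fit -> window selection (two refinement passes).
    """
    q, I = profile.q, profile.I
    pos = q > 0
    window = pos.copy()
    for _ in range(3):  # initial fit + two refinements
        idx = np.where(window)[0]
        if idx.size < min_points:
            raise GuinierError("fewer than %d points in the Guinier window" % min_points)
        if np.any(I[idx] <= 0):
            raise GuinierError("non-positive intensities in the Guinier window")
        coef, errs = _linfit_with_errors(q[idx] ** 2, np.log(I[idx]))
        slope = coef[0]
        if slope >= 0:
            raise GuinierError("non-negative Guinier slope: no decaying low-q region")
        rg = float(np.sqrt(-3.0 * slope))
        window = pos & (q * rg <= qRg_limit)
    i0 = float(np.exp(coef[1]))
    rg_err = 3.0 * errs[0] / (2.0 * rg)
    qs = q[np.where(window)[0]] if window.any() else q[idx]
    return GuinierResult(Rg=rg, I0=i0, Rg_err=float(rg_err), I0_err=float(i0 * errs[1]),
                         q_min=float(qs.min()), q_max=float(qs.max()), n_points=int(window.sum()))


# ---------------------------------------------------------------------------
# Molecular form factor of a swollen polymer (Flory exponent fit)
# ---------------------------------------------------------------------------


@dataclass
class FloryFitResult:
    nu: float
    Rg: float
    I0: float
    chi2: float


def mff_curve(q: np.ndarray, nu: float, Rg: float) -> np.ndarray:
    """Form factor of a polymer with excluded-volume statistics.

    Generalized Debye function parameterized by the Flory exponent nu and the
    radius of gyration; reduces exactly to the Debye function at nu = 1/2 and
    decays as q^(-1/nu) at high q.
    """
    q = np.asarray(q, dtype=float)
    u = q * q * Rg * Rg * (2 * nu + 1) * (2 * nu + 2) / 6.0
    out = np.ones_like(u)
    nz = u > 1e-12
    un = u[nz]
    a1, a2 = 1.0 / (2 * nu), 1.0 / nu
    g1 = special.gammainc(a1, un) * special.gamma(a1)
    g2 = special.gammainc(a2, un) * special.gamma(a2)
    out[nz] = g1 / (nu * un ** a1) - g2 / (nu * un ** a2)
    return out


def mff_fit(profile: ScatteringProfile, nu_bounds=(0.25, 1.15)) -> FloryFitResult:
    """Fit I(q) = I0 * MFF(q; nu, Rg) by weighted least squares."""
    q, I = profile.q, profile.I
    sig = profile.sigma
    if sig is None or np.all(sig <= 0):
        sig = np.maximum(0.01 * np.abs(I), 1e-12)
    keep = I > 0
    q, I, sig = q[keep], I[keep], sig[keep]

    try:
        rg0 = guinier_fit(ScatteringProfile(q, I, sig)).Rg
    except GuinierError:
        rg0 = 1.0 / max(q[len(q) // 3], 1e-3)
    i00 = float(I[0])

    def residuals(p):
        nu, rg, i0 = p
        return (i0 * mff_curve(q, nu, rg) - I) / sig

    res = optimize.least_squares(
        residuals, x0=[0.55, rg0, i00],
        bounds=([nu_bounds[0], 1e-3, 1e-12], [nu_bounds[1], 1e4, np.inf]))
    if not res.success:
        raise RuntimeError(f"MFF fit did not converge; residual norm {np.linalg.norm(res.fun):.3g}")
    nu, rg, i0 = res.x
    dof = max(q.size - 3, 1)
    chi2 = float(res.fun @ res.fun) / dof
    return FloryFitResult(nu=float(nu), Rg=float(rg), I0=float(i0), chi2=chi2)


# ---------------------------------------------------------------------------
# chi-square with analytic scale factor
# ---------------------------------------------------------------------------


@dataclass
class ChiSquareResult:
    chi2: float
    mu: float
    Q: int


def chi_square(model: ScatteringProfile, experiment: ScatteringProfile) -> ChiSquareResult:
    """Reduced chi-square between a theoretical and an experimental profile.

    chi2 = 1/(Q-1) * sum_i [(mu*I(q_i) - Iexp(q_i)) / sigma(q_i)]^2 with the
    scale factor mu chosen analytically (weighted least squares).  The model is
    interpolated onto the experimental grid when the grids differ.
    """
    if experiment.sigma is None or np.any(experiment.sigma <= 0):
        raise ValueError("experimental profile needs strictly positive sigma")
    q, Ie, sig = experiment.q, experiment.I, experiment.sigma
    if model.q.shape == q.shape and np.allclose(model.q, q):
        Im = model.I
    else:
        Im = np.interp(q, model.q, model.I)
    w = 1.0 / sig**2
    denom = float(np.sum(w * Im * Im))
    if denom <= 0:
        raise ValueError("model profile is identically zero")
    mu = float(np.sum(w * Im * Ie)) / denom
    resid = (mu * Im - Ie) / sig
    chi2 = float(resid @ resid) / max(q.size - 1, 1)
    return ChiSquareResult(chi2=chi2, mu=mu, Q=int(q.size))


def chi_square_given_mu(model: ScatteringProfile, experiment: ScatteringProfile,
                        mu: float) -> float:
    """Eq.-style reduced chi-square at a fixed scale factor (grid-search oracle hook)."""
    resid = (mu * model.I - experiment.I) / experiment.sigma
    return float(resid @ resid) / max(experiment.q.size - 1, 1)


# ---------------------------------------------------------------------------
# Kratky transforms
# ---------------------------------------------------------------------------


def kratky_transforms(profile: ScatteringProfile, Rg: float, I0: float):
    """Return the Kratky (q, q^2 I) and dimensionless Kratky tables.

    The dimensionless form plots (q*Rg)^2 * I/I0 against q*Rg, which removes
    size information and emphasizes chain compactness.
    """
    if Rg <= 0 or I0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    q, I = profile.q, profile.I
    kratky = np.column_stack([q, q * q * I])
    x = q * Rg
    norm = np.column_stack([x, x * x * I / I0])
    return kratky, norm


# ---------------------------------------------------------------------------
# I(0) extrapolation and contrast match point
# ---------------------------------------------------------------------------


@dataclass
class I0Extrapolation:
    I0: float
    slope: float
    n_points: int
    negative: bool = False


def extrapolate_I0_linear(profile: ScatteringProfile,
                          q_window: tuple[float, float]) -> I0Extrapolation:
    """Straight-line fit of I vs q over a low-q window, evaluated at q = 0.

    Used for associating samples where a Guinier analysis is no longer
    meaningful; a negative extrapolated intercept is flagged, not raised.
    """
    lo, hi = q_window
    m = (profile.q >= lo) & (profile.q <= hi)
    if m.sum() < 3:
        raise ValueError("I(0) extrapolation window must contain at least 3 points")
    coef = np.polyfit(profile.q[m], profile.I[m], 1)
    i0 = float(np.polyval(coef, 0.0))
    return I0Extrapolation(I0=i0, slope=float(coef[0]), n_points=int(m.sum()),
                           negative=i0 < 0)


def i0_fold_change(i0_sample: float, i0_reference: float) -> float:
    """I(0) fold change of a sample relative to a reference (molecular-weight proxy)."""
    if i0_reference == 0:
        raise ZeroDivisionError("reference I(0) is zero")
    return i0_sample / i0_reference


@dataclass
class MatchPointResult:
    rho_match: float  # e/A^3 buffer density at which I(0) vanishes
    sucrose_wv: float  # equivalent % w/v sucrose under the configured density map
    slope: float
    intercept: float
    monotonic: bool


def match_point(I0_values: Sequence[float], buffer_densities: Sequence[float],
                rho_water: float = RHO_WATER, rho_per_wv: float = RHO_PER_WV) -> MatchPointResult:
    """Contrast match point: buffer electron density at which I(0) crosses zero.

    Fits I(0) linearly against buffer density (I(0) itself, not sqrt(I0)) and
    extrapolates the zero crossing; the crossing density is converted to an
    equivalent % w/v sucrose through the linear density map rho(c).
    A non-monotonic I(0) trend is flagged on the result, not raised.
    """
    i0 = np.asarray(I0_values, dtype=float)
    rho = np.asarray(buffer_densities, dtype=float)
    if i0.size < 2 or i0.size != rho.size:
        raise ValueError("need at least two matched (I0, rho) pairs")
    d = np.diff(i0[np.argsort(rho)])
    monotonic = bool(np.all(d <= 0) or np.all(d >= 0))
    coef = np.polyfit(rho, i0, 1)
    if coef[0] == 0:
        raise ValueError("I(0) does not depend on buffer density; no crossing")
    rho_match = float(-coef[1] / coef[0])
    sucrose = (rho_match - rho_water) / rho_per_wv
    return MatchPointResult(rho_match=rho_match, sucrose_wv=float(sucrose),
                            slope=float(coef[0]), intercept=float(coef[1]),
                            monotonic=monotonic)


def peak_lengthscale(q_peak: float) -> float:
    """Real-space correlation length of a diffuse scattering peak, d = 2*pi/q."""
    if q_peak <= 0:
        raise ValueError("peak position must be positive")
    return 2.0 * np.pi / q_peak
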