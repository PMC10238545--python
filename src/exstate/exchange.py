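"""Forward models of two-site chemical exchange.

The central quantity is the effective transverse relaxation rate R2eff of a
spin exchanging between two environments A and B (populations pA, pB;
rates k1 = pB*kex for A->B and k-1 = pA*kex for B->A; chemical-shift
difference delta-omega) during a constant-time CPMG spin-echo train.

Two independent routes compute R2eff:

* :func:`r2eff_exact` -- the exact analytic solution, obtained by closed-form
  eigendecomposition of the 2x2 complex Bloch-McConnell propagator over the
  echo train (the all-timescale Carver-Richards family result, with no
  fast/slow-exchange approximation);
* :func:`r2eff_numeric` -- brute-force propagation using scipy's generic
  matrix exponential, echo by echo.

Also here: one-dimensional McConnell exchange lineshapes, the Arrhenius rate
law that couples exchange rates across temperatures, and the constant-time
intensity-to-R2eff conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg
from scipy.optimize import least_squares

from .constants import R_GAS, ppm_to_rad_s

NUCLEUS_OF = {"13C-methyl": "13C", "15N-amide": "15N"}


@dataclass
class TwoSiteExchangeParams:
    """State of the two-site exchange model A <=> B (B minor)."""

    pb: float                 # minor-state population fraction
    kex: float                # s^-1, k1 + k-1
    delta_omega: float        # ppm, |shift difference|
    r2a: float                # s^-1 intrinsic R2 of A
    r2b: float | None = None  # s^-1; None means equal to r2a
    nucleus: str = "13C"      # which nucleus the shift difference is on
    field_mhz: float = 700.0  # 1H frequency of the field

    def __post_init__(self):
        if not 0.0 <= self.pb <= 0.5:
            raise ValueError("pb must be in [0, 0.5] (minor-state convention)")
        if self.kex <= 0:
            raise ValueError("kex must be positive")
        if self.r2a < 0 or (self.r2b is not None and self.r2b < 0):
            raise ValueError("intrinsic R2 must be non-negative")

    @property
    def pa(self) -> float:
        return 1.0 - self.pb

    @property
    def k1(self) -> float:
        return self.pb * self.kex

    @property
    def km1(self) -> float:
        return self.pa * self.kex

    @property
    def r2b_eff(self) -> float:
        return self.r2a if self.r2b is None else self.r2b

    @property
    def domega_rad(self) -> float:
        return ppm_to_rad_s(self.delta_omega, self.nucleus, self.field_mhz)


@dataclass(frozen=True)
class ArrheniusLaw:
    """k(T) = A * exp(-Ea / (R T)); Ea in kJ/mol."""

    prefactor: float  # s^-1
    ea_kj_mol: float

    def __post_init__(self):
        if self.prefactor <= 0:
            raise ValueError("prefactor must be positive")

    @classmethod
    def from_rate_at(cls, k_ref: float, t_ref: float,
                     ea_kj_mol: float) -> "ArrheniusLaw":
        """Build from a rate at a reference temperature (better conditioned
        than specifying the prefactor directly)."""
        a = k_ref * np.exp(1e3 * ea_kj_mol / (R_GAS * t_ref))
        return cls(float(a), float(ea_kj_mol))


def arrhenius_k(law: ArrheniusLaw, temperature: float) -> float:
    """Rate constant (s^-1) at `temperature` (K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return law.prefactor * np.exp(-1e3 * law.ea_kj_mol / (R_GAS * temperature))


@dataclass
class DispersionProfile:
    """One residue's R2eff vs nu_cpmg at one field and temperature."""

    resnum: int
    nucleus: str          # "13C-methyl" or "15N-amide"
    field_mhz: float
    temperature: float    # K
    nu_cpmg: np.ndarray   # Hz
    r2eff: np.ndarray     # s^-1
    error: np.ndarray     # s^-1
    t_cp: float = 0.020   # s, constant-time spin-echo period

    def __post_init__(self):
        self.nu_cpmg = np.asarray(self.nu_cpmg, float)
        self.r2eff = np.asarray(self.r2eff, float)
        self.error = np.asarray(self.error, float)
        if len(np.unique(self.nu_cpmg)) < 4:
            raise ValueError("need >=4 distinct nu_cpmg values")
        if np.any(self.error <= 0):
            raise ValueError("errors must be positive")


@dataclass
class SpectrumGrid:
    """A simulated 1D spectrum: intensity on a frequency grid (rad/s)."""

    omega: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.omega = np.asarray(self.omega, float)
        self.intensity = np.asarray(self.intensity, float)
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("frequency axis must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("non-finite intensities")


# ---------------------------------------------------------------------------
# CPMG R2eff

def _echo_count(nu_cpmg: float, t_cp: float, strict: bool) -> int:
    n_float = t_cp * nu_cpmg
    n = int(round(n_float))
    if n < 1:
        raise ValueError(f"nu_cpmg={nu_cpmg} gives no complete echo block "
                         f"in T_CP={t_cp}")
    if abs(n - n_float) > 1e-6:
        if strict or abs(n - n_float) >= 0.01:
            raise ValueError(f"nu_cpmg={nu_cpmg} implies a non-integer echo "
                             f"count {n_float} in T_CP={t_cp}")
        warnings.warn(f"nu_cpmg={nu_cpmg}: echo count {n_float} rounded to {n}",
                      stacklevel=3)
    return n


def _bm_matrix(pa, pb, kex, domega_rad, r2a, r2b):
    """2x2 complex evolution matrix for transverse magnetization, rotating
    frame on site A."""
    k1 = pb * kex
    km1 = pa * kex
    return np.array([
        [-r2a - k1, km1],
        [k1, -r2b - km1 - 1j * domega_rad],
    ], dtype=complex)


def _expm2(a: np.ndarray) -> np.ndarray:
    """Closed-form exponential of a 2x2 complex matrix."""
    mu = 0.5 * (a[0, 0] + a[1, 1])
    q = np.sqrt(mu * mu - (a[0, 0] * a[1, 1] - a[0, 1] * a[1, 0]) + 0j)
    if abs(q) < 1e-14:
        f0, f1 = 1.0, 1.0
    else:
        f0, f1 = np.cosh(q), np.sinh(q) / q
    return np.exp(mu) * (f0 * np.eye(2) + f1 * (a - mu * np.eye(2)))


def _matpow2(u: np.ndarray, n: int) -> np.ndarray:
    """Closed-form n-th power of a 2x2 complex matrix via its spectrum."""
    mu = 0.5 * (u[0, 0] + u[1, 1])
    det = u[0, 0] * u[1, 1] - u[0, 1] * u[1, 0]
    q = np.sqrt(mu * mu - det + 0j)
    lp, lm = mu + q, mu - q
    if abs(lp - lm) < 1e-12 * max(abs(lp), 1.0):
        # defective/degenerate: U^n = l^n I + n l^(n-1) (U - l I)
        return lp ** n * np.eye(2) + n * lp ** (n - 1) * (u - lp * np.eye(2))
    return (lp ** n * (u - lm * np.eye(2)) -
            lm ** n * (u - lp * np.eye(2))) / (lp - lm)


def _r2eff_exact_sites(pa, pb, kex, domega_rad, r2a, r2b, nu_cpmg, t_cp,
                       strict_echo=False):
    n = _echo_count(nu_cpmg, t_cp, strict_echo)
    tau = t_cp / (4.0 * n)
    p = _expm2(_bm_matrix(pa, pb, kex, domega_rad, r2a, r2b) * tau)
    # one (tau-180-tau)^2 block: conjugations of the two 180 pulses cancel
    u = p @ np.conj(p) @ np.conj(p) @ p
    m = _matpow2(u, n) @ np.array([pa, pb], dtype=complex)
    signal = abs(m.sum())
    return -np.log(signal) / t_cp


def r2eff_exact(params: TwoSiteExchangeParams, nu_cpmg) -> float | np.ndarray:
    """Exact analytic two-site CPMG R2eff (s^-1) at `nu_cpmg` (Hz, scalar
    or array) for a 20-ms-class constant-time spin-echo train."""
    nu = np.asarray(nu_cpmg, float)
    if np.any(nu <= 0):
        raise ValueError("nu_cpmg must be positive")
    out = np.array([
        _r2eff_exact_sites(params.pa, params.pb, params.kex,
                           params.domega_rad, params.r2a, params.r2b_eff,
                           v, 0.020)
        for v in np.atleast_1d(nu)
    ])
    return float(out[0]) if nu.ndim == 0 else out


def r2eff_exact_grid(pa, pb, kex, domega_rad, nu_cpmg, t_cp: float = 0.020,
                     r2: float = 0.0) -> np.ndarray:
    """Vectorized exact CPMG R2eff over a grid of shift differences.

    `domega_rad` has shape (m,), `nu_cpmg` shape (k,); returns (m, k).
    Equal intrinsic R2 on both sites (`r2`); because equal intrinsic
    relaxation factors out of the propagator, fits evaluate this at r2=0
    and add the per-profile baseline analytically.
    """
    dw = np.atleast_1d(np.asarray(domega_rad, float))[:, None]
    nu = np.atleast_1d(np.asarray(nu_cpmg, float))[None, :]
    n = np.round(t_cp * nu)
    if np.any(n < 1):
        raise ValueError("nu_cpmg too small for T_CP")
    tau = t_cp / (4.0 * n)
    k1, km1 = pb * kex, pa * kex
    a11 = (-r2 - k1) * tau + 0j
    a12 = km1 * tau + 0j
    a21 = k1 * tau + 0j
    a22 = (-r2 - km1 - 1j * dw) * tau
    # closed-form 2x2 exponential, elementwise
    mu = 0.5 * (a11 + a22)
    q = np.sqrt(mu * mu - (a11 * a22 - a12 * a21))
    small = np.abs(q) < 1e-12
    qs = np.where(small, 1.0, q)
    f0 = np.where(small, 1.0, np.cosh(qs))
    f1 = np.where(small, 1.0, np.sinh(qs) / qs)
    e = np.exp(mu)
    p11 = e * (f0 + f1 * (a11 - mu))
    p12 = e * f1 * a12
    p21 = e * f1 * a21
    p22 = e * (f0 + f1 * (a22 - mu))
    c11, c12 = np.conj(p11), np.conj(p12)
    c21, c22 = np.conj(p21), np.conj(p22)
    # B = conj(P) P ; D = conj(P) B ; U = P D  (one (tau-180-tau)^2 block)
    b11 = c11 * p11 + c12 * p21
    b12 = c11 * p12 + c12 * p22
    b21 = c21 * p11 + c22 * p21
    b22 = c21 * p12 + c22 * p22
    d11 = c11 * b11 + c12 * b21
    d12 = c11 * b12 + c12 * b22
    d21 = c21 * b11 + c22 * b21
    d22 = c21 * b12 + c22 * b22
    u11 = p11 * d11 + p12 * d21
    u12 = p11 * d12 + p12 * d22
    u21 = p21 * d11 + p22 * d21
    u22 = p21 * d12 + p22 * d22
    # U^n via the 2x2 spectrum
    mu2 = 0.5 * (u11 + u22)
    q2 = np.sqrt(mu2 * mu2 - (u11 * u22 - u12 * u21))
    lp, lm = mu2 + q2, mu2 - q2
    diff = lp - lm
    deg = np.abs(diff) < 1e-12 * np.maximum(np.abs(lp), 1.0)
    diffs = np.where(deg, 1.0, diff)
    lpn, lmn = lp ** n, lm ** n
    g11 = (lpn * (u11 - lm) - lmn * (u11 - lp)) / diffs
    g12 = (lpn - lmn) * u12 / diffs
    g21 = (lpn - lmn) * u21 / diffs
    g22 = (lpn * (u22 - lm) - lmn * (u22 - lp)) / diffs
    if np.any(deg):
        nl = n * lp ** (n - 1)
        g11 = np.where(deg, lpn + nl * (u11 - lp), g11)
        g12 = np.where(deg, nl * u12, g12)
        g21 = np.where(deg, nl * u21, g21)
        g22 = np.where(deg, lpn + nl * (u22 - lp), g22)
    m_sum = (g11 + g21) * pa + (g12 + g22) * pb
    return -np.log(np.abs(m_sum)) / t_cp


def r2eff_numeric(params: TwoSiteExchangeParams, nu_cpmg: float,
                  t_cp: float = 0.020) -> float:
    """Numerical Bloch-McConnell oracle for :func:`r2eff_exact`.

    Propagates the magnetization echo by echo with scipy's generic matrix
    exponential; requires an integer echo count n = T_CP * nu_cpmg.
    """
    n_float = t_cp * nu_cpmg
    n = int(round(n_float))
    if n < 1 or abs(n - n_float) > 1e-6:
        raise ValueError(f"non-integer echo count {n_float}")
    tau = t_cp / (4.0 * n)
    a = _bm_matrix(params.pa, params.pb, params.kex, params.domega_rad,
                   params.r2a, params.r2b_eff)
    p = scipy.linalg.expm(a * tau)
    m = np.array([params.pa, params.pb], dtype=complex)
    for _ in range(n):
        for _ in range(2):  # two tau-180-tau echoes per block
            m = p @ m
            m = np.conj(m)
            m = p @ m
    return float(-np.log(abs(m.sum())) / t_cp)


def intensities_to_r2eff(intensity, ref_intensity, t_cp: float = 0.020,
                         sigma_intensity=None):
    """Constant-time relation R2eff = -(1/T_CP) ln(I/I0).

    If `sigma_intensity` is given, the propagated R2eff error
    sigma_I / (I * T_CP) is returned as a second value.
    """
    i = np.asarray(intensity, float)
    i0 = np.asarray(ref_intensity, float)
    if np.any(i <= 0) or np.any(i0 <= 0):
        raise ValueError("intensities must be positive")
    r2 = -np.log(i / i0) / t_cp
    if sigma_intensity is None:
        return r2
    return r2, np.asarray(sigma_intensity, float) / (i * t_cp)


# ---------------------------------------------------------------------------
# 1D exchange lineshapes

def two_site_exchange_matrix(pa: float, pb: float, kex: float) -> np.ndarray:
    """Kinetic matrix X (dM/dt = ... + X M) for A <=> B."""
    k1 = pb * kex
    km1 = pa * kex
    return np.array([[-k1, km1], [k1, -km1]])


def lineshape_1d(sites, exchange_matrix, omega_grid,
                 linewidth_floor: float = 1e-3) -> SpectrumGrid:
    """Frequency-domain McConnell lineshape for n exchanging sites.

    `sites` is a list of (population, offset rad/s, R2 s^-1);
    `exchange_matrix` X has X[i, j] = rate j->i (i != j) and column sums 0,
    and must satisfy detailed balance with the populations.
    I(w) = Re[ 1^T (i(w - Omega) + R2 + K)^-1 p ] with K = -X.
    """
    sites = list(sites)
    p = np.array([s[0] for s in sites], float)
    if abs(p.sum() - 1.0) > 1e-6:
        raise ValueError("populations must sum to 1")
    x = np.asarray(exchange_matrix, float)
    if np.any(np.abs(x.sum(axis=0)) > 1e-8 * (1 + np.abs(x).max())):
        raise ValueError("exchange matrix columns must sum to zero")
    db = x * p[np.newaxis, :] - (x * p[np.newaxis, :]).T
    np.fill_diagonal(db, 0.0)
    if np.abs(db).max() > 1e-6 * (1 + np.abs(x).max()):
        raise ValueError("exchange matrix violates detailed balance")
    omegas = np.array([s[1] for s in sites], float)
    r2 = np.maximum(np.array([s[2] for s in sites], float), linewidth_floor)
    grid = np.asarray(omega_grid, float)
    ones = np.ones(len(sites))
    inten = np.empty_like(grid)
    base = np.diag(r2 + 1j * (-omegas)) - x
    for i, w in enumerate(grid):
        a = base + 1j * w * np.eye(len(sites))
        inten[i] = np.real(ones @ np.linalg.solve(a, p.astype(complex)))
    return SpectrumGrid(grid, inten)


def populations_from_peaks(major_area: float, minor_area: float) -> float:
    """Minor-state population fraction from two peak areas."""
    if major_area < 0 or minor_area < 0:
        raise ValueError("areas must be non-negative")
    total = major_area + minor_area
    if total == 0:
        raise ValueError("both areas are zero")
    return minor_area / total


def fit_lorentzians(spectrum: SpectrumGrid, n_peaks: int = 2):
    """Fit a sum of Lorentzians; returns a list of (area, center, halfwidth)
    sorted by descending area."""
    w, y = spectrum.omega, spectrum.intensity
    # initial guesses: strongest grid maxima, spaced apart
    order = np.argsort(y)[::-1]
    centers: list[float] = []
    min_sep = (w[-1] - w[0]) / (6 * n_peaks)
    for i in order:
        if all(abs(w[i] - c) > min_sep for c in centers):
            centers.append(w[i])
        if len(centers) == n_peaks:
            break
    while len(centers) < n_peaks:
        centers.append(w[len(w) // 2])
    hw0 = (w[-1] - w[0]) / 50.0
    a0 = np.trapezoid(y, w) / n_peaks

    def model(theta):
        out = np.zeros_like(w)
        for k in range(n_peaks):
            a, c, hw = theta[3 * k:3 * k + 3]
            out = out + (a / np.pi) * hw / ((w - c) ** 2 + hw ** 2)
        return out

    theta0 = np.concatenate([[a0, c, hw0] for c in centers])
    lb = np.tile([0.0, w[0], 1e-6], n_peaks)
    ub = np.tile([np.inf, w[-1], w[-1] - w[0]], n_peaks)
    res = least_squares(lambda t: model(t) - y, theta0, bounds=(lb, ub))
    peaks = [tuple(res.x[3 * k:3 * k + 3]) for k in range(n_peaks)]
    return sorted(peaks, key=lambda p: -p[0])
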