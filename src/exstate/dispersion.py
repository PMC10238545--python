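"""Fitting of CPMG relaxation-dispersion profiles to two-site exchange.

Two fitting modes mirror the experimental analysis:

* single temperature -- all residues measured at one temperature share a
  global (kex, pB); each residue contributes its own shift difference and
  intrinsic R2 baseline;
* multi-temperature -- the forward (k1) and reverse (k-1) rates each follow
  an Arrhenius law, which couples (kex, pB) across temperatures, while the
  per-residue shift difference is temperature independent.

Every fit starts from an extensive grid search and finishes with bounded
least-squares descent; the descent is guaranteed monotone in the sense that
the returned solution never has a higher chi^2 than its starting point.
Parameter uncertainties are the standard deviations among the `n_keep`
best of `n_starts` fits launched from random initial points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .constants import R_GAS, ppm_to_rad_s
from .exchange import (ArrheniusLaw, DispersionProfile, NUCLEUS_OF,
                       arrhenius_k, intensities_to_r2eff, r2eff_exact_grid)
from .formats_io import DispersionRecord

# grid-search ranges (log-spaced kex)
KEX_GRID = np.geomspace(100.0, 6000.0, 20)
PB_GRID = np.linspace(0.01, 0.5, 10)
DW_GRID = np.linspace(0.1, 5.0, 10)
BOUNDS = {"kex": (10.0, 3.0e4), "pb": (1e-4, 0.5), "dw": (0.0, 10.0),
          "r20": (0.0, 200.0), "ea": (0.0, 200.0)}
T_REF = 298.15


@dataclass
class FitResult:
    """Outcome of a dispersion fit."""

    params: dict                     # named global parameter estimates
    per_residue: dict                # resnum -> {"dw": ppm, "r20": {...}, "detectable": bool}
    chi2: float
    red_chi2: float
    n_points: int
    n_params: int
    residuals: np.ndarray
    converged: bool
    param_std: dict | None = None    # from multi-start spread
    populations: dict = field(default_factory=dict)  # temperature -> pB
    message: str = ""


def profiles_from_records(records: list[DispersionRecord],
                          t_cp: float = 0.020) -> list[DispersionProfile]:
    """Assemble per-(residue, temperature) profiles from table records.

    Intensities are converted with the constant-time relation; when no
    per-point error column is present, point errors come from the spread of
    replicated nu_cpmg measurements (replicated points get their own group
    standard deviation, unreplicated points the pooled value). Replicates
    remain individual data points.
    """
    groups: dict[tuple, list[DispersionRecord]] = {}
    for r in records:
        groups.setdefault((r.resnum, r.temperature, r.field_mhz, r.nucleus),
                          []).append(r)
    profiles = []
    for (resnum, temp, field_mhz, nucleus), recs in groups.items():
        nu = np.array([r.nu_cpmg for r in recs])
        r2 = np.array([
            r.r2eff if r.r2eff is not None
            else intensities_to_r2eff(r.intensity, r.ref_intensity, t_cp)
            for r in recs
        ], dtype=float)
        err = np.array([r.error if r.error is not None else np.nan
                        for r in recs])
        if np.any(np.isnan(err)):
            group_sd: dict[float, float] = {}
            for v in np.unique(nu):
                vals = r2[nu == v]
                if len(vals) >= 2:
                    group_sd[v] = float(np.std(vals, ddof=1))
            if not group_sd:
                raise ValueError(
                    f"residue {resnum} at {temp} K: no error column and no "
                    f"replicated nu_cpmg points to estimate errors from")
            pooled = float(np.sqrt(np.mean(np.square(list(group_sd.values())))))
            pooled = max(pooled, 1e-3)
            est = np.array([max(group_sd.get(v, pooled), 1e-3) for v in nu])
            err = np.where(np.isnan(err), est, err)
        profiles.append(DispersionProfile(resnum, nucleus, field_mhz, temp,
                                          nu, r2, err, t_cp))
    return profiles


def detect_dispersion(profile: DispersionProfile,
                      threshold_factor: float = 2.0) -> tuple[bool, float]:
    """Dispersion amplitude R2eff(min nu) - R2eff(max nu) and whether it is
    well above the experimental errors (strictly greater than
    `threshold_factor` times the median point error)."""
    lo = profile.nu_cpmg == profile.nu_cpmg.min()
    hi = profile.nu_cpmg == profile.nu_cpmg.max()
    amplitude = float(profile.r2eff[lo].mean() - profile.r2eff[hi].mean())
    threshold = threshold_factor * float(np.median(profile.error))
    return amplitude > threshold, amplitude


def _dw_rad(dw_ppm: np.ndarray, profile: DispersionProfile) -> np.ndarray:
    nuc = NUCLEUS_OF.get(profile.nucleus, profile.nucleus.split("-")[0])
    return np.array([ppm_to_rad_s(d, nuc, profile.field_mhz)
                     for d in np.atleast_1d(dw_ppm)])


def _baseline_and_chi2(obs, err, g):
    """Optimal intrinsic-R2 baseline (weighted mean of obs - g) and the
    resulting chi^2; g is the exchange contribution at r2=0."""
    w = 1.0 / err ** 2
    r20 = np.sum(w * (obs - g), axis=-1) / np.sum(w)
    resid = (obs - g - np.atleast_1d(r20)[..., None]) / err
    return r20, np.sum(resid ** 2, axis=-1)


# ---------------------------------------------------------------------------
# single temperature

class SingleTemperatureProblem:
    """Global two-site fit at one temperature: shared (kex, pB), per-residue
    shift difference; intrinsic R2 baselines are profiled out analytically."""

    def __init__(self, profiles: list[DispersionProfile]):
        if not profiles:
            raise ValueError("need at least one profile")
        temps = {p.temperature for p in profiles}
        if len(temps) != 1:
            raise ValueError(f"profiles span several temperatures: {temps}")
        self.profiles = list(profiles)
        self.temperature = temps.pop()
        self.n_points = sum(len(p.nu_cpmg) for p in profiles)
        # free parameters: log10(kex), pB, dw per residue
        self.n_params = 2 + 2 * len(profiles)  # dw + analytic r20 per residue
        lo = [np.log10(BOUNDS["kex"][0]), BOUNDS["pb"][0]] + \
             [BOUNDS["dw"][0]] * len(profiles)
        hi = [np.log10(BOUNDS["kex"][1]), BOUNDS["pb"][1]] + \
             [BOUNDS["dw"][1]] * len(profiles)
        self.bounds = (np.array(lo), np.array(hi))
        self.param_names = ["kex", "pb"] + \
            [f"dw_{p.resnum}" for p in profiles]

    def residuals(self, x: np.ndarray) -> np.ndarray:
        kex, pb = 10.0 ** x[0], x[1]
        out = []
        for i, p in enumerate(self.profiles):
            dw_rad = _dw_rad(x[2 + i], p)
            g = r2eff_exact_grid(1 - pb, pb, kex, dw_rad, p.nu_cpmg, p.t_cp)[0]
            r20, _ = _baseline_and_chi2(p.r2eff, p.error, g)
            out.append((p.r2eff - g - r20) / p.error)
        return np.concatenate(out)

    def chi2(self, x: np.ndarray) -> float:
        return float(np.sum(self.residuals(x) ** 2))

    def baselines(self, x: np.ndarray) -> dict[int, float]:
        kex, pb = 10.0 ** x[0], x[1]
        out = {}
        for i, p in enumerate(self.profiles):
            g = r2eff_exact_grid(1 - pb, pb, kex, _dw_rad(x[2 + i], p),
                                 p.nu_cpmg, p.t_cp)[0]
            r20, _ = _baseline_and_chi2(p.r2eff, p.error, g)
            out[p.resnum] = float(r20)
        return out

    def grid_start(self) -> np.ndarray:
        best = (np.inf, None)
        for kex in KEX_GRID:
            for pb in PB_GRID:
                chi2 = 0.0
                dws = []
                for p in self.profiles:
                    g = r2eff_exact_grid(1 - pb, pb, kex, _dw_rad(DW_GRID, p),
                                         p.nu_cpmg, p.t_cp)
                    _, c = _baseline_and_chi2(p.r2eff, p.error, g)
                    j = int(np.argmin(c))
                    chi2 += c[j]
                    dws.append(DW_GRID[j])
                if chi2 < best[0]:
                    best = (chi2, np.array([np.log10(kex), pb] + dws))
        return best[1]

    def fit_from(self, x0: np.ndarray) -> tuple[np.ndarray, float, bool]:
        c0 = self.chi2(x0)
        res = least_squares(self.residuals, x0, bounds=self.bounds,
                            xtol=1e-10, ftol=1e-10, max_nfev=400)
        c1 = float(2 * res.cost)
        if c1 <= c0:  # monotone-descent contract
            return res.x, c1, bool(res.success)
        return x0, c0, False

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds
        return rng.uniform(lo, hi)

    def result(self, x: np.ndarray, chi2: float, converged: bool,
               message: str = "") -> FitResult:
        kex, pb = 10.0 ** x[0], x[1]
        r20 = self.baselines(x)
        per_res = {}
        for i, p in enumerate(self.profiles):
            detectable, amp = detect_dispersion(p)
            per_res[p.resnum] = {
                "dw": float(x[2 + i]), "r20": r20[p.resnum],
                "detectable": detectable, "amplitude": amp,
            }
        dof = max(self.n_points - self.n_params, 1)
        if not any(v["detectable"] for v in per_res.values()):
            message = (message + " exchange not detectable: dispersion "
                       "amplitudes within experimental error").strip()
        return FitResult(
            params={"kex": float(kex), "pb": float(pb)},
            per_residue=per_res, chi2=chi2, red_chi2=chi2 / dof,
            n_points=self.n_points, n_params=self.n_params,
            residuals=self.residuals(x), converged=converged,
            populations={self.temperature: float(pb)}, message=message)


def fit_single_temperature(profiles: list[DispersionProfile],
                           n_error_starts: int = 0, n_keep: int = 10,
                           seed: int = 0) -> FitResult:
    """Grid search + bounded descent for the shared (kex, pB) model."""
    prob = SingleTemperatureProblem(profiles)
    x, chi2, ok = prob.fit_from(prob.grid_start())
    result = prob.result(x, chi2, ok)
    if n_error_starts:
        result.param_std = estimate_errors(prob, n_starts=n_error_starts,
                                           n_keep=n_keep, seed=seed)
    return result


# ---------------------------------------------------------------------------
# multi-temperature with Arrhenius-coupled rates

class MultiTemperatureProblem:
    """Global fit over >=2 temperatures: two Arrhenius laws (k1 and k-1)
    shared by all residues, a temperature-independent shift difference per
    residue, and per-(residue, temperature) baselines profiled out."""

    def __init__(self, profiles: list[DispersionProfile], t_ref: float = T_REF):
        temps = sorted({p.temperature for p in profiles})
        if len(temps) < 2:
            raise ValueError("need profiles at >=2 distinct temperatures")
        self.profiles = list(profiles)
        self.temperatures = temps
        self.t_ref = t_ref
        self.resnums = sorted({p.resnum for p in profiles})
        self.n_points = sum(len(p.nu_cpmg) for p in profiles)
        # log10 k1(Tref), Ea1, log10 k-1(Tref), Ea-1, dw per residue
        # (+ one analytic baseline per profile)
        self.n_params = 4 + len(self.resnums) + len(self.profiles)
        n_res = len(self.resnums)
        lo = [np.log10(BOUNDS["kex"][0] * BOUNDS["pb"][0]), BOUNDS["ea"][0],
              np.log10(BOUNDS["kex"][0] * 0.5), BOUNDS["ea"][0]] + \
             [BOUNDS["dw"][0]] * n_res
        hi = [np.log10(BOUNDS["kex"][1]), BOUNDS["ea"][1],
              np.log10(BOUNDS["kex"][1]), BOUNDS["ea"][1]] + \
             [BOUNDS["dw"][1]] * n_res
        self.bounds = (np.array(lo), np.array(hi))
        self.param_names = ["k1_ref", "ea1", "km1_ref", "ea_m1"] + \
            [f"dw_{r}" for r in self.resnums]

    def rates_at(self, x: np.ndarray, temperature: float) -> tuple[float, float]:
        scale = (1e3 / R_GAS) * (1.0 / temperature - 1.0 / self.t_ref)
        k1 = 10.0 ** x[0] * np.exp(-x[1] * scale)
        km1 = 10.0 ** x[2] * np.exp(-x[3] * scale)
        return k1, km1

    def residuals(self, x: np.ndarray) -> np.ndarray:
        out = []
        for p in self.profiles:
            k1, km1 = self.rates_at(x, p.temperature)
            kex = k1 + km1
            pb = min(k1 / kex, 0.5)
            dw = x[4 + self.resnums.index(p.resnum)]
            g = r2eff_exact_grid(1 - pb, pb, kex, _dw_rad(dw, p),
                                 p.nu_cpmg, p.t_cp)[0]
            r20, _ = _baseline_and_chi2(p.r2eff, p.error, g)
            out.append((p.r2eff - g - r20) / p.error)
        return np.concatenate(out)

    def chi2(self, x: np.ndarray) -> float:
        return float(np.sum(self.residuals(x) ** 2))

    def fit_from(self, x0: np.ndarray) -> tuple[np.ndarray, float, bool]:
        c0 = self.chi2(x0)
        res = least_squares(self.residuals, x0, bounds=self.bounds,
                            xtol=1e-10, ftol=1e-10, max_nfev=600)
        c1 = float(2 * res.cost)
        if c1 <= c0:
            return res.x, c1, bool(res.success)
        return x0, c0, False

    def random_start(self, rng: np.random.Generator) -> np.ndarray:
        lo, hi = self.bounds
        return rng.uniform(lo, hi)

    def grid_start(self) -> np.ndarray:
        """Initialize from independent single-temperature grid fits followed
        by an Arrhenius regression of the implied k1(T), k-1(T)."""
        k1s, km1s, ts = [], [], []
        dw_by_res: dict[int, list[float]] = {}
        for t in self.temperatures:
            sub = [p for p in self.profiles if p.temperature == t]
            prob = SingleTemperatureProblem(sub)
            x, _, _ = prob.fit_from(prob.grid_start())
            kex, pb = 10.0 ** x[0], x[1]
            ts.append(t)
            k1s.append(max(pb * kex, 1e-3))
            km1s.append(max((1 - pb) * kex, 1e-3))
            for i, p in enumerate(sub):
                dw_by_res.setdefault(p.resnum, []).append(float(x[2 + i]))
        inv_t = (1e3 / R_GAS) * (1.0 / np.array(ts) - 1.0 / self.t_ref)
        ea1, b1 = np.polyfit(-inv_t, np.log(k1s), 1)
        eam1, bm1 = np.polyfit(-inv_t, np.log(km1s), 1)
        clip = lambda v, b: float(np.clip(v, b[0], b[1]))
        x0 = [clip(b1 / np.log(10.0), (self.bounds[0][0], self.bounds[1][0])),
              clip(ea1, BOUNDS["ea"]),
              clip(bm1 / np.log(10.0), (self.bounds[0][2], self.bounds[1][2])),
              clip(eam1, BOUNDS["ea"])]
        for r in self.resnums:
            x0.append(clip(np.mean(dw_by_res.get(r, [1.0])), BOUNDS["dw"]))
        return np.array(x0)

    def result(self, x: np.ndarray, chi2: float, converged: bool) -> FitResult:
        k1_ref, km1_ref = self.rates_at(x, self.t_ref)
        laws = {
            "k1": ArrheniusLaw.from_rate_at(k1_ref, self.t_ref, float(x[1])),
            "km1": ArrheniusLaw.from_rate_at(km1_ref, self.t_ref, float(x[3])),
        }
        pops = {}
        for t in self.temperatures:
            k1, km1 = self.rates_at(x, t)
            pops[t] = float(k1 / (k1 + km1))
        per_res = {}
        for p in self.profiles:
            det, amp = detect_dispersion(p)
            entry = per_res.setdefault(p.resnum, {
                "dw": float(x[4 + self.resnums.index(p.resnum)]),
                "r20": {}, "detectable": False, "amplitude": {}})
            k1, km1 = self.rates_at(x, p.temperature)
            kex = k1 + km1
            pb = min(k1 / kex, 0.5)
            g = r2eff_exact_grid(1 - pb, pb, kex,
                                 _dw_rad(entry["dw"], p), p.nu_cpmg, p.t_cp)[0]
            r20, _ = _baseline_and_chi2(p.r2eff, p.error, g)
            entry["r20"][p.temperature] = float(r20)
            entry["amplitude"][p.temperature] = amp
            entry["detectable"] = entry["detectable"] or det
        dof = max(self.n_points - self.n_params, 1)
        return FitResult(
            params={
                "k1_ref": float(k1_ref), "ea1": float(x[1]),
                "km1_ref": float(km1_ref), "ea_m1": float(x[3]),
                "kex_ref": float(k1_ref + km1_ref),
                "pb_ref": float(k1_ref / (k1_ref + km1_ref)),
                "t_ref": self.t_ref, "arrhenius": laws,
            },
            per_residue=per_res, chi2=chi2, red_chi2=chi2 / dof,
            n_points=self.n_points, n_params=self.n_params,
            residuals=self.residuals(x), converged=converged,
            populations=pops)


def fit_multitemperature(profiles: list[DispersionProfile],
                         t_ref: float = T_REF, n_error_starts: int = 0,
                         n_keep: int = 10, seed: int = 0) -> FitResult:
    """Arrhenius-coupled global fit across temperatures."""
    prob = MultiTemperatureProblem(profiles, t_ref)
    x, chi2, ok = prob.fit_from(prob.grid_start())
    result = prob.result(x, chi2, ok)
    if n_error_starts:
        result.param_std = estimate_errors(prob, n_starts=n_error_starts,
                                           n_keep=n_keep, seed=seed)
    return result


def estimate_errors(problem, n_starts: int = 100, n_keep: int = 10,
                    seed: int = 0) -> dict[str, float]:
    """Parameter uncertainties as standard deviations among the `n_keep`
    lowest-chi^2 fits out of `n_starts` random initial points."""
    if n_keep > n_starts:
        raise ValueError("n_keep must not exceed n_starts")
    rng = np.random.default_rng(seed)
    fits = []
    for _ in range(n_starts):
        x, chi2, ok = problem.fit_from(problem.random_start(rng))
        if np.isfinite(chi2):
            fits.append((chi2, x))
    if not fits:
        raise RuntimeError("no start converged to a finite chi^2")
    fits.sort(key=lambda t: t[0])
    kept = np.array([x for _, x in fits[:n_keep]])
    std = kept.std(axis=0, ddof=1) if len(kept) > 1 else np.zeros(kept.shape[1])
    out = {}
    for name, s, col in zip(problem.param_names, std, kept.T):
        if name in ("kex", "k1_ref", "km1_ref"):  # stored as log10
            vals = 10.0 ** col
            out[name] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        else:
            out[name] = float(s)
    return out
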