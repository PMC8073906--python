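"""Frequency-domain fluorescence: lifetimes, anisotropy, rigid-sphere rotation.

In phase-shift/demodulation fluorometry the excitation intensity is
modulated at angular frequency ω and the emission is characterised by its
phase lag and demodulation. For an intensity decay written with fractional
steady-state intensities f_i over lifetimes τ_i,

    N(ω) = Σ f_i ωτ_i / (1 + ω²τ_i²),    D(ω) = Σ f_i / (1 + ω²τ_i²),
    phase = arctan(N/D),                 modulation = √(N² + D²).

Anisotropy decays r(t) = r₀ Σ g_j exp(−t/φ_j) are measured differentially
between polarized components I∥(t) = I(t)(1 + 2r(t))/3 and
I⊥(t) = I(t)(1 − r(t))/3. Since every product of exponentials is again an
exponential, the sine/cosine transforms of both components are closed-form
sums of Lorentzian terms — no numerical integration is involved — and the
observables are the differential phase Δφ = φ⊥ − φ∥ (positive, peaked in
frequency, the standard sign convention) and the modulation ratio m∥/m⊥.

The expected rotational correlation time of the whole protein follows the
Stokes–Einstein–Debye relation for a hydrated sphere,

    φ_sph = η V_h / (k_B T),   V_h = M (v̄ + h) / N_A,

with partial specific volume v̄ and hydration shell h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.constants import Avogadro, Boltzmann
from scipy.optimize import least_squares

__all__ = [
    "FreqDomainSet",
    "LifetimeModel",
    "AnisotropyModel",
    "SphereSpec",
    "lifetime_response",
    "anisotropy_response",
    "fit_lifetimes",
    "fit_anisotropy",
    "sphere_rotation_time",
]

# default single-point measurement uncertainties for this instrument class
DEFAULT_SIGMA_PHASE = 0.2   # degrees
DEFAULT_SIGMA_MOD = 0.004   # dimensionless


@dataclass
class FreqDomainSet:
    """(frequency, phase, modulation) observations.

    For differential anisotropy data ``phase`` holds the polarized phase
    difference Δφ (degrees) and ``modulation`` the modulation ratio m∥/m⊥;
    ``kind`` records which convention applies.
    """

    freq: np.ndarray        # MHz, strictly increasing
    phase: np.ndarray       # degrees
    modulation: np.ndarray
    sigma_phase: np.ndarray | None = None
    sigma_mod: np.ndarray | None = None
    kind: str = "intensity"  # or "differential"

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.modulation = np.asarray(self.modulation, dtype=float)
        if not (self.freq.shape == self.phase.shape == self.modulation.shape):
            raise ValueError("freq, phase, modulation must have equal length")
        if np.any(self.freq <= 0) or np.any(np.diff(self.freq) <= 0):
            raise ValueError("frequencies must be positive and strictly increasing")
        for name in ("sigma_phase", "sigma_mod"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))


@dataclass
class LifetimeModel:
    """Multi-exponential intensity decay (≤ 4 components).

    ``taus`` in ns, strictly decreasing; ``fractions`` are fractional
    steady-state intensities summing to one.
    """

    taus: np.ndarray
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.taus.shape != self.fractions.shape:
            raise ValueError("taus and fractions must have equal length")
        if len(self.taus) > 4:
            raise ValueError("at most 4 lifetime components")
        if np.any(self.taus <= 0):
            raise ValueError("lifetimes must be positive")
        if np.any(np.diff(self.taus) >= 0):
            raise ValueError("taus must be strictly decreasing")
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValueError("fractions must be nonnegative and sum to 1")

    @property
    def amplitudes(self) -> np.ndarray:
        """Pre-exponential amplitudes α_i ∝ f_i/τ_i, normalised to Σα_iτ_i = 1."""
        a = self.fractions / self.taus
        return a / np.sum(a * self.taus)


@dataclass
class AnisotropyModel:
    """Bi-exponential anisotropy decay r(t) = r₀ Σ g_j exp(−t/φ_j)."""

    r0: float
    phis: np.ndarray   # ns, strictly decreasing
    gs: np.ndarray     # amplitude fractions summing to 1

    def __post_init__(self) -> None:
        self.phis = np.asarray(self.phis, dtype=float)
        self.gs = np.asarray(self.gs, dtype=float)
        if not 0 < self.r0 <= 0.4:
            raise ValueError("r0 must lie in (0, 0.4]")
        if self.phis.shape != self.gs.shape:
            raise ValueError("phis and gs must have equal length")
        if np.any(self.phis <= 0):
            raise ValueError("correlation times must be positive")
        if len(self.phis) > 1 and np.any(np.diff(self.phis) >= 0):
            raise ValueError("phis must be strictly decreasing")
        if np.any(self.gs < 0) or abs(self.gs.sum() - 1.0) > 1e-9:
            raise ValueError("gs must be nonnegative and sum to 1")


@dataclass
class SphereSpec:
    """Inputs of the Stokes–Einstein–Debye rotational-time prediction."""

    mass: float                 # Da
    vbar: float = 0.73          # cm^3/g partial specific volume
    hydration: float = 0.3      # g water per g protein
    viscosity: float = 1.002    # mPa s (water at 20 °C)
    temperature: float = 293.15  # K

    def __post_init__(self) -> None:
        for name in ("mass", "vbar", "hydration", "viscosity", "temperature"):
            if getattr(self, name) < 0 or (
                name != "hydration" and getattr(self, name) == 0
            ):
                raise ValueError(f"{name} must be positive")


def _omega_per_ns(freq_mhz: np.ndarray) -> np.ndarray:
    """Angular frequency in rad/ns for frequencies in MHz."""
    return 2.0 * np.pi * np.asarray(freq_mhz, dtype=float) * 1e-3


def lifetime_response(
    model: LifetimeModel, freq_mhz: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Phase (degrees) and modulation of a multi-exponential decay."""
    w = _omega_per_ns(freq_mhz)[:, None]
    with np.errstate(over="ignore"):  # huge ωτ legitimately saturates to 0
        wt = w * model.taus[None, :]
        denom = 1.0 + wt**2
        n = np.sum(model.fractions * wt / denom, axis=1)
        d = np.sum(model.fractions / denom, axis=1)
    phase = np.degrees(np.arctan2(n, d))
    modulation = np.hypot(n, d)
    return phase, modulation


def _exp_sum_transforms(c: np.ndarray, theta: np.ndarray, w: np.ndarray):
    """Sine/cosine transforms and DC integral of f(t) = Σ c_k exp(−t/θ_k)."""
    wt = w[:, None] * theta[None, :]
    denom = 1.0 + wt**2
    s = np.sum(c * theta * wt / denom, axis=1)
    cc = np.sum(c * theta / denom, axis=1)
    dc = np.sum(c * theta)
    return s, cc, dc


def _polarized_components(
    life: LifetimeModel, aniso: AnisotropyModel
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Exponential (coefficient, time-constant) expansion of I∥ and I⊥."""
    alpha = life.amplitudes
    taus = life.taus
    # cross terms exp(-t/tau_i) * exp(-t/phi_j) -> time constant theta_ij
    inv_theta = 1.0 / taus[:, None] + 1.0 / aniso.phis[None, :]
    theta_ij = (1.0 / inv_theta).ravel()
    cross = (alpha[:, None] * aniso.gs[None, :]).ravel() * aniso.r0
    c_par = np.concatenate([alpha / 3.0, 2.0 * cross / 3.0])
    c_perp = np.concatenate([alpha / 3.0, -cross / 3.0])
    thetas = np.concatenate([taus, theta_ij])
    return c_par, c_perp, thetas, thetas


def anisotropy_response(
    life: LifetimeModel, aniso: AnisotropyModel, freq_mhz: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Differential phase Δφ = φ⊥ − φ∥ (deg) and modulation ratio m∥/m⊥.

    All transforms are analytic sums of Lorentzian terms; no quadrature.
    """
    w = _omega_per_ns(freq_mhz)
    c_par, c_perp, th_par, th_perp = _polarized_components(life, aniso)
    s_par, cc_par, dc_par = _exp_sum_transforms(c_par, th_par, w)
    s_perp, cc_perp, dc_perp = _exp_sum_transforms(c_perp, th_perp, w)
    delta_phase = np.degrees(np.arctan2(s_perp, cc_perp) - np.arctan2(s_par, cc_par))
    mod_par = np.hypot(s_par, cc_par) / dc_par
    mod_perp = np.hypot(s_perp, cc_perp) / dc_perp
    return delta_phase, mod_par / mod_perp


@dataclass
class LifetimeFit:
    model: LifetimeModel
    chi2_red: float
    stderr_taus: np.ndarray | None
    stderr_fractions: np.ndarray | None
    warnings: list[str] = field(default_factory=list)


@dataclass
class AnisotropyFit:
    model: AnisotropyModel
    chi2_red: float
    stderr: dict[str, float] | None
    warnings: list[str] = field(default_factory=list)


def _fractions_from_z(z: np.ndarray, n: int) -> np.ndarray:
    """Softmax over (z_1..z_{n-1}, 0): unconstrained reals -> simplex."""
    full = np.concatenate([z, [0.0]])
    e = np.exp(full - full.max())
    return e / e.sum()


def _weighted_residuals(data: FreqDomainSet):
    sp = data.sigma_phase if data.sigma_phase is not None else DEFAULT_SIGMA_PHASE
    sm = data.sigma_mod if data.sigma_mod is not None else DEFAULT_SIGMA_MOD
    return sp, sm


def fit_lifetimes(
    data: FreqDomainSet, n_components: int, seed: int = 0
) -> LifetimeFit:
    """Weighted least-squares fit of an n-component lifetime model.

    Phase and modulation residuals are stacked with per-point uncertainties
    (instrument defaults when none given). Lifetimes are fitted on a log10
    scale and fractional intensities through a softmax parameterisation;
    ten seeded starting points are tried and the lowest-χ² solution kept,
    reported with lifetimes in canonical decreasing order.
    """
    if not 1 <= n_components <= 4:
        raise ValueError("n_components must be in 1..4")
    n_obs = 2 * len(data.freq)
    n_par = 2 * n_components - 1
    if n_obs < 2 * n_par:
        raise ValueError("too few data points for the requested model")
    sp, sm = _weighted_residuals(data)

    def unpack(x):
        taus = 10.0 ** np.clip(x[:n_components], -6.0, 6.0)
        fracs = _fractions_from_z(np.clip(x[n_components:], -30.0, 30.0), n_components)
        return taus, fracs

    def resid(x):
        taus, fracs = unpack(x)
        order = np.argsort(-taus)
        taus, fracs = taus[order], fracs[order]
        for i in range(1, len(taus)):
            if taus[i] >= taus[i - 1]:
                taus[i] = taus[i - 1] * (1 - 1e-12)
        model = LifetimeModel(taus=taus, fractions=fracs)
        ph, mod = lifetime_response(model, data.freq)
        return np.concatenate(
            [(ph - data.phase) / sp, (mod - data.modulation) / sm]
        )

    rng = np.random.default_rng(seed)
    # centre the starting lifetimes on the timescale the frequency band probes
    tau_c = 1e3 / (2 * np.pi * np.exp(np.mean(np.log(data.freq))))
    best = None
    for _ in range(10):
        taus0 = np.sort(
            10 ** rng.uniform(np.log10(tau_c / 60), np.log10(tau_c * 60), n_components)
        )[::-1]
        x0 = np.concatenate([np.log10(taus0), np.zeros(n_components - 1)])
        try:
            res = least_squares(resid, x0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("lifetime fit failed from all starts")

    taus, fracs = unpack(best.x)
    order = np.argsort(-taus)
    taus, fracs = taus[order], fracs[order]
    # guard against exactly coincident taus, which LifetimeModel rejects
    for i in range(1, len(taus)):
        if taus[i] >= taus[i - 1]:
            taus[i] = taus[i - 1] * (1 - 1e-12)
    model = LifetimeModel(taus=taus, fractions=fracs)
    dof = max(n_obs - n_par, 1)
    chi2_red = float(2 * best.cost / dof)

    stderr_taus = stderr_fracs = None
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac)
        # delta method through the (log-tau, softmax) transform
        jt = np.zeros((n_components, n_par))
        jt[np.arange(n_components), np.arange(n_components)] = (
            np.log(10.0) * 10.0 ** best.x[:n_components]
        )
        eps = 1e-7
        jf = np.zeros((n_components, n_par))
        for j in range(n_components, n_par):
            xp = best.x.copy()
            xp[j] += eps
            jf[:, j] = (
                _fractions_from_z(xp[n_components:], n_components)
                - _fractions_from_z(best.x[n_components:], n_components)
            ) / eps
        stderr_taus = np.sqrt(np.clip(np.diag(jt @ cov @ jt.T), 0, None))[order]
        stderr_fracs = np.sqrt(np.clip(np.diag(jf @ cov @ jf.T), 0, None))[order]
    except np.linalg.LinAlgError:
        pass

    warnings = []
    ratios = taus[:-1] / taus[1:]
    if np.any(ratios < 1.1):
        warnings.append("two lifetimes within 10%; consider merging components")
    return LifetimeFit(
        model=model,
        chi2_red=chi2_red,
        stderr_taus=stderr_taus,
        stderr_fractions=stderr_fracs,
        warnings=warnings,
    )


def fit_anisotropy(
    data: FreqDomainSet,
    life: LifetimeModel,
    n_terms: int = 2,
    seed: int = 0,
) -> AnisotropyFit:
    """Fit r₀, φ_j, g_j to differential phase / modulation-ratio data.

    The intensity decay is held fixed (fit it first). r₀ is bounded to
    (0, 0.4], correlation times are fitted on a log10 scale, and ten seeded
    starts are tried.
    """
    if n_terms not in (1, 2):
        raise ValueError("n_terms must be 1 or 2")
    if data.kind != "differential":
        raise ValueError("fit_anisotropy expects a differential FreqDomainSet")
    sp, sm = _weighted_residuals(data)

    def unpack(x):
        r0 = x[0]
        if n_terms == 1:
            return r0, np.array([10.0 ** x[1]]), np.array([1.0])
        phis = 10.0 ** x[1:3]
        g1 = x[3]
        order = np.argsort(-phis)
        return r0, phis[order], np.array([g1, 1.0 - g1])[order]

    def resid(x):
        r0, phis, gs = unpack(x)
        for i in range(1, len(phis)):
            if phis[i] >= phis[i - 1]:
                phis[i] = phis[i - 1] * (1 - 1e-12)
        model = AnisotropyModel(r0=r0, phis=phis, gs=np.clip(gs, 0, None) / np.clip(gs, 0, None).sum())
        dph, ratio = anisotropy_response(life, model, data.freq)
        return np.concatenate(
            [(dph - data.phase) / sp, (ratio - data.modulation) / sm]
        )

    tau_c = 1e3 / (2 * np.pi * np.exp(np.mean(np.log(data.freq))))
    lo_phi = np.log10(tau_c) - 4.0
    hi_phi = np.log10(tau_c) + 4.0
    if n_terms == 1:
        lo, hi = [1e-4, lo_phi], [0.4, hi_phi]
    else:
        lo, hi = [1e-4, lo_phi, lo_phi, 1e-6], [0.4, hi_phi, hi_phi, 1.0 - 1e-6]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(10):
        if n_terms == 1:
            x0 = np.array(
                [rng.uniform(0.1, 0.4), rng.uniform(np.log10(tau_c / 3), np.log10(tau_c * 30))]
            )
        else:
            x0 = np.array(
                [
                    rng.uniform(0.1, 0.4),
                    rng.uniform(np.log10(tau_c / 3), np.log10(tau_c * 30)),
                    rng.uniform(np.log10(tau_c / 100), np.log10(tau_c / 3)),
                    rng.uniform(0.3, 0.9),
                ]
            )
        try:
            res = least_squares(resid, x0, bounds=(lo, hi), max_nfev=5000)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise RuntimeError("anisotropy fit failed from all starts")

    r0, phis, gs = unpack(best.x)
    for i in range(1, len(phis)):
        if phis[i] >= phis[i - 1]:
            phis[i] = phis[i - 1] * (1 - 1e-12)
    model = AnisotropyModel(r0=r0, phis=phis, gs=gs / gs.sum())
    n_obs = 2 * len(data.freq)
    n_par = len(best.x)
    chi2_red = float(2 * best.cost / max(n_obs - n_par, 1))

    stderr = None
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {"r0": float(se[0])}
        for j, phi in enumerate(10.0 ** best.x[1 : 1 + len(phis)]):
            stderr[f"phi{j + 1}"] = float(np.log(10.0) * phi * se[1 + j])
        if n_terms == 2:
            stderr["g1"] = float(se[3])
    except np.linalg.LinAlgError:
        pass

    warnings = []
    if len(phis) == 2 and phis[0] / phis[1] < 1.1:
        warnings.append("correlation times within 10%; model may be over-specified")
    if np.any(model.gs < 1e-3):
        warnings.append("near-zero amplitude term; a single correlation time may suffice")
    return AnisotropyFit(model=model, chi2_red=chi2_red, stderr=stderr, warnings=warnings)


def sphere_rotation_time(s: SphereSpec) -> float:
    """Stokes–Einstein–Debye rotational correlation time in ns.

    φ = η V_h / (k_B T) with the hydrated molecular volume
    V_h = M (v̄ + h) / N_A.
    """
    v_h_cm3 = s.mass * (s.vbar + s.hydration) / Avogadro
    v_h_m3 = v_h_cm3 * 1e-6
    eta_pa_s = s.viscosity * 1e-3
    phi_s = eta_pa_s * v_h_m3 / (Boltzmann * s.temperature)
    return phi_s * 1e9
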