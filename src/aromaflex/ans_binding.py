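"""One-site ANS binding isotherm with ligand depletion (exact quadratic form).

ANS fluorescence reports binding to hydrophobic surface pockets. For the
equilibrium ANS + P ⇌ ANS·P at total protein concentration P₀ and total
ligand concentration L, the fluorescence is proportional to the bound
fraction obtained from the exact root of the binding quadratic:

    F(L) = F∞ · [ (L + P₀ + K_d) − √((L + P₀ + K_d)² − 4·L·P₀) ] / (2 P₀)

No hyperbolic (Langmuir) approximation is made, although the formula
reduces to F∞·L/(L+K_d) when P₀ ≪ K_d — the regime of a µM protein probed
with an mM-scale dissociation constant. Concentrations are handled in µM
internally; mM inputs are converted on construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = ["TitrationCurve", "BindingFit", "binding_model", "fit_binding"]

_UNIT_TO_UM = {"uM": 1.0, "µM": 1.0, "mM": 1000.0, "nM": 1e-3, "M": 1e6}


@dataclass
class TitrationCurve:
    """Ligand titration: fluorescence vs total ligand concentration.

    ``ligand_conc`` and ``p0`` are stored in µM regardless of the unit they
    were supplied in.
    """

    ligand_conc: np.ndarray
    fluorescence: np.ndarray
    p0: float
    unit: str = "uM"

    def __post_init__(self) -> None:
        scale = _UNIT_TO_UM.get(self.unit)
        if scale is None:
            raise ValueError(f"unknown concentration unit {self.unit!r}")
        self.ligand_conc = np.asarray(self.ligand_conc, dtype=float) * scale
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        self.p0 = float(self.p0) * scale
        self.unit = "uM"
        if self.ligand_conc.shape != self.fluorescence.shape:
            raise ValueError("concentration and fluorescence must have equal length")
        if np.any(self.ligand_conc < 0):
            raise ValueError("ligand concentrations must be nonnegative")
        if np.any(np.diff(self.ligand_conc) <= 0):
            raise ValueError("ligand concentrations must be strictly increasing")


@dataclass
class BindingFit:
    kd: float      # µM
    f_inf: float   # a.u.
    stderr: dict[str, float | None]
    chisq: float
    n_points: int
    warnings: list[str] = field(default_factory=list)

    @property
    def kd_mM(self) -> float:
        return self.kd / 1000.0

    def to_dict(self) -> dict:
        return {
            "kd_uM": self.kd,
            "kd_mM": self.kd_mM,
            "f_inf": self.f_inf,
            "stderr": self.stderr,
            "chisq": self.chisq,
            "n_points": self.n_points,
            "warnings": self.warnings,
        }


def binding_model(L, f_inf: float, p0: float, kd: float):
    """Exact one-site bound-fraction isotherm (all concentrations in µM).

    A radicand driven infinitesimally negative by rounding is clamped to 0.
    For p0 = 0 the formula degenerates 0/0; the Langmuir limit is returned.
    """
    L = np.asarray(L, dtype=float)
    if p0 < 0 or kd < 0:
        raise ValueError("p0 and kd must be nonnegative")
    if p0 == 0:
        with np.errstate(invalid="ignore"):
            out = np.where(L + kd > 0, f_inf * L / (L + kd), 0.0)
        return out
    b = L + p0 + kd
    rad = np.clip(b * b - 4.0 * L * p0, 0.0, None)
    return f_inf * (b - np.sqrt(rad)) / (2.0 * p0)


def fit_binding(curve: TitrationCurve) -> BindingFit:
    """χ² fit of (K_d, F∞) with P₀ fixed from the titration.

    Positivity is enforced by fitting log10 K_d and log10 F∞; the start is
    K_d at the half-maximal ligand concentration and F∞ = 1.2 × max(F). If
    the measured curve reaches less than 60 % of the fitted plateau, the
    K_d is an extrapolation and the result is flagged.
    """
    L, F = curve.ligand_conc, curve.fluorescence
    if len(L) < 5:
        raise ValueError("need at least 5 titration points")
    f_max = float(np.max(F))
    if f_max <= 0:
        raise ValueError("fluorescence values must contain positive entries")
    half = 0.5 * f_max
    kd0 = float(np.interp(half, F, L)) if np.any(F >= half) else float(L[-1])
    kd0 = max(kd0, 1e-9)

    def residual(params):
        kd = 10.0 ** params["log_kd"].value
        f_inf = 10.0 ** params["log_finf"].value
        return binding_model(L, f_inf, curve.p0, kd) - F

    params = lmfit.Parameters()
    params.add("log_kd", value=np.log10(kd0), min=-9, max=12)
    params.add("log_finf", value=np.log10(1.2 * f_max), min=-12, max=12)
    res = lmfit.minimize(residual, params, method="leastsq")
    if not res.success:
        raise RuntimeError("binding fit did not converge")
    kd = 10.0 ** res.params["log_kd"].value
    f_inf = 10.0 ** res.params["log_finf"].value

    def _stderr(name, scale):
        se = res.params[name].stderr
        return None if se is None else se * scale

    stderr = {
        "kd": _stderr("log_kd", np.log(10.0) * kd),
        "f_inf": _stderr("log_finf", np.log(10.0) * f_inf),
    }
    warnings = []
    if f_max < 0.6 * f_inf:
        warnings.append(
            f"titration reaches only {100 * f_max / f_inf:.0f}% of the fitted "
            "plateau; K_d is an extrapolation"
        )
    return BindingFit(
        kd=kd,
        f_inf=f_inf,
        stderr=stderr,
        chisq=float(res.chisqr),
        n_points=len(L),
        warnings=warnings,
    )
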