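"""Hydrogen/deuterium exchange kinetics from FTIR amide-II traces.

Deuteration of backbone amides shifts the amide II band; the absorbance
rise near 1460 cm⁻¹ (normalised on the amide I band at 1650 cm⁻¹) tracks
the fraction of exchanged protons over time. Two proton populations — a
partially exposed one exchanging within minutes and a buried one exchanging
over hours — give a biphasic uptake that is fitted with the constrained
double exponential

    y(t) = 1 − m₁·exp(−k₁ t) − (1 − m₁)·exp(−k₂ t),      k₁ ≥ k₂,

where m₁ is the initial fraction of the fast population and the amplitudes
sum to one (the trace is normalised to a unit plateau beforehand).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "Spectrum",
    "KineticTrace",
    "HdxFit",
    "hdx_model",
    "band_trace",
    "fit_hdx",
]


@dataclass
class Spectrum:
    wavenumber: np.ndarray  # cm^-1, strictly monotone
    absorbance: np.ndarray  # a.u.

    def __post_init__(self) -> None:
        self.wavenumber = np.asarray(self.wavenumber, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumber.shape != self.absorbance.shape:
            raise ValueError("wavenumber and absorbance must have equal length")
        d = np.diff(self.wavenumber)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("wavenumbers must be strictly monotone")

    def value_at(self, wn: float) -> float:
        """Absorbance at ``wn`` by linear interpolation between samples."""
        x, y = self.wavenumber, self.absorbance
        if x[0] > x[-1]:
            x, y = x[::-1], y[::-1]
        if not (x[0] <= wn <= x[-1]):
            raise ValueError(f"wavenumber {wn} outside spectrum range")
        return float(np.interp(wn, x, y))


@dataclass
class KineticTrace:
    t: np.ndarray  # minutes, strictly increasing, t >= 0
    y: np.ndarray  # exchanged fraction
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.shape != self.y.shape:
            raise ValueError("t and y must have equal length")
        if self.t.size and (self.t[0] < 0 or np.any(np.diff(self.t) <= 0)):
            raise ValueError("times must start at >= 0 and be strictly increasing")


@dataclass
class HdxFit:
    m1: float
    k1: float  # min^-1, fast
    k2: float  # min^-1, slow; k1 >= k2
    y_inf: float
    stderr: dict[str, float | None]
    rss: float
    n_points: int
    warnings: list[str] = field(default_factory=list)

    @property
    def m2(self) -> float:
        return 1.0 - self.m1

    def to_dict(self) -> dict:
        return {
            "m1": self.m1,
            "m2": self.m2,
            "k1_per_min": self.k1,
            "k2_per_min": self.k2,
            "stderr": self.stderr,
            "rss": self.rss,
            "n_points": self.n_points,
            "warnings": self.warnings,
        }


def hdx_model(t, m1: float, k1: float, k2: float):
    """Double-exponential uptake; y(0)=0, y(∞)=1, monotone increasing."""
    t = np.asarray(t, dtype=float)
    return 1.0 - m1 * np.exp(-k1 * t) - (1.0 - m1) * np.exp(-k2 * t)


def band_trace(
    series: list[tuple[float, Spectrum]],
    probe_wn: float = 1460.0,
    ref_wn: float = 1650.0,
    blank: Spectrum | None = None,
) -> KineticTrace:
    """Exchanged-fraction trace from a timed series of spectra.

    Each spectrum is blank-subtracted (optional), normalised by its amide-I
    absorbance at ``ref_wn``, and read at ``probe_wn``. The raw band values
    are rescaled to [0, 1] with (v − v_first)/(v_plateau − v_first), the
    plateau being the mean of the last three points.
    """
    if len(series) < 4:
        raise ValueError("need at least 4 time points")
    series = sorted(series, key=lambda ts: ts[0])
    times, vals = [], []
    for t, spec in series:
        a_probe = spec.value_at(probe_wn)
        a_ref = spec.value_at(ref_wn)
        if blank is not None:
            a_probe -= blank.value_at(probe_wn)
            a_ref -= blank.value_at(ref_wn)
        if a_ref <= 0:
            raise ValueError(f"reference absorbance at {ref_wn} cm^-1 is <= 0 (t={t})")
        times.append(t)
        vals.append(a_probe / a_ref)
    v = np.array(vals)
    plateau = v[-3:].mean()
    span = plateau - v[0]
    warnings = []
    if abs(span) < 1e-12:
        warnings.append("flat band trace; returning zeros")
        y = np.zeros_like(v)
    else:
        y = (v - v[0]) / span
    return KineticTrace(t=np.array(times), y=y, warnings=warnings)


# deterministic multi-start grid spanning the fast/slow rate decades
_HDX_STARTS = [
    (0.5, 1.0, 0.01),
    (0.5, 0.3, 0.02),
    (0.3, 0.1, 0.005),
    (0.7, 3.0, 0.05),
    (0.5, 0.05, 0.001),
]


def fit_hdx(trace: KineticTrace, weights: np.ndarray | None = None) -> HdxFit:
    """Constrained double-exponential least-squares fit of an uptake trace.

    m₁ is bounded to [0, 1]; the rates are fitted on a log10 scale to keep
    them positive. Five fixed starting points spanning the rate decades are
    tried and the best residual kept; the returned components are ordered so
    k₁ ≥ k₂. A rate separation k₁/k₂ < 3 flags the fit as poorly determined.
    """
    t, y = trace.t, trace.y
    if len(t) < 6:
        raise ValueError("need at least 6 points for a double-exponential fit")
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    def residual(params):
        m1 = params["m1"].value
        k1 = 10.0 ** params["log_k1"].value
        k2 = 10.0 ** params["log_k2"].value
        return (hdx_model(t, m1, k1, k2) - y) * w

    best = None
    for m1_0, k1_0, k2_0 in _HDX_STARTS:
        params = lmfit.Parameters()
        params.add("m1", value=m1_0, min=0.0, max=1.0)
        params.add("log_k1", value=np.log10(k1_0), min=-6, max=3)
        params.add("log_k2", value=np.log10(k2_0), min=-6, max=3)
        try:
            res = lmfit.minimize(residual, params, method="leastsq")
        except Exception:
            continue
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        raise RuntimeError("double-exponential fit failed from all starts")

    m1 = best.params["m1"].value
    k1 = 10.0 ** best.params["log_k1"].value
    k2 = 10.0 ** best.params["log_k2"].value

    def _stderr(name, scale=1.0):
        se = best.params[name].stderr
        return None if se is None else se * scale

    stderr = {
        "m1": _stderr("m1"),
        "k1": _stderr("log_k1", np.log(10.0) * k1),
        "k2": _stderr("log_k2", np.log(10.0) * k2),
    }
    if k1 < k2:  # canonical ordering: fast component first
        m1, k1, k2 = 1.0 - m1, k2, k1
        stderr = {"m1": stderr["m1"], "k1": stderr["k2"], "k2": stderr["k1"]}
    warnings = []
    if k2 > 0 and k1 / k2 < 3.0:
        warnings.append(f"rates poorly separated (k1/k2 = {k1 / k2:.2f} < 3)")
    return HdxFit(
        m1=m1,
        k1=k1,
        k2=k2,
        y_inf=1.0,
        stderr=stderr,
        rss=float(best.chisqr),
        n_points=len(t),
        warnings=warnings,
    )
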