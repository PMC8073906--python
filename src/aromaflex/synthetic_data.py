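"""Seeded generators for every input the analysis stages consume.

The pipeline is exercised end-to-end without instrument data or downloads:

* toy Cα structures with a planted two-module topology (two compact lobes
  bridged by a few connector residues) for the contact-network stage;
* biphasic H/D-exchange traces on the experimental sampling grid
  (1-minute steps to 10 min, 8-minute steps to 170 min);
* saturable one-site ANS titrations at micromolar protein and
  millimolar-scale dissociation constants;
* frequency-domain lifetime and differential-anisotropy data sets over
  30 log-spaced modulation frequencies between 2 and 250 MHz.

Noise models are additive Gaussian in measurement space for kinetics and
phase/modulation data and multiplicative Gaussian for fluorescence
intensities. Every generator is a pure function of (seed, parameters).
"""

from __future__ import annotations

import numpy as np

from .ans_binding import TitrationCurve, binding_model
from .freq_fluor import (
    AnisotropyModel,
    FreqDomainSet,
    LifetimeModel,
    anisotropy_response,
    lifetime_response,
)
from .hdx_kinetics import KineticTrace, Spectrum, hdx_model
from .structure_io import CalphaStructure, Residue

__all__ = [
    "gen_two_lobe_structure",
    "gen_hdx",
    "gen_hdx_spectra",
    "gen_titration",
    "gen_freqdomain",
    "hdx_time_grid",
    "default_frequencies",
]

MIN_CA_SPACING = 3.8       # Å, hard-core radius of the Cα packing
POINT_VOLUME = 110.0       # Å³ per residue: globular-protein packing density
LOBE_GAP = 10.0            # Å between the lobes' facing surface points
BRIDGE_RING = 4.5          # Å lateral radius of the connector seam


def hdx_time_grid() -> np.ndarray:
    """Experimental sampling grid: every minute to 10 min, every 8 min to 170."""
    return np.concatenate([np.arange(1.0, 11.0), np.arange(18.0, 171.0, 8.0)])


def default_frequencies(n: int = 30) -> np.ndarray:
    """Log-spaced modulation frequencies, 2–250 MHz."""
    return np.geomspace(2.0, 250.0, n)


def _pack_blob(n: int, rng: np.random.Generator, center: np.ndarray) -> np.ndarray:
    """Self-avoiding uniform packing of n points in a sphere around center."""
    radius = (3.0 * n * POINT_VOLUME / (4.0 * np.pi)) ** (1.0 / 3.0)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        if attempts > 1000 * n:
            raise RuntimeError("geometric packing failed; lower the density")
        attempts += 1
        p = rng.uniform(-radius, radius, 3)
        if np.dot(p, p) > radius**2:
            continue
        p = p + center
        if pts and np.min(np.linalg.norm(np.array(pts) - p, axis=1)) < MIN_CA_SPACING:
            continue
        pts.append(p)
    return np.array(pts)


def gen_two_lobe_structure(
    n_per_lobe: int = 30,
    n_bridge: int = 4,
    seed: int = 0,
    closed: bool = False,
) -> tuple[CalphaStructure, np.ndarray]:
    """Two dense Cα lobes bridged by connector residues in the seam.

    Each lobe is a compact self-avoiding blob (hard-core 3.8 Å, density
    chosen so the 4–8 Å window yields many intra-lobe contacts). The lobes
    face each other across a 10 Å gap — wider than the contact window, so
    no direct lobe–lobe contacts exist. The ``n_bridge`` connectors sit on
    a ring in the midplane of the gap, each within contact range of both
    lobes' facing surfaces; with ``n_bridge=0`` the network is
    disconnected. ``closed=True`` translates each lobe 2 Å toward the
    midplane (ligand-bound mimic: direct inter-lobe contacts appear across
    the seam).

    Returns the structure and the planted labels (0/1 per lobe; connectors
    take the label of the lobe contributing more of their contacts, by
    construction arbitrary — they are assigned alternately).
    """
    if n_per_lobe < 10:
        raise ValueError("n_per_lobe must be >= 10")
    rng = np.random.default_rng(seed)
    lobe1 = _pack_blob(n_per_lobe, rng, np.zeros(3))
    lobe2 = _pack_blob(n_per_lobe, rng, np.zeros(3))

    # anchor the facing surface points exactly LOBE_GAP apart on the x axis
    p_a = lobe1[np.argmax(lobe1[:, 0])]
    q = lobe2[np.argmin(lobe2[:, 0])]
    p_b = p_a + np.array([LOBE_GAP, 0.0, 0.0])
    lobe2 = lobe2 + (p_b - q)

    # connector seam: ring in the midplane, each node in contact range
    # (√(5² + r²) ≈ 6.7 Å) of both facing surfaces
    radius = max(BRIDGE_RING, n_bridge * 4.3 / (2.0 * np.pi))
    mid = p_a + np.array([LOBE_GAP / 2.0, 0.0, 0.0])
    bridge = []
    for i in range(n_bridge):
        angle = 2.0 * np.pi * i / max(n_bridge, 1) + rng.uniform(-0.1, 0.1)
        r_i = radius + rng.uniform(-0.3, 0.3)
        bridge.append(mid + np.array([0.0, r_i * np.cos(angle), r_i * np.sin(angle)]))
    bridge = np.array(bridge).reshape(n_bridge, 3)

    if closed:
        # ligand-bound mimic: each lobe translated 2 Å toward the seam,
        # creating direct lobe–lobe contacts at the interface
        direction = np.array([2.0, 0.0, 0.0])
        lobe1 = lobe1 + direction
        lobe2 = lobe2 - direction

    coords = np.vstack([lobe1, lobe2, bridge]) if n_bridge else np.vstack([lobe1, lobe2])
    labels = np.concatenate(
        [
            np.zeros(n_per_lobe, dtype=int),
            np.ones(n_per_lobe, dtype=int),
            np.arange(n_bridge, dtype=int) % 2,  # seam nodes: no true side
        ]
    )
    residues = [
        Residue(
            chain_id="A",
            residue_number=i + 1,
            insertion_code="",
            residue_name="ALA",
            coord=tuple(float(x) for x in c),
        )
        for i, c in enumerate(coords)
    ]
    return CalphaStructure(residues=residues), labels


def gen_hdx(
    m1: float, k1: float, k2: float, sigma: float = 0.01, seed: int = 0
) -> KineticTrace:
    """Biphasic uptake trace on the experimental time grid plus noise."""
    t = hdx_time_grid()
    rng = np.random.default_rng(seed)
    y = hdx_model(t, m1, k1, k2) + rng.normal(0.0, sigma, t.shape)
    return KineticTrace(t=t, y=y)


def gen_hdx_spectra(
    m1: float,
    k1: float,
    k2: float,
    sigma: float = 0.0,
    seed: int = 0,
    times: np.ndarray | None = None,
) -> list[tuple[float, Spectrum]]:
    """Timed amide-band spectra whose 1460 cm⁻¹ intensity grows biphasically.

    Band-intensity level only: a fixed amide-I Gaussian at 1650 cm⁻¹ and an
    amide-II Gaussian at 1460 cm⁻¹ whose amplitude tracks the uptake curve.
    """
    if times is None:
        times = hdx_time_grid()
    rng = np.random.default_rng(seed)
    wn = np.arange(1380.0, 1721.0, 2.0)
    out = []
    for t in times:
        y = hdx_model(t, m1, k1, k2)
        absorb = (
            1.0 * np.exp(-0.5 * ((wn - 1650.0) / 18.0) ** 2)
            + (0.15 + 0.5 * y) * np.exp(-0.5 * ((wn - 1460.0) / 14.0) ** 2)
            + 0.02
        )
        if sigma > 0:
            absorb = absorb + rng.normal(0.0, sigma, wn.shape)
        out.append((float(t), Spectrum(wavenumber=wn, absorbance=absorb)))
    return out


def gen_titration(
    kd: float,
    f_inf: float = 1.0,
    p0: float = 6.4,
    n_points: int = 12,
    sigma_rel: float = 0.01,
    seed: int = 0,
    unit: str = "uM",
) -> TitrationCurve:
    """Log-spaced titration from kd/30 to 10·kd with multiplicative noise.

    ``kd`` and ``p0`` are interpreted in ``unit``.
    """
    rng = np.random.default_rng(seed)
    scale = {"uM": 1.0, "mM": 1000.0}.get(unit)
    if scale is None:
        raise ValueError("unit must be 'uM' or 'mM'")
    L = np.geomspace(kd / 30.0, 10.0 * kd, n_points)
    f = binding_model(L * scale, f_inf, p0 * scale, kd * scale)
    f = f * (1.0 + rng.normal(0.0, sigma_rel, L.shape))
    return TitrationCurve(ligand_conc=L, fluorescence=f, p0=p0, unit=unit)


def gen_freqdomain(
    life: LifetimeModel,
    aniso: AnisotropyModel | None = None,
    freqs: np.ndarray | None = None,
    sigma_phase: float = 0.2,
    sigma_mod: float = 0.004,
    seed: int = 0,
    n_replicates: int = 1,
) -> FreqDomainSet:
    """Frequency-domain data from the forward models plus measurement noise.

    Without an anisotropy model: intensity-decay (phase, modulation) data.
    With one: differential (Δφ, modulation-ratio) data. ``n_replicates``
    averages that many independent noise realisations per frequency,
    emulating the usual repeated-measurement protocol (triplicate in this
    instrument class); the stored σ values remain the single-shot ones.
    """
    if freqs is None:
        freqs = default_frequencies()
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    if aniso is None:
        phase, mod = lifetime_response(life, freqs)
        kind = "intensity"
    else:
        phase, mod = anisotropy_response(life, aniso, freqs)
        kind = "differential"
    phase = phase + np.mean(
        rng.normal(0.0, sigma_phase, (n_replicates, *freqs.shape)), axis=0
    )
    mod = mod + np.mean(
        rng.normal(0.0, sigma_mod, (n_replicates, *freqs.shape)), axis=0
    )
    return FreqDomainSet(
        freq=freqs,
        phase=phase,
        modulation=mod,
        sigma_phase=np.full(freqs.shape, sigma_phase) if sigma_phase > 0 else None,
        sigma_mod=np.full(freqs.shape, sigma_mod) if sigma_mod > 0 else None,
        kind=kind,
    )
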