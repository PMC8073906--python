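"""Reported spectroscopic parameters for human aromatase R264 variants.

These literature values define the regimes the synthetic-data generators
emulate: biphasic H/D-exchange kinetics (fast fraction m₁ and rates k₁, k₂
per sample/ligand state), millimolar ANS dissociation constants at 6.4 µM
protein, a four-component tryptophan intensity decay whose ≈5 ns component
is quenched by ligand binding in the wild type, and whole-body rotational
correlation times of 21–33 ns for a ≈58 kDa protein.

They are inputs (generator defaults and demo parameters), not outputs: every
quantity the package reports is recomputed by fitting generated data.
"""

from __future__ import annotations

VARIANTS = ("wt", "R264H", "R264C")
STATES = ("free", "substrate", "inhibitor")

# (m1, k1 [1/min], k2 [1/min]) for the double-exponential H/D uptake
HDX_PARAMS: dict[tuple[str, str], tuple[float, float, float]] = {
    ("wt", "free"): (0.61, 0.40, 0.014),
    ("wt", "substrate"): (0.20, 0.18, 0.012),
    ("wt", "inhibitor"): (0.19, 0.23, 0.012),
    ("R264H", "free"): (0.59, 0.22, 0.017),
    ("R264H", "substrate"): (0.39, 0.19, 0.017),
    ("R264H", "inhibitor"): (0.32, 0.23, 0.015),
    ("R264C", "free"): (0.52, 0.23, 0.017),
    ("R264C", "substrate"): (0.38, 0.20, 0.020),
    ("R264C", "inhibitor"): (0.40, 0.25, 0.013),
}

# ANS dissociation constants in mM, ligand-bound samples
ANS_KD_MM: dict[tuple[str, str], float] = {
    ("wt", "substrate"): 40.0,
    ("wt", "inhibitor"): 41.0,
    ("R264H", "substrate"): 11.0,
    ("R264H", "inhibitor"): 13.0,
    ("R264C", "substrate"): 17.0,
    ("R264C", "inhibitor"): 16.0,
}

PROTEIN_CONC_UM = 6.4       # protein concentration in the ANS titrations
AROMATASE_MASS_DA = 58_000  # approximate molecular mass

# long rotational correlation time (whole-body tumbling), ligand-free, ns
PHI1_NS = {"wt": 21.0, "R264H": 33.0}
# short correlation time (local probe motion), ligand-free, ns
PHI2_NS = {"wt": 0.45, "R264H": 0.8, "R264C": 0.5}

# demo four-component intensity decays: taus in ns; the long ≈5 ns
# component's fractional intensity drops from 0.45 (ligand-free) to 0.15
# (ligand-bound) — the quenching signature of the buried tryptophan
LIFETIME_DEMO = {
    "free": {"taus": (5.0, 2.0, 0.5, 0.1), "fractions": (0.45, 0.30, 0.15, 0.10)},
    "bound": {"taus": (5.0, 2.0, 0.5, 0.1), "fractions": (0.15, 0.45, 0.25, 0.15)},
}

# emission decay used for the anisotropy demo: includes the longest (≈8 ns)
# component, which carries most of the whole-body rotational signal
ANISOTROPY_LIFETIME = {"taus": (8.0, 5.0, 1.5, 0.2), "fractions": (0.25, 0.45, 0.20, 0.10)}
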