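# Methods

This note documents the models implemented in `aromaflex`, the numerical
choices behind the fits, what the synthetic-data generators do and do not
emulate, and the package's known limitations.

## Contact networks and participation

A structure is reduced to its Cα positions (Å, no unit conversion
anywhere). The adjacency is strictly binary:

    A_ij = 1  iff  4 Å < d_ij < 8 Å,

with strict inequalities at both boundaries, so a pair at exactly 8.0 Å is
a non-edge and sequence-adjacent residues (Cα–Cα ≈ 3.8 Å) are never
linked — edges represent significant noncovalent contacts only. Distances
use Cα exclusively; there is no centroid or side-chain option and no
distance weighting.

Clustering is spectral: L = D − A, eigendecomposition with `scipy.linalg.eigh`,
and the sign pattern of the eigenvector of the second-smallest eigenvalue
(the Fiedler vector) defines the two-way split. Conventions, chosen for
determinism:

- the eigenvector sign is fixed so its first component is non-negative;
- exact-zero components join the non-negative cluster;
- eigenvalue gaps below 1e-8 are reported as a degeneracy warning (the
  partition still uses the first eigenvector of the degenerate block);
- a disconnected graph has no Fiedler vector: the default is an error, and
  `on_disconnected="largest"` partitions the largest component, labelling
  the rest −1 and listing them explicitly.

Deeper partitions reapply the split recursively inside each cluster
(2^depth clusters); sub-clusters smaller than 3 nodes are not split, and a
disconnected sub-cluster is split along its components (the zero-cost
cut). The default depth of 1 (two modules) is the configuration used for
the aromatase analysis.

Participation is P_i = 1 − (k_si/k_i)². Isolated nodes (k = 0) carry an
undefined (NaN) P and are excluded from the average ⟨P⟩, which is the
plain arithmetic mean over the remaining residues. For holo/apo
comparisons residues are matched by (chain, residue number, insertion
code) — the two forms are the same sequence, so no alignment is needed —
and cluster labels of the second structure are mapped onto the first by a
Hungarian assignment on the label-overlap table, because the Fiedler sign
(hence the raw 0/1 labelling) is arbitrary per structure. ΔP itself is
label-invariant; the alignment only matters for cluster-aware reporting.
Unmatched residues are listed, never dropped silently.

## H/D-exchange kinetics

The amide-II band trace is built per time point as
absorbance(probe)/absorbance(reference) with linear interpolation between
samples (probe 1460 cm⁻¹, reference 1650 cm⁻¹ — the amide-I normalisation
point), optional blank subtraction first. The series is rescaled to [0, 1]
by (v − v_first)/(v_plateau − v_first) with the plateau estimated as the
mean of the last three points; a flat series is returned as zeros with a
warning instead of dividing 0/0.

The kinetic model is the constrained double exponential

    y(t) = 1 − m₁·e^(−k₁t) − (1 − m₁)·e^(−k₂t),  k₁ ≥ k₂,

i.e. two proton populations whose amplitudes sum to one and a plateau
fixed at 1 after normalisation (only m₁, k₁, k₂ are reported; residual
non-exchanging protons are not modelled separately). Fitting is
unweighted least squares (no error model is assumed; per-point weights are
accepted), with m₁ bounded to [0, 1] and the rates fitted as log₁₀ values
to keep them positive. Five fixed starting points spanning the fast/slow
rate decades are tried and the best kept; components are reordered so
k₁ ≥ k₂, and a separation k₁/k₂ < 3 flags the fit as poorly determined.
Standard errors come from the fit covariance, transformed off the log
scale by the delta method.

## ANS binding

The isotherm is the exact quadratic-root bound fraction times F∞ — no
hyperbolic approximation and no free baseline (blanks are subtracted
upstream). Concentrations are handled in µM internally; mM inputs are
converted on construction, matching the experiment's mixed µM-protein /
mM-K_d regime. A radicand driven negative by rounding is clamped to zero.
The fit estimates (K_d, F∞) on log scales with P₀ fixed, starting from the
half-maximal ligand concentration and 1.2 × max(F); if the measured curve
reaches less than 60 % of the fitted plateau the K_d is flagged as an
extrapolation. In the dilute-protein regime of these experiments
(P₀/K_d ≈ 6 × 10⁻⁴) the exact form coincides with the Langmuir hyperbola
to better than 0.1 % relative — the property suite checks this.

## Frequency-domain fluorescence

The instrument vendor's analysis software is closed; the package therefore
implements the standard frequency-domain formalism directly and guards it
with numerical-quadrature oracles in the test suite. For fractional
steady-state intensities f_i over lifetimes τ_i:

    N(ω) = Σ f_i ωτ_i/(1+ω²τ_i²),  D(ω) = Σ f_i/(1+ω²τ_i²),
    phase = arctan(N/D),           modulation = √(N²+D²).

Phase lies in (0°, 90°) and modulation in (0, 1); modulation decreases
monotonically with frequency, while the phase of a *heterogeneous* decay
can dip at intermediate frequencies (only the single-exponential phase is
globally monotone — asserting otherwise would be wrong, and the tests
reflect that).

Anisotropy decays r(t) = r₀ Σ g_j e^(−t/φ_j) are observed through the
polarized components I∥ = I(1+2r)/3 and I⊥ = I(1−r)/3. Every product of
exponentials is an exponential, so the sine/cosine transforms of both
components are closed-form Lorentzian sums and the observables —
differential phase Δφ = φ⊥ − φ∥ and modulation ratio m∥/m⊥ — need no
numerical integration. The sign convention gives a positive,
frequency-peaked Δφ, the standard presentation for this experiment. The
G-factor and scattering corrections are assumed applied upstream; the
module consumes corrected data.

Fitting is weighted least squares on stacked phase/modulation residuals
with per-point uncertainties, defaulting to σ_phase = 0.2° and
σ_mod = 0.004 (typical for this instrument class, overridable). Lifetimes
are fitted on log₁₀ scales (clipped to ±6 decades), fractional intensities
through a softmax parameterisation, r₀ bounded to (0, 0.4], and ten seeded
multi-starts are run with starting timescales centred on
1/(2π·⟨f⟩_geometric) so the fits are equivariant under time-unit
rescaling. Reduced χ² uses 2·N_freq observations minus the free-parameter
count. Lifetimes within 10 % of each other, or near-zero anisotropy
amplitudes, raise merge/over-specification warnings.

The rigid-sphere rotational time is φ = ηV_h/(k_BT) with
V_h = M(v̄ + h)/N_A. Constants not fixed by the experiment are set to
standard values: v̄ = 0.73 cm³/g, hydration h = 0.3 g/g, η = 1.002 mPa·s
and T = 293.15 K (measurements thermostated at 20 °C); all are fields of
`SphereSpec`. For M = 58 kDa this gives φ ≈ 24.6 ns.

## Synthetic data

All generators are pure functions of (seed, parameters); identical calls
agree bit for bit. Noise models are the package's own choice (none is
specified by the experiments): additive Gaussian for kinetics and
phase/modulation data, multiplicative Gaussian for fluorescence
intensities. `n_replicates` averages independent noise draws per point,
mirroring the triplicate-measurement protocol of the fluorescence
experiments.

The two-lobe structure generator packs each lobe as a self-avoiding
uniform blob (hard-core 3.8 Å, ≈110 Å³ per residue — globular-protein
density, giving a dense 4–8 Å contact shell), faces the lobes across a
10 Å gap (wider than the contact window, so no direct inter-lobe
contacts), and places the connector residues on a ring in the midplane of
the gap, each within contact range (≈6.7 Å) of both facing surfaces. This
seam geometry makes the connectors genuine two-module bridges: the
spectral cut passes through the seam and the connectors dominate both the
participation ranking and the |ΔP| ranking of the "closed" variant, in
which each lobe is translated 2 Å toward the midplane and direct
inter-lobe contacts appear. With zero connectors the network is
disconnected by construction. Connector ground-truth labels are assigned
alternately, since a seam residue has no true side; label-recovery
statistics should expect up to n_bridge ambiguous nodes.

What the generators do *not* emulate: real secondary structure or chain
connectivity (the blobs are not polymers), realistic FTIR band shapes
beyond the two-Gaussian band-intensity level needed by the trace
extraction, correlated instrument drift, photobleaching, or
lifetime-linked (associative) anisotropy. Passing tests therefore
demonstrate that the estimators invert their own forward models under the
stated noise, at the study's sample sizes — not that the models are
correct for any particular real data set.

## Problem sizes and determinism

The test suite and the acceptance script run synthetic problems at the
study's natural sizes: 64-residue two-lobe structures (50 seeds for
label-recovery statistics), 30-point uptake traces on the experimental
grid (1-min steps to 10 min, 8-min steps to 170 min; 100 replicates for
noisy-recovery statistics), 12-point log-spaced titrations (100
replicates), and 30-frequency sets between 2 and 250 MHz (20 replicates
for anisotropy recovery; triplicate-averaged for the headline summary
quantities, median of 5 runs). Every random draw is seeded; workflow
reports contain no timestamps, so a given config and seed reproduce them
byte for byte.

## Known limitations

- The deposited aromatase crystal structure cannot be redistributed with
  the package; the crystal-structure participation check runs only when
  the user supplies `data/4kq8.pdb`. The published ⟨P⟩ ≈ 0.076 is also
  ambiguous about which model (crystal vs simulated apo) it was computed
  on, which is why that check carries a wide (±30 %) tolerance.
- Four-component lifetime fits at single-shot instrument noise are
  ill-conditioned when two lifetimes are closer than a factor ≈2; the
  package reports this via merge warnings rather than regularising.
- The differential-anisotropy fit holds the intensity decay fixed; no
  global (linked) multi-dataset analysis is provided.
- No weighted contact networks, no centrality measures beyond
  participation, no structure repair or symmetry expansion.
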