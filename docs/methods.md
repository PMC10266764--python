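# Methods

This note records the modeling assumptions, unit and sign conventions,
numerical choices and known limitations of the package. Equations are
stated in the package's own notation (see the module docstrings for the
per-model summaries).

## Units and conventions

Concentrations are in mM (= mol/m³), volumes in μm³ (= fL), particle
amounts as dimensionless counts (helpers convert attomol), pressures in
Pa, tensions in mN/m, potentials in kBT/e with a mV conversion at a
configurable temperature (default 300 K). One particle per μm³ is
1e18/N_A ≈ 1.66×10⁻⁶ mM.

All valences are stored as positive magnitudes (z, z_p, z_a, z_Af); the
physical charge of the impermeant species is −z. The Donnan potential
uses the anion Boltzmann factor, U_c = ln(n₋/n₀), which is the
convention that reproduces the measured membrane potential; the cation
relation is shifted by pumping and is not used for the potential.

Temperature: the tabulated external osmotic pressure of 7.2×10⁵ Pa for
300 mM total osmolytes corresponds to T ≈ 290 K, while −52 mV for
ln(20/150) corresponds to T ≈ 300 K. The package default is 300 K and
both values are reproduced at their respective temperatures; tests pin
each at its own T.

## Single-compartment Pump-Leak

Given (n₀, α₀, z, X, R, ΔP), electroneutrality plus the ion-product law
reduce the ion pair to n_± = (±z·x + √(z²x² + 4α₀n₀²))/2, leaving one
scalar osmotic residual that is strictly decreasing in V. It is bracketed
from below by the infinite-pumping volume (pumping removes ions, so α₀>0
only swells the cell) and solved with Brent's method (xtol 1e−14).
Solved states must satisfy electroneutrality and osmotic residuals below
1e−10/1e−8 relative or the solver raises.

Degenerate cases are surfaced, not patched: X = 0 leaves the volume
indeterminate (raises), and α₀ → 1 with ΔP = 0 means the osmotic balance
can only be met by a diverging volume (raises a dedicated error). ΔP is
an input, not solved: it is zero by default (mammalian cells) and held
constant for walled cells.

## Growth model

Four protein classes — ribosomes r, RNA polymerases p, amino-acid
enzymes e, other o — with gene fractions φ_j summing to 1. mRNA dynamics
are integrated explicitly but are fast (τ_m ≪ τ_p), so the nonsaturated
regime sits on the quasistatic manifold M_j = k₀τ_m φ_j P_p. Regime
switching is sharp, implemented as piecewise ODE integration (LSODA,
rtol 1e−8, atol 1 count) with terminal events at P_p = P_p* (DNA
saturation) and P_r = N_r^max·ΣM (mRNA saturation); switches are ordered
and irreversible, and the DNA-saturated intermediate regime is modeled
even though the headline formulas jump straight to mRNA saturation.
Counts are continuous reals: this is a deterministic mean-field model.

The wet volume counts free amino acids and their counterions only,
V = v_p·P_tot + (z_Af+1)·A_f/(2n₀); mRNA and protein counterion
contributions are neglected at leading order, and the dry volume is the
protein excluded volume R = v_p·P_tot. Total mass density uses an
effective water density ρ_w = 1.04 kg/L: the model books all dry mass as
protein, and the non-protein dry mass is absorbed into ρ_w.

### Default parameters (the synthetic study conditions)

The synthetic experiment emulates volume/density/protein tracks of
non-dividing budding yeast. Four observables define the conditions:
protein lifetime τ_p = 69 min, saturation time t** = 164 min,
exponential rate k_r = 0.5/h and initial volume v₁ = 30 fL — the last
two chosen once so that the asymptotic linear-regime slope is
~129 fL/h, the measured haploid value (k_r also gives a plausible 1.4 h
doubling time). `default_growth_params()` back-solves k_t, k_cat, the
initial counts and the ribosome packing N_r^max from these four targets
plus fixed coarse constants (Σg = 5000 genes, N_p^max = 40, k₀ = 6/h,
τ_m = 0.33 h, l_p = 400 aa, v_p = 4×10⁻⁸ μm³, M_a = 110 Da, z_Af = 1,
n₀ = 150 mM) and the flux ratio λ = φ_e·k_cat/(l_p·k_r) = 3.5.

λ controls the amino-acid/protein-residue pool ratio (λ−1). The value
3.5 places the model in the amino-acid-dominated volume regime its
closed-form density expressions assume, while keeping the post-t**
slope change (×2.2) in the observed range. With this choice the
simulated dry density is a few g/L — the model's reduced composition
(only proteins and amino acids) does not reproduce absolute cellular
densities, which is why the density channel is anchored by an initial
total density ρ_tot(0) (default 1.10 kg/L) and predicted in shape, not
in absolute dry-mass units.

## Four-parameter fit model

For t < t**, V = v₁e^{k_r t}. After t**, every protein class relaxes as
e^{−(t−t**)/τ_p} to its plateau (the plateau/pre-plateau ratio 1+k_rτ_p
follows from continuity of Ṗ_tot), and integrating the amino-acid
balance gives

V(u) = V**·[1 + (1+ε)k_r(1+k_rτ_p)u − ((1+ε)(k_rτ_p)² + ε·k_rτ_p)(1 − e^{−u/τ_p})]

with u = t − t**, V** = v₁e^{k_r t**}. The single structural constant
ε = 1/(λ−1) (default 0.4, matching the growth-model default λ = 3.5) is
the protein-residue/amino-acid pool ratio; it is a model constant, never
fitted. The curve is continuous in value and slope at t** (and in
curvature when ε = 0), asymptotically linear with slope
(1+ε)k_r(1+k_rτ_p)V**. In the quasistatic, sharp-switch limit this
closed form coincides exactly with the ODE trajectory; the ODE-vs-closed
form tests agree to ~0.3% (the residual is the mRNA relaxation
transient of width τ_m at the switches).

Fitting minimizes (weighted) least squares over (log τ_p, t**, log k_r,
log v₁) with `scipy.optimize.least_squares` from a grid of starts
(log-spaced k_r and τ_p, t** spread over the window), residuals
normalized by the data scale so the fit is invariant to volume-unit
rescaling. If per-point σ are given they weight the residuals; synthetic
channels carry σ = cv·y since the noise model is known multiplicative.
A fitted t** at the window edge is flagged unidentifiable.

Identifiability: on a single 2%-noise track the Fisher information
bounds τ_p recovery at ≈20% relative sd — no estimator does better —
while t**, k_r, v₁ are tightly determined. The recovery experiments
therefore fit the population-mean curve (100 cells, 2% per-cell noise),
mirroring how such growth curves are measured and fitted at the
population level; the mean track carries 0.2% scatter and all four
parameters recover within 5%.

Predictions use only the fitted four parameters plus fixed constants:
P_norm(t) = e^{k_r t} then plateau relaxation, and
ρ_tot(t) = ρ_w + (ρ_tot(0) − ρ_w)·P_norm/V_norm.

## Manning condensation and swelling

Chromatin is a uniformly charged line; no Poisson–Boltzmann numerics.
The partition (Q_eff, Q_cond) = (Q_tot/u, Q_tot(1−1/u)) applies for
u > 1 and is continuous at the threshold. The volume increment for
releasing ΔN counterions uses the osmotic-equivalent rule
ΔV = ΔN/(2n₀) by default, which yields ≈44 μm³ for the full 8×10⁹
release; conversion rules including Donnan/pumping corrections are
2–3× larger (toward ~10% of a mammalian cell volume) and can be passed
through the exposed conversion factor. The default is the conservative,
main-line rule; the gap is documented rather than tuned away.

## Nested Pump-Leak

Unknowns are log wet volumes, log cytoplasmic metabolite and cation
concentrations and the envelope potential U_n; the cytoplasmic anion is
eliminated by the ion product, nuclear ions and metabolites by Boltzmann
factors: n_n^+ = n_c^+e^{−U_n}, n_n^− = n_c^−e^{+U_n},
a_n = a_c·e^{+z_a·U_n}. Residuals (both electroneutralities, plasma
osmotic balance, envelope osmotic balance with the Laplace pressure,
metabolite conservation) are each scaled by their own equation magnitude
so tolerances stay relative across 10⁻⁹-fold osmolarity sweeps; the
system is solved with Powell's hybrid method from a fixed-point initial
guess (osmolarity 2n₀ per compartment, metabolites proportional to wet
volume), with continuation along sweep grids. Convergence requires max
scaled residual < 1e−9.

The nucleus is a sphere for area/Laplace purposes. Envelope tension is
fold-buffered: zero while the sphere area is below the unfolded
reference A₀(1+s) (A₀ at the isotonic volume, s the fold-area fraction),
then linear with modulus K; ΔP_n = 2γ_n/r. In shock sweeps the isotonic
reference is solved tension-free first, which defines V_n^iso and the
fold reservoir self-consistently. The saturated-swelling closed form
uses the at-saturation nuclear content N_n = (z_p+1)P_n + Q_eff (no
metabolites remain in a strongly swollen nucleus); the choice is exposed
for sensitivity analysis. Chromatin exerts no direct osmotic pressure
and no mechanical stress; it enters only through Q_eff.

Default composition (mammalian scale): P_n = 10⁹, P_c = 3.3×10⁹
(NC ≈ 0.3), Q_eff = 2×10⁹ (comparable to the trapped-protein
counterions), A_f = 1.2×10¹¹ (metabolite pool ~60× the chromatin
counterions), z_p = z_a = 1, α₀ = 0 — the monovalent high-pumping regime
with its analytic reduction (n_c = n₀, n_n = n₀ + q_eff/2,
U_n = −ln(1+q_eff/2n₀)) used as the solver oracle. Envelope mechanics
default to K = 50 mN/m and s = 4%. Growth-coupled NC simulations driven
by the yeast trajectory instead use a yeast-scale chromatin charge
(Q_eff = 5×10⁶: 12 Mbp × 2 charges/bp × 1/u at u ≈ 5).

## Synthetic data

Generators wrap the forward models bit-identically at cv = 0 and apply
multiplicative lognormal noise (mean-one; additive Gaussian available)
from `numpy.random.default_rng(seed)` — reproducible across platforms.
Channel defaults: 2% (volume), 0.5% (total density), 5% (fluorescence).
The population generator draws per-cell parameters lognormally around
the base values and can apply per-cell measurement noise before
averaging.

What the generators do **not** emulate: correlated measurement drift,
cell-cycle gating artifacts, single-cell regime-switch asynchrony in the
mean curve (dispersion smears the corner — fits to dispersed populations
inherit that bias), or instrument-specific density offsets. Passing the
recovery tests therefore demonstrates correctness of the estimation
machinery under the stated noise model, not robustness to every feature
of real measurements.

## Known limitations

- Two ion species only; no time-resolved ion fluxes (quasi-static).
- Ideal (Van 't Hoff) osmotic pressure; crowding enters only through the
  dry volume.
- The growth model's absolute densities are not calibrated (see λ above);
  density comparisons are shape-based with an anchored initial value.
- Nuclear transport is an input (fixed P_n/P_c); no envelope-breakdown
  dynamics; spherical nuclei only.
- The condensation ΔV estimate is order-of-magnitude by construction.
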