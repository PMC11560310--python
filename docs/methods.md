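# Methods

## Scope and design

`prolens` analyses proline *cis/trans* conformational subensembles of a
disordered peptide. It does not run molecular dynamics: the conformer
ensembles it consumes are either read from multi-model PDB files (with a
plain-text per-frame weight file) or produced by the package's own
synthetic generator, which serves as a desk-scale stand-in for
enhanced-sampling trajectories. Everything downstream — isomer
decomposition, convergence analysis, SAXS forward modelling and
reweighting, NMR observable analysis — operates identically on either
source.

Internal units are nm, kelvin, joules and seconds; angles cross the API
in degrees with the IUPAC torsion convention (0° = cis, right-handed,
range (−180°, 180°]). Unit conversions happen only at file boundaries
(PDB Å→nm; optional SAXS Å⁻¹→nm⁻¹ flag).

## Chain model and geometry

Conformers carry backbone atoms N, CA, C, O per residue plus the proline
ring Cδ (needed for the improper ζ angle (Cαᵢ₋₁, Oᵢ₋₁, Cδᵢ, Cαᵢ) that
tracks isomerization together with ω). Chains are built by sequential
internal-coordinate (NeRF) placement from per-residue (φ, ψ, ω) with
ideal bond lengths and angles (N–CA 0.1458 nm, CA–C 0.1525 nm, C–N
0.1329 nm, C=O 0.1231 nm, N–Cδ 0.1468 nm; standard junction angles), all
configurable via `BackboneGeometry`. The carbonyl O is placed anti to
the next amide nitrogen; the proline Cδ sits in the amide plane anti to
Cα across the C–N bond, so ζ ≈ ω up to small offsets. The builder is
vectorized across frames; per-frame construction and measurement
round-trip to < 1e-4° and the torsion sign convention is validated
against an independent projection-formula oracle (and, during
development, against a second trajectory library).

**Isomer classification.** cis iff |ω| < 90° after wrapping; the
boundary 90° is assigned trans. This is deterministic and separates the
two narrow planarity peaks (σ_ω = 8°) by > 11 standard deviations, so
the label is insensitive to the exact threshold.

## Synthetic ensembles

Backbone (φ, ψ) pairs are drawn per residue from a three-basin mixture
emulating coil-library statistics: PPII (−75°, 150°) with probability
0.45, β (−120°, 130°) with 0.35, α_R (−60°, −45°) with 0.20, all with
15° angular SD; proline φ is fixed at −65°. ω is Gaussian with 8° SD
about 180° everywhere except the bond preceding the proline, where it is
drawn about 0° with probability `cis_fraction` (default 0.10, matching
the population scale the NMR analysis of this peptide reports at body
temperature). Frames with any atom pair ≥ 3 bonds apart closer than
0.25 nm are rejected and redrawn. An optional compaction bias accepts a
frame with probability min(1, (R_ref/R_g)^c); c = 0 disables it, and
increasing c strictly decreases mean R_g.

Two design points deserve emphasis:

- **Stratified rejection.** The isomer label of every output frame is
  drawn once, up front, from a Bernoulli(p_cis); clash/compaction
  rejection then redraws *within* the label stratum. Joint rejection
  would bias the realized cis fraction several binomial SDs low, because
  cis conformers — being more turned-back — clash more often. With
  stratification the realized fraction is exactly binomial in the
  requested p_cis.
- **The cis kink compacts the chain intrinsically.** Even with identical
  (φ, ψ) statistics and no compaction bias, cis-labelled frames have
  smaller mean R_g than trans frames (≈1.29 vs 1.37 nm at the defaults;
  z ≈ −7 at n = 5000). This is a geometric consequence of the chain
  reversal at a cis peptide bond, not an artifact, and it matches the
  direction seen experimentally for cis subensembles. Tests assert this
  direction rather than pretending the two strata are exchangeable.

The generator is deterministic given config + seed (bit-identical
coordinates and weights). Its ensembles are backbone-only; absolute R_g
and R_h therefore differ systematically from all-atom ensembles, and no
attempt is made to reproduce force-field-specific values. What the
passing tests demonstrate is the correctness of the *analysis* operators
on ensembles with known ground truth — not the physical realism of the
generator's energetics.

Weight attachment supports uniform weights and the final-bias estimator
w ∝ exp(V/k_BT) for bias potentials in kJ/mol.

**NMR fixtures.** Tabular generators emulate the measured inputs: peak
volumes with V_cis/V_trans = exp(−(ΔH−TΔS)/RT) and optional
multiplicative log-normal noise; monoexponential relaxation decays;
Stejskal–Tanner diffusion decays. Noiseless fixtures round-trip through
the corresponding fits to machine precision, which pins the sign and
unit conventions end to end. The measurement temperatures are taken as
an even 10-point grid over 275.65–313.15 K (the stated 2.5–40 °C range;
the exact experimental grid is not published).

## SAXS forward model and reweighting

Scattering uses the Debye formula over one centre per residue (Cα, unit
form factor by default, per-residue table configurable):
I(q) = Σᵢⱼ fᵢfⱼ sinc(q rᵢⱼ), evaluated per q over the pair upper
triangle (memory O(n²)). This is deliberately coarse — no atomic form
factors or hydration shell — but exact in its own terms, linear in
frame weights, and sufficient to drive and test reweighting mechanics.
Guinier analysis fits ln I vs q² on the window q·R_g ≤ 1.3 (IDP
practice; configurable), iterated twice to self-consistency; on Debye
curves of single frames it recovers the geometric Cα R_g to ~5% and on
a numerically sampled homogeneous sphere it recovers √(3/5)·R to ~2%
when restricted to q·R_g ≤ 1.

Experimental/calculated matching minimizes Σ((I_exp − a·I_calc − b)/σ)²
with the offset optional (on by default; the offset-free variant is a
flag). SAXS uncertainty rescaling is accepted as a profile-level scalar.

**BME.** The reweighting dual Γ(λ) = ln Z(λ) + Σλ_jo_j + (θ/2)Σλ_j²σ_j²
is minimized by L-BFGS-B from λ = 0 with the analytic gradient
−⟨F_j⟩_w + o_j + θλ_jσ_j², using log-sum-exp throughout; weights below
1e-300 are floored to zero and renormalized. The optimizer is verified
against a grid+bisection search on a 1-D toy to 1e-4, and χ²_posterior ≤
χ²_prior holds across randomized instances. θ selection scans a grid and
takes the largest θ with χ²/n_restraints ≤ 1.2 ("minimal perturbation
that still fits"); χ² and φ_eff are monotone in θ. SAXS reweighting
alternates the scale/offset refit with multiplier updates for 5 rounds.
Note that the free scale/offset absorbs overall-intensity information,
so directional statements about subensemble populations are properties
of BME with fixed-scale restraints, not of the scale-refitted pipeline.

## Blocking and free-energy-surface errors

Weighted Flyvbjerg–Petersen blocking: for block size b, contiguous
blocks get weighted means m_k and normalized masses w̃_k, and
SE² = K/(K−1) Σ w̃_k²(m_k − m̄)². The default size ladder is powers of 2,
stopped while ≥ 64 blocks remain (for short series, n/2): SE estimates
from fewer blocks fluctuate by ≳ 1/√(2K) and cannot support plateau
detection. Convergence is declared when the relative change of SE across
the last three sizes stays below 0.10 (configurable); the plateau SE is
their mean. On AR(1) series with φ = 0.9 the plateau reproduces the
analytic √((1+φ)/(1−φ))/√n within 15% at n = 2¹⁷; the converged *flag*
at the default 10% tolerance is noise-limited and can fluctuate for
marginally converged series — the plateau value is the robust output.

FES errors: per-bin probabilities from the full weighted histogram give
F = −ln p (k_BT units, min-shifted to 0); the series is split into
contiguous blocks whose per-block probabilities give SE_p, propagated as
SE_F = SE_p/p. Bins empty in any block report SE as NaN (unavailable),
never zero.

## Subensemble statistics

Splitting renormalizes weights within each isomer subensemble and
reports populations as prior-weight sums (cis + trans = 1 exactly).
Uncertainties follow the trajectory-half convention: the metric is
evaluated on the first and second halves of the frame sequence and the
two-point SD |a−b|/√2 is reported. Weighted Gaussian KDEs default to
Silverman's bandwidth evaluated on the weighted effective sample size
n_eff = 1/Σw²; degenerate (zero-variance) input falls back to a
near-delta kernel. Secondary structure is assigned from (φ, ψ) regions
— helix φ∈(−100°,−30°), ψ∈(−77°,−7°); strand φ∈(−180°,−90°) with
ψ∈(90°,180°] or ψ<−170° — rather than hydrogen-bond based assignment,
which backbone-only ensembles cannot support reliably; the regions are
configurable in code and documented as a substitute.

## NMR thermodynamics

Populations: p = V_cis/(V_cis+V_trans) per residue; the aggregate is
mean ± sample SD across residues, excluding (and reporting) residues
missing either isomer peak. van 't Hoff: weighted least squares of ln K
on 1/T; ΔH = −R·slope, ΔS = R·intercept with R = 8.314 J K⁻¹ mol⁻¹; the
parameter covariance is unscaled when per-point ln K uncertainties are
supplied, residual-scaled otherwise. Temperatures are kelvin
internally (37 °C = 310.15 K) to avoid off-by-0.15 drift.

Amide temperature coefficients more negative than −4.5 ppb K⁻¹ flag "no
persistent H-bond". The proline ¹³Cβ−¹³Cγ difference classifies the
isomer with a conservative band: cis for Δ ≥ 8 ppm, trans for Δ ≤ 6 ppm,
ambiguous between (literature anchors ≈ 9.5 / 4.5 ppm).

**SSP score.** Secondary shifts (observed − random coil) are oriented
per nucleus by the sign of the helix reference shift, summed over a
5-residue end-truncated window, and normalized by the helix reference
magnitude when positive or the strand magnitude when negative, capped to
[−1, 1]. Coil input scores 0, full-helix +1, full-strand −1, and the
score is linear in mixture fraction. Exact sign antisymmetry under
negating the observed secondary shifts holds only when the α and β
reference vectors are mirror images; with realistic asymmetric
references the positive and negative branches have different
normalizations, as in standard SSP usage. The shipped random-coil and
secondary-shift reference table is an editable CSV because the
reference-set choice materially affects scores.

## Relaxation and diffusion

Constants: r_NH = 1.02 Å, Δσ(¹⁵N) = −160 ppm, standard gyromagnetic
ratios (γ_N < 0 handled with signs); dipolar constant
d = (μ₀/4π)ħγ_Hγ_N/r³ and CSA constant c = ω_NΔσ/√3, giving the usual
R1/R2/σ_NH expressions (module docstring). The reduced spectral density
mapping approximates all proton-frequency terms by J(0.87ω_H):

σ_NH = R1(NOE−1)γ_N/γ_H, J(0.87ω_H) = 4σ_NH/5d²,
J(ω_N) = (R1 − 7(d²/4)J(0.87ω_H))/(3d²/4 + c²),
J(0) = (R2 − (13d²/8)J(0.87ω_H) − (3d²/8 + c²/2)J(ω_N))/(d²/2 + 2c²/3).

The coefficient set is pinned by a round trip through the forward
dipolar+CSA model with single-Lorentzian J(ω): at 14.1 T the mapped J(0)
agrees with 2τ_c/5 to 0.5% at τ_c = 2 ns and within 5% for τ_c 1–5 ns.
The approximation genuinely degrades for sub-ns correlation times (5.2%
at 0.5 ns) — a documented limitation, irrelevant for the ns-scale
backbone dynamics this analysis targets. Errors propagate linearly
through the same map.

R2 from the rotating frame: R2 = (R1ρ − R1cos²θ)/sin²θ with the
spin-lock tilt θ; quadrature SEs. Exchange: Rex = R2 − κR_dd with κ a
config input (default 1 at matched conditions; the rescaling derives
from the exchange-free experiment's analysis and is not derivable here),
flagged "no detectable exchange" when |Rex| < 2 SE.

Diffusion: I(g) = I₀exp(−Dγ²g²δ²(Δ−δ/3)) fitted by nonlinear least
squares with log-linear initialization; noiseless decays recover D to
better than 6 significant figures. Subensemble comparisons use the
textbook one-tailed Welch t with Satterthwaite df; the direction of the
tail must be declared explicitly. Monte Carlo error propagation is
seeded and reproducible. Ensemble hydrodynamics uses the Kirkwood
approximation 1/R_h = ⟨1/r_ij⟩ per frame with mobility (harmonic)
averaging of 1/R_h across frames — fast exchange within a subensemble
averages diffusion coefficients — and the Stokes–Einstein relation at
15 °C water viscosity (1.138e-3 Pa·s) by default.

## Problem sizes and determinism

Default analysis sizes were chosen so every statistical check has ample
power while remaining interactive: 5000 frames for binomial population
recovery (3σ ≈ ±0.013 at p = 0.10), 2¹⁴–2¹⁷ points for blocking
accuracy, 100-frame ensembles with 8–10 restraints for reweighting
recovery, 3000 centres for the sphere scattering oracle. Every source of
randomness flows from explicit integer seeds; identical config + seed
reproduces coordinates, weights and all numeric outputs bit for bit.

## Known limitations

- Backbone-only chains: no side chains beyond proline Cδ, so absolute
  R_g/R_h are not comparable to all-atom ensembles, and hydrogen-bond
  based secondary structure assignment is unavailable.
- The Debye model's unit form factors ignore contrast and hydration;
  calculated curves are for reweighting mechanics and consistency
  checks, not for absolute comparison with measured intensities.
- The generator's basin mixture has no residue-specific Ramachandran
  statistics (except proline φ) and no energetics; populations and
  compactness are controls, not predictions.
- BME assumes Gaussian restraint errors and a fixed ensemble (no
  iterative regeneration); chemical shifts are treated as validation
  observables, not fitted restraints.
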