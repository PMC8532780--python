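# Methods

## Scope and model

The package analyzes the chemical-shift tensors (CSTs) of amide ¹⁵N and
carbonyl ¹³C nuclei along a helical peptide backbone and simulates the
orientation-dependent observables of oriented-sample SSNMR. The physical
model is the standard one for a helix in a magnetically oriented bilayer
with the membrane normal along the field: rotational averaging about the
normal leaves a parallel ¹⁵N component δ∥ = δ₁₁ sin²τ + δ₃₃ cos²τ (the
Euler-angle specialization with the first two angles set to 0 and τ), and
a carbonyl total anisotropy
Δδ(ρ, τ) = 3/2 sin²τ (δ₁₁ cos²ρ + δ₃₃ sin²ρ − δ₂₂) + δ₂₂ − (δ₁₁ + δ₃₃)/2.
Only these closed forms are implemented; powder/MAS line shapes, dynamic
order-parameter scaling and the explicit δ⊥ orientational formula are out
of scope.

## Tensor conventions

* Shieldings are ordered σ₁₁ ≥ σ₂₂ ≥ σ₃₃ with eigenvectors ξ₁, ξ₂, ξ₃;
  shifts (and calibrated theoretical shifts ε) the reverse, ε₁₁ ≤ ε₂₂ ≤ ε₃₃.
  The negative calibration slope means σ₁₁ ↔ ε₁₁ (most shielded ↔ smallest
  shift).
* The antisymmetric tensor part does not contribute to the observable
  shift to first order and is discarded before diagonalization.
* Eigenvector sign convention: ξ₁ and ξ₂ have their largest-magnitude
  component positive, ξ₃ = ξ₁ × ξ₂ (right-handed). The orientation angles
  are folded to acute values, so this convention is cosmetic.
* Frames with an eigenvalue gap below 10⁻⁶ ppm are flagged degenerate and
  refused by the orientation-angle functions — eigenvector directions are
  meaningless under degeneracy.
* Calibration lines: ¹⁵N ε = −0.93574·σ + 209.54 ppm; ¹³C
  ε = −0.99314·σ + 172.50 ppm (residual sd 1.8 ppm, adjusted R² 0.99918).
  The single-crystal reference datasets behind them are not distributed,
  so the coefficients ship as constants; `fit_calibration` (OLS, residual
  sd with n−2, adjusted R²) is validated on synthetic data instead.
* Table output rounds half-up to one decimal (ppm, degrees).

## Orientation angles

For ¹⁵N the peptide plane P_N passes through {N, H, Cα}; α is the
elevation of ξ₃ out of P_N (implemented as 90° minus the acute angle
between ξ₃ and the plane normal), β the angle between ξ₃ and the N–H
bond, γ the angle between ξ₂ and the normal. For ¹³C the plane P_C uses
{C′, O′, Cα} and the roles shift to ξ₂ (elevation α, angle β to C′=O′)
and ξ₁ (γ to the normal). All three angles are reported as acute values
in [0°, 90°]: eigenvectors are axes, not arrows, and the tabulated values
this mirrors never exceed 70°. γ is reported raw, without the rotational
averaging it would undergo in a membrane environment. Prolines have no
amide H (P_N undefined); a C-terminal amino alcohol such as phenylalaninol
has no carbonyl (P_C undefined).

## Helix parametrization

The helix axis is a least-squares cylinder fit to the Cα trace: parameters
are the axis direction (two spherical angles), an anchor point (two
in-plane offsets from the centroid) and the radius; residuals are
point-to-axis distances minus the radius. The refinement starts from both
the largest and smallest principal directions of the point cloud — the
former suits elongated helices, the latter the flat circular-arc limit —
and keeps the lower-cost solution. The axis sign points N→C. On an ideal
α-helix the fit is exact to numerical precision (axis within 0.1°, rise
1.5 Å/residue).

Per-residue azimuth ρ: the chosen site vector (default C′→O′, since the
carbonyl orientation is what the ¹³C oscillation probes; Cα→C′ by flag)
is projected perpendicular to the axis; ρ is its right-handed angle about
the axis from the reference residue (default: first residue with a usable
vector), reported in [0°, 360°). An ideal α-helix gives ~100°/residue
spacing. The tilt τ is the acute angle between axis and membrane normal.
These are this package's own parametrization choices; the validation
surface is exact recovery on ideal generated helices, not bit-agreement
with any external implementation.

## Backbone geometry

Dihedrals follow the signed IUPAC convention. The φ+ψ diagnostic column
is emitted as the signed sum (helical residues ≈ −105°); an
absolute-value label for this quantity would contradict its negative
values, so the sign is kept. Hydrogen bonds: amide N–H donors to carbonyl
O acceptors, defaults H···O ≤ 2.5 Å and N–H···O ≥ 120° (common practice
for SSNMR-refined structures; configurable), one acceptor per donor
(closest H···O), minimum sequence span 2, reported from the acceptor's
perspective (i→i+4 α-helical, i→i+3 for 3₁₀ turns). Missing amide
hydrogens are reconstructed in the C′(i−1)–N–Cα plane, 1.01 Å from N
along the external bisector — XRD-derived files usually lack them. No
DSSP-style helix-type classification is attempted; φ/ψ and H-bond spans
are exported for inspection.

## Synthetic data

The generator is the ground-truth source replacing non-distributed DFT
outputs. `build_helix` constructs backbones atom-by-atom by natural
extension (bond N–Cα 1.458 Å, Cα–C′ 1.525 Å, C′–N 1.329 Å, C′=O 1.231 Å,
N–H 1.01 Å, trans ω = 180°); φ/ψ default to −57°/−47°, the canonical
α-helix, making the default generated conditions an ideal right-handed
helix with emergent rise ≈ 1.5 Å/residue and twist ≈ 100°/residue. The
default sequence is the 20-residue alamethicin E18 peptaibol with an
acetyl cap (residue 0) and phenylalaninol terminus. Optional Gaussian
coordinate noise is seeded and reproducible.

`plant_tensors` inverts the orientation-angle definitions constructively:
the reference eigenvector is placed at elevation α with angle β to the
in-plane bond (feasible iff β ≥ α), its partner perpendicular to it at
angle γ to the normal (feasible iff γ ≥ α); the rotations are applied in
the order α, β, γ, and under that order the planted angles are exact.
Ground truth is always the noiseless tensor.

What the generator does not emulate: real DFT tensors (site-specific
asymmetries, crystal-packing effects), side-chain rotamers, the irregular
helix break at Gly11, solvent, or crystal symmetry images. Passing tests
therefore demonstrate correctness of the analysis chain on exactly
specified inputs, not accuracy of any electronic-structure prediction.

## Numerical notes and known inconsistencies

* `invert_tilt` returns the principal branch τ ∈ [0°, 90°]; the mirror
  solution 180° − τ maps to the same observable and is documented, not
  enumerated. Inputs outside [min(δ₁₁, δ₃₃), max(δ₁₁, δ₃₃)] raise a
  domain error naming the violated bound.
* The literature value δ∥ = 292.2 ppm quoted for the collective Aib
  inputs {64.5, 232.5} ppm at τ = 8.0° violates the bound δ∥ ≤ δ₃₃ and is
  not reproducible by the tilt law; it appears to be a digit transposition
  of 229.2 ppm, which this package computes and which reproduces both
  downstream site-specific tilts (5.0° with the Aib5 tensor, 11.9° with
  Aib8). The package refuses 292.2 rather than special-casing it.
* Recomputing the proteinogenic ε₁₁ group average from the one-decimal
  ¹⁵N table gives 52.3 ppm where 52.4 ppm has been quoted; the package
  reports the recomputed value.
* Reported "±" spreads are sample (n−1) standard deviations — the eight
  Aib β angles give 13.7° ± 1.3°, whereas a population sd would print 1.2°.
* Group averaging excludes prolines (undefined amide angles) and the
  phenylalaninol terminus from both the Aib and proteinogenic classes.
* Problem sizes: the full validation suite runs on 12–20-residue
  generated helices and the 19–20-row packaged shift tables; everything
  is closed-form or small least-squares, so the whole suite completes in
  seconds.
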