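# Methods

This note records the models, numerical choices and limitations behind each
module, in the order data flows through the analysis.

## Scattering curves and reduction

Curves are triples (q, I, σ) with q in Å⁻¹, strictly increasing. A
heuristic flags probable nm⁻¹ input (q_max > 2 Å⁻¹) with a warning rather
than converting silently. SEC frame reduction averages sample and buffer
frames on a shared q grid — mismatched grids are an error, never silently
interpolated — and propagates σ in quadrature divided by frame counts. The
per-frame total intensity is returned as the elution profile.

## Guinier analysis

Weighted least squares of ln I on q², weights (I/σ)², iterated so that the
window satisfies q_max·R_g ≤ 1.3 (the common globular-protein rule; the
limit is a parameter). Convergence is reached when the window stops
shrinking; at least 5 points are required. A non-negative slope (rising
low q, e.g. aggregation) returns a failure status rather than a number.
On the exact Guinier model the fit is exact to machine precision, which the
tests assert at 1e-6 relative.

## P(r) inversion and D_max

The indirect Fourier transform solves

  min‖(I − A·p)/σ‖² + α‖D₂p‖²,  p ≥ 0, p(0) = p(D_max) = 0,

with A the histogram kernel A_ij = 4πΔr·sin(q_i r_j)/(q_i r_j) on a uniform
101-point r grid, D₂ the second-difference operator (acting across the
pinned zero endpoints, which smooths p into the boundaries), and the
non-negative solution found by NNLS on the stacked system. α is
dimensionless: it scales the ratio of operator norms, and when not given is
chosen at the L-curve corner (maximum distance from the chord on the
log-log residual/seminorm curve) over a 9-point log grid.

D_max is estimated by scanning candidate values: the chosen D_max is the
*smallest* candidate whose fit χ² is within a factor 1.05 of the scan
minimum and whose unconstrained (sign-free) solution is non-negative near
D_max within 5% of its own peak. This explicit rule replaces the perceptual
criteria of classical IFT programs. Fit quality is reported as reduced χ²
with N−1 degrees of freedom throughout.

Known behavior: for shapes whose P(r) tail vanishes smoothly (the
two-sphere dumbbell), the smallest-acceptable rule sits one scan step below
the geometric D_max (115 vs 120 Å at a 5 Å step) because the last bin
carries negligible mass. The sphere, whose tail is fatter, is recovered
exactly. This is a property of any parsimony-based D_max rule, not a bug;
widening the tolerance factor trades it against overestimation on noisy
tails.

## Molecular weight

The default estimator is the volume of correlation: V_c = I(0)/∫q·I(q)dq
(trapezoid on the measured range, extended to q = 0 with the fitted Guinier
model, truncated at q = 0.3 Å⁻¹ per the published protein calibration),
Q_R = V_c²/R_g, MW(Da) = Q_R/0.1231. The method name and all constants are
emitted with every estimate. V_c is scale-invariant, so no intensity
calibration is needed; an absolute-I₀ mode (MW = I₀/calibration) is
provided for calibrated data. The protein power law underestimates
protein–RNA complexes; this caveat is attached to the output.

For an ideal uniform sphere the law closes analytically: ∫xΦ²(x)dx = 9/4
gives V_c = 4R²/9 and MW = R³/0.4827 Da, equivalent to an apparent
specific volume of ≈2.02 Å³/Da. `sphere_radius_for_mass` uses this
convention so synthetic spheres of a stated mass are consistent with the
estimator's own calibration; the recovery test then measures pipeline
error (Guinier fit, truncation, extrapolation), not the constant.

## Theoretical curves and multi-state fitting

Debye sums use one bead per residue at the Cα (residue centroid for
Cα-less residues) with a constant form factor — adequate for shape-level
comparisons and D_max round trips, not for atomic-resolution fitting. The
i = j and q → 0 limits are handled analytically, so I(0) = (Σf)² exactly.

Multi-state fitting enumerates candidate subsets up to the requested size;
for each subset non-negative coefficients are solved by NNLS (the
coefficient sum is the global scale, their normalization the weights) and
reduced χ² uses N−1 degrees of freedom (the FoXS convention). The reported
model is the smallest subset whose χ² is within 5% of the global best,
with a small absolute slack (1e-9) so that exact fits with χ² ≈ 0 resolve
to one state. Candidates may be supplied as curves or generated from
coordinates; no conformer sampling is performed.

## Cross-link quantitation and distance validation

A feature's fold change is mean(non-missing areas, condition B) over
mean(condition A); missing values are never imputed, and zero areas count
as missing. At threshold t (default 2): B-enriched when FC ≥ t, A-enriched
when FC ≤ 1/t, otherwise common. Features detected in only one condition
in ≥2 replicates are assigned to that condition's enriched class with an
infinite/zero FC and a presence/absence flag — these carry real
information (appearance or disappearance on RNA binding) and should not be
dropped. Everything else is unquantified. The rule is a pure fold-change
rule; no p-values are computed, matching how such data are typically
displayed.

Distance validation anchors each site at its Cα; EDC is a zero-length
chemistry, but the conventional Cα–Cα allowance of 24 Å is the default
contract (configurable). With symmetry enabled, site B is searched over
all crystallographic copies (space-group operators × lattice translations
in [−2, 2]³) having atoms within the identity-copy distance of site A —
any mate that improves on the identity distance necessarily lies inside
that radius, so the search is exact, and the tests verify it against
brute-force enumeration. Homodimeric ambiguity (one protein label mapping
to several chains) is resolved by minimizing over all chain assignments.
Assembly comparison ranks models by satisfied fraction, ties broken by the
mean distance of violated links.

## Variant depletion

V_d/V_p is the density of unique variants in a domain over the density
over the whole protein. The counting unit defaults to unique
(position, amino-acid change) pairs and can be switched to unique
positions; no allele-frequency weighting is applied. The whole protein as
its own domain gives exactly 1. Zero total variants is an explicit failure
status, not an exception or a NaN surprise.

One subtlety the synthetic generator exposes: planting a rate multiplier f
inside a domain does *not* plant V_d/V_p = f, because the domain
contributes to the whole-protein denominator — the expected ratio is
f·L/(f·L_d + (L − L_d)). The generator's truth record therefore carries
the analytically expected ratio, and `rate_factor_for_ratio` inverts the
relation so scenarios can plant a target ratio directly. Recovery tests
compare the simulation mean against this expected value within a 3-SE
confidence band plus a 1% allowance for the ratio-of-counts bias
(E[X/Y] ≠ E[X]/E[Y] at finite counts).

## Stoichiometry and footprint

Protein masses come from average-isotope sequence mass (free-chain
convention); dsRNA mass defaults to 2 × bp × 320.5 Da/nt with an optional
end correction, with the sequence-exact computation as the documented
alternative. Mass-photometry peaks are a Gaussian mixture (EM, BIC model
selection in auto mode, capped at 6 components). Composition assignment
enumerates all (n_protein ≤ max, n_RNA ≤ max) pairs; best is the minimal
|residual| within tolerance, ties broken by fewer total copies, then fewer
protein copies — and is verified against brute-force enumeration in the
tests.

The footprint model assumes complexes bind as sandwiching pairs across the
duplex (a helper converts complex counts to pairs by ceiling division).
Each maximal-occupancy observation (L bp, k pairs) brackets the per-pair
footprint into (L/(k+1), L/k]; observations intersect, and an empty
intersection is reported with per-observation diagnostics rather than
raised. Conversion between bp and Å uses the A-form helical rise of
2.81 Å/bp (configurable). Lateral oligomers are built by repeating a rigid
step (explicit rotation+translation, or a rise along an axis); the clash
report counts inter-copy heavy-atom pairs under 2.5 Å, and an identity
step is flagged as a failure.

## Synthetic data: what it does and does not show

One global seed fans out to named, independent child streams
(`SeedSequence(seed, spawn_key=(crc32(name),))`), so composed scenarios
are bit-reproducible and uncorrelated. Scattering noise is Gaussian with
σ(q) = max(rel·I, floor), default rel = 1%, mimicking the shape of
counting statistics without modeling a detector. Cross-link replicate
areas are log-normal around condition means (default CV 20%, 3
replicates); true links are sampled from Cα pairs within the cutoff on a
seeded compact random-walk fixture, decoys beyond it. Variant counts are
per-residue Poisson. Mass events are Gaussian around composition masses.
Bead strings are collinear with jittered spacing.

Passing these recovery tests shows the estimators are correct and
well-calibrated under their own noise models. It does not show robustness
to what real data add: inter-frame drift and capillary fouling in
SEC-SAXS, interparticle interference at high concentration, non-lognormal
MS1 interference and shared peptides in CLMS, ascertainment bias in
population variant catalogs, mass-photometry calibration drift, or picking
bias in negative-stain measurements. Structure-dependent stages use a
Cα-only fixture; all-atom effects (side-chain reach of cross-linked
residues, hydration-shell scattering) are outside the synthetic scope.

## Structure handling

PDB/mmCIF parsing, unit cells and space-group operators come from gemmi.
Author residue numbering is the only public addressing scheme. Altlocs
collapse to the highest-occupancy conformer (ties by altloc letter).
Hydrogens are excluded from distance work by default. The maximum pairwise
distance is exact: for large models the O(n²) scan runs on convex-hull
vertices, which preserves the maximum. Merged or user-edited models are
accepted as supplied; no refinement or assembly generation beyond symmetry
expansion is attempted.

## Problem sizes

Defaults used by the analysis drivers and the acceptance script: 120-point
q grids (0.005–0.3 Å⁻¹), 101-bin P(r) grids, 5 Å D_max scans, 60-residue
two-chain fixtures, 20-feature cross-link tables over 100 seeds for
sensitivity, 400-residue proteins with 500-seed depletion simulations,
4000 mass events, 50 five-bead strings. These sizes give stable statistics
while keeping a full run in seconds.
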