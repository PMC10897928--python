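# Methods

## Problem and approach

A small molecule with *n* unknown stereocenters has 2^(n−1) distinguishable
*relative* configurations (R\*/S\* patterns; a structure and its mirror image
give identical NMR observables, so enantiomeric pairs collapse). `stereonmr`
ranks those candidates against experimental NMR data and then resolves the
remaining mirror ambiguity with ECD. The package operates downstream of
quantum chemistry: conformer ensembles, computed shifts, shielding tensors
and rotatory strengths are inputs, never computed here.

## Anisotropic observables

**RDC model.** Every one-bond C–H residual dipolar coupling is linear in the
five free components of the Saupe order matrix **S** (symmetric, traceless):

    D = D_max(r) Σ_ab S_ab n_a n_b,   D_max(r) = −μ0 h γC γH / (16 π³ r³)

with **n** the C–H unit vector in the molecular frame and *r* taken from each
conformer's actual geometry (not a fixed 1.09 Å), keeping predictions
consistent with whatever optimized structures the user supplies. Methyl
couplings are reduced onto the C3 axis with the standard −1/3 projection for
fast internal rotation. Under the single-alignment-tensor approximation all
conformers of a candidate share one **S** and the observable is the
population-weighted average.

**Fitting.** For fixed populations the tensor is an exact linear
least-squares problem solved by SVD (`numpy.linalg.lstsq`); rank-deficient
direction sets yield the minimal-norm tensor and are flagged. Populations
are estimated by variable projection: the simplex is parameterized by a
softmax with the first logit pinned to zero, refined by Levenberg–Marquardt
(`scipy.optimize.least_squares`, method `lm`) from 8 multistarts drawn from
a fixed seed, with the tensor re-solved linearly inside every residual
evaluation. Logits are clipped at ±40 for numerical safety; results are
deterministic for a given seed.

**Model selection.** Conformer subsets are compared with the least-squares
AIC, `n ln(RSS/n) + 2k`, `k = 5 + (m_active − 1)`; subsets are enumerated
exhaustively up to 6 conformers and reduced by greedy backward elimination
above that, with ties broken toward fewer parameters, then lexicographic
subset order. RSS is floored at 1e−12 Hz² so exact fits stay finite. The
small-sample AICc is available as an option. The absolute AIC scale depends
on these conventions, so only rank order and AIC *differences* between
candidates are meaningful — a caveat shared with any closed-source
implementation of the same idea. Agreement is also reported as the Q factor,
`rms(D_calc − D_exp)/rms(D_exp)`, which is convention-free.

Error-weighted fitting (residuals divided by per-record errors) is
available behind `weighted=True`; the default is unweighted, which is what
the usual Q-factor reporting assumes. Records can be excluded via
include-flags, the conventional treatment of prochiral pairs that cannot be
assigned confidently.

**RCSA.** The alignment-induced shift of a carbon is
`−(2/3) Σ_ab S_ab σ'_ab` (σ′ the traceless shielding tensor in ppm; shift
and shielding have opposite sign; output in ppb). Double-referenced
ΔΔRCSA values (day-4 minus day-1 shift change, minus that of a
low-CSA reference carbon) remove common-mode isotropic drift; the same
subtraction is applied to the back-calculation. The tensor can be refit
from RCSA data alone (k = 5, ≥6 records) or carried over from the RDC fit
(k = 0). When shielding tensors exist for only one conformer they can be
rotated onto the others by heavy-atom Kabsch superposition — a documented
approximation that ignores geometry-dependence of the CSA itself.

## Isotropic cross-validation

**NOE.** Intensities convert to distances by ISPA, `r = r_ref (I_ref/I)^(1/6)`,
calibrated on a proton pair of fixed known separation, conventionally a
geminal methylene pair at 1.78 Å.
Model distances use `r_eff = (Σ w_k r_k⁻⁶)^(−1/6)` (slow internal motion;
an r⁻³ option exists for flexible pairs). Only NOEs between protons more
than five bonds apart (bond graph from SDF connectivity, else a covalent
radii × 1.3 distance heuristic) with model distance < 5 Å are scored —
shorter-range contacts carry constitution, not configuration, and longer
distances leave the reliable ISPA regime. The score is the distance-residual
AIC with k = m_active − 1.

**³J couplings.** Back-calculated with a Karplus curve, default classic
H–C–C–H parameters A = 9.5, B = −1.6, C = 1.8 Hz, ensemble-averaged over
weighted conformer dihedrals. Parameters are explicit in `PipelineConfig`
because no single parameterization suits all fragments; couplings to methyl
or aromatic protons should be excluded by the caller (they carry little
stereochemical information).

**¹³C shifts.** Ensemble-averaged computed shifts are linearly regressed
onto experiment per configuration (the DP4-style slope/intercept correction,
which makes the score invariant to any affine error of the shift protocol),
and scored by corrected MAE plus an AIC over residuals with k = 2. ¹H
shifts are excluded by default — their computed–experimental correlation is
typically much weaker — but the scorer accepts any nucleus.

## Ranking

Observables are scored separately per candidate; the default ranking key is
the RDC AIC, RDCs being the most discriminating observable whenever good
alignment data exist. An opt-in "combined" key sums per-observable AIC
offsets (each observable's minimum across candidates subtracted to prevent
scale dominance); this combination is a convenience of this package, not a
field standard, and is labelled as such in output. Ranking is deterministic:
ties break on configuration name, and all optimizer randomness flows from
one run-level seed.

## ECD

Rotatory strengths (10⁻⁴⁰ cgs) are broadened into Δε spectra by Gaussians
in the energy domain, `Δε(E) = Σ_j E_j R_j exp(−((E−E_j)/σ)²) / (2.296e−39 σ √π)`,
default σ = 0.3 eV, optional uniform UV shift in nm (default 0, recorded in
the manifest), on a 180–400 nm grid at 0.1 nm. Conformer spectra combine
with Boltzmann weights. Cotton effects are signed local extrema above an
amplitude threshold; the enantiomer call requires every compared band sign
to invert, with Pearson correlation on the grid overlap reported alongside.
Quantitative overlay of computed and measured intensities is *not* claimed —
band positions, amplitude ratios and especially signs are the reliable
content of such comparisons.

## Synthetic studies

The generator builds a saturated chain from idealized internal coordinates
(C–C 1.54 Å, C–H 1.09 Å, tetrahedral angles): terminal methyls, *n*
stereocenters each bearing one H and one methyl substituent on opposite
faces, methylene bridges between centers. Inverting a parity swaps the two
faces — precisely how diastereomers differ — so all 2^(n−1) candidates share
one atom numbering. Conformers are bounded torsional perturbations (methyl
spins, substituent swings, backbone torsions) whose rotation angles are
scaled by the group's lever arm so no single rotation displaces an atom by
more than the `flexibility` parameter (default 0.3 Å); `flexibility=0`
collapses the ensemble to identical copies.

Default study conditions: 5 centers (16 candidates), 2 conformers with true
populations (0.7, 0.3), 15 included RDCs (5 stereocenter C–H, 8 bridge
methylene C–H, 2 terminal methyls; the 5 substituent methyls are generated
but excluded, mimicking the exclusion of flexible side-chain couplings).
The random alignment tensor's largest |eigenvalue| defaults to 3.5e−3,
which keeps every simulated RDC inside ±100 Hz across seeds while reaching
roughly ±80 Hz in favourable orientations — the regime of a strongly
aligned small molecule. RDC noise is Gaussian with s.d. expressed as a
fraction of the noise-free RDC range (default 5%); NOE noise is
multiplicative lognormal; shift noise is additive Gaussian on the
"experimental" values, on top of configuration-dependent perturbations
(s.d. 1.5 ppm on stereocenter-adjacent carbons) drawn once per
(configuration, seed) so that shift scoring discriminates, but less sharply
than RDCs. Each observable draws from its own RNG stream derived from the
master seed, so toggling one observable never perturbs another's data, and
whole studies regenerate bit-identically.

What the generator does *not* emulate: real torsional energy surfaces,
anisotropic-medium physics (alignment is a free tensor, not predicted from
shape), spectral overlap/second-order artifacts, and any resemblance to a
specific natural product's geometry or shift values. Passing tests therefore
demonstrate correctness of the inference machinery under the stated noise
model — not that any particular real molecule would be assignable.

## Problem sizes and numerical choices

The test suite and the acceptance script use 5-center studies with 2
conformers, 15 RDCs and 100 replicates for the noise-recovery experiment,
and 200 randomized cases for the SVD exactness checks — sizes at which every
property being asserted is already fully expressed and a complete run takes
about a minute on one core. Degenerate inputs are errors, not warnings:
empty ensembles, all-zero experimental RDC vectors, sub-minimal record
counts (5 for an RDC tensor, 6 for an RCSA-only tensor, 3 for shift
regression) and degenerate shift regressions all raise `ValueError`.

## Known limitations

- One alignment tensor per candidate: strongly flexible molecules whose
  conformers align differently violate the model's central approximation.
- The AIC constant-offset convention makes absolute AIC values
  implementation-specific; compare differences only.
- ISPA ignores spin diffusion; distances from long mixing times will be
  systematically short.
- The shielding-tensor transfer between conformers assumes rigid CSA
  frames.
- CIP parities are bookkeeping labels attached by the user or generator;
  the package does not perceive R/S from 3D coordinates.
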