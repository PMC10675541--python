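# Methods

This note documents the models, numerical choices and limitations behind
`espqsar`. Units throughout: length in Å, charge in elementary charges e,
potential in e/Å with Coulomb constant 1 (only relative ESP patterns
matter downstream, so no SI prefactor is carried), activity as pIC50.

## Molecules and molecular-weight bands

A molecule is an ordered list of atoms (element, Cartesian position,
partial charge) with an id and an optional pIC50. Coordinates are taken
as given: the package performs no conformer generation, protonation
modeling or charge assignment. Molecular weights are sums of standard
atomic weights (RDKit's periodic table); van der Waals radii are Bondi
values from a bundled table.

Datasets are partitioned into seven contiguous 50-amu bands covering
250–600 amu. The bands are half-open, (250+50(k−1), 250+50k], with
250 amu itself assigned to band 1, so every real-valued weight in range
lands in exactly one band; weights outside [250, 600] are excluded with
a warning (optionally a hard error). Band boundaries are sometimes
quoted as integer ranges like 251–300; the half-open convention is the
only gap-free reading for non-integer weights. Each band is split
train:test at 4:1 (ceil for the training side: 70 → 56 + 14) by a seeded
permutation, stratified only by band. The band's template is its
heaviest member, ties broken by lexicographically smaller id.

## Charge density: the promolecule backend

The reference protocol derives ρ from ab initio RHF/6-31G**
wavefunctions. That step is deliberately out of scope; the package
instead defines a density-backend contract with two implementations:

* **promolecule** (default): ρ(x) = Σ_a q_a (2πσ_a²)^{−3/2}
  exp(−|x−R_a|²/2σ_a²) with σ_a = width_scale · r_vdw(element), default
  width_scale 0.5. Each atomic Gaussian integrates exactly to the atom's
  partial charge, the field is analytic, cheap, and exercises every
  downstream stage with realistic spatial structure. It is a signed
  *charge* density (nuclei + electrons combined), not an electron
  density.
* **cube**: densities imported from Gaussian cube files (any external QM
  code), resampled onto the requested grid by trilinear interpolation.

Gaussians are evaluated on a 6σ-cutoff sub-block per atom; beyond that
the contribution is below double-precision resolution relative to the
peak. Atoms within 2σ of a box face trigger a truncation warning.

## Grids and the Poisson solver

Grids are uniform and isotropic; a band's common box takes, per axis,
the largest van der Waals extent of any member plus a margin (default
2.7 Å, appended once per axis), node count floor(edge/spacing)+1, box
centred on the coordinate origin. The descriptor grid is the alignment
grid subsampled by stride 2 (0.106 → 0.212 Å at full resolution), so
descriptor nodes are a subset of alignment nodes.

The ESP is the free-space solution of Poisson's equation, computed as
the discrete convolution φ = ρ dV ∗ 1/r evaluated by FFT with zero
padding (factor 2 per axis, rounded up to FFT-friendly sizes), which
makes the convolution linear rather than circular — no periodic image
charges. The kernel's singular cell uses the cell-averaged value
⟨1/r⟩ = 2.3800774/h for a cube of side h. Against the analytic potential
of a Gaussian charge (q·erf(r/σ√2)/r) the solver is accurate to about
10⁻⁴ relative at r ≥ 3σ on a 64³ grid — two orders tighter than the 1%
the pipeline needs. The sign/constant convention (positive charge →
positive potential, Coulomb constant 1) is a documented choice: the
statistic fed to the QSAR stage is invariant to any fixed positive
rescaling of φ.

## Rigid field alignment

For a band with template *i* and target *j*, the score of a pose is
E = Σ_x φ_i(x) ρ_j(x+t) dV. The template, pinned with its vdW
bounding-box centre at the grid centre, has φ computed once. The target
density is evaluated once in its starting pose; each sampled rotation
("rotamer") is applied by pulling grid nodes back through the inverse
rotation about the grid centre and trilinearly interpolating the stored
density (values outside the support are zero) — so the expensive density
evaluation happens once per molecule, not once per rotamer. For each
rotamer the full translation map E(t) over all integer-cell shifts is
computed by one zero-padded FFT cross-correlation (linear, no
wraparound), and the global maximum over rotamers × shifts wins. Ties
are broken by lower rotamer index, then lexicographically smaller
translation. Translations are restricted to integer grid cells — the
natural resolution of the FFT formulation; there is no sub-cell pose
refinement, which bounds the aligned-pose accuracy by half a cell per
axis.

E is maximized as a signed overlap (same-sign regions of template
potential and target density score positively). A normalized-score
variant is deliberately not the default; the plain functional is the
field-standard choice for this protocol.

Rotations come from a deterministic Hopf-coordinate construction: a
Fibonacci lattice on the base 2-sphere crossed with an evenly spaced
circle fiber, lifted to unit quaternions
q = (cosθ/2 cosψ/2, cosθ/2 sinψ/2, sinθ/2 cos(φ+ψ/2), sinθ/2 sin(φ+ψ/2)),
with the fiber count m₁ ≈ (πn)^{1/3} balancing fiber and base spacing.
The identity rotation is always element 0, and the set needs no random
seed. Measured nearest-neighbour geodesic gaps stay within ~0.85× the
ideal uniform gap 2(3π/4n)^{1/3} for n from 24 to 2000 (the quaternion
metric arccos|q₁·q₂| is used throughout). With the default 2000 rotamers
the rotational resolution is ~12°; the desk profile's 128 rotamers give
~30°.

## Descriptors and PCA

The descriptor of an aligned molecule is its ESP on the descriptor grid,
flattened x-fastest (Fortran order) — K = 1,191,016 for the 106³ box the
full protocol uses. φ (not ρ) is the descriptor; it is solved on the
descriptor grid from the density evaluated there.

PCA is fitted on the training rows only, mean-centred, via SVD. The
default width equals the training-set size (56), matching the network's
input layer; since centred rank is at most n−1, the last component is a
zero vector and its score a zero feature, kept to preserve the fixed
input width. Components beyond the numerical rank are zero-padded the
same way. Component signs are fixed by making each component's
largest-magnitude loading positive, so serialized models are
reproducible. Test molecules are projected with the fitted model, never
refitted. Mean-centring before PCA is assumed (the convention of every
standard implementation) and verified by the zero-mean-scores property
test.

## The network

Architecture N × M × 1 (defaults 56 × 35 × 1), logistic activations,
**no bias terms** — faithful to the protocol's equations; a config flag
can enable biases for comparison but is off everywhere in this package.
Activities are min-max normalized to [0, 1] with training-set bounds;
test activities may fall outside [0, 1] and are not clipped. The loss is
the plain sum of squared errors F over training molecules; training is
full-batch gradient descent with analytic backpropagation gradients
(verified against central finite differences to 10⁻⁶), stopping at
F ≤ 10⁻⁴ or an iteration cap (default 200,000 for the bare trainer,
50,000 in the pipeline). Weights initialize uniformly in [−0.5, 0.5]
from a seed; training is bitwise deterministic.

Two step-size modes exist: fixed learning rate (default 0.1) with
optional momentum, and an accept/reject adaptive schedule (grow the rate
by 1.1× on improvement, halve and revert on worsening) that keeps F
non-increasing over accepted steps. The pipeline uses the adaptive mode:
a single fixed rate is not robust across bands whose score magnitudes
differ by orders of magnitude.

Because the output unit is a sigmoid rescaled by the training bounds,
predictions always lie strictly inside (act_min, act_max): the model
cannot extrapolate beyond the training activity range. This is an
explicit, documented limitation.

**Input scaling.** The raw PCA scores of ESP descriptors can be large
(they grow with √K), which saturates the sigmoids at initialization. The
pipeline therefore divides all scores by a single global constant chosen
so the largest component has RMS 0.25 (config `score_rms`). One global
scale — never per-component whitening — preserves the variance ordering
of the components; per-component normalization was observed to destroy
generalization by amplifying low-variance noise directions to the same
magnitude as the informative leading components. The small magnitude
starts the sigmoids in their linear range, so gradient descent builds
the fit from high-variance components before it can chase low-variance
directions; together with the iteration cap this acts as the implicit
regularizer that a 56-sample/56-feature interpolating network needs. The
scale is folded back into the input weights after training, so the
serialized model consumes raw PCA scores.

## Validation statistics

R² = 1 − SSE/SST with the evaluated set's own mean in SST, computed
separately for training and test sets on the denormalized pIC50 scale.
This quantity is often loosely called a squared Pearson correlation; the
two differ for biased predictions, and the 1 − SSE/SST form is what is
implemented. r²_pred replaces the SST mean with the *training*-set mean,
so the training set's location enters the external assessment; when the
training mean happens to equal the test mean the two statistics
coincide. Models are flagged qualified at r²_pred ≥ 0.6 (the
conventional threshold); the flag never aborts a run. Reports carry
every residual and surface the two largest with molecule ids.

## Synthetic benchmark

The generator emulates the *shape* of a hERG QSAR study — seven bands of
70 molecules (490 total), MW spanning 250–600 amu, activities in
3.5–9.0 pIC50 (inside the span typical of hERG datasets) — with abstract
rigid point-charge clusters, not chemistry. Each band is a congeneric
series: one random scaffold (atom count scaled to the band's mass,
positions in a compact ball with a 1.2 Å minimum-separation rule,
zero-sum charges in ±0.5 e), whose members differ by greedy element
substitutions from {C, N, O, S, Cl} that spread the mass across the band
within ±5 amu of target, by zero-sum charge perturbations (±0.15 e), and
by 0.03 Å coordinate jitter. Congeneric bands are what makes pairwise
field alignment well-posed, exactly as MW-banding does for real
datasets.

Activities come from a stored teacher: a linear function of the leading
five PCA scores of the members' canonical-pose ESP descriptors, mapped
affinely onto the activity range, plus optional Gaussian noise (a
separate noise seed can vary the draws while keeping the molecules
fixed). Applying the teacher to canonical-pose descriptors isolates the
descriptor/PCA/network stages from alignment error in the default mode;
a hard mode re-poses members by random rigid moves so alignment quality
is exercised too. Generation is a pure function of the spec — identical
specs yield byte-identical files.

What passing the synthetic study does *not* show: the promolecule
density is not a QM density; toy clusters have no bonds, conformers,
protonation states or hydrophobicity; and the planted
structure–activity map is low-dimensional and nearly linear. The
benchmark validates the machinery end to end, not chemical accuracy on
real hERG data.

## Problem sizes and profiles

The `full` profile (0.106 Å alignment grid, 0.212 Å descriptors, 2000
rotamers) reproduces the production protocol's settings and is intended
for real datasets on serious hardware. The package's own studies run the
`desk` profile — 0.4 Å alignment grid (descriptors at 0.8 Å), 128
rotamers — chosen so a full seven-band, 490-molecule study completes in
minutes on one CPU while leaving every algorithmic path identical. At
desk resolution the half-cell pose quantization (±0.2 Å) is the dominant
descriptor noise source; the noiseless synthetic study plateaus around
R²_test ≈ 0.9–0.97 per band for exactly that reason, and finer grids
tighten it.

## Known limitations

* Single-conformer, rigid-body treatment; no torsional flexibility in
  alignment or descriptors.
* In-vacuo fields: no dielectric screening or solvent model in the
  Poisson step.
* Predictions are confined to the training activity range by
  construction.
* Template choice (heaviest member) is a heuristic; a poor template
  degrades a whole band.
* The promolecule density ignores charge anisotropy (lone pairs, π
  systems) that a QM density would carry; the cube backend restores
  fidelity when external densities exist.
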