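# Methods

## The model

`stabscan` predicts the change in folding free energy upon single
amino-acid substitution (ΔΔG, kcal/mol; positive = destabilizing) from a
cleaned single-chain structure. It assumes the input has been protonated
and repaired externally (the parser warns when fewer than 5% of atoms are
hydrogens), that author residue numbering is authoritative (it is never
re-indexed, so predictions join against reference-numbered variant
tables), and that the wild-type structure is a sufficient description of
the site — there is no per-variant repacking or relaxation.

### Featurization

For each residue with a complete N/Cα/C backbone, the atoms within 9 Å of
the Cα — excluding every atom of the residue itself — are expressed in a
local right-handed frame built from the backbone by Gram–Schmidt (axis 1
along N−Cα, axis 2 the orthogonal component of C−Cα). Because the frame
co-moves with the protein, the features are exactly invariant under rigid
motions of the whole structure. Atoms are typed into six element channels
(C, N, O, H, S, P, in that fixed order); other elements (metals,
selenium) are dropped with a warning — how such atoms should contribute
is genuinely ambiguous, and dropping is the explicit, logged choice here.
Each atom increments the nearest-center voxel of an 18³ cube of 1 Å³
voxels circumscribing the sphere (centers at half-integer coordinates;
binning is nearest-center rather than trilinear because it makes the
brute-force oracle unambiguous). The occupancy grid is then smoothed
per-channel with an isotropic Gaussian, σ = 1.0 Å (one voxel edge) by
default, kernel truncated at 2σ and normalized to unit sum; mass falling
outside the cube at its faces is lost, which we accept and do not
renormalize. Blurring is applied as fixed preprocessing inside the
model's forward pass, and the grid geometry travels with every checkpoint
so inference can never silently mismatch featurization.

### Representation model

A 3D CNN classifies the masked wild-type residue from its environment:
three blocks of conv(3³, same padding) → batch-norm → leaky ReLU (slope
0.01) → max-pool(2³, stride 2) with 16/32/64 filters (18³ → 9³ → 4³ → 2³,
flatten 512), then fully connected layers of 100 and 20 nodes. The layer
ordering, padding, pool size and slope are our choices where convention
offers several options; the filter counts, layer sizes, optimizer
(Adam, lr 3·10⁻⁴, batches of 100 residues) and cross-entropy objective
are fixed. Labels use the alphabetical one-letter amino-acid order, the
same ordering as every one-hot block in the package. Training splits
strictly by protein — shared proteins between partitions are a hard
error — with early stopping on validation accuracy (patience 10, max 100
epochs by default) and restoration of the best-validation checkpoint. No
class re-balancing is applied: the downstream model consumes the same
natural frequencies as features. The post-activation output of the
100-node layer is the residue representation used downstream.

A `reduced_config()` variant (filters 4/8/16, lr 10⁻³) exists for
CPU-scale experiments; the larger step size suits its ~16× smaller
convolutional parameter count. All desk-scale learnability results in the
tests use it.

### Downstream regressor

Features per variant (length 142): representation (100) ⊕ one-hot wild
type (20) ⊕ one-hot mutant (20) ⊕ background frequencies of the wild-type
and mutant amino acids (2), the frequencies being empirical over the
training structure set and persisted with the model. The network is
FC 128 → BN → leaky ReLU → FC 64 → BN → leaky ReLU → FC 16 → BN → leaky
ReLU → scalar → sigmoid. Targets in kcal/mol are compressed by the Fermi
switching function F(ΔΔG) = 1/(1 + e^{−β(ΔΔG−α)}), β = 0.4, α = 3.0,
and the loss is the mean absolute error in this space (MAE_F), which
concentrates the learning signal in the −1…7 kcal/mol window where
training energies are most trustworthy; kcal/mol MAE is reported as a
secondary metric after inversion. Optimization is Adam, lr 5·10⁻⁴,
batches of 40 variants, early stopping per replica on validation MAE_F
(a `restore_best=False` escape hatch keeps final-epoch weights for
memorization experiments). Targets outside [−20, 30] kcal/mol are
rejected as probable unit errors; raw Rosetta-scale energies must first
be divided by 2.9.

Prediction is the median over an ensemble of independently seeded
replicas (10 by default, seeds 0–9). The median is taken in Fermi space
and then inverted; since the inverse is strictly monotone, taking it in
kcal/mol space would give identical results for odd ensembles and differs
only microscopically through the even-count average. Inversion clamps
scores to [10⁻⁴, 1−10⁻⁴] (the transform is not invertible at 0/1),
saturating predictions at roughly −20/+26 kcal/mol; clamping events are
logged.

Cystine handling: cysteines whose SG atoms lie within 2.5 Å of another
cysteine's SG are annotated as disulfide-bonded; training variants at
those positions are removed (the training energies are unreliable there),
while at prediction time wild-type cysteines are only flagged
(`wt_is_cysteine`) — such predictions tend to underestimate the true
destabilization and should not be taken as accurate. The 2.5 Å criterion
is our geometric operationalization (S–S bonds are ~2.05 Å).

### Scanning and burial

A saturation scan emits all 20 substitutions per resolvable site, ordered
by residue then mutant alphabet; the wild-type "self" row is kept for
table completeness with ΔΔG = 0.0 exactly and a flag. Relative SASA is
Shrake–Rupley (probe 1.4 Å, heavy atoms, the scanned chain only) divided
by the Sander–Rost per-residue maximum; terminal residues may exceed 1
and are not clipped. Exposed means relative SASA ≥ 0.2 — the boundary
value itself classifies as exposed, a choice the ≥ convention makes
explicit.

### Variant statistics

Variant tables join onto scans by (protein, residue, mutant); rows whose
stated wild type contradicts the structure are rejected and counted, and
variants at positions without scan coverage are dropped. Allele-frequency
bins are common (AF > 10⁻²), intermediate (10⁻⁴ < AF ≤ 10⁻²) and rare
(AF ≤ 10⁻⁴); a value exactly at a threshold goes to the lower bin. Group
summaries report the median and the 2.5–97.5 percentile range (linear
interpolation). Class comparisons use a bootstrap of the difference in
medians: each group is resampled with replacement at its own size 10⁴
times and the 95% CI is the percentile interval of the resampled
differences.

## The synthetic fixtures

The generators stand in for curated structure sets and physics-derived
training energies, and are designed so every pipeline property is
testable on one CPU in minutes.

* **Structures** are built from ideal backbone internal coordinates
  (helix φ=−57°, ψ=−47°; extended φ=ψ=180°; standard bond lengths and
  angles), with carbonyl O, amide H, and a single pseudo side-chain atom
  at the ideal Cβ position whose element encodes the residue class
  (S: Cys/Met; O: Ser/Thr/Asp/Glu/Asn/Gln/Tyr; N: Lys/Arg/His/Trp;
  C: the rest). `compact_bundle` packs seven axis-aligned helices (one
  core, six on a 6.3 Å ring, alternating direction) tightly enough that
  core sites fall below the 0.2 burial cutoff. The packing is much denser
  than real protein cores need to be, compensating for the toy residues'
  six atoms.
* **Sequences** ("random") come from a first-order Markov chain with
  self-transition 0.75 over natural amino-acid frequencies. This is what
  makes masked-environment classification learnable at toy scale: the
  target's own atoms are masked, so its identity must be read from its
  neighbours' side chains, and the Markov correlation puts that signal
  there — a stand-in for the regularities real structural neighbourhoods
  carry. The achievable accuracy is bounded (~0.25) by the four-way
  element coding; the desk-scale learnability check (>0.15, i.e. 3×
  chance) sits inside that bound. For memorization tests, iid-uniform sequences make
  every environment distinguishable instead.
* **ΔΔG landscape**: ΔΔG(wt→mut) = s(wt)·d(wt, mut)·(1 + 0.6·buried) +
  N(0, σ), with s a fixed per-residue scale in [0.6, 1.4], d(wt, mut) =
  1.2 + 2.6·q(mut) − 1.4·q(wt) over a rescaled Kyte–Doolittle propensity
  q ∈ [0, 1], and σ = 0.2 kcal/mol by default. Constants were calibrated
  once so ≥90% of values land in −1…7 kcal/mol (measured: ≈99%);
  self-substitutions are 0 exactly. The rule is deliberately recoverable
  from the features: q-terms from the one-hot blocks, burial from the
  environment representation.
* **Variant tables** sample variants with pathogenic probability
  logistic in the true ΔΔG (midpoint 1.5 kcal/mol), log-uniform allele
  frequencies in [10⁻⁶, 10⁻¹], and a configurable rate of planted
  wild-type-mismatch decoys to exercise join rejection.

What passing these tests does **not** show: the fixtures have no rotamer
diversity, no loops, no long-range packing statistics, and an energy rule
far simpler than real thermodynamics, so desk-scale accuracy numbers say
nothing about accuracy on real proteins — they verify the machinery
(featurization, masking, invariances, optimization, calibration of the
statistical procedures), not the biology. Published-scale accuracy
requires training on thousands of real structures and physics-derived
energies for dozens of proteins.

## Numerical choices

The networks are implemented in numpy with manual backpropagation (exact
gradients; the suite verifies them against central differences at 10⁻⁸)
and Adam (β₁ 0.9, β₂ 0.999, ε 10⁻⁸). Computation is float32; parameter
initialization is He-scaled and fully determined by the construction
seed, so equal seeds give bitwise-equal models, histories and scans.
Max-pool gradient ties share gradient equally; batch-norm uses ε 10⁻⁵
and momentum 0.1 with running statistics for inference. Degenerate
inputs: collinear backbones are an error naming the residue; empty
environments are legal (all-zero grid); an empty structure scans to an
error, an empty variant join is legal.

## Problem sizes in the shipped experiments

Representation learnability uses 26 helical proteins of 40 residues
(1,040 environments, 21/5 protein split) and the reduced configuration
for 25 epochs; landscape recovery uses 12 seven-helix bundles of 84
residues (~19,000 variants, 8/2/2 split) with a 3-replica ensemble, 40
epochs, patience 8; the bootstrap calibration uses 50 repetitions of a
1.0 kcal/mol known shift at n=500 with 10⁴ resamples. These sizes were
chosen as the smallest at which the properties are stable.

## Known limitations

* Predictions are not anti-symmetric: the model is trained on forward
  (wild-type-structure) variants only, and reverse variants computed from
  the mutant structure will not generally negate the forward value.
* Stability changes at disulfide-bonded cystines and, more mildly, at
  free cysteines are systematically underestimated; they are flagged, not
  fixed.
* Single chains only: interface effects, nucleic-acid contacts and
  multi-chain context are out of scope, as are protonation and structure
  repair (external tools) and per-variant relaxation (the slow physics
  this model is a shortcut around).
* The burial annotation uses the wild-type structure alone and makes no
  attempt to exclude chain termini from the exposed/buried statistics.
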