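# Methods

## Base reference frames and steps

Each base is assigned an orthonormal frame by rigid-body least-squares
(Kabsch/SVD) superposition of a standard planar base onto the observed ring
atoms — six atoms for pyrimidines (N1,C2,N3,C4,C5,C6), the nine-atom fused-ring
perimeter for purines. The templates follow the community standard reference
frame for nucleic-acid bases (planar, origin near the centre of an ideal
Watson–Crick pair, x into the major groove), under which the two bases of an
ideal pair share an origin and are related by a 180° rotation about x. The fit
is well-posed for planar point sets (the SVD determinant correction resolves
the out-of-plane axis); collinear inputs are rejected. `fit_rmsd` reports the
residual; for per-axis noise σ on n ring atoms it behaves as
σ·√((3n−6)/n), which the tests verify empirically.

Pairs are detected geometrically: C1′–C1′ distance within 8–12 Å, frame
origins within 2.5 Å after flipping the candidate partner's frame about its
x-axis, z-axes antiparallel (dot < −0.6), greedy one-to-one assignment by
origin distance. The thresholds are config values; no published pairing
criteria exist for this analysis, so the defaults were chosen to accept ideal
and mildly perturbed B-DNA and reject register-shifted neighbours (which sit
≥ 3.4 Å away in origin distance). The pair frame is the orthonormalized
(SVD-projected) mean of the Watson frame and the flipped Crick frame; the step
mid-frame is the analogous mean of the two pair frames.

**Helix axis.** S_OA needs "the plane perpendicular to the helix axis". We use
the *local* mid-step frame z-axis per step, matching the per-step character of
the statistic and remaining well-defined for bent duplexes; a config switch
(`global_helix_axis`) substitutes the best-fit line through all pair origins
for sensitivity checks. For the ideal straight fiber the two coincide.

## Stacking-overlap area S_OA

For each step, the four ring outlines are orthogonally projected onto the
plane through the mid-frame origin with normal along the step's helix axis
(a fixed deterministic in-plane basis; areas are origin-independent).
Exocyclic atoms — amino and keto groups, the thymine methyl, and the 5-methyl
of mC — are excluded, and van der Waals radii are not considered: the overlap
is between bare ring polygons. S_OA is the sum of the four cross-step
intersections (two intra-strand, two inter-strand); bases within one pair are
never intersected. Within-pair rings are essentially disjoint in projection,
so the sum and the union-vs-union intersection (available via
`union_overlap`) differ negligibly; the additive form is exact to test.
Clipping is delegated to a robust polygon library with an 1e-9 epsilon for
degenerate input; an independent Monte-Carlo oracle (uniform sampling over
bounding-box intersections with an even-odd membership test implemented from
scratch) validates every step in the test suite at the 1 % level, with a
0.01 Å² absolute floor where the overlap itself is near zero and a relative
tolerance is ill-defined.

Step classification: a dinucleotide step and its reverse complement belong to
one class (16 → 10 classes for unmethylated DNA). The canonical reading is the
one whose plain dinucleotide is lexicographically smaller; methylation marks
ride along — `mC` prefixes a methylated base on the read strand and a prime
(e.g. `AG'`) marks a base whose complement carries the methyl — so `AmC` and
`AC` are distinct classes while `AC` and `GT` are identical. The mark stays
attached to the cytosine-bearing strand throughout.

## Contacts and superposition

All criteria are heavy-atom only (crystal inputs lack hydrogens): a hydrogen
bond is a donor/acceptor N-or-O pair within 3.5 Å (no angle term), typed by a
residue/atom table covering nucleotides, the relevant protein side chains,
backbone and water, with unknown N/O defaulting to donor-and-acceptor. A water
bridge is a water oxygen within the cutoff of polar atoms on both selections.
For histidine-to-phosphate measurements both side-chain nitrogens are
measured and the minimum is the headline value, since the deposited
structures do not disambiguate the tautomer. Duplex-vs-duplex RMSD pairs all
DNA heavy atoms by residue position and atom name ("over all atoms" of the
duplex), dropping the 5-methyl carbon absent from the unmethylated partner;
superposition is on the DNA atoms themselves (whole-complex superposition is
possible by supplying a different atom map). Our Kabsch implementation is
cross-checked in the tests against an independent library rotation fit.

## Kinetics

Residence times follow a single-exponential decay; observations reaching the
recording window are right-censored. The default estimator is the censored
MLE k̂ = n_events/(Σt + n_censored·window) with SE k̂/√n_events from the
observed Fisher information; with no censoring it reduces to n/Σt exactly.
The MLE was preferred over histogram least squares because it is the
efficient realization of "fitting to a single-exponential decay"; a
least-squares fit of the empirical survival curve is provided for
comparison, and the R² of the straight-line fit to the log empirical
survival (counting censored observations in the at-risk set) flags
non-exponential data. When no window is supplied, the maximum observed time
is used with a logged warning. Error propagation for k_on = k_off/K_D and
for fold changes is first-order (delta method). Wald 95 % intervals achieve
93–97 % coverage at n = 200 (verified over 500 seeded simulations).

## Synthetic data — what it emulates and what it does not

The duplex builder places the standard base templates on frames generated by
fiber-like step parameters (defaults: twist 36°, rise 3.4 Å, all others 0 —
canonical straight B-form), derives the complementary strand by the pairing
flip, and attaches a schematic sugar–phosphate backbone (plausible bond
lengths, no energy minimisation; the 5′-terminal phosphate is omitted). The
step transform is a simplified local convention — origin advances by
(shift, slide, rise) in the current frame, orientation by
Rx(tilt)·Ry(roll)·Rz(twist) — exact for the default straight fiber.
5-methylcytosines (residue name 5CM, synonyms configurable) carry an
in-plane C5 methyl at 1.50 Å along the external bisector.

Per-step parameter overrides implement the *methylation-coupled slide*: an
extra −0.5 Å slide at every A-mC step (either strand), emulating the
observation that methylation changes DNA conformation most in the 5′-AC-3′
context; the sign is chosen so the affected step's S_OA increases, the
direction observed in the methylated complexes. This is a documented
stand-in for a conformational effect the ideal builder cannot produce from
chemistry — passing the ranking check shows the pipeline *recovers* an
AC-class signal when present, not that methylation physically causes it.
Two idealizations to keep in mind: the middle-methylated GRE has its single
mCH in a T-mC context, so this rule leaves it unchanged (the real complex
shows a smaller, propagated change), and the ideal zero-slide fiber gives
pyrimidine–purine steps (CA/TG, CG, TA) near-zero ring overlap, compressing
their class distributions toward zero. Coordinate ensembles are i.i.d.
isotropic Gaussian perturbations — a stand-in for thermal fluctuation with
no correlated backbone motion — so ensemble tests demonstrate statistical
plumbing, not conformational realism.

Kinetics study conditions: k_off = 0.30/0.10/0.20 s⁻¹ and K_D = 30/10/20 nM
for the unmethylated, side- and middle-methylated GRE, i.e. ~3-fold and
~1.5-fold stabilisation at constant k_on = 10⁷ M⁻¹s⁻¹ — rate magnitudes
typical of DNA-binding-domain/element interactions and embodying the
qualitative pattern that methylation slows dissociation without changing
association. Default sample sizes: 5,000 dwell times per construct with a
60 s window (≈ e⁻¹⁸ censoring at the slowest rate, effectively none);
recovery and coverage checks use n = 10,000 (window 6 s, ~5 % censored) and
500 replicates of n = 200.

## Numerical choices

Quartiles use linear interpolation (type-7), stated in output metadata;
whiskers follow the 1.5×IQR Tukey rule. Alternate locations keep the
highest-occupancy conformer (ties: first label alphabetically). Author
residue numbering is preserved verbatim. Polygon areas use exact clipping
plus shoelace; the clipping epsilon is 1e-9 Å. All simulations take explicit
seeds; problem sizes in the shipped drivers (8–20 duplexes of 10–12 bp,
10-model ensembles, 10⁶-point oracles) were chosen to characterise each
estimator's error well below the tolerances asserted on it.

## Known limitations

No energetics anywhere: S_OA is a geometric proxy for stacking, not a π–π
energy. Pair detection has no non-Watson–Crick taxonomy. Hydrogen bonds lack
angle criteria by design. The builder's backbone is schematic, so
backbone-dependent observables (e.g. phosphate distances) should only be
read off deposited or simulated coordinates, not built ones. The crystal
comparisons (duplex RMSD, His472 distances) require the deposited PDB
entries, which must be supplied locally.
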