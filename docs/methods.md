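# Methods

`writhenet` learns knot topology from geometry alone: it converts a 3D
polymer conformation into local-writhe representations and trains small
neural networks to classify the knot type or localise the knotted arc,
never computing an algebraic invariant at inference time.  Algebraic
invariants appear only inside the internal topology oracle that labels
and audits the training data.  This note records the models, the
numerical choices, and what the desk-scale experiments do and do not
show.

## Local writhe representations

For a closed discretized curve with bead positions r(x) and unit
segment tangents t(x), the segment-to-segment (StS) writhe is the Gauss
linking density of the curve with itself, resolved per segment pair:

    w_StS(x, y) = [solid angle of the skew quadrilateral spanned by
                   segments x and y] / (2 pi), signed by chirality.

Each entry is evaluated with the exact polygonal (Klenin–Langowski)
solid-angle formula; right-handed crossings are positive.  The
normalization is fixed so that the full pair sum equals twice the
global writhe, i.e. Wr = (1/2) Σ_x Σ_y w_StS(x, y).  Consecutive
polygonal segments are coplanar and contribute exactly zero, so the
exclusion band (self and nearest neighbour, two indices each side)
removes only numerically ill-defined algebra, not writhe; the identity
above is exact (tested to 1e-9), and the map agrees with a dense
quadrature of the Gauss double integral on smooth parametric curves to
better than 1e-2.

The segment-to-all (StA) profile is the contour sum over y of
w_StS(x, y), then smoothed with a centred moving average of window
l_w = 10 sigma (an odd 11-bead box for unit spacing, periodic on
rings, renormalized partial windows on open chains).  The unsigned
variant sums |w_StS| before smoothing and discards chirality.  The StS
feature fed to networks is smoothed the same way along both contour
indices (a separable periodic box filter); because the box filter
commutes with row summation, the smoothed map remains exactly
consistent with the StA profile.  Smoothing the map matters in
practice: it denoises the N x N input enough to lift the 15-class StS
accuracy by several points at desk scale.

Baseline features: centre-of-mass-corrected Cartesian coordinates
(3 neurons per bead), per-bead curvature (turning angle per unit
contour), and local density (fraction of beads within 2 sigma).  The
curvature and density definitions are this package's own baselines;
they are deliberately simple.

## Knot atlas and seed embeddings

Training ensembles start from verified seed embeddings.  Construction
routes: parametric torus curves (3_1, 5_1, 7_1, 8_19, 10_124); rational
knots from Conway notation realized as 3D tangle closures, with the
continued-fraction numerator as an independent determinant reference
(all remaining knots to 7 crossings; 7_5 uses the equivalent fraction
17/5 because the 17/7 realization coarsens badly); the pretzel
P(3,-3,2) for 8_20; connected sums for the square and granny knots; and
packaged fixture curves for the 11-crossing mutants (below).  Every
seed is resampled to the requested bead count at unit spacing, opened
to non-adjacent clearance >= 1 sigma by a topology-safe relaxation
(pair floors at 0.75–0.8 sigma — above the sqrt(2)/2 bound under which
unit segments could pass — with oracle re-verification after every
coarsening stage), canonicalized (centred, principal axes aligned), and
verified against its reference |Delta(-1)| (and |Delta(-2)| where a
reference is known).  The atlas also enumerates the full roster of 249
prime knots to 10 crossings by name; entries without a packaged recipe
raise a construction error when a seed is requested, so the 250-class
problem is listed but not generatable at desk scale.

### The Conway / Kinoshita–Terasaka pair

No external knot-embedding software is assumed: the two 11-crossing
mutants are built from 6-strand plat closures of braid words found by
a randomized search.  Each packaged embedding carries a certificate
computed by this package:

1. its diagram's Alexander polynomial is trivial (exact modular
   arithmetic);
2. a projection of the relaxed embedding simplifies (Reidemeister I/II
   reduction) to an 11-crossing diagram that is still Delta = 1 and has
   a non-unknot Jones polynomial (Kauffman bracket state sum);
3. the two knots are distinct: their knot groups admit 1512 vs 1176
   homomorphisms into PSL(2,7) (counted by seed-set enumeration with
   constraint propagation over the Wirtinger presentation).

A nontrivial knot with trivial Alexander polynomial has at least 11
crossings, and exactly two knots of 11 crossings have trivial Alexander
polynomial — the Conway knot K11n34 and the Kinoshita–Terasaka knot
K11n42 — so the certified pair is {Conway, KT}.  Which member carries
which name cannot be decided by any invariant this package computes
(mutants share all of them except the PSL(2,7) count, for which no
internal reference value exists); the assignment follows a documented
convention (the knot whose random-projection Seifert genus reached 3,
consistent with the genus-3 Conway knot, is named K11n34) and may be
swapped relative to the literature.  No computed number depends on the
assignment.  `scripts/build_mutant_fixtures.py` regenerates and
re-certifies the fixtures.

## Thermal sampler

The production engine is a crankshaft Monte Carlo on rings of N beads
with fixed unit bonds: a random arc (length biased toward short arcs,
up to half the ring) is rigidly rotated about its chord by up to 1.3
rad, subject to (i) a hard-core excluded volume of 0.9 sigma between
non-bonded beads, enforced at intermediate checkpoints spaced so that
no bead travels more than ~0.5 sigma between checks, and (ii) a
Metropolis test on the discrete worm-like-chain bending energy
E = k_bend Σ (1 − cos θ) with k_bend = l_p kT / sigma.  Per-bead
clearance flags (a bead whose distance to every nearby fixed bead
exceeds its own maximum travel cannot collide during the move) keep the
cost at ~2 ms per sweep for N = 100.  A Kremer–Grest Langevin engine
(FENE k = 30 eps/sigma^2, R0 = 1.5 sigma, WCA, cosine bending, BAOAB)
is provided as the alternative engine and passes the same topology
audits on short runs; it is not the dataset default because the
interpreter-level cost per decorrelated snapshot is far higher.

Checkpointed hard cores make strand passage rare rather than
impossible, so every emitted snapshot is audited by the oracle
(|Delta(-1)| against the seed's reference); failures restore the last
verified state, and more than 1% audited failures raise an error.  In
production runs the observed failure rate is zero.  For the mutant
classes the determinant audit is blind (their Delta equals the
unknot's); topology preservation there rests on the checkpointed hard
core alone, which the certification of the seed embeddings and the
near-perfect separability of the two mutant ensembles both corroborate.

Decorrelation: the default interval (30 sweeps at N = 100, scaled
with N above) keeps the lag-1 autocorrelation of both the radius of
gyration and the global writhe at or below about 0.2, measured by
`decorrelation_check`; the tangent-correlation fit recovers a
configured persistence length of 3 sigma within 20% on N = 100 rings.
Equilibration is 400–500 sweeps from the canonical seed.

## Topology oracle

Labels come from projection + Alexander determinant: a generic
direction (20 retries, tiny position jitter of 1e-3 sigma to break the
exactly-collinear runs of constructed curves, rejection of
near-vertex/near-tie crossings) yields a crossing diagram; the
Alexander matrix from Fox calculus on the Wirtinger presentation
((1−t)·over + t·in − out for positive crossings, row cleared of
t^{-1} for negative ones) is evaluated modulo the Mersenne prime
2^31 − 1 at k+1 interpolation points, the polynomial is recovered by
Lagrange interpolation, normalized (unit t^m stripped, Delta(1) = +1)
and evaluated exactly at t = −1 and −2.  Coefficients of every knot
type handled here are orders of magnitude below the modulus, so the
arithmetic is exact.  Classification majority-votes over several
directions; a fast det1-only path serves the sampler audit.  A
Kauffman-bracket state sum (diagrams up to 16 crossings) provides
Jones-based unknot detection, and a Reidemeister I/II reducer shrinks
noisy projections before exponential-cost steps.

Open chains are closed minimally-interferingly: the direct terminus
bridge is used when it clears the chain body by 1 sigma, otherwise the
termini are extended radially outward to three times the chain's
extent and bridged there (with a waypoint when the termini subtend a
wide angle).  The knotted-arc ground truth is the shortest contiguous
arc whose closure carries the whole ring's determinant label while the
complement closes to the unknot.  Two search strategies are
implemented: an exhaustive bottom-up stride-2 start/length scan (the
test oracle), and a production top-down stride shrink with single-bead
refinement that agrees with the scan on the spliced tight-trefoil
fixture at ~25x less cost; masks are generated with the latter.

## Networks

The classifier is a 4-hidden-layer feed-forward network (rectifier
activations, softmax output, sparse categorical cross-entropy, Adam at
1e-3, batch 256, early stopping on a held-out validation fraction with
patience 10), provided by scikit-learn's multilayer perceptron.  Hidden
widths follow a fixed 2:4:3:1 ratio scaled to a trainable-parameter
budget: ~4e5 parameters for per-bead features and ~3.6e6 for N x N StS
maps (both within ±25%, enforced at construction).  Features are
z-scored per input dimension with statistics from the training split
only; splits are stratified 80/10/10.

The localiser is a bidirectional LSTM implemented in NumPy (hidden
size 48 per direction, single recurrent layer, per-bead sigmoid output,
binary cross-entropy, Adam with gradient clipping, early stopping on
validation BCE; gradients verified against numerical differentiation).
A single bidirectional layer at hidden 48 replaces the initially
planned two-layer hidden-64 design: it trains in about a third of the
time at indistinguishable held-out accuracy for this task size.
Binarisation uses a Heaviside step at 0.5 with theta(0) = 1; accuracy
is correct bits over total bits.

## Desk scales and what they show

The reference experiments used 1e5 uncorrelated conformations per
class; desk scale here is 140–300 per class (stated per experiment in
the acceptance script), chosen so the full acceptance run fits in tens
of minutes on one CPU.  At these scales the StA-trained classifiers
reproduce the reference accuracies to within a few points, and the
orderings StA > XYZ and StS > XYZ are robust.  The full ordering
StS >= StA, which the reference results exhibit at 1e5 conformations,
is marginal at desk scale: the 1e4-dimensional StS input is far from
the data regime where it overtakes the 100-dimensional StA profile,
and the two saturate within a point of each other.  The synthetic
generator reproduces equilibrium ring ensembles of the bead-spring
model family; it does not emulate confinement, hydrodynamics,
open-chain dynamics, or generation-method shifts (e.g. freely jointed
chains), so transfer across those conditions is untested here, as it
was reported to degrade in the reference study.

Localisation ground truth differs from the original study's external
tool in search details (stride, refinement, closure discretization),
so masks may differ by a few beads; the per-bead accuracy target
carries the same caveat.  Knotted arcs at l_p = 10 sigma are broad
(60–90% of the contour for the 5-knot classes), which bounds the
trivial all-ones baseline near 65–70% and makes the ~90% localiser
accuracy a genuine margin over base rate.

## Known limitations

* Atlas constructions cover the knots the desk-scale experiments use;
  8–10-crossing primes (other than 8_19, 8_20, 10_124) are roster-only,
  so the 250-class problem cannot be generated.
* The mutant name assignment (K11n34 vs K11n42) is conventional, as
  discussed above.
* The sampler's topology guarantee is checkpointed-hard-core plus
  audit, not a mathematical impossibility proof; for Delta-trivial
  classes the audit adds no information.
* Reported accuracies at desk scale carry test-set noise of roughly
  ±1 point (a few hundred held-out items); seeds are fixed everywhere,
  so reruns are reproducible.
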