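# Methods

This note documents the models and numerical choices behind
`morphotraj`, what the synthetic-data generator does and does not
emulate, and the design decisions taken where the underlying procedure
admits more than one reading.

## Procrustes superimposition

Configurations are centered, scaled to unit centroid size and rotated to
the evolving consensus until the consensus displacement falls below
1e-10 (at most 200 sweeps; non-convergence is an error, not a warning).
Rotations are restricted to det +1: all specimens must be digitized
facing the same direction, and a mirrored specimen is treated as a data
error rather than silently reflected (`allow_reflection=True` exists for
controlled experiments). Each sweep optionally applies the optimal
per-specimen scale toward the consensus (full Procrustes fit, the
default); the final coordinates are always renormalized to unit centroid
size, so the full/partial distinction affects only the estimated
consensus and rotations, and for shape variation of the magnitude seen
in skull data the difference is far below the other error sources.

After convergence the solution is rotated into a canonical frame — the
consensus principal axes, signs fixed deterministically — so the output
is invariant (to floating-point tolerance) under a common similarity
transform of all inputs. Coordinates are then orthogonally projected
onto the tangent hyperplane {z : z·c = 1} at the consensus c. Two
consequences worth knowing:

* Euclidean operations (PCA, regression, distances) on tangent
  coordinates approximate Procrustes geometry well; chords between
  *unprojected* unit-size shapes bend off a common deformation axis at
  first order in shape distance, which is why the tests compare
  directions in the tangent plane.
* Re-running GPA on its own output is an exact fixed point for
  on-sphere coordinates; tangent-projected coordinates are re-fit only
  to curvature order (~squared shape distance). The fixed-point test
  therefore runs without the projection.

Semilandmarks receive full weight and are never slid; no sliding
implementation is provided, deliberately: sliding can create artificial
deformation on outline-dominated data sets, and treating semilandmarks
as landmarks keeps the fit reproducible.

TPS `SCALE=` records are applied before analysis only when present for
every specimen, because centroid sizes are comparable across specimens
only under a uniform scaling policy; otherwise they are ignored with a
warning.

## Ordination and component selection

PCA uses the sample covariance matrix (divisor n−1) of the Procrustes
coordinates. A 2D GPA leaves four near-null dimensions (two
translations, rotation, size); eigenvalues below 1e-12 of the largest
are excluded from the variance fractions and from the broken-stick pool
p, since including them would dilute the stick expectations with
dimensions that carry no shape information. Broken-stick retention is
the *initial run* of components whose observed fraction exceeds
bᵢ = (1/p)Σ_{j=i..p}1/j; a later component that beats its stick after a
failure is not retained. Component signs follow a deterministic
convention (largest-magnitude loading positive).

## Allometric regression and shape variables

The multivariate regression of shape on natural-log centroid size is an
ordinary least-squares fit of one common slope vector; the pooled
within-group variant centers both shape and log CS inside each group
(ontogenetic series) first, so group location differences do not
masquerade as allometry — with two-point series this makes the fitted
axis the noise-weighted average of the juvenile→adult contrasts. The
permutation test shuffles sizes against shapes (within groups when
pooled) and reports p = (b+1)/(n_perm+1) for b permutations whose
predicted sum of squares reaches the observed one; with the seed fixed
the p-value is bit-reproducible.

The regression score is the projection of (shape − grand mean) onto the
*unit-normalized* coefficient vector, so RS is measured in Procrustes
units and is commensurable with the Euclidean-distance variable
ED(x) = ‖x − x_ref‖, anchored at the smallest specimen (its ED is
exactly 0). Natural logs are used throughout; a different base would
only rescale slopes by a constant.

## Time calibration

Node ages are initialized to the age of the oldest descendant tip
(tip ages = midpoints of stratigraphic intervals, supplied as a table),
which makes the branch to the older child of every node zero. The root
is pushed back 1 Myr, and each remaining zero-length branch is resolved
by locating the nearest ancestral positive branch and dividing its
duration equally along the longest chain of consecutive zero branches
hanging from it; the affected node ages move up, side branches become
positive as a consequence, and the pass repeats until every branch is
strictly positive. Where several zero chains compete, the
longest-chain-first rule is this package's tie-break; it reproduces the
equal-sharing arithmetic on linear chains exactly (a 6-Myr branch above
two stacked zero branches becomes three branches of 2 Myr).

One practical consequence, visible in the validation experiments: this
calibration glues every internal node to its oldest descendant lineage
by short branches, so reconstructed ancestral states lean heavily on the
oldest sampled tips. That is a property of the calibration, not of the
reconstruction.

## Ancestral states and phylogenetic signal

Weighted squared-change parsimony minimizes Σ_b ‖Δstate_b‖²/l_b. The
first-order conditions form a weighted graph Laplacian over the nodes;
the internal block is solved exactly (one sparse solve per data set,
every coordinate simultaneously), giving the unique minimizer, which
coincides with the maximum-likelihood ancestral states under Brownian
motion (verified against an independent GLS conditional-mean
implementation to 1e-8). The minimized *weighted tree length* is the
permutation-test statistic: tip states are randomly reassigned to tips
and p is the fraction of permutations with tree length at most the
observed one (short = strong signal), with the (b+1)/(n+1) correction.
For speed the minimized length is evaluated through the Schur
complement M of the Laplacian (length = tr(YᵀMY)), so each permutation
costs O(n²) via the Gram matrix rather than a fresh solve.

The multivariate K statistic is
K = [tr(EᵀE)/tr(EᵀC⁻¹E)] · (n−1)/(tr C − n/(1ᵀC⁻¹1)), with C the
Brownian tip covariance (shared path lengths, Myr) and E the residuals
about the generalized-least-squares mean. K ≈ 1 under Brownian motion
(simulation check: mean over 200 replicates within 0.1); the p-value
permutes tips, again through Gram-matrix identities. Identical states
at all tips make K undefined and raise an error.

## Trajectories and heterochrony calls

Change vectors point juvenile→adult (the convention drawn in trajectory
figures; angles and lengths are unaffected as long as it is applied
consistently). Angles use the 2·atan2(‖û−v̂‖, ‖û+v̂‖) form, exact near
0° and 180° where arccos of a dot product loses precision.

For ancestor–descendant comparisons, ΔRS and ΔED are descendant-adult
minus ancestor-adult. The significance threshold is 1.5 × CI, where the
CI is the two-sided 95% t-interval half-width of the mean of the
branch-wise differences of the same variable over all 2n−2 branches of
the adult tree (child minus parent, reconstructed states at internal
nodes). The branch set is the only quantity in the analysis with
cardinality 2n−2, which is how the threshold's sample is defined here;
an empirical-quantile CI (half-width of the central 95% of the branch
differences themselves — considerably wider) is available behind
`ci_threshold(..., method="quantile")` since "the CI of the
differences" admits both readings. A call is paedomorphic only when
*both* variables are significantly negative, peramorphic only when both
are significantly positive; disagreement in sign or significance yields
"undetermined".

Known sensitivity: because internal-node variables are projections of
reconstructed states, an injected or real shift on one branch bleeds
into neighbouring reconstructions (smoothing), and single-specimen
digitization noise propagates into ancestor states roughly with the
reconstruction weight of the nearest tips. Calls on ancestor→terminal
pairs are noticeably noisier than internal-internal comparisons.

## The synthetic-data generator

`make_base_skull` builds a deterministic schematic lateral archosaur
skull — outline, naris, antorbital fenestra, orbit, infratemporal
fenestra — with 20 fixed landmarks and 51 semilandmarks by default
(regions partition the landmark roster and scale to other k).

The generative model, with defaults chosen once as the package's study
conditions:

* **Allometric growth.** Shape at log-size s is
  base + slope·(s − s_adult)·v, with v a deterministic unit growth
  field (snout elongation and deepening, relative orbit reduction —
  the general pattern of archosaur cranial ontogeny), orthogonal to the
  similarity directions. Default slope 0.1 Procrustes units per log CS
  and ontogenetic span 1.5 log units (≈ 4.5× linear size), giving a
  juvenile→adult shape change of 0.15 Procrustes units, in the range
  observed for embryo/hatchling-to-adult archosaur series.
* **Interspecific drift.** Adult mean shapes evolve by Brownian motion
  on the calibrated tree over a low-rank basis of eight smooth
  polynomial deformation fields (geometric rate decay 0.5, total rate
  2e-6 norm²/Myr, isotropic floor 2e-8 per coordinate) — real cranial
  variation concentrates on a few axes. The basis is orthogonalized
  against v: under the simulated null, lineages do not drift along the
  growth axis, because displacement along that axis *is* heterochrony
  in this framework; injected shifts (signed magnitudes along v,
  inherited by all descendants of the shifted branch) are therefore an
  unambiguous ground truth. This is a deliberate idealization: in real
  data, drift correlated with the allometric axis cannot be
  distinguished from heterochrony by this method, and passing recovery
  tests does not claim otherwise.
* **Observation noise.** Each emitted specimen gets isotropic Gaussian
  landmark noise of 0.5% of centroid size per landmark (the order of
  published digitization error for such data sets), a random pose
  (rotation ±15°, translation) and its stage's centroid size. Sizes
  evolve as Brownian motion on the log scale (rate 5e-4 /Myr).

Two study designs ship with the package. The **showcase fixture** (12
taxa, 5 juvenile/adult series, clade analogues CladeA–D, a paedomorphic
stem shift of −0.02 and a peramorphic terminal shift of +0.02) mirrors
the sparsely sampled fossil situation. The **recovery design** used for
the controlled classification experiments is a 32-taxon ladder with a
juvenile for every taxon and dense sampling (9+9 taxa) flanking the
focal divergence: with single-specimen noise, classification power is
governed by how many specimens support the focal ancestor and
descendant reconstructions, and the fully paired sampling removes a
small bias that arises when the regression axis is estimated from a
subset of the taxa that also enter the reconstructions. Each recovery
trial is two-pass: the clade is first simulated with no shift to
measure the spread (SD) of branch-wise differences of both shape
variables, then re-simulated under the same seed with the shift set to
the required multiple of the larger spread, and the focal pair is
classified.

What passing these tests shows: the pipeline recovers shifts of 3× the
branch-difference spread essentially always and stays below a 10%
false-call rate on shift-free clades *under the generator's
conditions* — modest non-allometric drift, noise at digitization scale,
well-supported focal nodes. It does not show that the method separates
heterochrony from correlated evolutionary drift, nor that sparsely
supported ancestor→terminal calls have controlled error rates; on the
showcase design those calls are visibly noisier.

## Numerical and degenerate-input policy

Exact zero-variance inputs raise errors (degenerate centroid size,
rank-0 PCA, zero size variance in regression, identical tip states in
K). Permutation p-values are never 0 by construction. All randomness
flows through seeded `numpy` generators; identical seeds give
bit-identical data sets, analyses and output files. Problem sizes in
the validation experiments (200 replicates for recovery and K
calibration, 400 for the type-I check, 10,000-round permutation tests
in the study pipeline) were fixed as the package's standard experiment
sizes; all run in seconds to a couple of minutes on one CPU.

## Known limitations

* MorphoJ project parsing is best-effort against a reverse-engineered
  XML-flavoured subset; export to TPS/CSV is the supported path.
* Trees must be strictly bifurcating; polytomies are the caller's
  problem (resolve before analysis).
* Two-stage trajectories cannot express curved ontogenies; angles and
  lengths inherit whatever stage-sampling inconsistency the data carry.
* Only paedomorphosis/peramorphosis can be inferred from allometric
  data; rate-based process labels (neoteny, acceleration, progenesis,
  hypermorphosis) require individual ages and are out of scope.
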