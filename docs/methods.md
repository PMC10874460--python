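# Methods

`jawmorph` reimplements, as a tested library, a complete ecomorphological
workflow for fossil carnivore lower jaws: functional and geometric
morphometrics, unsupervised classification into functional feeding groups
(FFGs) and subgroups (FFsGs), discriminant validation, and phylogenetic
comparative analyses of disparity and ancestral states. This note records
the models, the parameters that matter, the numerical choices, and the
limits of what the synthetic tests demonstrate.

## Data streams

**Function.** Nine dimensionless jaw characters are computed from twelve
linear measurements (mm): mean anterior and posterior mechanical advantage
(MAMA, MPMA; in-lever / out-lever, averaged over the two adductor
attachment arms), opening mechanical advantage (OMA), maximum aspect ratio
(MAR = max depth / jaw length), relative toothrow and symphyseal lengths
(RTL, RSL), symphyseal angle (SA, degrees), relative articulation offset
(RAO, signed), and symphyseal robusticity (SR = symphysis depth / length).
High closing MA marks force-efficient jaws, low MA speed-efficient ones.
The default character set is all nine minus SR; the set is a parameter
because analyses in this area variously use eight or nine, and the exact
membership of the "eight" is not derivable from the character list alone.
MAMA/MPMA can alternatively average over bite points along the toothrow
(`ma_mean="toothrow"`); the attachment-arm convention is the default. The
matrix is z-scored per character (sample sd, n−1) before ordination to
mitigate heteroscedasticity; means and sds are stored so the transform
inverts exactly.

**Shape.** 59 two-dimensional landmarks per jaw: 4 fixed homologous points
joined by 4 outline curves carrying 55 semi-landmarks. Generalized
Procrustes analysis removes position, size (unit centroid size) and
orientation (rotation only; reflections are disallowed because jaws are
digitised in one orientation). Semi-landmarks then slide along the chord
through their two curve neighbours to the point of that chord segment
closest to the corresponding mean-shape point, re-superimposing after each
pass. The projection is clamped to the chord segment so curves cannot
invert, and fixed landmarks never move in the sliding step. Sliding
targets the *re-estimated* mean each pass (the alternative — sliding
against the initial consensus — is a one-pass call). Because clamped
chord sliding against a moving mean admits a slow cumulative drift of
points along their curves, the slide/re-GPA loop is bounded at 10 passes by
default (GPA itself uses tol 1e-8 on mean-shape change, max 100
iterations); nearly all of the fit improvement occurs in the first pass.

## Ordination

Separate PCAs for shape (aligned coordinates, covariance PCA, no further
scaling — relative-warps style with α = 0, uniform and non-uniform
components together) and function (z-scored characters). Eigenvalues are
sample variances of the scores; the component count is capped at
min(n−1, p). Sign convention: the largest-magnitude loading of each
component is positive, making scores reproducible across platforms.

## Consensus clustering into FF(s)Gs

Three algorithms cluster the z-scored characters on Euclidean distances:
Ward hierarchical linkage, K-means (25 restarts), and PAM (greedy BUILD
then best-improvement SWAP). Each algorithm's K is selected independently
by the gap statistic over K = 2–10 with B = 2000 uniform reference sets
drawn over the principal-component-aligned bounding box (Tibshirani's
variant); the simulation error carries the √(1+1/B) factor and K is the
smallest value satisfying the one-standard-error rule, falling back to the
arg-max of the gap curve. Consensus is label-free: a taxon × taxon
coassignment matrix records the fraction of algorithms agreeing on each
pair (values 0, 1/3, 2/3, 1), and composite groups are connected components
of the graph with edges at coassignment ≥ 2/3. Singleton components, and
taxa whose removal disconnects their component (tie bridges), are flagged
"unstable"; the agreement rate is the fraction of stable taxa. Subgroups
come from re-running the same consensus inside each composite group
(K range truncated to the group size − 1; groups under 4 taxa pass through
unsplit), with subgroup ids namespaced by parent. Internal validation uses
silhouette widths; external validation against a reference partition (e.g.
clades) reports the adjusted Rand index, variation of information, and a
chance-corrected best-match agreement rate.

Choices the method description leaves open, fixed here as defaults:
consensus on z-scored characters (not functional PC scores; both are
Euclidean-equivalent when all components are kept), the ≥ 2/3 coassignment
threshold (majority semantics; unanimity trivially reproduces identical
partitions), Ward linkage for "hierarchical", and the 1-SE K rule. All are
config options.

## Discriminant validation and ancestral classification

LDA with the classical Gaussian equal-covariance model: class means, pooled
within-class covariance (denominator n−k; ridge ε = 1e-8·trace/p when
singular, which matters for small subgroups), priors proportional to class
size. Validation is leave-one-out: each taxon is classified by a model
refitted without it; classes with a single member are skipped from the
denominator with a warning. The same model classifies reconstructed
ancestral functional PC score vectors into subgroups, giving one of the two
ancestral-FFsG routes (the other being the discrete Mk reconstruction);
the pipeline reports both.

## Phylogenetic machinery

**Time-scaling.** Minimum-branch-length (MBL) dating: tips sit at their
first-appearance ages (Ma); a post-order pass dates every internal node at
max(child ages) + mbl with mbl = 0.1 myr by default. This is the unique
minimal dating with every branch ≥ mbl and respects all first appearances;
note it necessarily adds mbl along the path to the oldest descendant (a
node cannot sit exactly at its oldest child's age with strictly positive
branches).

**Imputation.** Missing body sizes (log10 femur length, mm) are filled by
the Brownian-motion conditional expectation given observed tips: root state
and rate σ² fitted by ML on the observed-tip covariance (shared
root-to-MRCA path lengths), missing tips given the phylogenetic-GLS
conditional mean with a conditional variance that includes root-estimate
uncertainty. Single-rate BM is the default; clade-specific relative rates
can be supplied as a regime map (the regime choice is the caller's, since
no principled automatic regime selection is implied by the workflow).

**Continuous ASR.** Same GLS machinery applied per trait axis to every
internal node; estimates are the BM maximum-likelihood ancestral states and
variances are reported per node.

**Discrete ASR.** Mk models with four rate structures — ER (1 parameter),
SYM (k(k−1)/2), ARD (k(k−1)), and ASYM, interpreted as a 2-parameter
ordered-state model in which all transitions up the state order share one
rate and all transitions down another (the "asymmetrical" structure is not
uniquely defined at k = 7; this interpretation is recorded in fit
metadata). Likelihoods come from Felsenstein pruning with per-branch matrix
exponentials; rates are optimised by L-BFGS-B on log rates with 5 seeded
starts (ARD at k = 7 has 42 parameters and is multimodal). The root prior
is flat by default (option: stationary distribution). Marginal node
probabilities use a two-pass (down/up) message scheme verified against
brute-force enumeration on small trees. Model averaging is the unweighted
mean of per-model node probability vectors, renormalised; AIC-weighted
averaging is an option.

**Time-slicing.** A slice at age a collects one vector per edge with
parent age > a ≥ child age. Tips whose stratigraphic range covers a
contribute their observed vector; other edges contribute either the
nearer endpoint's value ("proximity", default) or the linear interpolation
by elapsed fraction ("gradual"). Bins are half-open [older, younger) Ma.

## Disparity and macroevolutionary models

Disparity per time bin is the sum of variance (SOV): the trace of the
covariance matrix of lineage vectors at the bin's midpoint slice (all PC
axes; sample variances, n−1). Bootstrap: B = 1000 resamples of lineages
with replacement, 95% percentile intervals. Rarefaction subsamples each
draw without replacement to the minimum across-bin lineage count; the
rarefied *point estimate* deliberately uses rarefaction-only draws (no
bootstrap resampling) because the with-replacement bootstrap biases the
n−1 variance down by roughly (1−1/n) and would re-introduce exactly the
sample-size dependence rarefaction exists to remove.

The disparity series is compared across five paleontological time-series
models fitted by ML with per-bin sampling variance (bootstrap variance)
folded into the likelihood, all conditioned on the first observation except
Stasis: BM (increments N(0, σ²Δt)), Trend (N(μΔt, σ²Δt)), Stasis
(values i.i.d. N(θ, ω)), OU (Gaussian AR(1) toward θ at rate α), and EB
(BM with step variance σ²e^{rt}, r ≤ 0). Ranking is by AICc with Akaike
weights over the fitted set. The models are fitted to the disparity curve
itself (not to traits on the tree), matching the disparity-trend question;
tree-based multivariate OU is out of scope.

## Group statistics

One-way NPMANOVA (PERMANOVA) on Euclidean distances over score vectors:
pseudo-F from among/within sums of squared distances, p-value by label
permutation with the add-one convention p = (1 + #{F* ≥ F})/(1 + B),
default B = 9999; pairwise group tests carry a Bonferroni correction whose
multiplier counts only tested pairs (size-1 groups are excluded with a
warning). An exhaustive mode enumerates all permutations for tiny n and
returns the exact proportion. Body-size differences across time bins use
pairwise two-sided Mann–Whitney U tests — exact null when n₁n₂ ≤ 400 and
tie-free, tie-corrected normal approximation otherwise — again with
Bonferroni over tested pairs.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *structure* of the study design so every stage
is testable against planted truth: a birth–death tree conditioned on ~120
sampled tips (extinct lineages retained as fossil tips; retry cap 1000;
defaults λ = 0.09, μ = 0.045 per lineage-myr, root at 315.2 Ma — Late
Carboniferous to Early Triassic span), BM body size (σ² = 0.05 per myr on
log10 femur length, ~30% of tips masked as missing), a 3-group/7-subgroup
Gaussian mixture in 9 dimensions planted into the measurement matrix
(top-level centroids 8 within-subgroup sd apart; subgroup offsets a fixed
2.5 sd, confined to the subspace spanned by the group axes, so subgroups
stay subtle relative to groups — if the offsets scaled with the separation
the seven subgroups would become fully distinct clusters, and if they left
the group-axis subspace the per-character z-transform would amplify
subgroup-only directions to group-level magnitude; either way top-level
recovery would rightly fail), jaw-shaped landmark
configurations as a template outline deformed by three smooth sinusoidal
displacement fields plus i.i.d. jitter, and stratigraphic ranges
discretised from tip ages to half-stage bins (315.2–249.9 Ma).

The planted vectors enter the raw measurements as ~6% multiplicative
effects per planted sd, with planted dimensions assigned to measurement
columns so that no functional-character ratio cancels its own signal.
What the generator does **not** emulate: real measurement error structure,
allometry, phylogenetic autocorrelation of the functional characters
(labels are assigned in tree-adjacent blocks, not simulated along the
tree), taphonomic biases, or anatomical covariation between shape and
function. Passing tests therefore demonstrate algorithmic correctness and
recoverability under the planted model — not that real jaw data contain
three feeding groups.

## Problem sizes in tests and the acceptance script

Desk-scale sizes keep the whole suite in minutes on one CPU: pruning
checks enumerate all 3- and 4-tip topologies plus sampled 5-tip ones;
gap-statistic recovery uses 20 seeds per scenario at B = 100 with 5
K-means restarts; NPMANOVA calibration uses 500 null replicates at 999
permutations (the permutation loop is vectorised against a fixed
squared-distance matrix); series-model consistency uses 100 replicates of
20-bin series with step variance 0.05 (same order as the Stasis ω = 0.05
used in the simulations); the end-to-end pipeline runs 120 taxa with
B_gap = 60, 200 bootstrap cycles, ER+ASYM Mk models, and 199 permutations,
twice, to verify byte-identical reruns. Production defaults (B = 2000 gap
cycles, B = 1000 bootstrap, 9999 permutations, all four Mk models, 5
optimiser starts) remain the function defaults.

## Known limitations

- Chord sliding is the only semi-landmark scheme (no bending energy) and
  is 2-D only; missing landmarks are not estimated.
- The Mk ASYM structure assumes a meaningful state ordering; for feeding
  subgroups the lexicographic order is a convention, not biology.
- OU on a short, autocorrelated disparity series is weakly identified;
  AICc comparisons among the five models are more robust than OU's
  parameter estimates themselves.
- PERMANOVA assumes exchangeability under the null; strong dispersion
  differences between groups can masquerade as location effects.
- Consensus "unstable" flagging marks graph bridges and singletons only;
  it does not quantify assignment uncertainty the way a soft clustering
  would.
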