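# jawmorph

Ecomorphology of carnivore lower jaws: who was biting what, and how, across
deep time. `jawmorph` is a Python library and CLI for classifying
carnivores into **functional feeding groups** from jaw morphometrics and
tracing those groups across a dated phylogeny — built for fossil datasets
such as Permian synapsid predators, where feeding ecology must be inferred
from jaw mechanics rather than observed.

It is aimed at palaeobiologists and comparative morphologists who have (or
want to simulate) per-taxon jaw measurements, landmark outlines, a
phylogeny, and stratigraphic ages.

## What it computes

**Functional characters.** Dimensionless jaw biomechanics from linear
measurements: closing mechanical advantage MA = in-lever / out-lever at the
anterior and posterior bite points (high MA → forceful bite, low MA → fast
bite), opening MA, aspect ratio (depth/length), relative toothrow and
symphyseal lengths, symphyseal angle and robusticity, articulation offset.
Characters are z-scored per column before ordination.

**Shape.** Generalized Procrustes superimposition of 59-landmark outlines
(4 fixed points + 55 semi-landmarks on 4 curves), with chord–min-d²
sliding: each semi-landmark moves along the chord through its curve
neighbours to the point nearest the mean shape.

**Feeding groups.** Consensus clustering: Ward hierarchical, K-means and
PAM each cluster at the K chosen by the gap statistic
(Gap(K) = E*[log W_K] − log W_K over K = 2–10, B = 2000 reference sets,
one-standard-error rule); composite groups are connected components of the
taxon coassignment graph at agreement ≥ 2/3. Nested re-clustering inside
each group yields feeding subgroups; jack-knifed (leave-one-out) linear
discriminant analysis validates the labels.

**Phylogenetic comparative layer.** Minimum-branch-length time-scaling
from first appearance dates (mbl = 0.1 myr); Brownian-motion imputation of
missing body sizes and ML ancestral states (phylogenetic GLS); Mk
ancestral reconstruction of subgroup states under ER / SYM / ARD / ASYM
rate structures with model-averaged marginal node probabilities; sum-of
variance disparity through time from phylogenetic time-slices with
bootstrap CIs and rarefaction; fits of BM / Trend / Stasis / OU / Early
Burst models to the disparity series ranked by AICc and Akaike weights;
PERMANOVA and pairwise Mann–Whitney U group tests.

A synthetic-data module generates all inputs (birth–death trees with
fossil tips, planted 3-group / 7-subgroup measurement structure, deformed
landmark outlines, stratigraphic ranges) with known ground truth.

## Worked example

```python
from jawmorph import (SimConfig, simulate_dataset, compute_functional_characters,
                      z_standardise, pca, consensus_cluster, lda_fit_jackknife)

ds = simulate_dataset(SimConfig(n_tips=60, seed=7))
chars = z_standardise(compute_functional_characters(ds.measurements))
ord_fun = pca(chars.values, taxa=chars.taxa, variables=chars.characters)
print(f"functional PC1+PC2 variance: {100 * ord_fun.variance_proportions[:2].sum():.1f}%")

ffg = consensus_cluster(chars.values, taxa=chars.taxa, B=100, seed=7, restarts=5)
print(f"feeding groups: {len(ffg.group_members())}, "
      f"agreement rate: {ffg.agreement_rate:.2f}")

model, report = lda_fit_jackknife(ord_fun.scores_frame(), ffg.labels)
print(f"jack-knifed LDA correct-classification rate: {100 * report.overall_rate:.1f}%")
```

prints

```
functional PC1+PC2 variance: 81.6%
feeding groups: 3, agreement rate: 1.00
jack-knifed LDA correct-classification rate: 98.3%
```

The first two functional PCs carry 81.6% of the character variance; the
three algorithms unanimously recover the three planted feeding groups
(agreement 1.00 means no taxon was consensus-unstable), and leave-one-out
LDA re-assigns 98.3% of taxa to their own group — the planted functional
structure is both detected and linearly separable in score space.

The full pipeline (characters → ordination → FF(s)Gs → LDA →
time-scaling → imputation → ancestral states → disparity → statistics)
runs from one config:

```sh
jawmorph run --seed 11 --outdir results/run1
```

which writes one CSV per stage (feeding groups, ancestral state tables,
the disparity curve and model-fit table, test tables) plus
`run_report.json` echoing every parameter and per-stage seed. Identical
config and seed reproduce all numeric outputs byte for byte.

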