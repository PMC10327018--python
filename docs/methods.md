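# Methods

`crossconn` implements a comparative-connectomics pipeline: given neuron
morphologies and synaptic edge tables from several brain hemispheres, it
derives consensus cell types, quantifies how stereotyped type-level
connections are, separates technical from biological variability in edge
weights, and evaluates the Kenyon-cell expansion-coding model.  Everything
is exercised end to end on synthetic cohorts with planted ground truth.

## Morphological similarity

Skeletons are conditioned before comparison: terminal twigs shorter than
5 um are removed iteratively (a twig is the path from a leaf to the nearest
branch point), and branches are resampled to ~1 node per micrometre of
cable with branch points, tips and the root preserved.  The resampled
skeleton becomes a *dotprops* object — the point cloud plus a unit tangent
per point, the first principal direction of the point's k = 5 nearest
neighbours.  Tangents are sign-free.

The similarity score between a query and a target follows the NBLAST
recipe: each query point is paired with its nearest target point and the
pair contributes `f(d, |u.v|)`, summed over query points.  The published
empirical log-odds scoring matrix is not part of this package; the default
kernel is

    f(d, |dot|) = exp(-d / sigma) * |dot|,   sigma = 3 um,

chosen so that a self-comparison scores exactly the number of points and
the score decays on the scale of typical inter-neuron distances.  The
kernel is a pluggable argument, so an empirical scoring function can be
substituted without touching the search structure.  Forward score matrices
are symmetrised as (S + S^T)/2; distances are 1 minus the score normalised
by the geometric mean of the two self-scores, clipped to [0, 1].  Right-side
neurons are mirrored across the sagittal plane (x -> 2*midline - x) before
scoring; the synthetic brain is built with its midline at x = 0.

Morphology groups use Ward linkage cut at the most abrupt change in merge
height (the largest gap between successive merge heights); if all gaps are
equal within 1e-9 there is no elbow and a single group is returned.

## Consensus cell typing

The operational definition: *a cell type is a group of neurons more similar
to a group of neurons in another brain than to any other cell in the same
brain*.  Neurons from all hemispheres are co-clustered with Ward linkage on
morphology distances, connectivity (cosine) distances, or their sum.
Connectivity profiles are rows of synapse counts from/to each cell type
cross-identified in every hemisphere, with separate input and output
blocks; cosine distance makes the profiles scale-free, so raw counts and
input-normalised weights are interchangeable here.

From the dendrogram the smallest clusters are extracted that (1) contain at
least one neuron from every required hemisphere and (2) are approximately
balanced — the ratio of the largest to smallest per-hemisphere count is at
most `balance_tolerance` (default 3, so small clusters such as {1, 1, 2}
pass).  "Smallest" is formalised as assigning each leaf to its deepest
admissible ancestor, which yields a laminar partition.

Admissibility alone over-splits.  Within a true type the neurons of the
different hemispheres are statistically interchangeable, and Ward readily
finds balanced cross-hemisphere triplets that pass both criteria while
reflecting nothing but noise.  Two guards therefore stand in for the manual
review step such clusterings otherwise require:

- **Separation guard** (`split_gap`, default 2): an admissible node is a
  cluster candidate only if its parent's merge height is at least twice its
  own — a split must be supported by an abrupt change in cluster distance,
  the same principle as the elbow rule for morphology groups.  On planted
  cohorts, true type nodes show parent/child height ratios above 3 while
  spurious within-type nodes sit near 1.
- **Definition check** (`tie_fraction`, default 0.05): every member of an
  emitted cluster must be closer, by more than 0.05 x the median
  inter-neuron distance, to some cross-hemisphere member of its own cluster
  than to any same-hemisphere cell outside it.  Clusters that fail —
  including exact ties between indistinguishable neurons — are dissolved
  into the next candidate ancestor, deepest first, until all clusters
  stand.  The scale anchor matters: near-duplicate neurons have tiny mutual
  distances that are heterogeneous in relative terms but all
  indistinguishable at the scale of the data.

With `split_gap=None, definition_check=False` the function reduces to the
bare deepest-admissible-ancestor rule, which is what the enumeration oracle
in the test suite checks.  Leaves with no admissible ancestor are reported
as unassigned rather than attached to a neighbouring cluster.  Increasing
the balance tolerance enlarges the admissible set, so the partition can
only refine (tested); clusters whose balance ratio is within 10% of the
tolerance are flagged for review.

Consensus clusters are compared against a reference typing on the
bipartite incidence graph over shared neurons: each connected component is
one-to-one, a split (suffix labels "PS090a", "PS090b"), a merge
(composite labels "SIP078,SIP080"), or a recombination.

## Edge stereotypy

An *edge* is the set of connections between two cell types; its weight is
the summed synapse count.  Normalised weight divides by the target type's
total input (a 10-synapse edge onto a 200-input target is 5%), with
untyped partners kept in the denominator through a reserved UNTYPED
bucket.  Persistence curves ask, per weight bin, how often a reference
edge (weight >= 1) is found in each other hemisphere, in both, or in
neither; bins are per-value up to 30 synapses and log-spaced above, where
edges grow sparse.  Threshold extraction uses a plateau rule: the smallest
bin edge from which persistence stays at or above the requested level.
Weight agreement between hemispheres is summarised by conditional quantile
envelopes (bins with fewer than 20 matched edges merge upward) and by
Pearson correlation of log10 weights — weights span orders of magnitude,
so the raw scale would be dominated by a few strong edges.

## Technical-noise model

To ask how much edge-weight variability reconstruction alone explains, the
observed table is scaled to a fictive 100%-complete ground truth by
dividing each weight by its neuropil's postsynaptic completion rate
(45.8% completion scales by 100/45.8 = 2.18; round-half-to-even keeps
weights integral).  Each of 500 rounds then re-simulates reconstruction
twice: once with the original per-neuropil rates and once with left/right
rates swapped.  A draw retains exactly round(total x rate) synapses per
neuropil without replacement (multivariate hypergeometric across edges),
thins them at the detection recall (0.77), and injects false positives so
the expected FP fraction is 1 - precision (0.72), allocated to existing
edges proportional to fictive weight.  The order retain -> thin -> inject
is fixed.  Pooling (unflipped, flipped) weight pairs gives, for each
unflipped weight 1..30, the mean signed difference and 5-95% quantiles of
the flipped weight.  An observed left/right pair is "explained by
technical noise" if the right weight falls inside the closed band at the
left weight.  When observations are generated by the model itself the
in-band fraction sits slightly above the nominal 0.90 (typically 0.92)
because the weights are integers and the closed interval absorbs boundary
mass.

## Kenyon-cell model

Kenyon cells (KCs) mix input from N = 58 olfactory channels; K is the
number of distinct channels a KC samples.  Observed K counts, per KC, the
channels whose summed input exceeds a threshold (0 by default, i.e.
non-thresholded connectivity).  The linear rate model takes W as an M x N
matrix with K entries of 1 - alpha and N - K entries of -alpha per row,
alpha = A/M with A = 100, input activity white with identity covariance,
and scores the code by the participation ratio

    dim = (Tr C)^2 / Tr(C^2),   C = W W^T,

computed through the N x N Gram matrix (same non-zero spectrum, much
smaller).  The per-K dimensionality is a Monte-Carlo mean over 100 (tests:
1000) seeded draws of the random K-subset per row; the optimal K is the
argmax, smallest K on plateaus.  Holding N and A fixed, increasing M from
1,900 to 2,600 lowers the optimal K (5 -> 4 in the shipped configuration) —
the directional prediction that matches the observed shift between a
smaller and a larger KC population.  Budget fractions express connectivity
as shares of a source's output (or a target's input) across a partition of
cells, and the excitation/inhibition ratio per cell is normalised by the
cohort mean, making the population average 1 by construction.

## Synthetic cohorts

The generator plants a ground truth: cell types with random branched-tree
prototypes (40-200 nodes, ~2 um steps) grown from somata kept at least
15 um apart in a ~120 um arena, per-hemisphere target counts of
1 + Poisson(0.43) so that about 65% of types are singletons (the share
observed among cross-matched central-brain types), and type-level edges
appearing in each of 8 mirrored neuropils with probability 0.35.  Edge
mean weights are lognormal with median 4 synapses and sigma_log10 = 0.6 —
heavy-tailed like real connectomes.  Each edge carries a conservation
propensity mu/(mu + 5), the probability it is realised in a given
hemisphere; weak edges are thus the least conserved.

A hemisphere instantiation jitters counts (+/-1 with probability 0.2,
floored at 1), mirrors right-side morphologies and adds 0.5 um Gaussian
positional noise, draws a type-level weight max(1, round(mu x LogNormal))
with a 30% coefficient of variation, and distributes it multinomially over
member neuron pairs — so type aggregation inverts the realisation exactly,
and presence/absence is governed solely by the planted propensity.
Technical corruption applies per-synapse retention at completion x recall
and proportional false-positive injection, with hemibrain-style volume
truncation available as a soma-containment box.

What passing tests show, and what they do not: the cohorts have
well-separated type morphologies, independent hemispheres and no
segmentation or annotation errors, so recovery results (ARI 1.0 at 20
types under default noise) demonstrate correctness of the machinery, not
expected performance on real data, where types overlap in space, counts
run into the thousands and label noise is real.  Morphology distances here
are cleanly bimodal; the guards' constants (`split_gap`, `tie_fraction`)
were chosen against measured separation statistics of this geometry and
are exposed for tuning on real distance distributions.

## Numerical choices and degenerate inputs

Coordinates are micrometres throughout.  Duplicate edge rows are summed
with a warning; weights below 1 are rejected.  Zero-connectivity neurons
are excluded from cosine distances with a warning rather than pinned at an
arbitrary distance.  Queries whose best two candidate types tie within
1e-9 stay unassigned.  All-zero score vectors yield empty candidate sets.
Posterior types with zero total input are dropped from normalisation.
Every stochastic stage takes an explicit seed; cohort generation derives
per-hemisphere seeds from the master seed, and the whole pipeline is
bit-reproducible under a fixed seed.

## Problem sizes

Shipped defaults run cohorts of 10-20 types (about 40-100 neurons per
hemisphere, a few thousand planted edges), 500-round noise envelopes over
3,000 edges, and 1,000-realisation dimensionality sweeps over K = 1..15 at
M up to 2,600 — sizes chosen so the full suite and the acceptance script
each complete in about a minute on a single core while every statistical
check retains enough samples to be meaningful.
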