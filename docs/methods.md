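# Methods

`spamkit` implements the analysis workflow behind spatial-arrangement
(SpAM) stimulus norming: a stimulus set is characterized by (1) how novel
each object is to participants, (2) the dimensionality and geometry of the
perceived-similarity space, and (3) the "global categories" that emerge
from clustering that space, together with how stable those categories are
under resampling of participants. Because the package ships no human data,
a synthetic participant generator with planted ground truth stands in for
the study population; every claim the test suite makes is a recovery claim
about that generator.

## Pair-covering trial designs

A trial shows `K` of the `N` objects on a canvas, so a participant's
arrangement informs only the `C(K,2)` pairs on screen. Estimating a
complete `N x N` dissimilarity matrix requires a *covering design*: a set
of `K`-object blocks in which every one of the `C(N,2)` unordered pairs
co-occurs at least once. Blocks are grown greedily — seed with a uniformly
chosen uncovered pair, repeatedly add the object covering the most
still-uncovered pairs (ties broken uniformly at random) — and the search is
restarted from independent seeds, keeping the best design. At the default
study scale (`N = 30`, `K = 16`) the generator reliably reaches 6 blocks,
the counting lower bound being `ceil(435/120) = 4`; exhaustive search in
the test suite confirms the greedy attains the true covering number for
small `n`. The restart loop doubles as the block-size sweep
(`sweep_block_size`) used to choose `K`.

Object ids are 1-based. Determinism contract: restart `r` of a search uses
`seed + r`; a design is a pure function of its parameters and seed.

## From arrangements to dissimilarities

Only final object-center coordinates matter. Within a participant-trial,
the dissimilarity of a pair is the Euclidean distance of their centers in
canvas pixels (origin top-left, y downward, default canvas 1000 x 600). A
pair measured in several trials contributes its arithmetic mean; the group
matrix is the element-wise mean over participants. Distances are kept in
raw pixels by default; `normalize_coords` divides by the canvas diagonal
first, which changes only the overall scale of a single participant's
matrix but matters once participants are averaged or compared. Both modes
are exposed because both conventions appear in practice; all shipped
analyses use raw pixels.

## Metric MDS (SMACOF) and raw stress

The group matrix `D = (d_ij)` is embedded by minimizing **raw stress**

    sigma(X) = sum_{i<j} (d_ij - dhat_ij(X))^2

where `dhat_ij` are Euclidean distances of the embedded coordinates. The
loss is deliberately un-normalized and the transform is ratio (distances
fit directly, no intercept, no monotone re-estimation): SpAM distances are
meaningful at ratio level, and the covering design guarantees a complete
matrix, so nothing weaker than metric MDS is needed. Each start iterates
the Guttman transform, `X <- B(X) X / n`, which majorizes raw stress and
therefore yields a non-increasing stress sequence — asserted per-iteration
in the tests. Defaults: `max_iter = 300`, relative stress tolerance `1e-6`,
8 random starts for a final configuration, initial coordinates uniform in a
hypercube scaled to `mean(D)`. Note the squared residuals: a signed,
un-squared sum is not a loss function, and majorization is defined on the
squared form.

### Dimensionality selection

For each candidate dimensionality the stress of a *single-start* fit is
simulated many times (default 100 replicates per dimension in the
pipeline; scree curves stabilize quickly) and averaged; the elbow of the
mean-stress scree is located with the discrete kneedle rule: min-max
normalize both axes and take the confirmed local maximum of the difference
curve `1 - x - y` at sensitivity `S = 1`, with no interpolation (the grids
are small integer grids). Near-linear curves produce no elbow and are
reported as such.

The scree grid is dims 1..10. The grid length is not cosmetic: kneedle
can only place the elbow at dimension `d` if the normalized stress drop
beyond `d` exceeds the mean grid spacing `1/(G-1)` for a `G`-point grid.
One-dimensional SMACOF fits from random starts land in severe local minima
for *any* input, so the scree's first point towers over the rest
(`s1/s2 ≈ 7-8` across every geometry we measured, including pure-noise
matrices); on a short grid (ending at 7) the resulting spacing threshold
of 1/6 exceeds the stress signal at dimension 3 (~0.13-0.16 normalized)
and the elbow collapses to 2 regardless of the data. A 10-point grid puts
the threshold at 1/9 and the planted dimensionality is recovered reliably
(10/10 and 20/20 seeds in our checks). The same reasoning fixes the
k-means grid below.

## Global categories

* **k-means** (Lloyd, k-means++ seeding, 50 restarts by default) on the
  embedded coordinates; quality is the squared-error distortion, the mean
  squared distance of objects to their assigned centroid. The cluster
  count is the kneedle elbow of the distortion curve over k = 1..20 (see
  the grid argument above: the elbow at the planted `k` needs the
  normalized distortion drop at that `k` to clear the grid-spacing
  threshold).
* **Ward agglomerative clustering** on the embedded distance matrix
  (Lance–Williams recurrence; heights in scipy's convention, the square
  root of twice the within-cluster sum-of-squares increase). Because the
  embedded distances are Euclidean by construction, Ward's variance
  interpretation is exact here. Flat partitions come from undoing the last
  `c - 1` merges.

Ranked pair tables (all `C(N,2)` pairs sorted by embedded distance, ties
in lexical `(i, j)` order) are split into quartiles by rank; when the pair
count is not divisible by 4 the earlier (more similar) quartiles take the
extra pairs, so 435 pairs split 109/109/109/108. Quartile cutoff distances
are reported alongside.

## Bootstrap stability

The resampling unit is the participant: a replicate draws `sample_size`
participants with replacement (default: the original count), averages
their matrices, re-embeds at a fixed dimensionality (reduced to 4 SMACOF
starts per replicate for tractability) and re-clusters at a fixed `k`
with both methods. Agreement is the Adjusted Rand Index; within a method
the report averages over all `C(B,2)` replicate pairs, across methods
over replicate-matched pairs (both clusterings of the same bootstrap
sample), the latter being the primary cross-method figure. All
randomness in replicate `b` derives from `(seed, b)`, so k-means and Ward
see identical resamples.

## Color-confound control

Shape norming must check that arrangement distances do not simply track
color. Object images (RGBA, transparent background) are box-downsampled
to 20 x 20 on alpha-premultiplied channels (plain RGBA resampling would
bleed the background into edge pixels); pixels with resampled alpha below
0.5 are background and dropped; the rest are converted sRGB -> XYZ (D65,
2°) -> CIELAB. A pair's color dissimilarity is the mean CIEDE2000
difference (`kL = kC = kH = 1`, hue-rotation term included) over the full
cross product of the two pixel sets, and the confound statistic is the
Pearson correlation (with `df = n_pairs - 2` and a two-tailed t p-value)
between these scores and the embedded distances. Both quantities are
dissimilarities, so a color bias appears as a *positive* r. Note that
CIEDE2000 is not translation-invariant in CIELAB (its weighting functions
depend on absolute lightness and chroma), so no shift-invariance is
claimed for the score; symmetry and pixel-order invariance are.

## Novelty and naming agreement

Per object: the **novelty rate** is the percentage of "no" answers to the
seen-before question. Free-text descriptions arrive pre-coded as concept
tokens (the package deliberately does no NLP — real studies code
manually); a synonym map collapses variants to canonical tokens, and a
response is *single-concept* when its canonical tokens reduce to exactly
one. **Identity agreement** is the modal canonical concept's share of
single-concept responses (undefined and flagged when there are none; ties
broken lexically and flagged). Summaries report mean, sample SD (n−1) and
range, flag objects more than 2 SD above the mean, and compare agreement
to a configurable 85% "known object" benchmark. Consistency between the
two novelty measures is a two-tailed Spearman correlation with average
ranks for ties and `df = n - 2`.

## The synthetic world

What the generator emulates, and the defaults that define the simulated
study (all in `WorldParams` / `BehaviorParams`):

* **Latent geometry** — 30 objects in a 3-dimensional latent shape space,
  7 planted categories with sizes between 2 and 6. Category centers are
  spread through the unit hypercube by electrostatic repulsion (so no two
  categories are accidentally easy to merge), members are Gaussian around
  their center (`cluster_spread = 0.05`), and the finished cloud is
  whitened to equal RMS spread along every principal axis: the latent
  dimensions are equally salient by construction, which is precisely the
  regime in which a dimensionality elbow is meaningful.
* **Arrangement behavior** — a participant facing a trial lays the shown
  objects out as a 2-d metric MDS solution of their *attention-weighted*
  latent dissimilarities: per participant-trial, weights over the latent
  dimensions are drawn `Dirichlet(0.5)` (scaled to mean 1), reflecting the
  individual-differences-scaling view that people attend to different
  shape features on different occasions. This is load-bearing: with equal
  weights every converged 2-d layout crushes the same (third) latent axis
  and no amount of averaging can restore it; varying weights make the
  covering design's cross-trial averaging integrate the full geometry.
  The layout is rescaled into the 1000 x 600 canvas with a 60 px margin,
  jittered with isotropic Gaussian placement noise (`sigma = 30` px,
  roughly a tenth of a typical inter-object distance) and clipped to the
  canvas. Setting `attention_concentration=None` restores the plain
  unweighted layout.
* **Naming behavior** — "seen before" is Bernoulli in a per-object
  familiarity drawn uniform on (0.31, 0.81), which yields novelty rates
  spanning roughly 19-69% with a mean in the mid-40s, the range typical
  of adult norming samples. Concepts are drawn from a per-object
  Chinese-restaurant process whose rate is `1/kappa_o` with
  `kappa_o = 0.05 * odds(familiarity_o)`: familiar objects both attract
  "yes" answers and converge on a shared name, so novelty rate and
  identity agreement are negatively coupled, as in real data. Responses
  are single-concept with probability 0.56, hybrid (two concepts) with
  0.22, otherwise uncodable; every canonical concept surfaces as one of
  two spelling variants so the synonym-collapsing path is exercised.
* **Color** — each object gets three uniformly random palette colors,
  independent of the latent geometry, and simple flat-colored RGBA images
  are rendered from them; color is null with respect to shape by
  construction.

What the generator does **not** model: drag dynamics, fatigue, anchoring
or ordering effects within a trial; icon collision/overlap constraints;
any systematic relation between color and shape; cross-participant
variation in carefulness. Passing recovery tests therefore demonstrate
that the analysis chain is correct and well-calibrated under its own
assumptions, not that human data of this shape will be as clean: with real
participants the bootstrap ARIs, for example, sit well below the ~1.0 the
noiseless-to-low-noise synthetic world produces.

## Numerical conventions and degenerate inputs

* Ties: lexical `(i, j)` order everywhere a stable order is needed
  (ranked pairs, quartiles, modal-concept ties flagged).
* Kneedle returns "not found" on flat or near-linear curves rather than
  guessing; pipeline stages then fall back to the largest grid value and
  say so in the report.
* Empty pixel sets (fully transparent images), incomplete dissimilarity
  matrices, zero-variance correlation inputs, single-replicate bootstrap
  summaries and non-covering designs all raise typed errors naming the
  offending objects rather than propagating NaNs.
* All stochastic entry points take a seed and thread it through
  `numpy.random.SeedSequence` spawns; identical seeds give bit-identical
  outputs (asserted for designs, simulations and the full pipeline
  report).

## Problem sizes used by the shipped checks

The test suite and the acceptance script run the study at its natural
scale (30 objects, 96 participants, 6 x 16 trials) but scale down
iteration counts where the full-size figures are pure repetition: stress
scree 50-100 replicates per dimension (not 1000), bootstrap 50-200
replicates (not 1000), design search 1000 restarts (as stated). These
sizes were chosen so the whole validation runs in minutes on one core
while leaving every qualitative conclusion unchanged; all counts are
parameters, and the full-size settings are a flag away.
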