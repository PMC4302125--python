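# Methods

## The hierarchical model

A segment is a window of `n` neighboring CpG sites (default `n = 4`: short
enough that typical short reads cover it fully, long enough that a pattern is
informative), and its data are the `m × n` binary matrix of methylation
states of the reads that cover all `n` sites.  Reads partially covering the
window are dropped, not imputed: the model conditions on full coverage, and
imputation would manufacture pattern evidence.  Reads are assumed to derive
from `k` latent origins (alleles or cell types); origin `l` carries a
methylation-probability vector `p_l`, each read draws its origin
independently with proportions `q`, and sites are conditionally independent
Bernoulli draws.  Bipolar methylation is the `k = 2` case — one
hyper-methylated and one hypo-methylated origin — with `q` unknown, unlike
the allele-specific setting where the origins are balanced by construction.
More complex mixtures are interpreted as combinations of bipolar segments
rather than modeled directly.

## Step 1 — DPM clustering and bipolar grouping

Reads of one segment are clustered under a Dirichlet-process mixture of
product-Bernoulli components with Beta(`a0`, `b0`) priors per site and
concentration `alpha`.  Collapsing the Bernoulli parameters gives an exact
partition score

    score = Σ_clusters Σ_sites [ log B(a0+s, b0+m_C−s) − log B(a0, b0) ]
          + K log alpha + Σ_clusters log (m_C − 1)!

so MAP search is discrete optimization over set partitions, requiring
neither EM nor MCMC.  The search runs `n_orderings` (default 10) restarts of
greedy sequential allocation in random read order, each followed by
refinement that alternates (a) single-read reassignment sweeps with cluster
death, (b) greedy pairwise cluster merges, and (c) merge-with-repair:
tentatively merging each cluster pair, re-refining, and keeping the result
only if the score improves.  One extra pass starts from the single-cluster
partition.  Moves (b), (c) and the one-cluster start exist because
single-read moves alone demonstrably stall: a three-way merge can pay while
every pairwise step loses, and on one-origin (null) data the single-cluster
partition is exactly the state such paths fail to reach.  With all moves
enabled the search matched exhaustive enumeration on 300/300 random segments
with `m ≤ 8` (Bell(8) = 4140 partitions); the test suite re-verifies 100.
Ties prefer joining the lower-indexed existing cluster over opening a new
one, for determinism.

Priors default to `alpha = 1`, `a0 = b0 = 1` (uniform), the neutral choice
in the absence of stronger prior knowledge; all are exposed in `DpmConfig`.

Clusters whose mean is site-wise ≤ δ form the hypo candidate group, site-wise
≥ 1−δ the hyper candidate group; the two candidate means are therefore
separated by at least 1−2δ at every CpG.  δ defaults to 0.35.  Reads of
non-candidate clusters join the candidate group with the nearer mean
(Euclidean); exact distance ties go to the hypo group — the conservative
direction, since it weakens apparent separation.  When either candidate set
is empty, or when `m < 10` (the genome-scan coverage floor, below which
cluster means are too noisy for a fixed δ), 2-means on the cluster means
forms the groups instead; each cluster mean counts once (a size-weighted
variant is an option), and the side with the larger overall mean is the
hyper group.  One cluster, or identical cluster means, short-circuits to
"non-bipolar, p = 1".

## Step 2 — the calibrated permutation test

The hypotheses are `H0: 0 ≤ p^(1)_i − p^(2)_i ≤ τ ∀i` against
`Ha: p^(1)_i − p^(2)_i > τ ∀i`; τ (default 0.32, motivated by the separation
observed between purified-cell methylomes) sets the margin a bipolar call
must exceed and makes the test more conservative as it grows.  The statistic
is a τ-adjusted inverse Davies–Bouldin index: between-group distance
`d* = ‖max(p̂^(1) − p̂^(2) − τ, 0)‖` (component-wise soft-thresholding, so the
statistic is non-increasing in τ) over the summed mean within-group spreads,
stabilized by `eps = 1e-8` so pure groups give a finite, maximal score.  The
null distribution permutes group identity over the reads, preserving group
sizes and recomputing means and statistic per replicate; all `C(m, |G1|)`
assignments are enumerated when that count is ≤ 5000, otherwise 999
Monte-Carlo permutations with the add-one estimator `p = (1+x)/(B+1)`
(resolution 10⁻³, never exactly 0).

Groups produced by the 2-means fallback are additionally required to exceed
the τ margin at **every** site — the literal alternative hypothesis — with
the same requirement imposed on each permuted replicate; failing it zeroes
the statistic, and a zero observed statistic short-circuits to p = 1.  This
asymmetry is deliberate: δ-candidate groups carry a built-in 1−2δ separation
certificate, whereas the fallback always manufactures two groups, even from
homogeneous data, and an optimized split of exchangeable reads otherwise
ranks near the top of its own permutation distribution.  Without the margin
requirement the false-positive rate on one-origin segments reached 0.21–0.26
at `m = 10` and τ = 0.32; with it, measured type-I error stays at 0–0.015
across the simulated designs, below the 0.05 level.  The price is power on
marginal configurations: genuinely mixed segments whose true per-site
separation dips under τ at one site are declared non-bipolar, so power
saturates below 1 even at high coverage (e.g. ≈ 0.84 at `m = 100`, balanced
mixture, τ = 0.32 — the probability that all four Beta-drawn site
separations exceed τ is about 0.83).  This trades sensitivity for
specificity relative to detectors whose clustering step splits homogeneous
segments more readily; the simulation suite quantifies both sides.

Parametric Wald/likelihood-ratio variants are an explicit stub: typical
bisulfite coverage violates their large-sample assumptions.

## The DM-CpG comparator

For paired purified samples, each CpG's methylated/unmethylated counts form
a 2×2 table tested with a two-sided Fisher's exact test;
Benjamini–Hochberg adjustment runs across the supplied sites (FDR language
implies BH, not Bonferroni).  A segment is differentially methylated iff all
`n` sites are significant at the chosen FDR *and* share the direction of
difference.  Zero-total sites get p = 1 with a warning.

## Genome scan

Segments (non-overlapping tilings of `n` consecutive CpGs by default; step-1
sliding windows optional — tiling avoids double-counting and region merging
restores contiguity) pass a coverage floor of 10 reads, then an
allele-specific-methylation filter: a segment is removed when any of its CpG
positions falls in a supplied BED interval of known imprinted/ASM CpGs,
since ASM produces the same bipolar signature as CSM.  Stage counts are
conserved (input = tested + low_coverage + asm_overlap).  Calls default to
per-segment level 0.05 with no genome-wide adjustment; BH across tested
segments is available (`mtc=bh`).  Consecutive bipolar segments merge into
regions; untested (filtered) segments neither break a run nor extend its
coordinates, while a tested non-bipolar segment does break it.  Each input
segment gets an independent RNG stream spawned from the scan seed, so
results are byte-identical across reruns and insensitive to filtering of
other segments.  Pooling samples = concatenating epiread files (read ids
prefixed per sample); coordinates are 0-based half-open throughout, with a
segment's end at the last CpG's dinucleotide end.

## Simulation suite

*Study conditions.*  Null segments draw one probability vector per replicate
with sites i.i.d. Beta(8, 8) (mean 0.50, SD 0.12 — intermediate methylation,
where bipolar false calls are most tempting); alternative segments draw
hyper sites from Beta(5.96, 0.89) (mean 0.87) and hypo sites from
Beta(0.72, 4.42) (mean 0.14), with each read hyper with probability `w`.
Coverage `m ∈ {10, 20, 100}` spans low to high sequencing depth and
`w ∈ {0.1, …, 0.5}` unbalanced to balanced mixtures.  Vectors are redrawn
every replicate, keeping replicates exchangeable.  The 16-read pattern study
plants `i` all-zero and `j` all-one reads and fills the rest uniformly over
the 14 non-constant 4-bit patterns (the minimal assumption for "random other
patterns").  The clustering comparison scores DPM MAP search, k-means on the
raw binary vectors (Lloyd's, best of 10 restarts), and a two-component
collapsed-Gibbs Bernoulli mixture (Beta(1,1) sites, Dirichlet(1,1) weights,
MAP labeling over post-burn-in sweeps) by misclassification rate: the
optimal one-to-one relabeling error (for two classes, min(err, 1−err)) when
the method emits at most as many clusters as there are origins, majority
(many-to-one) mapping when it emits more.

*Scale.*  Routine runs use 500 replicates per design cell with 199
permutations inside the detector, and 200 replicates per cell for the
clustering comparison, sized so the full suite completes on a single CPU in
minutes; Monte-Carlo standard errors `sqrt(r(1−r)/reps)` accompany every
rate.  All simulations are bit-for-bit reproducible from (design, seed) via
spawned per-replicate RNG streams.

*What the generator does not emulate.*  Real bisulfite data have uneven
coverage, bisulfite conversion failure, mapping and strand biases,
correlated neighboring CpGs within an origin, and more than two cell types.
Passing these simulations therefore demonstrates correctness of the
machinery and calibration under the stated model, not performance on any
particular methylome.

## Known limitations

- The all-site margin makes the detector strict about τ: segments whose true
  separation is below τ at even one CpG are treated as non-bipolar.  Use
  τ = 0 for a pure "two groups differ" test.
- At `m = 10`, exact enumeration caps p-value resolution at 1/C(10, |G1|)
  (≥ 1/252), so very small p-values are unreachable at low coverage.
- The DPM prior details (α, a0, b0) matter for how readily homogeneous
  segments split; defaults are neutral rather than empirically tuned.
- `k > 2` origins, read trimming/alignment, and enrichment analyses are out
  of scope.
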