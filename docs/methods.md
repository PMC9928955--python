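# Methods

This note records the models behind each stage, the parameters that matter,
what the synthetic generators do and do not emulate, and the design choices
made where the design was genuinely open.

## Synthetic omics model

Reporter abundances are log-normal around a per-feature baseline. For feature
i in sample j of region r (treatment group g):

    log2 A_ij = b_i + e_ir·[g = PME] + log2 L_j + ε,   ε ~ N(0, σ)

- `b_i ~ N(13, 1.5)` on the log2 scale (baselines near 8·10³, spanning the
  dynamic range typical of reporter-ion summaries).
- `e_ir` is the planted log2 effect: a fraction `frac_differential` (default
  0.1) of features is differential at constant magnitude `effect_size_log2`
  (default 1) with random sign; of these, `frac_shared` (default 0.5) carry
  the same effect in all four regions and the rest are exclusive to a single
  region, assigned round-robin. Non-differential features have e = 0 in every
  region, and the shared/unique masks are disjoint by construction.
- `L_j ~ U(0.5, 2)` is a per-channel loading factor emulating unequal total
  peptide amounts; total-amount normalization removes it exactly.
- `σ` (`noise_sd`, default 0.3): the emulated study does not report the
  empirical dispersion of its reporter abundances, so 0.3 log2 units is a
  convention chosen once as a realistic figure for TMT group comparisons; at
  n = 8/8 it puts a |log2 FC| = 1 effect at ≈3.3 within-group SDs, i.e. high
  but not saturating t-test power. `noise_sd = 0` is allowed and gives exact
  noiseless planted ratios.

The design (four regions; 8 PME vs 8 PSE per region, 4M:4F per group) is the
emulated study's layout. Sex is recorded per sample but not modeled as a
factor, and litter identity is metadata only (no litter variance component by
default), because the emulated analysis contrasts treatment alone. The
log-normal/additive-effect structure makes log2 abundance ratios additive and
is standard for reporter intensities; the generator does **not** simulate
PSM-level spectra, isotopic impurity, missing values, peptide-to-protein
roll-up, or sex/litter effects — so passing tests demonstrate correctness of
the statistics on well-behaved intensity data, not robustness to those
real-data pathologies.

## Differential abundance

Normalization rescales every sample column so its sum equals the mean input
column sum ("total amount, no scaling"); within-column proportions are
untouched. The abundance ratio is the ratio of arithmetic group means of
normalized abundances (not the mean of per-sample ratios), with log2 taken
afterwards. The per-feature test is a two-sided two-sample t-test; the
default is Student's pooled-variance variant (the convention of grouped
reporter-abundance exports), with Welch available by config since the choice
is not prescribed. Significance is raw p < α (α = 0.05 a priori); no
multiple-testing correction is applied at this stage, matching the emulated
workflow's filter. Degenerate features with zero within-group variance in
both groups get p = 1 when means are equal, and a 0-adjacent p with a warning
when not (the statistic is unbounded but the direction is well defined).

Hierarchical clustering of the significant set z-scores each feature across
samples and applies group-average (average-linkage) agglomerative clustering
— the efficient algorithm usually cited by the name of its author — on
correlation distance, for features and samples independently. Correlation
distance is the default because the clustered quantity is a per-feature
standardized profile; Euclidean is available. Leaf order is deterministic:
ties are broken by observation index.

## KSEA

z = (s̄ − p̄)·√m / δ with δ the **population** SD (ddof = 0) of all quantified
site log2 FCs, the convention of the standard KSEA implementation; ddof is
configurable. Only localization-confirmed sites enter. A (kinase, substrate)
pair contributed by both PhosphoSitePlus and NetworKIN counts once. The
NetworKIN score cutoff (default 0) drops map rows below threshold; the
substrate-count cutoff of 0 is interpreted as "no minimum beyond m ≥ 1",
since a kinase needs at least one mapped quantified substrate to be scored.
p-values are two-sided normal tails; FDR is Benjamini–Hochberg across the
scored kinases. δ = 0 (all sites identical) is a degenerate-data error.

## Enrichment, overlap, cosine

Term enrichment is the hypergeometric upper tail: drawing |genes| from the
universe, P(X ≥ observed) for each term's membership. The universe is the set
of genes quantified in that region's table — the only universe the pipeline
can know, and standard ORA practice for proteomics. Strength =
log10(observed/expected). FDR (BH, within category) is computed and reported,
but the significance filter is raw p < α, matching the emulated workflow.
Note the hypergeometric test is discrete: its exact null discovery rate at
nominal 0.05 is the mean attained alpha over the database's terms (≈0.040 for
realistic term-size mixes), slightly conservative by construction; the test
suite calibrates against that exact rate rather than pretending the p-values
are continuous.

Cross-region agreement: the emulated study never defines its printed "%
similar across all brain regions", so the all-region overlap is
|∩ all| / |∪ all| and pairwise overlaps are Jaccard by default, with
numerator/denominator conventions configurable (`min`, `mean`). The
reference-region-vs-rest comparison vectorizes the term (or GeneID) sets as
binary indicators and takes the cosine |A∩B|/√(|A|·|B|), where "rest" is the
de-duplicated union of the non-reference regions' sets — binary vectors are
the only weighting the underlying lists support. An empty side scores 0 (the
"no score, interpreted as zero" convention). Venn counts tally exact
membership patterns over every region subset and sum to the union size.

## Network subclustering

Edges arrive as (node, node, combined score); integer scores 0–999 are
recognized as the STRING export dialect and divided by 1,000. The
highest-confidence filter keeps score ≥ 0.9 and the graph is edge-induced, so
nodes without a surviving edge are hidden. Subclustering runs k-means
(fixed seed, n_init = 10) on the top-k eigenvectors of the symmetrically
normalized adjacency D^{-1/2} A D^{-1/2}, row-normalized — standard spectral
clustering. Whether the original STRING "kmeans" operated on the graph or on
some term-profile feature space is not recoverable; the spectral embedding is
a principled stand-in and exact replication of STRING memberships is a
non-goal. k defaults to 5 for proteome and 3 for phosphoproteome graphs.
Cluster labels come from enriching each cluster's members against all
retained nodes; the label is the maximal-strength significant term, ties
broken by smaller p then lexicographic term id; clusters without a
significant term are "unlabeled". Assignments are invariant to node input
order (nodes are processed sorted) and deterministic under a fixed seed.

## Puncta colocalization

The synthetic stack renders each punctum as an isotropic 3D Gaussian whose
FWHM equals the marker diameter (0.5 µm presynaptic, 0.3 µm postsynaptic,
inside the 0.25–0.8 µm physiological band), on anisotropic voxel grids
(defaults 0.2 µm z, 0.1 µm xy); anisotropy is handled by computing
everything in physical µm, never in voxel units. Paired pre puncta sit at a
uniformly oriented 0.1–0.4 µm offset from their post partner; same-channel
puncta keep ≥ 1 µm apart so detection can resolve them, and unpaired puncta
keep > 0.7 µm from the opposite channel so they cannot form spurious pairs.
Noise is Poisson in scaled photon counts with peak SNR = `snr`. Occluders
(nucleus spheres, axis-aligned vessel tubes) are rendered into a separate
channel and no punctum is placed inside them.

Analysis: the occluder channel is Gaussian-smoothed, thresholded (Otsu unless
a manual threshold is given), morphologically closed (with edge-padding so
closing cannot erode objects at the stack border) and hole-filled to form the
exclusion mask. The default neuropil is the imaged field minus the exclusion
mask; this presumes the postsynaptic stain tiles the field, which holds for
the synthetic data and for dense neuropil staining. A "surface" method that
builds the neuropil from the smoothed, thresholded post-masked postsynaptic
channel is provided for sparse stains.

Detection is single-scale Laplacian-of-Gaussian matched to the expected
diameter (σ = d / 2√(2 ln 2) per axis in voxels), local maxima above a
threshold, parabolic sub-voxel refinement per axis, centroids in µm, spots
outside the neuropil discarded. The automatic threshold — the surrogate for
the per-animal manual calibration of the emulated workflow — is
max(Otsu of the response, median + 10·MAD): Otsu separates blob responses
from background when blobs exist, and the MAD floor (robust to sparse bright
blobs inflating the SD, generous because LoG-filtered Poisson noise is
heavy-tailed) keeps blob-free stacks empty. Per-image manual thresholds can
be passed instead.

Pairing accepts candidate pre/post pairs with centroid distance ≤ 0.5 µm
greedily in ascending distance, each punctum used at most once — one-to-one
matching prevents double counting and is symmetric in the two channels; a
many-to-one mode exists behind config. Density = synapses / neuropil µm³.
Group comparison is a two-sided t-test with Welch's correction applied when
Levene's test rejects variance equality at 0.05 (or forced on/off).
Descriptives flag points beyond [Q1, Q3] literally (the dot-plot annotation
convention of the emulated figures); a Tukey 1.5×IQR rule is available.

## Pipeline and seeding

One global seed fans out to per-stage children via
`numpy.random.SeedSequence(seed).spawn`, with a fixed stage order, so any
stage re-run in isolation reproduces its in-pipeline output bit for bit and
identical config + seed yield byte-identical reports (the config hash
excludes the output directory). Stage failures raise a stage-tagged error
with a distinct exit code; completed outputs are retained.

## Problem sizes

The test suite and the acceptance script run everything at desk scale, chosen
as the smallest sizes at which the statistical properties are sharp: 5,000
features for null calibration (binomial 3σ within [0.04, 0.06]); 1,000
features, 10% planted, for sensitivity; 100 replicates of 1,000 sites /
50 kinases for KSEA power; 60-node planted-partition graphs over 20 seeds;
one 20×256×256-voxel stack with 200 planted pairs for density recovery; and
a 2,000-protein / 1,200-phosphopeptide 4-region pipeline run.

## Known limitations

- The generator emulates intensity-level data only; conclusions about search,
  quantification or missing-data behavior are out of scope.
- Enrichment databases are synthetic and uncorrelated with the planted
  effects, so cross-region term overlaps exercise the set arithmetic, not
  biological term structure.
- The spectral k-means stand-in will not reproduce STRING's own cluster
  memberships, only the planted community structure.
- The Imaris-style detector is a scale-matched LoG, not the proprietary spot
  algorithm; agreement is demonstrated on synthetic ground truth, not on
  acquired stacks.
- Density reproduction for the emulated study's figures would require its
  deposited per-image measurements, which are an external input, not part of
  this package.
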