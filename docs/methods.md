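# Methods

`ctrlnet` implements a complete graph-theoretic group analysis of
functional connectivity among four task-control brain systems — the
frontoparietal (FPN), cingulo-opercular (CON), cerebellar (CN) and
default mode (DMN) networks — together with a synthetic-cohort
generator that stands in for raw resting-state fMRI.  This note records
the models, the parameters that matter, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## The analysis graph

Nodes are 34 spherical regions of interest with MNI millimetre centre
coordinates and a network label; the bundled atlas
(`ctrlnet/data/control_atlas_34.csv`) fixes the node order used by
every matrix in the package.  Hemisphere is derived from the sign of
the x coordinate, with |x| ≤ 3 mm treated as midline.  An edge's
anatomical length is the Euclidean distance between sphere centres;
edges longer than 75 mm (strictly) are *long-range*, and edges joining
regions of different networks are *inter-network*.  The bundled
reference component (`hypoconnectivity_component.csv`) lists the 30
region pairs reported as hypoconnected in children with ADHD, with the
published per-edge p-values, distances and network categories.  The
published distances were computed on a 3-mm voxel grid and differ from
direct centre-to-centre distances by up to ~1.3 mm; fixture-based
checks treat the published column as authoritative, while all other
computations use exact centre distances.

## Connectivity and thresholding

Per subject, connectivity is the Pearson correlation of T×34 regional
time series; negative correlations are set to zero (rectification)
before any graph analysis, because their interpretation after global
signal removal is ambiguous.  Binary graphs are formed two ways:

* a **correlation threshold** r0 common to all subjects (absolute
  organization — densities differ across subjects), and
* a **sparsity threshold** s retaining exactly `round(s·561)` strongest
  edges per subject (relative organization at fixed wiring cost), with
  ties broken by lexicographic node-pair order so the retained edge set
  is reproducible and nested across s.

Thresholds are chosen on a 0.01 grid such that every subject's graph
keeps mean degree above 2·ln(N) (natural log, the small-world
literature's convention; the criterion is applied per subject) and no
isolated nodes: the *largest* admissible r0 and the *smallest*
admissible s.

## Topological measures

Global efficiency is the mean of 1/d_ij over ordered pairs with
1/∞ = 0 for disconnected pairs; local efficiency is the mean over nodes
of the global efficiency of each node's neighbour subgraph (nodes with
fewer than two neighbours contribute 0).  Modularity
Q = Σ_s [l_s/L − (d_s/2L)²] is maximized by Newman's spectral
(leading-eigenvector) bisection on the modularity matrix with
Kernighan–Lin-style single-node fine-tuning at each split, followed by
a greedy refinement pass that moves nodes between modules while Q
improves.  The procedure involves no randomness and is deterministic;
disconnected graphs are handled jointly (the null term uses the full
graph's degree sequence).  Nodal measures are degree, nodal efficiency
and betweenness (unordered-pair convention, matching Freeman's
definition).

Global measures are normalized by their means over 100 degree-preserving
random graphs produced by double-edge swaps (10 attempted swaps per
edge), the standard small-world reference: normalized local efficiency
above 1 with normalized global efficiency near 1 is the small-world
signature.

## Group inference

**NBS.**  Edges positive in at least 50% of all subjects enter the
analysis; edge weights are residualized on age, gender, IQ and three
head-motion summaries by pooled ordinary least squares (a
Freedman–Lane-style approximation — the covariate fit is done once,
labels are permuted afterwards); pooled-variance two-sample t statistics
(signed controls-minus-patients) are thresholded at one-tailed p < 0.05
in the hypothesized direction (controls > patients by default;
two-sided and reversed tails are configurable).  Connected components
of the supra-threshold graph are the candidate effects, and their
family-wise-corrected significance comes from permuting group labels
(10,000 by default) and recording the maximal component size.  Two
p-values are reported per component: the published convention (the
proportion of null maxima strictly larger than the component size M),
and the add-one estimator (1 + #{null ≥ M})/(n_perm + 1).  The size
statistic is a small integer, so ties between M and null maxima are
common and the strictly-larger convention is measurably
anti-conservative (family-wise rate ≈ 0.08 at nominal 0.05 on null
cohorts in our simulations, versus ≈ 0.04 for the add-one rule);
significance decisions therefore use the add-one p-value.

**Distance profile.**  A component is profiled by its long-range and
inter-network edge shares, a pooled-variance t-test of its edge
distances against the remaining pairs (30 vs 531 in the reference
component), and a resampling null: random edge sets *constrained to be
connected and to match the component's edge and node counts*, drawn by
growth sampling — start from a uniform random edge, repeatedly add a
uniform random unused edge incident to the current node set, reject and
restart unless the final node count matches.  The growth sampler is not
exactly uniform over all connected (m, n) subgraphs; an exhaustive
enumerator is provided for tiny universes to quantify the bias, and the
sampler provably satisfies the (m, n, connected) contract on every
draw.  The sampling universe is all 561 region pairs by default (the
30-versus-531 arithmetic implies the complete pair set), configurable
to any restricted edge list.  The empirical p is the fraction of null
mean distances strictly above the observed mean.

**Topological measures.**  Per-metric permutation tests mirror the NBS
covariate handling: residualize, permute labels (exhaustively when the
label arrangements are few), compare the observed controls-minus-
patients mean difference to the null.  The one-tailed p uses the
add-one convention and the null's 95th percentile is reported as the
critical value.  Nodal metrics are corrected across the 34 nodes by
Benjamini–Hochberg FDR.

**Brain–clinical correlation and ROC.**  Rank partial correlation
transforms x, y and every covariate to average ranks, residualizes the
ranked x and y on the ranked covariates, and correlates the residuals
(t-approximation p on n − k − 2 df); without covariates this reduces
exactly to Spearman's rho.  ROC analysis uses the tie-corrected
Mann–Whitney AUC, a label-permutation p for the AUC, and a Youden-
optimal cutoff (smallest cutoff on ties); patients are classified
positive when the score falls *below* the cutoff, the hypoconnectivity
direction.  The ROC is in-sample, as a preliminary biomarker assessment,
not a cross-validated classifier.

## The synthetic cohort generator

The generator emulates post-preprocessed regional BOLD time series for
46 patients and 31 controls, 230 volumes each.  Its target
cross-sectional correlation has network-block structure: 0.45 within
networks, 0.15 between, unit diagonal.  A *planted component* — by
default a connected set of 30 edges spanning 26 nodes drawn
deterministically from the long-range inter-network pairs — carries the
group effect: its control-group correlation is `planted_base_r = 0.55`
before nuisance regression, reduced by `effect_delta = 0.25` in
patients.  This baseline is deliberately above the generic
between-network level because the planted component emulates
connections *present in most participants but weakened in patients*;
edges whose patient-group correlation sat at or below zero would be
eliminated by the 50% positive-prevalence rule before the NBS could
ever see them.  Planting violates positive-definiteness of the block
matrix (the planted edges close triangles inconsistent with the
background), which is repaired by clipping eigenvalues at 1e-6; the
repair compresses the realized control-minus-patient difference on
planted edges to ≈ 0.20.

Two inter-subject variability scales act on the planted edges and were
fixed while establishing the study conditions: a per-subject scalar
offset shared by all planted edges (`subject_sd = 0.08`, the
component-level individual differences that clinical scores couple to)
and independent per-edge heterogeneity (`edge_sd = 0.12`).  Together
with the T = 230 sampling noise they put single-edge group effects at
t ≈ 3–4 for the default group sizes — the moderate-effect regime
implied by the published per-edge p-values (0.002–0.048), in which
detection genuinely requires component-level aggregation — while the
30-edge component mean still separates the groups strongly at the
subject level (AUC ≈ 0.9).

Each subject's series are built as AR(1) innovations (lag-1
autocorrelation 0.3, a coarse stand-in for band-pass filtering) mixed
through the Cholesky factor of the subject's covariance, after which
the subject's mean regional signal is regressed out of every series
(`global_signal_regression = True`), as resting-state preprocessing
does.  This step matters twice over: it recentres the correlation
distribution near zero, producing the negative correlations that
rectification then removes, and it eliminates the shared global
fluctuation that would otherwise let hundreds of edges cross the NBS
primary threshold en bloc under label permutation, inflating null
component maxima several-fold beyond anything seen in published NBS
analyses.

Covariates are drawn from pooled distributions identical in the two
groups (age ≈ N(8.6, 1.8²) years in 6–13, IQ ≈ N(119, 12²) in 80–145,
78% male, three plausible head-motion summaries) — so any group
difference in them is sampling noise, as in the matched study design.
Clinical scores (hyperactivity index, impulsivity, 0–3 scales) are
elevated in patients, and in patients only they are coupled with
correlation ρ = 0.4 to the subject's shared planted-edge offset, so
measured component strength and symptom scores correlate positively.

What the generator does **not** emulate: raw image acquisition and
preprocessing, motion spikes and scrubbing, physiological noise,
spatial autocorrelation between neighbouring ROIs beyond the network
blocks, site effects, and any non-Gaussianity of BOLD.  Passing tests
on synthetic cohorts therefore demonstrate that the *analysis chain* is
correct and calibrated under the stated generative model, not that the
biological findings would replicate.

## Numerical choices and degenerate inputs

* Correlation thresholding uses strict inequality (weight > r0);
  sparsity uses banker's rounding of s·N(N−1)/2 and errors if more
  edges are requested than positive weights exist.
* Zero pooled variance in a t-test yields t = 0 with a warning;
  constant time series are rejected by name.
* Permutation indicator sets fall back to exhaustive enumeration (with
  a warning) when the requested count reaches the number of distinct
  label assignments; exact p-values are then reported.
* The covariance repair refuses to move any entry by more than 0.15
  (group targets) and reports the offending eigenvalue.
* The growth sampler aborts after 10⁶ rejections; infeasible
  (m, n) requests are detected up front from n−1 ≤ m ≤ n(n−1)/2.
* Pipeline stages derive their seeds from the global seed as
  (seed·1000003 + stage index) mod 2³¹, so any stage can be rerun in
  isolation with an identical stream.

## Problem sizes used by the test suite and acceptance script

Oracle equivalence uses 200 random graphs with up to 12 nodes and
exhaustive modularity search up to 10 nodes.  Calibration experiments
use 500 null cohorts of 20+20 subjects with 1,000 permutations, and 20
planted-effect replicates at the default 46+31 with 1,000 permutations
and 1,000 resampling draws; the library defaults remain 10,000.  These
sizes keep Monte-Carlo error comfortably inside the asserted bands
while letting the whole suite run on one CPU in minutes.

## Known limitations

* The growth sampler's non-uniformity over connected subgraphs is
  unquantified for the full 34-node universe (the exhaustive reference
  is only feasible for tiny universes).
* Covariate control by pooled residualization before permutation is an
  approximation; full Freedman–Lane permutation of residuals under the
  reduced model would be more exact.
* The spectral modularity optimizer guarantees no global optimum;
  tests bound its gap at ≤ 5% of the exhaustive optimum on small
  graphs only.
* Degrees of freedom for edgewise t statistics ignore the covariates
  already regressed out (as in common NBS practice); the permutation
  calibration absorbs the small miscount.
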