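# Methods

## Problem

Constructing a functional connectome from parcellated BOLD time series
involves a chain of choices — global signal regression (GSR), the node set,
the connectivity measure, the edge filtering scheme, binarisation — and
different choices can yield very different network topologies from the same
data. `connectobench` implements an end-to-end evaluation of this
construction grid: every pipeline is run over multi-session cohorts, the
resulting networks are compared with the Portrait Divergence, and each
pipeline is scored against five suitability criteria (low test-retest
divergence; sensitivity to a known condition contrast; discrimination of
individuals; independence from head motion; non-empty networks).

## The pipeline grid

The full grid is 2 (GSR) x 4 (node-set type) x 3 (node count) x 2
(connectivity measure) x 8 (filter) x 2 (binarisation) = 768 pipelines.
For synthetic cohorts the node-set axes are metadata: every synthetic node
set is statistically exchangeable, so the benchmark collapses the grid to
the 32 edge-stage combinations (measure x filter x binarisation) that
differentiate pipelines on such data.

Filtering schemes: absolute thresholds at 0.3 and 0.5; fixed density at
5/10/20%; structural density matching (SDM), which takes the target density
as a parameter (`sdm_density`, default 0.25 for ~100-node networks) because
deriving it from a diffusion-MRI connectome requires external data;
efficiency cost optimisation (ECO), operationalised as a proportional
threshold enforcing mean degree 3, with the objective J = (E_g + E_l)/rho
recorded for diagnostics; and orthogonal minimum spanning trees (OMST).
Negative weights are zeroed before every filter so "strongest edges" is
well defined on a non-negative scale; weighted path lengths use the
distance transform d = 1/w throughout (Brain Connectivity Toolbox
convention).

OMST iterates edge-disjoint minimum spanning trees on d = 1/w, evaluating
the global cost efficiency GCE = E_g - Cost on the union after each round
(Cost = selected weight / total positive weight) and returning the
GCE-maximising union, capped at floor((N-1)/2) rounds. On the smooth
correlation matrices the generator produces, the GCE typically peaks after
one or two rounds, so OMST networks are sparse (density near tree density)
but, unlike the MST baseline, can close triangles. Whether GCE is evaluated
per whole tree or per added edge differs between published variants; the
per-tree rule is the documented choice here.

Proportional thresholds round half away from zero and break weight ties by
the lexicographically smallest node pair, making every filter deterministic.

## Connectivity measures

Pearson correlation is the product-moment coefficient over the full session.
Mutual information uses an equal-width histogram plug-in estimator with
`ceil(sqrt(T/5))` bins bounded to [8, 32] (natural log). The estimator is
invariant to affine transforms of either series but not to general monotone
transforms (equal-frequency binning would be; it is not used here). Each
session's MI matrix is rescaled to [0, 1] by its maximum value taken over
the full matrix including the diagonal self-informations I(X;X) = H(X).
Since pairwise MI never exceeds the larger marginal entropy, normalised
edge weights reach 1 only for a pair matching the largest binned entropy;
weakly dependent data can fall entirely below an absolute threshold at
0.3/0.5, leaving an empty network — the failure mode criterion V exists to
catch.

## Portrait Divergence

The portrait of a binary network is the matrix B with B[l, k] = number of
nodes having exactly k nodes at shortest-path distance l, for l = 0..L
(L = diameter); it is a graph invariant. The divergence between two
networks is the Jensen-Shannon divergence, with base-2 logarithm so the
value lies in [0, 1], between the distributions

    P(k, l) = (B[l, k] / N) * (sum_k' k' B[l, k']) / (sum_c n_c^2),

where n_c are connected-component sizes. Conventions: 0 log 0 = 0; cells
where the mixture is zero contribute nothing; k = 0 columns are retained
(they receive no probability mass but keep row sums equal to N); infinite
distances never enter rows l >= 1, and the component-size term normalises
P(l) exactly. Graphs of different sizes are compared by zero-padding the
distributions to a common shape.

For weighted networks the shells are n_bins equal-width bins (default 50)
spanning (0, D] where D is the pooled maximum finite distance of the two
networks being compared — a shared support is required for the divergence
to be well defined; the self-distance shell is kept as row 0 so the
distribution still normalises through the component-size term. Pooling the
two graphs' distances (rather than binning each graph on its own range) is
the documented choice.

## Synthetic cohorts

The generator emulates the statistical structure the evaluation criteria
probe, not BOLD physiology. Region series are i.i.d. draws from a zero-mean
multivariate normal whose correlation matrix has a module structure:
`within_strength` (default 0.5) inside modules, `between_strength` (0.1)
across, 4 modules over 40 nodes. Defaults for dimensions follow typical
resting-state acquisitions: 200 samples per session, 15 subjects per
cohort; benchmark cohorts use 25/18 (retest) and 15/16 (condition)
subjects, the sample sizes of representative public test-retest and
anaesthesia studies.

* Subject identity: each subject's correlation matrix is the base plus a
  random symmetric perturbation whose entries have SD `subject_effect`
  (default 0.3), projected back to a unit-diagonal SPD matrix by eigenvalue
  clipping at 1e-6. The unit is the per-edge SD of the subject-specific
  deviation, chosen so the default sits in the empirically typical range of
  inter-subject FC variability (~0.1-0.3 per edge).
* Condition contrast: the perturbed session's matrix is
  (1-e) C + e M, where M is compound-symmetric at C's mean off-diagonal —
  a pure attenuation of modular contrast, with e = `condition_effect`
  (default 0.5). This changes topology at all scales without rotating the
  node set.
* Session noise: additive white noise with SD `session_noise` (default
  0.5, i.e. noise variance 25% of unit signal variance).
* Motion: each session draws a mean framewise displacement from a normal
  (mean 0.15 mm, SD 0.08 mm) truncated at zero; the noise SD becomes
  `session_noise + motion_coupling * (FD - 0.15)`, clipped at zero. With
  `motion_coupling = 0` motion is pure metadata (the null case for the
  motion criterion); coupling 3 — noise SD rising ~0.24 per FD standard
  deviation — is the "strong coupling" regime used in the power checks.

RNG streams are derived per (seed, subject, session) by hashing the labels,
so cohorts are bit-reproducible and independent of iteration order.

What the generator does not model: haemodynamics, temporal autocorrelation,
scanner drift, physiological noise spectra, spatially structured motion
artefacts. Passing criteria on this benchmark therefore demonstrates that
the evaluation machinery detects the intended effects under a
linear-Gaussian idealisation, not that any pipeline is optimal for real
fMRI.

## Evaluation design

* Criterion I (spurious differences): pipelines are ranked by group-mean
  test-retest PDiv within each retest dataset (rank 1 = lowest, average
  ranks on ties); the global rank is the mean across datasets; the pass cut
  is the top 20% (boundary inclusive), with a 50% relaxed variant also
  reported.
* Criterion II (condition contrast): Welch two-sample t between the
  reference retest cohort's PDiv list and each condition cohort's
  awake-vs-perturbed PDiv list, signed so negative t means the condition
  contrast is larger; significance by label permutation (add-one corrected,
  two-sided) at alpha 0.05, required in the expected direction in every
  condition dataset. The two lists come from independent cohorts: the
  within-cohort alternative (same subjects in both lists) makes the
  unpaired permutation test conservative (~2% null rejection measured vs
  5% nominal) and was rejected.
* Criterion III (individual discrimination): per subject, within-subject
  PDiv (rest1 vs rest2) against the mean of rest1 vs other subjects'
  rest2 (cross-session pairing keeps the temporal offset comparable); pass
  needs the within < between proportion >= 0.5 in every retest dataset.
  Because PDiv compares unlabelled topology, two subjects with different
  edge weights but similar network structure can legitimately look alike,
  so proportions near (not at) 1 are expected even for strong identity
  effects.
* Criterion IV (motion): Spearman correlation between per-subject retest
  PDiv and |delta mean FD|, two-sided t-approximation p, uncorrected, fail
  on p < 0.05 in any retest dataset; degenerate (constant) inputs count as
  a pass with an undefined coefficient.
* Criterion V: fail on any empty network in any retest dataset.

The enrichment test asks how likely a random optimal-set-sized subset of
the 768 pipelines is to place >= m members in a single edge-stage group
(32 groups of 24). Sampling uses the multivariate hypergeometric
distribution over group sizes, which is exactly equivalent to drawing the
subset without replacement; for m > k/2 the per-group events are disjoint,
so the exact answer is the hypergeometric tail sum over groups, used as an
independent cross-check of the Monte-Carlo estimate.

## Numerical choices and degenerate inputs

SPD projections clip eigenvalues at 1e-6 and renormalise the diagonal.
Constant columns are rejected at load and by both connectivity measures.
GSR requires T > 2 and a non-constant global signal; applying it twice
changes nothing (to 1e-10). Empty networks are flagged, not fatal, and
excluded subject-wise from PDiv lists so criterion V (not an exception)
reports them. Permutation p-values use the add-one correction, so the
smallest attainable p with 999 permutations is 1e-3.

## Problem sizes

The bundled benchmark and test suite run at desk scale: 20-40 node
networks, 100-200 timepoints, cohorts of 10-25 subjects, 32-pipeline
grids, 50-400 replicates for the power and calibration studies, and 1e6-1e7
Monte-Carlo draws for the enrichment test. These sizes were chosen so the
whole study re-runs from scratch on a single CPU while keeping every
statistical check adequately powered.

## Known limitations

* The spatial node axes (parcellation type/size) are pure metadata for
  synthetic cohorts; conclusions about parcellation choice require real
  data.
* The MI estimator's histogram bias is not corrected; it is adequate for
  ranking edges, which is all the filters need.
* SDM's structural target density is a user parameter, not derived from a
  structural connectome.
* OMST's published implementations differ in the granularity of the GCE
  optimisation; results can differ in density by one tree.
* The weighted-portrait binning (pooled-range equal-width) is one of
  several defensible conventions; divergence values are comparable only
  within a fixed convention.
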