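# Methods

## Pipeline overview

The analysis treats each subject's windowed functional connectivity as a
temporal multilayer network and asks how nodes change community membership
over time.  Stages: motion quality control → sliding-window Fisher-z
connectivity → multilayer modularity ensembles → connection-stability and
nodal reconfiguration metrics → three-group statistics and covariate-
adjusted correlations → MHE-vs-noHE discrimination.

## Windowed connectivity

Windows are rectangular (no taper), length and step in TR units, 1-based
inclusive volume indices; trailing volumes that do not fill a window are
dropped, so `T = floor((n_volumes − length)/step) + 1` (190 volumes at
length 45, step 1 → 146 windows).  Within each window the pairwise Pearson
correlation is Fisher z-transformed with |r| clipped to `1 − 1e−7` first:
synthetic data can produce exactly collinear node pairs, and the clip keeps
z finite without affecting realistic values (the clip changes z only beyond
|r| ≈ 0.9999999).  A node that is constant within a window leaves r
undefined and is treated as a hard input error rather than silently
imputed.  Defaults: window 45 TR, step 1 TR, TR 2.5 s.

## Multilayer modularity

The quality function combines per-layer Newman–Girvan terms at resolution
γ with an inter-layer coupling ω between copies of the same node.  Two
conventions had to be fixed where the formulation leaves room:

- **Coupling topology.** Coupling is *ordinal* — only adjacent layers are
  coupled, uniformly with strength ω.  All-pairs coupling would make the
  coupling term scale quadratically in the number of layers and swamp the
  intra-layer structure; the adjacent-layer convention is the established
  temporal reading and is what standard generalized-Louvain toolboxes
  implement.
- **Normalization.** `2μ` sums every copy's intra-layer strength plus its
  coupling strength, `2μ = Σ_js k_js + 2ωN(T−1)`, so Q is comparable
  across ω and reduces exactly to single-layer modularity at ω = 0 or
  T = 1.  The ordered-pair sum includes the `i = j` intra-layer null term,
  giving the textbook value Q = 1/2 for a single layer of two disconnected
  dyads split into its two natural modules.

Negative Fisher-z entries (anticorrelations) are zeroed before
optimization: the Newman–Girvan null is ill-behaved on signed weights, and
zeroing is the common practice with this family of methods.  A layer with
no positive weights leaves the null model undefined (`m_s = 0`) and is an
error.  Consequently a 1-node layer cannot be built at all — the null
model needs at least one edge — so the degenerate "single node" case is
rejected at construction rather than special-cased in the optimizer.

### Optimizer

`louvain_run` is a seeded generalized Louvain:

1. **Copy-level greedy phase.**  Node-layer copies are swept in a fresh
   uniform-random order per sweep (from the run's seed); each copy moves to
   the module with the largest modularity gain, computed from the implicit
   layer stack (the dense supra-modularity matrix is never formed, keeping
   memory at O(N²T)).  Candidates include a fresh singleton module.  Ties
   keep the current module, otherwise the lowest module id wins —
   determinism given the seed.  A move must improve Q by more than 1e−10.
2. **Aggregation.**  Modules are contracted into a reduced dense
   modularity matrix `B'_cd` (block sums of intra-layer and coupling
   terms) and the greedy phase repeats on supernodes until no aggregation
   level improves.
3. **Iterated refinement.**  Control then returns to the copy level and
   steps 1–2 repeat from the current partition until a full cycle gains no
   Q.  This matters in practice: from a singleton start with ω ≈ 1 the
   first greedy phase tends to converge to a fragmented local optimum, and
   a single aggregation pass then cannot move individual copies between the
   coarse modules.  With refinement, the optimizer recovers planted
   5-module structure reliably and matches exhaustive search on small
   graphs (the test suite requires ≥ 95% agreement on 200 random instances
   with ≤ 8 copies; observed agreement is typically 100%).

Greedy moves are accepted only for positive gains, so Q is monotone within
a run; each sweep is capped (100) to flag pathological inputs.  Ensembles
(default 100 runs; scaled studies use fewer, see below) derive per-run
seeds from a master `SeedSequence`, so results are independent of
evaluation order.

## Nodal metrics

Connection stability, flexibility, disjointness and cohesion are computed
per run and averaged across the ensemble; no cross-run label alignment is
needed since every metric is label-permutation invariant.  Decisions where
the verbal definitions were ambiguous:

- A change is **cohesive** only when source *and* destination modules
  match another mover's at the same transition (the Telesford-style
  convention); same source with different destinations is disjoint.
- **Cohesion strength** is a node strength — the number of partner nodes
  summed over transitions — normalized by (T−1) to be commensurate with
  flexibility; raw counts are also kept.
- Disjointness is normalized by (T−1), so per run
  `flexibility·(T−1) = #disjoint + #cohesive` and disjointness ≤
  flexibility; both identities are asserted in the tests.
- The connection-stability diagonal is fixed at 1 (a node is always with
  itself).
- Network-level stability averages over within-network node pairs (i < j);
  a single-node network has no pairs and is reported missing rather than 0.

## Motion QC

Framewise displacement follows the Power convention: the sum of absolute
framewise differences of the six rigid-body parameters with rotations
(radians) converted to arc length on a 50 mm sphere.  The exclusion
thresholds (mean FD > 0.2 mm, |translation| > 2 mm, |rotation| > 2°) are
strict inequalities; boundary values pass.  The FD variant is not uniquely
determined by the thresholds alone, but 0.2 mm is the Power-FD working
point, so that variant was adopted.  Subjects without motion files are
kept and logged, never silently imputed.

## Group statistics

MHE labeling regresses NCT-A and DST on age and education in HC only
(residual SD with n − 3 denominator) and flags a patient at > 2 residual
SDs in the impaired direction (DST below, NCT-A above prediction) on
either test — the standard psychometric-norm reading of a "2 SD" rule.
Group comparisons are tie-corrected Kruskal–Wallis per unit with pairwise
two-sided Mann–Whitney post hocs gated on omnibus p < 0.05; BH-FDR runs
across the units of one family (all networks, or all nodes, per metric).
Partial correlations are residual Pearson correlations (OLS with
intercept) with t-based p at df = n − #covariates − 2; the head-motion
covariate is the scalar mean FD (six separate regressors would spend five
extra degrees of freedom on n ≈ 60 patients).

## Discrimination

F-score uses sample variances (n − 1); zero pooled variance with unequal
means yields an infinite score, ranked first and logged.  LOOCV refits the
F-score ranking and the z-scoring inside every training fold (the test
suite checks that scrambling a held-out row cannot change that fold's
selection).  The SVM is C = 1 with RBF kernel of width 1/k (the
library-default `gamma='auto'` convention on the selected feature count);
a linear kernel is available via configuration.  ROC points come from a
threshold sweep over the decision scores; the trapezoid AUC equals the
Mann–Whitney U statistic over n⁺n⁻ (verified against pair counting).  The
permutation test reruns the entire LOOCV — selection included — under
shuffled labels and reports the add-one estimator, which never returns 0.
The feature budget k defaults to 23 (capped at the feature count); a
`select_k` helper scans a grid by mean LOOCV accuracy.

## Synthetic cohorts

The generator plants everything downstream stages must recover:

- **Signal model.**  Per epoch, each module has one latent standard-normal
  driver per volume plus a global driver; a node's signal is
  `c·global + a·driver + b·noise` with coefficients solved from the target
  correlations (within r = 0.6, between r = 0.1, noise SD 1).  Empirical
  block correlations match the targets to ±0.05 on long series (tested).
- **Switching.**  Epochs of 30 volumes; at each boundary a node makes a
  disjoint move with probability 0.05, and each module spawns a two-node
  cohesive move with probability 0.15.  Moves persist.  Destinations are
  sampled so no two events at a boundary share a (source, destination)
  pair, keeping planted event kinds unambiguous; ground-truth counts are
  derived from the planted label sequence with the same
  source-and-destination rule the metrics use, so they are consistent with
  the schedule by construction.
- **Group effect.**  MHE-like subjects get +0.3 disjoint-move probability
  on ten designated nodes inside the DMN/FPN/VAN-like networks.  DST and
  NCT-A are linear in age, education and the subject's mean planted
  disjointness over those networks (slopes −110 and +280, noise SD 5–6),
  chosen so group means and spreads resemble a realistic HC/noHE/MHE
  cohort (HC DST ≈ 43, MHE DST ≈ 30; HC NCT ≈ 42, MHE NCT ≈ 75) and the
  2-SD labeling rule separates the groups.  Blood ammonia (patients only)
  increases with the same quantity.
- **Default study conditions.**  41 HC / 32 noHE / 30 MHE (103 subjects),
  40 nodes in 5 equal networks, 150 volumes at TR 2.5 s, analysis windows
  of 30 TR at step 30 so one window per epoch — boundaries aligned to
  window strides make planted changes exactly recoverable when modules are
  recovered.

What the generator does **not** emulate: hemodynamic response convolution
and autocorrelated BOLD noise, scanner drift and physiological spectra,
head-motion artifacts in the series (motion traces are generated for the
QC path but are independent of the signal), spatially heterogeneous module
sizes, and 264-node scale.  Passing the planted-recovery tests therefore
demonstrates that the pipeline's inference chain is correct under its own
assumptions, not that the specific clinical effect sizes reported on real
patients would reproduce — the real cohort's scans are not available, and
no numeric claim is tied to them.

## Problem sizes in tests and the acceptance script

The package's own validation runs at deliberately scaled sizes: partition
ensembles of 20 runs per subject for the 103-subject default study,
10-run ensembles for the small-graph oracle comparison (200 instances with
≤ 8 node-layer copies against exhaustive search), 2-run ensembles for the
null-calibration suite (6 independent zero-effect cohorts of 30 subjects,
T = 21 layers, 240 Kruskal–Wallis units), and a 200-permutation
classification null.  These sizes give stable pass/fail behavior for the
stochastic properties (rank correlation > 0.8, enrichment p < 0.01,
accuracy above the null's 95th percentile, rejection rate inside the
binomial band around 0.05) while keeping a full run in minutes on one CPU.

## Known limitations

- The optimizer is a local heuristic; on larger graphs the ensemble best
  is a local optimum (acknowledged in the oracle test's 95% criterion).
- Signed (two-null) modularity is not implemented; anticorrelations are
  zeroed.
- Consensus clustering across runs is deliberately absent — all reported
  metrics are run-averaged, label-permutation-invariant aggregates.
- `select_k`'s grid scan reuses the same LOOCV folds it reports on; for
  unbiased k selection use a fixed a-priori k (the default) or nest it in
  an outer validation loop.
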