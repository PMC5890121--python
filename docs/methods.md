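# Methods

This note documents the models and procedures `ernet` implements, the
choices made where the design was genuinely open, what the synthetic cohort
generator does and does not emulate, and the numerical conventions. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Analysis chain

The pipeline reproduces a resting-state functional-connectivity analysis
relating trait emotion-regulation strategies to brain-network efficiency:

1. **Connectivity.** For each participant, the Pearson correlation between
   every pair of regional BOLD time series, Fisher-transformed
   (z = arctanh r). Sample correlations are clipped to ±(1 − 10⁻⁶) before
   the transform so collinear synthetic inputs stay finite.
2. **Threshold sweep.** Binary undirected graphs at 15 Fisher-z thresholds,
   0.15 to 0.85 in 0.05 steps. An edge requires z *strictly* above the
   threshold (the strict convention is fixed for determinism); thresholds
   are positive, so negative correlations never form edges and no absolute
   value is taken.
3. **Small-world screening** on the *group-average* z matrix, per network ×
   threshold: the cell enters later analysis only if (a) the small-world
   property is estimable, mean degree k > log n (natural log — the
   convention of the small-world literature; the base is configurable), and
   (b) it is present, σ = γ/λ > 1 strictly, with γ = C_net/C_ran and
   λ = L_net/L_ran against an ensemble of degree-preserving (double-edge
   swap) null graphs (defaults: 100 nulls, 10 swap attempts per edge,
   per-null seeds derived as seed + index).
4. **Global efficiency** per participant for each included cell:
   E_glob = mean over unordered pairs of 1/d(i,j), with unreachable pairs
   contributing 0 (the Latora–Marchiori "average inverse shortest path
   length"). The alternative reading, "inverse of the average shortest path
   length", coincides on well-connected graphs but differs on disconnected
   ones; it is available behind `efficiency_definition: inverse-mean` for
   sensitivity checks. L averages over reachable pairs only and is
   undefined on edgeless graphs.
5. **Structural equation model** per included cell: latent ES (4 items) and
   CR (6 items) factors; efficiency regressed on ES, CR, age, gender and
   the summed 9-item negative-affect (NA) score; all exogenous variables
   covary freely; all observed variables z-standardized internally;
   standardized solution reported. A configuration flag drops the NA
   covariate (the supplementary variant).
6. **Reporting.** Per strategy, a grid of standardized β and
   Bonferroni-corrected p over thresholds × networks, with excluded cells
   printed `N\A`. The correction multiplies raw p by m = 10 (the ten
   subnetworks); the whole-brain network is corrected with the same m and
   its raw p is also available in the tidy output, since its membership in
   the family is ambiguous. "Significant" means corrected p < 0.05;
   "marginally significant" is operationalized as corrected p ∈ [0.05, 0.10).

## SEM estimation

No SEM library is part of the dependency set; the engine is a normal-theory
maximum-likelihood covariance-structure fit written on numpy/scipy:

* Discrepancy F(θ) = ln|Σ(θ)| + tr(SΣ⁻¹) − ln|S| − p, minimized by L-BFGS-B
  with analytic gradients (verified against finite differences in the test
  suite). Factor scale is identified by marker indicators (es1, cr1 fixed
  at 1); the 5×5 exogenous covariance is parameterized by its Cholesky
  factor so it stays positive definite; unique variances are bounded below
  at 10⁻⁶. Starting values come from inter-item covariances; the fit is
  deterministic given the data.
* Standard errors: inverse observed information of F, scaled by 2/(n−1);
  delta method for the standardized solution; Wald z-tests for the
  structural coefficients. The optional "robust" flag applies a first-order
  sandwich correction built from per-observation scores — point estimates
  are unchanged. (Exact Mplus-style MLR scaling factors are not reproduced;
  only the estimator family is.)
* Fit indices: T = (n−1)F_min against df = p(p+1)/2 − q; CFI and TLI
  against the independence baseline (F_b = −ln|R|); RMSEA =
  √(max(T−df,0)/(df(n−1))); SRMR over standardized residuals including the
  diagonal. `fit_acceptable` applies the conventional cutoffs CFI ≥ .90,
  TLI ≥ .90, RMSEA ≤ .08, SRMR ≤ .08.
* Degenerate inputs: a zero-variance outcome or a non-positive-definite
  sample covariance raises an explicit error; non-convergence is flagged on
  the result, not raised. Ordinal 1–7 / 1–5 items are treated as continuous
  indicators under ML, the standard practice for this instrument.

The engine's measurement side is cross-checked in the tests against
statsmodels' independent ML factor analysis, and against exact recovery on
model-implied covariance input; its calibration (type-I rate of the ES test
at nominal .05) is verified by simulation.

## Synthetic cohort generator

The generator emulates the *statistical* structure the analysis assumes, so
every downstream stage is testable without imaging data:

* **Design constants.** 48 participants by default; 230 retained volumes
  per participant (mirroring 240 acquired minus 10 discarded); the
  264-region parcellation with 10 subnetworks (and 37 unassigned regions
  participating only in the whole-brain network). The bundled parcellation
  fixture carries published MNI coordinates, but its node-to-subnetwork
  labels are a synthetic assignment with the published per-network counts —
  the node-level membership list of the 10-network reduction is not
  redistributable here, and no analysis in this package depends on which
  specific node carries which label.
* **Questionnaire model.** Latent ES, CR and NA are independent standard
  normals (the emulated cohort reported no ES–CR or ES–NA correlation).
  Each item is loading·latent + residual (default loading 0.8), mapped to
  its ordinal scale by an affine shift, rounding and clipping (ES items
  centred near 3, CR near 5 on 1–7; NA items near 2.2 on 1–5, so the
  summed NA score sits near 20). Round-and-clip was chosen over threshold
  grids for simplicity; item marginals are documented by the defaults
  above. Age ~ rounded N(22.77, 1.59²) clipped to 18–30; gender ~
  Bernoulli(13/48), 1 = male.
* **Connectivity model.** A participant's regional time series are i.i.d.
  multivariate-normal volumes with a block-structured correlation target:
  between-network entries at ρ_b = 0.08, and within-network entries that
  decay with distance between the network's nodes arranged on a ring
  (Gaussian kernel on chordal distance, peak ρ₀ = 0.7 for nearest
  neighbours, length scale 0.8). Uniform within-network blocks would be
  degenerate for this pipeline: after group averaging, every pair in a
  block crosses a threshold together, densities jump between 0 and 100%,
  and thresholded subgraphs are either complete or empty — so σ > 1 can
  never hold and no cell would ever be included. The ring-kernel
  heterogeneity preserves the block-mean semantics while giving thresholded
  group graphs a lattice-with-shortcuts topology: high clustering, graded
  density, σ > 1 at low thresholds, and estimability failing progressively
  at high thresholds — the qualitative regime the screening procedure was
  designed around.
* **Trait effect.** For each affected network the whole within-network
  block of the participant's target correlations is shifted by
  β_conn · es_latent (default map: FPN at −0.06 per SD of latent ES), then
  clipped to [0.05, 0.95]. The effect is injected on *connectivity*, never
  on efficiency directly, so a negative trait–efficiency association must
  emerge through thresholding and graph metrics — the full causal chain.
  The magnitude −0.06 is chosen for testability; the real study reports no
  connectivity-level effect size to match.
* **Not emulated:** temporal autocorrelation (volumes are white noise —
  correlation estimates depend only on cross-regional covariance, though
  this makes the effective sample size per correlation optimistic relative
  to real BOLD), hemodynamics, motion and scanner artifacts, negative or
  long-range structured correlations, and site/session effects. Passing
  tests therefore demonstrate that the *pipeline* recovers what it assumes,
  not that the assumptions hold for real fMRI.
* Targets are Cholesky-factorized per participant; if a shifted target is
  not positive definite it is repaired by eigenvalue clipping (re-normalized
  to unit diagonal), with a hard error if the repair moves any entry by
  more than 0.05. All randomness descends from one `SeedSequence`, so
  cohorts are bit-reproducible from the config.

## Numerical and procedural conventions

* Averaging across participants is done on Fisher-z matrices, not raw r.
* Screening (estimability and σ) is evaluated on the group-average graph
  only; efficiency is per participant. Reported densities are those of the
  group-average graph, to two decimals.
* σ exactly 1 excludes a cell (strict σ > 1). A cell whose σ is undefined
  against its null ensemble (e.g. a saturated complete subgraph, or a null
  with zero clustering) is excluded with a warning rather than aborting the
  sweep.
* Rewiring performs swaps_per_edge × E swap *attempts*, rejecting swaps
  that would create self-loops or duplicate edges; the degree multiset is
  conserved exactly. Graphs with no valid swap (e.g. a triangle) return
  copies.
* Shortest paths use breadth-first search (scipy.sparse.csgraph); the test
  suite checks them against an independent Floyd–Warshall relaxation, and
  clustering/efficiency against brute-force enumeration and networkx.

## Problem sizes in the validation suites

The test suite and the acceptance script run simulations at sizes chosen as
a deliberate compromise between Monte-Carlo error and turnaround: 500
random graphs for oracle equivalence; 1,000 rewiring trials; 100-null
ensembles for the reference small-world graphs; 200 replicates (n = 500)
for SEM recovery and 1,000 for type-I calibration in the tests (100 and 500
in the acceptance script); 50 end-to-end cohorts of n = 200 in the tests
(20 cohorts of n = 150, 10-null screening ensembles, thresholds 0.15–0.40
over five networks in the acceptance script). The screening ensembles in
the end-to-end suites use 10–12 nulls rather than the default 100; σ is
correspondingly noisier there, which only makes the inclusion gate more
conservative. Expected behaviour at these sizes: recovery bias on β_ES
below 0.05, type-I rate within [0.03, 0.07], power above 0.8 for the
injected FPN effect, and false-positive rates near 0.05 elsewhere and for
CR throughout.

## Known limitations

* The standardized-coefficient bound |β| ≤ 1 holds asymptotically but can
  be exceeded on very small cohorts (n < 30 triggers a warning).
* The screening gate is evaluated per cohort; with few participants the
  group-average graph is noisy and inclusion patterns vary across seeds.
* Bonferroni correction treats the 10 networks as the family; thresholds
  within a network are not corrected for, mirroring the emulated analysis.
* The generator's single between-network ρ_b cannot reproduce realistic
  whole-brain density profiles (real cohorts show far denser cross-network
  connectivity at low thresholds); whole-brain results are therefore
  qualitative only.
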