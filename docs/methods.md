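# Methods

This note records the statistical model, the numerical choices and the
limits of what the synthetic-data tests demonstrate.

## The MET mixed model

The observation unit is a field plot. For trait values stacked over J
environments (location-by-year combinations),

    y = Xτ + Zu + Z_g g + e

with fixed effects τ (one intercept per environment; one indicator column
per control variety, so control plots never enter the genetic term;
optional centred linear row/column trends per environment; optional
covariate columns), an optional replicate-within-environment random term u
with a single variance σ²_u, genetic effects g for the m test lines with

    g ~ N(0, Σ ⊗ I_m),

and residuals independent between environments. Per environment the
residual is either iid with variance σ²_j or σ²_j times a separable
AR1×AR1 correlation, ρ_row^|Δrow| · ρ_col^|Δcol|, computed from integer
plot coordinates so that missing plots are handled by lag distance rather
than by re-indexing the grid.

Σ is the J×J between-environment genetic covariance:

* DIAG — independent genetic effects per environment, Σ = diag(σ²_g,j);
  used to assess per-trial genetic variance and as the starting point for
  everything else.
* FA(k) — factor-analytic, Σ = ΛΛ′ + Ψ with loadings Λ (J×k, entries above
  the diagonal fixed at zero for k > 1, first non-zero loading per factor
  made positive) and specific variances Ψ ≥ 0. FA(k) approximates the
  unstructured covariance with 
  far fewer parameters and is the structure under which genetic
  correlations between trials are read off.

## REML estimation

Variance parameters maximise the residual log-likelihood

    l_R = −½ [ log|V| + log|X′V⁻¹X| + y′Py + (n−p) log 2π ]

over an unconstrained parameterisation: log variances (offset by a floor
of 1e−8 × var(y); estimates within a factor 2 of the floor are reported as
boundary values), arctanh autocorrelations, free loadings. The
likelihood is evaluated by factoring V through the Woodbury identity on
the genetic term: per-environment residual blocks are solved directly
(scalar work for iid residuals — the per-environment Gram matrices are
cached, so an evaluation costs microseconds; dense Cholesky otherwise) and
the genetic term contributes a capacitance matrix C = Σ⁻¹⊗I + Z′R̃⁻¹Z.
For DIAG structures C is block-diagonal per environment; for FA structures
with one plot-to-line incidence per environment it decouples into m small
J×J systems solved in a batch. This is what makes hundreds of replicated
fits affordable in the simulation tests.

Optimisation is quasi-Newton (L-BFGS-B, numerical gradients) from
moment-based starts (per-environment line-mean ANOVA splits), with a
Nelder–Mead polish for low-dimensional problems — the polish is what
brings balanced-case estimates to within 1e−6 of the ANOVA solution — and
three perturbed starts for FA structures, which can have local optima.
FA(1) is initialised from the DIAG fit (Λ₁ = √(σ²_g/2), Ψ = σ²_g/2) and
each FA(k+1) from FA(k). Non-convergence returns the last iterate with a
flag rather than raising. The implementation targets likelihood
correctness, verified against brute-force dense evaluation, not
average-information algorithmic fidelity.

BLUPs and their prediction-error covariance are

    g̃ = (Σ⊗I) Z′_g P y,   PEV = (Σ⊗I) − (Σ⊗I) Z′_g P Z_g (Σ⊗I),

computed once at the optimum via a dense capacitance solve.

## Pipeline rules

* Trial filter: after the DIAG fit, environment j is removed when
  σ²_g,j < 0.01 σ²_j. Note the sampling caveat below.
* FA order: fit FA(1), FA(2), … until the common factors explain > 80 % of
  the summed genetic variance, or k = J−1.
* Scan: the fixed part is extended, one query position at a time, with the
  predictor main effect and its environment interaction in sum-to-zero
  coding (so the main effect is the across-environment mean effect), plus
  covariate predictors not on the scanned chromosome (covariates on it are
  excluded to avoid collinearity with the tested predictor). Variance
  parameters stay at the base-model estimates — the standard fast
  approximation; per-interval re-estimation is available via
  `refit_variance` but changes results negligibly at these sizes.
* Significance: Wald chi-square, p < 0.01 for either term; contiguous
  significant intervals merge into one QTL whose peak is the interval with
  the largest Wald statistic. The QTL term is "main" when only the main
  effect is significant at the peak, otherwise "QxE". Per-environment
  effects are main + interaction with normal-theory intervals
  (estimate ± 1.96 SE).
* Phenology covariates: when a phenology trait is named, it is scanned
  first and the flanking markers of its QTL become covariates for the
  other traits. Because covariates are excluded on their own chromosome, a
  pleiotropic phenology locus is still detected there; such records are
  flagged `phenology_colocated` (peak midpoints within 10 cM) rather than
  silently removed.
* Heritability: per environment, h² = 1 − PEV̄/(2σ²_g,j) with PEV̄ the mean
  over line pairs of PEV_ii + PEV_i′i′ − 2 PEV_ii′, clamped to [0, 1];
  boundary genetic variances report h² = 0 with a flag. In a balanced
  single trial this reduces exactly to σ²_g/(σ²_g + σ²_e/r).

## Genetic predictors

The predictor at a query position is E[x | flanking markers] for the
±1-coded DH genotype x (+1 = parent-1/Excalibur-role allele). Flanking
states are the nearest non-missing calls by outward search, distances are
converted cM→r with the Kosambi inverse r = ½ tanh(2d/100), and the
three-point conditional probabilities combine r's under no interference
(r_LR = r_L + r_R − 2 r_L r_R) — closed-form conditionals require that
additivity, so Kosambi is used only for the map↔r conversion. This is a
deliberate, documented mismatch between the map function and the
interference model; the simulator recombines marker-to-marker without
interference, making the predictor's conditional expectation exact there.
Values are never re-standardised: a predictor is exactly ±1 at an observed
homozygote, 0 with no information, strictly interior otherwise. The
default query scheme is one predictor per adjacent-marker interval
midpoint, labelled by its flanking markers; a marker-position scheme is
kept for diagnostics.

## NIL fine-mapping

Sib pairs fixed for opposite alleles over a marker segment are compared
per trait with a two-sided pooled-variance t-test (Welch optional); stars
follow p < 0.05/0.01/0.001 with strict inequalities. The QTL region is
delimited by set logic on segments: the intersection of segments of
significant pairs minus the union of segments of non-significant pairs,
reported with the markers immediately outside the surviving block and its
cM span. Discordant configurations (disjoint significant segments, or a
non-significant segment covering the whole candidate region) raise an
explicit error instead of being resolved silently — they are real
biological signals (background heterogeneity) that need human judgement.
Plot-level replicate values are assumed for the t-tests.

## Synthetic data

The simulator generates exactly the structure the model assumes: DH
genotypes from a first-order Markov recombination chain along the map (no
interference, no heterozygotes, Kosambi cM↔r), planted QTL with main and
per-environment effects (QTL between markers are drawn from their
conditional distribution given the flanks), an FA polygenic term
Λf_i + δ_ij, replicate effects, an AR1×AR1 Gaussian field per environment
and optional iid noise. Line-to-plot assignment is a seeded permutation
within consecutive replicate blocks of the grid; design generation
(alpha-lattices, nearest-neighbour layouts) is out of scope. A
`TruthRecord` carries realised QTL genotypes, effects, Σ and per-line
genetic values so recovery is scored without re-simulation.

Defaults mirror a wheat DH study loosely — ~200 lines, 2 replicates, 6–10
environments with heterogeneous variance, FA(1) G×E with 60 % common
variance, unit residual variance — and the simulation tests state their
sizes explicitly (typically 150–240 lines, 1–6 environments, maps of one
to fifty linkage groups). What passing tests show is internal
consistency: the pipeline recovers what the model class generates. They do
not show robustness to field realities the generator omits — interference,
segregation distortion, non-Gaussian residuals, trial-specific design
artefacts, genotype-by-management interactions.

## Known limitations and caveats

* The <1 % trial filter is a point decision on a noisy statistic: with m
  lines and r replicates the genetic-variance estimate of a truly
  zero-variance trial has sampling SD ≈ (σ²_e/r)√2·√(1/m + 1/(m(r−1))),
  about 8 % of σ²_e at m = 150, r = 2 — an order of magnitude above the
  1 % cutoff. Such a trial is therefore dropped only ~55–60 % of the time
  at two replicates; near-certain removal would need ~20 replicates. The
  rule is implemented exactly as stated; treat its output as a screen, not
  a test.
* Dense per-environment residual factorisations scale as O(n_j³); grids
  beyond a few thousand plots per trial would need sparse or Kronecker
  refinements the package does not implement.
* One-at-a-time scanning does not model linked QTL jointly; closely linked
  loci merge into single records by the contiguity rule.
* Wald p-values use the estimated-θ GLS covariance without degree-of-
  freedom correction; calibration is verified by simulation at the study's
  sizes (type-I error 0.0097 at a nominal 0.01 over 10,000 null tests)
  rather than guaranteed in small samples.
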