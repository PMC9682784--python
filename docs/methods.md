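# Methods

## Setting

A new three-arm randomized trial compares a negative control A, a reference
treatment B, and a new treatment Z on a binary adverse outcome (the
motivating application is retreatment after antibiotic therapy for bovine
respiratory disease, where A and B already sit in a 98-trial evidence
network and Z is a product absent from it). The comparison of interest is
Z-vs-B for non-inferiority, or Z-vs-A for superiority, on the
log-odds-ratio (LOR) scale. The package answers two design questions:
how to allocate a fixed total sample size over the three arms, and how
large the trial must be to reach a target power — in both cases with or
without borrowing strength from the existing network.

Sign convention everywhere: `lor(Y over X) = logit(p_Y) − logit(p_X)`; the
outcome is adverse, so negative values favor Y.

## Fixed-effects NMA by GLS

Each study contributes its observed within-study LORs relative to a study
anchor arm, `y_j`, with within-study covariance `S_j`. Under consistency,
`E[y] = X μ_b` where `μ_b` holds the T−1 basic parameters (every treatment
vs the network baseline) and X has entries in {−1, 0, +1}: a basic
comparison is a single +1; a comparison of two non-baseline treatments is a
+1/−1 pair. The GLS/ML estimate is `μ̂_b = (X'S⁻¹X)⁻¹X'S⁻¹y` with
covariance `(X'S⁻¹X)⁻¹`.

Numerical choices:

- The normal equations are accumulated study by study via Cholesky solves
  of the small per-study blocks; the stacked block-diagonal S is never
  formed or inverted. The final (T−1)×(T−1) system is also solved by
  Cholesky.
- Estimability is guaranteed by an explicit connectivity check of the
  comparison graph (networkx) before fitting, rather than by numerical
  rank detection.
- Basic parameters are ordered by treatment-label sort order excluding the
  baseline — deterministic and independent of input row order.
- The study anchor for expanding arms into contrasts is the network
  baseline when the study includes it, else the lexicographically first
  treatment. The anchor choice does not affect the fit (baseline invariance
  is a tested property); it only needs to be deterministic.
- Multi-arm studies: two contrasts sharing the anchor arm covary by the
  anchor arm's variance `1/(n p(1−p))`, equivalently
  `(σ²_AB + σ²_AZ − σ²_BZ)/2`. Contrast-level three-arm studies without an
  explicit covariance are accepted when all three pairwise contrasts are
  given, reconstructing the off-diagonal through that identity; an implied
  covariance that is not positive definite is an error naming the study.

## Borrowing: closed form and augmentation

Writing `v_i = 1/(n_i p_i (1−p_i))` for each arm's inverse information, the
new trial alone gives `Var(μ̂_BZ) = v_B + v_Z`. If the existing network
estimates the A-vs-B contrast with variance `σ²_AB,exg`, adding the trial
to the network and refitting gives

    Var(μ̂_BZ) = v_B + v_Z − v_B² / (σ²_AB,exg + v_A + v_B),

strictly smaller whenever `σ²_AB,exg` is finite. `σ²_AB,exg = ∞` is a
first-class input encoding "no network", so the stand-alone case is a limit
of the same code path, not a separate branch. The equality between this
closed form and the full augment-and-refit GLS variance (to 1e-10 relative)
is the package's central regression test: it ties the estimator, the
augmentation bookkeeping, and the design formulas together.

The superiority counterpart is not printed in the source material; it
follows from the same GLS reduction with the roles of A and B exchanged in
the borrowing term:

    Var(μ̂_AZ) = v_A + v_Z − v_A² / (σ²_AB,exg + v_A + v_B),

and is pinned to the augmented GLS fit by a cross-module oracle test. The
derivation: the trial provides independent arm-logit estimates, the network
contributes one extra pseudo-observation of `θ_B − θ_A`; profiling out the
nuisance logits leaves a precision-weighted combination of the direct arm
and the indirect route through the other arm.

Because the new trial's likelihood touches the existing parameters only
through `μ_AB`, the full network enters the updated Z-contrasts only
through the two-number summary `(μ̂_AB,exg, σ²_AB,exg)`. The Monte-Carlo
driver exploits this for speed; equality with the full refit is tested to
1e-10, so this is an algebraic shortcut, not an approximation.

## Power, allocation, sample size

Power is normal-approximation throughout (no exact binomial calculations —
the framework is asymptotic by construction):

- Non-inferiority of Z vs B with margin M (H0: `μ_BZ ≥ M`):
  `Power = Φ(−(μ_BZ − M)/se − z_{1−α})` with the one-sided critical value
  (1.645 at α = 0.05). The published operating characteristics are
  consistent only with the one-sided value here.
- Superiority of Z vs A (H0: `μ_AZ = 0`):
  `Power = Φ(μ_AZ/se − z_{1−α/2}) + Φ(−μ_AZ/se − z_{1−α/2})`, the
  two-sided pair (1.96 at α = 0.05). The matching simulation decision rule
  rejects when `estimate + z_{1−α/2}·se < 0`; the published superiority
  rates at small samples are consistent only with the two-sided critical
  value, so the package uses it for both the formula and the Monte-Carlo
  rule.

Allocation at fixed total n minimizes the relevant contrast variance over
integer `(n_A, n_B, n_C)` summing to n with a per-arm floor (default 10,
configurable — small floors like 3 or 5 are legitimate for some designs,
but inference with a binary outcome needs some minimum per arm). No closed
form exists; the solver runs scipy differential evolution on the continuous
2-D slice `(n_A, n_B)` with box bounds `[floor, n − 2·floor]` and a penalty
for `n_Z < floor` (keeps the simplex constraint exact and the search 2-D),
then enumerates all integers in an L∞ ball of radius 3 around the rounded
continuous optimum, plus the even split and floor-control reference
splits, keeping the best feasible triple. Ties break to the smallest
`n_A`, then `n_B`. The default DE seed is 20221122, fixed and surfaced in
the configuration, so results are reproducible; the radius-3 refinement is
validated against an exhaustive integer oracle on a randomized suite of 50
problems with totals up to 600 (the objective is smooth and convex along
feasible directions near the optimum, so a small ball suffices).

Sample-size inversion for a target power uses the monotonicity of power in
the total: a doubling phase brackets the target, then bisection finds the
smallest total. The even rule returns equal arms (total a multiple of 3,
rounded up — this reproduces 5355 = 3 × 1785 for the 80% non-inferiority
benchmark); the optimal rule nests the allocation optimizer at each probed
total.

## Monte-Carlo verification

Each replicate draws `r_i ~ Binomial(n_i, p_i)` for the three arms, fits
the saturated three-arm logistic model — whose MLE contrasts are the
empirical LORs and whose information-matrix Wald standard errors are
`sqrt(Σ 1/cell)` over the contrast's 2×2 table (verified against a
statsmodels GLM fit in the tests) — optionally folds the trial into the
network, and applies the one-sided upper-confidence-limit decision rule.
Replicates use independent RNG substreams spawned from the study seed
(`SeedSequence(seed).spawn(reps)`), so runs are bit-reproducible and could
be parallelized without changing results; no concurrency is actually used.

Degenerate replicates (a zero or full cell) are not dropped: 0.5 is added
to all four cells of the affected 2×2 (Haldane–Anscombe) and the replicate
is counted in `n_degenerate`. In the NMA covariance path the correction is
applied per degenerate arm instead, so a shared arm contributes the same
term to every contrast of its study; the two rules coincide for two-arm
tables. At the benchmark configurations (≥ 20 per arm, event probabilities
0.22–0.68) degenerate draws are vanishingly rare and the choice is
immaterial; it matters only for deliberately extreme inputs.

## Synthetic networks

The generator draws arm-level data under the same binomial/logistic model
the estimator assumes: baseline probability `p` at the baseline treatment,
other arms shifted by their true basic parameter on the log-odds scale.
Topology schemes: `star` (every study contains the baseline), `chain`, and
`random-connected`; each non-baseline treatment is seeded into the early
studies so the comparison graph is connected by construction, with a
retry-then-error guard. Same seed, same network, bit for bit.

`brd_like_blueprint()` emulates the motivating network's shape: 13
treatments, 98 studies, eight three-arm studies, star-heavy topology (most
trials compare against negative control), baseline event probability
0.681, the control-vs-reference LOR pinned at 2.007 and the
moderate-effect treatment at the LOR implied by an event probability of
0.4303. The remaining effects are fixed plausible values in the −0.45 to
−2.2 range, and arm sizes are uniform on 100–400 (field-trial scale). It is
a statistical stand-in sharing the structure, not a reconstruction of the
deposited dataset, so quantities that depend on the real data — notably the
realized `σ²_AB,exg` and the published with-network table cells — are not
reproduced by it; tests against those cells run only when the deposited
arm-level CSV is placed at `data/brd_arm_level.csv`. What the synthetic
fixture does support, exactly, is every structural property: estimator
correctness against oracles, baseline invariance, the closed-form/GLS
equivalence, optimizer-vs-oracle agreement, and parameter recovery. Being
generated from the model the estimator assumes, it cannot probe
inconsistency, heterogeneity or other model misspecification — a real
network can depart from all of these.

## Problem sizes used in verification

The shipped verification suite simulates 10,000 replicates per operating
characteristic (matching the published replication count) at the published
trial sizes (totals 2400–3600 for non-inferiority, 180 for superiority);
the randomized optimizer-vs-oracle suite uses totals up to 600, where
exhaustive enumeration is exact and cheap. Monte-Carlo agreement bands are
three standard errors of the difference of two independent 10,000-replicate
binomial proportions, since the published rates are themselves simulation
estimates.

## Known limitations

- Fixed-effects NMA only: no between-study heterogeneity, no
  inconsistency diagnostics, no random-effects extension. With one new
  trial the between-study variance of the new treatment is not estimable
  anyway, which is why the fixed-effects frame matches the stand-alone
  analysis it replaces.
- Binary outcomes and log odds ratios only; two CSV dialects only.
- All power statements are asymptotic (Wald); at very small arms the
  simulated and analytic powers drift apart, which the simulation module
  exists to quantify.
- One new treatment per trial; the three-arm trial cannot maximize the
  power of both comparisons simultaneously, and no multi-objective
  compromise is attempted.
- Historical information enters at face value; there is no discounting of
  the network relative to the new trial.
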