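# Methods

`divpath` implements an integrative macroevolutionary analysis of
diversification drivers on a time-calibrated phylogeny: candidate causal
models relating diversification to chromosome-number evolution, climate and
morphology (and their evolutionary rates) are compared by phylogenetic path
analysis; the evolutionary-rate predictors themselves come from a
heterogeneous-rate chromosome-number Markov model and multi-regime Brownian
trait models; a trait-dependent diversification likelihood closes the loop
by asking whether the chromosome evolutionary rate itself shapes speciation
and extinction. This note records the models, the numerical choices, and
what the synthetic-data tests do and do not establish.

## Phylogenetic path analysis (PPA)

A candidate causal model is a DAG over species-level variables. Its
d-separation basis set contains one conditional-independence claim per
non-adjacent variable pair, conditioned on the union of both variables'
parents (Shipley's basis). Each claim is tested by one phylogenetic
generalized least squares (PGLS) regression — the claim's later variable
(under the topological order described below) regressed on the earlier one
plus the conditioning set — and the claim p-values combine into Fisher's
C = −2 Σ ln p. Models are ranked by the small-sample information criterion

    CICc = C + 2 q · n / (n − 1 − q),

with q = number of edges plus number of endogenous variables (one intercept
per fitted regression) and n the number of species. Standardized path
coefficients are model-averaged over all candidates within 2 CICc units of
the minimum, weighting by exp(−Δ/2) and imputing coefficient zero (and
variance zero) where a model lacks a path ("full" averaging), which shrinks
weakly supported paths toward zero instead of biasing them away from it.

PGLS regressions assume Brownian residual covariance (the shared-path
matrix of the tree); Pagel's λ can optionally be profiled over [0, 1], but
the default is λ = 1 so that model-set comparisons are deterministic.
Variables are z-scored with ordinary mean and standard deviation before
fitting, so coefficients are standardized and comparable across paths. No
log transform is applied by default; callers may transform columns before
fitting.

### Claim orientation

The response of a claim's regression is the variable that comes later in a
topological sort of the model. Ties (non-descendant pairs) are broken by a
stack-based sort seeded with the parentless variables in reverse canonical
order — the behaviour of the reference R implementation of the basis-set
construction — over a canonical variable order that is part of each family's
definition (see below). Orientation does not affect which independencies
are tested, but it determines which regressions coincide across models and
therefore the deduplication statistics.

## The candidate model families

Three families are built from one grammar of structural templates. Six base
hypotheses concern the chromosome axis: chromosome → diversification,
chromosome → morphology, or both, each optionally preceded by
climate → chromosome. Each base model is expanded by direct morphology
and/or climate effects on diversification (×4) and doubled by optional
climate → morphology edges (×2), giving 48 templates. A template is
instantiated by substituting node blocks for the chromosome, climate and
morphology roles:

* **rates** family — blocks {R2n}, {RB4}, {RLI, RCU} over the five
  rate variables plus DI;
* **means** family — blocks {C2n}, {B1, B4, B7, B12}, {LI, CU} over the
  eight species-mean variables plus DI;
* **combined** family — seven groups over all twelve variables: the two
  families above; both with the chromosome role widened to {C2n, R2n}; the
  means family with C2n replaced by R2n; the rates family with R2n replaced
  by C2n; and a group in which every role carries both means and rates.
  Deduplicating in that order removes exactly the base chromosome → DI
  model from each of the last four groups: 3×48 + 4×47 = 332 models.

Every family additionally carries an edge-free null competitor, which takes
part in ranking and in the regression counts. Model identifiers are dot
codes (segments joined by "..": `d.<sources>` lists the predictors of DI,
`<target>.<sources>` the predictors of a block), and round-trip through a
parser/printer pair.

Canonical variable orders — rates (R2n, RLI, RCU, RB4, DI); means
(C2n, LI, CU, B1, B4, B7, B12, DI); combined (DI, C2n, R2n, B1, B4, B7,
B12, RB4, LI, CU, RLI, RCU) — are fixed parts of the family definitions.
Together with the orientation rule they determine the counts of unique
regressions (distinct response/predictor-set pairs) that the regression
cache exploits: 30 unique of 250 for the rates family, 66 of 844 for the
means family, 655 of 18 112 for the combined family.

### Model selection caveat

With the full 48-model family, the single best model is an unreliable
summary: every superset of the true model omits claims whose p-values are
uniform under the truth, so some superset overtakes the generating model
with appreciable probability regardless of sample size
(`examples/07_ppa_power_full_family.py` measures this). Inference should
therefore rest on the model average and on focused comparisons among the
six base hypotheses; the recovery tests are formulated accordingly.

## Chromosome-number evolution

The haploid number n evolves by a continuous-time Markov jump process:
gains n → n+1 at rate max(0, λ0 + λ1·n), losses n → n−1 at rate
max(0, δ0 + δ1·n) (dysploidy, linear in the absolute number, clamped at
zero), and duplication n → min(2n, n_max) at rate ρ. Units are events
Myr⁻¹ (λ1, δ1: events Myr⁻¹ n⁻¹). The state space spans
[max(1, min_obs − 10), 2·max_obs + 10]; duplication beyond the top state is
truncated there. The likelihood is Felsenstein pruning with per-branch
transition matrices expm(Q t); the root prior is uniform over states with
positive subtree likelihood (an ML-root option exists).

Rate heterogeneity: every branch belongs to a regime; shifts are searched
greedily. Each round, every internal node with ≥ `min_clade` (default 10)
descendant tips is scored by refitting the clade's data alone (on the
extracted subtree with a deliberately tight state space — a screen, not the
final objective; near-frozen clades additionally get a near-zero start,
since a ridge separates the zero-rate optimum from the background
parameters). Clades whose local gain exceeds half the 2·5-unit AIC penalty
are evaluated exactly — the new regime's five parameters optimized on the
full tree with the others fixed — and the best proposal is kept if the full
AIC improves by more than 2 ln(#candidate nodes) (the expected advantage
the best of many candidate locations enjoys by selection alone; the same
guard as in the trait-rate search), up to `max_regimes` (default 40)
regimes, with one coordinate polish pass after each acceptance. The greedy-screen design is
this package's heuristic; the reference heterogeneous-rate implementation's
search is not fully specified in the literature it comes from.

Numerics: expm actions use the eigendecomposition of Q, accepted when the
spectral reconstruction of Q is accurate (strictly, 1e-9, for reported
likelihoods). One-directional rate matrices are numerically defective; the
optimizer then falls back to dense expm per branch length (batched, and
with branch lengths quantized to a 3 %-relative geometric grid during
optimization only), and tolerates a looser 5e-3 eigen gate, which perturbs
the objective by far less than any AIC decision. Optimization is
Nelder–Mead on log rates (floor 1e-6 ≈ zero; ceilings 5 for ρ, 20 for
λ0, δ0, 1 for λ1, δ1) from balanced multi-starts. Final likelihoods are
recomputed with the strict propagator.

Per-taxon dysploidy rates — the r_chrom column the path analyses consume —
are max(0, λ0 + λ1·n_s) + max(0, δ0 + δ1·n_s) with the tip's regime
parameters and observed number n_s; gain-only and loss-only variants are
exposed, the default sums both directions.

## Trait evolutionary rates

Continuous traits follow Brownian motion with clade-specific diffusion rate
σ² (trait units² Myr⁻¹), fitted by maximum likelihood under the
regime-weighted covariance Σ_r σ²_r W_r (W_r = shared path length accrued
within regime r). The overall scale and the root value are profiled in
closed form, leaving only rate ratios to numerical optimization. Shifts are
added greedily while AICc improves, with two guards beyond plain AICc:
each extra regime is charged for its shift location as well as its σ², and
the improvement must clear 2 ln(#candidate locations) — the expected
log-likelihood advantage the best of many candidate shift points enjoys by
selection alone. Without the guards a spurious shift is accepted on
homogeneous data in most replicates; with them the test suite recovers the
no-shift model on almost all simulated homogeneous datasets while still
finding a genuine 25× rate shift in a ~100-tip clade.

This stand-in deliberately replaces reversible-jump MCMC machinery: the
path analyses consume only per-tip rates (the σ² of the regime governing
each terminal branch), not posterior shift configurations. It also assumes
constant σ² within a regime; rate change through time within regimes is not
modelled. Tip diversification rates are an input column (or synthesized by
the generators), not estimated here.

## Trait-dependent diversification

The QuaSSE-style likelihood couples a diffusing trait x with speciation
λ(x) and extinction μ(x) from four families: constant c; linear
max(0, a + b·x); sigmoid y0 + (y1−y0)/(1+exp((x_mid−x)/r)); and hump
y0 + (y1−y0)·exp(−(x−x_mid)²/2s²). The trait follows Brownian motion
(rate σ²), optionally with mean reversion toward an optimum θ at strength α
— implemented as an advection term, one reading of an "OU" trait process.
Along each branch D(x,t) and E(x,t) are integrated on a regular grid
(default 1024 bins spanning the data padded by 4 σ√depth) by operator
splitting: an RK4 reaction step, a Crank–Nicolson diffusion step with
reflecting boundaries, and an upwinded advection step (CFL-checked). The
time step resolves the shortest branch when affordable but is floored at
depth/1000; each branch takes at least one step. At nodes
D ← D_left·D_right·λ(x); the root integrates D against either a flat
weighting or the normalized D itself (default), and the likelihood is
conditioned on survival by dividing by the weighted λ(x)(1−E(x))².
Probability mass reaching the grid boundary above 0.5 % of a branch's total
raises an error asking for wider padding.

With trait-independent rates the likelihood factorizes exactly into the
constant-rate birth–death likelihood times the Brownian trait likelihood;
the test suite verifies the PDE machinery against that closed form to
better than 1e-3 relative and checks grid self-convergence under bin
doubling. Model fitting is Nelder–Mead over log-transformed positive
parameters for all requested (λ family, μ family, drift) combinations,
ranked by AIC = −2 logL + 2k.

## Synthetic data

The generators define the study conditions for every test:

* **Trees** — forward birth–death simulation conditioned on the tip count
  (stopped at the moment the (n+1)-th extant lineage would appear; extinct
  lineages pruned; for a pure-birth process the expected root age is
  Σ_{k=2..n} 1/(k·birth)). Recovery experiments use pure-birth trees of
  300 tips (birth 1 Myr⁻¹, depth ≈ ln 300 Myr).
* **Traits** — Brownian motion along the tree with per-regime σ².
* **Causal tables** — exogenous variables are unit-variance Brownian
  columns; each endogenous variable is the coefficient-weighted sum of its
  parents plus a Brownian residual scaled toward unit total variance, and
  every column is z-scored. Residual phylogenetic correlation matches the
  PGLS assumption, which makes recovery tests well-posed. Path
  coefficients in the recovery experiments are 0.6.
* **Chromosome numbers** — exact Gillespie simulation of the jump process
  per branch, regime-aware, with the duplication cap applied. The
  background parameter set (ρ=0.007, λ0=2.035, δ0=1.610, λ1=0.062,
  δ1=0.102; root state 12) is mean-reverting around n ≈ 11, so simulated
  numbers stay in a realistic 1–40 band.
* **Fixture tables** — standardized columns are mapped by monotone
  transforms onto field-plausible units (temperatures in °C, lognormal
  lengths, positive rates), preserving the generating causal order.

What passing these tests shows — and does not. The generators satisfy the
models' assumptions by construction (Brownian residuals, correctly
specified CTMC, ultrametric trees). Passing recovery tests therefore
demonstrates correctness of the machinery and adequate power at n = 300,
not robustness to model misspecification (measurement error, non-Brownian
traits, diversification-rate variation) that real data will exhibit.

## Problem sizes and determinism

Recovery experiments run at 300 tips with 50 replicates (path-analysis
chain recovery; planted zero-rate clade detection) or 8–10 replicates
(shift/no-shift discrimination), sizes at which each replicate's fit takes
seconds; the PDE oracle uses a 20-tip tree at 512–1024 bins. All
randomness flows from explicit integer seeds; a fixed seed reproduces
trees, tables, chromosome states and every pipeline artifact byte for byte
(the pipeline manifest records SHA-256 checksums to make this checkable).

## Known limitations

* The shift searches are greedy forward selections: nested or adjacent
  regime configurations can shadow each other, and the reported
  configuration is a local AIC optimum.
* The chromosome model excludes demi-polyploidy and base-number change,
  and treats duplication truncation at the state-space ceiling as exact.
* The "OU" trait option in the diversification model is an advection
  approximation, adequate for moderate α; strong mean reversion on coarse
  grids will trip the CFL guard.
* CICc ranking among highly nested families rewards parsimony only weakly
  (≈ 2 units per edge); see the model selection caveat above.
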