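# Methods

## The life-cycle model

The simulator follows a clonal population of cells through repeated
cycles of sporulation → germination → bottleneck → regrowth, the
synthetic life cycle used in laboratory evolution of *Myxococcus
xanthus* (predation is deliberately absent: the model isolates the
sporulation–germination trade-off). Each cell carries two heritable
quantitative traits in [0, 1]: sporulation ability *s* and germination
ability *g*.

**Initialization.** Both traits are drawn independently from a normal
distribution (mean 0.5, sd 0.15) truncated to [0, 1]. Truncation is
exact (inverse-CDF sampling), not clipping, so no probability mass
accumulates at the boundaries; the ancestral distributions are
unimodal and interior. The census starts at the carrying capacity
`n_max` (default 10⁶ cells).

**Cycle 1 (ancestral reference).** In the first cycle there is no
preceding bottleneck and no social game: each cell sporulates
independently with probability equal to its own ability *s*, and
germination uses a first-cycle privatization factor
`epsilon_first_cycle = 0.8`. The realized retention rates of this
cycle — spores per cell and germinated cells per spore — are the
ancestral reference rates for all later readouts.

**Sporulation (cycles ≥ 2).** Cells with *s* ≥ 0.5 are classified as
cooperators, the rest as exploiters. ⌊N/2⌋ pairs are formed: pair-type
counts are a multinomial draw with probabilities (p_c², 2p_c·p_e,
p_e²) and members are sampled without replacement from the matching
class. When sampling noise demands more cells than a class holds, the
counts are repaired by swapping same-type pairs between classes
(cc ↔ ee), which keeps the expected pair-type frequencies unbiased; at
most one cell per class is left unpaired, and unpaired cells do not
sporulate.

* **C–C**: each paired cooperator sporulates with probability γ·*s*,
  where γ ∈ [0, 1] is the cost-of-cooperation discount (γ = 1 means
  cost-free cooperation). The bookkeeping payoff is K = γ·½·Σ*s* over
  the paired cooperators.
* **C–E**: with D the difference between the mean abilities of the
  paired cooperators and exploiters, every paired exploiter gains
  D/*n* and every paired cooperator loses the same amount (*n* ≥ 1 is
  the sharing divisor, default 50; *n* = 1 reproduces total
  expropriation). Post-transfer abilities are clipped to [0, 1] —
  total ability is conserved exactly whenever no cell hits a
  boundary — and cells whose post-transfer ability clears 0.5 become
  spores. Payoffs L (cooperators) and M (exploiters) are the
  post-transfer ability sums over retained cells.
* **E–E**: never yields spores; N = 0 identically.

**Germination.** In the default "communal" mode every spore germinates
with probability ε·mean(*g*): germination runs entirely on the shared
pool of diffusible goods, scaled by the privatization factor
ε ∈ [0, 1]. A configurable "mixed" mode
(ε·mean(*g*) + (1 − ε)·*g*) is provided for sensitivity analyses in
which spores partly rely on their own goods; it is not the default
because the communal reading matches how germination on pooled,
post-harvest-mixed spores works.

**Bottleneck.** round(β·N) cells (half-up rounding, floored at one
survivor so a small scaled census cannot go spuriously extinct) are
retained uniformly at random; sampling is trait-blind.

**Growth with mutation.** Survivors double synchronously until the
census reaches `n_max`, then a uniform random subset of exactly
`n_max` cells is kept (a fixed census makes regimens comparable).
Each daughter mutates with probability `mutation_prob` (default 1: the
growth phase is the mutational step of the model and no per-division
rate is separately specified): the germination step is
Δg ~ Uniform(−0.1, +0.1) and the sporulation step is coupled through
the trade-off, Δs = −1.15·Δg. The trade-off coefficient is a slope,
not a correlation — its magnitude exceeds one, meaning sporulation
moves more than germination per mutation. Daughters pushed outside
[0, 1] in either trait die (lethal mutation); this boundary lethality
is the only force opposing directional selection on *s* and sets the
stationary trait spread.

**Readouts.** At each readout cycle (defaults 10 and 50) the relative
spore productivity and relative germination efficiency are
log₁₀(evolved rate / ancestral rate), where a "rate" is the realized
retained fraction at that phase in the focal cycle and the ancestral
rates come from cycle 1. Because cycle 1 sporulates by individual
ability and germinates at ε = 0.8, the γ discount and the focal ε
enter the evolved rates but not the reference — which is precisely
what lets a costly-cooperation parameterization lower spore
productivity, and a liberal-sharing ε raise germination efficiency,
relative to the common ancestor. A zero evolved rate is reported as an
explicit floor (−12) with a flag, never a silent −inf. An optional
min–max rescaling of a sweep to [−1, 1] exists for surface plotting
only; the signs and ordering of the raw log ratios are the scientific
output.

**Randomness and determinism.** One root seed drives a run; sweeps and
batteries derive independent child seeds deterministically via
`numpy.random.SeedSequence` spawning, so every command is reproducible
bit-for-bit and grid points are independent.

### What the model shows, and a known discrepancy

With the stringent-regimen parameterization (γ = 0.98, ε = 0.5) the
simulator reproduces the expected trade-off: spore productivity rises
and germination efficiency falls relative to the ancestor, cooperators
dominate, and the outcome is invariant to the bottleneck size β
(0.01 vs 0.15). Long-run cooperator proportions are stable (cycles
40–50 stay within a few percentage points of the cycle-10–50 mean).

The relaxed-regimen parameterization (γ = 0.65, ε = 0.9) lowers spore
productivity below the ancestor as expected, but does **not** raise
germination efficiency above it. The reason is structural: with the
sharing divisor at *n* = 50, a paired exploiter gains only
D/50 ≈ 0.006 ability, essentially never crossing the 0.5 retention
threshold. Exploiters therefore almost never sporulate, cooperators
win at every γ, and mean *s* rises (dragging *g* down through the
trade-off) in both regimens alike; the ε advantage
(log₁₀(0.9/0.8) ≈ +0.05) cannot outweigh that trait decline. For the
same reason the realized payoff ordering is L > K > M > N (per-capita
≈ 0.60 / 0.30 / 0.01 / 0), not K > M > L > N: retained C–E
cooperators keep near-full ability sums while retained exploiters are
a sliver. Both facts are reported as-is by the acceptance battery; a
C–E sharing rule generous enough to let exploiters sporulate would be
required to reverse them, and no such rule is consistent with the
per-cell transfer of D/*n* at *n* = 50 combined with threshold
retention.

## Assay statistics

Competition metrics follow the standard development-competition
design: D_i = log₁₀[N_i(t3)/N_i(t0)] from monocultures,
D_ij the same quantity in a 1:1 mix, W_ij = D_ij − D_ji (relative
performance; antisymmetric by construction) and C_ij = D_ij − D_i (the
one-way mixing effect: positive when strain *i* benefits from partner
*j*). Co-culture plates are deconvolved with a resistance marker:
selective-plate CFU = marker strain, nonselective − selective =
partner, floored at zero and flagged when plating noise drives the
difference negative. Zero counts yield explicit −inf log ratios that
are excluded from replicate means with a warning; an optional
half-minimum pseudo-count mode exists but is off by default.

Life-cycle relative fitness applies the signed square root
(sign(x)·√|x|) before a one-sample t-test against zero — the transform
tames the heavy tails of multi-cycle log-fold differences while
preserving sign — and reports the raw-scale mean as the effect.

Density-dependence fits are ordinary least squares of a per-capita
response on starting density; both plain and adjusted R² are reported
(the adjusted value is the headline number since near-null fits can
legitimately show small negative values), and for predation-style
assays (prey CFU as the response) a significant negative slope is the
signature of density-dependent predation. Trait correlations report
Pearson r with its exact t = r·√(df/(1 − r²)), df = n − 2.

The testing pipeline gates each declared test with Shapiro–Wilk
(normality) and, for two-sample designs, Levene (variance
homogeneity) at α = 0.05: a failed normality gate reroutes to the
rank-based fallback (Wilcoxon signed-rank / Mann–Whitney U), a failed
variance gate alone switches the pooled t to Welch. A design can also
declare itself parametric (gate recorded, no rerouting). FDR
correction is Benjamini–Hochberg, applied within each declared family
(one family per figure panel is the intended granularity, since family
boundaries are otherwise a reporting choice); pooled-variance t is the
default for two-sample tests because the published degrees of freedom
match pooling.

## Synthetic data

The generators emulate the statistical structure of the wet-lab
assays, not their biology:

* **Competitions** — true spore yields are t0·10^(D_i + C_ij + e)
  with e ~ Normal(0, 0.1) on the log₁₀ scale (multiplicative
  biological noise, the standard model for CFU data); observed counts
  pass through dilution plating with Poisson colony sampling at
  ≤ 300 colonies per plate. Default four replicates, monoculture
  inoculum 5×10⁸ cells (100 µL of 5×10⁹ cells/mL), 1:1 co-culture
  splits.
* **Density series** — per-capita response linear in density with
  Gaussian noise.
* **Trait-pair surveys** — bivariate normal sporulation/germination
  pairs truncated to plausible assay ranges; the latent correlation is
  pre-calibrated (deterministic large-sample bisection, cached) so the
  truncated pairs carry the design's target Pearson correlation.
  Defaults: 13 isolates, target r = −0.6.
* **Life-cycle competitions** — per-replicate log-fold differences =
  truth + Gaussian noise.

Every generator embeds its ground truth in a sidecar and is
deterministic under a fixed seed. What passing recovery tests show is
that the estimators are unbiased and correctly calibrated *under this
noise model*; real plating data can carry overdispersion, pipetting
drift and batch structure that these generators deliberately omit, so
recovery here bounds estimator correctness, not field performance.

Where the reproduction battery stands in for unavailable raw
spreadsheets, the generator parameters (group means, replicate counts,
and group sds back-calculated from published summary statistics) are
inputs, and the pipeline recomputes the statistics from the generated
replicate-level data. Monte-Carlo means over seeded experiment
replications are reported so the value reflects the estimator, not a
single noisy draw; note that the pooled-t statistic is slightly
inflated in expectation (E[1/S] bias, ≈ 8% at df = 10), which is
visible in the recovered germination t.

## Problem sizes and numerical choices

* Simulation batteries run at a census of 10⁴ cells with 10 cycles and
  20 seeds per setting (sign patterns), and 10⁵ cells for the 50-cycle
  stability battery — at 10⁴ a 1% bottleneck keeps ~10 cells and the
  cooperator-proportion series measures bottleneck sampling noise
  rather than dynamics. Sign patterns and payoff orderings are
  insensitive to census scale above ~10⁴.
* Pair-count repair prefers cc ↔ ee swaps (bias-free for the C–E
  count); the C–E fraction is unbiased to within Monte-Carlo error.
* Bottleneck size uses half-up rounding with a floor of one survivor.
* Ties at the cooperator threshold are cooperators (*s* ≥ 0.5
  inclusive).
* Growth caps at 10⁴ doubling rounds as a defensive guard; extinction
  anywhere is a flagged result, not an exception escaping a run.
* The trait-pair calibration solves the latent correlation to ~1e-4 on
  a fixed 2×10⁵-draw sample; the residual gap between the ensemble
  mean of r̂ and the target (≈ 0.02 at n = 13) is the standard
  small-sample bias of the Pearson estimator, not a generator error.

## Limitations

* The C–E sharing rule is the model's softest joint: the per-cell
  transfer D/*n* with threshold retention makes exploitation
  ineffective at *n* = 50 (see the discrepancy note above). The rule
  is isolated in `resolve_ce` so alternatives can be swapped in.
* Germination carries no individual selection in communal mode; all
  germination-side evolution is mutationally coupled to sporulation.
* The model is non-spatial: pairing approximates local assortment
  during development, and germination is fully mixed.
* No fitting of γ or ε to data is attempted; they are scanned.
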