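# Methods

`biomediv` implements the computational chain behind a classic macroecology /
macroevolution question: is a latitudinal diversity gradient produced by
geographic differences in speciation, extinction and dispersal? The package
maps diversity over a grid (species richness and Faith phylogenetic
diversity), extracts cells whose phylogenetic diversity is unusual for their
richness, characterizes diversification through time (lineage-through-time
series, piecewise birth–death shift estimation), and fits a two-region
geographic speciation–extinction–dispersal model contrasting tropical and
non-tropical biomes. Synthetic-data generators with known ground truth stand
in for the range maps, biome rasters and supertrees such analyses consume,
so every stage is testable end to end.

## Diversity mapping

**Community matrices and richness.** A species is present in a cell if any
part of its range overlaps the cell; per-cell richness is the row sum of the
resulting 0/1 cells-by-species matrix. Per-biome richness counts a species
once in each biome its range touches, so biome counts may sum above the
species total — the convention implied by published per-biome tables whose
columns exceed the species pool.

**Faith PD.** PD of a cell is the summed branch length of the minimal subtree
of the reference phylogeny connecting the cell's species, *root-inclusive*:
the path from the community MRCA to the tree root is counted, so a singleton
community has PD equal to its root-to-tip distance. This matches the default
of the standard community-phylogenetics toolchain and keeps PD(singleton)
nonzero, which the near-linear PD~SR scaling presumes. Species absent from
the tree are dropped from PD (never from richness) with a logged count,
mirroring the incomplete species coverage of real supertrees.

**PD ~ SR residuals.** PD is regressed on a degree-1 or degree-2 polynomial
of SR by least squares. Spatial autocorrelation, when requested, enters as a
generalized-additive-style smooth: a low-rank Gaussian radial-basis expansion
of the cell coordinates (default 50 centers chosen by a deterministic
farthest-point space-filling design, bandwidth = median inter-center
distance) with a ridge penalty on the basis coefficients selected by
generalized cross-validation over a log-spaced grid. The literature this
mirrors names only "a smooth term in a GAM", so the basis and penalty are one
standard construction, exposed as configuration. Degree choice is reported
via AIC. The top and bottom `ceil(0.1 n)` residuals are flagged high/low;
ties break by a stable sort on cell id so flagging is deterministic.

## Birth–death shift model

The reconstructed-tree likelihood uses the standard survival/density
functions of a birth–death process with piecewise-constant speciation
`lambda_i` and extinction `mu_i` (per Myr) between shift ages, and sampling
fraction `rho` at present only. Writing `F(t)` for the probability that a
lineage alive at age `t` leaves at least one sampled descendant and `q(t)`
for the reconstructed-lineage density factor, within an epoch

    F' = (lambda - mu) F - lambda F^2        F(0) = rho
    q' = (lambda - mu - 2 lambda (1 - F)) q  q(0) = rho

which have closed forms (logistic; with the `lambda = mu` analytic limit)
propagated across shift ages by continuity — no numerical integration. The
log-likelihood of branching times `x_1 >= ... >= x_{n-1}`, conditioned on
survival of both crown lineages (a flag),

    lnL = 2 [ln q(x_1) - ln F(x_1)] + sum_{i>=2} [ln lambda(x_i) + ln q(x_i)].

**Fitting.** Shift ages are searched on a grid (default step = height/100,
one step away from the present and the root): exhaustively for up to two
shifts, and by greedy placement plus two passes of coordinate refinement
above that. Per-epoch rates are optimized in log space (bounds 1e-6 to 10 per
Myr) by L-BFGS-B with seeded random restarts; along a grid scan each point is
warm-started from its neighbour and the winning ages get a full multi-restart
polish. Chained fits (`fit_sequence`) embed the `m-1` optimum as a degenerate
`m`-shift start, so the maximized likelihood is provably non-decreasing in
`m`. The number of shifts is selected by forward likelihood-ratio tests,
chi-square with 3 degrees of freedom per added shift (two rates + one age),
stopping at the first non-significant step (default alpha 0.05).

Two properties of this procedure deserve explicit note. First, the
likelihood is continuous in a shift age *between* node ages but jumps by
`ln(lambda_old / lambda_young)` as the shift age crosses a branching time —
the rate multiplying that branching event switches epochs; the tests assert
exactly this piecewise structure. Second, because the selected statistic is a
supremum over ~100 candidate shift ages, its null distribution is heavier
than chi-square(3); at alpha = 0.05 the realized false-shift rate on
constant-rate simulations is roughly 20–25%, not 5%. Users wanting stricter
error control should lower alpha or coarsen the grid; the defaults favour
sensitivity, and the shift-age estimates themselves are accurate (median
error well under one grid step in the test conditions).

## Two-region diversification model

Species occupy the tropical region A (tip state 1), the non-tropical region
B (state 2), or both (AB, state 0). Seven per-Myr rates: within-region
speciation `sA`, `sB`; between-region speciation `sAB` (an AB species splits
into one endemic daughter per region); regional extinction `xA`, `xB` (kills
an endemic; demotes AB to the other endemic); dispersal `dA`, `dB`
(endemic -> AB). The likelihood is computed by postorder pruning: along each
branch the extinction probabilities `E = (E_A, E_B, E_AB)` and partial
likelihoods `D = (D_A, D_B, D_AB)` obey the coupled ODE system of the
geographic state speciation–extinction class of models; at nodes daughters
combine with the cladogenetic kernel (AB nodes average the two assignments of
daughters to within-/between-region modes); per-state sampling fractions set
the tip conditions `D_state(0) = rho_state`, `E(0) = 1 - rho`.

**Numerics.** Branches are integrated by fixed-step classical RK4 with step
targeted at height/1000 (minimum 4 steps per branch), compiled with numba;
`D` is renormalized at every node into a log accumulator, so 2000-tip trees
do not underflow. An independently written per-branch RK4 oracle at step
1e-3 agrees with the production solver to better than 1e-6 in log-likelihood
on random instances; a fixed-step scheme was chosen over an adaptive stiff
solver because the system is smooth at these rate magnitudes and the fixed
cost per branch keeps full-battery fits fast.

**Root treatment.** Root state probabilities are weighted by each state's
relative `D` (observation weighting), without survival conditioning, the
default of the standard state-dependent-diversification toolchain; equal
weighting and survival conditioning are available as flags.

**Scenarios and selection.** The 16-model battery is the full 2^4 lattice of
{`sA=sB`} x {`xA=xB`} x {`dA=dB`} x {`sAB=0`} — the unique natural 16-member
family containing the full model and the named triple-equality scenario
(here scenario 11). Constrained parameters are tied or zeroed exactly; free
rates are optimized in log space, warm-started from the full-model MLE, and
a nesting-repair pass restarts any scenario from a better-scoring scenario
with a superset of constraints, so maximized likelihoods respect the lattice
ordering. Model selection uses AIC = 2k − 2 lnL with k counting free rate
parameters only (sampling fractions are data); models within ΔAIC < 2 of the
best are reported as equally supported.

**Time dependence.** Each rate may vary linearly with age before present,
`r(t) = max(0, r0 + m t)` (positive slope = larger rate deeper in time);
rates are clamped at zero rather than the slopes bounded, and the zero-slope
case reduces exactly to the constant-rate likelihood. With time dependence,
`k` doubles (intercept + slope per free rate).

**MCMC.** Metropolis–Hastings in log-rate space with independent exponential
priors whose common mean defaults to twice a crude net-diversification
estimate (`ln(n/2)/height`), coordinate-wise normal proposals, and a
discarded warm-up of 20% of the steps during which step sizes adapt toward
~30% acceptance. Chains are pure functions of the seed. MCMC is provided for
the time-constant models.

## Synthetic data

`sim_bd_tree` runs a forward birth–death process from two crown lineages by
exponential racing (exact for piecewise-constant rates; waiting times are
redrawn at epoch boundaries), prunes extinct lineages, optionally subsamples
extant tips binomially, and retries until sampled tips survive on *both*
crown lineages so the reconstructed crown age equals the configured span —
the conditioning the shift likelihood assumes. Epoch-shift models require
span stopping (shift ages are defined relative to the present, unknown
mid-simulation under a taxon-count rule); taxon-count stopping is supported
for single-epoch models. `sim_geosse_tree` starts one lineage in a chosen
state and applies the per-state event menus of the two-region model, with
optional per-state subsampling; tips are emitted in the 1/2/0 coding.
Time-dependent generative simulation is out of scope (inference-side only).

`sim_grid_world` builds a rectangular grid whose bottom band of rows carries
tropical biome codes (B1, B2, B3, B7) and the rest non-tropical codes, and
gives each species an axis-aligned rectangular range placed with wrap-around
(toroidal) geometry — so no grid edge is artificially species-poor and a
zero-gradient world is exactly uniform in expectation. Range centers are
biased toward the tropical band with weight `exp(-g * distance / n_rows)`;
`g = 0` is the uniform control and larger `g` steepens the richness
gradient. Range side lengths default to shifted-Poisson draws (mean 3
cells). The generator also emits the true band-membership state of every
species, which must round-trip exactly through the biome-based state coding.

What these generators do *not* emulate: spatially autocorrelated range
shapes, the GAM's spatial error field, fossil sampling, and non-random
(phylogenetically clustered) incompleteness. Passing tests therefore show
the estimators are correct and well calibrated under the model's own
assumptions, not that those assumptions hold for real range atlases.

## Default study conditions in the tests

Simulation-based tests fix their generating values up front: recovery runs
use the published global-scale magnitudes (sA = 0.15, sB = 0.0413,
xA = 0.076, xB = 0.51, sAB = 0, dB = 0.00152 per Myr, with dA scaled from
2.73 down to 0.27 to keep forward simulation of 200-tip trees tractable);
shift-detection runs use a 0.1 -> 0.3 speciation step at 5 Mya over a 33-Myr
crown span, with replicates conditioned to 120–180 tips (within 20% of the
150-tip target); battery-honesty runs use 120-tip trees with a true
speciation equality (sA = sB = 0.12) and unequal extinction. Problem sizes
(20–40 replicates, 120–200 tips) were chosen so the full suite runs on a
single desktop CPU in minutes while leaving the statistical assertions
well-powered.

## Known limitations

- Tables of per-epoch rates are only as identifiable as the data allow;
  extinction on pure-birth trees is estimated at the boundary (0) in about
  half of replicates and upward-noisy otherwise — a well-known property of
  reconstructed-tree likelihoods, not an implementation artifact.
- The LRT-based shift count is anticonservative at the default grid/alpha
  (see above).
- The 16-scenario lattice is one defensible reading of "16 scenarios";
  other batteries (e.g. one-sided zero constraints on dispersal) exist.
- Per-branch RK4 step size is resolution-tested at the rate magnitudes used
  here (rates <= ~1/Myr); rate regimes orders of magnitude faster would
  warrant a smaller `n_steps_height` target.
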