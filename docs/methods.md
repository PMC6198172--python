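# Methods

## Model

The community is modeled by generalized Lotka–Volterra (gLV) dynamics with a
shared logistic cap: for taxon *i*,

    dx_i/dt = x_i ( r_i + Σ_j a_ij · x_j/N ) ( 1 − N/K ),   N = Σ_i x_i .

Assumptions worth stating explicitly:

* **Interactions act through composition.** The effect of taxon *j* on *i*
  is `a_ij · x_j/N`, i.e. proportional to *j*'s relative abundance, not its
  absolute density. This matches what compositional surveys can constrain.
* **No intra-taxon terms.** The diagonal of `A` is fixed at zero;
  density regulation enters only through the community-wide factor
  `(1 − N/K)`. A consequence: once `N` reaches `K` the whole composition
  freezes, so all dynamical information lives in the colonization transient.
* **Zero is absorbing.** An extinct taxon cannot re-enter; there is no
  immigration term.
* **Units.** Time is in days throughout; growth rates in 1/day; abundances
  and `K` in cells (or CFU) per gram.

## Fitting and model selection

Only relative abundances are observed, so a candidate model is judged by
simulating absolute dynamics from the first observed time point and
converting to composition. The simulation starts at community size
`N0 = n0_fraction · K` (default 0.01·K — a colonizing community at 1% of
capacity).

**The initial composition is estimated, not pinned.** The obvious choice —
seeding the simulation with the observed composition at t0 — quietly treats
one noisy measurement as exact. That error is persistent and structured: an
offset in the starting log-composition propagates through the whole
trajectory, and growth-rate adjustments cannot absorb it (they change
slopes, not intercepts), so spurious interaction coefficients harvest it.
In controlled experiments, feeding the pipeline data whose t0 row was
noise-free eliminated essentially all false-positive edges on
interaction-free data, identifying the pinned start as the dominant
false-positive mechanism. The fitter therefore estimates the initial
composition as n−1 additional free parameters (a softmax over log-weights,
initialized at the observed t0 row and counted in V) — the
errors-in-variables correction that bootstrap aggregation alone cannot
provide, since every bootstrap round shares the same t0 measurement.
Setting `fit_initial_state=False` restores the pinned behavior. Observed
zeros at t0 are floored at relative abundance 1e-6 (row renormalized)
before use, because an exactly-zero start is absorbing and could never fit
later nonzero observations.

A model's free parameters are the `n` growth rates, the active interaction
coefficients (inactive ones pinned at 0) and the n−1 initial-composition
dofs. Fits use bounded derivative-based least squares (trust-region
reflective, the bounded member of the Levenberg–Marquardt family), bounds
r ∈ [−10, 10]/day, a ∈ [−50, 50], at most 200 iterations per fit. Scores:

* RSS (Eq. above) summed over *all* time points and taxa of the whole
  series, even though parameters are fitted on a training subset — selection
  thereby rewards both descriptive and predictive accuracy;
* BIC = U·ln(RSS/U) + ln(U)·V with an RSS floor of 1e-12 before the
  logarithm (noiseless data would otherwise give −∞).

**The U convention.** "Number of data points" is ambiguous for a T×n table.
We take U = T (one data point = one observed composition vector; default
`u_convention="t"`), with U = T·n available as an option. The choice is
consequential: the RSS-improvement threshold for one extra parameter is
roughly `exp(ln(U)/U) − 1`, i.e. ~11% at T = 30 but only ~4% at T·n = 90.
With the weaker T·n penalty, coefficients that fit dataset-level noise enter
the selection systematically, and because the aggregation t-test (below) is
very sensitive to consistently-signed values, the procedure then loses
type-I control on interaction-free data. With U = T the pipeline shows the
expected behavior: sparse networks, clean nulls, strong interactions called
with near-zero p-values.

**Forward stepwise search.** Start from the growth-only model. Each round
fits every remaining single coefficient and every fully-remaining reciprocal
pair {a_ij, a_ji} (pairs are natural candidates because the ecological
classification is defined on sign pairs), scores each on whole-series BIC,
and adopts the lowest; candidates within ΔBIC < 2 of the round's best *that
also lower the incumbent best* are treated as ties and one is chosen
uniformly at random. Iteration stops when no addition lowers the best BIC,
so the accepted-BIC trace is strictly decreasing. Per-candidate simulation
failures count as BIC = +∞ and never abort a round.

Each candidate is fitted from the standard cold initialization — r = 1/day,
a = 0, initial composition at the observed t0 row — so every candidate is
evaluated independently of the greedy path. Trajectory least squares is
multimodal, and warm starts from the incumbent round's parameters were
observed to land in worse optima and corrupt the greedy path by
under-fitting intermediate models (`stepwise_starts` selects cold, warm, or
best-of-both; optimizer tolerances 1e-7, far below the data's noise floor).

## Bagging, filtering, significance

Each bootstrap round draws a random train subset (`round(0.8·T)` time
points, always including t0 since it seeds every simulation; sampling
without replacement, temporal order preserved) and runs the stepwise search.
Per-round RNG streams derive from the master seed by a counter-based scheme
(`SeedSequence(master, spawn_key=(round,))`), so results are reproducible
and independent of execution order and thread count.

After all rounds: models violating biological constraints (any taxon below
`min_species_abundance`, or community below `min_community_size`, at any
output time when re-simulated over the observed span) are removed; then the
minimum-BIC slice is kept — models with BIC ≤ B* + 0.10·|B*|. The absolute
value makes the 10% band widen upward also when BIC is negative (the common
case); an absolute-ΔBIC band is available as an option.

For every ordered pair the t-test sample is the coefficient's value in each
retained model, **zero when unselected** (a coefficient absent from a model
is zero in that model by construction; an only-selected-values mode exists
for comparison). Two-sided one-sample t-test against 0; significant ⇔
p < 1 − confidence (default 0.95). Zero-variance conventions: an all-zero
sample has p = 1, a constant nonzero sample p = 0. No multiple-testing
correction is applied across the n(n−1) pairs — a deliberate property of the
procedure, not an oversight; note that the zero-inflated t-test is liberal:
a pair selected in even ~10% of models with a consistent sign can reach
significance. Growth rates are aggregated as means ± standard errors.

Edges: j → i exists iff a_ij is significant (a significant mean within
1e-12 of zero is treated as sign 0); weight = mean coefficient. Pair labels
from the sign table (+/+ mutualism, −/− competition, +/− parasitism,
+/0 commensalism, −/0 amensalism, 0/0 neutral).

## Numerics

* Integration is performed in carrying-capacity units (y = x/K) with an
  adaptive Dormand–Prince 5(4) stepper (compiled; rtol 1e-6, atol 1e-9 in
  scaled units ⇒ 1e-9·K absolute), clamping negative excursions to zero
  after each accepted step — the model preserves non-negativity
  analytically, so they are pure solver error. Parameter sets that defeat
  the explicit stepper (step-size underflow, step budget, non-finite state)
  are retried with LSODA, which handles stiffness; if that also fails, the
  candidate is penalized (large constant residuals mid-optimization; an
  infinite-RSS model at scoring time). Verified against the closed-form
  logistic solution to 1e-6 relative error.
* The empty community (N = 0) has identically zero derivative; composition
  of an empty community is reported as uniform 1/n with a degeneracy flag.

## Synthetic data: what it emulates and what it does not

The generator simulates a known gLV system, converts to composition, and
applies one of two observation-noise models: multiplicative lognormal
(plate-count-style enumeration error; each abundance multiplied by
exp(N(0, σ²)), row renormalized — σ = 0.05 is a typical 5% enumeration
error) or multinomial resampling at a given read depth (finite sequencing
depth). It does **not** emulate: taxonomic misassignment, day-to-day
compositional shocks (diet, antibiotics), process noise in the dynamics
themselves, or unobserved taxa aggregating into the modeled ones. Passing
tests on these data therefore demonstrate correctness of the *inference
machinery* under the model's own assumptions plus measurement noise, not
robustness to model misspecification on real surveys.

**Identifiability shapes the benchmark designs.** Because fractions sum
to 1, a coefficient a_ij (regressor p_j) can be largely re-expressed, within
a row, through the other fraction and a growth-rate shift; across rows,
different attributions of the same compositional drift are often
near-equivalent. Exhaustive-subset scoring on smooth, monotone composition
paths shows reciprocal +/− pairs between *any* two of three taxa fitting
equally well (ΔBIC < 1). Attribution becomes identifiable when the
composition path is genuinely two-dimensional (curved/spiral), and a long
saturation plateau further pins the interior equilibrium, leaving spurious
coefficients little room. The default three-taxon benchmark therefore hosts
one strong reciprocal +/− (parasitism) pair, T2→T1 +1.6 / T1→T2 −1.6, with
growth rates (0.10, 1.00, 0.50)/day chosen so the relative dynamics spiral
into a stable interior equilibrium (no taxon crashes; all fractions stay
above ~0.08), sampled at 30 points over 20 days from a community starting at
1% of K = 1e11 cells/g. The interaction-free null community uses mildly
distinct growth rates (0.50, 0.55, 0.45)/day — smooth compositional drift
fully explained by growth terms. The strong/weak benchmark adds a second,
weaker +/− pair (±1.3) between T1 and T3 to a ±1.6 T1–T2 pair, with rates
tuned the same way; the weaker pair's selection frequency across bootstrap
rounds is roughly an order of magnitude lower, so it reaches t-test
significance only at substantially larger ensembles. The 5-taxon "cheese-like" preset (K = 2e10 CFU/g,
21 daily samples, one strong yeast→bacteria promotion plus several
inhibitions) is a qualitative stand-in for a surface-ripening community used
in integration tests — synthetic, not a reconstruction of any real dataset.

A further consequence of compositional closure worth knowing: with only two
taxa, a_12 and a_21 are almost interchangeable (only the saturation factor's
reshaping of N(t) separates them), so two-taxon benchmarks test *selection
quality* (BIC attained), not directionality.

## Known limitations

* Greedy stepwise with pairwise additions can lock in the spurious partner
  of a real one-directional interaction; the t-test across bootstraps is the
  guard, not the search itself.
* Because all bootstrap rounds share one noise realization, dataset-level
  noise structure is not averaged away by bagging; on roughly 1–2 datasets in 10 a
  noise-fitting coefficient passes both the BIC bar and the t-test (measured
  on the benchmark conditions above).
* Communities whose composition freezes early (fast saturation) or whose
  fractions crash to zero carry little identifiable signal; inference
  quality is data-limited in exactly the way the closure analysis predicts.
* Runtime scales roughly as bootstraps × rounds × n² fits; each fit is a
  trajectory optimization. Default test and validation sizes (30 time
  points, 100–240 bootstraps, 2–5 taxa) were chosen to characterize the
  procedure well at interactive runtimes.
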