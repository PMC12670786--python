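# Methods

## The ARP property and why it is the organizing principle

For a target ratio `r_1:…:r_K` with proportions `ρ_j = r_j / Σ r_k`, a
sequential randomization procedure is *allocation-ratio preserving* (ARP)
when the unconditional probability that the i-th participant receives arm j
equals `ρ_j` for every i and j. Equal-allocation procedures that are
symmetric in their arms are ARP automatically; unequal-allocation expansions
often are not. A non-ARP procedure leaks design information: an observer who
knows the method (not the past assignments) knows which enrollment positions
are more likely to receive which arm, enabling selection and evaluation bias
even under double-blinding, and distorting re-randomization test statistics.
Every diagnostic in this package is therefore built to decide ARP *exactly*,
not approximately.

## Exact arithmetic

All transition probabilities are `fractions.Fraction`. Integer and rational
weights are exact; irrational weights (e.g. `√2`) are carried as the exact
rational value of their float, so all downstream computation is exact with
respect to that representation (error < 2⁻⁵², far below any tolerance used).
The ARP verdict compares an exact maximum deviation against a tolerance
(default 1e-9); for the shipped ARP constructions the deviation is exactly 0.

## Procedures

**Complete randomization** and **permuted blocks** are standard; their state
distributions are cross-checked in the tests against the multinomial and
multivariate hypergeometric laws from scipy.

**Mapping construction.** An equal-allocation procedure over `S = Σ Q_j`
fake arms is relabelled: the first `Q_1` fake arms become arm 1, the next
`Q_2` arm 2, etc. Symmetry of the inner rule gives each fake arm probability
`1/S` at every step, hence the pooled procedure is ARP at `Q_1:…:Q_K`. The
implementation keeps the inner chain as its internal state so diagnostics
stay exact.

**Minimization comparator.** The two-arm unequal minimization evaluates, for
each arm, the imbalance `|N'_1/ρ_1 − N'_2/ρ_2|` that would result from
allocating that arm, and prefers the minimizer with probability `coin_p`
(fair split on ties). Default `coin_p = 0.9`, configurable; the non-ARP
behaviour it exists to demonstrate holds for any `coin_p > 0.5`. With a 1:2
ratio its unconditional P(arm 1) is ≈0.1–0.2 at steps 1, 3, 4, 6, 7, 9 and
≈0.74–0.82 at steps 2, 5, 8 — computed by the exact DP, and the reason this
rule ships as a comparator rather than a recommendation. Restricted to
K = 2: the preferred-arm rule does not generalize unambiguously.

**Brick tunnel randomization.** Admissible states at step i are the lattice
points with `Σ_j N_j = i` and `|N_j − iρ_j| < 1` (strict: whenever `iρ_j` is
integral the total is forced to it, so rational ratios close the tunnel
exactly at multiples of the block size). Transitions from step i to i+1 are
flows `f(N → N+e_j) ≥ 0` constrained by

1. conservation: flows out of each state sum to its occupancy probability;
2. admissibility: flows only into admissible states at i+1;
3. ARP: the total flow emitting arm j equals `ρ_j`, for every j.

For K = 2 this system is exactly determined and `BrickTunnel2` implements
the closed form: admissible first-arm totals are `floor(iρ_1)` and (when
fractional) its ceiling, occupancy of the upper state is `frac(iρ_1)`, and
the three carry/no-carry transition cases follow. For K ≥ 3 the system is
underdetermined; the remaining freedom is resolved by a concentration rule:
admissible states at i+1 are ranked by squared Euclidean distance to the
ideal point `(i+1)ρ` (ties lexicographically) and their occupancies
maximized in that order; residual freedom among flows is then pinned by
maximizing each flow variable in (state, arm) lexicographic order. Each
maximization is a tiny linear program solved by the package's own exact
rational simplex (`_exactlp.py`, two-phase, Bland's rule — deterministic and
immune to floating-point feasibility noise). For the 5:5:7 worked example
the rule yields occupancies 15/17 and 1/17 + 1/17 at step 10; there the
ARP moment constraints already determine the occupancy uniquely, so the
concentration rule only matters at steps with more admissible states than
constraints. `BrickTunnel` at K = 2 reproduces `BrickTunnel2` transition
for transition (tested), which is the package's dual-route check on the LP
machinery. For rational ratios transitions are periodic with the block size
and only one period is computed; irrational ratios are computed stepwise
(occupancy denominators can grow, so diagnostic depths in the tests stay at
n ≤ ~30 for those).

**√K-control composite.** A two-arm BTR at `K:√K` (pooled investigational
vs. control) decides control placement; pooled slots are filled by an equal
permuted block over the K investigational arms (block size K). Control
adherence inherits the tunnel bound; investigational arms are within 1 of
equality at every prefix by block closure.

## Diagnostics

Forward dynamic programming over (internal state → probability) maps gives
the unconditional profile, the totals distribution at any step, and the
imbalance tail `P(Imb_i > x)` (strict inequality; comparisons done on exact
squared imbalances so boundary x values are unambiguous). The state budget
is 10⁶ states; beyond it the DP raises and `monte_carlo_profile` /
`simulate_state_counts` (aggregate multinomial propagation — equivalent in
law to per-participant simulation but O(states) per step) are the fallback.
`exhaustive_oracle` re-derives profile and totals distribution by full
depth-first path enumeration (n ≤ 12) and is kept algorithmically disjoint
from the DP as an internal consistency oracle.

## Platform operations

Adding an arm mid-trial: the m not-yet-assigned slots of the schedule are
interleaved with the n new-arm slots by a fresh two-arm BTR at exact ratio
m:n, so every prefix of the merged segment carries new-arm slots within 1 of
the proportional share, and the old arms keep their original relative order
(preserving their accumulated balance — also the sensible per-stratum rule
for stratified schedules). Ratio changes and closures void pending slots and
start a new segment generated from scratch; assigned slots are immutable
under every adaptation, and an append-only JSONL audit log (actions carry
their seeds) replays to the exact final schedule. The interleaving BTR is an
independent seeded stream from the original schedule's.

## Eligibility and supply

The two-step scheme randomizes first to an investigational-arm/matching-
control batch (per-subpopulation batch probabilities; independent draw per
participant — a restricted first step is not the default because the scheme
is defined by probabilities), then within batch at the treatment:control
ratio via a persistent mapped permuted block (ARP within batch).
`expected_composition` computes expected treatment counts
(`n · P(batch) · treat fraction`) and eligibility-matched pooled-control
counts (`n · Σ_eligible batches P(batch) · control fraction`) exactly; with
the example scheme and (120, 24) enrollees the batch-A cells are 40/40 (1:1)
and 8/12 (1:1.5), quantifying the control-composition bias that motivates
weight-optimized schemes.

Skip-and-backfill assigns each participant the earliest open slot that is
eligible and (when inventory applies) kit-covered; bypassed slots stay open
(FIFO backfill — deterministic and minimizes slot staleness; the choice of
*which* open slot a backfilling participant takes is a genuine design
freedom, resolved here as earliest-first). Skipped slots persist within a
segment and are voided only at segment boundaries. Its distributional
properties under heavy ineligibility are deliberately not claimed; the
diagnostics are exposed instead.

Supply policies: the block (modified Zelen) policy ships one kit per arm and
replaces the block on exhaustion; the partial policy ships c kits initially
and after every c randomizations at a center, composed to cover the earliest
open central slots the center cannot currently serve (padded round-robin) —
the composition rule is a design choice, made to maximize the center's
ability to follow the central schedule. Kit conservation (dispensed ≤
shipped, per center and arm) is enforced and tested.

## Synthetic enrollment streams

`gen_enrollment` draws subpopulation and center labels i.i.d. from supplied
mixes and eligibility per arm (or per subpopulation mapping), fully seeded.
It emulates arrival-order interleaving across centers and eligibility
heterogeneity; it does **not** emulate time-varying enrollment rates,
center activation waves, or correlated eligibility, so passing tests speak
to allocation mechanics, not to calendar-time supply dynamics.

## Numerical and scale choices

- DP/oracle agreement is asserted as exact rational equality (stronger than
  any float tolerance); closed-form cross-checks against scipy run at 1e-12.
- Printed-value comparisons round half-even to 2 decimals, matching how the
  reference probabilities are displayed.
- Test and acceptance problem sizes: step-10 distributions for the 5:5:7
  worked example, reachable-state walks to step 200 (periodicity makes this
  cheap for rational ratios), profiles to n = 12, Monte Carlo consistency at
  10⁵ replicates via aggregate multinomial propagation.

## Known limitations

- The multi-arm BTR concentration rule reproduces the published 5:5:7
  pin exactly, but no other printed multi-arm case exists to pin the rule
  at steps where the flow polytope has extra freedom; a different tie-break
  convention could differ there while remaining ARP and in-tunnel.
- Wide-tunnel (maximum-tolerated-imbalance) variants, urn designs, mass
  weighted urn, minimal sufficient balance, and covariate-adaptive balancing
  are out of scope.
- Irrational-ratio BTR has no periodic reset, so exact diagnostics deepen
  in cost with n; Monte Carlo is the intended tool at depth.
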