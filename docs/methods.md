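# Methods

This note records the models implemented in `ecnsim`, the defaults chosen
where the design was genuinely open, and what the test suite does and does
not demonstrate.

## Network model

A scenario describes nodes (hospitals and POCs), each with: bed capacity,
an insurer-agreement set, semester demand statistics, per-stage service
distributions and server counts, and 21 arrival pipelines — one per
(weekday × 8-hour slot) cell, with slots P1 = [00:00, 08:00),
P2 = [08:00, 16:00), P3 = [16:00, 24:00) (half-open boundaries). A node
without beds has no ED: it accepts no arrivals and is never a transfer
destination until enabled. Transfer-time matrices are per-slot, asymmetric,
and interpreted as total door-to-door transfer time. The built-in case
network prints only the afternoon matrix, so the fixture replicates it to
all three slots; scenario documents may override any slot.

### Semester-to-rate conversion

One semester = 182 days. A node's expected arrivals in slot *s* of weekday
*d* are `demand/182 · f_d · w_s`, with weekday factors `f_d` (mean 1;
defaults Mon 1.10 … Sun 0.95) and slot weights `w_s` (defaults P1 0.18,
P2 0.42, P3 0.40 — night light, day/evening heavy). The pipeline's mean
interarrival time is 480 min divided by that count. These weights are a
modelling default, not data; both are overridable.

### Service-time distributions

Distribution specs are a family plus target mean/variance, matched by
moments: exponential, gamma, lognormal, symmetric triangular, uniform,
deterministic. Bounded families require nonnegative support
(mean ≥ half-width). The case study never published its fitted per-stage
distributions, so the fixture's stage processes are **synthetic
stand-ins**: lognormal, coefficient of variation 0.5, means (minutes)
triage 5, admission 5, bed preparation 8, nursing 10, physician 12,
treatment 45 — typical urban-ED magnitudes. Stage server counts are sized
so each stage's offered load stays below 0.8 at the node's mean demand
(the source gives only bed counts; one server per stage would be
infeasible at hospital-scale demand).

Consequence: simulated absolute waits for the case network are *not*
predictions of the real system, and the published projected per-node waits
are not reproducible. The simulator's correctness is instead established
against Erlang-C closed forms on single-node M/M/c configurations,
patient-conservation and timestamp-monotonicity invariants, and bitwise
seed determinism.

## Discrete-event engine

Event-calendar simulation on a binary heap keyed by (time, insertion
order); all randomness flows from one root seed through
`numpy.random.SeedSequence` spawning two streams per node (arrivals +
patient attributes, service times), so identical seeds give bitwise
identical logs. The calendar starts Monday 00:00; the unit is minutes.

Flow per node: arrival → triage → (transfer decision) → admission → bed
preparation → nursing assistance → physician assessment → treatment →
departure. Queue discipline is priority by triage level (1 highest), FIFO
within a level — a clinical convention, not a sourced rule. Beds are
seized at bed preparation and released at departure; an arrival finding
all beds busy at its bed-request epoch is counted *blocked* but still
queues (no balking or loss — the source reports a blocking probability but
no loss rule). The waiting-time metric is door-to-physician (arrival to
physician-assessment start); registration-to-physician is available as an
alternative property on the patient record.

Transfers: decided once, immediately after triage completion, for
triage-4/5 patients only; the slot of the decision epoch selects the
transfer-time matrix. A transferred patient re-enters the destination at
its admission stage — triage is not repeated — and may not be transferred
again (configurable, `allow_chains`). Transferred patients' waits are
attributed to the treating (destination) node and still count from the
original arrival epoch, so transfer time is inside the metric.

The dynamic expected-wait estimator for a node is
`n_ahead · mean_pre_physician_service / effective_servers`, where
`n_ahead` counts patients past triage but not yet with a physician at or
above the arriving priority, the mean pre-physician service is the summed
means of admission + bed preparation + nursing, and effective servers is
the bottleneck (minimum) server count across those stages. The estimator
is pluggable; a static per-node mean table ("planning mode") reproduces
desk reasoning from published waits.

Replication control: `run_replications` spawns independent seeds,
reporting the mean of per-replication means with a Student-t half-width.
`required_replications` is the standard normal-quantile sample-size rule
`ceil((z·sd/h)²)`, floor 2, fed by a pre-sample (conventionally 10 runs).
Warm-up is assessed on the per-period blocking-probability series: the
smallest index after which successive (optionally moving-averaged) changes
stay within tolerance; a series still moving at its end returns the full
length. Validation against an observed mean is a one-sample t test (a
zero-variance degenerate sample reports p = 1 or 0 with a flag);
scenario comparison is Mann-Whitney with a Hodges-Lehmann interval for the
location difference, reported as proposed − current (note the interval is
computed from all pairwise differences — O(n₁·n₂) memory).

## Capability analysis

One-sided (upper-limit) capability only: `Zu = (USL − μ)/σ`, `Cps = Zu/3`,
`P(error) = Φ(−Zu)`, `PPM = 10⁶·P(error)`, efficiency `1 − P(error)`,
long-term sigma = `Zu − 1.5`. Normality screening uses a correlation-type
statistic (order statistics vs Blom normal scores) with Royston's normal
approximation for the p-value of `ln(1 − r²)` — chosen over published
critical-value polynomials because those are only calibrated for small
samples, while a year of ED admissions runs to tens of thousands. A
warning is raised below p = 0.05. X-mR charts use the standard constants:
individuals limits center ± 2.66·mR̄, range chart [0, 3.267·mR̄].

Known source inconsistency: the case study's printed pre-improvement Cps
(−0.73) and PPM (985,306.3) do not follow from its own mean 201.6 /
sd 81.6 (standard formulas give −0.70 and ≈982,269). The standard formulas
are implemented; Zu (−2.10) and the sigma pair (−2.10/−3.60), which are
self-consistent, are the authoritative checks.

## Input analysis

Runs-about-the-median test (ties at the median dropped, normal
approximation without continuity correction — empirical size ≈ 5% at
n = 50); Kruskal-Wallis homogeneity with the "Homogeneous"/"Heterogeneous"
labelling at α = 0.05; chi-squared goodness of fit with moment-matched
parameters, equal-probability bins (count `max(5, n/50)` capped at 30,
df = bins − 1 − parameters). Arrival partitioning assigns each timestamp
to its (weekday, slot) cell, computes interarrival gaps within contiguous
(date, slot) blocks, pools them by cell, and tests across-cell
homogeneity — Kruskal-Wallis by default because interarrival gaps are
skewed; a classical one-way F-test is available.

## Payment settlement

Destination share `max{floor(arrangement), M(1+r)/(1+γ+θ)}`; origin share
is the remainder, so shares conserve M exactly; same-node admissions pay M
to the treating node. The denominator is `1+γ+θ`: every worked
per-admission value in the source back-solves to 1.65 = 1 + 0.19 + 0.46,
although its rendered formula reads like a product; the product variant is
available behind `denominator="product"` for sensitivity analysis. `r` is
a Pearson correlation per (direction, insurer), estimated from per-period
aggregates (weekly by default in the exporters), clamped to [0, 1], with
zero-variance series returning 0 under a warning. Arithmetic is kept exact
internally; reports round half-away-from-zero to cents (shares) or dollars
(totals). One published coalition-ledger origin cell is arithmetically
inconsistent with conservation and is treated as a misprint; the ledger
block for the reverse direction appears to carry swapped row labels
relative to the accompanying text, and this implementation follows the
text semantics (the destination receives the floored share).

## FMEA

`RPN = S·F·D` on 1-10 ordinal scales; RPN > 125 prioritises a risk:
"double-star" when S ≥ 8, "single-star" otherwise. The source bands leave
S = 7 unassigned ("8-10" vs "< 7"); it is mapped to single-star. Sorting
is RPN desc, severity desc, label — deterministic under permutation.

## Problem sizes used in the test suite

Closed-form queueing checks run 30 replications of 30 days (5 warm-up) on
M/M/1 and M/M/2 at utilisation 0.8; network-level checks run the case
fixture for 2-6 days; randomized property suites use 300-2,000 draws.
These sizes give stable verdicts for the invariants checked while keeping
the suite quick to iterate on.

## Limitations

- The synthetic-scenario generator emulates heterogeneous weekday/slot
  arrival pipelines and minute-scale service stages, but not seasonality,
  staff rosters, boarding, ambulance availability, or correlated demand
  across nodes; passing tests demonstrate correctness of the mechanics,
  not fidelity to any particular real ED.
- Geographic routing, transfer costs and ambulance fleet modelling are out
  of scope, as are alternative cooperative-game allocations of the payment
  surplus.
- Planning-mode transfer decisions use static mean waits and ignore the
  feedback a mass of transfers would induce; the dynamic estimator inside
  the simulator captures that feedback but is itself a heuristic
  (bottleneck-server approximation).
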