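# Methods

`swarmevo` models the evolution of pheromone-mediated group foraging in a
population of clonal robot swarms.  It has three layers: an embodied
agent-based foraging simulator whose bout count is a swarm's fitness, a
Wright–Fisher population of swarms evolving four binary loci, and an
analytical stochastic-tunneling model of the waiting time until the
swarm-level adaptation is complete.  This note records the model, its
assumptions, the parameters that matter, and the limits of what the
desk-scale experiments show.

## Genetics

Each swarm is clonal: every robot carries the same 4-bit genome
`{b1,b2,b3;p}`.  `b_i` sets the collision reaction of a robot currently in
behavioural state `S_i` (0 = Stay: halt for `stay_duration_s`; 1 = Leave:
back up `leave_distance_mm`).  `p` gates the ability to detect the trail
pheromone.  Sixteen genotypes exist; four matter for the valley-crossing
story: the ancestor `{0,0,0;0}`, the original `{1,0,0;0}` (efficient
searchers, no communication), the neutral intermediate `{1,0,1;0}` (the
traffic-rule allele is silent while p = 0), the inferior intermediate
`{1,0,0;1}` (communication without the traffic rule: the trail jams), and
the final genotype `{1,0,1;1}` (communication plus the inbound-priority
traffic rule: outbound trail followers give way to food-laden carriers).

## Arena and controller

A rectangular walled arena (900 × 9000 mm full scale) has the nest
(⌀ 1000 mm, marked by an overhead beacon every robot can sense) centred on
one end wall and the food disk (⌀ 300 mm, emitting light detectable within
`food_light_radius_mm`) near the opposite end.  30 rigid-disk robots
(⌀ 150 mm, max 100 mm/s) run a three-state controller at dt = 0.1 s
(12,000 ticks = 20 simulated minutes at full scale):

* **S1 searching** — correlated random walk (per-tick Gaussian heading
  noise, σ = 0.2 rad), phototaxis toward the food once inside the light
  radius, reflective walls.
* **S2 carrying/recruiting** — beeline to the nest beacon at full speed,
  depositing `deposit_amount_per_step` into the containing pheromone cell
  every tick.  A delivery (entering the nest disk) counts one foraging
  bout — the unit of swarm fitness.
* **S3 recruited** — reachable only when p = 1 and the local concentration
  is at or above `detection_threshold`.  Steering combines an outbound
  cone and two-sensor lane keeping: if the heading points more than
  `s3_outbound_cone_rad` (60°) away from the nest-opposite bearing, a
  restoring turn takes priority; otherwise two forward sensors
  (± 0.5 rad, 90 mm) steer toward the higher concentration with a constant
  right-hand bias of half a turn so counterflowing traffic separates into
  lanes.  The cone-priority design is load-bearing: summing the two
  torques instead lets the concentration gradient (which increases toward
  the nest, where carrier paths converge) trap followers in orbit around
  the nest-end pheromone blob.  After `trail_lost_steps` consecutive
  below-threshold sensor readings the robot resumes searching.

State changes at the food happen on body contact with the disk boundary.
All states except homing reflect off walls.  Small motor noise
(0.05 rad/tick) perturbs goal-directed headings; it represents actuation
error and keeps pushing contests from being perfectly collinear.

## Collisions

Bodies are rigid disks.  On each new pair contact both robots react
according to the allele at their own current state's locus; a robot whose
reaction is still active does not re-trigger against the same partner
until contact is broken.  A robot frozen by Stay is never displaced;
moving partners absorb the whole overlap correction.  The resolver
separates bodies to a 1 mm clearance, so persistent pushing breaks and
remakes contact; every remake is a countable collision event and can
legitimately re-trigger reactions.  This clearance matters: it is what
makes dense Stay-clots costly (chained re-freezing) and collision counts
sensitive to grinding traffic rather than only to first encounters.

## Pheromone field

A square grid (30 mm cells) holds the trail.  Each tick: deposits are
added, one step of mass-conserving 4-neighbour diffusion
(`diffusion_coeff` = 0.02, stability requires ≤ 0.25) runs with no-flux
walls, then multiplicative evaporation (`evaporation_coeff` = 0.005).
With `deposit_amount_per_step` = 3 a reinforced trail segment falls below
the detection threshold roughly a minute after traffic stops, so trails
are transient and must be maintained by active carriers.

The detection threshold (2.0) is deliberately high: only the near-nest
trunk, where every carrier's path converges, stays reliably above it.
Recruitment therefore happens at the nest — as it does in real ant
colonies — while far-field searchers keep searching.  This keeps the
search-efficiency locus b1 expressed in communicating swarms (otherwise
recruitment absorbs every searcher and b1 becomes invisible to
selection).  Recruits bridge sub-threshold mid-field stretches by dead
reckoning inside the outbound cone (`trail_lost_steps` = 40 ticks).

## Randomness and reproducibility

A trial seed derives one placement stream and one Philox noise stream per
robot; exactly one noise value per robot is consumed per tick whether or
not it is used.  Trials are therefore bit-reproducible and prefix-stable:
a longer trial replays the same prefix, so bout counts are non-decreasing
in trial length, and flipping b3 at p = 0 reproduces a trial bit for bit.

## Desk-scale study conditions

Mapping the landscape at full scale (16 genotypes × many trials ×
12,000 ticks) is a cluster-scale computation.  The package's desk-scale
conditions (`reduced_config()`) use a 900 × 3000 mm arena, 3,000 ticks
(5 simulated minutes), 30 robots, and a food-light radius scaled with the
arena (300 mm).  Scaling the light with the arena preserves the relative
difficulty of search versus recruitment; keeping the full-scale 600 mm
light in a short arena makes search trivially easy and abolishes the
benefit of communication altogether rather than scaling it down.  At these
conditions (256 trials/genotype) the landscape shows the qualitative
structure of the full-scale system: `{1,0,1;1}` is the unique peak
(≈ 20 bouts/trial), `{1,0,0;0}` ≈ 17, the inferior intermediate ≈ 9–10
with more collisions than the final genotype, b1 = 1 roughly doubles
fitness regardless of p, and b2 = 1 (carriers giving way) is
catastrophic.

## Wright–Fisher layer

N = 200 non-interacting clonal swarms, constant size, non-overlapping
generations.  Each generation every swarm realizes one fitness value —
one foraging trial, or one draw from stored per-genotype samples (the
surrogate provider used for desk-scale work; the two are exchangeable by
construction).  Parents are chosen in proportion to realized fitness by
inverse-CDF sampling with one uniform draw per offspring (uniform choice,
logged, if a whole generation realizes zero fitness).  Each offspring
genome then flips each locus independently with probability mu = 0.001.
Runs start all-`{0,0,0;0}` and stop when `{1,0,1;1}` is fixed.  The full
parent map is retained; the genealogy of the lowest-index swarm of the
fixed generation is traced to generation 0 and classified b3-first /
p-first / irregular by the order of the first 0→1 flips at b3 and p after
the lineage first carries `{1,0,0;0}` (shortest-path visits required; any
detour is irregular).

A single noisy fitness draw per swarm per generation is the minimal
reading of swarm-level selection and preserves the stochasticity that the
resampling analysis depends on; redrawing versus caching per-genotype
means was checked to be immaterial for the classification statistics at
the scales tested.

## Stochastic tunneling analytics

For one candidate path (original → intermediate with relative fitness r_x
→ final with relative fitness a; both mutation steps at rate mu), the
module computes:

* `U(r)` — fixation probability of a single mutant, solved exactly as the
  absorption probability of the Wright–Fisher mutant-count chain
  (binomial resampling at success probability i·r/(i·r + N − i)); the
  neutral case is returned as exactly 1/N.
* `v1` — non-appearance-or-extinction probability of the final lineage
  from one intermediate swarm, from the Galton–Watson self-consistency
  equation v = exp(r_x((1−mu)v + mu(1−ρ) − 1)) with ρ = U(a), solved by
  monotone fixed-point iteration to 1e−12 (non-convergence raises with
  the iteration count).
* `T = N·mu·[1 − U(r_x)]·(1 − v1)` — the tunneling rate, and sequential
  rates `S1 = N·mu·U(r_x)`, `S2 = N·mu·U(a/r_x)`.
* `expected_time` — the waiting-time formula
  `E[t] = T/(T+S1)² + S1(S1+S2+T)/(S2(T+S1)²)`, which tends to
  1/S1 + 1/S2 as T → 0.

The rate decomposition treats every fixation event as instantaneous.  For
small populations or near-neutral intermediates the sweeps themselves take
a comparable number of generations, so `TunnelingResult` also carries
`expected_time_total`: the same formula evaluated with T and S1 computed
from the exact finite-N thinned lineage chain (each of a lineage's k
offspring per generation carries the secondary mutation with probability
mu and establishes with probability ρ), plus the route-weighted
conditional sweep durations (Doob h-transform absorption times of the
exact chain) and the mid-lineage success latency.  Against brute-force
two-step Wright–Fisher simulation (10⁴ replicates per point) on the grid
N ∈ {10, 50} × mu ∈ {0.01, 0.005} × r_x ∈ {0.5, 1} × a ∈ {2, 5} the
worst-case disagreement of `expected_time_total` is under 4%.

Path prediction uses `expected_time` (the printed-form comparison, as the
waiting times enter only through their order for the path choice); bulk
outcome-set evaluation uses a log-spaced interpolation table of the exact
U and the Galton–Watson v1, which is accurate at N = 200 and mu = 0.001
where lineage sizes stay far from the population cap.

`predict_outcome_sets` draws (r0, r−, a) triples from bootstrap
distributions of relative mean fitness (resampling-with-replacement of
per-trial bout counts, ratio of resampled means, 10,000 replicates by
default), computes both candidate paths' expected times, predicts the
shorter one (exact ties, a measure-zero event, go to the neutral path and
are counted), and summarizes per-set path counts and mean waiting times
with 2.5th/97.5th percentiles.  Non-positive draws are rejected, redrawn
and counted.

## What the desk-scale experiments do and do not show

The acceptance experiments reproduce, at desk scale: bit-exact b3
neutrality at p = 0; the landscape ordering and the collision cost of
ruleless communication; the dominance of b3-first genealogies (47–50 of
50 across replicate batches, against the full-scale report of 44/50); the
preference of the analytic model for the neutral-intermediate path; and
the oracle equivalence of the waiting-time analytics.

Two quantitative checks sit at the edge of what the reduction preserves.
The collision excess of the ruleless communicator over the final genotype,
unambiguous at full scale, shrinks to about one per cent of ~7,500 events
per trial at desk scale — within sampling noise of a few hundred trials,
so its sign can flip between batches even though the pooled estimate is
positive.  More fundamentally, one full-scale statistic does not survive
the reduction: the requirement
that `{1,0,0;0}` peak at ≥ 0.985 population frequency before the winning
lineage's first b3/p mutation in *every* replicate.  At desk scale the
fitness advantage of the final genotype is a ≈ 1.15 (versus roughly 2 at
full scale), so the tunneling wait (~200–400 generations) is only ~20×
the b1 sweep duration (~12–17 generations).  With N·mu = 0.2 mutations
per generation, a few per cent of replicates have a neutral b3 subclade
arise *during* the sweep, ride it to a non-trivial frequency, and later
capture the p mutation; in those runs the pre-mutation peak of
`{1,0,0;0}` is far below 0.985.  This is a timescale property of the
reduced conditions, not an implementation artifact: shrinking it requires
fitness contrasts (and hence arena scales) near the full-scale ones.  The
corresponding acceptance check is expected to fail at desk scale and is
reported as computed.

Full-scale reproduction of the waiting-time numbers (mean 157.68
generations inside the predicted [145.54, 354.76] interval) requires the
100,000-trial landscape and live-fitness evolutionary runs; the pipeline
supports it (`LiveFitness`, full-scale `SimConfig` defaults) but it is a
cluster-scale computation and is not part of the desk-scale suite.

## Numerical and design notes

* Diffusion uses antisymmetric pairwise exchanges (exact mass
  conservation) and is skipped while the field is identically zero.
* Overlap resolution iterates at most 16 passes to the 1 mm clearance;
  collision events are counted per new pair contact.
* Robot placement rejects overlapping initial positions; headings are
  uniform.
* The seed scheme is counter-based throughout (SeedSequence with fixed
  spawn keys per stage, per trial, per robot), so enlarging a batch never
  perturbs existing results, and schedule order is irrelevant.
* Degenerate analytic inputs (mu ≤ 0, r ≤ 0, S2 = 0) raise descriptive
  errors rather than returning NaN.
* `stay_duration_s` = 0.9 s balances the individual costs of Stay
  (9 ticks frozen) and Leave (≈ 30 ticks for retreat and return) so that
  the traffic rule, not freezing, is what wins on the trail; the
  collision-reaction costs are otherwise unconstrained by the full-scale
  description.
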