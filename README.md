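# swarmevo

Evolution of pheromone-mediated group foraging in simulated robot swarms:
an embodied agent-based foraging simulator, a Wright–Fisher population of
clonal swarms, and the analytical stochastic-tunneling model of the
waiting time to adaptation.

## The scientific problem

Ant-like mass foraging rests on a *core* capacity — trail-pheromone
communication — that malfunctions on its own: once recruits crowd the
trail, head-on collisions between outbound (recruited) and inbound
(food-carrying) agents throttle delivery.  A *regulatory* trait, a traffic
rule in which outbound agents give way to inbound ones, rescues it.  The
package asks how such a layered system evolves when the regulatory trait
is useless without the core trait and the core trait is harmful without
the regulatory one.

Each robot swarm is clonal with a 4-locus binary genome `{b1,b2,b3;p}`:
`b_i` is the collision reaction (0 = Stay, 1 = Leave) of a robot in
behavioural state `S_i` (S1 searching, S2 carrying/recruiting, S3
recruited/trail-following), and `p` is the ability to detect the trail
pheromone.  Swarm fitness is the number of foraging bouts (food
deliveries) in one embodied trial.  A Wright–Fisher population of N = 200
swarms with per-locus mutation µ = 0.001 starts at `{0,0,0;0}` and is run
until `{1,0,1;1}` — communication plus the traffic rule — is fixed.

The headline phenomenon is *stochastic tunneling across a fitness
valley*: the population first fixes `{1,0,0;0}`; from there the direct
route through `{1,0,0;1}` (communication first) crosses a fitness valley,
while the route through `{1,0,1;0}` (traffic rule first) is selectively
neutral because b3 is unexpressed while p = 0.  Genealogies of the final
genotype therefore acquire the regulatory mutation *before* the core one
in most runs.  The analytic layer computes, for each candidate path, the
expected time to fixation

    E[t] = T/(T+S1)^2 + S1(S1+S2+T)/(S2(T+S1)^2),
    T  = N·µ·[1−U(r_x)]·(1−v1),   S1 = N·µ·U(r_x),   S2 = N·µ·U(a/r_x),

where `U(r)` is the Wright–Fisher fixation probability of a single mutant
of relative fitness r, and `v1` the probability that a single
intermediate swarm never founds an established final-genotype lineage.

## Worked example

Desk-scale conditions (900 × 3000 mm arena, 3,000 ticks, 30 robots — see
`docs/methods.md` for why the food light scales with the arena):

```python
import swarmevo as se

cfg = se.reduced_config()

# one embodied trial of the final genotype
print(se.simulate_trial(se.FINAL, cfg, seed=1))
# TrialResult(genotype=Genotype(b1=1, b2=0, b3=1, p=1), seed=1, bouts=19,
#             collisions=7187, state_steps=(63035, 8610, 18355), n_steps=3000, ...)

# fitness landscape corners (64 trials each)
for g in (se.ANCESTOR, se.ORIGINAL, se.INFERIOR_INTERMEDIATE, se.FINAL):
    d = se.estimate_fitness_samples(g, 64, cfg, seed=17)
    print(g, round(d.samples.mean(), 1))
# {0,0,0;0} 6.5     <- all-Stay ancestor
# {1,0,0;0} 17.8    <- efficient searchers, no communication
# {1,0,0;1} 8.7     <- communication without the traffic rule: the valley
# {1,0,1;1} 20.5    <- communication + traffic rule: the peak

# evolve one population on that landscape and classify its genealogy
provider = se.SurrogateFitness.from_distributions(se.map_landscape(cfg, 64, 17))
run = se.run_evolution(cfg.evolution, provider, seed=3)
print(run.fixation_generation, se.classify_genealogy(run).label)
# 258 b3_first      <- the traffic-rule mutation preceded the pheromone one

# analytic waiting times for the two candidate paths (N=200, mu=0.001)
neutral = se.expected_fixation_time(se.TunnelingParams(200, 0.001, 1.0, 1.15))
valley  = se.expected_fixation_time(se.TunnelingParams(200, 0.001, 0.49, 1.15))
print(round(neutral.expected_time), round(valley.expected_time))
# 215 20790         <- the neutral-intermediate path is predicted
```

Numbers are deterministic for a given seed; your exact values depend only
on the seeds shown.

A command-line interface mirrors the library:

```
swarmevo trial --genotype "{1,0,1;1}" --seed 1
swarmevo landscape --trials 200 --seed 0 --out landscape.csv
swarmevo evolve --replicates 50 --fitness surrogate:landscape.csv --out-dir runs/
swarmevo tunnel --n 200 --mu 0.001 --samples landscape.csv --out tunnel.json
swarmevo full --stage full --seed 0 --out-dir results/
```

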