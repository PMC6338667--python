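"""Analytical stochastic-tunneling model of two-step valley crossing.

A Wright-Fisher population of N clonal swarms starts fixed on an original
genotype (relative fitness 1).  A primary mutation (probability mu per
offspring) produces an intermediate with relative fitness r_x (r0 ~ 1 for
the neutral intermediate, r- < 1 for the inferior one); a secondary
mutation (again mu) on an intermediate background produces the final
genotype with relative fitness a.  The population can reach the final
genotype either sequentially (intermediate fixes first) or by tunneling
(the final type arises and fixes out of a transient intermediate
subpopulation).  With

* ``U(r)``   the fixation probability of a single mutant of relative
  fitness r under the same Wright-Fisher update,
* ``v1``     the probability that the lineage founded by a single
  intermediate swarm never yields an established final-genotype lineage,
* ``T  = N mu [1 - U(r_x)] (1 - v1)``            (tunneling rate),
* ``S1 = N mu U(r_x)``, ``S2 = N mu U(a / r_x)`` (sequential-step rates),

the expected number of generations until the final genotype is fixed is

    E[t] = T / (T + S1)^2  +  S1 (S1 + S2 + T) / (S2 (T + S1)^2),

whose first term is the tunneling contribution and whose second term is the
sequential contribution (E[t] -> 1/S1 + 1/S2 as T -> 0).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .fitness import RelativeFitnessSamples


@dataclass(frozen=True)
class TunnelingParams:
    N: int
    mu: float
    r_x: float  # relative fitness of the intermediate (vs the original = 1)
    a: float  # relative fitness of the final genotype

    def validate(self) -> "TunnelingParams":
        if self.N < 2:
            raise ValueError(f"N must be >= 2, got {self.N}")
        if not 0.0 < self.mu < 1.0:
            raise ValueError(f"mu must be in (0, 1), got {self.mu}")
        if self.r_x <= 0:
            raise ValueError(f"r_x must be > 0, got {self.r_x}")
        if self.a <= 0:
            raise ValueError(f"a must be > 0, got {self.a}")
        return self


@dataclass
class TunnelingResult:
    params: TunnelingParams
    U_rx: float
    v1: float
    T: float
    rate_S1: float
    rate_S2: float
    expected_time: float  # waiting-time formula (rate decomposition)
    expected_time_total: float = float("nan")  # + conditional sweep phases


@lru_cache(maxsize=4096)
def fixation_probability(r: float, N: int) -> float:
    """Fixation probability of one mutant of relative fitness r among N.

    Exact absorption probability of the Wright-Fisher chain on mutant
    counts i with binomial resampling at success probability
    i r / (i r + N - i); the neutral case is returned as exactly 1/N.
    """
    if r <= 0:
        raise ValueError(f"relative fitness must be > 0, got {r}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    if r == 1.0:
        return 1.0 / N
    i = np.arange(1, N)
    p = i * r / (i * r + (N - i))
    # interior transition matrix and absorption column at N
    P = stats.binom.pmf(i[None, :], N, p[:, None])
    rhs = p ** N
    h = np.linalg.solve(np.eye(N - 1) - P, rhs)
    return float(min(max(h[0], 0.0), 1.0))


@lru_cache(maxsize=1024)
def conditional_sweep_time(r: float, N: int) -> float:
    """Mean generations for one mutant of relative fitness r to sweep to
    fixation, conditioned on fixation (exact WF chain, h-transform).

    The rate formulation treats each fixation event as instantaneous; for
    small populations or weak selection the conditional sweep itself takes
    a non-negligible number of generations, computed here exactly from the
    Doob h-transform of the mutant-count chain.
    """
    if r <= 0:
        raise ValueError(f"relative fitness must be > 0, got {r}")
    if N < 2:
        raise ValueError(f"N must be >= 2, got {N}")
    i = np.arange(1, N)
    p = i * r / (i * r + (N - i))
    P = stats.binom.pmf(i[None, :], N, p[:, None])  # interior -> interior
    to_N = p ** N
    if r == 1.0:
        h = i / N
    else:
        h = np.linalg.solve(np.eye(N - 1) - P, to_N)
    h = np.clip(h, 1e-300, 1.0)
    # conditioned transition matrix on transient states
    Pc = P * (h[None, :] / h[:, None])
    t = np.linalg.solve(np.eye(N - 1) - Pc, np.ones(N - 1))
    return float(t[0])


class FixationTable:
    """Log-spaced interpolation table of U(r, N) for bulk evaluation."""

    def __init__(self, N: int, r_min: float, r_max: float, n_points: int = 512):
        if not 0 < r_min < r_max:
            raise ValueError("need 0 < r_min < r_max")
        self.N = N
        self._logr = np.linspace(np.log(r_min), np.log(r_max), n_points)
        self._u = np.array([fixation_probability(float(np.exp(lr)), N)
                            for lr in self._logr])

    def __call__(self, r: np.ndarray) -> np.ndarray:
        r = np.asarray(r, dtype=np.float64)
        out = np.interp(np.log(r), self._logr, self._u)
        return np.where(r == 1.0, 1.0 / self.N, out)


def _v1_fixed_point(r_x, mu, rho, tol: float = 1e-12, max_iter: int = 200000):
    """Least fixed point of v = exp(r_x ((1-mu) v + mu (1-rho) - 1)).

    The intermediate sublineage is approximated by a Galton-Watson process
    with Poisson(r_x) offspring; each offspring independently mutates to
    the final genotype with probability mu, and an arisen final lineage
    establishes (fixes) with probability rho.  Monotone iteration from 0
    converges to the extinction-or-non-appearance probability.
    """
    r_x = np.asarray(r_x, dtype=np.float64)
    mu = float(mu)
    rho = np.asarray(rho, dtype=np.float64)
    v = np.zeros(np.broadcast(r_x, rho).shape or (1,))
    for it in range(max_iter):
        s = (1.0 - mu) * v + mu * (1.0 - rho)
        v_new = np.exp(r_x * (s - 1.0))
        delta = np.max(np.abs(v_new - v))
        v = v_new
        if delta < tol:
            return np.clip(v, 0.0, 1.0)
    raise RuntimeError(
        f"v1 fixed-point iteration did not converge in {max_iter} iterations "
        f"(last max update {delta:.3e})")


def solve_v1(params: TunnelingParams, rho: float | None = None) -> float:
    """Probability that one intermediate swarm never founds an established
    final-genotype lineage.  mu = 0 would give v1 = 1 identically (handled
    by the caller via the validated mu > 0 domain)."""
    params.validate()
    if rho is None:
        rho = fixation_probability(params.a, params.N)
    return float(_v1_fixed_point(params.r_x, params.mu, rho).reshape(-1)[0])


@lru_cache(maxsize=1024)
def _lineage_rates_exact(N: int, mu: float, r_x: float, rho: float
                         ) -> tuple[float, float, float]:
    """Finite-population rates (T, S1) from the thinned mutant-count chain.

    Follows one intermediate lineage on the exact Wright-Fisher chain; each
    generation every one of its k offspring independently carries the
    secondary mutation with probability mu and, if so, establishes with
    probability rho (thinning factor (1 - mu rho)^k).  T is N mu times the
    probability of a mid-lineage establishment; S1 is N mu times the
    probability the lineage fixes with no such event.  Replaces the
    branching-process v1 where the lineage-size cap at N matters.
    """
    i = np.arange(1, N)
    p = i * r_x / (i * r_x + (N - i))
    P = stats.binom.pmf(i[None, :], N, p[:, None])
    thin = (1.0 - mu * rho) ** i
    M = P * thin[None, :]
    to_N = (p ** N) * (1.0 - mu * rho) ** N
    to_0 = (1.0 - p) ** N
    A = np.eye(N - 1) - M
    q = np.linalg.solve(A, to_0 + to_N)   # P(no mid-lineage success)
    u = np.linalg.solve(A, to_N)          # P(fix, no mid-lineage success)
    w = np.clip(1.0 - q, 0.0, 1.0)        # P(mid-lineage success)
    T = N * mu * float(w[0])
    S1 = N * mu * max(float(u[0]), 0.0)
    # conditional latency from lineage founding to the establishment event:
    # m(j) = E[steps x 1(success)] solves m = M m + w
    if w[0] > 0.0:
        m = np.linalg.solve(A, w)
        latency = float(m[0] / w[0])
    else:
        latency = 0.0
    return T, S1, latency


def sequential_rates(params: TunnelingParams) -> tuple[float, float]:
    """(S1, S2): per-generation rates of the two sequential fixation steps."""
    params.validate()
    S1 = params.N * params.mu * fixation_probability(params.r_x, params.N)
    S2 = params.N * params.mu * fixation_probability(params.a / params.r_x, params.N)
    return S1, S2


def tunneling_rate(params: TunnelingParams, v1: float | None = None) -> float:
    """T = N mu [1 - U(r_x)] (1 - v1)."""
    params.validate()
    U = fixation_probability(params.r_x, params.N)
    if v1 is None:
        v1 = solve_v1(params)
    return params.N * params.mu * (1.0 - U) * (1.0 - v1)


def _expected_time(T, S1, S2):
    T = np.asarray(T, dtype=np.float64)
    S1 = np.asarray(S1, dtype=np.float64)
    S2 = np.asarray(S2, dtype=np.float64)
    if np.any(S2 <= 0) or np.any(T + S1 <= 0):
        raise ValueError("degenerate rates: need S2 > 0 and T + S1 > 0")
    return T / (T + S1) ** 2 + S1 * (S1 + S2 + T) / (S2 * (T + S1) ** 2)


def expected_fixation_time(params: TunnelingParams) -> TunnelingResult:
    """Evaluate the displayed waiting-time formula for one parameter set."""
    params.validate()
    U = fixation_probability(params.r_x, params.N)
    v1 = solve_v1(params)
    rho = fixation_probability(params.a, params.N)
    T, S1, latency = _lineage_rates_exact(params.N, params.mu, params.r_x, rho)
    S2 = params.N * params.mu * fixation_probability(params.a / params.r_x, params.N)
    et = float(_expected_time(T, S1, S2))
    if not np.isfinite(et) or et <= 0:
        raise ValueError(f"expected fixation time is not finite/positive: {et}")
    # total time additionally counts the conditional duration of the sweeps
    # themselves (the rate decomposition treats them as instantaneous),
    # weighting the tunneling and sequential routes by their rates
    p_tun = T / (T + S1)
    sweep_tun = latency + conditional_sweep_time(params.a, params.N)
    sweep_seq = (conditional_sweep_time(params.r_x, params.N)
                 + conditional_sweep_time(params.a / params.r_x, params.N))
    total = et + p_tun * sweep_tun + (1.0 - p_tun) * sweep_seq
    return TunnelingResult(params, U, v1, T, S1, S2, et, total)


def _expected_time_bulk(N: int, mu: float, r_x: np.ndarray, a: np.ndarray,
                        table: FixationTable) -> np.ndarray:
    U_rx = table(r_x)
    rho = table(a)
    v1 = _v1_fixed_point(r_x, mu, rho)
    T = N * mu * (1.0 - U_rx) * (1.0 - v1)
    S1 = N * mu * U_rx
    S2 = N * mu * table(a / r_x)
    return _expected_time(T, S1, S2)


@dataclass
class OutcomeSetPrediction:
    """Predicted path choice and waiting time over replicated outcome sets."""

    n_sets: int
    set_size: int
    neutral_counts: np.ndarray  # per set: outcomes predicted via the neutral intermediate
    mean_times: np.ndarray  # per set: mean predicted waiting time (generations)
    count_percentiles: tuple[float, float]  # 2.5th / 97.5th of neutral_counts
    time_percentiles: tuple[float, float]  # 2.5th / 97.5th of mean_times
    n_redrawn: int = 0
    n_ties: int = 0

    def count_within_interval(self, observed: int) -> bool:
        lo, hi = self.count_percentiles
        return lo <= observed <= hi

    def time_within_interval(self, observed: float) -> bool:
        lo, hi = self.time_percentiles
        return lo <= observed <= hi


def _extract(samples) -> np.ndarray:
    if isinstance(samples, RelativeFitnessSamples):
        return samples.ratios
    return np.asarray(samples, dtype=np.float64)


def predict_outcome_sets(r0_samples, rminus_samples, a_samples, n_sets: int,
                         set_size: int, N: int, mu: float, seed: int = 0,
                         ) -> OutcomeSetPrediction:
    """Hybrid analysis: push relative-fitness distributions through the model.

    For each of ``n_sets * set_size`` outcomes, one (r0, r-, a) triple is
    drawn; the expected fixation time is computed for the neutral- and the
    inferior-intermediate path; the shorter path is the predicted outcome
    (exact ties, a measure-zero event, go to the neutral intermediate and
    are counted).  Non-positive fitness draws are rejected and redrawn.
    """
    if n_sets < 1 or set_size < 1:
        raise ValueError("n_sets and set_size must be >= 1")
    r0 = _extract(r0_samples)
    rm = _extract(rminus_samples)
    a = _extract(a_samples)
    if min(len(r0), len(rm), len(a)) == 0:
        raise ValueError("sample vectors must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0x70D5)))
    total = n_sets * set_size
    n_redrawn = 0

    def draw(pool: np.ndarray) -> np.ndarray:
        nonlocal n_redrawn
        if (pool > 0).sum() == 0:
            raise ValueError("no positive values to draw from")
        out = pool[rng.integers(0, len(pool), size=total)]
        bad = out <= 0
        while bad.any():
            n_redrawn += int(bad.sum())
            out[bad] = pool[rng.integers(0, len(pool), size=int(bad.sum()))]
            bad = out <= 0
        return out

    r0_d, rm_d, a_d = draw(r0), draw(rm), draw(a)
    all_r = np.concatenate([r0_d, rm_d, a_d, a_d / r0_d, a_d / rm_d])
    table = FixationTable(N, float(all_r.min()) / 1.5, float(all_r.max()) * 1.5)
    t_neutral = _expected_time_bulk(N, mu, r0_d, a_d, table)
    t_inferior = _expected_time_bulk(N, mu, rm_d, a_d, table)
    neutral = t_neutral <= t_inferior
    ties = int((t_neutral == t_inferior).sum())
    chosen = np.where(neutral, t_neutral, t_inferior)
    counts = neutral.reshape(n_sets, set_size).sum(axis=1)
    means = chosen.reshape(n_sets, set_size).mean(axis=1)
    cp = np.percentile(counts, [2.5, 97.5])
    tp = np.percentile(means, [2.5, 97.5])
    return OutcomeSetPrediction(n_sets, set_size, counts, means,
                                (float(cp[0]), float(cp[1])),
                                (float(tp[0]), float(tp[1])), n_redrawn, ties)


def simulate_two_step(params: TunnelingParams, n_replicates: int, seed: int = 0,
                      max_generations: int = 2_000_000) -> np.ndarray:
    """Brute-force oracle: forward Wright-Fisher simulation of the two-step
    process (original -> intermediate -> final), returning the fixation
    generation of the final genotype for each replicate.

    This is an independent stochastic implementation used to cross-check
    the analytic waiting time; it shares no code with the formula path.
    """
    params.validate()
    N, mu = params.N, params.mu
    w = np.array([1.0, params.r_x, params.a])
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 0x0A1E)))
    counts = np.zeros((n_replicates, 3), dtype=np.int64)
    counts[:, 0] = N
    times = np.full(n_replicates, -1, dtype=np.int64)
    active = np.arange(n_replicates)
    gen = 0
    while active.size:
        gen += 1
        if gen > max_generations:
            raise RuntimeError("two-step simulation exceeded the generation guard")
        sub = counts[active]
        weights = sub * w
        probs = weights / weights.sum(axis=1, keepdims=True)
        off = rng.multinomial(N, probs)
        m1 = rng.binomial(off[:, 0], mu)
        m2 = rng.binomial(off[:, 1], mu)
        off[:, 0] -= m1
        off[:, 1] += m1 - m2
        off[:, 2] += m2
        counts[active] = off
        done = off[:, 2] == N
        times[active[done]] = gen
        active = active[~done]
    return times
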