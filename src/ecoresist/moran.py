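"""Generalized Moran birth-death process for a single mutant clone.

A fixed population of size ``N`` holds ``s`` mutants and ``N - s`` ancestors;
one birth-death event happens per step and the states ``s = 0`` (extinction)
and ``s = N`` (fixation) are absorbing.  There is no mutation.  Frequency
dependence enters through the 2x2 evolutionary game

====================  ==========  ==========
payoff to \\ against   mutant      ancestor
====================  ==========  ==========
mutant (R)            ``1 - fc``  ``fe``
ancestor (A)          ``1``       ``1``
====================  ==========  ==========

so the expected payoff of a mutant in a population of ``s`` mutants excludes
self-interaction,

    P_R(s) = (s-1)/(N-1) * (1 - fc)  +  (N-s)/(N-1) * fe,       P_A = 1.

Each event chooses the reproducing individual proportionally to payoff and
the dying individual uniformly at random (the standard generalized Moran
process of the frequency-dependent-selection literature), giving

    b_s = [s P_R / (s P_R + (N-s) P_A)] * (N-s)/N,
    d_s = [(N-s) P_A / (s P_R + (N-s) P_A)] * s/N.

Everything in this module is exact linear algebra on the resulting
birth-death chain: absorption probabilities, first-passage (extinction) time
distributions via the phase-type recursion, and conditional mean absorption
times via a banded linear solve.  Time is measured in events; divide by ``N``
for generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "MoranSpec",
    "ExtinctionDistribution",
    "expected_payoffs",
    "transition_probabilities",
    "absorption_probabilities",
    "extinction_time_distribution",
    "conditional_mean_extinction_steps",
]


@dataclass(frozen=True)
class MoranSpec:
    """Parameters of the two-type birth-death chain.

    ``fc`` is the mutant's fitness cost (intrinsic fitness ``1 - fc``),
    ``fe`` its ecological fitness, ``s0`` the initial mutant count.
    """

    N: int
    fc: float
    fe: float
    s0: int = 1

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("population size N must be >= 2")
        if not (0.0 <= self.fc < 1.0):
            raise ValueError(f"fitness cost fc={self.fc} outside [0, 1)")
        if self.fe < 0.0:
            raise ValueError(f"ecological fitness fe={self.fe} must be >= 0")
        if not (0 <= self.s0 <= self.N):
            raise ValueError(f"initial mutant count s0={self.s0} outside [0, N]")


def expected_payoffs(s, spec: MoranSpec):
    """Expected payoffs ``(P_R, P_A)`` in a population of ``s`` mutants.

    ``s`` may be a scalar or array with ``1 <= s <= N - 1`` (payoffs are
    undefined at the absorbing states).
    """
    s_arr = np.asarray(s)
    if np.any((s_arr < 1) | (s_arr > spec.N - 1)):
        raise ValueError("mutant count s must satisfy 1 <= s <= N-1")
    s_arr = s_arr.astype(float)
    p_r = (s_arr - 1.0) / (spec.N - 1.0) * (1.0 - spec.fc) + (
        spec.N - s_arr
    ) / (spec.N - 1.0) * spec.fe
    p_a = np.ones_like(p_r)
    if np.isscalar(s):
        return float(p_r), float(p_a)
    return p_r, p_a


def transition_probabilities(s, spec: MoranSpec):
    """One-step probabilities ``(b_s, d_s, stay_s)``; zero at s=0 and s=N."""
    s_arr = np.atleast_1d(np.asarray(s)).astype(float)
    if np.any((s_arr < 0) | (s_arr > spec.N)):
        raise ValueError("state s must lie in {0, ..., N}")
    N = float(spec.N)
    b = np.zeros_like(s_arr)
    d = np.zeros_like(s_arr)
    interior = (s_arr >= 1) & (s_arr <= N - 1)
    si = s_arr[interior]
    p_r, _ = expected_payoffs(si, spec)
    tot = si * p_r + (N - si) * 1.0
    b[interior] = (si * p_r / tot) * ((N - si) / N)
    d[interior] = ((N - si) * 1.0 / tot) * (si / N)
    stay = 1.0 - b - d
    if np.isscalar(s):
        return float(b[0]), float(d[0]), float(stay[0])
    return b, d, stay


def _interior_rates(spec: MoranSpec):
    """Vectors ``b, d`` over the transient states 1..N-1."""
    s = np.arange(1, spec.N)
    b, d, _ = transition_probabilities(s, spec)
    return b, d


def _fixation_profile(spec: MoranSpec) -> np.ndarray:
    """Fixation probability from every state 0..N (log-space ratio formula).

    Uses p_fix(s) = S(s)/S(N) with S(k) = sum_{i<k} prod_{j<=i} d_j/b_j and
    d_j/b_j = 1/P_R(j).  A state with ``b_j = 0`` (possible only when the
    mutant payoff vanishes, e.g. fe=0 at j=1) blocks upward passage: starting
    at or below it fixation is impossible, and starting above it the chain is
    restricted to states > j.
    """
    N = spec.N
    s = np.arange(1, N)
    p_r, _ = expected_payoffs(s, spec)
    pfix = np.zeros(N + 1)
    pfix[N] = 1.0
    blocked = np.flatnonzero(p_r <= 0.0) + 1  # states j with b_j = 0
    j0 = int(blocked.max()) if blocked.size else 0
    # states 1..j0 can never cross j0 upward -> pfix 0 there; above j0 the
    # chain behaves as a birth-death process on {j0, ..., N} with j0 fatal.
    with np.errstate(divide="ignore"):
        log_gamma = -np.log(p_r[j0:])  # states j0+1 .. N-1
    cum = np.concatenate([[0.0], np.cumsum(log_gamma)])  # S-terms, log scale
    running = np.logaddexp.accumulate(cum)  # log S(k) for k = 1, 2, ...
    pfix[j0 + 1 : N] = np.exp(running[: N - j0 - 1] - running[-1])
    return pfix


def absorption_probabilities(spec: MoranSpec) -> tuple[float, float]:
    """Exact ``(p_ext, p_fix)`` from the initial state ``s0``."""
    pfix = float(_fixation_profile(spec)[spec.s0])
    return 1.0 - pfix, pfix


def _extinction_profile(spec: MoranSpec) -> np.ndarray:
    return 1.0 - _fixation_profile(spec)


def conditional_mean_extinction_steps(spec: MoranSpec) -> float:
    """Mean number of events to extinction, conditioned on extinction.

    Solves the tridiagonal first-step system ``(I - Q) w = a`` over the
    transient states, where ``a`` is the per-state extinction probability;
    the conditional mean from state ``s0`` is ``w[s0] / a[s0]``.
    """
    if spec.s0 == 0:
        return 0.0
    if spec.s0 == spec.N:
        raise ValueError("extinction is impossible from s0 = N")
    N = spec.N
    b, d = _interior_rates(spec)
    a = _extinction_profile(spec)[1:N]
    n = N - 1
    ab = np.zeros((3, n))
    ab[0, 1:] = -b[:-1]  # superdiagonal: up-moves
    ab[1, :] = b + d  # I - stay
    ab[2, :-1] = -d[1:]  # subdiagonal: down-moves
    w = solve_banded((1, 1), ab, a)
    return float(w[spec.s0 - 1] / a[spec.s0 - 1])


@dataclass
class ExtinctionDistribution:
    """First-passage-time distribution of absorption at extinction (s=0).

    ``pmf[t]`` is the probability that extinction happens exactly at event
    step ``t``; if ``conditioned`` the mass is divided by the total
    extinction probability so it sums to 1 as the horizon grows.
    ``mean_steps`` comes from the exact linear system; ``pmf_mean_steps``
    from the (possibly truncated) pmf.  ``truncated`` flags a horizon that
    captured less than 99.9% of the conditional mass.
    """

    pmf: np.ndarray
    p_ext: float
    p_fix: float
    mean_steps: float
    mean_generations: float
    pmf_mean_steps: float
    captured_mass: float
    conditioned: bool
    truncated: bool
    spec: MoranSpec = field(repr=False)

    def moments(self) -> tuple[float, float, float]:
        """(mean, sd, skewness) of the captured conditional distribution."""
        t = np.arange(self.pmf.size, dtype=float)
        w = self.pmf / self.pmf.sum()
        m = float(np.sum(w * t))
        var = float(np.sum(w * (t - m) ** 2))
        sd = np.sqrt(var)
        skew = float(np.sum(w * (t - m) ** 3) / sd**3) if sd > 0 else 0.0
        return m, sd, skew


def extinction_time_distribution(
    spec: MoranSpec, horizon: int, conditioned: bool = True
) -> ExtinctionDistribution:
    """Extinction-time pmf by iterating the transient transition structure.

    The sub-stochastic tridiagonal kernel over states 1..N-1 is applied
    repeatedly to the initial point mass; the probability flowing into state
    0 at each step is the extinction-time pmf (a discrete phase-type
    distribution).  Cost is O(N * horizon).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    N = spec.N
    if spec.s0 == 0:
        pmf = np.zeros(horizon + 1)
        pmf[0] = 1.0
        return ExtinctionDistribution(
            pmf, 1.0, 0.0, 0.0, 0.0, 0.0, 1.0, conditioned, False, spec
        )
    if spec.s0 == N:
        raise ValueError("s0 = N is absorbing at fixation; no extinction time")

    b, d = _interior_rates(spec)
    stay = 1.0 - b - d
    v = np.zeros(N - 1)
    v[spec.s0 - 1] = 1.0
    pmf = np.zeros(horizon + 1)
    for t in range(1, horizon + 1):
        pmf[t] = v[0] * d[0]
        nxt = v * stay
        nxt[1:] += v[:-1] * b[:-1]
        nxt[:-1] += v[1:] * d[1:]
        v = nxt

    p_ext, p_fix = absorption_probabilities(spec)
    mean_exact = conditional_mean_extinction_steps(spec)
    captured = float(pmf.sum() / p_ext)
    truncated = captured < 0.999
    if truncated:
        warnings.warn(
            f"horizon={horizon} captured only {captured:.4f} of the conditional "
            "extinction mass; increase the horizon",
            RuntimeWarning,
            stacklevel=2,
        )
    mass = pmf.sum()
    pmf_mean = float(np.sum(np.arange(horizon + 1) * pmf) / mass) if mass > 0 else 0.0
    if conditioned:
        pmf = pmf / p_ext
    return ExtinctionDistribution(
        pmf=pmf,
        p_ext=p_ext,
        p_fix=p_fix,
        mean_steps=mean_exact,
        mean_generations=mean_exact / N,
        pmf_mean_steps=pmf_mean,
        captured_mass=captured,
        conditioned=conditioned,
        truncated=truncated,
        spec=spec,
    )
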