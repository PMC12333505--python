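"""Lineage-tracking Wright-Fisher simulator with frequency-dependent fitness.

The population has constant size ``N``.  Each generation consists of

1. a mutation step: every ancestor individual mutates with probability
   ``mu``; each new mutant founds its own lineage of size 1 with a fresh
   (fi, fe) draw from the configured DFE/DEE;
2. a selection step: the next generation is one multinomial draw of ``N``
   individuals with probabilities proportional to ``count * fitness``, where
   the ancestor has fitness 1 and lineage ``j`` has fitness
   ``fi_j + (fe_j - fi_j) * x`` at ancestor fraction ``x`` (evaluated once
   per generation, after mutation).

Only ancestors mutate (mutant back- and double-mutation are ignored), and
mutant lineages interact only through the shared ancestor fraction and the
normalization -- the dilute-mutant assumption of the model.  A lineage whose
count hits zero is extinct; its extinction time ``tau`` is the number of
generations survived after emergence, so a mutant with no offspring in its
first selection step has ``tau = 0``.  Lineages alive at the end of the run
are censored and excluded from mean-``tau`` summaries.

Long quiescent stretches (no mutants alive, which dominates small-``N mu``
runs) are advanced in one step by sampling the waiting time to the next
mutation event from its exact geometric law and the number of simultaneous
mutants from the exact zero-truncated binomial, so the fast path changes
nothing about the process distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitness import EffectDistribution, FitnessProfile, UniformEffect, uniform_dfe

__all__ = [
    "WFParams",
    "MutantLineage",
    "WFResult",
    "wf_generation",
    "run",
    "run_replicates",
    "extinction_time_curve",
    "stationary_fe_histogram",
    "stationary_mean_mutants",
    "simulate_fixation",
]

DEFAULT_FMAX = 0.999


@dataclass
class WFParams:
    """Configuration of a Wright-Fisher run.

    ``fc`` is the minimum fitness cost: the default DFE is uniform on
    [0, 1-fc].  The default DEE is uniform on [0, 0.999].  ``burn_in``
    generations are excluded from stationary summaries.  When ``ecology``
    is False each mutant's fe is set equal to its fi (constant-fitness
    lineages; the no-ecology null model).
    """

    N: int
    mu: float
    generations: int
    fc: float = 0.0
    dee: Optional[EffectDistribution] = None
    dfe: Optional[EffectDistribution] = None
    burn_in: int = 0
    seed: Optional[int] = None
    ecology: bool = True
    record_trajectories: bool = False
    initial_lineages: Sequence[tuple[FitnessProfile, int]] = ()
    _dfe_cache: Optional[EffectDistribution] = field(
        default=None, init=False, repr=False, compare=False
    )
    _dee_cache: Optional[EffectDistribution] = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not (0.0 <= self.mu < 1.0):
            raise ValueError(f"mutation probability mu={self.mu} outside [0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not (0 <= self.burn_in < self.generations):
            raise ValueError("burn_in must satisfy 0 <= burn_in < generations")
        if not (0.0 <= self.fc < 1.0):
            raise ValueError(f"minimum fitness cost fc={self.fc} outside [0, 1)")

    def resolved_dfe(self) -> EffectDistribution:
        if self._dfe_cache is None:
            self._dfe_cache = self.dfe if self.dfe is not None else uniform_dfe(self.fc)
        return self._dfe_cache

    def resolved_dee(self) -> EffectDistribution:
        if self._dee_cache is None:
            self._dee_cache = (
                self.dee if self.dee is not None else UniformEffect(0.0, DEFAULT_FMAX)
            )
        return self._dee_cache


@dataclass
class MutantLineage:
    """Record of one mutant lineage (row view of the lineage table)."""

    id: int
    profile: FitnessProfile
    birth_generation: int
    tau: Optional[int]  # None while censored
    censored: bool
    person_generations: float  # post-burn-in individuals summed over time
    trajectory: Optional[np.ndarray] = None


class _Records:
    """Flat, amortized-growth storage for finished lineage records."""

    _FIELDS = ("ids", "fi", "fe", "birth", "tau", "persongen")

    def __init__(self, capacity: int = 1024):
        self.n = 0
        self.ids = np.empty(capacity, dtype=np.int64)
        self.fi = np.empty(capacity)
        self.fe = np.empty(capacity)
        self.birth = np.empty(capacity, dtype=np.int64)
        self.tau = np.empty(capacity, dtype=np.int64)  # -1 == censored
        self.persongen = np.empty(capacity)

    def _grow(self, need: int) -> None:
        cap = self.fi.size
        while cap < need:
            cap *= 2
        for name in self._FIELDS:
            arr = getattr(self, name)
            new = np.empty(cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def append(self, ids, fi, fe, birth, tau, persongen) -> None:
        k = len(fi)
        if self.n + k > self.fi.size:
            self._grow(self.n + k)
        sl = slice(self.n, self.n + k)
        self.ids[sl] = ids
        self.fi[sl] = fi
        self.fe[sl] = fe
        self.birth[sl] = birth
        self.tau[sl] = tau
        self.persongen[sl] = persongen
        self.n += k


class WFState:
    """Mutable simulator state: ancestor count plus live-lineage arrays."""

    __slots__ = (
        "N",
        "gen",
        "anc",
        "L",
        "cnt",
        "fi",
        "fe",
        "dif",
        "birth",
        "persongen",
        "ids",
        "next_id",
        "records",
        "trajectories",
        "_pbuf",
    )

    _ARRAYS = ("cnt", "fi", "fe", "dif", "birth", "persongen", "ids")

    def __init__(self, N: int, capacity: int = 64):
        self.N = N
        self.gen = 0
        self.anc = N
        self.L = 0
        self.cnt = np.zeros(capacity, dtype=np.int64)
        self.fi = np.zeros(capacity)
        self.fe = np.zeros(capacity)
        self.dif = np.zeros(capacity)  # fe - fi, cached for the hot loop
        self.birth = np.zeros(capacity, dtype=np.int64)
        self.persongen = np.zeros(capacity)
        self.ids = np.zeros(capacity, dtype=np.int64)
        self.next_id = 0
        self.records = _Records()
        self.trajectories: Optional[dict[int, list]] = None
        self._pbuf = np.empty(capacity + 1)

    def _ensure(self, need: int) -> None:
        cap = self.cnt.size
        if need <= cap:
            return
        while cap < need:
            cap *= 2
        for name in self._ARRAYS:
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: self.L] = arr[: self.L]
            setattr(self, name, new)
        self._pbuf = np.empty(cap + 1)

    def add_lineages(self, fi, fe, counts, birth: Optional[int] = None) -> None:
        """Register new lineages.  ``birth`` defaults to the generation whose
        mutation step is running (``gen + 1``); pass 0 for initial lineages."""
        k = len(fi)
        self._ensure(self.L + k)
        sl = slice(self.L, self.L + k)
        self.cnt[sl] = counts
        self.fi[sl] = fi
        self.fe[sl] = fe
        self.dif[sl] = np.asarray(fe) - np.asarray(fi)
        self.birth[sl] = self.gen + 1 if birth is None else birth
        self.persongen[sl] = 0.0
        self.ids[sl] = np.arange(self.next_id, self.next_id + k)
        self.next_id += k
        self.L += k
        self.anc -= int(np.sum(counts))
        if self.anc < 0:
            raise ValueError("initial lineages exceed population size")

    def mutant_total(self) -> int:
        return int(self.cnt[: self.L].sum())


def wf_generation(state: WFState, params: WFParams, rng: np.random.Generator) -> WFState:
    """Advance the state by one generation (mutation step, then selection).

    Mutates ``state`` in place and returns it.  Extinct lineages are moved
    to the finished-record store with their extinction time.
    """
    # --- mutation step: ancestors mutate with probability mu
    k = rng.binomial(state.anc, params.mu) if (params.mu > 0.0 and state.anc > 0) else 0
    if k > 0:
        _spawn_mutants(state, params, rng, k)
    if state.L == 0:
        state.gen += 1
        return state
    _select_only(state, params, rng)
    return state


def _spawn_mutants(state, params, rng, k: int) -> None:
    """Found ``k`` new size-1 lineages with fresh (fi, fe) draws."""
    fi = np.asarray(params.resolved_dfe().sample(rng, k), dtype=float)
    if params.ecology:
        fe = np.asarray(params.resolved_dee().sample(rng, k), dtype=float)
    else:
        fe = fi  # constant-fitness lineages: no frequency dependence
    state.add_lineages(fi, fe, np.ones(k, dtype=np.int64))


@dataclass
class WFResult:
    """Outcome of one Wright-Fisher run.

    ``lineages`` is a table with one row per emerged lineage: id, fi, fe,
    birth_generation, tau (NaN while censored), censored flag and post-
    burn-in person-generations.  ``mutant_totals[g]`` is the total mutant
    count after the selection step of generation ``g`` (index 0 is the
    initial state); ancestor counts are ``N - mutant_totals``.
    """

    params: WFParams
    lineages: pd.DataFrame
    mutant_totals: np.ndarray
    trajectories: Optional[dict[int, np.ndarray]] = field(default=None, repr=False)

    @property
    def ancestor_totals(self) -> np.ndarray:
        return self.params.N - self.mutant_totals

    @property
    def n_lineages(self) -> int:
        return len(self.lineages)

    def lineage(self, lineage_id: int) -> MutantLineage:
        row = self.lineages.loc[self.lineages["id"] == lineage_id].iloc[0]
        traj = None
        if self.trajectories is not None:
            traj = self.trajectories.get(lineage_id)
        tau = None if row["censored"] else int(row["tau"])
        return MutantLineage(
            id=int(row["id"]),
            profile=FitnessProfile(fi=float(row["fi"]), fe=float(row["fe"])),
            birth_generation=int(row["birth_generation"]),
            tau=tau,
            censored=bool(row["censored"]),
            person_generations=float(row["person_generations"]),
            trajectory=traj,
        )


def run(params: WFParams, rng: Optional[np.random.Generator] = None) -> WFResult:
    """Run the simulator for ``params.generations`` generations.

    Reproducible given ``params.seed``; every emerged lineage is recorded,
    including those with ``tau = 0``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    state = WFState(params.N)
    if params.record_trajectories:
        state.trajectories = {}
    for profile, count in params.initial_lineages:
        state.add_lineages(
            np.array([profile.fi]), np.array([profile.fe]), np.array([count]),
            birth=0,
        )
    gens = params.generations
    totals = np.zeros(gens + 1, dtype=np.int64)
    totals[0] = state.mutant_total()
    N = params.N
    mu = params.mu
    # exact fast path through all-ancestor stretches
    p_event = 1.0 - (1.0 - mu) ** N if mu > 0.0 else 0.0
    log_p0 = N * np.log1p(-mu) if mu > 0.0 else 0.0
    use_skip = mu > 0.0 and not params.record_trajectories
    while state.gen < gens:
        if state.L == 0 and use_skip:
            wait = int(rng.geometric(p_event)) if p_event > 0 else gens + 1
            if state.gen + wait > gens:
                state.gen = gens
                break  # totals already zero-filled
            state.gen += wait - 1  # quiescent generations
            # conditional number of simultaneous mutants (zero-truncated binomial)
            p0 = np.exp(log_p0)
            u = p0 + rng.random() * (1.0 - p0)
            k = max(int(stats.binom.ppf(u, N, mu)), 1)
            _spawn_mutants(state, params, rng, k)
            _select_only(state, params, rng)
            totals[state.gen] = N - state.anc
        else:
            wf_generation(state, params, rng)
            totals[state.gen] = N - state.anc
    # censor survivors
    L = state.L
    if L > 0:
        state.records.append(
            state.ids[:L],
            state.fi[:L],
            state.fe[:L],
            state.birth[:L],
            np.full(L, -1, dtype=np.int64),
            state.persongen[:L],
        )
    rec = state.records
    n = rec.n
    censored = rec.tau[:n] == -1
    order = np.argsort(rec.ids[:n], kind="stable")
    censored = censored[order]
    lineages = pd.DataFrame(
        {
            "id": rec.ids[:n][order],
            "fi": rec.fi[:n][order],
            "fe": rec.fe[:n][order],
            "birth_generation": rec.birth[:n][order],
            "tau": np.where(censored, np.nan, rec.tau[:n][order]),
            "censored": censored,
            "person_generations": rec.persongen[:n][order],
        }
    )
    trajectories = None
    if state.trajectories is not None:
        trajectories = {k: np.asarray(v) for k, v in state.trajectories.items()}
    return WFResult(
        params=params, lineages=lineages, mutant_totals=totals, trajectories=trajectories
    )


def _select_only(state: WFState, params: WFParams, rng: np.random.Generator) -> None:
    """Selection step (one multinomial draw) and retirement of extinct lineages."""
    N = state.N
    L = state.L
    x = state.anc / N  # ancestor fraction after mutation
    cnt = state.cnt[:L]
    w = cnt * (state.fi[:L] + state.dif[:L] * x)
    total = state.anc + w.sum()
    if total <= 0.0:  # unreachable while the ancestor persists
        raise RuntimeError("total selection weight vanished")
    p = state._pbuf[: L + 1]
    np.divide(w, total, out=p[:L])
    p[L] = state.anc / total
    draw = rng.multinomial(N, p)
    cnt[:] = draw[:L]
    state.anc = N - int(draw[:L].sum())
    state.gen += 1
    if state.gen > params.burn_in:
        state.persongen[:L] += cnt
    if state.trajectories is not None:
        for j in range(L):
            state.trajectories.setdefault(int(state.ids[j]), []).append(int(cnt[j]))
    dead = cnt == 0
    if dead.any():
        alive = ~dead
        state.records.append(
            state.ids[:L][dead],
            state.fi[:L][dead],
            state.fe[:L][dead],
            state.birth[:L][dead],
            state.gen - state.birth[:L][dead],  # tau; 0 if died immediately
            state.persongen[:L][dead],
        )
        La = int(alive.sum())
        for name in WFState._ARRAYS:
            arr = getattr(state, name)
            arr[:La] = arr[:L][alive]
        state.L = La


def run_replicates(params: WFParams, replicates: int, seed: Optional[int] = None):
    """Independent replicate runs with child seeds spawned from one seed.

    The global seed is expanded through ``numpy.random.SeedSequence.spawn``
    so adding replicates never perturbs earlier streams.
    """
    root = np.random.SeedSequence(seed if seed is not None else params.seed)
    out = []
    for child in root.spawn(replicates):
        out.append(run(params, rng=np.random.default_rng(child)))
    return out


def _pooled_lineages(results) -> pd.DataFrame:
    if isinstance(results, WFResult):
        return results.lineages
    return pd.concat([r.lineages for r in results], ignore_index=True)


def extinction_time_curve(results, bin_edges) -> pd.DataFrame:
    """Mean extinction time binned by ecological fitness.

    Censored lineages are excluded from the means and counted per bin.
    Empty bins are reported with NaN means, not zeros.
    """
    lin = _pooled_lineages(results)
    edges = np.asarray(bin_edges, dtype=float)
    fe = lin["fe"].to_numpy()
    tau = lin["tau"].to_numpy()
    cens = lin["censored"].to_numpy()
    idx = np.digitize(fe, edges) - 1  # bin of each lineage
    nb = edges.size - 1
    ok = (idx >= 0) & (idx < nb) & ~cens
    okc = (idx >= 0) & (idx < nb) & cens
    n = np.bincount(idx[ok], minlength=nb)
    n_cens = np.bincount(idx[okc], minlength=nb)
    s1 = np.bincount(idx[ok], weights=tau[ok], minlength=nb)
    s2 = np.bincount(idx[ok], weights=tau[ok] ** 2, minlength=nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s1 / np.maximum(n, 1), np.nan)
        var = np.where(n > 1, (s2 - n * mean**2) / np.maximum(n - 1, 1), np.nan)
        se = np.sqrt(var / np.maximum(n, 1))
    return pd.DataFrame(
        {
            "fe_lo": edges[:-1],
            "fe_hi": edges[1:],
            "fe_mid": (edges[:-1] + edges[1:]) / 2.0,
            "n": n,
            "n_censored": n_cens,
            "mean_tau": mean,
            "se_tau": se,
        }
    )


def _postburn_generations(result: WFResult) -> int:
    return result.params.generations - result.params.burn_in


def stationary_mean_mutants(result: WFResult) -> float:
    """Time-averaged total mutant count over post-burn-in generations."""
    return float(result.mutant_totals[result.params.burn_in + 1 :].mean())


def stationary_fe_histogram(results, bin_edges) -> pd.DataFrame:
    """Mean mutant individuals per generation, binned by ecological fitness.

    Weighting is by mutant individuals (each lineage contributes its summed
    post-burn-in counts), matching the stationary-density prediction whose
    integral is the expected mutant fraction.  A by-lineage variant is the
    ``n_lineages`` column.  The table's ``attrs['stationary']`` flag records
    a first-half/second-half comparison of the total mutant count (batch
    means, 3 SE); a failure leaves a warning flag rather than an error.
    """
    if isinstance(results, WFResult):
        results = [results]
    edges = np.asarray(bin_edges, dtype=float)
    nb = edges.size - 1
    persongen = np.zeros(nb)
    n_lin = np.zeros(nb, dtype=np.int64)
    total_gens = 0
    stationary = True
    for r in results:
        lin = r.lineages
        idx = np.digitize(lin["fe"].to_numpy(), edges) - 1
        ok = (idx >= 0) & (idx < nb)
        persongen += np.bincount(
            idx[ok], weights=lin["person_generations"].to_numpy()[ok], minlength=nb
        )
        n_lin += np.bincount(idx[ok], minlength=nb)
        total_gens += _postburn_generations(r)
        series = r.mutant_totals[r.params.burn_in + 1 :]
        if not _halves_consistent(series):
            stationary = False
    out = pd.DataFrame(
        {
            "fe_lo": edges[:-1],
            "fe_hi": edges[1:],
            "fe_mid": (edges[:-1] + edges[1:]) / 2.0,
            "mean_mutants": persongen / max(total_gens, 1),
            "n_lineages": n_lin,
        }
    )
    out.attrs["stationary"] = stationary
    if not stationary:
        warnings.warn(
            "first/second-half mutant totals differ by more than 3 SE; "
            "the run may not have reached stationarity",
            RuntimeWarning,
            stacklevel=2,
        )
    return out


def _halves_consistent(series: np.ndarray, n_batches: int = 20) -> bool:
    """Batch-means check that two halves of a time series agree within 3 SE."""
    half = series.size // 2
    if half < n_batches * 2:
        return True
    a, b = series[:half], series[half : 2 * half]
    means = []
    ses = []
    for part in (a, b):
        batches = part[: (part.size // n_batches) * n_batches].reshape(n_batches, -1)
        bm = batches.mean(axis=1)
        means.append(bm.mean())
        ses.append(bm.std(ddof=1) / np.sqrt(n_batches))
    se = float(np.hypot(ses[0], ses[1]))
    if se == 0.0:
        return means[0] == means[1]
    return abs(means[0] - means[1]) <= 3.0 * se


def simulate_fixation(
    N: int,
    profile: FitnessProfile,
    s0: int,
    replicates: int,
    seed: Optional[int] = None,
    max_generations: int = 1_000_000,
) -> dict:
    """Fixation/extinction frequencies of a single clone (no mutation).

    Vectorized two-type Wright-Fisher: the mutant count follows
    ``m' ~ Binomial(N, m f(x) / (m f(x) + N - m))`` with the mutant fitness
    evaluated at the current ancestor fraction ``x``.  Returns counts of
    fixed / extinct / still-segregating replicates plus the fixation
    estimate and its binomial standard error.
    """
    rng = np.random.default_rng(seed)
    m = np.full(replicates, s0, dtype=np.int64)
    active = np.ones(replicates, dtype=bool)
    fixed = 0
    lost = 0
    for _ in range(max_generations):
        if not active.any():
            break
        ma = m[active]
        x = (N - ma) / N
        f = profile.fi + (profile.fe - profile.fi) * x
        w = ma * f
        p = w / (w + (N - ma))
        ma = rng.binomial(N, p)
        m[active] = ma
        done_fix = ma == N
        done_lost = ma == 0
        fixed += int(done_fix.sum())
        lost += int(done_lost.sum())
        still = ~(done_fix | done_lost)
        idx = np.flatnonzero(active)
        active[idx[~still]] = False
    p_fix = fixed / replicates
    se = np.sqrt(max(p_fix * (1 - p_fix), 1e-300) / replicates)
    return {
        "n_fixed": fixed,
        "n_extinct": lost,
        "n_pending": int(active.sum()),
        "p_fix": p_fix,
        "se": float(se),
    }

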