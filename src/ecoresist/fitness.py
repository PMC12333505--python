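"""Fitness model shared by the simulators and the closed-form layer.

A resistant mutant is characterized by two dimensionless growth rates, both
relative to the ancestor's (normalized to 1):

* intrinsic fitness ``fi`` -- the mutant's monoculture growth rate; the
  fitness cost of resistance is ``fc = 1 - fi``;
* ecological fitness ``fe`` -- the mutant's growth rate in an almost-all-
  ancestor population.

Between the two endpoints the mutant growth rate is assumed to vary linearly
with the ancestor fraction ``x``:  ``f(x) = fi + (fe - fi) * x``.  A mutant
with ``fe > fi`` experiences negative frequency-dependent selection (its
fitness rises as the ancestor becomes more common); ``fe > 1`` additionally
permits stable coexistence with the ancestor.

New mutants draw ``fi`` from a distribution of fitness effects (DFE) and,
independently, ``fe`` from a distribution of ecological effects (DEE).  Both
are represented by :class:`EffectDistribution` objects with a density, a CDF
and a sampler on a bounded support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "FitnessProfile",
    "EffectDistribution",
    "UniformEffect",
    "GaussianEffect",
    "TabulatedEffect",
    "mutant_fitness",
    "draw_mutant",
    "uniform_dfe",
    "uniform_dee",
    "distribution_from_spec",
]

#: Ancestor reference fitness.  All mutant fitness values are relative to it.
ANCESTOR_FITNESS = 1.0

#: Largest ecological fitness the simulators accept.  Closed-form results
#: additionally require the DEE upper bound to be strictly below 1.
FE_CEILING = 1.5


@dataclass(frozen=True)
class FitnessProfile:
    """Intrinsic and ecological fitness of a single mutant lineage.

    Parameters
    ----------
    fi
        Monoculture growth rate, in [0, 1].  (``fi = 1`` is the exactly
        neutral edge case used by drift cross-checks; distributions of
        fitness effects draw strictly below 1 whenever the minimum cost is
        positive.)
    fe
        Growth rate in an almost-all-ancestor population, >= 0.
    """

    fi: float
    fe: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fi <= 1.0):
            raise ValueError(f"intrinsic fitness fi={self.fi} outside [0, 1]")
        if not (self.fe >= 0.0):
            raise ValueError(f"ecological fitness fe={self.fe} must be >= 0")

    @property
    def cost(self) -> float:
        """Fitness cost of resistance, ``1 - fi``."""
        return 1.0 - self.fi


def mutant_fitness(profile: FitnessProfile, ancestor_fraction):
    """Growth rate of a mutant in a population with the given ancestor fraction.

    Linear interpolation between the monoculture rate ``fi`` (ancestor
    fraction 0) and the ecological rate ``fe`` (ancestor fraction 1).

    Parameters
    ----------
    profile
        The mutant's fitness profile.
    ancestor_fraction
        Scalar or array in [0, 1].

    Returns
    -------
    float or ndarray
        ``fi + (fe - fi) * ancestor_fraction``.
    """
    x = np.asarray(ancestor_fraction, dtype=float)
    if np.any((x < 0.0) | (x > 1.0)):
        raise ValueError("ancestor_fraction must lie in [0, 1]")
    out = profile.fi + (profile.fe - profile.fi) * x
    return float(out) if np.isscalar(ancestor_fraction) else out


class EffectDistribution:
    """A distribution over fitness values on a bounded support [lo, hi].

    Subclasses implement :meth:`pdf`, :meth:`cdf` and :meth:`sample`; the
    density integrates to 1 over the support and samples never leave it.
    """

    kind: str = "abstract"
    lo: float
    hi: float

    @property
    def support(self) -> tuple[float, float]:
        return (self.lo, self.hi)

    def pdf(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def cdf(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def sample(self, rng: np.random.Generator, size=None):  # pragma: no cover
        raise NotImplementedError

    def spec(self) -> dict:
        """Serializable description (kind + parameters) for config files."""
        raise NotImplementedError


class UniformEffect(EffectDistribution):
    """Uniform density on [lo, hi]."""

    kind = "uniform"

    def __init__(self, lo: float, hi: float):
        if not hi > lo:
            raise ValueError(f"uniform support requires hi > lo, got [{lo}, {hi}]")
        self.lo = float(lo)
        self.hi = float(hi)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        inside = (x >= self.lo) & (x <= self.hi)
        return np.where(inside, 1.0 / (self.hi - self.lo), 0.0)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.clip((x - self.lo) / (self.hi - self.lo), 0.0, 1.0)

    def sample(self, rng, size=None):
        return rng.uniform(self.lo, self.hi, size)

    def spec(self):
        return {"kind": "uniform", "lo": self.lo, "hi": self.hi}

    def __repr__(self):
        return f"UniformEffect(lo={self.lo}, hi={self.hi})"


class GaussianEffect(EffectDistribution):
    """Gaussian density truncated to [lo, hi] and renormalized.

    The location/scale parameters refer to the parent (untruncated) normal.
    """

    kind = "gaussian"

    def __init__(self, center: float, sd: float, lo: float, hi: float):
        if not hi > lo:
            raise ValueError(f"gaussian support requires hi > lo, got [{lo}, {hi}]")
        if not sd > 0:
            raise ValueError("gaussian sd must be > 0")
        self.center = float(center)
        self.sd = float(sd)
        self.lo = float(lo)
        self.hi = float(hi)
        a = (self.lo - self.center) / self.sd
        b = (self.hi - self.center) / self.sd
        self._dist = stats.truncnorm(a, b, loc=self.center, scale=self.sd)
        self._cdf_lo = stats.norm.cdf(a)
        self._cdf_hi = stats.norm.cdf(b)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x >= self.lo) & (x <= self.hi), self._dist.pdf(x), 0.0)

    def cdf(self, x):
        return self._dist.cdf(np.asarray(x, dtype=float))

    def sample(self, rng, size=None):
        # inverse-CDF of the parent normal restricted to [lo, hi]; much
        # cheaper than the frozen-distribution rvs in tight loops
        u = rng.uniform(self._cdf_lo, self._cdf_hi, size)
        out = self.center + self.sd * special.ndtri(u)
        out = np.clip(out, self.lo, self.hi)  # guard endpoint rounding
        return float(out) if size is None else out

    def spec(self):
        return {
            "kind": "gaussian",
            "center": self.center,
            "sd": self.sd,
            "lo": self.lo,
            "hi": self.hi,
        }

    def __repr__(self):
        return (
            f"GaussianEffect(center={self.center}, sd={self.sd}, "
            f"lo={self.lo}, hi={self.hi})"
        )


class TabulatedEffect(EffectDistribution):
    """Density given as a table of (value, density) points.

    Linearly interpolated between the tabulated points and renormalized so
    the density integrates to 1 over [x[0], x[-1]].  Sampling uses the exact
    inverse CDF of the interpolated (piecewise-linear) density on a refined
    grid.
    """

    kind = "custom"
    _GRID = 4096  # refinement for the inverse-CDF sampler

    def __init__(self, x, density):
        x = np.asarray(x, dtype=float)
        density = np.asarray(density, dtype=float)
        if x.ndim != 1 or x.shape != density.shape or x.size < 2:
            raise ValueError("tabulated density needs two 1-d columns, >= 2 rows")
        order = np.argsort(x)
        x, density = x[order], density[order]
        if np.any(np.diff(x) <= 0):
            raise ValueError("tabulated abscissae must be distinct")
        if np.any(density < 0) or not np.any(density > 0):
            raise ValueError("tabulated density must be nonnegative and nonzero")
        self.lo, self.hi = float(x[0]), float(x[-1])
        norm = np.trapezoid(density, x)
        self._x = x
        self._d = density / norm
        grid = np.linspace(self.lo, self.hi, self._GRID)
        pdf_grid = np.interp(grid, self._x, self._d)
        cdf = np.concatenate(
            [[0.0], np.cumsum((pdf_grid[1:] + pdf_grid[:-1]) / 2.0 * np.diff(grid))]
        )
        cdf /= cdf[-1]
        self._grid = grid
        self._cdf_grid = cdf

    @classmethod
    def from_file(cls, path) -> "TabulatedEffect":
        """Read a two-column delimited text file (value, density)."""
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] != 2:
            raise ValueError(f"{path}: expected two columns (value, density)")
        return cls(arr[:, 0], arr[:, 1])

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self._x, self._d, left=0.0, right=0.0)
        return np.where((x >= self.lo) & (x <= self.hi), out, 0.0)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.interp(x, self._grid, self._cdf_grid, left=0.0, right=1.0)

    def sample(self, rng, size=None):
        u = rng.uniform(0.0, 1.0, size)
        return np.interp(u, self._cdf_grid, self._grid)

    def spec(self):
        return {"kind": "custom", "x": self._x.tolist(), "density": self._d.tolist()}

    def __repr__(self):
        return f"TabulatedEffect(lo={self.lo}, hi={self.hi}, n={self._x.size})"


def uniform_dfe(fc: float) -> UniformEffect:
    """DFE used throughout: intrinsic fitness uniform on [0, 1 - fc].

    ``fc`` is the *minimum* fitness cost; each mutant's own cost is
    ``1 - fi``.
    """
    if not (0.0 <= fc < 1.0):
        raise ValueError(f"minimum fitness cost fc={fc} outside [0, 1)")
    return UniformEffect(0.0, 1.0 - fc)


def uniform_dee(fmax: float) -> UniformEffect:
    """Uniform DEE on [0, fmax]; the null model for ecological effects."""
    if not (0.0 < fmax <= FE_CEILING):
        raise ValueError(f"fmax={fmax} outside (0, {FE_CEILING}]")
    return UniformEffect(0.0, fmax)


def distribution_from_spec(spec: dict) -> EffectDistribution:
    """Build an :class:`EffectDistribution` from a serializable description.

    ``{"kind": "uniform", "lo": .., "hi": ..}``,
    ``{"kind": "gaussian", "center": .., "sd": .., "lo": .., "hi": ..}`` or
    ``{"kind": "custom", "path": ..}`` (two-column text: value, density).
    """
    spec = dict(spec)
    kind = spec.pop("kind", None)
    if kind == "uniform":
        return UniformEffect(spec["lo"], spec["hi"])
    if kind == "gaussian":
        return GaussianEffect(spec["center"], spec["sd"], spec["lo"], spec["hi"])
    if kind == "custom":
        if "path" in spec:
            return TabulatedEffect.from_file(spec["path"])
        return TabulatedEffect(spec["x"], spec["density"])
    raise ValueError(f"unknown distribution kind: {kind!r}")


def draw_mutant(
    dfe: EffectDistribution,
    dee: EffectDistribution,
    rng: np.random.Generator,
    size=None,
):
    """Draw a new mutant's fitness profile: fi ~ DFE and fe ~ DEE, independent.

    Returns a single :class:`FitnessProfile` when ``size`` is None, else a
    pair of arrays ``(fi, fe)``.
    """
    if dfe.lo < 0.0 or dfe.hi > 1.0:
        raise ValueError(f"DFE support {dfe.support} must lie within [0, 1]")
    if dee.lo < 0.0 or dee.hi > FE_CEILING:
        raise ValueError(f"DEE support {dee.support} must lie within [0, {FE_CEILING}]")
    if size is None:
        return FitnessProfile(fi=float(dfe.sample(rng)), fe=float(dee.sample(rng)))
    return np.asarray(dfe.sample(rng, size), float), np.asarray(
        dee.sample(rng, size), float
    )
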