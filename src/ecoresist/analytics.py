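"""Closed-form layer: extinction times, expected mutant numbers, stationary
distributions, regime classification and the coexistence fixed point.

All of these describe the dilute-mutant Wright-Fisher model: ancestors
mutate at rate ``mu`` per individual per generation, each mutant draws an
intrinsic fitness ``fi ~ U(0, 1-fc)`` and an ecological fitness ``fe`` from
the DEE (uniform on [0, fmax] unless stated otherwise), and a mutant's
growth rate in a predominantly ancestor population is approximately ``fe``.

Key results
-----------
* ``tau_approx``: mean extinction time of a single mutant lineage,
  ``tau(fe) = 3 ln(1 - fe) / (fe^2 - 3)`` generations -- a function of the
  ecological fitness only (not of N, mu or the cost).
* ``n_mut_noeco`` / ``n_mut_eco_small_mu``: expected stationary mutant
  numbers from mutation-selection balance, without and with ecological
  interactions, in the small-``mu`` limit:

      N mu (-ln(fc)/(1-fc) - 1)   and   N mu (-ln(1-fmax)/fmax - 1).

* ``n_mut_eco``: a Lambert-W closed form valid across decades of ``mu``,
  obtained from the self-consistent balance M = mu (1-M) E[g/(wbar-g)] with
  mean fitness ``wbar = 1 - mu`` and per-class growth
  ``g = fe (1-M) + fi M``.  Averaging the log-divergence over the uniform
  DFE through its geometric mean G = fc^(fc/(fc-1))/e gives

      M = -(mu/fmax) ln((1 - fmax - mu) + G M) - mu/(1-mu),

  solved exactly by the principal Lambert-W branch (evaluated through the
  Wright omega function for numerical range).  ``n_mut_eco_selfconsistent``
  solves the unapproximated balance numerically and serves as an
  independent cross-check.
* ``stationary_density``: expected mutant-fraction density over fe,
  ``P(fe) = fe mu / (1 - fe) * rho0(fe)`` for any DEE density ``rho0``.
* ``coexistence_fixed_point``: for ``fe > 1`` the mutant outcompetes the
  ancestor when rare and loses when common, giving the stable ancestor
  fraction ``x* = (1 - fi) / (fe - fi)`` where both grow at rate 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import wrightomega

from .fitness import EffectDistribution, FitnessProfile

__all__ = [
    "tau_approx",
    "n_mut_noeco",
    "n_mut_eco_small_mu",
    "n_mut_eco",
    "n_mut_eco_selfconsistent",
    "stationary_density",
    "RegimeReport",
    "classify_regime",
    "regime_map",
    "coexistence_fixed_point",
]

#: Below this mutation rate the small-mu formula is used by ``n_mut_eco``
#: (the two branches agree to <0.1% there; the simple form is exact as mu->0).
SMALL_MU_SWITCH = 1e-6


def _as_float(x):
    return np.asarray(x, dtype=float)


def _ret(out):
    out = np.asarray(out)
    return float(out) if out.ndim == 0 else out


def tau_approx(fe):
    """Mean extinction time (generations) of a mutant with ecological fitness fe.

    ``tau(fe) = 3 ln(1-fe) / (fe^2 - 3)``; valid for ``fe in [0, 1)`` and
    diverging as fe -> 1.  For small fe, ``tau ~ fe``.
    """
    fe_arr = _as_float(fe)
    if np.any((fe_arr < 0.0) | (fe_arr >= 1.0)):
        raise ValueError("tau_approx requires 0 <= fe < 1")
    out = 3.0 * np.log1p(-fe_arr) / (fe_arr**2 - 3.0)
    return _ret(out)


def n_mut_noeco(N, mu, fc):
    """Expected stationary mutant number with no ecological interactions.

    ``N mu (-ln(fc)/(1-fc) - 1)``: mutation-selection balance with each
    lineage decaying at its own cost ``1 - fi``, averaged over the uniform
    DFE on [0, 1-fc].  Diverges as fc -> 0; tends to 0 as fc -> 1 (taken as
    the limit).
    """
    N_arr, mu_arr, fc_arr = np.broadcast_arrays(_as_float(N), _as_float(mu), _as_float(fc))
    if np.any((fc_arr <= 0.0) | (fc_arr > 1.0)):
        raise ValueError("n_mut_noeco requires 0 < fc <= 1 (fc=0 diverges)")
    if np.any((mu_arr <= 0.0) | (mu_arr >= 1.0)):
        raise ValueError("n_mut_noeco requires 0 < mu < 1")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(fc_arr < 1.0, -np.log(fc_arr) / (1.0 - fc_arr), 1.0)
    out = N_arr * mu_arr * (ratio - 1.0)
    return _ret(out)


def n_mut_eco_small_mu(N, mu, fmax):
    """Expected mutant number with ecological interactions, small-mu limit.

    ``N mu (-ln(1-fmax)/fmax - 1)`` for a uniform DEE on [0, fmax];
    ``fmax`` must be strictly below 1 for the normalization to exist.
    Identical to :func:`n_mut_noeco` under the substitution
    ``fc -> 1 - fmax``.
    """
    N_arr, mu_arr, fm = np.broadcast_arrays(_as_float(N), _as_float(mu), _as_float(fmax))
    if np.any((fm <= 0.0) | (fm >= 1.0)):
        raise ValueError("n_mut_eco_small_mu requires 0 < fmax < 1")
    if np.any(mu_arr > 1e-3):
        warnings.warn(
            "small-mu approximation requested at mu > 1e-3; "
            "prefer n_mut_eco there",
            RuntimeWarning,
            stacklevel=2,
        )
    out = N_arr * mu_arr * (-np.log1p(-fm) / fm - 1.0)
    return _ret(out)


def _n_mut_eco_lambertw(N, mu, fc, fmax):
    """Lambert-W closed form for the stationary mutant fraction.

    Solves M = -(mu/fmax) ln(A + G M) - mu/(1-mu) with A = 1 - fmax - mu
    and G = fc^(fc/(fc-1))/e (geometric mean of 1 - fi under the uniform
    DFE).  Substituting u = A + G M turns it into u + b ln u = c with
    b = G mu / fmax and c = A - G mu/(1-mu), whose solution is
    u = b * W((1/b) e^(c/b)); the exponent is evaluated through the Wright
    omega function, W(e^t) = omega(t), to avoid overflow at small mu.
    """
    G = fc ** (fc / (fc - 1.0)) / np.e
    A = 1.0 - fmax - mu
    b = G * mu / fmax
    c = A - G * mu / (1.0 - mu)
    u = b * wrightomega(c / b - np.log(b)).real
    M = (u - A) / G
    return N * M


def n_mut_eco(N, mu, fc, fmax, method: str = "auto"):
    """Expected stationary mutant number with ecological interactions.

    Parameters
    ----------
    N, mu, fc, fmax
        Population size, per-individual mutation probability (0 < mu <= 0.1),
        minimum fitness cost in (0, 1), and DEE upper bound in (0, 1).
    method
        ``"auto"`` uses the small-mu form below ``mu = 1e-6`` and the
        Lambert-W form otherwise; ``"lambertw"`` or ``"small_mu"`` force a
        branch.

    The Lambert-W branch agrees with the small-mu form to <1% at
    ``mu <= 1e-5`` and remains within ~10% of stochastic simulations across
    several decades of mu.
    """
    N_arr, mu_arr, fc_arr, fm = np.broadcast_arrays(
        _as_float(N), _as_float(mu), _as_float(fc), _as_float(fmax)
    )
    if np.any((fc_arr <= 0.0) | (fc_arr >= 1.0)):
        raise ValueError("n_mut_eco requires 0 < fc < 1")
    if np.any((fm <= 0.0) | (fm >= 1.0)):
        raise ValueError("n_mut_eco requires 0 < fmax < 1 "
                         "(normalization breaks down at fmax >= 1)")
    if np.any((mu_arr <= 0.0) | (mu_arr > 0.1)):
        raise ValueError("n_mut_eco requires 0 < mu <= 0.1")
    if method not in ("auto", "lambertw", "small_mu"):
        raise ValueError(f"unknown method {method!r}")
    if method == "small_mu":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = n_mut_eco_small_mu(N_arr, mu_arr, fm)
        out = _as_float(out)
    elif method == "lambertw":
        out = _n_mut_eco_lambertw(N_arr, mu_arr, fc_arr, fm)
    else:
        small = mu_arr < SMALL_MU_SWITCH
        out = np.where(
            small,
            N_arr * mu_arr * (-np.log1p(-fm) / fm - 1.0),
            _n_mut_eco_lambertw(N_arr, np.where(small, 1e-6, mu_arr), fc_arr, fm),
        )
    if not np.all(np.isfinite(out)):
        raise ValueError("Lambert-W evaluation left the principal branch domain")
    return _ret(out)


def n_mut_eco_selfconsistent(N: float, mu: float, fc: float, fmax: float) -> float:
    """Numerically exact deterministic mutant number (cross-check oracle).

    Solves the unapproximated balance  M = mu (1-M) E[g/(wbar-g)]  with
    ``wbar = 1 - mu`` and ``g = fe (1-M) + fi M``, the expectation running
    over the uniform DFE x uniform DEE.  Both integrals are closed-form;
    only the scalar self-consistency is solved numerically.
    """
    wbar = 1.0 - mu
    hi_fi = 1.0 - fc

    def mean_log_ratio(M: float) -> float:
        # E_fi[ ln(P/Q) ],  P = wbar - fi*M,  Q = P - fmax*(1-M)
        def e_log(a: float, bcoef: float) -> float:
            # mean of ln(a - bcoef*fi) for fi ~ U(0, hi_fi)
            if bcoef == 0.0:
                return np.log(a)
            lo_arg = a - bcoef * hi_fi
            return (
                a * (np.log(a) - 1.0) - lo_arg * (np.log(lo_arg) - 1.0)
            ) / (bcoef * hi_fi)

        return e_log(wbar, M) - e_log(wbar - fmax * (1.0 - M), M)

    def residual(M: float) -> float:
        return mu * (1.0 - mu) / (fmax * (1.0 - M)) * mean_log_ratio(M) * (
            1.0 - M
        ) - mu * (1.0 - M) - M

    # keep every log argument positive over the bracket: the binding
    # constraints are wbar - (1-fc)*M > 0 and Q(M) > 0 at fi = 1-fc
    upper = 0.5 * wbar / max(hi_fi, 1e-12)
    if hi_fi > fmax:  # Q decreases with M in this corner
        upper = min(upper, 0.999 * (wbar - fmax) / (hi_fi - fmax))
    upper = min(0.99, upper)
    return N * brentq(residual, 1e-15, upper, xtol=1e-15, rtol=1e-13)


def stationary_density(fe, mu, dee: EffectDistribution):
    """Stationary mutant-fraction density over ecological fitness.

    ``P(fe) = fe mu / (1 - fe) * rho0(fe)``: the inflow of new surviving
    mutants (proportional to ``fe mu rho0``) balances the outflow of
    existing ones (proportional to ``1 - fe``).  For a uniform DEE on
    [0, fmax] this is ``mu fe / (fmax (1 - fe))``, and its integral equals
    ``n_mut_eco_small_mu / N``.
    """
    fe_arr = _as_float(fe)
    if np.any((fe_arr < 0.0) | (fe_arr >= 1.0)):
        raise ValueError("stationary_density requires 0 <= fe < 1")
    out = fe_arr * mu / (1.0 - fe_arr) * dee.pdf(fe_arr)
    return _ret(out)


@dataclass(frozen=True)
class RegimeReport:
    """Expected mutant numbers and the preexistence regime they imply."""

    n_mut_noeco: float
    n_mut_eco: float
    regime: str  # "small-Nmu" | "rare-mutant" | "many-mutant"
    N: float
    mu: float
    fc: float
    fmax: float


def classify_regime(N, mu, fc, fmax) -> RegimeReport:
    """Label the preexistence regime from the two expected mutant numbers.

    * ``small-Nmu``: both below 1 -- preexisting resistance unlikely either way;
    * ``rare-mutant``: ecology pushes the expected number above 1 while the
      no-ecology count stays below -- ecological interactions are the
      primary mode of preexistence;
    * ``many-mutant``: both above 1 -- mutants abundant regardless, ecology
      shapes their distribution.

    The fourth combination (no-ecology above 1 with ecology below) cannot
    occur for ``fmax >= 1 - fc`` because the two formulas are the same
    increasing function evaluated at ``fmax`` and ``1 - fc``.
    """
    ne = float(n_mut_noeco(N, mu, fc))
    we = float(n_mut_eco(N, mu, fc, fmax))
    if we <= 1.0 < ne:
        if fmax >= 1.0 - fc:
            raise AssertionError(
                "n_mut_noeco > 1 >= n_mut_eco is impossible for fmax >= 1 - fc"
            )
        regime = "small-Nmu"  # fmax < 1-fc: ecology only weakens mutants
    elif ne <= 1.0 and we <= 1.0:
        regime = "small-Nmu"
    elif ne <= 1.0 < we:
        regime = "rare-mutant"
    else:
        regime = "many-mutant"
    return RegimeReport(
        n_mut_noeco=ne, n_mut_eco=we, regime=regime,
        N=float(np.asarray(N, dtype=float)), mu=float(mu), fc=float(fc),
        fmax=float(fmax),
    )


def regime_map(N, mus, fcs=None, fmaxs=None, fc=0.25, fmax=0.99) -> pd.DataFrame:
    """Phase-diagram table over a mutation-rate grid crossed with fc or fmax.

    Exactly one of ``fcs``/``fmaxs`` may be a grid; the other axis is held
    at the scalar ``fc``/``fmax``.
    """
    if fcs is not None and fmaxs is not None:
        raise ValueError("provide a grid for fc or fmax, not both")
    fcs_arr = np.atleast_1d(_as_float(fcs if fcs is not None else fc))
    fmaxs_arr = np.atleast_1d(_as_float(fmaxs if fmaxs is not None else fmax))
    rows = []
    for mu in np.atleast_1d(_as_float(mus)):
        for fc_i in fcs_arr:
            for fm_i in fmaxs_arr:
                rep = classify_regime(N, mu, fc_i, fm_i)
                rows.append(
                    {
                        "N": N,
                        "mu": mu,
                        "Nmu": N * mu,
                        "fc": fc_i,
                        "fmax": fm_i,
                        "n_mut_noeco": rep.n_mut_noeco,
                        "n_mut_eco": rep.n_mut_eco,
                        "regime": rep.regime,
                    }
                )
    return pd.DataFrame(rows)


def coexistence_fixed_point(profile: FitnessProfile):
    """Stable ancestor fraction at which mutant and ancestor growth rates match.

    For ``fe > 1`` (and ``fi < 1``, i.e. a nonzero cost) the mutant grows
    faster than the ancestor when rare and slower when common, so the
    linear fitness crosses 1 at the ancestor fraction

        x* = (1 - fi) / (fe - fi),   0 < x* < 1,

    a stable coexistence point: the slope ``fe - fi`` is positive, the
    mutant fitness exceeds 1 for ancestor fractions above ``x*`` and falls
    below 1 beneath it.  For ``fe <= 1`` the ancestor is favored at every
    frequency and the function returns None (extinction is a matter of
    when, not if).
    """
    if profile.fi >= 1.0:
        raise ValueError("coexistence requires a nonzero fitness cost (fi < 1)")
    if profile.fe <= 1.0:
        return None
    return (1.0 - profile.fi) / (profile.fe - profile.fi)
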