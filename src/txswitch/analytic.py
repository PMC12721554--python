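"""Exact stationary statistics of promoter-modulated mRNA dynamics.

The mRNA copy number M follows a birth-death process whose birth rate is
gated by a finite promoter-state CTMC: production at rate alpha in producing
states, degradation at rate beta per molecule.  For such systems the
stationary mean and variance are available exactly from linear moment
equations.  Writing pi for the stationary law of the promoter chain with
generator Q, and defining state-resolved moments

    m_i = E[M ; state = i],      s_i = E[M(M-1) ; state = i],

stationarity of the joint process gives two linear systems,

    m (Q - beta I) = -(pi * a),        s (Q - 2 beta I) = -2 (m * a),

with a_i = alpha for producing states and 0 otherwise.  Then
E[M] = sum(m), Var[M] = sum(s) + E[M] - E[M]^2 and the Fano factor is
Var[M]/E[M].  The transcriptional activity (probability that the promoter is
producing) equals beta/alpha * E[M].

For the indirect-repression switches the same quantities are also available
in closed form (functions ``indirect_ta`` / ``indirect_ff``); the
sequestration-blocking-displacement Fano factor is implemented from an exact
re-derivation of the 3-state chain's moment equations, since published
renderings of that expression are typographically ambiguous — equivalence
with the moment solver is the defining test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import (CooperativeSwitchSpec, DnaStateModel, IndirectSwitchSpec,
                     build_cooperative_model, build_indirect_model)

__all__ = [
    "StationaryStats",
    "IndirectClosedFormTerms",
    "mrna_moments",
    "coop_occupancy_distribution",
    "coop_stats",
    "indirect_terms",
    "indirect_ta",
    "indirect_ff",
    "activity_curve",
    "fano_curve",
    "indirect_stats",
    "solver_stats",
]


@dataclass(frozen=True)
class StationaryStats:
    """Stationary promoter activity and mRNA moments."""

    activity: float
    mean_mrna: float
    var_mrna: float
    fano: float


@dataclass(frozen=True)
class IndirectClosedFormTerms:
    """Displacement correction factors of the three-mechanism switch.

    Both reduce to 1 at detailed balance (sigma = 1)."""

    I: float
    J: float


def mrna_moments(model: DnaStateModel, alpha: float, beta: float) -> StationaryStats:
    """Exact stationary mRNA statistics for a promoter-gated birth-death process.

    Uses dense linear algebra (promoter chains here have at most 16 states).
    Raises ``numpy.linalg.LinAlgError`` for reducible chains and warns when
    the moment systems are ill-conditioned.
    """
    Q = model.rate_matrix
    n = model.n_states
    pi = model.stationary()
    a = np.where(model.producing, float(alpha), 0.0)

    A1 = (Q - beta * np.eye(n)).T
    A2 = (Q - 2.0 * beta * np.eye(n)).T
    cond = max(np.linalg.cond(A1), np.linalg.cond(A2))
    if cond > 1e12:
        warnings.warn(f"moment system condition number {cond:.2e} exceeds 1e12",
                      RuntimeWarning, stacklevel=2)
    m = np.linalg.solve(A1, -(pi * a))
    s = np.linalg.solve(A2, -2.0 * (m * a))
    mean = float(m.sum())
    var = float(s.sum()) + mean - mean * mean
    activity = float(pi[model.producing].sum())
    fano = var / mean if mean > 0 else float("nan")
    return StationaryStats(activity=activity, mean_mrna=mean,
                           var_mrna=var, fano=fano)


# --------------------------------------------------------------------------
# cooperative switch
# --------------------------------------------------------------------------

def coop_occupancy_distribution(x: float, c: float) -> np.ndarray:
    """Stationary occupancy law of the four-site cooperative switch.

    Detailed balance on the occupancy birth-death chain gives
    ``pi(n+1)/pi(n) = (4-n) x / ((n+1) c**n)`` with ``x = RT/(Omega*Kr)``.
    At c = 1 this is Binomial(4, x/(1+x)).
    """
    if x < 0:
        raise ValueError("x must be nonnegative")
    if not 0 < c <= 1:
        raise ValueError("c must satisfy 0 < c <= 1")
    w = np.empty(5)
    w[0] = 1.0
    for n in range(4):
        w[n + 1] = w[n] * (4 - n) * x / ((n + 1) * c ** n)
    return w / w.sum()


def coop_stats(spec: CooperativeSwitchSpec) -> StationaryStats:
    """Stationary activity and mRNA noise of the cooperative switch.

    Activity follows from the occupancy law (``1 - pi(4)`` in repressor
    mode, ``pi(4)`` in the activator variant); the moments come from the
    full 16-state chain, because unlike the activity they depend on the
    switching speed, not just on the occupancy equilibrium.
    """
    model = build_cooperative_model(spec)
    return mrna_moments(model, spec.context.alpha, spec.context.beta)


# --------------------------------------------------------------------------
# indirect-repression closed forms
# --------------------------------------------------------------------------
# All formulas are evaluated in normalized variables: counts in units of AT,
# rates in units of (kf/Omega)*AT, so dissociation constants appear as
# K~x = Omega*Kx/AT and the free-protein levels as fractions of AT.

def _free_fractions(rt, ks):
    """Normalized titration roots (A~, R~, RA~) as functions of RT/AT."""
    from .models import _titration_roots
    return _titration_roots(1.0, np.asarray(rt, float), ks)


def _terms(r, ks, ka, kb, kd):
    sig = ks * kd / (ka * kb)
    den = ks + sig * ka + sig * r
    return (ks + sig * ka + r) / den, (ks + ka + r) / den


def indirect_terms(spec: IndirectSwitchSpec) -> IndirectClosedFormTerms:
    """Displacement correction factors I, J at the spec's repressor level."""
    p = spec.normalized()
    _, r, _ = _free_fractions(p["rt"], p["ks"])
    I, J = _terms(r, p["ks"], p["ka"], p["kb"], p["kd"])
    return IndirectClosedFormTerms(I=float(I), J=float(J))


def _ta(mech, rt, ks, ka, kb, kd):
    a, r, _ = _free_fractions(rt, ks)
    if mech == "S":
        x = a / ka
        return x / (1.0 + x)
    if mech == "SB":
        x = a / ka
        y = x * r / kb
        return x / (1.0 + x + y)
    I, J = _terms(r, ks, ka, kb, kd)
    x = I * a / ka
    y = J * (a / ka) * (r / kb)
    return x / (1.0 + x + y)


def _ff(mech, rt, ks, ka, kb, kd, alpha, beta):
    a, r, ra = _free_fractions(rt, ks)
    if mech == "S":
        return 1.0 + alpha / ((1.0 + a / ka) * (a + ka + beta))
    if mech == "SB":
        x = a / ka
        y = x * r / kb
        num = alpha * (kb + beta + (a + beta) * y)
        den = (1.0 + x + y) * (ka * (kb + beta)
                               + (a + beta) * (r + kb + beta))
        return 1.0 + num / den
    # sequestration + blocking + displacement: exact moment-equation form
    p1 = (a * kb + a * kd + a * r + ka * kb + ka * kd + ka * ra
          + kb * ra + kd * r + r * ra)
    p2 = p1 + beta * (a + ka + kb + kd + r + ra + beta)
    num = (a * a * r + a * ka * ra + a * kd * r + 2 * a * r * ra + a * r * beta
           + ka * kb * kb + 2 * ka * kb * kd + ka * kb * ra + ka * kb * beta
           + ka * kd * kd + 2 * ka * kd * ra + ka * kd * beta + ka * ra * ra
           + ka * ra * beta + kb * kd * r + kd * kd * r + 2 * kd * r * ra
           + kd * r * beta + r * ra * ra + r * ra * beta)
    return 1.0 + alpha * num / (p1 * p2)


def indirect_ta(spec: IndirectSwitchSpec) -> float:
    """Closed-form stationary transcriptional activity of an indirect switch."""
    p = spec.normalized()
    return float(_ta(spec.mechanisms, p["rt"], p["ks"], p["ka"], p["kb"], p["kd"]))


def indirect_ff(spec: IndirectSwitchSpec) -> float:
    """Closed-form stationary mRNA Fano factor of an indirect switch."""
    p = spec.normalized()
    return float(_ff(spec.mechanisms, p["rt"], p["ks"], p["ka"], p["kb"],
                     p["kd"], p["alpha"], p["beta"]))


def activity_curve(spec: IndirectSwitchSpec, rt_ratios) -> np.ndarray:
    """Vectorized activity over an array of molar ratios RT/AT."""
    p = spec.normalized()
    return _ta(spec.mechanisms, np.asarray(rt_ratios, float),
               p["ks"], p["ka"], p["kb"], p["kd"])


def fano_curve(spec: IndirectSwitchSpec, rt_ratios) -> np.ndarray:
    """Vectorized Fano factor over an array of molar ratios RT/AT."""
    p = spec.normalized()
    return _ff(spec.mechanisms, np.asarray(rt_ratios, float), p["ks"],
               p["ka"], p["kb"], p["kd"], p["alpha"], p["beta"])


def indirect_stats(spec: IndirectSwitchSpec) -> StationaryStats:
    """Stats assembled from the closed forms (activity, mean, var, Fano)."""
    ta = indirect_ta(spec)
    ff = indirect_ff(spec)
    mean = spec.context.alpha / spec.context.beta * ta
    return StationaryStats(activity=ta, mean_mrna=mean,
                           var_mrna=ff * mean, fano=ff)


def solver_stats(spec: IndirectSwitchSpec) -> StationaryStats:
    """Same statistics through the generic moment solver (cross-check path)."""
    model = build_indirect_model(spec)
    return mrna_moments(model, spec.context.alpha, spec.context.beta)
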