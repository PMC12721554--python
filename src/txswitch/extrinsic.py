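"""mRNA statistics under fluctuating regulator totals (extrinsic noise).

When the repressor total RT (or the activator total AT) is itself a random
variable with law pi, the stationary mRNA moments follow from the laws of
total mean and total variance,

    E[M]   = E_pi[ E[M | RT] ],
    Var[M] = Var_pi[ E[M | RT] ] + E_pi[ Var[M | RT] ],

with the conditional moments supplied by the intrinsic theory:
E[M | RT] = (alpha/beta) * TA(RT) and Var[M | RT] = E[M | RT] * FF(RT).

Mixing is carried out over integer counts.  Two regulator laws are
provided: a Poisson repressor (simple birth-death production) and the
activator birth-death chain in which bound activators are degraded faster
through their repressor complex, whose stationary law is computed from the
exact birth-death recursion with the titration QSSA roots (a piecewise-
linear approximation of those roots is available for cross-checks only).

By construction of these analyses the *conditional mean* curve is shared
across mechanism sets ("matched activity"): the three repression
architectures are compared at identical conditional activity, so their
total means coincide exactly and all differences are carried by the
conditional Fano factor.  Set ``matched_ta=False`` to use each mechanism's
own activity curve instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import poisson

from .analytic import fano_curve, activity_curve
from .models import IndirectSwitchSpec, qssa_partition

__all__ = [
    "CountDistribution",
    "poisson_counts",
    "repressor_mixture_stats",
    "activator_count_distribution",
    "activator_mixture_stats",
    "MixtureStats",
]


@dataclass(frozen=True)
class CountDistribution:
    """Probability mass function on a contiguous integer support."""

    support: np.ndarray
    pmf: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.support, np.int64)
        p = np.asarray(self.pmf, float)
        if s.shape != p.shape:
            raise ValueError("support/pmf shape mismatch")
        if len(s) and not np.all(np.diff(s) == 1):
            raise ValueError("support must be contiguous")
        if (p < 0).any() or abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("pmf must be nonnegative and sum to 1")
        object.__setattr__(self, "support", s)
        object.__setattr__(self, "pmf", p)

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.pmf))

    @property
    def var(self) -> float:
        m = self.mean
        return float(np.dot((self.support - m) ** 2, self.pmf))

    @classmethod
    def degenerate(cls, n: int) -> "CountDistribution":
        return cls(support=np.array([n]), pmf=np.array([1.0]))


def poisson_counts(mean: float, tail_mass: float = 1e-12) -> CountDistribution:
    """Poisson law truncated where the discarded tail mass is below tol."""
    lo = int(poisson.ppf(tail_mass, mean)) if mean > 30 else 0
    hi = int(poisson.isf(tail_mass, mean)) + 1
    support = np.arange(lo, hi + 1)
    pmf = poisson.pmf(support, mean)
    return CountDistribution(support=support, pmf=pmf / pmf.sum())


@dataclass(frozen=True)
class MixtureStats:
    """Law-of-total-moments output for one mechanism set."""

    total_mean: float
    total_var: float
    total_fano: float
    between_var: float     # Var_pi[E[M|.]] — regulator-driven component
    within_var: float      # E_pi[Var[M|.]] — intrinsic component


def _mixture(ta: np.ndarray, ff: np.ndarray, pmf: np.ndarray,
             alpha_over_beta: float) -> MixtureStats:
    cond_mean = alpha_over_beta * ta
    total_mean = float(np.dot(pmf, cond_mean))
    between = float(np.dot(pmf, (cond_mean - total_mean) ** 2))
    within = float(np.dot(pmf, cond_mean * ff))
    var = between + within
    return MixtureStats(total_mean=total_mean, total_var=var,
                        total_fano=var / total_mean if total_mean > 0 else
                        float("nan"),
                        between_var=between, within_var=within)


def repressor_mixture_stats(spec: IndirectSwitchSpec,
                            distribution: CountDistribution | float,
                            mechanisms=("S", "SB", "SBD"),
                            matched_ta: bool = True) -> dict[str, MixtureStats]:
    """Total mRNA moments when RT fluctuates.

    ``distribution`` is either a :class:`CountDistribution` for RT or a
    float, taken as the mean of a Poisson law.  With ``matched_ta`` the
    conditional mean uses one shared activity curve (the sole-sequestration
    one), so total means agree across mechanisms exactly.
    """
    if not isinstance(distribution, CountDistribution):
        distribution = poisson_counts(float(distribution))
    ratios = distribution.support / spec.AT
    aob = spec.context.alpha / spec.context.beta
    shared_ta = activity_curve(replace(spec, mechanisms="S"), ratios)
    out = {}
    for mech in mechanisms:
        m = replace(spec, mechanisms=mech)
        ta = shared_ta if matched_ta else activity_curve(m, ratios)
        out[mech] = _mixture(ta, fano_curve(m, ratios), distribution.pmf, aob)
    return out


def activator_count_distribution(alpha_a: float, beta_a: float, beta_ra: float,
                                 omega: float, RT: float, Ks: float,
                                 max_n: int | None = None,
                                 tail_mass: float = 1e-12,
                                 approximate_partition: bool = False
                                 ) -> CountDistribution:
    """Stationary law of a birth-death activator with complex-mediated decay.

    Activators are produced at rate ``alpha_a``; free activators degrade at
    ``beta_a * A(AT)/Omega`` and complexed ones at ``beta_ra * RA(AT)/Omega``
    where (A, RA) is the titration partition at total count AT.  Detailed
    balance of the birth-death chain gives the stationary recursion

        P(AT+1) = alpha_a * P(AT) / d(AT+1),
        d(n) = beta_a*A(n)/Omega + beta_ra*RA(n)/Omega.

    With ``beta_a == beta_ra`` the law is exactly Poisson with mean
    ``alpha_a * Omega / beta_a``.  ``approximate_partition`` replaces the
    exact titration roots by their piecewise-linear limits (cross-check
    only).
    """
    for name, v in (("alpha_a", alpha_a), ("beta_a", beta_a),
                    ("beta_ra", beta_ra), ("omega", omega), ("Ks", Ks)):
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    mean_scale = alpha_a * omega / min(beta_a, beta_ra)
    if max_n is None:
        max_n = int(mean_scale + RT + 12 * np.sqrt(mean_scale + RT) + 50)
    logw = np.empty(max_n + 1)
    logw[0] = 0.0
    for n in range(1, max_n + 1):
        if approximate_partition:
            A = max(n - RT, 0.0)
            RA = min(float(n), float(RT))
        else:
            part = qssa_partition(float(n), RT, Ks, omega)
            A, RA = part.A, part.RA
        death = (beta_a * A + beta_ra * RA) / omega
        logw[n] = logw[n - 1] + np.log(alpha_a) - np.log(death)
    w = np.exp(logw - logw.max())
    pmf = w / w.sum()
    tail = pmf[-1]
    if tail > tail_mass:
        if max_n > 10_000_000:
            raise RuntimeError("truncation mass does not decay; check rates")
        return activator_count_distribution(
            alpha_a, beta_a, beta_ra, omega, RT, Ks, max_n=2 * max_n,
            tail_mass=tail_mass, approximate_partition=approximate_partition)
    keep = pmf > 0
    first = int(np.argmax(keep))
    last = len(pmf) - int(np.argmax(keep[::-1]))
    pmf = pmf[first:last]
    return CountDistribution(support=np.arange(first, last),
                             pmf=pmf / pmf.sum())


def activator_mixture_stats(spec: IndirectSwitchSpec,
                            distribution: CountDistribution,
                            mechanisms=("S", "SB", "SBD"),
                            matched_ta: bool = True) -> dict[str, MixtureStats]:
    """Total mRNA moments when AT fluctuates (RT held at the spec value).

    The conditional statistics at each AT come from the closed forms with
    the raw dissociation constants fixed; the molar ratio RT/AT therefore
    varies along the support.
    """
    aob = spec.context.alpha / spec.context.beta
    n_pts = len(distribution.support)
    ta = {mech: np.empty(n_pts) for mech in mechanisms}
    ff = {mech: np.empty(n_pts) for mech in mechanisms}
    for i, at in enumerate(distribution.support):
        at = max(float(at), 1e-9)  # closed forms are continuous in AT
        for mech in mechanisms:
            m = replace(spec, AT=at, mechanisms=mech)
            ta[mech][i] = activity_curve(m, spec.RT / at)
            ff[mech][i] = fano_curve(m, spec.RT / at)
    shared = ta[mechanisms[0]] if matched_ta else None
    return {mech: _mixture(shared if matched_ta else ta[mech], ff[mech],
                           distribution.pmf, aob)
            for mech in mechanisms}
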