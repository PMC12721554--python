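"""Parameter sweeps and scalar metrics for switch performance.

Two axes organize the analysis: how *ultrasensitive* the activity curve is
(effective Hill exponent from its 10%/90% response points) and how *noisy*
the output is (stationary mRNA Fano factor).  The central sweep varies the
per-volume binding rate kf/Omega and the mRNA half-life ln2/beta while
holding all dissociation constants and the ratio alpha/beta fixed — the
regime question being whether low noise is reachable inside the
biologically realistic box kf/Omega in [6e-6, 6e-5] ymol^-1 min^-1 and
half-life in [30, 984.5] min.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import brentq

from .analytic import (activity_curve, coop_occupancy_distribution, coop_stats,
                       fano_curve)
from .models import CooperativeSwitchSpec, IndirectSwitchSpec, MultiTargetSpec

__all__ = [
    "BIO_BOX",
    "HeatmapResult",
    "ff_heatmap",
    "max_ff_near_unity",
    "hill_coefficient",
    "fano_auc",
    "s5_grid",
    "multitarget_noise_curve",
    "multitarget_reference_curve",
]

#: biologically realistic rectangle: (kf/Omega lo, hi) ymol^-1 min^-1,
#: (half-life lo, hi) min
BIO_BOX = ((6e-6, 6e-5), (30.0, 984.5))


@dataclass(frozen=True)
class HeatmapResult:
    """Metric surface over (kf/Omega, mRNA half-life)."""

    x_axis: np.ndarray           # kf/Omega grid, ymol^-1 min^-1
    y_axis: np.ndarray           # half-life grid, min
    values: np.ndarray           # (len(y), len(x)) metric matrix
    metric_name: str
    box: tuple = BIO_BOX
    axis_names: tuple[str, str] = ("kf_per_volume", "halflife_min")

    def __post_init__(self) -> None:
        x, y = np.asarray(self.x_axis, float), np.asarray(self.y_axis, float)
        if not (np.all(np.diff(x) > 0) and np.all(np.diff(y) > 0)):
            raise ValueError("grids must be strictly increasing")
        if not np.any(np.isfinite(self.values)):
            raise ValueError("metric surface has no finite values")

    def box_mask(self) -> np.ndarray:
        (x0, x1), (y0, y1) = self.box
        mx = (self.x_axis >= x0 * (1 - 1e-12)) & (self.x_axis <= x1 * (1 + 1e-12))
        my = (self.y_axis >= y0 * (1 - 1e-12)) & (self.y_axis <= y1 * (1 + 1e-12))
        return np.outer(my, mx)

    def box_min(self) -> float:
        return float(self.values[self.box_mask()].min())

    def box_max(self) -> float:
        return float(self.values[self.box_mask()].max())

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x_axis, self.y_axis)
        return pd.DataFrame({self.axis_names[0]: xx.ravel(),
                             self.axis_names[1]: yy.ravel(),
                             self.metric_name: self.values.ravel()})


def _log_grid(lo: float, hi: float, n: int) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def cooperative_half_activity_x(c: float) -> float:
    """Binding strength x = RT/(Omega*Kr) at which activity is exactly 1/2."""
    f = lambda lx: coop_occupancy_distribution(10 ** lx, c)[4] - 0.5
    return 10 ** brentq(f, -9, 9, xtol=1e-13)


def ff_heatmap(spec: CooperativeSwitchSpec | IndirectSwitchSpec,
               kf_per_volume_grid: np.ndarray | None = None,
               halflife_grid: np.ndarray | None = None,
               n_grid: int = 25,
               window: tuple[float, float] = (0.5, 1.5),
               at_half_activity: bool = False) -> HeatmapResult:
    """Fano-factor surface over (kf/Omega, half-life).

    Per grid cell the context is rebuilt with alpha = (alpha/beta)*beta so
    the effective transcription rate is unchanged.  For the cooperative
    switch the metric is the Fano factor at the spec's operating point
    (or, with ``at_half_activity=True``, with RT tuned so the activity is
    exactly one half); for indirect switches it is the maximum Fano factor
    over the near-threshold window of molar ratios.
    """
    if kf_per_volume_grid is None:
        kf_per_volume_grid = _log_grid(*BIO_BOX[0], n_grid)
    if halflife_grid is None:
        halflife_grid = _log_grid(*BIO_BOX[1], n_grid)
    vals = np.empty((len(halflife_grid), len(kf_per_volume_grid)))
    cooperative = isinstance(spec, CooperativeSwitchSpec)
    if cooperative and at_half_activity:
        x_star = cooperative_half_activity_x(spec.c)
        spec = replace(spec, RT=x_star * spec.context.omega * spec.Kr)
    for iy, hl in enumerate(halflife_grid):
        for ix, kfo in enumerate(kf_per_volume_grid):
            cell = replace(spec, context=spec.context.with_rates(
                kf_per_volume=kfo, halflife=hl))
            if cooperative:
                vals[iy, ix] = coop_stats(cell).fano
            else:
                vals[iy, ix] = max_ff_near_unity(cell, window=window)[0]
    return HeatmapResult(x_axis=np.asarray(kf_per_volume_grid, float),
                         y_axis=np.asarray(halflife_grid, float),
                         values=vals,
                         metric_name="max_fano" if not cooperative else "fano")


def max_ff_near_unity(spec: IndirectSwitchSpec,
                      window: tuple[float, float] = (0.5, 1.5),
                      n_grid: int = 801, refine: bool = True
                      ) -> tuple[float, float]:
    """Maximum closed-form Fano factor over the near-threshold window.

    Returns ``(max_fano, argmax molar ratio)``.  The window in RT/AT is a
    reporting convention — the published analyses speak of the maximum
    "near" the titration threshold without defining the range — so it is an
    explicit, logged parameter.  A refinement pass around the coarse argmax
    makes the result stable to grid-density doubling at the 0.1% level.
    """
    lo, hi = window
    grid = np.linspace(lo, hi, n_grid)
    ff = fano_curve(spec, grid)
    k = int(np.argmax(ff))
    best, arg = float(ff[k]), float(grid[k])
    if refine:
        lo2 = grid[max(k - 2, 0)]
        hi2 = grid[min(k + 2, n_grid - 1)]
        g2 = np.linspace(lo2, hi2, n_grid)
        f2 = fano_curve(spec, g2)
        k2 = int(np.argmax(f2))
        if f2[k2] > best:
            best, arg = float(f2[k2]), float(g2[k2])
    return best, arg


def hill_coefficient(rt_values: np.ndarray, activity: np.ndarray) -> float:
    """Effective Hill exponent of a decreasing dose-response curve.

    Uses the classical 10%/90% definition
    ``n_H = ln 81 / ln(EC10 / EC90)`` where ECp is the input at which the
    response has fallen to p% of its recorded maximum; crossings are found
    by monotone interpolation in log input.  Exact for true Hill functions.
    Raises if the curve does not span both response levels.
    """
    r = np.asarray(rt_values, float)
    a = np.asarray(activity, float)
    if np.any(r <= 0):
        raise ValueError("inputs must be positive for log interpolation")
    if np.any(np.diff(a) > 1e-12 * a.max()):
        raise ValueError("activity curve must be nonincreasing")
    amax = a.max()
    lo, hi = 0.1 * amax, 0.9 * amax
    if a[-1] > lo or a[0] < hi:
        raise ValueError("curve does not span 10%-90% of its maximum")
    # a is decreasing in r: interpolate log10(r) against increasing a
    ec = np.interp([lo, hi], a[::-1], np.log10(r)[::-1])
    ec10, ec90 = 10 ** ec[0], 10 ** ec[1]
    return float(np.log(81.0) / np.log(ec10 / ec90))


def hill_from_spec(spec: IndirectSwitchSpec, lo: float = 1e-3, hi: float = 1e3,
                   n: int = 4001) -> float:
    """Hill exponent of an indirect switch's analytic activity curve."""
    grid = np.geomspace(lo, hi, n)
    return hill_coefficient(grid, activity_curve(spec, grid))


def fano_auc(spec: IndirectSwitchSpec, rt_range: tuple[float, float] = (0.1, 10.0),
             n: int = 2001, method: str = "trapezoid") -> float:
    """Area under the Fano-factor curve over log10 molar ratio.

    The abscissa is log10(RT/AT) (the published range is given in powers of
    ten); a constant Fano factor F integrates to F times the log-range
    width.  ``method="quad"`` uses adaptive quadrature as a cross-check.
    """
    lo, hi = np.log10(rt_range[0]), np.log10(rt_range[1])
    if method == "quad":
        val, _ = quad(lambda u: float(fano_curve(spec, 10 ** u)), lo, hi,
                      limit=200)
        return float(val)
    u = np.linspace(lo, hi, n)
    return float(np.trapezoid(fano_curve(spec, 10 ** u), u))


def s5_grid(spec: IndirectSwitchSpec, ka_printed: np.ndarray,
            ks_printed: np.ndarray, kb_printed: float | None = None,
            kd_factor: float = 1.0, convention: str = "per_activator",
            hill_range: tuple[float, float] = (1e-3, 1e3)
            ) -> tuple[HeatmapResult, HeatmapResult]:
    """Paired (Hill exponent, Fano AUC) surfaces over (Ka, Ks).

    ``kd_factor`` scales the detailed-balance displacement constant:
    Kd = kd_factor * Ka*Kb/Ks.  Cells where the activity curve does not
    span its 10%-90% response (Hill undefined) are marked NaN, never
    interpolated.
    """
    from .models import resolve_constant
    hills = np.empty((len(ks_printed), len(ka_printed)))
    aucs = np.empty_like(hills)
    for iy, ksp in enumerate(ks_printed):
        for ix, kap in enumerate(ka_printed):
            kw = dict(
                Ks=resolve_constant(ksp, convention, spec.AT, spec.context.omega),
                Ka=resolve_constant(kap, convention, spec.AT, spec.context.omega))
            if kb_printed is not None:
                kw["Kb"] = resolve_constant(kb_printed, convention, spec.AT,
                                            spec.context.omega)
            cell = replace(spec, Kd=None, **kw)
            if kd_factor != 1.0:
                cell = replace(cell, Kd=kd_factor * cell.Ka * cell.Kb / cell.Ks)
            try:
                hills[iy, ix] = hill_from_spec(cell, *hill_range)
            except ValueError:
                hills[iy, ix] = np.nan
            aucs[iy, ix] = fano_auc(cell)
    axes = ("Ka_printed", "Ks_printed")
    h = HeatmapResult(x_axis=np.asarray(ka_printed, float),
                      y_axis=np.asarray(ks_printed, float), values=hills,
                      metric_name="hill_coefficient", axis_names=axes)
    a = HeatmapResult(x_axis=np.asarray(ka_printed, float),
                      y_axis=np.asarray(ks_printed, float), values=aucs,
                      metric_name="fano_auc", axis_names=axes)
    return h, a


# --------------------------------------------------------------------------
# multi-target competition sweep
# --------------------------------------------------------------------------

def multitarget_reference_curve(spec: MultiTargetSpec,
                                rt_grid: np.ndarray | None = None) -> pd.DataFrame:
    """DT = 0 analytic (activity, Fano) reference parameterized by RT/AT."""
    if rt_grid is None:
        rt_grid = np.geomspace(1e-3, 10.0, 2001)
    base = IndirectSwitchSpec(context=spec.context, AT=spec.AT, RT=0.0,
                              Ks=spec.Ks, Ka=spec.Ka, Kb=spec.Kb, Kd=spec.Kd,
                              mechanisms=spec.mechanisms)
    return pd.DataFrame({
        "rt_ratio": rt_grid,
        "activity": activity_curve(base, rt_grid),
        "fano": fano_curve(base, rt_grid),
    })


def multitarget_noise_curve(spec: MultiTargetSpec, dt_list: Sequence[int],
                            rt_list: Sequence[float], n_runs: int = 1000,
                            t_snapshot: float = 5000.0,
                            master_seed: int = 0) -> pd.DataFrame:
    """(activity, Fano) ensemble points across target-gene numbers.

    Each (DT, RT) point is an independent Gillespie snapshot ensemble of the
    fully kinetic shared-activator system, started near the titration
    equilibrium to clear the slow sequestration burn-in.
    """
    from .models import build_multitarget_system
    from .ssa import _equilibrium_initial, _seeds, ensemble_stationary

    rows = []
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(len(dt_list) * len(rt_list))
    k = 0
    for dt in dt_list:
        for rt in rt_list:
            child = children[k]
            k += 1
            s = MultiTargetSpec(context=spec.context, AT=spec.AT, RT=rt,
                                DT=int(dt), Ks=spec.Ks, Ka=spec.Ka,
                                Kb=spec.Kb, Kd=spec.Kd,
                                mechanisms=spec.mechanisms)
            system = build_multitarget_system(s)
            rng = np.random.default_rng(child)
            inits = np.stack([_equilibrium_initial(s, rng)
                              for _ in range(n_runs)])
            summ = ensemble_stationary(system, n_runs, t_snapshot,
                                       int(child.generate_state(1)[0] % 2**31),
                                       initial_states=inits)
            rows.append({"DT": int(dt), "RT": float(rt),
                         "activity": summ.activity_estimate,
                         "fano": summ.fano, "mean": summ.mean,
                         "se_activity": summ.se_activity,
                         "se_fano": summ.se_fano,
                         "n_runs": n_runs})
    return pd.DataFrame(rows)
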