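"""Exact stochastic simulation (Gillespie direct method) and ensemble statistics.

The headline estimator follows the snapshot-across-runs protocol: many
independent trajectories are run past a burn-in and sampled once at a common
snapshot time; transcriptional activity is the fraction of runs whose
promoter is in a producing configuration at the snapshot, and the mRNA mean,
variance and Fano factor are computed across runs.  A time-average estimator
over one long trajectory is available for cross-checking but is never used
for headline numbers.

For switches whose promoter dynamics are far slower than the mRNA lifetime
(the regime where bimodality appears) relaxation from a fixed initial
promoter state can take arbitrarily long.  ``ensemble_stationary`` therefore
supports drawing the initial promoter state of each run from the chain's
exact stationary law (``init_model=...``), after which only the fast
mRNA coordinate needs to relax; stationarity of the snapshot is verified by
doubling the snapshot time and checking the statistics move by less than
their standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .models import (DnaStateModel, IndirectSwitchSpec, MultiTargetSpec,
                     ReactionSystem, build_indirect_model,
                     build_multitarget_system, dna_mrna_system,
                     qssa_partition)

__all__ = [
    "Trajectory",
    "EnsembleSummary",
    "simulate",
    "sample_on_grid",
    "ensemble_stationary",
    "stationary_histogram",
    "time_average_stats",
    "compare_full_vs_qssa",
    "QssaComparison",
    "default_burn_in",
]


@dataclass(frozen=True)
class Trajectory:
    """Event-resolved sample path.

    ``counts[k]`` is the state immediately after the k-th event
    (``counts[0]`` is the initial state at time 0)."""

    times: np.ndarray
    counts: np.ndarray
    species: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("event times must be strictly increasing")
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")

    def resample(self, grid: np.ndarray) -> np.ndarray:
        """Piecewise-constant counts evaluated on a time grid."""
        idx = np.searchsorted(self.times, grid, side="right") - 1
        return self.counts[np.clip(idx, 0, len(self.times) - 1)]


def _seeds(master_seed: int, n: int) -> np.ndarray:
    """Per-run kernel seeds derived from a master seed (counter-based)."""
    return np.random.SeedSequence(master_seed).generate_state(n, np.uint32)


def _kernel_args(system: ReactionSystem):
    return (system.rates, system.reactants, system.kinds, system.stoich,
            system.qssa_at, system.qssa_omega_ks, system.qssa_rt_species)


def simulate(system: ReactionSystem, t_end: float, seed: int,
             max_events: int = 20_000_000, audit: bool = False) -> Trajectory:
    """Exact sample path of the chemical master equation.

    Bit-reproducible for a given seed.  Raises if the event budget is hit
    before ``t_end`` (the trajectory would be truncated, not statistically
    exact).  With ``audit=True`` the declared conservation laws are checked
    at every event."""
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    times, states, n, _ = _kernel.ssa_events(
        np.uint32(seed), system.initial.copy(), float(t_end), max_events,
        *_kernel_args(system))
    if n >= max_events:
        raise RuntimeError(
            f"event budget {max_events} exhausted at t={times[-1]:.3f} "
            f"(state: {dict(zip(system.species, states[-1]))})")
    if audit:
        system.check_conservation(states)
    return Trajectory(times=times, counts=states, species=system.species,
                      seed=int(seed))


def sample_on_grid(system: ReactionSystem, grid: np.ndarray, seed: int,
                   initial: np.ndarray | None = None) -> np.ndarray:
    """States on a fixed time grid (memory-bounded; for long runs)."""
    init = system.initial if initial is None else np.asarray(initial, np.int64)
    return _kernel.ssa_grid(np.uint32(seed), init.copy(),
                            np.asarray(grid, float), *_kernel_args(system))


@dataclass(frozen=True)
class EnsembleSummary:
    """Snapshot-across-runs stationary statistics."""

    n_runs: int
    t_snapshot: float
    activity_estimate: float
    mean: float
    var: float
    fano: float
    se_activity: float
    se_mean: float
    se_fano: float
    master_seed: int
    counts: np.ndarray = field(repr=False)   # (n_runs, n_species) snapshot
    species: tuple[str, ...] = ()


def _fano_se(x: np.ndarray, n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of var/mean across snapshot samples."""
    rng = np.random.default_rng(seed)
    n = len(x)
    idx = rng.integers(0, n, size=(n_boot, n))
    b = x[idx]
    mean = b.mean(axis=1)
    var = b.var(axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(mean > 0, var / mean, np.nan)
    f = f[np.isfinite(f)]
    return float(f.std()) if len(f) else float("nan")


def _stationary_inits(system: ReactionSystem, model: DnaStateModel | None,
                      n_runs: int, rng: np.random.Generator) -> np.ndarray | None:
    """Initial states with the promoter coordinate drawn from its exact
    stationary law (one-hot species layout produced by dna_mrna_system)."""
    if model is None:
        return None
    pi = model.stationary()
    draws = rng.choice(model.n_states, size=n_runs, p=pi)
    inits = np.tile(system.initial, (n_runs, 1))
    inits[:, :model.n_states] = 0
    inits[np.arange(n_runs), draws] = 1
    return inits


def ensemble_stationary(system: ReactionSystem, n_runs: int, t_snapshot: float,
                        master_seed: int,
                        init_model: DnaStateModel | None = None,
                        initial_states: np.ndarray | None = None) -> EnsembleSummary:
    """Snapshot statistics across independent runs.

    ``init_model`` (for promoter+mRNA systems) draws each run's initial
    promoter state from the chain's stationary law; ``initial_states`` sets
    explicit per-run initial conditions."""
    if n_runs < 2:
        raise ValueError("need at least 2 runs")
    seeds = _seeds(master_seed, n_runs)
    rng = np.random.default_rng(np.random.SeedSequence(master_seed).spawn(1)[0])
    if initial_states is None:
        initial_states = _stationary_inits(system, init_model, n_runs, rng)
    grid = np.array([float(t_snapshot)])
    counts = np.empty((n_runs, system.n_species), np.int64)
    for i in range(n_runs):
        init = None if initial_states is None else initial_states[i]
        counts[i] = sample_on_grid(system, grid, seeds[i], initial=init)[0]
    m = counts[:, system.mrna_species].astype(float)
    act = counts[:, list(system.active_species)].sum(axis=1) >= 1
    mean = float(m.mean())
    var = float(m.var(ddof=1))
    fano = var / mean if mean > 0 else float("nan")
    p = float(act.mean())
    return EnsembleSummary(
        n_runs=n_runs, t_snapshot=float(t_snapshot), activity_estimate=p,
        mean=mean, var=var, fano=fano,
        se_activity=float(np.sqrt(p * (1 - p) / n_runs)),
        se_mean=float(m.std(ddof=1) / np.sqrt(n_runs)),
        se_fano=_fano_se(m, seed=master_seed),
        master_seed=int(master_seed), counts=counts, species=system.species)


def stationary_histogram(system: ReactionSystem, n_runs: int, t_snapshot: float,
                         master_seed: int,
                         init_model: DnaStateModel | None = None) -> np.ndarray:
    """Exact integer-count tally of the focal mRNA at the snapshot time.

    ``out[k]`` is the number of runs with exactly k mRNA molecules."""
    summ = ensemble_stationary(system, n_runs, t_snapshot, master_seed,
                               init_model=init_model)
    m = summ.counts[:, system.mrna_species]
    return np.bincount(m)


def count_modes(tally: np.ndarray, sigma: float = 4.0,
                min_mass: float = 1e-3,
                min_prominence_ratio: float = 0.5) -> int:
    """Number of modes of an integer-count tally.

    The empirical pmf is Gaussian-smoothed (std ``sigma`` counts); a local
    maximum counts as a mode if its topographic prominence is at least
    ``min_prominence_ratio`` of its height (rejecting bumps riding on the
    slope of a larger mode) and its basin carries at least ``min_mass`` of
    the total probability (rejecting isolated stray samples).  Intended for
    the qualitative unimodal/bimodal distinction, not density estimation."""
    from scipy.signal import find_peaks

    tally = np.asarray(tally, float)
    n = tally.sum()
    if n == 0:
        raise ValueError("empty tally")
    pmf = tally / n
    k = np.arange(len(pmf))
    kern = np.exp(-0.5 * ((k[:, None] - k[None, :]) / sigma) ** 2)
    kern /= kern.sum(axis=1, keepdims=True)
    sm = kern @ pmf
    padded = np.concatenate([[-1.0], sm, [-1.0]])  # expose boundary modes
    peaks, props = find_peaks(padded, prominence=0)
    modes = 0
    for p, prom, lb, rb in zip(peaks, props["prominences"],
                               props["left_bases"], props["right_bases"]):
        height = padded[p]
        basin = pmf[max(lb - 1, 0):min(rb, len(pmf))]
        if prom >= min_prominence_ratio * height and basin.sum() >= min_mass:
            modes += 1
    return modes


def time_average_stats(system: ReactionSystem, t_end: float, burn_in: float,
                       dt: float, seed: int) -> tuple[float, float, float]:
    """(activity, mean, fano) from a single long run, time-averaged.

    Cross-check estimator only; the snapshot ensemble is the headline."""
    grid = np.arange(burn_in, t_end, dt)
    counts = sample_on_grid(system, grid, seed)
    m = counts[:, system.mrna_species].astype(float)
    act = (counts[:, list(system.active_species)].sum(axis=1) >= 1).mean()
    mean = m.mean()
    return float(act), float(mean), float(m.var() / mean if mean > 0 else np.nan)


def default_burn_in(system_halflife_min: float, slowest_dna_rate: float) -> float:
    """Default snapshot time: 10 mRNA half-lives + 10 slowest-transition times."""
    return 10.0 * system_halflife_min + 10.0 / max(slowest_dna_rate, 1e-12)


# --------------------------------------------------------------------------
# full-kinetics vs QSSA-reduced comparison
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class QssaComparison:
    """Distance metrics between the full and QSSA-reduced switch."""

    rt_ratio: float
    mean_abs_diff: float      # mean |<M>_full - <M>_reduced| over the grid
    tv_distance: float        # total variation between snapshot histograms
    grid: np.ndarray
    mean_full: np.ndarray
    mean_reduced: np.ndarray


def _tv(h1: np.ndarray, h2: np.ndarray, bin_width: int = 4) -> float:
    n = max(len(h1), len(h2))
    a = np.zeros(n)
    b = np.zeros(n)
    a[:len(h1)] = h1 / h1.sum()
    b[:len(h2)] = h2 / h2.sum()
    nb = int(np.ceil(n / bin_width))
    a = np.add.reduceat(a, np.arange(0, n, bin_width))
    b = np.add.reduceat(b, np.arange(0, n, bin_width))
    return float(0.5 * np.abs(a - b).sum())


def _equilibrium_initial(spec: MultiTargetSpec,
                         rng: np.random.Generator) -> np.ndarray:
    """Initial counts near the titration equilibrium (protein partition
    rounded, focal/pooled genes drawn from the reduced chain's stationary
    law) to shorten the burn-in of slow sequestration modes."""
    system = build_multitarget_system(spec)
    part = qssa_partition(spec.AT, spec.RT, spec.Ks, spec.context.omega)
    model = build_indirect_model(
        IndirectSwitchSpec(context=spec.context, AT=spec.AT, RT=spec.RT,
                           Ks=spec.Ks, Ka=spec.Ka, Kb=spec.Kb, Kd=spec.Kd,
                           mechanisms=spec.mechanisms))
    pi = model.stationary()
    init = np.zeros(system.n_species, np.int64)
    gene = rng.choice(model.n_states, p=pi)
    init[3 + gene] = 1  # EF/EA/ER block
    if spec.DT:
        d = rng.multinomial(spec.DT, pi)
        init[6:6 + len(d)] = d
    n_ea = init[4] + init[7]            # activators held on DNA (EA, DA)
    n_er = init[5] + init[8]            # activator+repressor held (ER, DR)
    A = int(round(part.A))
    RA = int(round(part.RA))
    AT, RT = int(round(spec.AT)), int(round(spec.RT))
    A = min(A, AT - n_ea - n_er)
    RA = min(RA, AT - A - n_ea - n_er, RT - n_er)
    init[0] = max(A, 0)
    init[2] = max(RA, 0)
    init[1] = max(RT - init[2] - n_er, 0)
    # push any rounding slack into the free pools
    init[0] = AT - init[2] - n_ea - n_er
    return init


def compare_full_vs_qssa(spec: MultiTargetSpec, rt_ratios=(0.2, 1.0, 5.0),
                         n_runs: int = 1000, t_snapshot: float = 6000.0,
                         master_seed: int = 0, n_grid: int = 60,
                         rate_scale: float = 1.0) -> list[QssaComparison]:
    """Full-kinetics vs QSSA-reduced single-gene switch at several ratios.

    ``rate_scale`` multiplies all protein binding/unbinding rates of the
    full model (the QSSA becomes exact as it grows)."""
    if spec.DT != 0:
        raise ValueError("comparison is defined for the single-gene case")
    out = []
    ss = np.random.SeedSequence(master_seed)
    for rt_ratio, seed_pair in zip(rt_ratios, ss.spawn(len(rt_ratios))):
        s_full = MultiTargetSpec(
            context=spec.context, AT=spec.AT, RT=rt_ratio * spec.AT, DT=0,
            Ks=spec.Ks, Ka=spec.Ka, Kb=spec.Kb, Kd=spec.Kd,
            mechanisms=spec.mechanisms)
        full = build_multitarget_system(s_full)
        if rate_scale != 1.0:
            rates = full.rates.copy()
            for i, name in enumerate(full.reaction_names):
                if name in ("R+A->RA", "RA->R+A"):
                    rates[i] *= rate_scale
            full = ReactionSystem(
                species=full.species, initial=full.initial, rates=rates,
                reactants=full.reactants, stoich=full.stoich, kinds=full.kinds,
                reaction_names=full.reaction_names,
                active_species=full.active_species,
                mrna_species=full.mrna_species,
                conservations=full.conservations)
        red_spec = s_full.reduced_spec()
        model = build_indirect_model(red_spec)
        reduced = dna_mrna_system(model, spec.context.alpha, spec.context.beta)
        seeds = seed_pair.generate_state(2)
        grid = np.linspace(0.0, t_snapshot, n_grid)
        rng = np.random.default_rng(seeds[0])
        mf = np.zeros(n_grid)
        hist_f = np.zeros(1, int)
        run_seeds = _seeds(int(seeds[0]), n_runs)
        for i in range(n_runs):
            init = _equilibrium_initial(s_full, rng)
            c = sample_on_grid(full, grid, run_seeds[i], initial=init)
            mf += c[:, full.mrna_species]
            m = c[-1, full.mrna_species]
            if m >= len(hist_f):
                hist_f = np.concatenate([hist_f, np.zeros(m + 1 - len(hist_f), int)])
            hist_f[m] += 1
        mf /= n_runs
        pi = model.stationary()
        rng_r = np.random.default_rng(seeds[1])
        inits = _stationary_inits(reduced, model, n_runs, rng_r)
        mr = np.zeros(n_grid)
        hist_r = np.zeros(1, int)
        run_seeds_r = _seeds(int(seeds[1]), n_runs)
        for i in range(n_runs):
            c = sample_on_grid(reduced, grid, run_seeds_r[i], initial=inits[i])
            mr += c[:, reduced.mrna_species]
            m = c[-1, reduced.mrna_species]
            if m >= len(hist_r):
                hist_r = np.concatenate([hist_r, np.zeros(m + 1 - len(hist_r), int)])
            hist_r[m] += 1
        mr /= n_runs
        out.append(QssaComparison(
            rt_ratio=float(rt_ratio),
            mean_abs_diff=float(np.abs(mf - mr).mean()),
            tv_distance=_tv(hist_f, hist_r),
            grid=grid, mean_full=mf, mean_reduced=mr))
    return out
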