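"""Model definitions for stochastic transcriptional switches.

Two families of ultrasensitive gene switches are described here:

* **Cooperative binding** — a repressor R occupies four identical DNA sites;
  each additional bound repressor lowers the unbinding rate by a factor
  ``c`` (cooperativity, 0 < c <= 1).  Transcription is inhibited only when
  all four sites are occupied (or, in the activator variant, enabled only
  when all four are occupied).

* **Indirect repression** — an activator A must bind free DNA to enable
  transcription, and a repressor R interferes indirectly through up to three
  mechanisms: *sequestration* (R binds free A into an inert RA complex),
  *blocking* (R binds DNA-bound A, silencing it in place) and *displacement*
  (R strips DNA-bound A off the DNA as RA; equivalently RA binds free DNA).

Copy numbers are treated as molecule counts (the literature often quotes
them in yoctomoles; 1 count per ymol here), volumes in attolitres, all rates
in min^-1, and dissociation constants as concentrations in ymol * aL^-1 so
that ``Omega * K`` is a copy number.  Every bimolecular association shares a
single rate constant ``kf`` (aL * ymol^-1 * min^-1); unbinding rates follow
from the dissociation constants, e.g. ``ka = kf * Ka``.

Promoter-state dynamics are represented as a :class:`DnaStateModel` (a small
continuous-time Markov chain with per-state transcription flags) that both
the closed-form and moment-solver paths consume, while fully kinetic systems
(the oscillator and the multi-target competition model) are represented as a
:class:`ReactionSystem` consumed by the Gillespie engine.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "CellContext",
    "CooperativeSwitchSpec",
    "IndirectSwitchSpec",
    "NflSpec",
    "MultiTargetSpec",
    "ProteinPartition",
    "DnaStateModel",
    "ReactionSystem",
    "qssa_partition",
    "resolve_constant",
    "build_cooperative_model",
    "build_indirect_model",
    "dna_mrna_system",
    "build_nfl_system",
    "build_multitarget_system",
]

Mechanism = Literal["S", "SB", "SBD"]

#: propensity kinds understood by the SSA kernel
MASS_ACTION = 0
QSSA_FREE_ACTIVATOR = 1   # rate * n_i * A(RT=n_rt)
QSSA_FREE_REPRESSOR = 2   # rate * n_i * R(RT=n_rt)
QSSA_COMPLEX = 3          # rate * n_i * RA(RT=n_rt)


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class CellContext:
    """Shared kinetic environment.

    Parameters
    ----------
    omega : cell volume, aL.
    kf : association rate constant shared by all binding reactions,
        aL * ymol^-1 * min^-1.
    alpha : transcription rate from an active promoter, min^-1.
    beta : mRNA degradation rate, min^-1.
    """

    omega: float = 1e7
    kf: float = 600.0
    alpha: float = 100.0 * math.log(2.0) / 984.5
    beta: float = math.log(2.0) / 984.5

    def __post_init__(self) -> None:
        for name in ("omega", "kf", "alpha", "beta"):
            v = getattr(self, name)
            _require(np.isfinite(v) and v > 0, f"{name} must be finite and > 0")
        _require(np.isfinite(self.alpha / self.beta), "alpha/beta must be finite")

    @property
    def kf_per_volume(self) -> float:
        """Per-molecule binding propensity prefactor kf/Omega, ymol^-1 min^-1."""
        return self.kf / self.omega

    @property
    def halflife(self) -> float:
        """mRNA half-life ln2/beta, min."""
        return math.log(2.0) / self.beta

    def with_rates(self, kf_per_volume: float | None = None,
                   halflife: float | None = None) -> "CellContext":
        """Return a context with new kinetics, preserving alpha/beta and Omega.

        Used by parameter sweeps that vary kf and the mRNA half-life while
        holding the dissociation constants and the ratio alpha/beta fixed.
        """
        ratio = self.alpha / self.beta
        beta = math.log(2.0) / halflife if halflife is not None else self.beta
        kf = kf_per_volume * self.omega if kf_per_volume is not None else self.kf
        return CellContext(omega=self.omega, kf=kf, alpha=ratio * beta, beta=beta)


@dataclass(frozen=True)
class ProteinPartition:
    """Quasi-steady-state solution of the activator-repressor titration.

    ``A`` free activators, ``R`` free repressors and ``RA`` complexes satisfy
    ``A + RA = AT``, ``R + RA = RT`` and the mass-action balance
    ``A * R = Omega * Ks * RA``.
    """

    A: float
    R: float
    RA: float


def _titration_roots(at, rt, oks):
    """Vectorized nonnegative roots (A, R, RA) of the titration quadratic.

    Each root is taken through its numerically benign branch (direct sum
    when the linear term is positive, product identity otherwise), and the
    complex count through whichever of the three equivalent expressions is
    free of cancellation, so that the conservation laws and the mass-action
    balance A*R = oks*RA all hold to machine relative accuracy.
    """
    at, rt, oks = np.broadcast_arrays(*map(np.asarray, (at, rt, oks)))
    at = at.astype(float)
    rt = rt.astype(float)
    oks = oks.astype(float)
    da = at - rt - oks
    disc = np.sqrt(da * da + 4.0 * oks * at)
    with np.errstate(divide="ignore", invalid="ignore"):
        A = np.where(da >= 0, 0.5 * (da + disc),
                     2.0 * oks * at / (disc - da))
        dr = rt - at - oks
        R = np.where(dr >= 0, 0.5 * (dr + disc),
                     2.0 * oks * rt / (disc - dr))
        R = np.where(rt == 0, 0.0, R)
        A = np.where(at == 0, 0.0, A)
        RA = np.where(A <= 0.5 * at, at - A,
                      np.where(R <= 0.5 * rt, rt - R, A * R / oks))
    return A, R, RA


def qssa_partition(AT: float, RT: float, Ks: float, omega: float) -> ProteinPartition:
    """Solve the activator-repressor titration equilibrium.

    Returns the unique nonnegative solution of ``A*R = Omega*Ks*RA`` under
    the conservation laws ``A + RA = AT`` and ``R + RA = RT``; the identity
    ``A - R = AT - RT`` holds exactly.
    """
    if AT < 0 or RT < 0:
        raise ValueError("AT and RT must be nonnegative")
    if Ks <= 0 or omega <= 0:
        raise ValueError("Ks and omega must be positive")
    if AT == 0:
        return ProteinPartition(0.0, float(RT), 0.0)
    if RT == 0:
        return ProteinPartition(float(AT), 0.0, 0.0)
    A, R, RA = _titration_roots(float(AT), float(RT), omega * Ks)
    return ProteinPartition(float(A), float(R), float(RA))


def resolve_constant(printed: float, convention: str, AT: float, omega: float) -> float:
    """Convert a published dissociation-constant entry to ymol * aL^-1.

    The tables that report these switches quote constants in three
    inconsistent notations; the convention switch makes the choice explicit:

    * ``"per_activator"`` — the printed number is Kx/AT; raw Kx = printed*AT.
      This is the reading under which the published Fano-factor benchmarks
      (49 / ~3 / 17 / 1) are reproduced, and it leaves the normalized
      constant Omega*Kx/AT independent of AT, so activity curves are
      identical across activator-abundance panels.
    * ``"normalized"`` — the printed number is the dimensionless
      Omega*Kx/AT; raw Kx = printed*AT/Omega.
    * ``"raw"`` — the printed number is the concentration itself.
    """
    if convention == "per_activator":
        return printed * AT
    if convention == "normalized":
        return printed * AT / omega
    if convention == "raw":
        return printed
    raise ValueError(f"unknown constant convention {convention!r}")


# --------------------------------------------------------------------------
# promoter-state Markov chains
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DnaStateModel:
    """Finite promoter-state CTMC with per-state transcription flags.

    ``rate_matrix`` holds the full generator: off-diagonal entries are
    transition rates (min^-1), diagonal entries are minus the row sums.
    """

    states: tuple[str, ...]
    rate_matrix: np.ndarray
    producing: np.ndarray

    def __post_init__(self) -> None:
        Q = np.asarray(self.rate_matrix, float)
        p = np.asarray(self.producing, bool)
        n = len(self.states)
        _require(Q.shape == (n, n), "rate matrix shape mismatch")
        _require(p.shape == (n,), "producing flag shape mismatch")
        off = Q - np.diag(np.diag(Q))
        _require((off >= 0).all(), "off-diagonal rates must be nonnegative")
        _require(np.allclose(Q.sum(axis=1), 0, atol=1e-9 * max(1.0, np.abs(Q).max())),
                 "generator rows must sum to zero")
        _require(p.any() and (~p).any(),
                 "need at least one producing and one non-producing state")
        object.__setattr__(self, "rate_matrix", Q)
        object.__setattr__(self, "producing", p)

    @property
    def n_states(self) -> int:
        return len(self.states)

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the promoter chain (pi Q = 0)."""
        Q = self.rate_matrix
        n = self.n_states
        if np.linalg.matrix_rank(Q, tol=1e-12 * max(1.0, np.abs(Q).max())) < n - 1:
            raise np.linalg.LinAlgError("promoter chain is reducible")
        A = np.vstack([Q.T, np.ones(n)])
        b = np.zeros(n + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0.0, None)
        return pi / pi.sum()


@dataclass(frozen=True)
class CooperativeSwitchSpec:
    """Four-binding-site cooperative switch.

    ``c`` is the cooperativity factor: with n sites already occupied, each
    occupied site unbinds at ``c**(n-1) * kr`` where ``kr = kf * Kr``.
    ``mode`` selects whether the ligand is a repressor (transcription off
    only in the fully occupied state) or an activator (transcription on only
    in the fully occupied state).
    """

    context: CellContext = field(default_factory=CellContext)
    c: float = 1e-2
    Kr: float = 1e-2
    RT: float = 100.0
    mode: Literal["repressor_inhibits", "activator_activates"] = "repressor_inhibits"

    def __post_init__(self) -> None:
        _require(0 < self.c <= 1, "cooperativity c must satisfy 0 < c <= 1")
        _require(self.Kr > 0, "Kr must be positive")
        _require(self.RT >= 0, "RT must be nonnegative")
        _require(self.mode in ("repressor_inhibits", "activator_activates"),
                 f"unknown mode {self.mode!r}")

    @property
    def kr(self) -> float:
        """Single-occupancy unbinding rate kf*Kr, min^-1."""
        return self.context.kf * self.Kr

    @property
    def x(self) -> float:
        """Binding strength RT / (Omega*Kr), dimensionless."""
        return self.RT / (self.context.omega * self.Kr)


_SITE_STATES = tuple("".join(map(str, bits))
                     for bits in itertools.product((0, 1), repeat=4))


def build_cooperative_model(spec: CooperativeSwitchSpec) -> DnaStateModel:
    """16-state promoter chain of the four-site cooperative switch.

    From every state, each unoccupied site is bound at ``(kf/Omega)*RT`` and
    each occupied site unbinds at ``c**(n_occ - 1) * kr``; the chain has
    exactly 64 directed transitions.
    """
    kon = spec.context.kf_per_volume * spec.RT
    kr = spec.kr
    n = len(_SITE_STATES)
    idx = {s: i for i, s in enumerate(_SITE_STATES)}
    Q = np.zeros((n, n))
    for s in _SITE_STATES:
        n_occ = s.count("1")
        for site in range(4):
            t = s[:site] + ("1" if s[site] == "0" else "0") + s[site + 1:]
            if s[site] == "0":
                Q[idx[s], idx[t]] += kon
            else:
                Q[idx[s], idx[t]] += spec.c ** (n_occ - 1) * kr
    np.fill_diagonal(Q, -Q.sum(axis=1))
    full = np.array([s == "1111" for s in _SITE_STATES])
    producing = full if spec.mode == "activator_activates" else ~full
    return DnaStateModel(states=_SITE_STATES, rate_matrix=Q, producing=producing)


@dataclass(frozen=True)
class IndirectSwitchSpec:
    """Indirect-repression switch under the protein-titration QSSA.

    ``mechanisms`` selects the repression set: ``"S"`` sequestration only,
    ``"SB"`` adds blocking, ``"SBD"`` adds displacement.  ``Kd`` defaults to
    the detailed-balance value ``Ka*Kb/Ks`` (sigma = 1, no net free-energy
    dissipation around the binding cycle).
    """

    context: CellContext = field(default_factory=CellContext)
    AT: float = 1e3
    RT: float = 0.0
    Ks: float = 4.5e-7
    Ka: float = 7e-6
    Kb: float = 1e-3
    Kd: float | None = None
    mechanisms: Mechanism = "SBD"

    def __post_init__(self) -> None:
        _require(self.mechanisms in ("S", "SB", "SBD"),
                 f"unknown mechanism set {self.mechanisms!r}")
        _require(self.AT >= 0 and self.RT >= 0, "counts must be nonnegative")
        for name in ("Ks", "Ka", "Kb"):
            _require(getattr(self, name) > 0, f"{name} must be positive")
        if self.Kd is None:
            object.__setattr__(self, "Kd", self.Ka * self.Kb / self.Ks)
        _require(self.Kd > 0, "Kd must be positive")

    @classmethod
    def from_printed(cls, context: CellContext, AT: float, RT: float,
                     ks: float, ka: float, kb: float, kd: float | None = None,
                     mechanisms: Mechanism = "SBD",
                     convention: str = "per_activator") -> "IndirectSwitchSpec":
        """Build a spec from published table entries under a stated convention."""
        res = lambda v: resolve_constant(v, convention, AT, context.omega)
        return cls(context=context, AT=AT, RT=RT, Ks=res(ks), Ka=res(ka),
                   Kb=res(kb), Kd=None if kd is None else res(kd),
                   mechanisms=mechanisms)

    @property
    def sigma(self) -> float:
        """Cycle affinity Ks*Kd/(Ka*Kb); 1 at detailed balance."""
        return self.Ks * self.Kd / (self.Ka * self.Kb)

    @property
    def rt_ratio(self) -> float:
        """Molar ratio RT/AT (the threshold sits near 1)."""
        return self.RT / self.AT

    def normalized(self) -> dict[str, float]:
        """Dimensionless parameters: K~x = Omega*Kx/AT, rates over (kf/Omega)*AT."""
        ctx = self.context
        scale = ctx.kf_per_volume * self.AT
        s = ctx.omega / self.AT
        return {
            "ks": s * self.Ks, "ka": s * self.Ka, "kb": s * self.Kb,
            "kd": s * self.Kd, "alpha": ctx.alpha / scale,
            "beta": ctx.beta / scale, "rt": self.rt_ratio,
        }

    def partition(self) -> ProteinPartition:
        return qssa_partition(self.AT, self.RT, self.Ks, self.context.omega)

    def at_rt_ratio(self, rt_ratio: float) -> "IndirectSwitchSpec":
        return replace(self, RT=rt_ratio * self.AT)


def build_indirect_model(spec: IndirectSwitchSpec) -> DnaStateModel:
    """Promoter chain {EF, EA[, ER]} of the indirect-repression switch.

    Protein counts are closed through :func:`qssa_partition`; binding rates
    are ``(kf/Omega)`` times the relevant free count, unbinding rates are
    ``kf`` times the dissociation constants.  Only ``EA`` transcribes.
    """
    ctx = spec.context
    part = spec.partition()
    kfo = ctx.kf_per_volume
    ka = ctx.kf * spec.Ka
    if spec.mechanisms == "S":
        Q = np.array([[-kfo * part.A, kfo * part.A], [ka, -ka]])
        return DnaStateModel(states=("EF", "EA"), rate_matrix=Q,
                             producing=np.array([False, True]))
    kb = ctx.kf * spec.Kb
    Q = np.zeros((3, 3))
    Q[0, 1] = kfo * part.A
    Q[1, 0] = ka
    Q[1, 2] = kfo * part.R
    Q[2, 1] = kb
    if spec.mechanisms == "SBD":
        Q[0, 2] = kfo * part.RA
        Q[2, 0] = ctx.kf * spec.Kd
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return DnaStateModel(states=("EF", "EA", "ER"), rate_matrix=Q,
                         producing=np.array([False, True, False]))


# --------------------------------------------------------------------------
# discrete reaction systems for the SSA engine
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ReactionSystem:
    """Discrete-species system with mass-action or QSSA-closed propensities.

    Each reaction's propensity is ``rate * n_i [* n_j]`` over the (at most
    two) reactant species, or, for the QSSA kinds, ``rate * n_i * f(n_rt)``
    where ``f`` is the free-activator / free-repressor / complex branch of
    the titration equilibrium evaluated at the current repressor count.
    """

    species: tuple[str, ...]
    initial: np.ndarray
    rates: np.ndarray
    reactants: np.ndarray          # (n_rxn, 2) species indices, -1 = absent
    stoich: np.ndarray             # (n_rxn, n_species) integer changes
    kinds: np.ndarray              # propensity kind per reaction
    reaction_names: tuple[str, ...] = ()
    active_species: tuple[int, ...] = ()   # promoter-active indicator species
    mrna_species: int = -1
    qssa_at: float = 0.0
    qssa_omega_ks: float = 1.0
    qssa_rt_species: int = -1
    conservations: tuple[tuple[tuple[float, ...], float], ...] = ()

    def __post_init__(self) -> None:
        ns, nr = len(self.species), len(self.rates)
        object.__setattr__(self, "initial", np.asarray(self.initial, np.int64))
        object.__setattr__(self, "rates", np.asarray(self.rates, float))
        object.__setattr__(self, "reactants", np.asarray(self.reactants, np.int64))
        object.__setattr__(self, "stoich", np.asarray(self.stoich, np.int64))
        object.__setattr__(self, "kinds", np.asarray(self.kinds, np.int8))
        _require(self.initial.shape == (ns,), "initial shape mismatch")
        _require(self.stoich.shape == (nr, ns), "stoichiometry shape mismatch")
        _require(self.reactants.shape == (nr, 2), "reactants shape mismatch")
        _require((self.rates >= 0).all(), "rates must be nonnegative")
        _require((self.initial >= 0).all(), "initial counts must be nonnegative")
        if (self.kinds != MASS_ACTION).any():
            _require(self.qssa_rt_species >= 0,
                     "QSSA propensities need a repressor-count species")

    @property
    def n_species(self) -> int:
        return len(self.species)

    def index(self, name: str) -> int:
        return self.species.index(name)

    def check_conservation(self, counts: np.ndarray) -> None:
        """Raise if declared conserved quantities are violated."""
        counts = np.atleast_2d(counts)
        for coef, total in self.conservations:
            got = counts @ np.asarray(coef)
            if not np.allclose(got, total):
                raise AssertionError(
                    f"conservation {coef} = {total} violated (got {got})")


def dna_mrna_system(model: DnaStateModel, alpha: float, beta: float,
                    init_state: int = 0) -> ReactionSystem:
    """Embed a promoter chain plus one mRNA species as a reaction system.

    Promoter states become one-hot indicator species; transcription fires at
    ``alpha`` from each producing state and mRNA degrades at ``beta``.
    """
    n = model.n_states
    species = tuple(model.states) + ("M",)
    m_idx = n
    rates, reac, stoich, names = [], [], [], []
    Q = model.rate_matrix
    for i in range(n):
        for j in range(n):
            if i != j and Q[i, j] > 0:
                rates.append(Q[i, j])
                reac.append((i, -1))
                row = np.zeros(n + 1, np.int64)
                row[i], row[j] = -1, 1
                stoich.append(row)
                names.append(f"{model.states[i]}->{model.states[j]}")
    for i in np.flatnonzero(model.producing):
        rates.append(alpha)
        reac.append((i, -1))
        row = np.zeros(n + 1, np.int64)
        row[m_idx] = 1
        stoich.append(row)
        names.append(f"{model.states[i]}->+M")
    rates.append(beta)
    reac.append((m_idx, -1))
    row = np.zeros(n + 1, np.int64)
    row[m_idx] = -1
    stoich.append(row)
    names.append("M->0")
    initial = np.zeros(n + 1, np.int64)
    initial[init_state] = 1
    return ReactionSystem(
        species=species, initial=initial, rates=np.array(rates),
        reactants=np.array(reac), stoich=np.array(stoich),
        kinds=np.zeros(len(rates), np.int8), reaction_names=tuple(names),
        active_species=tuple(int(i) for i in np.flatnonzero(model.producing)),
        mrna_species=m_idx,
        conservations=(((1.0,) * n + (0.0,), 1.0),),
    )


@dataclass(frozen=True)
class NflSpec:
    """Transcriptional negative-feedback oscillator.

    mRNA (M) is translated into a cytoplasmic repressor (Rc) that enters the
    nucleus (R) and represses its own transcription through the indirect
    mechanisms, with the protein partition closed by the QSSA at the current
    nuclear repressor count.  ``table_literal`` reproduces the published
    reaction table verbatim (translation consumes the mRNA and nuclear
    import fires at ``alpha * n_EA``); the default reading uses catalytic
    translation ``M -> M + Rc`` at ``alpha2 * n_M`` and first-order import
    ``Rc -> R`` at ``alpha3 * n_Rc``, which respects mass-action kinetics
    and gives the import rate ``alpha3`` a role.
    """

    context: CellContext = field(default_factory=lambda: CellContext(
        alpha=100 * math.log(2.0) / 120.0, beta=math.log(2.0) / 120.0))
    alpha2: float = 5.0 / 12.0
    alpha3: float = 5.0 / 12.0
    AT: float = 1e3
    Ks: float = 9e-9
    Ka: float = 2e-6
    Kb: float = 5e-6
    Kd: float | None = None
    mechanisms: Mechanism = "SBD"
    table_literal: bool = False

    def __post_init__(self) -> None:
        _require(self.alpha2 > 0 and self.alpha3 > 0, "rates must be positive")
        _require(self.mechanisms in ("S", "SB", "SBD"),
                 f"unknown mechanism set {self.mechanisms!r}")
        _require(self.AT > 0, "AT must be positive")
        if self.Kd is None:
            object.__setattr__(self, "Kd", self.Ka * self.Kb / self.Ks)

    def switch_spec(self, RT: float = 0.0) -> IndirectSwitchSpec:
        """The static indirect switch seen at a frozen repressor count."""
        return IndirectSwitchSpec(context=self.context, AT=self.AT, RT=RT,
                                  Ks=self.Ks, Ka=self.Ka, Kb=self.Kb,
                                  Kd=self.Kd, mechanisms=self.mechanisms)


def build_nfl_system(spec: NflSpec) -> ReactionSystem:
    """Reaction system of the negative-feedback oscillator."""
    ctx = spec.context
    species = ("EF", "EA", "ER", "M", "Rc", "R")
    iEF, iEA, iER, iM, iRc, iR = range(6)
    kfo = ctx.kf_per_volume
    rates, reac, kinds, stoich, names = [], [], [], [], []

    def add(rate, reactant, kind, changes, name):
        rates.append(rate)
        reac.append((reactant, -1))
        kinds.append(kind)
        row = np.zeros(6, np.int64)
        for sp, d in changes.items():
            row[sp] = d
        stoich.append(row)
        names.append(name)

    add(ctx.alpha, iEA, MASS_ACTION, {iM: 1}, "EA->EA+M")
    add(ctx.beta, iM, MASS_ACTION, {iM: -1}, "M->0")
    if spec.table_literal:
        add(spec.alpha2, iM, MASS_ACTION, {iM: -1, iRc: 1}, "M->Rc")
        add(ctx.alpha, iEA, MASS_ACTION, {iRc: -1, iR: 1}, "Rc->R")
    else:
        add(spec.alpha2, iM, MASS_ACTION, {iRc: 1}, "M->M+Rc")
        add(spec.alpha3, iRc, MASS_ACTION, {iRc: -1, iR: 1}, "Rc->R")
    add(ctx.beta, iRc, MASS_ACTION, {iRc: -1}, "Rc->0")
    add(ctx.beta, iR, MASS_ACTION, {iR: -1}, "R->0")
    add(kfo, iEF, QSSA_FREE_ACTIVATOR, {iEF: -1, iEA: 1}, "EF->EA")
    add(ctx.kf * spec.Ka, iEA, MASS_ACTION, {iEA: -1, iEF: 1}, "EA->EF")
    if spec.mechanisms in ("SB", "SBD"):
        add(kfo, iEA, QSSA_FREE_REPRESSOR, {iEA: -1, iER: 1}, "EA->ER")
        add(ctx.kf * spec.Kb, iER, MASS_ACTION, {iER: -1, iEA: 1}, "ER->EA")
    if spec.mechanisms == "SBD":
        add(kfo, iEF, QSSA_COMPLEX, {iEF: -1, iER: 1}, "EF->ER")
        add(ctx.kf * spec.Kd, iER, MASS_ACTION, {iER: -1, iEF: 1}, "ER->EF")
    initial = np.zeros(6, np.int64)
    initial[iEF] = 1
    return ReactionSystem(
        species=species, initial=initial, rates=np.array(rates),
        reactants=np.array(reac), stoich=np.array(stoich),
        kinds=np.array(kinds, np.int8), reaction_names=tuple(names),
        active_species=(iEA,), mrna_species=iM,
        qssa_at=float(spec.AT),
        qssa_omega_ks=ctx.omega * spec.Ks,
        qssa_rt_species=iR,
        conservations=(((1, 1, 1, 0, 0, 0), 1.0),),
    )


@dataclass(frozen=True)
class MultiTargetSpec:
    """One focal gene plus ``DT`` pooled additional target genes competing
    for a shared activator pool, with fully kinetic protein dynamics
    (no QSSA).  Only the focal gene produces the tracked mRNA."""

    context: CellContext = field(default_factory=lambda: CellContext(
        alpha=100 * math.log(2.0) / 120.0, beta=math.log(2.0) / 120.0))
    AT: float = 1e3
    RT: float = 0.0
    DT: int = 0
    Ks: float = 4.5e-7
    Ka: float = 7e-6
    Kb: float = 1e-3
    Kd: float | None = None
    mechanisms: Mechanism = "SBD"

    def __post_init__(self) -> None:
        _require(self.DT >= 0, "DT must be nonnegative")
        _require(self.mechanisms in ("S", "SB", "SBD"),
                 f"unknown mechanism set {self.mechanisms!r}")
        if self.Kd is None:
            object.__setattr__(self, "Kd", self.Ka * self.Kb / self.Ks)

    def reduced_spec(self) -> IndirectSwitchSpec:
        """The QSSA-reduced single-gene switch with the same constants."""
        _require(self.DT == 0, "reduction is defined for the single-gene case")
        return IndirectSwitchSpec(context=self.context, AT=self.AT, RT=self.RT,
                                  Ks=self.Ks, Ka=self.Ka, Kb=self.Kb,
                                  Kd=self.Kd, mechanisms=self.mechanisms)


def build_multitarget_system(spec: MultiTargetSpec) -> ReactionSystem:
    """Fully kinetic shared-activator system (focal gene + DT-gene pool)."""
    ctx = spec.context
    species = ("A", "R", "RA", "EF", "EA", "ER", "DF", "DA", "DR", "M")
    iA, iR, iRA, iEF, iEA, iER, iDF, iDA, iDR, iM = range(10)
    kfo = ctx.kf_per_volume
    ka = ctx.kf * spec.Ka
    ks = ctx.kf * spec.Ks
    kb = ctx.kf * spec.Kb
    kd = ctx.kf * spec.Kd
    rates, reac, stoich, names = [], [], [], []

    def add(rate, reactants, changes, name):
        rates.append(rate)
        reac.append(tuple(reactants) if len(reactants) == 2 else (reactants[0], -1))
        row = np.zeros(10, np.int64)
        for sp, d in changes.items():
            row[sp] = d
        stoich.append(row)
        names.append(name)

    add(ctx.alpha, [iEA], {iM: 1}, "EA->EA+M")
    add(ctx.beta, [iM], {iM: -1}, "M->0")
    # sequestration (always present)
    add(kfo, [iR, iA], {iR: -1, iA: -1, iRA: 1}, "R+A->RA")
    add(ks, [iRA], {iRA: -1, iR: 1, iA: 1}, "RA->R+A")
    # activator binding, focal and pooled genes
    add(kfo, [iA, iEF], {iA: -1, iEF: -1, iEA: 1}, "A+EF->EA")
    add(ka, [iEA], {iEA: -1, iA: 1, iEF: 1}, "EA->A+EF")
    add(kfo, [iA, iDF], {iA: -1, iDF: -1, iDA: 1}, "A+DF->DA")
    add(ka, [iDA], {iDA: -1, iA: 1, iDF: 1}, "DA->A+DF")
    if spec.mechanisms in ("SB", "SBD"):
        add(kfo, [iR, iEA], {iR: -1, iEA: -1, iER: 1}, "R+EA->ER")
        add(kb, [iER], {iER: -1, iR: 1, iEA: 1}, "ER->R+EA")
        add(kfo, [iR, iDA], {iR: -1, iDA: -1, iDR: 1}, "R+DA->DR")
        add(kb, [iDR], {iDR: -1, iR: 1, iDA: 1}, "DR->R+DA")
    if spec.mechanisms == "SBD":
        add(kfo, [iRA, iEF], {iRA: -1, iEF: -1, iER: 1}, "RA+EF->ER")
        add(kd, [iER], {iER: -1, iRA: 1, iEF: 1}, "ER->RA+EF")
        add(kfo, [iRA, iDF], {iRA: -1, iDF: -1, iDR: 1}, "RA+DF->DR")
        add(kd, [iDR], {iDR: -1, iRA: 1, iDF: 1}, "DR->RA+DF")
    initial = np.zeros(10, np.int64)
    initial[iA] = int(round(spec.AT))
    initial[iR] = int(round(spec.RT))
    initial[iEF] = 1
    initial[iDF] = spec.DT
    return ReactionSystem(
        species=species, initial=initial, rates=np.array(rates),
        reactants=np.array(reac), stoich=np.array(stoich),
        kinds=np.zeros(len(rates), np.int8), reaction_names=tuple(names),
        active_species=(iEA,), mrna_species=iM,
        conservations=(
            ((1, 0, 1, 0, 1, 1, 0, 1, 1, 0), float(int(round(spec.AT)))),
            ((0, 1, 1, 0, 0, 1, 0, 0, 1, 0), float(int(round(spec.RT)))),
            ((0, 0, 0, 1, 1, 1, 0, 0, 0, 0), 1.0),
            ((0, 0, 0, 0, 0, 0, 1, 1, 1, 0), float(spec.DT)),
        ),
    )
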