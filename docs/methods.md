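# Methods

## The models

`txswitch` analyses stochastic transcriptional switches in which a gene's
output must respond ultrasensitively to a repressor while keeping mRNA
noise low, under two physiological constraints that are often idealized
away: finite DNA binding kinetics and finite activator abundance.

All models live in a shared kinetic environment (`CellContext`): cell
volume Ω (default 10⁷ aL), a single association rate constant kf for every
bimolecular binding step (default 600 aL·ymol⁻¹·min⁻¹, i.e. kf/Ω =
6×10⁻⁵ ymol⁻¹min⁻¹), transcription rate α from an active promoter, and
mRNA degradation rate β. Copy numbers are molecule counts (equivalently
yoctomoles), dissociation constants Kx are concentrations in ymol·aL⁻¹, so
ΩKx is a copy number and every unbinding rate is kf·Kx. Defaults follow
the reference tables: α/β = 100, mRNA half-life ln2/β = 984.5 min for the
static switches and 120 min for the oscillator and multi-target settings.

**Cooperative switch.** A repressor binds four identical DNA sites at
(kf/Ω)·RT per free site; with n sites occupied each occupied site unbinds
at c^(n−1)·kr, kr = kf·Kr, c ≤ 1 the cooperativity. Transcription runs
unless all four sites are filled (an activator-gated variant inverts the
producing set). The promoter is the 16-state chain over site
configurations; aggregated by occupancy it is a birth–death chain with
detailed-balance law π(n+1)/π(n) = (4−n)x/((n+1)cⁿ), x = RT/(ΩKr). The
reference operating point c = 10⁻², ΩKr = 10⁵, RT = c^1.5·ΩKr = 100 sits
at transcriptional activity ≈ 0.5 with an effective Hill exponent ≈ 4.

**Indirect-repression switch.** An activator A must occupy the promoter
(EF ⇌ EA) for transcription; a repressor R interferes by sequestration
(R + A ⇌ RA in solution), blocking (R binds DNA-bound A: EA ⇌ ER) and
displacement (RA ⇌ DNA: EF ⇌ ER). Mechanism sets "S", "SB", "SBD" nest
these. Protein copy numbers equilibrate much faster than DNA binding, so
the chain is closed over the titration quasi-steady state: A(RT, AT, Ks)
is the positive root of A·R = ΩKs·RA under A + RA = AT, R + RA = RT. The
default displacement constant is the detailed-balance value
Kd = Ka·Kb/Ks (cycle affinity σ = Ks·Kd/(Ka·Kb) = 1), so the three-state
chain dissipates no free energy.

**Negative-feedback oscillator.** mRNA (M) → cytoplasmic repressor (Rc) →
nuclear repressor (R) → repression of the gene through the indirect
mechanisms, with the promoter propensities closed over the titration QSSA
at the *current* nuclear count (RT = n_R). The published reaction table
prints translation as "M → Rc" with propensity α₂·n_M and nuclear import
with propensity α·n_EA, which consumes mRNA on translation and leaves α₃
unused; the default reading here is catalytic translation (M → M + Rc at
α₂·n_M) and first-order import (Rc → R at α₃·n_Rc). A `table_literal`
flag reproduces the verbatim lines for comparison.

**Multi-target competition.** One focal gene plus DT pooled additional
genes share an activator pool, with fully kinetic protein dynamics (no
QSSA): every binding at kf/Ω, unbinding at kf·Kx. Only the focal gene's
mRNA is tracked. DT = 0 is the "full-kinetics" single-gene model used to
validate the QSSA reduction.

## Dissociation-constant notation

The published parameter tables print entries such as "KsAT = 4.5×10⁻¹⁰
ymol". The package resolves them through an explicit convention switch
(`resolve_constant`): the default, `per_activator`, reads the printed
number as Kx/AT, i.e. raw Kx = printed·AT and normalized
K̃x = ΩKx/AT = Ω·printed. Two facts select this reading. First, it makes
K̃x independent of AT, so the activity curves are identical across the
activator-abundance panels, as the figures require. Second, it is the
only reading that reproduces the printed Fano-factor benchmarks (box
minimum 49.85 ≈ 49 for the cooperative switch; near-threshold maximum
16.8 ≈ 17 for sole sequestration at AT = 10⁵ with the Hill-50 constants;
Poisson floor ≈ 1 for all three mechanisms at AT = 10⁵ with the Hill-4
constants) and the matched Hill exponents themselves (4.7 and 48.5 for
the SBD presets, against the published references 4 and 50). The
alternative readings (`normalized`: printed = ΩKx/AT; `raw`: printed =
Kx) remain available and are recorded in every manifest.

## Exact stationary moments

For a promoter chain with generator Q (states i, stationary law π) gating
mRNA production (rate a_i = α·[i producing], degradation β per molecule),
the state-resolved moments m_i = E[M; i] and s_i = E[M(M−1); i] satisfy
linear systems m(Q − βI) = −π∘a and s(Q − 2βI) = −2 m∘a; activity, mean,
variance and the Fano factor F = Var/E follow exactly. The solver uses
dense linear algebra (≤ 16 states), checks irreducibility by a rank test,
and warns above condition number 10¹². It is validated against the
classical telegraph-model Fano factor
F = 1 + α·koff/((kon+koff)(kon+koff+β)).

Closed forms for the indirect switches are implemented in normalized
variables (counts over AT, rates over (kf/Ω)·AT). The sole-sequestration
and sequestration+blocking expressions follow the published forms. For
the full SBD switch the published rendering of the Fano factor is
typographically ambiguous; the implementation therefore carries the exact
expression re-derived from the three-state chain's moment equations
(stationary vector by the Markov-tree theorem, then the two linear moment
systems, symbolically reduced): F = 1 + α̃·N/(P₁P₂) with

    P₁ = ÃK̃b + ÃK̃d + ÃR̃ + K̃aK̃b + K̃aK̃d + K̃aR̃A + K̃bR̃A + K̃dR̃ + R̃R̃A
    P₂ = P₁ + β̃(Ã + K̃a + K̃b + K̃d + R̃ + R̃A + β̃)

and N the analogous cubic polynomial (see `analytic._ff`). The published
SBD *activity* expression, with its displacement correction factors
I = (K̃s+σK̃a+R̃)/(K̃s+σK̃a+σR̃) and J = (K̃s+K̃a+R̃)/(K̃s+σK̃a+σR̃), verified
exact against the chain and is implemented as printed. Equivalence of
closed forms and moment solver is enforced at 10⁻⁸ relative over random
parameter draws; the titration roots themselves are computed through
cancellation-free branches so conservation and mass action hold to
machine precision over a 10⁶-point sweep.

## Stochastic simulation

The Gillespie direct method (numba kernels) simulates any reaction
system; propensities are mass action over at most two unit-order
reactants, plus dedicated kinds for the oscillator's QSSA-closed promoter
propensities (kf/Ω times the free-activator, free-repressor or complex
branch of the titration root at the current nuclear repressor count).
Trajectories are bit-reproducible given a seed; per-run seeds derive from
a master seed via `numpy.random.SeedSequence`. Declared conservation laws
can be audited at every event.

Headline statistics use the snapshot-across-runs protocol (default 1000
runs): activity is the fraction of runs with the producing state occupied
at the snapshot, and mean/variance/Fano are computed across runs, with a
bootstrap standard error for the Fano factor. Burn-in: the default
snapshot time is 10 mRNA half-lives plus 10 times the slowest promoter
timescale; for the deliberately slow-switching regimes (where that
timescale reaches 10⁵ min) the initial promoter state of each run is
instead drawn from the chain's exact stationary law, after which only the
fast mRNA coordinate must relax. Stationarity is verified by the doubling
test (snapshot time × 2 moves statistics by less than their standard
errors; asserted in the test suite). For the multi-target model, runs
start from the titration equilibrium (partition rounded to integers, gene
states drawn from the reduced chain's stationary law) to clear the slow
sequestration mode; snapshots are taken at 5000 min with the 120-min mRNA
half-life, and the doubling check was repeated there.

The QSSA validation compares the DT = 0 full-kinetics model against the
reduced promoter chain at molar ratios 0.2, 1 and 5: mean-trajectory
distance and total-variation distance between snapshot histograms (bin
width 4). The declared tolerance is TV < 0.15; two independent
1000-sample histograms of the same law already carry ~0.06–0.10 of
sampling TV, and the measured values are 0.07 / 0.10 / 0.01. Scaling the
protein binding/unbinding rates up by 10³ shrinks the distances, as the
QSSA limit requires.

## Oscillator analysis

Each oscillator run is resampled on a uniform grid (default dt = 10 min)
after a 6000-min burn-in; the autocorrelation of M(t) (unbiased per-lag
normalization, C(0) = 1) is fitted with e^(−t/τ)·cos(2πt/T) by
least squares, with initial periods from the first zero crossing and
multi-starts at half and double that guess; the final fit windows lags to
three estimated periods, which stabilizes τ without over-weighting the
decayed tail. Non-converged fits are flagged and reported, and the
period variance is taken over converged fits with the convergence
fraction attached (ensembles under 50% convergence are rejected).
Rhythm-precision comparisons use Var(T) across mechanisms with one-sided
bootstrap tests.

The oscillator preset uses AT = 10³ activators. The published table
prints AT = 10⁵ for this model, but with the printed production rates
(α = 100β, β = ln2/120 min⁻¹, α₂ = α₃ = 5/12 min⁻¹) the stationary
nuclear repressor count saturates near 7×10³ and can never cross a 10⁵
titration threshold: simulated at AT = 10⁴–10⁵ the loop sits at a quiet
fixed point with activity ≈ 0.95, which contradicts the published
oscillatory traces. At AT = 10³ the loop oscillates with noisy periods of
~600 min (SBD), ~900 min (SB) and ~3500 min (S) and reproduces the
published precision ordering Var(T): SBD < SB < S by orders of magnitude.
AT remains a free parameter for users who wish to explore the boundary.

## Sweeps and metrics

Heatmaps vary kf/Ω and the mRNA half-life on log grids while holding
every dissociation constant and α/β fixed (α is rebuilt per cell). The
cooperative metric is the Fano factor at the preset operating point (or
with RT tuned to activity exactly ½); the indirect metric is the maximum
Fano factor over the near-threshold window RT/AT ∈ [0.5, 1.5] (801-point
grid plus a refinement pass, stable to 0.1% under grid doubling). The
window is a reporting convention — the sources speak of the maximum
"near" the threshold without defining a range — so it is an explicit,
logged parameter. The biologically realistic box is kf/Ω ∈ [6×10⁻⁶,
6×10⁻⁵] ymol⁻¹min⁻¹ and half-life ∈ [30, 984.5] min; box extrema are
reported from the grid restricted to the box (empirically the minimum
sits at the fast-binding, long-half-life corner).

The effective Hill exponent of a decreasing activity curve uses the
classical 10%/90% definition n_H = ln 81 / ln(EC10/EC90) with crossings
interpolated in log input; it inverts true Hill functions exactly and is
undefined (flagged, never interpolated) when a curve does not span both
response levels. The noise summary over a whole titration curve is the
area under the Fano curve against log₁₀(RT/AT) over [0.1, 10]
(trapezoid, cross-checked against adaptive quadrature to 0.1%).

## Extrinsic-noise mixtures

When a regulator total fluctuates, total moments follow the laws of total
mean and variance with conditional moments from the intrinsic theory:
E[M|·] = (α/β)·TA, Var[M|·] = E[M|·]·FF. Mixing is over integer counts,
truncated where the tail mass falls below 10⁻¹². Two regulator laws are
provided: Poisson repressor counts, and the activator birth–death chain
with complex-mediated degradation (production α_A; death
β_A·A(n)/Ω + β_RA·RA(n)/Ω with the exact titration roots, the
piecewise-linear approximation being available for cross-checks only),
whose stationary law follows from the birth–death recursion with the
death rate evaluated at n+1 — the discretization under which equal
degradation rates yield an exactly Poisson law. Because these analyses
compare mechanisms at *matched* conditional activity, the default mixture
uses one shared activity curve (the sole-sequestration one) for the
conditional mean and each mechanism's own Fano factor for the conditional
variance; total means then agree across mechanisms exactly, and all
differences sit in the intrinsic-variance term. `matched_ta=False`
switches to each mechanism's own activity curve.

## What the simulations do and do not show

The generators and presets emulate the idealized study conditions: a
single gene copy, one effective repressor and activator species,
instantaneous protein equilibration (except where full kinetics is the
point), no cell division, growth, volume fluctuation or extrinsic
rate variation beyond the regulator-count mixtures above. Passing tests
therefore certify the mathematical behavior of these models — not that a
particular biological circuit realizes them. Parameter values sit in
physiological ranges (binding rates 10⁶–10⁷ M⁻¹s⁻¹, mammalian cell
volume, mRNA half-lives 0.5–16 h, transcription-factor abundances
10³–10⁵ copies), which is what makes the box extrema biologically
meaningful.

## Numerical choices and limitations

- Titration roots: branch-stable quadratic plus product identities;
  degenerate inputs (AT = 0 or RT = 0) short-circuit to boundary values.
- Moment solver: dense solves only; reducible chains raise; condition
  numbers above 10¹² warn.
- SSA: direct method only (exactness is part of the test surface); no
  tau-leaping, delays, or hybrid schemes. Event budgets guard against
  runaway propensities. In the verbatim-table oscillator variant the
  import propensity does not depend on its substrate, so counts are
  clamped at zero — a pathology of the literal reading, not of the
  default model.
- Histograms are exact integer tallies; the unimodal/bimodal classifier
  smooths with a Gaussian kernel (σ = 4 counts) and keeps local maxima
  with topographic prominence at least half their height and basin mass
  at least 10⁻³ — adequate for the qualitative distinction, not density
  estimation.
- Multi-target runs treat the additional genes as a pooled count (they
  are exchangeable), which keeps the state space small; per-gene
  identities are not tracked.
- The Hill metric assumes a monotone decreasing response; non-monotone
  curves are rejected rather than forced.
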