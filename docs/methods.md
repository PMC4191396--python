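# Methods

This note documents the models, conventions and numerical choices behind
`cgtwist`, and what the synthetic study conditions do and do not establish
about real trajectories.

## The synthetic coupled-dynamics generator

Microsecond explicit-solvent MD cannot be regenerated at desk scale, so
every analysis stage is exercised on a discrete-time stochastic emulator
(`cgtwist.synthgen`).  The generator reproduces the *statistical*
structure of CG-step dynamics — state-conditioned twist Gaussians, a
four-state ζ ladder, two-state minor-groove ion occupancy, and a
programmed ion-lead coupling — with no forces, water or real torsion
dynamics.  Time is discrete at the snapshot cadence (dt = 1 ps, matching
1 ps trajectory sampling); a per-ps Markov chain was preferred over an
event-driven (Gillespie) scheme because every downstream statistic is
defined on the snapshot grid.

**Ion occupancy** of the inner minor-groove region is a two-state chain
with per-step exit probability dt/τ_res and entry probability chosen by
detailed balance so the stationary occupied fraction equals the target
occupancy: p_entry = φ·dt/((1−φ)·τ_res).  Occupied runs are geometric
with mean τ_res.  Real residence distributions are heavy-tailed (stays up
to ~1 ns coexist with a ~6–11 ps mean); the geometric model has no such
tail, which matters only for the choreography condition (below).

**The ζ substate chain** lives on the single-flip graph
g⁻g⁻ ↔ {tg⁻, g⁻t} ↔ tt; direct g⁻g⁻ ↔ tt double flips are structurally
impossible, encoding as a hard constraint the observation that such
transitions are vanishingly rare and pass through the one-flip
intermediates.  Transitions are Metropolis moves with a per-edge attempt
rate q, so the stationary law is exactly Boltzmann in the substate ΔG
ladder (kT from R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹ at 298 K, i.e.
0.5922 kcal/mol).  Defaults: q = 0.02 ps⁻¹ per edge at baseline, giving
substate dwell times of tens of ps and roughly 10⁴ ζ transitions per
2×10⁵ ps, the right order of magnitude.

**Ion → backbone coupling.**  While an ion has been continuously present
longer than an activation lag, the chain targets a *tilted* law
π_i ∝ π_i^Boltz · h^{n_t(i)} (n_t = number of strands in t), with h solved
so that the stationary BII/BII probability of the activated mode equals
`p_bii_given_ion`; the attempt rate is simultaneously raised
(q_act = 0.45 ps⁻¹) so the flip completes within a few ps of activation.
Setting `p_bii_given_ion = p_bii_given_no_ion` (and equal attempt rates)
decouples the chain from the ions exactly.  The observed mean ion lead —
the time from ion arrival to the completed ζ flip — is programmed as
follows: the activation lag is deterministic and equals
`ion_lead_time_ps` minus the analytic mean first-passage time
g⁻g⁻ → tt of the activated chain (≈ 4 ps at the defaults), so realized
leads average the programmed value with a few-ps spread.  An exponential
lag model is available as an option, but a dispersed lag makes the mean
lead unrecoverable by any threshold-crossing onset estimator (the
estimator reads the tail of the lead distribution, not its mean), so the
concentrated model is the default.  The real mechanism behind the
observed ~45 ps lead is unknown; this is one admissible generative choice
and is labelled as such.

**Emissions.**  Twist is Gaussian conditioned on the current substate
(means from the per-substate twist table; SDs from the published mixture
components: HT SD for g⁻g⁻, LT SD for tt, their mean for intermediates).
ζ angles are truncated normals inside each class interval, so
re-classifying emitted angles reproduces the hidden states exactly.
Minor-groove width, slide and the C8H8···O3′ contact flag are
deterministic substate levels plus noise (widened groove, high slide and
frequent contact in tt).  Note one deliberate simplification: because the
marginal twist is really a four-component mixture weighted by substate
occupancies, a two-component EM fit of generator output recovers
*effective* components (e.g. 18.6°/31.4° at weight 0.59 for the TCGA-K
condition), not the published two-component parameters; recovery checks of
the mixture machinery therefore draw directly from the published
two-Gaussian mixtures.

**Choreography study condition** (`CHOREO` preset): ACGA-like ΔG ladder
(low baseline BII/BII ≈ 0.07), strong coupling (p_BII|ion = 0.8),
occupancy 0.30 and τ_res = 25 ps.  The mean residence is set above the
published per-sequence means because activation requires continuous
presence through a ~41 ps lag: with a geometric 6–11 ps run model such
events would be vanishingly rare, whereas in real trajectories they are
supplied by the heavy residence tail.  The 25 ps value was fixed once
from the analytic event-rate estimate (entries/ps × P(run > lag)) to
yield thousands of ion-driven events per 2×10⁶ ps.

## Curvilinear mapping and densities

Ion positions are expressed relative to per-level axis frames (origin,
unit tangent, unit reference): D = level + fractional position along the
bracketing segment (the fraction solved so the residual is perpendicular
to the interpolated tangent; Newton iterations with segment hand-off at
level boundaries), R = perpendicular distance, A = right-handed angle
from the re-orthonormalized interpolated reference, in [0, 360), with
A = 0 at R = 0 by convention.  Frames are inputs; producers must orient
references so the minor-groove centre maps to A = 90°.  Between-level
interpolation is linear with re-orthonormalization (the choice is not
dictated by anything upstream; it makes the forward/inverse pair exactly
consistent, which the round-trip tests exploit at 10⁻⁶).

Region partition around step N: D ∈ [N−0.2, N+1.2), inner R < 10.25 Å,
outer 10.25 ≤ R < 15 Å, minor A ∈ [33°, 147°), major = complement through
0°.  All intervals are lower-closed/upper-open so the five labels
partition space; in particular R = 10.25 Å is "outer".  Densities use the
curvilinear bin volume V = Δs · (R₂²−R₁²)/2 · ΔA_rad with Δs the arc
length of the bin's D interval (a fixed rise of 3.38 Å/level when no axis
is supplied), and molarity = mean count / (V × 6.022×10⁻⁴).

## Substate classification and mixtures

ζ is reduced mod 360° and classed g⁻ iff ζ ∈ [150°, 315°).  The state
centres (g⁻ ≈ 270°, t ≈ 360°) are published; the boundaries are not, so
the class interval uses the midpoint 315° and a symmetric lower bound,
and both edges are configurable.  BII is identified with ζ = t alone; the
ε torsion is not consulted.  Joint labels put the Watson strand first.

Twist mixtures: EM (scikit-learn `GaussianMixture`, full covariance,
reg_covar 10⁻⁸, tol 10⁻⁸, multi-start with a fixed seed policy) for k = 1
and 2; BIC_k = k_params ln n − 2 ln L decides, with the analysis limited
to two components.  Components are reported LT-first (ascending mean,
ties by descending weight).  Snapshots are treated as independent in the
BIC despite trajectory autocorrelation — the same simplification the
population analysis makes — so BIC values on correlated input are
optimistic in n; an optional thinning stride is exposed.  An independent
grid-search ML oracle bounds the EM solution in the tests (log-likelihood
tolerance 10⁻³ at n ≤ 200).

## Ion dynamics

Occupancy is the fraction of snapshots with ≥ 1 ion in the region;
residence is the mean length of maximal per-ion runs of consecutive
snapshots with **no gap tolerance** (a single-snapshot exit ends a run) —
no smoothing is applied anywhere upstream, and the choice is configurable
in effect by pre-filtering records.  Runs truncated by the series ends
are included (bias < 1 % when the series is ≫ residence).  Because
"transition count" is ambiguous between entries, exits and their sum, all
three are reported.  Multi-ion fractions are normalized over occupied
snapshots; zero occupied snapshots yields (0, 0, 0) with an `undefined`
flag rather than an error.

## Thermodynamics and WHAM

ΔG_s = −kT ln(p_s/p_gg) exactly, +∞ for unvisited substates, error if the
reference is unvisited.  Statistical errors use a moving-block bootstrap
(default block 1 ns at 1 ps sampling) because snapshots are
autocorrelated.  The transition matrix counts ordered consecutive-label
pairs and summarizes the direct g⁻g⁻↔tt fraction among label changes.

WHAM: per-window histograms on a uniform grid (default 1°), standard
self-consistent iteration of the window shifts, convergence when the
largest shift change < 10⁻⁶ kcal/mol, error with the residual otherwise;
windows whose histograms do not chain into a connected range are
rejected.  The profile is anchored at min = 0 (defined up to a constant);
permuting windows or adding a constant to all biases leaves it unchanged.
The umbrella sampler draws from exp(−(F + k(ζ−c)²)/kT) by inverse-CDF on
a 0.05° grid with within-bin jitter, i.e. exact up to discretization,
with the published force constant k = 0.02 kcal mol⁻¹ deg⁻² and 10°
window spacing as defaults.

## Choreography

Transition events are completions: time 0 is the first snapshot in the
target label, reached from the source through at most one intermediate
run (dwell ≤ 100 ps by default); the intermediate dwell is part of the
pre-window.  Direct double flips are recorded but flagged.  Events closer
together than the 250 ps window are all kept — overlapping windows
correlate events and shrink the effective sample size, so the per-τ SEs
are mildly optimistic.  The onset estimator takes the baseline mean and
SD of the profile over τ ∈ [−250, −150] ps and reports the earliest τ
from which the channel stays above baseline + 3 SD until 0.  This
estimator has an absolute resolution floor of ~4–5 ps (the duration of
the two-flip path after activation): programmed leads of 45 and 100 ps
are recovered within a few percent, while a 10 ps lead reads ~5 ps high.

The ion-influence ratio follows the published procedure literally:
maximal runs of constant regional presence lasting ≥ 40 ps; within the
last 20 ps of each run the per-ps frequency of tt is pooled separately
for with-ion and without-ion runs; the ratio of the two probabilities is
the influence.  The "per ps" pooling is the default reading; a per-state
(run-averaged) variant is exposed as an option.  Applied to the coupled
generator itself the statistic is *diluted* relative to the programmed
conditionals (e.g. 0.52 vs 0.80 with ion), because the with-ion tails of
40 ps runs include pre-activation snapshots — the recovery checks of the
procedure therefore use series with directly programmed per-ps
conditionals.

## Oligonucleotide counting

Overlapping windows (step 1) of width k ∈ {2, 3, 4}; windows containing N
are skipped and excluded from the normalization denominator; only k-mers
whose forward string contains "CG" are tabulated.  Each k-mer is pooled
with its reverse complement under the lexicographically smaller key;
self-complementary k-mers (TCGA, ACGT, CG, …) are pooled with themselves
exactly once.  Frequencies are pooled counts per counted window.
Annotation-region normalization (introns/exons/promoters) would require
external annotation inputs and is out of scope.

## Problem sizes and limitations

The default study conditions use 2×10⁵-snapshot series (a 200 ns analysis
window at 1 ps) for the population statistics and 2×10⁶ snapshots for the
event-aligned kinetics, which give ≥ 5×10³ aligned transitions under the
CHOREO condition.  Tests run the same machinery at these or smaller sizes
with seeded generators throughout.

Passing tests establish that each stage recovers the parameters of the
emulator that generated its input at the published operating points.
They do not establish force-field realism, the physical mechanism of the
ion lead, convergence properties of real trajectories, or behavior under
features the generator lacks (heavy-tailed residences, correlated
multi-ion occupancy, sequence context beyond the preset parameters).
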