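# Methods

`myosim` models the first five days of skeletal-muscle differentiation in
a culture dish as an off-lattice, nuclei-centred agent-based model (ABM),
measures the same quantities from its output that an imaging pipeline
measures from micrographs, calibrates the unobservable parameters by
ABC–SMC, and fits response surfaces over the culture-medium composition.
This note records the model, its assumptions, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## The agent-based model

**Agents and domain.** Every agent is a cell nucleus: a *myoblast*
(mononucleated precursor) or a *myonucleus* (resident in a multinucleated
myotube). The domain is a continuous 2-D rectangle (default
1000 × 1000 μm) with periodic boundaries, which avoids edge-density
artefacts that a reflecting wall would introduce. Time advances in fixed
steps of `dt` = 5 min — the live-imaging frame interval the behaviour
metrics are defined at — in a fixed order per step: motion →
proliferation → residence clocks → fusion → mechanics. All randomness
flows from one seeded generator, so a `(parameters, seed)` pair
reproduces every output bit for bit, including the fusion-event log.

**Myoblast motion** is a persistent random walk. Each cell draws a speed
once at birth from Normal(`s_mb_mean`, `s_mb_sd`) truncated at zero (the
metric S_mb is a per-cell summary, so per-cell sampling rather than
per-step is the faithful reading), and each step turns by
Normal(0, `omega_mb_sd`·dt) degrees. Myoblasts divide independently with
probability `p_rate`·dt per step (configurations with `p_rate`·dt ≥ 1
are rejected); daughters are placed one AoI radius away in a uniform
direction with fresh speed and heading, which prevents an immediate
self-contact artefact. There is no cell death, quiescence or
differentiation-competence heterogeneity — deliberate model assumptions,
shared with the biology the model encodes, and the reason the total
nucleus count can only grow.

**Fusion** follows a residence-time rule. Contact means two nuclei lie
within one area-of-influence radius (`aoi_radius`, default 15 μm ≈ one
nucleus diameter) under the periodic metric; a myoblast contacts a
myotube when it contacts any member myonucleus, and two tubes are in
contact when any cross-pair of members is. Every eligible pair in
contact accumulates `dt` on a clock; losing contact resets the clock to
zero (no memory — the simplest reading of a residence-time counter).
When a clock crosses `t_rmax`, exactly one fusion is queued:
myoblast–myotube fusion absorbs the myoblast as a new myonucleus;
myoblast–myoblast fusion (enabled by default, so fusion can start in a
dish seeded without tubes) founds a two-nucleus tube; myotube–myotube
fusion merges the member sets, but only if the *initiating* — younger —
tube's age is at most `t_mtfuse` (days); the merged tube keeps the
earlier formation time. The AoI radius is held fixed and `t_rmax` is the
inferred quantity; the combined parameter γ = π·AoI²/t_rmax is always
derived, never stored. Fusion never changes the nucleus count, so at
every instant *myoblasts + myonuclei = initial count + cumulative
divisions* — the conservation law the test suite asserts at every
recorded time.

**Myonuclei mechanics.** Each step, every tube's axis is recomputed as
the first principal direction of its member positions
(minimum-image-unwrapped; the sign convention — non-negative x component,
then non-negative y — only makes runs reproducible). Each myonucleus
feels a lateral spring toward the axis, f_lat = −k_lat·d_perp, and a
lengthwise inverse-square repulsion from every other member,
|f_nuc| = k_nuc / max(d, d_min)² projected onto the axis, with
d_min = 1 μm as a singularity guard. Only "distance-dependent" forms are
specified by the biology; linear and inverse-square are the simplest
monotone choices and are declared as such. Positions update by
overdamped explicit Euler with unit mobility (the coefficients absorb
the mobility scale). A step that would move a nucleus more than one AoI
radius is clamped and counted — at k_lat·dt > 2 the explicit scheme
would otherwise oscillate; the clamp keeps the dynamics bounded and the
count flags the run. With both coefficients positive and fusion off, a
perturbed 12-nucleus tube relaxes toward even spacing: the spacing
coefficient of variation falls within 24 simulated hours in ≥ 9/10
seeded replicates.

## Metrics

Behaviour metrics are computed exactly as an imaging pipeline would
compute them from a tracking export: S_mb is the mean over steps of
displacement per frame interval (μm·min⁻¹); ω_mb is the sample standard
deviation (n−1) of the signed heading change per minute, with heading
changes from adjacent displacement vectors wrapped to (−180°, 180°] and
zero-length steps contributing no angular sample; persistence is net
displacement over path length; P is divisions per observed cell·minute.
Tracks shorter than two frames are excluded and counted.

Quality indicators: dM is the myonuclei areal density change between
day 0 and day 5 (mm⁻²; the whole imaged/simulated area, not a
tube-masked area). Within each tube, nuclei are projected onto the tube
axis, ordered, and consecutive-neighbour Euclidean distances taken —
the consecutive rather than all-pairs convention matches how distances
are drawn on micrographs. Distances are pooled across tubes before
computing D (mean) and D_var (sample SD over mean); per-tube summaries
are also emitted. Pooling is a choice (the per-tube alternative is not
distinguishable from published material); the sample (n−1) SD is
conservative at small per-tube counts. The fusion index is myonuclei
over total nuclei. On simulation output dM is read from the recorded
density series and cross-checks exactly against the event log
(dM·area = mb–mt events + 2·mb–mb events).

## ABC–SMC calibration

`t_rmax`, `t_mtfuse`, `k_lat`, `k_nuc` are inferred against observed
(dM, D, D_var) under independent uniform priors — t_rmax 1–100 (the
range is printed unitless in the source material; this package reads it
as minutes, which is the plausible scale for contact durations at a
5-min step, and keeps it configurable), t_MTfuse 0.5–4.5 days, both
force coefficients 0–1. The distance is a weighted sum of relative
errors, d = Σ w_i·|s_i − o_i| / max(|o_i|, 10⁻⁶), with an undefined
simulated component (e.g. D when no tube formed) contributing its
weight × 10. Weights default to equal. The SMC scheme: population 0
samples the prior (ε = ∞); each later ε is the weighted median of the
previous accepted distances (hence non-increasing by construction);
proposals perturb a weight-drawn ancestor by an independent Gaussian
kernel with per-parameter scale 1.5 × the weighted particle SD,
rejected to the prior box; per-particle distance averages
`replicates_per_particle` forward runs; importance weights are uniform
prior over kernel mixture. Every forward-run seed derives
deterministically from (config seed, population, attempt, replicate),
so a parallel executor cannot change results. If a population's
acceptance rate falls below a floor (default 2%), the run returns the
completed populations with a warning flag rather than spinning.

Defaults (100 particles, 6 populations, 3 replicates) are sized to the
same order of forward-model budget as the calibration workflow this
package re-implements; the validation suite uses a reduced
configuration (64 particles, 4 populations, 2 replicates).

**What the recovery experiment shows.** The parameter-recovery test
generates a pseudo-observation at known parameters (t_rmax = 60 min,
t_mtfuse = 1.5 d, k_lat = 0.15, k_nuc = 0.6) in a small-domain setting —
100 nuclei on 500 × 500 μm, five days, 25% of day-0 nuclei seeded in
tubes so tube ages probe the whole t_MTfuse prior — and averages the
observed indicators over three replicate "wells", as a lab would.
Identifiability is structural here: three summaries constrain four
parameters, so one direction is informed only weakly. dM pins t_rmax
sharply; D carries k_nuc with t_mtfuse and k_lat as partial confounders;
D_var separates them only coarsely because it is by far the noisiest
indicator (replicate CV ≈ 15% at this size). Pilot sensitivity runs at
these conditions put the per-parameter signal at 2–10 replicate SDs for
t_rmax and k_nuc and ~2 SDs for t_mtfuse, which is what the acceptance
bands (25% relative; one day; k_lat unchecked) reflect.

## Synthetic data

The generator module emulates the two imaging products. Trajectory
tables are persistent random walks with per-track truncated-normal
speeds and per-step Gaussian turning — by construction the same sampling
process the engine uses, so metrics recovered from them validate the
measurement code, not the biology. Nuclei tables place day-5 myotubes
on random axes with consecutive spacings drawn from a gamma distribution
moment-matched to a target mean and CV (gamma for non-negative support
with a free CV; any two-parameter non-negative family would serve), so
D and D_var have exact targets. What passing these tests does **not**
show: anything about segmentation/tracking error, uneven illumination,
cell-shape effects, out-of-plane motion, or myoblast death — real
imaging data carry all of these and the generators none.

Two validation experiments are run under controlled conditions chosen by
design, and their conditions matter:

* *Motion recovery* runs at per-cell speed CV 0.2 (not the default 0.4)
  so that the 2% recovery check is ~3 standard errors wide at n = 1000
  tracks; at CV 0.4 the estimator's own sampling error (1.3%) plus the
  truncation bias (0.7%) would make the check a coin flip about the
  estimator's noise, not a statement about correctness.
* *Fusion-event monotonicity in t_rmax* is a ceteris-paribus claim about
  the fusion mechanism, and the model contains two confounders that
  reverse it in uncontrolled runs: with proliferation on, slow-fusing
  conditions accumulate more dividing myoblasts and end up with *more*
  events; at saturating density the event total reflects the
  mb–mb/mb–mt mix rather than the amount of fusion. The experiment
  therefore runs with p_rate = 0 at contact-limited density (50 nuclei
  on 0.49 mm²). The companion check — mean D non-decreasing in k_nuc —
  needs no such control and uses the reference conditions.
* The *fusion-index sweep* varies the fusion speed alone (12 t_rmax
  values, geometric from 10 to 240 min) at fixed proliferation. The
  inverse relation between day-1 fusion index and day-5 dM is a supply
  effect: eager early fusion exhausts the myoblast pool, slow fusion
  lets it keep growing. Sweeping proliferation at the same time moves
  dM directly at nearly constant early fusion index and dilutes the
  relation — the single-axis sweep isolates the mechanism being
  demonstrated.

## Response-surface optimization

Effect sizes of behaviours on quality indicators come from ordinary
least squares on z-scored (sample SD) responses and predictors, with
t-based inference on residual degrees of freedom and no multiple-testing
correction (raw p values are reported, matching the field's practice for
small trial counts); constant predictors are dropped with a warning and
rank deficiency is an error naming the collinear set. Surfaces over the
media space are six-term quadratics, z = c₀ + c_α·α + c_β·β + c_αα·α² +
c_ββ·β² + c_αβ·α·β, fit by least squares (exact on data from the model
class; ≥ 6 points in a design of full rank required). The interior
stationary point solves the 2 × 2 linear system and is classified by the
Hessian; each domain edge is a closed-form 1-D quadratic; all candidates
are clipped to the domain (with a 10⁻⁹ relative tolerance so a
stationary point on the boundary is not lost to round-off) and ranked.
The next-composition suggestion lets each surface vote for the grid
points within 10% of its own optimum (10% of that surface's value range
over the domain — scale-free across indicators with different units);
the most-voted point wins, ties broken toward the centroid of the tied
set, and the per-surface votes are reported for audit.

## Problem sizes and tolerances

The validation suite runs entirely on synthetic inputs at deliberately
modest sizes — domains of 0.25–1 mm², 40–300 nuclei, one to five
simulated days, 10–200 replicates per statistical check, and the reduced
ABC configuration above — chosen so the full suite documents the model's
behaviour at desk scale. Numerical comparisons against brute-force
oracles use 10⁻¹² (force sums) and 10⁻⁹ (axes, quantiles, OLS);
statistical checks state their tolerance in estimator standard errors.

## Known limitations

* Tube geometry is nuclei-only: no membrane outline, width, or actin
  striation; tube–tube contact via member nuclei is a proxy.
* The lateral spring with explicit Euler is only conditionally stable;
  k_lat·dt > 2 runs survive via the displacement clamp but should be
  re-run with a smaller dt.
* Lengthwise repulsion is unopposed along the axis, so tubes lengthen
  indefinitely (slowly, as d³ ~ k_nuc·t); runs much longer than the
  five-day horizon on small domains can violate the half-domain
  assumption behind periodic unwrapping.
* With three observed summaries and four free parameters, the ABC
  posterior is structurally degenerate along one direction; k_lat in
  particular is weakly identified, and point estimates on the degenerate
  ridge shrink toward the prior.
* Whether seeded day-0 myonuclei form one tube or several, and whether
  the t_MTfuse gate acts per tube or per nucleus, are modelling choices
  (chains of five; per-tube age of the younger, initiating tube); the
  alternatives are noted in code and would change mt–mt dynamics only.
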