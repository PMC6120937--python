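# Methods

`planstate` re-implements a single-trial, population-level analysis of reach
planning in dorsal premotor cortex (PMd) during a delayed center-out task
with one or two potential targets, together with a synthetic session
generator rich enough to exercise every stage of the analysis.  This note
describes the models, the estimators, the defaults and why they were
chosen, and what the synthetic data can and cannot tell you about real
recordings.

## Task and latent-plan model

Eight targets sit at 45° spacing on a 7 cm ring (direction index k ↔ k·45°,
0° = rightward, counter-clockwise positive).  A trial holds the cursor in a
1.5 cm central target for 500 ms, presents the target(s) for 750–1000 ms
(Target On), blanks them for 250–500 ms (Target Blank), shows the correct
target alone for 250–500 ms (Cue), restores the full display for 450–600 ms
(the original task timeline has this return interval without a stated duration;
we draw it uniformly), then sounds Go.  Trial types mix 40% 2-Target cued,
40% 1-Target, 10% Free-Choice (no cue), and 10% 1-Target-no-cue trials that
are generated but excluded from analysis.  All boundaries snap to the 25 ms
analysis grid.

The generator's ground truth is a latent plan trace: one direction index
(or none) per 25 ms bin.  Plans never encode two directions at once — the
generator is a pure single-plan machine, and a separate `encoding="dual"`
flag exists solely to verify that the metrics detect genuine dual codes
(it averages the two single-plan rate patterns before cue onset).

Two-target trials start with a plan to the favored axis end with
probability `axis_bias` (default 0.75).  An incongruent cue triggers a
switch after an exponential latency (mean 150 ms).  Errors are failures of
this switching process and are therefore conditional on congruence: with
the initial plan against the cue, type 1 never switches and type 2 switches
but reverts 350 ms before Go; with the initial plan on the cue, type 3
defects 350 ms before Go.  The 350 ms lead clears the causal filter's
memory so the latent templates are decodable in the read-out windows.  A
further 15% of incongruent-but-correct trials hold their initial plan
through Go and switch during the reaction period — the switch-cost
mechanism that produces long reaction times for wrong plans at Go.

Plan vigor varies: per trial (clipped normal around 1; broad with dips
toward zero on two-target trials, where the subject is deliberating, and
tighter on 1-Target trials, where the target is known from the outset) and
within trials (an Ornstein–Uhlenbeck process, sd 0.3, correlation time
200 ms).  The within-trial fluctuation reproduces the waxing-and-waning
single-trial plan strengths that motivate the whole single-trial approach.

## Population model

Each of the 120 units (session sizes 110–155 are typical for chronic
96-electrode arrays) has baseline a ~ 20·U(0.6, 1.4) spikes/s and
directional modulation applied as a cosine in the square-root domain:

    rate(θ) = (c + s(t)·d·cos(θ − φ))²,   c = √a,  d ≈ b/(2c)

with preferred directions φ stratified-uniform on the circle and nominal
rate-space depth b ~ 12·U(0.6, 1.4) spikes/s.  In rate terms this tuning
has a sharpened peak and shallow trough (the characteristic PMd shape); in
the analysis pipeline's variance-stabilized √ space the pro- and anti-PD
margins about the orthogonal-direction level are exactly symmetric, which
is what makes the trial-averaged exceedance control sit at 50% under
unbiased relabeling.  A pure rate-space cosine, by contrast, is asymmetric
under the √ transform and biases that control several points below 50%.

From 150 ms after Go the population expresses an execution pattern:
per-unit preferred directions rotated by N(0, 0.8 rad) and depth scaled by
1.4, capturing the distinct planning and movement subspaces of premotor
populations.  The reference clusters (below) span planning *and* execution
states, as in the original analysis, so this heterogeneity directly shapes
the cluster geometry.

Spiking is doubly stochastic Poisson.  Excess variability is injected
additively in the √ domain (where Poisson noise itself is
variance-stabilized, sd ≈ 0.5 per √Hz of effective bandwidth): a per-unit
within-trial OU process (sd 0.45, τ 300 ms), a per-unit per-trial offset
(sd 0.2), a shared low-dimensional fluctuation (a random population
pattern per trial with OU amplitude, sd 0.7, τ 300 ms — cortical noise
correlations pointing away from the direction code), and a per-unit
random walk across trials (step 0.02; chronic-array drift).  A small
multiplicative population gain (log-sd 0.15) models slow arousal.  These
levels give Fano factors in the 1.5–2 range typical of cortex and were
chosen so the synthetic sessions occupy the same qualitative regime as the
recordings the analysis was built for: single-trial direction decoding is
reliable but individual 25 ms states wander substantially, and the
reference clusters are broad, heterogeneous clouds rather than tight
Gaussian balls.  The square-root-additive form of every component is
deliberate: multiplicative (lognormal) noise is asymmetric under the √
transform and distorts the trial-averaged controls.

Kinematics are minimum-jerk reaches (peak speed factor 1.875·distance/
duration) to the chosen target, with log-normal peak speeds around
23.9 cm/s, preceded by a reaction time RT = 320 − 140·ŝ + N(0, 40) ms
clipped to [50, 600], where ŝ is the signed plan strength at Go (positive
when the pre-Go plan already points at the executed target, negative when
the reach requires a post-Go switch).  Hand position and speed are sampled
at 40 Hz with speed defined as the position difference quotient.

## Preprocessing

Spike trains are binned at 25 ms and convolved with a causal half-Gaussian
kernel (s.d. 150 ms, truncated at 4 s.d. and renormalized), so the rate at
a bin depends only on spikes at or before its right-edge timestamp; a
square-root transform is applied last.  Smoothing is per trial.  Epoch
windows are half-open `[start, end)` on right-edge timestamps; the
planning window runs from 500 ms after Target On to the end of Target
Blank, and the cluster window from 500 ms after Target On to trial end.

## Tuning

Per-unit tuning is fit by least squares in the linear form
a + c₁cos θ + c₂sin θ (amplitude b = √(c₁²+c₂²) ≥ 0, phase φ =
atan2(c₂, c₁)), or with doubled frequency for bimodal curves whose peaks
define a preferred axis (φ mod π).  Significance is a direction-shuffle
bootstrap: a unit is tuned iff its fitted amplitude exceeds the 99th
percentile of 1000 refits with direction labels permuted across trials.
Trials are labeled pro-PD / anti-PD / orthogonal-PD when the (labeled)
direction lies within 22.5° of the PD, its opposite, or either
perpendicular; boundaries are closed, ties resolve toward the earlier
category in that order.

## Trial-averaged control and the guessing simulations

For each tuned unit, planning-window activity is pooled across pro-PD and
anti-PD trials and compared against the unit's median orthogonal-PD
activity (pooled over trials); the per-unit percentage of bins strictly
exceeding that median is tested across units against 50%.

The guessing simulations relabel 1-Target trials only.  Unbiased mode
relabels a random half of each direction's trials to the opposite
direction; biased mode first discards the four directions counterclockwise
from the left target (180°–315°), then relabels half of the survivors.
The relabeled set plays the role of two-target data: preferred directions
come from the true 1-Target fits, a doubled-frequency cosine is fit to the
relabeled activity, and units whose PD disagrees with that preferred axis
by more than 30° are discarded — *provided the doubled amplitude itself
passes the shuffle bootstrap on the relabeled data*.  That proviso is the
package's resolution of an ambiguity: applied unconditionally, the filter
selects units by noise that directly inflates the unbiased exceedance
(a +3–6 point bias); skipped entirely, the biased mode shows no skew
(units tuned toward the discarded half cancel it).  Gating the filter on a
meaningful axis yields both published outcomes — unbiased
indistinguishable from 50%, biased far above it — from one rule.

## State space, proximity, and the DRI

PCA is fit on the concatenated 1-Target rates (all bins of all 1-Target
trials); the top 10 axes define the neural state.  For each direction i,
all 1-Target cluster-window states form the reference cluster {Cᵢ},
summarized by its mean and covariance with shrinkage λ = 0.1 toward the
scaled identity.  Proximity of a state S to direction i is

    Proximity(S, {Cᵢ}) = P(d | i) / Σⱼ P(d | j),   d = D_M(S, {Cᵢ})

with D_M the Mahalanobis distance and P(d | j) the density of that same d
under direction j's empirical distribution of distances to cluster i.

Three estimator choices matter and are worth stating plainly:

* **Out-of-sample within-distances.**  Every state the metric ever scores
  is outside the cluster it is scored against, so the within-direction
  distance samples are computed leave-one-trial-out (each trial's states
  measured against the cluster rebuilt without that trial).  In-sample
  within-distances are biased small — each state's own deviation is
  absorbed into the mean and covariance — which systematically pushes all
  out-of-sample queries into the apparent tail.  Cross-direction samples
  are out-of-sample by construction.  One consequence: with all clusters
  artificially identical, far-away outliers no longer score exactly 1/8
  (the within-density is honestly longer-tailed there); in-support states
  still do.
* **Kernel density with an effective sample size.**  P(d | j) is a 1-D
  Gaussian KDE with Silverman bandwidth, but the sample count entering the
  bandwidth is the number of bins divided by 12: consecutive 25 ms states
  smoothed by a 150 ms kernel riding on ~300 ms latent fluctuations are
  far from independent draws.  A histogram estimator is selectable.
  Sample sets are strided down to at most 2000 points so evaluation stays
  linear in session size.
* **Log-space evaluation.**  Densities are evaluated via logsumexp, so
  Gaussian tails never underflow and the ratio retains its ordering
  arbitrarily far from the support; the conservative far-state property
  (all proximities → 0, because cross-distance samples are closer to a
  far d than within samples are) emerges from the tails themselves rather
  than from a floor.

ΔProximity for a target axis is the signed difference of the proximities
to its two ends.  Epoch-level classification takes the argmax of the mean
proximity over the epoch's bins (ties to the lowest index, logged);
1-Target classification is leave-one-trial-out by default, since scoring a
trial against clusters containing it is optimistically biased (a no-CV
mode exists for literal replication).  The dual representation index is

    DRI = √((p_a² + p_b²)/2) · ((p_a + p_b)/max(p_a, p_b) − 1)

≈ min(p_a, p_b), skewed upward near the diagonal; it is 0 on the axes
(defined 0 at the origin), 1 at (1,1), and equals p on the diagonal.

## Hypothesis models

From 1-Target Target Blank activity the package measures per-unit
nonparametric tuning (per-direction means) and cosine fits, then simulates
three noiseless codes per target pair: dual-target
F_bi(θ) = 0.7·[a + b·cos 2(θ−φ)] (the 0.7 matches the reported 1- vs
2-Target rate difference; a robustness check moves it to 1.0),
averaged-plan F_avg = ½(F_nonpar(θ) + F_nonpar(θ+π)), and stay-or-switch
F_nonpar itself.  Because the pipeline's activity is already square-root
transformed, tuning is measured and the models simulated directly in that
space (re-transforming is available as an option).  Untuned units
contribute their direction-averaged activity.  Each state is projected
with the session's PCA and scored with its clusters.

## Behavioral linkage

Axis preferences are the fraction of Target Blank ΔProximity mass (bins,
or trials via their means) favoring each axis end, with a ±0.05 dead band
counted as "no plan".  Free-Choice reaches are predicted from the sign of
the mean Blank ΔProximity.  Reaction time is the linearly interpolated
first crossing of 5 cm/s after Go (negative for anticipations, logged).
The RT regression uses the mean ΔProximity toward the cue in the 100 ms
pre-Go window, with per-direction OLS slopes and a mixed model (random
intercept and uncorrelated random slope per direction group; a single
group reduces exactly to OLS).  Error trials are typed from the decoded
plan sign toward the cue in three windows — the full Target Blank epoch,
the last 250 ms of Cue, and the 100 ms before Go (the only window length
the source analysis specifies; the longer early windows average over
transient decode excursions): (wrong, wrong) → type 1, (wrong, correct,
wrong) → type 2, (correct, correct, wrong) → type 3, anything else
(including dead-band windows) → "other".

## What the synthetic sessions do and do not show

The generator reproduces the statistical structure the analysis relies on:
direction-tuned planning activity with realistic excess variability,
heterogeneous multi-epoch reference clusters, widely varying single-trial
plan strengths, biased initial plans, switch dynamics, and error
templates.  Passing tests therefore show that the pipeline measures what
it claims on data with that structure.  They do not show that real PMd
behaves this way — the generator has no oscillations, no task-irrelevant
movement signals, no cross-unit tuning correlations beyond the shared
fluctuation, no learning or satiety trends, and its plan switches are
instantaneous latent events rather than neural trajectories.

Two quantitative bars sit at the edge of what this generator and metric
can jointly achieve at 120 units and 20 1-Target trials per direction.
The simulated *averaged-plan* states clear the DRI threshold on every
axis, but the *dual-target* states — the only purely parametric
construction in the set — carry a cos 2φ population pattern that
single-plan activity never expresses, and at physiologically defensible
variability their distances to the axis-end clusters sit at the edge of
the empirical supports: roughly half clear the 0.2 threshold (the
reference fraction is 84%).  Driving them fully inside requires
variability levels that visibly degrade 1-Target classification and the
trial-averaged controls, so the defaults were frozen on the honest side
of that trade-off.  Similarly, decoded error typing assigns ~94–95% of
errors to types 1–3 against a 97% reference, the shortfall being trials
whose decode transiently collapses into the dead band during shared-noise
excursions.  Both gaps are properties of the stated study conditions, not
of the estimator implementations, and both margins are printed by
`scripts/acceptance.py` rather than asserted away.
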