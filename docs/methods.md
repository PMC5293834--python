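# Methods

This note documents the model implemented by `refnav`: its equations,
parameters, numerical conventions, the design choices that were
genuinely open, and what the simulated experiments do and do not show.

## Population coding

All directional variables (head direction, allocentric/egocentric goal
direction, egocentric cue direction) are encoded by populations of N =
360 units, one per degree of preferred direction.  Unit i responds
with `exp(-Δ²/σ²)` where Δ is the *wrapped* circular difference between
its preferred angle and the input and σ = 10° globally.  The wrapped
difference is a deliberate choice: a raw (unwrapped) difference would
make units near 0°/360° blind to inputs on the other side of the cut.
σ² (not 2σ²) in the denominator follows the model's defining form.

After encoding, each unit receives additive noise and the population is
divided by its maximum, so the strongest unit always fires at exactly
1.  The noise is zero-mean Gaussian with standard deviation 0.05 by
default.  The originally printed noise law (mean e_i, variance 5) is
not zero-mean and would swamp activities bounded by 1; it remains
available as `noise_mode="literal"` for comparison, but the calibrated
zero-mean form is the default.  Negative post-noise activities are
clamped to zero (firing rates are non-negative); if nothing survives,
the input is unencodable and an error is raised.  Decoding is
winner-take-all (argmax, ties to the lowest preferred angle).  Under
the default noise the decoded peak stays within 3° of the encoded
direction in ≥ 99% of draws (property-tested).

## Hippocampus: cognitive map

The map is a landmark graph: nodes carry Cartesian coordinates, edges
carry their Euclidean length; edge directions are derived from the
coordinates with `atan2` (0° along +x, degrees).  Localization is
winner-take-all over landmarks (nearest landmark = active place cell,
ties to the lowest id).  Routes are minimum-total-distance paths
(Dijkstra via networkx, with a deterministic lowest-id reconstruction).
The goal vector of a route is the vector sum of its connection vectors,
which telescopes to the straight displacement from first to last
landmark.  The allocentric goal direction fed to the AGD population is
recomputed every step from the agent's live position, since the goal
direction is defined relative to where the agent actually is, not to
its place cell.

## Retrosplenial cortex: transformation and arbitration

The EGD population encodes `wrap(AGD_peak − heading)`, decoded from the
(noisy) AGD and HD populations; −80° means the goal is 80° into the
hemifield labelled "left".  The movement pathway is wired consistently
with this label: the left movement cell integrates EGCD units at
angles [−179°, 0°], the forward cell [−54°, 54°], the right cell
[1°, 180°] (the printed overlapping bands: 180/109/180 units), the
wheel velocities are `v_left = mv_fwd + mv_right`,
`v_right = mv_fwd + mv_left`, and the heading update is
`dθ ∝ (v_left − v_right)`.  Under these conventions a goal at negative
(left-labelled) egocentric angle drives the right wheel faster and the
heading converges onto the goal bearing — the orientation of "left" vs
screen coordinates is a mirror symmetry with no physical content.

Confidence dynamics per step, in order: all strategies decay by
`×(1−λ_default)`; then the active strategy receives the event terms
(approach bonus `+u_default`, receding decay `×(1−λ_dist)`, alignment
bonus, progress bonus, stuck penalty `×(1−λ_stuck)` with `+u_stuck` to
the others); finally values are clamped to [0, 1].  "Approaching" and
"receding" compare straight-line goal distance between consecutive
steps with a 10⁻⁶ dead-band; "aligned" means the decoded EGD peak is
within ±10° of straight ahead; "progress" means the route strategy
reached its next landmark; "stuck" fires while the agent has stayed
near a single place cell for more than 50 steps.

Strategy selection is a softmax draw `p_i = exp(c_i/T)/Σ exp(c_j/T)`
realized as one uniform draw over the cumulative partition of [0, 1) in
strategy order.  The cadence is a design choice the defining equations
leave open: the initial strategy is held for `initial_hold` = 50 steps
(re-evaluating immediately with near-equal confidences would undo a
prescribed initial draw), then re-evaluated every P steps.  The
temperature T and period P are the only calibrated quantities in the
package; they were calibrated once against the starmaze category
distribution on a dedicated seed set and then frozen: starmaze
T = 0.075, P = 10; vista T = 0.02, P = 80.  The vista values differ
for a mechanistic reason: with the stuck rule active, short tenures
make the active strategy's confidence sink below its competitors before
it can accomplish anything, producing rapid musical-chairs switching in
which no strategy ever escapes a wall corner.  An 80-step tenure lets a
selected strategy traverse a region; the large route-progress bonus
(u_progress = 0.25) then locks in whichever strategy actually makes
progress.

Parameter table (dimensionless rates per step):

| parameter | value | used in |
|---|---|---|
| c_i(0) | 0.8 | all |
| λ_default | 0.02 | all |
| u_default | 0.025 | all |
| λ_dist | 0.002 | all |
| u_ego | 0.05 | starmaze (alignment bonus) |
| u_progress | 0.25 | vista (route progress) |
| u_direction | 0.005 | vista (alignment bonus) |
| λ_stuck | 0.02 | vista |
| u_stuck | 0.01 | vista |

## Posterior parietal cortex: cue coding and strategies

ECD cells sum, over visible cues, Gaussian bumps at each cue's
egocentric direction weighted by D/d (D = 3, d the cue distance); a cue
at distance 3 yields raw activation 1 at its preferred unit.  The agent
may never occupy a cue position.  The EGCD modulation multiplies each
ECD unit by `Σ_m egd_m·w_i(m)` for strong EGD units (> 0.5) and
`Σ_m egd_m·(w_i(m)−1)` for weak ones, with `w_i(m)` a broad Gaussian
weight (σ = 80°) between preferred angles; negative products are
clamped to zero before the movement-cell sums.  The effect — verified
against a brute-force double loop and over a grid of cue/goal
geometries — is that the cue angularly closest to the goal direction
wins.

Route memories come in two kinds.  *Sequential egocentric*: ordered
(landmark, turn) commands recorded on a supervised traversal (signed
heading change at each junction, threshold 10°).  Replay is id-blind —
the k-th stored command fires at the k-th *choice-point* landmark
encountered — which is what lets a sequence trained from alley 1
replay from alley 5.  A triggered turn is executed as a saturated
steering drive (full left/right movement-cell override) whose final
step is trimmed to the stored angle; storing the actual signed angle
rather than a bare ±180 flag is required because the turning circle of
a saturated drive is smaller than the landmark capture radius, so "turn
until the landmark is passed" never terminates.  *Cue following*: an
ordered list of targets (region centroids, then the goal cue, which is
taken to be visible from everywhere); the EGCD is a pure Gaussian bump
at the next target's egocentric direction, and a target within the
capture radius (0.5) advances the sequence.

Conjunctive cells multiply the HD-population activity at their
preferred head direction with the ECD-population activity at their
preferred cue direction; the response factorizes exactly (noise off)
and peaks when both preferences are met simultaneously.  Because the
natural (heading, cue-angle) occupancy of a free-running session is
sparse, the blinking-light runner additionally probes each recorded
cell's tuning surface on a full 2°-grid using the run's noise model
(the simulation analogue of mapping a rate surface); the per-step
responses are logged as well.

## Motor layer

Movement-cell activity maps to wheel velocities as above, normalized by
twice the maximum so both lie in [0, 0.5] and the faster wheel is
exactly 0.5; all-zero drive halts the agent for the step (wheels never
reverse).  The pose update is a standard differential-drive step:
translation `0.5·(v_l+v_r)·speed_scale` along the (updated) heading,
rotation `(v_l−v_r)·speed_scale/wheelbase`.  speed_scale = 0.2,
wheelbase = 0.3 and body radius 0.15 (length units) are package
defaults chosen to give smooth trajectories at the worlds' unit scale
(max 0.1 units and ~19° per step).  Collisions are resolved by
iteratively pushing the body circle out of penetrated wall segments;
the tangential motion component survives, so driving obliquely into a
wall becomes a slide — this is what lets the allocentric strategy
follow maze corridors.

## Environments

*Blinking-light arena*: radius 5, 32 boundary lights 11.25° apart,
exactly one active; arriving within the 0.5 capture radius hands the
blink to a uniformly random other light.  *Starmaze*: pentagonal ring
of radius 5 with five radial arms of length 5, corridors 1 wide (walls
are buffered centrelines), arms odd-numbered clockwise with arm 1 at
90°; landmarks at the five ring junctions (choice points) and five arm
ends; exact dimensions are free choices since only the topology decides
trial classification.  The shortest alley-1→7 route crosses two ring
edges, giving a three-command training sequence (−54°, +72°, −54°).
*Vista world*: eight 6×6 regions on a 3×3 grid with the top-right cell
absent, numbered 1–9 without 8; 1-wide corridors at the midpoints of
shared walls connect grid neighbours except region 5's north corridor,
which is omitted — region 5 is the trap a goal-seeker falls into and
escapes from only by route-centric navigation.  Region centroids are
the route landmarks; each region carries one goal cue, re-scattered
uniformly (margin 1) per trial.  All environments serialize to plain
YAML and reload bit-identically.

## Experiments and their statistics

*Blinking light* disables the hippocampal and retrosplenial modules;
steering comes straight from the active cue's ECD signal.

*Starmaze*: one supervised 1→7 training traversal records the turn
sequence; each of the 130 probes starts at the alley-5 end, draws its
initial strategy 25%/75% (allocentric / sequential egocentric), and
runs the arbitration.  A trial terminates at the goal (alley-7 end), at
the alley-1 end while the route strategy is active, or at the 20 000
step budget.  Classification is purely trajectory-based: egocentric =
terminal alley 1; allocentric = terminal alley 7 without crossing the
ring toward alley 1; mixed = terminal alley 7 after crossing (operation-
alized as passing the midpoint of the first ring segment on the replay
path, or entering alley 1).  With the frozen parameters the six-seed
calibration mean was 33.8 allocentric / 60.5 egocentric / 34.3 mixed
out of 130, with one or two non-terminating trials per batch (an
exhausted replay circling the maze while the approach bonus keeps its
confidence high) reported separately as timeouts.  Counts fluctuate
seed-to-seed with a binomial standard deviation of about 5 trials.

*Vista space*: 80 trials, random goal region per trial, all three
strategies active with the vista confidence rules.  Completion was
100% in all verification batches.  The contribution metric computes,
per step, the shortest-route length from the agent (via its nearest
landmark) to the goal landmark; steps on which it strictly decreases
are credited to the strategy active at that step and contributions are
normalized to 100%.  The route-centric strategy dominates the mean
contribution in every batch, with the allocentric and egocentric
strategies sharing the remainder — the qualitative ordering the
hierarchical-planning account predicts.

## Problem sizes and runtime

The default test and acceptance runs use the full published problem
sizes — 130 starmaze probes, 80 vista trials, 32-light arena — and
complete in a few minutes on one CPU; population operations are 360-
dimensional vector/matrix products and the per-step cost is dominated
by the 360×360 EGCD modulation.

## Limitations

The map is prior knowledge: no learning, exploration or SLAM, and no
learning across trials (hence no analogue of participants who *shift*
strategy between sessions).  Neurons are rate-coded Gaussian units, not
spiking models.  The kinematics have no inertia, slip or reverse gear.
The wall-slide contact model is geometric, not physical.  Synthetic
worlds are deterministic polygons; the noise model perturbs neural
activities only, not the sensors' geometry, so real-sensor effects
(occlusion, aliasing, odometry drift) are outside what passing tests
demonstrate.  Confidence-trace timing (when exactly a trace dips or
recovers within a trial) depends on the step scale and is checked only
as an ordering, never against wall-clock-like step indices.
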