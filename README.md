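# refnav — reference-frame based spatial navigation simulator

`refnav` simulates a navigating agent whose behaviour is produced by
cooperating models of three brain regions, each holding a different
*spatial reference frame*:

* **Hippocampus (HPC)** — an allocentric frame: a cognitive map of
  landmarks with connection vectors (distance + allocentric direction),
  winner-take-all place cells, shortest-route search over the landmark
  graph, and a population of 360 allocentric goal direction (AGD) cells.
* **Retrosplenial cortex (RSC)** — the frame *transformer and arbiter*:
  360 head-direction (HD) cells track the agent's compass heading; the
  AGD signal is shifted by the heading into an egocentric goal direction
  (EGD, 0° = straight ahead, negative = left hemifield).  The RSC also
  maintains a confidence value c_i ∈ [0, 1] per navigation strategy and
  periodically draws the strategy to deploy from a softmax over the
  confidences.
* **Posterior parietal cortex (PPC)** — egocentric and route-centric
  frames: egocentric cue direction (ECD) cells respond to visible cues
  with distance-attenuated Gaussian bumps (gain D/d); an egocentric
  goal-cue direction (EGCD) population modulates the cue signal by the
  goal signal so the cue nearest the goal direction wins; stored routes
  are replayed either as turn commands at choice points
  (sequential-egocentric) or as a cue sequence (cue following).
  Movement cells (left / forward / right) integrate EGCD activity over
  hemifield bands.

Every directional signal is a Gaussian-tuned population code
`e_i = exp(-(θ_i - θ_input)² / σ²)` with σ = 10° (wrapped circular
difference), plus zero-mean activity noise and max-normalization.
Movement-cell activity becomes two wheel velocities
`v = (mv_fwd + mv_right, mv_fwd + mv_left) / (2·max)` ∈ [0, 0.5]² that
drive a differential-drive body with wall-sliding collision handling.

Confidence dynamics: every step all confidences decay by λ_default =
0.02; the active strategy gains u_default = 0.025 when the goal gets
closer, decays by λ_dist when it recedes, gains a heading-alignment
bonus (u_ego = 0.05 or u_direction = 0.005) when it faces the goal
within ±10°, gains u_progress = 0.25 on route progress, and loses to
the competitors when the agent is stuck near one place cell.  Strategy
selection is `p_i = exp(c_i/T) / Σ_j exp(c_j/T)` sampled with a single
uniform draw.

Three built-in experiments exercise the model:

1. **Blinking light** — a circular arena with 32 boundary lights, one
   active at a time; the agent chases the light purely egocentrically
   while conjunctive HD×ECD cells are recorded.
2. **Starmaze** — a pentagonal ring with five arms; after a supervised
   training traversal from alley 1 to the goal in alley 7, probe trials
   start in alley 5 and the arbitration between the allocentric and the
   sequential-egocentric strategy decides whether the agent ends in
   alley 7 (allocentric), alley 1 (egocentric replay) or first crosses
   toward alley 1 and then turns to alley 7 (mixed).
3. **Vista space** — eight rectangular regions joined by narrow
   corridors; goals are cues in random regions and all three strategies
   (allocentric, egocentric, route-centric cue following over region
   centroids) compete.  A contribution metric credits each strategy
   with the steps on which the shortest remaining route length
   decreased.

## Worked example

```python
from refnav.config import starmaze_config
from refnav.experiments import run_starmaze

res = run_starmaze(starmaze_config(), n_trials=130, seed=0)
print('counts      :', res.counts)
print('percentages :', {k: round(v, 1) for k, v in res.percentages.items()})
print('trained turn sequence:', res.extras['trained_sequence'])
```

prints

```
counts      : {'allocentric': 37, 'egocentric': 53, 'mixed': 38, 'timeout': 2}
percentages : {'allocentric': 28.5, 'egocentric': 40.8, 'mixed': 29.2, 'timeout': 1.5}
trained turn sequence: [('j1', -54.0), ('j9', 72.0), ('j7', -54.0)]
```

The trained sequence is the motor memory recorded on the training
traversal: turn left 54° entering the ring, right 72° at the middle
junction, left 54° into the goal arm.  Of 130 probe trials from alley
5, 37 went straight to the goal (allocentric), 53 replayed the sequence
into alley 1 (sequential egocentric), 38 started the replay and then
switched to the allocentric strategy (mixed), and 2 exhausted the step
budget.  The same simulations are reachable from a shell:

```bash
refnav starmaze --trials 130 --seed 0 --out out/starmaze
refnav blinking-light --seed 3 --steps 5000 --out out/blink
refnav vista --trials 80 --seed 17 --out out/vista
```

Each run writes its config snapshot (YAML), per-trial trajectory logs
(TSV), aggregate results (YAML) and optional plots.

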