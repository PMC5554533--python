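# Methods

## Model

A single-layer linear associative network maps `n_cues` cue units onto
`n_outcomes` outcome units through a weight matrix `w` (cues × outcomes).
Two learning rules update `w` once per trial, both evaluated simultaneously
from the pre-trial weights (one right-hand-side evaluation per trial, no
intermediate decay-then-learn staging):

* Hebbian with decay: `w' = w − d·w + k·outer(a, t)`. The outcome activity
  is clamped to the observed target during learning (teacher forcing), so
  the rule uses only what was presented. The decay applies to **every**
  weight on every trial — it has no activity gate — which is what bounds
  Hebbian weights at `k/d` for one-hot inputs and targets in `[0, 1]`.
* Widrow-Hoff (delta) with decay: `w' = w − d·w + k·outer(a, t − a@w)`.
  The raw linear prediction `a@w` enters the error term unnormalized.

Parameter ranges: learning rate `0 ≤ k < 1`, decay rate `0 < d ≤ 1`.
Initial weights default to zero (a naive learner, and the convention that
makes early prediction errors maximal); any start can be supplied.

Closed-form anchors used as test oracles: under constant unit input the
Hebbian rule converges to `w* = k/d` and the delta rule to `w* = k/(d+k)`;
with `k = 0` both reduce to geometric decay `w(τ) = (1−d)^τ w0`.

## Synthetic task

The generator emulates a quasi-stochastic associative-learning experiment:
`n_cues` one-hot cues presented in deterministic round-robin order (an
optional within-block shuffle exists, off by default, because the
deterministic order keeps every test reproducible trial-for-trial), each cue
bound to one outcome by the base mapping `cue i → outcome i mod n_outcomes`
(a bijection in the standard square design). Each trial independently
violates the mapping with probability `violation_prob`; a categorical
violation draws uniformly among the other outcomes, a continuous violation
substitutes another cue's profile. The standard conditions used throughout
the tests and the acceptance script are 4 cues, 4 outcomes, 10% violations,
50 trials.

The continuous variant assigns cue `i` the target level `(i+1)/n_cues` in
its mapped outcome slot and adds Gaussian observation noise (sd
`continuous_noise_sd`) to that slot only; the remaining slots stay exactly
zero. Placing noise only on the active slot keeps the single-outcome case
(the parameter-estimation setting of the equivalence analysis) identical to
a scalar noisy-target task.

A `compound_cues` flag activates all cue units on every trial while the
target keeps its round-robin schedule. It exists to probe overlapping cue
representations — the regime in which the delta rule's summed prediction
has no per-synapse Hebbian counterpart.

What the generator does **not** emulate: reward magnitudes, reaction times,
attention or salience modulation, cue similarity structure beyond full
overlap, or non-stationary contingencies. Passing tests therefore speak to
the internal logic of the two rules under idealized stationary statistics,
not to fits of behavioural or imaging data.

## Population metrics

* `|ΔW|`: summed absolute per-synapse change on one trial.
* Normalized prediction: raw activations are rectified at zero (negative
  activation has no probability reading) and divided by their sum. A cue
  whose rectified activations sum to zero — before its first presentation,
  or at `k = 0` — yields the uniform vector with a `degenerate` flag rather
  than an exception, so every trial of a session is well defined.
* `|PE|`: summed absolute difference between the target and the normalized
  prediction, computed from the **pre-update** weights (the prediction
  available at stimulus onset). Bounded by 2 for one-hot targets.
* Classification error `E`: after training, each cue's normalized
  prediction is compared against its noiseless mapped outcome; absolute
  differences are summed per outcome and per cue. The absolute values are
  deliberate: a signed per-cue sum would cancel to near zero for any
  normalized prediction and measure nothing.

## Parameter sweep

`run_sweep` evaluates a (k, d) grid — default 10×10, uniform over
[0.05, 0.95] on both axes — with `n_replicates = 20` freshly drawn task
realizations per cell. Replicate seeds derive from the root seed only, so
every cell sees the same tasks (common random numbers; cells differ only in
parameters). Per replicate the Pearson correlation (Spearman available)
between the |PE| and |ΔW| series is computed; replicates with a constant
series, or fewer than 3 usable trials, are flagged undefined and excluded
from the cell mean. `E` is evaluated on the final weights and averaged over
all replicates.

Design choices worth recording:

* **Degenerate trials are excluded from the correlation by default.** The
  normalized prediction is 0/0 for a never-presented cue; the uniform
  fallback is a convention of this package, and letting its fabricated |PE|
  values into the correlation measures the convention rather than the
  dynamics (from a zero start the first `n_cues` trials are all degenerate,
  and their fallback |PE| pairs with a still-rising |ΔW|, systematically
  depressing a 50-trial correlation). A flag restores inclusion.
* **Grid capped at 0.95 rather than d = 1.** At `d = 1` the network is
  memoryless: after any trial only the just-presented cue's row is nonzero,
  every other cue's prediction is degenerate, and both maps are dominated
  by the fallback convention. That boundary artifact says nothing about
  learning dynamics, so the grid stops short of it.
* **Structural fact: both maps are constant along k.** From a zero start,
  Hebbian weights are exactly linear in k, and the normalized prediction,
  the Pearson correlation and E are invariant to a positive rescaling of
  the weights. All variation in the maps therefore lives on the d axis.
  Consequently E cannot be selectively degraded where *both* k and d are
  small: measured at 400 replicates, expected E rises gently with d (0.80
  at d = 0.05 to 0.84 at d = 0.95) and the small-d corner is, if anything,
  the most accurate. Observing a degraded near-origin corner would require
  a nonzero initial condition (which small k and d cannot escape) or
  unnormalized predictions; with 20 replicates, apparent corner elevation
  at particular seeds is sampling noise (per-replicate E has sd ≈ 0.4–1.1).

Problem sizes: the standard sweep is 100 cells × 20 replicates × 50 trials
(2,000 sessions), which completes in a few seconds; the randomized
equivalence check uses 100 draws of 50-trial sessions.

## Equivalence analysis

With one always-active cue both rules collapse to scalar difference
equations, identical whenever `k_H = k_WH` and `d_H = d_WH + k_WH`
(the delta rule's `k·(t − w)` is a Hebbian drive `k·t` plus extra decay
`−k·w`). `map_wh_to_hebbian` applies the mapping and rejects parameters
with `d_WH + k_WH > 1`, which would push the mapped decay out of range.
`verify_single_cue` runs both rules on the same sequence and reports the
maximum absolute trajectory divergence; the equivalence tolerance is 1e-12
(machine precision over 50 trials), and a property test sweeps randomized
admissible parameters, starts and noisy target sequences.

The mapping fails for any task in which more than one cue carries weight,
for two independent reasons: (i) the weights of a momentarily inactive cue
decay at rate `d_WH` under the delta rule but `d_WH + k_WH` under the mapped
Hebbian rule, so plain cue alternation already separates the trajectories;
(ii) on compound trials the delta rule's error contains the prediction
summed over co-active cues, which no per-synapse Hebbian term reproduces.
`verify_multi_cue` measures the divergence; the non-equivalence witness
threshold is 1e-3 (clearly material against the 1e-12 equivalence scale),
and the compound two-cue task exceeds it by two orders of magnitude.

## Numerical conventions and degenerate inputs

Ties and edge cases: `n_trials = 0` returns the bare initial state;
`k = 0` makes |ΔW| identically zero from a zero start, so the correlation
is flagged undefined rather than computed; correlation means skip undefined
replicates and a cell with no defined replicate reports NaN (serialized as
null in JSON). All weight states store read-only array copies, and updates
are pure functions. Every stochastic component (task generation, replicate
redraws) derives from a single root seed through `numpy.random.SeedSequence`
child streams, so identical configurations reproduce outputs byte for byte.

## Known limitations

* Linear activations only; no multi-layer structure, eligibility traces, or
  activity-gated (Oja-style quadratic) decay — the decay here is linear by
  construction.
* The sweep's correlation is a within-session statistic averaged over
  replicates; it is not a hemodynamic forward model, and no BOLD convolution
  is attempted.
* The classification-error landscape is intrinsically one-dimensional here
  (see the k-invariance note above); claims about joint (k, d) structure of
  E cannot be probed from a zero-weight start.
* Continuous-outcome tasks reuse the categorical normalization for |PE| and
  E; for targets that are not probability-like the two scales are not
  directly comparable across variants.
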