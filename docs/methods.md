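# Methods

## Model

The package simulates a fixed population of `N` microtubules in a 1-D
neurite `[0, L]`, cell body at 0, tip at `L`. An MT is a closed interval
with an orientation flag: PEO MTs have their plus end at the upper
(tip-facing) coordinate, MEO MTs at the lower. Both ends are independent
two-state (growing/shrinking) telegraph processes. Rescue rates are
constant; the catastrophe rate of either end rises linearly with the MT's
current length,

    λg→s±(L) = max(λmin, λ̃± + γ (L − L0)),

which acts as a restoring force toward the characteristic length `L0`: the
rate is elevated above `L0` and reduced (down to the floor `λmin`) below
it. Note the consequence that a *larger* `γ` lengthens MTs in a population
living below `L0` — `γ` tightens length regulation, it does not uniformly
shorten.

Tubulin is conserved: `free + Σ lengths = Ttot` at every step boundary.
Shrinking ends release polymer to the free pool; growing ends consume it.

Space is continuous (µm); time is internally in minutes (the rates are per
minute) and the simulation advances on a fixed 1-second step.

### Per-step loop

1. **Polymerization.** End states switch first, using start-of-step
   lengths, with per-step probability `1 − exp(−rate·dt)` (exact for a
   constant rate, always in [0,1]). Displacements are applied second:
   shrinking ends retract by `vs·dt`, growing ends request `vg·dt`. If the
   step's total growth demand exceeds the free pool plus the step's
   guaranteed shrink release, every growing end is throttled by the common
   ratio free/demand (proportional rationing — exact conservation, full
   speed when tubulin is ample; the velocity response is isolated behind
   `apply_polymerization` so a smooth saturating form could be swapped in).
   Ends that would leave the domain are set to the boundary, keep their
   growing state (a clipped end is stalled, not catastrophed), and the
   unconsumed tubulin stays free. An MT whose length would reach ≤ 0 is
   removed with exactly its pre-step length credited back to the pool.
2. **Checkpoint** (if enabled). Every MT nucleated in the *previous* step
   — i.e. after one growth step — is tested: autofail with probability
   `P(autofail)`; otherwise `ns` draws with replacement from the MTs
   crossing its nucleation site (closed-interval crossing, the new MT
   excluded from its own crossing set, since its seed always contains the
   site). The MT survives iff a drawn MT shares its orientation; an empty
   site counts as a match. Failures return their polymer to the pool.
3. **Nucleation.** Each MT removed in steps 1–2 is replaced: a site is
   drawn uniformly, the MEO probability is the site's current crossing MEO
   fraction (feedback on) or 1/2 (feedback off or empty site), and the seed
   (0.1 µm) is placed with its minus end at the site, plus end one seed
   length above (PEO) or below (MEO), both ends growing. Replacements are
   sequential, so a seed placed earlier in the step is visible to later
   crossing sets in the same step.

The population is therefore constant at every step boundary. One RNG
stream drives a run; per step it is consumed in a fixed order (state
flips as one `(N, 2)` uniform block, then per-pending-MT checkpoint draws
in slot order, then per-replacement site/orientation draws), so runs are
bit-reproducible given (configuration, seed). Replicate seeds are a fixed
affine-modular function of the master seed and run index.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `vg+ / vg−` | 6 / 0.75 | µm/min | growth speeds, plus/minus end |
| `vs+ / vs−` | 6 / 3.5 | µm/min | shrink speeds |
| `λ̃+ / λ̃−` | 0.5 / 0.25 | 1/min | catastrophe rates at `L0` |
| rescue `+ / −` | 0.2811 / 0.67 | 1/min | shrink→growth switching |
| `γ` | 0.01 | (µm·min)⁻¹ | catastrophe slope (length feedback) |
| `λmin` | 0.05 | 1/min | catastrophe floor |
| `L0` | 20 | µm | characteristic length |
| `Ttot` | 50·N | µm polymer | conserved tubulin budget |
| `N` | 20 / 60 | MTs | population, short / long domain |
| initial length | 15 | µm | all MTs at t = 0, uniform placement |
| seed length | 0.1 | µm | newly-nucleated MT |
| `P(autofail)` | 0.25 | — | automatic checkpoint failure |
| `ns` | 6 | MTs | checkpoint sample size |
| `dt` | 1 | s | simulation step |

The growth-model constants are the measured *Drosophila* dendrite values;
`P(autofail)` and `ns` come from the package's own calibration solvers (see
below). The mean growth-run lengths implied by the constants —
`vg+/λ̃+ = 12` µm for plus ends versus 3 µm for minus ends — are what
create the intrinsic spatial bias (MEO near the cell body, PEO near the
tip) that the nucleation mechanisms then amplify.

**The tubulin budget.** The printed value of `Ttot` is typographically
corrupted in the source material, so the package treats it as a
configurable scalar and fixes the default by consistency with the rest of
the printed configuration: the budget must assemble the initial array
(N × 15 µm) and reproduce the reported steady-state cross-section
occupancy (~9 MTs in the short domain, ~13 in the long — the long-domain
figure alone requires `Ttot > 910` µm there). The default `Ttot = 50·N` µm
(1000 / 3000) satisfies both; at this level the pool is a safeguard cap
rather than the operative length limiter (per-step demand is a few µm
against a free pool of hundreds), and steady-state lengths are set by the
length-dependent catastrophe and boundary confinement. Smaller budgets
(≈15 µm/MT) shave roughly half an MT off the long-domain cross-section and
slow long-domain polarization slightly.

## Analytic checkpoint model and calibration

For a nucleation of one orientation in a background environment where a
local MT opposes it with probability `p∓`:

    P(success±) = P(Δy≥2) · (1 − P(autofail)) · (1 − p∓^ns)

`P(Δy≥2) ≈ 0.9` is the baseline probability that an isolated new MT's plus
end ever grows 2 µm past its nucleation position under the growth dynamics
alone (estimated by `simulate_lifetimes`; the `estimate_exit_probability`
helper reports it with its binomial standard error). The calibration
proceeds in two closed-form steps: in the ~90%-MEO control environment the
sampling factor for MEO nucleations is ≈ 1, so
`P(autofail) = 1 − observed/baseline` (reported raw and rounded to the
nearest 0.05); then the mixed-environment MEO rate fixes
`ns = log(1 − observed/(baseline·(1−autofail))) / log(p∓)`. The integer
reported for `ns` is the one whose *forward* success probability is
nearest the observed rate, which can differ from arithmetic rounding of
the real root because the success curve is concave in `ns` (for the
printed inputs the real root is 5.49 and the nearest-forward integer is 6).
Both solvers are exact inverses of the forward model before rounding and
reject infeasible inputs (observed rate above the attainable ceiling).

## Checkpoint validation harness

The experimental success rates the checkpoint is calibrated against are
measured in an environment of roughly fixed composition (~90% MEO), but no
mechanism combination of the model *holds* that composition: checkpoint
alone erodes toward mixed polarity (surviving entries are ~95% MEO from
90/10 attempts, while feedback-free orientation draws are 50/50), and
feedback absorbs at 100%. The engine therefore provides an explicit
measurement mode (`RunOptions.pinned_environment` + `checkpoint_probe`):
replacement orientations are drawn from the fixed environment composition,
and every nucleation's checkpoint is evaluated and logged *without*
removing failures, so the array composition stays at the environment's
value by construction while trials accumulate. A trial succeeds when the
MT passes autofail and sampling *and* its plus end subsequently grows 2 µm
past the nucleation site before full catastrophe — the same event the
experimental success rates count, and the reason the analytic model
carries the `P(Δy≥2)` factor.

## Observables

* **Polarity series** — the MEO fraction over all N MTs, recorded every
  step.
* **Bias events** — first time the fraction hits exactly 0 or 1; first
  later excursion away from {0, 1} lasting more than `grace_steps`
  consecutive samples (default 1: the checkpoint removes wrong-way
  nucleations after a single step, so one-step excursions are forgiven);
  first return to the original biased value. Events are evaluated on the
  per-step series; on coarser snapshot grids detection is conservative.
* **Per-site polarity** — MEO fraction over each site's crossing set,
  undefined when nothing crosses; binned into five 20%-wide categories.
* **Phase interface** — sites classified MEO-majority (fraction > 0.5;
  ties count PEO, an explicit tie-break) form a phase-separated profile
  when they are a contiguous block nearest the cell body followed only by
  PEO-majority sites; the interface index is the MEO block size.
* **Cross-section occupancy** — MTs overlapping each point of a 1 µm grid,
  averaged over positions and post-burn-in snapshots. The reference
  measurement uses the bare set-up (no nucleation mechanisms), a 6 h
  burn-in of a 1-day run, and three replicates: without mechanisms the
  occupancy is an intrinsic, stable property of the geometry and growth
  dynamics, whereas with the checkpoint enabled it depends on the polarity
  state (mixed-polarity episodes sustain checkpoint-failure turnover, so
  the array carries more young, short MTs and runs a couple of MTs
  lighter).
* **Ensemble summaries** — per-time mean and interquartile range, final
  polarity histograms, empirical CDFs of hit/depart/return times with the
  percentage of runs achieving each event.

## Problem sizes

The full study design is 100 replicates × 5 simulated days per mechanism
combination; the package exposes it through `mtpolarity reproduce`. The
test suite and acceptance script run scaled designs chosen so each
quantity is still estimated meaningfully: 1800 lifetimes for the baseline
exit probability; three 1-day replicates per domain for cross-sections;
20 short-domain and 10 long-domain replicates for first-passage maxima
(caps of 12 h and 4 days, so the reported maximum is a true first-passage
time, not a censoring artifact); ≥500 resolved trials per orientation for
the checkpoint validation; 10 × 1-day long-domain replicates for the
mixed-polarity control band. The 100-run 5-day statistics (fraction of
runs ever returning to mixed polarity, full CDF shapes, end-of-run
distributions) are reproducible through the CLI but are not part of the
automated tests.

## Numerical and degenerate-input choices

* Fixed-step discretization with `1 − exp(−λ dt)` switching; states flip
  before displacement so each step is a clean Markov kernel.
* Conservation is maintained incrementally (not recomputed from the mass),
  and asserted to 1e-9 relative tolerance by the engine's optional
  validator; sub-1e-9 negative pool values arising from the rationing
  ratio's float rounding are clamped to zero.
* The rationing scale uses a conservative lower bound on the step's shrink
  release (`min(shrink displacement, current length)` per MT), so the free
  pool cannot be over-committed even when an MT dies mid-step.
* A nucleation when the free pool holds less than one seed length places a
  correspondingly shorter seed (the pool is never driven negative); with
  the default budget this cannot occur in practice.
* Boundary-clipped ends keep their growing state ("stalled"); whether a
  stalled minus end should instead catastrophe is unknown, and the choice
  only matters for MTs pinned at a boundary.
* Initial end states are growing at both ends (unspecified in the source
  material; configurable in principle through the array API).
* `simulate_lifetimes` hard-caps each lifetime at 2×10⁶ steps and raises
  if reached — the length process has negative drift everywhere above a
  few µm, so this is orders of magnitude beyond the observed tail.

## What the simulations do and do not emulate

The generator reproduces the study conditions: measured per-end speeds and
switching rates, 1-second stepping, 15 µm initial MTs uniformly placed with
independent 50/50 (or specified) orientations, constant MT number, and the
two nucleation mechanisms with their calibrated constants. It does not
model branched dendrite geometry, MT entry or nucleation at boundaries,
motor-driven sliding or steering, injury-induced nucleation up-regulation,
or any mechanistic basis for autofail; orientation categories richer than
PEO/MEO (e.g. peripheral nucleation directions seen in imaging) are
collapsed onto the 1-D axis. Passing tests therefore validate the model's
internal logic and its agreement with the published summary statistics,
not the biology of real dendrites beyond what those statistics capture.

## Known limitations

* First-passage times to full bias in the long domain have a heavy tail;
  a few percent of feedback-only replicates take longer than 2 simulated
  days, so small-sample maxima fluctuate around that scale.
* The checkpoint-validation success rates are measured in the pinned-
  composition probe mode described above; in a free-running simulation the
  local composition, and hence the measured rates, drift with the global
  polarity state.
* Even with the global composition pinned, the minority-orientation (PEO)
  success rate in the spatial model sits a few percentage points below the
  homogeneous-environment analytic value. Two effects, both visible in the
  per-site event logs, combine: the array stratifies within tens of minutes
  (the 12 µm plus-end runs versus 3 µm minus-end runs enrich MEO near the
  cell body and deplete it near the tip), and the checkpoint samples small,
  fluctuating crossing sets (~10 MTs). Success is concave in the local MEO
  fraction, so both the site-to-site spread and the within-site
  fluctuations lower the aggregate (Jensen's inequality); the
  majority-orientation rate is insensitive because its matching
  probability saturates near 1. This is emergent behavior of the spatial
  model, not present in the well-mixed analytic calculation, and the
  validation experiment pools replicates and aggregates over sites — the
  same aggregation the observed rates represent.
* The proportional-rationing response to tubulin scarcity is a modeling
  choice; at the default budget it is essentially never engaged, so its
  functional form is untested by the reported statistics.
* With `record_interval` coarser than `dt`, bias-event detection and
  site-profile tallies are computed on snapshots and are conservative
  relative to per-step evaluation (the polarity series itself is always
  per-step).
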