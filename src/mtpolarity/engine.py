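"""Three-phase fixed-step simulation loop over the spatial domain.

Every step (1 s by default) executes, in order:

1. **Polymerization** — end states switch using start-of-step lengths, ends
   displace with tubulin rationing and boundary clipping, fully-catastrophed
   MTs (length <= 0) are removed and counted.
2. **Checkpoint** — each MT nucleated in the previous step is tested against
   the MTs crossing its nucleation site (autofail draw, then ``n_s`` samples
   with replacement); failures are removed and counted.
3. **Nucleation** — every removed MT is replaced at a uniformly-random site,
   with orientation drawn from the nucleation-feedback rule, keeping the
   population size constant.  Replacements within one step are sequential,
   so a seed placed earlier in the step is visible to later crossing sets.

The MT count is therefore constant at every step boundary, and tubulin is
conserved exactly: checkpoint failures and full catastrophes return their
polymer to the free pool, seeds consume one seed length.

A validation harness for checkpoint success-rate measurements is built in:
``pinned_environment`` draws every replacement's orientation from a fixed
background composition instead of local feedback, and ``checkpoint_probe``
evaluates and logs every checkpoint decision without removing failures, so
the array's polarity composition is held at the environment's value while
trials accumulate.  A trial's final outcome additionally requires the new
plus end to grow 2 um past its nucleation site before full catastrophe,
matching what the experimentally-reported success rates measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (
    CheckpointEnvironment,
    DomainConfig,
    DynamicsParams,
    MechanismConfig,
    Microtubule,
    validate_config,
)
from .dynamics import (
    MicrotubuleArray,
    TubulinPool,
    advance_end_states,
    apply_polymerization,
)

__all__ = [
    "SimulationState",
    "SimulationRecord",
    "RunOptions",
    "initialize_array",
    "crossing_set",
    "step",
    "run",
]

EXIT_THRESHOLD_UM = 2.0


@dataclass
class RunOptions:
    """Engine switches beyond the scientific configuration.

    ``track_exit`` follows every checkpointed nucleation until its plus end
    grows 2 um past the site or the MT dies, logging a success/failure
    trial.  ``pinned_environment``/``checkpoint_probe`` form the
    success-rate validation harness (see module docstring).
    ``stop_when_fully_biased`` ends the run at the first step where the MEO
    fraction hits 0 or 1.  ``stop_after_trials`` ends it once that many
    PEO and MEO trials have each been resolved.  ``validate_every`` asserts
    the conservation/confinement/population invariants every k steps.
    """

    track_exit: bool = False
    pinned_environment: CheckpointEnvironment | None = None
    checkpoint_probe: bool = False
    stop_when_fully_biased: bool = False
    stop_after_trials: int | None = None
    record_snapshots: bool = True
    validate_every: int = 0


@dataclass
class SimulationState:
    """Mutable state advanced by :func:`step`."""

    arr: MicrotubuleArray
    pool: TubulinPool
    rng: np.random.Generator
    time_s: float = 0.0
    step_index: int = 0
    next_id: int = 0
    # exit-trial bookkeeping (parallel to arr slots)
    trial_open: np.ndarray | None = None
    trial_site_pos: np.ndarray | None = None
    trial_passed: np.ndarray | None = None


@dataclass
class SimulationRecord:
    """Per-step polarity series, periodic snapshots, and event logs."""

    dt: float
    sites: tuple[float, ...]
    # per-step
    step_times_s: np.ndarray = field(default_factory=lambda: np.empty(0))
    meo_fraction: np.ndarray = field(default_factory=lambda: np.empty(0))
    # periodic snapshots
    snapshot_times_s: list[float] = field(default_factory=list)
    snapshot_lower: list[np.ndarray] = field(default_factory=list)
    snapshot_upper: list[np.ndarray] = field(default_factory=list)
    snapshot_is_meo: list[np.ndarray] = field(default_factory=list)
    snapshot_plus_grow: list[np.ndarray] = field(default_factory=list)
    snapshot_minus_grow: list[np.ndarray] = field(default_factory=list)
    snapshot_free_tubulin: list[float] = field(default_factory=list)
    # event logs
    nucleations: list[tuple] = field(default_factory=list)
    # (time_s, site_idx, is_meo, crossing_n_peo, crossing_n_meo, cause)
    checkpoints: list[tuple] = field(default_factory=list)
    # (time_s, site_idx, is_meo, autofailed, passed)
    trials: list[tuple] = field(default_factory=list)
    # (is_meo, passed_checkpoint, success)
    n_trials_peo: int = 0
    n_trials_meo: int = 0
    n_full_catastrophes: int = 0

    def trial_success_rates(self) -> dict:
        """Per-orientation exit success over resolved trials."""
        out = {}
        for label, meo in (("PEO", False), ("MEO", True)):
            rows = [t for t in self.trials if t[0] == meo]
            n = len(rows)
            succ = sum(1 for t in rows if t[2])
            rate = succ / n if n else float("nan")
            se = float(np.sqrt(rate * (1 - rate) / n)) if n else float("nan")
            out[label] = {"n": n, "successes": succ, "rate": rate, "stderr": se}
        return out


def initialize_array(
    domain: DomainConfig,
    params: DynamicsParams,
    rng: np.random.Generator,
) -> SimulationState:
    """Place N MTs of the initial length uniformly at random in the domain.

    Orientations are independent Bernoulli(initial_meo_fraction) draws; both
    ends start growing; the free pool holds whatever tubulin the initial
    polymer does not.
    """
    n = domain.n_mts
    free0 = params.T_tot - n * domain.initial_length
    if free0 < -1e-9:
        raise ValueError(
            f"total tubulin {params.T_tot} cannot assemble {n} MTs of length "
            f"{domain.initial_length}"
        )
    arr = MicrotubuleArray(n)
    arr.lower[:] = rng.uniform(0.0, domain.length - domain.initial_length, size=n)
    arr.upper[:] = arr.lower + domain.initial_length
    arr.is_meo[:] = rng.random(n) < domain.initial_meo_fraction
    arr.bind_params(params)
    state = SimulationState(
        arr=arr,
        pool=TubulinPool(free=max(free0, 0.0), total=params.T_tot),
        rng=rng,
        next_id=n,
    )
    state.trial_open = np.zeros(n, dtype=bool)
    state.trial_site_pos = np.zeros(n, dtype=float)
    state.trial_passed = np.zeros(n, dtype=bool)
    return state


def crossing_set(mts: list[Microtubule], site_position: float) -> list[Microtubule]:
    """MTs whose closed interval contains the site (inclusive endpoints)."""
    return [mt for mt in mts if mt.crosses(site_position)]


def _resolve_trial(
    state: SimulationState, record: SimulationRecord, i: int, success: bool
) -> None:
    is_meo = bool(state.arr.is_meo[i])
    record.trials.append((is_meo, bool(state.trial_passed[i]), success))
    if is_meo:
        record.n_trials_meo += 1
    else:
        record.n_trials_peo += 1
    state.trial_open[i] = False


def _nucleate_into_slot(
    state: SimulationState,
    record: SimulationRecord,
    domain: DomainConfig,
    params: DynamicsParams,
    mech: MechanismConfig,
    options: RunOptions,
    slot: int,
    cause: str,
) -> None:
    arr = state.arr
    rng = state.rng
    site_idx = int(rng.integers(0, len(domain.nucleation_sites)))
    site_pos = domain.nucleation_sites[site_idx]

    cross = arr.crossing_mask(site_pos)
    n_meo = int(np.count_nonzero(arr.is_meo & cross))
    n_cross = int(np.count_nonzero(cross))
    n_peo = n_cross - n_meo

    if options.pinned_environment is not None:
        p_meo = options.pinned_environment.p_pre_meo
    elif mech.feedback_on and n_cross > 0:
        p_meo = n_meo / n_cross
    else:
        p_meo = 0.5
    is_meo = bool(rng.random() < p_meo)

    seed = min(domain.seed_length, state.pool.free) if not state.pool.unlimited \
        else domain.seed_length
    if is_meo:
        lo, up = site_pos - seed, site_pos
    else:
        lo, up = site_pos, site_pos + seed
    arr.lower[slot] = lo
    arr.upper[slot] = up
    arr.is_meo[slot] = is_meo
    arr.up_grow[slot] = True
    arr.lo_grow[slot] = True
    arr.alive[slot] = True
    arr.site_idx[slot] = site_idx
    arr.ids[slot] = state.next_id
    state.next_id += 1
    arr.pending_checkpoint[slot] = mech.checkpoint_on
    arr.rebind_slot(slot, params)
    if not state.pool.unlimited:
        state.pool.free -= seed

    if options.track_exit:
        state.trial_open[slot] = True
        state.trial_site_pos[slot] = site_pos
        state.trial_passed[slot] = not mech.checkpoint_on  # no gate to pass

    record.nucleations.append(
        (state.time_s, site_idx, is_meo, n_peo, n_meo, cause)
    )


def step(
    state: SimulationState,
    domain: DomainConfig,
    params: DynamicsParams,
    mech: MechanismConfig,
    record: SimulationRecord,
    options: RunOptions,
) -> None:
    """Advance one time step in place (polymerize, checkpoint, nucleate)."""
    arr = state.arr
    dt_min = domain.dt_min
    state.time_s += domain.dt
    state.step_index += 1

    # --- 1. polymerization -------------------------------------------------
    advance_end_states(arr, params, dt_min, state.rng)
    dead = apply_polymerization(arr, state.pool, domain.length, params, dt_min)
    record.n_full_catastrophes += dead.size
    removed = list(dead)
    if options.track_exit and dead.size:
        for i in dead:
            if state.trial_open[i]:
                _resolve_trial(state, record, i, False)

    # --- 2. checkpoint -----------------------------------------------------
    if mech.checkpoint_on:
        pending = np.flatnonzero(arr.pending_checkpoint & arr.alive)
        for i in pending:
            arr.pending_checkpoint[i] = False
            site_pos = domain.nucleation_sites[arr.site_idx[i]]
            cross = arr.crossing_mask(site_pos)
            cross[i] = False  # the new MT never observes itself
            autofailed = state.rng.random() < mech.p_autofail
            if autofailed:
                passed = False
            else:
                idx = np.flatnonzero(cross)
                if idx.size == 0:
                    passed = True
                else:
                    draws = state.rng.integers(0, idx.size, size=mech.n_s)
                    passed = bool(
                        np.any(arr.is_meo[idx[draws]] == arr.is_meo[i])
                    )
            record.checkpoints.append(
                (state.time_s, int(arr.site_idx[i]), bool(arr.is_meo[i]),
                 bool(autofailed), bool(passed))
            )
            if passed:
                if options.track_exit and state.trial_open[i]:
                    state.trial_passed[i] = True
            else:
                if options.track_exit and state.trial_open[i]:
                    _resolve_trial(state, record, i, False)
                if not options.checkpoint_probe:
                    if not state.pool.unlimited:
                        state.pool.free += arr.upper[i] - arr.lower[i]
                    arr.alive[i] = False
                    arr.lower[i] = 0.0
                    arr.upper[i] = 0.0
                    removed.append(int(i))

    # --- 3. nucleation -----------------------------------------------------
    for slot in removed:
        _nucleate_into_slot(
            state, record, domain, params, mech, options, slot, "replacement"
        )

    # --- exit-trial growth tracking ----------------------------------------
    if options.track_exit:
        open_idx = np.flatnonzero(state.trial_open & arr.alive)
        if open_idx.size:
            plus = np.where(
                arr.is_meo[open_idx], arr.lower[open_idx], arr.upper[open_idx]
            )
            sign = np.where(arr.is_meo[open_idx], -1.0, 1.0)
            exc = sign * (plus - state.trial_site_pos[open_idx])
            done = exc >= EXIT_THRESHOLD_UM
            for j in open_idx[done]:
                # success only if the checkpoint gate (if any) was passed
                _resolve_trial(state, record, j, bool(state.trial_passed[j]))

    if options.validate_every and state.step_index % options.validate_every == 0:
        _check_invariants(state, domain, params)


def _check_invariants(
    state: SimulationState, domain: DomainConfig, params: DynamicsParams
) -> None:
    arr = state.arr
    if not arr.alive.all():
        raise AssertionError("population not constant at step boundary")
    if not state.pool.unlimited:
        balance = state.pool.free + arr.polymer_mass()
        if abs(balance - state.pool.total) > 1e-9 * state.pool.total:
            raise AssertionError(
                f"tubulin not conserved: free+polymer={balance} "
                f"vs total={state.pool.total}"
            )
        if state.pool.free < -1e-12:
            raise AssertionError(f"negative free tubulin {state.pool.free}")
    if arr.lower.min() < -1e-12 or arr.upper.max() > domain.length + 1e-12:
        raise AssertionError("MT outside the domain")
    if (arr.upper - arr.lower).min() < 0:
        raise AssertionError("inverted MT interval")


def run(
    domain: DomainConfig,
    params: DynamicsParams,
    mech: MechanismConfig,
    rng: np.random.Generator | int,
    duration: float | None = None,
    options: RunOptions | None = None,
) -> SimulationRecord:
    """Simulate for ``duration`` seconds (default ``domain.duration``).

    Deterministic given the configuration and the RNG seed.  Records the
    MEO fraction at every step, snapshots every ``domain.record_interval``
    seconds, and the nucleation/checkpoint event logs.
    """
    validate_config(domain, params, mech)
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    options = options or RunOptions()
    duration = domain.duration if duration is None else duration
    n_steps = int(round(duration / domain.dt))
    record_every = max(1, int(round(domain.record_interval / domain.dt)))

    state = initialize_array(domain, params, rng)
    record = SimulationRecord(dt=domain.dt, sites=domain.nucleation_sites)
    times = np.empty(n_steps, dtype=float)
    fracs = np.empty(n_steps, dtype=float)

    def snapshot() -> None:
        arr = state.arr
        record.snapshot_times_s.append(state.time_s)
        record.snapshot_lower.append(arr.lower.copy())
        record.snapshot_upper.append(arr.upper.copy())
        record.snapshot_is_meo.append(arr.is_meo.copy())
        record.snapshot_plus_grow.append(np.asarray(arr.plus_grow))
        record.snapshot_minus_grow.append(np.asarray(arr.minus_grow))
        record.snapshot_free_tubulin.append(state.pool.free)

    if options.record_snapshots:
        snapshot()

    done_steps = 0
    for k in range(n_steps):
        step(state, domain, params, mech, record, options)
        times[k] = state.time_s
        f = float(np.mean(state.arr.is_meo))
        fracs[k] = f
        done_steps = k + 1
        if options.record_snapshots and state.step_index % record_every == 0:
            snapshot()
        if options.stop_when_fully_biased and (f == 0.0 or f == 1.0):
            break
        if (
            options.stop_after_trials is not None
            and record.n_trials_peo >= options.stop_after_trials
            and record.n_trials_meo >= options.stop_after_trials
        ):
            break

    record.step_times_s = times[:done_steps]
    record.meo_fraction = fracs[:done_steps]
    return record
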