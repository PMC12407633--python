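"""Two-ended dynamic instability with length regulation.

Each MT end is a two-state (growing/shrinking) telegraph process.  The
catastrophe (growth -> shrinking) rate increases linearly with MT length,

    lambda_cat(L) = max(lambda_min, lambda_tilde + gamma * (L - L0)),

while rescue rates are constant.  Growth consumes free tubulin from a
conserved pool; when the total growth demand of a step exceeds the free pool
(after crediting that step's shrinkage), every growing end is throttled by
the common factor free/demand.  The simulation advances on a fixed step
(1 s by default) with per-step switching probability 1 - exp(-rate * dt),
state switches evaluated first using start-of-step lengths, displacements
applied second.

The hot path operates on :class:`MicrotubuleArray`, a struct-of-arrays
container; :class:`~mtpolarity.core.Microtubule` dataclasses are converted
at the API boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DynamicsParams, EndState, Microtubule, Orientation

__all__ = [
    "TubulinPool",
    "LifetimeResult",
    "MicrotubuleArray",
    "catastrophe_rate",
    "switch_probability",
    "advance_end_states",
    "apply_polymerization",
    "simulate_lifetime",
    "simulate_lifetimes",
    "estimate_exit_probability",
    "sample_growth_run_lengths",
]


@dataclass
class TubulinPool:
    """Free/total tubulin in um of polymer equivalent.

    ``free + sum(MT lengths) == total`` at every step boundary.  An
    unlimited pool (``total = inf``) is used for isolated-MT studies.
    """

    free: float
    total: float

    @property
    def unlimited(self) -> bool:
        return not np.isfinite(self.total)


@dataclass
class LifetimeResult:
    """Outcome of one isolated-MT lifetime, nucleation to full catastrophe."""

    max_plus_excursion: float  # um past the nucleation position
    lifetime: float            # minutes


def catastrophe_rate(length, end: str, params: DynamicsParams):
    """Length-dependent catastrophe rate (1/min) for ``end`` ('plus'|'minus')."""
    length = np.asarray(length, dtype=float)
    if np.any(length < 0):
        raise ValueError("negative MT length")
    tilde = params.lambda_tilde_plus if end == "plus" else params.lambda_tilde_minus
    rate = np.maximum(params.lambda_min, tilde + params.gamma * (length - params.L0))
    return rate if rate.shape else float(rate)


def switch_probability(rate, dt: float):
    """Probability of at least one switching event in a step of ``dt`` minutes."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    rate = np.asarray(rate, dtype=float)
    if np.any(rate < 0):
        raise ValueError("negative rate")
    p = -np.expm1(-rate * dt)
    return p if p.shape else float(p)


class MicrotubuleArray:
    """Struct-of-arrays MT population for vectorized stepping.

    Ends are stored by geometric role (upper = tip-facing, lower =
    body-facing); per-end speed and rate constants are cached per slot from
    the orientation so the step loop needs no orientation branching.  The
    ``alive`` mask is False only transiently, between a full catastrophe or
    checkpoint failure and the same step's re-nucleation.
    """

    __slots__ = (
        "n", "ids", "is_meo", "lower", "upper", "up_grow", "lo_grow",
        "alive", "site_idx", "pending_checkpoint",
        "_vg_up", "_vs_up", "_vg_lo", "_vs_lo",
        "_lt_up", "_lt_lo", "_res_up", "_res_lo",
    )

    def __init__(self, n: int):
        self.n = n
        self.ids = np.arange(n, dtype=np.int64)
        self.is_meo = np.zeros(n, dtype=bool)
        self.lower = np.zeros(n, dtype=float)
        self.upper = np.zeros(n, dtype=float)
        self.up_grow = np.ones(n, dtype=bool)
        self.lo_grow = np.ones(n, dtype=bool)
        self.alive = np.ones(n, dtype=bool)
        self.site_idx = np.full(n, -1, dtype=np.int64)
        self.pending_checkpoint = np.zeros(n, dtype=bool)
        self._vg_up = np.zeros(n, dtype=float)
        self._vs_up = np.zeros(n, dtype=float)
        self._vg_lo = np.zeros(n, dtype=float)
        self._vs_lo = np.zeros(n, dtype=float)
        self._lt_up = np.zeros(n, dtype=float)
        self._lt_lo = np.zeros(n, dtype=float)
        self._res_up = np.zeros(n, dtype=float)
        self._res_lo = np.zeros(n, dtype=float)

    # -- orientation-dependent constant caches ------------------------------

    def bind_params(self, params: DynamicsParams) -> None:
        """(Re)compute the per-slot end constants from orientations."""
        meo = self.is_meo
        peo = ~meo
        # upper end is the plus end of a PEO MT, minus end of a MEO MT
        self._vg_up = np.where(peo, params.vg_plus, params.vg_minus)
        self._vs_up = np.where(peo, params.vs_plus, params.vs_minus)
        self._vg_lo = np.where(peo, params.vg_minus, params.vg_plus)
        self._vs_lo = np.where(peo, params.vs_minus, params.vs_plus)
        self._lt_up = np.where(peo, params.lambda_tilde_plus, params.lambda_tilde_minus)
        self._lt_lo = np.where(peo, params.lambda_tilde_minus, params.lambda_tilde_plus)
        self._res_up = np.where(peo, params.lambda_rescue_plus, params.lambda_rescue_minus)
        self._res_lo = np.where(peo, params.lambda_rescue_minus, params.lambda_rescue_plus)

    def rebind_slot(self, i: int, params: DynamicsParams) -> None:
        """Refresh the cached constants of one slot after re-orientation."""
        peo = not self.is_meo[i]
        self._vg_up[i] = params.vg_plus if peo else params.vg_minus
        self._vs_up[i] = params.vs_plus if peo else params.vs_minus
        self._vg_lo[i] = params.vg_minus if peo else params.vg_plus
        self._vs_lo[i] = params.vs_minus if peo else params.vs_plus
        self._lt_up[i] = params.lambda_tilde_plus if peo else params.lambda_tilde_minus
        self._lt_lo[i] = params.lambda_tilde_minus if peo else params.lambda_tilde_plus
        self._res_up[i] = params.lambda_rescue_plus if peo else params.lambda_rescue_minus
        self._res_lo[i] = params.lambda_rescue_minus if peo else params.lambda_rescue_plus

    # -- views --------------------------------------------------------------

    @property
    def length(self) -> np.ndarray:
        return self.upper - self.lower

    @property
    def plus_grow(self) -> np.ndarray:
        return np.where(self.is_meo, self.lo_grow, self.up_grow)

    @property
    def minus_grow(self) -> np.ndarray:
        return np.where(self.is_meo, self.up_grow, self.lo_grow)

    @property
    def plus_position(self) -> np.ndarray:
        return np.where(self.is_meo, self.lower, self.upper)

    def polymer_mass(self) -> float:
        if self.alive.all():
            return float(np.sum(self.upper - self.lower))
        return float(np.sum((self.upper - self.lower)[self.alive]))

    def crossing_mask(self, position: float) -> np.ndarray:
        """Alive MTs whose closed interval contains ``position``."""
        return self.alive & (self.lower <= position) & (position <= self.upper)

    # -- dataclass conversion ------------------------------------------------

    @classmethod
    def from_microtubules(
        cls, mts: list[Microtubule], params: DynamicsParams
    ) -> "MicrotubuleArray":
        arr = cls(len(mts))
        for i, mt in enumerate(mts):
            arr.ids[i] = mt.id
            meo = mt.orientation is Orientation.MEO
            arr.is_meo[i] = meo
            arr.lower[i] = mt.lower
            arr.upper[i] = mt.upper
            plus_g = mt.plus_state is EndState.GROWING
            minus_g = mt.minus_state is EndState.GROWING
            arr.up_grow[i] = minus_g if meo else plus_g
            arr.lo_grow[i] = plus_g if meo else minus_g
            arr.site_idx[i] = -1 if mt.nucleation_site is None else mt.nucleation_site
            arr.pending_checkpoint[i] = mt.pending_checkpoint
        arr.bind_params(params)
        return arr

    def to_microtubules(self) -> list[Microtubule]:
        out = []
        plus_grow = self.plus_grow
        minus_grow = self.minus_grow
        for i in range(self.n):
            if not self.alive[i]:
                continue
            out.append(
                Microtubule(
                    id=int(self.ids[i]),
                    orientation=Orientation.MEO if self.is_meo[i] else Orientation.PEO,
                    lower=float(self.lower[i]),
                    upper=float(self.upper[i]),
                    plus_state=EndState.GROWING if plus_grow[i] else EndState.SHRINKING,
                    minus_state=EndState.GROWING if minus_grow[i] else EndState.SHRINKING,
                    nucleation_site=int(self.site_idx[i]) if self.site_idx[i] >= 0 else None,
                    pending_checkpoint=bool(self.pending_checkpoint[i]),
                )
            )
        return out


def advance_end_states(
    arr: MicrotubuleArray,
    params: DynamicsParams,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """Flip end states in place using start-of-step lengths.

    Each end switches independently: growing ends catastrophe with
    probability ``1 - exp(-lambda_cat(L) dt)``, shrinking ends rescue with
    ``1 - exp(-lambda_res dt)``.  Draws a fixed-shape uniform block per call
    so the random stream is independent of the population's alive pattern.
    """
    u = rng.random((arr.n, 2))
    excess = params.gamma * (arr.length - params.L0)
    lam_up = np.maximum(params.lambda_min, arr._lt_up + excess)
    lam_lo = np.maximum(params.lambda_min, arr._lt_lo + excess)

    p_up = np.where(arr.up_grow, -np.expm1(-lam_up * dt), -np.expm1(-arr._res_up * dt))
    p_lo = np.where(arr.lo_grow, -np.expm1(-lam_lo * dt), -np.expm1(-arr._res_lo * dt))

    flip_up = arr.alive & (u[:, 0] < p_up)
    flip_lo = arr.alive & (u[:, 1] < p_lo)
    np.logical_xor(arr.up_grow, flip_up, out=arr.up_grow)
    np.logical_xor(arr.lo_grow, flip_lo, out=arr.lo_grow)


def apply_polymerization(
    arr: MicrotubuleArray,
    pool: TubulinPool,
    domain_length: float | None,
    params: DynamicsParams,
    dt: float,
) -> np.ndarray:
    """Displace ends, ration tubulin, clip at boundaries; return catastrophes.

    Shrinking ends retract at their shrink speed and release polymer to the
    pool.  Growing ends request ``vg * dt``; if the total request exceeds the
    free pool plus this step's guaranteed release, all growth increments are
    scaled by the common ratio free/demand.  Ends that would leave
    ``[0, domain_length]`` are set to the boundary and the unconsumed tubulin
    stays free.  MTs whose length would reach <= 0 are removed with exactly
    their pre-step length credited back to the pool.  Returns the slot
    indices of fully-catastrophed MTs.
    """
    alive = arr.alive
    length0 = arr.upper - arr.lower

    g_up = np.where(alive & arr.up_grow, arr._vg_up * dt, 0.0)
    g_lo = np.where(alive & arr.lo_grow, arr._vg_lo * dt, 0.0)
    s_up = np.where(alive & ~arr.up_grow, arr._vs_up * dt, 0.0)
    s_lo = np.where(alive & ~arr.lo_grow, arr._vs_lo * dt, 0.0)

    if not pool.unlimited:
        demand = float(np.sum(g_up) + np.sum(g_lo))
        if demand > 0.0:
            # shrinkage guaranteed back this step: a surviving MT releases its
            # full shrink displacement, a catastrophing one its whole length
            release_lb = float(np.sum(np.minimum(s_up + s_lo, length0)))
            avail = pool.free + release_lb
            if demand > avail:
                scale = avail / demand
                g_up *= scale
                g_lo *= scale

    new_up = arr.upper + g_up - s_up
    new_lo = arr.lower - g_lo + s_lo
    if domain_length is not None:
        np.minimum(new_up, domain_length, out=new_up)
        np.maximum(new_lo, 0.0, out=new_lo)

    new_len = new_up - new_lo
    dead = alive & (new_len <= 0.0)
    surv = alive & ~dead

    if not pool.unlimited:
        released = float(np.sum(length0[surv] - new_len[surv])) + float(
            np.sum(length0[dead])
        )
        pool.free += released
        if -1e-9 < pool.free < 0.0:  # float dust from the rationing ratio
            pool.free = 0.0

    arr.upper[surv] = new_up[surv]
    arr.lower[surv] = new_lo[surv]
    arr.alive[dead] = False
    arr.lower[dead] = 0.0
    arr.upper[dead] = 0.0
    return np.flatnonzero(dead)


# --- isolated-MT lifetime studies --------------------------------------------

def simulate_lifetimes(
    n: int,
    params: DynamicsParams,
    dt: float,
    rng: np.random.Generator,
    seed_length: float = 0.1,
    max_steps: int = 2_000_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n`` independent isolated MTs from nucleation to death.

    Each MT starts as a seed ``[0, seed_length]`` with both ends growing, in
    unbounded space with unlimited tubulin and the length-dependent
    catastrophe active.  Returns ``(max_plus_excursions, lifetimes_min)``
    where the excursion is the maximum displacement of the plus end past the
    nucleation position (the seed's lower coordinate at 0).

    Raises ``RuntimeError`` if any MT survives ``max_steps`` steps.
    """
    # plus end at `pos_plus` (starts at seed_length), minus end at `pos_minus`
    pos_plus = np.full(n, seed_length, dtype=float)
    pos_minus = np.zeros(n, dtype=float)
    plus_grow = np.ones(n, dtype=bool)
    minus_grow = np.ones(n, dtype=bool)
    max_exc = np.full(n, seed_length, dtype=float)
    lifetime = np.zeros(n, dtype=float)

    out_exc = np.empty(n, dtype=float)
    out_life = np.empty(n, dtype=float)
    idx = np.arange(n)  # positions in the output arrays

    step = 0
    t = 0.0
    while idx.size and step < max_steps:
        step += 1
        t += dt
        m = idx.size
        u = rng.random((m, 2))
        length = pos_plus - pos_minus
        excess = params.gamma * (length - params.L0)
        lam_p = np.maximum(params.lambda_min, params.lambda_tilde_plus + excess)
        lam_m = np.maximum(params.lambda_min, params.lambda_tilde_minus + excess)

        p_p = np.where(plus_grow, -np.expm1(-lam_p * dt), -np.expm1(-params.lambda_rescue_plus * dt))
        p_m = np.where(minus_grow, -np.expm1(-lam_m * dt), -np.expm1(-params.lambda_rescue_minus * dt))
        plus_grow ^= u[:, 0] < p_p
        minus_grow ^= u[:, 1] < p_m

        pos_plus += np.where(plus_grow, params.vg_plus, -params.vs_plus) * dt
        pos_minus += np.where(minus_grow, -params.vg_minus, params.vs_minus) * dt
        np.maximum(max_exc, pos_plus, out=max_exc)

        dead = pos_plus - pos_minus <= 0.0
        if dead.any():
            out_exc[idx[dead]] = max_exc[dead]
            out_life[idx[dead]] = t
            keep = ~dead
            idx = idx[keep]
            pos_plus = pos_plus[keep]
            pos_minus = pos_minus[keep]
            plus_grow = plus_grow[keep]
            minus_grow = minus_grow[keep]
            max_exc = max_exc[keep]

    if idx.size:
        raise RuntimeError(
            f"{idx.size} MT lifetimes exceeded the {max_steps}-step cap"
        )
    # excursion is measured from the nucleation position at 0
    np.maximum(out_exc, 0.0, out=out_exc)
    return out_exc, out_life


def simulate_lifetime(
    params: DynamicsParams,
    dt: float,
    rng: np.random.Generator,
    seed_length: float = 0.1,
    max_steps: int = 2_000_000,
) -> LifetimeResult:
    """Single isolated-MT lifetime; see :func:`simulate_lifetimes`."""
    exc, life = simulate_lifetimes(1, params, dt, rng, seed_length, max_steps)
    return LifetimeResult(max_plus_excursion=float(exc[0]), lifetime=float(life[0]))


def estimate_exit_probability(
    n_lifetimes: int,
    threshold: float,
    params: DynamicsParams,
    dt: float,
    rng: np.random.Generator,
    seed_length: float = 0.1,
) -> tuple[float, float]:
    """Fraction of lifetimes whose plus end ever grew ``threshold`` um past
    the nucleation position, with the binomial Monte-Carlo standard error."""
    if n_lifetimes < 1:
        raise ValueError("n_lifetimes must be >= 1")
    exc, _ = simulate_lifetimes(n_lifetimes, params, dt, rng, seed_length)
    p = float(np.mean(exc >= threshold))
    se = float(np.sqrt(p * (1.0 - p) / n_lifetimes))
    return p, se


def sample_growth_run_lengths(
    end: str,
    params: DynamicsParams,
    dt: float,
    rng: np.random.Generator,
    n_ends: int = 400,
    n_steps: int = 6000,
    length: float | None = None,
) -> np.ndarray:
    """Completed growth-run lengths (um) of independent plus or minus ends.

    Simulates ``n_ends`` telegraph end-state processes at a fixed MT length
    (default ``L0``, where the catastrophe rate equals its printed value) and
    returns ``vg * run duration`` for every growth excursion that both starts
    and ends inside the window.
    """
    if end == "plus":
        vg, lam_tilde, res = params.vg_plus, params.lambda_tilde_plus, params.lambda_rescue_plus
    elif end == "minus":
        vg, lam_tilde, res = params.vg_minus, params.lambda_tilde_minus, params.lambda_rescue_minus
    else:
        raise ValueError("end must be 'plus' or 'minus'")
    L = params.L0 if length is None else length
    lam = max(params.lambda_min, lam_tilde + params.gamma * (L - params.L0))
    p_cat = -np.expm1(-lam * dt)
    p_res = -np.expm1(-res * dt)

    growing = np.zeros(n_ends, dtype=bool)  # start shrinking: runs begin in-window
    run_steps = np.zeros(n_ends, dtype=np.int64)
    completed: list[np.ndarray] = []
    for _ in range(n_steps):
        u = rng.random(n_ends)
        flip = u < np.where(growing, p_cat, p_res)
        ended = growing & flip
        if ended.any():
            completed.append(run_steps[ended].copy())
            run_steps[ended] = 0
        growing ^= flip
        run_steps[growing] += 1
    if not completed:
        return np.empty(0)
    return np.concatenate(completed) * dt * vg
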