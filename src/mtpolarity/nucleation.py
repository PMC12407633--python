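"""Nucleation feedback, the stochastic checkpoint, and its analytic calibration.

Two mechanisms act on newly-nucleated MTs at a nucleation site:

* **Nucleation feedback** — the probability that a new MT nucleates MEO
  equals the MEO fraction of the MTs currently crossing the site (1/2 when
  the site is empty or feedback is off).

* **Checkpoint** — one growth step after nucleation, the new MT first fails
  outright with probability ``p_autofail``; otherwise ``n_s`` MTs are drawn
  with replacement from those crossing the site, and the new MT survives iff
  at least one drawn MT shares its orientation (an empty site counts as a
  match).

The analytic calculators express the checkpoint success probability for a
nucleation of a given orientation in a background polarity environment:

    P_success = P(dy >= 2) * (1 - P(autofail)) * (1 - p_opposite ** n_s)

where ``P(dy >= 2)`` is the baseline probability that a new plus end grows
at least 2 um past its nucleation site under the growth dynamics alone.
The two solvers invert this forward model for ``p_autofail`` (from the
control-environment MEO success rate, where the sampling factor is ~1) and
for ``n_s`` (from the mixed-environment MEO success rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import CheckpointEnvironment, Microtubule, Orientation

__all__ = [
    "LocalPolarityCount",
    "CheckpointParams",
    "meo_nucleation_probability",
    "nucleate",
    "checkpoint_decision",
    "simple_checkpoint_success",
    "proposed_checkpoint_success",
    "solve_autofail",
    "solve_ns",
    "calibrate",
]

#: Baseline probability that a new MT plus end grows >= 2 um past its
#: nucleation site (growth dynamics alone, no checkpoint).
BASELINE_EXIT_DEFAULT = 0.9


@dataclass(frozen=True)
class LocalPolarityCount:
    """PEO/MEO counts of the MTs crossing one nucleation site."""

    n_plus: int   # PEO
    n_minus: int  # MEO

    def __post_init__(self) -> None:
        if self.n_plus < 0 or self.n_minus < 0:
            raise ValueError("polarity counts must be non-negative")

    @property
    def n(self) -> int:
        return self.n_plus + self.n_minus


@dataclass(frozen=True)
class CheckpointParams:
    """Constants of the two-step checkpoint."""

    p_autofail: float = 0.25
    n_s: int = 6
    baseline_exit: float = BASELINE_EXIT_DEFAULT

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_autofail <= 1.0):
            raise ValueError("p_autofail must be in [0, 1]")
        if not (0.0 <= self.baseline_exit <= 1.0):
            raise ValueError("baseline_exit must be in [0, 1]")
        if self.n_s < 1:
            raise ValueError("n_s must be >= 1")


def meo_nucleation_probability(
    counts: LocalPolarityCount, feedback_on: bool
) -> float:
    """P(new MT nucleates MEO) from the local crossing composition."""
    if not feedback_on or counts.n == 0:
        return 0.5
    return counts.n_minus / counts.n


def nucleate(
    site_position: float,
    orientation: Orientation,
    seed_length: float,
    domain_length: float | None = None,
    mt_id: int = 0,
    site_index: int | None = None,
    pending_checkpoint: bool = False,
) -> Microtubule:
    """Seed a new MT at a nucleation site.

    The minus end sits at the site; the plus end sits one seed length above
    (PEO) or below (MEO).
    """
    if seed_length <= 0:
        raise ValueError("seed_length must be positive")
    if orientation is Orientation.PEO:
        lower, upper = site_position, site_position + seed_length
    else:
        lower, upper = site_position - seed_length, site_position
    if lower < 0 or (domain_length is not None and upper > domain_length):
        raise ValueError(
            f"seed [{lower}, {upper}] exits the domain for site {site_position}"
        )
    return Microtubule(
        id=mt_id,
        orientation=orientation,
        lower=lower,
        upper=upper,
        nucleation_site=site_index,
        pending_checkpoint=pending_checkpoint,
    )


def checkpoint_decision(
    new_mt_orientation: Orientation,
    crossing_orientations,
    params: CheckpointParams,
    rng: np.random.Generator,
) -> bool:
    """One stochastic checkpoint trial; True = pass.

    ``crossing_orientations`` is a boolean array (True = MEO) of the MTs
    crossing the site, excluding the new MT itself.  The baseline-growth
    factor is *not* applied here: in the spatial simulation it emerges from
    the growth dynamics.
    """
    if rng.random() < params.p_autofail:
        return False
    crossing = np.asarray(crossing_orientations, dtype=bool)
    if crossing.size == 0:
        return True  # behaves as if a parallel MT were observed
    draws = rng.integers(0, crossing.size, size=params.n_s)
    want_meo = new_mt_orientation is Orientation.MEO
    return bool(np.any(crossing[draws] == want_meo))


# --- analytic models and calibration -----------------------------------------

def simple_checkpoint_success(
    env: CheckpointEnvironment,
    direction: Orientation,
    n: int,
    baseline_exit: float = BASELINE_EXIT_DEFAULT,
) -> float:
    """Success probability if any one of ``n`` local MTs matching suffices."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return baseline_exit * (1.0 - env.p_opposite(direction) ** n)


def proposed_checkpoint_success(
    env: CheckpointEnvironment,
    direction: Orientation,
    params: CheckpointParams,
) -> float:
    """Two-step checkpoint: autofail, then sample ``n_s`` local MTs."""
    p_opp = env.p_opposite(direction)
    return (
        params.baseline_exit
        * (1.0 - params.p_autofail)
        * (1.0 - p_opp ** params.n_s)
    )


def solve_autofail(
    observed_success: float, baseline_exit: float
) -> tuple[float, float]:
    """Invert the forward model for ``p_autofail``.

    Uses the environment where nearly all local MTs match the nucleation, so
    the sampling factor is ~1 and ``observed = baseline * (1 - p_autofail)``.
    Returns ``(raw, rounded_to_nearest_0.05)``.
    """
    if not (0.0 < observed_success <= baseline_exit):
        raise ValueError(
            "observed success must be in (0, baseline_exit]"
        )
    raw = 1.0 - observed_success / baseline_exit
    return raw, round(raw / 0.05) * 0.05


def solve_ns(
    observed_success: float,
    baseline_exit: float,
    p_autofail: float,
    p_opposite: float,
) -> tuple[float, int]:
    """Invert the forward model for the checkpoint sample size ``n_s``.

    Solves ``observed = baseline * (1 - autofail) * (1 - p_opposite**ns)``
    for real ``ns``.  The returned integer is the one whose *forward* success
    probability is closest to the observed rate (the success curve is concave
    in ``ns``, so this can differ from arithmetic rounding of the real root).
    """
    if not (0.0 < p_opposite < 1.0):
        raise ValueError("p_opposite must be in (0, 1)")
    ceiling = baseline_exit * (1.0 - p_autofail)
    if not (0.0 < observed_success < ceiling):
        raise ValueError(
            f"observed success must be in (0, {ceiling}) for these inputs"
        )
    raw = float(np.log(1.0 - observed_success / ceiling) / np.log(p_opposite))

    def forward(k: int) -> float:
        return ceiling * (1.0 - p_opposite**k)

    lo = max(1, int(np.floor(raw)))
    hi = max(1, int(np.ceil(raw)))
    best = min((lo, hi), key=lambda k: abs(forward(k) - observed_success))
    return raw, best


def calibrate(
    ctrl_meo_success: float,
    mixed_meo_success: float,
    baseline_exit: float = BASELINE_EXIT_DEFAULT,
    mixed_p_opposite: float = 0.5,
) -> dict:
    """Full checkpoint calibration from two observed MEO success rates.

    First solves for the automatic-failure probability from the control
    environment (where sampling almost surely finds a parallel MT), then for
    the sample size from the mixed environment, using the rounded autofail.
    """
    af_raw, af_rounded = solve_autofail(ctrl_meo_success, baseline_exit)
    ns_raw, ns_rounded = solve_ns(
        mixed_meo_success, baseline_exit, af_rounded, mixed_p_opposite
    )
    return {
        "p_autofail": {"raw": af_raw, "rounded": af_rounded},
        "n_s": {"raw": ns_raw, "rounded": ns_rounded},
        "baseline_exit": baseline_exit,
    }
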