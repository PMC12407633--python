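"""Observables of the polarity simulations.

Global and per-site MEO polarity, cross-section occupancy, the spatial
phase-separation interface between MEO- and PEO-majority nucleation sites,
and first-passage statistics for fully-biased polarity states (all MTs
sharing one orientation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import SimulationRecord

__all__ = [
    "PolarityTimeSeries",
    "BiasEventTimes",
    "meo_fraction",
    "site_polarity_profile",
    "polarity_bin",
    "cross_section_counts",
    "time_averaged_cross_section",
    "bias_event_times",
    "phase_interface",
    "ensemble_summary",
]

#: Fig-style 20%-wide polarity bins.
POLARITY_BINS = ("0-20", "20-40", "40-60", "60-80", "80-100")


@dataclass
class PolarityTimeSeries:
    """MEO fraction of the whole array over time."""

    times_s: np.ndarray
    meo_fraction: np.ndarray

    @classmethod
    def from_record(cls, record: SimulationRecord) -> "PolarityTimeSeries":
        return cls(record.step_times_s, record.meo_fraction)


@dataclass
class BiasEventTimes:
    """First-passage times around a fully-biased polarity state (seconds)."""

    hit_time: float | None = None
    depart_time: float | None = None
    return_time: float | None = None
    bias_side: str | None = None  # "MEO_FULL" | "PEO_FULL"


def meo_fraction(is_meo) -> float:
    """Fraction of MTs oriented minus-end-out."""
    arr = np.asarray(is_meo, dtype=bool)
    if arr.size == 0:
        raise ValueError("no MTs")
    return float(np.mean(arr))


def polarity_bin(fraction: float) -> str:
    """20%-wide bin label for a MEO fraction."""
    i = min(4, int(fraction * 100) // 20)
    return POLARITY_BINS[i]


def site_polarity_profile(
    lower, upper, is_meo, sites
) -> list[dict]:
    """Per-site MEO fraction over the crossing MTs (None when none cross)."""
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    is_meo = np.asarray(is_meo, dtype=bool)
    out = []
    for s in sites:
        cross = (lower <= s) & (s <= upper)
        n = int(np.count_nonzero(cross))
        if n == 0:
            out.append({"site": float(s), "n": 0, "meo_fraction": None, "bin": None})
        else:
            f = float(np.mean(is_meo[cross]))
            out.append(
                {"site": float(s), "n": n, "meo_fraction": f, "bin": polarity_bin(f)}
            )
    return out


def cross_section_counts(
    lower, upper, domain_length: float, grid_spacing: float = 1.0
) -> tuple[float, np.ndarray, np.ndarray]:
    """MTs overlapping each grid cross-section; returns (mean, positions, counts)."""
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    xs = np.arange(grid_spacing, domain_length, grid_spacing)
    counts = np.count_nonzero(
        (lower[None, :] <= xs[:, None]) & (xs[:, None] <= upper[None, :]), axis=1
    )
    return float(np.mean(counts)), xs, counts


def time_averaged_cross_section(
    record: SimulationRecord,
    domain_length: float,
    grid_spacing: float = 1.0,
    burn_in_s: float = 0.0,
) -> float:
    """Mean cross-section count averaged over snapshots after ``burn_in_s``."""
    means = [
        cross_section_counts(lo, up, domain_length, grid_spacing)[0]
        for t, lo, up in zip(
            record.snapshot_times_s, record.snapshot_lower, record.snapshot_upper
        )
        if t >= burn_in_s
    ]
    if not means:
        raise ValueError("no snapshots after the burn-in")
    return float(np.mean(means))


def bias_event_times(
    series: PolarityTimeSeries, grace_steps: int = 1
) -> BiasEventTimes:
    """Hit/depart/return times for the first fully-biased polarity episode.

    The hit is the first sample with MEO fraction exactly 0 or 1.  A
    departure is the first later excursion away from {0, 1} lasting more
    than ``grace_steps`` consecutive samples (the checkpoint removes
    wrong-way nucleations after a single step, so one-sample excursions are
    forgiven by default).  The return is the first sample after the
    departure equal to the original biased value again.
    """
    if grace_steps < 0:
        raise ValueError("grace_steps must be >= 0")
    f = np.asarray(series.meo_fraction, dtype=float)
    t = np.asarray(series.times_s, dtype=float)
    ev = BiasEventTimes()

    extreme = (f == 0.0) | (f == 1.0)
    hits = np.flatnonzero(extreme)
    if hits.size == 0:
        return ev
    h = int(hits[0])
    ev.hit_time = float(t[h])
    ev.bias_side = "MEO_FULL" if f[h] == 1.0 else "PEO_FULL"
    bias_value = f[h]

    away = ~extreme
    i = h + 1
    n = f.size
    depart_idx = None
    while i < n:
        if away[i]:
            j = i
            while j < n and away[j]:
                j += 1
            if j - i > grace_steps:
                depart_idx = i
                break
            i = j
        else:
            i += 1
    if depart_idx is None:
        return ev
    ev.depart_time = float(t[depart_idx])

    back = np.flatnonzero(f[depart_idx + 1:] == bias_value)
    if back.size:
        ev.return_time = float(t[depart_idx + 1 + int(back[0])])
    return ev


def phase_interface(profile) -> tuple[bool, int | None, int]:
    """Classify the ordered per-site profile into MEO/PEO blocks.

    ``profile`` is an iterable of per-site MEO fractions ordered from cell
    body to tip; ``None`` entries (sites nobody crosses) are ignored.  A
    site is MEO-majority when its fraction exceeds 0.5 (ties count PEO).
    The profile is phase-separated when the MEO-majority sites form a
    (possibly empty) contiguous block nearest the cell body followed only by
    PEO-majority sites; the interface index is then the size of the MEO
    block.  ``adjacency_mismatches`` counts neighbour pairs ordered
    PEO-below/MEO-above, which a separated profile has none of.
    """
    fractions = [f for f in profile if f is not None]
    meo = [f > 0.5 for f in fractions]
    mismatches = sum(
        1 for a, b in zip(meo, meo[1:]) if (not a) and b
    )
    separated = mismatches == 0
    interface = sum(meo) if separated else None
    return separated, interface, mismatches


def _empirical_cdf(values: list[float]) -> dict:
    if not values:
        return {"times_s": [], "cdf": []}
    xs = np.sort(np.asarray(values, dtype=float))
    return {
        "times_s": xs.tolist(),
        "cdf": (np.arange(1, xs.size + 1) / xs.size).tolist(),
    }


def ensemble_summary(
    records: list[SimulationRecord],
    grace_steps: int = 1,
    profile_times_s: tuple[float, ...] = (),
) -> dict:
    """Ensemble statistics across replicate runs.

    Returns per-time mean and interquartile range of the MEO fraction
    (on the common time grid of the shortest run), the end-of-run polarity
    histogram, empirical CDFs and achievement percentages of the
    hit/depart/return events, and per-site polarity-bin tallies at the
    requested snapshot times.
    """
    if not records:
        raise ValueError("at least one record required")
    n_common = min(r.meo_fraction.size for r in records)
    mat = np.stack([r.meo_fraction[:n_common] for r in records])
    times = records[0].step_times_s[:n_common]
    q25, q75 = np.percentile(mat, [25, 75], axis=0)

    finals = mat[:, -1] if n_common else np.array([])
    hist, edges = np.histogram(finals, bins=np.linspace(0, 1, 11))

    events = [
        bias_event_times(PolarityTimeSeries.from_record(r), grace_steps)
        for r in records
    ]
    n = len(records)
    cdfs = {}
    for name in ("hit", "depart", "return"):
        vals = [getattr(e, f"{name}_time") for e in events]
        achieved = [v for v in vals if v is not None]
        cdfs[name] = {
            "percent_achieved": 100.0 * len(achieved) / n,
            **_empirical_cdf(achieved),
        }

    profiles = {}
    for t_req in profile_times_s:
        tallies = {b: [0] * len(records[0].sites) for b in POLARITY_BINS}
        for r in records:
            snap_t = np.asarray(r.snapshot_times_s)
            if snap_t.size == 0:
                continue
            k = int(np.argmin(np.abs(snap_t - t_req)))
            prof = site_polarity_profile(
                r.snapshot_lower[k], r.snapshot_upper[k], r.snapshot_is_meo[k],
                r.sites,
            )
            for j, entry in enumerate(prof):
                if entry["bin"] is not None:
                    tallies[entry["bin"]][j] += 1
        profiles[t_req] = tallies

    return {
        "n_runs": n,
        "times_s": times.tolist(),
        "mean_meo": mat.mean(axis=0).tolist(),
        "iqr_low": q25.tolist(),
        "iqr_high": q75.tolist(),
        "final_histogram": {
            "bin_edges": edges.tolist(),
            "counts": hist.tolist(),
        },
        "events": cdfs,
        "site_polarity_bins": profiles,
    }
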