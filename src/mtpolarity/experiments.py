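"""End-to-end experiment pipelines and reproducible run manifests.

Each pipeline runs the model at the study conditions (or a user-scaled
replication), computes its summary quantities, and can write data + summary
to an artifact directory traceable through a :class:`RunManifest`.
Per-run seeds are a fixed deterministic function of the master seed and the
run index, so any experiment re-run from its manifest reproduces identical
outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    CTRL_ENVIRONMENT,
    CheckpointEnvironment,
    DomainConfig,
    DynamicsParams,
    MechanismConfig,
    default_params_for,
    long_domain,
    short_domain,
)
from .dynamics import simulate_lifetimes
from .engine import RunOptions, SimulationRecord, run
from .metrics import (
    PolarityTimeSeries,
    bias_event_times,
    ensemble_summary,
    time_averaged_cross_section,
)
from .nucleation import BASELINE_EXIT_DEFAULT, calibrate

__all__ = [
    "RunManifest",
    "per_run_seed",
    "run_ensemble",
    "MECHANISM_COMBOS",
    "baseline_exit_experiment",
    "checkpoint_calibration_experiment",
    "checkpoint_validation_experiment",
    "cross_section_experiment",
    "bistability_timing_experiment",
    "domain_grid_experiment",
    "bias_event_cdf_experiment",
    "reproduce",
    "EXPERIMENTS",
    "snapshots_to_dataframe",
    "events_to_dataframe",
]

#: The four mechanism scenarios, in the order they are reported.
MECHANISM_COMBOS: dict[str, MechanismConfig] = {
    "neither": MechanismConfig(feedback_on=False, checkpoint_on=False),
    "checkpoint": MechanismConfig(feedback_on=False, checkpoint_on=True),
    "feedback": MechanismConfig(feedback_on=True, checkpoint_on=False),
    "both": MechanismConfig(feedback_on=True, checkpoint_on=True),
}

_PRESETS = {"short": short_domain, "long": long_domain}


def per_run_seed(master_seed: int, run_index: int) -> int:
    """Deterministic child seed (< 2^31) for one replicate."""
    return int((int(master_seed) * 1_000_003 + 7919 * int(run_index) + 1) % (2**31))


@dataclass
class RunManifest:
    """Everything needed to reproduce an experiment byte-for-byte."""

    experiment: str
    master_seed: int
    per_run_seeds: list[int]
    configuration: dict
    code_version: str = __version__
    created_unix: float = field(default_factory=time.time)

    def write(self, out_dir: Path) -> Path:
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2, default=str))
        return path


def run_ensemble(
    domain: DomainConfig,
    params: DynamicsParams,
    mech: MechanismConfig,
    master_seed: int,
    n_runs: int,
    duration: float | None = None,
    options: RunOptions | None = None,
) -> list[SimulationRecord]:
    return [
        run(domain, params, mech, per_run_seed(master_seed, i), duration, options)
        for i in range(n_runs)
    ]


# --- pipelines ----------------------------------------------------------------

def baseline_exit_experiment(
    seed: int,
    n_lifetimes: int = 1800,
    threshold_um: float = 2.0,
    dt_s: float = 1.0,
) -> dict:
    """P(dy >= threshold) from isolated-MT lifetimes, with lifetime stats."""
    rng = np.random.default_rng(per_run_seed(seed, 0))
    params = DynamicsParams(T_tot=np.inf)
    exc, life = simulate_lifetimes(n_lifetimes, params, dt_s / 60.0, rng)
    p = float(np.mean(exc >= threshold_um))
    return {
        "n_lifetimes": n_lifetimes,
        "threshold_um": threshold_um,
        "exit_probability": p,
        "mc_stderr": float(np.sqrt(p * (1 - p) / n_lifetimes)),
        "mean_lifetime_min": float(np.mean(life)),
        "mean_max_excursion_um": float(np.mean(exc)),
        "excursions_um": exc,
        "lifetimes_min": life,
    }


def checkpoint_calibration_experiment(
    ctrl_meo_success: float = 0.66,
    mixed_meo_success: float = 0.66,
    baseline_exit: float = BASELINE_EXIT_DEFAULT,
    mixed_p_opposite: float = 0.5,
) -> dict:
    """Closed-form autofail / sample-size calibration from the observed rates."""
    return calibrate(
        ctrl_meo_success, mixed_meo_success, baseline_exit, mixed_p_opposite
    )


def checkpoint_validation_experiment(
    seed: int,
    min_trials: int = 500,
    environment: CheckpointEnvironment = CTRL_ENVIRONMENT,
    max_days: float = 6.0,
    n_replicates: int = 1,
) -> dict:
    """Checkpoint success rates measured inside the spatial simulation.

    Long domain with the checkpoint evaluated for every nucleation while the
    array composition is pinned at the environment's polarity (probe mode,
    see :class:`~mtpolarity.engine.RunOptions`); each replicate runs until
    at least ``min_trials`` PEO and MEO trials are resolved, and trials are
    pooled across replicates.  Success requires both passing the checkpoint
    and growing 2 um past the nucleation site.
    """
    domain = long_domain(initial_meo_fraction=environment.p_pre_meo)
    params = default_params_for(domain)
    mech = MechanismConfig(feedback_on=False, checkpoint_on=True)
    options = RunOptions(
        track_exit=True,
        pinned_environment=environment,
        checkpoint_probe=True,
        stop_after_trials=min_trials,
        record_snapshots=True,
    )
    records = [
        run(domain, params, mech, per_run_seed(seed, i),
            duration=max_days * 86400.0, options=options)
        for i in range(n_replicates)
    ]
    pooled: dict[str, dict] = {}
    for label, meo in (("PEO", False), ("MEO", True)):
        n = sum(1 for r in records for t in r.trials if t[0] == meo)
        succ = sum(1 for r in records for t in r.trials if t[0] == meo and t[2])
        rate = succ / n if n else float("nan")
        pooled[label] = {
            "n": n,
            "successes": succ,
            "rate": rate,
            "stderr": float(np.sqrt(rate * (1 - rate) / n)) if n else float("nan"),
        }
    return {
        "environment": {"p_pre_peo": environment.p_pre_peo,
                        "p_pre_meo": environment.p_pre_meo},
        "n_replicates": n_replicates,
        "simulated_seconds": float(
            sum(r.step_times_s[-1] for r in records)
        ),
        "mean_array_meo_fraction": float(
            np.mean([np.mean(r.meo_fraction) for r in records])
        ),
        "success_rates": pooled,
    }


def cross_section_experiment(
    seed: int,
    preset: str,
    days: float = 1.0,
    burn_in_hours: float = 6.0,
    grid_spacing_um: float = 1.0,
    mechanism: str = "neither",
    n_runs: int = 3,
) -> dict:
    """Time-averaged mean cross-section MT count at steady state.

    Defaults to the bare set-up (no nucleation mechanisms): the occupancy is
    then an intrinsic, stable property of the geometry and growth dynamics.
    With the checkpoint enabled it instead depends on the polarity state the
    run wanders through (mixed-polarity episodes sustain extra turnover and
    run a couple of MTs lighter), so mechanism-on estimates average a few
    replicates over their post-burn-in windows.
    """
    domain = _PRESETS[preset]()
    params = default_params_for(domain)
    records = [
        run(domain, params, MECHANISM_COMBOS[mechanism], per_run_seed(seed, i),
            duration=days * 86400.0)
        for i in range(n_runs)
    ]
    per_run = [
        time_averaged_cross_section(
            r, domain.length, grid_spacing_um, burn_in_s=burn_in_hours * 3600.0
        )
        for r in records
    ]
    return {
        "preset": preset,
        "mechanism": mechanism,
        "days": days,
        "burn_in_hours": burn_in_hours,
        "n_runs": n_runs,
        "per_run_counts": per_run,
        "mean_cross_section_count": float(np.mean(per_run)),
        "records": records,
    }


def bistability_timing_experiment(
    seed: int,
    preset: str,
    n_runs: int,
    max_duration_s: float,
    mechanisms: tuple[str, ...] = ("feedback", "both"),
) -> dict:
    """First times to full polarity bias under feedback-enabled scenarios.

    Splits ``n_runs`` evenly over the mechanism combinations, stops each run
    at its first fully-biased step, and reports every hit time (``None`` for
    runs that never became fully biased within the duration cap).
    """
    domain = _PRESETS[preset]()
    params = default_params_for(domain)
    options = RunOptions(stop_when_fully_biased=True, record_snapshots=False)
    hit_times: list[float | None] = []
    per_mech: dict[str, list[float | None]] = {m: [] for m in mechanisms}
    idx = 0
    for i in range(n_runs):
        mech_name = mechanisms[i % len(mechanisms)]
        record = run(
            domain, params, MECHANISM_COMBOS[mech_name],
            per_run_seed(seed, idx), duration=max_duration_s, options=options,
        )
        idx += 1
        f = record.meo_fraction
        hit = float(record.step_times_s[-1]) if f.size and f[-1] in (0.0, 1.0) else None
        hit_times.append(hit)
        per_mech[mech_name].append(hit)
    achieved = [t for t in hit_times if t is not None]
    return {
        "preset": preset,
        "n_runs": n_runs,
        "mechanisms": list(mechanisms),
        "hit_times_s": hit_times,
        "per_mechanism": per_mech,
        "all_achieved": len(achieved) == n_runs,
        "max_hit_time_s": max(achieved) if achieved else None,
    }


def domain_grid_experiment(
    seed: int,
    preset: str,
    n_runs: int = 100,
    days: float = 5.0,
    mechanisms: tuple[str, ...] = tuple(MECHANISM_COMBOS),
    profile_times_s: tuple[float, ...] = (3 * 3600.0,),
) -> dict:
    """All mechanism combinations on one domain; ensemble summaries per combo."""
    domain = _PRESETS[preset]()
    params = default_params_for(domain)
    out = {"preset": preset, "n_runs": n_runs, "days": days, "scenarios": {}}
    for k, name in enumerate(mechanisms):
        records = [
            run(domain, params, MECHANISM_COMBOS[name],
                per_run_seed(seed, k * n_runs + i), duration=days * 86400.0)
            for i in range(n_runs)
        ]
        out["scenarios"][name] = {
            "summary": ensemble_summary(
                records, profile_times_s=profile_times_s
            ),
            "records": records,
        }
    return out


def bias_event_cdf_experiment(
    seed: int,
    n_runs: int = 100,
    days: float = 5.0,
    mechanisms: tuple[str, ...] = ("feedback", "both"),
) -> dict:
    """Hit/depart/return CDFs for the long domain (feedback-enabled combos)."""
    domain = long_domain()
    params = default_params_for(domain)
    out = {"n_runs": n_runs, "days": days, "scenarios": {}}
    for k, name in enumerate(mechanisms):
        records = [
            run(domain, params, MECHANISM_COMBOS[name],
                per_run_seed(seed, k * n_runs + i), duration=days * 86400.0)
            for i in range(n_runs)
        ]
        events = [
            bias_event_times(PolarityTimeSeries.from_record(r)) for r in records
        ]
        out["scenarios"][name] = {
            "summary": ensemble_summary(records),
            "hit_times_s": [e.hit_time for e in events],
            "depart_times_s": [e.depart_time for e in events],
            "return_times_s": [e.return_time for e in events],
        }
    return out


# --- CSV export ---------------------------------------------------------------

def snapshots_to_dataframe(record: SimulationRecord) -> pd.DataFrame:
    rows = []
    for t, lo, up, meo, pg, mg in zip(
        record.snapshot_times_s, record.snapshot_lower, record.snapshot_upper,
        record.snapshot_is_meo, record.snapshot_plus_grow,
        record.snapshot_minus_grow,
    ):
        for i in range(lo.size):
            rows.append(
                (t, i, "MEO" if meo[i] else "PEO", lo[i], up[i],
                 "growing" if pg[i] else "shrinking",
                 "growing" if mg[i] else "shrinking")
            )
    return pd.DataFrame(
        rows,
        columns=["time_s", "mt_id", "orientation", "lower_um", "upper_um",
                 "plus_state", "minus_state"],
    )


def events_to_dataframe(record: SimulationRecord) -> pd.DataFrame:
    rows = [
        (t, "nucleation", record.sites[site], "MEO" if meo else "PEO",
         f"crossing_peo={n_peo};crossing_meo={n_meo};cause={cause}")
        for (t, site, meo, n_peo, n_meo, cause) in record.nucleations
    ] + [
        (t, "checkpoint", record.sites[site], "MEO" if meo else "PEO",
         ("autofail" if autof else ("pass" if passed else "sample_fail")))
        for (t, site, meo, autof, passed) in record.checkpoints
    ]
    df = pd.DataFrame(
        rows, columns=["time_s", "event", "site_um", "orientation", "detail"]
    )
    return df.sort_values("time_s", kind="stable").reset_index(drop=True)


# --- reproduce ----------------------------------------------------------------

def _strip_records(obj):
    """Drop in-memory records / large arrays before JSON serialization."""
    if isinstance(obj, dict):
        return {
            k: _strip_records(v)
            for k, v in obj.items()
            if k not in ("record", "records", "excursions_um", "lifetimes_min")
        }
    if isinstance(obj, (list, tuple)):
        return [_strip_records(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


EXPERIMENTS = (
    "baseline_exit",
    "checkpoint_calibration",
    "short_domain_grid",
    "long_domain_grid",
    "checkpoint_validation",
    "bias_event_cdfs",
)


def reproduce(
    experiment_id: str,
    out_dir,
    seed: int = 1,
    overrides: dict | None = None,
) -> Path:
    """Run one named experiment end-to-end and write its artifacts.

    ``overrides`` scale the replication (e.g. ``{"n_runs": 4, "days": 0.5}``)
    or adjust experiment parameters; every output directory contains a
    ``manifest.json`` and a ``summary.json``.
    """
    overrides = dict(overrides or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if experiment_id == "baseline_exit":
        result = baseline_exit_experiment(seed, **overrides)
        pd.DataFrame(
            {
                "replicate": np.arange(result["n_lifetimes"]),
                "max_plus_excursion_um": result["excursions_um"],
                "lifetime_min": result["lifetimes_min"],
            }
        ).to_csv(out / "lifetimes.csv", index=False)
        n_runs = 1
    elif experiment_id == "checkpoint_calibration":
        result = checkpoint_calibration_experiment(**overrides)
        n_runs = 0
    elif experiment_id in ("short_domain_grid", "long_domain_grid"):
        preset = "short" if experiment_id.startswith("short") else "long"
        overrides.setdefault("n_runs", 100)
        overrides.setdefault("days", 5.0)
        result = domain_grid_experiment(seed, preset, **overrides)
        for name, scen in result["scenarios"].items():
            for i, rec in enumerate(scen["records"]):
                pd.DataFrame(
                    {"time_s": rec.step_times_s, "meo_fraction": rec.meo_fraction}
                ).to_csv(out / f"{name}_run{i:03d}_polarity.csv", index=False)
        n_runs = overrides["n_runs"] * len(result["scenarios"])
    elif experiment_id == "checkpoint_validation":
        result = checkpoint_validation_experiment(seed, **overrides)
        n_runs = 1
    elif experiment_id == "bias_event_cdfs":
        overrides.setdefault("n_runs", 100)
        overrides.setdefault("days", 5.0)
        result = bias_event_cdf_experiment(seed, **overrides)
        n_runs = overrides["n_runs"] * len(result["scenarios"])
    else:
        raise ValueError(
            f"unknown experiment {experiment_id!r}; choose from {EXPERIMENTS}"
        )

    manifest = RunManifest(
        experiment=experiment_id,
        master_seed=seed,
        per_run_seeds=[per_run_seed(seed, i) for i in range(n_runs)],
        configuration={"overrides": {k: str(v) for k, v in overrides.items()}},
    )
    manifest.write(out)
    (out / "summary.json").write_text(
        json.dumps(_strip_records(result), indent=2, default=float)
    )
    return out
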