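"""Domain model for the neurite microtubule-polarity simulator.

The model lives on a 1-D axis oriented along the neurite: position 0 is the
cell body, position ``length`` is the neurite tip.  Microtubules (MTs) are
closed intervals ``[lower, upper]`` on that axis with an orientation flag
recording where the plus end sits: plus-end-out (PEO) MTs have their plus end
at ``upper`` (facing the tip), minus-end-out (MEO) MTs have it at ``lower``
(facing the cell body).  New MTs are seeded at fixed nucleation locations
spaced 10 um apart.

All positions are in micrometers, all times internally in minutes (the
printed rates are per minute); the simulation step ``dt`` is one second by
default.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field, asdict, replace

import yaml

__all__ = [
    "EndState",
    "Orientation",
    "Microtubule",
    "DynamicsParams",
    "DomainConfig",
    "MechanismConfig",
    "CheckpointEnvironment",
    "ConfigError",
    "validate_config",
    "short_domain",
    "long_domain",
    "config_to_yaml",
    "config_from_yaml",
    "CTRL_ENVIRONMENT",
    "PAT_ENVIRONMENT",
]

SITE_SPACING_UM = 10.0


class EndState(enum.Enum):
    """Dynamic state of one microtubule end."""

    GROWING = "growing"
    SHRINKING = "shrinking"


class Orientation(enum.Enum):
    """PEO: plus end is the upper (tip-facing) end; MEO: plus end is lower."""

    PEO = "PEO"
    MEO = "MEO"

    @property
    def opposite(self) -> "Orientation":
        return Orientation.MEO if self is Orientation.PEO else Orientation.PEO


@dataclass
class Microtubule:
    """A single MT as an oriented closed interval on the neurite axis."""

    id: int
    orientation: Orientation
    lower: float
    upper: float
    plus_state: EndState = EndState.GROWING
    minus_state: EndState = EndState.GROWING
    nucleation_site: int | None = None
    pending_checkpoint: bool = False

    @property
    def length(self) -> float:
        return self.upper - self.lower

    @property
    def plus_position(self) -> float:
        return self.upper if self.orientation is Orientation.PEO else self.lower

    @property
    def minus_position(self) -> float:
        return self.lower if self.orientation is Orientation.PEO else self.upper

    def crosses(self, position: float) -> bool:
        """Inclusive at both endpoints."""
        return self.lower <= position <= self.upper


@dataclass
class DynamicsParams:
    """Rates and speeds of the two-ended dynamic-instability model.

    Defaults are the experimentally-informed constants for *Drosophila*
    dendrites: growth/shrink speeds per end, catastrophe rates at the
    characteristic length ``L0``, rescue rates, the slope ``gamma`` of the
    length-dependent catastrophe rate, its floor ``lambda_min``, and the
    conserved tubulin budget ``T_tot`` (in um of polymer equivalent).

    The catastrophe rate of each end at MT length L is
    ``max(lambda_min, lambda_tilde_end + gamma * (L - L0))``.
    """

    vg_plus: float = 6.0          # um/min
    vg_minus: float = 0.75        # um/min
    vs_plus: float = 6.0          # um/min
    vs_minus: float = 3.5         # um/min
    lambda_tilde_plus: float = 0.5    # 1/min, catastrophe at L0
    lambda_tilde_minus: float = 0.25  # 1/min
    lambda_rescue_plus: float = 0.2811   # 1/min
    lambda_rescue_minus: float = 0.67    # 1/min
    gamma: float = 0.01           # (um min)^-1
    lambda_min: float = 0.05      # 1/min
    L0: float = 20.0              # um
    T_tot: float = 1000.0         # um of polymer-equivalent tubulin (50/MT)

    def with_total_tubulin(self, t_tot: float) -> "DynamicsParams":
        return replace(self, T_tot=t_tot)


@dataclass
class DomainConfig:
    """Geometry, population and run-control settings for one simulation."""

    length: float                       # um
    nucleation_sites: tuple[float, ...]
    n_mts: int
    initial_length: float = 15.0        # um
    initial_meo_fraction: float = 0.5
    seed_length: float = 0.1            # um
    dt: float = 1.0                     # seconds
    duration: float = 5 * 24 * 3600.0   # seconds
    record_interval: float = 60.0       # seconds

    def __post_init__(self) -> None:
        self.nucleation_sites = tuple(float(s) for s in self.nucleation_sites)

    @property
    def dt_min(self) -> float:
        """Step length in minutes (rates are per minute)."""
        return self.dt / 60.0


@dataclass
class MechanismConfig:
    """Switches and constants for the two nucleation mechanisms."""

    feedback_on: bool = False
    checkpoint_on: bool = False
    p_autofail: float = 0.25
    n_s: int = 6


@dataclass(frozen=True)
class CheckpointEnvironment:
    """Background polarity composition used by the analytic checkpoint model.

    ``p_pre_peo`` / ``p_pre_meo`` are the probabilities that a local
    pre-existing MT is PEO / MEO; they must sum to one.
    """

    p_pre_peo: float
    p_pre_meo: float

    def p_opposite(self, direction: Orientation) -> float:
        """Probability that a pre-existing MT opposes ``direction``."""
        if direction is Orientation.PEO:
            return self.p_pre_meo
        return self.p_pre_peo


#: Control environment: ~90% of pre-existing MTs are MEO.
CTRL_ENVIRONMENT = CheckpointEnvironment(p_pre_peo=0.10, p_pre_meo=0.90)
#: Patronin-knockdown (mixed) environment: ~50% MEO.
PAT_ENVIRONMENT = CheckpointEnvironment(p_pre_peo=0.50, p_pre_meo=0.50)


#: Default tubulin budget per MT (um of polymer equivalent).  Generous enough
#: that the pool caps runaway polymer rather than throttling routine growth:
#: with it, the array reproduces the expected steady-state cross-section
#: occupancy (~9 MTs short domain, ~13 long) and can assemble the 15 um
#: initial array outright.
TUBULIN_PER_MT_UM = 50.0


def _default_total_tubulin(n_mts: int, initial_length: float) -> float:
    return n_mts * TUBULIN_PER_MT_UM


def short_domain(**overrides) -> DomainConfig:
    """20 um domain, one nucleation site at 10 um, 20 MTs."""
    cfg = DomainConfig(length=20.0, nucleation_sites=(10.0,), n_mts=20)
    return replace(cfg, **overrides) if overrides else cfg


def long_domain(**overrides) -> DomainConfig:
    """70 um domain, six sites at 10..60 um, 60 MTs."""
    cfg = DomainConfig(
        length=70.0,
        nucleation_sites=(10.0, 20.0, 30.0, 40.0, 50.0, 60.0),
        n_mts=60,
    )
    return replace(cfg, **overrides) if overrides else cfg


def default_params_for(domain: DomainConfig, **overrides) -> DynamicsParams:
    """Dynamics defaults with the tubulin budget sized to the domain."""
    params = DynamicsParams(
        T_tot=_default_total_tubulin(domain.n_mts, domain.initial_length)
    )
    return replace(params, **overrides) if overrides else params


class ConfigError(ValueError):
    """Raised when a configuration violates a model invariant.

    ``errors`` lists every violated invariant, one message each.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


def validate_config(
    domain: DomainConfig,
    params: DynamicsParams,
    mech: MechanismConfig,
) -> tuple[DomainConfig, DynamicsParams, MechanismConfig]:
    """Check every invariant; return the configuration unchanged or raise.

    Raises :class:`ConfigError` naming each violated invariant.
    """
    errors: list[str] = []

    if domain.length <= 0:
        errors.append(f"domain length must be positive, got {domain.length}")
    for s in domain.nucleation_sites:
        if not (0.0 < s < domain.length):
            errors.append(
                f"site {s} on boundary or outside the (0, {domain.length}) domain"
            )
    sites = domain.nucleation_sites
    if any(b <= a for a, b in zip(sites, sites[1:])):
        errors.append("nucleation sites must be strictly increasing")
    if domain.n_mts < 1:
        errors.append(f"n_mts must be >= 1, got {domain.n_mts}")
    if domain.dt <= 0:
        errors.append(f"dt must be positive, got {domain.dt}")
    if not (0.0 < domain.seed_length):
        errors.append(f"seed_length must be positive, got {domain.seed_length}")
    if domain.initial_length > domain.length:
        errors.append(
            f"initial_length {domain.initial_length} exceeds domain length "
            f"{domain.length}"
        )
    if not (0.0 <= domain.initial_meo_fraction <= 1.0):
        errors.append(
            f"initial_meo_fraction must be in [0, 1], got "
            f"{domain.initial_meo_fraction}"
        )
    if domain.record_interval < domain.dt:
        errors.append("record_interval must be at least one time step")

    rate_fields = (
        "vg_plus", "vg_minus", "vs_plus", "vs_minus",
        "lambda_tilde_plus", "lambda_tilde_minus",
        "lambda_rescue_plus", "lambda_rescue_minus",
        "gamma", "lambda_min",
    )
    for name in rate_fields:
        value = getattr(params, name)
        if value < 0:
            errors.append(f"negative rate or speed {name}={value}")
    if params.L0 <= 0:
        errors.append(f"L0 must be positive, got {params.L0}")
    if params.T_tot <= 0:
        errors.append(f"T_tot must be positive, got {params.T_tot}")

    if not (0.0 <= mech.p_autofail <= 1.0):
        errors.append(f"p_autofail must be in [0, 1], got {mech.p_autofail}")
    if mech.n_s < 1:
        errors.append(f"n_s must be >= 1, got {mech.n_s}")

    if errors:
        raise ConfigError(errors)
    return domain, params, mech


# --- configuration file round trip -------------------------------------------

_PRESETS = {"short": short_domain, "long": long_domain}


def config_to_yaml(
    domain: DomainConfig,
    params: DynamicsParams,
    mech: MechanismConfig,
    stream=None,
) -> str | None:
    doc = {
        "domain": asdict(domain),
        "dynamics": asdict(params),
        "mechanisms": asdict(mech),
    }
    doc["domain"]["nucleation_sites"] = list(domain.nucleation_sites)
    return yaml.safe_dump(doc, stream, sort_keys=False)


def config_from_yaml(source) -> tuple[DomainConfig, DynamicsParams, MechanismConfig]:
    """Parse a configuration document (path, file object, or YAML string).

    A top-level ``preset: short|long`` expands to the canonical geometry;
    any explicit ``domain``/``dynamics``/``mechanisms`` keys override the
    preset field-by-field.
    """
    if isinstance(source, (str, bytes)) and "\n" not in str(source):
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    elif isinstance(source, io.IOBase) or hasattr(source, "read"):
        doc = yaml.safe_load(source)
    else:
        doc = yaml.safe_load(source)
    doc = doc or {}

    preset = doc.get("preset")
    if preset is not None:
        if preset not in _PRESETS:
            raise ConfigError([f"unknown preset {preset!r}"])
        domain = _PRESETS[preset]()
    else:
        domain = None

    dom_over = dict(doc.get("domain") or {})
    if "nucleation_sites" in dom_over:
        dom_over["nucleation_sites"] = tuple(dom_over["nucleation_sites"])
    if domain is None:
        domain = DomainConfig(**dom_over)
    elif dom_over:
        domain = replace(domain, **dom_over)

    dyn_over = dict(doc.get("dynamics") or {})
    if "T_tot" in dyn_over:
        params = DynamicsParams(**dyn_over)
    else:
        params = default_params_for(domain, **dyn_over)
    mech = MechanismConfig(**(doc.get("mechanisms") or {}))
    return validate_config(domain, params, mech)
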