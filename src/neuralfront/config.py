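"""Structured run configuration: TOML loading, validation and serialisation.

A run configuration names the two kernels, the speed and delay
distributions, the synaptic weights and threshold, a task selector and
task options.  Parsing uses the stdlib TOML reader; validation is strict
(unknown keys are rejected with the offending field named).  Dumping uses
a small emitter for this flat schema so configurations round-trip.
"""

from __future__ import annotations

import hashlib
import tomllib
from typing import List, Literal, Optional

from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from . import kernels as kern
from .kernels import AtomicDistribution, ModelParameters, SpatialKernel
from .simulate import SimulationConfig

__all__ = ["RunConfig", "ConfigError", "load_config", "loads_config",
           "dump_config", "config_hash"]

TASKS = ("speed", "profile", "evans", "zeros", "standing", "simulate", "scan")


class ConfigError(ValueError):
    """A configuration file failed to parse or validate."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class KernelSpec(_Strict):
    family: Literal["difference_of_exponentials", "single_exponential"]
    s: Optional[float] = None
    r: Optional[float] = None
    rho: Optional[float] = None
    sigma: Optional[float] = None

    @model_validator(mode="after")
    def _check_params(self):
        if self.family == "difference_of_exponentials":
            if self.s is None or self.r is None:
                raise ValueError("difference_of_exponentials needs 's' and 'r'")
        else:
            if self.sigma is None:
                raise ValueError("single_exponential needs 'sigma'")
        return self

    def build(self) -> SpatialKernel:
        if self.family == "difference_of_exponentials":
            return kern.make_difference_of_exponentials_kernel(
                self.s, self.r, self.rho if self.rho is not None else 1.0)
        return kern.make_single_exponential_kernel(self.sigma)


class DistributionSpec(_Strict):
    atoms: List[float]
    weights: Optional[List[float]] = None

    def build(self) -> AtomicDistribution:
        if self.weights is None:
            w = [1.0 / len(self.atoms)] * len(self.atoms)
        else:
            w = self.weights
        return AtomicDistribution(atoms=tuple(self.atoms), weights=tuple(w))


class ModelSpec(_Strict):
    alpha: float
    beta: float
    theta: float

    def build(self) -> ModelParameters:
        return ModelParameters(alpha=self.alpha, beta=self.beta, theta=self.theta)


class SimulationSpec(_Strict):
    L: float = 60.0
    n_cells: int = 600
    dt: float = 0.02
    t_end: float = 40.0
    ic: Literal["perturbed_front", "step"] = "perturbed_front"
    front_position: Optional[float] = None
    noise_amplitude: float = 0.025
    noise_window: float = 12.0
    quadrature: Literal["riemann", "monte_carlo"] = "riemann"
    mc_draws: int = 5000
    delay_interpolation: Literal["nearest", "linear"] = "nearest"


class TaskOptions(_Strict):
    mu0: Optional[float] = None          # wave-speed override (profile/evans)
    z_min: float = -20.0                 # profile grid
    z_max: float = 20.0
    n_points: int = 2001
    re_min: float = 0.05                 # evans grid / zeros rectangle
    re_max: float = 5.0
    im_min: float = -5.0
    im_max: float = 5.0
    n_re: int = 21
    n_im: int = 21
    bracket: List[float] = [-0.999, 10.0]   # standing real-root bracket
    magnitude_normalisation: bool = False
    scan_variable: Literal["c0", "tau0"] = "c0"
    scan_values: List[float] = []
    kappa: float = 2.0
    probe_x: Optional[float] = None
    window: Optional[List[float]] = None


class RunConfig(_Strict):
    """Validated run configuration (see the shipped examples)."""

    task: Literal["speed", "profile", "evans", "zeros", "standing",
                  "simulate", "scan"]
    seed: int = 0
    model: ModelSpec
    kernel_k: KernelSpec
    kernel_w: KernelSpec
    speeds: DistributionSpec
    delays: DistributionSpec
    simulation: SimulationSpec = SimulationSpec()
    options: TaskOptions = TaskOptions()

    @model_validator(mode="after")
    def _cross_validate(self):
        xi = self.speeds.build()
        self.delays.build()
        self.model.build()
        self.kernel_k.build()
        self.kernel_w.build()
        if self.options.mu0 is not None and not (0.0 < self.options.mu0
                                                 < xi.min_support):
            raise ValueError(
                f"options.mu0={self.options.mu0} must lie in "
                f"(0, c0={xi.min_support})")
        return self

    # -- builders ----------------------------------------------------------
    def build_objects(self):
        return (self.kernel_k.build(), self.kernel_w.build(),
                self.model.build(), self.speeds.build(), self.delays.build())

    def build_simulation(self, front=None) -> SimulationConfig:
        K, W, params, xi, eta = self.build_objects()
        s = self.simulation
        return SimulationConfig(
            K=K, W=W, params=params, xi=xi, eta=eta, L=s.L, n_cells=s.n_cells,
            dt=s.dt, t_end=s.t_end, ic_kind=s.ic, front=front,
            front_position=s.front_position, noise_amplitude=s.noise_amplitude,
            noise_window=s.noise_window, seed=self.seed, quadrature=s.quadrature,
            mc_draws=s.mc_draws, delay_interpolation=s.delay_interpolation)


def _format_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def loads_config(text: str) -> RunConfig:
    """Parse and validate a TOML configuration string."""
    try:
        data = tomllib.loads(text)
    except tomllib.TOMLDecodeError as exc:
        raise ConfigError(f"TOML parse error: {exc}") from exc
    if not data:
        raise ConfigError("empty configuration")
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(_format_error(exc)) from exc


def load_config(path) -> RunConfig:
    """Load and validate a TOML configuration file."""
    try:
        with open(path, "rb") as fh:
            text = fh.read().decode()
    except OSError as exc:
        raise ConfigError(f"cannot read {path}: {exc}") from exc
    return loads_config(text)


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return '"' + v.replace("\\", "\\\\").replace('"', '\\"') + '"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialise {type(v)}")


def dump_config(config: RunConfig) -> str:
    """Emit the configuration as TOML text (round-trips through loads_config)."""
    data = config.model_dump(exclude_none=True)
    lines = []
    for key in ("task", "seed"):
        lines.append(f"{key} = {_toml_value(data.pop(key))}")
    for section, content in data.items():
        lines.append("")
        lines.append(f"[{section}]")
        for key, value in content.items():
            lines.append(f"{key} = {_toml_value(value)}")
    return "\n".join(lines) + "\n"


def config_hash(config: RunConfig) -> str:
    """Short stable hash of the resolved configuration, for run logs."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()[:12]
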