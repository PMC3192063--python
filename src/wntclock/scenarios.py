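"""Ready-to-run scenario configs for every in-silico experiment.

Each :class:`Scenario` bundles parameter overrides, a gradient schedule,
an optional elongation config and a seed, so every experiment in the
study — the reference oscillation, the sensitivity scans, the gradient
response, the synchronization/desynchronization runs and the tail-bud
drift runs — can be reproduced from a single name with no external
inputs.  The definitions live in ``data/scenarios.yaml`` inside the
package; :func:`builtin_scenarios` loads them.

The module also provides synthetic fixtures: log-normally perturbed
parameter sets for robustness checks and synthetic front series for
exercising the period detector.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import yaml

from .dynamics import ScanResult, Trajectory, integrate, modifier_scan, oscillation_stats, parameter_scan
from .errors import ConfigurationError
from .gradient import parse_schedule, tailbud_drift
from .model import ParameterSet, reference_parameters
from .psm import ElongationConfig, ElongationResult, FrontSeries, run_elongation

__all__ = [
    "Scenario",
    "builtin_scenarios",
    "get_scenario",
    "run_scenario",
    "perturbed_parameter_sets",
    "synthetic_front_series",
]

#: Parameters never perturbed by :func:`perturbed_parameter_sets`:
#: conserved totals and the (integer) Hill coefficient.
UNPERTURBED = ("G_tot", "L_tot", "h")


@dataclass
class Scenario:
    """A named, seeded, fully serializable experiment configuration.

    ``kind`` selects the runner: ``timeseries`` (one integration),
    ``scan`` / ``scan_suite`` (one-parameter scans), ``modifier_scan``
    (static Wnt-level scan), ``elongation`` (budding-PSM run) or
    ``placeholder`` (configuration intentionally incomplete).
    """

    name: str
    kind: str
    description: str = ""
    seed: int = 0
    overrides: dict = field(default_factory=dict)
    schedule: str | list[str] | None = None
    elongation: dict | None = None
    drift: dict | None = None
    scans: list[dict] | None = None
    modifiers: list[float] | None = None
    duration: float = 6000.0
    transient: float = 2000.0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "Scenario":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown scenario keys {sorted(unknown)}")
        return cls(**data)

    def parameters(self) -> ParameterSet:
        if self.overrides is None:
            raise ConfigurationError(
                f"scenario {self.name!r} has no usable parameter values; "
                "supply the h=2 parameter set explicitly to run it"
            )
        return reference_parameters().with_overrides(**self.overrides)

    @property
    def available(self) -> bool:
        """False for placeholder scenarios that need values not bundled
        with the package."""
        return self.kind != "placeholder"


def _scenario_path() -> Path:
    return Path(importlib.resources.files("wntclock").joinpath("data/scenarios.yaml"))


def builtin_scenarios() -> list[Scenario]:
    """Load the bundled scenario definitions (one per experiment)."""
    with open(_scenario_path()) as fh:
        raw = yaml.safe_load(fh)
    return [Scenario.from_dict(entry) for entry in raw]


def get_scenario(name: str) -> Scenario:
    for s in builtin_scenarios():
        if s.name == name:
            return s
    raise ConfigurationError(f"no builtin scenario named {name!r}")


def _schedules(scn: Scenario):
    if scn.schedule is None:
        return None
    specs = [scn.schedule] if isinstance(scn.schedule, str) else list(scn.schedule)
    scheds = tuple(parse_schedule(s) for s in specs)
    return scheds[0] if len(scheds) == 1 else scheds


def run_scenario(
    scenario: Scenario,
    *,
    out_dir: str | Path | None = None,
    n_cells: int | None = None,
    duration: float | None = None,
    max_scan_points: int | None = None,
):
    """Execute a scenario and optionally write its outputs as CSV.

    ``n_cells``, ``duration`` and ``max_scan_points`` cap the problem
    size (useful for quick smoke runs); they never enlarge it.
    Returns the Trajectory / ScanResult(s) / ElongationResult.
    """
    if not scenario.available:
        scenario.parameters()  # raises with the explanatory message
    params = scenario.parameters()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    dur = min(duration, scenario.duration) if duration is not None else scenario.duration
    transient = min(scenario.transient, dur / 2.0)

    if scenario.kind == "timeseries":
        traj = integrate(params, duration=dur, schedule=_schedules(scenario))
        if out is not None:
            traj.to_csv(out / f"{scenario.name}_trajectory.csv")
        return traj

    if scenario.kind == "modifier_scan":
        values = list(scenario.modifiers or [])
        if max_scan_points is not None:
            values = values[:: max(1, len(values) // max_scan_points)]
        result = modifier_scan(params, values, duration=dur, transient=transient)
        if out is not None:
            result.to_csv(out / f"{scenario.name}.csv")
        return result

    if scenario.kind in ("scan", "scan_suite"):
        results: list[ScanResult] = []
        for spec in scenario.scans or []:
            values = np.geomspace(spec["lo"], spec["hi"], int(spec.get("n", 9)))
            if max_scan_points is not None and len(values) > max_scan_points:
                values = np.geomspace(spec["lo"], spec["hi"], max_scan_points)
            res = parameter_scan(params, spec["name"], values, duration=dur, transient=transient)
            results.append(res)
            if out is not None:
                res.to_csv(out / f"{scenario.name}_{spec['name']}.csv")
        return results if scenario.kind == "scan_suite" else results[0]

    if scenario.kind == "elongation":
        econf = dict(scenario.elongation or {})
        if n_cells is not None:
            econf["n_cells"] = min(n_cells, econf.get("n_cells", n_cells))
        drift = None
        if scenario.drift is not None:
            drift = tailbud_drift(
                scenario.drift["start_level"],
                scenario.drift["end_level"],
                scenario.drift.get("t_start", 0.0),
                scenario.drift.get("t_end", econf.get("n_cells", 180) * econf.get("R", 10.0)),
            )
        config = ElongationConfig(
            schedule=_schedules(scenario),
            drift=drift,
            seed=scenario.seed,
            **econf,
        )
        result = run_elongation(params, config)
        if out is not None:
            result.front.to_csv(out / f"{scenario.name}_front.csv")
            result.cells_frame().to_csv(out / f"{scenario.name}_cells.csv", index=False)
        return result

    raise ConfigurationError(f"unknown scenario kind {scenario.kind!r}")


def perturbed_parameter_sets(seed: int, n: int, relative_sd: float) -> list[ParameterSet]:
    """``n`` parameter sets with every rate multiplied by an independent
    log-normal factor (median 1, log-sd ``relative_sd``).

    Conserved totals and the Hill coefficient are left untouched.
    Log-normal factors keep all rates positive without clipping bias.
    Deterministic for a given seed.
    """
    if n < 1:
        raise ConfigurationError(f"n must be >= 1, got {n!r}")
    if not 0 < relative_sd <= 0.5:
        raise ConfigurationError(f"relative_sd must be in (0, 0.5], got {relative_sd!r}")
    rng = np.random.default_rng(seed)
    ref = reference_parameters()
    names = [f.name for f in dc_fields(ref) if f.name not in UNPERTURBED]
    sets = []
    for _ in range(n):
        factors = np.exp(rng.normal(0.0, relative_sd, size=len(names)))
        sets.append(ref.with_overrides(**{k: getattr(ref, k) * f for k, f in zip(names, factors)}))
    return sets


def synthetic_front_series(
    kind: str,
    period: float = 120.0,
    n: int = 120,
    R: float = 10.0,
    seed: int = 0,
    *,
    noise_sd: float = 0.05,
    mean: float = 300.0,
    amplitude: float = 150.0,
) -> FrontSeries:
    """Synthetic determination-front fixtures for the period detector.

    ``periodic``: clean sinusoid of the given period; ``constant``: flat
    series; ``noisy-periodic``: sinusoid with seeded multiplicative
    Gaussian noise of relative sd ``noise_sd``; ``aperiodic``: seeded
    white noise with no periodic component.
    """
    if n < 30:
        raise ConfigurationError(f"n must be >= 30, got {n!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(n) * R
    if kind == "periodic":
        values = mean + amplitude * np.sin(2.0 * np.pi * t / period)
    elif kind == "constant":
        values = np.full(n, mean)
    elif kind == "noisy-periodic":
        clean = mean + amplitude * np.sin(2.0 * np.pi * t / period)
        values = clean * (1.0 + noise_sd * rng.standard_normal(n))
    elif kind == "aperiodic":
        values = mean + amplitude * rng.standard_normal(n)
    else:
        raise ConfigurationError(f"unknown synthetic series kind {kind!r}")
    return FrontSeries(exit_times=t, dkk1=values, R=R)
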