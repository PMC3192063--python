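"""Wavefront schedules: the Wnt gradient as a time-dependent rate modifier.

A cell moving anteriorly through the presomitic mesoderm sees a falling
Wnt level.  Because Wnt--LRP5/6 binding is fast, the whole gradient can
be folded into a single dimensionless multiplier on the formation rate of
the membrane signalling complex (``k_lga_modifier`` in
:func:`wntclock.model.rhs`): the multiplier is the bound fraction
``W/(K_W + W)`` of the receptor, so a spatial Wnt profile becomes, in the
co-moving frame of the cell, a function of its age since budding.

A :class:`Schedule` maps cell age (min) to that multiplier.  The default
profile is Gaussian (expected if the gradient is shaped mainly by
diffusion); an exponential profile models a gradient set purely by Wnt
turnover, and both are normalised to the same fold change over one
transit time, so they agree at the two ends of the PSM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "WntBinding",
    "bound_fraction",
    "Schedule",
    "constant_schedule",
    "gaussian_schedule",
    "exponential_schedule",
    "TailbudDrift",
    "tailbud_drift",
    "parse_schedule",
]


@dataclass(frozen=True)
class WntBinding:
    """Wnt concentration and Wnt--LRP5/6 dissociation constant (nM).

    The dissociation constant has no measured value; 1 nM is the
    package's placeholder default when the explicit binding form is
    requested.
    """

    W: float
    K_W: float = 1.0

    def __post_init__(self):
        if self.W < 0 or self.K_W < 0:
            raise ConfigurationError("Wnt concentration and K_W must be non-negative")


def bound_fraction(binding: WntBinding) -> float:
    """Fraction ``W/(K_W + W)`` of LRP5/6 receptors carrying Wnt.

    Multiplying the bare LGA formation rate by this fraction realises the
    quasi-steady-state reduction of explicit Wnt--receptor binding.
    """
    if binding.W == 0 and binding.K_W == 0:
        raise ConfigurationError("bound fraction undefined for W = K_W = 0")
    return binding.W / (binding.K_W + binding.W)


@dataclass(frozen=True)
class Schedule:
    """Time-dependent multiplier for one rate parameter.

    ``value(t)`` gives the multiplier at cell age ``t`` (min).  ``start``
    is the multiplier at age zero; profiles with fold change ``F > 1``
    decay monotonically to ``start / F`` at one transit time.  ``target``
    names the parameter being scaled: ``"k_LGA"`` (the Wnt proxy,
    default) or ``"S_B"`` (graded beta-catenin source).
    """

    kind: str
    start: float = 1.0
    fold: float | None = None
    transit: float | None = None
    target: str = "k_LGA"
    _fn: Callable[[float], float] = field(repr=False, compare=False, default=None)

    def __post_init__(self):
        if self.target not in ("k_LGA", "S_B"):
            raise ConfigurationError(f"unknown schedule target {self.target!r}")
        if self.start <= 0:
            raise ConfigurationError(f"schedule start value must be > 0, got {self.start!r}")

    def value(self, t: float) -> float:
        return self.start * self._fn(t)

    __call__ = value

    def scaled(self, factor: float) -> "Schedule":
        """Same profile with the start level multiplied by ``factor``."""
        if factor <= 0:
            raise ConfigurationError(f"scale factor must be > 0, got {factor!r}")
        return Schedule(self.kind, self.start * factor, self.fold, self.transit, self.target, self._fn)

    @property
    def spec(self) -> str:
        """Compact config string, e.g. ``gaussian:fold=2,transit=1200,target=k_LGA``."""
        parts = []
        if self.kind == "constant":
            parts.append(f"value={self.start:g}")
        else:
            parts.append(f"fold={self.fold:g}")
            parts.append(f"transit={self.transit:g}")
            if self.start != 1.0:
                parts.append(f"start={self.start:g}")
        parts.append(f"target={self.target}")
        return f"{self.kind}:" + ",".join(parts)


def constant_schedule(value: float = 1.0, target: str = "k_LGA") -> Schedule:
    """A flat modifier; ``value(t) = value`` for all t."""
    return Schedule("constant", value, None, None, target, lambda t: 1.0)


def _check_fold_transit(fold: float, transit: float) -> None:
    if not fold > 1:
        raise ConfigurationError(f"fold change must be > 1, got {fold!r}")
    if not transit > 0:
        raise ConfigurationError(f"transit time must be > 0, got {transit!r}")


def gaussian_schedule(fold: float = 2.0, transit: float = 1200.0,
                      start: float = 1.0, target: str = "k_LGA") -> Schedule:
    """Gaussian decay ``exp(-t^2 / 2 sigma^2)`` normalised so that the
    modifier falls by ``fold`` over one ``transit`` time.

    ``sigma = transit / sqrt(2 ln fold)``; the expected profile when the
    gradient is shaped mainly by diffusion.
    """
    _check_fold_transit(fold, transit)
    sigma = transit / math.sqrt(2.0 * math.log(fold))
    return Schedule("gaussian", start, fold, transit, target,
                    lambda t, s2=2.0 * sigma * sigma: math.exp(-(t * t) / s2))


def exponential_schedule(fold: float = 2.0, transit: float = 1200.0,
                         start: float = 1.0, target: str = "k_LGA") -> Schedule:
    """Exponential decay with the same endpoints as the Gaussian profile.

    ``exp(-t ln(fold)/transit)``: the profile of a gradient controlled
    purely by the half-life of Wnt (effective half-life
    ``transit / log2(fold)``).
    """
    _check_fold_transit(fold, transit)
    rate = math.log(fold) / transit
    return Schedule("exponential", start, fold, transit, target,
                    lambda t, r=rate: math.exp(-r * t))


@dataclass(frozen=True)
class TailbudDrift:
    """Linear drift of the tail-bud Wnt level over developmental time.

    Maps a cell's budding time to the starting multiplier of its
    schedule: linear between ``(t_start, start_level)`` and
    ``(t_end, end_level)``, clamped outside.  A falling drift mimics the
    Wnt downregulation seen at late somitogenesis stages; end levels
    above 1 probe the hypothesised tail-bud Wnt increase.
    """

    start_level: float
    end_level: float
    t_start: float
    t_end: float

    def __post_init__(self):
        if not self.t_end > self.t_start:
            raise ConfigurationError("t_end must exceed t_start")
        for level in (self.start_level, self.end_level):
            if not 0 < level <= 10:
                raise ConfigurationError(f"drift levels must be in (0, 10], got {level!r}")

    def __call__(self, budding_time: float) -> float:
        if budding_time <= self.t_start:
            return self.start_level
        if budding_time >= self.t_end:
            return self.end_level
        frac = (budding_time - self.t_start) / (self.t_end - self.t_start)
        return self.start_level + frac * (self.end_level - self.start_level)


def tailbud_drift(start_level: float, end_level: float,
                  t_start: float, t_end: float) -> TailbudDrift:
    """Build a linear birth-time -> starting-modifier map (see
    :class:`TailbudDrift`)."""
    return TailbudDrift(start_level, end_level, t_start, t_end)


def parse_schedule(spec: str) -> Schedule:
    """Parse a config string like ``gaussian:fold=2,transit=1200,target=k_LGA``."""
    kind, _, rest = spec.partition(":")
    kind = kind.strip()
    kwargs: dict[str, str] = {}
    if rest:
        for item in rest.split(","):
            key, _, val = item.partition("=")
            if not val:
                raise ConfigurationError(f"malformed schedule item {item!r} in {spec!r}")
            kwargs[key.strip()] = val.strip()
    target = kwargs.pop("target", "k_LGA")
    try:
        if kind == "constant":
            return constant_schedule(float(kwargs.pop("value", 1.0)), target)
        if kind in ("gaussian", "exponential"):
            builder = gaussian_schedule if kind == "gaussian" else exponential_schedule
            sched = builder(
                fold=float(kwargs.pop("fold", 2.0)),
                transit=float(kwargs.pop("transit", 1200.0)),
                start=float(kwargs.pop("start", 1.0)),
                target=target,
            )
        else:
            raise ConfigurationError(f"unknown schedule kind {kind!r}")
    except ValueError as exc:
        raise ConfigurationError(f"bad numeric value in schedule spec {spec!r}: {exc}") from exc
    if kwargs:
        raise ConfigurationError(f"unknown schedule keys {sorted(kwargs)} in {spec!r}")
    return sched
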