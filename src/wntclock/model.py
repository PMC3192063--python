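"""Core reaction network of the Dkk1 negative-feedback Wnt oscillator.

The model tracks ten concentrations in a single presomitic-mesoderm cell:
the destruction complex ``C``, the GSK3beta--Axin complex ``GA``, free
GSK3beta ``G``, beta-catenin ``B``, free LRP5/6 ``L``, Dkk1 mRNA ``Dm``,
free Dkk1 protein ``D``, the inhibitory Dkk1--LRP5/6 complex ``LD``, free
Axin ``A`` and the membrane signalling complex ``LGA`` (LRP5/6--Axin--
GSK3beta).  All concentrations are in nM and all times in minutes.

The negative feedback loop closes through Dkk1: Wnt signalling (formation
of ``LGA``) degrades Axin, which depletes the destruction complex and lets
beta-catenin accumulate; beta-catenin drives *dkk1* transcription; Dkk1
protein sequesters LRP5/6 into ``LD`` and thereby shuts the ``LGA`` route
down again.

Two moieties are conserved by construction: total GSK3beta
``G + GA + LGA + C`` and total LRP5/6 ``L + LGA + LD``.  Both are
integrated explicitly rather than eliminated algebraically, so checking
the conservation laws doubles as an integration-quality check.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping

import numpy as np
import yaml

from .errors import InvalidParameterError, StateDomainError

__all__ = [
    "SPECIES",
    "ParameterSet",
    "SystemState",
    "reference_parameters",
    "association_rate",
    "rhs",
    "conserved_totals",
]

#: Canonical species ordering used by every array in the package.
SPECIES = ("C", "GA", "G", "B", "L", "Dm", "D", "LD", "A", "LGA")

#: Index of each species in a state vector.
SPECIES_INDEX = {name: i for i, name in enumerate(SPECIES)}

#: Tolerance below zero at which a concentration is considered unphysical.
NEGATIVE_TOLERANCE = 1e-6


@dataclass(frozen=True)
class ParameterSet:
    """Kinetic constants of the Wnt/Dkk1 network.

    Dissociation constants ``K_X`` are in nM, breaking rates ``kminus_X``
    in min^-1; the mass-action association rate of each complex is the
    derived ``kminus_X / K_X`` (nM^-1 min^-1).  ``alpha`` is the rate at
    which beta-catenin is phosphorylated and degraded inside the
    destruction complex, ``v`` the rate at which Axin is degraded at the
    membrane complex.  ``S_B`` and ``S_A`` are the constitutive sources of
    beta-catenin and Axin (nM/min); free beta-catenin and Axin are
    otherwise stable.  *dkk1* transcription is the non-saturating Hill
    term ``k_tx * B**h`` (k_tx in nM^(1-h) min^-1) and translation is
    ``k_tl * Dm``; mRNA and protein decay with mean lifetimes ``tau_Dm``
    and ``tau_D``.  ``G_tot`` and ``L_tot`` are the conserved totals of
    GSK3beta and LRP5/6.
    """

    K_C: float = 8.0
    kminus_C: float = 7.0
    alpha: float = 2.2
    K_GA: float = 1.5
    kminus_GA: float = 4.0
    K_LGA: float = 1.0
    kminus_LGA: float = 10.0
    v: float = 3.8
    K_LD: float = 0.5
    kminus_LD: float = 0.02
    S_B: float = 1.0
    S_A: float = 0.02
    k_tx: float = 0.02
    k_tl: float = 0.025
    tau_Dm: float = 8.0
    tau_D: float = 16.0
    G_tot: float = 45.0
    L_tot: float = 15.0
    h: int = 3

    #: Source and expression rates may be set to zero (knockout-style
    #: runs); every other parameter must be strictly positive.
    _ZERO_ALLOWED = frozenset({"S_B", "S_A", "k_tx", "k_tl"})

    def __post_init__(self):
        for f in fields(self):
            value = getattr(self, f.name)
            lower_ok = value >= 0 if f.name in self._ZERO_ALLOWED else value > 0
            if not np.isfinite(value) or not lower_ok:
                raise InvalidParameterError(
                    f"parameter {f.name} must be finite and "
                    f"{'non-negative' if f.name in self._ZERO_ALLOWED else 'strictly positive'}, "
                    f"got {value!r}"
                )
        if self.h != int(self.h) or self.h < 1:
            raise InvalidParameterError(f"Hill coefficient h must be a positive integer, got {self.h!r}")
        object.__setattr__(self, "h", int(self.h))

    # -- derived mass-action association rates (nM^-1 min^-1) ------------
    @property
    def kplus_C(self) -> float:
        return association_rate(self.K_C, self.kminus_C)

    @property
    def kplus_GA(self) -> float:
        return association_rate(self.K_GA, self.kminus_GA)

    @property
    def kplus_LGA(self) -> float:
        return association_rate(self.K_LGA, self.kminus_LGA)

    @property
    def kplus_LD(self) -> float:
        return association_rate(self.K_LD, self.kminus_LD)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: Mapping) -> "ParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**dict(data))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "ParameterSet":
        return cls.from_dict(yaml.safe_load(text))

    def with_overrides(self, **overrides) -> "ParameterSet":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **overrides)


@dataclass
class SystemState:
    """Concentrations (nM) of the ten species at one instant."""

    C: float = 0.0
    GA: float = 0.0
    G: float = 0.0
    B: float = 0.0
    L: float = 0.0
    Dm: float = 0.0
    D: float = 0.0
    LD: float = 0.0
    A: float = 0.0
    LGA: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, s) for s in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "SystemState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(SPECIES),):
            raise ValueError(f"state vector must have shape ({len(SPECIES)},), got {arr.shape}")
        return cls(**{s: float(v) for s, v in zip(SPECIES, arr)})

    @classmethod
    def default(cls, params: ParameterSet) -> "SystemState":
        """All GSK3beta and LRP5/6 free, everything else absent.

        The unique state satisfying both conservation laws with no
        preformed complexes; used as the standard initial condition.
        """
        return cls(G=params.G_tot, L=params.L_tot)


def reference_parameters() -> ParameterSet:
    """The default parameter set of the model (Hill coefficient 3)."""
    return ParameterSet()


def association_rate(dissociation_constant: float, breaking_rate: float) -> float:
    """Mass-action association rate ``k+ = k- / K`` (nM^-1 min^-1)."""
    if not (dissociation_constant > 0 and np.isfinite(dissociation_constant)):
        raise InvalidParameterError(f"dissociation constant must be positive, got {dissociation_constant!r}")
    if not (breaking_rate > 0 and np.isfinite(breaking_rate)):
        raise InvalidParameterError(f"breaking rate must be positive, got {breaking_rate!r}")
    return breaking_rate / dissociation_constant


def _as_array(state) -> np.ndarray:
    if isinstance(state, SystemState):
        return state.to_array()
    return np.asarray(state, dtype=float)


def rhs(
    state,
    t: float,
    params: ParameterSet,
    k_lga_modifier: float = 1.0,
    s_b_modifier: float = 1.0,
    *,
    validate: bool = True,
) -> np.ndarray:
    """Time derivative (nM/min) of all ten species.

    ``k_lga_modifier`` scales the formation rate of the membrane complex
    ``LGA`` and is the proxy for the extracellular Wnt level: under the
    quasi-steady-state treatment of Wnt--LRP5/6 binding the effective
    formation rate is the bare rate times the bound fraction of the
    receptor.  ``s_b_modifier`` analogously scales the beta-catenin
    source, for the variant with a graded beta-catenin supply.

    The reaction set (mass action throughout):

    1. ``G + A <-> GA``
    2. ``L + GA <-> LGA``   (formation scaled by ``k_lga_modifier``)
    3. ``LGA -> L + G``     (Axin degraded at the receptor, rate ``v``)
    4. ``B + GA <-> C``
    5. ``C -> GA``          (beta-catenin degraded in the complex, ``alpha``)
    6. constant sources ``S_B`` into B and ``S_A`` into A
    7. ``dDm/dt = k_tx B^h - Dm/tau_Dm``
    8. ``dD/dt = k_tl Dm - D/tau_D``  (only free Dkk1 decays)
    9. ``L + D <-> LD``

    There are no other production or loss terms; in particular GSK3beta
    and LRP5/6 have no source or sink, so their totals are conserved.
    """
    y = _as_array(state)
    if validate:
        if y.min() < -NEGATIVE_TOLERANCE:
            bad = SPECIES[int(np.argmin(y))]
            raise StateDomainError(f"concentration of {bad} is {y.min():g} nM at t={t:g} min")
        if not k_lga_modifier > 0:
            raise InvalidParameterError(f"k_lga_modifier must be > 0, got {k_lga_modifier!r}")
        if not s_b_modifier > 0:
            raise InvalidParameterError(f"s_b_modifier must be > 0, got {s_b_modifier!r}")

    p = params
    C, GA, G, B, L, Dm, D, LD, A, LGA = y

    flux_GA = p.kplus_GA * G * A - p.kminus_GA * GA
    flux_LGA = p.kplus_LGA * k_lga_modifier * L * GA - p.kminus_LGA * LGA
    flux_C = p.kplus_C * B * GA - p.kminus_C * C
    flux_LD = p.kplus_LD * L * D - p.kminus_LD * LD
    axin_deg = p.v * LGA
    bcat_deg = p.alpha * C

    return np.array(
        [
            flux_C - bcat_deg,                       # C
            flux_GA - flux_LGA - flux_C + bcat_deg,  # GA (recycled from C)
            -flux_GA + axin_deg,                     # G  (released from LGA)
            p.S_B * s_b_modifier - flux_C,           # B
            -flux_LGA - flux_LD + axin_deg,          # L
            p.k_tx * B ** p.h - Dm / p.tau_Dm,       # Dm
            p.k_tl * Dm - D / p.tau_D - flux_LD,     # D
            flux_LD,                                 # LD
            p.S_A - flux_GA,                         # A
            flux_LGA - axin_deg,                     # LGA
        ]
    )


def conserved_totals(state) -> tuple[float, float]:
    """Return ``(G + GA + LGA + C, L + LGA + LD)``, the conserved totals."""
    y = _as_array(state)
    g_total = y[SPECIES_INDEX["G"]] + y[SPECIES_INDEX["GA"]] + y[SPECIES_INDEX["LGA"]] + y[SPECIES_INDEX["C"]]
    l_total = y[SPECIES_INDEX["L"]] + y[SPECIES_INDEX["LGA"]] + y[SPECIES_INDEX["LD"]]
    return float(g_total), float(l_total)
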