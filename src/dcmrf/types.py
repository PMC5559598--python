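"""Core value types shared across the dcmrf pipeline.

Units are uniform throughout the package: relaxation times in ms, relaxation
rates in ms^-1, relaxivities in mM^-1 ms^-1, concentrations in mM.  Much of
the contrast-agent literature quotes relaxivities in s^-1 mM^-1; divide such
values by 1000 to obtain the mM^-1 ms^-1 values used here (e.g. a typical
gadolinium chelate r1 of ~4-5 s^-1 mM^-1 is 0.004-0.005 mM^-1 ms^-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from ._exceptions import InputDomainError

__all__ = [
    "AgentRelaxivity",
    "BaselineRelaxation",
    "RelaxationTimes",
    "ConcentrationPair",
    "CalibrationFit",
]


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise InputDomainError(f"{name} must be finite, got {value!r}")


def _require_positive(name: str, value: float) -> None:
    _require_finite(name, value)
    if value <= 0:
        raise InputDomainError(f"{name} must be > 0, got {value!r}")


@dataclass(frozen=True)
class AgentRelaxivity:
    """Relaxivities of one paramagnetic contrast agent.

    Parameters
    ----------
    name : str
        Agent label (e.g. ``"Gd"`` for gadobenate dimeglumine, ``"Mn"``
        for MnCl2).
    r1, r2 : float
        Longitudinal / transverse relaxivity in mM^-1 ms^-1: the increase in
        R1 = 1/T1 (resp. R2 = 1/T2) per mM of agent.
    """

    name: str
    r1: float
    r2: float

    def __post_init__(self):
        _require_positive(f"{self.name}.r1", self.r1)
        _require_positive(f"{self.name}.r2", self.r2)


@dataclass(frozen=True)
class BaselineRelaxation:
    """Pre-contrast relaxation times (T1_0, T2_0) of the solvent or tissue, ms."""

    T1_0: float
    T2_0: float

    def __post_init__(self):
        _require_positive("T1_0", self.T1_0)
        _require_positive("T2_0", self.T2_0)


@dataclass(frozen=True)
class RelaxationTimes:
    """A measured or modelled (T1, T2) pair, ms."""

    T1: float
    T2: float

    def __post_init__(self):
        _require_positive("T1", self.T1)
        _require_positive("T2", self.T2)


@dataclass(frozen=True)
class ConcentrationPair:
    """Concentrations of the two agents, mM.

    ``agent_a`` plays the gadolinium role and ``agent_b`` the manganese role
    in the dual-agent model.  Values may be negative when produced by
    inverting noisy measurements; forward modelling requires both >= 0.
    """

    agent_a: float
    agent_b: float

    def __post_init__(self):
        _require_finite("agent_a", self.agent_a)
        _require_finite("agent_b", self.agent_b)


@dataclass(frozen=True)
class CalibrationFit:
    """Result of a linear relaxivity calibration (rate vs concentration).

    ``slope`` is the relaxivity estimate in mM^-1 ms^-1, ``intercept`` the
    zero-concentration rate in ms^-1.  ``r_squared`` is the squared Pearson
    correlation and ``p_two_tailed`` the two-sided p-value of the correlation
    from the t distribution with n-2 degrees of freedom (NaN for n < 3).
    """

    slope: float
    intercept: float
    r_squared: float
    p_two_tailed: float
    n: int
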