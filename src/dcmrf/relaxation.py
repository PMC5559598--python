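"""Dual-agent linear relaxation model, its closed-form inversion, and
relaxivity calibration.

Model
-----
Two paramagnetic agents A and B at concentrations [A], [B] (mM) shift the
water relaxation rates linearly and independently::

    1/T1 = 1/T1_0 + r1A*[A] + r1B*[B]
    1/T2 = 1/T2_0 + r2A*[A] + r2B*[B]

With the four relaxivities and the pre-contrast baseline (T1_0, T2_0) known,
a simultaneous (T1, T2) measurement gives two linear equations in the two
concentrations, solved in closed form::

    dR1 = 1/T1 - 1/T1_0,  dR2 = 1/T2 - 1/T2_0
    [A] = (dR2*r1B - dR1*r2B) / (r2A*r1B - r1A*r2B)
    [B] = (dR2 - r2A*[A]) / r2B

The denominator ``r2A*r1B - r1A*r2B`` is the relaxivity determinant; the
inversion is only well-posed when the two agents' (r1, r2) pairs are not
proportional.  Error in the recovered concentrations scales with the inverse
of this determinant, which is why agent pairs with strongly contrasting
r2/r1 ratios (e.g. a Gd chelate vs MnCl2) are preferred.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from ._exceptions import DegenerateDesignError, InputDomainError, SingularModelError
from .types import (
    AgentRelaxivity,
    BaselineRelaxation,
    CalibrationFit,
    ConcentrationPair,
    RelaxationTimes,
)

__all__ = [
    "forward_relaxation",
    "invert_dual_agent",
    "invert_dual_agent_arrays",
    "relaxivity_determinant",
    "fit_relaxivity",
    "DEFAULT_DETERMINANT_THRESHOLD",
]

#: Below this |r2A*r1B - r1A*r2B| (mM^-2 ms^-2) the agent pair is treated as
#: algebraically degenerate.  Configurable per call for sensitivity studies.
DEFAULT_DETERMINANT_THRESHOLD = 1e-12


def relaxivity_determinant(agent_a: AgentRelaxivity, agent_b: AgentRelaxivity) -> float:
    """Determinant ``r2A*r1B - r1A*r2B`` of the dual-agent system, mM^-2 ms^-2."""
    return agent_a.r2 * agent_b.r1 - agent_a.r1 * agent_b.r2


def forward_relaxation(
    baseline: BaselineRelaxation,
    agent_a: AgentRelaxivity,
    agent_b: AgentRelaxivity,
    conc: ConcentrationPair,
) -> RelaxationTimes:
    """Post-contrast (T1, T2) for a voxel containing both agents.

    Raises
    ------
    InputDomainError
        If either concentration is negative or non-finite.
    """
    ca, cb = conc.agent_a, conc.agent_b
    if not (np.isfinite(ca) and np.isfinite(cb)):
        raise InputDomainError("concentrations must be finite")
    if ca < 0 or cb < 0:
        raise InputDomainError(
            f"forward model requires non-negative concentrations, got ({ca}, {cb})"
        )
    r1 = 1.0 / baseline.T1_0 + agent_a.r1 * ca + agent_b.r1 * cb
    r2 = 1.0 / baseline.T2_0 + agent_a.r2 * ca + agent_b.r2 * cb
    return RelaxationTimes(T1=1.0 / r1, T2=1.0 / r2)


def invert_dual_agent(
    baseline: BaselineRelaxation,
    agent_a: AgentRelaxivity,
    agent_b: AgentRelaxivity,
    meas: RelaxationTimes,
    *,
    det_threshold: float = DEFAULT_DETERMINANT_THRESHOLD,
) -> ConcentrationPair:
    """Closed-form per-agent concentrations from one measured (T1, T2) pair.

    Negative outputs are returned raw: they arise naturally when noisy
    measurements are inverted and should only be clamped at the map level,
    explicitly (see :func:`dcmrf.quantify.concentration_maps`).

    Raises
    ------
    SingularModelError
        If the relaxivity determinant magnitude falls below ``det_threshold``
        ("similar r1 and r2" degeneracy of the two agents).
    InputDomainError
        For non-finite measured times.
    """
    a, b = invert_dual_agent_arrays(
        np.asarray(meas.T1, float),
        np.asarray(meas.T2, float),
        baseline,
        agent_a,
        agent_b,
        det_threshold=det_threshold,
    )
    return ConcentrationPair(agent_a=float(a), agent_b=float(b))


def invert_dual_agent_arrays(
    t1,
    t2,
    baseline: BaselineRelaxation,
    agent_a: AgentRelaxivity,
    agent_b: AgentRelaxivity,
    *,
    det_threshold: float = DEFAULT_DETERMINANT_THRESHOLD,
):
    """Vectorized dual-agent inversion over arrays of T1/T2 (ms).

    Returns two arrays (concentration of agent A, of agent B), mM.  Elements
    with non-positive T1 or T2 are invalid input (the caller is expected to
    mask background first) and raise ``InputDomainError``.
    """
    det = relaxivity_determinant(agent_a, agent_b)
    if abs(det) < det_threshold:
        raise SingularModelError(
            f"relaxivity determinant {det:.3e} below threshold {det_threshold:.3e}; "
            f"agents {agent_a.name!r} and {agent_b.name!r} cannot be separated"
        )
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    if not (np.all(np.isfinite(t1)) and np.all(np.isfinite(t2))):
        raise InputDomainError("measured T1/T2 must be finite")
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise InputDomainError("measured T1/T2 must be > 0")
    d_r1 = 1.0 / t1 - 1.0 / baseline.T1_0
    d_r2 = 1.0 / t2 - 1.0 / baseline.T2_0
    conc_a = (d_r2 * agent_b.r1 - d_r1 * agent_b.r2) / det
    conc_b = (d_r2 - agent_a.r2 * conc_a) / agent_b.r2
    return conc_a, conc_b


def fit_relaxivity(
    concentrations,
    rates,
    *,
    fixed_intercept: float | None = None,
) -> CalibrationFit:
    """Calibrate a relaxivity as the OLS slope of rate vs concentration.

    Parameters
    ----------
    concentrations : array-like
        Agent concentrations, mM.
    rates : array-like
        Measured relaxation rates R1 or R2, ms^-1, one per concentration.
    fixed_intercept : float, optional
        If given, the intercept is pinned (e.g. to a separately measured
        baseline rate 1/T1_0) and only the slope is estimated; the free
        intercept is the default, standard calibration practice.

    Notes
    -----
    ``r_squared`` is always the squared Pearson correlation of rate with
    concentration, and ``p_two_tailed`` its two-sided p-value (t distribution,
    n-2 degrees of freedom; NaN for n < 3), regardless of intercept handling.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(rates, dtype=float)
    if c.shape != r.shape or c.ndim != 1:
        raise InputDomainError("concentrations and rates must be equal-length 1-D")
    n = c.size
    if n < 2:
        raise InputDomainError(f"need at least 2 points to fit a slope, got {n}")
    if np.ptp(c) == 0:
        raise DegenerateDesignError("all concentrations identical: slope undefined")

    if np.ptp(r) == 0:
        # Flat response: zero relaxivity, correlation undefined -> r^2 = 0.
        intercept = float(r[0]) if fixed_intercept is None else float(fixed_intercept)
        return CalibrationFit(slope=0.0, intercept=intercept,
                              r_squared=0.0, p_two_tailed=float("nan"), n=n)

    res = stats.linregress(c, r)
    r_squared = float(res.rvalue) ** 2
    p = float(res.pvalue) if n >= 3 else float("nan")
    if fixed_intercept is None:
        slope, intercept = float(res.slope), float(res.intercept)
    else:
        r0 = r - fixed_intercept
        slope = float(np.dot(c, r0) / np.dot(c, c))
        intercept = float(fixed_intercept)
    return CalibrationFit(slope=slope, intercept=intercept,
                          r_squared=r_squared, p_two_tailed=p, n=n)
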