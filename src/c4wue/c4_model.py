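"""Forward C4 photosynthesis model and derived limitation statistics.

The enzyme-limited C4 net assimilation rate is modelled as

    A(ci) = min(Vpmax * ci / (ci + Kp), Vmax) - Rd

where the first branch is PEPC-limited carboxylation (a rectangular
hyperbola in intercellular CO2, ci), Vmax is the CO2-saturated asymptote
(combined Rubisco / PEP-regeneration capacity), Kp is the PEPC Michaelis
constant for CO2, and Rd is day respiration.  Mesophyll CO2 is taken
equal to ci (no mesophyll conductance term), so Vpmax governs the
initial slope and Vmax the asymptote — exactly the two quantities a
standard C4 A/ci fit reports.

The two branches meet at the inflection point

    ci* = Vmax * Kp / (Vpmax - Vmax)

Above ci* assimilation is flat at Vmax - Rd; a C4 leaf operating above
ci* can lose stomatal conductance without losing carbon.  Stomatal
limitation (SL) quantifies the shortfall of assimilation at the actual
operating point relative to a hypothetical leaf with no diffusive
resistance (ci = ca):

    SL = (A(ca) - A(ci_op)) / A(ca)

The operating point itself is the intersection of the biochemical demand
curve A(ci) with the diffusive supply line A = gs_co2 * (ca - ci).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import brentq

#: Ratio of diffusivities of water vapour to CO2 in air; converts
#: stomatal conductance to water vapour into conductance to CO2.
GS_H2O_TO_CO2 = 1.6

#: Default PEPC Michaelis constant for CO2 (µmol mol⁻¹), a typical
#: C4-literature value at 25–30 °C.
DEFAULT_KP = 80.0

#: Default day respiration (µmol m⁻² s⁻¹).
DEFAULT_RD = 2.0


@dataclass(frozen=True)
class ACiObservation:
    """One stabilized gas-exchange record at a cuvette CO2 step.

    Units: ``ca_sample``, ``ci`` in µmol CO2 mol⁻¹; ``a_n`` in
    µmol CO2 m⁻² s⁻¹; ``gs`` in mol H2O m⁻² s⁻¹.  ``a_n`` may be
    negative at sub-compensation steps.
    """

    plant_id: str
    genotype: str
    step_index: int
    ca_sample: float
    a_n: float
    gs: float
    ci: float
    leaf_temp: float = 27.0
    rh: float = 65.0
    ppfd: float = 1800.0

    def __post_init__(self) -> None:
        if self.ci <= 0:
            raise ValueError(f"ci must be positive, got {self.ci}")
        if self.ca_sample <= 0:
            raise ValueError(f"ca_sample must be positive, got {self.ca_sample}")
        if self.gs <= 0:
            raise ValueError(f"gs must be positive, got {self.gs}")


@dataclass(frozen=True)
class C4Params:
    """Parameters of the reduced enzyme-limited C4 model.

    ``vpmax`` (apparent maximum PEPC carboxylation rate) and ``vmax``
    (asymptote of the A/ci curve) are in µmol m⁻² s⁻¹; ``kp`` in
    µmol mol⁻¹; ``rd`` in µmol m⁻² s⁻¹.  A finite inflection point
    requires ``vpmax > vmax``.
    """

    vpmax: float
    vmax: float
    kp: float = DEFAULT_KP
    rd: float = DEFAULT_RD

    def __post_init__(self) -> None:
        if self.vpmax <= 0:
            raise ValueError(f"vpmax must be positive, got {self.vpmax}")
        if self.vmax <= 0:
            raise ValueError(f"vmax must be positive, got {self.vmax}")
        if self.kp <= 0:
            raise ValueError(f"kp must be positive, got {self.kp}")
        if self.rd < 0:
            raise ValueError(f"rd must be non-negative, got {self.rd}")


class OperatingPointSource(str, Enum):
    OBSERVED_MEAN = "observed_mean"
    SOLVED = "solved"


@dataclass(frozen=True)
class OperatingPoint:
    """The (ci, A) point a leaf realizes at ambient CO2 under its actual gs."""

    ci_op: float
    a_op: float
    source: OperatingPointSource = OperatingPointSource.SOLVED
    positive_a: bool = True

    def __post_init__(self) -> None:
        if self.ci_op <= 0:
            raise ValueError(f"ci_op must be positive, got {self.ci_op}")


@dataclass(frozen=True)
class LimitationSummary:
    """Stomatal limitation and efficiency summary for one leaf."""

    sl: float
    ci_inflection: float
    operating: OperatingPoint
    above_inflection: bool
    iwue: float | None = None


def predict_a(ci, params: C4Params):
    """Net assimilation A_N (µmol m⁻² s⁻¹) at intercellular CO2 ``ci``.

    Accepts a scalar or array ``ci`` (µmol mol⁻¹); negative ci is a
    domain error.  Continuous, non-decreasing in ci, and constant at
    ``vmax - rd`` above the inflection point.
    """
    ci_arr = np.asarray(ci, dtype=float)
    if np.any(ci_arr < 0):
        raise ValueError("ci must be non-negative")
    a = np.minimum(params.vpmax * ci_arr / (ci_arr + params.kp), params.vmax) - params.rd
    return float(a) if np.isscalar(ci) or ci_arr.ndim == 0 else a


def inflection_ci(params: C4Params) -> float:
    """ci* (µmol mol⁻¹) where the PEPC-limited branch meets the asymptote.

    Closed form ``vmax * kp / (vpmax - vmax)``; raises if ``vpmax <= vmax``
    (no finite inflection).
    """
    if params.vpmax <= params.vmax:
        raise ValueError(
            f"no finite inflection: vpmax ({params.vpmax}) must exceed vmax ({params.vmax})"
        )
    return params.vmax * params.kp / (params.vpmax - params.vmax)


def solve_operating_point(
    gs_co2: float, ca: float, params: C4Params, *, tol: float = 1e-10
) -> OperatingPoint:
    """Intersection of biochemical demand with the diffusive supply line.

    Solves A(ci) = gs_co2 * (ca - ci) for ci.  ``gs_co2`` is stomatal
    conductance to CO2 (mol m⁻² s⁻¹), i.e. gs to water vapour / 1.6.
    The solution is unique because demand is non-decreasing and supply
    strictly decreasing in ci.  If the only root has A <= 0 (leaf at or
    below compensation) the point is returned with ``positive_a=False``.
    """
    if gs_co2 <= 0:
        raise ValueError(f"gs_co2 must be positive, got {gs_co2}")
    if ca <= 0:
        raise ValueError(f"ca must be positive, got {ca}")

    a_sat = params.vmax - params.rd
    # Saturated branch first: supply line meets A = vmax - rd at
    # ci = ca - a_sat/gs; valid when that ci is at or above the inflection.
    try:
        ci_star = inflection_ci(params)
    except ValueError:
        ci_star = np.inf
    ci_sat = ca - a_sat / gs_co2
    if np.isfinite(ci_star) and ci_sat >= ci_star and ci_sat > 0:
        return OperatingPoint(ci_op=ci_sat, a_op=a_sat, positive_a=a_sat > 0)

    def residual(ci: float) -> float:
        return predict_a(ci, params) - gs_co2 * (ca - ci)

    # residual is strictly increasing; bracket the root.  At ci -> 0 the
    # leaf only respires so residual < 0; expand above ca if respiration
    # pushes the equilibrium past ambient (A < 0 there).
    lo = tol
    hi = ca
    while residual(hi) < 0:
        hi += ca  # equilibrium with ci > ca (efflux); A will be <= 0
        if hi > 100 * ca:  # pragma: no cover - unreachable for valid params
            raise RuntimeError("operating point bracket expansion failed")
    if residual(lo) > 0:
        # gs so small the supply line is below -rd near ci=0: no
        # physical root with ci > 0 other than essentially ci -> 0.
        ci_root = lo
    else:
        ci_root = brentq(residual, lo, hi, xtol=1e-12, rtol=1e-15)
    a_root = predict_a(ci_root, params)
    return OperatingPoint(ci_op=ci_root, a_op=a_root, positive_a=a_root > 0)


def stomatal_limitation(
    op_point: OperatingPoint,
    params: C4Params,
    ca: float,
    gs: float | None = None,
) -> LimitationSummary:
    """Stomatal limitation SL = (A(ca) - A(ci_op)) / A(ca).

    SL measures how much lower assimilation at the operating point is
    than a theoretical leaf with no diffusive resistance (ci = ca).
    Computed from the fitted curve in both numerator terms, so noise
    cannot drive SL below zero; SL < 0 arises only when ci_op > ca and
    is then clipped to 0 with a warning.  ``gs`` (mol H2O m⁻² s⁻¹), if
    given, fills in iWUE = a_op / gs.

    Raises if A(ca) <= 0 (SL undefined at or below compensation).
    """
    a_at_ca = predict_a(ca, params)
    if a_at_ca <= 0:
        raise ValueError("SL undefined at or below compensation (predicted A(ca) <= 0)")
    sl = (a_at_ca - predict_a(op_point.ci_op, params)) / a_at_ca
    if sl < 0:
        if op_point.ci_op > ca:
            warnings.warn(
                f"operating ci ({op_point.ci_op:.1f}) exceeds ca ({ca:.1f}); SL clipped to 0",
                stacklevel=2,
            )
        sl = 0.0
    try:
        ci_star = inflection_ci(params)
    except ValueError:
        ci_star = np.inf
    return LimitationSummary(
        sl=sl,
        ci_inflection=ci_star,
        operating=op_point,
        above_inflection=bool(op_point.ci_op >= ci_star),
        iwue=iwue(op_point.a_op, gs) if gs is not None else None,
    )


def iwue(a_n: float, gs: float) -> float:
    """Intrinsic water-use efficiency A_N / g_s (µmol CO2 mol⁻¹ H2O)."""
    if gs <= 0:
        raise ValueError(f"gs must be positive, got {gs}")
    return a_n / gs
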