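"""Estimation of C4 A/ci parameters from measured response curves.

One curve is a list of stabilized gas-exchange steps obtained by
stepping cuvette CO2 through the measurement protocol
(400, 200, 50, 150, 300, 400, 500, 600, 700, 800, 1200 µmol mol⁻¹).
Least squares with a seeded multistart estimates Vpmax and Vmax (and
optionally Rd) in A = min(Vpmax·ci/(ci+Kp), Vmax) − Rd; the hard
minimum makes the objective only piecewise smooth, so each start is a
bounded trust-region solve and the best of the starts is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from c4wue.c4_model import ACiObservation, C4Params, DEFAULT_KP, DEFAULT_RD, inflection_ci, predict_a

#: The stepwise cuvette CO2 protocol (µmol mol⁻¹).
PROTOCOL_CA_STEPS: tuple[float, ...] = (400, 200, 50, 150, 300, 400, 500, 600, 700, 800, 1200)

_BOUNDS = {"vpmax": (1e-6, 500.0), "vmax": (1e-6, 200.0), "rd": (0.0, 10.0)}


@dataclass(frozen=True)
class FitConfig:
    """Controls for a single-curve fit.

    ``free_parameters`` always includes vpmax and vmax; rd may be fixed
    at ``rd_fixed`` instead of fitted.  ``multistart_count`` seeded
    restarts perturb the data-driven initial guess to escape local
    minima of the non-smooth objective.
    """

    free_parameters: frozenset[str] = frozenset({"vpmax", "vmax", "rd"})
    kp_fixed: float = DEFAULT_KP
    rd_fixed: float = DEFAULT_RD
    multistart_count: int = 5
    seed: int = 0
    tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if not {"vpmax", "vmax"} <= self.free_parameters:
            raise ValueError("vpmax and vmax must always be free parameters")
        if not self.free_parameters <= {"vpmax", "vmax", "rd"}:
            raise ValueError(f"unknown free parameters: {self.free_parameters - {'vpmax', 'vmax', 'rd'}}")
        if self.multistart_count < 1:
            raise ValueError("multistart_count must be >= 1")


@dataclass(frozen=True)
class ACiFitResult:
    """Outcome of fitting one A/ci curve."""

    params: C4Params
    rss: float
    n_points: int
    converged: bool
    identifiable_vmax: bool
    per_point_residuals: tuple[float, ...]


def validate_protocol(curve: Sequence[ACiObservation], rel_tol: float = 0.05) -> tuple[bool, list[str]]:
    """Check a curve's ca steps against the 11-step cuvette protocol.

    Returns ``(matches, warnings)``: ``matches`` is True when the
    recorded ``ca_sample`` sequence matches the printed protocol within
    ``rel_tol`` per step.  Missing or extra steps produce warnings, not
    failure of the whole call; drift between the two 400-ppm steps
    greater than 10% of the first is also flagged.
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    msgs: list[str] = []
    ca = [obs.ca_sample for obs in curve]
    n = min(len(ca), len(PROTOCOL_CA_STEPS))
    matches = len(ca) == len(PROTOCOL_CA_STEPS) and all(
        abs(c - p) <= rel_tol * p for c, p in zip(ca, PROTOCOL_CA_STEPS)
    )
    if len(ca) < len(PROTOCOL_CA_STEPS):
        msgs.append(f"curve has {len(ca)} steps; protocol has {len(PROTOCOL_CA_STEPS)}")
    elif len(ca) > len(PROTOCOL_CA_STEPS):
        msgs.append(f"curve has {len(ca)} steps; protocol has {len(PROTOCOL_CA_STEPS)}")
    for c, p in zip(ca[:n], PROTOCOL_CA_STEPS[:n]):
        if abs(c - p) > rel_tol * p:
            msgs.append(f"ca step {c:.0f} deviates from protocol step {p:.0f} by more than {rel_tol:.0%}")
    # Stability check: the protocol revisits 400 ppm; large drift in A
    # between the two visits signals a non-stationary leaf.
    idx400 = [i for i, p in enumerate(PROTOCOL_CA_STEPS[:n]) if p == 400 and abs(ca[i] - 400) <= rel_tol * 400]
    if len(idx400) >= 2:
        a0, a1 = curve[idx400[0]].a_n, curve[idx400[1]].a_n
        if a0 != 0 and abs(a1 - a0) > 0.10 * abs(a0):
            msgs.append(f"drift between repeated 400-ppm steps: A changed {a0:.2f} -> {a1:.2f} (>10%)")
    return matches, msgs


def initial_guess(curve: Sequence[ACiObservation], kp_fixed: float = DEFAULT_KP, rd0: float = DEFAULT_RD) -> C4Params:
    """Data-driven starting values for the optimizer.

    vmax0 is the largest observed assimilation plus rd0; vpmax0 inverts
    the hyperbola secant through the two lowest-ci points at the fixed
    Kp (the PEPC branch satisfies
    ΔA/Δci = vpmax·kp / ((ci1+kp)(ci2+kp))).  A flat or decreasing
    low-ci slope falls back to vpmax0 = 2·vmax0.
    """
    if len(curve) < 3:
        raise ValueError(f"initial_guess needs >= 3 points, got {len(curve)}")
    a = np.array([obs.a_n for obs in curve])
    ci = np.array([obs.ci for obs in curve])
    vmax0 = max(float(a.max()) + rd0, 1e-3)
    order = np.argsort(ci)
    i1, i2 = order[0], order[1]
    dci = ci[i2] - ci[i1]
    slope = (a[i2] - a[i1]) / dci if dci > 0 else 0.0
    if slope > 0:
        vpmax0 = slope * (ci[i1] + kp_fixed) * (ci[i2] + kp_fixed) / kp_fixed
    else:
        vpmax0 = 2 * vmax0
    vpmax0 = float(np.clip(vpmax0, 1e-3, _BOUNDS["vpmax"][1]))
    vmax0 = float(np.clip(vmax0, 1e-3, _BOUNDS["vmax"][1]))
    return C4Params(vpmax=vpmax0, vmax=vmax0, kp=kp_fixed, rd=rd0)


def fit_aci(curve: Sequence[ACiObservation], config: FitConfig | None = None) -> ACiFitResult:
    """Least-squares fit of one A/ci curve.

    Minimizes Σ (a_n − A(ci))² over the free parameters with bounded
    trust-region least squares, restarting ``multistart_count`` times
    from seeded perturbations of :func:`initial_guess` and keeping the
    best solution.  ``identifiable_vmax`` is False when the fitted
    inflection lies beyond the largest observed ci (saturation never
    observed, so the asymptote is unconstrained by the data).
    Estimates do not depend on point ordering.
    """
    if config is None:
        config = FitConfig()
    if len(curve) < 4:
        raise ValueError(f"fit_aci needs >= 4 points, got {len(curve)}")

    a_obs = np.array([obs.a_n for obs in curve])
    ci_obs = np.array([obs.ci for obs in curve])
    fit_rd = "rd" in config.free_parameters
    guess = initial_guess(curve, config.kp_fixed, config.rd_fixed)

    names = ["vpmax", "vmax"] + (["rd"] if fit_rd else [])
    x0_base = np.array([guess.vpmax, guess.vmax] + ([guess.rd] if fit_rd else []))
    lb = np.array([_BOUNDS[n][0] for n in names])
    ub = np.array([_BOUNDS[n][1] for n in names])

    def unpack(x: np.ndarray) -> C4Params:
        rd = x[2] if fit_rd else config.rd_fixed
        return C4Params(vpmax=x[0], vmax=x[1], kp=config.kp_fixed, rd=rd)

    def residuals(x: np.ndarray) -> np.ndarray:
        return predict_a(ci_obs, unpack(x)) - a_obs

    rng = np.random.default_rng(config.seed)
    starts = [x0_base]
    # Breakpoint scan: assign the k lowest-ci points to the PEPC branch
    # and the rest to the asymptote, estimate each branch in closed form,
    # and use the resulting parameters as additional starts.  With clean
    # data one of these splits is the true branch assignment, so the
    # subsequent polish lands in the global basin of the non-smooth
    # objective rather than a kink-induced local minimum.
    order = np.argsort(ci_obs)
    ci_s, a_s = ci_obs[order], a_obs[order]
    x_s = ci_s / (ci_s + config.kp_fixed)
    k_min = 2 if fit_rd else 1  # one low point pins vpmax only when rd is fixed
    for k in range(k_min, len(curve)):
        xk, ak = x_s[:k], a_s[:k]
        if fit_rd:
            # regression a = vpmax*x - rd over the low branch
            denom = np.var(xk)
            if denom <= 0:
                continue
            vp = float(np.cov(xk, ak, bias=True)[0, 1] / denom)
            rd_k = float(vp * xk.mean() - ak.mean())
            rd_k = float(np.clip(rd_k, *_BOUNDS["rd"]))
        else:
            rd_k = config.rd_fixed
            sx2 = float((xk**2).sum())
            if sx2 <= 0:
                continue
            vp = float(((ak + rd_k) * xk).sum() / sx2)
        if not np.isfinite(vp) or vp <= 0:
            continue
        vm = float(a_s[k:].mean() + rd_k)
        cand = [np.clip(vp, *_BOUNDS["vpmax"]), np.clip(max(vm, 1e-3), *_BOUNDS["vmax"])]
        if fit_rd:
            cand.append(rd_k)
        starts.append(np.array(cand))
    for _ in range(config.multistart_count - 1):
        starts.append(np.clip(x0_base * rng.lognormal(0.0, 0.3, size=x0_base.size), lb, ub))

    best = None
    any_success = False
    for x0 in starts:
        try:
            sol = least_squares(
                residuals, np.clip(x0, lb, ub), bounds=(lb, ub),
                xtol=1e-14, ftol=config.tolerance, gtol=1e-14, method="trf",
            )
        except Exception:
            continue
        any_success = any_success or sol.success
        rss = float(2 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol, rss)
    if best is None or not any_success:
        raise RuntimeError("A/ci optimizer failed across all starts")
    sol, rss = best
    params = unpack(sol.x)
    identifiable = _vmax_identifiable(ci_obs, a_obs, params, rss, config)
    res = predict_a(ci_obs, params) - a_obs
    return ACiFitResult(
        params=params,
        rss=rss,
        n_points=len(curve),
        converged=bool(sol.success),
        identifiable_vmax=bool(identifiable),
        per_point_residuals=tuple(float(r) for r in res),
    )


def _vmax_identifiable(
    ci_obs: np.ndarray, a_obs: np.ndarray, params: C4Params, rss_full: float, config: FitConfig
) -> bool:
    """True when the asymptote is actually constrained by the data.

    Two conditions must hold: the fitted inflection lies within the
    observed ci range, and a pure PEPC hyperbola (no asymptote) fits
    the data detectably worse than the full model — otherwise the data
    never leave the sub-inflection branch and vmax is arbitrary.
    """
    try:
        if inflection_ci(params) > float(ci_obs.max()):
            return False
    except ValueError:
        return False
    x = ci_obs / (ci_obs + config.kp_fixed)
    fit_rd = "rd" in config.free_parameters
    if fit_rd:
        denom = float(np.var(x))
        if denom <= 0:
            return False
        vp = float(np.cov(x, a_obs, bias=True)[0, 1] / denom)
        rd = vp * x.mean() - a_obs.mean()
    else:
        vp = float(((a_obs + config.rd_fixed) * x).sum() / (x**2).sum())
        rd = config.rd_fixed
    rss_hyp = float(((vp * x - rd - a_obs) ** 2).sum())
    sst = float(((a_obs - a_obs.mean()) ** 2).sum())
    return rss_hyp - rss_full > 1e-6 * max(sst, 1.0)


def mean_curve_with_se(fits: Sequence[ACiFitResult], ci_grid: Iterable[float]) -> pd.DataFrame:
    """Pointwise mean and SE of the fitted curves on a ci grid.

    This is the "mean fit ± SE band" summary used to display replicate
    A/ci fits for one genotype.  A single fit yields SE = 0 everywhere
    with a warning.
    """
    if len(fits) == 0:
        raise ValueError("mean_curve_with_se needs at least one fit")
    grid = np.asarray(list(ci_grid), dtype=float)
    preds = np.vstack([predict_a(grid, f.params) for f in fits])
    mean = preds.mean(axis=0)
    if len(fits) == 1:
        warnings.warn("SE undefined for a single fit; reporting 0", stacklevel=2)
        se = np.zeros_like(mean)
    else:
        se = preds.std(axis=0, ddof=1) / np.sqrt(len(fits))
    return pd.DataFrame({"ci": grid, "a_mean": mean, "a_se": se})


# ---------------------------------------------------------------------------
# CSV interface

GAS_EXCHANGE_COLUMNS = [
    "plant_id", "genotype", "step_index", "ca_sample", "a_n", "gs", "ci",
    "leaf_temp", "rh", "ppfd",
]


def read_gas_exchange_csv(path: str | Path) -> pd.DataFrame:
    """Read a tidy gas-exchange log (one row per stabilized CO2 step)."""
    df = pd.read_csv(path)
    missing = set(GAS_EXCHANGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"gas-exchange CSV {path} missing columns: {sorted(missing)}")
    return df


def curves_from_frame(df: pd.DataFrame) -> dict[str, list[ACiObservation]]:
    """Group a gas-exchange frame into per-plant ordered curves."""
    curves: dict[str, list[ACiObservation]] = {}
    for plant_id, sub in df.groupby("plant_id", sort=True):
        sub = sub.sort_values("step_index")
        curves[str(plant_id)] = [
            ACiObservation(
                plant_id=str(r.plant_id), genotype=str(r.genotype), step_index=int(r.step_index),
                ca_sample=float(r.ca_sample), a_n=float(r.a_n), gs=float(r.gs), ci=float(r.ci),
                leaf_temp=float(r.leaf_temp), rh=float(r.rh), ppfd=float(r.ppfd),
            )
            for r in sub.itertuples()
        ]
    return curves


def fits_to_frame(fits: dict[str, ACiFitResult], genotypes: dict[str, str] | None = None) -> pd.DataFrame:
    """One row per plant: estimates, rss, and quality flags."""
    rows = []
    for plant_id, fit in fits.items():
        rows.append({
            "plant_id": plant_id,
            "genotype": (genotypes or {}).get(plant_id, ""),
            "vpmax": fit.params.vpmax,
            "vmax": fit.params.vmax,
            "kp": fit.params.kp,
            "rd": fit.params.rd,
            "rss": fit.rss,
            "n_points": fit.n_points,
            "converged": fit.converged,
            "identifiable_vmax": fit.identifiable_vmax,
        })
    return pd.DataFrame(rows)
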