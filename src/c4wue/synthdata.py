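"""Seeded synthetic greenhouse experiment generator.

Generates every input the analysis stages read — A/ci gas-exchange
curves, gravimetric dry-down pot-mass series, and stomatal field counts
and complex sizes — with the statistical structure the analysis
assumes, so the whole pipeline is testable without the original raw
measurements.

What it emulates
----------------
* The 11-step cuvette CO2 protocol at 27 °C, 65% RH, and
  1800 µmol m⁻² s⁻¹ PPFD, with multiplicative measurement noise on
  A_N and between-plant variation in g_s.  Within a curve g_s is held
  constant across CO2 steps (steady-state steps; the fit uses only
  (A, ci)), and each step's (ci, A) pair is the supply–demand operating
  point for that cuvette CO2.
* Genotype effects of the magnitude seen in engineered low-stomatal-
  density sorghum: a strong line (g_s −32%, V_pmax −32%, V_max −20%,
  stomatal density −69%) and a moderate line (g_s −18%, V_pmax −21%,
  stomatal density −45%) relative to the wild type.
* A single-bucket soil dry-down: transpiration proceeds at its
  potential rate while the fraction of transpirable soil water (FTSW)
  exceeds a threshold (default 0.4), then declines linearly to zero —
  reproducing the pattern where a low-g_s genotype conserves water and
  exhausts the pot days later than the wild type.
* Poisson field counts on a 0.64 mm² field of view with abaxial
  density exceeding adaxial, and truncated-Gaussian stomatal complex
  dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from c4wue.c4_model import (
    ACiObservation,
    C4Params,
    GS_H2O_TO_CO2,
    solve_operating_point,
)
from c4wue.aci_fit import PROTOCOL_CA_STEPS
from c4wue.stomata import DEFAULT_FIELD_AREA_MM2, StomatalComplexMeasure, StomatalFieldCount
from c4wue.water_budget import PotMassRecord, PotReference

#: Wild-type baseline biochemistry used throughout the simulations.
BASE_PARAMS = C4Params(vpmax=120.0, vmax=45.0, kp=80.0, rd=2.0)

#: Wild-type light-saturated g_s to water vapour (mol m⁻² s⁻¹), chosen
#: so the operating ci/ca is ~0.4 at ambient 400 µmol mol⁻¹ — i.e. the
#: operating point sits on the saturated branch of the A/ci curve, as
#: observed in well-watered C4 leaves.
BASE_GS_H2O = GS_H2O_TO_CO2 * (BASE_PARAMS.vmax - BASE_PARAMS.rd) / (400.0 - 160.0)


@dataclass(frozen=True)
class GenotypeEffect:
    """Multiplicative genotype effects relative to the wild type."""

    name: str
    gs_scale: float = 1.0
    vpmax_scale: float = 1.0
    vmax_scale: float = 1.0
    sd_abaxial: float = 50.0  # stomata mm⁻²
    sd_adaxial: float = 35.0
    leaf_area_scale: float = 1.0
    complex_size_scale: float = 1.0

    def __post_init__(self) -> None:
        for attr in ("gs_scale", "vpmax_scale", "vmax_scale", "leaf_area_scale", "complex_size_scale"):
            if getattr(self, attr) <= 0:
                raise ValueError(f"{attr} must be positive")

    def scaled_params(self, base: C4Params = BASE_PARAMS) -> C4Params:
        return replace(base, vpmax=base.vpmax * self.vpmax_scale, vmax=base.vmax * self.vmax_scale)


#: Default genotype panel: wild type plus a strong and a moderate
#: low-stomatal-density line.  Stomatal complexes of the engineered
#: lines are slightly larger (a common compensation).
DEFAULT_EFFECTS: tuple[GenotypeEffect, ...] = (
    GenotypeEffect(name="WT"),
    GenotypeEffect(
        name="epf_strong", gs_scale=0.68, vpmax_scale=0.68, vmax_scale=0.80,
        sd_abaxial=50.0 * 0.31, sd_adaxial=35.0 * 0.31, leaf_area_scale=0.88,
        complex_size_scale=1.10,
    ),
    GenotypeEffect(
        name="epf_moderate", gs_scale=0.82, vpmax_scale=0.79, vmax_scale=0.95,
        sd_abaxial=50.0 * 0.55, sd_adaxial=35.0 * 0.55, leaf_area_scale=0.93,
        complex_size_scale=1.05,
    ),
)


@dataclass(frozen=True)
class SimConfig:
    """Gas-exchange simulation settings; ``seed`` fixes all outputs."""

    seed: int = 0
    n_plants: int = 10
    noise_cv_a: float = 0.02
    noise_cv_gs: float = 0.05
    ca_steps: tuple[float, ...] = PROTOCOL_CA_STEPS
    ambient_ca: float = 400.0
    leaf_temp: float = 27.0
    rh: float = 65.0
    ppfd: float = 1800.0


@dataclass(frozen=True)
class DryDownConfig:
    """Bucket-model dry-down settings.

    ``available_water0`` is the transpirable water in a saturated pot;
    ``potential_use`` is the wild-type unstressed daily use (g day⁻¹ at
    gs_scale = leaf_area_scale = 1); below ``ftsw_threshold`` relative
    transpiration declines linearly with FTSW to zero.  Defaults put
    the wild type near pot exhaustion by day 6 of a 9-day dry-down.
    """

    available_water0: float = 3000.0
    potential_use: float = 600.0
    ftsw_threshold: float = 0.4
    n_days: int = 9
    noise_cv: float = 0.05
    n_pots: int = 10
    tare_plus_drysoil: float = 9000.0
    plant_mass: float = 300.0

    def __post_init__(self) -> None:
        if not 0.0 < self.ftsw_threshold < 1.0:
            raise ValueError("ftsw_threshold must be in (0, 1)")


def sim_aci_curve(
    effect: GenotypeEffect,
    base_params: C4Params = BASE_PARAMS,
    config: SimConfig = SimConfig(),
    *,
    plant_id: str = "p1",
    rng: np.random.Generator | None = None,
) -> list[ACiObservation]:
    """One plant's A/ci curve under the stepwise CO2 protocol.

    The plant's g_s is the wild-type baseline scaled by the genotype
    effect with multiplicative lognormal noise, held constant across
    steps.  At each cuvette CO2 the recorded (ci, A) is the
    supply–demand operating point, with multiplicative noise applied to
    the recorded A only (ci is reported as realized).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    params = effect.scaled_params(base_params)
    gs_h2o = BASE_GS_H2O * effect.gs_scale
    if config.noise_cv_gs > 0:
        gs_h2o *= _lognormal_cv(rng, config.noise_cv_gs)
    gs_co2 = gs_h2o / GS_H2O_TO_CO2
    obs = []
    for step, ca in enumerate(config.ca_steps):
        op = solve_operating_point(gs_co2, ca, params)
        a_rec = op.a_op
        if config.noise_cv_a > 0:
            a_rec *= _lognormal_cv(rng, config.noise_cv_a)
        obs.append(
            ACiObservation(
                plant_id=plant_id, genotype=effect.name, step_index=step,
                ca_sample=ca, a_n=a_rec, gs=gs_h2o, ci=op.ci_op,
                leaf_temp=config.leaf_temp, rh=config.rh, ppfd=config.ppfd,
            )
        )
    return obs


def sim_aci_panel(
    effects: Sequence[GenotypeEffect] = DEFAULT_EFFECTS,
    base_params: C4Params = BASE_PARAMS,
    config: SimConfig = SimConfig(),
) -> pd.DataFrame:
    """Replicate A/ci curves for a genotype panel, as a tidy frame."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for effect in effects:
        for i in range(config.n_plants):
            pid = f"{effect.name}-{i + 1:02d}"
            for o in sim_aci_curve(effect, base_params, config, plant_id=pid, rng=rng):
                rows.append(o.__dict__)
    return pd.DataFrame(rows)


def _lognormal_cv(rng: np.random.Generator, cv: float) -> float:
    """Unit-median multiplicative noise with coefficient of variation cv."""
    sigma = np.sqrt(np.log1p(cv**2))
    return float(rng.lognormal(mean=0.0, sigma=sigma))


def sim_drydown(
    effects: Sequence[GenotypeEffect] = DEFAULT_EFFECTS,
    ddconfig: DryDownConfig = DryDownConfig(),
    seed: int = 0,
) -> tuple[list[PotMassRecord], list[PotReference]]:
    """Bucket-model gravimetric dry-down for a genotype panel.

    Each pot starts saturated; each day's mass decrement is

        potential_use * gs_scale * leaf_area_scale * rt(FTSW) * noise

    where rt(FTSW) = min(1, FTSW / ftsw_threshold) evaluated at the
    start of the day, and FTSW is the fraction of transpirable soil
    water remaining.  Masses are reconstructed from the decrements, so
    cumulative use equals mass(0) − mass(last) exactly.
    """
    rng = np.random.default_rng(seed)
    masses: list[PotMassRecord] = []
    refs: list[PotReference] = []
    for effect in effects:
        for i in range(ddconfig.n_pots):
            pot_id = f"{effect.name}-pot{i + 1:02d}"
            sat = ddconfig.tare_plus_drysoil + ddconfig.plant_mass + ddconfig.available_water0
            refs.append(
                PotReference(
                    pot_id=pot_id, tare_plus_drysoil=ddconfig.tare_plus_drysoil,
                    plant_mass=ddconfig.plant_mass, saturated_mass=sat,
                )
            )
            remaining = ddconfig.available_water0
            masses.append(PotMassRecord(pot_id=pot_id, genotype=effect.name, day=0, mass=sat))
            demand0 = ddconfig.potential_use * effect.gs_scale * effect.leaf_area_scale
            for day in range(1, ddconfig.n_days + 1):
                ftsw = remaining / ddconfig.available_water0
                rt = min(1.0, ftsw / ddconfig.ftsw_threshold)
                use = demand0 * rt
                if ddconfig.noise_cv > 0:
                    use *= _lognormal_cv(rng, ddconfig.noise_cv)
                use = min(use, remaining)
                remaining -= use
                masses.append(
                    PotMassRecord(
                        pot_id=pot_id, genotype=effect.name, day=day,
                        mass=ddconfig.tare_plus_drysoil + ddconfig.plant_mass + remaining,
                    )
                )
    return masses, refs


def drydown_day_to_threshold(
    effect: GenotypeEffect, ddconfig: DryDownConfig = DryDownConfig()
) -> int | None:
    """First day a deterministic (noise-free) pot falls below the FTSW
    threshold, or None if it never does within the dry-down window."""
    cfg = replace(ddconfig, noise_cv=0.0, n_pots=1)
    masses, _ = sim_drydown([effect], cfg, seed=0)
    avail = cfg.available_water0
    base = cfg.tare_plus_drysoil + cfg.plant_mass
    for m in masses:
        if (m.mass - base) / avail < cfg.ftsw_threshold:
            return m.day
    return None


def sim_stomatal_fields(
    effect: GenotypeEffect,
    n_plants: int = 10,
    seed: int = 0,
    *,
    n_fields: int = 4,
    leaf_positions: Sequence[int] = (4, 5, 6),
    field_area: float = DEFAULT_FIELD_AREA_MM2,
    n_complexes: int = 6,
    rng: np.random.Generator | None = None,
) -> tuple[list[StomatalFieldCount], list[StomatalComplexMeasure]]:
    """Stomatal field counts and complex sizes for one genotype.

    Counts per field are Poisson with mean density × field area, for
    each surface and leaf position; six stomatal complexes per plant
    get width/length from zero-truncated Gaussians (wild-type scale
    ~30 × 45 µm, CV 10%), scaled by the genotype's complex size effect.
    """
    if effect.sd_abaxial <= 0 or effect.sd_adaxial <= 0:
        raise ValueError("stomatal density intensities must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts: list[StomatalFieldCount] = []
    measures: list[StomatalComplexMeasure] = []
    intensity = {"abaxial": effect.sd_abaxial, "adaxial": effect.sd_adaxial}
    for i in range(n_plants):
        pid = f"{effect.name}-{i + 1:02d}"
        for leaf in leaf_positions:
            for surface, dens in intensity.items():
                lam = dens * field_area
                for f_ix in range(1, n_fields + 1):
                    counts.append(
                        StomatalFieldCount(
                            plant_id=pid, genotype=effect.name, leaf_position=leaf,
                            surface=surface, field_index=f_ix,
                            count=int(rng.poisson(lam)), field_area=field_area,
                        )
                    )
        w_mu = 30.0 * effect.complex_size_scale
        l_mu = 45.0 * effect.complex_size_scale
        for _ in range(n_complexes):
            w = _truncated_normal(rng, w_mu, 0.10 * w_mu)
            l = _truncated_normal(rng, l_mu, 0.10 * l_mu)
            measures.append(StomatalComplexMeasure(plant_id=pid, genotype=effect.name, width=min(w, l), length=max(w, l)))
    return counts, measures


def _truncated_normal(rng: np.random.Generator, mu: float, sigma: float) -> float:
    """Gaussian draw truncated at zero (redraw on non-positive values)."""
    for _ in range(1000):
        x = rng.normal(mu, sigma)
        if x > 0:
            return float(x)
    raise RuntimeError("truncated normal failed to produce a positive draw")


def sim_leaf_areas(
    effects: Sequence[GenotypeEffect] = DEFAULT_EFFECTS,
    n_plants: int = 10,
    seed: int = 0,
    *,
    n_leaves: int = 9,
) -> pd.DataFrame:
    """Per-leaf width × length records (cm) for whole-plant leaf area."""
    rng = np.random.default_rng(seed)
    rows = []
    for effect in effects:
        scale = np.sqrt(effect.leaf_area_scale)
        for i in range(n_plants):
            pid = f"{effect.name}-{i + 1:02d}"
            for leaf in range(1, n_leaves + 1):
                frac = 0.4 + 0.6 * leaf / n_leaves  # younger leaves larger
                width = _truncated_normal(rng, 6.0 * frac * scale, 0.4)
                length = _truncated_normal(rng, 75.0 * frac * scale, 4.0)
                rows.append({
                    "plant_id": pid, "genotype": effect.name, "leaf_index": leaf,
                    "width": width, "length": length,
                })
    return pd.DataFrame(rows)
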