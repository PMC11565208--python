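"""Gravimetric dry-down bookkeeping.

During a dry-down experiment each pot is soaked to ~100% relative soil
water content (rSWC), water is then withheld, and the pot is weighed
daily.  Relative soil water content on a dry-basis reference is

    rSWC(t) = 100 * (mass(t) - tare - plant) / (saturated - tare - plant)

where ``tare`` is pot weight plus dry soil at the start, ``plant`` is
plant fresh mass estimated from replicates harvested on the day
withholding began (treated as constant over the window), and the
denominator is the plant-available water between saturation and the dry
reference.  Daily water use is the day-over-day mass decrement,
attributed to the plant (soil evaporation is not separated).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class PotMassRecord:
    """One daily pot weighing (g)."""

    pot_id: str
    genotype: str
    day: int
    mass: float

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if self.day < 0:
            raise ValueError(f"day must be >= 0, got {self.day}")


@dataclass(frozen=True)
class PotReference:
    """Reference masses (g) needed to convert pot mass to rSWC."""

    pot_id: str
    tare_plus_drysoil: float
    plant_mass: float
    saturated_mass: float

    def __post_init__(self) -> None:
        if self.saturated_mass <= self.tare_plus_drysoil + self.plant_mass:
            raise ValueError(
                "saturated_mass must exceed tare_plus_drysoil + plant_mass "
                f"({self.saturated_mass} <= {self.tare_plus_drysoil} + {self.plant_mass})"
            )


@dataclass(frozen=True)
class SoilWaterSeries:
    """Per-day rSWC (%) and daily water use (g day⁻¹) for one pot."""

    pot_id: str
    genotype: str
    days: tuple[int, ...]
    rswc: tuple[float, ...]
    water_use: tuple[float, ...]  # aligned with days[1:]


def rswc_series(masses: Sequence[PotMassRecord], ref: PotReference) -> SoilWaterSeries:
    """Relative soil water content and daily water use for one pot.

    Requires day 0 (the saturated start) and strictly increasing days.
    rSWC is clamped to [0, 100] with a warning when a weighing falls
    outside the reference envelope.
    """
    if len(masses) == 0:
        raise ValueError("empty mass series")
    days = np.array([m.day for m in masses])
    if days[0] != 0:
        raise ValueError("mass series must start at day 0")
    if np.any(np.diff(days) <= 0):
        raise ValueError("days must be strictly increasing per pot")
    mass = np.array([m.mass for m in masses], dtype=float)
    dry_ref = ref.tare_plus_drysoil + ref.plant_mass
    available = ref.saturated_mass - dry_ref
    rswc = 100.0 * (mass - dry_ref) / available
    if np.any(rswc < 0) or np.any(rswc > 100):
        warnings.warn(
            f"pot {ref.pot_id}: rSWC outside [0, 100] clamped "
            f"(range {rswc.min():.1f}..{rswc.max():.1f})",
            stacklevel=2,
        )
        rswc = np.clip(rswc, 0.0, 100.0)
    use = daily_water_use(masses) if len(masses) >= 2 else ()
    return SoilWaterSeries(
        pot_id=masses[0].pot_id, genotype=masses[0].genotype,
        days=tuple(int(d) for d in days), rswc=tuple(float(r) for r in rswc),
        water_use=tuple(use),
    )


def daily_water_use(masses: Sequence[PotMassRecord]) -> tuple[float, ...]:
    """Day-over-day mass decrements (g day⁻¹), aligned with days[1:].

    Negative decrements (a pot gaining mass, e.g. unlogged watering)
    are clamped to 0 with a warning.
    """
    if len(masses) < 2:
        raise ValueError("daily_water_use needs at least 2 records")
    mass = np.array([m.mass for m in masses], dtype=float)
    use = -np.diff(mass)
    if np.any(use < 0):
        warnings.warn(
            f"pot {masses[0].pot_id}: {int((use < 0).sum())} negative daily "
            "decrement(s) clamped to 0 (mass increased between weighings)",
            stacklevel=2,
        )
        use = np.maximum(use, 0.0)
    return tuple(float(u) for u in use)


def total_leaf_area(leaves: Sequence[tuple[float, float]]) -> float:
    """Whole-plant leaf area (cm²) as Σ width × length over every leaf.

    No shape-correction factor is applied.  An empty list is a plant
    with no leaves (area 0).
    """
    for w, l in leaves:
        if w <= 0 or l <= 0:
            raise ValueError(f"leaf dimensions must be positive, got ({w}, {l})")
    return float(sum(w * l for w, l in leaves))


# ---------------------------------------------------------------------------
# CSV interface

MASS_COLUMNS = ["pot_id", "genotype", "day", "mass"]
REFERENCE_COLUMNS = ["pot_id", "tare_plus_drysoil", "plant_mass", "saturated_mass"]
LEAF_AREA_COLUMNS = ["plant_id", "genotype", "width", "length"]


def read_pot_mass_csv(path: str | Path) -> dict[str, list[PotMassRecord]]:
    df = pd.read_csv(path)
    missing = set(MASS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pot-mass CSV {path} missing columns: {sorted(missing)}")
    out: dict[str, list[PotMassRecord]] = {}
    for pot_id, sub in df.groupby("pot_id", sort=True):
        sub = sub.sort_values("day")
        out[str(pot_id)] = [
            PotMassRecord(pot_id=str(r.pot_id), genotype=str(r.genotype), day=int(r.day), mass=float(r.mass))
            for r in sub.itertuples()
        ]
    return out


def read_pot_reference_csv(path: str | Path) -> dict[str, PotReference]:
    df = pd.read_csv(path)
    missing = set(REFERENCE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"pot-reference CSV {path} missing columns: {sorted(missing)}")
    return {
        str(r.pot_id): PotReference(
            pot_id=str(r.pot_id), tare_plus_drysoil=float(r.tare_plus_drysoil),
            plant_mass=float(r.plant_mass), saturated_mass=float(r.saturated_mass),
        )
        for r in df.itertuples()
    }


def read_leaf_area_csv(path: str | Path) -> pd.DataFrame:
    """Per-leaf width/length records; returns per-plant total areas."""
    df = pd.read_csv(path)
    missing = set(LEAF_AREA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"leaf-area CSV {path} missing columns: {sorted(missing)}")
    df["area"] = df["width"] * df["length"]
    return df.groupby(["plant_id", "genotype"], as_index=False).agg(total_area=("area", "sum"))


def series_to_frame(series: Sequence[SoilWaterSeries]) -> pd.DataFrame:
    """Long-format rSWC/water-use table, one row per pot × day."""
    rows = []
    for s in series:
        use_by_day = dict(zip(s.days[1:], s.water_use))
        for day, rswc in zip(s.days, s.rswc):
            rows.append({
                "pot_id": s.pot_id, "genotype": s.genotype, "day": day,
                "rswc": rswc, "water_use": use_by_day.get(day, np.nan),
            })
    return pd.DataFrame(rows)
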