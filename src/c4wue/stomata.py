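"""Stomatal patterning summaries.

Stomata are counted in four 800 × 800 µm fields of view per leaf
surface (0.64 mm² each), arranged in a transect between mid-rib and
margin on leaves four, five, and six, on both the abaxial and adaxial
surfaces.  Density is the mean over fields of count / field area;
per-plant averages of the field subsamples are the unit of replication
for all downstream statistics.  Stomatal complex width and length are
measured on six randomly chosen complexes per sample and averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

#: Area of one field of view: 800 µm × 800 µm = 0.64 mm².
DEFAULT_FIELD_AREA_MM2 = 0.64


@dataclass(frozen=True)
class StomatalFieldCount:
    """Stomata counted in one microscope field of view."""

    plant_id: str
    genotype: str
    leaf_position: int
    surface: str  # "abaxial" | "adaxial"
    field_index: int
    count: int
    field_area: float = DEFAULT_FIELD_AREA_MM2

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError(f"count must be non-negative, got {self.count}")
        if self.field_area <= 0:
            raise ValueError(f"field_area must be positive, got {self.field_area}")
        if self.surface not in ("abaxial", "adaxial"):
            raise ValueError(f"surface must be 'abaxial' or 'adaxial', got {self.surface!r}")


@dataclass(frozen=True)
class StomatalComplexMeasure:
    """Width and length (µm) of one stomatal complex, measured between
    the most extreme points.  Length is the major axis by convention;
    a width exceeding length warns (orientation ambiguity) but is kept."""

    plant_id: str
    genotype: str
    width: float
    length: float

    def __post_init__(self) -> None:
        if self.width <= 0 or self.length <= 0:
            raise ValueError("width and length must be positive")
        if self.width > self.length:
            warnings.warn(
                f"width ({self.width}) exceeds length ({self.length}) for plant "
                f"{self.plant_id}: check measurement orientation",
                stacklevel=3,
            )


@dataclass(frozen=True)
class PlantStomatalSummary:
    """Per-plant, per-surface, per-leaf density and mean complex size."""

    plant_id: str
    genotype: str
    surface: str
    leaf_position: int
    density: float  # stomata mm⁻²
    mean_width: float | None = None
    mean_length: float | None = None


def density_from_counts(fields: Sequence[StomatalFieldCount]) -> PlantStomatalSummary:
    """Stomatal density (mm⁻²) for one plant/surface/leaf from its fields.

    Density is the mean over fields of count / field_area — the
    subsample average that becomes the single replicate-plant value in
    the statistical layer.  All fields must share plant, surface, and
    leaf position.
    """
    if len(fields) == 0:
        raise ValueError("density_from_counts needs at least one field")
    keys = {(f.plant_id, f.surface, f.leaf_position) for f in fields}
    if len(keys) != 1:
        raise ValueError(f"fields mix grouping keys: {sorted(keys)}")
    f0 = fields[0]
    density = sum(f.count / f.field_area for f in fields) / len(fields)
    return PlantStomatalSummary(
        plant_id=f0.plant_id, genotype=f0.genotype, surface=f0.surface,
        leaf_position=f0.leaf_position, density=density,
    )


def complex_size_summary(measures: Sequence[StomatalComplexMeasure]) -> pd.DataFrame:
    """Per-plant mean stomatal complex width and length (µm)."""
    if len(measures) == 0:
        raise ValueError("complex_size_summary needs at least one measure")
    df = pd.DataFrame(
        {"plant_id": m.plant_id, "genotype": m.genotype, "width": m.width, "length": m.length}
        for m in measures
    )
    out = df.groupby(["plant_id", "genotype"], as_index=False).agg(
        mean_width=("width", "mean"), mean_length=("length", "mean"), n=("width", "size")
    )
    return out


def surface_contrast_table(summaries: Iterable[PlantStomatalSummary]) -> pd.DataFrame:
    """Long-format density table keyed by genotype × leaf × surface.

    One row per plant summary, ready for a two-way ANOVA with an
    interaction term and for surface contrasts across leaf positions.
    """
    rows = [
        {
            "plant_id": s.plant_id, "genotype": s.genotype,
            "leaf_position": s.leaf_position, "surface": s.surface,
            "density": s.density,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interface

COUNT_COLUMNS = ["plant_id", "genotype", "leaf_position", "surface", "field_index", "count", "field_area"]
MEASURE_COLUMNS = ["plant_id", "genotype", "width", "length"]


def read_counts_csv(path: str | Path) -> list[StomatalFieldCount]:
    df = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"stomatal counts CSV {path} missing columns: {sorted(missing)}")
    return [
        StomatalFieldCount(
            plant_id=str(r.plant_id), genotype=str(r.genotype),
            leaf_position=int(r.leaf_position), surface=str(r.surface),
            field_index=int(r.field_index), count=int(r.count), field_area=float(r.field_area),
        )
        for r in df.itertuples()
    ]


def read_measures_csv(path: str | Path) -> list[StomatalComplexMeasure]:
    df = pd.read_csv(path)
    missing = set(MEASURE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"complex measures CSV {path} missing columns: {sorted(missing)}")
    return [
        StomatalComplexMeasure(
            plant_id=str(r.plant_id), genotype=str(r.genotype),
            width=float(r.width), length=float(r.length),
        )
        for r in df.itertuples()
    ]


def summarize_counts(fields: Sequence[StomatalFieldCount]) -> pd.DataFrame:
    """All per-plant/surface/leaf densities from a flat list of fields."""
    df = pd.DataFrame(
        {
            "plant_id": f.plant_id, "genotype": f.genotype,
            "leaf_position": f.leaf_position, "surface": f.surface,
            "density": f.count / f.field_area,
        }
        for f in fields
    )
    return df.groupby(
        ["plant_id", "genotype", "leaf_position", "surface"], as_index=False
    ).agg(density=("density", "mean"))
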