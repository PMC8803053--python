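"""Adipocyte morphometry: area-range filtering and per-ROI summary statistics.

The summary mirrors spreadsheet-style COUNTIFS/AVERAGEIFS aggregation over a
detection table: objects are filtered to a plausible adipocyte area range
(default 500–100 000 µm², inclusive at both ends), then count, mean ± SD area,
mean ± SD circular-equivalent diameter and density (cells per 10⁶ µm² of the
annotated ROI) are reported. Diameters are averaged per object — the mean of
diameters, not the diameter of the mean area; for right-skewed adipocyte
size distributions the former is strictly smaller (Jensen's inequality).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import MultiPoint

from .objects import AdipocyteObject

__all__ = [
    "AreaFilter",
    "MorphometrySummary",
    "circular_diameter",
    "filter_by_area",
    "summarize",
    "summaries_to_csv",
    "objects_to_dataframe",
]


def circular_diameter(area_um2: float) -> float:
    """Circular-equivalent diameter 2·√(area/π) in µm."""
    if area_um2 < 0:
        raise ValueError(f"area must be non-negative, got {area_um2}")
    return 2.0 * math.sqrt(area_um2 / math.pi)


@dataclass(frozen=True)
class AreaFilter:
    """Inclusive adipocyte area range in µm² (spreadsheet range semantics)."""

    lower_um2: float = 500.0
    upper_um2: float = 100_000.0

    def __post_init__(self) -> None:
        if not 0 <= self.lower_um2 <= self.upper_um2:
            raise ValueError("require 0 <= lower_um2 <= upper_um2")

    def keeps(self, area_um2: float) -> bool:
        return self.lower_um2 <= area_um2 <= self.upper_um2


@dataclass
class MorphometrySummary:
    """Per-ROI morphometry. Means/SDs are NaN when undefined (count 0, or
    count 1 for SDs); density is count / ROI-area × 10⁶."""

    count: int
    mean_area_um2: float
    sd_area_um2: float
    mean_diameter_um: float
    sd_diameter_um: float
    density_per_1e6um2: float
    roi_area_um2: float
    roi_id: str = ""


def filter_by_area(
    objects: Sequence[AdipocyteObject], area_filter: AreaFilter | None = None
) -> list[AdipocyteObject]:
    """Keep objects with lower ≤ area ≤ upper; input order preserved."""
    if area_filter is None:
        area_filter = AreaFilter()
    return [o for o in objects if area_filter.keeps(o.area_um2)]


def summarize(
    objects: Sequence[AdipocyteObject],
    roi_area_um2: float | None = None,
    area_filter: AreaFilter | None = None,
    roi_id: str = "",
    density_denominator: str = "roi",
) -> MorphometrySummary:
    """Summarise a detection list over one ROI.

    ``density_denominator`` selects the density convention: ``"roi"`` (the
    annotated region's area — the default) or ``"hull"`` (area of the convex
    hull of object centroids, a tighter drawn-around-the-cells alternative).
    """
    if density_denominator not in ("roi", "hull"):
        raise ValueError("density_denominator must be 'roi' or 'hull'")
    kept = filter_by_area(objects, area_filter)
    if density_denominator == "hull":
        if len(kept) < 3:
            raise ValueError("hull density needs at least 3 detected cells")
        denom = float(MultiPoint([o.centroid_um for o in kept]).convex_hull.area)
        roi_area = denom if roi_area_um2 is None else roi_area_um2
    else:
        if roi_area_um2 is None or roi_area_um2 <= 0:
            raise ValueError("roi_area_um2 must be positive")
        denom = roi_area = float(roi_area_um2)
    if denom <= 0:
        raise ValueError("density denominator must be positive")
    n = len(kept)
    areas = np.array([o.area_um2 for o in kept], dtype=float)
    diams = np.array([o.diameter_um for o in kept], dtype=float)
    mean = lambda v: float(np.mean(v)) if n >= 1 else math.nan
    sd = lambda v: float(np.std(v, ddof=1)) if n >= 2 else math.nan
    return MorphometrySummary(
        count=n,
        mean_area_um2=mean(areas),
        sd_area_um2=sd(areas),
        mean_diameter_um=mean(diams),
        sd_diameter_um=sd(diams),
        density_per_1e6um2=n / denom * 1e6,
        roi_area_um2=roi_area,
        roi_id=roi_id,
    )


def objects_to_dataframe(objects: Iterable[AdipocyteObject]) -> pd.DataFrame:
    """Flat per-object detail table (id, area, diameter, centroid, tile)."""
    rows = [
        {
            "object_id": o.object_id,
            "pixel_count": o.pixel_count,
            "area_um2": o.area_um2,
            "diameter_um": o.diameter_um,
            "centroid_x_um": o.centroid_um[0],
            "centroid_y_um": o.centroid_um[1],
            "tile_id": o.tile_id,
        }
        for o in objects
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "object_id",
            "pixel_count",
            "area_um2",
            "diameter_um",
            "centroid_x_um",
            "centroid_y_um",
            "tile_id",
        ],
    )


def summaries_to_csv(
    summaries: Iterable[MorphometrySummary], path: str | Path
) -> pd.DataFrame:
    df = pd.DataFrame([asdict(s) for s in summaries])
    df.to_csv(path, index=False)
    return df
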