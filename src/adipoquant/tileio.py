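"""Calibrated image I/O and tiled large-area analysis.

Whole-slide scans are far too large to classify in one piece (interactive
tools freeze above ~20×10⁶ µm²; a full-slide feature stack would not fit in
memory either), so large regions are processed as a grid of tiles: each tile
has a *core* (the tiles' cores partition the ROI) plus a surrounding *halo*
wide enough that any cell crossing a core boundary is seen whole by every
tile that touches it. Objects entirely inside a core are kept directly;
objects crossing core boundaries are re-assembled by unioning their pixel
sets across neighbouring tiles in global pixel coordinates, so each cell is
counted exactly once. Peak memory is bounded by the tile size, never by the
ROI: no full-ROI raster is materialised.

Calibration source of truth: TIFF resolution tags (pixels per inch or per
centimetre); PNG images use a JSON sidecar ``<name>.calibration.json``. An
explicit µm-per-pixel override always wins.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile
import zarr
from scipy import ndimage as ndi
from shapely.geometry import Polygon, box

from .classifier import PixelClassifierModel, classify_pixels
from .image import CalibratedImage, CalibrationError, ClassMask
from .morphometry import AreaFilter, MorphometrySummary, summarize
from .objects import (
    AdipocyteObject,
    ObjectBuilderSettings,
    mask_to_objects,
    objects_from_labels,
    _build_label_mask,
)

logger = logging.getLogger("adipoquant")

__all__ = [
    "read_image",
    "read_region",
    "write_image",
    "TilePlan",
    "plan_tiles",
    "tiled_analysis",
    "objects_to_geojson",
    "read_roi_geojson",
]

INCH_UM = 25400.0
CM_UM = 10000.0


# ---------------------------------------------------------------------------
# Calibrated read/write


def write_image(image: CalibratedImage, path: str | Path) -> Path:
    """Write PNG (with calibration sidecar) or TIFF (with resolution tags).

    TIFFs larger than ~16 Mpx are written tiled so regions can be read back
    without loading the full raster.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        kwargs = {}
        if image.pixels.shape[0] * image.pixels.shape[1] > 16e6:
            kwargs["tile"] = (512, 512)
        if image.pixel_size_um is not None:
            ppcm = CM_UM / image.pixel_size_um
            kwargs["resolution"] = (ppcm, ppcm)
            kwargs["resolutionunit"] = "CENTIMETER"
        tifffile.imwrite(path, image.pixels, photometric="rgb", **kwargs)
    elif suffix == ".png":
        iio.imwrite(path, image.pixels)
        if image.pixel_size_um is not None:
            sidecar = path.with_suffix(path.suffix + ".calibration.json")
            sidecar.write_text(
                json.dumps({"pixel_size_um": image.pixel_size_um}, sort_keys=True) + "\n"
            )
    else:
        raise ValueError(f"unsupported image format: {suffix}")
    return path


def _tiff_pixel_size(page: tifffile.TiffPage) -> float | None:
    try:
        xres = page.tags["XResolution"].value
        unit = page.tags["ResolutionUnit"].value
    except KeyError:
        return None
    num, den = (xres if isinstance(xres, tuple) else (xres, 1))
    if num == 0:
        return None
    per_px = den / num  # units per pixel
    unit = int(unit)
    if unit == 2:  # inch
        return per_px * INCH_UM
    if unit == 3:  # centimetre
        return per_px * CM_UM
    return None


def _png_pixel_size(path: Path) -> float | None:
    sidecar = path.with_suffix(path.suffix + ".calibration.json")
    if sidecar.exists():
        return float(json.loads(sidecar.read_text())["pixel_size_um"])
    return None


def read_image(path: str | Path, mpp: float | None = None) -> CalibratedImage:
    """Read a full image with its calibration (``mpp`` override wins)."""
    return read_region(path, bbox_um=None, mpp=mpp)


def read_region(
    path: str | Path,
    bbox_um: tuple[float, float, float, float] | None = None,
    mpp: float | None = None,
) -> CalibratedImage:
    """Read the µm bounding box ``(x0, y0, x1, y1)`` from a PNG or TIFF.

    The box is snapped outward to whole pixels; ``origin_um`` of the result
    is set so exported polygons land in slide coordinates. For tiled TIFFs
    only the needed chunks are read. Missing calibration with no ``mpp``
    override is an error, as is a box extending outside the image.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            pixel_size = mpp if mpp is not None else _tiff_pixel_size(page)
            if pixel_size is None:
                raise CalibrationError(
                    f"{path.name}: no resolution tags and no --mpp override"
                )
            shape = page.shape[:2]
            if bbox_um is None:
                return CalibratedImage(page.asarray(), pixel_size, (0.0, 0.0))
            r0, r1, c0, c1 = _bbox_to_px(bbox_um, pixel_size, shape, path.name)
            z = zarr.open(tf.aszarr(), mode="r")
            pixels = np.asarray(z[r0:r1, c0:c1])
            return CalibratedImage(
                pixels, pixel_size, (c0 * pixel_size, r0 * pixel_size)
            )
    if suffix == ".png":
        pixels = np.asarray(iio.imread(path))
        if pixels.ndim == 2:
            pixels = np.stack([pixels] * 3, axis=-1)
        pixel_size = mpp if mpp is not None else _png_pixel_size(path)
        if pixel_size is None:
            raise CalibrationError(
                f"{path.name}: no calibration sidecar and no --mpp override"
            )
        if bbox_um is None:
            return CalibratedImage(pixels, pixel_size, (0.0, 0.0))
        r0, r1, c0, c1 = _bbox_to_px(bbox_um, pixel_size, pixels.shape[:2], path.name)
        return CalibratedImage(
            pixels[r0:r1, c0:c1], pixel_size, (c0 * pixel_size, r0 * pixel_size)
        )
    raise ValueError(f"unsupported image format: {suffix}")


def _bbox_to_px(
    bbox_um: tuple[float, float, float, float],
    pixel_size: float,
    shape: tuple[int, int],
    name: str,
) -> tuple[int, int, int, int]:
    x0, y0, x1, y1 = bbox_um
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"empty bbox {bbox_um}")
    c0 = int(math.floor(x0 / pixel_size + 1e-9))
    r0 = int(math.floor(y0 / pixel_size + 1e-9))
    c1 = int(math.ceil(x1 / pixel_size - 1e-9))
    r1 = int(math.ceil(y1 / pixel_size - 1e-9))
    if r0 < 0 or c0 < 0 or r1 > shape[0] or c1 > shape[1]:
        raise ValueError(
            f"{name}: bbox {bbox_um} µm exceeds image extent "
            f"{shape[1] * pixel_size} × {shape[0] * pixel_size} µm"
        )
    return r0, r1, c0, c1


# ---------------------------------------------------------------------------
# Tile planning


@dataclass
class TilePlan:
    """Core/halo tiling of a ROI bounding box (all µm).

    ``cores`` partition the ROI bbox exactly once; ``windows`` are the cores
    expanded by the halo and clipped to the image bounds.
    """

    tile_size_um: float
    halo_um: float
    cores: list[tuple[float, float, float, float]]
    windows: list[tuple[float, float, float, float]]


def plan_tiles(
    roi_bbox_um: tuple[float, float, float, float],
    image_extent_um: tuple[float, float],
    tile_size_um: float = 2000.0,
    halo_um: float = 200.0,
    grid_um: float = 1.0,
    expected_max_cell_diameter_um: float = 150.0,
) -> TilePlan:
    """Grid the ROI bbox into cores of ``tile_size_um`` with ``halo_um`` overlap.

    All bounds are snapped to multiples of ``grid_um`` (the working pixel
    size) so tile rasters align with the global working grid. A halo below
    half the expected maximum cell diameter risks cross-boundary cells not
    being seen whole by any tile and triggers a warning.
    """
    if halo_um < expected_max_cell_diameter_um / 2.0:
        logger.warning(
            "halo %.0f µm is below half the expected max cell diameter (%.0f µm); "
            "cells crossing tile cores may merge incompletely",
            halo_um,
            expected_max_cell_diameter_um,
        )
    snap = lambda v, up: (math.ceil if up else math.floor)(v / grid_um + (1e-9 if up else -1e-9) * 0) * grid_um
    x0, y0, x1, y1 = roi_bbox_um
    x0, y0 = snap(x0, False), snap(y0, False)
    x1, y1 = snap(x1, True), snap(y1, True)
    W, H = image_extent_um
    cores, windows = [], []
    ny = max(1, math.ceil((y1 - y0) / tile_size_um))
    nx = max(1, math.ceil((x1 - x0) / tile_size_um))
    for iy in range(ny):
        for ix in range(nx):
            cx0 = x0 + ix * tile_size_um
            cy0 = y0 + iy * tile_size_um
            cx1 = min(x1, cx0 + tile_size_um)
            cy1 = min(y1, cy0 + tile_size_um)
            core = (snap(cx0, False), snap(cy0, False), snap(cx1, True), snap(cy1, True))
            win = (
                max(0.0, snap(cx0 - halo_um, False)),
                max(0.0, snap(cy0 - halo_um, False)),
                min(snap(W, False), snap(cx1 + halo_um, True)),
                min(snap(H, False), snap(cy1 + halo_um, True)),
            )
            cores.append(core)
            windows.append(win)
    return TilePlan(tile_size_um, halo_um, cores, windows)


# ---------------------------------------------------------------------------
# Tiled analysis with cross-boundary merging


class _RegionSource:
    """Uniform region access for an on-disk image or an in-memory one."""

    def __init__(self, source: str | Path | CalibratedImage, mpp: float | None = None):
        self._image = source if isinstance(source, CalibratedImage) else None
        self._path = None if self._image is not None else Path(source)
        self._mpp = mpp
        if self._image is not None:
            self._pixel_size = self._image.require_calibration()
            self._extent = (self._image.width_um, self._image.height_um)
        else:
            probe = read_region(self._path, bbox_um=(0, 0, 1, 1), mpp=mpp) if (
                self._path.suffix.lower() in (".tif", ".tiff")
            ) else read_image(self._path, mpp=mpp)
            self._pixel_size = probe.require_calibration()
            if self._path.suffix.lower() in (".tif", ".tiff"):
                with tifffile.TiffFile(self._path) as tf:
                    shape = tf.pages[0].shape[:2]
            else:
                shape = iio.imread(self._path).shape[:2]
            self._extent = (shape[1] * self._pixel_size, shape[0] * self._pixel_size)

    @property
    def pixel_size_um(self) -> float:
        return self._pixel_size

    @property
    def extent_um(self) -> tuple[float, float]:
        return self._extent

    def read(self, bbox_um: tuple[float, float, float, float]) -> CalibratedImage:
        if self._image is not None:
            ps = self._pixel_size
            r0, r1, c0, c1 = _bbox_to_px(
                bbox_um, ps, self._image.pixels.shape[:2], "<memory>"
            )
            return CalibratedImage(
                self._image.pixels[r0:r1, c0:c1],
                ps,
                (
                    self._image.origin_um[0] + c0 * ps,
                    self._image.origin_um[1] + r0 * ps,
                ),
            )
        return read_region(self._path, bbox_um, mpp=self._mpp)


def tiled_analysis(
    source: str | Path | CalibratedImage,
    model: PixelClassifierModel,
    roi_polygon: Polygon | None = None,
    settings: ObjectBuilderSettings | None = None,
    area_filter: AreaFilter | None = None,
    tile_size_um: float = 2000.0,
    halo_um: float = 200.0,
    mpp: float | None = None,
    roi_id: str = "",
) -> tuple[list[AdipocyteObject], MorphometrySummary]:
    """Classify → create objects tile by tile, merging cells that cross cores.

    Returns the deduplicated object list (slide µm coordinates) and the
    morphometry summary computed over the merged set with the ROI polygon
    area as the density denominator.
    """
    if settings is None:
        settings = ObjectBuilderSettings()
    src = _RegionSource(source, mpp=mpp)
    W, H = src.extent_um
    if roi_polygon is None:
        roi_polygon = box(0.0, 0.0, W, H)
    wps = model.working_pixel_size_um
    bounds = roi_polygon.bounds
    plan = plan_tiles(bounds, (W, H), tile_size_um, halo_um, grid_um=wps)

    interior: list[AdipocyteObject] = []
    boundary_coords: list[np.ndarray] = []  # encoded global px per object
    boundary_tile: list[str] = []
    pixel_owner: dict[int, int] = {}
    parent: list[int] = []

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    n_cols_global = int(math.ceil(W / wps)) + 2

    for t, (core, window) in enumerate(zip(plan.cores, plan.windows)):
        tile_id = f"tile{t:04d}"
        if not roi_polygon.intersects(box(*window)):
            continue
        image = src.read(window)
        mask = classify_pixels(model, image, roi_polygon=roi_polygon, image_id=tile_id)
        labels = _build_label_mask(mask, settings)
        n = int(labels.max())
        if n == 0:
            continue
        # Global working-grid offsets of this window.
        off_c = int(round(window[0] / wps))
        off_r = int(round(window[1] / wps))
        core_c0 = int(round(core[0] / wps))
        core_r0 = int(round(core[1] / wps))
        core_c1 = int(round(core[2] / wps))
        core_r1 = int(round(core[3] / wps))
        slices = ndi.find_objects(labels)
        for lab in range(1, n + 1):
            sl = slices[lab - 1]
            if sl is None:
                continue
            g_r0, g_r1 = sl[0].start + off_r, sl[0].stop + off_r
            g_c0, g_c1 = sl[1].start + off_c, sl[1].stop + off_c
            in_core = (
                g_r0 >= core_r0 and g_r1 <= core_r1 and g_c0 >= core_c0 and g_c1 <= core_c1
            )
            touches_core = (
                g_r1 > core_r0 and g_r0 < core_r1 and g_c1 > core_c0 and g_c0 < core_c1
            )
            if in_core:
                sub = np.zeros(labels[sl].shape, dtype=np.int32)
                sub[labels[sl] == lab] = 1
                submask = ClassMask(
                    sub > 0,
                    wps,
                    (g_c0 * wps, g_r0 * wps),
                    mask.provenance,
                )
                objs = objects_from_labels(sub, submask, tile_id=tile_id)
                interior.extend(objs)
            elif touches_core:
                rr, cc = np.nonzero(labels[sl] == lab)
                enc = (rr + g_r0).astype(np.int64) * n_cols_global + (cc + g_c0)
                idx = len(boundary_coords)
                boundary_coords.append(enc)
                boundary_tile.append(tile_id)
                parent.append(idx)
                for e in enc:
                    owner = pixel_owner.get(int(e))
                    if owner is None:
                        pixel_owner[int(e)] = idx
                    else:
                        union(owner, idx)
            # else: entirely in the halo; some neighbour's core owns it.

    merged_objects = _merge_boundary_objects(
        boundary_coords, boundary_tile, parent, find, n_cols_global, wps, halo_um
    )
    all_objects = interior + merged_objects
    for i, obj in enumerate(all_objects, start=1):
        obj.object_id = i
    summary = summarize(
        all_objects,
        roi_area_um2=float(roi_polygon.area),
        area_filter=area_filter,
        roi_id=roi_id,
    )
    return all_objects, summary


def _merge_boundary_objects(
    boundary_coords: list[np.ndarray],
    boundary_tile: list[str],
    parent: list[int],
    find,
    n_cols_global: int,
    wps: float,
    halo_um: float,
) -> list[AdipocyteObject]:
    groups: dict[int, list[int]] = {}
    for i in range(len(boundary_coords)):
        groups.setdefault(find(i), []).append(i)
    merged: list[AdipocyteObject] = []
    for root, members in sorted(groups.items()):
        enc = np.unique(np.concatenate([boundary_coords[m] for m in members]))
        rows = enc // n_cols_global
        cols = enc % n_cols_global
        r0, r1 = int(rows.min()), int(rows.max()) + 1
        c0, c1 = int(cols.min()), int(cols.max()) + 1
        span_um = max(r1 - r0, c1 - c0) * wps
        if span_um > halo_um:
            logger.warning(
                "merged object near (%.0f, %.0f) µm spans %.0f µm > halo %.0f µm; "
                "its union across tiles may be incomplete",
                c0 * wps,
                r0 * wps,
                span_um,
                halo_um,
            )
        sub = np.zeros((r1 - r0, c1 - c0), dtype=np.int32)
        sub[rows - r0, cols - c0] = 1
        submask = ClassMask(sub > 0, wps, (c0 * wps, r0 * wps), "merged")
        tile_id = "+".join(sorted({boundary_tile[m] for m in members}))
        merged.extend(objects_from_labels(sub, submask, tile_id=tile_id))
    return merged


# ---------------------------------------------------------------------------
# GeoJSON for objects and ROIs


def objects_to_geojson(objects: list[AdipocyteObject], path: str | Path) -> None:
    """Export detections as a GeoJSON FeatureCollection in µm coordinates,
    importable by common slide viewers."""
    features = []
    for o in objects:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [np.asarray(o.boundary_polygon_um).tolist()],
                },
                "properties": {
                    "object_id": o.object_id,
                    "classification": "adipocyte",
                    "area_um2": o.area_um2,
                    "diameter_um": o.diameter_um,
                    "centroid_x_um": o.centroid_um[0],
                    "centroid_y_um": o.centroid_um[1],
                    "tile_id": o.tile_id,
                },
            }
        )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True) + "\n")


def read_roi_geojson(path: str | Path) -> Polygon:
    """Read the first polygon of a GeoJSON file as the ROI (µm coordinates)."""
    from shapely.geometry import shape as shapely_shape
    from shapely.ops import unary_union

    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in doc["features"]]
    elif doc.get("type") == "Feature":
        geoms = [shapely_shape(doc["geometry"])]
    else:
        geoms = [shapely_shape(doc)]
    if not geoms:
        raise ValueError(f"{path}: no geometry found")
    return unary_union(geoms)
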