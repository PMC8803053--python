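"""Calibrated raster images.

Every length threshold downstream (object size, hole size, area filters) is
expressed in µm or µm², so each image carries its µm-per-pixel calibration and
the µm offset of pixel (0, 0) in slide coordinates. Pixel (i, j) covers the
slide-square [origin + j*mpp, origin + (j+1)*mpp) × [... i ...); its centre is
at origin + (j + 0.5, i + 0.5) * mpp.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize


class CalibrationError(ValueError):
    """Raised when an operation needs a µm-per-pixel calibration that is absent."""


@dataclass
class CalibratedImage:
    """An 8-bit RGB image with physical calibration.

    Parameters
    ----------
    pixels:
        ``(H, W, 3)`` uint8 array.
    pixel_size_um:
        Side of one pixel in µm (µm per pixel). ``None`` marks an
        uncalibrated image, which is rejected by every quantitative step.
    origin_um:
        Slide-coordinate (x, y) of the top-left corner of pixel (0, 0), µm.
    """

    pixels: np.ndarray
    pixel_size_um: float | None
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) RGB array, got {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def width_um(self) -> float:
        self.require_calibration()
        return self.pixels.shape[1] * float(self.pixel_size_um)

    @property
    def height_um(self) -> float:
        self.require_calibration()
        return self.pixels.shape[0] * float(self.pixel_size_um)

    def require_calibration(self) -> float:
        if self.pixel_size_um is None:
            raise CalibrationError(
                "image has no µm-per-pixel calibration; supply pixel_size_um "
                "(e.g. via an --mpp override) before quantitative analysis"
            )
        return float(self.pixel_size_um)


@dataclass
class ClassMask:
    """Binary fat mask at the classifier's working resolution.

    ``mask`` is True where the pixel was called *fat lumen*; everything else
    (stained membrane, other tissue, outside-ROI) is False.
    """

    mask: np.ndarray
    pixel_size_um: float
    origin_um: tuple[float, float] = (0.0, 0.0)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_um is None or self.pixel_size_um <= 0:
            raise CalibrationError("ClassMask requires a positive pixel_size_um")

    @property
    def pixel_area_um2(self) -> float:
        return float(self.pixel_size_um) ** 2


def resample_to_working(
    image: CalibratedImage, working_pixel_size_um: float
) -> np.ndarray:
    """Return the RGB pixels resampled to ``working_pixel_size_um`` as float32 in [0, 255].

    Downsampling uses local-mean anti-aliasing; identical resolutions pass the
    pixel data through unchanged (as float32). Integer downsampling factors
    that divide the image evenly take an exact block-mean fast path.
    """
    src = image.require_calibration()
    if working_pixel_size_um < src:
        raise ValueError(
            f"working pixel size {working_pixel_size_um} µm finer than source {src} µm"
        )
    if np.isclose(working_pixel_size_um, src):
        return image.pixels.astype(np.float32)
    ratio = working_pixel_size_um / src
    n = int(round(ratio))
    h, w = image.pixels.shape[:2]
    if np.isclose(ratio, n) and h % n == 0 and w % n == 0:
        blocks = image.pixels.reshape(h // n, n, w // n, n, 3).astype(np.float32)
        return blocks.mean(axis=(1, 3))
    scale = src / working_pixel_size_um
    out_shape = (
        max(1, int(round(image.pixels.shape[0] * scale))),
        max(1, int(round(image.pixels.shape[1] * scale))),
        3,
    )
    out = resize(
        image.pixels.astype(np.float32),
        out_shape,
        order=1,
        anti_aliasing=True,
        preserve_range=True,
    )
    return out.astype(np.float32)
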