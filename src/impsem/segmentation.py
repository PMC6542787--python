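"""STEM micrograph segmentation and per-particle geometry.

Bright-field transmission contrast renders particles dark on a bright
substrate.  Segmentation is a manually set global threshold or a mean
adaptive threshold, followed by connected-component labelling; each
component becomes a :class:`ParticleRecord` with area, equivalent
circular diameter (ECD = 2 sqrt(A/pi)), perimeter, circularity
(4 pi A / P^2) and aspect ratio (major/minor axis of the inertia
ellipse), all in physical units via the pixel size.

Frames acquired on the metal grid bars carry no signal and are dropped
by :func:`discard_blank` before any statistics are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ConfigError


@dataclass
class MicrographImage:
    """A grayscale micrograph plus acquisition metadata.

    ``stage_x``/``stage_y`` are the microscope stage coordinates of the
    frame centre in micrometres; ``pixel_size`` is in nm per pixel.
    """

    pixels: np.ndarray
    pixel_size: float  # nm / px
    stage_x: float = 0.0  # um
    stage_y: float = 0.0  # um
    image_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("micrograph must be a 2-D grayscale array")
        if min(self.pixels.shape) < 64:
            raise ValueError("micrograph must be at least 64x64 pixels")
        if not self.pixel_size > 0:
            raise ValueError("pixel size must be positive")

    @property
    def area_um2(self) -> float:
        """Imaged area in um^2."""
        h, w = self.pixels.shape
        return h * w * (self.pixel_size * 1e-3) ** 2


@dataclass(frozen=True)
class SegmentationConfig:
    """Thresholding and labelling parameters.

    ``global_threshold`` and ``adaptive_offset`` are in intensity units
    of the image; ``adaptive_window`` must be odd.  ``min_area`` (px)
    sets the detection limit; components touching the frame edge are
    dropped under ``border_policy='exclude'``.
    """

    mode: str = "global"  # global | adaptive_mean
    global_threshold: float = 128.0
    adaptive_window: int = 51
    adaptive_offset: float = 10.0
    polarity: str = "dark_particles"  # dark_particles | bright_particles
    min_area: int = 30
    connectivity: int = 8  # 4 | 8
    border_policy: str = "exclude"  # exclude | include
    fill_holes: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("global", "adaptive_mean"):
            raise ConfigError(f"unknown segmentation mode {self.mode!r}")
        if self.polarity not in ("dark_particles", "bright_particles"):
            raise ConfigError(f"unknown polarity {self.polarity!r}")
        if self.adaptive_window < 3 or self.adaptive_window % 2 == 0:
            raise ConfigError("adaptive window must be odd and >= 3")
        if self.min_area < 1:
            raise ConfigError("min_area must be >= 1")
        if self.connectivity not in (4, 8):
            raise ConfigError("connectivity must be 4 or 8")
        if self.border_policy not in ("exclude", "include"):
            raise ConfigError(f"unknown border policy {self.border_policy!r}")


@dataclass(frozen=True)
class ParticleRecord:
    """Geometry of one segmented particle, in physical units."""

    particle_id: int
    image_id: str
    area: float  # nm^2
    ecd: float  # nm
    perimeter: float  # nm
    circularity: float  # (0, 1], clipped
    aspect_ratio: float  # >= 1
    centroid_x: float  # px, 0-based, x = column
    centroid_y: float  # px, 0-based, y = row
    touches_border: bool


def discard_blank(image: MicrographImage, variance_floor: float = 8.0,
                  mean_bounds: tuple[float, float] = (1.0, 254.0)) -> bool:
    """True when a frame carries no usable signal.

    A frame is blank when its intensity standard deviation falls below
    ``variance_floor`` (flat frame: beam on a grid bar, or featureless
    substrate below the noise floor) or its mean lies outside
    ``mean_bounds`` (dead or saturated detector).  Defaults assume
    8-bit-scaled intensities.
    """
    px = np.asarray(image.pixels, dtype=float)
    mean = float(px.mean())
    return bool(px.std() < variance_floor
                or not (mean_bounds[0] <= mean <= mean_bounds[1]))


def segment(image: MicrographImage, config: SegmentationConfig) -> np.ndarray:
    """Binary foreground mask of particle pixels.

    Global mode compares each pixel with ``global_threshold``; adaptive
    mode compares it with the local window mean offset by
    ``adaptive_offset`` towards the background, which tolerates slow
    illumination gradients.  Holes inside components are filled when
    ``fill_holes`` is set so hollow-looking projections count their full
    projected area.
    """
    px = np.asarray(image.pixels, dtype=float)
    dark = config.polarity == "dark_particles"
    if config.mode == "global":
        mask = px < config.global_threshold if dark else px > config.global_threshold
    else:
        if config.adaptive_window > min(px.shape):
            raise ConfigError(
                f"adaptive window {config.adaptive_window} exceeds image "
                f"size {min(px.shape)}")
        local_mean = ndimage.uniform_filter(px, size=config.adaptive_window,
                                            mode="reflect")
        if dark:
            mask = px < local_mean - config.adaptive_offset
        else:
            mask = px > local_mean + config.adaptive_offset
    if config.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    return mask.astype(bool)


def _touches_border(prop, shape) -> bool:
    minr, minc, maxr, maxc = prop.bbox
    return minr == 0 or minc == 0 or maxr == shape[0] or maxc == shape[1]


def extract_particles(mask: np.ndarray, image: MicrographImage,
                      config: SegmentationConfig) -> list[ParticleRecord]:
    """Connected components of ``mask`` as particle records.

    Components smaller than ``min_area`` px are dropped; border-touching
    components are dropped under the exclude policy.  Touching particles
    are deliberately not split: co-deposition is a sampling condition to
    avoid, not a segmentation problem to solve.
    """
    if mask.shape != image.pixels.shape:
        raise ValueError("mask and image shapes differ")
    skim_conn = 1 if config.connectivity == 4 else 2
    labels = measure.label(mask, connectivity=skim_conn)
    ps = image.pixel_size
    records: list[ParticleRecord] = []
    for prop in measure.regionprops(labels):
        if prop.area < config.min_area:
            continue
        touches = _touches_border(prop, mask.shape)
        if touches and config.border_policy == "exclude":
            continue
        area_nm2 = prop.area * ps * ps
        perim_nm = prop.perimeter * ps
        circ = 4.0 * math.pi * area_nm2 / perim_nm**2 if perim_nm > 0 else 1.0
        minor = prop.axis_minor_length
        major = prop.axis_major_length
        aspect = major / minor if minor > 0 else float("inf")
        cy, cx = prop.centroid
        records.append(ParticleRecord(
            particle_id=len(records) + 1,
            image_id=image.image_id,
            area=area_nm2,
            ecd=2.0 * math.sqrt(area_nm2 / math.pi),
            perimeter=perim_nm,
            circularity=min(circ, 1.0),
            aspect_ratio=max(aspect, 1.0),
            centroid_x=float(cx), centroid_y=float(cy),
            touches_border=touches))
    return records


def detection_limit(config: SegmentationConfig, pixel_size: float) -> float:
    """Smallest reportable ECD in nm: the ECD of a min_area component."""
    return 2.0 * pixel_size * math.sqrt(config.min_area / math.pi)


def segment_image(image: MicrographImage,
                  config: SegmentationConfig) -> list[ParticleRecord]:
    """Convenience: segment then extract particle records."""
    return extract_particles(segment(image, config), image, config)
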