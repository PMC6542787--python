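"""Shared fixtures: reference curve, rendered fixtures with ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from impsem.collection_efficiency import EfficiencyCurve
from impsem.segmentation import MicrographImage, ParticleRecord
from impsem.synthetic import FrameGeometry, render_micrograph


@pytest.fixture()
def reference_curve() -> EfficiencyCurve:
    """Bounce-limited sigmoid efficiency of a 0.29 mm round-jet stage."""
    return EfficiencyCurve(cmax=0.53, d50=73.0, steepness=2.29)


def random_disk_fixture(seed: int, n_disks: int = 6, frame_px: int = 256,
                        pixel_size: float = 3.7, noise_sigma: float = 7.5,
                        d_range=(90.0, 280.0)):
    """Non-overlapping random disks with ground truth.

    Rejection-samples centres so disks never touch and stay clear of the
    frame border; noise defaults to 5 % of the 150-intensity contrast.
    Returns (image, truth table).
    """
    rng = np.random.default_rng(seed)
    diams = np.sort(rng.uniform(*d_range, size=n_disks))[::-1]
    radii_px = diams / (2.0 * pixel_size)
    xs, ys, placed = [], [], []
    for r, d in zip(radii_px, diams):  # biggest first packs reliably
        for _ in range(4000):
            x = rng.uniform(r + 6, frame_px - r - 6)
            y = rng.uniform(r + 6, frame_px - r - 6)
            if all((x - xo) ** 2 + (y - yo) ** 2 > (r + ro + 4) ** 2
                   for xo, yo, ro in zip(xs, ys, placed)):
                xs.append(x)
                ys.append(y)
                placed.append(r)
                break
        else:  # pragma: no cover - generous retry budget
            raise RuntimeError("could not place disks without overlap")
    truth = pd.DataFrame({"x_px": xs, "y_px": ys,
                          "diameter_nm": diams[:len(xs)]})
    frame = FrameGeometry(width_px=frame_px, height_px=frame_px,
                          pixel_size_nm=pixel_size,
                          image_id=f"fixture_{seed}")
    image, truth = render_micrograph(truth, frame, noise_sigma=noise_sigma,
                                     seed=seed + 1)
    return image, truth


def grid_frame_images(extent_um: float, n_per_side: int,
                      frame_px: int = 64) -> list[MicrographImage]:
    """Square grid of small frames tiling [-extent, extent]^2."""
    centers = np.linspace(-extent_um, extent_um, n_per_side)
    pitch = centers[1] - centers[0] if n_per_side > 1 else 2 * extent_um
    pixel_size = pitch * 1e3 / frame_px  # frames tile the plane
    pixels = np.full((frame_px, frame_px), 200.0)
    return [MicrographImage(pixels=pixels, pixel_size=pixel_size,
                            stage_x=float(cx), stage_y=float(cy),
                            image_id=f"g_{i}_{j}")
            for i, cx in enumerate(centers)
            for j, cy in enumerate(centers)]


def records_from_positions(positions: pd.DataFrame,
                           images: list[MicrographImage]
                           ) -> list[ParticleRecord]:
    """Ideal particle records for deposited particles inside frames.

    ECD is taken as the true diameter (perfect segmentation); particles
    outside every frame are dropped, matching what imaging would see.
    """
    x = positions["x_um"].to_numpy()
    y = positions["y_um"].to_numpy()
    d = positions["diameter_nm"].to_numpy()
    records = []
    pid = 1
    for im in images:
        h, w = im.pixels.shape
        half_w = w * im.pixel_size * 1e-3 / 2.0
        half_h = h * im.pixel_size * 1e-3 / 2.0
        inside = ((np.abs(x - im.stage_x) < half_w)
                  & (np.abs(y - im.stage_y) < half_h))
        for xi, yi, di in zip(x[inside], y[inside], d[inside]):
            cx = (xi - im.stage_x + half_w) * 1e3 / im.pixel_size
            cy = (yi - im.stage_y + half_h) * 1e3 / im.pixel_size
            records.append(ParticleRecord(
                particle_id=pid, image_id=im.image_id,
                area=np.pi * (di / 2) ** 2, ecd=float(di),
                perimeter=np.pi * di, circularity=1.0, aspect_ratio=1.0,
                centroid_x=float(cx), centroid_y=float(cy),
                touches_border=False))
            pid += 1
    return records
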