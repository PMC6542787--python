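"""Size-resolved radial deposition pattern analysis.

A tapered round jet focuses particles aerodynamically: the larger the
particle above the cut-off, the closer to the impact centre (and the
narrower the ring) it deposits, while particles near and below the
cut-off spread almost uniformly.  This module maps per-image particle
statistics onto normalized radial distance from the impact centre (in
units of orifice radius), averages them per TEM grid square to even out
local film deflection, and fits a Gaussian radial trend per size bin.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

from .errors import InsufficientDataError, ManifestError
from .segmentation import MicrographImage, ParticleRecord

#: 400 mesh TEM grid pitch in micrometres (25.4 mm / 400).
DEFAULT_GRID_PITCH_UM = 63.5
#: Images must reach this many orifice radii to capture all sizes above
#: the cut-off.
REQUIRED_RADIAL_EXTENT = 1.5


@dataclass(frozen=True)
class SizeBinning:
    """Ascending ECD bin edges in nm; the last edge may be +inf."""

    edges: tuple = (0.0, 80.0, 160.0, 240.0, math.inf)

    def __post_init__(self) -> None:
        e = self.edges
        if len(e) < 2 or any(b <= a for a, b in zip(e, e[1:])):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        out = []
        for a, b in zip(self.edges, self.edges[1:]):
            out.append(f">{a:g}" if math.isinf(b) else f"{a:g}-{b:g}")
        return out

    def assign(self, ecd) -> np.ndarray:
        """Bin index per ECD value; -1 when outside all bins."""
        idx = np.searchsorted(self.edges, np.asarray(ecd, dtype=float),
                              side="right") - 1
        idx[np.asarray(ecd) >= self.edges[-1]] = -1
        return np.where((idx >= 0) & (idx < len(self.edges) - 1), idx, -1)


@dataclass(frozen=True)
class RadialGaussianFit:
    """Gaussian trend a * exp(-(r - r0)^2 / (2 sigma^2)) for one bin."""

    amplitude: float
    center: float  # orifice-radius units
    width: float  # orifice-radius units
    converged: bool = True
    unconstrained: bool = False


def _images_by_id(images) -> dict[str, MicrographImage]:
    if isinstance(images, dict):
        return images
    return {im.image_id: im for im in images}


def particle_stage_positions(records: list[ParticleRecord],
                             images) -> pd.DataFrame:
    """Stage coordinates (um) of each particle.

    The particle position is the image stage centre plus the pixel
    offset of the particle centroid from the frame centre, converted via
    the pixel size.  Columns: image_id, ecd, x_um, y_um.
    """
    imgs = _images_by_id(images)
    rows = []
    for rec in records:
        if rec.image_id not in imgs:
            raise ManifestError(f"record references unknown image "
                                f"{rec.image_id!r}")
        im = imgs[rec.image_id]
        h, w = im.pixels.shape
        scale = im.pixel_size * 1e-3  # nm/px -> um/px
        rows.append((rec.image_id, rec.ecd,
                     im.stage_x + (rec.centroid_x - w / 2) * scale,
                     im.stage_y + (rec.centroid_y - h / 2) * scale))
    return pd.DataFrame(rows, columns=["image_id", "ecd", "x_um", "y_um"])


def estimate_impact_center(records: list[ParticleRecord], images,
                           min_ecd: float = 240.0) -> tuple[float, float]:
    """Impact centre (um) from the positions of the largest particles.

    Particles well above the cut-off deposit in a tight spot under the
    nozzle, so the centroid of particles with ECD >= ``min_ecd``
    localizes the centre.  Falls back (with a warning) to all particles
    when none qualify.
    """
    if not records:
        raise InsufficientDataError("no particles to locate the centre from")
    pos = particle_stage_positions(records, images)
    big = pos[pos["ecd"] >= min_ecd]
    if big.empty:
        warnings.warn(f"no particles above {min_ecd} nm; falling back to "
                      "the centroid of all particles", stacklevel=2)
        big = pos
    return float(big["x_um"].mean()), float(big["y_um"].mean())


def normalized_radius(image: MicrographImage, center: tuple[float, float],
                      orifice_radius_um: float) -> float:
    """Stage distance from frame centre to impact centre, over R."""
    if orifice_radius_um <= 0:
        raise ValueError("orifice radius must be positive")
    return math.hypot(image.stage_x - center[0],
                      image.stage_y - center[1]) / orifice_radius_um


def density_profile(records: list[ParticleRecord], images,
                    bins: SizeBinning = SizeBinning(),
                    center: tuple[float, float] | None = None,
                    orifice_radius_um: float | None = None) -> pd.DataFrame:
    """Per-image, per-size-bin counts and number densities (um^-2).

    One row per image with columns image_id, stage_x, stage_y, area_um2,
    count_<bin>, density_<bin>, plus normalized radius columns ``r``
    (absolute) and ``r_signed`` (signed along the dominant axis of the
    image positions, for line-scan plots) when ``center`` and
    ``orifice_radius_um`` are given.
    """
    imgs = _images_by_id(images)
    for rec in records:
        if rec.image_id not in imgs:
            raise ManifestError(f"record references unknown image "
                                f"{rec.image_id!r}")
    labels = bins.labels
    rec_df = pd.DataFrame({"image_id": [r.image_id for r in records],
                           "bin": bins.assign([r.ecd for r in records])
                           if records else np.empty(0, dtype=int)})
    counts = (rec_df[rec_df["bin"] >= 0]
              .groupby(["image_id", "bin"]).size().unstack(fill_value=0)
              if len(rec_df) else pd.DataFrame())
    rows = []
    for iid, im in imgs.items():
        row = {"image_id": iid, "stage_x": im.stage_x, "stage_y": im.stage_y,
               "area_um2": im.area_um2}
        for k, lab in enumerate(labels):
            n = int(counts.loc[iid, k]) if (iid in counts.index
                                            and k in counts.columns) else 0
            row[f"count_{lab}"] = n
            row[f"density_{lab}"] = n / im.area_um2
        rows.append(row)
    df = pd.DataFrame(rows)
    if center is not None and orifice_radius_um is not None:
        dx = df["stage_x"] - center[0]
        dy = df["stage_y"] - center[1]
        df["r"] = np.hypot(dx, dy) / orifice_radius_um
        # Signed radius: project onto the principal axis of the imaging
        # sequence so a line scan through the centre reads left/right.
        xy = np.column_stack([dx, dy])
        if len(df) > 1 and np.any(xy.std(axis=0) > 0):
            _, _, vt = np.linalg.svd(xy - xy.mean(axis=0), full_matrices=False)
            axis = vt[0]
            df["r_signed"] = np.sign(xy @ axis) * df["r"]
        else:
            df["r_signed"] = df["r"]
    return df


def square_bin_fractions(profile: pd.DataFrame,
                         bins: SizeBinning = SizeBinning(),
                         grid_pitch_um: float = DEFAULT_GRID_PITCH_UM,
                         center: tuple[float, float] = (0.0, 0.0)) -> pd.DataFrame:
    """Per-grid-square fraction of particles in each size bin.

    Images are assigned to grid squares by floor division of their
    centre-aligned stage coordinates by the pitch.  For each bin the
    mean per-image count within a square evens out local film
    deflection; fractions are those means normalized over squares, so
    they sum to 1 per populated bin.  Unpopulated bins are NaN.
    """
    if profile.empty:
        raise InsufficientDataError("empty density profile")
    labels = bins.labels
    df = profile.copy()
    df["sq_ix"] = np.floor((df["stage_x"] - center[0]) / grid_pitch_um
                           + 0.5).astype(int)
    df["sq_iy"] = np.floor((df["stage_y"] - center[1]) / grid_pitch_um
                           + 0.5).astype(int)
    agg = {f"count_{lab}": "mean" for lab in labels}
    if "r" in df.columns:
        agg["r"] = "mean"
    out = df.groupby(["sq_ix", "sq_iy"]).agg(agg).reset_index()
    for lab in labels:
        total = out[f"count_{lab}"].sum()
        out[f"fraction_{lab}"] = (out[f"count_{lab}"] / total
                                  if total > 0 else np.nan)
    return out


def _gauss(r, a, r0, sigma):
    return a * np.exp(-((r - r0) ** 2) / (2.0 * sigma**2))


def fit_radial_gaussian(r, fractions) -> RadialGaussianFit:
    """Gaussian fit of bin fractions against absolute normalized radius.

    Bounds: r0 >= 0, sigma in (0, 5].  A fit whose width exceeds the
    radial span of the data (flat profile) is flagged unconstrained.
    """
    r = np.asarray(r, dtype=float)
    y = np.asarray(fractions, dtype=float)
    keep = np.isfinite(r) & np.isfinite(y)
    r, y = r[keep], y[keep]
    if r.size < 3:
        raise InsufficientDataError(
            f"need >= 3 squares with data, got {r.size}")
    span = float(r.max() - r.min()) or 1.0
    p0 = [max(float(y.max()), 1e-6), float(r[np.argmax(y)]), span / 4.0]
    try:
        popt, _ = curve_fit(_gauss, r, y, p0=p0,
                            bounds=([0.0, 0.0, 1e-6], [np.inf, 10.0, 5.0]),
                            maxfev=20_000)
    except RuntimeError:
        return RadialGaussianFit(np.nan, np.nan, np.nan, converged=False)
    a, r0, sigma = (float(v) for v in popt)
    return RadialGaussianFit(a, r0, sigma,
                             unconstrained=sigma >= span)


def fit_deposition_trend(squares: pd.DataFrame,
                         bins: SizeBinning = SizeBinning()
                         ) -> dict[str, RadialGaussianFit]:
    """Per-bin Gaussian radial trend from square fractions.

    Bins with no particles anywhere, or whose fit does not converge,
    are omitted from the result.
    """
    out: dict[str, RadialGaussianFit] = {}
    for lab in bins.labels:
        y = squares[f"fraction_{lab}"]
        if y.isna().all():
            continue
        try:
            fit = fit_radial_gaussian(squares["r"], y)
        except InsufficientDataError:
            continue  # too few populated squares; no trend for this bin
        if fit.converged:
            out[lab] = fit
    return out


def coverage_extent_check(images, center: tuple[float, float],
                          orifice_radius_um: float,
                          required: float = REQUIRED_RADIAL_EXTENT) -> dict:
    """Flag imaging sequences that stop short of ``required`` radii.

    The broadest deposit ring (sizes just above the cut-off) reaches
    about 1.5 orifice radii, so shorter sequences miss particles.
    """
    imgs = list(_images_by_id(images).values())
    if not imgs:
        return {"max_radius": 0.0, "required": required, "complete": False,
                "flag": "no images"}
    max_r = max(normalized_radius(im, center, orifice_radius_um)
                for im in imgs)
    complete = max_r >= required
    return {"max_radius": max_r, "required": required, "complete": complete,
            "flag": None if complete else
            f"sequence reaches {max_r:.2f} R < required {required} R"}


def radial_uniformity_test(radii, r_max: float, n_annuli: int = 8) -> float:
    """Chi-square p-value against uniform areal deposition on a disc.

    ``radii`` are particle radial distances (any consistent unit) within
    a sampled disc of radius ``r_max``.  Uniform deposition implies
    counts proportional to annulus area; equal-area annuli give equal
    expected counts.
    """
    radii = np.asarray(radii, dtype=float)
    if radii.size < 5 * n_annuli:
        raise InsufficientDataError("too few particles for the chi-square")
    edges = r_max * np.sqrt(np.linspace(0.0, 1.0, n_annuli + 1))
    counts, _ = np.histogram(radii, bins=edges)
    return float(stats.chisquare(counts).pvalue)
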