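"""Synthetic instrument data with known ground truth.

Every analysis stage in the package can be exercised without instrument
access: deposition patterns are drawn from a size-dependent radial law
(aerodynamic focusing moves large particles towards the impact centre
and narrows their ring), micrographs are rendered as dark anti-aliased
disks/ellipses on a noisy bright substrate, collection-efficiency
experiments are emitted as Poisson-noised CPC pairs composed of a
sigmoid impaction efficiency and a size-dependent wall loss, and SMPS
scans are multimodal lognormals on geometric channels.  All generators
are seed-deterministic and return ground truth alongside the data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .collection_efficiency import CpcSeries, EfficiencyCurve, evaluate_ceff
from .psd import (SizeDistribution, SmpsScan, apply_ceff, compare_psd,
                  psd_from_images, rebin_log_to_linear)
from .segmentation import (MicrographImage, SegmentationConfig, discard_blank,
                           segment_image)

#: Sigmoid efficiency parameters used as the generator default
#: (plateau 0.53, cut-off 73 nm, steepness 2.29 - a bounce-limited
#: 0.29 mm round-jet stage at 0.76 L/min).
DEFAULT_CURVE = EfficiencyCurve(cmax=0.53, d50=73.0, steepness=2.29)

#: SMPS channel range emulated by default (nm).
SMPS_RANGE_NM = (17.5, 532.8)


@dataclass(frozen=True)
class DepositionModel:
    """Size-dependent radial deposition law for a round tapered jet.

    Above the cut-off, deposit radii are |Normal(mu(d) R, sigma(d) R)|
    with uniform angle; the ring centre mu(d) decays towards 0 and the
    width sigma(d) narrows as the diameter grows, reproducing the
    focusing trend (ring near one orifice radius just above the
    cut-off, tight central spot for the largest sizes).  Below the
    cut-off, deposition is uniform over the sampled disc of radius
    ``sample_radius_factor`` R, thinned by ``sub_cutoff_fraction``
    (diffusive deposition is roughly an order of magnitude sparser than
    impaction).  The decay constants are configuration, not physics.
    """

    orifice_radius_um: float = 145.0
    cutoff_nm: float = 73.0
    mu_amplitude: float = 1.0
    mu_decay_nm: float = 300.0
    sigma_amplitude: float = 0.4
    sigma_decay_nm: float = 600.0
    sub_cutoff_fraction: float = 0.1
    sample_radius_factor: float = 2.0

    def ring_center(self, d) -> np.ndarray:
        """mu(d) in orifice-radius units; non-increasing, in [0, 1.5]."""
        d = np.asarray(d, dtype=float)
        mu = self.mu_amplitude * np.exp(-(d - self.cutoff_nm)
                                        / self.mu_decay_nm)
        return np.clip(mu, 0.0, 1.5)

    def ring_width(self, d) -> np.ndarray:
        """sigma(d) in orifice-radius units; strictly positive."""
        d = np.asarray(d, dtype=float)
        return self.sigma_amplitude * np.exp(-(d - self.cutoff_nm)
                                             / self.sigma_decay_nm)


def deposit_positions(diameters, model: DepositionModel,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Stage positions (um) for particles of the given diameters (nm)."""
    d = np.asarray(diameters, dtype=float)
    n = d.size
    r_um = np.empty(n)
    above = d > model.cutoff_nm
    r_orifice = model.orifice_radius_um
    if above.any():
        mu = model.ring_center(d[above]) * r_orifice
        sig = model.ring_width(d[above]) * r_orifice
        r_um[above] = np.abs(rng.normal(mu, sig))
    below = ~above
    if below.any():
        rmax = model.sample_radius_factor * r_orifice
        r_um[below] = rmax * np.sqrt(rng.uniform(size=int(below.sum())))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return pd.DataFrame({"x_um": r_um * np.cos(theta),
                         "y_um": r_um * np.sin(theta),
                         "diameter_nm": d})


def simulate_deposition(n: int, size_mixture, model: DepositionModel,
                        seed: int) -> pd.DataFrame:
    """Deposit ``n`` candidate particles drawn from a size mixture.

    ``size_mixture`` is a list of (diameter_nm, weight) pairs; weights
    are normalized internally.  Sub-cutoff candidates are thinned by the
    model's collection fraction, so the returned frame may hold fewer
    than ``n`` rows.  Columns: x_um, y_um, diameter_nm.
    """
    mixture = list(size_mixture)
    if not mixture:
        raise ValueError("size mixture must not be empty")
    rng = np.random.default_rng(seed)
    diams = np.array([m[0] for m in mixture], dtype=float)
    weights = np.array([m[1] for m in mixture], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must have positive sum")
    weights = weights / weights.sum()
    d = rng.choice(diams, size=n, p=weights)
    keep = (d > model.cutoff_nm) | (rng.uniform(size=n)
                                    < model.sub_cutoff_fraction)
    return deposit_positions(d[keep], model, rng).reset_index(drop=True)


@dataclass(frozen=True)
class FrameGeometry:
    """Geometry and stage placement of one rendered frame."""

    width_px: int = 1024
    height_px: int = 1024
    pixel_size_nm: float = 3.7
    stage_x_um: float = 0.0
    stage_y_um: float = 0.0
    image_id: str = "frame"

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_nm * 1e-3

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_nm * 1e-3


def render_micrograph(truth: pd.DataFrame, frame: FrameGeometry,
                      noise_sigma: float = 5.0, seed: int = 0,
                      substrate_level: float = 200.0,
                      particle_level: float = 50.0
                      ) -> tuple[MicrographImage, pd.DataFrame]:
    """Render dark particles on a bright noisy substrate.

    ``truth`` columns: x_px, y_px (frame pixel coordinates, origin
    top-left), diameter_nm; optional shape ('disk'|'ellipse'),
    axis_ratio (>= 1) and angle_rad for ellipses (area-preserving, so
    the ECD equals diameter_nm).  Objects are anti-aliased with a
    one-pixel soft edge; overlapping objects merge (coverage saturates).
    Returns the image and a copy of the truth table with a
    ``touches_border`` column.
    """
    rng = np.random.default_rng(seed)
    h, w = frame.height_px, frame.width_px
    coverage = np.zeros((h, w))
    touches = []
    for row in truth.itertuples(index=False):
        r_px = row.diameter_nm / (2.0 * frame.pixel_size_nm)
        q = float(getattr(row, "axis_ratio", 1.0) or 1.0)
        shape = getattr(row, "shape", "disk")
        ang = float(getattr(row, "angle_rad", 0.0) or 0.0)
        a_px = r_px * math.sqrt(q) if shape == "ellipse" else r_px
        b_px = r_px / math.sqrt(q) if shape == "ellipse" else r_px
        x0, y0 = float(row.x_px), float(row.y_px)
        rmax = a_px + 1.5
        touches.append(x0 - rmax < 0 or y0 - rmax < 0
                       or x0 + rmax > w - 1 or y0 + rmax > h - 1)
        ilo, ihi = max(0, int(y0 - rmax)), min(h, int(y0 + rmax) + 2)
        jlo, jhi = max(0, int(x0 - rmax)), min(w, int(x0 + rmax) + 2)
        if ilo >= ihi or jlo >= jhi:
            continue
        yy, xx = np.mgrid[ilo:ihi, jlo:jhi]
        u = (xx - x0) * math.cos(ang) + (yy - y0) * math.sin(ang)
        v = -(xx - x0) * math.sin(ang) + (yy - y0) * math.cos(ang)
        rho = np.sqrt((u / a_px) ** 2 + (v / b_px) ** 2)
        # Soft edge ~1 px wide scaled by the smaller semi-axis.
        cov = np.clip(0.5 + (1.0 - rho) * b_px, 0.0, 1.0)
        patch = coverage[ilo:ihi, jlo:jhi]
        np.maximum(patch, cov, out=patch)
    pixels = substrate_level + (particle_level - substrate_level) * coverage
    pixels = pixels + rng.normal(0.0, noise_sigma, size=pixels.shape)
    np.clip(pixels, 0.0, 255.0, out=pixels)
    image = MicrographImage(pixels=pixels, pixel_size=frame.pixel_size_nm,
                            stage_x=frame.stage_x_um,
                            stage_y=frame.stage_y_um,
                            image_id=frame.image_id)
    out = truth.copy()
    out["touches_border"] = touches
    return image, out


def render_deposition_frames(positions: pd.DataFrame,
                             frames: list[FrameGeometry],
                             noise_sigma: float = 5.0, seed: int = 0
                             ) -> list[tuple[MicrographImage, pd.DataFrame]]:
    """Render each frame with the deposited particles that fall in it.

    ``positions`` must have x_um, y_um, diameter_nm in stage
    coordinates; stage y maps to the pixel row axis.  Particles whose
    footprint intersects a frame are rendered (clipped at the edge).
    """
    rng = np.random.default_rng(seed)
    x = positions["x_um"].to_numpy()
    y = positions["y_um"].to_numpy()
    d = positions["diameter_nm"].to_numpy()
    r_um = d * 1e-3 / 2.0
    out = []
    for frame in frames:
        half_w, half_h = frame.width_um / 2.0, frame.height_um / 2.0
        inside = ((np.abs(x - frame.stage_x_um) <= half_w + r_um)
                  & (np.abs(y - frame.stage_y_um) <= half_h + r_um))
        scale = 1e3 / frame.pixel_size_nm  # um -> px
        truth = pd.DataFrame({
            "x_px": (x[inside] - frame.stage_x_um + half_w) * scale,
            "y_px": (y[inside] - frame.stage_y_um + half_h) * scale,
            "diameter_nm": d[inside]})
        out.append(render_micrograph(truth, frame, noise_sigma=noise_sigma,
                                     seed=int(rng.integers(2**31))))
    return out


def default_wall_loss(d) -> np.ndarray:
    """Size-dependent non-impaction loss fraction.

    About 92 % of 20 nm particles are lost to walls/pump/evaporation,
    decaying to a 15 % floor above ~120 nm.
    """
    d = np.asarray(d, dtype=float)
    return np.clip(0.15 + 0.77 * np.exp(-(d - 20.0) / 25.0), 0.0, 1.0)


def simulate_ceff_experiment(curve: EfficiencyCurve = DEFAULT_CURVE,
                             wall_loss=default_wall_loss,
                             mean_counts: float = 500.0,
                             diameters=None, n_samples: int = 12,
                             noise: bool = True, seed: int = 0):
    """Paired CPC series for a collection-efficiency experiment.

    For each DMA setpoint (20-200 nm step 10 by default) four series are
    produced: upstream/downstream with and without the collection
    plate.  Downstream means compose the wall loss and (with plate) the
    impaction efficiency multiplicatively:

        down_without = up * (1 - wall_loss(d))
        down_with    = up * (1 - wall_loss(d)) * (1 - Ceff(d))

    Each series is Poisson noise around its mean (exact means when
    ``noise`` is false).  Returns a list of 4-tuples
    (up_with, down_with, up_without, down_without).
    """
    if diameters is None:
        diameters = np.arange(20.0, 201.0, 10.0)
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) * 10.0
    out = []
    for d in diameters:
        wl = float(np.clip(wall_loss(d), 0.0, 1.0))
        ce = evaluate_ceff(curve, float(d))
        means = {
            ("upstream", "with_plate"): mean_counts,
            ("downstream", "with_plate"): mean_counts * (1 - wl) * (1 - ce),
            ("upstream", "without_plate"): mean_counts,
            ("downstream", "without_plate"): mean_counts * (1 - wl),
        }
        series = {}
        for (pos, cfg), m in means.items():
            conc = (rng.poisson(m, size=n_samples).astype(float) if noise
                    else np.full(n_samples, m))
            series[(pos, cfg)] = CpcSeries(selected_diameter=float(d),
                                           timestamps=t, concentrations=conc,
                                           position=pos, configuration=cfg)
        out.append((series[("upstream", "with_plate")],
                    series[("downstream", "with_plate")],
                    series[("upstream", "without_plate")],
                    series[("downstream", "without_plate")]))
    return out


def simulate_smps(modes, d_min: float = SMPS_RANGE_NM[0],
                  d_max: float = SMPS_RANGE_NM[1], channels: int = 64,
                  scans: int = 5, noise: float = 0.05,
                  seed: int = 0) -> SmpsScan:
    """Multimodal lognormal SMPS scans on geometric channels.

    ``modes`` is a list of (median_nm, gsd, N_cm3) triples with
    gsd > 1.  Each scan applies independent multiplicative Gaussian
    noise per channel; the integral of the mean dN/dlogDp over log10 d
    equals the total N of the modes.
    """
    mids = np.geomspace(d_min, d_max, channels)
    dndlog = np.zeros(channels)
    for median, gsd, n_total in modes:
        if gsd <= 1:
            raise ValueError("geometric standard deviation must exceed 1")
        sig = math.log10(gsd)
        dndlog += (n_total / (math.sqrt(2 * math.pi) * sig)
                   * np.exp(-((np.log10(mids) - math.log10(median)) ** 2)
                            / (2 * sig * sig)))
    rng = np.random.default_rng(seed)
    data = np.clip(dndlog * (1.0 + noise * rng.standard_normal((scans,
                                                                channels))),
                   0.0, None)
    if noise == 0:
        data = np.tile(dndlog, (scans, 1))
    return SmpsScan(midpoints=mids, data=data)


def _sample_sizes_from_distribution(dist: SizeDistribution, n: int,
                                    rng: np.random.Generator) -> np.ndarray:
    """Draw diameters from a binned distribution, uniform within bins."""
    p = dist.values / dist.total
    idx = rng.choice(dist.values.size, size=n, p=p)
    lo = dist.edges[idx]
    hi = dist.edges[idx + 1]
    return rng.uniform(lo, hi)


def simulate_validation_study(seed: int,
                              curve: EfficiencyCurve = DEFAULT_CURVE,
                              model: DepositionModel | None = None,
                              modes=((140.0, 1.2, 1500.0),
                                     (210.0, 1.15, 400.0)),
                              n_frames: int = 96, frame_px: int = 1024,
                              pixel_size_nm: float = 3.7,
                              n_deposit: int = 150_000,
                              bin_width: float = 10.0,
                              noise_sigma: float = 5.0) -> dict:
    """End-to-end SEM-vs-SMPS cross validation on synthetic data.

    Simulates SMPS scans of a multimodal aerosol, deposits particles
    with sizes drawn from the Ceff-corrected airborne distribution
    (collection probability is already contained in Ceff, so the
    model's extra sub-cutoff thinning is disabled here), renders frames
    placed uniformly at random inside the 1.5-orifice-radius deposit
    disc (uniform area sampling keeps the per-image-averaged PSD
    unbiased), segments them, and compares the pooled SEM histogram
    with the rebinned, Ceff-corrected SMPS distribution above the
    cut-off.
    """
    model = model or DepositionModel(cutoff_nm=curve.d50)
    rng = np.random.default_rng(seed)
    scan = simulate_smps(modes, seed=int(rng.integers(2**31)))
    edges = np.arange(0.0, math.ceil(SMPS_RANGE_NM[1] / bin_width + 2)
                      * bin_width, bin_width)
    airborne = rebin_log_to_linear(scan, edges)
    corrected = apply_ceff(airborne, curve)

    sizes = _sample_sizes_from_distribution(corrected, n_deposit, rng)
    deposit_model = replace(model, sub_cutoff_fraction=1.0)
    positions = deposit_positions(sizes, deposit_model, rng)

    r_extent = 1.5 * model.orifice_radius_um
    rad = r_extent * np.sqrt(rng.uniform(size=n_frames))
    ang = rng.uniform(0.0, 2 * math.pi, size=n_frames)
    frames = [FrameGeometry(width_px=frame_px, height_px=frame_px,
                            pixel_size_nm=pixel_size_nm,
                            stage_x_um=float(rad[i] * math.cos(ang[i])),
                            stage_y_um=float(rad[i] * math.sin(ang[i])),
                            image_id=f"sim_{i:03d}")
              for i in range(n_frames)]
    rendered = render_deposition_frames(positions, frames,
                                        noise_sigma=noise_sigma,
                                        seed=int(rng.integers(2**31)))
    config = SegmentationConfig(mode="global", global_threshold=125.0)
    images, records = [], []
    for image, _truth in rendered:
        if discard_blank(image):
            continue
        images.append(image)
        records.extend(segment_image(image, config))
    sem = psd_from_images(records, images, edges=edges)
    comparison = compare_psd(sem, corrected, d_min=curve.d50)
    return {"scan": scan, "airborne": airborne, "corrected": corrected,
            "sem": sem, "comparison": comparison, "records": records,
            "images": images, "positions": positions}
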