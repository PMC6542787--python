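"""Particle size distributions: SEM histograms vs SMPS scans.

The SEM side is a linear-bin ECD histogram pooled over an imaging
sequence, with sqrt(N) counting uncertainties.  The SMPS side arrives
as dN/dlogDp on geometrically spaced mobility-diameter channels; it is
averaged over scans, converted to numbers per channel
(N_ch = dN/dlogDp * dlog10Dp), redistributed onto the linear SEM bins
proportionally to log-overlap (conserving total number), and multiplied
by the fitted impactor collection efficiency so the two distributions
describe the same collected population.  Shapes are compared above the
cut-off after unit-sum normalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .collection_efficiency import EfficiencyCurve, evaluate_ceff
from .errors import CoverageError, InsufficientDataError, SchemaError
from .segmentation import ParticleRecord


@dataclass
class SizeDistribution:
    """Binned size distribution on strictly increasing linear edges.

    ``values`` are counts or number concentrations per bin;
    ``uncertainties`` share their units.  ``normalization`` records
    whether the values have been scaled to unit sum.  ``flags`` holds
    per-bin quality notes (e.g. below the imaging detection limit).
    """

    edges: np.ndarray  # nm
    values: np.ndarray
    uncertainties: np.ndarray | None = None
    normalization: str = "raw"  # raw | unit_sum
    flags: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")
        if self.values.size != self.edges.size - 1:
            raise ValueError("need one value per bin")
        if np.any(self.values < -1e-12):
            raise ValueError("bin values must be non-negative")
        if self.uncertainties is None:
            self.uncertainties = np.zeros_like(self.values)
        else:
            self.uncertainties = np.asarray(self.uncertainties, dtype=float)
            if self.uncertainties.shape != self.values.shape:
                raise ValueError("one uncertainty per bin required")

    @property
    def midpoints(self) -> np.ndarray:
        """Geometric bin midpoints (arithmetic when the lower edge is 0)."""
        lo, hi = self.edges[:-1], self.edges[1:]
        mids = np.where(lo > 0, np.sqrt(np.clip(lo, 1e-300, None) * hi),
                        (lo + hi) / 2.0)
        return mids

    @property
    def total(self) -> float:
        return float(self.values.sum())

    def normalized(self) -> "SizeDistribution":
        """Unit-sum copy (idempotent)."""
        tot = self.total
        if tot == 0:
            raise InsufficientDataError("cannot normalize an empty distribution")
        return replace(self, values=self.values / tot,
                       uncertainties=self.uncertainties / tot,
                       normalization="unit_sum")

    def restrict(self, d_min: float = -math.inf,
                 d_max: float = math.inf) -> "SizeDistribution":
        """Sub-distribution of bins whose midpoints lie in [d_min, d_max]."""
        keep = (self.midpoints >= d_min) & (self.midpoints <= d_max)
        if not keep.any():
            raise CoverageError("no bins left after restriction")
        idx = np.nonzero(keep)[0]
        edges = np.append(self.edges[idx], self.edges[idx[-1] + 1])
        return SizeDistribution(edges=edges, values=self.values[idx],
                                uncertainties=self.uncertainties[idx],
                                normalization="raw")


@dataclass
class SmpsScan:
    """SMPS scans: dN/dlogDp per geometric channel midpoint.

    ``data`` has shape (n_scans, n_channels); midpoints must be
    geometrically spaced within 1 %.
    """

    midpoints: np.ndarray  # nm
    data: np.ndarray  # cm^-3, (n_scans, n_channels)

    def __post_init__(self) -> None:
        self.midpoints = np.asarray(self.midpoints, dtype=float)
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if np.any(np.diff(self.midpoints) <= 0):
            raise SchemaError("SMPS midpoints must be strictly increasing")
        if self.data.shape[1] != self.midpoints.size:
            raise SchemaError("scan length does not match channel count")
        ratios = self.midpoints[1:] / self.midpoints[:-1]
        if ratios.size and (ratios.max() / ratios.min() - 1.0) > 0.01:
            raise SchemaError("SMPS channels are not geometrically spaced "
                              "(>1% tolerance)")

    @property
    def n_scans(self) -> int:
        return self.data.shape[0]

    @property
    def mean_scan(self) -> np.ndarray:
        return self.data.mean(axis=0)

    @property
    def scan_std(self) -> np.ndarray:
        if self.n_scans < 2:
            return np.zeros(self.midpoints.size)
        return self.data.std(axis=0, ddof=1)

    @property
    def channel_edges(self) -> np.ndarray:
        """Geometric channel edges inferred from the midpoints."""
        m = self.midpoints
        if m.size == 1:
            # Degenerate: assume a decade/64 channel either side.
            ratio = 10 ** (1 / 64)
            return np.array([m[0] / math.sqrt(ratio), m[0] * math.sqrt(ratio)])
        inner = np.sqrt(m[:-1] * m[1:])
        ratio = m[1] / m[0]
        return np.concatenate([[m[0] / math.sqrt(ratio)], inner,
                               [m[-1] * math.sqrt(m[-1] / m[-2])]])


def _histogram_edges(ecds: np.ndarray, bin_width: float) -> np.ndarray:
    top = max(float(ecds.max()) if ecds.size else bin_width, bin_width)
    n = int(math.ceil(top / bin_width)) + 1
    return np.arange(0.0, (n + 0.5) * bin_width, bin_width)


def psd_from_images(records: list[ParticleRecord], images,
                    bin_width: float = 10.0,
                    edges: np.ndarray | None = None,
                    detection_limit_nm: float | None = None) -> SizeDistribution:
    """ECD histogram over an imaging sequence with sqrt(N) errors.

    Counts are pooled over all (non-discarded) images of the sequence;
    after unit-sum normalization this equals the average of the
    per-image histograms.  Bins whose midpoint falls below
    ``detection_limit_nm`` are flagged ``highly_uncertain``.
    """
    imgs = images if isinstance(images, dict) else \
        {im.image_id: im for im in images}
    if not imgs:
        raise InsufficientDataError("no images in the sequence")
    ecds = np.array([r.ecd for r in records if r.image_id in imgs])
    if edges is None:
        edges = _histogram_edges(ecds, bin_width)
    counts, _ = np.histogram(ecds, bins=edges)
    dist = SizeDistribution(edges=edges, values=counts.astype(float),
                            uncertainties=np.sqrt(counts))
    if detection_limit_nm is not None:
        flags = tuple("highly_uncertain" if m < detection_limit_nm else ""
                      for m in dist.midpoints)
        dist.flags = flags
    return dist


def rebin_log_to_linear(scan: SmpsScan,
                        linear_edges: np.ndarray) -> SizeDistribution:
    """Convert dN/dlogDp channels onto linear SEM bins.

    Each channel number N_ch = mean(dN/dlogDp) * log10(e_hi/e_lo) is
    distributed over the overlapping linear bins proportionally to the
    log-overlap, which conserves the total number over the covered
    range.  The per-channel scan standard deviation propagates with the
    same fractions (summed in quadrature).
    """
    linear_edges = np.asarray(linear_edges, dtype=float)
    if np.any(np.diff(linear_edges) <= 0):
        raise ValueError("linear edges must be strictly increasing")
    ch_edges = scan.channel_edges
    if linear_edges[-1] <= ch_edges[0] or linear_edges[0] >= ch_edges[-1]:
        raise CoverageError("linear edges do not overlap the SMPS range")
    dlog = np.log10(ch_edges[1:] / ch_edges[:-1])
    n_ch = scan.mean_scan * dlog
    n_ch_sig = scan.scan_std * dlog

    values = np.zeros(linear_edges.size - 1)
    var = np.zeros_like(values)
    log_ch = np.log10(ch_edges)
    for j in range(linear_edges.size - 1):
        b_lo, b_hi = linear_edges[j], linear_edges[j + 1]
        lo = np.log10(np.clip(np.maximum(b_lo, ch_edges[:-1]), 1e-300, None))
        hi = np.log10(np.clip(np.minimum(b_hi, ch_edges[1:]), 1e-300, None))
        frac = np.clip(hi - lo, 0.0, None) / (log_ch[1:] - log_ch[:-1])
        values[j] = np.sum(frac * n_ch)
        var[j] = np.sum((frac * n_ch_sig) ** 2)
    return SizeDistribution(edges=linear_edges, values=values,
                            uncertainties=np.sqrt(var))


def _ceff_sigma(curve: EfficiencyCurve, d: np.ndarray) -> np.ndarray:
    """First-order uncertainty of the fitted curve at diameters d."""
    eps = 1e-6
    c0 = evaluate_ceff(curve, d)
    grads = []
    sig2 = np.zeros_like(np.asarray(d, dtype=float))
    if curve.covariance is not None and np.all(np.isfinite(curve.covariance)):
        for i, (attr, step) in enumerate((("d50", curve.d50 * eps + eps),
                                          ("steepness",
                                           curve.steepness * eps + eps))):
            bumped = replace(curve, **{attr: getattr(curve, attr) + step})
            grads.append((evaluate_ceff(bumped, d) - c0) / step)
        g = np.stack(grads)
        cov = np.asarray(curve.covariance)
        sig2 = np.einsum("id,ij,jd->d", g, cov, g)
    if curve.cmax_sigma > 0:
        sig2 = sig2 + (c0 / curve.cmax * curve.cmax_sigma) ** 2
    return np.sqrt(np.clip(sig2, 0.0, None))


def apply_ceff(dist: SizeDistribution,
               curve: EfficiencyCurve) -> SizeDistribution:
    """Scale each bin by the collection efficiency at its midpoint.

    The fitted-curve parameter uncertainty enters as an additional
    relative error band combined in quadrature with the scaled bin
    uncertainties.  No bin can increase (cmax <= 1).
    """
    mids = dist.midpoints
    ceff = np.where(mids > 0, evaluate_ceff(curve, np.clip(mids, 1e-9, None)),
                    0.0)
    values = dist.values * ceff
    scaled_sig = dist.uncertainties * ceff
    rel_band = _ceff_sigma(curve, np.clip(mids, 1e-9, None))
    extra = dist.values * rel_band
    return SizeDistribution(edges=dist.edges, values=values,
                            uncertainties=np.hypot(scaled_sig, extra),
                            flags=dist.flags)


def shape_filtered_psd(records: list[ParticleRecord],
                       circularity_min: float = 0.0,
                       aspect_max: float = math.inf,
                       bin_width: float = 10.0,
                       edges: np.ndarray | None = None) -> SizeDistribution:
    """ECD histogram restricted to particles meeting shape criteria.

    E.g. ``circularity_min=0.90`` isolates compact near-spherical
    particles, separating them from agglomerates and fibres.
    """
    kept = [r for r in records
            if r.circularity >= circularity_min
            and r.aspect_ratio <= aspect_max]
    ecds = np.array([r.ecd for r in kept])
    if edges is None:
        edges = _histogram_edges(ecds, bin_width)
    counts, _ = np.histogram(ecds, bins=edges)
    return SizeDistribution(edges=edges, values=counts.astype(float),
                            uncertainties=np.sqrt(counts))


def rebin_linear(dist: SizeDistribution,
                 new_edges: np.ndarray) -> SizeDistribution:
    """Redistribute a linear-bin distribution onto new linear edges.

    Assumes the value is uniformly dense within each source bin.
    """
    new_edges = np.asarray(new_edges, dtype=float)
    old = dist.edges
    values = np.zeros(new_edges.size - 1)
    var = np.zeros_like(values)
    width = old[1:] - old[:-1]
    for j in range(new_edges.size - 1):
        lo = np.maximum(new_edges[j], old[:-1])
        hi = np.minimum(new_edges[j + 1], old[1:])
        frac = np.clip(hi - lo, 0.0, None) / width
        values[j] = np.sum(frac * dist.values)
        var[j] = np.sum((frac * dist.uncertainties) ** 2)
    return SizeDistribution(edges=new_edges, values=values,
                            uncertainties=np.sqrt(var))


@dataclass(frozen=True)
class PsdComparison:
    """Shape comparison of two unit-sum distributions above a cut-off."""

    mode_sem: float  # nm, midpoint of the SEM modal bin
    mode_smps: float  # nm
    mode_difference: float  # nm, |sem - smps|
    peak_ratio: float  # SEM peak fraction / SMPS peak fraction
    max_fraction_difference: float
    d_min: float


def compare_psd(sem: SizeDistribution, smps_corrected: SizeDistribution,
                d_min: float) -> PsdComparison:
    """Compare SEM and Ceff-corrected SMPS distribution shapes.

    Both are restricted to midpoints >= ``d_min`` (normally the fitted
    D50, below which the image statistics are unreliable), rebinned to
    the SEM edges when needed, and normalized to unit sum.
    """
    sem_r = sem.restrict(d_min=d_min)
    if not np.array_equal(smps_corrected.edges, sem.edges):
        smps_corrected = rebin_linear(smps_corrected, sem_r.edges)
        smps_r = smps_corrected.restrict(d_min=d_min)
    else:
        smps_r = smps_corrected.restrict(d_min=d_min)
    if sem_r.total == 0 or smps_r.total == 0:
        raise CoverageError("empty distribution above d_min")
    a, b = sem_r.normalized(), smps_r.normalized()
    ia, ib = int(np.argmax(a.values)), int(np.argmax(b.values))
    return PsdComparison(
        mode_sem=float(a.midpoints[ia]),
        mode_smps=float(b.midpoints[ib]),
        mode_difference=abs(float(a.midpoints[ia] - b.midpoints[ib])),
        peak_ratio=float(a.values[ia] / b.values[ib]),
        max_fraction_difference=float(np.max(np.abs(a.values - b.values))),
        d_min=d_min)
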