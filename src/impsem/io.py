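"""Readers and writers for the package's tabular and image formats.

All tabular files are comma-separated with a mandatory header row;
``#``-prefixed lines before the header carry ``key = value`` metadata.
Stage coordinates are micrometres; frame-internal pixel coordinates are
0-based with the origin at the top-left.  Micrographs are single-page
grayscale TIFF (8- or 16-bit).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .collection_efficiency import CpcSeries
from .concentration_sampling import SP_LOWER_DEFAULT, SP_UPPER_DEFAULT
from .errors import ConfigError, ManifestError, SchemaError
from .psd import SizeDistribution, SmpsScan
from .segmentation import MicrographImage, ParticleRecord, SegmentationConfig

MANIFEST_COLUMNS = ("image_id", "path", "stage_x_um", "stage_y_um",
                    "pixel_size_nm")
PARTICLE_COLUMNS = ("particle_id", "image_id", "area_nm2", "ecd_nm",
                    "perimeter_nm", "circularity", "aspect_ratio",
                    "centroid_x_px", "centroid_y_px", "touches_border")


def _read_table(path) -> tuple[pd.DataFrame, dict]:
    """CSV with '#'-metadata lines; returns (frame, metadata)."""
    meta: dict[str, str] = {}
    path = Path(path)
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "=" in line:
                key, _, value = line[1:].partition("=")
                meta[key.strip()] = value.strip()
    try:
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except ValueError as exc:
        raise SchemaError(f"{path}: cannot parse as CSV: {exc}") from exc
    return df, meta


def _write_table(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def _require_numeric(df: pd.DataFrame, cols, path) -> None:
    for col in cols:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise SchemaError(f"{path}: non-numeric value in column "
                              f"{col!r} at data row {row}")
        df[col] = coerced


def read_manifest(path) -> pd.DataFrame:
    """Validated micrograph manifest.

    Required columns: image_id, path, stage_x_um, stage_y_um,
    pixel_size_nm.  Duplicate image ids, non-positive pixel sizes and
    missing files are rejected with the offending rows named.
    """
    df, _ = _read_table(path)
    _require_columns(df, MANIFEST_COLUMNS, path)
    _require_numeric(df, ("stage_x_um", "stage_y_um", "pixel_size_nm"), path)
    dupes = df["image_id"][df["image_id"].duplicated()]
    if not dupes.empty:
        raise ManifestError(f"{path}: duplicate image_id "
                            f"{dupes.iloc[0]!r}")
    bad_ps = df.index[df["pixel_size_nm"] <= 0]
    if len(bad_ps):
        raise SchemaError(f"{path}: pixel_size_nm must be positive "
                          f"(row {bad_ps[0]})")
    base = Path(path).parent
    missing = [f"row {i}: {p}" for i, p in df["path"].items()
               if not (base / p).is_file() and not Path(p).is_file()]
    if missing:
        raise ManifestError(f"{path}: missing image file(s): "
                            + "; ".join(missing))
    return df


def load_micrographs(manifest_path) -> list[MicrographImage]:
    """Read every TIFF listed in a manifest into MicrographImage objects."""
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    out = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_file():
            p = base / row.path
        pixels = tifffile.imread(p)
        if pixels.ndim != 2:
            raise SchemaError(f"{p}: expected a single-page grayscale TIFF")
        out.append(MicrographImage(pixels=pixels,
                                   pixel_size=float(row.pixel_size_nm),
                                   stage_x=float(row.stage_x_um),
                                   stage_y=float(row.stage_y_um),
                                   image_id=str(row.image_id)))
    return out


def write_micrograph(image: MicrographImage, path) -> None:
    """Write pixels as an 8-bit grayscale TIFF."""
    px = np.clip(np.asarray(image.pixels), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, px)


def write_cpc(series: CpcSeries, path) -> None:
    _write_table(pd.DataFrame({"time_s": series.timestamps,
                               "concentration_cm3": series.concentrations}),
                 path,
                 metadata={"diameter_nm": series.selected_diameter,
                           "position": series.position,
                           "configuration": series.configuration})


def read_cpc(path) -> CpcSeries:
    """One CPC series: columns time_s, concentration_cm3 plus metadata."""
    df, meta = _read_table(path)
    _require_columns(df, ("time_s", "concentration_cm3"), path)
    _require_numeric(df, ("time_s", "concentration_cm3"), path)
    try:
        diameter = float(meta["diameter_nm"])
    except KeyError as exc:
        raise SchemaError(f"{path}: missing '# diameter_nm = ...' metadata "
                          "line") from exc
    return CpcSeries(selected_diameter=diameter,
                     timestamps=df["time_s"].to_numpy(),
                     concentrations=df["concentration_cm3"].to_numpy(),
                     position=meta.get("position", "upstream"),
                     configuration=meta.get("configuration", "with_plate"))


def write_cpc_long(pairs, path) -> None:
    """Long-format CPC file for a whole efficiency experiment."""
    rows = []
    for group in pairs:
        for s in group:
            for t, c in zip(s.timestamps, s.concentrations):
                rows.append((s.selected_diameter, s.position,
                             s.configuration, t, c))
    _write_table(pd.DataFrame(rows, columns=[
        "diameter_nm", "position", "configuration", "time_s",
        "concentration_cm3"]), path)


def read_cpc_long(path):
    """Long-format CPC file -> list of 4-tuples of CpcSeries.

    Each DMA setpoint must appear with all four
    (position, configuration) combinations.
    """
    df, _ = _read_table(path)
    cols = ("diameter_nm", "position", "configuration", "time_s",
            "concentration_cm3")
    _require_columns(df, cols, path)
    _require_numeric(df, ("diameter_nm", "time_s", "concentration_cm3"), path)
    out = []
    for d, group in df.groupby("diameter_nm", sort=True):
        series = {}
        for (pos, cfg), sub in group.groupby(["position", "configuration"]):
            series[(pos, cfg)] = CpcSeries(
                selected_diameter=float(d),
                timestamps=sub["time_s"].to_numpy(),
                concentrations=sub["concentration_cm3"].to_numpy(),
                position=pos, configuration=cfg)
        try:
            out.append((series[("upstream", "with_plate")],
                        series[("downstream", "with_plate")],
                        series[("upstream", "without_plate")],
                        series[("downstream", "without_plate")]))
        except KeyError as exc:
            raise SchemaError(f"{path}: setpoint {d} nm lacks the "
                              f"{exc.args[0]} series") from exc
    return out


def write_smps(scan: SmpsScan, path) -> None:
    df = pd.DataFrame(scan.data.T,
                      columns=[f"dndlogdp_scan{i + 1}"
                               for i in range(scan.n_scans)])
    df.insert(0, "diameter_nm", scan.midpoints)
    _write_table(df, path)


def read_smps(path) -> SmpsScan:
    """SMPS file: first column midpoint diameter, then one column per scan."""
    df, _ = _read_table(path)
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need a diameter column plus at least "
                          "one scan column")
    _require_numeric(df, df.columns, path)
    mids = df.iloc[:, 0].to_numpy()
    if np.any(np.diff(mids) <= 0):
        raise SchemaError(f"{path}: diameters must be strictly increasing")
    return SmpsScan(midpoints=mids, data=df.iloc[:, 1:].to_numpy().T)


def write_particles(records: list[ParticleRecord], path,
                    metadata: dict | None = None) -> None:
    rows = [(r.particle_id, r.image_id, r.area, r.ecd, r.perimeter,
             r.circularity, r.aspect_ratio, r.centroid_x, r.centroid_y,
             r.touches_border) for r in records]
    _write_table(pd.DataFrame(rows, columns=PARTICLE_COLUMNS), path,
                 metadata=metadata)


def read_particles(path) -> list[ParticleRecord]:
    df, _ = _read_table(path)
    _require_columns(df, PARTICLE_COLUMNS, path)
    num_cols = [c for c in PARTICLE_COLUMNS
                if c not in ("image_id", "touches_border")]
    _require_numeric(df, num_cols, path)
    return [ParticleRecord(
        particle_id=int(r.particle_id), image_id=str(r.image_id),
        area=float(r.area_nm2), ecd=float(r.ecd_nm),
        perimeter=float(r.perimeter_nm), circularity=float(r.circularity),
        aspect_ratio=float(r.aspect_ratio),
        centroid_x=float(r.centroid_x_px), centroid_y=float(r.centroid_y_px),
        touches_border=bool(r.touches_border))
        for r in df.itertuples(index=False)]


def write_distribution(dist: SizeDistribution, path,
                       metadata: dict | None = None) -> None:
    flags = dist.flags if dist.flags else ("",) * dist.values.size
    df = pd.DataFrame({"edge_lo_nm": dist.edges[:-1],
                       "edge_hi_nm": dist.edges[1:],
                       "value": dist.values,
                       "uncertainty": dist.uncertainties,
                       "flag": flags})
    meta = dict(metadata or {})
    meta["normalization"] = dist.normalization
    _write_table(df, path, metadata=meta)


def read_distribution(path) -> SizeDistribution:
    df, meta = _read_table(path)
    _require_columns(df, ("edge_lo_nm", "edge_hi_nm", "value",
                          "uncertainty"), path)
    _require_numeric(df, ("edge_lo_nm", "edge_hi_nm", "value",
                          "uncertainty"), path)
    edges = np.append(df["edge_lo_nm"].to_numpy(),
                      df["edge_hi_nm"].to_numpy()[-1])
    flags = tuple(df["flag"].fillna("")) if "flag" in df.columns else ()
    return SizeDistribution(edges=edges, values=df["value"].to_numpy(),
                            uncertainties=df["uncertainty"].to_numpy(),
                            normalization=meta.get("normalization", "raw"),
                            flags=flags)


@dataclass
class InstrumentConfig:
    orifice_mm: float = 0.29
    flow_lpm: float = 0.76
    temperature_c: float = 25.0
    pressure_kpa: float = 101.325
    stk50: float = 0.24
    particle_density_kgm3: float = 1000.0


@dataclass
class PatternConfig:
    grid_pitch_um: float = 63.5
    bin_edges_nm: tuple = (0.0, 80.0, 160.0, 240.0, float("inf"))
    center_override_um: tuple | None = None


@dataclass
class PsdConfig:
    bin_width_nm: float = 10.0
    detection_limit_nm: float | None = None


@dataclass
class SamplingConfig:
    sp_lower: float = SP_LOWER_DEFAULT
    sp_upper: float = SP_UPPER_DEFAULT
    midpoint: str = "geometric"


@dataclass
class ProjectConfig:
    """Whole-project configuration; round-trips losslessly through JSON."""

    instrument: InstrumentConfig = field(default_factory=InstrumentConfig)
    segmentation: SegmentationConfig = field(
        default_factory=SegmentationConfig)
    pattern: PatternConfig = field(default_factory=PatternConfig)
    psd: PsdConfig = field(default_factory=PsdConfig)
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    seed: int = 0

    _SECTIONS = {"instrument": InstrumentConfig,
                 "segmentation": SegmentationConfig,
                 "pattern": PatternConfig, "psd": PsdConfig,
                 "sampling": SamplingConfig}

    @classmethod
    def from_dict(cls, data: dict) -> "ProjectConfig":
        unknown = set(data) - set(cls._SECTIONS) - {"seed"}
        if unknown:
            raise ConfigError(f"unknown config section(s): "
                              f"{', '.join(sorted(unknown))}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            section = data.get(name, {})
            valid = {f.name for f in dataclasses.fields(section_cls)}
            bad = set(section) - valid
            if bad:
                raise ConfigError(f"unknown key(s) in [{name}]: "
                                  f"{', '.join(sorted(bad))}")
            if name == "pattern":
                section = dict(section)
                if section.get("bin_edges_nm") is not None:
                    section["bin_edges_nm"] = tuple(
                        float(e) for e in section["bin_edges_nm"])
                if section.get("center_override_um") is not None:
                    section["center_override_um"] = tuple(
                        float(e) for e in section["center_override_um"])
            kwargs[name] = section_cls(**section)
        return cls(seed=int(data.get("seed", 0)), **kwargs)

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, (tuple, list)):
                return [clean(x) for x in obj]
            if isinstance(obj, float) and math.isinf(obj):
                return "inf"
            return obj
        out = {name: {k: clean(v) for k, v in asdict(getattr(self,
                                                             name)).items()}
               for name in self._SECTIONS}
        out["seed"] = self.seed
        return out

    @classmethod
    def from_json(cls, path) -> "ProjectConfig":
        with Path(path).open() as fh:
            data = json.load(fh)
        for section in data.values():
            if isinstance(section, dict):
                for k, v in section.items():
                    if v == "inf":
                        section[k] = float("inf")
                if isinstance(section.get("bin_edges_nm"), list):
                    section["bin_edges_nm"] = tuple(
                        float("inf") if e == "inf" else float(e)
                        for e in section["bin_edges_nm"])
        return cls.from_dict(data)

    def to_json(self, path) -> None:
        with Path(path).open("w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
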