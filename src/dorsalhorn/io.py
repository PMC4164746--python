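"""File formats: multi-page TIFF micrographs, YAML sidecars, CSV tables.

Each micrograph is stored as a multi-page TIFF (one page per channel,
16-bit container holding 12-bit data) next to a YAML sidecar carrying
the channel names, the physical pixel size and the section geometry.
Cohort ground truth goes into a tidy CSV manifest; per-image puncta
into per-image CSVs.  All tables carry a ``schema_version`` column.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import GeometryConfig, Rect, SectionGeometry
from .synth import Micrograph, NoiseModel, PunctaField
from .timecourse import TimecourseConfig

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "write_micrograph",
    "read_micrograph",
    "geometry_to_dict",
    "geometry_from_dict",
    "write_puncta_csv",
]

SCHEMA_VERSION = 1


def geometry_to_dict(geom: SectionGeometry) -> dict:
    lz = geom.lesion_zone
    return {
        "pixel_size_um": float(geom.pixel_size_um),
        "image_shape": [int(v) for v in geom.image_shape],
        "wm_x_um": [float(v) for v in geom.wm_x_um],
        "wm_y_um": [float(v) for v in geom.wm_y_um],
        "li_band_thickness_um": float(geom.li_band_thickness_um),
        "lii_band_thickness_um": float(geom.lii_band_thickness_um),
        "midline_x_um": float(geom.midline_x_um),
        "lesion_zone_um": [float(lz.x_um), float(lz.y_um), float(lz.width_um), float(lz.height_um)],
        "side": geom.side,
    }


def geometry_from_dict(d: dict) -> SectionGeometry:
    x, y, w, h = d["lesion_zone_um"]
    geom = SectionGeometry(
        pixel_size_um=float(d["pixel_size_um"]),
        image_shape=tuple(int(v) for v in d["image_shape"]),
        wm_x_um=np.asarray(d["wm_x_um"], dtype=float),
        wm_y_um=np.asarray(d["wm_y_um"], dtype=float),
        li_band_thickness_um=float(d["li_band_thickness_um"]),
        lii_band_thickness_um=float(d["lii_band_thickness_um"]),
        midline_x_um=float(d["midline_x_um"]),
        lesion_zone=Rect(x, y, w, h),
        side=d.get("side", "ipsilateral"),
    )
    geom.validate()
    return geom


def write_micrograph(path: str | Path, micrograph: Micrograph, geometry: SectionGeometry | None = None) -> Path:
    """Write a multi-page TIFF and its YAML sidecar; returns the TIFF path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, micrograph.data, photometric="minisblack")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "channels": list(micrograph.channels),
        "pixel_size_um": float(micrograph.pixel_size_um),
    }
    if geometry is not None:
        sidecar["geometry"] = geometry_to_dict(geometry)
    path.with_suffix(".yaml").write_text(yaml.safe_dump(sidecar, sort_keys=False))
    return path


def read_micrograph(path: str | Path) -> tuple[Micrograph, SectionGeometry | None]:
    """Read a TIFF + sidecar pair; the sidecar is required for pixel size."""
    path = Path(path)
    sidecar_path = path.with_suffix(".yaml")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = yaml.safe_load(sidecar_path.read_text())
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    micro = Micrograph(
        data=np.asarray(data, dtype=np.uint16),
        channels=tuple(meta["channels"]),
        pixel_size_um=float(meta["pixel_size_um"]),
    )
    geom = geometry_from_dict(meta["geometry"]) if "geometry" in meta else None
    return micro, geom


def write_puncta_csv(path: str | Path, fields: dict[str, list[PunctaField]]) -> Path:
    rows = []
    for channel, fls in fields.items():
        for f in fls:
            for x, y, a, i in zip(f.x_um, f.y_um, f.area_um2, f.intensity):
                rows.append(dict(x_um=x, y_um=y, area_um2=a, intensity=i, channel=channel))
    df = pd.DataFrame(rows, columns=["x_um", "y_um", "area_um2", "intensity", "channel"])
    df.insert(0, "schema_version", SCHEMA_VERSION)
    df.to_csv(path, index=False)
    return Path(path)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    timecourse: TimecourseConfig = field(default_factory=TimecourseConfig)
    days: tuple[int, ...] | None = None  # None = the timecourse's days
    seed: int = 0
    detection: dict = field(default_factory=dict)  # per-channel overrides
    write_puncta: bool = False

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        missing = [k for k in ("timecourse",) if k not in raw]
        if missing:
            raise ValueError(f"invalid run config: missing key(s) {', '.join(missing)}")
        tc_kwargs = dict(raw["timecourse"] or {})
        for key, cls in (("geometry", GeometryConfig), ("noise", NoiseModel)):
            sub = tc_kwargs.get(key, raw.get(key))
            if isinstance(sub, dict):
                tc_kwargs[key] = cls(**sub)
            elif key in tc_kwargs and sub is None:
                del tc_kwargs[key]
        for tup_key in ("days", "histology_days"):
            if tup_key in tc_kwargs:
                tc_kwargs[tup_key] = tuple(tc_kwargs[tup_key])
        # dict-valued timecourse tables keyed by tuples serialize as lists
        for k in ("baseline_density", "cuff_ipsi_pct", "cuff_contra_pct"):
            if k in tc_kwargs:
                tc_kwargs[k] = {_parse_key(kk): float(v) for kk, v in tc_kwargs[k].items()}
        for k in ("cuff_vf_pct", "cuff_hg_pct"):
            if k in tc_kwargs:
                tc_kwargs[k] = {int(kk): float(v) for kk, v in tc_kwargs[k].items()}
        known = {f.name for f in dc_fields(TimecourseConfig)}
        unknown = set(tc_kwargs) - known
        if unknown:
            raise ValueError(f"invalid run config: unknown timecourse key(s) {sorted(unknown)}")
        tc = TimecourseConfig(**tc_kwargs)
        return RunConfig(
            timecourse=tc,
            days=tuple(raw["days"]) if raw.get("days") else None,
            seed=int(raw.get("seed", 0)),
            detection=raw.get("detection", {}),
            write_puncta=bool(raw.get("write_puncta", False)),
        )

    def to_yaml(self, path: str | Path) -> None:
        tc = asdict(self.timecourse)
        for k in ("baseline_density", "cuff_ipsi_pct", "cuff_contra_pct"):
            tc[k] = {_format_key(kk): v for kk, v in tc[k].items()}
        raw = {
            "schema_version": SCHEMA_VERSION,
            "seed": self.seed,
            "days": list(self.days) if self.days else None,
            "timecourse": tc,
            "detection": self.detection,
            "write_puncta": self.write_puncta,
        }
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


def _parse_key(k):
    if isinstance(k, str) and "/" in k:
        parts = k.split("/")
        return tuple(int(p) if p.isdigit() else p for p in parts)
    return k


def _format_key(k):
    if isinstance(k, tuple):
        return "/".join(str(p) for p in k)
    return k
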