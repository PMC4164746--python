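"""Parametric geometry of one transverse dorsal-horn section.

Coordinates are in micrometres with the origin at the top-left image
corner, ``x`` running medio-laterally (columns) and ``y`` dorso-ventrally
(rows, increasing with depth).  Pixel bins are half-open:
pixel ``(r, c)`` covers ``[c*px, (c+1)*px) x [r*px, (r+1)*px)``.

A rendered section image contains both dorsal horns; a
:class:`SectionGeometry` describes one horn (one side).  The mirror axis
``midline_x_um`` maps an ipsilateral geometry onto the contralateral one.
The white-matter boundary is a polyline spanning the horn's medio-lateral
extent; lamina I (LI) is the band immediately below it, lamina II (LII)
the band below LI.  The "lesion zone" is the rectangle of LII in the
intermediate medio-lateral third where IB4 labelling is depleted after a
cuff injury.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "Rect",
    "GeometryConfig",
    "SectionGeometry",
    "generate_geometry",
]


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in μm (origin = top-left corner)."""

    x_um: float
    y_um: float
    width_um: float
    height_um: float

    @property
    def x1_um(self) -> float:
        return self.x_um + self.width_um

    @property
    def y1_um(self) -> float:
        return self.y_um + self.height_um

    @property
    def center_x_um(self) -> float:
        return self.x_um + self.width_um / 2.0

    @property
    def center_y_um(self) -> float:
        return self.y_um + self.height_um / 2.0

    @property
    def area_um2(self) -> float:
        return self.width_um * self.height_um

    def contains_point(self, x_um: float, y_um: float) -> bool:
        return (self.x_um <= x_um < self.x1_um) and (self.y_um <= y_um < self.y1_um)

    def intersection_area(self, other: "Rect") -> float:
        w = min(self.x1_um, other.x1_um) - max(self.x_um, other.x_um)
        h = min(self.y1_um, other.y1_um) - max(self.y_um, other.y_um)
        return max(0.0, w) * max(0.0, h)


@dataclass(frozen=True)
class GeometryConfig:
    """Parameters of the synthetic section geometry.

    ``width_um``/``height_um`` are the full two-horn image extent; each
    horn spans ``horn_width_um`` from its lateral edge to the midline.
    ``wm_sag_um`` bows the white-matter boundary ventrally at the horn
    centre (0 = flat).  Per-section jitter (seeded) moves the boundary
    depth and the lesion centre slightly between sections.
    """

    pixel_size_um: float = 0.1
    width_um: float = 620.0
    height_um: float = 300.0
    horn_width_um: float = 300.0
    wm_depth_um: float = 40.0
    wm_sag_um: float = 0.0
    li_band_thickness_um: float = 20.0
    lii_band_thickness_um: float = 80.0
    lesion_width_um: float = 80.0
    wm_depth_jitter_um: float = 3.0
    lesion_center_jitter_um: float = 8.0

    @property
    def midline_x_um(self) -> float:
        return self.width_um / 2.0


@dataclass(frozen=True)
class SectionGeometry:
    """Geometry of one dorsal horn within a two-horn section image."""

    pixel_size_um: float
    image_shape: tuple[int, int]  # (rows, cols)
    wm_x_um: np.ndarray  # polyline nodes, ascending
    wm_y_um: np.ndarray
    li_band_thickness_um: float
    lii_band_thickness_um: float
    midline_x_um: float
    lesion_zone: Rect
    side: str = "ipsilateral"

    # -- extents ---------------------------------------------------------
    @property
    def x0_um(self) -> float:
        return float(self.wm_x_um[0])

    @property
    def x1_um(self) -> float:
        return float(self.wm_x_um[-1])

    @property
    def horn_width_um(self) -> float:
        return self.x1_um - self.x0_um

    @property
    def image_width_um(self) -> float:
        return self.image_shape[1] * self.pixel_size_um

    @property
    def image_height_um(self) -> float:
        return self.image_shape[0] * self.pixel_size_um

    def middle_third(self) -> tuple[float, float]:
        """Medio-lateral interval of the horn's intermediate third."""
        w = self.horn_width_um / 3.0
        lo, hi = self.x0_um + w, self.x0_um + 2.0 * w
        return (lo, hi) if lo <= hi else (hi, lo)

    # -- white-matter boundary ------------------------------------------
    def wm_y(self, x_um):
        """Depth of the white-matter boundary at medio-lateral position x."""
        return np.interp(x_um, self.wm_x_um, self.wm_y_um)

    def wm_normal(self, x_um: float) -> tuple[float, float]:
        """Unit normal of the boundary at x, pointing into the grey matter."""
        eps = 1.0
        dy = (self.wm_y(x_um + eps) - self.wm_y(x_um - eps)) / (2.0 * eps)
        n = np.array([-dy, 1.0])
        n /= np.hypot(*n)
        return float(n[0]), float(n[1])

    # -- laminar bands ---------------------------------------------------
    def band_rect(self, lamina: str) -> Rect:
        """Bounding rectangle of a laminar band (exact for a flat boundary)."""
        y_top = float(np.max(self.wm_y_um))
        if lamina == "LI":
            y0, y1 = y_top, y_top + self.li_band_thickness_um
        elif lamina == "LII":
            y0 = y_top + self.li_band_thickness_um
            y1 = y0 + self.lii_band_thickness_um
        else:
            raise ValueError(f"unknown lamina {lamina!r}")
        return Rect(self.x0_um, y0, self.horn_width_um, y1 - y0)

    def lamina_of_depth(self, depth_um) -> str:
        if depth_um < self.li_band_thickness_um:
            return "LI"
        if depth_um < self.li_band_thickness_um + self.lii_band_thickness_um:
            return "LII"
        return "deep"

    # -- mirroring -------------------------------------------------------
    def mirror_x(self, x_um):
        return 2.0 * self.midline_x_um - np.asarray(x_um, dtype=float)

    def mirrored(self) -> "SectionGeometry":
        """The homotopic geometry on the opposite side of the midline."""
        mx = self.mirror_x(self.wm_x_um)[::-1]
        lz = self.lesion_zone
        return replace(
            self,
            wm_x_um=np.ascontiguousarray(mx),
            wm_y_um=np.ascontiguousarray(self.wm_y_um[::-1]),
            lesion_zone=Rect(
                2.0 * self.midline_x_um - lz.x1_um, lz.y_um, lz.width_um, lz.height_um
            ),
            side="contralateral" if self.side == "ipsilateral" else "ipsilateral",
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be > 0")
        if self.li_band_thickness_um <= 0 or self.lii_band_thickness_um <= 0:
            raise ValueError("laminar band thicknesses must be > 0")
        lii = self.band_rect("LII")
        lz = self.lesion_zone
        if not (
            lii.x_um <= lz.x_um
            and lz.x1_um <= lii.x1_um
            and lii.y_um <= lz.y_um
            and lz.y1_um <= lii.y1_um
        ):
            raise ValueError("lesion_zone must lie within the LII band")
        lo, hi = self.middle_third()
        if not (lo - 1e-9 <= lz.x_um and lz.x1_um <= hi + 1e-9):
            raise ValueError(
                "lesion_zone must lie within the intermediate medio-lateral third"
            )
        if lii.y1_um > self.image_height_um or self.x1_um > self.image_width_um:
            raise ValueError("geometry does not fit inside image_shape")


def generate_geometry(config: GeometryConfig, seed: int, side: str = "ipsilateral") -> SectionGeometry:
    """Draw one seeded section geometry from ``config``.

    The white-matter boundary depth and the lesion centre are jittered
    per section (within the containment invariants); identical
    ``(config, seed)`` give identical geometry.
    """
    if config.width_um < 300.0 or config.height_um < 300.0:
        raise ValueError("image extent must be at least 300 x 300 um")
    if config.lii_band_thickness_um <= 0 or config.li_band_thickness_um <= 0:
        raise ValueError("laminar band thicknesses must be > 0")
    roi_reach = 50.0 + 30.0  # LII quantification rectangle, 50 um from the WM
    if config.li_band_thickness_um + config.lii_band_thickness_um < roi_reach:
        raise ValueError(
            "LI+LII bands too shallow to contain the 30x50 um rectangle at 50 um depth"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x6E0]))
    wm_depth = config.wm_depth_um + rng.uniform(
        -config.wm_depth_jitter_um, config.wm_depth_jitter_um
    )

    nx = 61
    x = np.linspace(0.0, config.horn_width_um, nx)
    # gentle ventral bow, maximal at the horn centre
    y = wm_depth + config.wm_sag_um * np.sin(np.pi * x / config.horn_width_um)

    li = config.li_band_thickness_um
    lii = config.lii_band_thickness_um
    y_top = float(np.max(y))
    lii_y0 = y_top + li
    if lii_y0 + lii > config.height_um:
        raise ValueError("laminar bands exceed the image extent")

    third = config.horn_width_um / 3.0
    lo, hi = third, 2.0 * third
    half = config.lesion_width_um / 2.0
    if config.lesion_width_um > third:
        raise ValueError("lesion_width_um exceeds the middle third")
    c0 = (lo + hi) / 2.0
    cmax = min(hi - half, c0 + config.lesion_center_jitter_um)
    cmin = max(lo + half, c0 - config.lesion_center_jitter_um)
    center = rng.uniform(cmin, cmax) if cmax > cmin else c0
    lesion = Rect(center - half, lii_y0, config.lesion_width_um, lii)

    shape = (
        int(round(config.height_um / config.pixel_size_um)),
        int(round(config.width_um / config.pixel_size_um)),
    )
    geom = SectionGeometry(
        pixel_size_um=config.pixel_size_um,
        image_shape=shape,
        wm_x_um=x,
        wm_y_um=y,
        li_band_thickness_um=li,
        lii_band_thickness_um=lii,
        midline_x_um=config.midline_x_um,
        lesion_zone=lesion,
        side="ipsilateral",
    )
    geom.validate()
    if side == "contralateral":
        geom = geom.mirrored()
        geom.validate()
    return geom
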