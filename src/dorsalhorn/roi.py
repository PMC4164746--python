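"""Placement of the quantification rectangles and section-level densities.

Two rectangles are quantified per side: a 15 x 40 μm rectangle in LI
with its 40 μm side flush against the white-matter boundary, and a
30 x 50 μm rectangle in LII placed horizontally with its near edge
50 μm from the boundary, both centred on the medio-lateral middle of
the IB4 lesion.  On the contralateral side the rectangles mirror their
ipsilateral position across the midline; in sham sections (no lesion
contrast) they are placed where the lesion normally occurs.

Blobs are assigned to a rectangle if their centroid falls inside it,
which keeps the density unbiased under translation of the section.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Rect, SectionGeometry
from .quantify import Blob, DEFAULT_PARAMS, DetectionParams, accentuate, overlap_correct, segment
from .synth import Micrograph

__all__ = [
    "ROI",
    "LI_ROI_SIZE_UM",
    "LII_ROI_SIZE_UM",
    "LII_ROI_WM_OFFSET_UM",
    "detect_lesion_zone",
    "place_rois",
    "quantify_section",
]

log = logging.getLogger(__name__)

#: (medio-lateral width, depth) of the LI rectangle, μm
LI_ROI_SIZE_UM = (40.0, 15.0)
#: (medio-lateral width, depth) of the LII rectangle, μm
LII_ROI_SIZE_UM = (50.0, 30.0)
#: distance of the LII rectangle's near edge from the white matter, μm
LII_ROI_WM_OFFSET_UM = 50.0


@dataclass(frozen=True)
class ROI:
    rect: Rect
    lamina: str  # LI | LII
    side: str
    placement_mode: str  # lesion | mirrored | sham_homotopic

    @property
    def area_um2(self) -> float:
        return self.rect.area_um2


def detect_lesion_zone(
    ib4_blobs: list[Blob],
    geometry: SectionGeometry,
    window_um: float = 30.0,
    stride_um: float = 5.0,
    contrast: float = 0.5,
) -> Rect:
    """Locate the interval of depleted IB4 labelling within LII.

    A sliding window of ``window_um`` (stride ``stride_um``) counts IB4
    blob centroids inside the LII band.  Windows in the middle third
    whose density falls below ``contrast`` x the outer-thirds density
    are lesion candidates; the contiguous candidate run containing the
    global minimum is returned as a rectangle spanning LII's depth.
    Without a sufficient contrast (sham sections, uniform labelling,
    or an empty channel) the geometry's default middle-third rectangle
    is returned.
    """
    if geometry.lii_band_thickness_um <= 0:
        raise ValueError("geometry has no LII band")
    lii = geometry.band_rect("LII")
    default = geometry.lesion_zone
    xs = np.array([b.centroid_x_um for b in ib4_blobs], dtype=float)
    ys = np.array([b.centroid_y_um for b in ib4_blobs], dtype=float)
    in_band = (
        (xs >= lii.x_um) & (xs < lii.x1_um) & (ys >= lii.y_um) & (ys < lii.y1_um)
    )
    xs = xs[in_band]
    if len(xs) == 0:
        warnings.warn("no IB4 blobs in LII; using the default middle-third rectangle")
        return default

    # windows span the medio-lateral range actually covered by blobs, so a
    # cropped (middle-third + flanks) segmentation yields no phantom-empty
    # reference windows
    s_lo = max(lii.x_um, float(xs.min()))
    s_hi = min(lii.x1_um, float(xs.max()))
    starts = np.arange(s_lo, s_hi - window_um + 1e-9, stride_um)
    if len(starts) == 0:
        return default
    counts = np.array([np.count_nonzero((xs >= s) & (xs < s + window_um)) for s in starts])
    centers = starts + window_um / 2.0

    lo, hi = geometry.middle_third()
    mid = (centers >= lo) & (centers <= hi)
    outer = ~mid
    if not mid.any() or not outer.any():
        return default
    baseline = counts[outer].mean()
    if baseline <= 0:
        warnings.warn("IB4 reference density is zero; using the default rectangle")
        return default
    candidate = mid & (counts < contrast * baseline)
    if not candidate.any():
        return default
    mid_idx = np.nonzero(mid)[0]
    i_min = mid_idx[np.argmin(counts[mid_idx])]
    if not candidate[i_min]:
        return default
    i0 = i_min
    while i0 - 1 >= 0 and candidate[i0 - 1]:
        i0 -= 1
    i1 = i_min
    while i1 + 1 < len(starts) and candidate[i1 + 1]:
        i1 += 1
    x_lo = max(float(starts[i0]), lii.x_um)
    x_hi = min(float(starts[i1] + window_um), lii.x1_um)
    return Rect(x_lo, lii.y_um, x_hi - x_lo, lii.height_um)


def place_rois(
    geometry: SectionGeometry,
    lesion: Rect,
    side: str = "ipsilateral",
    placement_mode: str = "lesion",
) -> tuple[ROI, ROI]:
    """Place the LI and LII rectangles at the lesion's medio-lateral centre.

    Depth offsets are measured along the local white-matter boundary
    normal at the rectangle centre; the rectangles stay axis-aligned.
    """
    cx = lesion.center_x_um
    nx, ny = geometry.wm_normal(cx)
    y_wm = float(geometry.wm_y(cx))

    li_w, li_h = LI_ROI_SIZE_UM
    li_rect = Rect(cx - li_w / 2.0, y_wm, li_w, li_h)

    lii_w, lii_h = LII_ROI_SIZE_UM
    off = LII_ROI_WM_OFFSET_UM
    lii_rect = Rect(cx + off * nx - lii_w / 2.0, y_wm + off * ny, lii_w, lii_h)

    for r, name in ((li_rect, "LI"), (lii_rect, "LII")):
        if (
            r.x_um < 0
            or r.y_um < 0
            or r.x1_um > geometry.image_width_um
            or r.y1_um > geometry.image_height_um
        ):
            raise ValueError(
                f"{name} rectangle {r} exceeds the image bounds "
                f"({geometry.image_width_um} x {geometry.image_height_um} um)"
            )
    return (
        ROI(li_rect, "LI", side, placement_mode),
        ROI(lii_rect, "LII", side, placement_mode),
    )


def _mirror_roi(roi: ROI, geometry: SectionGeometry) -> ROI:
    r = roi.rect
    return ROI(
        Rect(2.0 * geometry.midline_x_um - r.x1_um, r.y_um, r.width_um, r.height_um),
        roi.lamina,
        "contralateral" if roi.side == "ipsilateral" else "ipsilateral",
        "mirrored",
    )


def _segment_bands(
    micrograph: Micrograph,
    geometry: SectionGeometry,
    params: dict[str, DetectionParams],
    margin_um: float = 3.0,
) -> dict[str, list[Blob]]:
    """Accentuate and segment the LI+LII bands of one horn, per channel.

    Processing is restricted to the laminar bands and, medio-laterally,
    to the middle third plus 40 μm flanks — every legal rectangle
    placement lies in the middle third and the flanks provide the
    reference density for lesion detection.  Blob coordinates are
    reported in whole-image μm.
    """
    px = micrograph.pixel_size_um
    y0 = max(0.0, float(np.min(geometry.wm_y_um)) - margin_um)
    y1 = min(
        geometry.image_height_um,
        float(np.max(geometry.wm_y_um))
        + geometry.li_band_thickness_um
        + geometry.lii_band_thickness_um
        + margin_um,
    )
    mid_lo, mid_hi = geometry.middle_third()
    x0 = max(0.0, geometry.x0_um - margin_um, mid_lo - 40.0)
    x1 = min(geometry.image_width_um, geometry.x1_um + margin_um, mid_hi + 40.0)
    r0, r1 = int(y0 / px), int(np.ceil(y1 / px))
    c0, c1 = int(x0 / px), int(np.ceil(x1 / px))
    out: dict[str, list[Blob]] = {}
    for name in micrograph.channels:
        p = params[name]
        crop = micrograph.channel(name)[r0:r1, c0:c1]
        acc = accentuate(crop, px, p.bouton_diameter_um)
        blobs = segment(acc, p.threshold_dn, px, p.min_area_um2)
        out[name] = [
            Blob(
                b.area_um2,
                b.centroid_x_um + c0 * px,
                b.centroid_y_um + r0 * px,
                b.mean_intensity,
                b.peak_intensity,
                b.area_px,
            )
            for b in blobs
        ]
    return out


def quantify_section(
    micrograph: Micrograph,
    geometry: SectionGeometry,
    params: dict[str, DetectionParams] | None = None,
    sham: bool = False,
    meta: dict | None = None,
    blob_sink: dict | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Quantify one section: 8 density records (side x lamina x marker).

    The lesion is located on the ipsilateral side from the IB4 channel
    (sham sections take the homotopic default placement); contralateral
    rectangles mirror the ipsilateral ones.  Returns the tidy record
    table and a placement audit (rectangle and lesion coordinates).
    If ``blob_sink`` is given it is filled with the segmented blobs per
    side and channel.
    """
    params = params or DEFAULT_PARAMS
    meta = meta or {}
    ipsi = geometry if geometry.side == "ipsilateral" else geometry.mirrored()
    contra = ipsi.mirrored()

    blobs_ipsi = _segment_bands(micrograph, ipsi, params)
    blobs_contra = _segment_bands(micrograph, contra, params)
    if blob_sink is not None:
        blob_sink["ipsilateral"] = blobs_ipsi
        blob_sink["contralateral"] = blobs_contra

    if sham:
        lesion = ipsi.lesion_zone
        mode = "sham_homotopic"
    else:
        lesion = detect_lesion_zone(blobs_ipsi["IB4"], ipsi)
        mode = "lesion"
    roi_li, roi_lii = place_rois(ipsi, lesion, "ipsilateral", mode)
    rois = {
        ("ipsilateral", "LI"): roi_li,
        ("ipsilateral", "LII"): roi_lii,
        ("contralateral", "LI"): _mirror_roi(roi_li, ipsi),
        ("contralateral", "LII"): _mirror_roi(roi_lii, ipsi),
    }

    rows = []
    for (side, lamina), roi in rois.items():
        side_blobs = blobs_ipsi if side == "ipsilateral" else blobs_contra
        for marker in micrograph.channels:
            inside = [
                b
                for b in side_blobs[marker]
                if roi.rect.contains_point(b.centroid_x_um, b.centroid_y_um)
            ]
            res = overlap_correct(
                inside,
                params[marker].mean_area_um2,
                params[marker].correction,
                region_area_um2=roi.area_um2,
            )
            rows.append(
                dict(
                    **meta,
                    side=side,
                    lamina=lamina,
                    marker=marker,
                    raw_count=res.raw_blob_count,
                    corrected_count=res.corrected_count,
                    roi_area_um2=roi.area_um2,
                    density=100.0 * res.corrected_count / roi.area_um2,
                    placement_mode=roi.placement_mode,
                )
            )
    audit = {
        "lesion_rect_um": [lesion.x_um, lesion.y_um, lesion.width_um, lesion.height_um],
        "placement_mode": mode,
        "rois": {
            f"{side}/{lamina}": [r.rect.x_um, r.rect.y_um, r.rect.width_um, r.rect.height_um]
            for (side, lamina), r in rois.items()
        },
    }
    return pd.DataFrame(rows), audit
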