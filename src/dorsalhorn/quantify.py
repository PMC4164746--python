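"""Detection and counting of labelled varicosities in one image channel.

The counting chain mirrors a classic densitometry workflow:

1. *accentuate* — a white top-hat that flattens structures much larger
   than a bouton while preserving bouton-scale spots, so a single global
   threshold separates puncta from background and from large bright
   features.
2. *segment* — supra-threshold 4-connected components, discarding
   objects below 0.05 μm² (cut axon fragments).
3. *overlap_correct* — merged varicosities appear as one blob; each
   blob contributes ``max(1, round(area / mean_area))`` counts, where
   ``mean_area`` is the marker's mean single-varicosity area
   (IB4 0.3 μm², GAD65 0.2 μm²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, white_tophat

from .synth import MEAN_AREA_UM2

__all__ = [
    "Blob",
    "CountResult",
    "DetectionParams",
    "DEFAULT_PARAMS",
    "accentuate",
    "segment",
    "overlap_correct",
    "count_channel",
]


@dataclass(frozen=True)
class Blob:
    """One supra-threshold 4-connected component (pixel set summarized)."""

    area_um2: float
    centroid_x_um: float
    centroid_y_um: float
    mean_intensity: float
    peak_intensity: float
    area_px: int


@dataclass(frozen=True)
class CountResult:
    """Raw and overlap-corrected counts of one channel in one region.

    Under the per-blob rule ``corrected_count >= raw_blob_count`` always
    holds (with equality when no blob exceeds 1.5x the assumed mean
    area); the area-based rules can fall below the raw count when blobs
    run smaller than the assumed mean.
    """

    raw_blob_count: int
    corrected_count: float
    total_blob_area_um2: float
    mean_blob_area_um2: float
    mean_area_assumed_um2: float
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class DetectionParams:
    """Per-channel detection settings.

    ``threshold_dn`` applies to the accentuated (background-flattened)
    channel.  The packaged default threshold (450 DN, roughly half the
    dimmest punctum peak under the default rendering model) was chosen by
    calibration against synthetic ground truth: it keeps the measured
    area of an isolated varicosity close to its true area, which the
    mean-area overlap correction assumes.  ``structure_scale_um`` is the
    expected bouton diameter; ``None`` derives it from ``mean_area_um2``.

    ``correction`` selects the overlap-correction rule used by the
    pipeline.  The packaged default is ``boolean`` (area-fraction
    inversion of the mean-area rule): ground-truth calibration showed
    the per-blob rounding rule inflates counts of *isolated* boutons by
    ~+14% when single-varicosity areas vary (CV 0.5, the right tail
    rounds to 2), and the plain total-area rule under-counts by ~4%
    where varicosities clump; the Boolean inversion holds the bias
    within about ±1-3% across 0.4-40 puncta per 100 μm² for both
    markers.  ``per_blob`` and ``total_area`` remain available.
    """

    threshold_dn: float = 450.0
    min_area_um2: float = 0.05
    mean_area_um2: float = 0.2
    structure_scale_um: float | None = None
    correction: str = "boolean"

    @property
    def bouton_diameter_um(self) -> float:
        if self.structure_scale_um is not None:
            return self.structure_scale_um
        return 2.0 * np.sqrt(self.mean_area_um2 / np.pi)


#: packaged defaults per marker channel
DEFAULT_PARAMS = {
    "IB4": DetectionParams(mean_area_um2=MEAN_AREA_UM2["IB4"]),
    "GAD65": DetectionParams(mean_area_um2=MEAN_AREA_UM2["GAD65"]),
}


def accentuate(
    image_channel: np.ndarray,
    pixel_size_um: float,
    structure_scale_um: float,
) -> np.ndarray:
    """White top-hat that suppresses structures larger than bouton scale.

    The structuring element is a disc whose radius is 1.5× the expected
    bouton diameter (i.e. diameter ≈ 3× the bouton diameter): boutons
    pass nearly unchanged, anything much wider is levelled.
    """
    if image_channel.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if structure_scale_um < pixel_size_um:
        raise ValueError("structure_scale_um must be at least one pixel")
    radius_px = max(1, int(round(1.5 * structure_scale_um / pixel_size_um)))
    footprint = disk(radius_px, decomposition="sequence")
    return white_tophat(image_channel, footprint=footprint)


def segment(
    image_channel: np.ndarray,
    intensity_threshold: float,
    pixel_size_um: float,
    min_area_um2: float = 0.05,
) -> list[Blob]:
    """Supra-threshold 4-connected components of at least ``min_area_um2``."""
    mask = image_channel > intensity_threshold
    labels, n = ndimage.label(mask)  # default structure = 4-connectivity
    if n == 0:
        return []
    px2 = pixel_size_um**2
    rr, cc = np.nonzero(mask)
    lab = labels[rr, cc]
    vals = image_channel[rr, cc].astype(np.float64)
    areas_px = np.bincount(lab, minlength=n + 1)[1:]
    keep = areas_px * px2 >= min_area_um2
    if not keep.any():
        return []
    sum_r = np.bincount(lab, weights=rr, minlength=n + 1)[1:]
    sum_c = np.bincount(lab, weights=cc, minlength=n + 1)[1:]
    sum_v = np.bincount(lab, weights=vals, minlength=n + 1)[1:]
    max_v = np.zeros(n + 1)
    np.maximum.at(max_v, lab, vals)
    max_v = max_v[1:]
    blobs = []
    for i in np.nonzero(keep)[0]:
        apx = int(areas_px[i])
        blobs.append(
            Blob(
                area_um2=float(apx * px2),
                centroid_x_um=(sum_c[i] / apx + 0.5) * pixel_size_um,
                centroid_y_um=(sum_r[i] / apx + 0.5) * pixel_size_um,
                mean_intensity=float(sum_v[i] / apx),
                peak_intensity=float(max_v[i]),
                area_px=apx,
            )
        )
    return blobs


def overlap_correct(
    blobs: list[Blob],
    mean_area_um2: float,
    mode: str = "per_blob",
    region_area_um2: float | None = None,
) -> CountResult:
    """Estimate the varicosity count from blobs and the mean varicosity area.

    ``per_blob`` (default): each blob counts ``max(1, round(area/mean))``
    with round-half-to-even, so isolated boutons keep their raw count
    and only merged blobs are split; the corrected count never falls
    below the raw blob count.  ``total_area``: the pooled blob area is
    divided by the mean area.  ``boolean``: like ``total_area`` but
    inverting the Boolean (random-coverage) model — for Poisson-placed
    varicosities the covered fraction is
    ``p = 1 - exp(-lambda*mean_area)``, so the count over a region of
    area ``A`` is ``-A*ln(1 - total/A)/mean_area``; this also recovers
    the union area lost where varicosities clump, and reduces to
    ``total_area`` as coverage goes to zero.  ``boolean`` requires
    ``region_area_um2`` (the area the blobs were collected from).  The
    area-based rules deliberately do not floor at the raw count: with
    dispersed single-varicosity areas that floor is one-sided and
    inflates sparse-region counts.
    """
    if mean_area_um2 <= 0:
        raise ValueError("mean_area_um2 must be > 0")
    if mode not in ("per_blob", "total_area", "boolean"):
        raise ValueError(f"unknown correction mode {mode!r}")
    areas = np.array([b.area_um2 for b in blobs], dtype=float)
    raw = len(blobs)
    total = float(areas.sum()) if raw else 0.0
    if raw == 0:
        corrected = 0.0
    elif mode == "per_blob":
        corrected = float(np.maximum(1, np.round(areas / mean_area_um2)).sum())
    elif mode == "total_area":
        corrected = float(np.round(total / mean_area_um2))
    else:
        if region_area_um2 is None or region_area_um2 <= 0:
            raise ValueError("boolean correction needs the sampled region_area_um2")
        p = min(total / region_area_um2, 0.999)
        corrected = float(np.round(-region_area_um2 * np.log1p(-p) / mean_area_um2))
    return CountResult(
        raw_blob_count=raw,
        corrected_count=corrected,
        total_blob_area_um2=total,
        mean_blob_area_um2=total / raw if raw else 0.0,
        mean_area_assumed_um2=mean_area_um2,
        params={"mode": mode},
    )


def count_channel(
    image_channel: np.ndarray,
    pixel_size_um: float,
    params: DetectionParams,
) -> CountResult:
    """Accentuate, segment and overlap-correct one channel."""
    if image_channel.size and image_channel.min() >= 4095:
        warnings.warn("channel is saturated everywhere; returning an empty result")
        return CountResult(0, 0.0, 0.0, 0.0, params.mean_area_um2, {"saturated": True})
    acc = accentuate(image_channel, pixel_size_um, params.bouton_diameter_um)
    blobs = segment(acc, params.threshold_dn, pixel_size_um, params.min_area_um2)
    res = overlap_correct(
        blobs,
        params.mean_area_um2,
        params.correction,
        region_area_um2=image_channel.size * pixel_size_um**2,
    )
    logged = dict(res.params)
    logged.update(
        threshold_dn=params.threshold_dn,
        min_area_um2=params.min_area_um2,
        structure_scale_um=params.bouton_diameter_um,
    )
    return CountResult(
        res.raw_blob_count,
        res.corrected_count,
        res.total_blob_area_um2,
        res.mean_blob_area_um2,
        res.mean_area_assumed_um2,
        logged,
    )
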