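"""Synthetic two-channel dorsal-horn micrographs with known ground truth.

Puncta (axonal varicosities / boutons) are simulated as a homogeneous
spatial Poisson process within a rectangular region, with log-normally
distributed areas whose mean matches the marker's mean single-varicosity
area (IB4 0.3 μm², GAD65 0.2 μm²).  Each punctum is rendered as a
compact blob of exactly its area (the ``n`` pixels nearest its centre,
``n = round(area / pixel_size²)``), convolved with a Gaussian PSF, on a
noisy background, quantized to 12-bit counts in a 16-bit container.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Rect, SectionGeometry

__all__ = [
    "CHANNELS",
    "MEAN_AREA_UM2",
    "NoiseModel",
    "PunctaField",
    "Micrograph",
    "sample_puncta",
    "render_micrograph",
]

CHANNELS = ("IB4", "GAD65")

#: mean single-varicosity area per marker, μm²
MEAN_AREA_UM2 = {"IB4": 0.3, "GAD65": 0.2}

#: default punctum peak amplitude band above background, 12-bit DN
DEFAULT_INTENSITY_RANGE = (800.0, 1000.0)


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition model: additive Gaussian background, optional shot noise.

    Defaults keep punctum peaks (background + ~1000 DN) well below the
    4095 DN ceiling, matching an acquisition tuned to avoid saturation.
    """

    background_level: float = 200.0
    background_sd: float = 15.0
    psf_sigma_um: float = 0.08
    photon_noise: bool = False
    bit_depth: int = 12

    @property
    def max_dn(self) -> int:
        return (1 << self.bit_depth) - 1


@dataclass
class PunctaField:
    """Ground-truth puncta of one channel within one region."""

    x_um: np.ndarray
    y_um: np.ndarray
    area_um2: np.ndarray
    intensity: np.ndarray  # peak amplitude above background, DN
    channel: str
    region: Rect
    true_density: float  # puncta per 100 μm²

    def __len__(self) -> int:
        return len(self.x_um)

    @property
    def count(self) -> int:
        return len(self.x_um)

    def __post_init__(self) -> None:
        if len(self.x_um) and (
            np.any(self.x_um < self.region.x_um)
            or np.any(self.x_um >= self.region.x1_um)
            or np.any(self.y_um < self.region.y_um)
            or np.any(self.y_um >= self.region.y1_um)
        ):
            raise ValueError("puncta centres must lie inside the field's region")
        if np.any(self.area_um2 <= 0):
            raise ValueError("puncta areas must be positive")

    @staticmethod
    def concatenate(fields: "list[PunctaField]") -> "PunctaField":
        """Merge fields of one channel; region becomes the bounding box."""
        if not fields:
            raise ValueError("nothing to concatenate")
        ch = fields[0].channel
        if any(f.channel != ch for f in fields):
            raise ValueError("cannot merge fields of different channels")
        x0 = min(f.region.x_um for f in fields)
        y0 = min(f.region.y_um for f in fields)
        x1 = max(f.region.x1_um for f in fields)
        y1 = max(f.region.y1_um for f in fields)
        bbox = Rect(x0, y0, x1 - x0, y1 - y0)
        tot = sum(f.count for f in fields)
        dens = 100.0 * tot / bbox.area_um2 if bbox.area_um2 > 0 else 0.0
        return PunctaField(
            x_um=np.concatenate([f.x_um for f in fields]),
            y_um=np.concatenate([f.y_um for f in fields]),
            area_um2=np.concatenate([f.area_um2 for f in fields]),
            intensity=np.concatenate([f.intensity for f in fields]),
            channel=ch,
            region=bbox,
            true_density=dens,
        )


@dataclass
class Micrograph:
    """Two-channel 12-bit raster with physical pixel size metadata."""

    data: np.ndarray  # uint16, shape (n_channels, rows, cols)
    channels: tuple[str, ...]
    pixel_size_um: float

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]


def sample_puncta(
    region: Rect,
    density: float,
    mean_area_um2: float,
    area_cv: float = 0.5,
    seed: int | np.random.Generator = 0,
    channel: str = "GAD65",
    intensity_range: tuple[float, float] = DEFAULT_INTENSITY_RANGE,
) -> PunctaField:
    """Sample a homogeneous Poisson punctum field.

    Parameters
    ----------
    density : puncta per 100 μm² (expected count = density × area / 100).
    mean_area_um2 : mean of the log-normal single-punctum area.
    area_cv : coefficient of variation of the area distribution.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    if mean_area_um2 <= 0:
        raise ValueError("mean_area_um2 must be > 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x5A]))
    )
    n = rng.poisson(density * region.area_um2 / 100.0)
    x = rng.uniform(region.x_um, region.x1_um, size=n)
    y = rng.uniform(region.y_um, region.y1_um, size=n)
    # log-normal with the requested arithmetic mean and CV
    sigma2 = np.log1p(area_cv**2)
    mu = np.log(mean_area_um2) - sigma2 / 2.0
    areas = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=n)
    amp = rng.uniform(*intensity_range, size=n)
    return PunctaField(x, y, areas, amp, channel, region, density)


def _paint_puncta(
    img: np.ndarray, fld: PunctaField, pixel_size_um: float
) -> None:
    """Add each punctum as the ``round(area/px²)`` pixels nearest its centre."""
    if fld.count == 0:
        return
    px2 = pixel_size_um**2
    npix = np.maximum(1, np.round(fld.area_um2 / px2).astype(int))
    rmax = int(np.ceil(np.sqrt(npix.max() / np.pi))) + 2
    offs = np.mgrid[-rmax : rmax + 1, -rmax : rmax + 1].reshape(2, -1)  # (2, K)
    cx = fld.x_um / pixel_size_um - 0.5  # punctum centre in pixel-centre coords
    cy = fld.y_um / pixel_size_um - 0.5
    ix = np.round(cx).astype(int)
    iy = np.round(cy).astype(int)
    H, W = img.shape
    inside = (
        (ix - rmax >= 0) & (ix + rmax < W) & (iy - rmax >= 0) & (iy + rmax < H)
    )
    if not inside.all():
        warnings.warn(
            "puncta extend beyond the image and are clipped",
            stacklevel=3,
        )
    # distances from each candidate pixel centre to the (sub-pixel) centre
    dx = (ix[:, None] + offs[1][None, :]) - cx[:, None]
    dy = (iy[:, None] + offs[0][None, :]) - cy[:, None]
    d2 = dx * dx + dy * dy
    rank = np.argsort(np.argsort(d2, axis=1), axis=1)
    sel = rank < npix[:, None]
    rows = iy[:, None] + offs[0][None, :]
    cols = ix[:, None] + offs[1][None, :]
    ok = sel & (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    amp = np.broadcast_to(fld.intensity[:, None], d2.shape)
    np.add.at(img, (rows[ok], cols[ok]), amp[ok])


def render_micrograph(
    geometry: SectionGeometry,
    fields: dict[str, PunctaField | list[PunctaField]],
    noise: NoiseModel = NoiseModel(),
    seed: int | np.random.Generator = 0,
) -> Micrograph:
    """Render per-channel punctum fields into a two-channel micrograph.

    Channels are rendered independently; each gets its own noise
    realization.  Values are clipped to ``[0, 2^bit_depth - 1]`` and
    stored as uint16.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xB1]))
    )
    shape = geometry.image_shape
    chans = []
    names = tuple(fields.keys()) if fields else CHANNELS
    px = geometry.pixel_size_um
    sig_px = noise.psf_sigma_um / px
    for name in names:
        fl = fields.get(name, [])
        if isinstance(fl, PunctaField):
            fl = [fl]
        img = np.zeros(shape, dtype=np.float32)
        for f in fl:
            _paint_puncta(img, f, px)
        if sig_px > 0 and fl:
            # blur only the row band that holds puncta (plus the kernel reach)
            pad = int(np.ceil(3.0 * sig_px)) + 1
            r0 = max(0, int(min(f.region.y_um for f in fl) / px) - pad)
            r1 = min(shape[0], int(np.ceil(max(f.region.y1_um for f in fl) / px)) + pad)
            img[r0:r1] = gaussian_filter(img[r0:r1], sig_px, truncate=3.0)
        if noise.background_sd > 0:
            img += rng.standard_normal(shape, dtype=np.float32) * noise.background_sd
        img += noise.background_level
        if noise.photon_noise:
            img = rng.poisson(np.maximum(img, 0.0)).astype(np.float32)
        np.clip(img, 0, noise.max_dn, out=img)
        chans.append((img + 0.5).astype(np.uint16))
    return Micrograph(np.stack(chans), names, geometry.pixel_size_um)
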