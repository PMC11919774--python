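"""Itti-Koch bottom-up saliency maps for static images.

Implements the classic architecture: a 9-level Gaussian pyramid of
low-level features (intensity, red-green and blue-yellow double-opponency,
and oriented Gabor energy at 0/45/90/135 degrees), center-surround
differences between pyramid levels c in {2,3,4} and s = c + {3,4}, Itti's
peak-promotion normalization operator N(.), across-scale summation into
per-channel conspicuity maps at pyramid level 4, and an equal-weight
combination into the full saliency map.

For the 1280 x 1024 study display, level 4 is exactly 80 x 64 cells; other
input sizes are first resized to the display resolution so every map shares
that grid. Maps are finally normalized to probability densities (sum 1)
so they can be read as endpoint densities by the scoring stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter
from scipy.signal import fftconvolve
from skimage.filters import gabor_kernel
from skimage.transform import resize

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry

N_LEVELS = 9
CENTER_LEVELS = (2, 3, 4)
SURROUND_DELTAS = (3, 4)
OUT_LEVEL = 4
#: Bar orientations of the four Gabor channels, degrees counter-clockwise
#: from the horizontal axis (90 = vertical bars).
ORIENTATIONS = (0, 45, 90, 135)
GABOR_FREQUENCY = 0.20  # cycles / pixel at every pyramid level
CHANNELS = ("full", "color", "luminance", "orientation")

_LUM_FLOOR = 0.1  # hue is undefined at low luminance; Itti's 1/10 rule


@dataclass(frozen=True)
class SaliencyMap:
    """A per-image saliency density on the shared 80 x 64 cell grid.

    ``values[row, col]`` is non-negative and sums to one; ``channel`` is one
    of ``full``, ``color``, ``luminance``, ``orientation``.
    """

    values: np.ndarray
    channel: str
    image_id: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (DEFAULT_GEOMETRY.grid_rows, DEFAULT_GEOMETRY.grid_cols):
            raise ValueError(f"saliency map must be 64 rows x 80 cols, got {v.shape}")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if (v < 0).any():
            raise ValueError("saliency map has negative values")
        if abs(v.sum() - 1.0) > 1e-9:
            raise ValueError("saliency map is not normalized to sum 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def second_moment(self) -> float:
        """Sum of squared cell densities; the expected density under the map
        itself (used for generator calibration)."""
        return float((self.values**2).sum())


class FeaturePyramid:
    """Gaussian feature pyramid for one image.

    ``intensity[k]``, ``rg[k]``, ``by[k]`` exist for all 9 levels;
    ``orientation[k][theta]`` (Gabor energy) is computed for the levels the
    center-surround stage actually reads (2..8).
    """

    def __init__(self, intensity, rg, by, orientation):
        self.intensity = intensity
        self.rg = rg
        self.by = by
        self.orientation = orientation

    @property
    def n_levels(self) -> int:
        return len(self.intensity)

    def feature(self, name: str, level: int, theta: int | None = None):
        if name == "intensity":
            return self.intensity[level]
        if name == "rg":
            if self.rg[level] is None:
                raise ValueError(f"opponency not built at level {level}")
            return self.rg[level]
        if name == "by":
            if self.by[level] is None:
                raise ValueError(f"opponency not built at level {level}")
            return self.by[level]
        if name == "orientation":
            out = self.orientation[level]
            if out is None:
                raise ValueError(f"orientation energy not built at level {level}")
            return out[theta]
        raise ValueError(f"unknown feature {name!r}")


def _reduce(a: np.ndarray) -> np.ndarray:
    """One pyramid step: sigma ~ 1 px Gaussian blur, then x2 decimation."""
    return gaussian_filter(a, 1.0, mode="nearest")[::2, ::2]


def _make_gabor(theta: int) -> np.ndarray:
    # zero-DC even component so constant regions give exactly no response
    k = gabor_kernel(GABOR_FREQUENCY, theta=np.deg2rad(theta + 90))
    return k - k.mean()


_GABOR_KERNELS = {theta: _make_gabor(theta) for theta in ORIENTATIONS}


def _gabor_energy(intensity: np.ndarray, theta: int) -> np.ndarray:
    """Quadrature (even + odd) Gabor energy for bars oriented at ``theta``.

    The image is reflect-padded before convolution so borders see no
    artificial step edge. Callers must not pass images smaller than the
    kernel (see ``build_pyramids``, which continues the energy pyramid by
    decimation at the coarsest levels instead).
    """
    k = _GABOR_KERNELS[theta]
    hy, hx = k.shape[0] // 2, k.shape[1] // 2
    padded = np.pad(intensity, ((hy, hy), (hx, hx)), mode="reflect")
    resp = fftconvolve(padded, k, mode="same")[hy:hy + intensity.shape[0],
                                               hx:hx + intensity.shape[1]]
    return np.abs(resp)


_MAX_KERNEL = max(max(k.shape) for k in _GABOR_KERNELS.values())


def build_pyramids(image: np.ndarray) -> FeaturePyramid:
    """Decompose an RGB (or grayscale) raster into the Itti-Koch features.

    Grayscale input is accepted (opponency planes are then identically
    zero); images smaller than 64 x 64 are rejected.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an H x W x 3 image")
    if image.shape[0] < 64 or image.shape[1] < 64:
        raise ValueError("image too small; need at least 64 x 64 pixels")
    img = image[..., :3].astype(float)
    if img.max() > 1.0:
        img = img / 255.0

    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    intensity, rgs, bys, oris = [], [], [], []
    for level in range(N_LEVELS):
        inten = (r + g + b) / 3.0
        intensity.append(inten)
        if level < CENTER_LEVELS[0]:
            # levels 0-1 are never read by the center-surround stage
            # (centers start at level 2); only the pyramid chain is kept
            rgs.append(None)
            bys.append(None)
            oris.append(None)
        else:
            # hue normalization: divide by intensity where it is above 1/10
            # of the level maximum, else the pixel carries no usable hue
            imax = inten.max()
            if imax > 0:
                mask = inten > _LUM_FLOOR * imax
            else:
                mask = np.zeros_like(inten, dtype=bool)
            with np.errstate(divide="ignore", invalid="ignore"):
                rn = np.where(mask, r / inten, 0.0)
                gn = np.where(mask, g / inten, 0.0)
                bn = np.where(mask, b / inten, 0.0)
            R = np.clip(rn - (gn + bn) / 2.0, 0, None)
            G = np.clip(gn - (rn + bn) / 2.0, 0, None)
            B = np.clip(bn - (rn + gn) / 2.0, 0, None)
            Y = np.clip((rn + gn) / 2.0 - np.abs(rn - gn) / 2.0 - bn, 0, None)
            rgs.append(R - G)
            bys.append(B - Y)
            if min(inten.shape) >= _MAX_KERNEL:
                oris.append({t: _gabor_energy(inten, t) for t in ORIENTATIONS})
            else:
                # level smaller than the Gabor kernel: continue the energy
                # pyramid by blur + decimation of the previous level
                prev = oris[-1]
                oris.append({t: _reduce(prev[t]) for t in ORIENTATIONS}
                            if prev is not None
                            else {t: np.zeros_like(inten) for t in ORIENTATIONS})
        if level < N_LEVELS - 1:
            r, g, b = _reduce(r), _reduce(g), _reduce(b)
    return FeaturePyramid(intensity, rgs, bys, oris)


def center_surround(
    pyramid: FeaturePyramid,
    feature: str,
    c: int,
    s: int,
    theta: int | None = None,
) -> np.ndarray:
    """|center - surround| feature contrast, evaluated at level ``c``.

    The coarse level ``s`` is bilinearly upsampled to the shape of level
    ``c`` before subtraction; the result is non-negative by construction.
    """
    if s >= pyramid.n_levels:
        raise ValueError(f"surround level {s} beyond pyramid depth")
    center = pyramid.feature(feature, c, theta)
    surround = pyramid.feature(feature, s, theta)
    surround_up = resize(
        surround, center.shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    return np.abs(center - surround_up)


def normalize_map(m: np.ndarray, peak_floor: float = 0.05) -> np.ndarray:
    """Itti's normalization operator N(.).

    Rescale to [0, 1], then multiply by (1 - mbar)^2 where mbar is the mean
    of the local maxima excluding (one instance of) the global maximum. A
    map with one dominant peak is promoted (multiplier ~1); a map with many
    near-equal peaks is suppressed toward zero. All-zero maps pass through
    unchanged.
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("N(.) expects a non-negative map")
    mx = m.max()
    # features are O(1); anything at rounding scale is a flat map
    if mx <= 1e-12:
        return np.zeros_like(m)
    m = m / mx
    size = max(3, 2 * round(min(m.shape) / 20) + 1)
    peaks = (maximum_filter(m, size=size, mode="nearest") == m) & (m >= peak_floor)
    vals = m[peaks]
    if vals.size <= 1:
        mbar = 0.0
    else:
        mbar = (vals.sum() - 1.0) / (vals.size - 1)
    return m * (1.0 - mbar) ** 2


def _scale_pairs():
    for c in CENTER_LEVELS:
        for d in SURROUND_DELTAS:
            yield c, c + d


def conspicuity(pyramid: FeaturePyramid, channel: str) -> np.ndarray:
    """Across-scale combination of normalized center-surround maps.

    Returns the channel's conspicuity map at pyramid level 4 (80 x 64 for a
    display-resolution input). ``luminance`` sums intensity contrasts;
    ``color`` sums RG and BY opponency contrasts; ``orientation`` sums the
    four per-orientation maps after a second N(.) pass each.
    """
    out_shape = pyramid.intensity[OUT_LEVEL].shape

    def across_scale(feature, theta=None):
        acc = np.zeros(out_shape)
        for c, s in _scale_pairs():
            cs = normalize_map(center_surround(pyramid, feature, c, s, theta))
            acc += resize(cs, out_shape, order=1, mode="edge",
                          anti_aliasing=False, preserve_range=True)
        return acc

    if channel == "luminance":
        return across_scale("intensity")
    if channel == "color":
        return across_scale("rg") + across_scale("by")
    if channel == "orientation":
        acc = np.zeros(out_shape)
        for theta in ORIENTATIONS:
            acc += normalize_map(across_scale("orientation", theta))
        return acc
    raise ValueError(f"unknown conspicuity channel {channel!r}")


def combine_full(color: np.ndarray, luminance: np.ndarray,
                 orientation: np.ndarray) -> np.ndarray:
    """Equal-weight combination of the three normalized conspicuity maps."""
    if not (color.shape == luminance.shape == orientation.shape):
        raise ValueError("conspicuity maps must share one shape")
    return (normalize_map(color) + normalize_map(luminance)
            + normalize_map(orientation)) / 3.0


def to_density(m: np.ndarray) -> np.ndarray:
    """Normalize a non-negative map so its values sum to one.

    An all-zero map (e.g. the color channel of an achromatic image) falls
    back to the uniform density 1/N over the grid.
    """
    m = np.asarray(m, dtype=float)
    if (m < 0).any():
        raise ValueError("density normalization expects a non-negative map")
    total = m.sum()
    if total <= 1e-12 * m.size:
        return np.full(m.shape, 1.0 / m.size)
    return m / total


def compute_saliency(
    image: np.ndarray,
    image_id: str = "",
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
) -> dict[str, SaliencyMap]:
    """Full saliency pipeline for one image.

    Resizes the image to the display resolution, builds the feature
    pyramid, and returns the four density-normalized 80 x 64 maps keyed by
    channel (``full``, ``color``, ``luminance``, ``orientation``).
    """
    image = np.asarray(image)
    target = (geometry.height_px, geometry.width_px)
    if image.shape[:2] != target:
        if image.shape[0] < 64 or image.shape[1] < 64:
            raise ValueError("image too small; need at least 64 x 64 pixels")
        image = resize(image, target, order=1, mode="edge",
                       anti_aliasing=True, preserve_range=True)
    pyr = build_pyramids(image)
    cons = {ch: conspicuity(pyr, ch) for ch in ("color", "luminance", "orientation")}
    full = combine_full(cons["color"], cons["luminance"], cons["orientation"])
    maps = {"full": full, **cons}
    return {
        ch: SaliencyMap(to_density(m), channel=ch, image_id=image_id)
        for ch, m in maps.items()
    }


def save_map_txt(smap: SaliencyMap, path) -> None:
    """Write a map as a plain-text grid (loadable with ``np.loadtxt``)."""
    header = f"channel={smap.channel} image_id={smap.image_id} rows=64 cols=80"
    np.savetxt(path, smap.values, header=header)


def load_map_txt(path, channel: str, image_id: str = "") -> SaliencyMap:
    return SaliencyMap(np.loadtxt(path), channel=channel, image_id=image_id)
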