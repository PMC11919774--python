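"""Synthetic study generator: stimuli, 1 kHz gaze traces, and cohorts.

The clinical free-viewing dataset this pipeline was written for is not
public, so this module fabricates inputs with the statistical structure
the analysis assumes:

* a 20-image stimulus set, 4 images in each of five categories
  (buildings, everyday items, foods, fractal patterns, and achromatic
  noise patterns);
* per-trial monocular gaze traces — 8 s at 1 kHz — built from fixation
  epochs joined by saccade-like ramps, with fixational jitter and blinks;
  each regular saccade endpoint is drawn from the image's full-model
  saliency density with probability ``pi`` (the subject's salience-
  following bias) and uniformly over the screen otherwise;
* multi-site cohorts in which ``pi`` varies by diagnostic group, with
  per-subject Beta scatter, per-site offsets, and age/sex covariates.

Because the salience score is linear in ``pi`` (the expected density at a
mixture endpoint is ``pi * sum(p^2) + (1 - pi)/N``), group separations can
be *calibrated*: given a target standardized effect size d, the required
``pi`` gap follows in closed form from the maps' second moments and the
per-endpoint sampling variance. ``calibrate_design`` implements this; by
default the schizophrenia-vs-control gap is set to d = 0.8.

``simulate_scores`` is a score-level fast path that draws the same
endpoint mixture and scores it identically to the full trace pipeline,
for experiments whose subject counts make 1 kHz synthesis pointless.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.draw import disk, polygon
from skimage.transform import resize

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .saliency import SaliencyMap

CATEGORIES = ("buildings", "items", "foods", "fractals", "noise")
NOISE_CATEGORY = "noise"
DIAGNOSES = ("HC", "SZ", "BD", "MDD", "ASD")
TRIAL_MS = 8000
SAMPLE_HZ = 1000

# ---------------------------------------------------------------------------
# stimuli
# ---------------------------------------------------------------------------


@dataclass
class StimulusSet:
    """Procedural test images with category labels.

    Invariants: equal counts per category (default 4 x 5 = 20); every
    image in the ``noise`` category is achromatic (R = G = B exactly).
    """

    images: list[np.ndarray]
    categories: list[str]
    image_ids: list[str]

    def __post_init__(self) -> None:
        if not (len(self.images) == len(self.categories) == len(self.image_ids)):
            raise ValueError("images, categories and image_ids must align")
        for img, cat in zip(self.images, self.categories):
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
            if cat == NOISE_CATEGORY and not (
                (img[..., 0] == img[..., 1]).all()
                and (img[..., 1] == img[..., 2]).all()
            ):
                raise ValueError("noise-category image is not achromatic")

    def __len__(self) -> int:
        return len(self.images)

    def image(self, image_id: str) -> np.ndarray:
        return self.images[self.image_ids.index(image_id)]

    def save(self, directory) -> None:
        import imageio.v3 as iio
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for img, cat, iid in zip(self.images, self.categories, self.image_ids):
            iio.imwrite(directory / f"{iid}.png", img)
            rows.append({"image_id": iid, "category": cat})
        pd.DataFrame(rows).to_csv(directory / "images.csv", index=False)

    @classmethod
    def load(cls, directory) -> "StimulusSet":
        import imageio.v3 as iio
        from pathlib import Path

        directory = Path(directory)
        meta = pd.read_csv(directory / "images.csv")
        images = [np.asarray(iio.imread(directory / f"{iid}.png"))
                  for iid in meta["image_id"]]
        return cls(images, list(meta["category"]), list(meta["image_id"]))


def _palette(rng: np.random.Generator, n: int, sat: float = 0.8,
             warm: bool = False) -> np.ndarray:
    """n random saturated RGB colors in [0, 255]."""
    hues = rng.random(n) * (0.17 if warm else 1.0)  # warm = red..yellow
    cols = np.empty((n, 3))
    for i, h in enumerate(hues):
        import colorsys

        cols[i] = colorsys.hsv_to_rgb(h, sat, 0.5 + 0.5 * rng.random())
    return (cols * 255).astype(np.uint8)


def _buildings(rng, shape):
    h, w = shape
    img = np.empty((h, w, 3), np.uint8)
    sky = np.linspace(180, 120, h)[:, None]
    img[..., 0] = sky * 0.8
    img[..., 1] = sky * 0.9
    img[..., 2] = np.minimum(sky * 1.2, 255)
    horizon = int(h * 0.85)
    img[horizon:] = (90, 85, 80)
    for _ in range(rng.integers(5, 9)):
        bw = int(rng.integers(w // 12, w // 5))
        bh = int(rng.integers(h // 4, int(h * 0.7)))
        x0 = int(rng.integers(0, w - bw))
        y0 = horizon - bh
        shade = rng.integers(60, 150)
        tint = rng.integers(-15, 16, 3)
        img[y0:horizon, x0:x0 + bw] = np.clip(shade + tint, 0, 255)
        # window grid
        wy, wx = max(12, bh // 12), max(10, bw // 8)
        lit = rng.random((bh // wy + 1, bw // wx + 1)) < 0.4
        for iy, y in enumerate(range(y0 + wy // 2, horizon - wy // 2, wy)):
            for ix, x in enumerate(range(x0 + wx // 2, x0 + bw - wx // 2, wx)):
                col = (230, 220, 140) if lit[iy, ix] else (40, 40, 55)
                img[y:y + wy // 2, x:x + wx // 2] = col
    return img


def _items(rng, shape):
    h, w = shape
    img = np.full((h, w, 3), rng.integers(190, 226, 3, dtype=np.uint8), np.uint8)
    cols = _palette(rng, 9)
    for i in range(rng.integers(5, 10)):
        cy, cx = rng.integers(h // 8, 7 * h // 8), rng.integers(w // 8, 7 * w // 8)
        r = rng.integers(h // 16, h // 7)
        kind = rng.integers(3)
        if kind == 0:
            rr, cc = disk((cy, cx), r, shape=(h, w))
        elif kind == 1:
            rr, cc = polygon([cy - r, cy - r, cy + r, cy + r],
                             [cx - r, cx + r, cx + r, cx - r], shape=(h, w))
        else:
            rr, cc = polygon([cy - r, cy + r, cy + r],
                             [cx, cx - r, cx + r], shape=(h, w))
        img[rr, cc] = cols[i % len(cols)]
    return img


def _foods(rng, shape):
    h, w = shape
    img = np.full((h, w, 3), (120, 80, 50), np.uint8)  # table
    cy, cx = h // 2 + rng.integers(-h // 10, h // 10), w // 2 + rng.integers(-w // 10, w // 10)
    rr, cc = disk((cy, cx), int(h * 0.38), shape=(h, w))
    img[rr, cc] = (235, 232, 225)  # plate
    cols = _palette(rng, 10, warm=True)
    for i in range(rng.integers(6, 11)):
        ang = rng.random() * 2 * np.pi
        rad = rng.random() * h * 0.25
        by, bx = int(cy + rad * np.sin(ang)), int(cx + rad * np.cos(ang))
        r = rng.integers(h // 24, h // 10)
        rr, cc = disk((by, bx), r, shape=(h, w))
        img[rr, cc] = cols[i % len(cols)]
    return img


def _midpoint_displacement(rng, n_pow: int = 9, roughness: float = 0.55):
    """Diamond-square heightfield on a (2^n + 1) square grid."""
    size = 2**n_pow + 1
    z = np.zeros((size, size))
    z[0, 0], z[0, -1], z[-1, 0], z[-1, -1] = rng.random(4)
    step, scale = size - 1, 1.0
    while step > 1:
        half = step // 2
        # diamond
        for y in range(half, size, step):
            for x in range(half, size, step):
                avg = (z[y - half, x - half] + z[y - half, x + half]
                       + z[y + half, x - half] + z[y + half, x + half]) / 4
                z[y, x] = avg + (rng.random() - 0.5) * scale
        # square
        for y in range(0, size, half):
            shift = half if (y // half) % 2 == 0 else 0
            for x in range(shift, size, step):
                s, n_ = 0.0, 0
                for dy, dx in ((-half, 0), (half, 0), (0, -half), (0, half)):
                    yy, xx = y + dy, x + dx
                    if 0 <= yy < size and 0 <= xx < size:
                        s += z[yy, xx]
                        n_ += 1
                z[y, x] = s / n_ + (rng.random() - 0.5) * scale
        step, scale = half, scale * roughness
    return z


def _fractals(rng, shape):
    z = _midpoint_displacement(rng, n_pow=7)
    z = resize(z, shape, order=1, mode="edge", anti_aliasing=False)
    z = (z - z.min()) / np.ptp(z) if np.ptp(z) > 0 else z * 0
    anchors = _palette(rng, 3).astype(float)
    # piecewise-linear 3-color palette over height
    t = np.clip(z * 2, 0, 1)
    lo = anchors[0] + (anchors[1] - anchors[0]) * t[..., None]
    t2 = np.clip(z * 2 - 1, 0, 1)
    out = lo + (anchors[2] - anchors[1]) * t2[..., None]
    return np.clip(out, 0, 255).astype(np.uint8)


def _noise(rng, shape):
    z = rng.standard_normal(shape)
    z = gaussian_filter(z, sigma=3.0)
    z = (z - z.min()) / np.ptp(z)
    gray = (z * 255).astype(np.uint8)
    return np.stack([gray] * 3, axis=-1)  # achromatic by construction


_MAKERS = {
    "buildings": _buildings,
    "items": _items,
    "foods": _foods,
    "fractals": _fractals,
    "noise": _noise,
}


def generate_stimulus_set(
    seed: int,
    images_per_category: int = 4,
    shape: tuple[int, int] = (1024, 1280),
) -> StimulusSet:
    """Procedural stimulus set: ``images_per_category`` images per category,
    deterministic given ``seed``."""
    rng = np.random.default_rng(seed)
    images, categories, ids = [], [], []
    for cat in CATEGORIES:
        for i in range(images_per_category):
            images.append(_MAKERS[cat](rng, shape))
            categories.append(cat)
            ids.append(f"{cat}_{i:02d}")
    return StimulusSet(images, categories, ids)


def popout_image(
    kind: str,
    seed: int,
    grid: tuple[int, int] = (6, 8),
    shape: tuple[int, int] = (1024, 1280),
) -> tuple[np.ndarray, tuple[float, float]]:
    """Oddball search array with one unique item; returns (image, target px).

    ``kind='color'``: gray distractor squares, one red square.
    ``kind='orientation'``: vertical bars, one 45-degree bar.
    Target position (x_px, y_px) is the oddball centre.
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    gy, gx = grid
    img = np.full((h, w, 3), 96, np.uint8)
    target_idx = int(rng.integers(gy * gx))
    pitch_y, pitch_x = h // (gy + 1), w // (gx + 1)
    target = (0.0, 0.0)
    for idx in range(gy * gx):
        ry, rx = divmod(idx, gx)
        cy = (ry + 1) * pitch_y + int(rng.integers(-8, 9))
        cx = (rx + 1) * pitch_x + int(rng.integers(-8, 9))
        odd = idx == target_idx
        if kind == "color":
            half = 24
            col = (210, 60, 50) if odd else (160, 160, 160)
            img[cy - half:cy + half, cx - half:cx + half] = col
        elif kind == "orientation":
            length, width_ = 44, 7
            ang = np.deg2rad(45 if odd else 90)
            dy, dx = -np.sin(ang), np.cos(ang)
            py = [cy + length * dy - width_ * dx, cy + length * dy + width_ * dx,
                  cy - length * dy + width_ * dx, cy - length * dy - width_ * dx]
            px = [cx + length * dx + width_ * dy, cx + length * dx - width_ * dy,
                  cx - length * dx - width_ * dy, cx - length * dx + width_ * dy]
            rr, cc = polygon(py, px, shape=(h, w))
            img[rr, cc] = (225, 225, 225)
        else:
            raise ValueError("kind must be 'color' or 'orientation'")
        if odd:
            target = (float(cx), float(cy))
    return img, target


# ---------------------------------------------------------------------------
# gaze trials
# ---------------------------------------------------------------------------


@dataclass
class GazeTrial:
    """One 8 s monocular trace at 1 kHz.

    ``x``/``y`` are degrees of visual angle from screen centre (y down);
    ``pupil`` is in arbitrary units and exactly 0 during blinks, where
    positions are NaN. ``truth`` (optional) records the programmed events
    for generator-based ground-truth tests; it is not serialized.
    """

    time_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    pupil: np.ndarray
    image_id: str = ""
    subject_id: str = ""
    truth: pd.DataFrame | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.time_ms)
        if len(t) < 2 or (np.diff(t) != 1).any():
            raise ValueError("trial samples must be spaced at exactly 1 ms")
        if (np.asarray(self.pupil) < 0).any():
            raise ValueError("pupil area must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "x_deg": self.x, "y_deg": self.y,
             "pupil": self.pupil}
        )

    def save_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, image_id: str = "",
                   subject_id: str = "") -> "GazeTrial":
        return cls(
            frame["time_ms"].to_numpy(), frame["x_deg"].to_numpy(float),
            frame["y_deg"].to_numpy(float), frame["pupil"].to_numpy(float),
            image_id=image_id, subject_id=subject_id,
        )

    @classmethod
    def load_csv(cls, path, image_id: str = "", subject_id: str = "") -> "GazeTrial":
        return cls.from_frame(pd.read_csv(path), image_id, subject_id)


@dataclass(frozen=True)
class TrialParams:
    """Kinematic/noise settings of the trace generator.

    Saccades are raised-cosine position ramps — detectable events, not
    physiologic main-sequence profiles. Blinks are pupil=0 gaps placed
    inside fixation epochs.
    """

    n_saccades: int = 20          # programmed regular saccades per trial
    n_micro: int = 2              # small (< 1 deg) extra saccades
    saccade_ms: int = 30
    jitter_sd: float = 0.05       # fixational position noise, deg
    blink_rate: float = 1.0       # expected blinks per trial
    blink_ms: tuple[int, int] = (100, 300)
    min_regular_amp: float = 1.2  # deg; redraw endpoints closer than this
    pupil_base: float = 1000.0
    pupil_sd: float = 10.0


DEFAULT_TRIAL_PARAMS = TrialParams()


def sample_endpoints(
    smap: SaliencyMap,
    pi: float,
    n: int,
    rng: np.random.Generator,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``n`` saccade endpoints from ``pi * map + (1 - pi) * uniform``.

    A flat cell index is drawn (categorical over the 80 x 64 density with
    probability ``pi``, uniform over cells otherwise) followed by uniform
    within-cell jitter. Returns (x_deg, y_deg, flat_cell).
    """
    if not 0.0 <= pi <= 1.0:
        raise ValueError("bias pi must lie in [0, 1]")
    p = smap.values.ravel()
    cum = np.cumsum(p)
    cum[-1] = 1.0
    from_map = rng.random(n) < pi
    cells = np.where(
        from_map,
        np.searchsorted(cum, rng.random(n), side="right"),
        rng.integers(0, p.size, n),
    )
    rows, cols = np.divmod(cells, geometry.grid_cols)
    x, y = geometry.cell_to_deg(rows, cols, rng=rng)
    return x, y, cells


def generate_trial(
    smap: SaliencyMap,
    pi: float,
    n_saccades: int | None = None,
    seed: int | np.random.Generator = 0,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    params: TrialParams = DEFAULT_TRIAL_PARAMS,
    image_id: str = "",
    subject_id: str = "",
) -> GazeTrial:
    """Synthesize one free-viewing trial over the given saliency density.

    Fixation epochs (constant position + Gaussian jitter) alternate with
    raised-cosine saccade ramps whose endpoints follow the ``pi`` mixture;
    endpoints closer than ``params.min_regular_amp`` to the current
    position are redrawn (a point-mass density can defeat the redraw, in
    which case the small movement is recorded as kind='micro'). Blinks
    zero the pupil and invalidate position.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if n_saccades is not None:
        params = replace(params, n_saccades=int(n_saccades))
    n_reg, n_mic = params.n_saccades, params.n_micro if params.n_saccades else 0

    kinds = ["regular"] * n_reg + ["micro"] * n_mic
    rng.shuffle(kinds)
    n_ev = len(kinds)
    sacc_total = n_ev * params.saccade_ms
    if sacc_total >= TRIAL_MS:
        raise ValueError("too many saccades for an 8 s trial")
    base = (TRIAL_MS - sacc_total) / (n_ev + 1)
    fix_dur = base * rng.uniform(0.6, 1.4, n_ev + 1)
    fix_dur = np.maximum(60, np.round(fix_dur * (TRIAL_MS - sacc_total) / fix_dur.sum()))
    fix_dur = fix_dur.astype(int)
    fix_dur[-1] += TRIAL_MS - sacc_total - fix_dur.sum()

    x = np.empty(TRIAL_MS)
    y = np.empty(TRIAL_MS)
    cur = np.array([0.0, 0.0])  # start at screen centre
    t = 0
    truth_rows = []
    fix_spans = []
    for i in range(n_ev + 1):
        d = fix_dur[i]
        x[t:t + d] = cur[0]
        y[t:t + d] = cur[1]
        fix_spans.append((t, t + d))
        t += d
        if i == n_ev:
            break
        if kinds[i] == "regular":
            for _ in range(30):
                ex, ey, _c = sample_endpoints(smap, pi, 1, rng, geometry)
                end = np.array([ex[0], ey[0]])
                if np.hypot(*(end - cur)) >= params.min_regular_amp:
                    break
        else:
            amp = rng.uniform(0.15, 0.8)
            ang = rng.uniform(0, 2 * np.pi)
            end = cur + amp * np.array([np.cos(ang), np.sin(ang)])
            hx, hy = geometry.half_extent_deg
            end = np.clip(end, [-hx, -hy], [hx, hy])
        dur = params.saccade_ms
        tau = (np.arange(dur) + 1) / dur
        ramp = (1 - np.cos(np.pi * tau)) / 2
        x[t:t + dur] = cur[0] + (end[0] - cur[0]) * ramp
        y[t:t + dur] = cur[1] + (end[1] - cur[1]) * ramp
        amp = float(np.hypot(*(end - cur)))
        truth_rows.append(
            {"onset": t, "offset": t + dur - 1, "x0": cur[0], "y0": cur[1],
             "x1": end[0], "y1": end[1], "amplitude": amp,
             "kind": kinds[i] if amp > 1.0 else "micro"}
        )
        cur = end
        t += dur

    x += rng.normal(0, params.jitter_sd, TRIAL_MS)
    y += rng.normal(0, params.jitter_sd, TRIAL_MS)
    pupil = np.clip(rng.normal(params.pupil_base, params.pupil_sd, TRIAL_MS), 1.0, None)

    n_blinks = rng.poisson(params.blink_rate)
    margin = 80  # keep blinks clear of saccade ramps
    for _ in range(n_blinks):
        dur = int(rng.integers(*params.blink_ms))
        candidates = [s for s in fix_spans if s[1] - s[0] > dur + 2 * margin]
        if not candidates:
            continue
        s0, s1 = candidates[int(rng.integers(len(candidates)))]
        b0 = int(rng.integers(s0 + margin, s1 - margin - dur))
        pupil[b0:b0 + dur] = 0.0
        x[b0:b0 + dur] = np.nan
        y[b0:b0 + dur] = np.nan

    truth = pd.DataFrame(
        truth_rows,
        columns=["onset", "offset", "x0", "y0", "x1", "y1", "amplitude", "kind"],
    )
    return GazeTrial(np.arange(TRIAL_MS), x, y, pupil,
                     image_id=image_id, subject_id=subject_id, truth=truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: Default standardized group shifts (in within-group score SDs) relative
#: to healthy controls; the SZ-HC gap is the study's headline effect.
DEFAULT_D_OFFSETS = {"HC": 0.0, "SZ": 0.8, "BD": 0.55, "MDD": 0.35, "ASD": 0.10}

#: Wider spacing used by the cross-disorder ordering experiment, chosen by
#: a normal-approximation power calculation so the full five-group ordering
#: of marginal means holds in ~98% of runs at the reference sample sizes.
ORDERING_D_OFFSETS = {"HC": 0.0, "ASD": 0.28, "MDD": 0.76, "BD": 1.34, "SZ": 1.82}


@dataclass
class GroupCell:
    """Sample-size/demographics cell of a cohort design (one site x group)."""

    site: str
    diagnosis: str
    n: int
    age_mean: float = 35.0
    age_sd: float = 12.0
    p_male: float = 0.5

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("cell size must be >= 0")
        if self.diagnosis not in DIAGNOSES:
            raise ValueError(f"unknown diagnosis {self.diagnosis!r}")


@dataclass
class CohortDesign:
    """Everything that determines a synthetic cohort's statistics.

    ``d_offsets`` are target standardized group shifts vs HC; they are
    converted to ``pi`` gaps by ``calibrate_design`` using the stimulus
    maps. ``base_pi`` is the HC salience-following bias and ``sigma_pi``
    the between-subject SD of ``pi`` within a group.
    """

    cells: list[GroupCell]
    base_pi: float = 0.30
    sigma_pi: float = 0.05
    d_offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_D_OFFSETS))
    site_pi_spread: float = 0.02  # sites evenly offset in [-spread, +spread]
    n_saccades: int = DEFAULT_TRIAL_PARAMS.n_saccades

    def __post_init__(self) -> None:
        if not self.cells:
            raise ValueError("cohort design has no cells")
        if not 0.0 <= self.base_pi <= 1.0:
            raise ValueError("base_pi must lie in [0, 1]")

    @property
    def sites(self) -> list[str]:
        seen: list[str] = []
        for c in self.cells:
            if c.site not in seen:
                seen.append(c.site)
        return seen

    def site_offsets(self) -> dict[str, float]:
        sites = self.sites
        if len(sites) == 1:
            return {sites[0]: 0.0}
        offs = np.linspace(-self.site_pi_spread, self.site_pi_spread, len(sites))
        return dict(zip(sites, offs))


def two_group_design(
    n_sites: int = 3, n_hc: int = 100, n_sz: int = 100, d: float = 0.8, **kw
) -> CohortDesign:
    """HC-vs-SZ design used for effect-size parameter recovery."""
    cells = []
    for i in range(n_sites):
        site = f"S{i + 1}"
        cells.append(GroupCell(site, "HC", n_hc))
        cells.append(GroupCell(site, "SZ", n_sz))
    return CohortDesign(cells, d_offsets={"HC": 0.0, "SZ": d}, **kw)


def reference_design(d_offsets: dict[str, float] | None = None, **kw) -> CohortDesign:
    """Cohort design with the demographic structure of the seven-site
    free-viewing study (1012 subjects; 550 HC, 238 SZ, 41 BD, 50 MDD,
    133 ASD), read from the packaged reference table."""
    ref = importlib.resources.files("gazesal.data") / "cohort_reference.csv"
    table = pd.read_csv(ref)
    cells = []
    for row in table.itertuples():
        n = int(row.n_male + row.n_female)
        cells.append(
            GroupCell(row.site, row.diagnosis, n, float(row.age_mean),
                      float(row.age_sd), row.n_male / n)
        )
    if d_offsets is not None:
        kw["d_offsets"] = dict(d_offsets)
    return CohortDesign(cells, **kw)


@dataclass(frozen=True)
class Calibration:
    """Closed-form link between the bias ``pi`` and the salience score.

    ``slope`` is d(score)/d(pi) = mean(sum p^2) - 1/N over the analysis
    maps; ``sigma_eps`` the endpoint-sampling SD of a subject's score;
    ``sigma_score`` the total within-group score SD; ``pi_by_group`` the
    group means of ``pi`` realizing the design's d offsets.
    """

    slope: float
    sigma_eps: float
    sigma_score: float
    pi_by_group: dict[str, float]


def calibrate_design(maps: list[SaliencyMap], design: CohortDesign) -> Calibration:
    """Solve group ``pi`` means so group score shifts hit the target d's.

    Uses E[score | pi] = pi * slope + 1/N and
    Var[score] = (sigma_pi * slope)^2 + sigma_eps^2, with sigma_eps
    computed exactly from the map densities at the HC bias and the
    per-image endpoint count.
    """
    n_cells = maps[0].values.size
    uniform = 1.0 / n_cells
    second = np.array([m.second_moment() for m in maps])
    slope = float(second.mean() - uniform)
    if slope <= 0:
        raise ValueError("maps carry no structure; cannot separate groups")
    k = design.n_saccades
    var_sum = 0.0
    for m in maps:
        p = m.values.ravel()
        q = design.base_pi * p + (1 - design.base_pi) * uniform
        var_sum += float((q * p**2).sum() - (q * p).sum() ** 2)
    sigma_eps = np.sqrt(var_sum / (len(maps) ** 2 * k))
    sigma_score = float(np.hypot(design.sigma_pi * slope, sigma_eps))
    pi_by_group = {}
    for diag, d in design.d_offsets.items():
        pi = design.base_pi + d * sigma_score / slope
        if not 0.0 < pi < 1.0:
            raise ValueError(f"target d={d} for {diag} drives pi out of (0, 1)")
        pi_by_group[diag] = float(pi)
    return Calibration(slope, float(sigma_eps), sigma_score, pi_by_group)


def _beta_draw(rng, mean, sd, size):
    """Beta draw with the given mean and SD (mean clipped to keep a valid
    parameterization)."""
    mean = np.clip(mean, 0.02, 0.98)
    v = min(sd**2, 0.9 * mean * (1 - mean))
    conc = mean * (1 - mean) / v - 1
    return rng.beta(mean * conc, (1 - mean) * conc, size)


def generate_cohort(
    design: CohortDesign,
    maps: list[SaliencyMap],
    seed: int,
) -> pd.DataFrame:
    """Cohort metadata table with per-subject latent bias ``pi``.

    Columns: subject_id, site, diagnosis, age, sex, pi, scale_score,
    med_dose. ``pi`` is the subject's latent salience-following bias
    (Beta-scattered around the calibrated group mean plus the site
    offset). Symptom-scale scores and medication doses are generated for
    patients with no built-in association to ``pi`` (a null screen).
    """
    rng = np.random.default_rng(seed)
    calib = calibrate_design(maps, design)
    offsets = design.site_offsets()
    rows = []
    sid = 0
    for cell in design.cells:
        if cell.diagnosis not in calib.pi_by_group:
            raise ValueError(f"design has no d offset for {cell.diagnosis}")
        mu = calib.pi_by_group[cell.diagnosis] + offsets[cell.site]
        pis = _beta_draw(rng, mu, design.sigma_pi, cell.n)
        ages = np.clip(rng.normal(cell.age_mean, max(cell.age_sd, 0.1), cell.n),
                       13, 80)
        sexes = np.where(rng.random(cell.n) < cell.p_male, "M", "F")
        for j in range(cell.n):
            patient = cell.diagnosis != "HC"
            rows.append(
                {
                    "subject_id": f"sub{sid:05d}",
                    "site": cell.site,
                    "diagnosis": cell.diagnosis,
                    "age": float(np.round(ages[j], 1)),
                    "sex": sexes[j],
                    "pi": float(pis[j]),
                    "scale_score": float(np.round(rng.normal(60, 15), 1))
                    if patient else np.nan,
                    "med_dose": float(np.round(rng.gamma(2.0, 150.0), 1))
                    if patient else np.nan,
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def simulate_scores(
    cohort: pd.DataFrame,
    maps_by_channel: dict[str, list[SaliencyMap]],
    seed: int,
    n_saccades: int = DEFAULT_TRIAL_PARAMS.n_saccades,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Score-level fast path: per-subject salience scores without trace
    synthesis.

    For each analysis image, endpoint cells are drawn from the full-model
    mixture (the same draw the trace generator makes) and every channel's
    map is read at those cells; per-image means are then averaged across
    images — identical to the scoring stage's aggregation.
    """
    full_maps = maps_by_channel["full"]
    n_img = len(full_maps)
    n_sub = len(cohort)
    pis = cohort["pi"].to_numpy(float)
    rng = np.random.default_rng(seed)
    sums = {ch: np.zeros(n_sub) for ch in maps_by_channel}
    for i, fmap in enumerate(full_maps):
        p = fmap.values.ravel()
        cum = np.cumsum(p)
        cum[-1] = 1.0
        u = rng.random((n_sub, n_saccades))
        from_map = rng.random((n_sub, n_saccades)) < pis[:, None]
        cells = np.where(
            from_map,
            np.searchsorted(cum, u, side="right"),
            rng.integers(0, p.size, (n_sub, n_saccades)),
        )
        for ch, maps in maps_by_channel.items():
            vals = maps[i].values.ravel()[cells]
            sums[ch] += vals.mean(axis=1)
    out = cohort.drop(columns=["pi"]).copy()
    for ch in maps_by_channel:
        out[f"score_{ch}"] = sums[ch] / n_img
    out["n_images_used"] = n_img
    out["n_saccades_total"] = n_img * n_saccades
    return out
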