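"""Salience scores: saliency-map density at saccade endpoints.

For one image, the score is the mean map density over the endpoints of
the regular (> 1 deg) saccades made while the image was shown; a
subject's salience score for a channel is the unweighted mean of those
per-image means across the analysis images (the four zero-color-contrast
noise images are excluded, leaving 16 of 20 by default). The aggregation
order — per-image first, then across images — is part of the definition
and differs from pooling all endpoints.

Lookups are nearest-cell on the 80 x 64 grid (maps are density
histograms over cells, so interpolation would mix cell masses); endpoints
off the display are missing and drop out of the means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_events import EventList
from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .saliency import CHANNELS, SaliencyMap
from .synthetic_data import NOISE_CATEGORY, StimulusSet

log = logging.getLogger(__name__)


def lookup_salience(
    smap: SaliencyMap,
    x_deg,
    y_deg,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
):
    """Map density at gaze positions (degrees); NaN when off the display."""
    row, col, on = geometry.deg_to_cell(x_deg, y_deg)
    vals = smap.values[row, col]
    return np.where(on, vals, np.nan) if np.ndim(vals) else (
        float(vals) if on else float("nan")
    )


def score_image(
    smap: SaliencyMap,
    events: EventList,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    include_micro: bool = False,
) -> float:
    """Mean density at this trial's saccade endpoints (NaN if unusable).

    Only regular saccades count by default; off-screen endpoints are
    excluded from the mean rather than zeroed.
    """
    saccades = events.saccades if include_micro else events.regular_saccades()
    if not saccades:
        return float("nan")
    x = np.array([s.x1 for s in saccades])
    y = np.array([s.y1 for s in saccades])
    vals = lookup_salience(smap, x, y, geometry)
    if np.isnan(vals).all():
        return float("nan")
    return float(np.nanmean(vals))


def filter_images(stimulus_set: StimulusSet) -> list[str]:
    """Analysis image ids: everything outside the noise category."""
    return [iid for iid, cat in zip(stimulus_set.image_ids, stimulus_set.categories)
            if cat != NOISE_CATEGORY]


@dataclass
class SubjectScores:
    """Per-subject salience scores for the four map channels."""

    subject_id: str
    site: str
    diagnosis: str
    age: float
    sex: str
    score_full: float
    score_color: float
    score_luminance: float
    score_orientation: float
    n_images_used: int
    n_saccades_total: int


def subject_score(
    events_by_image: dict[str, EventList],
    maps_by_channel: dict[str, dict[str, SaliencyMap]],
    meta: dict,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    include_micro: bool = False,
) -> SubjectScores | None:
    """Aggregate per-image scores into one row per subject.

    ``events_by_image`` maps analysis image ids to that trial's events;
    ``maps_by_channel[channel][image_id]`` holds the densities. Images
    without a usable score are dropped from the mean; a subject with no
    usable image at all is flagged and excluded (returns None).
    """
    per_channel: dict[str, list[float]] = {ch: [] for ch in CHANNELS}
    n_used = 0
    n_sacc = 0
    for iid, events in events_by_image.items():
        vals = {
            ch: score_image(maps_by_channel[ch][iid], events, geometry, include_micro)
            for ch in CHANNELS
        }
        if np.isnan(vals["full"]):
            continue
        n_used += 1
        n_sacc += len(events.saccades if include_micro else events.regular_saccades())
        for ch in CHANNELS:
            per_channel[ch].append(vals[ch])
    if n_used == 0:
        log.warning("subject %s: no usable analysis image; excluded",
                    meta.get("subject_id", "?"))
        return None
    means = {ch: float(np.nanmean(v)) for ch, v in per_channel.items()}
    return SubjectScores(
        subject_id=meta.get("subject_id", ""),
        site=meta.get("site", ""),
        diagnosis=meta.get("diagnosis", ""),
        age=float(meta.get("age", np.nan)),
        sex=meta.get("sex", ""),
        score_full=means["full"],
        score_color=means["color"],
        score_luminance=means["luminance"],
        score_orientation=means["orientation"],
        n_images_used=n_used,
        n_saccades_total=n_sacc,
    )


def score_cohort(
    events_by_subject: dict[str, dict[str, EventList]],
    maps_by_channel: dict[str, dict[str, SaliencyMap]],
    cohort: pd.DataFrame,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    include_micro: bool = False,
) -> pd.DataFrame:
    """Subject-level scores table (one row per subject with usable data)."""
    rows = []
    for rec in cohort.to_dict("records"):
        ev = events_by_subject.get(rec["subject_id"])
        if ev is None:
            continue
        scores = subject_score(ev, maps_by_channel, rec, geometry, include_micro)
        if scores is not None:
            rows.append(vars(scores))
    return pd.DataFrame(rows)
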