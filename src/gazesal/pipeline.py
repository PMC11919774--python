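"""End-to-end orchestration: generate -> saliency -> events -> scores -> stats.

Each stage reads and writes plain files under the run directory, so a run
can be resumed from any stage's on-disk outputs, and the whole chain is
deterministic under the configured seed (stage seeds are spawned from one
``SeedSequence``). A manifest with SHA-256 checksums of every artifact
plus a serialized copy of the configuration is written at the end.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .gaze_events import detect_events
from .saliency import CHANNELS, SaliencyMap, compute_saliency, load_map_txt, save_map_txt
from .scoring import filter_images, score_cohort
from .stats import (
    cross_disorder_glm,
    fixed_effects_meta,
    forest_table,
    per_site_effect_sizes,
)
from .synthetic_data import StimulusSet, generate_cohort, generate_trial

log = logging.getLogger(__name__)

SCORE_COLS = {ch: f"score_{ch}" for ch in CHANNELS}


def _stage_seeds(seed: int, n: int = 8) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


def stage_stimuli(cfg: RunConfig, out: Path, seed_seq) -> StimulusSet:
    seed = int(seed_seq.generate_state(1)[0] % 2**31)
    shape = (cfg.geometry.height_px, cfg.geometry.width_px)
    stimuli = generate_stimulus_set_cached(seed, cfg.generator.images_per_category, shape)
    stimuli.save(out / "stimuli")
    return stimuli


def generate_stimulus_set_cached(seed, images_per_category, shape):
    # thin alias kept for monkeypatch-ability in tests
    from .synthetic_data import generate_stimulus_set

    return generate_stimulus_set(seed, images_per_category, shape)


def stage_saliency(stimuli: StimulusSet, out: Path,
                   geometry) -> dict[str, dict[str, SaliencyMap]]:
    """Compute and persist the four channel maps for every image."""
    maps_dir = out / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    by_channel: dict[str, dict[str, SaliencyMap]] = {ch: {} for ch in CHANNELS}
    for img, iid in zip(stimuli.images, stimuli.image_ids):
        maps = compute_saliency(img, iid, geometry)
        for ch, m in maps.items():
            by_channel[ch][iid] = m
            save_map_txt(m, maps_dir / f"{iid}__{ch}.txt")
    return by_channel


def load_saliency(maps_dir: Path) -> dict[str, dict[str, SaliencyMap]]:
    by_channel: dict[str, dict[str, SaliencyMap]] = {ch: {} for ch in CHANNELS}
    for path in sorted(Path(maps_dir).glob("*__*.txt")):
        iid, ch = path.stem.rsplit("__", 1)
        by_channel[ch][iid] = load_map_txt(path, channel=ch, image_id=iid)
    return by_channel


def stage_cohort(cfg: RunConfig, analysis_full_maps, out: Path, seed_seq) -> pd.DataFrame:
    seed = int(seed_seq.generate_state(1)[0] % 2**31)
    cohort = generate_cohort(cfg.generator.design(), analysis_full_maps, seed)
    cohort.to_csv(out / "cohort.csv", index=False)
    return cohort


def stage_events(cfg: RunConfig, stimuli: StimulusSet, maps_by_channel,
                 cohort: pd.DataFrame, out: Path, seed_seq):
    """Synthesize every subject's 20 trials and detect their events.

    Trials follow a subject-specific random image order; raw 1 kHz traces
    are only written when ``generator.save_traces`` is set (they are two
    orders of magnitude larger than the events).
    """
    geometry = cfg.geometry.build()
    det = cfg.detection.build()
    params = cfg.generator.trial_params()
    full_maps = maps_by_channel["full"]
    trace_dir = out / "traces"
    if cfg.generator.save_traces:
        trace_dir.mkdir(parents=True, exist_ok=True)
    events_by_subject: dict[str, dict] = {}
    frames = []
    subject_seeds = seed_seq.spawn(len(cohort))
    for rec, sseq in zip(cohort.to_dict("records"), subject_seeds):
        rng = np.random.default_rng(sseq)
        order = rng.permutation(len(stimuli))
        per_image = {}
        for idx in order:
            iid = stimuli.image_ids[idx]
            trial = generate_trial(full_maps[iid], rec["pi"], seed=rng,
                                   geometry=geometry, params=params,
                                   image_id=iid, subject_id=rec["subject_id"])
            if cfg.generator.save_traces:
                trial.save_csv(trace_dir / f"{rec['subject_id']}__{iid}.csv")
            per_image[iid] = detect_events(trial, det)
        events_by_subject[rec["subject_id"]] = per_image
        frames.extend(ev.to_frame() for ev in per_image.values())
    pd.concat(frames, ignore_index=True).to_csv(out / "events.csv", index=False)
    return events_by_subject


def stage_scores(cfg: RunConfig, events_by_subject, maps_by_channel,
                 cohort: pd.DataFrame, analysis_ids: list[str],
                 out: Path) -> pd.DataFrame:
    analysis_events = {
        sid: {iid: ev for iid, ev in per_image.items() if iid in analysis_ids}
        for sid, per_image in events_by_subject.items()
    }
    scores = score_cohort(analysis_events, maps_by_channel, cohort,
                          cfg.geometry.build(), cfg.stats.include_micro)
    scores.to_csv(out / "scores.csv", index=False)
    return scores


def stage_stats(cfg: RunConfig, scores: pd.DataFrame, out: Path) -> None:
    """Effect sizes + meta per channel where feasible, GLM when >= 2 groups."""
    stats_dir = out / "stats"
    stats_dir.mkdir(parents=True, exist_ok=True)
    eff_rows, meta_rows = [], []
    for ch, col in SCORE_COLS.items():
        records = per_site_effect_sizes(scores, col, groups=cfg.stats.meta_groups,
                                        channel=ch)
        if not records:
            continue
        meta = fixed_effects_meta(records, channel=ch)
        table = forest_table(meta)
        table.insert(0, "channel", ch)
        eff_rows.append(table)
        meta_rows.append({"channel": ch, "d": meta.d_overall, "se": meta.se_overall,
                          "z": meta.z, "p": meta.p, "n_sites": len(records)})
    if eff_rows:
        pd.concat(eff_rows, ignore_index=True).to_csv(
            stats_dir / "effect_sizes.csv", index=False)
        pd.DataFrame(meta_rows).to_csv(stats_dir / "meta.csv", index=False)
    if scores["diagnosis"].nunique() >= 2:
        emm_frames, pair_frames = [], []
        for ch, col in SCORE_COLS.items():
            res = cross_disorder_glm(scores, col, ref_age=cfg.stats.ref_age,
                                     channel=ch)
            emm = res.emmeans.copy()
            emm.insert(0, "channel", ch)
            emm["p_diagnosis"] = res.p_diagnosis
            emm_frames.append(emm)
            pw = res.pairwise.copy()
            pw.insert(0, "channel", ch)
            pair_frames.append(pw)
        pd.concat(emm_frames, ignore_index=True).to_csv(
            stats_dir / "glm_emmeans.csv", index=False)
        pd.concat(pair_frames, ignore_index=True).to_csv(
            stats_dir / "glm_pairwise.csv", index=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig, out_dir) -> Path:
    """Execute the full synthetic study and return the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    stage = "config"
    try:
        cfg.to_yaml(out / "config.yaml")
        stage = "stimuli"
        stimuli = stage_stimuli(cfg, out, seeds[0])
        stage = "saliency"
        maps_by_channel = stage_saliency(stimuli, out, cfg.geometry.build())
        analysis_ids = filter_images(stimuli)
        analysis_full = [maps_by_channel["full"][iid] for iid in analysis_ids]
        stage = "cohort"
        cohort = stage_cohort(cfg, analysis_full, out, seeds[1])
        stage = "events"
        events = stage_events(cfg, stimuli, maps_by_channel, cohort, out, seeds[2])
        stage = "scores"
        scores = stage_scores(cfg, events, maps_by_channel, cohort, analysis_ids, out)
        stage = "stats"
        stage_stats(cfg, scores, out)
    except Exception as exc:  # tag failures with the stage that raised
        raise RuntimeError(f"pipeline failed in stage '{stage}': {exc}") from exc
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
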