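#!/usr/bin/env python
"""Compute per-subject salience scores.

Two routes, both per image first and then averaged over the 16 analysis
images (noise excluded):

* the demo subcohort is scored from its *detected* saccade endpoints
  (events_demo.csv from step 03) — the full recording pipeline;
* the 1012-subject reference cohort is scored through the endpoint-level
  simulator, which draws the same endpoint mixture without synthesizing
  1 kHz traces.

Writes results/scores_demo.csv and results/scores_reference.csv.
"""

from pathlib import Path

import pandas as pd

from gazesal.gaze_events import EventList, Saccade
from gazesal.pipeline import load_saliency
from gazesal.scoring import filter_images, score_cohort
from gazesal.synthetic_data import StimulusSet, simulate_scores

SEED = 20240903
RESULTS = Path(__file__).resolve().parents[1] / "results"


def events_from_csv(path) -> dict[str, dict[str, EventList]]:
    frame = pd.read_csv(path)
    out: dict[str, dict[str, EventList]] = {}
    for (sid, iid), grp in frame.groupby(["subject_id", "image_id"]):
        ev = EventList(image_id=iid, subject_id=sid)
        for row in grp.to_dict("records"):
            if row["event"] == "saccade":
                ev.saccades.append(Saccade(int(row["onset"]), int(row["offset"]),
                                           row["x0"], row["y0"], row["x1"],
                                           row["y1"], row["class"]))
        out.setdefault(sid, {})[iid] = ev
    return out


def main() -> None:
    stimuli = StimulusSet.load(RESULTS / "stimuli")
    maps = load_saliency(RESULTS / "maps")
    analysis_ids = filter_images(stimuli)
    analysis_maps = {ch: {iid: by_img[iid] for iid in analysis_ids}
                     for ch, by_img in maps.items()}

    # demo subcohort: scores from detected events
    events = events_from_csv(RESULTS / "events_demo.csv")
    events = {sid: {iid: ev for iid, ev in per.items() if iid in analysis_ids}
              for sid, per in events.items()}
    cohort_demo = pd.read_csv(RESULTS / "cohort_demo.csv")
    scores_demo = score_cohort(events, analysis_maps, cohort_demo)
    scores_demo.to_csv(RESULTS / "scores_demo.csv", index=False)
    print(f"demo scores (trace pipeline): {len(scores_demo)} subjects -> "
          f"{RESULTS / 'scores_demo.csv'}")
    print(scores_demo.groupby("diagnosis")["score_full"]
          .agg(["mean", "std"]).to_string())

    # reference cohort: endpoint-level fast path
    cohort = pd.read_csv(RESULTS / "cohort.csv")
    maps_by_channel = {ch: [analysis_maps[ch][iid] for iid in analysis_ids]
                       for ch in analysis_maps}
    scores = simulate_scores(cohort, maps_by_channel, SEED)
    scores.to_csv(RESULTS / "scores_reference.csv", index=False)
    print(f"reference scores (endpoint simulator): {len(scores)} subjects -> "
          f"{RESULTS / 'scores_reference.csv'}")
    print(scores.groupby("diagnosis")["score_full"]
          .agg(["mean", "std"]).to_string())


if __name__ == "__main__":
    main()
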