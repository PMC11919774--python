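#!/usr/bin/env python
"""Compute Itti-Koch saliency maps for every stimulus image.

Reads results/stimuli/ (from 01), writes the four density-normalized
80 x 64 channel maps per image as plain-text grids under results/maps/,
plus a heatmap preview figure, and reports the map contract (shape,
non-negativity, unit sum) and how concentrated each channel is relative
to a uniform density.
"""

from pathlib import Path

import numpy as np

from gazesal.saliency import CHANNELS, compute_saliency, save_map_txt
from gazesal.synthetic_data import StimulusSet

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    stimuli = StimulusSet.load(RESULTS / "stimuli")
    maps_dir = RESULTS / "maps"
    maps_dir.mkdir(exist_ok=True)

    concentration = {ch: [] for ch in CHANNELS}
    maps_by_image = {}
    for img, iid in zip(stimuli.images, stimuli.image_ids):
        maps = compute_saliency(img, iid)
        maps_by_image[iid] = maps
        for ch, m in maps.items():
            assert m.shape == (64, 80) and m.values.min() >= 0
            assert abs(m.values.sum() - 1) < 1e-9
            save_map_txt(m, maps_dir / f"{iid}__{ch}.txt")
            concentration[ch].append(m.second_moment() * m.values.size)

    print(f"maps for {len(stimuli)} images x {len(CHANNELS)} channels "
          f"-> {maps_dir} (all 80 x 64, sum 1)")
    for ch, vals in concentration.items():
        print(f"  {ch:12s} concentration (sum p^2 x N, 1 = uniform): "
              f"median {np.median(vals):.2f}, max {max(vals):.2f}")

    # preview: one image per category with its full-model map
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cats = list(dict.fromkeys(stimuli.categories))
    fig, axes = plt.subplots(2, len(cats), figsize=(3 * len(cats), 5))
    for j, cat in enumerate(cats):
        iid = stimuli.image_ids[stimuli.categories.index(cat)]
        axes[0, j].imshow(stimuli.image(iid))
        axes[0, j].set_title(iid, fontsize=8)
        axes[1, j].imshow(maps_by_image[iid]["full"].values, cmap="inferno")
        for ax in (axes[0, j], axes[1, j]):
            ax.set_xticks([]), ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(RESULTS / "figures_saliency_preview.png", dpi=110)
    print(f"preview figure -> {RESULTS / 'figures_saliency_preview.png'}")


if __name__ == "__main__":
    main()
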