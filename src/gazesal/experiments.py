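"""Reusable validation experiments over the synthetic study.

These functions bundle the package's standard self-checks — pop-out
localization of the saliency channels, saccade-detection recovery on
generator ground truth, effect-size parameter recovery with coverage, and
the cross-disorder ordering of GLM marginal means — so the test suite,
the acceptance script, and the analysis drivers all run the identical
procedures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gaze_events import DEFAULT_DETECTION, DetectionParams, detect_events
from .saliency import SaliencyMap, compute_saliency, to_density
from .stats import cross_disorder_glm, fixed_effects_meta, per_site_effect_sizes
from .synthetic_data import (
    ORDERING_D_OFFSETS,
    CohortDesign,
    TrialParams,
    generate_cohort,
    generate_trial,
    reference_design,
    simulate_scores,
    two_group_design,
)

CELL_TOLERANCE = 2  # pop-out hit = argmax within this many cells of the target


def popout_localization(kind: str, n_placements: int, seed: int) -> float:
    """Fraction of oddball arrays whose single-channel saliency argmax
    lands on the oddball (within ``CELL_TOLERANCE`` cells)."""
    from .synthetic_data import popout_image

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_placements):
        img, (tx, ty) = popout_image(kind, int(rng.integers(2**31)))
        m = compute_saliency(img)[kind].values
        r, c = np.unravel_index(int(m.argmax()), m.shape)
        if abs(r - ty / 16) <= CELL_TOLERANCE + 0.5 and \
           abs(c - tx / 16) <= CELL_TOLERANCE + 0.5:
            hits += 1
    return hits / n_placements


@dataclass(frozen=True)
class RecoveryResult:
    recall: float
    precision: float
    mean_endpoint_error: float
    n_trials: int


def saccade_recovery(
    n_trials: int,
    seed: int,
    smap: SaliencyMap | None = None,
    params: TrialParams | None = None,
    detection: DetectionParams = DEFAULT_DETECTION,
    onset_tol_ms: int = 25,
) -> RecoveryResult:
    """Detect programmed regular saccades across seeded synthetic trials.

    A programmed saccade is recovered when a detected regular saccade's
    onset lies within ``onset_tol_ms``; precision counts detected regular
    saccades with a programmed match. Endpoint error is the mean distance
    between matched detected and programmed endpoints (degrees).
    """
    if smap is None:
        rng0 = np.random.default_rng(12345)
        smap = SaliencyMap(to_density(rng0.random((64, 80))), "full")
    params = params or TrialParams()
    rng = np.random.default_rng(seed)
    n_truth = n_det = n_hit = n_matched_det = 0
    errors: list[float] = []
    for _ in range(n_trials):
        trial = generate_trial(smap, pi=0.4, seed=rng, params=params)
        events = detect_events(trial, detection)
        truth = trial.truth[trial.truth["kind"] == "regular"]
        detected = events.regular_saccades()
        n_truth += len(truth)
        n_det += len(detected)
        for row in truth.itertuples():
            matches = [s for s in detected if abs(s.onset - row.onset) <= onset_tol_ms]
            if matches:
                n_hit += 1
                s = min(matches, key=lambda s: abs(s.onset - row.onset))
                errors.append(float(np.hypot(s.x1 - row.x1, s.y1 - row.y1)))
        for s in detected:
            if any(abs(s.onset - r.onset) <= onset_tol_ms for r in truth.itertuples()):
                n_matched_det += 1
    return RecoveryResult(
        recall=n_hit / max(n_truth, 1),
        precision=n_matched_det / max(n_det, 1),
        mean_endpoint_error=float(np.mean(errors)) if errors else float("nan"),
        n_trials=n_trials,
    )


@dataclass(frozen=True)
class EffectRecoveryResult:
    true_d: float
    mean_pooled_d: float
    sd_pooled_d: float
    coverage: float  # fraction of 95% CIs containing the true d
    n_replicates: int
    pooled: tuple[float, ...]


def effect_size_recovery(
    full_maps: list[SaliencyMap],
    n_replicates: int = 50,
    seed: int = 0,
    true_d: float = 0.8,
    n_sites: int = 3,
    n_per_group: int = 100,
) -> EffectRecoveryResult:
    """Recover a calibrated HC-vs-SZ effect through the whole statistical
    chain (scores -> per-site covariate-adjusted d -> fixed-effects pool)."""
    design = two_group_design(n_sites, n_per_group, n_per_group, d=true_d)
    rng = np.random.default_rng(seed)
    pooled, covered = [], 0
    maps_by_channel = {"full": full_maps}
    for _ in range(n_replicates):
        s1, s2 = rng.integers(2**31, size=2)
        cohort = generate_cohort(design, full_maps, int(s1))
        scores = simulate_scores(cohort, maps_by_channel, int(s2),
                                 n_saccades=design.n_saccades)
        records = per_site_effect_sizes(scores, "score_full")
        meta = fixed_effects_meta(records, channel="full")
        pooled.append(meta.d_overall)
        lo = meta.d_overall - 1.959963984540054 * meta.se_overall
        hi = meta.d_overall + 1.959963984540054 * meta.se_overall
        covered += lo <= true_d <= hi
    pooled_arr = np.array(pooled)
    return EffectRecoveryResult(
        true_d=true_d, mean_pooled_d=float(pooled_arr.mean()),
        sd_pooled_d=float(pooled_arr.std(ddof=1)), coverage=covered / n_replicates,
        n_replicates=n_replicates, pooled=tuple(pooled),
    )


def ordering_fraction(
    full_maps: list[SaliencyMap],
    n_runs: int = 40,
    seed: int = 0,
    design: CohortDesign | None = None,
) -> float:
    """Fraction of seeded cohort runs whose GLM marginal means reproduce
    the SZ > BD > MDD > ASD >= HC ordering at the reference sample sizes."""
    if design is None:
        design = reference_design(d_offsets=ORDERING_D_OFFSETS)
    rng = np.random.default_rng(seed)
    maps_by_channel = {"full": full_maps}
    ordered = 0
    for _ in range(n_runs):
        s1, s2 = rng.integers(2**31, size=2)
        cohort = generate_cohort(design, full_maps, int(s1))
        scores = simulate_scores(cohort, maps_by_channel, int(s2),
                                 n_saccades=design.n_saccades)
        res = cross_disorder_glm(scores, "score_full")
        emm = res.emmeans.set_index("diagnosis")["emmean"]
        if (emm["SZ"] > emm["BD"] > emm["MDD"] > emm["ASD"]
                and emm["ASD"] >= emm["HC"]):
            ordered += 1
    return ordered / n_runs


def score_vs_bias_curve(
    full_maps: list[SaliencyMap],
    pis: np.ndarray,
    n_saccades_per_image: int,
    seed: int,
    n_subjects: int = 16,
) -> pd.DataFrame:
    """Mean simulated salience score at each bias level (monotonicity
    check: E[score] is strictly increasing in pi).

    The per-level mean is taken over ``n_subjects`` independent subjects
    so the Monte-Carlo error stays well below the score change between
    adjacent bias levels.
    """
    rng = np.random.default_rng(seed)
    maps_by_channel = {"full": full_maps}
    rows = []
    for pi in pis:
        cohort = pd.DataFrame({
            "subject_id": [f"p{pi:.3f}_{j}" for j in range(n_subjects)],
            "site": "S1", "diagnosis": "HC", "age": 35.0, "sex": "M",
            "pi": float(pi),
        })
        scores = simulate_scores(cohort, maps_by_channel,
                                 int(rng.integers(2**31)),
                                 n_saccades=n_saccades_per_image)
        rows.append({"pi": float(pi),
                     "score": float(scores["score_full"].mean())})
    return pd.DataFrame(rows)
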