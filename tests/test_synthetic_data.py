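import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from gazesal import synthetic_data as sd
from gazesal.geometry import DEFAULT_GEOMETRY
from gazesal.saliency import SaliencyMap, to_density


def point_mass_map(row=10, col=10):
    v = np.zeros((64, 80))
    v[row, col] = 1.0
    return SaliencyMap(v, "full")


def uniform_map():
    return SaliencyMap(np.full((64, 80), 1 / 5120), "full")


class TestStimuli:
    def test_default_set_has_four_images_per_category(self, stimulus_set):
        assert len(stimulus_set) == 20
        counts = pd.Series(stimulus_set.categories).value_counts()
        assert (counts == 4).all() and set(counts.index) == set(sd.CATEGORIES)

    def test_noise_images_have_zero_color_contrast(self, stimulus_set):
        for img, cat in zip(stimulus_set.images, stimulus_set.categories):
            if cat == "noise":
                assert np.abs(img[..., 0].astype(int) - img[..., 1]).max() == 0
                assert np.abs(img[..., 1].astype(int) - img[..., 2]).max() == 0

    def test_same_seed_reproduces_identical_bytes(self, stimulus_set):
        again = sd.generate_stimulus_set(0)
        for a, b in zip(stimulus_set.images, again.images):
            assert a.tobytes() == b.tobytes()

    def test_roundtrip_through_png(self, stimulus_set, tmp_path):
        small = sd.StimulusSet(stimulus_set.images[:2], stimulus_set.categories[:2],
                               stimulus_set.image_ids[:2])
        small.save(tmp_path)
        back = sd.StimulusSet.load(tmp_path)
        assert back.image_ids == small.image_ids
        assert (back.images[0] == small.images[0]).all()


class TestEndpointMixture:
    def test_pure_salience_draw_hits_the_point_mass_cell(self, rng):
        x, y, cells = sd.sample_endpoints(point_mass_map(20, 30), pi=1.0,
                                          n=500, rng=rng)
        assert (cells == 20 * 80 + 30).all()
        r, c, on = DEFAULT_GEOMETRY.deg_to_cell(x, y)
        assert on.all() and (r == 20).all() and (c == 30).all()

    def test_pure_background_draw_is_uniform(self, rng):
        """pi=0 endpoints over a uniform map pass a chi-square GOF test."""
        _, _, cells = sd.sample_endpoints(uniform_map(), pi=0.0, n=10_000, rng=rng)
        # coarse 8 x 10 blocks -> expected 125 per bin
        rows, cols = np.divmod(cells, 80)
        bins = (rows // 8) * 8 + cols // 10
        counts = np.bincount(bins, minlength=64)
        assert sps.chisquare(counts).pvalue > 0.01

    def test_bias_outside_unit_interval_rejected(self, rng):
        with pytest.raises(ValueError):
            sd.sample_endpoints(uniform_map(), pi=1.5, n=1, rng=rng)


class TestTrialGeneration:
    def test_point_mass_trial_lands_every_endpoint_in_cell(self):
        trial = sd.generate_trial(point_mass_map(10, 10), pi=1.0, seed=0,
                                  params=sd.TrialParams(n_micro=0, blink_rate=0))
        r, c, on = DEFAULT_GEOMETRY.deg_to_cell(trial.truth["x1"], trial.truth["y1"])
        assert on.all() and (r == 10).all() and (c == 10).all()

    def test_zero_saccades_gives_single_fixation_epoch(self):
        trial = sd.generate_trial(uniform_map(), pi=0.5, n_saccades=0, seed=1,
                                  params=sd.TrialParams(blink_rate=0))
        assert len(trial.truth) == 0
        # position never strays from the start beyond jitter
        assert np.nanstd(trial.x) < 0.2 and np.nanstd(trial.y) < 0.2

    def test_trial_contract(self):
        trial = sd.generate_trial(uniform_map(), pi=0.5, seed=2)
        assert len(trial.x) == 8000
        assert (np.diff(trial.time_ms) == 1).all()
        assert (trial.pupil >= 0).all()
        # blink samples (pupil 0) have invalid position
        blink = trial.pupil == 0
        if blink.any():
            assert np.isnan(trial.x[blink]).all()

    def test_trial_csv_roundtrip(self, tmp_path):
        trial = sd.generate_trial(uniform_map(), pi=0.5, seed=3)
        path = tmp_path / "trial.csv"
        trial.save_csv(path)
        back = sd.GazeTrial.load_csv(path, image_id="img", subject_id="s")
        np.testing.assert_allclose(back.pupil, trial.pupil)
        np.testing.assert_allclose(back.x, trial.x, atol=1e-9)


class TestCalibration:
    def test_expected_score_increases_with_bias(self, analysis_full_maps):
        """Spearman rho > 0.99 between bias pi and simulated score over a
        0..1 grid (~1000 endpoints per level)."""
        from gazesal.experiments import score_vs_bias_curve

        pis = np.linspace(0, 1, 11)
        curve = score_vs_bias_curve(analysis_full_maps, pis,
                                    n_saccades_per_image=63, seed=11)
        rho = sps.spearmanr(curve["pi"], curve["score"]).statistic
        assert rho > 0.99

    def test_calibrated_pi_orders_match_d_offsets(self, analysis_full_maps):
        design = sd.reference_design()
        calib = sd.calibrate_design(analysis_full_maps, design)
        pis = calib.pi_by_group
        assert pis["SZ"] > pis["BD"] > pis["MDD"] > pis["ASD"] > pis["HC"]
        assert all(0 < v < 1 for v in pis.values())

    def test_unreachable_effect_size_is_rejected(self, analysis_full_maps):
        design = sd.two_group_design(d=50.0)
        with pytest.raises(ValueError):
            sd.calibrate_design(analysis_full_maps, design)


class TestCohort:
    def test_reference_design_counts(self):
        design = sd.reference_design()
        totals = {}
        for cell in design.cells:
            totals[cell.diagnosis] = totals.get(cell.diagnosis, 0) + cell.n
        assert totals == {"HC": 550, "SZ": 238, "BD": 41, "MDD": 50, "ASD": 133}

    def test_cohort_is_deterministic(self, analysis_full_maps):
        design = sd.two_group_design(n_sites=2, n_hc=10, n_sz=10)
        a = sd.generate_cohort(design, analysis_full_maps, 42)
        b = sd.generate_cohort(design, analysis_full_maps, 42)
        pd.testing.assert_frame_equal(a, b)

    def test_cohort_sizes_and_columns(self, analysis_full_maps):
        design = sd.two_group_design(n_sites=3, n_hc=5, n_sz=4)
        cohort = sd.generate_cohort(design, analysis_full_maps, 0)
        assert len(cohort) == 27
        assert cohort.groupby("diagnosis").size().to_dict() == {"HC": 15, "SZ": 12}
        assert cohort["pi"].between(0, 1).all()
        assert set(cohort["sex"]) <= {"M", "F"}

    def test_null_design_gives_null_effect(self, analysis_full_maps):
        """All group biases equal -> HC/SZ effect size ~ 0 at n=200/group."""
        from gazesal.stats import unbiased_d

        design = sd.two_group_design(n_sites=1, n_hc=200, n_sz=200, d=0.0)
        cohort = sd.generate_cohort(design, analysis_full_maps, 7)
        scores = sd.simulate_scores(cohort, {"full": analysis_full_maps}, 8)
        rec = unbiased_d(scores, "score_full", site="S1")
        assert abs(rec.d) < 0.1

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            sd.CohortDesign(cells=[])
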