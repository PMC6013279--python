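"""Synthetic cohort generator: determinism, noiseless limits, distributions."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import kstest

from engramtrack import CohortConfig, generate_cohort
from engramtrack.cohort import analyze_cohort, compute_deltas, correlate, score_session
from engramtrack.fluorescence import RoiMask, extract_roi_means
from engramtrack.simulate import (
    DEFAULT_SESSION_SCHEDULE,
    AnimalTruth,
    ImageGeometry,
    generate_behavior,
    generate_image_stack,
)

NOISELESS = dict(
    baseline_rate=0.0,
    noise_scale=0.0,
    nonspecific_fraction=0.0,
    pair_jitter=0.0,
)


class TestSchedule:
    def test_default_schedule_matches_study_timeline(self):
        assert len(DEFAULT_SESSION_SCHEDULE) == 13
        days = {s.label: s.day for s in DEFAULT_SESSION_SCHEDULE}
        assert days == {
            "H": 0, "1": 1, "4": 4, "7": 7, "10": 10, "13": 13, "16": 16,
            "19": 19, "C1": 22, "R1": 25, "N": 28, "C2": 40, "R2": 43,
        }
        conditions = [s.condition for s in DEFAULT_SESSION_SCHEDULE]
        assert conditions.count("training") == 7
        assert conditions.count("control") == 2
        assert conditions.count("retention") == 2

    def test_config_rejects_bad_values_naming_field(self):
        with pytest.raises(ValueError, match="baseline_rate"):
            CohortConfig(baseline_rate=1.5)
        with pytest.raises(ValueError, match="noise_scale"):
            CohortConfig(noise_scale=float("nan"))
        with pytest.raises(ValueError, match="reinstatement_fidelity"):
            CohortConfig(reinstatement_fidelity=[2.0] * 8)

    def test_emergence_probability_monotone_saturating(self):
        cfg = CohortConfig()
        probs = [cfg.task_probability(s) for s in cfg.training_sessions()]
        assert all(p1 <= p2 for p1, p2 in zip(probs, probs[1:]))
        assert probs[-1] == 1.0


class TestDeterminism:
    def test_identical_seed_bit_identical(self, tiny_config):
        c1 = generate_cohort(tiny_config)
        c2 = generate_cohort(dataclasses.replace(tiny_config))
        assert c1.traces.tobytes() == c2.traces.tobytes()
        assert c1.behavior == c2.behavior
        for t1, t2 in zip(c1.truth, c2.truth):
            assert np.array_equal(t1.activation, t2.activation)
            assert np.array_equal(t1.ensemble, t2.ensemble)

    def test_different_seed_differs(self, tiny_config):
        c1 = generate_cohort(tiny_config)
        c2 = generate_cohort(dataclasses.replace(tiny_config, seed=tiny_config.seed + 1))
        assert c1.traces.tobytes() != c2.traces.tobytes()


class TestNoiselessLimits:
    def test_retention_equals_final_training_session(self):
        cfg = CohortConfig(
            n_animals=2, n_cells_per_animal=200, reinstatement_fidelity=1.0, **NOISELESS
        )
        cohort = generate_cohort(cfg)
        labels = cohort.session_labels
        for truth in cohort.truth:
            s19 = set(np.nonzero(truth.activation[:, labels.index("19")])[0])
            for ret in ("R1", "R2"):
                assert set(np.nonzero(truth.activation[:, labels.index(ret)])[0]) == s19
        # the same holds for the detected active sets
        from engramtrack.cohort import detect_activity

        for m in detect_activity(cohort):
            assert m.active["R2"].equals(m.active["19"])
            assert m.active["R1"].equals(m.active["19"])

    def test_control_sessions_silent_without_cage_ensemble(self):
        cfg = CohortConfig(
            n_animals=1, n_cells_per_animal=300, cage_rate=0.0, **NOISELESS
        )
        cohort = generate_cohort(cfg)
        labels = cohort.session_labels
        for lab in ("C1", "C2"):
            assert cohort.truth[0].activation[:, labels.index(lab)].sum() == 0

    def test_activated_delta_f_equals_amplitude(self):
        cfg = CohortConfig(n_animals=1, n_cells_per_animal=200, **NOISELESS)
        cohort = generate_cohort(cfg)
        deltas = compute_deltas(cohort)[0]
        act = cohort.truth[0].activation
        assert deltas[act] == pytest.approx(cfg.active_amplitude)
        assert deltas[~act] == pytest.approx(0.0)


class TestDistributions:
    def test_traces_within_8bit_range(self, default_cohort):
        assert default_cohort.traces.min() >= 0.0
        assert default_cohort.traces.max() <= 255.0

    def test_noise_only_delta_f_is_laplace(self):
        cfg = CohortConfig(
            n_animals=1,
            n_cells_per_animal=10_000,
            ensemble_fraction=0.0,
            exploration_fraction=0.0,
            cage_fraction=0.0,
            nonspecific_fraction=0.0,
            novelty_multiplier=0.0,
            baseline_rate=0.0,
            seed=11,
        )
        deltas = compute_deltas(generate_cohort(cfg)).ravel()
        stat = kstest(deltas, "laplace", args=(0.0, cfg.noise_scale))
        assert stat.pvalue > 0.01

    def test_ensemble_activation_nondecreasing_over_training(self):
        cfg = CohortConfig(n_animals=1, n_cells_per_animal=4000, seed=5)
        cohort = generate_cohort(cfg)
        truth = cohort.truth[0]
        labels = cohort.session_labels
        rates = [
            truth.activation[truth.ensemble, labels.index(s.label)].mean()
            for s in cfg.training_sessions()
        ]
        # empirical fractions of a 100-cell ensemble; allow binomial jitter
        assert all(r2 >= r1 - 0.08 for r1, r2 in zip(rates, rates[1:]))
        assert rates[-1] > rates[0]


class TestBehavior:
    def _truth(self, fidelity):
        empty = np.array([], dtype=int)
        return AnimalTruth(empty, empty, empty, empty, empty,
                           np.zeros((1, 13), dtype=bool), float(fidelity))

    def test_zero_error_probability_visits_only_baited(self):
        cfg = CohortConfig(error_floor=0.0, error_scale=0.0)
        beh = generate_behavior(self._truth(0.5), cfg, rng=0)
        for trials in beh.values():
            for visits in trials:
                assert set(visits) <= set(cfg.baited_arms)
                assert len(visits) == len(cfg.baited_arms)

    def test_perfect_fidelity_matches_final_training_error_rate(self):
        cfg = CohortConfig()
        s19 = cfg.stability(cfg.training_sessions()[-1], fidelity=1.0)
        for sess in cfg.session_schedule:
            if sess.condition == "retention":
                assert cfg.stability(sess, fidelity=1.0) == pytest.approx(s19)

    def test_retention_interpolation(self):
        cfg = CohortConfig()
        r1 = next(s for s in cfg.session_schedule if s.label == "R1")
        r2 = next(s for s in cfg.session_schedule if s.label == "R2")
        assert cfg.retention_probability(r2, 0.4) == pytest.approx(0.4)
        assert cfg.retention_probability(r1, 0.4) == pytest.approx(1 - 0.6 * 6 / 24)

    def test_fidelity_spread_drives_error_difference(self):
        # Monte-Carlo: with fidelities spread over [0.3, 1], the correlation
        # between (1 - fidelity) and the R2-minus-19 reference-error
        # difference is positive with p < 0.05 in >= 90% of seeds at n = 8.
        cfg = CohortConfig()
        fid = cfg.fidelities()
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            diffs = []
            for i, f in enumerate(fid):
                rng = np.random.default_rng((seed, i))
                beh = generate_behavior(self._truth(f), cfg, rng)
                rm = {
                    lab: score_session(trials, cfg.baited_arms).rm_errors
                    for lab, trials in beh.items()
                }
                diffs.append(rm["R2"] - rm["19"])
            r, p = correlate(1 - fid, np.array(diffs, dtype=float))
            hits += (r > 0) and (p < 0.05)
        assert hits >= 0.9 * n_seeds


class TestImageStacks:
    GEOM = ImageGeometry(nx=64, ny=64, nz=10, background=0.0, background_noise=0.0)

    def test_single_cell_roi_mean_constant_over_timepoints(self):
        cells = [{"cell_id": 0, "x": 32.0, "y": 30.0, "z": 5, "values": [40.0, 40.0, 40.0]}]
        stack, masks = generate_image_stack(cells, self.GEOM, seed=0)
        roi = RoiMask(0, (masks[0]["center_x"], masks[0]["center_y"]), masks[0]["z"],
                      radius_px=masks[0]["radius_px"])
        means = [
            extract_roi_means(stack[k], [roi], smooth_sigma=0.0)[0]
            for k in range(3)
        ]
        assert means[0] == pytest.approx(means[1]) == pytest.approx(means[2])
        # oracle: peak-weighted mean of the rendered blob over the mask pixels
        rows, cols = roi.pixel_indices((64, 64))
        blob = np.exp(
            -0.5 * ((cols - 32.0) ** 2 + (rows - 30.0) ** 2)
            / (self.GEOM.blob_sigma_um / self.GEOM.um_per_px) ** 2
        )
        expected = 40.0 * blob.mean()
        assert means[0] == pytest.approx(expected, rel=0.01)

    def test_zero_cells_returns_background(self):
        geom = ImageGeometry(nx=32, ny=32, nz=5, background=17.0, background_noise=0.0)
        stack, masks = generate_image_stack([], geom, seed=0)
        assert masks == []
        assert stack == pytest.approx(np.full((1, 5, 32, 32), 17.0))

    def test_twenty_cell_mask_centroids_match_ground_truth(self):
        rng = np.random.default_rng(2)
        cells = [
            {
                "cell_id": i,
                "x": float(rng.uniform(20, 236)),
                "y": float(rng.uniform(20, 236)),
                "z": float(rng.uniform(1, 58)),
                "values": [30.0],
            }
            for i in range(20)
        ]
        _, masks = generate_image_stack(cells, ImageGeometry(background_noise=0.0), seed=0)
        for cell, mask in zip(cells, masks):
            assert mask["center_x"] == pytest.approx(cell["x"], abs=1.0)
            assert mask["center_y"] == pytest.approx(cell["y"], abs=1.0)
            assert abs(mask["z"] - cell["z"]) <= 1.0

    def test_heavy_overlap_warns(self):
        cells = [
            {"cell_id": i, "x": 30.0 + i, "y": 30.0, "z": 5, "values": [50.0]}
            for i in range(3)
        ]
        with pytest.warns(UserWarning, match="more than one cell"):
            generate_image_stack(cells, self.GEOM, seed=0)

    def test_out_of_bounds_cell_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            generate_image_stack(
                [{"cell_id": 0, "x": 99.0, "y": 5.0, "z": 2, "values": [1.0]}],
                ImageGeometry(nx=64, ny=64, nz=10),
            )
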