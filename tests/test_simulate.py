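"""Synthetic movement archetypes: distributional closed forms, round-trip
through the on-disk schema, parameter recovery and phase-diagram placement."""

import numpy as np
import pytest
from scipy.optimize import brentq

from orientnull import mean_vector_length, read_trials, turning_angles
from orientnull.circular import InvalidParameterError, bessel_ratio
from orientnull.simulate import (
    MovementSpec,
    generate_cohort,
    generate_study,
    generate_trial,
)


def cohort_stat(spec, rng, stat):
    return np.array([stat(t.bearings) for t in generate_cohort(spec, rng)])


class TestArchetypes:
    def test_degenerate_bias_walks_straight(self):
        spec = MovementSpec("brw", 21, 1, "sp", parameters={"goal": 70.0, "kappa_bias": 399.0})
        t = generate_trial(spec, np.random.default_rng(0))
        assert mean_vector_length(t.bearings) > 0.99

    def test_crw_turn_consistency_matches_bessel_ratio(self):
        spec = MovementSpec("crw_vm", 300, 200, "sp", parameters={"kappa": 2.0})
        rng = np.random.default_rng(1)
        r = cohort_stat(spec, rng, lambda b: mean_vector_length(turning_angles(b)))
        se = r.std(ddof=1) / np.sqrt(r.size)
        # finite-sample E[R-hat] slightly exceeds A(2); allow for that bias
        bias = (1 - bessel_ratio(2.0) ** 2) / (2 * 299 * bessel_ratio(2.0))
        assert r.mean() == pytest.approx(bessel_ratio(2.0) + bias, abs=3 * se)

    def test_zigzag_mixture_resultant(self):
        # alternating +/- delta turns: population resultant A(kappa) * cos(delta)
        spec = MovementSpec("zigzag", 90, 200, "sp", parameters={"delta": 60.0, "kappa": 20.0})
        rng = np.random.default_rng(2)
        r = cohort_stat(spec, rng, lambda b: mean_vector_length(turning_angles(b)))
        target = bessel_ratio(20.0) * np.cos(np.radians(60.0))
        se = r.std(ddof=1) / np.sqrt(r.size)
        assert r.mean() == pytest.approx(target, abs=max(3 * se, 0.01))

    def test_one_sided_bias_scores_low_against_crw(self, vm21):
        """Consistent one-sided turning keeps turn consistency high while
        curling the path: most trials fall below the CRW median."""
        from orientnull import trial_quantile_theoretical

        spec = MovementSpec("one_sided", 21, 200, "sp", parameters={"delta": 20.0, "kappa": 10.0})
        rng = np.random.default_rng(3)
        qs = []
        for t in generate_cohort(spec, rng):
            qs.append(
                trial_quantile_theoretical(
                    vm21,
                    mean_vector_length(turning_angles(t.bearings)),
                    mean_vector_length(t.bearings),
                )
            )
        assert np.median(qs) < 50

    def test_bcrw_reduces_to_crw_at_zero_weight(self):
        rng = np.random.default_rng(4)
        spec = MovementSpec(
            "bcrw", 90, 50, "sp", parameters={"goal": 10.0, "kappa": 5.0, "w": 0.0}
        )
        r_th = cohort_stat(spec, rng, mean_vector_length)
        rng2 = np.random.default_rng(5)
        crw = MovementSpec("crw_vm", 90, 50, "sp", parameters={"kappa": 5.0})
        r_th_crw = cohort_stat(crw, rng2, mean_vector_length)
        # same process family: distributions agree in location within noise
        assert abs(r_th.mean() - r_th_crw.mean()) < 4 * np.hypot(
            r_th.std(ddof=1) / np.sqrt(50), r_th_crw.std(ddof=1) / np.sqrt(50)
        )

    def test_bcrw_bias_raises_straightness(self):
        rng = np.random.default_rng(6)
        weak = MovementSpec("bcrw", 90, 40, "sp", parameters={"goal": 10.0, "kappa": 5.0, "w": 0.0})
        strong = MovementSpec("bcrw", 90, 40, "sp", parameters={"goal": 10.0, "kappa": 5.0, "w": 0.6})
        r_weak = cohort_stat(weak, rng, mean_vector_length)
        r_strong = cohort_stat(strong, rng, mean_vector_length)
        assert r_strong.mean() > r_weak.mean() + 0.1

    def test_composite_crw_with_equal_states_reduces_to_crw(self):
        rng = np.random.default_rng(7)
        spec = MovementSpec(
            "composite_crw", 90, 50, "sp",
            parameters={"kappa1": 5.0, "kappa2": 5.0, "p_switch": 0.2},
        )
        r = cohort_stat(spec, rng, lambda b: mean_vector_length(turning_angles(b)))
        se = r.std(ddof=1) / np.sqrt(r.size)
        bias = (1 - bessel_ratio(5.0) ** 2) / (2 * 89 * bessel_ratio(5.0))
        assert r.mean() == pytest.approx(bessel_ratio(5.0) + bias, abs=max(4 * se, 0.01))

    def test_composite_crw_mixes_turn_concentrations(self):
        rng = np.random.default_rng(8)
        spec = MovementSpec(
            "composite_crw", 90, 50, "sp",
            parameters={"kappa1": 1.0, "kappa2": 50.0, "p_switch": 0.1},
        )
        r = cohort_stat(spec, rng, lambda b: mean_vector_length(turning_angles(b)))
        # between the two pure-state resultants
        assert bessel_ratio(1.0) < r.mean() < bessel_ratio(50.0)

    @pytest.mark.parametrize(
        "model, params",
        [
            ("crw_vm", {"kappa": -1}),
            ("crw_wc", {"rho": 1.0}),
            ("bcrw", {"goal": 0, "kappa": 1, "w": 1.5}),
            ("one_sided", {"delta": 0, "kappa": 1}),
            ("composite_crw", {"kappa1": 1, "kappa2": 2, "p_switch": 0.0}),
            ("brw", {"goal": 0}),
        ],
    )
    def test_invalid_parameters_rejected(self, model, params):
        with pytest.raises(InvalidParameterError):
            MovementSpec(model, 21, 1, "sp", parameters=params)


class TestParameterRecovery:
    @pytest.mark.parametrize("kappa", [2.0, 5.0, 10.0])
    def test_kappa_recovered_from_turn_consistency(self, kappa):
        """Inverting the Bessel ratio at the cohort-mean turn consistency
        recovers the generating concentration to within 15%."""
        spec = MovementSpec("crw_vm", 300, 200, "sp", parameters={"kappa": kappa})
        rng = np.random.default_rng(int(kappa))
        r_mean = cohort_stat(
            spec, rng, lambda b: mean_vector_length(turning_angles(b))
        ).mean()
        kappa_hat = brentq(lambda k: bessel_ratio(k) - r_mean, 1e-6, 500.0)
        assert abs(kappa_hat - kappa) / kappa < 0.15


class TestStudyGeneration:
    def test_round_trip_preserves_per_trial_statistics(self, tmp_path):
        specs = [
            MovementSpec("crw_vm", 21, 5, "spA", parameters={"kappa": 5.0}),
            MovementSpec("brw", 21, 5, "spB", parameters={"goal": 30.0, "kappa_bias": 2.0}),
        ]
        out = tmp_path / "study.csv"
        table, manifest = generate_study(specs, seed=7, out_path=out)
        trials = read_trials(out)
        assert len(trials) == 10
        by_id = {t.trial_id: t for t in trials}
        for trial_id, grp in table.groupby("trial_id"):
            np.testing.assert_allclose(
                mean_vector_length(by_id[trial_id].bearings),
                mean_vector_length(grp.sort_values("time_index")["bearing_deg"].to_numpy()),
            )
        assert set(manifest["model"]) == {"crw_vm", "brw"}

    def test_deterministic_under_seed(self):
        specs = [MovementSpec("crw_vm", 21, 3, "sp", parameters={"kappa": 5.0})]
        a, _ = generate_study(specs, seed=11)
        b, _ = generate_study(specs, seed=11)
        np.testing.assert_array_equal(a["bearing_deg"], b["bearing_deg"])

    def test_empty_spec_list_gives_header_only(self, tmp_path):
        out = tmp_path / "empty.csv"
        table, _ = generate_study([], seed=0, out_path=out)
        assert table.empty
        assert out.read_text().startswith("trial_id,")

    def test_duplicate_species_labels_rejected(self):
        spec = MovementSpec("crw_vm", 21, 1, "sp", parameters={"kappa": 1.0})
        with pytest.raises(InvalidParameterError):
            generate_study([spec, spec])


class TestArchetypePlacement:
    def test_placement_relative_to_crw_mean_curve(self, vm21):
        """Biased walkers sit mostly above the CRW mean curve, one-sided
        turners mostly below, and CRW cohorts straddle it."""
        from orientnull import delta_r

        rng = np.random.default_rng(8)
        cases = {
            "brw": ({"goal": 0.0, "kappa_bias": 2.0}, lambda f: f > 0.9),
            "one_sided": ({"delta": 25.0, "kappa": 10.0}, lambda f: f < 0.3),
            "crw_vm": ({"kappa": 8.0}, lambda f: 0.25 < f < 0.75),
        }
        for model, (params, check) in cases.items():
            spec = MovementSpec(model, 21, 200, "sp", parameters=params)
            above = []
            for t in generate_cohort(spec, rng):
                dr = delta_r(
                    vm21,
                    mean_vector_length(turning_angles(t.bearings)),
                    mean_vector_length(t.bearings),
                )
                above.append(dr > 0)
            assert check(np.mean(above)), model
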