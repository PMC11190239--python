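"""Synthetic population generator: determinism, structure, dynamics, effects."""

import datetime as dt

import numpy as np
import pytest

from sleepscape._errors import ConfigError, GenerationError
from sleepscape.preprocess import FEATURE_NAMES, build_windows, filter_nights, nights_to_frame
from sleepscape.simulate import (
    ARCHETYPES,
    ConditionEffect,
    GeneratorConfig,
    PhenotypeArchetype,
    apply_condition_effects,
    generate_night,
    generate_population,
    simulate_phenotype_sequences,
)

#: Planned (kind-per-window) structure of every night type.
PLANNED = {
    "one_long": ["long"],
    "short_only": ["short"],
    "long_short": ["long", "short"],
    "double_long": ["long", "long"],
    "double_short": ["short", "short"],
}


class TestGenerateNight:
    def test_sd0_recommended_night_is_one_long_window_at_table_length(self):
        rng = np.random.default_rng(0)
        arch = ARCHETYPES["rec"].with_sd(0.0)
        night = generate_night(arch, rng, onset_jitter_h=0.0)
        (w,) = build_windows(night)
        assert w.kind == "long"
        # exact up to one 30-s epoch of rounding
        assert w.length_h == pytest.approx(8.087, abs=1 / 120)
        sleep_pct = w.sleep_time_h / night.duration_h
        assert sleep_pct == pytest.approx(0.870, abs=1 / 120)

    def test_very_short_sleep_archetype_emits_only_short_windows(self):
        rng = np.random.default_rng(1)
        arch = ARCHETYPES["c4"]
        for _ in range(30):
            night = generate_night(arch, rng)
            ws = build_windows(night)
            assert ws and all(w.kind == "short" and w.length_h < 3 for w in ws)

    def test_multi_long_archetype_emits_double_long_nights(self):
        rng = np.random.default_rng(2)
        arch = ARCHETYPES["c3"]
        found = False
        for _ in range(40):
            ws = build_windows(generate_night(arch, rng))
            if len(ws) == 2 and all(w.kind == "long" for w in ws):
                gap_h = (ws[1].start - ws[0].end) / np.timedelta64(1, "h")
                assert gap_h > 1.0
                found = True
        assert found

    @pytest.mark.parametrize("name", sorted(ARCHETYPES))
    def test_sd0_round_trip_recovers_planned_structure_for_every_type(self, name):
        # preprocessing must recover the planned window count and kinds for
        # 100% of zero-variance nights
        rng = np.random.default_rng(3)
        arch = ARCHETYPES[name].with_sd(0.0)
        for night_type in arch.night_type_probs:
            for _ in range(10):
                night = generate_night(arch, rng, night_type=night_type)
                ws = build_windows(night)
                assert [w.kind for w in ws] == PLANNED[night_type]

    def test_infeasible_sleep_percent_with_mandatory_gap_raises(self):
        arch = PhenotypeArchetype(
            "c2",
            (1.0, 0.0),
            (7.0, 0.0),
            (0.5, 0.0),
            {"long_short": 1.0},
            "long+short",
        )
        with pytest.raises(GenerationError):
            generate_night(arch, np.random.default_rng(0))


class TestGeneratePopulation:
    def test_degenerate_single_archetype_chain(self):
        config = GeneratorConfig(
            archetypes=("rec",),
            truth_transition_matrix=np.eye(1),
            initial_distribution=np.ones(1),
            n_individuals=2,
            n_nights=5,
            missing_night_prob=0.0,
            seed=0,
        )
        nights, survey, symptoms, truth = generate_population(config)
        assert len(nights) == 10
        for ind in truth.individual_ids:
            assert all(truth.archetype_names[s] == "rec" for s in truth.night_labels[ind])
        assert survey.empty and symptoms.empty

    def test_identity_matrix_makes_states_absorbing(self):
        config = GeneratorConfig(
            archetypes=("rec", "1-a"),
            truth_transition_matrix=np.eye(2),
            initial_distribution=np.array([0.0, 1.0]),
            n_individuals=3,
            n_nights=30,
            seed=1,
        )
        _, _, _, truth = generate_population(config)
        for ind in truth.individual_ids:
            assert set(truth.block_labels[ind]) == {1}  # never leaves 1-a

    def test_two_state_switch_frequency_matches_chain_parameter(self):
        config = GeneratorConfig(
            archetypes=("rec", "1-a"),
            truth_transition_matrix=np.array([[0.7, 0.3], [0.3, 0.7]]),
            initial_distribution=np.array([0.5, 0.5]),
            n_individuals=200,
            n_nights=50,
            seed=0,
        )
        _, _, _, truth = generate_population(config)
        assert truth.switch_frequency() == pytest.approx(0.3, abs=0.02)

    def test_identical_seed_and_config_give_byte_identical_output(self):
        config = dict(n_individuals=4, n_nights=14, missing_night_prob=0.1, seed=9)
        n1, s1, y1, t1 = generate_population(GeneratorConfig(**config))
        n2, s2, y2, t2 = generate_population(GeneratorConfig(**config))
        assert len(n1) == len(n2)
        for a, b in zip(n1, n2):
            assert a.individual_id == b.individual_id
            assert a.sleep_onset == b.sleep_onset
            assert np.array_equal(a.stages, b.stages)
            assert a.nonwear_hours == b.nonwear_hours
        for ind in t1.individual_ids:
            assert np.array_equal(t1.block_labels[ind], t2.block_labels[ind])

    def test_non_stochastic_matrix_rejected(self):
        with pytest.raises(ConfigError):
            GeneratorConfig(
                archetypes=("rec", "1-a"),
                truth_transition_matrix=np.array([[0.9, 0.2], [0.3, 0.7]]),
            )

    def test_missing_nights_are_skipped(self):
        config = GeneratorConfig(
            archetypes=("rec",),
            truth_transition_matrix=np.eye(1),
            initial_distribution=np.ones(1),
            n_individuals=5,
            n_nights=40,
            missing_night_prob=0.3,
            seed=4,
        )
        nights, _, _, truth = generate_population(config)
        expected = sum((~truth.missing[i]).sum() for i in truth.individual_ids)
        assert len(nights) == expected < 200

    def test_feature_calibration_against_published_population_means(self):
        # nightly-feature population means on a default-mix simulation stay
        # within 3 published sds of the published means for the features the
        # archetypes control
        published_mean = dict(
            zip(FEATURE_NAMES, (0.859, 6.992, 1.074, 0.924, 0.401, 0.988, 0.030, 8.066, 1.312))
        )
        published_sd = dict(
            zip(FEATURE_NAMES, (0.089, 1.274, 0.578, 0.918, 0.353, 0.148, 0.180, 1.416, 1.023))
        )
        config = GeneratorConfig(n_individuals=40, n_nights=60, seed=5)
        nights, *_ = generate_population(config)
        frame = nights_to_frame(filter_nights(nights))
        for feat in ("sleep_percent", "st_long_h", "wt_long_h", "lw_count", "lw_length_h"):
            mean = frame[feat].mean()
            assert abs(mean - published_mean[feat]) < 3 * published_sd[feat], feat


class TestConditionEffects:
    @staticmethod
    def _config(effects, **kw):
        base = dict(
            archetypes=("rec", "1-a"),
            truth_transition_matrix=np.array([[0.5, 0.5], [0.5, 0.5]]),
            initial_distribution=np.array([0.5, 0.5]),
            n_individuals=80,
            n_nights=120,
            condition_effects=effects,
            seed=6,
        )
        base.update(kw)
        return GeneratorConfig(**base)

    def test_no_effects_leave_truth_unchanged(self):
        config = self._config(())
        _, _, _, truth = generate_population(config)
        labels = {i: truth.block_labels[i].copy() for i in truth.individual_ids}
        out = apply_condition_effects(truth, config)
        assert out is truth
        for i, lab in labels.items():
            assert np.array_equal(out.block_labels[i], lab)

    def test_chronic_identity_effect_freezes_positive_individuals(self):
        eff = ConditionEffect("diabetes", "chronic", np.eye(2), prevalence=0.25)
        _, survey, _, truth = generate_population(self._config((eff,)))
        positives = truth.chronic_positive["diabetes"]
        assert positives
        for ind in positives:
            assert np.unique(truth.block_labels[ind]).size == 1
        # negatives still switch
        neg = [i for i in truth.individual_ids if i not in positives]
        assert any(np.unique(truth.block_labels[i]).size > 1 for i in neg)
        resp = survey.set_index("individual_id")["response"]
        assert all(resp[i] == "positive" for i in positives)
        assert set(survey["response"]) <= {"positive", "negative", "no_answer"}

    def test_acute_effect_reduces_switching_inside_window(self):
        sticky = np.array([[0.95, 0.05], [0.05, 0.95]])
        eff = ConditionEffect(
            "flu", "acute", sticky, prevalence=0.5, window_days=(-14, 14), report_day=72
        )
        config = self._config((eff,), seed=7)
        _, _, symptoms, truth = generate_population(config)
        reports = truth.acute_reports["flu"]
        assert reports and set(symptoms["condition"]) == {"flu"}
        in_sw, in_tot, out_sw, out_tot = 0, 0, 0, 0
        for ind, report in reports.items():
            chain = truth.block_labels[ind]
            for b in range(1, chain.size):
                block_date = config.start_date + dt.timedelta(days=config.block_start_day(b))
                offset = (block_date - report).days
                switched = chain[b] != chain[b - 1]
                if -14 <= offset <= 14:
                    in_sw += switched
                    in_tot += 1
                else:
                    out_sw += switched
                    out_tot += 1
        assert in_tot > 0 and out_tot > 0
        assert in_sw / in_tot < out_sw / out_tot

    def test_overlapping_acute_reports_rejected(self):
        config = self._config(())
        _, _, _, truth = generate_population(config)
        truth.acute_reports = {
            "flu": {truth.individual_ids[0]: dt.date(2020, 3, 1)},
            "fever": {truth.individual_ids[0]: dt.date(2020, 3, 20)},
        }
        effects = (
            ConditionEffect("flu", "acute", np.eye(2), prevalence=0.0),
            ConditionEffect("fever", "acute", np.eye(2), prevalence=0.0),
        )
        bad = self._config(effects)
        with pytest.raises(ConfigError):
            apply_condition_effects(truth, bad)


class TestLabelChains:
    def test_simulated_sequences_match_transition_parameter(self):
        rng = np.random.default_rng(0)
        t = np.array([[0.8, 0.2], [0.4, 0.6]])
        seqs = simulate_phenotype_sequences(2000, 20, t, np.array([0.5, 0.5]), rng)
        from_0 = (seqs[:, :-1] == 0).sum()
        to_1 = ((seqs[:, :-1] == 0) & (seqs[:, 1:] == 1)).sum()
        assert to_1 / from_0 == pytest.approx(0.2, abs=0.01)
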