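"""Cohort assignment, chi-square and information gain."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import day, oracle_information_gain
from sleepscape._errors import DataError
from sleepscape.health import (
    CohortDesign,
    ContingencyTable,
    assign_cohort,
    build_contingency_table,
    chi_square_test,
    information_gain,
    static_vs_dynamic,
)


def units(rows):
    return pd.DataFrame(rows, columns=["individual_id", "start_date", "subcluster"])


SURVEY = pd.DataFrame(
    {
        "individual_id": ["p1", "n1", "q1"],
        "condition": "apnea",
        "response": ["positive", "negative", "no_answer"],
    }
)


class TestCohorts:
    def test_chronic_groups_exclude_no_answer(self):
        u = units(
            [(ind, day(0), "2") for ind in ("p1", "n1", "q1", "zz")]
        )
        out = assign_cohort(u, CohortDesign("chronic", "apnea"), survey=SURVEY)
        assert dict(zip(out["individual_id"], out["group"])) == {
            "p1": "pos",
            "n1": "neg",
        }

    def test_acute_windows_and_gap_zone(self):
        report = day(100)
        symptoms = pd.DataFrame(
            {"individual_id": ["a"], "condition": ["flu"], "report_date": [report]}
        )
        offsets = {-60: "baseline", -51: "baseline", -30: None, -14: "during",
                   0: "during", 13: "during", 14: "during", 15: None}
        u = units([("a", report + dt.timedelta(days=o), "2") for o in offsets])
        out = assign_cohort(u, CohortDesign("acute", "flu"), symptoms=symptoms)
        got = dict(zip(out["start_date"], out["group"]))
        for o, expected in offsets.items():
            d = report + dt.timedelta(days=o)
            assert got.get(d) == expected, o

    def test_acute_individual_without_baseline_dropped(self):
        symptoms = pd.DataFrame(
            {"individual_id": ["a"], "condition": ["flu"], "report_date": [day(100)]}
        )
        u = units([("a", day(100), "2"), ("a", day(105), "3")])
        out = assign_cohort(u, CohortDesign("acute", "flu"), symptoms=symptoms)
        assert out.empty

    def test_acute_clean_rule_excludes_overlapping_reports(self):
        symptoms = pd.DataFrame(
            {
                "individual_id": ["a", "a"],
                "condition": ["flu", "fever"],
                "report_date": [day(100), day(70)],  # fever 30 d before flu
            }
        )
        u = units([("a", day(10), "2"), ("a", day(100), "2")])
        out = assign_cohort(u, CohortDesign("acute", "flu"), symptoms=symptoms)
        assert out.empty


def table(counts, groups=("pos", "neg")):
    counts = np.asarray(counts)
    return ContingencyTable(
        categories=tuple(f"c{i}" for i in range(counts.shape[1])),
        groups=groups,
        counts=counts,
    )


class TestChiSquare:
    def test_equal_distributions_give_zero_statistic_p_one(self):
        stat, dof, p = chi_square_test(table([[10, 20, 30], [10, 20, 30]]))
        assert stat == 0.0 and dof == 2 and p == 1.0

    def test_hand_computed_example(self):
        stat, dof, p = chi_square_test(table([[12, 8], [10, 10]]))
        assert stat == pytest.approx(0.8)
        assert dof == 1
        assert p == pytest.approx(0.3711, abs=1e-4)

    def test_matches_scipy_chisquare_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            k = int(rng.integers(2, 8))
            obs = rng.integers(1, 60, size=k)
            ref = rng.integers(1, 60, size=k)
            stat, dof, p = chi_square_test(table(np.vstack([obs, ref])))
            expected = ref / ref.sum() * obs.sum()
            ref_stat, ref_p = stats.chisquare(obs, expected)
            assert stat == pytest.approx(ref_stat, rel=1e-12)
            assert p == pytest.approx(ref_p, abs=1e-9)

    def test_zero_expected_nonzero_observed_raises_unless_pseudocount(self):
        t = table([[5, 5], [0, 10]])
        with pytest.raises(DataError):
            chi_square_test(t)
        stat, _, _ = chi_square_test(t, pseudocount=0.5)
        assert np.isfinite(stat)

    def test_type_one_error_near_nominal_under_null(self):
        rng = np.random.default_rng(1)
        p_true = np.array([0.4, 0.3, 0.2, 0.1])
        rejections = 0
        reps = 200
        for _ in range(reps):
            obs = rng.multinomial(400, p_true)
            ref = rng.multinomial(20000, p_true)
            _, _, p = chi_square_test(table(np.vstack([obs, ref])))
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.04)


class TestInformationGain:
    def test_independent_table_has_zero_gain(self):
        row = np.array([5, 10, 25, 60.0])
        t = table(np.vstack([3 * row, 7 * row]))
        assert information_gain(t) == pytest.approx(0.0, abs=1e-12)

    def test_perfect_association_equals_group_entropy(self):
        assert information_gain(table([[10, 0], [0, 10]])) == pytest.approx(1.0)
        # unbalanced groups: IG equals H[P] of the marginal
        t = table([[30, 0], [0, 10]])
        h_p = -(0.75 * np.log2(0.75) + 0.25 * np.log2(0.25))
        assert information_gain(t) == pytest.approx(h_p, abs=1e-12)

    def test_matches_brute_force_mutual_information(self):
        rng = np.random.default_rng(2)
        for _ in range(300):
            k = int(rng.integers(2, 7))
            counts = rng.integers(0, 40, size=(2, k))
            counts[:, 0] += 1  # keep both groups non-empty
            t = table(counts)
            assert information_gain(t) == pytest.approx(
                oracle_information_gain(counts), abs=1e-12
            )

    def test_bounded_by_marginal_entropies(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            counts = rng.integers(1, 30, size=(2, 5))
            t = table(counts)
            total = counts.sum()
            h = lambda p: -np.sum(p[p > 0] * np.log2(p[p > 0]))
            ig = information_gain(t)
            assert -1e-12 <= ig <= min(
                h(counts.sum(axis=1) / total), h(counts.sum(axis=0) / total)
            ) + 1e-12


class TestContingency:
    def test_empty_categories_dropped_and_dof_reduced(self):
        u = pd.DataFrame(
            {
                "group": ["pos"] * 3 + ["neg"] * 3,
                "subcluster": ["2", "2", "3", "3", "3", "2"],
            }
        )
        t = build_contingency_table(u, "subcluster", groups=("pos", "neg"))
        assert t.categories == ("2", "3") and t.dof == 1
        assert t.dropped_categories == ()


class TestStaticVsDynamic:
    @staticmethod
    def _population(t_pos, t_neg, pi_pos, pi_neg, n_per_group=800, length=6, seed=0):
        from sleepscape.simulate import simulate_phenotype_sequences

        rng = np.random.default_rng(seed)
        names = ("0-center", "1-a")
        rows, survey_rows = [], []
        for group, t, pi in (("pos", t_pos, pi_pos), ("neg", t_neg, pi_neg)):
            seqs = simulate_phenotype_sequences(n_per_group, length, t, pi, rng)
            for k, seq in enumerate(seqs):
                ind = f"{group}{k}"
                survey_rows.append(
                    {
                        "individual_id": ind,
                        "condition": "x",
                        "response": "positive" if group == "pos" else "negative",
                    }
                )
                for i, s in enumerate(seq):
                    rows.append(
                        {
                            "individual_id": ind,
                            "period_index": i,
                            "start_date": day(6 * i),
                            "subcluster": names[s],
                        }
                    )
        return pd.DataFrame(rows), pd.DataFrame(survey_rows)

    def test_dynamics_only_effect_raises_ig_ratio_above_one(self):
        from sleepscape.dynamics import extract_transition_pairs

        # same uniform stationary distribution, very different mixing
        t_pos = np.array([[0.9, 0.1], [0.1, 0.9]])
        t_neg = np.array([[0.5, 0.5], [0.5, 0.5]])
        pi = np.array([0.5, 0.5])
        periods, survey = self._population(t_pos, t_neg, pi, pi)
        rep = static_vs_dynamic(
            periods,
            extract_transition_pairs(periods),
            CohortDesign("chronic", "x"),
            survey=survey,
        )
        assert rep["ig_dynamic_bits"] > 5 * rep["ig_static_bits"]
        assert rep["ig_ratio"] > 1

    def test_prevalence_only_effect_keeps_ig_ratio_near_one(self):
        from sleepscape.dynamics import extract_transition_pairs

        # identity chains: transitions conditionally identical, only the
        # phenotype prevalence differs between groups
        eye = np.eye(2)
        periods, survey = self._population(
            eye, eye, np.array([0.7, 0.3]), np.array([0.3, 0.7]), seed=1
        )
        rep = static_vs_dynamic(
            periods,
            extract_transition_pairs(periods),
            CohortDesign("chronic", "x"),
            survey=survey,
        )
        assert rep["ig_ratio"] == pytest.approx(1.0, abs=0.02)
        assert rep["p_static"] < 1e-6 and rep["p_dynamic"] < 1e-6
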