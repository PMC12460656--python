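"""Synthetic EEG, evoked trial sets, and report-table generators."""

import numpy as np
import pytest
from scipy.signal import welch

import dreamcomplexity as dc
from dreamcomplexity.reports import Q1_CATEGORIES, Q2_CATEGORIES
from dreamcomplexity.synthetic import ReportMarginals, TepSpec


class TestSpontaneous:
    def test_seed_determinism_bitwise(self):
        prof = dc.default_profiles()["wake_ec"]
        a = dc.gen_spontaneous(prof, 4, 10.0, 250.0, seed=7)
        b = dc.gen_spontaneous(prof, 4, 10.0, 250.0, seed=7)
        assert np.array_equal(a.data, b.data)

    def test_silent_profile_gives_zero_signal(self):
        prof = dc.StateProfile("flat", {b: 0.0 for b in
                                        ("delta", "theta", "alpha", "beta")},
                               one_over_f_exponent=1.0, broadband_rms=0.0)
        e = dc.gen_spontaneous(prof, 3, 10.0, 250.0, seed=1)
        assert np.all(e.data == 0.0)

    def test_epoch_layout(self):
        prof = dc.default_profiles()["wake_eo"]
        e = dc.gen_spontaneous(prof, 2, 17.0, 250.0, seed=0)
        assert e.data.shape == (3, 2, 1250)  # floor(17 / 5) epochs of 5 s

    @pytest.mark.parametrize("kwargs", [
        dict(n_channels=0), dict(duration=3.0), dict(fs=50.0),
    ])
    def test_invalid_arguments_rejected(self, kwargs):
        prof = dc.default_profiles()["wake_eo"]
        args = dict(n_channels=2, duration=10.0, fs=250.0)
        args.update(kwargs)
        with pytest.raises(ValueError):
            dc.gen_spontaneous(prof, args["n_channels"], args["duration"],
                               args["fs"], seed=0)

    def test_default_profiles_satisfy_stated_contrasts(self):
        p = dc.default_profiles()
        assert p["sedation"].band_powers["delta"] \
            > p["wake_eo"].band_powers["delta"]
        assert p["wake_ec"].band_powers["alpha"] \
            > p["wake_eo"].band_powers["alpha"]

    def test_eyes_closed_has_more_alpha_power(self):
        """Welch alpha power EC > EO at matched broadband RMS, 50 seeds."""
        profiles = dc.default_profiles()
        assert profiles["wake_eo"].broadband_rms \
            == profiles["wake_ec"].broadband_rms
        wins = 0
        for seed in range(50):
            powers = {}
            for name in ("wake_eo", "wake_ec"):
                e = dc.gen_spontaneous(profiles[name], 8, 30.0, 250.0,
                                       seed=seed)
                f, pxx = welch(e.data.reshape(-1, e.n_samples), fs=250.0,
                               nperseg=512)
                band = (f >= 8) & (f <= 12)
                powers[name] = pxx[:, band].mean()
            wins += powers["wake_ec"] > powers["wake_eo"]
        assert wins >= 45


class TestTep:
    def test_seed_determinism_bitwise(self):
        spec = dc.wake_tep_spec(4, 10, seed=3)
        a = dc.gen_tep(spec, 4, 500.0, seed=3)
        b = dc.gen_tep(spec, 4, 500.0, seed=3)
        assert np.array_equal(a.data, b.data)

    def test_noise_only_average_obeys_sqrt_n_law(self):
        spec = TepSpec(components=[], trial_noise_rms=10.0, n_trials=500)
        t = dc.gen_tep(spec, 4, 500.0, seed=2)
        avg = t.data.mean(axis=0)
        assert np.sqrt(np.mean(avg ** 2)) < spec.trial_noise_rms / 10.0

    def test_noiseless_single_component_trials_identical(self):
        spec = dc.make_tep_spec(1, n_channels=4, n_trials=5,
                                trial_noise_rms=0.0, seed=1)
        t = dc.gen_tep(spec, 4, 500.0, seed=1)
        assert np.array_equal(t.data[0], t.data[1])
        assert np.all(t.data[:, :, :t.onset_idx] == 0.0)

    def test_latency_outside_window_rejected(self):
        spec = dc.make_tep_spec(1, n_channels=4, seed=0)
        bad = TepSpec(components=[
            dc.synthetic.TepComponent(10.0, 100.0, 600.0, 5.0,
                                      spec.components[0].topography)],
            n_trials=2)
        with pytest.raises(ValueError):
            dc.gen_tep(bad, 4, 500.0, epoch_window=(-250.0, 500.0), seed=0)

    def test_window_must_span_stimulus(self):
        with pytest.raises(ValueError):
            dc.gen_tep(TepSpec(n_trials=2), 4, 500.0,
                       epoch_window=(10.0, 500.0), seed=0)

    def test_baseline_is_stationary_around_zero(self, wake_tep):
        base = wake_tep.data[:, :, :wake_tep.onset_idx]
        se = base.std() / np.sqrt(base.size / 50)  # ~50-sample correlation
        assert abs(base.mean()) < 3 * se

    def test_matched_energy_specs_have_equal_evoked_energy(self):
        def energy(spec):
            t = dc.gen_tep(TepSpec(spec.components, trial_noise_rms=0.0,
                                   n_trials=1), 8, 500.0, seed=0)
            return np.sum(t.data[0] ** 2)

        e8 = energy(dc.make_tep_spec(8, total_energy=5e4, seed=1))
        e1 = energy(dc.make_tep_spec(1, total_energy=5e4, seed=1))
        assert e8 == pytest.approx(e1, rel=0.01)


class TestReportsGeneration:
    def test_default_cohort_counts(self):
        counts = dc.default_awakening_counts()
        assert len(counts) == 20 and sum(counts) == 52
        reports = dc.gen_reports(dc.default_marginals(), counts, seed=0)
        assert len(reports) == 52
        assert len({r.participant_id for r in reports}) == 20

    def test_single_forced_report(self):
        m = ReportMarginals(
            q1_counts={"nothing": 0, "no_info": 0, "white": 0, "vague": 0,
                       "vivid": 1},
            q2_counts={"no": 0, "no_info": 0, "maybe": 0, "yes": 1},
            class_totals={"experience": 1, "no_information": 0,
                          "no_experience": 0},
            n_awakenings=1)
        (r,) = dc.gen_reports(m, [1], seed=0)
        assert (r.q1, r.q2) == ("vivid", "yes")

    def test_infeasible_marginals_error_names_total(self):
        m = ReportMarginals(
            q1_counts={"nothing": 1, "no_info": 28, "white": 2, "vague": 9,
                       "vivid": 12},
            q2_counts={"no": 8, "no_info": 22, "maybe": 4, "yes": 17},
            class_totals={"experience": 24, "no_information": 23,
                          "no_experience": 5},
            n_awakenings=52)
        with pytest.raises(ValueError, match="q2_counts"):
            dc.gen_reports(m, dc.default_awakening_counts(), seed=0)

    def test_participant_counts_must_match_awakenings(self):
        with pytest.raises(ValueError, match="infeasible"):
            dc.gen_reports(dc.default_marginals(), [3] * 10, seed=0)

    def test_classification_of_generated_reports_hits_class_totals(self):
        reports = dc.gen_reports(dc.default_marginals(),
                                 dc.default_awakening_counts(), seed=5)
        tab = dc.tabulate(reports)
        assert tab.class_counts == {"experience": 24, "no_information": 23,
                                    "no_experience": 5}

    def test_determinism(self):
        a = dc.gen_reports(dc.default_marginals(),
                           dc.default_awakening_counts(), seed=9)
        b = dc.gen_reports(dc.default_marginals(),
                           dc.default_awakening_counts(), seed=9)
        assert a == b


class TestJointTable:
    def test_default_table_reproduces_all_marginals(self):
        m = dc.default_marginals()
        table = dc.fixture_joint_table(m)
        assert table.sum() == 52
        assert table.sum(axis=1).tolist() == [m.q1_counts[q]
                                              for q in Q1_CATEGORIES]
        assert table.sum(axis=0).tolist() == [m.q2_counts[q]
                                              for q in Q2_CATEGORIES]

    def test_default_table_class_totals(self):
        m = dc.default_marginals()
        table = dc.fixture_joint_table(m)
        rule = dc.default_rule()
        totals = {"experience": 0, "no_information": 0, "no_experience": 0}
        for i, q1 in enumerate(Q1_CATEGORIES):
            for j, q2 in enumerate(Q2_CATEGORIES):
                totals[rule.classify(q1, q2)] += int(table[i, j])
        assert totals == m.class_totals

    def test_three_positive_reports_with_negative_q2_are_forced(self):
        """23 positive Q1 + one (no_info, yes) must reach 24 'experience',
        and 8 Q2-no minus 5 'no_experience' leaves exactly 3 conflicts."""
        table = dc.fixture_joint_table(dc.default_marginals())
        positive_rows = [Q1_CATEGORIES.index(q)
                         for q in ("white", "vague", "vivid")]
        assert int(table[positive_rows, 0].sum()) == 3

    def test_degenerate_marginals_force_single_table(self):
        m = ReportMarginals(
            q1_counts={"nothing": 0, "no_info": 0, "white": 0, "vague": 7,
                       "vivid": 0},
            q2_counts={"no": 0, "no_info": 0, "maybe": 7, "yes": 0},
            class_totals={"experience": 7, "no_information": 0,
                          "no_experience": 0},
            n_awakenings=7)
        table = dc.fixture_joint_table(m)
        expected = np.zeros((5, 4), dtype=int)
        expected[Q1_CATEGORIES.index("vague"), Q2_CATEGORIES.index("maybe")] = 7
        assert np.array_equal(table, expected)

    def test_marginals_from_random_tables_are_always_solvable(self, rng):
        rule = dc.default_rule()
        for _ in range(10):
            source = rng.integers(0, 6, size=(5, 4))
            n = int(source.sum())
            q1 = {q: int(source[i].sum())
                  for i, q in enumerate(Q1_CATEGORIES)}
            q2 = {q: int(source[:, j].sum())
                  for j, q in enumerate(Q2_CATEGORIES)}
            totals = {"experience": 0, "no_information": 0,
                      "no_experience": 0}
            for i, a in enumerate(Q1_CATEGORIES):
                for j, b in enumerate(Q2_CATEGORIES):
                    totals[rule.classify(a, b)] += int(source[i, j])
            m = ReportMarginals(q1, q2, totals, n)
            table = dc.fixture_joint_table(m)
            assert np.array_equal(table.sum(axis=1), source.sum(axis=1))
            assert np.array_equal(table.sum(axis=0), source.sum(axis=0))

    def test_unsolvable_marginals_raise(self):
        m = ReportMarginals(
            q1_counts={"nothing": 2, "no_info": 0, "white": 0, "vague": 0,
                       "vivid": 0},
            q2_counts={"no": 0, "no_info": 0, "maybe": 0, "yes": 2},
            class_totals={"experience": 0, "no_information": 0,
                          "no_experience": 2},
            n_awakenings=2)
        # (nothing, yes) classifies as experience, so 2 no_experience is
        # unreachable
        with pytest.raises(ValueError, match="no joint table"):
            dc.fixture_joint_table(m)
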