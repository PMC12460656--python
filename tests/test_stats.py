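"""Mixed models, Wilcoxon signed rank, Holm correction, IQR screening."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

import dreamcomplexity as dc

from helpers import holm_oracle

CLASSES = ("no_experience", "no_information", "experience")


def _lmm_table(n_part, betas, sigma_u, sigma_e, rng, balanced=True):
    rows = []
    for p in range(n_part):
        u = rng.normal(0, sigma_u) if sigma_u else 0.0
        if balanced:
            draws = list(zip(CLASSES, betas))
        else:
            draws = [(CLASSES[rng.integers(len(CLASSES))], None)]
            draws = [(c, betas[CLASSES.index(c)]) for c, _ in draws * 3]
        for cls, b in draws:
            rows.append((f"P{p:03d}", b + u + rng.normal(0, sigma_e), cls))
    return pd.DataFrame(rows, columns=["participant_id", "value",
                                       "experience_class"])


class TestWilcoxon:
    @pytest.mark.parametrize("n,expected", [(20, -3.92), (17, -3.62),
                                            (15, -3.41)])
    def test_fully_concordant_closed_form(self, n, expected):
        x = np.arange(n, dtype=float) + 10.0
        y = x - np.linspace(1.0, 2.0, n)  # all negative, distinct ranks
        res = dc.wilcoxon_z(x, y)
        assert round(res.Z, 2) == expected
        assert res.t_plus == 0.0

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=12)
        assert dc.wilcoxon_z(x, y).Z == -dc.wilcoxon_z(y, x).Z

    def test_matches_scipy_normal_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.choice([-0.5, 0.5, 1.0, -1.0], size=30)  # forces ties
        mine = dc.wilcoxon_z(x, y)
        ref = sps.wilcoxon(x, y, zero_method="wilcox", correction=False,
                           method="approx")
        assert mine.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_single_discordant_pair_sets_sign(self):
        x = np.arange(6, dtype=float)
        y = x.copy()
        y[3] += 2.0
        assert dc.wilcoxon_z(x, y).Z > 0
        y[3] -= 4.0
        assert dc.wilcoxon_z(x, y).Z < 0

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            dc.wilcoxon_z(np.ones(8), np.ones(8))
        with pytest.raises(ValueError, match="pairs"):
            dc.wilcoxon_z(np.arange(3.0), np.arange(3.0) + 1)


class TestHolm:
    def test_six_test_step_down(self):
        # thresholds 0.05/6, /5, /4, ...: 0.001 and 0.004 pass, then
        # 0.02 > 0.0125 stops the step-down
        pvals = list(zip("abcdef", [0.001, 0.004, 0.02, 0.03, 0.2, 0.9]))
        decisions = dc.holm(pvals)
        assert [d.reject for d in decisions] == [True, True, False, False,
                                                 False, False]

    def test_single_test_reduces_to_alpha(self):
        (d,) = dc.holm([("only", 0.04)])
        assert d.reject and d.threshold == 0.05

    def test_nothing_rejected_at_p_one(self):
        decisions = dc.holm([("a", 1.0), ("b", 1.0), ("c", 1.0)])
        assert not any(d.reject for d in decisions)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    def test_matches_enumeration_oracle(self, pvals):
        named = [(str(i), p) for i, p in enumerate(pvals)]
        mine = [d.reject for d in dc.holm(named)]
        assert mine == holm_oracle(pvals)

    def test_decisions_are_monotone_in_p(self, rng):
        for _ in range(50):
            pvals = rng.uniform(size=6)
            before = holm_oracle(list(pvals))
            i = rng.integers(6)
            pvals[i] *= rng.uniform()
            after = holm_oracle(list(pvals))
            assert all(a or not b for a, b in
                       zip(after, before)) or after[i] >= before[i]
            # lowering one p never un-rejects any other test
            assert all(after[j] or not before[j] for j in range(6) if j != i)


class TestIqrOutliers:
    def test_single_extreme_value_flagged(self):
        flags = dc.iqr_outliers([1, 2, 3, 4, 100])
        assert flags.tolist() == [False, False, False, False, True]

    def test_constant_list_unflagged(self):
        assert not dc.iqr_outliers([5.0] * 6).any()

    def test_symmetric_list_unflagged(self):
        assert not dc.iqr_outliers([-2, -1, 0, 1, 2]).any()

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            dc.iqr_outliers([1, 2, 3])


class TestLmm:
    def test_noiseless_group_structure_recovered(self, rng):
        df = _lmm_table(6, (10.0, 20.0, 30.0), 0.0, 1e-6, rng)
        res = dc.fit_lmm(df)
        emms = res.emms.set_index("level")["emm"]
        assert emms["no_experience"] == pytest.approx(10.0, abs=1e-3)
        assert emms["no_information"] == pytest.approx(20.0, abs=1e-3)
        assert emms["experience"] == pytest.approx(30.0, abs=1e-3)
        assert res.p < 1e-6

    def test_ols_variant_equals_oneway_anova(self, rng):
        df = _lmm_table(8, (0.0, 1.0, 2.0), 0.5, 1.0, rng)
        res = dc.fit_lmm(df, dc.LmmSpec(random_intercept=None))
        groups = [g["value"].to_numpy()
                  for _, g in df.groupby("experience_class")]
        f_ref, p_ref = sps.f_oneway(*groups)
        assert res.F == pytest.approx(f_ref, abs=1e-6)
        assert res.p == pytest.approx(p_ref, rel=1e-6)

    def test_balanced_emms_equal_raw_class_means(self, rng):
        df = _lmm_table(10, (1.0, 2.0, 3.0), 1.0, 0.5, rng)
        res = dc.fit_lmm(df)
        raw = df.groupby("experience_class")["value"].mean()
        for _, row in res.emms.iterrows():
            assert row["emm"] == pytest.approx(raw[row["level"]], abs=1e-9)

    def test_unbalanced_emm_downweights_dominant_participant(self, rng):
        # participant D contributes most 'experience' rows with a high
        # random intercept; the EMM should sit below the raw class mean
        rows = []
        for p, u in zip("ABC", (0.0, 0.0, 0.0)):
            for cls, b in (("no_experience", 0.0), ("experience", 1.0)):
                for _ in range(3):
                    rows.append((p, b + u + rng.normal(0, 0.3), cls))
        for _ in range(12):
            rows.append(("D", 1.0 + 3.0 + rng.normal(0, 0.3), "experience"))
        rows.append(("D", 0.0 + 3.0 + rng.normal(0, 0.3), "no_experience"))
        df = pd.DataFrame(rows, columns=["participant_id", "value",
                                         "experience_class"])
        res = dc.fit_lmm(df)
        raw = df[df.experience_class == "experience"]["value"].mean()
        emm_exp = res.emms.set_index("level").loc["experience", "emm"]
        assert emm_exp < raw

    def test_single_class_emm_is_intercept(self, rng):
        rows = [(f"P{p}", 5.0 + rng.normal(), "experience")
                for p in range(6) for _ in range(2)]
        df = pd.DataFrame(rows, columns=["participant_id", "value",
                                         "experience_class"])
        res = dc.fit_lmm(df)
        assert np.isnan(res.F)
        assert res.emms["emm"].iloc[0] == pytest.approx(
            res.coefficients["estimate"].iloc[0])

    def test_singular_fit_flagged_not_failed(self, rng):
        df = _lmm_table(8, (0.0, 0.0, 0.0), 0.0, 1.0, rng)
        res = dc.fit_lmm(df)
        assert res.singular in (True, False)  # no exception either way
        assert 0 <= res.p <= 1 and res.F >= 0

    def test_emm_accessor_returns_copy(self, rng):
        res = dc.fit_lmm(_lmm_table(6, (0, 1, 2), 1.0, 1.0, rng))
        frame = dc.emm(res)
        frame.loc[0, "emm"] = -999
        assert res.emms.loc[0, "emm"] != -999


def _measure_table(n_part=12, wake_shift=2.0, rng=None, duplicate=False):
    rng = rng or np.random.default_rng(0)
    rows = []
    for p in range(n_part):
        pid = f"P{p:02d}"
        for measure in ("lzc", "pcist"):
            base = 10.0 if measure == "pcist" else 0.25
            rows.append((pid, "wake_eo", measure,
                         base + wake_shift + rng.normal(0, 0.1), None))
            rows.append((pid, "wake_ec", measure,
                         base + wake_shift * 0.8 + rng.normal(0, 0.1), None))
            for k in (1, 2):
                cls = CLASSES[rng.integers(3)]
                rows.append((pid, f"sedation_{k}", measure,
                             base + rng.normal(0, 0.1), cls))
    df = pd.DataFrame(rows, columns=["participant_id", "condition",
                                     "measure", "value", "experience_class"])
    if duplicate:
        df = pd.concat([df, df], ignore_index=True)
    return df


class TestRunPaperTests:
    def test_battery_layout(self):
        report = dc.run_full_battery(_measure_table())
        assert set(report.wilcoxon) == {"pcist_w_vs_sed", "lzc_wo_vs_wc",
                                        "lzc_wo_vs_sed", "lzc_wc_vs_sed"}
        assert set(report.lmm) == {"lmm_class_pcist", "lmm_class_lzc"}
        assert len(report.holm_decisions) == 6

    def test_single_participant_skips_wilcoxon(self):
        table = _measure_table(n_part=1)
        report = dc.run_full_battery(table)
        assert len(report.skipped) >= 4
        assert not report.wilcoxon

    def test_duplicated_rows_leave_report_unchanged(self):
        a = dc.run_full_battery(_measure_table()).to_frame()
        b = dc.run_full_battery(_measure_table(duplicate=True)).to_frame()
        pd.testing.assert_frame_equal(a, b)

    def test_outlier_flags_present_per_distribution(self):
        report = dc.run_full_battery(_measure_table())
        assert set(report.outliers) == {"pcist_wake", "pcist_sedation",
                                        "lzc_wake_eo", "lzc_wake_ec",
                                        "lzc_sedation"}
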