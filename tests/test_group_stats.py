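"""Group-level statistics: rank-sum, pooled t, Fisher exact, Pearson,
Holm adjustment and the hierarchical band→pair workflow."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from phaselag.group_stats import (
    compare_groups,
    fa_group_screen,
    fisher_exact_2x2,
    holm_bonferroni,
    pearson_corr_test,
    structure_function_correlation,
    two_sample_t_from_data,
    two_sample_t_pooled,
    wilcoxon_rank_sum,
)

from conftest import enumerate_rank_sum_p


class TestWilcoxon:
    def test_exact_small_sample_hand_case(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0], [3.0, 4.0])
        assert p == pytest.approx(2 / 6)

    def test_identical_groups_give_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_exact_path_matches_enumeration_oracle(self, rng):
        for n1 in range(2, 6):
            for n2 in range(2, 6):
                if n1 + n2 > 10:
                    continue
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                _, p = wilcoxon_rank_sum(x, y)
                assert p == pytest.approx(enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_exact_and_asymptotic_paths_agree(self, rng):
        # 6 vs 6 sits at the exact-path threshold; the normal approximation
        # with continuity correction should track it closely
        diffs = []
        for _ in range(100):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            _, p_exact = wilcoxon_rank_sum(x, y)
            p_approx = stats.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
            diffs.append(abs(p_exact - p_approx))
        assert max(diffs) < 0.02

    def test_too_small_groups_error(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([1.0], [2.0, 3.0])


class TestPooledT:
    def test_hand_arithmetic(self):
        t, df, _ = two_sample_t_pooled(0.0, 1.0, 10, 1.0, 1.0, 10)
        assert t == pytest.approx(1.0 / np.sqrt(0.2), abs=1e-4)
        assert df == 18

    def test_equal_means_give_zero(self):
        t, _, p = two_sample_t_pooled(5.0, 1.0, 8, 5.0, 2.0, 8)
        assert t == 0.0
        assert p == 1.0

    def test_raw_vectors_match_summary_form(self, rng):
        case = rng.normal(0, 1, 15)
        control = rng.normal(0.5, 1.2, 22)
        t_raw, df_raw, p_raw = two_sample_t_from_data(case, control)
        t_sum, df_sum, p_sum = two_sample_t_pooled(
            case.mean(), case.std(ddof=1), 15, control.mean(), control.std(ddof=1), 22
        )
        assert t_raw == pytest.approx(t_sum, abs=1e-12)
        assert df_raw == df_sum
        assert p_raw == pytest.approx(p_sum, abs=1e-12)

    def test_zero_pooled_variance_errors(self):
        with pytest.raises(ValueError):
            two_sample_t_pooled(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestFisherExact:
    def test_symmetric_table(self):
        p, _ = fisher_exact_2x2([[1, 0], [0, 1]])
        assert p == 1.0

    def test_diagonal_table_enumeration(self):
        # margins 5/5, 5/5: only the two diagonal tables are as extreme;
        # each has probability 1/C(10,5)
        p, point = fisher_exact_2x2([[5, 0], [0, 5]])
        assert p == pytest.approx(2 / 252, abs=1e-12)
        assert point == pytest.approx(1 / 252, abs=1e-12)

    def test_point_probability_and_two_sided_both_reported(self):
        p, point = fisher_exact_2x2([[2, 13], [3, 19]])
        assert 0 < point <= p <= 1

    def test_probabilities_sum_to_one_over_fixed_margins(self):
        for r1, r2, c1 in [(15, 22, 33), (4, 6, 5), (12, 17, 20)]:
            n = r1 + r2
            ks = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
            total = stats.hypergeom.pmf(ks, n, r1, c1).sum()
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_margin(self):
        p, point = fisher_exact_2x2([[0, 0], [3, 4]])
        assert p == 1.0 and point == 1.0


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, _, p, n = pearson_corr_test(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-12 and n == 10

    def test_exactly_orthogonal_gives_zero(self):
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0])
        y = y - y.mean()
        y -= (y @ x) / (x @ x) * x  # force r = 0 exactly
        r, _, p, _ = pearson_corr_test(x, y)
        assert abs(r) < 1e-12
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_t_statistic_for_known_r(self, rng):
        # construct a sample whose Pearson r is exactly 0.68 at n = 12
        n, r_target = 12, 0.68
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z = z - z.mean()
        z -= (z @ x) / (x @ x) * x
        z /= z.std()
        y = r_target * x + np.sqrt(1 - r_target**2) * z
        r, t, p, _ = pearson_corr_test(x, y)
        assert r == pytest.approx(0.68, abs=1e-10)
        assert t == pytest.approx(2.933, abs=1e-3)
        assert p < 0.05

    def test_fisher_z_variant(self, rng):
        x = rng.normal(size=20)
        y = x + rng.normal(0, 1.0, 20)
        r, z, p, n = pearson_corr_test(x, y, method="fisher-z")
        assert z == pytest.approx(np.arctanh(r) * np.sqrt(n - 3), abs=1e-12)

    def test_missing_values_dropped_pairwise(self, rng):
        x = np.array([1.0, 2, 3, 4, 5, np.nan])
        y = np.array([2.0, 4, 6, 8, 10, 1])
        r, _, _, n = pearson_corr_test(x, y)
        assert n == 5 and r == pytest.approx(1.0)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_corr_test([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestHolm:
    def test_step_down_by_hand(self):
        adj = holm_bonferroni([0.01, 0.04, 0.03])
        assert adj == pytest.approx([0.03, 0.06, 0.06])

    def test_single_p_unchanged(self):
        assert holm_bonferroni([0.2]) == pytest.approx([0.2])

    def test_empty_list(self):
        assert holm_bonferroni([]) == []

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=20))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_adjusted_never_below_raw_and_capped(self, pvals):
        adj = holm_bonferroni(pvals)
        assert all(a >= p - 1e-12 for a, p in zip(adj, pvals))
        assert all(a <= 1.0 for a in adj)


def _conn_table(values_by_subject, bands=("theta", "low_gamma")):
    rows = []
    for sid, v in values_by_subject.items():
        for band in bands:
            rows.append((sid, "Fz", "Cz", band, v))
            rows.append((sid, "Fz", "Pz", band, v * 0.9))
    return pd.DataFrame(rows, columns=["subject_id", "channel_a", "channel_b", "band", "value"])


def _cohort(case_ids, control_ids):
    rows = [(s, "case") for s in case_ids] + [(s, "control") for s in control_ids]
    return pd.DataFrame(rows, columns=["subject_id", "group"])


class TestCompareGroups:
    def test_identical_groups_give_p_one_and_no_stage_two(self):
        vals = {f"s{i}": 0.1 * i for i in range(6)}
        conn = _conn_table(vals)
        cohort = _cohort(["s0", "s1", "s2"], ["s3", "s4", "s5"])
        # copy case values onto controls so groups are identical
        conn2 = conn.copy()
        mapping = dict(zip(["s3", "s4", "s5"], ["s0", "s1", "s2"]))
        conn2["value"] = conn2.apply(
            lambda r: conn[
                (conn.subject_id == mapping.get(r.subject_id, r.subject_id))
                & (conn.band == r.band)
                & (conn.channel_b == r.channel_b)
            ]["value"].iloc[0],
            axis=1,
        )
        rep = compare_groups(conn2, cohort)
        assert (rep.band_tests["p"] == 1.0).all()
        assert rep.pair_tests.empty

    def test_strong_effect_triggers_stage_two_in_target_band_only(self):
        case = {f"c{i}": 0.01 * i for i in range(8)}
        ctrl = {f"k{i}": 1.0 + 0.01 * i for i in range(8)}
        rows = []
        for sid in {**case, **ctrl}:
            base = case.get(sid, ctrl.get(sid))
            for band in ("theta", "low_gamma"):
                v = base if band == "low_gamma" else 0.5  # no theta effect
                rows.append((sid, "Fz", "Cz", band, v))
                rows.append((sid, "Fz", "Pz", band, v))
        conn = pd.DataFrame(rows, columns=["subject_id", "channel_a", "channel_b", "band", "value"])
        cohort = _cohort(list(case), list(ctrl))
        rep = compare_groups(conn, cohort)
        sig = dict(zip(rep.band_tests["band"], rep.band_tests["significant"]))
        assert sig["low_gamma"] and not sig["theta"]
        assert set(rep.pair_tests["band"]) == {"low_gamma"}
        assert len(rep.pair_tests) == 2

    def test_missing_subject_excluded_with_warning(self, caplog):
        vals = {f"s{i}": float(i) for i in range(6)}
        conn = _conn_table(vals)
        cohort = _cohort(["s0", "s1", "s2"], ["s3", "s4", "s5", "s-missing"])
        with caplog.at_level("WARNING", logger="phaselag"):
            rep = compare_groups(conn, cohort)
        assert any("s-missing" in m for m in caplog.messages)
        assert rep.band_tests["n_control"].iloc[0] == 3


class TestFaScreen:
    def _tables(self, rng, n_case=6, n_control=8, effect_roi=None, effect=0.0):
        from phaselag.reference_data import DEFAULT_ROI_VOCABULARY

        sids = [(f"c{i}", "case") for i in range(n_case)] + [
            (f"k{i}", "control") for i in range(n_control)
        ]
        cohort = pd.DataFrame(sids, columns=["subject_id", "group"])
        rows = []
        for sid, group in sids:
            for roi, side in DEFAULT_ROI_VOCABULARY:
                fa = 0.3 + rng.normal(0, 0.01)
                if (roi, side) == effect_roi and group == "control":
                    fa += effect
                rows.append((sid, roi, side, fa))
        fa = pd.DataFrame(rows, columns=["subject_id", "roi", "side", "fa"])
        return fa, cohort

    def test_default_vocabulary_yields_28_tests(self, rng):
        fa, cohort = self._tables(rng)
        out = fa_group_screen(fa, cohort)
        assert len(out) == 28
        assert (out["p_adjusted"] >= out["p"] - 1e-15).all()

    def test_single_affected_roi_attains_smallest_p(self, rng):
        roi = ("inferior cerebellar peduncle", "right")
        fa, cohort = self._tables(rng, effect_roi=roi, effect=0.05)
        out = fa_group_screen(fa, cohort)
        best = out.loc[out["p"].idxmin()]
        assert (best["roi"], best["side"]) == roi

    def test_identical_groups_give_p_one(self):
        from phaselag.reference_data import DEFAULT_ROI_VOCABULARY

        sids = [("c0", "case"), ("c1", "case"), ("k0", "control"), ("k1", "control")]
        cohort = pd.DataFrame(sids, columns=["subject_id", "group"])
        rows = [
            (sid, roi, side, 0.3)
            for sid, _ in sids
            for roi, side in DEFAULT_ROI_VOCABULARY
        ]
        fa = pd.DataFrame(rows, columns=["subject_id", "roi", "side", "fa"])
        out = fa_group_screen(fa, cohort)
        assert (out["p"] == 1.0).all()


class TestStructureFunction:
    def test_constant_fa_errors(self):
        sync = pd.DataFrame({"subject_id": [f"s{i}" for i in range(5)], "z": np.arange(5.0)})
        fa = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(5)],
                "roi": ["icp"] * 5,
                "side": ["right"] * 5,
                "fa": [0.3] * 5,
            }
        )
        cohort = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(5)], "group": ["case"] * 5}
        )
        with pytest.raises(ValueError):
            structure_function_correlation(sync, fa, "icp", "right", "case", cohort)

    def test_linear_relation_recovered(self, rng):
        z = rng.normal(size=10)
        sync = pd.DataFrame({"subject_id": [f"s{i}" for i in range(10)], "z": z})
        fa = pd.DataFrame(
            {
                "subject_id": [f"s{i}" for i in range(10)],
                "roi": ["icp"] * 10,
                "side": ["right"] * 10,
                "fa": 0.3 + 0.01 * z,
            }
        )
        cohort = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(10)], "group": ["case"] * 10}
        )
        res = structure_function_correlation(sync, fa, "icp", "right", "case", cohort)
        assert res["r"] == pytest.approx(1.0)
        assert res["n"] == 10
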