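"""Metabolomics QC, batch correction, differential abundance and
category permutation enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gemreporter.metabolomics import (MetabolomicsMatrix, batch_correct,
                                      category_permutation_test,
                                      differential_abundance, qc_filter,
                                      read_metabolomics, write_metabolomics)


def make_matrix(values: dict[str, list], batch, stype, group):
    n = len(batch)
    samples = pd.DataFrame({"batch": batch, "sample_type": stype,
                            "group": group},
                           index=[f"s{i}" for i in range(n)])
    vals = pd.DataFrame(values, index=samples.index).T
    return MetabolomicsMatrix(vals, samples)


def simple_matrix():
    # 10 samples: 6 primary (3 per group), 4 QC; two batches
    batch = ["B1"] * 5 + ["B2"] * 5
    stype = ["primary"] * 3 + ["QC"] * 2 + ["primary"] * 3 + ["QC"] * 2
    group = ["IPH-"] * 3 + ["none"] * 2 + ["IPH+"] * 3 + ["none"] * 2
    values = {
        "stable":  [10, 11, 12, 10, 10, 13, 14, 15, 10, 10],
        "missing": [np.nan, np.nan, np.nan, 10, 10, 13, 14, 15, 10, 10],
        "noisy":   [10, 11, 12, 1, 100, 13, 14, 15, 1, 100],
    }
    return make_matrix(values, batch, stype, group)


class TestQcFilter:
    def test_hand_built_rules(self):
        filtered, log = qc_filter(simple_matrix())
        assert list(filtered.values.index) == ["stable"]
        rules = dict(zip(log["metabolite"], log["rule"]))
        assert rules["missing"] == "missingness"  # 3/10 = 30% > 20%
        assert rules["noisy"] == "rsd"

    def test_zero_rsd_retained(self):
        m = make_matrix({"m": [5, 6, 7, 10, 10, 10]},
                        ["B1"] * 6, ["primary"] * 3 + ["QC"] * 3,
                        ["IPH-"] * 3 + ["none"] * 3)
        filtered, log = qc_filter(m)
        assert "m" in filtered.values.index and log.empty

    def test_rules_commute(self):
        m = simple_matrix()
        a, _ = qc_filter(m, max_missing_frac=0.2, max_rsd=0.5)
        # apply rules in the other order via two passes
        b1, _ = qc_filter(m, max_missing_frac=1.0, max_rsd=0.5)
        b2, _ = qc_filter(b1, max_missing_frac=0.2, max_rsd=1e9)
        assert list(a.values.index) == list(b2.values.index)

    def test_no_qc_samples_skips_rsd(self):
        m = make_matrix({"m": [1, 100, 1, 100, 1, 100]},
                        ["B1"] * 6, ["primary"] * 6,
                        ["IPH-"] * 3 + ["IPH+"] * 3)
        filtered, _ = qc_filter(m)
        assert "m" in filtered.values.index


class TestBatchCorrect:
    def test_two_batch_arithmetic(self):
        # QC medians 10 and 20 -> global 15 -> factors 1.5 and 0.75
        batch = ["B1"] * 4 + ["B2"] * 4
        stype = (["primary", "QC", "QC", "primary"] * 2)
        group = (["IPH-", "none", "none", "IPH+"] * 2)
        m = make_matrix({"m": [8.0, 10, 10, 12, 16, 20, 20, 24]},
                        batch, stype, group)
        out = batch_correct(m)
        row = out.values.loc["m"]
        assert row["s0"] == pytest.approx(12.0)   # 8 * 1.5
        assert row["s4"] == pytest.approx(12.0)   # 16 * 0.75
        qc_b1 = row[["s1", "s2"]].median()
        qc_b2 = row[["s5", "s6"]].median()
        assert qc_b1 == pytest.approx(15.0) and qc_b2 == pytest.approx(15.0)

    def test_single_batch_identity(self):
        m = simple_matrix()
        single = MetabolomicsMatrix(m.values.copy(),
                                    m.samples.assign(batch="B1"))
        out = batch_correct(single)
        pd.testing.assert_frame_equal(out.values, single.values)

    def test_idempotent(self):
        m = simple_matrix()
        once = batch_correct(m)
        twice = batch_correct(once)
        np.testing.assert_allclose(twice.values.to_numpy(dtype=float),
                                   once.values.to_numpy(dtype=float),
                                   rtol=1e-9, equal_nan=True)

    def test_zero_qc_median_left_uncorrected(self):
        batch = ["B1"] * 3 + ["B2"] * 3
        stype = ["primary", "QC", "QC"] * 2
        group = ["IPH-", "none", "none", "IPH+", "none", "none"]
        m = make_matrix({"m": [5.0, 0.0, 0.0, 7.0, 10.0, 10.0]},
                        batch, stype, group)
        out = batch_correct(m)
        pd.testing.assert_series_equal(out.values.loc["m"],
                                       m.values.loc["m"])

    def test_additive_mode(self):
        batch = ["B1"] * 3 + ["B2"] * 3
        stype = ["primary", "QC", "QC"] * 2
        group = ["IPH-", "none", "none", "IPH+", "none", "none"]
        m = make_matrix({"m": [5.0, 10.0, 10.0, 7.0, 20.0, 20.0]},
                        batch, stype, group)
        out = batch_correct(m, mode="additive")
        assert out.values.loc["m", "s0"] == pytest.approx(10.0)   # +5
        assert out.values.loc["m", "s3"] == pytest.approx(2.0)    # -5


class TestDifferentialAbundance:
    def base(self, values: dict[str, list]):
        n = len(next(iter(values.values()))) // 2
        return make_matrix(values, ["B1"] * 2 * n, ["primary"] * 2 * n,
                           ["IPH-"] * n + ["IPH+"] * n)

    def test_identical_groups_unchanged(self):
        m = self.base({"m": [1, 2, 3, 4, 1, 2, 3, 4]})
        calls = differential_abundance(m)
        assert calls.loc["m", "call"] == "unchanged"

    def test_extreme_ranksum_matches_enumeration(self):
        # {1,2,3} vs {4,5,6}: most extreme of C(6,3)=20 assignments
        m = self.base({"m": [1, 2, 3, 4, 5, 6]})
        calls = differential_abundance(m, alpha_adj=0.2, test="wilcoxon")
        # enumeration oracle for the two-sided exact rank-sum p
        obs = sum([4, 5, 6])
        sums = [sum(c) for c in itertools.combinations(range(1, 7), 3)]
        lo, hi = min(sums), max(sums)
        extreme = sum(1 for s in sums if s >= obs or s <= lo + (hi - obs))
        assert calls.loc["m", "p"] == pytest.approx(extreme / 20)
        assert calls.loc["m", "p"] == pytest.approx(0.1)

    def test_planted_shift_called_up(self):
        rng = np.random.default_rng(0)
        n = 13
        base = rng.normal(100, 1, size=n)
        shifted = rng.normal(200, 1, size=n)
        values = {"m": np.concatenate([base, shifted]).tolist()}
        for j in range(5):
            values[f"null{j}"] = rng.normal(50, 1, size=2 * n).tolist()
        m = make_matrix(values, ["B1"] * 2 * n, ["primary"] * 2 * n,
                        ["IPH-"] * n + ["IPH+"] * n)
        calls = differential_abundance(m)
        assert calls.loc["m", "call"] == "up"
        # null metabolites should mostly stay unchanged (BH with a very
        # significant anchor can promote an occasional small raw p)
        unchanged = sum(calls.loc[f"null{j}", "call"] == "unchanged"
                        for j in range(5))
        assert unchanged >= 3

    def test_degenerate_equal_values(self):
        m = self.base({"m": [5, 5, 5, 5, 5, 5]})
        calls = differential_abundance(m)
        assert calls.loc["m", "p"] == 1.0
        assert calls.loc["m", "call"] == "unchanged"

    def test_normal_branch_uses_t(self):
        rng = np.random.default_rng(1)
        m = self.base({"m": rng.normal(10, 1, size=26).tolist()})
        calls = differential_abundance(m)
        assert calls.loc["m", "test"] in ("t", "wilcoxon")
        if calls.loc["m", "test"] == "t":
            x = m.values.loc["m"].iloc[13:]
            y = m.values.loc["m"].iloc[:13]
            assert calls.loc["m", "p"] == pytest.approx(
                stats.ttest_ind(x, y, equal_var=True).pvalue)

    def test_type_i_error_under_null(self):
        """No planted shift: called fraction at adj-p < 0.1 stays small."""
        from gemreporter.synth import SyntheticScenario, generate_metabolomics
        from gemreporter.synth import generate_toy_model
        called = total = 0
        for seed in range(50):
            sc = SyntheticScenario(seed=seed, met_shift_fold=1.0,
                                   n_metabolomics=40)
            model, _ = generate_toy_model(sc)
            matrix, _cats, _truth = generate_metabolomics(model, sc)
            filtered, _ = qc_filter(matrix)
            corrected = batch_correct(filtered)
            calls = differential_abundance(corrected, alpha_adj=0.1)
            called += int((calls["call"] != "unchanged").sum())
            total += len(calls)
        assert called / total <= 0.12


def test_bh_matches_brute_force_step_up():
    rng = np.random.default_rng(5)
    from statsmodels.stats.multitest import multipletests
    for _ in range(10):
        p = rng.uniform(size=rng.integers(3, 40))
        adj = multipletests(p, method="fdr_bh")[1]
        # brute-force BH step-up
        n = len(p)
        order = np.argsort(p)
        stepped = p[order] * n / (np.arange(n) + 1)
        monotone = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(monotone, 1.0)
        np.testing.assert_allclose(adj, expected, rtol=1e-12)


class TestCategoryPermutation:
    def make_calls(self, n=109, n_up=30):
        mets = [f"m{i}" for i in range(n)]
        call = ["up"] * n_up + ["unchanged"] * (n - n_up)
        return pd.DataFrame({"call": call}, index=mets)

    def test_all_metabolites_category_p_one(self):
        calls = self.make_calls(20, 5)
        cats = {m: "everything" for m in calls.index}
        res = category_permutation_test(calls, cats, "up", n_perm=2000,
                                        seed=0)
        assert res.loc[0, "p_perm"] == 1.0

    def test_matches_hypergeometric_tail(self):
        # 109 metabolites, 20-member category: the permutation null is
        # exchangeable, so the over-representation tail is hypergeometric
        calls = self.make_calls(109, 30)
        cats = {f"m{i}": ("lipid" if i < 20 else "rest")
                for i in range(109)}
        res = category_permutation_test(calls, cats, "up", n_perm=100000,
                                        seed=1)
        row = res.set_index("category").loc["lipid"]
        observed = int(row["n_dysregulated_in_category"])
        p_hyper = stats.hypergeom.sf(observed - 1, 109, 30, 20)
        assert abs(row["p_perm"] - p_hyper) <= 0.005

    def test_empty_category_skipped(self):
        calls = self.make_calls(10, 2)
        cats = {"not_present": "ghost"}
        res = category_permutation_test(calls, cats, "up", n_perm=100, seed=0)
        assert res.empty

    def test_seed_determinism(self):
        calls = self.make_calls(30, 8)
        cats = {f"m{i}": "a" if i < 10 else "b" for i in range(30)}
        r1 = category_permutation_test(calls, cats, "up", 5000, seed=9)
        r2 = category_permutation_test(calls, cats, "up", 5000, seed=9)
        pd.testing.assert_frame_equal(r1, r2)


class TestIO:
    def test_tsv_round_trip(self, tmp_path):
        m = simple_matrix()
        path = tmp_path / "metabolomics.tsv"
        write_metabolomics(m, str(path))
        again = read_metabolomics(str(path))
        pd.testing.assert_frame_equal(again.values, m.values)
        pd.testing.assert_frame_equal(again.samples, m.samples)

    def test_validation_rejects_qc_with_group(self):
        with pytest.raises(ValueError):
            make_matrix({"m": [1, 2]}, ["B1", "B1"], ["QC", "primary"],
                        ["IPH-", "IPH+"])
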