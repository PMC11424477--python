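import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import brute_bh, brute_median_polish, brute_two_sample_t
from conftest import make_design
from phosphokin import (
    KinaseSubstrateMap,
    adjust_bh,
    differential_sites,
    flag_sample_outliers,
    median_polish,
    normalize_median_equalization,
    simulate_experiment,
    summarize_median_polish,
    summarize_site_groups,
    to_site_groups,
)
from phosphokin.errors import ParameterError, ParseError
from phosphokin.io import log2_intensities


# ---------------------------------------------------------------------------
# site grouping


class TestToSiteGroups:
    def test_peptides_with_same_site_set_share_a_group(self, tiny_evidence):
        extra = tiny_evidence.iloc[[0]].assign(peptide="other_pep", fragment="other.f1")
        grouped = to_site_groups(pd.concat([tiny_evidence, extra], ignore_index=True))
        p1 = grouped[grouped["phosphosites"] == "P1_S45"]
        assert set(p1["site_group"]) == {"P1_S45"}
        assert p1["peptide"].nunique() == 2

    def test_distinct_site_sets_get_distinct_groups(self, tiny_evidence):
        multi = tiny_evidence.iloc[[0]].assign(
            peptide="pep_multi", fragment="multi.f1", phosphosites="P1_S45;P1_S49"
        )
        grouped = to_site_groups(pd.concat([tiny_evidence, multi], ignore_index=True))
        assert "P1_S45;S49" in set(grouped["site_group"])
        assert "P1_S45" in set(grouped["site_group"])

    def test_idempotent_and_row_preserving(self, tiny_evidence):
        once = to_site_groups(tiny_evidence)
        twice = to_site_groups(once)
        assert len(once) == len(tiny_evidence)
        pd.testing.assert_frame_equal(once, twice)

    def test_empty_site_set_rejected(self, tiny_evidence):
        bad = tiny_evidence.copy()
        bad.loc[0, "phosphosites"] = ""
        with pytest.raises(ParseError):
            to_site_groups(bad)


# ---------------------------------------------------------------------------
# normalization


class TestMedianEqualization:
    def test_worked_two_sample_fixture(self):
        df = pd.DataFrame(
            {"sample": ["A"] * 3 + ["B"] * 3, "log2_intensity": [1.0, 2, 3, 11, 12, 13]}
        )
        out = normalize_median_equalization(df)
        assert out["log2_intensity"].tolist() == [6.0, 7.0, 8.0, 6.0, 7.0, 8.0]

    def test_equal_medians_is_a_fixed_point(self):
        df = pd.DataFrame(
            {"sample": ["A", "A", "B", "B"], "log2_intensity": [1.0, 3.0, 0.0, 4.0]}
        )
        out = normalize_median_equalization(df)
        pd.testing.assert_frame_equal(out, df)

    def test_single_sample_unchanged(self):
        df = pd.DataFrame({"sample": ["A"] * 3, "log2_intensity": [5.0, 6.0, 9.0]})
        pd.testing.assert_frame_equal(normalize_median_equalization(df), df)

    def test_sample_without_observations_is_an_error_naming_it(self):
        df = pd.DataFrame(
            {"sample": ["A", "A", "B"], "log2_intensity": [1.0, 2.0, np.nan]}
        )
        with pytest.raises(ParameterError, match="B"):
            normalize_median_equalization(df)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_medians_equalized_and_differences_preserved(self, data):
        n_samples = data.draw(st.integers(2, 6))
        frames = []
        for s in range(n_samples):
            vals = data.draw(
                st.lists(
                    st.floats(-50, 50, allow_nan=False, width=32), min_size=1, max_size=20
                )
            )
            frames.append(pd.DataFrame({"sample": f"S{s}", "log2_intensity": np.asarray(vals, float)}))
        df = pd.concat(frames, ignore_index=True)
        out = normalize_median_equalization(df)
        medians = out.groupby("sample")["log2_intensity"].median()
        assert np.all(np.abs(medians - medians.iloc[0]) < 1e-9)
        for s, sub in out.groupby("sample"):
            orig = df[df["sample"] == s]["log2_intensity"].to_numpy()
            new = sub["log2_intensity"].to_numpy()
            assert np.allclose(np.diff(orig), np.diff(new), atol=1e-9)


# ---------------------------------------------------------------------------
# median polish


def random_matrix(rng, with_missing):
    nrow = rng.integers(1, 7)
    ncol = rng.integers(1, 7)
    X = rng.normal(0, 2, size=(nrow, ncol))
    if with_missing:
        mask = rng.random(size=X.shape) < 0.25
        # keep at least one observation in every row and column
        for i in range(nrow):
            if mask[i].all():
                mask[i, rng.integers(ncol)] = False
        for j in range(ncol):
            if mask[:, j].all():
                mask[rng.integers(nrow), j] = False
        X[mask] = np.nan
    return X


class TestMedianPolish:
    def test_two_by_two_fixture(self):
        out = summarize_median_polish(np.array([[0.0, 1.0], [2.0, 3.0]]))
        assert np.allclose(out, [1.0, 2.0], atol=1e-12)

    def test_single_fragment_returned_unchanged(self):
        row = np.array([[5.0, 6.5, 4.2]])
        assert np.allclose(summarize_median_polish(row), row[0])

    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(7)
        for k in range(200):
            X = random_matrix(rng, with_missing=k % 2 == 1)
            expected = brute_median_polish(
                [[None if np.isnan(v) else float(v) for v in row] for row in X]
            )
            got = summarize_median_polish(X)
            for e, g in zip(expected, got):
                if e is None:
                    assert np.isnan(g)
                else:
                    assert abs(e - g) < 1e-9

    def test_exactly_additive_matrix_decomposed_exactly(self):
        rng = np.random.default_rng(3)
        r = rng.normal(size=5)
        c = rng.normal(size=4)
        X = r[:, None] + c[None, :]
        res = median_polish(X)
        assert np.all(np.abs(res.residuals) < 1e-9)
        assert np.allclose(res.col_summaries, np.median(r) + c, atol=1e-9)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(5, 4))
        X[1, 2] = np.nan
        base = summarize_median_polish(X)
        perm = summarize_median_polish(X[rng.permutation(5)])
        assert np.allclose(base, perm, equal_nan=True)

    def test_fully_missing_column_stays_missing(self):
        X = np.array([[1.0, np.nan, 2.0], [2.0, np.nan, 4.0]])
        out = summarize_median_polish(X)
        assert np.isnan(out[1]) and not np.isnan(out[0]) and not np.isnan(out[2])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ParameterError):
            median_polish(np.empty((0, 0)))
        with pytest.raises(ParameterError):
            median_polish(np.full((2, 2), np.nan))


# ---------------------------------------------------------------------------
# differential testing


def matrix_from(a_vals, b_vals, group="P1_S1"):
    cols = {f"A_{i + 1}": [v] for i, v in enumerate(a_vals)}
    cols.update({f"B_{i + 1}": [v] for i, v in enumerate(b_vals)})
    return pd.DataFrame(cols, index=[group])


class TestDifferentialSites:
    design = make_design(3)

    def test_identical_groups_give_zero_fc_and_p_one(self):
        res = differential_sites(matrix_from([1, 2, 3], [1, 2, 3]), self.design, ("A", "B"))
        assert res.loc[0, "log2FC"] == 0.0
        assert res.loc[0, "pvalue"] == pytest.approx(1.0)

    def test_worked_t_fixture(self):
        res = differential_sites(matrix_from([1, 2, 3], [3, 4, 5]), self.design, ("A", "B"))
        t_oracle, df_oracle = brute_two_sample_t([1, 2, 3], [3, 4, 5])
        assert res.loc[0, "log2FC"] == -2.0
        assert res.loc[0, "t"] == pytest.approx(t_oracle, abs=1e-9)
        assert res.loc[0, "t"] == pytest.approx(-2.449, abs=1e-3)
        assert res.loc[0, "df"] == df_oracle == 4
        assert res.loc[0, "pvalue"] == pytest.approx(0.0705, abs=1e-3)

    def test_zero_variance_with_unequal_means_flagged_not_p_zero(self):
        design = make_design(2)
        res = differential_sites(matrix_from([1, 1], [2, 2]), design, ("A", "B"))
        assert res.loc[0, "reason"] == "zero_variance"
        assert np.isnan(res.loc[0, "pvalue"])
        assert res.loc[0, "log2FC"] == -1.0  # estimate still reported

    def test_insufficient_replicates_reason(self):
        mat = matrix_from([1.0, np.nan, np.nan], [3.0, 4.0, 5.0])
        res = differential_sites(mat, self.design, ("A", "B"))
        assert res.loc[0, "reason"] == "insufficient_replicates"
        assert np.isnan(res.loc[0, "pvalue"])
        assert res.loc[0, "nA"] == 1 and res.loc[0, "nB"] == 3

    def test_contrast_reversal_flips_log2fc_sign(self):
        mat = matrix_from([1, 2, 3], [3, 4, 5])
        fwd = differential_sites(mat, self.design, ("A", "B"))
        rev = differential_sites(mat, self.design, ("B", "A"))
        assert fwd.loc[0, "log2FC"] == -rev.loc[0, "log2FC"]
        assert fwd.loc[0, "pvalue"] == pytest.approx(rev.loc[0, "pvalue"])

    def test_unknown_condition_rejected(self):
        with pytest.raises(ParameterError, match="unknown condition"):
            differential_sites(matrix_from([1, 2, 3], [3, 4, 5]), self.design, ("A", "C"))

    def test_adjusted_p_at_least_raw_p(self):
        rng = np.random.default_rng(5)
        mat = pd.DataFrame(
            rng.normal(size=(40, 6)),
            index=[f"P{i}_S1" for i in range(40)],
            columns=self.design.index,
        )
        res = differential_sites(mat, self.design, ("A", "B"))
        tested = res.dropna(subset=["pvalue"])
        assert (tested["adj_pvalue"] >= tested["pvalue"] - 1e-12).all()
        assert tested["adj_pvalue"].between(0, 1).all()


class TestAdjustBH:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005, 0.05], [0.01, 0.05]),
            ([0.3], [0.3]),
        ],
    )
    def test_worked_fixtures(self, raw, expected):
        assert np.allclose(adjust_bh(raw), expected, atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(19)
        for _ in range(1000):
            p = rng.random(size=rng.integers(1, 30))
            assert np.allclose(adjust_bh(p), brute_bh(list(p)), atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(23)
        p = rng.random(200)
        adj = adjust_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([-0.1, 0.5], [0.5, 1.1], [np.nan, 0.5]):
            with pytest.raises(ParameterError):
                adjust_bh(bad)


# ---------------------------------------------------------------------------
# sample outliers


class TestFlagSampleOutliers:
    def test_statistically_identical_samples_unflagged(self, tiny_evidence):
        assert flag_sample_outliers(tiny_evidence, threshold=3.0) == []

    def test_sample_with_one_percent_detection_flagged(self, tiny_evidence):
        # a fifth sample observed in 1 of ~100 ions while the others carry all of them
        rng = np.random.default_rng(2)
        rows = []
        for i in range(100):
            site = f"P{i + 10}_S1"
            for sample in ["s1", "s2", "s3", "s4", "s5"]:
                if sample == "s5" and i > 0:
                    continue
                rows.append(
                    {
                        "peptide": f"pep_{site}",
                        "protein": f"P{i + 10}",
                        "phosphosites": site,
                        "fragment": f"{site}.f1",
                        "sample": sample,
                        "condition": "A",
                        "intensity": float(2.0 ** rng.normal(20, 0.5)),
                    }
                )
        flagged = flag_sample_outliers(pd.DataFrame(rows), threshold=3.0)
        assert flagged == ["s5"]

    def test_single_sample_has_no_reference_population(self, tiny_evidence):
        single = tiny_evidence[tiny_evidence["sample"] == "s1"]
        assert flag_sample_outliers(single) == []

    def test_empty_evidence_rejected(self):
        with pytest.raises(ParameterError):
            flag_sample_outliers(pd.DataFrame())


# ---------------------------------------------------------------------------
# global-null calibration of the site-level t-test


def test_sitewise_t_pvalues_uniform_under_global_null():
    """With no planted activities the raw t-test P < 0.05 rate is ~5%."""
    design = make_design(3)
    evidence, _ = simulate_experiment(
        KinaseSubstrateMap({}),
        design,
        activities={},
        fragments_per_group=1,
        noise_sd=0.5,
        sample_offset_sd=0.2,
        missing_rate=0.0,
        seed=101,
        n_null_sites=1000,
    )
    grouped = to_site_groups(evidence)
    grouped["log2_intensity"] = log2_intensities(grouped)
    normalized = normalize_median_equalization(grouped)
    matrix = summarize_site_groups(normalized)
    res = differential_sites(matrix, design, ("A", "B"))
    frac = (res["pvalue"] < 0.05).mean()
    n = res["pvalue"].notna().sum()
    band = 3 * np.sqrt(0.05 * 0.95 / n)
    assert n == 1000
    assert abs(frac - 0.05) < band
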