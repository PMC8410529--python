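"""Cutoff fitting, phenotype rules, biomarker scoring, co-expression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctcquant import classify_cells, composition_table, fit_cutoff, fit_gating_config, score_biomarker
from ctcquant.core import bgsub_col
from ctcquant.gating import GatingConfig
from ctcquant.synthetic import ChannelLaw, default_phenotypes, generate_cell_table


def brute_force_split_cutoff(values):
    """Independent oracle: scan every split of the sorted values."""
    xs = np.sort(np.asarray(values, float))
    n = len(xs)
    best = None
    for k in range(1, n):
        left, right = xs[:k], xs[k:]
        sse = left.var() * k + right.var() * (n - k)
        if best is None or sse < best[0] - 1e-12:
            best = (sse, (left.mean() + right.mean()) / 2.0)
    return best[1]


class TestFitCutoff:
    def test_symmetric_two_cluster_midpoint(self):
        assert fit_cutoff([0, 0, 0, 10, 10, 10]) == pytest.approx(5.0)

    def test_gaussian_mixture_cutoff_lands_between_components(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(0, 1, 500), rng.normal(8, 1, 500)])
        assert 3.0 <= fit_cutoff(x) <= 5.0

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_split_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 201))
        sep = rng.uniform(4, 9)
        x = np.concatenate(
            [rng.normal(0, 1, n // 2), rng.normal(sep, 1, n - n // 2)]
        )
        assert fit_cutoff(x) == pytest.approx(brute_force_split_cutoff(x), abs=1e-9)

    @pytest.mark.parametrize("seed", range(10))
    def test_cluster_path_matches_oracle_on_arbitrary_data(self, seed):
        """With the unimodality fallback disabled the split is always the
        exhaustive optimum, whatever the data shape."""
        rng = np.random.default_rng(100 + seed)
        x = rng.normal(0, 1, int(rng.integers(2, 150)))
        got = fit_cutoff(x, min_cluster_separation=0.0)
        assert got == pytest.approx(brute_force_split_cutoff(x), abs=1e-9)

    @settings(derandomize=True, max_examples=40)
    @given(
        shift=st.floats(-1e4, 1e4, allow_nan=False),
        seed=st.integers(0, 100),
    )
    def test_translation_equivariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        x = np.concatenate([rng.normal(0, 1, 40), rng.normal(6, 1, 40)])
        assert fit_cutoff(x + shift) == pytest.approx(
            fit_cutoff(x) + shift, abs=1e-6
        )

    def test_identical_values_fall_back_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            assert fit_cutoff([4.0, 4.0, 4.0]) == pytest.approx(4.0)

    def test_unimodal_data_uses_mean_plus_3sd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(10, 2, 2000)
        cutoff = fit_cutoff(x)
        assert cutoff == pytest.approx(x.mean() + 3 * x.std(), rel=1e-9)
        # and the cutoff clears essentially the whole population
        assert (x < cutoff).mean() > 0.99

    def test_too_few_values_raise(self):
        with pytest.raises(ValueError, match=">= 2"):
            fit_cutoff([1.0])


def _table(rows):
    df = pd.DataFrame(rows)
    for col in ("qc_saturated", "qc_size", "qc_border"):
        if col not in df.columns:
            df[col] = False
    return df


_CONFIG = GatingConfig(
    cutoffs={"exclusion": 100.0, "caxii": 100.0, "ck": 100.0, "biomarker": 50.0}
)


def _row(excl, caxii, ck, **kw):
    hi, lo = 200.0, 0.0
    return {
        "cell_id": kw.pop("cell_id", 0),
        bgsub_col("exclusion"): hi if excl else lo,
        bgsub_col("caxii"): hi if caxii else lo,
        bgsub_col("ck"): hi if ck else lo,
        bgsub_col("biomarker"): kw.pop("biomarker", 0.0),
        **kw,
    }


class TestClassifyCells:
    def test_rule_set_truth_table(self):
        """All 8 exclusion x CAXII x CK combinations map to the published
        rule set: exclusion wins, CAXII/CK define the subtype, and
        triple-negative cells are never CTCs."""
        rows, expected = [], []
        for i, (excl, caxii, ck) in enumerate(
            itertools.product([False, True], repeat=3)
        ):
            rows.append(_row(excl, caxii, ck, cell_id=i))
            if excl:
                expected.append("EXCLUDED")
            elif caxii and ck:
                expected.append("DP")
            elif caxii:
                expected.append("CAXII_S")
            elif ck:
                expected.append("CK_S")
            else:
                expected.append("TRIPLE_NEG")
        calls = classify_cells(_table(rows), _CONFIG)
        assert list(calls["label"]) == expected
        assert not calls.loc[calls["label"] == "TRIPLE_NEG", "countable"].any()
        assert not calls.loc[calls["label"] == "EXCLUDED", "countable"].any()
        assert calls.loc[
            calls["label"].isin(["CAXII_S", "DP", "CK_S"]), "countable"
        ].all()

    def test_exclusion_beats_marker_positivity(self):
        calls = classify_cells(_table([_row(True, True, True)]), _CONFIG)
        assert calls["label"].iloc[0] == "EXCLUDED"

    def test_qc_flagged_cells_are_labeled_but_not_countable(self):
        row = _row(False, True, False)
        row["qc_border"] = True
        calls = classify_cells(_table([row]), _CONFIG)
        assert calls["label"].iloc[0] == "CAXII_S"
        assert not calls["countable"].iloc[0]

    def test_missing_role_column_names_the_role(self):
        bad = _table([_row(False, True, False)]).drop(columns=[bgsub_col("ck")])
        with pytest.raises(ValueError, match="ck"):
            classify_cells(bad, _CONFIG)

    def test_row_permutation_permutes_calls(self):
        rng = np.random.default_rng(0)
        rows = [
            _row(bool(e), bool(a), bool(c), cell_id=i)
            for i, (e, a, c) in enumerate(rng.integers(0, 2, (30, 3)))
        ]
        table = _table(rows)
        perm = rng.permutation(len(table))
        calls_a = classify_cells(table, _CONFIG).set_index("cell_id")
        calls_b = classify_cells(table.iloc[perm], _CONFIG).set_index("cell_id")
        pd.testing.assert_frame_equal(
            calls_a.sort_index(), calls_b.sort_index()
        )
        assert len(calls_a) == len(table)  # label counts conserved


class TestScoreBiomarker:
    def test_percent_positive_and_mean_arithmetic(self):
        rows = [
            _row(False, True, False, biomarker=v, cell_id=i)
            for i, v in enumerate([-1.0, 2.0, 9.0])
        ]
        summary = score_biomarker(classify_cells(_table(rows), _CONFIG), cutoff=1.0)
        caxii = summary.loc["CAXII_S"]
        assert caxii["n_cells"] == 3
        assert caxii["pct_positive"] == pytest.approx(100 * 2 / 3)
        assert caxii["mean_expression"] == pytest.approx(10 / 3)
        # the mean is reported independently of the cutoff
        high = score_biomarker(
            classify_cells(_table(rows), _CONFIG), cutoff=100.0
        ).loc["CAXII_S"]
        assert high["pct_positive"] == 0.0
        assert high["mean_expression"] == pytest.approx(10 / 3)

    def test_empty_subpopulations_reported_missing_not_zero(self):
        rows = [_row(False, True, False, biomarker=5.0)]
        summary = score_biomarker(classify_cells(_table(rows), _CONFIG), cutoff=0.0)
        assert summary.loc["CK_S", "n_cells"] == 0
        assert np.isnan(summary.loc["CK_S", "pct_positive"])
        assert np.isnan(summary.loc["CK_S", "mean_expression"])

    def test_subpopulation_counts_are_consistent(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(60):
            e, a, c = rng.integers(0, 2, 3)
            rows.append(_row(bool(e), bool(a), bool(c),
                             biomarker=float(rng.normal()), cell_id=i))
        summary = score_biomarker(classify_cells(_table(rows), _CONFIG), cutoff=0.0)
        assert summary.loc["ALL_CTC", "n_cells"] == (
            summary.loc["CAXII_S", "n_cells"]
            + summary.loc["DP", "n_cells"]
            + summary.loc["CK_S", "n_cells"]
        )
        assert summary.loc["CK_PLUS", "n_cells"] == (
            summary.loc["CK_S", "n_cells"] + summary.loc["DP", "n_cells"]
        )

    def test_bimodal_dp_population_scores_near_half_positive(self):
        """A 50/50 positive/negative DP mixture yields ~50% positive.

        The sample carries WBC and triple-negative cells alongside the
        DP cells so every per-channel cutoff can be fitted from the
        sample itself, as in real fields."""
        phenos = default_phenotypes()
        mix = [(phenos["DP"], 0.5), (phenos["WBC"], 0.3),
               (phenos["TRIPLE_NEG"], 0.2)]
        table = generate_cell_table(mix, 2000, seed=8)
        config = fit_gating_config(table)
        summary = score_biomarker(
            classify_cells(table, config), config["biomarker"]
        )
        n = summary.loc["DP", "n_cells"]
        assert n > 500
        sd = 100 * np.sqrt(0.25 / n)
        assert abs(summary.loc["DP", "pct_positive"] - 50.0) <= 3 * sd


class TestEndToEndGating:
    @pytest.mark.parametrize("seed", range(10))
    def test_labels_recovered_from_well_separated_laws(self, seed):
        phenos = default_phenotypes(signal_law=ChannelLaw(500.0, 100.0))
        mix = [(phenos[k], w) for k, w in
               [("CAXII_S", 0.2), ("DP", 0.15), ("CK_S", 0.15),
                ("WBC", 0.4), ("TRIPLE_NEG", 0.1)]]
        table = generate_cell_table(mix, 400, seed=seed)
        config = fit_gating_config(table)
        calls = classify_cells(table, config)
        truth = table["truth_label"].replace({"WBC": "EXCLUDED"})
        assert (calls["label"].to_numpy() == truth.to_numpy()).mean() >= 0.99

    def test_all_wbc_mix_is_fully_excluded(self):
        # well-separated exclusion law: WBC signal far above the noise
        phenos = default_phenotypes(exclusion_law=ChannelLaw(600.0, 100.0))
        table = generate_cell_table(
            [(phenos["WBC"], 0.5), (phenos["CK_S"], 0.5)], 300, seed=2
        )
        config = fit_gating_config(table)
        calls = classify_cells(table, config)
        wbc = table["truth_label"] == "WBC"
        assert (calls.loc[wbc.to_numpy(), "label"] == "EXCLUDED").all()

    def test_truth_columns_do_not_affect_calls(self):
        from ctcquant.core import strip_truth

        phenos = default_phenotypes()
        table = generate_cell_table([(phenos["DP"], 1.0)], 100, seed=5)
        config = fit_gating_config(table)
        a = classify_cells(table, config)
        b = classify_cells(strip_truth(table), config)
        pd.testing.assert_frame_equal(a, b)


class TestCompositionTable:
    def test_single_combination_dominates(self):
        df = pd.DataFrame({"CK": [True] * 10, "CAIX": [False] * 10})
        result = composition_table(df)
        combos = result.combinations
        only_ck = combos.loc[combos["CK"] & ~combos["CAIX"], "pct"].iloc[0]
        assert only_ck == pytest.approx(100.0)
        assert combos["pct"].sum() == pytest.approx(100.0)

    @settings(derandomize=True, max_examples=25)
    @given(seed=st.integers(0, 1000), n=st.integers(1, 200))
    def test_combination_frequencies_always_sum_to_100(self, seed, n):
        rng = np.random.default_rng(seed)
        df = pd.DataFrame(
            rng.integers(0, 2, (n, 3)).astype(bool),
            columns=["CK", "EpCAM", "CAIX"],
        )
        result = composition_table(df)
        assert result.combinations["pct"].sum() == pytest.approx(100.0)

    def test_exclusion_positive_cells_are_dropped(self):
        df = pd.DataFrame(
            {"CK": [True, True, False], "CAIX": [True, False, True],
             "exclusion": [False, False, True]}
        )
        result = composition_table(df, exclusion_column="exclusion")
        # only the two exclusion-negative cells are tabulated
        assert result.combinations["pct"].sum() == pytest.approx(100.0)
        ck_caix = result.combinations.loc[
            result.combinations["CK"] & result.combinations["CAIX"], "pct"
        ].iloc[0]
        assert ck_caix == pytest.approx(50.0)

    def test_empty_subset_raises(self):
        df = pd.DataFrame({"CK": [True], "exclusion": [True]})
        with pytest.raises(ValueError, match="exclusion-negative"):
            composition_table(df, exclusion_column="exclusion")

    def test_marginal_frequency_recovery_within_ck_stratum(self):
        """A synthetic mix with 75% CAIX within CK+ is recovered."""
        rng = np.random.default_rng(12)
        n = 2000
        ck = rng.random(n) < 0.4
        caix = np.where(ck, rng.random(n) < 0.75, rng.random(n) < 0.38)
        result = composition_table(pd.DataFrame({"CK": ck, "CAIX": caix}))
        marg = result.ck_strata_marginals.set_index(["stratum", "marker"])
        got = marg.loc[("CK+", "CAIX"), "pct_positive"]
        n_ck = marg.loc[("CK+", "CAIX"), "n_cells"]
        sd = 100 * np.sqrt(0.75 * 0.25 / n_ck)
        assert abs(got - 75.0) <= 3 * sd
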