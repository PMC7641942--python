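"""Autoantibody positivity calls, panel summaries and C-peptide coding."""

import numpy as np
import pandas as pd
import pytest

from t1dgrs.biomarkers import (
    CPEPTIDE_CODED_VALUE,
    PANEL_ANALYTES,
    call_positive,
    code_cpeptide,
    cpeptide_group_summary,
    iaa_duration_summary,
    parse_cpeptide,
    summarize_panel,
)


class TestCallPositive:
    def test_titre_at_cutoff_is_negative(self):
        assert call_positive(5.0, 5.0) is False

    def test_double_cutoff_is_positive(self):
        assert call_positive(10.0, 5.0) is True

    def test_negative_titre_rejected(self):
        with pytest.raises(ValueError):
            call_positive(-1.0, 5.0)
        with pytest.raises(ValueError):
            call_positive(1.0, 0.0)

    def test_control_positivity_rate_near_one_percent(self, rng):
        # titres from the cutoff-defining healthy distribution: log-normal
        # with the cutoff at its 99th percentile
        mu, sigma = 0.0, 0.5
        cutoff = 10 ** (mu + 2.3263478740408408 * sigma)
        titres = 10 ** rng.normal(mu, sigma, size=20000)
        rate = np.mean([call_positive(t, cutoff) for t in titres])
        assert rate == pytest.approx(0.01, abs=3 * np.sqrt(0.01 * 0.99 / 20000))


def _calls_frame(rows):
    return pd.DataFrame(rows, columns=["individual_id", "group", "analyte", "positive"])


class TestSummarizePanel:
    def test_nine_of_twenty_two_any_positive(self):
        # 22 individuals fully measured; 9 positive for >=1 analyte,
        # 2 positive for two, 1 for all three
        rows = []
        pattern = (
            [("GADA",)] * 6 + [("IA2A",)] * 0 + [("ZnT8A",)] * 0
        )
        positives = [
            {"GADA"}, {"GADA"}, {"GADA"}, {"GADA"}, {"GADA"},
            {"IA2A"}, {"ZnT8A"},
            {"GADA", "IA2A"},
            {"GADA", "IA2A", "ZnT8A"},
        ] + [set()] * 13
        for i, pos in enumerate(positives):
            for analyte in PANEL_ANALYTES:
                rows.append((f"p{i}", "high", analyte, analyte in pos))
        summary = summarize_panel(_calls_frame(rows))["high"]
        assert summary.n_measured == 22
        assert summary.n_any_positive == 9
        assert round(100 * summary.n_any_positive / summary.n_measured) == 41
        assert summary.n_two_positive == 2
        assert summary.n_three_positive == 1

    def test_empty_input_gives_empty_summary(self):
        out = summarize_panel(_calls_frame([]))
        assert out == {}

    @pytest.mark.parametrize("seed", range(3))
    def test_counts_match_row_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(40):
            measured = rng.random(3) < 0.8
            for analyte, meas in zip(PANEL_ANALYTES, measured):
                if meas:
                    rows.append((f"p{i}", "g", analyte, bool(rng.random() < 0.3)))
        df = _calls_frame(rows)
        if df.empty:
            return
        summary = summarize_panel(df)["g"]
        by_ind = {}
        for _, r in df.iterrows():
            by_ind.setdefault(r.individual_id, []).append(r.positive)
        assert summary.n_measured == len(by_ind)
        assert summary.n_any_positive == sum(1 for v in by_ind.values() if sum(v) >= 1)
        assert summary.n_two_positive == sum(1 for v in by_ind.values() if sum(v) >= 2)
        for analyte in PANEL_ANALYTES:
            sub = df[df.analyte == analyte]
            assert summary.per_analyte[analyte] == (int(sub.positive.sum()), len(sub))

    def test_adding_a_positive_call_never_decreases_any_positive(self):
        rows = [("p1", "g", "GADA", False), ("p1", "g", "IA2A", False)]
        base = summarize_panel(_calls_frame(rows))["g"]
        more = summarize_panel(_calls_frame(rows + [("p2", "g", "GADA", True)]))["g"]
        assert more.n_any_positive >= base.n_any_positive
        assert more.n_measured == base.n_measured + 1

    def test_duplicate_call_rejected(self):
        rows = [("p1", "g", "GADA", True), ("p1", "g", "GADA", False)]
        with pytest.raises(ValueError, match="duplicate"):
            summarize_panel(_calls_frame(rows))

    def test_iaa_rows_never_enter_panel(self):
        rows = [("p1", "g", "IAA", True), ("p1", "g", "GADA", False)]
        summary = summarize_panel(_calls_frame(rows))["g"]
        assert summary.n_any_positive == 0


class TestIaaDurationSummary:
    def _frame(self, rows):
        return pd.DataFrame(
            rows,
            columns=["individual_id", "group", "positive", "insulin_duration_weeks"],
        )

    def test_short_duration_contrast(self):
        # 8 short-duration high-score (4 positive) vs 75 short-duration
        # monogenic (6 positive): proportions 0.50 and 0.08
        rows = []
        for i in range(8):
            rows.append((f"h{i}", "high", i < 4, 10.0))
        for i in range(75):
            rows.append((f"m{i}", "mono", i < 6, 10.0))
        out = iaa_duration_summary(self._frame(rows))
        short = out[out.stratum == "<=13w"].set_index("group")
        assert short.loc["high", "n_positive"] == 4 and short.loc["high", "n"] == 8
        assert short.loc["high", "proportion"] == pytest.approx(0.50)
        assert short.loc["mono", "proportion"] == pytest.approx(0.08)

    def test_boundary_is_left_inclusive(self):
        rows = [("a", "g", True, 13.0), ("b", "g", False, 13.01)]
        out = iaa_duration_summary(self._frame(rows))
        assert out[out.stratum == "<=13w"].iloc[0]["n"] == 1
        assert out[out.stratum == ">13w"].iloc[0]["n"] == 1

    def test_all_short_collapses_to_single_stratum(self):
        rows = [(f"i{k}", "g", k % 2 == 0, 5.0) for k in range(10)]
        out = iaa_duration_summary(self._frame(rows))
        assert list(out.stratum.unique()) == ["<=13w"]
        assert out.iloc[0]["proportion"] == pytest.approx(0.5)

    def test_missing_duration_excluded_with_warning(self, caplog):
        rows = [("a", "g", True, 10.0), ("b", "g", True, np.nan)]
        with caplog.at_level("WARNING"):
            out = iaa_duration_summary(self._frame(rows))
        assert out["n"].sum() == 1
        assert any("missing insulin duration" in r.message for r in caplog.records)

    @pytest.mark.parametrize("seed", range(2))
    def test_matches_stratified_recount(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            (f"i{k}", "g", bool(rng.random() < 0.4), float(rng.uniform(1, 40)))
            for k in range(60)
        ]
        df = self._frame(rows)
        out = iaa_duration_summary(df).set_index("stratum")
        short = df[df.insulin_duration_weeks <= 13.0]
        assert out.loc["<=13w", "n_positive"] == short.positive.sum()
        assert out.loc["<=13w", "n"] == len(short)


class TestCpeptide:
    def test_below_lod_coded(self):
        assert code_cpeptide(1.2) == 2.9
        assert code_cpeptide("<3") == 2.9

    def test_at_and_above_lod_unchanged(self):
        assert code_cpeptide(3.0) == 3.0
        assert code_cpeptide(250.0) == 250.0

    def test_coding_idempotent(self):
        for raw in (0.0, 1.2, 2.9, 3.0, 40.0):
            once = code_cpeptide(raw)
            assert code_cpeptide(once) == once

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            code_cpeptide(-0.1)

    def test_group_summary_undetectable_fraction(self):
        # 19 values of which 14 below the detection limit -> 74%
        values = ["<3"] * 14 + ["10", "12", "20", "39", "8"]
        df = pd.DataFrame(
            {
                "group": "high",
                "coded_value": parse_cpeptide(values),
                "diabetes_duration_months": 6.0,
            }
        )
        out = cpeptide_group_summary(df)
        row = out[(out.group == "high") & (out.n > 0)].iloc[0]
        assert row["n"] == 19
        assert row["undetectable_fraction"] == pytest.approx(14 / 19)
        assert round(100 * row["undetectable_fraction"]) == 74
        assert row["median"] == CPEPTIDE_CODED_VALUE

    def test_all_detectable_constant(self):
        df = pd.DataFrame(
            {"group": "g", "coded_value": [100.0] * 5, "diabetes_duration_months": 3.0}
        )
        row = cpeptide_group_summary(df).iloc[0]
        assert (row["median"], row["q25"], row["q75"]) == (100.0, 100.0, 100.0)
        assert row["undetectable_fraction"] == 0.0

    def test_empty_stratum_reported_with_zero_n(self):
        df = pd.DataFrame(
            {"group": "g", "coded_value": [50.0], "diabetes_duration_months": 3.0}
        )
        out = cpeptide_group_summary(df)
        late = out[(out.group == "g") & (out.stratum == ">12mo")].iloc[0]
        assert late["n"] == 0 and np.isnan(late["median"])

    def test_summary_matches_sort_oracle(self, rng):
        from test_calibration import sort_and_interpolate

        vals = parse_cpeptide(np.round(rng.lognormal(2.5, 1.2, size=30), 1))
        df = pd.DataFrame(
            {"group": "g", "coded_value": vals, "diabetes_duration_months": 5.0}
        )
        row = cpeptide_group_summary(df).iloc[0]
        assert row["median"] == pytest.approx(sort_and_interpolate(vals, 0.5))
        assert row["q25"] == pytest.approx(sort_and_interpolate(vals, 0.25))
        assert row["q75"] == pytest.approx(sort_and_interpolate(vals, 0.75))

    def test_uncoded_input_rejected(self):
        df = pd.DataFrame(
            {"group": "g", "coded_value": [1.0], "diabetes_duration_months": 2.0}
        )
        with pytest.raises(ValueError, match="code_cpeptide"):
            cpeptide_group_summary(df)
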