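"""Habitat-paired fold ratios, range fractions, and the ratio tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ssdcompare.compare import (
    DegenerateRatioError,
    PairingError,
    build_comparison,
    check_hc5_consistency,
    fraction_within,
    moa_ratio_ttest,
    species_number_correlation,
    subset_min_species,
)
from ssdcompare.ssd import InsufficientDataError


class TestBuildComparison:
    def test_identical_fits_give_unit_folds(self, fits_frame):
        fits = fits_frame({"c": {"freshwater": (1.0, 0.5, 8),
                                 "saltwater": (1.0, 0.5, 6)}})
        row = build_comparison(fits).iloc[0]
        for col in ("mean_fold_fw_sw", "sd_ratio_fw_sw", "hc5_fold_fw_sw"):
            assert row[col] == pytest.approx(1.0)
        assert row["n_min"] == 6

    def test_one_log10_mean_shift_is_a_tenfold_difference(self, fits_frame):
        fits = fits_frame({"c": {"freshwater": (2.0, 0.5, 8),
                                 "saltwater": (1.0, 0.5, 8)}})
        row = build_comparison(fits).iloc[0]
        assert row["mean_fold_fw_sw"] == pytest.approx(10.0)
        assert row["hc5_fold_fw_sw"] == pytest.approx(10.0)

    def test_reciprocals_are_exact(self, fits_frame):
        fits = fits_frame({"c": {"freshwater": (2.3, 0.7, 11),
                                 "saltwater": (1.1, 0.4, 5)}})
        row = build_comparison(fits).iloc[0]
        for a, b in (("mean_fold_fw_sw", "mean_fold_sw_fw"),
                     ("sd_ratio_fw_sw", "sd_ratio_sw_fw"),
                     ("hc5_fold_fw_sw", "hc5_fold_sw_fw")):
            assert row[a] * row[b] == pytest.approx(1.0, abs=1e-15)

    def test_missing_habitat_partner_names_the_chemical(self, fits_frame):
        fits = fits_frame({"orphan": {"freshwater": (1.0, 0.5, 8)}})
        with pytest.raises(PairingError, match="orphan"):
            build_comparison(fits)

    def test_hc5_consistency_identity_holds_rowwise(self, fits_frame):
        rng = np.random.default_rng(12)
        params = {
            f"c{i}": {"freshwater": (rng.normal(2, 1), rng.uniform(0.2, 1), 10),
                      "saltwater": (rng.normal(2, 1), rng.uniform(0.2, 1), 7)}
            for i in range(20)
        }
        fits = fits_frame(params)
        rows = build_comparison(fits)
        assert check_hc5_consistency(rows, fits)

    def test_habitat_swap_maps_folds_to_reciprocals(self, fits_frame):
        rng = np.random.default_rng(4)
        params = {
            f"c{i}": {"freshwater": (rng.normal(2, 1), rng.uniform(0.2, 1),
                                     int(rng.integers(5, 30))),
                      "saltwater": (rng.normal(2, 1), rng.uniform(0.2, 1),
                                    int(rng.integers(5, 30)))}
            for i in range(10)
        }
        fits = fits_frame(params)
        swapped = fits.assign(habitat=fits["habitat"].map(
            {"freshwater": "saltwater", "saltwater": "freshwater"}))
        rows, rows_sw = build_comparison(fits), build_comparison(swapped)
        assert np.allclose(rows["mean_fold_fw_sw"], rows_sw["mean_fold_sw_fw"])
        assert np.allclose(rows["hc5_fold_fw_sw"], rows_sw["hc5_fold_sw_fw"])
        # symmetric summaries are invariant under the swap
        fr = fraction_within(rows, "mean", (0.1, 10.0)).fraction_within
        fr_sw = fraction_within(rows_sw, "mean", (0.1, 10.0)).fraction_within
        assert fr == pytest.approx(fr_sw)
        _, p, _ = species_number_correlation(rows, "mean")
        _, p_sw, _ = species_number_correlation(rows_sw, "mean")
        assert p == pytest.approx(p_sw)


class TestFractionWithin:
    def _rows(self, folds, n_min=5):
        return pd.DataFrame({
            "chemical_id": [f"c{i}" for i in range(len(folds))],
            "mode_of_action": "narcotic",
            "n_min": n_min,
            "mean_fold_fw_sw": folds,
            "sd_ratio_fw_sw": folds,
            "hc5_fold_fw_sw": folds,
            "mean_fold_sw_fw": 1 / np.asarray(folds),
            "sd_ratio_sw_fw": 1 / np.asarray(folds),
            "hc5_fold_sw_fw": 1 / np.asarray(folds),
        })

    def test_offenders_are_itemized(self):
        summary = fraction_within(self._rows([0.5, 20.0]), "mean", (0.1, 10.0))
        assert summary.fraction_within == pytest.approx(0.5)
        assert summary.outside_ids == ["c1"]

    def test_all_unit_folds_are_within(self):
        summary = fraction_within(self._rows([1.0, 1.0, 1.0]), "sd", (0.25, 4.0))
        assert summary.fraction_within == 1.0 and summary.n_outside == 0

    def test_closed_interval_boundaries_count_as_within(self):
        summary = fraction_within(self._rows([0.1, 10.0]), "hc5", (0.1, 10.0))
        assert summary.fraction_within == 1.0

    def test_symmetric_range_equals_abs_log_criterion(self):
        rng = np.random.default_rng(8)
        folds = 10 ** rng.normal(0, 1, 200)
        summary = fraction_within(self._rows(folds), "mean", (0.1, 10.0))
        assert summary.fraction_within == pytest.approx(
            np.mean(np.abs(np.log10(folds)) <= 1.0))


class TestSpeciesNumberCorrelation:
    def test_matches_direct_formula(self):
        n_min = np.arange(5, 15)
        folds = 10.0 ** (2.0 / n_min)  # |log10 ratio| strictly decreasing
        rows = pd.DataFrame({
            "chemical_id": [f"c{i}" for i in range(10)],
            "mode_of_action": "narcotic", "n_min": n_min,
            "mean_fold_fw_sw": folds, "sd_ratio_fw_sw": folds,
            "hc5_fold_fw_sw": folds, "mean_fold_sw_fw": 1 / folds,
            "sd_ratio_sw_fw": 1 / folds, "hc5_fold_sw_fw": 1 / folds,
        })
        r, p, n = species_number_correlation(rows, "mean")
        abs_log = np.abs(np.log10(folds))
        r_direct = (np.corrcoef(n_min, abs_log))[0, 1]
        t_direct = r_direct * np.sqrt((n - 2) / (1 - r_direct**2))
        p_direct = 2 * stats.t.sf(abs(t_direct), n - 2)
        assert r == pytest.approx(r_direct) and r < 0
        assert p == pytest.approx(p_direct)

    def test_constant_ratios_are_degenerate(self):
        rows = pd.DataFrame({
            "chemical_id": list("abc"), "mode_of_action": "narcotic",
            "n_min": [5, 6, 7], "mean_fold_fw_sw": [2.0, 2.0, 2.0],
        })
        with pytest.raises(DegenerateRatioError):
            species_number_correlation(rows, "mean")

    def test_ratio_spread_shrinking_with_n_gives_negative_r(self):
        """Corpus built so the log-ratio spread scales as 1/sqrt(n_min):
        the correlation with |log ratio| must come out clearly negative."""
        rng = np.random.default_rng(21)
        n_chem = 100
        n_min = rng.integers(5, 60, n_chem)
        log_ratio = rng.normal(0, 1.5 / np.sqrt(n_min))
        rows = pd.DataFrame({
            "chemical_id": [f"c{i}" for i in range(n_chem)],
            "mode_of_action": "narcotic", "n_min": n_min,
            "mean_fold_fw_sw": 10.0 ** log_ratio,
        })
        r, p, _ = species_number_correlation(rows, "mean")
        assert r < 0 and p < 0.05


class TestMoaRatioTTest:
    def _rows(self, log_ratios_sw_fw, moa="narcotic"):
        folds_fw_sw = 10.0 ** (-np.asarray(log_ratios_sw_fw))
        return pd.DataFrame({
            "chemical_id": [f"c{i}" for i in range(len(folds_fw_sw))],
            "mode_of_action": moa, "n_min": 5,
            "mean_fold_fw_sw": folds_fw_sw, "sd_ratio_fw_sw": folds_fw_sw,
            "hc5_fold_fw_sw": folds_fw_sw,
        })

    def test_symmetric_ratios_give_t_zero(self):
        mean, t, df, p = moa_ratio_ttest(self._rows([-1.0, 1.0]), "mean", "narcotic")
        assert mean == pytest.approx(0.0)
        assert t == pytest.approx(0.0) and df == 1 and p == pytest.approx(1.0)

    def test_zero_variance_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            moa_ratio_ttest(self._rows([0.3, 0.3, 0.3]), "mean", "narcotic")

    def test_matches_closed_form(self):
        rng = np.random.default_rng(14)
        ratios = rng.normal(0.3, 0.5, 20)
        mean, t, df, p = moa_ratio_ttest(self._rows(ratios), "mean", "narcotic")
        se = ratios.std(ddof=1) / np.sqrt(20)
        t_direct = ratios.mean() / se
        assert mean == pytest.approx(ratios.mean())
        assert t == pytest.approx(t_direct) and df == 19
        assert p == pytest.approx(2 * stats.t.sf(abs(t_direct), 19))

    def test_missing_group_is_insufficient(self):
        with pytest.raises(InsufficientDataError):
            moa_ratio_ttest(self._rows([0.1, 0.2]), "mean", "specific")


class TestSubset:
    def test_threshold_filtering(self):
        rows = pd.DataFrame({"chemical_id": list("abcd"), "n_min": [5, 9, 10, 12]})
        assert len(subset_min_species(rows, 0)) == 4
        assert list(subset_min_species(rows, 10)["chemical_id"]) == ["c", "d"]
        assert subset_min_species(rows, 99).empty
        with pytest.raises(ValueError):
            subset_min_species(rows, -1)
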