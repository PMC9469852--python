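"""SPE fraction handling: blank subtraction, area-% profiles, fraction shares."""

import numpy as np
import pandas as pd
import pytest

import famequant as fq
from famequant.fractions import (
    BlankSubtractionError,
    FractionError,
    blank_subtract,
    fraction_area_percent,
    fraction_shares,
    replicate_fraction_shares,
)
from famequant.indices import class_sums

from fraction_reference import COLUMNS, FRACTION_COMPOSITION, PRINTED_SUBTOTALS


def frame(rows):
    return pd.DataFrame(rows, columns=["sample_id", "fish_id", "group", "series",
                                       "fraction", "fa_name", "area", "column_type"])


def ffa_peak(fa, area, sample="s1", fish="f1", col="A"):
    return ("%s" % sample, fish, "g", 1, "FFA", fa, area, col)


def blank_peak(fa, area, sample="b1", col="A"):
    return (sample, "blank", "blank", 0, "blank", fa, area, col)


class TestBlankSubtract:
    def test_mean_blank_area_subtracted(self):
        peaks = frame([ffa_peak("C16:0", 1000.0)])
        blanks = frame([blank_peak("C16:0", 900.0, "b1"), blank_peak("C16:0", 950.0, "b2")])
        out = blank_subtract(peaks, blanks)
        assert out["area"].iloc[0] == pytest.approx(75.0)
        assert not out["blank_clipped"].iloc[0]

    def test_zero_blanks_leave_peaks_unchanged(self):
        peaks = frame([ffa_peak("C16:0", 1000.0), ffa_peak("C18:1n-9c", 500.0)])
        blanks = frame([blank_peak("C16:0", 0.0)])
        out = blank_subtract(peaks, blanks)
        assert list(out["area"]) == [1000.0, 500.0]

    def test_oversubtraction_clips_to_zero_and_flags(self):
        peaks = frame([ffa_peak("C16:0", 100.0)])
        blanks = frame([blank_peak("C16:0", 150.0)])
        out = blank_subtract(peaks, blanks)
        assert out["area"].iloc[0] == 0.0
        assert bool(out["blank_clipped"].iloc[0])

    def test_non_contaminated_and_other_fractions_pass_through(self):
        rows = [ffa_peak("C22:6n-3c", 800.0),
                ("s1", "f1", "g", 1, "NL", "C16:0", 700.0, "A")]
        peaks = frame(rows)
        blanks = frame([blank_peak("C16:0", 100.0)])
        out = blank_subtract(peaks, blanks)
        assert list(out["area"]) == [800.0, 700.0]

    def test_double_correction_guard(self):
        peaks = frame([ffa_peak("C16:0", 1000.0)])
        blanks = frame([blank_peak("C16:0", 100.0)])
        once = blank_subtract(peaks, blanks)
        with pytest.raises(BlankSubtractionError, match="double"):
            blank_subtract(once, blanks)
        # re-subtracting with all-zero blanks is a no-op, not an error
        zero_blanks = frame([blank_peak("C16:0", 0.0)])
        again = blank_subtract(once, zero_blanks)
        assert list(again["area"]) == list(once["area"])

    def test_missing_blanks_or_column_type_errors(self):
        peaks = frame([ffa_peak("C16:0", 1000.0, col="B")])
        with pytest.raises(BlankSubtractionError, match="no blank runs"):
            blank_subtract(peaks, peaks.iloc[0:0])
        blanks = frame([blank_peak("C16:0", 100.0, col="A")])
        with pytest.raises(BlankSubtractionError, match="column type"):
            blank_subtract(peaks, blanks)


class TestAreaPercent:
    def test_single_peak_fraction_is_100(self):
        peaks = frame([ffa_peak("C16:0", 321.0)])
        out = fraction_area_percent(peaks)
        assert out["area_percent"].iloc[0] == pytest.approx(100.0)

    def test_is_peaks_excluded_from_totals(self):
        peaks = frame([ffa_peak("C16:0", 300.0), ffa_peak("C19:0 FFA", 700.0)])
        out = fraction_area_percent(peaks)
        assert len(out) == 1
        assert out["area_percent"].iloc[0] == pytest.approx(100.0)

    def test_zero_total_names_the_fraction(self):
        peaks = frame([ffa_peak("C16:0", 0.0)])
        with pytest.raises(FractionError, match="FFA"):
            fraction_area_percent(peaks)

    def test_percentages_sum_to_100_per_fraction(self, wild_fraction_peaks_noiseless):
        corr = blank_subtract(
            wild_fraction_peaks_noiseless[wild_fraction_peaks_noiseless.fraction != "blank"],
            wild_fraction_peaks_noiseless[wild_fraction_peaks_noiseless.fraction == "blank"],
        )
        pct = fraction_area_percent(corr)
        sums = pct.groupby(["sample_id", "fraction"])["area_percent"].sum()
        assert np.allclose(sums, 100.0, atol=0.1)


class TestShares:
    @staticmethod
    def three_fraction_frame(nl, ffa, pl, sample="s1", fish="f1", group="g"):
        return frame([
            (sample, fish, group, 1, "NL", "C16:0", nl, "A"),
            (sample, fish, group, 1, "FFA", "C16:0", ffa, "A"),
            (sample, fish, group, 1, "PL", "C16:0", pl, "A"),
        ])

    def test_equal_totals_give_equal_thirds(self):
        out = replicate_fraction_shares(self.three_fraction_frame(10.0, 10.0, 10.0))
        assert np.allclose(out["share_percent"], 100.0 / 3)

    def test_shares_sum_to_exactly_100_per_replicate(self):
        out = replicate_fraction_shares(self.three_fraction_frame(70.0, 25.0, 5.0))
        assert out["share_percent"].sum() == pytest.approx(100.0, abs=1e-12)

    def test_missing_fraction_errors(self):
        df = self.three_fraction_frame(10.0, 10.0, 10.0)
        with pytest.raises(FractionError, match="missing fraction"):
            replicate_fraction_shares(df[df.fraction != "PL"])

    def test_noiseless_simulation_recovers_configured_shares(self, wild_fraction_peaks_noiseless):
        """Generator/analyzer round trip: with zero noise and blank
        subtraction, the wild NL/FFA/PL shares come back exactly."""
        samples = wild_fraction_peaks_noiseless[wild_fraction_peaks_noiseless.fraction != "blank"]
        blanks = wild_fraction_peaks_noiseless[wild_fraction_peaks_noiseless.fraction == "blank"]
        shares = fraction_shares(blank_subtract(samples, blanks)).set_index("fraction")
        assert shares.loc["NL", "share_percent_mean"] == pytest.approx(74.4, abs=1e-9)
        assert shares.loc["FFA", "share_percent_mean"] == pytest.approx(20.1, abs=1e-9)
        assert shares.loc["PL", "share_percent_mean"] == pytest.approx(5.5, abs=1e-9)
        assert np.allclose(shares["share_percent_sd"], 0.0, atol=1e-9)


def test_published_fraction_class_sums_reconstructed():
    """Within each fraction, class sums recomputed from the published per-FA
    area-% rows match the printed subtotal rows within 0.05 points."""
    for j, (group, fraction) in enumerate(COLUMNS):
        profile = {
            name: vals[j]
            for name, vals in FRACTION_COMPOSITION.items()
            if vals[j] is not None
        }
        sums = class_sums(profile)
        assert sums.sum_sfa == pytest.approx(PRINTED_SUBTOTALS["SFA"][j], abs=0.05), (group, fraction)
        assert sums.sum_mufa == pytest.approx(PRINTED_SUBTOTALS["MUFA"][j], abs=0.05), (group, fraction)
        assert sums.sum_pufa == pytest.approx(PRINTED_SUBTOTALS["PUFA"][j], abs=0.05), (group, fraction)
        assert sums.sum_n3 == pytest.approx(PRINTED_SUBTOTALS["n-3"][j], abs=0.05), (group, fraction)
        assert sums.sum_n6 == pytest.approx(PRINTED_SUBTOTALS["n-6"][j], abs=0.05), (group, fraction)
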