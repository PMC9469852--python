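"""Internal-standard quantitation: IS mass, amounts, composition, aggregation."""

import io

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import famequant as fq
from famequant.quantitation import (
    ConfigError,
    FAProfile,
    ISSpec,
    QuantitationError,
    RunConfig,
    SchemaError,
    aggregate,
    composition,
    is_mass,
    quantify,
    read_peaks_csv,
)


def peaks_df(areas, sample_id="s1", is_name="C19:0 TAG", is_area=1000.0):
    rows = [
        {"sample_id": sample_id, "fish_id": "f1", "group": "g", "series": 1,
         "fraction": "whole", "fa_name": n, "area": a}
        for n, a in areas.items()
    ]
    if is_name is not None:
        rows.append({"sample_id": sample_id, "fish_id": "f1", "group": "g", "series": 1,
                     "fraction": "whole", "fa_name": is_name, "area": is_area})
    return pd.DataFrame(rows)


class TestISMass:
    def test_stock_times_volume(self):
        assert is_mass(ISSpec("C19:0 TAG", 10.0, 200.0)) == pytest.approx(2.0)
        assert is_mass(ISSpec("C19:0 FFA", 1.0, 15.0)) == pytest.approx(0.015)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ConfigError):
            ISSpec("C19:0 TAG", 10.0, 0.0)
        with pytest.raises(ConfigError):
            ISSpec("C19:0 TAG", -1.0, 10.0)

    def test_acyl_correction_shrinks_tag_mass(self):
        spec = ISSpec("C19:0 TAG", 10.0, 200.0)
        corrected = is_mass(spec, acyl_correction=True)
        assert corrected < 2.0
        assert corrected == pytest.approx(2.0 * 3 * 298.50 / 933.56)


class TestQuantify:
    cfg = RunConfig(sample_mass_g=0.5, is_specs=(ISSpec("C19:0 TAG", 10.0, 200.0),))

    def test_unit_ratio(self):
        # analyte area equal to IS area, 2 mg spike, 0.5 g sample -> 400 mg/100 g
        prof = quantify(peaks_df({"C16:0": 1000.0}), self.cfg)
        assert prof.amounts["C16:0"] == pytest.approx(400.0)

    def test_zero_area_gives_zero_amount(self):
        prof = quantify(peaks_df({"C16:0": 0.0}), self.cfg)
        assert prof.amounts["C16:0"] == 0.0

    def test_missing_is_peak_errors(self):
        with pytest.raises(QuantitationError, match="IS peak"):
            quantify(peaks_df({"C16:0": 10.0}, is_name=None), self.cfg)

    def test_zero_area_is_peak_errors(self):
        with pytest.raises(QuantitationError, match="non-positive area"):
            quantify(peaks_df({"C16:0": 10.0}, is_area=0.0), self.cfg)

    def test_c19_analyte_collides_with_is(self):
        with pytest.raises(QuantitationError, match="C19:0"):
            quantify(peaks_df({"C19:0": 10.0}), self.cfg)

    def test_dilution_factor_never_changes_amounts(self):
        diluted = RunConfig(sample_mass_g=0.5,
                            is_specs=(ISSpec("C19:0 TAG", 10.0, 200.0),),
                            dilution_factor=50.0)
        a = quantify(peaks_df({"C16:0": 123.0}), self.cfg).amounts
        b = quantify(peaks_df({"C16:0": 123.0}), diluted).amounts
        assert a == b

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(1e-6, 1e6))
    def test_homogeneity(self, k):
        """Scaling all areas (IS included) by k leaves every amount unchanged."""
        base = quantify(peaks_df({"C16:0": 250.0, "C22:6n-3c": 40.0}), self.cfg).amounts
        scaled = quantify(
            peaks_df({"C16:0": 250.0 * k, "C22:6n-3c": 40.0 * k}, is_area=1000.0 * k), self.cfg
        ).amounts
        for n in base:
            assert scaled[n] == pytest.approx(base[n], rel=1e-9)

    @settings(max_examples=50, derandomize=True)
    @given(st.floats(1e-6, 1e6))
    def test_linearity(self, k):
        """Scaling only analyte areas by k scales amounts by k."""
        base = quantify(peaks_df({"C16:0": 250.0}), self.cfg).amounts
        scaled = quantify(peaks_df({"C16:0": 250.0 * k}), self.cfg).amounts
        assert scaled["C16:0"] == pytest.approx(k * base["C16:0"], rel=1e-9)


class TestComposition:
    def test_reference_epa_dha_percentages(self):
        """EPA and DHA amounts over the wild reference total reproduce the
        published composition percentages."""
        prof = composition(FAProfile(amounts=fq.reference.amounts("wild")))
        assert prof.compositions["C20:5n-3c"] == pytest.approx(6.11, abs=0.01)
        assert prof.compositions["C22:6n-3c"] == pytest.approx(12.94, abs=0.01)

    def test_single_fa_is_100_percent(self):
        prof = composition(FAProfile(amounts={"C16:0": 5.0}))
        assert prof.compositions["C16:0"] == pytest.approx(100.0)

    def test_zero_total_errors(self):
        with pytest.raises(QuantitationError, match="total"):
            composition(FAProfile(amounts={"C16:0": 0.0}))

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=30))
    def test_compositions_sum_to_100(self, amounts):
        names = [f"C{12 + i % 13}:0" for i in range(len(amounts))]
        merged = {}
        for n, a in zip(names, amounts):
            merged[n] = merged.get(n, 0.0) + a
        prof = composition(FAProfile(amounts=merged))
        assert sum(prof.compositions.values()) == pytest.approx(100.0, abs=0.1)


class TestAggregate:
    @staticmethod
    def entry(group, fish, amounts):
        return (group, fish, FAProfile(amounts=amounts))

    def test_closed_form_mean_sd_across_fish(self):
        entries = [
            self.entry("g", f"fish{i}", {"C16:0": a, "C18:0": 1.0})
            for i, a in enumerate([470.0, 480.0, 490.0])
        ]
        out = aggregate(entries)
        assert out.loc[("g", "C16:0"), "amount_mean"] == pytest.approx(480.0)
        assert out.loc[("g", "C16:0"), "amount_sd"] == pytest.approx(10.0)

    def test_identical_profiles_have_zero_sd(self):
        entries = [self.entry("g", f"fish{i}", {"C16:0": 7.0}) for i in range(3)]
        out = aggregate(entries)
        assert out.loc[("g", "C16:0"), "amount_sd"] == 0.0
        assert out.loc[("g", "C16:0"), "amount_mean"] == pytest.approx(7.0)

    def test_technical_replicates_averaged_within_fish_first(self):
        # fish1 has two replicates (400, 500 -> mean 450); fish2 one (550)
        entries = [
            self.entry("g", "fish1", {"C16:0": 400.0}),
            self.entry("g", "fish1", {"C16:0": 500.0}),
            self.entry("g", "fish2", {"C16:0": 550.0}),
        ]
        out = aggregate(entries)
        assert out.loc[("g", "C16:0"), "amount_mean"] == pytest.approx((450.0 + 550.0) / 2)
        pooled = aggregate(entries, pooled=True)
        assert pooled.loc[("g", "C16:0"), "amount_mean"] == pytest.approx(1450.0 / 3)

    def test_absent_fa_counts_as_zero_and_all_absent_is_nd(self):
        entries = [
            self.entry("g", "fish1", {"C16:0": 100.0, "C12:0": 2.0}),
            self.entry("g", "fish2", {"C16:0": 100.0}),
        ]
        out = aggregate(entries)
        assert out.loc[("g", "C12:0"), "amount_mean"] == pytest.approx(1.0)
        assert bool(out.loc[("g", "C12:0"), "detected"])
        entries_nd = [
            self.entry("g", "fish1", {"C16:0": 100.0, "C12:0": 0.0}),
            self.entry("g", "fish2", {"C16:0": 100.0, "C12:0": 0.0}),
        ]
        out = aggregate(entries_nd)
        assert not bool(out.loc[("g", "C12:0"), "detected"])

    def test_empty_group_errors(self):
        with pytest.raises(QuantitationError):
            aggregate([])


class TestPeakCSV:
    def test_schema_violations_reported_with_rows(self, tmp_path):
        good = "sample_id,fish_id,group,series,fraction,fa_name,area\ns1,f1,g,1,whole,C16:0,10\n"
        p = tmp_path / "peaks.csv"
        p.write_text(good)
        assert len(read_peaks_csv(p)) == 1

        p.write_text(good.replace("whole", "nope"))
        with pytest.raises(SchemaError, match="fraction"):
            read_peaks_csv(p)

        p.write_text(good.replace("C16:0", "X16:0"))
        with pytest.raises(SchemaError, match="data row 1"):
            read_peaks_csv(p)

        p.write_text("sample_id,fa_name,area\ns1,C16:0,10\n")
        with pytest.raises(SchemaError, match="missing required columns"):
            read_peaks_csv(p)

        p.write_text(good.replace(",10", ",-10"))
        with pytest.raises(SchemaError, match="negative area"):
            read_peaks_csv(p)
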