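"""SPE lipid-class fractions: blank subtraction, area-% profiles, shares.

Total lipid extracts are fractionated on aminopropyl solid-phase extraction
(SPE) columns into neutral lipids (NL, mainly triacylglycerols), free fatty
acids (FFA) and polar lipids (PL, mainly phospholipids).  The FFA eluent is
known to pick up C14:0/C16:0/C18:0 bleed from the column material, so blank
runs (pure solvent through the same column type) are used to estimate and
subtract that contribution before any profile is computed.

Fraction profiles are reported as percentages of the fraction's total peak
area (internal standards excluded), and the relative abundance of the three
lipid classes as each fraction's share of the summed area across NL + FFA +
PL, per extraction replicate, aggregated to mean +/- SD across fish.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .quantitation import IS_NAMES

__all__ = [
    "BlankSubtractionError",
    "FractionError",
    "DEFAULT_CONTAMINATED",
    "LIPID_FRACTIONS",
    "blank_subtract",
    "fraction_area_percent",
    "replicate_fraction_shares",
    "fraction_shares",
    "aggregate_fraction_percent",
]

LIPID_FRACTIONS = ("NL", "FFA", "PL")
DEFAULT_CONTAMINATED = ("C14:0", "C16:0", "C18:0")


class BlankSubtractionError(ValueError):
    """Blank subtraction cannot proceed (no blanks, column mismatch, reapplication)."""


class FractionError(ValueError):
    """A fraction operation failed (empty or missing fraction)."""


def _column_types(df: pd.DataFrame) -> pd.Series:
    if "column_type" in df.columns:
        return df["column_type"].fillna("default")
    return pd.Series("default", index=df.index)


def blank_subtract(
    peaks: pd.DataFrame,
    blanks: pd.DataFrame,
    contaminated: Sequence[str] = DEFAULT_CONTAMINATED,
) -> pd.DataFrame:
    """Subtract mean blank-run areas from FFA-fraction sample peaks.

    For each contaminated FA the mean blank area is computed per SPE column
    type and subtracted from the matching FFA-fraction peaks; results that
    would go negative are clipped to 0 and flagged in a ``blank_clipped``
    column.  All other peaks pass through unchanged.  The returned frame
    carries a ``blank_corrected`` marker column; passing an already
    corrected frame back in with nonzero blanks raises, guarding against
    double correction.
    """
    if blanks is None or len(blanks) == 0:
        raise BlankSubtractionError("blank subtraction requested but no blank runs supplied")

    blanks = blanks.copy()
    blanks["column_type"] = _column_types(blanks)
    blank_means = (
        blanks[blanks["fa_name"].isin(contaminated)]
        .groupby(["column_type", "fa_name"])["area"]
        .mean()
    )

    out = peaks.copy()
    out["column_type"] = _column_types(out)
    if "blank_corrected" in peaks.columns and peaks["blank_corrected"].any():
        if (blank_means > 0).any():
            raise BlankSubtractionError(
                "peaks are already blank-corrected; re-subtracting nonzero blanks "
                "would double-correct"
            )
    out["blank_corrected"] = out.get("blank_corrected", False)
    out["blank_clipped"] = out.get("blank_clipped", False)

    target = (out["fraction"] == "FFA") & out["fa_name"].isin(contaminated)
    sample_types = set(out.loc[target, "column_type"])
    blank_types = set(blank_means.index.get_level_values("column_type"))
    unmatched = sample_types - blank_types
    if unmatched and (blank_means > 0).any():
        raise BlankSubtractionError(
            f"no blank runs for column type(s) {sorted(unmatched)}; "
            f"blanks cover {sorted(blank_types)}"
        )

    for idx in out.index[target]:
        key = (out.at[idx, "column_type"], out.at[idx, "fa_name"])
        mean = float(blank_means.get(key, 0.0))
        corrected = out.at[idx, "area"] - mean
        if corrected < 0:
            out.at[idx, "area"] = 0.0
            out.at[idx, "blank_clipped"] = True
        else:
            out.at[idx, "area"] = corrected
        out.at[idx, "blank_corrected"] = True
    return out


def _analyte_rows(peaks: pd.DataFrame) -> pd.DataFrame:
    """Sample rows of the three lipid fractions, IS peaks excluded."""
    df = peaks[peaks["fraction"].isin(LIPID_FRACTIONS)]
    return df[~df["fa_name"].isin(IS_NAMES)]


def fraction_area_percent(peaks: pd.DataFrame) -> pd.DataFrame:
    """Per-FA percentage of the fraction's total peak area, per replicate.

    Returns a tidy frame with columns ``sample_id, fish_id, group, fraction,
    fa_name, area_percent``.  Internal-standard peaks are excluded from the
    totals.  A fraction whose total area is zero raises, naming the
    fraction.
    """
    df = _analyte_rows(peaks)
    if df.empty:
        raise FractionError("no lipid-fraction peaks (NL/FFA/PL) in input")
    totals = df.groupby(["sample_id", "fraction"])["area"].transform("sum")
    zero = df.loc[totals <= 0, ["sample_id", "fraction"]].drop_duplicates()
    if not zero.empty:
        sid, frac = zero.iloc[0]
        raise FractionError(f"fraction {frac!r} of sample {sid!r} has zero total area")
    out = df[["sample_id", "fish_id", "group", "fraction", "fa_name"]].copy()
    out["area_percent"] = df["area"] / totals * 100.0
    return out.reset_index(drop=True)


def replicate_fraction_shares(peaks: pd.DataFrame) -> pd.DataFrame:
    """Each fraction's share (%) of the summed NL+FFA+PL area, per replicate.

    Shares sum to exactly 100 within every replicate.  A replicate missing
    one of the three fractions raises.
    """
    df = _analyte_rows(peaks)
    if df.empty:
        raise FractionError("no lipid-fraction peaks (NL/FFA/PL) in input")
    totals = df.groupby(["sample_id", "fraction"], as_index=False).agg(
        fish_id=("fish_id", "first"), group=("group", "first"), area=("area", "sum")
    )
    for sid, sdf in totals.groupby("sample_id"):
        missing = set(LIPID_FRACTIONS) - set(sdf["fraction"])
        if missing:
            raise FractionError(f"sample {sid!r} is missing fraction(s) {sorted(missing)}")
    grand = totals.groupby("sample_id")["area"].transform("sum")
    totals["share_percent"] = totals["area"] / grand * 100.0
    return totals[["sample_id", "fish_id", "group", "fraction", "share_percent"]]


def _two_stage(df: pd.DataFrame, value: str, by: Sequence[str]) -> pd.DataFrame:
    """Mean over replicates within fish, then mean/SD (n-1) across fish."""
    fish_means = df.groupby(list(by) + ["fish_id"], as_index=False)[value].mean()
    agg = fish_means.groupby(list(by))[value].agg(["mean", "std", "count"]).reset_index()
    agg = agg.rename(columns={"mean": f"{value}_mean", "std": f"{value}_sd", "count": "n_fish"})
    agg[f"{value}_sd"] = agg[f"{value}_sd"].fillna(0.0)
    return agg


def fraction_shares(peaks: pd.DataFrame) -> pd.DataFrame:
    """Group-level fraction shares: mean +/- SD across fish.

    Per-replicate shares from :func:`replicate_fraction_shares` are averaged
    within each fish, then mean and sample SD are taken across fish, per
    group and fraction.
    """
    per_rep = replicate_fraction_shares(peaks)
    return _two_stage(per_rep, "share_percent", ["group", "fraction"])


def aggregate_fraction_percent(peaks: pd.DataFrame) -> pd.DataFrame:
    """Group-level per-FA area-% within each fraction, mean +/- SD across fish.

    An FA absent from a replicate of a fraction counts as 0% in that
    replicate, mirroring the amount aggregation.
    """
    pct = fraction_area_percent(peaks)
    # complete the FA grid within each (group, fraction) so absences count as 0
    full = (
        pct.pivot_table(
            index=["group", "fraction", "fa_name"],
            columns=["sample_id"],
            values="area_percent",
            fill_value=np.nan,
        )
    )
    fish_of = pct.drop_duplicates("sample_id").set_index("sample_id")["fish_id"]
    frames = []
    for (group, fraction), sub in full.groupby(level=["group", "fraction"]):
        block = sub.droplevel(["group", "fraction"])
        block = block.dropna(axis=1, how="all").fillna(0.0)
        tidy = block.stack().rename("area_percent").reset_index()
        tidy.columns = ["fa_name", "sample_id", "area_percent"]
        tidy["fish_id"] = tidy["sample_id"].map(fish_of)
        agg = _two_stage(tidy, "area_percent", ["fa_name"])
        agg.insert(0, "fraction", fraction)
        agg.insert(0, "group", group)
        frames.append(agg)
    return pd.concat(frames, ignore_index=True)
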