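"""Reference fatty-acid profiles of Atlantic salmon muscle and salmon feed.

These are published GC-MS reference values for wild Atlantic salmon muscle,
farmed Atlantic salmon muscle, and the commercial feed given to the farmed
fish: per-FA composition (% of total FA content) and absolute amount
(mg per 100 g of muscle or feed), quantitated against C19:0 internal
standards.  They serve two purposes here:

* ground-truth presets for the synthetic peak-table generator, so every
  pipeline stage can be exercised end-to-end without instrument data, and
* worked-example inputs for the nutritional indices and dietary assessment.

``None`` means the FA was not detected (n.d.) in that group.
"""

from __future__ import annotations

from typing import Dict, Optional

__all__ = [
    "GROUPS",
    "FA_ROWS",
    "amounts",
    "compositions",
    "LIPID_CONTENT_PERCENT",
    "FRACTION_SHARES_PERCENT",
    "PROVISIONAL_IDS",
]

GROUPS = ("wild", "farmed", "feed")

# name -> (composition %, amount mg/100 g) per group; None for not detected.
# Row order follows the conventional report layout: SFAs, then MUFAs, then
# PUFAs, each by increasing chain length.
FA_ROWS: Dict[str, Dict[str, Optional[tuple]]] = {
    # --- saturated ---
    "C12:0":                    {"wild": (0.05, 1.38),    "farmed": None,            "feed": None},
    "C13:0 (4,8,12-trimethyl)": {"wild": (0.063, 1.71),   "farmed": None,            "feed": None},
    "C14:0":                    {"wild": (3.43, 93.7),    "farmed": (1.71, 145.5),   "feed": (2.18, 653.1)},
    "C14:0 (13-methyl)":        {"wild": (0.14, 3.71),    "farmed": (0.03, 2.71),    "feed": (0.07, 19.53)},
    "C14:0 (12-methyl)":        {"wild": (0.09, 2.33),    "farmed": (0.018, 1.57),   "feed": (0.027, 8.04)},
    "C15:0":                    {"wild": (0.30, 8.13),    "farmed": (0.09, 7.94),    "feed": (0.19, 56.11)},
    "C16:0":                    {"wild": (17.43, 475.7),  "farmed": (9.61, 819.0),   "feed": (10.32, 3097.4)},
    "C17:0":                    {"wild": (0.43, 11.67),   "farmed": (0.18, 15.44),   "feed": (0.34, 101.22)},
    "C18:0":                    {"wild": (4.31, 117.7),   "farmed": (2.94, 250.4),   "feed": (4.37, 1312.0)},
    "C20:0":                    {"wild": (0.08, 2.22),    "farmed": (0.29, 24.54),   "feed": (0.49, 146.34)},
    "C22:0":                    {"wild": None,            "farmed": (0.09, 7.81),    "feed": (0.23, 70.27)},
    "C24:0":                    {"wild": None,            "farmed": (0.035, 2.95),   "feed": (0.119, 35.71)},
    # --- monounsaturated ---
    "C16:1n-9c":                {"wild": (0.13, 3.66),    "farmed": (0.11, 9.63),    "feed": (0.09, 25.77)},
    "C16:1n-7c":                {"wild": (6.39, 174.5),   "farmed": (2.57, 219.1),   "feed": (3.12, 935.8)},
    "C16:1n-5c":                {"wild": (0.19, 5.14),    "farmed": None,            "feed": None},
    "C17:1n-7c":                {"wild": (0.26, 6.95),    "farmed": (0.08, 6.78),    "feed": (0.09, 27.50)},
    "C18:1n-12c":               {"wild": (0.78, 21.32),   "farmed": (0.12, 10.25),   "feed": None},
    "C18:1n-9c":                {"wild": (17.14, 467.7),  "farmed": (44.0, 3756.0),  "feed": (41.42, 12427.0)},
    "C18:1n-7c":                {"wild": (3.86, 105.46),  "farmed": (3.00, 256.3),   "feed": (2.96, 887.6)},
    "C18:1n-5c":                {"wild": (0.22, 6.12),    "farmed": None,            "feed": None},
    "C20:1n-11c":               {"wild": (0.79, 21.54),   "farmed": (0.14, 11.88),   "feed": (0.13, 37.60)},
    "C20:1n-9c":                {"wild": (8.05, 219.0),   "farmed": (3.43, 292.3),   "feed": (1.95, 583.9)},
    "C20:1n-7c":                {"wild": (0.23, 6.31),    "farmed": (0.09, 7.47),    "feed": (0.09, 26.48)},
    "C22:1n-9c":                {"wild": (8.85, 241.5),   "farmed": (1.46, 124.8),   "feed": (1.17, 352.5)},
    "C24:1n-9c":                {"wild": (0.50, 13.50),   "farmed": (0.36, 30.3),    "feed": (0.21, 61.57)},
    # --- polyunsaturated ---
    "C16:2n-4c":                {"wild": (0.24, 6.62),    "farmed": (0.14, 11.58),   "feed": (0.28, 83.11)},
    "C18:2n-6c":                {"wild": (0.84, 22.94),   "farmed": (13.83, 1179.0), "feed": (13.86, 4157.0)},
    "C18:3n-6c":                {"wild": None,            "farmed": (0.06, 5.54),    "feed": (0.053, 16.04)},
    "C18:3n-3c":                {"wild": (0.64, 17.51),   "farmed": (5.66, 482.9),   "feed": (7.99, 2396.5)},
    "C18:4n-3c":                {"wild": (0.86, 23.58),   "farmed": (0.43, 36.29),   "feed": (0.56, 167.5)},
    "C20:2n-6c":                {"wild": (0.21, 5.71),    "farmed": (0.84, 71.5),    "feed": (0.09, 26.17)},
    "C20:3n-6c":                {"wild": (0.06, 1.54),    "farmed": (0.16, 14.00),   "feed": (0.044, 62.00)},
    "C20:3n-3c":                {"wild": (0.15, 3.98),    "farmed": (0.34, 29.27),   "feed": (0.036, 10.67)},
    "C20:4n-6c":                {"wild": (0.26, 7.17),    "farmed": (0.13, 10.75),   "feed": (0.21, 10.01)},
    "C20:4n-3c":                {"wild": (1.10, 29.93),   "farmed": (0.59, 50.7),    "feed": (0.22, 66.29)},
    "C20:5n-3c":                {"wild": (6.11, 166.8),   "farmed": (2.19, 186.7),   "feed": (3.01, 903.8)},
    "C21:5n-3c":                {"wild": (0.30, 8.24),    "farmed": (0.22, 18.68),   "feed": (0.18, 55.20)},
    "C22:5n-3c":                {"wild": (2.57, 70.18),   "farmed": (1.11, 94.7),    "feed": (0.54, 160.0)},
    "C22:6n-3c":                {"wild": (12.94, 353.2),  "farmed": (3.94, 335.8),   "feed": (3.39, 1016.1)},
}

# Externally measured total lipid content (% of muscle mass); not available
# for the feed in this dataset.
LIPID_CONTENT_PERCENT: Dict[str, Optional[float]] = {
    "wild": 2.14,
    "farmed": 8.97,
    "feed": None,
}

# Share of summed peak area per SPE lipid-class fraction (% of total), used
# as default fraction partitions by the synthetic generator.
FRACTION_SHARES_PERCENT: Dict[str, Dict[str, float]] = {
    "wild": {"NL": 74.4, "FFA": 20.1, "PL": 5.5},
    "farmed": {"NL": 86.9, "FFA": 6.1, "PL": 7.0},
}

# FAs identified only by spectral-library search, not confirmed against an
# authentic standard; reports can flag these when configured to.
PROVISIONAL_IDS = frozenset({"C13:0 (4,8,12-trimethyl)", "C20:1n-7c"})


def amounts(group: str) -> Dict[str, float]:
    """Per-FA amounts (mg/100 g) for one group, detected FAs only."""
    _check_group(group)
    return {name: vals[group][1] for name, vals in FA_ROWS.items() if vals[group] is not None}


def compositions(group: str) -> Dict[str, float]:
    """Per-FA composition (% of total FA content) for one group, detected FAs only."""
    _check_group(group)
    return {name: vals[group][0] for name, vals in FA_ROWS.items() if vals[group] is not None}


def _check_group(group: str) -> None:
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
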