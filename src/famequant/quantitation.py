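"""Internal-standard quantitation of identified GC-MS FAME peaks.

Absolute amounts are obtained by single-point internal-standard (IS)
calibration: a known mass of a C19:0 species (absent from fish lipids) is
spiked into each sample before extraction, and every analyte amount follows
from its peak-area ratio to the IS peak under a unit mass-response
assumption::

    amount_i [mg/100 g] = (area_i / area_IS) * m_IS [mg] * 100 / m_sample [g]

Because IS and analytes share the vial, any dilution or injection-volume
factor multiplies both areas and cancels in the ratio; the configured
dilution factor is bookkeeping only and never changes a result.

Compositions (% of total FA content) are derived from amounts, and replicate
tables are aggregated in two stages: technical replicates are averaged
within each fish, then the mean and sample standard deviation (n-1
denominator) are taken across fish.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence, Tuple

import pandas as pd

from .nomenclature import FANameError, parse_fa_name

__all__ = [
    "ISSpec",
    "RunConfig",
    "FAProfile",
    "ConfigError",
    "QuantitationError",
    "SchemaError",
    "IS_NAMES",
    "IS_FOR_FRACTION",
    "is_mass",
    "quantify",
    "composition",
    "aggregate",
    "read_peaks_csv",
    "PEAK_COLUMNS",
]


class ConfigError(ValueError):
    """Invalid run configuration (non-positive masses, volumes, ...)."""


class QuantitationError(ValueError):
    """Quantitation cannot proceed (missing/zero IS peak, IS as analyte, ...)."""


class SchemaError(ValueError):
    """A peak-table CSV violates the expected schema."""


# The three IS species and the SPE fraction each one calibrates.
IS_NAMES = ("C19:0 TAG", "C19:0 FFA", "C19:0 Pl")
IS_FOR_FRACTION = {"whole": "C19:0 TAG", "NL": "C19:0 TAG", "FFA": "C19:0 FFA", "PL": "C19:0 Pl"}

# Fatty-acid mass per mg of spiked standard, used by the optional acyl
# correction: a TAG or phospholipid spike weighs more than the fatty acids
# it contributes to the FAME pool (glycerol/head-group overhead).
# C19:0 free acid 298.50 g/mol; trinonadecanoin 933.56; di-C19:0 PC 818.22.
_ACYL_MASS_FRACTION = {
    "C19:0 TAG": 3 * 298.50 / 933.56,
    "C19:0 FFA": 1.0,
    "C19:0 Pl": 2 * 298.50 / 818.22,
}

PEAK_COLUMNS = ("sample_id", "fish_id", "group", "series", "fraction", "fa_name", "area")
FRACTIONS = ("whole", "NL", "FFA", "PL", "blank")


@dataclass(frozen=True)
class ISSpec:
    """One internal-standard spike: stock concentration and added volume."""

    name: str
    concentration_mg_per_ml: float
    volume_ul: float

    def __post_init__(self) -> None:
        if self.name not in IS_NAMES:
            raise ConfigError(f"unknown internal standard {self.name!r}; expected one of {IS_NAMES}")
        if self.concentration_mg_per_ml <= 0:
            raise ConfigError(f"IS stock concentration must be positive, got {self.concentration_mg_per_ml}")
        if self.volume_ul <= 0:
            raise ConfigError(f"IS spike volume must be positive, got {self.volume_ul}")


@dataclass(frozen=True)
class RunConfig:
    """Per-sample quantitation parameters.

    Parameters
    ----------
    sample_mass_g:
        Wet mass of muscle/feed worked up per replicate (default 0.5 g).
    is_specs:
        One :class:`ISSpec` per IS species in use.
    dilution_factor:
        Final dilution of the vial before injection (>= 1).  IS and analytes
        are diluted together, so this cancels in quantitation.
    acyl_correction:
        If True, use the fatty-acid (acyl) mass of the spike rather than the
        full spike mass, correcting for the glycerol/head-group overhead of
        TAG and phospholipid standards.
    """

    sample_mass_g: float = 0.5
    is_specs: Tuple[ISSpec, ...] = (ISSpec("C19:0 TAG", 10.0, 100.0),)
    dilution_factor: float = 1.0
    acyl_correction: bool = False

    def __post_init__(self) -> None:
        if self.sample_mass_g <= 0:
            raise ConfigError(f"sample mass must be positive, got {self.sample_mass_g}")
        if self.dilution_factor < 1:
            raise ConfigError(f"dilution factor must be >= 1, got {self.dilution_factor}")
        if not self.is_specs:
            raise ConfigError("at least one internal standard must be configured")
        names = [s.name for s in self.is_specs]
        if len(set(names)) != len(names):
            raise ConfigError(f"duplicate internal standards configured: {names}")
        object.__setattr__(self, "is_specs", tuple(self.is_specs))

    def is_spec(self, name: str) -> ISSpec:
        for spec in self.is_specs:
            if spec.name == name:
                return spec
        raise ConfigError(f"no spike configured for internal standard {name!r}")


def is_mass(spec: ISSpec, acyl_correction: bool = False) -> float:
    """Spiked IS mass in mg: concentration (mg/ml) x volume (ul -> ml).

    With ``acyl_correction`` the result is the fatty-acid-equivalent mass of
    the spike (TAG/phospholipid overhead removed).
    """
    mg = spec.concentration_mg_per_ml * spec.volume_ul / 1000.0
    if acyl_correction:
        mg *= _ACYL_MASS_FRACTION[spec.name]
    return mg


@dataclass
class FAProfile:
    """Per-sample (or aggregated) fatty-acid profile.

    ``amounts`` maps canonical FA name to mg per 100 g of sample;
    ``compositions`` (filled by :func:`composition`) maps the same names to
    % of total FA content.  ``lipid_content`` is the externally measured
    total lipid mass fraction of the sample in %, carried along for dietary
    arithmetic.
    """

    amounts: Dict[str, float]
    lipid_content: Optional[float] = None
    compositions: Optional[Dict[str, float]] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, amt in self.amounts.items():
            if amt < 0:
                raise QuantitationError(f"negative amount for {name}: {amt}")

    @property
    def total_fa(self) -> float:
        """Total FA amount, mg/100 g."""
        return float(sum(self.amounts.values()))

    def scaled(self, k: float) -> "FAProfile":
        return replace(self, amounts={n: a * k for n, a in self.amounts.items()}, compositions=None)


def quantify(peaks: pd.DataFrame, cfg: RunConfig, fraction: str = "whole") -> FAProfile:
    """Convert one sample's identified peak areas into amounts (mg/100 g).

    ``peaks`` must hold the rows of a single sample (one extraction
    replicate) for one fraction, including exactly one IS peak whose
    ``fa_name`` matches the IS species for that fraction.

    Raises
    ------
    QuantitationError
        If the IS peak is missing, duplicated or has zero area; if an
        analyte is itself a C19:0 species (indistinguishable from the IS);
        or if an analyte name fails to parse.
    """
    is_name = IS_FOR_FRACTION.get(fraction)
    if is_name is None:
        raise QuantitationError(f"cannot quantify fraction {fraction!r}")
    if peaks.empty:
        raise QuantitationError("empty peak set")
    sample_ids = peaks["sample_id"].unique() if "sample_id" in peaks else ["<unknown>"]
    if len(sample_ids) != 1:
        raise QuantitationError(f"quantify() expects one sample at a time, got {list(sample_ids)}")

    is_rows = peaks[peaks["fa_name"] == is_name]
    if len(is_rows) != 1:
        raise QuantitationError(
            f"sample {sample_ids[0]}: expected exactly one {is_name} IS peak, found {len(is_rows)}"
        )
    area_is = float(is_rows["area"].iloc[0])
    if area_is <= 0:
        raise QuantitationError(f"sample {sample_ids[0]}: IS peak {is_name} has non-positive area")

    m_is = is_mass(cfg.is_spec(is_name), cfg.acyl_correction)
    factor = m_is * 100.0 / cfg.sample_mass_g

    amounts: Dict[str, float] = {}
    for _, row in peaks[peaks["fa_name"] != is_name].iterrows():
        name = row["fa_name"]
        if name in IS_NAMES:
            continue  # IS peaks of other fractions never enter analyte totals
        try:
            fa = parse_fa_name(name)
        except FANameError as exc:
            raise QuantitationError(f"sample {sample_ids[0]}: {exc}") from exc
        if fa.chain_length == 19 and fa.double_bonds == 0 and not fa.branches:
            raise QuantitationError(
                f"sample {sample_ids[0]}: analyte {name} collides with the C19:0 internal standard"
            )
        area = float(row["area"])
        if area < 0:
            raise QuantitationError(f"sample {sample_ids[0]}: negative area for {name}")
        amounts[fa.display_name] = amounts.get(fa.display_name, 0.0) + area / area_is * factor
    return FAProfile(amounts=amounts, meta={"sample_id": sample_ids[0], "fraction": fraction})


def composition(profile: FAProfile) -> FAProfile:
    """Fill per-FA composition (% of total FA amount) into a profile."""
    total = profile.total_fa
    if total <= 0:
        raise QuantitationError("composition undefined: total FA amount is zero")
    comps = {name: amt / total * 100.0 for name, amt in profile.amounts.items()}
    return replace(profile, compositions=comps)


def aggregate(
    entries: Sequence[Tuple[str, str, FAProfile]],
    pooled: bool = False,
) -> pd.DataFrame:
    """Aggregate replicate profiles to group-level mean +/- SD tables.

    Parameters
    ----------
    entries:
        ``(group, fish_id, profile)`` triples, one per technical replicate.
    pooled:
        If False (default), average technical replicates within each fish
        first, then take mean and sample SD (n-1) across fish.  If True,
        pool all replicates of a group into one mean/SD.

    Returns
    -------
    DataFrame indexed by ``(group, fa_name)`` with columns ``amount_mean``,
    ``amount_sd``, ``composition_mean``, ``composition_sd``, ``n_fish``,
    ``detected``.  An FA absent from a replicate contributes 0 to that
    replicate; an FA absent from every replicate of a group is marked
    ``detected=False`` (reported as n.d.).
    """
    if not entries:
        raise QuantitationError("nothing to aggregate")

    rows = []
    for i, (group, fish_id, profile) in enumerate(entries):
        prof = profile if profile.compositions is not None else composition(profile)
        for name in prof.amounts:
            rows.append(
                {
                    "group": group,
                    "fish_id": fish_id,
                    "replicate": i,
                    "fa_name": name,
                    "amount": prof.amounts[name],
                    "composition": prof.compositions[name],
                }
            )
    tidy = pd.DataFrame(rows)

    out_frames = []
    for group, gdf in tidy.groupby("group", sort=False):
        # complete FA x replicate grid; absent FA counts as 0 in that replicate
        amt = gdf.pivot_table(index="fa_name", columns="replicate", values="amount", fill_value=0.0)
        comp = gdf.pivot_table(index="fa_name", columns="replicate", values="composition", fill_value=0.0)
        fish_of = gdf.drop_duplicates("replicate").set_index("replicate")["fish_id"]

        if pooled:
            amt_mean, amt_sd = amt.mean(axis=1), amt.std(axis=1, ddof=1)
            comp_mean, comp_sd = comp.mean(axis=1), comp.std(axis=1, ddof=1)
            n_fish = fish_of.nunique()
        else:
            amt_fish = amt.T.groupby(fish_of).mean().T
            comp_fish = comp.T.groupby(fish_of).mean().T
            amt_mean, amt_sd = amt_fish.mean(axis=1), amt_fish.std(axis=1, ddof=1)
            comp_mean, comp_sd = comp_fish.mean(axis=1), comp_fish.std(axis=1, ddof=1)
            n_fish = amt_fish.shape[1]

        detected = (amt > 0).any(axis=1)
        out = pd.DataFrame(
            {
                "amount_mean": amt_mean,
                "amount_sd": amt_sd.fillna(0.0),
                "composition_mean": comp_mean,
                "composition_sd": comp_sd.fillna(0.0),
                "n_fish": n_fish,
                "detected": detected,
            }
        )
        out.insert(0, "group", group)
        out_frames.append(out.reset_index())
    result = pd.concat(out_frames, ignore_index=True)
    return result.set_index(["group", "fa_name"])


def read_peaks_csv(path) -> pd.DataFrame:
    """Read a peak-table CSV and validate its schema.

    Required columns: ``sample_id, fish_id, group, series, fraction,
    fa_name, area`` (UTF-8, '.' decimal separator).  An optional
    ``column_type`` column carries the SPE column type for fraction data.
    Violations are reported with 1-based data row numbers.
    """
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"peak table is missing required columns: {missing}")

    areas = pd.to_numeric(df["area"], errors="coerce")
    bad = df.index[areas.isna()].tolist()
    if bad:
        raise SchemaError(f"non-numeric area values at data rows {[i + 1 for i in bad[:5]]}")
    df["area"] = areas.astype(float)
    neg = df.index[df["area"] < 0].tolist()
    if neg:
        raise SchemaError(f"negative area values at data rows {[i + 1 for i in neg[:5]]}")

    bad_frac = df.index[~df["fraction"].isin(FRACTIONS)].tolist()
    if bad_frac:
        raise SchemaError(
            f"unknown fraction values at data rows {[i + 1 for i in bad_frac[:5]]}; "
            f"expected one of {FRACTIONS}"
        )

    for i, name in df["fa_name"].items():
        if name in IS_NAMES:
            continue
        try:
            parse_fa_name(name)
        except FANameError as exc:
            raise SchemaError(f"data row {i + 1}: {exc}") from exc
    return df
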