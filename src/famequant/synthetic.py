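"""Synthetic GC-MS FAME peak tables with known ground truth.

Emulates the experimental design the pipeline targets — n fish per group,
two series of technical replicates, C19:0 IS spikes of known mass, per-vial
dilution, SPE fractionation on two column types, and FFA-fraction blank
contamination — so every downstream stage can be tested end-to-end against
a known truth without instrument data.

The signal model per replicate is a proportional detector response::

    area_i  = R * m_i / D * F_fish * eps_i      (analyte i)
    area_IS = R * m_IS / D * eps_IS             (internal standard)

where ``m_i`` is the analyte mass in the vial (true amount x sample mass /
100), ``D`` the dilution factor, ``F_fish`` a per-fish lognormal multiplier
(biological variation, CV ``fish_cv``) and ``eps`` i.i.d. lognormal
measurement noise with CV ``cv``.  All lognormal factors have mean 1, and
the same per-replicate response ``R`` and dilution apply to the IS, so the
unit-response IS calibration inverts the model exactly when both CVs are 0.
Multiplicative lognormal noise keeps areas positive and right-skewed, as
detector areas are.

Default noise magnitudes are chosen to emulate the reference data: a
technical CV of 5% and a between-fish CV of 15%, the order of the
between-fish SDs reported for salmon muscle FA amounts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from . import reference
from .quantitation import IS_FOR_FRACTION, RunConfig, ISSpec, is_mass

__all__ = [
    "TrueProfile",
    "NoiseModel",
    "SyntheticError",
    "preset_profile",
    "preset_config",
    "simulate_peaks",
    "simulate_fraction_run",
    "DEFAULT_BLANK_AREAS",
]

#: Detector response, area counts per mg in the vial.  Arbitrary: all
#: quantitation is ratio-based, so its value never affects a result.
_RESPONSE = 5.0e4

#: Default mean blank-bleed areas for the FFA fraction (area counts).
DEFAULT_BLANK_AREAS = {"C14:0": 900.0, "C16:0": 2500.0, "C18:0": 1400.0}

_COLUMN_TYPE_OF_SERIES = {1: "Discovery", 2: "Bond-Elut"}


class SyntheticError(ValueError):
    """Invalid generator configuration."""


@dataclass
class TrueProfile:
    """Ground truth for one group: per-FA amounts and fraction split.

    ``fraction_partition`` maps each FA to its mass share over (NL, FFA, PL),
    each triple summing to 1; ``None`` disables fraction simulation.
    """

    amounts: Dict[str, float]
    lipid_content: Optional[float] = None
    fraction_partition: Optional[Dict[str, Tuple[float, float, float]]] = None

    def __post_init__(self) -> None:
        for name, amt in self.amounts.items():
            if amt < 0:
                raise SyntheticError(f"negative true amount for {name}")
        if self.fraction_partition is not None:
            for name, triple in self.fraction_partition.items():
                if len(triple) != 3 or any(p < 0 for p in triple):
                    raise SyntheticError(f"invalid partition for {name}: {triple}")
                if abs(sum(triple) - 1.0) > 1e-9:
                    raise SyntheticError(
                        f"partition for {name} sums to {sum(triple)}, expected 1"
                    )


@dataclass
class NoiseModel:
    """Multiplicative noise and contamination settings for the generator."""

    cv: float = 0.05
    fish_cv: float = 0.15
    blank_areas: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BLANK_AREAS))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cv < 0 or self.fish_cv < 0:
            raise SyntheticError("noise CVs must be non-negative")
        if any(a < 0 for a in self.blank_areas.values()):
            raise SyntheticError("blank areas must be non-negative")


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    """Mean-1 lognormal multiplier(s) with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=size))


def preset_profile(group: str, with_fractions: bool = True) -> TrueProfile:
    """Ground-truth profile for one reference group (wild / farmed / feed).

    Amounts are the reference mg/100 g values; the fraction partition (when
    available and requested) applies the group's reference NL/FFA/PL shares
    uniformly to every FA.
    """
    amounts = reference.amounts(group)
    partition = None
    if with_fractions and group in reference.FRACTION_SHARES_PERCENT:
        shares = reference.FRACTION_SHARES_PERCENT[group]
        total = sum(shares.values())
        triple = tuple(shares[f] / total for f in ("NL", "FFA", "PL"))
        partition = {name: triple for name in amounts}
    return TrueProfile(
        amounts=amounts,
        lipid_content=reference.LIPID_CONTENT_PERCENT[group],
        fraction_partition=partition,
    )


def preset_config(group: str, fractions: bool = False) -> RunConfig:
    """Run configuration mirroring the reference workup for one group.

    First-series IS volumes and the per-group dilution factors of the
    reference protocol: wild 1:10, farmed 1:50, feed 1:100; fraction runs
    are injected undiluted and carry all three IS species.
    """
    volumes = {"wild": 100.0, "farmed": 200.0, "feed": 200.0}
    dilution = {"wild": 10.0, "farmed": 50.0, "feed": 100.0}
    if fractions:
        v_ffa = {"wild": 10.0, "farmed": 15.0, "feed": 15.0}
        v_pl = {"wild": 25.0, "farmed": 50.0, "feed": 50.0}
        return RunConfig(
            sample_mass_g=0.5,
            is_specs=(
                ISSpec("C19:0 TAG", 10.0, volumes[group]),
                ISSpec("C19:0 FFA", 10.0, v_ffa[group]),
                ISSpec("C19:0 Pl", 10.0, v_pl[group]),
            ),
            dilution_factor=1.0,
        )
    return RunConfig(
        sample_mass_g=0.5,
        is_specs=(ISSpec("C19:0 TAG", 10.0, volumes[group]),),
        dilution_factor=dilution[group],
    )


def _series_of(rep: int, n_replicates: int) -> int:
    return 1 if rep < (n_replicates + 1) // 2 else 2


def simulate_peaks(
    true: TrueProfile,
    cfg: RunConfig,
    noise: NoiseModel,
    n_fish: int = 3,
    n_replicates: int = 4,
    group: str = "wild",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate whole-lipid peak tables for one group.

    ``n_replicates`` technical replicates per fish, split over two series.
    Deterministic for a fixed ``noise.seed``.
    """
    if n_fish < 1 or n_replicates < 1:
        raise SyntheticError("n_fish and n_replicates must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    spec = cfg.is_spec(IS_FOR_FRACTION["whole"])
    m_is = is_mass(spec)
    rows = []
    for fish in range(1, n_fish + 1):
        fish_id = f"{group}_fish{fish}"
        f_mult = _lognormal(rng, noise.fish_cv)
        for rep in range(1, n_replicates + 1):
            sample_id = f"{group}_f{fish}_r{rep}"
            series = _series_of(rep - 1, n_replicates)
            base = _RESPONSE / cfg.dilution_factor
            for name, amount in true.amounts.items():
                m_i = amount * cfg.sample_mass_g / 100.0
                area = base * m_i * f_mult * _lognormal(rng, noise.cv)
                rows.append((sample_id, fish_id, group, series, "whole", name, area))
            area_is = base * m_is * _lognormal(rng, noise.cv)
            rows.append((sample_id, fish_id, group, series, "whole", spec.name, area_is))
    return pd.DataFrame(
        rows, columns=["sample_id", "fish_id", "group", "series", "fraction", "fa_name", "area"]
    )


def simulate_fraction_run(
    true: TrueProfile,
    cfg: RunConfig,
    noise: NoiseModel,
    n_fish: int = 3,
    n_replicates: int = 4,
    n_blank_replicates: int = 4,
    group: str = "wild",
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate SPE fraction peak tables (NL/FFA/PL) plus blank runs.

    Analyte mass is split over the fractions by ``true.fraction_partition``;
    each fraction carries its own IS.  Column-bleed contamination is added
    to the FFA-fraction C14:0/C16:0/C18:0 peaks around ``noise.blank_areas``
    and matching blank runs are emitted per column type, so blank
    subtraction is exercised end-to-end.
    """
    if true.fraction_partition is None:
        raise SyntheticError("true profile has no fraction partition")
    if n_fish < 1 or n_replicates < 1 or n_blank_replicates < 1:
        raise SyntheticError("replicate counts must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(noise.seed)
    fraction_index = {"NL": 0, "FFA": 1, "PL": 2}
    rows = []
    for fish in range(1, n_fish + 1):
        fish_id = f"{group}_fish{fish}"
        f_mult = _lognormal(rng, noise.fish_cv)
        for rep in range(1, n_replicates + 1):
            sample_id = f"{group}_f{fish}_s{rep}"
            series = _series_of(rep - 1, n_replicates)
            col_type = _COLUMN_TYPE_OF_SERIES[series]
            base = _RESPONSE / cfg.dilution_factor
            for fraction, fidx in fraction_index.items():
                for name, amount in true.amounts.items():
                    share = true.fraction_partition[name][fidx]
                    m_i = amount * cfg.sample_mass_g / 100.0 * share
                    area = base * m_i * f_mult * _lognormal(rng, noise.cv)
                    if fraction == "FFA" and name in noise.blank_areas:
                        area += noise.blank_areas[name] * _lognormal(rng, noise.cv)
                    if area > 0 or share > 0:
                        rows.append(
                            (sample_id, fish_id, group, series, fraction, name, area, col_type)
                        )
                spec = cfg.is_spec(IS_FOR_FRACTION[fraction])
                area_is = base * is_mass(spec) * _lognormal(rng, noise.cv)
                rows.append(
                    (sample_id, fish_id, group, series, fraction, spec.name, area_is, col_type)
                )
    for col_type in sorted(set(_COLUMN_TYPE_OF_SERIES.values())):
        for rep in range(1, n_blank_replicates + 1):
            sample_id = f"blank_{col_type}_r{rep}"
            for name, mean_area in noise.blank_areas.items():
                area = mean_area * _lognormal(rng, noise.cv)
                rows.append((sample_id, "blank", "blank", 0, "blank", name, area, col_type))
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "fish_id", "group", "series", "fraction", "fa_name", "area", "column_type",
        ],
    )
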