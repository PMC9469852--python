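"""Lipid-class sums and nutritional quality indices (AI, TI, n-6/n-3).

The atherogenicity index (AI) and thrombogenicity index (TI) of Ulbricht &
Southgate weigh pro-atherogenic/thrombogenic saturated FAs against the
protective unsaturated classes::

    AI = (C12:0 + 4*C14:0 + C16:0) / (sum MUFA + sum n-6 + sum n-3)
    TI = (C14:0 + C16:0 + C18:0)
         / (0.5*sum MUFA + 0.5*sum n-6 + 3*sum n-3 + (sum n-3 / sum n-6))

Both are defined on the composition basis (% of total FA content).  This
matters for TI: its last denominator term is a dimensionless quotient while
the other terms carry the profile's scale, so the formula applied to raw
mg/100 g amounts would give a different number.  The functions here
normalize any input profile to percent of total before applying the
formulas, which makes every index invariant under uniform scaling of the
profile — amounts and compositions give identical results.

The named saturated FAs in the numerators are the straight-chain species
only; branched isomers (e.g. 13-methyl-C14:0) count toward the SFA sum but
never toward an index numerator.  Values below 1.0 are conventionally read
as nutritionally favorable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple, Union

from .nomenclature import MUFA, PUFA, SFA, classify, parse_fa_name
from .quantitation import FAProfile

__all__ = [
    "NutritionIndices",
    "UndefinedIndexError",
    "class_sums",
    "ai",
    "ti",
    "n6_n3",
    "nutrition_indices",
    "BENEFICIAL_THRESHOLD",
]

ProfileLike = Union[FAProfile, Mapping[str, float]]

#: AI/TI values below this are conventionally considered beneficial.
BENEFICIAL_THRESHOLD = 1.0


class UndefinedIndexError(ValueError):
    """An index is undefined for this profile (zero denominator)."""


@dataclass(frozen=True)
class NutritionIndices:
    """Class sums (on the input basis) and the three quality indices."""

    sum_sfa: float
    sum_mufa: float
    sum_pufa: float
    sum_n3: float
    sum_n6: float
    n6_n3_ratio: Optional[float] = None
    ai: Optional[float] = None
    ti: Optional[float] = None

    @property
    def beneficial(self) -> Optional[bool]:
        """True when both AI and TI fall below 1.0."""
        if self.ai is None or self.ti is None:
            return None
        return self.ai < BENEFICIAL_THRESHOLD and self.ti < BENEFICIAL_THRESHOLD


def _values(profile: ProfileLike) -> Dict[str, float]:
    if isinstance(profile, FAProfile):
        return dict(profile.compositions if profile.compositions is not None else profile.amounts)
    return dict(profile)


def _sums_and_named(profile: ProfileLike) -> Tuple[Dict[str, float], Dict[int, float]]:
    """Class/omega sums plus straight-chain C12/C14/C16/C18 saturated totals."""
    sums = {"SFA": 0.0, "MUFA": 0.0, "PUFA": 0.0, "n-3": 0.0, "n-6": 0.0}
    named = {12: 0.0, 14: 0.0, 16: 0.0, 18: 0.0}
    for name, value in _values(profile).items():
        fa = parse_fa_name(name)
        cls = classify(fa)
        sums[cls.saturation_class] += value
        if cls.omega_family in ("n-3", "n-6"):
            sums[cls.omega_family] += value
        if fa.is_saturated and not fa.is_branched and fa.chain_length in named:
            named[fa.chain_length] += value
    return sums, named


def class_sums(profile: ProfileLike) -> NutritionIndices:
    """Sum the profile over saturation classes and omega families.

    Sums are on the same basis as the input (% or mg/100 g).  Omega sums
    cover every PUFA and MUFA of that family, so minor families (n-4, n-7,
    ...) appear in the class totals but in neither the n-3 nor n-6 sum.
    """
    sums, _ = _sums_and_named(profile)
    return NutritionIndices(
        sum_sfa=sums["SFA"],
        sum_mufa=sums["MUFA"],
        sum_pufa=sums["PUFA"],
        sum_n3=sums["n-3"],
        sum_n6=sums["n-6"],
    )


def _normalized(profile: ProfileLike) -> Dict[str, float]:
    values = _values(profile)
    total = sum(values.values())
    if total <= 0:
        raise UndefinedIndexError("indices undefined: profile total is zero")
    return {name: v / total * 100.0 for name, v in values.items()}


def ai(profile: ProfileLike) -> float:
    """Atherogenicity index; basis-independent (profile is normalized first)."""
    sums, named = _sums_and_named(_normalized(profile))
    denom = sums["MUFA"] + sums["n-6"] + sums["n-3"]
    if denom <= 0:
        raise UndefinedIndexError("AI undefined: sum MUFA + sum n-6 + sum n-3 is zero")
    return (named[12] + 4.0 * named[14] + named[16]) / denom


def ti(profile: ProfileLike) -> float:
    """Thrombogenicity index; computed on the percent-of-total basis."""
    sums, named = _sums_and_named(_normalized(profile))
    if sums["n-6"] <= 0:
        raise UndefinedIndexError("TI undefined: sum n-6 is zero (ratio term)")
    denom = 0.5 * sums["MUFA"] + 0.5 * sums["n-6"] + 3.0 * sums["n-3"] + sums["n-3"] / sums["n-6"]
    if denom <= 0:
        raise UndefinedIndexError("TI undefined: zero denominator")
    return (named[14] + named[16] + named[18]) / denom


def n6_n3(profile: ProfileLike) -> float:
    """The n-6/n-3 ratio; basis-independent."""
    sums, _ = _sums_and_named(_values(profile))
    if sums["n-3"] <= 0:
        raise UndefinedIndexError("n-6/n-3 undefined: sum n-3 is zero")
    return sums["n-6"] / sums["n-3"]


def nutrition_indices(profile: ProfileLike) -> NutritionIndices:
    """Class sums plus AI, TI and the n-6/n-3 ratio for one profile."""
    base = class_sums(profile)
    return NutritionIndices(
        sum_sfa=base.sum_sfa,
        sum_mufa=base.sum_mufa,
        sum_pufa=base.sum_pufa,
        sum_n3=base.sum_n3,
        sum_n6=base.sum_n6,
        n6_n3_ratio=n6_n3(profile),
        ai=ai(profile),
        ti=ti(profile),
    )
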