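"""Consumer-facing dietary arithmetic on fatty-acid profiles.

Translates a per-100 g fatty-acid profile into what one serving delivers:
fat and key FA intakes per portion, the fillet mass needed to meet the EFSA
recommendation for marine n-3 FAs (EPA + DHA, 250-500 mg/day or
1.75-3.50 g/week), and a check against the EFSA erucic-acid guidance of
7 mg per kg body weight per day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

from .indices import class_sums
from .quantitation import FAProfile

__all__ = [
    "PortionAssessment",
    "LimitCheck",
    "DietaryError",
    "EPA",
    "DHA",
    "ERUCIC",
    "EFSA_DAILY_EPA_DHA_MG",
    "EFSA_WEEKLY_EPA_DHA_G",
    "ERUCIC_LIMIT_MG_PER_KG_DAY",
    "DEFAULT_PORTION_G",
    "portion_intake",
    "grams_to_meet",
    "erucic_check",
]

EPA = "C20:5n-3c"
DHA = "C22:6n-3c"
ERUCIC = "C22:1n-9c"

EFSA_DAILY_EPA_DHA_MG = (250.0, 500.0)
EFSA_WEEKLY_EPA_DHA_G = (1.75, 3.50)
ERUCIC_LIMIT_MG_PER_KG_DAY = 7.0
DEFAULT_PORTION_G = 200.0


class DietaryError(ValueError):
    """A dietary computation is undefined for this profile."""


@dataclass(frozen=True)
class LimitCheck:
    """One intake checked against a named limit or recommendation."""

    name: str
    limit_mg: float
    intake_mg: float
    exceeded: bool


@dataclass
class PortionAssessment:
    """Nutritional content of one portion of fillet.

    All intakes are in mg per portion and scale linearly with portion mass;
    ``fat_g`` requires the profile to carry a measured lipid content.
    """

    portion_mass_g: float
    fat_g: Optional[float]
    epa_dha_mg: float
    n3_mg: float
    n6_mg: float
    erucic_mg: float
    limit_checks: List[LimitCheck] = field(default_factory=list)


def portion_intake(
    profile: FAProfile,
    portion_mass_g: float = DEFAULT_PORTION_G,
    efsa_daily_mg: Tuple[float, float] = EFSA_DAILY_EPA_DHA_MG,
) -> PortionAssessment:
    """Intakes delivered by one portion of the profiled food.

    ``intake_x = amount_x [mg/100 g] * portion_mass_g / 100``; fat follows
    the same rule from the lipid content (%).  The EFSA daily band for
    EPA + DHA is checked against the portion's intake.
    """
    if portion_mass_g < 0:
        raise DietaryError(f"portion mass must be non-negative, got {portion_mass_g}")
    scale = portion_mass_g / 100.0
    sums = class_sums(profile.amounts)
    epa_dha = (profile.amounts.get(EPA, 0.0) + profile.amounts.get(DHA, 0.0)) * scale
    fat_g = None
    if profile.lipid_content is not None:
        fat_g = profile.lipid_content * portion_mass_g / 100.0
    lo, hi = efsa_daily_mg
    checks = [
        LimitCheck("EFSA daily EPA+DHA minimum", lo, epa_dha, exceeded=epa_dha >= lo),
        LimitCheck("EFSA daily EPA+DHA upper bound", hi, epa_dha, exceeded=epa_dha > hi),
    ]
    return PortionAssessment(
        portion_mass_g=portion_mass_g,
        fat_g=fat_g,
        epa_dha_mg=epa_dha,
        n3_mg=sums.sum_n3 * scale,
        n6_mg=sums.sum_n6 * scale,
        erucic_mg=profile.amounts.get(ERUCIC, 0.0) * scale,
        limit_checks=checks,
    )


def grams_to_meet(
    profile: FAProfile,
    daily_target_mg: float = EFSA_DAILY_EPA_DHA_MG[0],
    rounded: bool = True,
) -> float:
    """Fillet grams needed to supply ``daily_target_mg`` of EPA + DHA.

    Rounded to the nearest gram for display by default; pass
    ``rounded=False`` for the exact value.
    """
    if daily_target_mg < 0:
        raise DietaryError(f"target must be non-negative, got {daily_target_mg}")
    if daily_target_mg == 0:
        return 0.0
    per_100g = profile.amounts.get(EPA, 0.0) + profile.amounts.get(DHA, 0.0)
    if per_100g <= 0:
        raise DietaryError("target unreachable: profile contains no EPA or DHA")
    grams = daily_target_mg / per_100g * 100.0
    return float(round(grams)) if rounded else grams


def erucic_check(
    profile: FAProfile,
    body_mass_kg: float,
    consumed_g: float,
    limit_mg_per_kg: float = ERUCIC_LIMIT_MG_PER_KG_DAY,
) -> LimitCheck:
    """Erucic-acid intake from ``consumed_g`` vs the body-mass-scaled limit.

    The EFSA guidance is 7 mg erucic acid (C22:1n-9c) per kg body weight
    per day, e.g. 175 mg/day for a 25 kg child.
    """
    if body_mass_kg <= 0:
        raise DietaryError(f"body mass must be positive, got {body_mass_kg}")
    if consumed_g < 0:
        raise DietaryError(f"consumed mass must be non-negative, got {consumed_g}")
    limit = limit_mg_per_kg * body_mass_kg
    intake = profile.amounts.get(ERUCIC, 0.0) * consumed_g / 100.0
    return LimitCheck(
        name=f"EFSA erucic acid limit ({limit_mg_per_kg:g} mg/kg/day, {body_mass_kg:g} kg)",
        limit_mg=limit,
        intake_mg=intake,
        exceeded=intake > limit,
    )
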