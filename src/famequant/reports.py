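"""Pipeline orchestration, report rendering and config handling.

``run_pipeline`` ties the modules together: validate a peak table, quantify
every sample against its internal standard, aggregate to group level,
compute class sums and nutritional indices, process SPE fractions (with
blank subtraction) when present, and derive the dietary assessment.  The
result is a :class:`ReportBundle` of tidy DataFrames plus a rendered
plain-text report laid out like the field's standard composition tables:
SFA / MUFA / PUFA blocks with subtotal rows, then totals, omega sums, the
n-6/n-3 ratio, AI and TI, with "mean ± SD" cells and "n.d." for
fatty acids absent from every replicate of a group.

Display rounding is fixed per column type (amounts: 0 decimals at >= 1000,
1 at >= 100, else 2; compositions and indices: 2 decimals, half-up) and
affects rendering only, never computation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field as dc_field
from datetime import datetime, timezone
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml

from . import fractions as fr
from . import reference
from .dietary import (
    DEFAULT_PORTION_G,
    EFSA_DAILY_EPA_DHA_MG,
    ERUCIC_LIMIT_MG_PER_KG_DAY,
    erucic_check,
    grams_to_meet,
    portion_intake,
)
from .indices import nutrition_indices
from .nomenclature import classify, parse_fa_name
from .quantitation import (
    FAProfile,
    ISSpec,
    RunConfig,
    aggregate,
    composition,
    quantify,
    read_peaks_csv,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "load_config",
    "run_pipeline",
    "render_fa_table",
    "write_outputs",
    "round_half_up",
]


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PipelineConfig:
    """Everything the pipeline needs besides the peak table itself."""

    run: RunConfig = dc_field(default_factory=RunConfig)
    lipid_content: Dict[str, float] = dc_field(default_factory=dict)  # group -> %
    portion_mass_g: float = DEFAULT_PORTION_G
    efsa_daily_mg: float = EFSA_DAILY_EPA_DHA_MG[0]
    erucic_limit_mg_per_kg: float = ERUCIC_LIMIT_MG_PER_KG_DAY
    body_mass_kg: float = 25.0
    flag_provisional: bool = False
    pooled: bool = False


@dataclass
class ReportBundle:
    """All pipeline outputs: tidy tables, rendered report, provenance."""

    fa_table: pd.DataFrame
    indices: pd.DataFrame
    dietary: pd.DataFrame
    fraction_percent: Optional[pd.DataFrame] = None
    fraction_shares: Optional[pd.DataFrame] = None
    report_text: str = ""
    provenance: Dict[str, object] = dc_field(default_factory=dict)


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file.

    Recognized keys mirror :class:`PipelineConfig`; ``run`` holds the
    quantitation parameters (``sample_mass_g``, ``is_specs`` as a list of
    ``{name, concentration_mg_per_ml, volume_ul}``, ``dilution_factor``,
    ``acyl_correction``).
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    run_raw = raw.pop("run", {})
    specs = tuple(ISSpec(**s) for s in run_raw.pop("is_specs", []))
    run = RunConfig(**run_raw, **({"is_specs": specs} if specs else {}))
    return PipelineConfig(run=run, **raw)


# ---------------------------------------------------------------------------
# report layout


def _sort_key(name: str):
    fa = parse_fa_name(name)
    cls = classify(fa)
    class_order = {"SFA": 0, "MUFA": 1, "PUFA": 2}[cls.saturation_class]
    first_branch = fa.branches[0][0] if fa.branches else 0
    return (
        class_order,
        fa.chain_length,
        fa.double_bonds,
        -(fa.n_series or 0),
        bool(fa.branches),
        -first_branch,
    )


def _fmt_amount(mean: float, sd: float) -> str:
    d = 0 if mean >= 1000 else (1 if mean >= 100 else 2)
    return f"{round_half_up(mean, d):,.{d}f} ± {round_half_up(sd, d):,.{d}f}"


def _fmt_comp(mean: float, sd: float) -> str:
    return f"{round_half_up(mean, 2):.2f} ± {round_half_up(sd, 2):.2f}"


def render_fa_table(
    fa_table: pd.DataFrame,
    indices: Optional[pd.DataFrame] = None,
    flag_provisional: bool = False,
) -> str:
    """Render an aggregated profile as a composition/amount grid.

    ``fa_table`` is the output of :func:`famequant.quantitation.aggregate`
    (reset or not); FAs undetected in a group render as ``n.d.``.  When
    ``indices`` is given, subtotal and index rows are appended beneath the
    FA blocks in the conventional order.
    """
    df = fa_table.reset_index() if fa_table.index.nlevels > 1 else fa_table.copy()
    groups = list(dict.fromkeys(df["group"]))
    names = sorted(df["fa_name"].unique(), key=_sort_key)
    by_class: Dict[str, List[str]] = {"SFA": [], "MUFA": [], "PUFA": []}
    for name in names:
        by_class[classify(parse_fa_name(name)).saturation_class].append(name)

    cells = df.set_index(["group", "fa_name"])
    header = ["Fatty acid"]
    for g in groups:
        header += [f"{g} %", f"{g} mg/100 g"]
    lines = [header]

    def fa_row(name: str) -> List[str]:
        label = name + (" *" if flag_provisional and name in reference.PROVISIONAL_IDS else "")
        row = [label]
        for g in groups:
            try:
                rec = cells.loc[(g, name)]
            except KeyError:
                rec = None
            if rec is None or not bool(rec["detected"]):
                row += ["n.d.", "n.d."]
            else:
                row += [
                    _fmt_comp(rec["composition_mean"], rec["composition_sd"]),
                    _fmt_amount(rec["amount_mean"], rec["amount_sd"]),
                ]
        return row

    idx = indices.set_index("group") if indices is not None else None

    def index_row(label: str, col: str, decimals: int = 2) -> List[str]:
        row = [label]
        for g in groups:
            val = idx.loc[g, col] if (idx is not None and g in idx.index) else None
            row += ["" if val is None else f"{round_half_up(float(val), decimals):.{decimals}f}", ""]
        return row

    for cls, sum_col in (("SFA", "sum_sfa"), ("MUFA", "sum_mufa"), ("PUFA", "sum_pufa")):
        for name in by_class[cls]:
            lines.append(fa_row(name))
        if idx is not None:
            lines.append(index_row(f"∑ {cls}", sum_col))
    if idx is not None:
        total_row = ["Total"]
        for g in groups:
            tot = cells.loc[g]["amount_mean"].where(cells.loc[g]["detected"], 0.0).sum()
            total_row += ["", _fmt_amount(tot, 0.0).split(" ±")[0]]
        lines.append(total_row)
        lines.append(index_row("∑ n-6", "sum_n6"))
        lines.append(index_row("∑ n-3", "sum_n3"))
        lines.append(index_row("n-6/n-3", "n6_n3"))
        lines.append(index_row("AI", "ai"))
        lines.append(index_row("TI", "ti"))

    widths = [max(len(r[i]) for r in lines) for i in range(len(header))]
    out = []
    for r in lines:
        out.append("  ".join(c.ljust(w) for c, w in zip(r, widths)).rstrip())
    if flag_provisional:
        out.append("")
        out.append("* identified by spectral library search only, not confirmed by a standard")
    out.append("")
    out.append("n.d., not detected")
    return "\n".join(out)


# ---------------------------------------------------------------------------
# pipeline


def _group_profiles(fa_table: pd.DataFrame, cfg: PipelineConfig) -> Dict[str, FAProfile]:
    """Group-level mean profiles (detected FAs only) for indices and dietary."""
    profiles = {}
    for group, gdf in fa_table.reset_index().groupby("group", sort=False):
        det = gdf[gdf["detected"]]
        prof = FAProfile(
            amounts=dict(zip(det["fa_name"], det["amount_mean"])),
            lipid_content=cfg.lipid_content.get(group),
        )
        profiles[group] = composition(prof)
    return profiles


def run_pipeline(
    peaks: Union[pd.DataFrame, str, Path],
    cfg: Optional[PipelineConfig] = None,
) -> ReportBundle:
    """Run the full analysis on a peak table (DataFrame or CSV path)."""
    cfg = cfg or PipelineConfig()
    provenance: Dict[str, object] = {
        "timestamp": datetime.now(timezone.utc).isoformat(timespec="seconds"),
        "config": repr(cfg),
    }
    if not isinstance(peaks, pd.DataFrame):
        provenance["peaks_sha256"] = hashlib.sha256(Path(peaks).read_bytes()).hexdigest()
        peaks = read_peaks_csv(peaks)

    whole = peaks[peaks["fraction"] == "whole"]
    frac = peaks[peaks["fraction"].isin(fr.LIPID_FRACTIONS)]
    blanks = peaks[peaks["fraction"] == "blank"]

    entries = []
    for sample_id, sdf in whole.groupby("sample_id", sort=False):
        profile = quantify(sdf, cfg.run, fraction="whole")
        entries.append((sdf["group"].iloc[0], sdf["fish_id"].iloc[0], composition(profile)))
    if not entries:
        raise ValueError("peak table contains no whole-lipid samples")
    fa_table = aggregate(entries, pooled=cfg.pooled)

    profiles = _group_profiles(fa_table, cfg)
    idx_rows = []
    for group, prof in profiles.items():
        ni = nutrition_indices({n: prof.compositions[n] for n in prof.compositions})
        idx_rows.append(
            {
                "group": group,
                "sum_sfa": ni.sum_sfa,
                "sum_mufa": ni.sum_mufa,
                "sum_pufa": ni.sum_pufa,
                "sum_n3": ni.sum_n3,
                "sum_n6": ni.sum_n6,
                "n6_n3": ni.n6_n3_ratio,
                "ai": ni.ai,
                "ti": ni.ti,
            }
        )
    indices_df = pd.DataFrame(idx_rows)

    diet_rows = []
    for group, prof in profiles.items():
        pa = portion_intake(prof, cfg.portion_mass_g, (cfg.efsa_daily_mg, 2 * cfg.efsa_daily_mg))
        ec = erucic_check(prof, cfg.body_mass_kg, 100.0, cfg.erucic_limit_mg_per_kg)
        diet_rows.append(
            {
                "group": group,
                "portion_mass_g": cfg.portion_mass_g,
                "fat_g": pa.fat_g,
                "epa_dha_mg": pa.epa_dha_mg,
                "n3_mg": pa.n3_mg,
                "n6_mg": pa.n6_mg,
                "erucic_mg_per_100g": ec.intake_mg,
                "erucic_limit_mg": ec.limit_mg,
                "erucic_exceeded": ec.exceeded,
                "grams_to_meet_target": grams_to_meet(prof, cfg.efsa_daily_mg),
            }
        )
    dietary_df = pd.DataFrame(diet_rows)

    fraction_percent = fraction_shares_df = None
    if not frac.empty:
        corrected = fr.blank_subtract(frac, blanks) if not blanks.empty else frac
        fraction_percent = fr.aggregate_fraction_percent(corrected)
        fraction_shares_df = fr.fraction_shares(corrected)

    report = render_fa_table(fa_table, indices_df, cfg.flag_provisional)
    bundle = ReportBundle(
        fa_table=fa_table,
        indices=indices_df,
        dietary=dietary_df,
        fraction_percent=fraction_percent,
        fraction_shares=fraction_shares_df,
        report_text=report,
        provenance=provenance,
    )
    return bundle


def write_outputs(bundle: ReportBundle, outdir) -> None:
    """Write tidy CSVs, the rendered report, and provenance JSON to a directory."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.fa_table.reset_index().to_csv(out / "fa_profile.csv", index=False)
    bundle.indices.to_csv(out / "indices.csv", index=False)
    bundle.dietary.to_csv(out / "dietary.csv", index=False)
    if bundle.fraction_percent is not None:
        bundle.fraction_percent.to_csv(out / "fraction_percent.csv", index=False)
    if bundle.fraction_shares is not None:
        bundle.fraction_shares.to_csv(out / "fraction_shares.csv", index=False)
    (out / "report.txt").write_text(bundle.report_text, encoding="utf-8")
    (out / "provenance.json").write_text(json.dumps(bundle.provenance, indent=2), encoding="utf-8")
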