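"""Fatty-acid shorthand nomenclature: parsing, validation, and classification.

Fatty acids (FAs) are written in the GC-MS literature in a compact shorthand,
``C<chain>:<double bonds>[n-<position>][c|t]`` with an optional parenthesized
branch suffix, e.g. ``C18:1n-9c`` (oleic acid), ``C20:5n-3c`` (EPA) or
``C14:0 (13-methyl)`` (a branched saturated FA).  The ``n-<position>`` part is
the omega family: the position of the first double bond counted from the
methyl terminus, which determines the biological family (n-3, n-6, ...) of an
unsaturated FA.  A trailing ``c`` or ``t`` marks cis/trans geometry.

This module parses that grammar into a structured :class:`FattyAcid`,
round-trips it back to a canonical ASCII string, and classifies FAs into
saturation classes (SFA / MUFA / PUFA) and omega families.  Typographic
dashes (U+2010, en dash, minus sign, ...) are accepted as equivalent to the
ASCII hyphen, since shorthand names copied from typeset tables commonly carry
them; canonical output always uses ASCII.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Tuple

__all__ = [
    "FattyAcid",
    "LipidClass",
    "FANameError",
    "parse_fa_name",
    "format_fa_name",
    "classify",
]


class FANameError(ValueError):
    """Raised when a fatty-acid shorthand name cannot be parsed or is implausible."""


# Typographic dash variants normalized to the ASCII hyphen-minus.
_DASHES = dict.fromkeys(map(ord, "‐‑‒–—−"), "-")
# Non-breaking / thin spaces normalized to a plain space.
_SPACES = dict.fromkeys(map(ord, "   "), " ")

_NAME_RE = re.compile(
    r"^C(?P<chain>\d+):(?P<db>\d+)"
    r"(?:n-(?P<pos>\d+)(?P<geo>[ct])?)?"
    r"(?:\s*\((?P<branch>[^()]*)\))?$"
)
_BRANCH_RE = re.compile(r"^(?P<positions>\d+(?:,\d+)*)-(?P<prefix>di|tri|tetra)?(?P<group>methyl|ethyl)$")

_MULTIPLICITY = {None: 1, "di": 2, "tri": 3, "tetra": 4}
_PREFIX = {1: "", 2: "di", 3: "tri", 4: "tetra"}

GEOMETRY_CIS = "cis"
GEOMETRY_TRANS = "trans"
GEOMETRY_NA = "n/a"

SFA = "SFA"
MUFA = "MUFA"
PUFA = "PUFA"


def _normalize(name: str) -> str:
    return name.translate(_DASHES).translate(_SPACES).strip()


@dataclass(frozen=True)
class FattyAcid:
    """Structural identity of one fatty acid parsed from shorthand.

    Attributes
    ----------
    chain_length:
        Carbons in the main chain (branch carbons not counted).
    double_bonds:
        Number of C=C double bonds; 0 for saturated FAs.
    n_series:
        Position of the first double bond from the methyl end (the omega
        family), or ``None`` for saturated FAs and names lacking the suffix.
    geometry:
        ``"cis"``, ``"trans"`` or ``"n/a"`` (saturated, or unspecified).
    branches:
        Tuple of ``(position, group)`` pairs, e.g. ``((13, "methyl"),)``.
    """

    chain_length: int
    double_bonds: int
    n_series: Optional[int] = None
    geometry: str = GEOMETRY_NA
    branches: Tuple[Tuple[int, str], ...] = field(default=())

    def __post_init__(self) -> None:
        if self.chain_length <= 0:
            raise FANameError(f"chain length must be positive, got {self.chain_length}")
        if self.double_bonds < 0:
            raise FANameError(f"double bond count must be non-negative, got {self.double_bonds}")
        if self.chain_length < 2 * self.double_bonds:
            raise FANameError(
                f"implausible structure: {self.double_bonds} double bonds do not fit "
                f"in a C{self.chain_length} chain"
            )
        if self.double_bonds == 0:
            if self.n_series is not None:
                raise FANameError("saturated FA cannot carry an n-series")
            if self.geometry != GEOMETRY_NA:
                raise FANameError("saturated FA cannot carry cis/trans geometry")
        else:
            if self.n_series is not None and not (1 <= self.n_series < self.chain_length):
                raise FANameError(f"n-series position {self.n_series} outside chain")
        for pos, group in self.branches:
            if not (1 <= pos <= self.chain_length):
                raise FANameError(f"branch position {pos} outside C{self.chain_length} chain")
            if group not in ("methyl", "ethyl"):
                raise FANameError(f"unsupported branch group {group!r}")

    @property
    def display_name(self) -> str:
        """Canonical shorthand string; ``parse_fa_name`` round-trips it."""
        return format_fa_name(self)

    @property
    def is_saturated(self) -> bool:
        return self.double_bonds == 0

    @property
    def is_branched(self) -> bool:
        return bool(self.branches)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.display_name


@dataclass(frozen=True)
class LipidClass:
    """Saturation class and omega family of one fatty acid.

    ``saturation_class`` partitions all FAs into SFA (0 double bonds),
    MUFA (exactly 1) and PUFA (2 or more).  ``omega_family`` is ``"n-<k>"``
    for unsaturated FAs with a known first-double-bond position and
    ``"none"`` otherwise (all SFAs, by definition).
    """

    saturation_class: str
    omega_family: str

    def __post_init__(self) -> None:
        if self.saturation_class not in (SFA, MUFA, PUFA):
            raise ValueError(f"unknown saturation class {self.saturation_class!r}")
        if (self.saturation_class == SFA) != (self.omega_family == "none"):
            raise ValueError("omega_family must be 'none' exactly for SFAs")


def parse_fa_name(name: str) -> FattyAcid:
    """Parse a fatty-acid shorthand name into a :class:`FattyAcid`.

    Accepts the grammar ``C<len>:<db>[n-<pos>][c|t]`` with an optional
    parenthesized branch suffix such as ``(13-methyl)`` or
    ``(4,8,12-trimethyl)``.  Unicode dash variants are treated as hyphens.

    Raises
    ------
    FANameError
        If the string does not match the grammar, names an implausible
        structure, or the branch multiplicity prefix disagrees with the
        number of listed positions.
    """
    if not isinstance(name, str) or not name.strip():
        raise FANameError("fatty-acid name must be a non-empty string")
    norm = _normalize(name)
    m = _NAME_RE.match(norm)
    if m is None:
        raise FANameError(f"cannot parse fatty-acid name {name!r}")
    chain = int(m.group("chain"))
    db = int(m.group("db"))
    pos = m.group("pos")
    geo = m.group("geo")

    if db == 0 and (pos is not None or geo is not None):
        raise FANameError(f"{name!r}: saturated FA cannot carry an n-series or geometry")

    branches: Tuple[Tuple[int, str], ...] = ()
    branch_text = m.group("branch")
    if branch_text is not None:
        bm = _BRANCH_RE.match(branch_text.strip())
        if bm is None:
            raise FANameError(f"{name!r}: cannot parse branch suffix ({branch_text!r})")
        positions = [int(p) for p in bm.group("positions").split(",")]
        expected = _MULTIPLICITY[bm.group("prefix")]
        if len(positions) != expected:
            raise FANameError(
                f"{name!r}: branch prefix implies {expected} positions, got {len(positions)}"
            )
        branches = tuple((p, bm.group("group")) for p in positions)

    geometry = GEOMETRY_NA
    if geo == "c":
        geometry = GEOMETRY_CIS
    elif geo == "t":
        geometry = GEOMETRY_TRANS

    return FattyAcid(
        chain_length=chain,
        double_bonds=db,
        n_series=int(pos) if pos is not None else None,
        geometry=geometry,
        branches=branches,
    )


def format_fa_name(fa: FattyAcid) -> str:
    """Serialize a :class:`FattyAcid` to its canonical ASCII shorthand."""
    out = f"C{fa.chain_length}:{fa.double_bonds}"
    if fa.n_series is not None:
        out += f"n-{fa.n_series}"
        if fa.geometry == GEOMETRY_CIS:
            out += "c"
        elif fa.geometry == GEOMETRY_TRANS:
            out += "t"
    if fa.branches:
        groups = {g for _, g in fa.branches}
        if len(groups) != 1:
            raise FANameError("mixed branch groups are not representable in shorthand")
        group = groups.pop()
        positions = ",".join(str(p) for p, _ in fa.branches)
        out += f" ({positions}-{_PREFIX[len(fa.branches)]}{group})"
    return out


def classify(fa: FattyAcid) -> LipidClass:
    """Classify a fatty acid into its saturation class and omega family.

    Branched saturated FAs are SFAs.  The omega family is copied from the
    n-series, so e.g. C16:2n-4c is a PUFA of family n-4 — counted in the
    PUFA total but in neither the n-3 nor the n-6 sum.
    """
    if fa.double_bonds == 0:
        saturation = SFA
    elif fa.double_bonds == 1:
        saturation = MUFA
    else:
        saturation = PUFA
    omega = "none" if (fa.double_bonds == 0 or fa.n_series is None) else f"n-{fa.n_series}"
    return LipidClass(saturation_class=saturation, omega_family=omega)
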