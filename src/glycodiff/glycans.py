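"""Glycan composition model.

Compositions are written in the compact letter+count notation used in
glycoproteomics annotation strings, e.g. ``N4H5S1F1``:

=======  ==========================  ==================
letter   residue                     elemental formula
=======  ==========================  ==================
H        hexose                      C6H10O5
N        N-acetylhexosamine          C8H13NO5
F        deoxyhexose (fucose)        C6H10O4
S        N-acetylneuraminic acid     C11H17NO8
=======  ==========================  ==================

Only composition-level information is modelled; linkage and positional
isomers are out of scope.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

__all__ = [
    "GlycanComposition",
    "GlycanClass",
    "GlycanFeatures",
    "GlycanParseError",
    "parse_composition",
    "render_composition",
    "glycan_mass",
    "glycopeptide_mass",
    "classify",
    "derive_features",
]

# Monoisotopic atomic masses (CODATA / IUPAC 2021).
_MASS_C = 12.0
_MASS_H = 1.0078250319
_MASS_N = 14.0030740052
_MASS_O = 15.9949146221


def _formula_mass(c: int, h: int, n: int, o: int) -> float:
    return c * _MASS_C + h * _MASS_H + n * _MASS_N + o * _MASS_O


#: Monoisotopic residue masses (condensation water already removed).
RESIDUE_MASSES = {
    "H": _formula_mass(6, 10, 0, 5),   # hexose, 162.05282
    "N": _formula_mass(8, 13, 1, 5),   # HexNAc, 203.07937
    "F": _formula_mass(6, 10, 0, 4),   # deoxyhexose, 146.05791
    "S": _formula_mass(11, 17, 1, 8),  # NeuAc, 291.09542
}

# Canonical rendering order: N, H, F, S (matches common annotation style).
_CANONICAL_ORDER = ("N", "H", "F", "S")

_TOKEN_RE = re.compile(r"([A-Za-z])(\d+)")


class GlycanParseError(ValueError):
    """Raised for malformed glycan composition strings."""


class GlycanClass(enum.Enum):
    """Maturation class of an N-glycan, inferred from composition alone."""

    OLIGOMANNOSE = "oligomannose"
    COMPLEX = "complex"
    HYBRID = "hybrid"
    PAUCIMANNOSE_OTHER = "paucimannose_other"


@dataclass(frozen=True, order=True)
class GlycanComposition:
    """Monosaccharide counts of one N-glycan composition."""

    H: int = 0
    N: int = 0
    F: int = 0
    S: int = 0

    def __post_init__(self) -> None:
        for letter in _CANONICAL_ORDER:
            count = getattr(self, letter)
            if not isinstance(count, int) or count < 0:
                raise ValueError(
                    f"residue count {letter}={count!r} must be a non-negative integer"
                )

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            H=self.H + other.H, N=self.N + other.N,
            F=self.F + other.F, S=self.S + other.S,
        )

    def render(self) -> str:
        """Canonical string: N, H, F, S order, zero counts omitted."""
        return render_composition(self)

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class GlycanFeatures:
    """Derived structural attributes of one composition."""

    glycan_class: GlycanClass
    antennae: int
    sialic_antennae: int
    galactoses: int
    is_fucosylated: bool
    is_sialylated: bool
    has_antennae: bool


def parse_composition(text: str) -> GlycanComposition:
    """Parse a compact composition string such as ``"N4H5S1F1"``.

    Letters are case-insensitive and may appear in any order, each at most
    once; absent residues default to zero.

    Raises
    ------
    GlycanParseError
        If the string contains an unknown residue letter, a repeated
        letter, or is not a clean concatenation of letter+count tokens.
    """
    if not isinstance(text, str):
        raise GlycanParseError(f"expected a string, got {type(text).__name__}")
    stripped = text.strip()
    if not stripped:
        raise GlycanParseError("empty composition string")

    counts: dict[str, int] = {}
    pos = 0
    for match in _TOKEN_RE.finditer(stripped):
        if match.start() != pos:
            raise GlycanParseError(
                f"malformed composition {text!r}: unexpected text "
                f"{stripped[pos:match.start()]!r}"
            )
        letter = match.group(1).upper()
        if letter not in RESIDUE_MASSES:
            raise GlycanParseError(
                f"unknown residue code in token {match.group(0)!r} of {text!r}"
            )
        if letter in counts:
            raise GlycanParseError(
                f"repeated residue letter {letter!r} in {text!r}"
            )
        counts[letter] = int(match.group(2))
        pos = match.end()
    if pos != len(stripped):
        raise GlycanParseError(
            f"malformed composition {text!r}: trailing text {stripped[pos:]!r}"
        )
    return GlycanComposition(**{k: counts.get(k, 0) for k in _CANONICAL_ORDER})


def render_composition(c: GlycanComposition) -> str:
    """Render in canonical order (N, H, F, S), omitting zero counts.

    The all-zero composition renders as ``"N0"`` so the string stays
    parseable.
    """
    parts = [
        f"{letter}{getattr(c, letter)}"
        for letter in _CANONICAL_ORDER
        if getattr(c, letter) > 0
    ]
    return "".join(parts) if parts else "N0"


def glycan_mass(c: GlycanComposition) -> float:
    """Monoisotopic mass of the glycan moiety in Da.

    Sum of residue masses (water of condensation already removed from each
    residue), so masses are additive over compositions.
    """
    return (
        c.H * RESIDUE_MASSES["H"]
        + c.N * RESIDUE_MASSES["N"]
        + c.F * RESIDUE_MASSES["F"]
        + c.S * RESIDUE_MASSES["S"]
    )


def glycopeptide_mass(peptide_mass: float, c: GlycanComposition) -> float:
    """Monoisotopic mass of a glycopeptide: backbone plus glycan residues."""
    if peptide_mass < 0:
        raise ValueError(f"peptide mass must be non-negative, got {peptide_mass}")
    return peptide_mass + glycan_mass(c)


def classify(c: GlycanComposition) -> GlycanClass:
    """Assign the maturation class from composition alone.

    Rules (composition-level heuristics; no linkage information):

    - OLIGOMANNOSE: exactly the two core HexNAc (N=2), at least five
      hexoses, no fucose or sialic acid.
    - HYBRID: N=3 with H>=5 (one antenna GlcNAc plus retained mannose arm).
    - COMPLEX: N>=3 otherwise.
    - PAUCIMANNOSE_OTHER: everything else (truncated / unmatured cores).
    """
    if c.N == 2 and c.H >= 5 and c.F == 0 and c.S == 0:
        return GlycanClass.OLIGOMANNOSE
    if c.N == 3 and c.H >= 5:
        return GlycanClass.HYBRID
    if c.N >= 3:
        return GlycanClass.COMPLEX
    return GlycanClass.PAUCIMANNOSE_OTHER


def derive_features(c: GlycanComposition) -> GlycanFeatures:
    """Derive branching / decoration attributes used by the site metrics.

    Antenna count is N-2 for complex glycans (two core HexNAc), a fixed 1
    for hybrid, 0 otherwise. Galactoses on complex glycans are estimated
    as hexoses beyond the three core mannoses, clamped to the antenna
    count. Sialic acids are capped at one per antenna.
    """
    cls = classify(c)
    if cls is GlycanClass.COMPLEX:
        antennae = c.N - 2
        galactoses = min(max(c.H - 3, 0), antennae)
    elif cls is GlycanClass.HYBRID:
        antennae = 1
        galactoses = 0
    else:
        antennae = 0
        galactoses = 0
    return GlycanFeatures(
        glycan_class=cls,
        antennae=antennae,
        sialic_antennae=min(c.S, antennae),
        galactoses=galactoses,
        is_fucosylated=c.F >= 1,
        is_sialylated=c.S >= 1,
        has_antennae=antennae >= 1,
    )
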