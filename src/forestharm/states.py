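"""Discrete vegetation states.

A stand-year is condensed into a categorical state combining three axes:

* composition — the dominant species (> 66 % of stand basal area) and any
  admixed species (>= 20 %), coded by the first two letters of genus and
  epithet (upper case for the dominant, lower case for admixed);
* function — the leaf area index grouped into three classes
  (sparse LAI < 2, moderate 2 <= LAI <= 4, dense LAI > 4);
* structure — the dominant canopy height grouped into 2-m bins.

The canonical serialized form is e.g. ``PIABfasy_3_20_22``: a stand dominated
by Picea abies with admixed Fagus sylvatica, a dense canopy and a dominant
height between 20 and 22 m.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

__all__ = [
    "CompositionState",
    "VegetationState",
    "StateParseError",
    "MIXED_TOKEN",
    "species_code",
    "classify_composition",
    "lai_class",
    "height_bin",
    "encode_state",
    "decode_state",
]

DOMINANCE_THRESHOLD = 0.66
ADMIXTURE_THRESHOLD = 0.20
LAI_EDGES = (2.0, 4.0)
HEIGHT_BIN_WIDTH = 2

#: Composition token for stands in which no species reaches the admixture
#: threshold (the grammar needs a total encoding; see docs/methods.md).
MIXED_TOKEN = "mixd"

_SHARE_TOL = 1e-6


class StateParseError(ValueError):
    """A state string does not match the encoding grammar."""

    def __init__(self, text: str, position: int, message: str):
        self.text = text
        self.position = position
        super().__init__(f"cannot parse state string {text!r} at position {position}: {message}")


@dataclass(frozen=True)
class CompositionState:
    """Dominant / admixed species of one stand-year, as 4-letter codes.

    ``dominant`` holds the upper-case code of the single species exceeding
    the dominance threshold, if any; ``admixed`` is the ordered tuple of
    lower-case codes of species at or above the admixture threshold
    (descending share, ties broken alphabetically by code), the dominant
    excluded. Codes rather than full names are stored so that encoding and
    decoding are exact inverses.
    """

    dominant: str | None = None
    admixed: tuple[str, ...] = ()


@dataclass(frozen=True)
class VegetationState:
    composition: CompositionState
    lai_class: int
    height_bin: tuple[int, int]

    def __post_init__(self) -> None:
        if self.lai_class not in (1, 2, 3):
            raise ValueError(f"lai_class must be 1, 2 or 3, got {self.lai_class}")
        lo, hi = self.height_bin
        if lo < 0 or lo % HEIGHT_BIN_WIDTH != 0 or hi != lo + HEIGHT_BIN_WIDTH:
            raise ValueError(f"invalid height bin {self.height_bin}")


def species_code(name: str, role: str = "dominant") -> str:
    """Four-letter code: two genus letters + two epithet letters.

    The code is upper case for a dominant species and lower case for an
    admixed one, e.g. ``("Pinus sylvestris", "dominant") -> "PISY"`` and
    ``("Fagus sylvatica", "admixed") -> "fasy"``.
    """
    if role not in ("dominant", "admixed"):
        raise ValueError(f"role must be 'dominant' or 'admixed', got {role!r}")
    parts = name.strip().casefold().split()
    if len(parts) == 1 and len(parts[0]) == 4 and parts[0].isalpha():
        # already a 4-letter code (e.g. re-encoding a decoded state)
        return parts[0].upper() if role == "dominant" else parts[0]
    if len(parts) < 2:
        raise ValueError(f"species name {name!r} must contain genus and epithet")
    genus, epithet = parts[0], parts[1]
    if len(genus) < 2 or len(epithet) < 2 or not (genus[:2] + epithet[:2]).isalpha():
        raise ValueError(f"species name {name!r} too short to derive a 2+2 letter code")
    code = genus[:2] + epithet[:2]
    return code.upper() if role == "dominant" else code.lower()


def classify_composition(
    shares: dict[str, float],
    dominance_threshold: float = DOMINANCE_THRESHOLD,
    admixture_threshold: float = ADMIXTURE_THRESHOLD,
) -> CompositionState:
    """Classify basal-area shares into dominant and admixed species.

    A species is dominant if its share strictly exceeds the dominance
    threshold; admixed species are those at or above the admixture threshold,
    the dominant excluded. Shares are fractions of total stand basal area and
    must sum to at most one, which guarantees at most one dominant.
    """
    total = 0.0
    for name, s in shares.items():
        if not math.isfinite(s) or s < 0:
            raise ValueError(f"share for {name!r} must be a finite non-negative fraction, got {s}")
        if s > 1 + _SHARE_TOL:
            raise ValueError(f"share for {name!r} exceeds 1: {s}")
        total += s
    if total > 1 + _SHARE_TOL:
        raise ValueError(f"shares sum to {total}, exceeding 1")

    dominant = None
    for name, s in shares.items():
        if s > dominance_threshold:
            assert dominant is None, "shares summing to <= 1 admit at most one dominant"
            dominant = name
    admixed = [
        name
        for name, s in shares.items()
        if name != dominant and s >= admixture_threshold
    ]
    admixed.sort(key=lambda n: (-shares[n], species_code(n, "admixed")))
    return CompositionState(
        dominant=None if dominant is None else species_code(dominant, "dominant"),
        admixed=tuple(species_code(n, "admixed") for n in admixed),
    )


def lai_class(lai: float, edges: tuple[float, float] = LAI_EDGES) -> int:
    """LAI class: 1 sparse (< 2), 2 moderate (2 <= LAI <= 4), 3 dense (> 4)."""
    if not math.isfinite(lai) or lai < 0:
        raise ValueError(f"LAI must be finite and >= 0, got {lai}")
    low, high = edges
    if lai < low:
        return 1
    if lai <= high:
        return 2
    return 3


def height_bin(dominant_height: float, width: int = HEIGHT_BIN_WIDTH) -> tuple[int, int]:
    """2-m dominant-height bin, half-open: 21.0 -> (20, 22), 20.0 -> (20, 22)."""
    if not math.isfinite(dominant_height) or dominant_height < 0:
        raise ValueError(f"dominant height must be finite and >= 0, got {dominant_height}")
    lower = width * math.floor(dominant_height / width)
    return (lower, lower + width)


def encode_state(state: VegetationState) -> str:
    """Serialize a state, e.g. ``PIABfasy_3_20_22``.

    The composition block concatenates the upper-case dominant code (if any)
    and the lower-case admixed codes in canonical order; a stand without any
    species at the admixture threshold gets the literal token ``mixd``.
    """
    comp = state.composition
    block = ""
    if comp.dominant is not None:
        block += species_code(comp.dominant, "dominant")
    block += "".join(species_code(c, "admixed") for c in comp.admixed)
    if not block:
        block = MIXED_TOKEN
    lo, hi = state.height_bin
    return f"{block}_{state.lai_class}_{lo}_{hi}"


_STATE_RE = re.compile(r"^(?P<codes>[A-Za-z]+)_(?P<lai>\d+)_(?P<lo>\d+)_(?P<hi>\d+)$")


def decode_state(text: str) -> VegetationState:
    """Parse a canonical state string back into a :class:`VegetationState`.

    The species names cannot be recovered from 4-letter codes, so the
    composition carries the codes themselves (they re-encode identically
    because a 4-letter lower-case token is its own code).
    """
    m = _STATE_RE.match(text)
    if m is None:
        # locate the first offending character for the error message
        pos = next((i for i, c in enumerate(text) if not (c.isalnum() or c == "_")), len(text))
        raise StateParseError(text, pos, "expected CODES_<lai>_<low>_<high>")
    codes = m.group("codes")
    if codes == MIXED_TOKEN:
        comp = CompositionState()
    else:
        if len(codes) % 4 != 0:
            raise StateParseError(text, len(codes), "composition block length must be a multiple of 4")
        blocks = [codes[i : i + 4] for i in range(0, len(codes), 4)]
        dominant = None
        admixed: list[str] = []
        for i, b in enumerate(blocks):
            if b.isupper():
                if i != 0:
                    raise StateParseError(text, i * 4, "dominant (upper-case) code must come first")
                dominant = b
            elif b.islower():
                admixed.append(b)
            else:
                raise StateParseError(text, i * 4, f"mixed-case species code {b!r}")
        comp = CompositionState(dominant=dominant, admixed=tuple(admixed))
    lai = int(m.group("lai"))
    lo, hi = int(m.group("lo")), int(m.group("hi"))
    if lai not in (1, 2, 3):
        raise StateParseError(text, m.start("lai"), f"LAI class {lai} out of range 1..3")
    if hi != lo + HEIGHT_BIN_WIDTH or lo % HEIGHT_BIN_WIDTH != 0:
        raise StateParseError(text, m.start("lo"), f"invalid height bin ({lo}, {hi})")
    return VegetationState(composition=comp, lai_class=lai, height_bin=(lo, hi))
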