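"""Heptad register assignment (a-g) with stutter support and position roles.

Registers are anchor-driven: the caller declares one or more
(residue number, letter) anchors per chain and letters propagate cyclically,
one step per residue.  Declared stutter intervals carry no letter and delay
the downstream register phase by their length (classically four residues).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["RegisterMap", "PositionRole", "assign_register", "role_of"]

HEPTAD = "abcdefg"

_ROLES = {
    "a": "hydrophobic_core",
    "d": "hydrophobic_core",
    "e": "ionic_rim",
    "g": "ionic_rim",
    "b": "surface",
    "c": "surface",
    "f": "surface",
}


@dataclass(frozen=True)
class PositionRole:
    letter: str
    role: str


@dataclass
class RegisterMap:
    """Per-residue heptad letters for one chain."""

    letters: dict[int, str | None]
    stutters: list[tuple[int, int]]

    def letter(self, resnum: int) -> str | None:
        try:
            return self.letters[resnum]
        except KeyError:
            raise KeyError(f"residue {resnum} outside assigned register range") from None


def _stutter_shift(resnum: int, stutters: list[tuple[int, int]]) -> int | None:
    """Accumulated phase delay at ``resnum``; None if inside a stutter."""
    shift = 0
    for lo, hi in stutters:
        if lo <= resnum <= hi:
            return None
        if resnum > hi:
            shift += hi - lo + 1
    return shift


def assign_register(
    chain_range: tuple[int, int],
    anchors: list[tuple[int, str]],
    stutters: list[tuple[int, int]] | None = None,
) -> RegisterMap:
    """Assign heptad letters over ``chain_range`` (inclusive) from anchors.

    All anchors must agree under cyclic propagation (with stutter delays);
    the first conflicting anchor raises.  Residues inside stutter intervals
    get no letter.
    """
    start, end = chain_range
    if end < start:
        raise ValueError("empty chain range")
    if not anchors:
        raise ValueError("at least one register anchor required")
    stutters = sorted(stutters or [])
    for lo, hi in stutters:
        if hi < lo:
            raise ValueError(f"invalid stutter interval ({lo}, {hi})")

    def phase_at(resnum: int, anchor_num: int, anchor_letter: str) -> int | None:
        sh_r = _stutter_shift(resnum, stutters)
        sh_a = _stutter_shift(anchor_num, stutters)
        if sh_r is None:
            return None
        if sh_a is None:
            raise ValueError(f"anchor {anchor_num} lies inside a stutter interval")
        return (HEPTAD.index(anchor_letter) + (resnum - anchor_num) - (sh_r - sh_a)) % 7

    a0_num, a0_letter = anchors[0]
    if a0_letter not in HEPTAD:
        raise ValueError(f"invalid register letter {a0_letter!r}")
    for num, letter in anchors[1:]:
        if letter not in HEPTAD:
            raise ValueError(f"invalid register letter {letter!r}")
        expected = phase_at(num, a0_num, a0_letter)
        if expected is None or HEPTAD[expected] != letter:
            raise ValueError(
                f"inconsistent anchor ({num}, {letter!r}): propagation from "
                f"({a0_num}, {a0_letter!r}) gives "
                f"{'a stutter position' if expected is None else HEPTAD[expected]!r}"
            )

    letters: dict[int, str | None] = {}
    for resnum in range(start, end + 1):
        ph = phase_at(resnum, a0_num, a0_letter)
        letters[resnum] = None if ph is None else HEPTAD[ph]
    return RegisterMap(letters, stutters)


def role_of(letter: str) -> PositionRole:
    """Structural role of a heptad letter: a/d hydrophobic core, e/g ionic
    rim, b/c/f surface."""
    try:
        return PositionRole(letter, _ROLES[letter])
    except KeyError:
        raise ValueError(f"invalid heptad letter {letter!r}") from None
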