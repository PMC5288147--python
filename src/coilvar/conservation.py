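"""Per-column conservation classes from a multiple sequence alignment.

The three-tier symbol scheme follows the classic Clustal convention:
'*' for identical columns (no gaps), ':' when all residues fall in one
strong substitution group, '.' when all fall in one weak group, ' '
otherwise.  A designated reference row maps columns to residue numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from ._data import read_tsv_rows

__all__ = ["ConservationTrack", "column_conservation", "map_conservation", "read_alignment"]

CLASS_ORDER = {" ": 0, ".": 1, ":": 2, "*": 3}


@lru_cache(maxsize=None)
def _groups() -> tuple[tuple[frozenset[str], ...], tuple[frozenset[str], ...]]:
    strong, weak = [], []
    for strength, members in read_tsv_rows("clustal_groups.tsv")[1:]:
        (strong if strength == "strong" else weak).append(frozenset(members))
    return tuple(strong), tuple(weak)


@dataclass
class ConservationTrack:
    classes: list[str]
    col_to_resnum: dict[int, int]
    resnum_to_col: dict[int, int]

    def class_at_column(self, col: int) -> str:
        return self.classes[col]


def _column_class(column: str) -> str:
    residues = set(column)
    if "-" in residues or "." in residues:
        return " "
    if len(residues) == 1:
        return "*"
    strong, weak = _groups()
    if any(residues <= g for g in strong):
        return ":"
    if any(residues <= g for g in weak):
        return "."
    return " "


def column_conservation(
    alignment: list[str],
    reference_index: int = 0,
    reference_start: int = 1,
) -> ConservationTrack:
    """Conservation classes for every column of an aligned set of rows.

    ``reference_index`` selects the row whose non-gap columns define the
    column-to-residue-number mapping, starting at ``reference_start``.
    """
    if len(alignment) < 2:
        raise ValueError("alignment needs at least two sequences")
    width = len(alignment[0])
    if any(len(row) != width for row in alignment):
        raise ValueError("ragged alignment: rows differ in length")
    rows = [row.upper() for row in alignment]
    classes = [_column_class("".join(r[i] for r in rows)) for i in range(width)]

    col_to_resnum: dict[int, int] = {}
    resnum = reference_start
    for col, ch in enumerate(rows[reference_index]):
        if ch not in "-.":
            col_to_resnum[col] = resnum
            resnum += 1
    resnum_to_col = {v: k for k, v in col_to_resnum.items()}
    return ConservationTrack(classes, col_to_resnum, resnum_to_col)


def map_conservation(track: ConservationTrack, site: int) -> str:
    """Conservation class of the column containing reference residue ``site``."""
    try:
        col = track.resnum_to_col[site]
    except KeyError:
        raise KeyError(f"residue {site} not covered by the reference mapping") from None
    return track.classes[col]


def read_alignment(path, fmt: str | None = None) -> list[str]:
    """Read an aligned FASTA or Clustal file into a list of row strings."""
    from Bio import AlignIO

    if fmt is None:
        with open(path, encoding="utf-8") as fh:
            first = fh.readline()
        fmt = "clustal" if first.upper().startswith("CLUSTAL") else "fasta"
    aln = AlignIO.read(str(path), fmt)
    return [str(rec.seq) for rec in aln]
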