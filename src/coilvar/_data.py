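"""Access to packaged data tables (internal)."""

from __future__ import annotations

from functools import lru_cache
from importlib import resources
from pathlib import Path


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    p = resources.files("coilvar.data").joinpath(name)
    return Path(str(p))


def read_tsv_rows(name: str) -> list[list[str]]:
    """Rows of a packaged TSV, comments ('#') and blank lines skipped."""
    rows = []
    with open(data_path(name), encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


@lru_cache(maxsize=None)
def vdw_radii() -> dict[str, float]:
    rows = read_tsv_rows("vdw_radii.tsv")
    return {el: float(r) for el, r in rows[1:]}
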