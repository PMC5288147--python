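"""Regenerate the packaged 2B sequence and alignment fixtures (maintenance).

Run from the repository root: python scripts/generate_fixtures.py

Sequences carry every residue identity named in the packaged variant/
interaction tables; remaining positions are filled by a heptad-patterned
filler keyed on the register letter.  Alignments encode the documented
conservation classes per column.
"""
import sys

sys.path.insert(0, "src")
from coilvar.conservation import _groups, column_conservation  # noqa: E402

HEPTAD = "abcdefg"
FILLER = {"a": "L", "b": "A", "c": "E", "d": "L", "e": "K", "f": "N", "g": "E"}

K1_RANGE = (373, 493)
K10_RANGE = (340, 460)
K1_ANCHOR = 479  # letter 'a'
K10_ANCHOR = 443

K1_FIXED = {
    403: "R", 428: "D", 431: "Q", 432: "R", 435: "N", 437: "L", 439: "D",
    450: "A", 457: "D", 463: "R", 464: "D", 468: "L", 471: "T", 472: "K",
    475: "L", 476: "D", 478: "E", 479: "I", 481: "T", 482: "Y", 483: "R",
    484: "R", 485: "L", 486: "L", 487: "E", 488: "G", 489: "E", 490: "E",
}
K10_FIXED = {
    380: "Q", 399: "R", 403: "Q", 404: "L", 410: "Q", 420: "Q", 439: "K",
    442: "L", 443: "E", 445: "E", 446: "I", 447: "Q", 448: "T", 449: "Y",
    450: "R", 451: "S", 452: "L", 453: "L", 454: "E", 455: "G", 456: "E",
}


def make_seq(rng, anchor, fixed):
    lo, hi = rng
    out = []
    for pos in range(lo, hi + 1):
        if pos in fixed:
            out.append(fixed[pos])
        else:
            out.append(FILLER[HEPTAD[(pos - anchor) % 7]])
    return "".join(out)


K1_CLASSES = {437: " ", 478: "*", 479: "*", 481: "*", 482: "*", 485: "*", 486: "*",
              403: ":", 457: ":", 464: ":",
              428: " ", 431: " ", 432: " ", 435: " ", 439: " ", 450: " ", 463: " "}
K10_CLASSES = {439: "*", 442: "*", 445: "*", 446: "*", 447: "*", 449: "*", 450: ".",
               452: "*", 453: "*", 399: ":", 443: "*",
               380: " ", 410: " ", 420: " ", 451: " "}

STRONG, WEAK = _groups()


def in_one(groups, resset):
    return any(resset <= g for g in groups)


def column_variants(x, cls):
    """Residues to put in rows 0..5 for desired class."""
    if cls == "*":
        return [x] * 6
    if cls == ":":
        for g in STRONG:
            if x in g:
                for y in sorted(g - {x}):
                    return [x, x, x, y, y, x]
        raise ValueError(f"no strong partner for {x}")
    if cls == ".":
        for g in WEAK:
            if x not in g:
                continue
            for y in sorted(g - {x}):
                if not in_one(STRONG, {x, y}):
                    return [x, x, y, y, y, x]
            for y in sorted(g - {x}):
                for z in sorted(g - {x, y}):
                    if not in_one(STRONG, {x, y, z}):
                        return [x, x, y, y, z, x]
        raise ValueError(f"no weak partner for {x}")
    # cls == " "
    for y in ("W", "G", "P", "R"):
        if y != x and not in_one(STRONG, {x, y}) and not in_one(WEAK, {x, y}):
            return [x, x, x, y, y, x]
    raise ValueError(f"no breaker for {x}")


def make_alignment(seq, rng, classes):
    lo, _ = rng
    rows = [[] for _ in range(6)]
    for i, x in enumerate(seq):
        cls = classes.get(lo + i, ".")
        col = column_variants(x, cls)
        for r, ch in zip(rows, col):
            r.append(ch)
    return ["".join(r) for r in rows]


k1 = make_seq(K1_RANGE, K1_ANCHOR, K1_FIXED)
k10 = make_seq(K10_RANGE, K10_ANCHOR, K10_FIXED)
assert len(k1) == len(k10) == 121

with open("src/coilvar/data/k1_k10_2b.fasta", "w") as fh:
    fh.write(f">K1_2B positions {K1_RANGE[0]}-{K1_RANGE[1]}\n{k1}\n")
    fh.write(f">K10_2B positions {K10_RANGE[0]}-{K10_RANGE[1]}\n{k10}\n")

for gene, seq, rng, classes in (
    ("k1", k1, K1_RANGE, K1_CLASSES),
    ("k10", k10, K10_RANGE, K10_CLASSES),
):
    rows = make_alignment(seq, rng, classes)
    track = column_conservation(rows, 0, rng[0])
    for pos, want in classes.items():
        got = track.classes[track.resnum_to_col[pos]]
        assert got == want, (gene, pos, want, got)
    names = [f"{gene.upper()}_2B_ref"] + [f"{gene.upper()}_homolog_{i}" for i in range(1, 6)]
    with open(f"src/coilvar/data/{gene}_family_alignment.fasta", "w") as fh:
        for name, row in zip(names, rows):
            fh.write(f">{name}\n{row}\n")

print("K1 :", k1)
print("K10:", k10)
print("fixtures written and class assertions passed")
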