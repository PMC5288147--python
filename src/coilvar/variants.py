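"""Curated catalog of 2B-domain missense variants (disease mutations and
SNPs) for the K1/K10 heterodimer, with HGVS-style parsing, duplicate
collapsing and genotype-phenotype grouping.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from ._data import data_path
from .sidechains import AA1, STANDARD_AAS

__all__ = [
    "Variant",
    "VariantCatalog",
    "GroupAssignment",
    "GENE_RANGES",
    "parse_hgvs_pair",
    "load_catalog",
    "packaged_catalog",
    "group_variants",
]

# 2B-domain residue ranges in full-length protein numbering.
GENE_RANGES = {"K1": (373, 493), "K10": (340, 460)}

DISEASES = frozenset({"BCIE/EHK", "NEPPK", "CIEH", "EPPK", "none"})
SEVERITY_ORDER = {"n/a": 0, "unknown": 1, "mild": 2, "moderate": 3, "severe": 4}

_PROTEIN_RE = re.compile(r"^p\.([A-Za-z]{1,3})(\d+)([A-Za-z]{1,3})$")


class VariantParseError(ValueError):
    pass


@dataclass(frozen=True)
class Variant:
    """One missense change in full-length protein numbering."""

    gene: str
    cdna: str
    wt_aa: str
    position: int
    mut_aa: str
    category: str = "disease_mutation"
    diseases: frozenset[str] = frozenset()
    severity: str = "unknown"

    def __post_init__(self):
        if self.gene not in GENE_RANGES:
            raise VariantParseError(f"unknown gene {self.gene!r} (expected K1 or K10)")
        lo, hi = GENE_RANGES[self.gene]
        if not lo <= self.position <= hi:
            raise VariantParseError(
                f"position {self.position} outside {self.gene} 2B range {lo}-{hi}"
            )
        if self.wt_aa == self.mut_aa:
            raise VariantParseError(f"synonymous change {self.wt_aa}{self.position}{self.mut_aa}")
        if self.category not in ("disease_mutation", "snp"):
            raise VariantParseError(f"invalid category {self.category!r}")
        if self.category == "snp" and self.diseases != frozenset({"none"}):
            raise VariantParseError("SNP records must carry diseases={'none'}")
        bad = self.diseases - DISEASES
        if bad:
            raise VariantParseError(f"unknown disease labels {sorted(bad)}")
        if self.severity not in SEVERITY_ORDER:
            raise VariantParseError(f"unknown severity {self.severity!r}")

    @property
    def protein(self) -> str:
        return f"p.{self.wt_aa}{self.position}{self.mut_aa}"

    @property
    def site(self) -> tuple[str, int]:
        return (self.gene, self.position)

    def __str__(self) -> str:
        return f"{self.gene}-{self.protein}"


def _parse_aa(token: str) -> str:
    if len(token) == 1:
        aa = token.upper()
        if aa not in STANDARD_AAS:
            raise VariantParseError(f"invalid amino-acid code {token!r}")
        return aa
    if len(token) == 3:
        try:
            return AA1[token.upper()]
        except KeyError:
            raise VariantParseError(f"invalid amino-acid code {token!r}") from None
    raise VariantParseError(f"invalid amino-acid code {token!r}")


def parse_hgvs_pair(cdna: str, protein: str, gene: str, **kw) -> Variant:
    """Build a :class:`Variant` from cDNA and protein HGVS-style notation.

    ``protein`` must match ``p.<WT><pos><MUT>`` with one- or three-letter
    codes; the position is validated against the gene's 2B range.
    """
    m = _PROTEIN_RE.match(protein.strip())
    if not m:
        raise VariantParseError(f"malformed protein notation {protein!r}")
    wt, pos, mut = m.groups()
    return Variant(
        gene=gene,
        cdna=cdna.strip(),
        wt_aa=_parse_aa(wt),
        position=int(pos),
        mut_aa=_parse_aa(mut),
        **kw,
    )


@dataclass
class VariantCatalog:
    records: list[Variant] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self):
        for cat in ("disease_mutation", "snp"):
            keys = [
                (v.gene, v.position, v.mut_aa) for v in self.records if v.category == cat
            ]
            if len(keys) != len(set(keys)):
                raise ValueError(f"duplicate {cat} records in catalog")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_category(self, category: str) -> list[Variant]:
        return [v for v in self.records if v.category == category]

    def counts(self) -> dict:
        out: dict = {"total": len(self.records), "by_gene": {}, "by_category": {}}
        for v in self.records:
            out["by_gene"].setdefault(v.gene, 0)
            out["by_gene"][v.gene] += 1
            out["by_category"].setdefault(v.category, {"total": 0, "by_gene": {}})
            c = out["by_category"][v.category]
            c["total"] += 1
            c["by_gene"][v.gene] = c["by_gene"].get(v.gene, 0) + 1
        return out

    def summary_json(self) -> str:
        return json.dumps({"provenance": self.provenance, **self.counts()}, indent=2, sort_keys=True)

    def to_tsv(self, path) -> None:
        lines = ["gene\tcdna\tprotein\tcategory\tdiseases\tseverity"]
        for v in self.records:
            lines.append(
                "\t".join(
                    [v.gene, v.cdna, v.protein, v.category, "|".join(sorted(v.diseases)), v.severity]
                )
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_catalog(path) -> VariantCatalog:
    """Load a TSV variant catalog, collapsing duplicate protein-level rows.

    Duplicates (same gene, position and substitution) have their disease
    sets unioned; conflicting severities keep the most severe with a
    warning.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if len(lines) < 2:
        raise ValueError(f"empty variant catalog: {path}")
    header = lines[0].split("\t")
    required = ["gene", "cdna", "protein", "category", "diseases", "severity"]
    if [h.strip() for h in header[: len(required)]] != required:
        raise ValueError(f"bad catalog header in {path}: {header}")

    merged: dict[tuple, Variant] = {}
    for ln in lines[1:]:
        gene, cdna, protein, category, diseases, severity = (x.strip() for x in ln.split("\t"))
        dset = frozenset(d for d in diseases.split("|") if d)
        v = parse_hgvs_pair(
            cdna, protein, gene, category=category, diseases=dset, severity=severity
        )
        key = (v.category, v.gene, v.position, v.mut_aa)
        if key in merged:
            prev = merged[key]
            sev = v.severity
            if prev.severity != v.severity:
                sev = max(prev.severity, v.severity, key=lambda s: SEVERITY_ORDER[s])
                warnings.warn(
                    f"conflicting severities for {v}: keeping most severe ({sev})"
                )
            merged[key] = replace(
                prev,
                diseases=prev.diseases | v.diseases,
                severity=sev,
                cdna=prev.cdna if prev.cdna == v.cdna else f"{prev.cdna};{v.cdna}",
            )
        else:
            merged[key] = v
    return VariantCatalog(list(merged.values()), provenance=str(path))


def packaged_catalog(which: str = "mutations") -> VariantCatalog:
    """The packaged disease-mutation or SNP catalog fixture."""
    names = {"mutations": "k1_k10_mutations.tsv", "snps": "k1_k10_snps.tsv"}
    return load_catalog(data_path(names[which]))


@dataclass
class GroupAssignment:
    group_id: str
    members: frozenset[Variant]
    site: tuple[str, int] | None = None

    def __post_init__(self):
        if not self.members:
            raise ValueError("group members must be nonempty")


def group_variants(catalog: VariantCatalog) -> list[GroupAssignment]:
    """Genotype-phenotype groups over the disease mutations of the catalog.

    Group 1: sites with >=2 distinct substitutions whose disease sets differ.
    Group 2: single variants annotated with >=2 diseases.
    Group 3: sites with >=2 distinct substitutions sharing identical disease
    sets.  (The interaction-loss commonality group is a derived view of the
    impact layer, not assigned here.)
    """
    if not len(catalog):
        raise ValueError("empty catalog")
    muts = catalog.by_category("disease_mutation")
    groups: list[GroupAssignment] = []

    by_site: dict[tuple[str, int], list[Variant]] = {}
    for v in muts:
        by_site.setdefault(v.site, []).append(v)
    for site in sorted(by_site):
        members = by_site[site]
        if len(members) < 2:
            continue
        disease_sets = {v.diseases for v in members}
        gid = "same_site_diff_phenotype" if len(disease_sets) > 1 else "diff_variant_same_phenotype"
        groups.append(GroupAssignment(gid, frozenset(members), site))

    for v in sorted(muts, key=lambda v: (v.gene, v.position, v.mut_aa)):
        if len(v.diseases) >= 2:
            groups.append(GroupAssignment("same_variant_diff_phenotype", frozenset([v]), v.site))
    return groups
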