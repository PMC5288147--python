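"""Pipeline configuration: YAML loading with packaged defaults.

The default configuration describes the packaged reference heterodimer
(chain A = K1 residues 373-493, chain B = K10 residues 340-460, registers
anchored at K1:479='a' and K10:443='a'), the packaged catalogs and
alignment fixtures, interaction/clash criteria and the side-chain pose
groups of the reference model.  ``coilvar://NAME`` paths refer to packaged
data files.
"""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from ._data import data_path
from .interactions import InteractionCriteria
from .rotamers import ClashCriteria
from .structure import CrickParams

__all__ = ["load_config", "default_config", "resolve_path", "PipelineConfig"]


def resolve_path(p: str | Path) -> Path:
    """Resolve a config path; ``coilvar://NAME`` maps to packaged data."""
    p = str(p)
    if p.startswith("coilvar://"):
        return data_path(p[len("coilvar://"):])
    return Path(p)


def default_config() -> dict:
    with open(data_path("default_config.yaml"), encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _deep_update(base: dict, upd: dict) -> dict:
    for k, v in upd.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
    return base


class PipelineConfig:
    """Validated view over the configuration mapping."""

    def __init__(self, raw: dict):
        self.raw = raw

    # -- structure ---------------------------------------------------------
    @property
    def source(self) -> str:
        return self.raw["structure"]["source"]

    @property
    def pdb_path(self) -> Path | None:
        p = self.raw["structure"].get("pdb_path")
        return resolve_path(p) if p else None

    def crick_params(self) -> CrickParams:
        return CrickParams(**self.raw["structure"].get("crick", {}))

    @property
    def noise_sd(self) -> float:
        return float(self.raw["structure"].get("noise_sd", 0.0))

    @property
    def seed(self) -> int:
        return int(self.raw["structure"].get("seed", 0))

    def chain(self, cid: str) -> dict:
        return self.raw["chains"][cid]

    @property
    def chain_ids(self) -> list[str]:
        return list(self.raw["chains"])

    def chain_for_gene(self, gene: str) -> str:
        for cid, spec in self.raw["chains"].items():
            if spec["gene"] == gene:
                return cid
        raise KeyError(f"no chain configured for gene {gene}")

    # -- analysis ----------------------------------------------------------
    def interaction_criteria(self) -> InteractionCriteria:
        return InteractionCriteria(**self.raw.get("interaction_criteria", {}))

    def clash_criteria(self) -> ClashCriteria:
        return ClashCriteria(**self.raw.get("clash_criteria", {}))

    @property
    def top_n(self) -> int:
        return int(self.raw.get("top_n", 5))

    @property
    def pose_groups(self) -> list[dict]:
        return self.raw.get("pose_groups", [])

    def catalog_path(self, which: str) -> Path:
        return resolve_path(self.raw["catalogs"][which])

    def alignment_path(self, gene: str) -> Path:
        return resolve_path(self.raw["conservation"]["alignments"][gene])

    @property
    def table1_path(self) -> Path:
        return resolve_path(self.raw["concordance"]["table"])


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load the packaged default configuration, optionally overlaid with a
    user YAML file and/or an override mapping."""
    cfg = default_config()
    if path is not None:
        with open(path, encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        _deep_update(cfg, user)
    if overrides:
        _deep_update(cfg, copy.deepcopy(overrides))
    return PipelineConfig(cfg)
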