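"""Run configuration: thresholds, paths, seeding.

Defaults are the method's published operating point: DE cutoff 0.01,
10,000 permutations, GO–GO retention at p < 0.01, and link-classification
cutoffs 0.9 / 0.6 / 0.9 for min_PCC / diff_PCC / full_PCC.
"""

from __future__ import annotations

import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed from the master seed and stage name."""
    return (int(master_seed) ^ zlib.crc32(stage.encode("utf-8"))) % (2**31)


@dataclass
class RunConfig:
    """All inputs, outputs and thresholds for an end-to-end run."""

    network: str | None = None
    go_annotation: str | None = None
    go_format: str = "tsv"  # or "gaf"
    deg_table: str | None = None
    expression: str | None = None
    design: str | None = None
    out_dir: str = "gogonet_out"

    days: tuple[int, ...] = (2, 4, 6, 7)
    alpha: float = 0.01
    p_cutoff: float = 0.01
    n_perm: int = 10_000
    min_pcc: float = 0.9
    diff_pcc: float = 0.6
    full_pcc: float = 0.9
    alpha_effect: float = 0.05
    alpha_sync: float = 0.2
    seed: int = 0
    paper_df: bool = False
    abs_full_pcc: bool = False
    bh_correction: bool = False
    min_score: float | None = None
    formats: tuple[str, ...] = ("sif", "graphml", "edge_tsv", "node_tsv")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "days" in raw:
            raw["days"] = tuple(int(d) for d in raw["days"])
        if "formats" in raw:
            raw["formats"] = tuple(raw["formats"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["days"] = list(self.days)
        data["formats"] = list(self.formats)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def sub_seed(self, stage: str) -> int:
        return stage_seed(self.seed, stage)
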