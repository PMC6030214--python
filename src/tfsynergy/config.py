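"""Run configuration: every tunable knob of the pipeline in one dataclass.

Defaults mirror the published procedure: a 3-TF seed stage keeping the 1%
most synergistic triples, ten seeds carried per extension level, cores capped
at 15 TFs, and the top three cores reported per subpopulation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from ._exceptions import DataValidationError

UNIT_REGIMES = ("fpkm_like", "normalized_counts", "umi")


@dataclass
class RunConfig:
    #: expression cutoff; None uses the unit-regime default (1 for FPKM/RPKM/TPM
    #: and UMI counts, 10 for normalized read counts)
    expression_threshold: float | None = None
    #: fraction of annotated TFs shortlisted by expressing frequency
    top_frequency_fraction: float = 0.10
    #: TFs expressed in at most this fraction of cells are dropped (strict >)
    min_expressing_fraction: float = 0.30
    #: hard cap on candidate TFs; excess trimmed by highest coefficient of variation
    max_tf_count: int = 150
    #: fraction of triples kept by lowest MMI, and of that shortlist by highest TC
    seed_fraction: float = 0.01
    #: a (k+1)-combination is kept iff MMI(new) - MMI(seed) < -extension_delta
    extension_delta: float = 0.05
    #: combinations carried to the next level, ranked by TC
    seeds_per_level: int = 10
    #: pool size (best-TC combinations over all levels) re-scored at finalization
    final_pool_size: int = 20
    #: search terminates when cores reach this many TFs
    max_core_size: int = 15
    #: cores reported per subpopulation
    reported_cores: int = 3
    #: cell population on which MMI is evaluated: "complement" scores each
    #: subpopulation's candidate TFs on all *other* cells (bins are always fit
    #: on the subpopulation itself); "within" scores on the subpopulation's own cells
    mmi_population: str = "complement"
    #: conversion-TF ranking key: absolute or signed log2 fold change
    fc_rank: str = "abs_log"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("top_frequency_fraction", "min_expressing_fraction", "seed_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DataValidationError(f"{name} must be in (0, 1], got {v}")
        if self.max_core_size < 3:
            raise DataValidationError("max_core_size must be >= 3")
        if self.mmi_population not in ("complement", "within"):
            raise DataValidationError(f"unknown mmi_population {self.mmi_population!r}")
        if self.fc_rank not in ("abs_log", "signed"):
            raise DataValidationError(f"unknown fc_rank {self.fc_rank!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise DataValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)
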