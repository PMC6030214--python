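"""Ranking of identity-conversion TFs between subpopulation pairs.

The TFs of a target subpopulation's rank-1 synergistic core are ranked by mean
expression fold change between target and source cells — candidates for up- or
down-regulation when converting the source identity into the target's. A
pseudocount of 1 (matching the zero→1 convention used before log transforms)
keeps fold changes finite for silent genes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from ._exceptions import DataValidationError
from .io import ExpressionMatrix, SubpopulationPartition
from .search import SynergyCore


@dataclass(frozen=True)
class RankedConversionTF:
    tf: str
    fold_change: float
    direction: str  # "up" | "down"
    log2_fold_change: float


@dataclass
class ConversionPlan:
    source: str
    target: str
    ranked_tfs: list[RankedConversionTF]


def rank_conversion_tfs(
    target_core: SynergyCore,
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    source: str,
    pseudocount: float = 1.0,
    fc_rank: str = "abs_log",
) -> ConversionPlan:
    """Rank a target core's TFs by expression fold change from a source subpopulation.

    ``fold_change = (mean_target + ε) / (mean_source + ε)`` on the raw scale
    (ε = ``pseudocount``); direction "up" iff the fold change exceeds 1.
    Default ranking key is ``|log2 FC|`` descending (so strong down-regulation
    candidates rank as high as strong up-regulation ones); ``fc_rank="signed"``
    ranks by the signed log2 fold change instead. Lexicographic tie-break.
    """
    target = target_core.subpopulation
    if source == target:
        raise DataValidationError("source and target subpopulations must differ")
    for label in (source, target):
        if not partition.is_eligible(label):
            raise DataValidationError(f"subpopulation {label!r} is not eligible")
    if fc_rank not in ("abs_log", "signed"):
        raise DataValidationError(f"unknown fc_rank {fc_rank!r}")

    tfs = list(target_core.tfs)
    mean_t = matrix.submatrix(partition.cells(target), tfs).mean(axis=0)
    mean_s = matrix.submatrix(partition.cells(source), tfs).mean(axis=0)

    ranked = []
    for tf, mt, ms in zip(tfs, mean_t, mean_s):
        fc = (mt + pseudocount) / (ms + pseudocount)
        ranked.append(
            RankedConversionTF(
                tf=tf,
                fold_change=float(fc),
                direction="up" if fc > 1.0 else "down",
                log2_fold_change=float(math.log2(fc)),
            )
        )
    if fc_rank == "abs_log":
        ranked.sort(key=lambda r: (-abs(r.log2_fold_change), r.tf))
    else:
        ranked.sort(key=lambda r: (-r.log2_fold_change, r.tf))
    return ConversionPlan(source=source, target=target, ranked_tfs=ranked)


def all_pairs_catalog(
    cores_by_subpop: dict[str, list[SynergyCore]],
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    use_union: bool = False,
    pseudocount: float = 1.0,
    fc_rank: str = "abs_log",
) -> list[ConversionPlan]:
    """One conversion plan per ordered (source, target) pair with cores.

    ``k`` subpopulations yield exactly ``k·(k−1)`` plans. By default the
    target's rank-1 core supplies the TFs; ``use_union=True`` pools the TFs of
    all reported cores instead.
    """
    labels = sorted(cores_by_subpop)
    plans = []
    for target in labels:
        cores = cores_by_subpop[target]
        if use_union:
            tfs = tuple(sorted({tf for core in cores for tf in core.tfs}))
            core = SynergyCore(
                subpopulation=target, tfs=tfs, mmi=cores[0].mmi, tc=cores[0].tc,
                summed_mean_expression=cores[0].summed_mean_expression, rank=1,
            )
        else:
            core = cores[0]
        for source in labels:
            if source == target:
                continue
            plans.append(
                rank_conversion_tfs(core, matrix, partition, source,
                                    pseudocount=pseudocount, fc_rank=fc_rank)
            )
    return plans


def catalog_to_frame(plans: list[ConversionPlan]) -> pd.DataFrame:
    """Flatten plans into a tidy table (one row per source/target/TF)."""
    rows = []
    for plan in plans:
        for rank, r in enumerate(plan.ranked_tfs, start=1):
            rows.append(
                {
                    "source": plan.source,
                    "target": plan.target,
                    "rank": rank,
                    "tf": r.tf,
                    "fold_change": r.fold_change,
                    "log2_fold_change": r.log2_fold_change,
                    "direction": r.direction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["source", "target", "rank", "tf", "fold_change",
                 "log2_fold_change", "direction"],
    )
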