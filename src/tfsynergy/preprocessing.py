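"""Per-subpopulation TF filtering producing the candidate set for the synergy search.

The pipeline, in fixed order: restrict to annotated TFs present in the matrix;
compute each TF's expressing fraction within the subpopulation; shortlist the
top 10% most frequently expressed (ties at the cutoff retained); drop TFs
expressed in ≤ 30% of cells; for UMI data drop TFs with within-subpopulation
mean count < 1; trim to at most 150 TFs by discarding those with the highest
coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._exceptions import DataValidationError, InsufficientTFsError
from .config import RunConfig
from .io import ExpressionMatrix, SubpopulationPartition

#: "expressed" cutoffs per unit regime: ≥1 for FPKM/RPKM/TPM and UMI counts,
#: ≥10 for normalized read counts
UNIT_THRESHOLDS = {"fpkm_like": 1.0, "normalized_counts": 10.0, "umi": 1.0}

MIN_CANDIDATE_TFS = 3


@dataclass
class TFCandidateSet:
    """Candidate TFs for one subpopulation, ordered by expressing fraction
    (descending, ties lexicographic)."""

    subpopulation: str
    tfs: list[str]
    expressing_fraction: dict[str, float]
    mean_expression: dict[str, float]

    def __len__(self) -> int:
        return len(self.tfs)


def expression_threshold(unit_regime: str, override_threshold: float | None = None) -> float:
    if override_threshold is not None:
        return float(override_threshold)
    try:
        return UNIT_THRESHOLDS[unit_regime]
    except KeyError:
        raise DataValidationError(f"unknown unit_regime {unit_regime!r}") from None


def is_expressed(value, unit_regime: str, override_threshold: float | None = None):
    """Whether an expression value crosses the regime's "expressed" cutoff.

    Accepts scalars or arrays; the cutoff is inclusive (value ≥ threshold).
    """
    thr = expression_threshold(unit_regime, override_threshold)
    result = np.asarray(value, dtype=np.float64) >= thr
    return bool(result) if np.isscalar(value) or result.ndim == 0 else result


def _cv(values: np.ndarray) -> float:
    # degenerate mean-zero TF carries no signal: treated as +inf, dropped first
    m = values.mean()
    if m == 0:
        return math.inf
    return float(values.std(ddof=1) / m)


def select_candidate_tfs(
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    subpop: str,
    tf_list,
    config: RunConfig | None = None,
    binary_status: ExpressionMatrix | None = None,
) -> TFCandidateSet:
    """Run the TF filtering pipeline for one subpopulation.

    ``binary_status``, if given, is a precomputed 0/1 expressed-status matrix
    (same ids) used for the expressing-fraction step only — for datasets whose
    original study provides binarized expression calls.

    Raises :class:`InsufficientTFsError` if fewer than three TFs survive.
    """
    config = config or RunConfig()
    if not partition.is_eligible(subpop):
        raise DataValidationError(f"subpopulation {subpop!r} is not eligible")

    tfs_present = sorted(set(tf_list) & set(matrix.gene_ids))
    if not tfs_present:
        raise DataValidationError("no TF from the list is present in the matrix")

    cells = partition.cells(subpop)
    sub = matrix.submatrix(cells, tfs_present)  # cells × tfs

    if binary_status is not None:
        expressed = binary_status.submatrix(cells, tfs_present) > 0
    else:
        expressed = is_expressed(sub, matrix.unit_regime, config.expression_threshold)
    fraction = expressed.mean(axis=0)
    mean_expr = sub.mean(axis=0)

    frac_of = dict(zip(tfs_present, fraction))
    mean_of = dict(zip(tfs_present, mean_expr))

    # top-X% shortlist by expressing fraction; ties at the cutoff all retained
    k = math.ceil(config.top_frequency_fraction * len(tfs_present))
    cutoff = sorted(fraction, reverse=True)[k - 1]
    kept = [tf for tf in tfs_present if frac_of[tf] >= cutoff]

    # strictly more than min_expressing_fraction of cells
    kept = [tf for tf in kept if frac_of[tf] > config.min_expressing_fraction]

    if matrix.unit_regime == "umi":
        kept = [tf for tf in kept if mean_of[tf] >= 1.0]

    if len(kept) > config.max_tf_count:
        # discard highest-CV TFs until the cap holds (ties: drop later names first)
        cv = {tf: _cv(matrix.submatrix(cells, [tf])[:, 0]) for tf in kept}
        order = sorted(kept, key=lambda tf: (cv[tf], tf))  # ascending CV, keep front
        kept = order[: config.max_tf_count]

    if len(kept) < MIN_CANDIDATE_TFS:
        raise InsufficientTFsError(
            f"subpopulation {subpop!r}: {len(kept)} candidate TFs survive filtering "
            f"(need ≥ {MIN_CANDIDATE_TFS})"
        )

    kept.sort(key=lambda tf: (-frac_of[tf], tf))
    return TFCandidateSet(
        subpopulation=subpop,
        tfs=kept,
        expressing_fraction={tf: float(frac_of[tf]) for tf in kept},
        mean_expression={tf: float(mean_of[tf]) for tf in kept},
    )
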