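"""Comparator methods: JSD identity scoring, pairwise-MI networks, GRN hubs.

These are the bulk-era / network-topology alternatives the synergy search is
judged against: ranking TFs by Jensen–Shannon divergence of their mean
expression profile against a subpopulation indicator; significance-filtered
pairwise-MI networks with a permutation null; and hub extraction from
correlation- or MI-based co-expression networks (PCC, SCC, MRNET). Random
forest GRN inference (GENIE3) is not re-implemented — externally computed
weighted adjacencies plug into the same hub extraction via
:func:`hubs_from_adjacency`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.stats
from scipy.spatial.distance import jensenshannon
from sklearn.base import BaseEstimator

from ._exceptions import DataValidationError
from .infotheory import (
    BinningScheme,
    discretize_matrix,
    log_transform,
    nats_to_bits,
    pairwise_mi,
)
from .io import ExpressionMatrix, SubpopulationPartition


@dataclass(frozen=True)
class JSDScore:
    tf: str
    subpopulation: str
    jsd: float  # base-2: in [0, 1]


@dataclass(frozen=True)
class MIEdge:
    tf_a: str
    tf_b: str
    mi: float  # bits
    p_value: float
    kept: bool


# ---------------------------------------------------------------------------
# JSD identity scoring


def jsd_identity_tfs(
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    subpop: str,
    tf_list,
    top_n: int = 10,
) -> list[JSDScore]:
    """Rank TFs by JSD between the subpopulation indicator and their
    normalized mean-expression profile across subpopulations.

    The ideal vector puts 1 on the query subpopulation and 0 elsewhere; the
    observed vector is each subpopulation's mean expression divided by the sum
    over subpopulations. JSD is base-2 (maximum 1); the ``top_n`` lowest-JSD
    TFs are returned, with ties at the final rank included. TFs with zero mean
    everywhere are excluded (their observed vector is undefined).
    """
    labels = partition.eligible_labels
    if len(labels) < 2:
        raise DataValidationError("JSD scoring needs at least 2 eligible subpopulations")
    if subpop not in labels:
        raise DataValidationError(f"subpopulation {subpop!r} is not eligible")
    tfs = sorted(set(tf_list) & set(matrix.gene_ids))
    means = np.vstack(
        [matrix.submatrix(partition.cells(label), tfs).mean(axis=0) for label in labels]
    )  # subpops × tfs
    ideal = np.array([1.0 if label == subpop else 0.0 for label in labels])

    scores = []
    for j, tf in enumerate(tfs):
        total = means[:, j].sum()
        if total == 0.0:
            continue
        observed = means[:, j] / total
        jsd = float(jensenshannon(ideal, observed, base=2.0) ** 2)
        scores.append(JSDScore(tf=tf, subpopulation=subpop, jsd=jsd))
    scores.sort(key=lambda s: (s.jsd, s.tf))
    if len(scores) <= top_n:
        return scores
    cutoff = scores[top_n - 1].jsd
    return [s for s in scores if s.jsd <= cutoff]


# ---------------------------------------------------------------------------
# pairwise-MI network with permutation significance


def _discretized_log2(matrix, partition, subpop, tfs):
    cells = partition.cells(subpop)
    logged_source = matrix.submatrix(cells, tfs)
    log_vals = log_transform(logged_source, base=2)
    scheme = BinningScheme.fit(
        {tf: log_vals[:, j] for j, tf in enumerate(tfs)},
        matrix.unit_regime,
        subpopulation=subpop,
    )
    return discretize_matrix(logged_source, tfs, scheme, log_base=2)


def mi_network(
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    subpop: str,
    core_tfs,
    n_permutations: int = 50,
    rng_seed: int = 0,
    p_method: str = "ttest",
) -> list[MIEdge]:
    """Pairwise-MI edges within a subpopulation, significance-filtered.

    MI (bits) is computed on log2-transformed, FD-discretized values. Each
    edge's null comes from ``n_permutations`` independent within-TF cell
    permutations; ``p_method="ttest"`` runs a one-sided one-sample t-test of
    the null replicates against the observed MI, ``"empirical"`` uses the
    permutation tail probability. Edges with p-values in the lowest 1%
    (minimum one) are flagged ``kept``.
    """
    if n_permutations < 2:
        raise DataValidationError("need at least 2 permutation replicates")
    if p_method not in ("ttest", "empirical"):
        raise DataValidationError(f"unknown p_method {p_method!r}")
    tfs = sorted(set(core_tfs) & set(matrix.gene_ids))
    if len(tfs) < 2:
        raise DataValidationError("MI network needs at least 2 TFs")
    profiles = _discretized_log2(matrix, partition, subpop, tfs)
    rng = np.random.default_rng(rng_seed)

    pairs = list(combinations(range(len(tfs)), 2))
    observed = np.array(
        [nats_to_bits(pairwise_mi(profiles[i], profiles[j])) for i, j in pairs]
    )

    null = np.empty((n_permutations, len(pairs)))
    for r in range(n_permutations):
        shuffled = [
            type(p)(tf=p.tf, symbols=rng.permutation(p.symbols), bin_count=p.bin_count)
            for p in profiles
        ]
        null[r] = [
            nats_to_bits(pairwise_mi(shuffled[i], shuffled[j])) for i, j in pairs
        ]

    pvals = np.empty(len(pairs))
    for e in range(len(pairs)):
        if p_method == "empirical":
            pvals[e] = (1.0 + (null[:, e] >= observed[e]).sum()) / (n_permutations + 1.0)
        else:
            if np.allclose(null[:, e], null[0, e]):
                # degenerate null spread: decide by direct comparison
                pvals[e] = 0.0 if observed[e] > null[0, e] else 1.0
            else:
                pvals[e] = scipy.stats.ttest_1samp(
                    null[:, e], popmean=observed[e], alternative="less"
                ).pvalue

    n_keep = max(1, math.ceil(0.01 * len(pairs)))
    order = sorted(range(len(pairs)), key=lambda e: (pvals[e], -observed[e], pairs[e]))
    kept = set(order[:n_keep])
    return [
        MIEdge(
            tf_a=tfs[i], tf_b=tfs[j], mi=float(observed[e]),
            p_value=float(pvals[e]), kept=e in kept,
        )
        for e, (i, j) in enumerate(pairs)
    ]


# ---------------------------------------------------------------------------
# GRN hub extraction


def mrnet_adjacency(mim: np.ndarray) -> np.ndarray:
    """MRNET: maximum-relevance/minimum-redundancy network from an MI matrix.

    For each target variable, predictors are ranked by forward MRMR selection
    (score = relevance MI minus mean MI with already-selected predictors,
    stopping when no score is positive); an edge's weight is the larger of its
    two directed MRMR scores, floored at 0. Retained (positive-weight) edges
    are always a subset of the positive-MI edges.
    """
    n = mim.shape[0]
    score = np.zeros((n, n))
    for target in range(n):
        predictors = [i for i in range(n) if i != target]
        selected: list[int] = []
        remaining = set(predictors)
        while remaining:
            best, best_s = None, -math.inf
            for i in sorted(remaining):
                red = np.mean([mim[i, s] for s in selected]) if selected else 0.0
                s = mim[i, target] - red
                if s > best_s:
                    best, best_s = i, s
            if best_s <= 0.0:
                break
            score[best, target] = best_s
            selected.append(best)
            remaining.discard(best)
    adj = np.maximum(score, score.T)
    np.fill_diagonal(adj, 0.0)
    return adj


def grn_adjacency(
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    subpop: str,
    tfs: list[str],
    method: str,
) -> pd.DataFrame:
    """Weighted co-expression adjacency within one subpopulation.

    ``pcc``/``scc``: absolute Pearson/Spearman correlation on log2-transformed
    values (UMI counts enter untransformed); ``mrnet``: MRMR-filtered MI
    network on FD-discretized log2 values.
    """
    cells = partition.cells(subpop)
    raw = matrix.submatrix(cells, tfs)
    if method in ("pcc", "scc"):
        vals = raw if matrix.unit_regime == "umi" else log_transform(raw, base=2)
        if method == "pcc":
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(vals, rowvar=False)
        else:
            corr = scipy.stats.spearmanr(vals).statistic
            if np.ndim(corr) == 0:  # scipy collapses the 2-variable case to a scalar
                corr = np.array([[1.0, corr], [corr, 1.0]])
        adj = np.abs(np.nan_to_num(corr, nan=0.0))
        np.fill_diagonal(adj, 0.0)
    elif method == "mrnet":
        profiles = _discretized_log2(matrix, partition, subpop, tfs)
        n = len(tfs)
        mim = np.zeros((n, n))
        for i, j in combinations(range(n), 2):
            mim[i, j] = mim[j, i] = max(
                0.0, nats_to_bits(pairwise_mi(profiles[i], profiles[j]))
            )
        adj = mrnet_adjacency(mim)
    else:
        raise DataValidationError(f"unknown GRN method {method!r}; use pcc, scc, or mrnet")
    return pd.DataFrame(adj, index=tfs, columns=tfs)


def hubs_from_adjacency(adjacency: pd.DataFrame, top_n: int = 10) -> list[str]:
    """Top hub genes by weighted degree of a symmetric adjacency."""
    degree = adjacency.sum(axis=1)
    order = sorted(degree.index, key=lambda g: (-degree[g], g))
    return order[:top_n]


def grn_hubs(
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    subpop: str,
    tf_list,
    method: str = "pcc",
    top_n: int = 10,
) -> list[str]:
    """Top-``top_n`` hub TFs (by weighted degree) of a subpopulation's GRN."""
    tfs = sorted(set(tf_list) & set(matrix.gene_ids))
    if len(tfs) < top_n + 1:
        raise DataValidationError(f"hub extraction needs at least {top_n + 1} TFs")
    return hubs_from_adjacency(grn_adjacency(matrix, partition, subpop, tfs, method), top_n)


def unique_hubs(hubs_by_subpop: dict[str, list[str]], subpop: str) -> list[str]:
    """Hubs in the query subpopulation's top list but in no other subpopulation's."""
    others = {h for label, hubs in hubs_by_subpop.items() if label != subpop for h in hubs}
    return [h for h in hubs_by_subpop[subpop] if h not in others]


# ---------------------------------------------------------------------------
# estimator wrappers


class JSDIdentityScorer(BaseEstimator):
    """Per-subpopulation JSD identity-TF ranking over a labeled matrix.

    After ``fit(matrix, labels)``: ``scores_`` maps each eligible
    subpopulation to its top TF list (lowest JSD, ties included).
    """

    def __init__(self, tf_list=None, top_n: int = 10):
        self.tf_list = tf_list
        self.top_n = top_n

    def fit(self, X: ExpressionMatrix, y):
        partition = _partition_from(X, y)
        tf_list = self.tf_list if self.tf_list is not None else X.gene_ids
        self.scores_ = {
            label: jsd_identity_tfs(X, partition, label, tf_list, self.top_n)
            for label in partition.eligible_labels
        }
        return self


class MINetwork(BaseEstimator):
    """Significance-filtered pairwise-MI network per subpopulation."""

    def __init__(self, core_tfs=None, n_permutations: int = 50, rng_seed: int = 0,
                 p_method: str = "ttest"):
        self.core_tfs = core_tfs
        self.n_permutations = n_permutations
        self.rng_seed = rng_seed
        self.p_method = p_method

    def fit(self, X: ExpressionMatrix, y):
        partition = _partition_from(X, y)
        tfs = self.core_tfs if self.core_tfs is not None else X.gene_ids
        self.edges_ = {
            label: mi_network(X, partition, label, tfs, self.n_permutations,
                              self.rng_seed, self.p_method)
            for label in partition.eligible_labels
        }
        return self


class GRNHubExtractor(BaseEstimator):
    """Correlation/MI GRN hub extraction per subpopulation, with unique-hub sets."""

    def __init__(self, tf_list=None, method: str = "pcc", top_n: int = 10):
        self.tf_list = tf_list
        self.method = method
        self.top_n = top_n

    def fit(self, X: ExpressionMatrix, y):
        partition = _partition_from(X, y)
        tf_list = self.tf_list if self.tf_list is not None else X.gene_ids
        self.hubs_ = {
            label: grn_hubs(X, partition, label, tf_list, self.method, self.top_n)
            for label in partition.eligible_labels
        }
        self.unique_hubs_ = {
            label: unique_hubs(self.hubs_, label) for label in self.hubs_
        }
        return self


def _partition_from(matrix: ExpressionMatrix, y) -> SubpopulationPartition:
    y = list(map(str, y))
    if len(y) != matrix.n_cells:
        raise DataValidationError("labels and matrix rows differ in length")
    return SubpopulationPartition(dict(zip(matrix.cell_ids, y)))
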