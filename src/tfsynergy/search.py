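"""Seed-and-extend search for the most synergistic transcriptional core.

Exhaustive MMI over all TF subsets is combinatorially hopeless (the 3–6-TF
combinations from 100 TFs alone number over 1.27 billion), so the search is
greedy: score every 3-TF combination, shortlist the 1% most synergistic
(lowest MMI), seed with the 1% highest-TC of those, then repeatedly extend each
seed by one TF, keeping extensions whose MMI drops by more than
``extension_delta`` and carrying the ten highest-TC survivors to the next
level. The search stops when no extension improves synergy or cores reach 15
TFs; the 20 best-TC combinations seen anywhere are then re-ranked by MMI
(ties: TC, then summed mean expression) and the top three reported.

Discretization is always fit on the subpopulation's own cells; MMI is
evaluated, per configuration, either on the complement of the subpopulation
(all other cells of the dataset, the default) or on the subpopulation itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from ._exceptions import DataValidationError, InsufficientTFsError, TFSynergyError
from .config import RunConfig
from .infotheory import BinningScheme, discretize_matrix, log_transform
from .io import ExpressionMatrix, SubpopulationPartition
from .preprocessing import TFCandidateSet, select_candidate_tfs


def search_space_size(n_tfs: int, sizes=(3, 4, 5, 6)) -> int:
    """Number of TF combinations of the given sizes from ``n_tfs`` candidates."""
    return sum(math.comb(n_tfs, k) for k in sizes)


@dataclass(frozen=True)
class SynergyScore:
    """A scored TF combination: ids (sorted), MMI, TC, and the internal bitmask."""

    tfs: tuple[str, ...]
    mmi: float
    tc: float
    mask: int


@dataclass
class SynergyCore:
    """A reported core: the method's output unit."""

    subpopulation: str
    tfs: tuple[str, ...]
    mmi: float
    tc: float
    summed_mean_expression: float
    rank: int


@dataclass
class SearchTrace:
    """Per-level audit trail of one subpopulation's search."""

    levels: list[dict] = field(default_factory=list)
    termination_reason: str = ""

    def record(self, level: int, n_seeds: int, n_scored: int, n_accepted: int,
               best_mmi: float, best_tc: float) -> None:
        self.levels.append(
            {"level": level, "n_seeds": n_seeds, "n_scored": n_scored,
             "n_accepted": n_accepted, "best_mmi": best_mmi, "best_tc": best_tc}
        )


class SynergyScorer:
    """Mask-indexed MMI/TC evaluator for one subpopulation's candidate TFs.

    Holds the discretized evaluation cells and a cache of normalized subset
    entropies, so repeated scoring of overlapping combinations during the
    greedy search reuses every subset already seen.
    """

    def __init__(
        self,
        matrix: ExpressionMatrix,
        partition: SubpopulationPartition,
        subpop: str,
        candidates: TFCandidateSet,
        config: RunConfig | None = None,
    ):
        config = config or RunConfig()
        self.subpopulation = subpop
        self.tfs = list(candidates.tfs)
        self.mean_expression = dict(candidates.mean_expression)

        sub_cells = partition.cells(subpop)
        sub_log = log_transform(matrix.submatrix(sub_cells, self.tfs))
        scheme = BinningScheme.fit(
            {tf: sub_log[:, j] for j, tf in enumerate(self.tfs)},
            matrix.unit_regime,
            subpopulation=subpop,
        )
        self.scheme = scheme

        eval_cells = sub_cells
        self.population = "within"
        if config.mmi_population == "complement":
            comp = partition.complement_cells(subpop)
            if comp:  # single-subpopulation data has no complement to score on
                eval_cells = comp
                self.population = "complement"
        profiles = discretize_matrix(matrix.submatrix(eval_cells, self.tfs), self.tfs, scheme)
        self.n_cells = profiles[0].n_cells
        self._symbols = np.column_stack([p.symbols for p in profiles])
        self._bins = np.array([p.bin_count for p in profiles], dtype=np.int64)
        self._logb = np.log(self._bins.astype(np.float64))
        self._hn: dict[int, float] = {0: 0.0}

    @property
    def n_tfs(self) -> int:
        return len(self.tfs)

    def mask_of(self, tfs) -> int:
        index = {tf: i for i, tf in enumerate(self.tfs)}
        mask = 0
        for tf in tfs:
            mask |= 1 << index[tf]
        return mask

    def tfs_of(self, mask: int) -> tuple[str, ...]:
        return tuple(sorted(self.tfs[i] for i in range(self.n_tfs) if mask >> i & 1))

    def _entropy_norm(self, mask: int) -> float:
        """Normalized joint entropy of the TFs in ``mask`` (cached)."""
        cached = self._hn.get(mask)
        if cached is not None:
            return cached
        idx = [i for i in range(self.n_tfs) if mask >> i & 1]
        hmax = float(self._logb[idx].sum())
        if hmax == 0.0:
            h = 0.0
        else:
            code = np.zeros(self.n_cells, dtype=np.int64)
            for i in idx:
                code = code * self._bins[i] + self._symbols[:, i]
            counts = np.bincount(code)
            counts = counts[counts > 0]
            p = counts / counts.sum()
            h = float(-(p * np.log(p)).sum()) / hmax
        self._hn[mask] = h
        return h

    def mmi(self, mask: int) -> float:
        """Inclusion–exclusion MMI over all non-empty submasks (normalized entropies)."""
        total = 0.0
        sub = mask
        while sub:
            h = self._entropy_norm(sub)
            total += h if sub.bit_count() % 2 else -h
            sub = (sub - 1) & mask
        return total

    def tc(self, mask: int) -> float:
        total = 0.0
        i, rest = 0, mask
        while rest:
            if rest & 1:
                total += self._entropy_norm(1 << i)
            rest >>= 1
            i += 1
        return total - self._entropy_norm(mask)

    def score(self, mask: int) -> SynergyScore:
        return SynergyScore(tfs=self.tfs_of(mask), mmi=self.mmi(mask), tc=self.tc(mask), mask=mask)

    def summed_mean_expression(self, mask: int) -> float:
        return float(sum(self.mean_expression[tf] for tf in self.tfs_of(mask)))

    def all_subset_mmi(self, max_size: int | None = None) -> dict[int, float]:
        """Exhaustive MMI for every subset of size ≥ 2 (subset-sum transform).

        Intended as the brute-force oracle on small candidate sets; refuses
        more than 16 TFs.
        """
        n = self.n_tfs
        if n > 16:
            raise DataValidationError("exhaustive enumeration limited to 16 TFs")
        f = np.zeros(1 << n)
        for mask in range(1, 1 << n):
            h = self._entropy_norm(mask)
            f[mask] = h if mask.bit_count() % 2 else -h
        for i in range(n):
            bit = 1 << i
            idx = np.arange(1 << n)
            has = (idx & bit) > 0
            f[idx[has]] += f[idx[has] ^ bit]
        max_size = max_size or n
        return {
            mask: float(f[mask])
            for mask in range(1, 1 << n)
            if 2 <= mask.bit_count() <= max_size
        }


# ---------------------------------------------------------------------------
# search stages


def enumerate_seed_triples(scorer: SynergyScorer, config: RunConfig | None = None):
    """Score all 3-TF combinations and pick the initial seeds.

    Shortlist = the ``seed_fraction`` (default 1%) lowest-MMI triples
    (ceiling, minimum one); seeds = the ``seed_fraction`` highest-TC of the
    shortlist (ceiling, minimum one). Ties break lexicographically on TF ids.
    Returns ``(seeds, shortlist, n_scored)`` — the whole shortlist stays in
    play for the final re-ranking pool.
    """
    config = config or RunConfig()
    n = scorer.n_tfs
    if n < 3:
        raise InsufficientTFsError("need at least 3 candidate TFs")
    # fast path: MMI3 = sum(Hi) - sum(Hij) + Hijk on cached normalized entropies
    singles = [scorer._entropy_norm(1 << i) for i in range(n)]
    scored = []
    for i, j, k in combinations(range(n), 3):
        hij = scorer._entropy_norm((1 << i) | (1 << j))
        hik = scorer._entropy_norm((1 << i) | (1 << k))
        hjk = scorer._entropy_norm((1 << j) | (1 << k))
        mask = (1 << i) | (1 << j) | (1 << k)
        hijk = scorer._entropy_norm(mask)
        s = singles[i] + singles[j] + singles[k]
        scored.append(SynergyScore(
            tfs=scorer.tfs_of(mask),
            mmi=s - hij - hik - hjk + hijk,
            tc=s - hijk,
            mask=mask,
        ))
    scored.sort(key=lambda s: (s.mmi, s.tfs))
    n_short = max(1, math.ceil(config.seed_fraction * len(scored)))
    shortlist = scored[:n_short]
    by_tc = sorted(shortlist, key=lambda s: (-s.tc, s.tfs))
    n_seeds = max(1, math.ceil(config.seed_fraction * len(shortlist)))
    return by_tc[:n_seeds], shortlist, len(scored)


def extend_level(seeds, scorer: SynergyScorer, config: RunConfig | None = None):
    """Extend each seed by one TF; keep combinations whose MMI drops by more
    than ``extension_delta`` below their seed's.

    Identical combinations reached from different seeds are scored once (and
    accepted if any of their seeds accepts them). Returns all survivors ranked
    by TC descending (callers carry the top ``seeds_per_level`` forward as
    seeds) plus the number of distinct combinations scored.
    """
    config = config or RunConfig()
    scored: dict[int, SynergyScore] = {}
    accepted: dict[int, SynergyScore] = {}
    for seed in seeds:
        for i in range(scorer.n_tfs):
            bit = 1 << i
            if seed.mask & bit:
                continue
            new_mask = seed.mask | bit
            sc = scored.get(new_mask)
            if sc is None:
                sc = scorer.score(new_mask)
                scored[new_mask] = sc
            if sc.mmi - seed.mmi < -config.extension_delta:
                accepted[new_mask] = sc
    survivors = sorted(accepted.values(), key=lambda s: (-s.tc, s.tfs))
    return survivors, len(scored)


def finalize(pool, scorer: SynergyScorer, config: RunConfig | None = None):
    """Re-rank the best-TC pool by MMI and emit the reported cores.

    The ``final_pool_size`` highest-TC combinations accumulated over all
    levels are re-scored; cores are ordered by MMI ascending, ties broken by
    TC descending, then by summed within-subpopulation mean expression
    descending, then lexicographically. The incumbent — the lowest-MMI
    combination the search encountered, its candidate core at termination —
    always stays in the re-scored pool, whatever its TC rank.
    """
    config = config or RunConfig()
    unique = {s.mask: s for s in pool}
    if not unique:
        raise TFSynergyError("search produced no cores")
    by_tc = sorted(unique.values(), key=lambda s: (-s.tc, s.tfs))
    finalists = by_tc[: config.final_pool_size]
    incumbent = min(unique.values(), key=lambda s: (s.mmi, s.tfs))
    if incumbent.mask not in {s.mask for s in finalists}:
        finalists.append(incumbent)
    rescored = [scorer.score(s.mask) for s in finalists]
    rescored.sort(
        key=lambda s: (s.mmi, -s.tc, -scorer.summed_mean_expression(s.mask), s.tfs)
    )
    cores = []
    for rank, s in enumerate(rescored[: config.reported_cores], start=1):
        cores.append(
            SynergyCore(
                subpopulation=scorer.subpopulation,
                tfs=s.tfs,
                mmi=s.mmi,
                tc=s.tc,
                summed_mean_expression=scorer.summed_mean_expression(s.mask),
                rank=rank,
            )
        )
    return cores


def search_subpopulation(scorer: SynergyScorer, config: RunConfig | None = None):
    """Full seed → extend → finalize search for one subpopulation."""
    config = config or RunConfig()
    trace = SearchTrace()
    seeds, shortlist, n_scored = enumerate_seed_triples(scorer, config)
    # the MMI shortlist was "taken" at level 3: it stays eligible for the
    # final top-TC pool even when TC-based seed selection passes it over
    pool = list(shortlist)
    trace.record(3, len(seeds), n_scored, len(shortlist),
                 min(s.mmi for s in shortlist), max(s.tc for s in shortlist))
    while seeds:
        size = seeds[0].mask.bit_count()
        if size >= config.max_core_size:
            trace.termination_reason = "size_cap"
            break
        survivors, n_scored = extend_level(seeds, scorer, config)
        if not survivors:
            trace.termination_reason = "no_improvement"
            break
        trace.record(size + 1, len(seeds), n_scored, len(survivors),
                     min(s.mmi for s in survivors), max(s.tc for s in survivors))
        pool.extend(survivors)
        seeds = survivors[: config.seeds_per_level]
    cores = finalize(pool, scorer, config)
    return cores, trace


@dataclass
class CoreSearchResults:
    """Per-subpopulation cores, traces, candidate sets, and skip reasons."""

    cores: dict[str, list[SynergyCore]] = field(default_factory=dict)
    traces: dict[str, SearchTrace] = field(default_factory=dict)
    candidates: dict[str, TFCandidateSet] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    def rank1(self, subpop: str) -> SynergyCore:
        return self.cores[subpop][0]


def find_cores(
    matrix: ExpressionMatrix,
    partition: SubpopulationPartition,
    tf_list,
    config: RunConfig | None = None,
    binary_status: ExpressionMatrix | None = None,
) -> CoreSearchResults:
    """Run the full pipeline for every eligible subpopulation.

    Subpopulations that fail the TF filters are recorded in ``skipped`` rather
    than aborting the run. Deterministic given inputs and config.
    """
    config = config or RunConfig()
    results = CoreSearchResults()
    for label in partition.eligible_labels:
        try:
            candidates = select_candidate_tfs(
                matrix, partition, label, tf_list, config, binary_status=binary_status
            )
        except InsufficientTFsError as exc:
            results.skipped[label] = str(exc)
            continue
        scorer = SynergyScorer(matrix, partition, label, candidates, config)
        cores, trace = search_subpopulation(scorer, config)
        results.cores[label] = cores
        results.traces[label] = trace
        results.candidates[label] = candidates
    return results


class SynergyCoreFinder(BaseEstimator):
    """Estimator interface to the core search.

    Parameters mirror :class:`~tfsynergy.config.RunConfig`; ``fit`` takes a
    cells × genes matrix (``ExpressionMatrix``, DataFrame with gene columns,
    or ndarray plus ``gene_ids``) and per-cell subpopulation labels ``y``.

    Attributes (after fit)
    ----------------------
    cores_ : dict mapping subpopulation label to its ranked ``SynergyCore`` list
    traces_ : dict of per-subpopulation ``SearchTrace``
    candidate_sets_ : dict of per-subpopulation ``TFCandidateSet``
    skipped_ : dict of subpopulations skipped, with reasons
    """

    def __init__(
        self,
        tf_list=None,
        unit_regime: str = "fpkm_like",
        gene_ids=None,
        expression_threshold: float | None = None,
        top_frequency_fraction: float = 0.10,
        min_expressing_fraction: float = 0.30,
        max_tf_count: int = 150,
        seed_fraction: float = 0.01,
        extension_delta: float = 0.05,
        seeds_per_level: int = 10,
        final_pool_size: int = 20,
        max_core_size: int = 15,
        reported_cores: int = 3,
        mmi_population: str = "complement",
    ):
        self.tf_list = tf_list
        self.unit_regime = unit_regime
        self.gene_ids = gene_ids
        self.expression_threshold = expression_threshold
        self.top_frequency_fraction = top_frequency_fraction
        self.min_expressing_fraction = min_expressing_fraction
        self.max_tf_count = max_tf_count
        self.seed_fraction = seed_fraction
        self.extension_delta = extension_delta
        self.seeds_per_level = seeds_per_level
        self.final_pool_size = final_pool_size
        self.max_core_size = max_core_size
        self.reported_cores = reported_cores
        self.mmi_population = mmi_population

    def _config(self) -> RunConfig:
        return RunConfig(
            expression_threshold=self.expression_threshold,
            top_frequency_fraction=self.top_frequency_fraction,
            min_expressing_fraction=self.min_expressing_fraction,
            max_tf_count=self.max_tf_count,
            seed_fraction=self.seed_fraction,
            extension_delta=self.extension_delta,
            seeds_per_level=self.seeds_per_level,
            final_pool_size=self.final_pool_size,
            max_core_size=self.max_core_size,
            reported_cores=self.reported_cores,
            mmi_population=self.mmi_population,
        )

    def _as_matrix(self, X) -> ExpressionMatrix:
        if isinstance(X, ExpressionMatrix):
            return X
        import pandas as pd

        if isinstance(X, pd.DataFrame):
            return ExpressionMatrix(
                values=X.to_numpy(dtype=np.float64),
                cell_ids=list(map(str, X.index)),
                gene_ids=list(map(str, X.columns)),
                unit_regime=self.unit_regime,
            )
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise DataValidationError("X must be 2-D (cells × genes)")
        gene_ids = self.gene_ids or [f"G{j}" for j in range(X.shape[1])]
        return ExpressionMatrix(
            values=X,
            cell_ids=[f"C{i}" for i in range(X.shape[0])],
            gene_ids=list(gene_ids),
            unit_regime=self.unit_regime,
        )

    def fit(self, X, y):
        matrix = self._as_matrix(X)
        y = list(map(str, y))
        if len(y) != matrix.n_cells:
            raise DataValidationError("labels and matrix rows differ in length")
        partition = SubpopulationPartition(dict(zip(matrix.cell_ids, y)))
        tf_list = self.tf_list if self.tf_list is not None else matrix.gene_ids
        results = find_cores(matrix, partition, tf_list, self._config())
        self.cores_ = results.cores
        self.traces_ = results.traces
        self.candidate_sets_ = results.candidates
        self.skipped_ = results.skipped
        self.results_ = results
        self.n_features_in_ = matrix.n_genes
        return self
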