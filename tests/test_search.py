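import itertools
import math

import numpy as np
import pytest

from tfsynergy import (
    PlantedMotif,
    RunConfig,
    SyntheticSpec,
    SynergyScore,
    TFSynergyError,
    generate,
    find_cores,
    search_space_size,
)
from tfsynergy.preprocessing import select_candidate_tfs
from tfsynergy.search import (
    SynergyScorer,
    enumerate_seed_triples,
    extend_level,
    finalize,
    search_subpopulation,
)
from tfsynergy.io import ExpressionMatrix


@pytest.mark.parametrize(
    "n,sizes,expected",
    [
        (100, (3, 4, 5, 6), 1271422845),
        (100, (3,), 161700),
        (3, (3,), 1),
    ],
)
def test_search_space_size(n, sizes, expected):
    assert search_space_size(n, sizes) == expected
    assert expected == sum(math.comb(n, k) for k in sizes)


def _scorer(seed=0, n_background=27, gate="xor3", flip=0.0, config=None):
    spec = SyntheticSpec(
        n_background_tfs=n_background,
        planted_motifs=[PlantedMotif(subpopulation="S1", gate=gate, flip_rate=flip)],
        rng_seed=seed,
    )
    matrix, partition, tfs, truth = generate(spec)
    config = config or RunConfig(top_frequency_fraction=1.0, mmi_population="within")
    cand = select_candidate_tfs(matrix, partition, "S1", tfs, config)
    return SynergyScorer(matrix, partition, "S1", cand, config), truth, config


class TestSeedTriples:
    def test_counts_and_minimum_one_seed(self):
        scorer, truth, config = _scorer()
        seeds, shortlist, n_scored = enumerate_seed_triples(scorer, config)
        assert n_scored == math.comb(30, 3)
        assert len(shortlist) == math.ceil(0.01 * n_scored)
        assert len(seeds) == max(1, math.ceil(0.01 * len(shortlist)))

    def test_planted_xor_is_unique_minimum_by_enumeration(self):
        scorer, truth, config = _scorer(flip=0.0)
        planted = tuple(sorted(truth["planted"]["S1"][0]))
        scores = {}
        for combo in itertools.combinations(range(scorer.n_tfs), 3):
            mask = sum(1 << i for i in combo)
            scores[scorer.tfs_of(mask)] = scorer.mmi(mask)
        ranked = sorted(scores, key=scores.get)
        assert ranked[0] == planted
        # strictly below every competitor
        assert scores[planted] < scores[ranked[1]] - 1e-6

    def test_three_candidates_single_triple_is_seed(self):
        scorer, truth, config = _scorer(n_background=0)
        seeds, shortlist, n_scored = enumerate_seed_triples(scorer, config)
        assert n_scored == 1
        assert len(seeds) == 1
        assert seeds[0].tfs == tuple(sorted(truth["planted"]["S1"][0]))


class TestExtendLevel:
    def test_duplicate_extensions_scored_once(self):
        scorer, _, config = _scorer(n_background=2)  # 5 TFs
        s1 = scorer.score(0b00111)
        s2 = scorer.score(0b01011)
        survivors, n_scored = extend_level(
            [s1, s2], scorer, RunConfig(extension_delta=-10.0,
                                        top_frequency_fraction=1.0,
                                        mmi_population="within")
        )
        # each seed has 2 possible extensions; {0b01111} is reachable from both
        assert n_scored == 3
        masks = {s.mask for s in survivors}
        assert 0b01111 in masks  # delta = -10 accepts everything, deduplicated
        assert len(masks) == 3

    def test_even_parity_extension_is_rejected(self):
        # interaction information alternates sign with order: a clean
        # parity-of-3-inputs quadruple scores *higher* MMI than its mutually
        # independent triples, so the extension must not be accepted
        scorer, truth, config = _scorer(gate="parity4", n_background=4, flip=0.0)
        planted = truth["planted"]["S1"][0]
        seed = scorer.score(scorer.mask_of(planted[:3]))
        full = scorer.score(scorer.mask_of(planted))
        assert full.mmi > seed.mmi  # anti-synergistic, not lower
        survivors, _ = extend_level([seed], scorer, config)
        assert full.mask not in {s.mask for s in survivors}

    def test_acceptance_rule_dedup_and_tc_ranking(self):
        # stub-driven mechanics: accept iff MMI(new) - MMI(seed) < -delta,
        # de-duplicate across seeds, rank survivors by TC, truncate to top 10
        masks3 = [0b00111, 0b01011]
        seeds = [SynergyScore(("a", "b", "c"), 0.50, 0.2, masks3[0]),
                 SynergyScore(("a", "b", "d"), 0.60, 0.2, masks3[1])]
        mmi4 = {0b01111: 0.44, 0b10111: 0.46, 0b11011: 0.30}
        tc4 = {0b01111: 0.9, 0b10111: 0.5, 0b11011: 0.7}
        scores = [SynergyScore(tuple("wxyz"), mmi4[m], tc4[m], m) for m in mmi4]
        stub = _StubScorer(seeds + scores, {})
        stub.n_tfs = 5
        survivors, n_scored = extend_level(seeds, stub, RunConfig())
        assert n_scored == 3  # 0b01111 reachable from both seeds, scored once
        # 0b01111: Δ=-0.06 vs seed1 → accepted; 0b10111: Δ=-0.04 → rejected;
        # 0b11011: Δ=-0.30 vs seed2 → accepted; ranked by TC descending
        assert [s.mask for s in survivors] == [0b01111, 0b11011]

    def test_no_improvement_gives_empty_list(self):
        # background-only data: no extension drops MMI by > delta
        spec = SyntheticSpec(n_background_tfs=10, planted_motifs=[], rng_seed=5)
        matrix, partition, tfs, _ = generate(spec)
        config = RunConfig(top_frequency_fraction=1.0, mmi_population="within")
        cand = select_candidate_tfs(matrix, partition, "S1", tfs, config)
        scorer = SynergyScorer(matrix, partition, "S1", cand, config)
        seeds, _, _ = enumerate_seed_triples(scorer, config)
        survivors, _ = extend_level(seeds, scorer, config)
        assert survivors == []


class _StubScorer:
    """Fixed-score scorer for exercising finalize()'s tie-breaking rules."""

    subpopulation = "stub"

    def __init__(self, scores, means):
        self._scores = {s.mask: s for s in scores}
        self._means = means

    def score(self, mask):
        return self._scores[mask]

    def summed_mean_expression(self, mask):
        return self._means[mask]


class TestFinalize:
    def test_empty_pool_is_an_error(self):
        with pytest.raises(TFSynergyError, match="no cores"):
            finalize([], _StubScorer([], {}), RunConfig())

    def test_pool_of_one(self):
        s = SynergyScore(tfs=("A", "B", "C"), mmi=-0.2, tc=0.5, mask=0b111)
        cores = finalize([s], _StubScorer([s], {0b111: 1.0}), RunConfig())
        assert len(cores) == 1 and cores[0].rank == 1 and cores[0].tfs == ("A", "B", "C")

    def test_mmi_tie_broken_by_tc_then_expression(self):
        a = SynergyScore(tfs=("A", "B", "C"), mmi=0.1, tc=0.9, mask=0b0111)
        b = SynergyScore(tfs=("A", "B", "D"), mmi=0.1 + 1e-12, tc=0.5, mask=0b1011)
        c = SynergyScore(tfs=("A", "C", "D"), mmi=0.1 + 1e-12, tc=0.5, mask=0b1101)
        means = {0b0111: 1.0, 0b1011: 3.0, 0b1101: 5.0}
        cores = finalize([b, c, a], _StubScorer([a, b, c], means), RunConfig())
        # near-exact MMI tie: a wins on TC; b vs c tie on TC → c wins on expression
        assert [k.tfs for k in cores] == [a.tfs, c.tfs, b.tfs]


class TestFindCores:
    def test_planted_xor_is_rank1_core(self):
        spec = SyntheticSpec(rng_seed=2)
        matrix, partition, tfs, truth = generate(spec)
        config = RunConfig(top_frequency_fraction=1.0, mmi_population="within")
        results = find_cores(matrix, partition, tfs, config)
        assert results.rank1("S1").tfs == tuple(sorted(truth["planted"]["S1"][0]))
        assert results.traces["S1"].termination_reason in ("no_improvement", "size_cap")

    def test_all_independent_terminates_at_size_3(self):
        spec = SyntheticSpec(n_background_tfs=15, planted_motifs=[], rng_seed=9)
        matrix, partition, tfs, _ = generate(spec)
        config = RunConfig(top_frequency_fraction=1.0, mmi_population="within")
        results = find_cores(matrix, partition, tfs, config)
        assert results.traces["S1"].termination_reason == "no_improvement"
        for core in results.cores["S1"]:
            assert len(core.tfs) == 3
            assert abs(core.mmi) < 2.0  # normalized scale; no synergy claimed

    def test_core_never_exceeds_max_size(self):
        scorer, truth, _ = _scorer(gate="parity5", n_background=3, flip=0.0)
        config = RunConfig(top_frequency_fraction=1.0, mmi_population="within",
                           max_core_size=4, extension_delta=0.0)
        cores, trace = search_subpopulation(scorer, config)
        assert all(len(c.tfs) <= 4 for c in cores)

    def test_results_invariant_to_candidate_order(self):
        spec = SyntheticSpec(n_background_tfs=12, rng_seed=4)
        matrix, partition, tfs, _ = generate(spec)
        config = RunConfig(top_frequency_fraction=1.0, mmi_population="within")
        base = find_cores(matrix, partition, tfs, config)

        rng = np.random.default_rng(0)
        perm = rng.permutation(matrix.n_genes)
        shuffled = ExpressionMatrix(
            values=matrix.values[:, perm],
            cell_ids=matrix.cell_ids,
            gene_ids=[matrix.gene_ids[j] for j in perm],
            unit_regime=matrix.unit_regime,
        )
        out = find_cores(shuffled, partition, list(reversed(tfs)), config)
        assert out.rank1("S1").tfs == base.rank1("S1").tfs
        assert out.rank1("S1").mmi == pytest.approx(base.rank1("S1").mmi, abs=1e-12)

    def test_trace_best_mmi_non_increasing(self):
        scorer, truth, _ = _scorer(gate="parity4", n_background=2, flip=0.0)
        config = RunConfig(top_frequency_fraction=1.0, mmi_population="within")
        cores, trace = search_subpopulation(scorer, config)
        best = [lvl["best_mmi"] for lvl in trace.levels]
        assert all(b <= a + 1e-12 for a, b in zip(best, best[1:]))

    def test_insufficient_tfs_skipped_not_fatal(self):
        spec = SyntheticSpec(n_cells=50, n_subpopulations=2, n_background_tfs=12, rng_seed=8)
        matrix, partition, tfs, _ = generate(spec)
        # S2 has no motif; demand an impossible expressing fraction there by
        # restricting the TF list to the 3 planted TFs (absent from S2's gate)
        config = RunConfig(top_frequency_fraction=1.0, min_expressing_fraction=0.999,
                           mmi_population="within")
        results = find_cores(matrix, partition, tfs, config)
        assert set(results.skipped) | set(results.cores) == {"S1", "S2"}
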