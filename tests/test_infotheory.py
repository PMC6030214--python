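import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from tfsynergy import (
    DataValidationError,
    DiscreteProfile,
    discretize,
    fd_bin_count,
    group_mi,
    log_transform,
    mmi,
    normalized_entropy,
    pairwise_mi,
    tc,
)
from tfsynergy.infotheory import nats_to_bits

import oracles

LN2 = math.log(2.0)


class TestLogTransform:
    @pytest.mark.parametrize("value,expected", [(0.0, 0.0), (1.0, 0.0), (100.0, 2.0)])
    def test_closed_form(self, value, expected):
        assert log_transform([value])[0] == pytest.approx(expected)

    def test_rejects_negative(self):
        with pytest.raises(DataValidationError):
            log_transform([-1.0])


class TestFDBinCount:
    def test_constant_vector_single_bin(self):
        assert fd_bin_count(np.full(50, 3.3), "fpkm_like") == 1
        assert fd_bin_count(np.zeros(50), "umi") == 1

    def test_reference_value_0_to_99(self):
        # cross-checked against R nclass.FD on a length-101 vector:
        # h = 2*49.5/101^(1/3), ceil(99/h) = 5
        assert fd_bin_count(np.arange(100.0), "fpkm_like") == 5

    def test_umi_offset_narrows_bins(self):
        values = np.arange(100.0)
        # m = 106 gives a strictly smaller bin width than m = 101
        h = lambda m: 2.0 * 49.5 / m ** (1 / 3)
        assert h(106) < h(101)
        assert fd_bin_count(values, "umi") >= fd_bin_count(values, "fpkm_like")
        assert fd_bin_count(values, "umi") == math.ceil(99.0 / h(106))


class TestDiscretize:
    def test_single_bin_all_zero_entropy(self):
        prof = discretize(np.array([0.1, 0.5, 0.9]), "t", 1, 1.0)
        assert prof.symbols.tolist() == [0, 0, 0]
        assert normalized_entropy(prof) == 0.0

    def test_two_bins_unit_range(self):
        prof = discretize(np.array([0.0, 0.0, 1.0, 1.0]), "t", 2, 1.0)
        assert prof.symbols.tolist() == [0, 0, 1, 1]

    def test_interior_edge_goes_up_and_overflow_clamps(self):
        # edges [0, 0.5, 1]: 0.5 belongs to the upper bin; 1.5 (out of the
        # fitted range) clamps into the last bin; counts are conserved
        prof = discretize(np.array([0.49, 0.5, 1.5]), "t", 2, 1.0)
        assert prof.symbols.tolist() == [0, 1, 1]
        assert prof.symbols.size == 3


class TestNormalizedEntropy:
    def test_uniform_is_one(self):
        prof = DiscreteProfile("t", np.tile(np.arange(4), 25), 4)
        assert normalized_entropy(prof) == pytest.approx(1.0)

    def test_constant_is_zero(self):
        prof = DiscreteProfile("t", np.zeros(40, dtype=int), 3)
        assert normalized_entropy(prof) == 0.0

    def test_joint_of_independent_uniforms_is_one(self):
        # 4 equiprobable (x, y) pairs: H = log 4 = the theoretical maximum
        x = DiscreteProfile("x", np.array([0, 0, 1, 1]), 2)
        y = DiscreteProfile("y", np.array([0, 1, 0, 1]), 2)
        assert normalized_entropy(x, y) == pytest.approx(1.0)


class TestMMIandTC:
    def test_independent_triple_unnormalized_zero(self):
        # jointly independent fair binary variables, exact product table
        grids = np.indices((2, 2, 2)).reshape(3, -1)
        profs = [DiscreteProfile(f"v{i}", grids[i], 2) for i in range(3)]
        assert mmi(profs, normalized=False) == pytest.approx(0.0, abs=1e-12)
        assert tc(profs, normalized=False) == pytest.approx(0.0, abs=1e-12)

    def test_xor_triple(self, xor_profiles):
        assert nats_to_bits(mmi(xor_profiles, normalized=False)) == pytest.approx(-1.0)
        assert nats_to_bits(tc(xor_profiles, normalized=False)) == pytest.approx(1.0)

    def test_identical_triple_is_redundant(self):
        x = np.array([0, 1] * 10)
        profs = [DiscreteProfile(n, x, 2) for n in "abc"]
        h = LN2  # H(X) for a fair bit, in nats
        assert mmi(profs, normalized=False) == pytest.approx(h)
        # TC of three identical variables: 3H - H = 2H
        assert tc(profs, normalized=False) == pytest.approx(2 * h)

    def test_pairwise_mi_printed_counts(self):
        # joint counts {(0,0): 4, (1,1): 4} → 1 bit
        x = DiscreteProfile("x", np.array([0] * 4 + [1] * 4), 2)
        y = DiscreteProfile("y", np.array([0] * 4 + [1] * 4), 2)
        assert nats_to_bits(pairwise_mi(x, y)) == pytest.approx(1.0)

    def test_mismatched_cells_rejected(self):
        a = DiscreteProfile("a", np.zeros(4, dtype=int), 2)
        b = DiscreteProfile("b", np.zeros(5, dtype=int), 2)
        with pytest.raises(DataValidationError):
            mmi([a, b])


def _random_profiles(rng, k, n=48, max_bins=3):
    profs = []
    for i in range(k):
        b = int(rng.integers(2, max_bins + 1))
        profs.append(DiscreteProfile(f"v{i}", rng.integers(0, b, size=n), b))
    return profs


class TestProperties:
    @pytest.mark.parametrize("k", [3, 4])
    def test_permutation_symmetry(self, k):
        rng = np.random.default_rng(11)
        for _ in range(25):
            profs = _random_profiles(rng, k)
            base_mmi, base_tc = mmi(profs), tc(profs)
            for _ in range(3):
                perm = [profs[i] for i in rng.permutation(k)]
                assert mmi(perm) == pytest.approx(base_mmi, abs=1e-12)
                assert tc(perm) == pytest.approx(base_tc, abs=1e-12)

    def test_mmi_of_two_equals_pairwise_mi(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            x, y = _random_profiles(rng, 2)
            assert mmi([x, y]) == pytest.approx(pairwise_mi(x, y, normalized=True))
            assert mmi([x, y], normalized=False) == pytest.approx(pairwise_mi(x, y))

    def test_tc_nonnegative_and_zero_iff_product(self):
        rng = np.random.default_rng(13)
        for _ in range(40):
            profs = _random_profiles(rng, int(rng.integers(2, 5)))
            assert tc(profs) >= -1e-12
            assert tc(profs, normalized=False) >= -1e-12
        # exact product distribution → 0; any dependence → > 0
        grids = np.indices((2, 2)).reshape(2, -1)
        indep = [DiscreteProfile("a", grids[0], 2), DiscreteProfile("b", grids[1], 2)]
        assert tc(indep, normalized=False) == pytest.approx(0.0, abs=1e-14)
        dep = [
            DiscreteProfile("a", np.array([0, 0, 1, 1]), 2),
            DiscreteProfile("b", np.array([0, 0, 1, 1]), 2),
        ]
        assert tc(dep, normalized=False) > 0.1

    def test_invariant_under_bin_relabeling(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            profs = _random_profiles(rng, 3)
            relabeled = []
            for p in profs:
                perm = rng.permutation(p.bin_count)
                relabeled.append(DiscreteProfile(p.tf, perm[p.symbols], p.bin_count))
            assert mmi(relabeled) == pytest.approx(mmi(profs), abs=1e-12)
            assert tc(relabeled) == pytest.approx(tc(profs), abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        symbols=hnp.arrays(np.int64, (4, 30), elements=st.integers(0, 2)),
    )
    def test_oracle_equivalence_random_tables(self, symbols):
        """Inclusion–exclusion via the package equals an independent
        Counter-based probability-table oracle on random 4-variable tables."""
        profs = [DiscreteProfile(f"v{i}", symbols[i], 3) for i in range(4)]
        cols = [symbols[i].tolist() for i in range(4)]
        assert mmi(profs, normalized=False) == pytest.approx(
            oracles.mmi_oracle(cols), abs=1e-10
        )
        assert mmi(profs) == pytest.approx(
            oracles.mmi_oracle(cols, bin_counts=[3] * 4, normalized=True), abs=1e-10
        )
        assert tc(profs, normalized=False) == pytest.approx(
            oracles.tc_oracle(cols), abs=1e-10
        )


def test_group_mi_decomposition(xor_profiles):
    """MMI(X;Y;Z) = I(X;Z) + I(Y;Z) - I(X,Y;Z) on the XOR table."""
    x, y, z = xor_profiles
    lhs = mmi([x, y, z], normalized=False)
    rhs = pairwise_mi(x, z) + pairwise_mi(y, z) - group_mi([x, y], [z])
    assert lhs == pytest.approx(rhs, abs=1e-12)
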