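r"""Discretization and entropy-based dependence measures.

Expression values are log10-transformed (zeros mapped to 1 first, so they land
at 0), binned per TF within a subpopulation with a Freedman–Diaconis rule over
the range [0, subpopulation maximum], and all entropies are plug-in Shannon
entropies on the resulting symbols.

Because each TF ends up with a different bin count, every entropy — marginal
and joint — is normalized by its theoretical maximum, ``log`` of the product of
bin counts, before entering the inclusion–exclusion sums:

    MMI(S) = -sum_{T ⊆ S, T ≠ ∅} (-1)^{|T|} H(T)
    TC(S)  = sum_i H(X_i) - H(S)

For two variables MMI reduces to the mutual information
``I(X;Y) = H(X) + H(Y) - H(X,Y)``; negative MMI on three or more variables
signals synergy (the joint carries more information than its parts). Internal
log base is natural; normalized quantities are dimensionless, and callers who
want bits divide unnormalized values by ``log(2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from ._exceptions import DataValidationError

_LN2 = math.log(2.0)

#: Freedman–Diaconis sample-size adjustment per unit regime: the bin-width
#: denominator uses (n_cells + offset)^(1/3)
FD_SIZE_OFFSET = {"fpkm_like": 1, "normalized_counts": 1, "umi": 6}


def log_transform(values, base: int = 10) -> np.ndarray:
    """log-transform non-negative expression, mapping every value below 1 to 1 first.

    With the default base 10 this is the transform used ahead of MMI binning;
    base 2 is the convention for the pairwise-MI network.
    """
    values = np.asarray(values, dtype=np.float64)
    if (values < 0).any():
        raise DataValidationError("expression values must be non-negative")
    clipped = np.maximum(values, 1.0)
    return np.log10(clipped) if base == 10 else np.log2(clipped)


def fd_bin_count(values, unit_regime: str) -> int:
    """Freedman–Diaconis bin count over [0, max(values)].

    Emulates R's ``nclass.FD`` with the sample size replaced by
    ``n_cells + 1`` (FPKM/RPKM/TPM, normalized counts) or ``n_cells + 6``
    (UMI): bin width ``h = 2·IQR/m^(1/3)`` (type-7 quantiles), bin count
    ``ceil(max/h)``. Degenerate inputs (zero IQR or zero range) get one bin.
    """
    try:
        offset = FD_SIZE_OFFSET[unit_regime]
    except KeyError:
        raise DataValidationError(f"unknown unit_regime {unit_regime!r}") from None
    values = np.asarray(values, dtype=np.float64)
    if values.size < 2:
        raise DataValidationError("need at least 2 cells to bin")
    q75, q25 = np.percentile(values, [75.0, 25.0])
    iqr = q75 - q25
    vmax = float(values.max())
    if iqr <= 0.0 or vmax <= 0.0:
        return 1
    m = values.size + offset
    h = 2.0 * iqr / m ** (1.0 / 3.0)
    return int(math.ceil(vmax / h))


@dataclass
class BinningScheme:
    """Per-TF equal-width discretization fixed on one subpopulation's cells.

    ``bins[tf] = (bin_count, vmax)``: bin edges are ``linspace(0, vmax,
    bin_count + 1)`` on log-transformed values. Fit once on the subpopulation,
    then applied unchanged to whatever cells are scored (values above ``vmax``
    clamp into the last bin).
    """

    subpopulation: str
    bins: dict[str, tuple[int, float]]

    @classmethod
    def fit(
        cls,
        log_values_by_tf: dict[str, np.ndarray],
        unit_regime: str,
        subpopulation: str = "",
    ) -> "BinningScheme":
        bins = {}
        for tf, vals in log_values_by_tf.items():
            vals = np.asarray(vals, dtype=np.float64)
            bins[tf] = (fd_bin_count(vals, unit_regime), float(vals.max()))
        return cls(subpopulation=subpopulation, bins=bins)

    def edges(self, tf: str) -> np.ndarray:
        count, vmax = self.bins[tf]
        return np.linspace(0.0, vmax, count + 1)


@dataclass
class DiscreteProfile:
    """One TF's discretized expression: an integer bin symbol per cell."""

    tf: str
    symbols: np.ndarray
    bin_count: int

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        if self.bin_count < 1:
            raise DataValidationError("bin_count must be >= 1")
        if self.symbols.size and (
            self.symbols.min() < 0 or self.symbols.max() >= self.bin_count
        ):
            raise DataValidationError("symbols out of [0, bin_count) range")

    @property
    def n_cells(self) -> int:
        return self.symbols.size

    @property
    def theoretical_max_entropy(self) -> float:
        """log(bin_count) in nats — entropy of the uniform distribution over bins."""
        return math.log(self.bin_count)


def discretize(values, tf: str, bin_count: int, vmax: float) -> DiscreteProfile:
    """Assign each (log-transformed) value to an equal-width bin over [0, vmax].

    A value exactly on an interior edge goes to the higher bin; values at or
    above ``vmax`` (possible when scoring cells outside the subpopulation the
    scheme was fit on) clamp into the last bin.
    """
    values = np.asarray(values, dtype=np.float64)
    if bin_count == 1 or vmax <= 0.0:
        return DiscreteProfile(tf=tf, symbols=np.zeros(values.shape, dtype=np.int64), bin_count=max(bin_count, 1))
    sym = np.floor(values * (bin_count / vmax)).astype(np.int64)
    np.clip(sym, 0, bin_count - 1, out=sym)
    return DiscreteProfile(tf=tf, symbols=sym, bin_count=bin_count)


def discretize_matrix(
    raw_values: np.ndarray, tfs: list[str], scheme: BinningScheme, log_base: int = 10
) -> list[DiscreteProfile]:
    """Log-transform and discretize a cells × TFs matrix under a fitted scheme."""
    logged = log_transform(raw_values, base=log_base)
    profiles = []
    for j, tf in enumerate(tfs):
        count, vmax = scheme.bins[tf]
        profiles.append(discretize(logged[:, j], tf, count, vmax))
    return profiles


# ---------------------------------------------------------------------------
# entropies

def _check_aligned(profiles) -> int:
    n = profiles[0].n_cells
    for p in profiles[1:]:
        if p.n_cells != n:
            raise DataValidationError("profiles cover different cell sets")
    return n


def joint_counts(profiles) -> np.ndarray:
    """Non-zero joint cell counts over the mixed-radix product of bin indices."""
    n = _check_aligned(profiles)
    code = np.zeros(n, dtype=np.int64)
    for p in profiles:
        code = code * p.bin_count + p.symbols
    counts = np.bincount(code)
    return counts[counts > 0]


def entropy_nats(profiles) -> float:
    """Plug-in joint Shannon entropy (nats) of one or more profiles."""
    counts = joint_counts(profiles)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


def max_entropy_nats(profiles) -> float:
    return float(sum(math.log(p.bin_count) for p in profiles))


def normalized_entropy(*profiles) -> float:
    """Joint entropy divided by its theoretical maximum, in [0, 1].

    The maximum is ``log`` of the product of the members' bin counts; if every
    member has a single bin the ratio is defined as 0.
    """
    hmax = max_entropy_nats(profiles)
    if hmax == 0.0:
        _check_aligned(profiles)
        return 0.0
    return entropy_nats(profiles) / hmax


def _subset_entropy(profiles, normalized: bool) -> float:
    return normalized_entropy(*profiles) if normalized else entropy_nats(profiles)


def mmi(profiles, normalized: bool = True) -> float:
    """Multivariate mutual information by inclusion–exclusion over subset entropies.

    Symmetric in its arguments; equals pairwise MI for two profiles. Computed
    on normalized entropies by default (the comparable-across-TFs form used by
    the core search); ``normalized=False`` gives plain nats.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise DataValidationError("MMI requires at least 2 profiles")
    _check_aligned(profiles)
    total = 0.0
    for r in range(1, len(profiles) + 1):
        sign = -((-1.0) ** r)
        for subset in combinations(profiles, r):
            total += sign * _subset_entropy(subset, normalized)
    return total


def tc(profiles, normalized: bool = True) -> float:
    """Total correlation: sum of marginal entropies minus the joint entropy (≥ 0)."""
    profiles = list(profiles)
    if len(profiles) < 2:
        raise DataValidationError("TC requires at least 2 profiles")
    _check_aligned(profiles)
    marg = sum(_subset_entropy((p,), normalized) for p in profiles)
    return marg - _subset_entropy(profiles, normalized)


def pairwise_mi(x: DiscreteProfile, y: DiscreteProfile, normalized: bool = False) -> float:
    """I(X;Y) = H(X) + H(Y) - H(X,Y), in nats unless normalized."""
    return (
        _subset_entropy((x,), normalized)
        + _subset_entropy((y,), normalized)
        - _subset_entropy((x, y), normalized)
    )


def group_mi(group_a, group_b, normalized: bool = False) -> float:
    """Mutual information between two groups of profiles, I(A; B) = H(A)+H(B)-H(A,B)."""
    group_a, group_b = list(group_a), list(group_b)
    return (
        _subset_entropy(group_a, normalized)
        + _subset_entropy(group_b, normalized)
        - _subset_entropy(group_a + group_b, normalized)
    )


def nats_to_bits(value: float) -> float:
    return value / _LN2
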