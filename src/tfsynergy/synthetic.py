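"""Synthetic expression matrices with planted higher-order TF dependencies.

Real multi-dataset inputs are large downloads; this generator produces
matrices in which synergy is known by construction, so every pipeline stage —
expression thresholds, FD discretization, the seed-and-extend search, recovery
scoring — can be exercised end to end.

Background TFs are independent across cells: log-normal for FPKM-like and
normalized-count regimes (zero-inflated by ``dropout_rate``), negative
binomial for UMI counts. Planted motifs are binary latent states mapped to
"high" (≈ ``expression_scale``) and "low" (just below the regime's expressed
cutoff) levels; the gate constraint ties the last TF's state to the others
(e.g. ``xor3``: third = XOR of first two) and is corrupted independently per
cell with probability ``flip_rate``. Latent driver states are balanced across
input combinations (tiled, then shuffled), so at ``flip_rate`` 0 the planted
XOR triple's unnormalized MMI on the latent states is exactly −1 bit. Outside
a motif's own subpopulation its TFs carry gate-free independent states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import DataValidationError
from .io import ExpressionMatrix, SubpopulationPartition
from .preprocessing import UNIT_THRESHOLDS
from .search import SynergyCore

#: gate name → number of TFs it spans
GATE_SIZES = {"xor3": 3, "parity4": 4, "parity5": 5, "copy_chain": 3}


@dataclass(frozen=True)
class PlantedMotif:
    subpopulation: str
    gate: str  # xor3 | parity4 | parity5 | copy_chain
    flip_rate: float = 0.05
    tf_ids: tuple[str, ...] | None = None  # auto-named if omitted

    def __post_init__(self) -> None:
        if self.gate not in GATE_SIZES:
            raise DataValidationError(f"unknown gate {self.gate!r}")
        if not 0.0 <= self.flip_rate < 0.5:
            raise DataValidationError("flip_rate must be in [0, 0.5)")
        if self.tf_ids is not None and len(self.tf_ids) != GATE_SIZES[self.gate]:
            raise DataValidationError(
                f"gate {self.gate} needs {GATE_SIZES[self.gate]} TF ids"
            )


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset.

    Defaults describe the standard recovery scenario: one subpopulation of 300
    cells, 27 background TFs plus one planted 3-TF XOR motif (30 TFs total)
    at a 5% gate flip rate, FPKM-like units with a typical expressed level of
    100 and 30% dropout.
    """

    n_cells: int = 300  # per subpopulation
    n_subpopulations: int = 1
    n_background_tfs: int = 27
    planted_motifs: list[PlantedMotif] = field(
        default_factory=lambda: [PlantedMotif(subpopulation="S1", gate="xor3")]
    )
    unit_regime: str = "fpkm_like"
    expression_scale: float = 100.0
    dropout_rate: float = 0.30
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise DataValidationError("dropout_rate must be in [0, 1)")
        if self.n_cells < 1 or self.n_subpopulations < 1:
            raise DataValidationError("need at least one cell and one subpopulation")

    @property
    def subpopulation_labels(self) -> list[str]:
        return [f"S{i + 1}" for i in range(self.n_subpopulations)]


def _balanced_states(n_inputs: int, n_cells: int, rng) -> np.ndarray:
    """Binary input states balanced over all 2^k combinations, order shuffled."""
    combos = np.array(
        [[(c >> b) & 1 for b in range(n_inputs)] for c in range(2**n_inputs)],
        dtype=np.int8,
    )
    reps = n_cells // len(combos)
    rows = np.tile(combos, (reps, 1))
    remainder = n_cells - len(rows)
    if remainder:
        extra = combos[rng.integers(0, len(combos), size=remainder)]
        rows = np.vstack([rows, extra]) if len(rows) else extra
    return rows[rng.permutation(n_cells)]


def _gate_states(gate: str, n_cells: int, flip_rate: float, rng) -> np.ndarray:
    """Latent 0/1 states (cells × motif TFs) realizing the gate constraint."""
    size = GATE_SIZES[gate]
    if gate in ("xor3", "parity4", "parity5"):
        inputs = _balanced_states(size - 1, n_cells, rng)
        out = inputs.sum(axis=1) % 2
        out ^= rng.random(n_cells) < flip_rate
        return np.column_stack([inputs, out.astype(np.int8)])
    # copy_chain: redundant cascade, each link flipped at flip_rate
    states = np.empty((n_cells, size), dtype=np.int8)
    states[:, 0] = _balanced_states(1, n_cells, rng)[:, 0]
    for j in range(1, size):
        states[:, j] = states[:, j - 1] ^ (rng.random(n_cells) < flip_rate)
    return states


def _states_to_expression(states, unit_regime, scale, rng) -> np.ndarray:
    """Map latent 0/1 states to expression: high ≈ scale, low just below the
    regime's expressed cutoff (so thresholding recovers the latent state)."""
    threshold = UNIT_THRESHOLDS[unit_regime]
    if unit_regime == "umi":
        high = 1.0 + rng.poisson(max(scale, 1.0), size=states.shape)
        low = np.zeros(states.shape)
    else:
        high = scale * rng.lognormal(0.0, 0.25, size=states.shape)
        low = threshold * rng.uniform(0.0, 0.9, size=states.shape)
    return np.where(states > 0, high, low)


def _background(n_cells, n_tfs, unit_regime, scale, dropout_rate, rng) -> np.ndarray:
    if unit_regime == "umi":
        mean = max(scale, 1.0)
        # NB with moderate overdispersion (size 2)
        vals = rng.negative_binomial(2, 2.0 / (2.0 + mean), size=(n_cells, n_tfs)).astype(float)
    else:
        # per-TF median spread around the typical expressed level
        medians = scale * rng.lognormal(0.0, 0.5, size=n_tfs)
        vals = medians * rng.lognormal(0.0, 0.5, size=(n_cells, n_tfs))
    drop = rng.random((n_cells, n_tfs)) < dropout_rate
    vals[drop] = 0.0
    return vals


def generate(spec: SyntheticSpec):
    """Generate (matrix, partition, tf_list, ground_truth) from a spec.

    ``ground_truth`` carries the planted TF sets per subpopulation and the
    latent 0/1 states of every planted TF (for oracle computations on the
    uncorrupted structure). Bit-reproducible from ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    labels = spec.subpopulation_labels

    motifs = []
    next_id = 1
    for m in spec.planted_motifs:
        if m.subpopulation not in labels:
            raise DataValidationError(f"motif subpopulation {m.subpopulation!r} not generated")
        if m.tf_ids is None:
            ids = tuple(f"SYNTF{next_id + j:02d}" for j in range(GATE_SIZES[m.gate]))
            next_id += GATE_SIZES[m.gate]
            m = PlantedMotif(m.subpopulation, m.gate, m.flip_rate, ids)
        motifs.append(m)

    planted_tfs = [tf for m in motifs for tf in m.tf_ids]
    if len(set(planted_tfs)) != len(planted_tfs):
        raise DataValidationError("planted motifs share TF ids")
    background_tfs = [f"BGTF{j + 1:03d}" for j in range(spec.n_background_tfs)]
    if set(background_tfs) & set(planted_tfs):
        raise DataValidationError("planted TF ids collide with background names")
    tf_list = planted_tfs + background_tfs

    n_total = spec.n_cells * spec.n_subpopulations
    cell_ids, cell_labels = [], []
    for label in labels:
        for i in range(spec.n_cells):
            cell_ids.append(f"{label}_cell{i + 1:04d}")
            cell_labels.append(label)

    values = np.zeros((n_total, len(tf_list)))
    latent = np.zeros((n_total, len(planted_tfs)), dtype=np.int8)
    col_of = {tf: j for j, tf in enumerate(tf_list)}

    for s, label in enumerate(labels):
        rows = slice(s * spec.n_cells, (s + 1) * spec.n_cells)
        for m in motifs:
            if m.subpopulation == label:
                states = _gate_states(m.gate, spec.n_cells, m.flip_rate, rng)
            else:
                # same TFs elsewhere: independent states, no gate
                states = np.column_stack(
                    [_balanced_states(1, spec.n_cells, rng)[:, 0] for _ in m.tf_ids]
                )
            cols = [col_of[tf] for tf in m.tf_ids]
            values[rows, :][:, cols] = _states_to_expression(
                states, spec.unit_regime, spec.expression_scale, rng
            )
            lcols = [planted_tfs.index(tf) for tf in m.tf_ids]
            latent[rows, :][:, lcols] = states
        bg_cols = [col_of[tf] for tf in background_tfs]
        values[rows, :][:, bg_cols] = _background(
            spec.n_cells, len(background_tfs), spec.unit_regime,
            spec.expression_scale, spec.dropout_rate, rng,
        )

    matrix = ExpressionMatrix(
        values=values, cell_ids=cell_ids, gene_ids=tf_list, unit_regime=spec.unit_regime
    )
    partition = SubpopulationPartition(dict(zip(cell_ids, cell_labels)))
    ground_truth = {
        "planted": {
            label: [list(m.tf_ids) for m in motifs if m.subpopulation == label]
            for label in labels
        },
        "gates": {",".join(m.tf_ids): m.gate for m in motifs},
        "latent_tfs": planted_tfs,
        "latent_states": latent,
    }
    return matrix, partition, tf_list, ground_truth


def jaccard(a, b) -> float:
    a, b = set(a), set(b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def evaluate_recovery(cores_by_subpop: dict[str, list[SynergyCore]], ground_truth) -> dict:
    """Jaccard overlap of each subpopulation's rank-1 core with its planted set.

    For subpopulations with several motifs the best-matching motif counts.
    Returns per-subpopulation values plus mean and min over subpopulations
    that have both a core and a planted motif.
    """
    per_subpop = {}
    for label, planted_sets in ground_truth["planted"].items():
        if not planted_sets or label not in cores_by_subpop:
            continue
        rank1 = cores_by_subpop[label][0].tfs
        per_subpop[label] = max(jaccard(rank1, p) for p in planted_sets)
    vals = list(per_subpop.values())
    return {
        "per_subpopulation": per_subpop,
        "mean_jaccard": float(np.mean(vals)) if vals else float("nan"),
        "min_jaccard": float(np.min(vals)) if vals else float("nan"),
    }
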