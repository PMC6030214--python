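# tfsynergy

Identify, for each labeled subpopulation in a single-cell RNA-seq dataset, the
combination of transcription factors (TFs) with the highest *transcriptional
synergy* — and rank TFs for converting one subpopulation's identity into
another's.

## The idea

Cell-subpopulation identity often rests on TFs that act *jointly*: knowing the
expression of the whole combination says more about the cell state than the
sum of what each TF says alone. That excess is measured by multivariate mutual
information over discretized expression values,

```
MMI(S) = − Σ_{T ⊆ S, T ≠ ∅} (−1)^{|T|} H(T),
```

the inclusion–exclusion combination of subset entropies H(T). For two
variables MMI reduces to the mutual information I(X;Y) = H(X)+H(Y)−H(X,Y);
for three, MMI(X;Y;Z) = I(X;Z)+I(Y;Z)−I(X,Y;Z), so negative values mean the
pair (X,Y) jointly predicts Z better than X and Y do separately — synergy.
The canonical example is an XOR relation: every pairwise MI is 0 while
I(X,Y;Z) = 1 bit, giving MMI = −1 bit.

Equally synergistic combinations are ranked by total correlation,

```
TC(S) = Σ_i H(X_i) − H(S)  ≥ 0,
```

a measure of overall dependence strength.

Scoring every TF subset is hopeless (3- to 6-TF combinations from 100 TFs
already number 1,271,422,845), so the search is greedy: score all 3-TF
combinations, shortlist the 1% most synergistic, seed from the highest-TC of
those, then extend each seed one TF at a time, keeping extensions whose MMI
drops by more than 0.05 and carrying the ten highest-TC survivors per level,
until no extension helps or cores reach 15 TFs. The best-TC combinations seen
during the search (plus the lowest-MMI incumbent) are then re-ranked by MMI
and the top three reported per subpopulation.

Also included, as comparison baselines: Jensen–Shannon-divergence identity
scoring of TFs against a subpopulation indicator profile, pairwise-MI networks
with a permutation-null significance filter, and GRN hub extraction (Pearson,
Spearman, MRNET).

## Who this is for

Computational biologists with a cells × genes expression matrix (FPKM/RPKM/
TPM, normalized counts, or UMI counts), a per-cell subpopulation labeling,
and a TF annotation (e.g. an AnimalTFDB export), who want candidate identity
TFs per subpopulation and candidate up-/down-regulation targets for identity
conversion between subpopulations.

## Worked example

A synthetic dataset with a known answer: two subpopulations of 200 cells,
12 background TFs, and a 3-TF XOR motif planted in subpopulation S1 (5% gate
noise), searched with the estimator interface:

```python
from tfsynergy import (RunConfig, SyntheticSpec, PlantedMotif, generate,
                       SynergyCoreFinder, rank_conversion_tfs)

spec = SyntheticSpec(n_cells=200, n_subpopulations=2, n_background_tfs=12,
                     planted_motifs=[PlantedMotif("S1", "xor3", flip_rate=0.05)],
                     rng_seed=0)
matrix, partition, tf_list, truth = generate(spec)

finder = SynergyCoreFinder(tf_list=tf_list, top_frequency_fraction=1.0,
                           mmi_population="within")
finder.fit(matrix, [partition.assignment[c] for c in matrix.cell_ids])

core = finder.cores_["S1"][0]
print(f"rank-1 core for S1: {core.tfs}")
print(f"  MMI = {core.mmi:.4f}   TC = {core.tc:.4f}")

plan = rank_conversion_tfs(core, matrix, partition, source="S2")
for r in plan.ranked_tfs:
    print(f"  {r.tf}: fold change {r.fold_change:.2f} ({r.direction})")
```

prints

```
rank-1 core for S1: ('SYNTF01', 'SYNTF02', 'SYNTF03')
  MMI = 0.3695   TC = 1.1532
  SYNTF02: fold change 0.97 (down)
  SYNTF03: fold change 1.01 (up)
  SYNTF01: fold change 1.00 (down)
```

The search recovers exactly the planted triple. Its MMI (computed on
max-entropy-normalized entropies, so the independence baseline is the mean
normalized marginal entropy ≈ 0.9 here, not 0) is far below every competing
triple. The conversion ranking then compares mean expression between S2 and
S1: in this synthetic design the motif TFs are expressed at similar levels in
both groups, so all fold changes sit near 1 — modulating them is ranked as
uninformative, which is the correct call for these data.

The same pipeline is available from the shell:

```sh
tfsynergy simulate --out data/ --n-subpopulations 2 --seed 0
tfsynergy cores --matrix data/matrix.mtx --format mtx \
    --labels data/labels.tsv --tfs data/tf_list.txt --out run/
tfsynergy convert --matrix data/matrix.mtx --format mtx \
    --labels data/labels.tsv --cores run/cores.tsv --all-pairs --out catalog.tsv
```

`run/` receives a tidy `cores.tsv`, per-subpopulation search traces, and a
`manifest.json` (config snapshot, input digests, version) that pins the run.

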