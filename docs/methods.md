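# Methods

## Model and procedure

`tfsynergy` treats a subpopulation's identity TFs as the TF combination whose
discretized expression carries the most *synergy*: the most negative
multivariate mutual information (MMI), the inclusion–exclusion sum
`MMI(S) = −Σ_{T⊆S,T≠∅} (−1)^{|T|} H(T)` over plug-in Shannon entropies of
every non-empty subset. For |S| = 2 this is the mutual information; for
|S| = 3 it equals I(X;Z) + I(Y;Z) − I(X,Y;Z), negative exactly when the joint
out-predicts the parts. Ties in synergy are broken by total correlation
`TC(S) = Σ H(X_i) − H(S)`, a non-negative overall-dependence measure.

The per-subpopulation pipeline:

1. **TF filtering.** Restrict to annotated TFs present in the matrix; compute
   each TF's expressing fraction within the subpopulation ("expressed" = value
   ≥ 1 for FPKM/RPKM/TPM and UMI counts, ≥ 10 for normalized read counts, with
   a per-run override for datasets where 1 admits too many TFs); shortlist the
   top 10% most frequently expressed (ceiling; ties at the cutoff retained);
   drop TFs expressed in ≤ 30% of cells (strictly greater required); for UMI
   data drop TFs with mean count < 1; if more than 150 TFs remain, discard
   highest coefficient of variation first until 150 (CV of a zero-mean TF is
   treated as +∞). Subpopulations retaining < 3 TFs are skipped and reported.
   Datasets with externally binarized expression calls are supported by
   passing the 0/1 matrix for the expressing-fraction step only.
2. **Discretization.** Values are log10-transformed with every value below 1
   mapped to 1 first (so zeros land at 0), then binned per TF with equal-width
   bins over [0, subpopulation maximum]. The bin count follows the
   Freedman–Diaconis rule, `h = 2·IQR/m^(1/3)` with type-7 quantiles and
   `count = ceil(max/h)`, where the effective sample size m is the cell count
   plus 1 (FPKM-like, normalized counts) or plus 6 (UMI); degenerate inputs
   (zero IQR or range) get one bin. This emulation reproduces R's `nclass.FD`
   (verified: `nclass.FD(0:99)` = 5 = the emulation at m = 101). A value
   exactly on an interior edge goes to the higher bin; values above the fitted
   maximum clamp into the last bin.
3. **Entropy normalization.** Every entropy, marginal and joint, is divided by
   its theoretical maximum — log of the product of the members' bin counts —
   before entering MMI and TC, making scores comparable across TFs with
   different bin counts. Internal logs are natural; normalized quantities are
   dimensionless and unnormalized ones are converted to bits where reported.
4. **Evaluation population.** Bins are always fit on the subpopulation's own
   cells. The MMI itself is evaluated, per `mmi_population`, on the complement
   cells (all other cells of the dataset; the default) or on the
   subpopulation's own cells (`"within"`). With a single subpopulation the
   complement is empty and the search falls back to `"within"`.
5. **Seed-and-extend search.** Score all C(n,3) triples; shortlist the 1%
   lowest-MMI (ceiling, min 1); seed with the 1% highest-TC of the shortlist
   (ceiling, min 1). Each level extends every seed by each unused TF, keeps a
   combination iff `MMI(new) − MMI(seed) < −extension_delta` (default 0.05;
   0 reproduces the strict "any negative difference" rule), de-duplicates
   combinations reached from several seeds, ranks survivors by TC and carries
   the top 10 as next-level seeds. Termination: no survivors, or cores of 15
   TFs. Finalization re-scores the 20 highest-TC combinations accumulated over
   all levels **plus the incumbent** (the lowest-MMI combination encountered)
   and reports the top 3 by MMI ascending, ties by TC descending, then by
   summed within-subpopulation mean expression, then lexicographically.
6. **Conversion ranking.** For a (source, target) pair, the target's rank-1
   core TFs are ranked by mean-expression fold change
   `(mean_target + 1)/(mean_source + 1)` (pseudocount 1, matching the zero→1
   log convention), by default on |log2 FC| so strong down-regulation
   candidates rank as high as strong up-regulation ones (`fc_rank="signed"`
   gives the literal signed ranking). The all-pairs catalog emits one plan per
   ordered pair: k subpopulations → k·(k−1) plans.

Baselines: per-TF Jensen–Shannon divergence (base 2, maximum 1) between the
subpopulation indicator and the TF's normalized mean-expression profile, top
10 lowest with ties; pairwise-MI networks on log2-transformed FD-discretized
values with a 50-replicate within-TF permutation null and a one-sided
one-sample t-test per edge (empirical permutation p available via
`p_method="empirical"`), keeping the 1% lowest p-values (min 1); and GRN hubs
by weighted degree of |Pearson|/|Spearman| correlation (log2-transformed
except UMI, which enters raw) or a hand-written MRNET (forward
max-relevance/min-redundancy selection per target, edge weight = max of the
two directed MRMR scores, positive weights retained — retained edges are
always a subset of positive-MI pairs). Random-forest GRN inference is out of
scope; externally computed weighted adjacencies plug into the same hub
extraction (`hubs_from_adjacency`).

## Behavior of normalized MMI — what "negative" means

With unnormalized entropies, jointly independent variables have MMI = 0 and
the XOR triple −1 bit, so negative ⇔ synergy. The max-entropy normalization
shifts the baseline: for independent variables with equal bin counts the
normalized MMI equals the mean normalized marginal entropy (positive, ≈ 0.5–1
on realistic data), and the XOR triple scores 2/3 of that. Synergy therefore
appears as a *low* normalized MMI relative to that baseline rather than a
negative number; ranking by lowest MMI — what the search does — is unaffected.
One further consequence, verified by exact enumeration: interaction
information alternates sign with order, so an even-order parity gate (output =
XOR of three inputs) scores *higher* MMI (+1 bit unnormalized) than its
mutually independent triples. Clean even parity is anti-synergistic under this
definition and is not recoverable by the seed-and-extend search; the
generator's `parity4` gate is kept as exactly this documented hard case.

## Finalization pool (design choice)

The re-scored pool is the 20 best-TC combinations accumulated over all levels
— where the level-3 contribution is the whole 1%-lowest-MMI shortlist, which
the seed stage "takes" before TC selection — plus the incumbent lowest-MMI
combination. Without the incumbent, a pure top-20-TC pool can discard the
search's own best candidate whenever its TC ranks 21st or lower among
accumulated combinations; on 30-TF synthetic instances this happened in about
one replicate in five, returning a strictly worse core than one already
scored. Keeping the incumbent restores the guarantee that the reported rank-1
core is never worse than the best combination the search encountered.

## Tunable parameters

| parameter | default | meaning |
| --- | --- | --- |
| `expression_threshold` | regime default (1 / 10 / 1) | "expressed" cutoff, raw units |
| `top_frequency_fraction` | 0.10 | shortlist fraction by expressing frequency |
| `min_expressing_fraction` | 0.30 | strict lower bound on expressing fraction |
| `max_tf_count` | 150 | candidate cap (CV trimming above it) |
| `seed_fraction` | 0.01 | MMI shortlist and TC seed fractions at level 3 |
| `extension_delta` | 0.05 | required MMI drop per added TF (dimensionless) |
| `seeds_per_level` | 10 | combinations carried per level |
| `final_pool_size` | 20 | best-TC pool re-scored at finalization |
| `max_core_size` | 15 | search size cap |
| `reported_cores` | 3 | cores reported per subpopulation |
| `mmi_population` | `complement` | cells MMI is evaluated on |
| `fc_rank` | `abs_log` | conversion ranking key |

## Synthetic data: what it emulates, what it does not

The generator produces cells × TFs matrices with independent background TFs —
zero-inflated log-normal for FPKM-like/normalized regimes (per-TF median
spread ×2^±, 30% dropout by default), negative binomial (size 2) for UMI —
plus planted motifs: binary latent states mapped to "high" (≈
`expression_scale`, default 100) and "low" (just below the regime's expressed
cutoff) levels, with a gate (`xor3`, `parity4`, `parity5`, `copy_chain`) tying
the output TF to the inputs, corrupted per cell at `flip_rate`. Latent input
states are balanced across input combinations (tiled, then shuffled) so that
at `flip_rate` 0 the planted XOR triple's unnormalized MMI is exactly −1 bit;
outside its own subpopulation a motif's TFs carry gate-free independent
states. Defaults — 300 cells per subpopulation, 27 background TFs + one xor3
at 5% flips — are the standard recovery scenario.

What passing recovery tests shows: thresholding, FD binning, entropy
normalization, and the greedy search jointly recover a genuinely synergistic
triple against a realistic marginal background, and produce no spuriously
synergistic core on background-only data. What they do not show: behavior
under real-data features the generator omits — library-size variation,
gene–gene correlation backbones, batch effects, continuous (non-switch-like)
co-regulation, and candidate pools at the 150-TF scale.

Two settings differ deliberately between synthetic experiments and the
real-data defaults, fixed as experimental design before any measurement:
synthetic searches use `mmi_population="within"` (motifs are planted within a
subpopulation's cells; the complement carries no gate) and
`top_frequency_fraction=1.0` (the 10% shortlist is sized for TF annotations of
~1500 genes, where it yields ≈150 candidates; on a 30-TF pool it would
degenerate to 3).

## Numerical choices and degenerate inputs

- Plug-in (maximum-likelihood) entropies, no bias correction.
- All score ties break lexicographically on TF identifiers, making every
  stage deterministic given inputs and configuration; nothing in the core
  search consumes randomness.
- Joint-entropy normalization uses the product of marginal bin counts (the
  theoretical maximum), not the realized joint support.
- Complement-cell evaluation never re-fits bins; out-of-range values clamp.
- One-bin TFs have normalized entropy defined as 0.
- Exhaustive enumeration (`SynergyScorer.all_subset_mmi`, the brute-force
  oracle) refuses more than 16 TFs.
- The MI-network t-test falls back to a direct comparison when the
  permutation null is degenerate (zero spread).

## Problem sizes used in the shipped experiments

Recovery and false-positive control: 20 replicates × 300 cells × 30 TFs.
Greedy-vs-exhaustive comparison: 20 replicates × 300 cells × 12 TFs,
brute force over all 3–12-TF subsets. These sizes make every claim fully
recomputable in about a minute while keeping the search's combinatorial
regime (thousands of scored triples per run) intact.

## Known limitations

- Greedy seed-and-extend finds the global MMI minimum only when a synergistic
  triple already ranks into the seed shortlist; structures whose synergy
  appears only at order ≥ 4 with independent lower-order margins (odd parity)
  are invisible to it, by construction.
- Normalized MMI comparisons are only meaningful between combinations of TFs
  with broadly similar marginal entropies (see the baseline-shift note above);
  the filtering stage's "frequently expressed" requirement is what keeps this
  reasonable in practice.
- Plug-in entropies are biased downward for joint supports approaching the
  cell count; deep cores estimated from few cells should be read with
  caution.
- No imputation, normalization, batch correction, doublet handling, or
  re-clustering: labels and values are taken as given.
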