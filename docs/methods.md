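# Methods

This note documents the models, numerical conventions and design choices
behind `phylarray`, and what the synthetic benchmark does and does not show.

## Probe-level model and presence calling

An OTU is interrogated by a set of PM/MM 25-mer probe pairs (on the chips
this package targets, 37 pairs per OTU on average, s.d. 9.6). A pair's raw
observables are two fluorescence intensities; the calling chain is:

**Preprocessing.** Per array, background *b* is the 2nd percentile of all PM
and MM intensities; every intensity becomes `max(x − b, 1)` and is then
scaled by `spikein_level / mean(background-subtracted spike-in controls)`.
The floor of 1 intensity unit keeps the later log2 abundance weights
non-negative. Spike-in controls are identified by the `CTRL_` probe-id
prefix (chips differ in their control layouts; a prefix convention keeps the
file format self-describing).

**Pair scores.** The response score is `d = (PM − MM)/(PM + MM)` (0 when the
denominator is 0; PM = MM ties are *not* positive — "higher" is strict).
The ranked response score *r* answers "does this pair respond more strongly
than probes of similar base composition respond to nothing?": probes are
binned by their A+T count (bins of width 5: 0–4, 5–9, …), and *r* is the
fraction of null values in the pair's bin strictly below its *d*.

The null pool is array-specific and label-free: the pairs of every OTU whose
positive fraction falls below the Stage-1 cutoff (0.92), i.e. OTUs that are
non-responders by the calling's own standard. Two refinements matter in
practice:

* *Why positive fraction and not a positive-pair count:* with ~37 pairs per
  OTU and sign-symmetric noise, a truly absent OTU still has ≈50% positive
  pairs, so a count-based ineligibility rule (e.g. "<7 positive pairs")
  selects almost nothing and the pool would be empty.
* *Reflected null:* cross-hybridizing pairs of non-responding OTUs
  contaminate only the positive side of the pool and would cap the
  attainable *r* well below the Stage-1 quartile cutoffs. A non-responding
  pair's *d* is symmetric about 0, so the per-bin null is built from the
  pool's non-positive *d* values reflected about zero. This makes *r*
  robust to cross-hybridization without using any presence labels.

An empty A+T bin raises an error (widen binning or add background probes)
rather than silently degrading.

**Stage 1** (per OTU, all four criterion flags recorded): ≥7 pairs scored;
≥7 pairs positive; *r*-quartiles ≥ 0.80 / 0.93 / 0.98; positive fraction
≥ 0.92. Quartiles are computed by linear interpolation between order
statistics (the "type 7" rule) for bit-reproducibility.

**Stage 2** (cross-hybridization): for each pair of a Stage-1 passer,
`rx = r / s`, where *s* counts Stage-1-passing OTUs on this array whose
probe sets contain the same probe id (so `rx ≤ r`, with equality for
unshared probes). A *species* is present when the quartiles of the pooled
*rx* values of its Stage-1-passing OTUs reach 0.22 / 0.40 / 0.42 (the
quartiles are pooled per species, not per OTU); an OTU is present iff it
passed Stage 1 and its species is present.

**Consensus and roll-up.** An OTU is present in a sample when called on at
least 2 of its 3 replicate arrays; when replicates were pooled into a single
hybridization, presence on that one array suffices. A taxon at any rank
from phylum to genus is present iff at least one present species lies in its
lineage.

**Abundance proxy.** The hybridization score is the mean PM intensity after
removing exactly one maximum and one minimum occurrence (not all tied
extremes — deterministic under ties); it requires ≥3 pairs.

## Community matrices and transforms

Matrices are OTU × replicate-array, with rows restricted to OTUs
consensus-present in ≥1 sample and cells holding the array's hybridization
score where the OTU was called on that array, else 0. A *kind* tag enforces
pipeline order: `raw → relativized → arcsine`, and the distance functions
accept only relativized/arcsine input. "General relativization" divides by
the column total (exponent 1, the standard default). Row z-scoring (display
transform for heat plots) maps constant rows to zeros and flags them rather
than erroring.

## Comparison statistics

**Bray–Curtis** `d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ)` over sample columns (scipy's
implementation behind the kind-tag guard).

**Clustering** is Lance–Williams agglomeration: group-average (UPGMA,
`d(k, i∪j) = (nᵢ d(ki) + nⱼ d(kj))/(nᵢ+nⱼ)`) or flexible beta
(`αᵢ = αⱼ = (1−β)/2, γ = 0`, default β = −0.25, the conventional value).
Equal-distance merge candidates break toward the lexicographically smallest
cluster-index pair, so dendrograms are deterministic. Cutting at "cluster
level k" removes the top k−1 merges, leaving k clusters.

**MRPP** uses δ = Σ_g (n_g/N) · (mean within-group pairwise distance) — the
common group-size weighting — and A = 1 − δ_obs/δ_exp. When the number of
distinct label arrangements is ≤ 10,000 the permutation distribution is
enumerated exhaustively (δ_exp and p exact for the design); otherwise Monte
Carlo with the add-one correction `p = (1 + #{δ_perm ≤ δ_obs})/(1 + B)`,
with δ_exp estimated from the same permutation stream. The add-one
correction keeps p > 0 and super-uniform under the null.

**INDVAL**: specificity `a(i,j)` = mean abundance of OTU i in group j over
the sum of its group means; fidelity `b(i,j)` = fraction of group-j members
where i is present; `INDVAL = a·b·100`; each OTU's statistic is its maximum
over groups, with Monte-Carlo label-permutation p (add-one corrected).
Abundance enters as the relativized (pre-arcsine) matrix; presence for the
fidelity term comes from the calling module, not from abundance > 0.
Zero-total-abundance OTUs are reported with INDVAL 0 and a flag.

## UniFrac and PCoA

Abundance weights are `log2(hybridization score)` for present OTUs (the
preprocessing floor guarantees non-negativity), 0 for absent ones,
normalized within each sample *before* any subtree aggregation. The
normalized weighted UniFrac between samples A and B is
`Σ_b l_b·|p_A(b) − p_B(b)|` over branches, divided by
`Σ_leaf depth(leaf)·(p_A + p_B)`; the unnormalized variant is available
behind a flag. Trees must be rooted (two children at the root); a basal
trifurcation is rejected rather than silently midpoint-rooted. Leaves
carrying zero weight in both samples can be pruned without changing any
distance, provided pruning preserves root-to-leaf depths —
`prune_zero_weight` collapses unary internal nodes by summing branch
lengths and never collapses the root (a plain shear would shorten the root
paths and change the normalization denominator).

PCoA is classical metric scaling: Gower double-centering of −d²/2,
symmetric eigendecomposition, coordinates = eigenvectors · √eigenvalue,
axes ordered by decreasing eigenvalue. Axes with non-positive eigenvalues
(within a relative tolerance of 1e-12) carry no coordinates; % variation is
the share of the sum of *positive* eigenvalues. Each axis's sign is fixed
by making its first nonzero coordinate positive, so plots are reproducible.

## The synthetic benchmark

The simulator defines the study conditions under which everything is tested
(all defaults in `SimulationConfig`; fully deterministic under `seed`):

* **Design**: 120 OTUs in 60 species across 5 phyla; per-OTU pair counts ~
  Normal(37, 9.6) truncated below at 10; A+T counts uniform on 8–17 (probes
  carry no sequence); 24 spike-in controls; a random rooted binary tree
  whose clades follow the taxonomy.
* **Communities**: 3 groups × 3 replicate arrays; a shared presence set
  (each OTU present with probability 0.4); log-normal baseline abundances
  (ln-scale mean 3.0, sd 0.8); per-group up-shifts of 2² (effect size 2 in
  log2 units) on a random 20% of present OTUs; 2 planted indicator OTUs per
  group, present in every replicate of their group and absent elsewhere;
  replicate jitter is multiplicative log-normal with sd 0.15.
* **Arrays**: a probe's signal is `gain · Σ abundance` over the OTUs owning
  it (gain 100 intensity units per abundance unit); PM responds fully, MM
  at a leak fraction of 0.15; PM and MM share one nonspecific-binding level
  per pair (Normal(50, 10)) with small independent multiplicative jitter —
  modelling the background as *shared* within a pair is essential, because
  independent additive PM/MM noise is amplified by background subtraction
  into |d| ≈ 1 tails that no threshold separates. Cross-hybridization acts
  twice, both driven by `crosshyb_rate` (0.05): probes are shared among
  same-species sibling OTUs at the design level (this is what exercises the
  Stage-2 divisor s > 1), and at the signal level a probe picks up half the
  signal of the tree-nearest present OTU when that neighbour is within tree
  distance 0.5 (cross-hybridization is a close-relative phenomenon; without
  the distance gate the background pool degrades unrealistically). Each
  array gets a global log-normal scale factor (sd 0.1) that preprocessing
  must undo via the spike-ins.

What passing tests on these conditions show: the calling logic, the
statistics and the ordination are internally correct (oracle-verified), and
the chain recovers planted structure under realistic noise,
cross-hybridization and array-level scale variation. What they do not
show: performance on real chips with probe-specific affinity biases,
saturation, spatial artifacts, or taxon panels three orders of magnitude
larger; the published field results (thousands of OTUs per sample, their
MRPP and ordination statistics) depend on the proprietary probe annotation
and real arrays and are not reproduced here.

## Problem sizes and numerical conventions

The test suite and the acceptance script run the default 120-OTU, 9-array
study plus ~100-array null panels at 40 OTUs; oracle-equivalence checks use
100 random instances of ≤8 samples at 1e-9. Degenerate inputs follow fixed
rules rather than raising where a display semantic exists (constant rows →
zero z-scores with a flag; zero-abundance OTUs → INDVAL 0 with a flag), and
raise early, naming the offending entity, where a computation is undefined
(zero-sum sample columns, <3 probe pairs, groups of size 1, unrooted trees,
empty A+T bins). Every permutation result records its seed and permutation
count, and rerunning any stage with the same config and seed is
byte-identical; the run manifest's stage timings are the one wall-clock
(non-reproducible) field, so reproducibility checks compare the data files
or the manifest's checksum inventory.
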