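# Methods

## Problem setting

RT-qPCR expression values (quantification cycles, Cq) confound true
transcription with per-sample "loading": RNA yield and integrity, reverse
transcription efficiency, pipetting. Normalization divides each target's
relative quantity by a normalization factor (NF) built from reference genes
assumed stable across all conditions. `refstab` scores candidate reference
genes by four complementary stability criteria, integrates them, and
validates the chosen panel. The package is organised around a
model-object/results-object pair (`ReferenceGeneStability` → `fit()` →
`StabilityResults`) over plain functional modules, one per method.

## Data model and transforms

* **CqMatrix** — replicate-collapsed Cq, genes × samples, complete-case:
  samples missing any gene are dropped at load time (the four algorithms all
  assume a rectangular matrix, and sample-level QC exclusion mirrors how
  such datasets are actually curated). Technical replicates are averaged
  arithmetically on the Cq scale; their SD is retained and sets with SD > 0.5
  cycles are flagged in the log but never mutated or dropped.
* **RQMatrix** — RQ(g, s) = E^(calibrator_g − Cq(g, s)), calibrator = the
  gene's minimum Cq, so RQ ∈ (0, 1] with max exactly 1 per gene. E is one
  run-wide constant (default 2.0, admissible 1.6–2.2, i.e. 60 %–120 %
  amplification efficiency). Any per-gene calibrator cancels in every
  ratio-based statistic downstream, and a common E rescales all log
  quantities per gene without changing ranks — so a transparent global
  constant is preferred over per-gene efficiencies, which the data format
  does not carry.
* BestKeeper and deltaCt consume raw Cq; geNorm and NormFinder consume RQ.
  Log base 2 is used everywhere a logarithm appears; conventional
  thresholds (geNorm M < 0.5, V ≤ 0.2) are quoted on that scale and
  reported as annotations only, never applied as filters.

## The four stability methods

**BestKeeper.** Index(s) = geometric mean over genes of Cq(g, s) (the
original definition; an arithmetic option exists and differs negligibly at
typical Cq). Each gene is scored by Pearson r with the index; ranking is by
descending r, ties broken by lower Cq SD then name. A gene with zero Cq
variance has undefined r and ranks last. The original method's SD > 1
exclusion is computed as a flag but not applied. The gene under analysis is
included in its own index. Because the index is dominated by whatever is
common to all genes, BestKeeper *rewards* correlation with sample loading —
the documented, and deliberate, disagreement with the ratio-based methods
(see the loading-cancellation test).

**geNorm.** M(j) = mean over partners k of the unbiased SD over samples of
log2(RQ_j/RQ_k). The argmax-M gene is eliminated (ties broken by gene-name
order, logged) and M recomputed until two genes remain; these form the best
pair and are reported tied at rank 1.5 (their mutual ratio cannot rank them
internally). V(n/n+1) is the SD over samples of log2(NF_n/NF_{n+1}) where
NF_n is the geometric-mean RQ of the n most stable genes, n = 2 … k−1.

**deltaCt.** score(j) = mean over partners of SD_s(Cq_j − Cq_k). The mean
(not the sum) keeps scores comparable across panel sizes; the ranking is
identical either way. Since log2 RQ = −Cq + const per gene at E = 2, the
deltaCt score *equals* geNorm's first-round M exactly; the test suite
asserts agreement to 1e-10 on a thousand random matrices.

**NormFinder.** Let y = log2 RQ and r_igj = y_igj − mean over genes within
sample j (centering that removes the common loading term). With k genes,
s²_ig the unbiased within-(gene, group) variance of r, the centering bias is
corrected by

    σ̂²_ig = max{ (k/(k−2)) (s²_ig − T̂_g/k²), 0 },  T̂_g = (k/(k−1)) Σ_i s²_ig.

Grouped mode: z_ig = within-group mean of r, d_ig = z_ig − Σ n_g z_ig/Σ n_g
(so Σ n_g d_ig = 0 per gene), shrinkage d̃_ig = d_ig·γ²/(γ² + σ̂²_ig/n_g),
and per-group stability

    ρ_ig = |d̃_ig| + sqrt( (σ̂²_ig/n_g)·γ²/(γ² + σ̂²_ig/n_g) ),

averaged over groups. Ungrouped mode is the single-group limit where d ≡ 0
and ρ = sqrt(σ̂²). The best pair minimises the same expression with
d̃ replaced by the pair mean (d̃_a + d̃_b)/2, variance term
(σ̂²_a + σ̂²_b)/(4 n_g), and the pair-level γ² the mean of the two genes' γ².

*γ² estimation.* The intergroup variance is estimated by pooling over all
genes and groups, γ̂² = max{ Σ_ig d_ig²/((k−1)(G−1)) − mean_ig(σ̂²_ig/n_g), 0 },
consistent with modelling the gene-by-group interactions as draws from one
common N(0, γ²). A per-gene variant (`gamma_mode="per_gene"`,
Var_g(d_ig) − mean_g(σ̂²_ig/n_g)) is kept as a diagnostic, but with two-level
groupings it has a single degree of freedom and truncates to zero for
roughly half the genes, collapsing their grouped stability to exactly 0 and
reducing best-pair selection to alphabetical tie-breaks — which is why it is
not the default. When the pooled γ̂² itself truncates to zero, the honest
reading is that the grouping carries no detectable intergroup variance; all
grouped stabilities then vanish and the ranking is uninformative by design
(the grouped score measures group-linked bias, not noise).

## Consensus, NF, validation

The four scores live on different scales (a correlation, two cycle-scale
SDs, a log2-scale model quantity), so integration uses **ranks**: aggregate
= (Π of the four ranks)^(1/4), geNorm's tied pair entering as 1.5 + 1.5
(rank-sum preserving). Final order ascending aggregate, ties by arithmetic
mean rank then name. The aggregate is provably bounded by the min and max
of the four ranks, which the tests assert on every dataset.

NF(s) = geometric mean of the reference genes' RQ (≥ 2 genes enforced — a
single reference is refused outright per the MIQE guidelines; exactly two
draws a warning). Validation divides a target's RQ by NF and compares
within-group CoV (SD/mean on the *linear* scale, as conventionally printed;
log2 values are emitted alongside for plotting) before and after.
Normalizing the NF's own references leaves a per-sample geometric mean of
exactly 1 — an algebraic identity the tests check to machine precision.
NormFinder's aggregate contribution uses its ungrouped (whole-dataset)
ranking, the view commensurate with the other three methods; grouped
results are carried separately with their best pairs.

## Synthetic data generator

Generative model on the cycle scale:

    Cq(g, s, rep) = baseline_g + coupling_g·L(s) + Σ effects matching s
                    + N(0, gene_noise_sd_g) + N(0, replicate_sd),
    L(s) ~ N(0, loading_sd).

Noise is Gaussian on Cq — multiplicative in quantity — which is the standard
qPCR error model. The shared loading offset L is the normalizable part;
`loading_coupling < 1` creates genes that only partially track loading
(an rRNA tracking total RNA rather than mRNA input), the regime where
BestKeeper and geNorm legitimately disagree.

The default study configuration emulates a rat tendon-injury design:
11 candidates (*18S*, *ACTB*, *AP3D1*, *B2M*, *CSNK2A2*, *GAPDH*, *HPRT1*,
*PAK1IP1*, *RPL13a*, *SDHA*, *UBC*), 35 samples in a 2×2×2 factorial
(injured/uninjured limb × rapamycin/vehicle × day 7/21) with n = 4–5 per
cell giving the canonical subset sizes 35/19/16/18/17, triplicate wells
(replicate SD 0.12 cycles), loading SD 0.8 cycles. Baselines follow the
observed abundance ordering (rRNA near Cq 8.5; abundant genes 18.5–20;
modest genes 22.5–25.5). Designated unstable genes: *SDHA* carries a
+1.0-cycle injury effect (halved expression after injury); *GAPDH* a
rapamycin-by-injury interaction (±0.8 cycles, opposite signs by limb) plus
elevated noise (0.45); *18S* is noisy (0.8) with injury and
injury-by-timepoint shifts (the early inflammatory cellularity peak); *UBC*
is noisy (0.6); *B2M* shifts with treatment (+0.4) and timepoint (+0.5) but
not injury — so it scores better when samples are grouped by injury status,
a pattern the tests assert. A few abundant genes carry small injury-linked
shifts (−0.25 to −0.3) so that whole-dataset stability is modestly worse
than within-subset stability, as in real injured-vs-control designs.
All noise SDs and effect sizes are in cycles; effect sign positive = lower
expression.

What the generator does **not** model: amplification-curve shape,
PCR inhibitors, pipetting outliers, inter-plate batch structure, or
non-Gaussian heavy-tailed failures. Passing recovery tests therefore shows
the algorithms behave correctly under the assumed error model, not that any
particular wet-lab dataset satisfies that model.

Benchmark configurations used by the tests and the acceptance script:

* `recovery_config` — 11 exchangeable genes (noise 0.15), loading 0.8, one
  gene (+1.0-cycle injury effect), single wells. Expected behaviour: the
  shifted gene lands in the bottom 3 of all four methods' rankings in ≥95 %
  of 200 seeds, and the grouped NormFinder contrast d_injured − d_uninjured
  recovers the injected log2 effect scaled by (k−1)/k ≈ 0.91 (the
  per-sample centering absorbs 1/k of any single-gene shift).
* `null_config` — fully exchangeable genes; every gene must win the ranking
  equally often (chi-square over 500 seeds, α = 0.01).
* `validation_config` — three low-noise references plus a loading-only
  target; NF division must shrink every within-group CoV in ≥95 % of
  200 seeds.

## Numerical choices

* Unbiased (n−1) SDs and variances throughout.
* All elimination/ranking ties broken deterministically (documented above)
  and logged; identical inputs give byte-identical outputs.
* σ̂² and γ̂² truncated at zero, with truncation counts logged.
* Degenerate inputs: constant genes give zero deltaCt/geNorm contributions,
  undefined BestKeeper r (ranked last), and zero NormFinder ρ; subsets with
  < 2 samples are excluded, < 3 warned.
* Problem sizes in the default test and acceptance runs — 1000 random
  matrices (≤10×≤40) for the cross-method identity, 25 five-gene fixtures
  for oracle equivalence, 200 seeds for recovery and validation, 500 for
  null calibration — were chosen as the smallest sizes at which the
  Monte-Carlo rates are stable to well under the asserted margins.

## Known limitations

* BestKeeper reports r, Cq SD and CV only (no pairwise regression p-values).
* NormFinder confidence intervals are not computed; one crossed grouping at
  a time.
* The NormFinder best-pair and standard-error algebra is internally
  consistent and brute-force-verified, but reconciling the exact constants
  against the original published tool's code is deliberately out of scope.
* Efficiency is global, not per gene; standard-curve efficiency estimation
  and instrument-native file parsing are out of scope.
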