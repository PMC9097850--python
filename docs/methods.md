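# Methods

## Data model

The unit of analysis is a Ct (quantification-cycle) matrix: one
technical-replicate-collapsed Ct value per biological sample and candidate
gene, with three per-sample design labels — condition (`SHAM` | `tMCAO`),
time after reperfusion (`12h` | `24h` | `3d` | `7d`) and brain region
(`CX` cortex, `HIP` hippocampus, `DS` dorsal striatum). Labels form
closed, case-sensitive vocabularies: a silently mis-assigned group is the
worst failure mode of a stability screen, so an unknown token is a hard
error (an alias map can translate input spellings). Replicate averaging
and Cq determination are upstream of this package.

Every stability metric runs on an *analysis block*, the samples of one
region × time point. By default a block pools the SHAM and tMCAO arms
(2 × n samples); `composition="tmcao_only"` restricts to occluded animals.
Pooling is the default because the reference-gene question is "is this
gene stable across everything the experiment contains", and because the
grouped NormFinder model needs both arms. Missing values (parsed from
`NA`-like tokens, never coerced to 0) are handled per block: the default
`drop_sample` policy removes and logs any sample with a missing Ct;
`error` aborts. Fewer than three remaining samples, or fewer than two
genes, is an error for every metric.

## Stability metrics

All four methods score genes so that **lower = more stable**, and all SDs
use the unbiased n−1 denominator (the method literature's convention; the
choice is irrelevant to rankings, which are scale-free).

**Relative quantities.** geNorm and NormFinder operate on
`q_ij = E^(Ctmin_j − Ct_ij)` with amplification factor `E` per cycle
(default 2.0, i.e. perfect efficiency; TaqMan assays justify this default
but `E` is a parameter because assay efficiencies vary). `log2 q` ratios
equal negated Ct differences exactly when E = 2, which makes the
full-panel geNorm M identical to the comparative-ΔCt score — the test
suite asserts this equivalence to 1e−12 as an algebra check on both
implementations.

**Comparative ΔCt.** `score_j = mean_{k≠j} SD_i(Ct_ij − Ct_ik)`, in
cycles. No parameters.

**geNorm.** `V_jk = SD_i(log2(q_ij/q_ik))`, `M_j = mean_{k≠j} V_jk`.
The ranking procedure iteratively removes the gene with the highest M and
recomputes M on the remainder until two genes are left; those two share an
identical lowest M by construction and are flagged as the tied top pair.
Because downstream aggregation needs integer ranks 1..G, the pair is
assigned distinct positions 1 and 2, ordered by the comparative-ΔCt score
(computed on `log_E q`, so the tie-break is efficiency-consistent).
Exclusion ties — two genes with numerically identical worst M, which
occurs only in degenerate inputs such as identical genes — are broken
toward the gene with the larger raw-Ct SD and logged.

The pairwise-variation profile uses normalization factors
`NF_n(i) = geometric mean of q over the top-n ranked genes`;
`V_{n/n+1} = SD_i(log2(NF_n/NF_{n+1}))` for n = 2..G−1. The recommended
reference-gene count is the smallest n with V below the cutoff (default
0.15, the conventional threshold below which adding a gene is considered
unnecessary). If no V clears the cutoff the profile is flagged rather than
forced; `effective_n()` then reports the full panel size G, the honest
"this panel does not suffice" answer used when comparing regions.

**NormFinder.** The additive model on y = log2 q decomposes each gene's
variation within sample group j (default groups: SHAM vs tMCAO of the
block) into intragroup variance σ²_gj and an intergroup (gene × group
interaction) difference d_gj.

- σ²_gj: residuals of the per-group two-way (sample + gene) fit are
  double-centered; the naive per-gene mean squared residual
  `u_g = Σ_i r²_ig/(n−1)` satisfies
  `E[u_g] = (1 − 2/G) σ²_g + σ̄²/G`, so the de-biased estimator is
  `σ̂²_g = G/(G−2) · (u_g − ū/(G−1))`, floored at 0 with a logged warning
  (this needs G ≥ 3).
- d_gj: group means of sample-centered y, double-centered across groups
  and genes (so Σ_g d_gj = 0 within each group).
- Shrinkage: with `γ² = max(0, Σ d²/((G−1)(J−1)) − mean(σ̂²_gj/n_j))` as
  the between-gene variance of true group differences,
  `d̃_gj = d_gj · γ²/(γ² + σ̂²_gj/n_j)` — noisy estimates of d are pulled
  toward 0.
- Stability: `S_g = mean_j (|d̃_gj| + σ̂_gj/√n_j)`, the shrunken group
  bias plus the standard error of its estimate.

With `use_groups=False` (or a single-group block, to which grouped calls
fall back with a log message) the stability value is the corrected SD of
the gene's sample-centered values. The two modes sit on different scales —
the grouped S carries a 1/√n_j factor — so they are compared on the
orderings they induce, not on values. No printed S values exist to
validate against; the implementation is validated by its derived
properties (noiseless data → S ≈ 0, an injected group shift is detected in
≥95 % of replicates, grouped and ungrouped modes agree on orderings under
group-identical distributions) and by an independent loop-based oracle.

**BestKeeper.** Per gene, on raw Ct: `SD(±Ct)` and `CV(%Ct) = 100·SD/mean`.
Genes with SD above the exclusion cutoff (default 1.0 cycle, i.e. a ~2-fold
spread at E = 2) are flagged unstable and left out of the BestKeeper index,
the per-sample geometric mean of the remaining genes' Ct. Every gene —
included or not — is then correlated against the index (Pearson r with a
two-sided p). The ranking key is r descending among included genes, then
excluded genes by r descending; r ties break by smaller SD, then gene
name; a zero-variance gene has no defined r and ranks last in its stratum
with a warning. Note the index lives on the Ct scale, so statistics tied
to it (r) are only approximately invariant to constant Ct offsets; SD and
CV behave exactly as expected.

## Rank aggregation

Each method contributes a permutation of integer ranks 1..G (fractional
tied ranks are never emitted; all tie-breaks above exist to guarantee
this). The comprehensive score of a gene is the geometric mean of its four
ranks; the consensus ordering is ascending geomean with ties broken by the
ΔCt score and logged. Display rounding is half-up to two decimals; full
precision is kept internally, and test comparisons against printed values
use |diff| ≤ 0.005. Study-level orderings take the geometric mean of a
gene's per-block comprehensive positions (never raw scores, which are not
comparable across blocks). Alternative aggregation schemes (Borda, Kemeny)
are deliberately out of scope.

`refstab.datasets` carries the printed six-gene, twelve-block ranking
table of a published rat tMCAO study, the only quantitative surface
available for that experiment (its raw Ct data were never deposited).
`verify_published_geomeans()` recomputes every consensus cell from the
printed per-method positions and flags — without correcting — cells that
disagree by more than 0.005. Four cells fail: one (DS 12 h *B2m*, printed
4.73 vs 6.00 from unanimous rank-6 positions) is a clear transplantation
of another cell's value; two differ by exactly 0.01 in a way consistent
with truncation rather than rounding; one (CX 3 d *Actb*, printed 4.68 vs
4.47) matches no combination of its printed ranks. Likewise one printed
BestKeeper column (DS 12 h) lists two adjacent genes in an order that
contradicts their own printed r values; the ranking rule reproduces the
other eleven columns exactly, and the mismatch is surfaced as a
discrepancy rather than special-cased.

## Variance screen and fold changes

The screen runs a one-way ANOVA per gene across the condition × time
groups of one region, by default on sample-centered log2 quantities
(centering removes loading differences; raw Ct and uncentered log
quantities are config options since the appropriate scale is debatable).
Welch's unequal-variance ANOVA is available behind a flag; no post-hoc
tests are run because the screen only feeds a stable/unstable label at
level α (default 0.05). Fold changes are reported tMCAO vs time-matched
SHAM as `2^(−ΔΔCt)` against a caller-chosen normalizer set; a gene may not
normalize itself.

## Synthetic data

The generator draws
`Ct = baseline + loading + shift + noise`, truncated to (10, 40) cycles
(truncation is logged): a per-sample Gaussian loading effect shared by all
genes (SD 0.3 cycles) models RNA input/RT efficiency and induces the
between-gene correlation BestKeeper's index expects; per-gene Gaussian
technical noise models assay scatter; shifts are condition × time × region
specific expression changes in cycles (`fold F ⇒ −log2 F` at E = 2).
Noise is additive on the Ct scale, i.e. log-normal on abundance — the
standard qPCR error model.

`tmcao_preset()` encodes the destabilization pattern reported after
tMCAO: *Actb* −2.32 cycles (5-fold, the midpoint of the reported 4–6×) in
CX and DS at 3 d/7 d; *B2m* −2.82 cycles (~7-fold, geometric midpoint of
5–10×) in CX at 3 d/7 d and in DS at all four time points (the striatum is
the ischaemic core and shows persistent *B2m* instability); *Gapdh* −0.8
in CX at 3 d/7 d and −1.5 in DS at 24 h (its reported exclusion there);
*Ppia*, *Hprt1*, *Ywhaz* shift-free; SHAM always neutral. DS additionally
carries a 1.75× technical-noise scale, since infarct-core tissue is
uniformly harder to measure and gene-specific shifts alone cannot
reproduce the observation that the core demands more reference genes (the
geNorm ranking pushes shifted genes to the bottom, so the V profile of the
top genes never sees them).

Per-gene noise SDs (cycles): Ppia 0.20, Hprt1 0.22, Ywhaz 0.22, Actb 0.30,
B2m 0.35, Gapdh 0.40. These sit inside the realistic 0.2–0.5 band and are
jointly constrained by the preset's two calibration targets: the recovered
*Actb* fold at CX 3 d must fall inside the reported 4–6× window in ≥90 %
of realizations (capping Actb noise at ~0.30, since
SE(ΔΔCt) ≈ √(σ²_Actb + σ²_norm)·√(2/8) must stay below ~0.17 cycles), and
the shift-free trio must occupy the top three consensus positions in
≥90 % of realizations (requiring the trio to be quieter than the
perturbed genes in the blocks where the latter carry no shift). The
ordering of the noise levels matches the published pattern of ΔCt average
SDs (Ppia best, Actb/B2m/Gapdh worst).

What the generator does **not** model: per-block biological variance
beyond the loading effect, efficiency differences between assays, plate
and batch effects, inter-animal correlation across regions (each
region × animal draw is independent), and non-Gaussian outliers. Passing
recovery tests therefore demonstrates that the pipeline detects the
encoded instability structure at realistic noise — not that it would
reproduce the published per-block score values, which depend on data that
were never released.

## Numerical choices and degenerate inputs

- Geometric means are computed as `exp(mean(log))` for numerical
  symmetry; display rounding is decimal half-up.
- Variance estimates that come out negative after bias correction are
  floored at 0 and logged, never silently clipped.
- Deterministic tie-breaks everywhere (documented above), each logged, so
  identical inputs yield byte-identical reports; simulation is fully
  reproducible from a single integer seed via `numpy.random.default_rng`.
- Blocks failing a precondition inside the full-study runner are skipped
  with a logged reason and flagged in the bundle (CLI exit code 1) rather
  than aborting the remaining blocks.

## Problem sizes

The Monte-Carlo checks in the test suite and the acceptance script use
100-seed recovery loops on the full 192 × 6 design, 200-seed sign tests
for noise monotonicity, 500–1000 random blocks for the algebraic
equivalence check, and ~1000 gene-level tests for the type-I-error
calibration of the screen — sizes at which every asserted rate has a
binomial standard error comfortably below the asserted margin.

## Known limitations

- BestKeeper's r is computed against an index that changes composition
  with the exclusion set; comparing r across blocks with different
  exclusions is therefore not meaningful.
- The NormFinder variance correction requires at least three genes and
  two samples per group; two-gene panels only support ΔCt/geNorm/
  BestKeeper.
- The screen's ANOVA treats condition × time cells as independent groups;
  it does not model time as ordered.
- No instrument-native formats (RDML, thermocycler XML) and no
  amplification-curve processing.
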