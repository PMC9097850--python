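# refstab

Reference-gene stability analysis for RT-qPCR.

Quantitative RT-PCR measures a target transcript relative to one or more
*reference genes* (RGs, "housekeeping genes") assumed to be stably
expressed. That assumption fails routinely — in brain
ischaemia/reperfusion models, classic references such as *Actb* and *B2m*
are strongly regulated — so candidate RGs must be validated per tissue,
per time point, per condition. `refstab` implements the four standard
stability algorithms, their consensus ranking, a per-gene variance screen,
and a synthetic Ct-data generator emulating a rat transient middle
cerebral artery occlusion (tMCAO) study (SHAM vs tMCAO × 12 h/24 h/3 d/7 d
× cortex/hippocampus/dorsal striatum, n = 8 per group, six candidate
genes: *Ywhaz*, *Ppia*, *Gapdh*, *Hprt1*, *Actb*, *B2m*).

## Methods

All methods consume one *analysis block* — the samples × genes Ct matrix
of a single region and time point — and score each gene; lower is always
more stable. With amplification factor `E` per cycle (default 2), relative
quantities are `q_ij = E^(min_i Ct_ij − Ct_ij)`.

- **Comparative ΔCt** — `score_j = mean_{k≠j} SD_i(Ct_ij − Ct_ik)`
  (cycles).
- **geNorm** — `M_j = mean_{k≠j} SD_i(log2 (q_ij/q_ik))`; genes are
  iteratively removed from the highest M until a tied most-stable pair
  remains. The pairwise variation `V_{n/n+1} = SD_i(log2 (NF_n/NF_{n+1}))`
  between normalization factors built from the top *n* and *n+1* genes
  gives the recommended RG count (smallest *n* with V < 0.15). At E = 2,
  full-panel M is algebraically identical to the ΔCt score.
- **NormFinder** — model-based stability `S_g` on log2 quantities:
  sample-loading effects are removed by centering, intragroup variances
  `σ²_gj` estimated with a bias correction, intergroup differences
  `d_gj` shrunken toward zero by their sampling noise, and
  `S_g = mean_j(|d̃_gj| + σ_gj/√n_j)`.
- **BestKeeper** — per-gene Ct SD and CV; genes with SD > 1 cycle are
  flagged unstable and excluded from the BestKeeper index (per-sample
  geometric mean Ct); remaining genes rank by Pearson `r` against the
  index, excluded genes last.
- **Comprehensive ranking** — each method contributes integer ranks 1..G;
  a gene's consensus score is the geometric mean of its four ranks
  (RefFinder-style), reported to two decimals; study-level orderings take
  the geometric mean of per-block positions.

The package also ships the published stability rankings of a rat tMCAO
six-gene study (`refstab.datasets`) so that the aggregation pipeline can
be checked against printed values, and a verification pass that flags the
handful of cells in that table that are not reproducible from their own
printed rank positions.

## Worked example

```python
import refstab as rs

m = rs.simulate(rs.tmcao_preset(seed=1))     # 192 samples x 6 genes
block = rs.slice_block(m, "CX", "3d")        # cortex, 3 days, 8+8 animals
rep = rs.analyse_block(block)
print(rep.comprehensive.as_frame().round(2))
```

```
       delta_ct  genorm  normfinder  bestkeeper  geomean  comprehensive_rank
Hprt1         2       1           2           1     1.41                   1
Gapdh         1       4           1           2     1.68                   2
Ppia          4       2           4           3     3.13                   3
Ywhaz         3       3           3           4     3.22                   4
Actb          5       5           5           6     5.23                   5
B2m           6       6           6           5     5.73                   6
```

The preset injects a ~5-fold *Actb* and ~7-fold *B2m* up-regulation in the
tMCAO animals of this block, and both genes fall to the bottom of the
consensus ranking (BestKeeper additionally excludes them, SD > 1). The
geNorm pairwise-variation profile for the same block,
`rep.v_profile.v.round(3)` → `{2: 0.079, 3: 0.149, 4: 0.209, 5: 0.208}`,
recommends two reference genes (V₂/₃ < 0.15). Aggregating all twelve
blocks:

```python
bundle = rs.run_full_analysis(rs.RunConfig(preset="tmcao", seed=1))
print(bundle.study_ranking.round(2))
```

```
Hprt1    1.80
Ppia     2.06
Ywhaz    2.14
Gapdh    3.44
Actb     4.83
B2m      5.46
```

The three genes the preset leaves unperturbed occupy the top three
study-level positions; the destabilized *Actb* and *B2m* sit at the
bottom. The same pipeline is available from the shell:

```sh
refstab simulate --preset tmcao --seed 1 --out ct.csv
refstab report --input ct.csv --out results/
refstab screen --input ct.csv --region CX
refstab aggregate ranks.csv        # geomeans from an external rank table
```

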