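"""The four reference-gene stability algorithms.

All four methods score each candidate gene of an analysis block; lower
scores always mean more stable expression.

* comparative dCt — mean over partner genes of the SD of pairwise Ct
  differences ("average SD", in cycles);
* geNorm — pairwise-variation stability value M, iterative gene exclusion
  and the V(n/n+1) profile for the optimal number of reference genes;
* NormFinder — model-based stability value S combining intergroup bias and
  intragroup variance on the log-expression scale;
* BestKeeper — descriptive Ct statistics (SD, CV) plus Pearson correlation
  of each gene with the BestKeeper index (per-sample geometric mean Ct of
  the genes that pass the SD cutoff).

geNorm and NormFinder operate on relative quantities
``q = E**(Ct_min - Ct)`` where E is the amplification factor per PCR cycle
(E = 2 for a perfectly efficient assay).  With E = 2 a log2 ratio of
quantities is exactly a Ct difference, which makes the full-panel geNorm M
algebraically identical to the comparative-dCt score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import AnalysisBlock, CtDataError, require_block_shape

logger = logging.getLogger("refstab")

DEFAULT_EFFICIENCY = 2.0
DEFAULT_SD_CUTOFF = 1.0     # BestKeeper: Ct SD above this flags a gene unstable
DEFAULT_V_CUTOFF = 0.15     # geNorm: V(n/n+1) below this means n genes suffice

METHODS = ("delta_ct", "genorm", "normfinder", "bestkeeper")


@dataclass(frozen=True)
class RelativeQuantityMatrix:
    """Samples x genes relative quantities q = E**(Ct_min - Ct)."""

    q: pd.DataFrame
    efficiency: float = DEFAULT_EFFICIENCY

    @property
    def genes(self) -> list[str]:
        return list(self.q.columns)

    @property
    def n_samples(self) -> int:
        return self.q.shape[0]

    def log2(self) -> pd.DataFrame:
        return np.log2(self.q)

    def log_e(self) -> pd.DataFrame:
        """log base E of q — equals Ct_min - Ct, i.e. Ct up to a constant."""
        return np.log2(self.q) / np.log2(self.efficiency)


@dataclass(frozen=True)
class StabilityResult:
    """Per-gene scores of one stability method on one analysis block.

    ``scores`` is ordered most-stable-first when the method defines its own
    ordering (geNorm, BestKeeper); ``aux`` carries method-specific
    statistics; ``excluded`` the genes failing the BestKeeper SD rule.
    """

    method: str
    scores: pd.Series
    aux: pd.DataFrame | None = None
    excluded: frozenset = frozenset()
    order: tuple[str, ...] | None = None  # explicit ranking, when not score-ascending

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class PairwiseVariationProfile:
    """geNorm V(n/n+1) values for n = 2..G-1 and the recommended RG count."""

    v: pd.Series                 # index n, value V(n/n+1)
    cutoff: float
    recommended_n: int | None    # None = no V below cutoff ("needs more genes")

    @property
    def all_above_cutoff(self) -> bool:
        return self.recommended_n is None

    def effective_n(self) -> int:
        """recommended_n, or the full panel size G when no V clears the cutoff."""
        return self.recommended_n if self.recommended_n is not None else len(self.v) + 2


# ---------------------------------------------------------------------------
# Relative quantities
# ---------------------------------------------------------------------------

def to_relative_quantities(
    b: AnalysisBlock, efficiency: float = DEFAULT_EFFICIENCY
) -> RelativeQuantityMatrix:
    """Convert a block's Ct values to relative quantities.

    ``q_ij = E**(min_i Ct_ij - Ct_ij)``: per gene, the most abundant sample
    (lowest Ct) gets q = 1 and every other sample a value in (0, 1].
    """
    if not efficiency > 1.0:
        raise ValueError(f"amplification efficiency must exceed 1, got {efficiency}")
    require_block_shape(b, min_genes=2, min_samples=2)
    ct = b.ct
    q = np.power(efficiency, ct.min(axis=0) - ct)
    return RelativeQuantityMatrix(q=q, efficiency=float(efficiency))


# ---------------------------------------------------------------------------
# Comparative dCt
# ---------------------------------------------------------------------------

def delta_ct_stability(b: AnalysisBlock) -> StabilityResult:
    """Comparative-dCt stability: mean SD of pairwise Ct differences.

    For gene j the score is the average over every partner gene k of
    ``SD_i(Ct_ij - Ct_ik)`` (sample SD, n-1 denominator), in cycles.
    """
    require_block_shape(b)
    ct = b.ct.to_numpy(dtype=float)
    genes = b.genes
    G = len(genes)
    # SD of the difference for every ordered pair; diagonal is 0.
    diff_sd = np.empty((G, G))
    for j in range(G):
        diff_sd[j] = np.std(ct[:, [j]] - ct, axis=0, ddof=1)
    score = (diff_sd.sum(axis=1)) / (G - 1)  # diagonal contributes 0
    pair_cols = pd.DataFrame(diff_sd, index=genes, columns=[f"sd_vs_{g}" for g in genes])
    return StabilityResult(
        method="delta_ct",
        scores=pd.Series(score, index=genes, name="avg_sd"),
        aux=pair_cols,
    )


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def genorm_m(q: RelativeQuantityMatrix, subset=None) -> pd.Series:
    """geNorm stability value M for each gene of ``subset``.

    ``M_j = mean_{k != j} SD_i(log2(q_ij / q_ik))`` over the genes of the
    subset (default: all genes).  Requires at least two genes.
    """
    genes = list(subset) if subset is not None else q.genes
    if len(genes) < 2:
        raise ValueError("geNorm M needs at least 2 genes")
    y = np.log2(q.q[genes].to_numpy(dtype=float))
    if not np.isfinite(y).all():
        raise ValueError("zero or missing relative quantity encountered")
    G = len(genes)
    m = np.empty(G)
    for j in range(G):
        sd = np.std(y[:, [j]] - y, axis=0, ddof=1)
        m[j] = sd.sum() / (G - 1)
    return pd.Series(m, index=genes, name="M")


@dataclass(frozen=True)
class GenormRanking:
    """Result of the iterative geNorm exclusion procedure."""

    order: tuple[str, ...]            # most stable first; order[0:2] is the tied pair
    m_at_exclusion: pd.Series         # M of each gene in the panel where it was excluded
    full_panel_m: pd.Series           # M of each gene in the complete panel
    tied_pair: tuple[str, str]
    tie_broken: tuple[str, ...] = ()  # genes whose exclusion needed a tie-break


def genorm_rank(q: RelativeQuantityMatrix) -> GenormRanking:
    """Iterative geNorm ranking: repeatedly drop the least stable gene.

    The gene with the highest M is excluded and M recomputed on the
    remaining panel until two genes remain.  Those two share (by
    construction) an identical lowest M and are reported as a tied pair;
    within the pair, rank 1 goes to the gene with the lower comparative-dCt
    score so that integer ranks 1..G are always defined.  Exclusion ties
    (identical max M) are broken toward the gene with the larger raw-Ct SD.
    """
    genes = list(q.genes)
    if len(genes) < 3:
        raise ValueError("geNorm ranking needs at least 3 genes")
    full_m = genorm_m(q)
    ct_like = q.log_e()                      # Ct up to sign/offset: same SDs
    ct_sd = ct_like.std(axis=0, ddof=1)

    remaining = list(genes)
    excluded: list[str] = []
    m_at_exclusion = {}
    tie_broken: list[str] = []
    while len(remaining) > 2:
        m = genorm_m(q, subset=remaining)
        worst_m = m.max()
        worst = [g for g in remaining if np.isclose(m[g], worst_m, rtol=0, atol=1e-12)]
        if len(worst) > 1:
            worst.sort(key=lambda g: (-ct_sd[g], g))
            logger.warning(
                "geNorm exclusion tie at M=%.4f between %s; excluding %s "
                "(largest raw-Ct SD)", worst_m, worst, worst[0]
            )
            tie_broken.append(worst[0])
        gene = worst[0]
        m_at_exclusion[gene] = float(m[gene])
        remaining.remove(gene)
        excluded.append(gene)

    final_m = genorm_m(q, subset=remaining)
    for g in remaining:
        m_at_exclusion[g] = float(final_m[g])
    # Distinct ranks 1 and 2 inside the tied pair: lower dCt-style score first.
    pair_score = {
        g: float(np.mean([np.std(ct_like[g] - ct_like[k], ddof=1)
                          for k in genes if k != g]))
        for g in remaining
    }
    pair = sorted(remaining, key=lambda g: (pair_score[g], g))
    order = tuple(pair + excluded[::-1])
    return GenormRanking(
        order=order,
        m_at_exclusion=pd.Series(m_at_exclusion, name="M_at_exclusion").reindex(order),
        full_panel_m=full_m.reindex(order),
        tied_pair=(pair[0], pair[1]),
        tie_broken=tuple(tie_broken),
    )


def genorm_stability(q: RelativeQuantityMatrix) -> StabilityResult:
    """Package the geNorm ranking as a StabilityResult (scores = M at exclusion)."""
    r = genorm_rank(q)
    aux = pd.DataFrame({
        "m_at_exclusion": r.m_at_exclusion,
        "full_panel_m": r.full_panel_m,
        "tied_top_pair": [g in r.tied_pair for g in r.order],
    })
    return StabilityResult(
        method="genorm", scores=r.m_at_exclusion.rename("M"), aux=aux, order=r.order
    )


def genorm_pairwise_v(
    q: RelativeQuantityMatrix,
    ranking: GenormRanking | tuple[str, ...] | None = None,
    cutoff: float = DEFAULT_V_CUTOFF,
) -> PairwiseVariationProfile:
    """geNorm pairwise variation V(n/n+1) for n = 2..G-1.

    ``NF_n(i)`` is the geometric mean of sample i's quantities over the n
    top-ranked genes; ``V(n/n+1) = SD_i(log2(NF_n(i)/NF_{n+1}(i)))``.  The
    recommended reference-gene count is the smallest n with V below the
    cutoff (0.15 by geNorm convention); if no V clears it the profile is
    flagged — the panel does not contain enough stable genes.
    """
    genes = q.genes
    if len(genes) < 3:
        raise ValueError("pairwise variation needs at least 3 genes")
    if ranking is None:
        ranking = genorm_rank(q)
    order = list(ranking.order if isinstance(ranking, GenormRanking) else ranking)
    if sorted(order) != sorted(genes):
        raise ValueError("ranking must be a permutation of the panel genes")
    y = np.log2(q.q[order].to_numpy(dtype=float))
    G = len(order)
    # cumulative mean of log2 q over the top-n genes = log2 NF_n
    cum = np.cumsum(y, axis=1) / np.arange(1, G + 1)
    v = {}
    for n in range(2, G):
        v[n] = float(np.std(cum[:, n - 1] - cum[:, n], ddof=1))
    v_series = pd.Series(v, name="V")
    below = [n for n, val in v.items() if val < cutoff]
    rec = min(below) if below else None
    if rec is None:
        logger.info("no V(n/n+1) below %.2f: more reference genes needed", cutoff)
    return PairwiseVariationProfile(v=v_series, cutoff=float(cutoff), recommended_n=rec)


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def _normfinder_group_variances(y: np.ndarray) -> tuple[np.ndarray, float]:
    """Bias-corrected per-gene intragroup variances for one group.

    ``y`` is samples x genes on the log scale.  Residuals of the additive
    sample + gene model are double-centered; the naive per-gene mean squared
    residual u_g underestimates sigma2_g because the sample mean mixes all
    genes, so the estimator solves E[u_g] = (1-2/G) sigma2_g + sigma2_bar/G:

        sigma2_g = G/(G-2) * (u_g - u_bar/(G-1)),  floored at 0.

    Returns the per-gene variances and the mean raw residual term u_bar.
    """
    n, G = y.shape
    if n < 2:
        raise CtDataError("NormFinder needs >= 2 samples per group")
    if G < 3:
        raise CtDataError("NormFinder variance correction needs >= 3 genes")
    r = y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True) + y.mean()
    u = (r ** 2).sum(axis=0) / (n - 1)
    u_bar = float(u.mean())
    sigma2 = (G / (G - 2)) * (u - u_bar / (G - 1))
    neg = sigma2 < 0
    if neg.any():
        logger.warning("NormFinder: %d negative variance estimate(s) floored at 0",
                       int(neg.sum()))
        sigma2 = np.where(neg, 0.0, sigma2)
    return sigma2, u_bar


def normfinder_s(
    b: AnalysisBlock,
    use_groups: bool = True,
    efficiency: float = DEFAULT_EFFICIENCY,
) -> StabilityResult:
    """NormFinder stability value S per gene (lower = more stable).

    The model works on log2 relative quantities and decomposes each gene's
    variation into an intergroup component (systematic expression difference
    between the sample groups, e.g. SHAM vs tMCAO) and an intragroup
    variance.  Group differences d_gj are shrunken toward 0 in proportion
    to their sampling noise and combined with their standard error:

        S_g = mean_j ( |d~_gj| + sigma_gj / sqrt(n_j) )

    With ``use_groups=False`` the stability value is simply the corrected
    SD of the gene's sample-centered log expression — appropriate when no
    grouping is trusted.
    """
    require_block_shape(b, min_genes=3, min_samples=3)
    q = to_relative_quantities(b, efficiency=efficiency)
    y_all = q.log2().to_numpy(dtype=float)
    genes = b.genes
    G = len(genes)

    if not use_groups:
        sigma2, _ = _normfinder_group_variances(y_all)
        s = np.sqrt(sigma2)
        return StabilityResult(
            method="normfinder",
            scores=pd.Series(s, index=genes, name="S"),
            aux=pd.DataFrame({"intragroup_var": sigma2}, index=genes),
        )

    labels = b.group_labels
    groups = [g for g in pd.unique(labels)]
    if len(groups) < 2:
        raise CtDataError("grouped NormFinder needs >= 2 groups (use_groups=False?)")
    sizes = {g: int((labels == g).sum()) for g in groups}
    small = [g for g, n in sizes.items() if n < 2]
    if small:
        raise CtDataError(f"group(s) {small} have < 2 samples")

    J = len(groups)
    sigma2 = np.empty((J, G))
    z_mean = np.empty((J, G))   # group mean of sample-centered log expression
    n_j = np.empty(J)
    for jx, grp in enumerate(groups):
        y = y_all[(labels == grp).to_numpy()]
        sigma2[jx], _ = _normfinder_group_variances(y)
        z = y - y.mean(axis=1, keepdims=True)  # remove per-sample loading
        z_mean[jx] = z.mean(axis=0)
        n_j[jx] = y.shape[0]

    # Intergroup difference: gene-by-group interaction of the centered means.
    d = z_mean - z_mean.mean(axis=0, keepdims=True)
    d = d - d.mean(axis=1, keepdims=True)      # sums to 0 over genes within group
    samp_var = sigma2 / n_j[:, None]
    gamma2 = d.var(ddof=0) * d.size / ((G - 1) * (J - 1)) - samp_var.mean()
    gamma2 = max(0.0, float(gamma2))
    denom = gamma2 + samp_var
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(denom > 0, gamma2 / np.where(denom > 0, denom, 1.0), 0.0)
    d_tilde = d * shrink
    rho = np.abs(d_tilde) + np.sqrt(samp_var)
    s = rho.mean(axis=0)

    aux = pd.DataFrame(
        {
            **{f"d_{grp}": d[jx] for jx, grp in enumerate(groups)},
            **{f"var_{grp}": sigma2[jx] for jx, grp in enumerate(groups)},
        },
        index=genes,
    )
    return StabilityResult(
        method="normfinder", scores=pd.Series(s, index=genes, name="S"), aux=aux
    )


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def bestkeeper(
    b: AnalysisBlock, sd_exclusion_cutoff: float = DEFAULT_SD_CUTOFF
) -> StabilityResult:
    """BestKeeper descriptive statistics and index correlation.

    Per gene: SD of raw Ct (cycles), CV = 100*SD/mean (% of mean Ct), and
    the Pearson correlation r (with two-sided p) between the gene's Ct and
    the BestKeeper index — the per-sample geometric mean Ct over the genes
    whose SD does not exceed the cutoff (1.0 cycle by convention).  Genes
    above the cutoff are flagged excluded: they do not enter the index but
    are still correlated against it.  Ranking uses r descending with
    excluded genes last (see :func:`refstab.ranking.ranks_from_scores`).
    """
    require_block_shape(b)
    ct = b.ct
    genes = b.genes
    sd = ct.std(axis=0, ddof=1)
    cv = 100.0 * sd / ct.mean(axis=0)
    excluded = frozenset(sd.index[sd > sd_exclusion_cutoff])
    kept = [g for g in genes if g not in excluded]
    if not kept:
        raise CtDataError(
            f"block {b.label}: every gene exceeds the BestKeeper SD cutoff "
            f"({sd_exclusion_cutoff})"
        )
    if excluded:
        logger.warning("block %s: BestKeeper excluded %s (Ct SD > %.2f)",
                       b.label, sorted(excluded), sd_exclusion_cutoff)
    index = np.exp(np.log(ct[kept]).mean(axis=1))  # geometric mean Ct per sample
    r = pd.Series(np.nan, index=genes, name="r")
    pval = pd.Series(np.nan, index=genes, name="p")
    for g in genes:
        if sd[g] == 0:
            logger.warning("block %s: gene %s has zero Ct variance; r undefined",
                           b.label, g)
            continue
        res = sps.pearsonr(ct[g], index)
        r[g], pval[g] = float(res.statistic), float(res.pvalue)
    aux = pd.DataFrame({"sd": sd, "cv": cv, "r": r, "p": pval,
                        "excluded": [g in excluded for g in genes]})
    order = _bestkeeper_order(aux)
    return StabilityResult(
        method="bestkeeper",
        scores=sd.rename("sd"),
        aux=aux,
        excluded=excluded,
        order=order,
    )


def _bestkeeper_order(aux: pd.DataFrame) -> tuple[str, ...]:
    """BestKeeper ranking: r descending, SD-excluded genes last (also by r).

    Ties in r are broken by smaller Ct SD, then gene name; an undefined r
    (zero-variance gene) sorts after every defined one in its stratum.
    """
    def key(g):
        r = aux.at[g, "r"]
        return (
            bool(aux.at[g, "excluded"]),
            np.isnan(r),
            -(r if np.isfinite(r) else 0.0),
            aux.at[g, "sd"],
            g,
        )
    return tuple(sorted(aux.index, key=key))
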