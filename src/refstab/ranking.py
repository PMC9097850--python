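"""Rank aggregation: per-method integer ranks and the comprehensive
geometric-mean ranking.

Every method contributes a permutation of ranks 1..G (1 = most stable);
the comprehensive score of a gene is the geometric mean of its four ranks,
displayed rounded half-up to two decimals.  Integer ranks (never fractional
tied ranks) are used throughout because the published comprehensive
geomeans are only reproducible from distinct integer positions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

from .metrics import StabilityResult

logger = logging.getLogger("refstab")


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round half away from zero (5 rounds up), as in the published tables."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class RankTable:
    """Per-method integer ranks (1 = most stable) for one analysis block."""

    region: str
    time_point: str
    ranks: pd.DataFrame  # index gene, one int column per method

    def __post_init__(self) -> None:
        G = self.ranks.shape[0]
        for col in self.ranks.columns:
            if sorted(self.ranks[col]) != list(range(1, G + 1)):
                raise ValueError(
                    f"ranks for method {col!r} are not a permutation of 1..{G}"
                )

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)

    @property
    def label(self) -> str:
        return f"{self.region}-{self.time_point}"


@dataclass(frozen=True)
class ComprehensiveRanking:
    """Geometric mean of per-method ranks and the final ordering."""

    region: str
    time_point: str
    geomean: pd.Series        # index gene, ordered most stable first
    ranks: pd.DataFrame       # the aggregated rank table, same row order

    @property
    def order(self) -> tuple[str, ...]:
        return tuple(self.geomean.index)

    def rounded(self) -> pd.Series:
        return self.geomean.map(round_half_up)

    def as_frame(self) -> pd.DataFrame:
        out = self.ranks.copy()
        out["geomean"] = self.geomean
        out["comprehensive_rank"] = np.arange(1, len(out) + 1)
        return out


def _order_to_ranks(order, genes) -> pd.Series:
    rank = {g: i + 1 for i, g in enumerate(order)}
    return pd.Series([rank[g] for g in genes], index=genes, dtype=int)


def ranks_from_scores(
    results: list[StabilityResult],
    region: str = "",
    time_point: str = "",
) -> RankTable:
    """Integer rank positions per method from a set of stability results.

    dCt and NormFinder rank by score ascending; geNorm and BestKeeper carry
    their own ordering (iterative-exclusion order; r descending with
    SD-excluded genes last).  Score ties are broken deterministically by
    gene name and logged.
    """
    if not results:
        raise ValueError("no stability results supplied")
    gene_sets = {frozenset(r.scores.index) for r in results}
    if len(gene_sets) != 1:
        raise ValueError("stability results cover different gene sets")
    genes = list(results[0].scores.index)
    methods = [r.method for r in results]
    if len(set(methods)) != len(methods):
        raise ValueError(f"duplicate methods in {methods}")

    cols = {}
    for res in results:
        if res.order is not None:
            order = list(res.order)
        else:
            scores = res.scores
            if scores.duplicated().any():
                tied = scores.index[scores.duplicated(keep=False)].tolist()
                logger.warning(
                    "%s: tied scores for %s; breaking ties by gene name",
                    res.method, tied,
                )
            order = sorted(genes, key=lambda g: (scores[g], g))
        cols[res.method] = _order_to_ranks(order, genes)
    return RankTable(region=region, time_point=time_point,
                     ranks=pd.DataFrame(cols, index=genes))


def geometric_mean_rank(ranks) -> float:
    """Geometric mean of a sequence of rank positions (all >= 1)."""
    ranks = list(ranks)
    if not ranks:
        raise ValueError("empty rank list")
    if any(r < 1 for r in ranks):
        raise ValueError("rank positions must be >= 1")
    return float(math.exp(np.mean(np.log(np.asarray(ranks, dtype=float)))))


def comprehensive_ranking(
    rt: RankTable, tie_break_scores: pd.Series | None = None
) -> ComprehensiveRanking:
    """Geometric mean of each gene's per-method ranks, ordered ascending.

    Geomean ties are broken by the comparative-dCt score when supplied
    (else by gene name), and logged.
    """
    gm = rt.ranks.apply(geometric_mean_rank, axis=1)
    if gm.duplicated().any():
        tied = gm.index[gm.duplicated(keep=False)].tolist()
        logger.warning("block %s: tied geomeans for %s", rt.label, tied)

    def key(g):
        tb = tie_break_scores[g] if tie_break_scores is not None else 0.0
        return (gm[g], tb, g)

    order = sorted(rt.genes, key=key)
    return ComprehensiveRanking(
        region=rt.region,
        time_point=rt.time_point,
        geomean=gm.reindex(order),
        ranks=rt.ranks.reindex(order),
    )


def study_level_ranking(per_block: list) -> pd.Series:
    """Integrated ordering across blocks: geomean of per-block rank positions.

    Accepts :class:`ComprehensiveRanking` objects (their final orderings
    define the per-block positions) or :class:`RankTable` objects for a
    single-method aggregation (the table must have exactly one column).
    Returns the study-level geomeans ordered most stable first.
    """
    if not per_block:
        raise ValueError("no blocks supplied")
    positions = []
    for blk in per_block:
        if isinstance(blk, ComprehensiveRanking):
            positions.append(_order_to_ranks(blk.order, blk.order))
        elif isinstance(blk, RankTable):
            if blk.ranks.shape[1] != 1:
                raise ValueError(
                    "study-level aggregation of a RankTable needs exactly one method"
                )
            positions.append(blk.ranks.iloc[:, 0])
        else:
            raise TypeError(f"unsupported block type {type(blk).__name__}")
    genes = set(positions[0].index)
    for pos in positions[1:]:
        if set(pos.index) != genes:
            missing = sorted(genes.symmetric_difference(pos.index))
            raise ValueError(f"gene set mismatch across blocks: {missing}")
    mat = pd.concat(positions, axis=1)
    gm = mat.apply(geometric_mean_rank, axis=1)
    if gm.duplicated().any():
        logger.warning("study-level geomean ties for %s; breaking by gene name",
                       gm.index[gm.duplicated(keep=False)].tolist())
    gm = gm.loc[sorted(gm.index)]  # name-ordered so ties break alphabetically
    return gm.sort_values(kind="stable").rename("geomean")
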