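"""Whole-study orchestration and report assembly.

``run_full_analysis`` applies the four stability methods, the rank
aggregation and the geNorm V profile to every (region, time point) block
of a Ct matrix, then integrates the per-block comprehensive rankings into
a study-level ordering.  Results are returned as an in-memory bundle and
optionally written as tidy CSVs plus a JSON summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import metrics
from .simulate import simulate as _simulate, tmcao_preset as _tmcao_preset
from .io import AnalysisBlock, CtDataError, CtMatrix, drop_missing, iter_blocks, read_ct_table
from .ranking import ComprehensiveRanking, RankTable, comprehensive_ranking, ranks_from_scores, study_level_ranking

logger = logging.getLogger("refstab")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full stability analysis run."""

    input_path: str | None = None
    preset: str | None = None            # "tmcao": simulate instead of reading
    composition: str = "pooled"          # pooled | tmcao_only
    efficiency: float = metrics.DEFAULT_EFFICIENCY
    sd_exclusion_cutoff: float = metrics.DEFAULT_SD_CUTOFF
    v_cutoff: float = metrics.DEFAULT_V_CUTOFF
    use_groups: bool = True
    missing_policy: str = "drop_sample"
    out_dir: str | None = None
    seed: int = 0
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.preset is None):
            raise ValueError("supply exactly one of input_path / preset")

    def load_matrix(self) -> CtMatrix:
        if self.input_path is not None:
            return read_ct_table(self.input_path)
        if self.preset != "tmcao":
            raise ValueError(f"unknown preset {self.preset!r}")
        return _simulate(_tmcao_preset(seed=self.seed))


@dataclass(frozen=True)
class BlockReport:
    """All results for one (region, time point) analysis block."""

    block: AnalysisBlock
    stabilities: dict              # method -> StabilityResult
    rank_table: RankTable
    comprehensive: ComprehensiveRanking
    v_profile: metrics.PairwiseVariationProfile


@dataclass(frozen=True)
class ReportBundle:
    """Per-block reports plus the integrated study-level ranking."""

    blocks: list[BlockReport]
    study_ranking: pd.Series
    skipped: dict = field(default_factory=dict)  # block label -> reason

    @property
    def partial(self) -> bool:
        return bool(self.skipped)


def analyse_block(
    b: AnalysisBlock,
    efficiency: float = metrics.DEFAULT_EFFICIENCY,
    sd_exclusion_cutoff: float = metrics.DEFAULT_SD_CUTOFF,
    v_cutoff: float = metrics.DEFAULT_V_CUTOFF,
    use_groups: bool = True,
) -> BlockReport:
    """Four stability methods + ranks + geNorm V for one block."""
    if use_groups and b.group_labels.nunique() < 2:
        logger.info("block %s: single group; NormFinder falls back to ungrouped",
                    b.label)
        use_groups = False
    q = metrics.to_relative_quantities(b, efficiency=efficiency)
    stab = {
        "delta_ct": metrics.delta_ct_stability(b),
        "genorm": metrics.genorm_stability(q),
        "normfinder": metrics.normfinder_s(b, use_groups=use_groups,
                                           efficiency=efficiency),
        "bestkeeper": metrics.bestkeeper(b, sd_exclusion_cutoff=sd_exclusion_cutoff),
    }
    rt = ranks_from_scores(list(stab.values()), region=b.region,
                           time_point=b.time_point)
    comp = comprehensive_ranking(rt, tie_break_scores=stab["delta_ct"].scores)
    v = metrics.genorm_pairwise_v(q, cutoff=v_cutoff)
    return BlockReport(block=b, stabilities=stab, rank_table=rt,
                       comprehensive=comp, v_profile=v)


def run_full_analysis(cfg: RunConfig) -> ReportBundle:
    """Analyse every block of the configured input; write reports if asked.

    Blocks that fail a method precondition (too few samples after missing-
    value handling, all genes excluded, ...) are skipped with a logged
    reason and flagged in the bundle rather than aborting the run.
    """
    m = cfg.load_matrix()
    reports: list[BlockReport] = []
    skipped: dict[str, str] = {}
    for block in iter_blocks(m, composition=cfg.composition):
        try:
            block = drop_missing(block, policy=cfg.missing_policy)
            reports.append(analyse_block(
                block,
                efficiency=cfg.efficiency,
                sd_exclusion_cutoff=cfg.sd_exclusion_cutoff,
                v_cutoff=cfg.v_cutoff,
                use_groups=cfg.use_groups,
            ))
        except (CtDataError, ValueError) as exc:
            logger.error("block %s skipped: %s", block.label, exc)
            skipped[block.label] = str(exc)
    if not reports:
        raise CtDataError("no analysable blocks in the input")
    study = study_level_ranking([r.comprehensive for r in reports])
    bundle = ReportBundle(blocks=reports, study_ranking=study, skipped=skipped)
    if cfg.out_dir is not None:
        write_bundle(bundle, cfg.out_dir, make_plots=cfg.make_plots)
    return bundle


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def stability_frame(bundle: ReportBundle) -> pd.DataFrame:
    """Tidy per-gene results: one row per block x method x gene."""
    rows = []
    for rep in bundle.blocks:
        for method, res in rep.stabilities.items():
            ranks = rep.rank_table.ranks[method]
            for gene in res.scores.index:
                row = {
                    "region": rep.block.region,
                    "time_point": rep.block.time_point,
                    "method": method,
                    "gene": gene,
                    "score": float(res.scores[gene]),
                    "rank": int(ranks[gene]),
                    "excluded": gene in res.excluded,
                }
                if res.aux is not None:
                    for col in ("sd", "cv", "r", "p", "m_at_exclusion",
                                "full_panel_m"):
                        if col in res.aux.columns:
                            row[col] = float(res.aux.at[gene, col])
                rows.append(row)
    return pd.DataFrame(rows)


def comprehensive_frame(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for rep in bundle.blocks:
        frame = rep.comprehensive.as_frame().reset_index(names="gene")
        frame.insert(0, "region", rep.block.region)
        frame.insert(1, "time_point", rep.block.time_point)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


def pairwise_v_frame(bundle: ReportBundle) -> pd.DataFrame:
    rows = []
    for rep in bundle.blocks:
        for n, v in rep.v_profile.v.items():
            rows.append({
                "region": rep.block.region,
                "time_point": rep.block.time_point,
                "n": int(n),
                "v": float(v),
                "recommended_n": rep.v_profile.recommended_n,
                "all_above_cutoff": rep.v_profile.all_above_cutoff,
            })
    return pd.DataFrame(rows)


def write_bundle(bundle: ReportBundle, out_dir, make_plots: bool = False) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stability_frame(bundle).to_csv(out / "stability.csv", index=False)
    comprehensive_frame(bundle).to_csv(out / "comprehensive.csv", index=False)
    pairwise_v_frame(bundle).to_csv(out / "pairwise_v.csv", index=False)
    bundle.study_ranking.rename_axis("gene").reset_index().to_csv(
        out / "study_ranking.csv", index=False)
    summary = {
        "blocks": [r.block.label for r in bundle.blocks],
        "skipped": bundle.skipped,
        "study_order": list(bundle.study_ranking.index),
        "study_geomeans": {g: float(v) for g, v in bundle.study_ranking.items()},
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    if make_plots:
        plot_bundle(bundle, out)


def plot_bundle(bundle: ReportBundle, out_dir) -> None:
    """Optional M-value and V-profile figures (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    fig, axes = plt.subplots(1, 2, figsize=(11, 4))
    for rep in bundle.blocks:
        gn = rep.stabilities["genorm"]
        axes[0].plot(list(gn.order), gn.scores.reindex(list(gn.order)), "o-",
                     label=rep.block.label, alpha=0.6)
        axes[1].plot(rep.v_profile.v.index, rep.v_profile.v.values, "s-",
                     label=rep.block.label, alpha=0.6)
    axes[0].set_ylabel("geNorm M at exclusion")
    axes[0].tick_params(axis="x", rotation=45)
    axes[1].axhline(bundle.blocks[0].v_profile.cutoff, ls="--", c="grey")
    axes[1].set_xlabel("n")
    axes[1].set_ylabel("V(n/n+1)")
    axes[1].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(out / "genorm_profiles.png", dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Aggregation from an external rank table
# ---------------------------------------------------------------------------

def aggregate_from_ranks(source) -> list[ComprehensiveRanking]:
    """Comprehensive rankings from a per-method integer rank table.

    ``source`` is a CSV path or DataFrame with columns region, time_point,
    gene and one integer rank column per method.  Row order is irrelevant;
    each block's column must be a permutation of 1..G (validated by
    :class:`RankTable`).  This is the entry point for checking published
    rank tables.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    needed = {"region", "time_point", "gene"}
    if not needed.issubset(df.columns):
        raise CtDataError(f"rank table needs columns {sorted(needed)}")
    methods = [c for c in df.columns if c not in needed]
    if not methods:
        raise CtDataError("rank table has no method columns")
    out = []
    for (region, tp), sub in df.groupby(["region", "time_point"], sort=True):
        ranks = sub.set_index("gene")[methods].astype(int).sort_index()
        rt = RankTable(region=str(region), time_point=str(tp), ranks=ranks)
        out.append(comprehensive_ranking(rt))
    return out
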