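"""Per-gene expression-variation screen and fold-change reporting.

The screen asks, for each candidate gene within one brain region, whether
its expression differs across the condition x time groups — a gene that
does cannot serve as a reference gene for that region.  The default test
is a one-way ANOVA across the eight SHAM/tMCAO x time groups on
sample-centered log2 expression (centering removes loading differences);
Welch's unequal-variance ANOVA is available behind a flag.

Fold changes are reported tMCAO vs time-matched SHAM as 2**(-ddCt) against
a caller-chosen normalizer gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.oneway import anova_oneway

from .io import CtDataError, CtMatrix

logger = logging.getLogger("refstab")

#: What the ANOVA runs on: raw Ct, sample-centered log2 quantities
#: (the default — robust to loading), or uncentered log2 quantities.
SCREEN_VALUES = ("ct", "centered_log_q", "log_q")


@dataclass(frozen=True)
class GroupEffectReport:
    """ANOVA result for one gene in one region."""

    gene: str
    region: str
    statistic: float
    p_value: float
    stable: bool               # p >= alpha: no detectable group variation
    alpha: float
    group_summary: pd.DataFrame  # per condition x time group: n, mean, sd

    def __repr__(self) -> str:  # keep the embedded frame out of reprs
        return (f"GroupEffectReport(gene={self.gene!r}, region={self.region!r}, "
                f"F={self.statistic:.3f}, p={self.p_value:.4g}, "
                f"stable={self.stable})")


def _screen_values(m: CtMatrix, kind: str) -> pd.DataFrame:
    ct = m.ct
    if kind == "ct":
        return ct
    y = -ct  # log2 quantity up to per-gene constants (efficiency 2)
    if kind == "log_q":
        return y
    return y.sub(y.mean(axis=1), axis=0)  # centered_log_q


def variation_screen(
    m: CtMatrix,
    region: str,
    alpha: float = 0.05,
    value: str = "centered_log_q",
    welch: bool = False,
) -> list[GroupEffectReport]:
    """One-way ANOVA per gene across condition x time groups of a region."""
    if value not in SCREEN_VALUES:
        raise ValueError(f"value must be one of {SCREEN_VALUES}")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    mask = m.meta["region"] == region
    if not mask.any():
        raise CtDataError(f"region {region!r} not present")
    meta = m.meta.loc[mask]
    data = _screen_values(CtMatrix(ct=m.ct.loc[mask], meta=meta), value)
    if data.isna().to_numpy().any():
        raise CtDataError("variation_screen requires complete data; drop missing first")
    groups = meta["condition"] + ":" + meta["time_point"]
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise CtDataError(f"region {region}: need >= 2 condition x time groups")
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise CtDataError(f"region {region}: group(s) {small} have < 2 samples")

    reports = []
    for gene in data.columns:
        per_group = [data.loc[groups == g, gene].to_numpy() for g in sizes.index]
        res = anova_oneway(per_group, use_var="unequal" if welch else "equal",
                           welch_correction=welch)
        summary = pd.DataFrame({
            "n": [len(v) for v in per_group],
            "mean": [float(np.mean(v)) for v in per_group],
            "sd": [float(np.std(v, ddof=1)) for v in per_group],
        }, index=pd.Index(sizes.index, name="group")).sort_index()
        reports.append(GroupEffectReport(
            gene=gene,
            region=region,
            statistic=float(res.statistic),
            p_value=float(res.pvalue),
            stable=bool(res.pvalue >= alpha),
            alpha=alpha,
            group_summary=summary,
        ))
    return reports


def screen_frame(reports: list[GroupEffectReport]) -> pd.DataFrame:
    """Tidy one-row-per-gene summary of a variation screen."""
    return pd.DataFrame({
        "region": [r.region for r in reports],
        "gene": [r.gene for r in reports],
        "statistic": [r.statistic for r in reports],
        "p_value": [r.p_value for r in reports],
        "stable": [r.stable for r in reports],
    })


def fold_change(
    m: CtMatrix,
    gene: str,
    region: str,
    normalizer,
) -> pd.Series:
    """tMCAO vs time-matched SHAM fold change of ``gene`` in ``region``.

    Per sample ``dCt = Ct_gene - mean(Ct_normalizers)``; per time point the
    fold change is ``2**-(mean dCt_tMCAO - mean dCt_SHAM)``.  Values above
    1 mean up-regulation after occlusion.
    """
    normalizer = list(normalizer)
    if not normalizer:
        raise ValueError("normalizer gene set is empty")
    if gene in normalizer:
        raise ValueError(f"{gene!r} cannot normalize itself")
    missing = [g for g in [gene, *normalizer] if g not in m.ct.columns]
    if missing:
        raise CtDataError(f"gene(s) {missing} not in the Ct matrix")
    mask = m.meta["region"] == region
    if not mask.any():
        raise CtDataError(f"region {region!r} not present")
    ct = m.ct.loc[mask]
    meta = m.meta.loc[mask]
    dct = ct[gene] - ct[normalizer].mean(axis=1)

    out = {}
    for tp in pd.unique(meta["time_point"]):
        sel = meta["time_point"] == tp
        sham = dct[sel & (meta["condition"] == "SHAM")]
        mcao = dct[sel & (meta["condition"] == "tMCAO")]
        if sham.empty or mcao.empty:
            logger.warning("fold_change: time point %s lacks a SHAM or tMCAO arm; "
                           "skipped", tp)
            continue
        out[tp] = float(2.0 ** -(mcao.mean() - sham.mean()))
    if not out:
        raise CtDataError(f"no time point with both conditions in region {region}")
    return pd.Series(out, name=f"fold_{gene}")
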