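"""Ct data model, tabular readers/writers and analysis-block slicing.

A :class:`CtMatrix` holds one quantification-cycle (Ct/Cq) value per
biological sample and candidate gene, together with the design metadata of
a focal cerebral ischaemia (tMCAO) study: condition (SHAM vs tMCAO
surgery), time after reperfusion and brain region.  Every stability metric
in :mod:`refstab.metrics` consumes an :class:`AnalysisBlock` — the samples
of a single region at a single time point.

Ct values are assumed to be technical-replicate-collapsed (one Ct per
sample x gene); replicate averaging happens upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("refstab")

#: Closed label vocabularies (case-sensitive) — a mis-typed token must fail
#: loudly rather than silently create a new experimental group.
CONDITIONS = ("SHAM", "tMCAO")
TIME_POINTS = ("12h", "24h", "3d", "7d")
REGIONS = ("CX", "HIP", "DS")

#: The six candidate reference genes of the rat tMCAO panel.
DEFAULT_GENES = ("Ywhaz", "Ppia", "Gapdh", "Hprt1", "Actb", "B2m")

META_COLUMNS = ("condition", "time_point", "region")

#: Physically plausible Ct range (PCR cycles).
CT_MIN, CT_MAX = 0.0, 45.0


class CtDataError(ValueError):
    """Raised for malformed Ct tables or invalid design metadata."""


@dataclass(frozen=True)
class CtMatrix:
    """Samples x genes Ct values plus per-sample design metadata.

    Parameters
    ----------
    ct
        DataFrame indexed by unique sample id, one float column per gene.
        Missing measurements are ``NaN`` (never zero).
    meta
        DataFrame with the same index and columns ``condition``,
        ``time_point`` and ``region`` drawn from the closed vocabularies.
    """

    ct: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ct.index.equals(self.meta.index):
            raise CtDataError("ct and meta must share the same sample index")
        if self.ct.index.has_duplicates:
            dupes = self.ct.index[self.ct.index.duplicated()].unique().tolist()
            raise CtDataError(f"duplicate sample_id values: {dupes}")
        if self.ct.columns.has_duplicates:
            raise CtDataError("duplicate gene columns")
        for col in META_COLUMNS:
            if col not in self.meta.columns:
                raise CtDataError(f"metadata column {col!r} missing")
        _check_tokens(self.meta["condition"], CONDITIONS, "condition")
        _check_tokens(self.meta["time_point"], TIME_POINTS, "time_point")
        _check_tokens(self.meta["region"], REGIONS, "region")
        vals = self.ct.to_numpy(dtype=float)
        finite = np.isfinite(vals)
        bad = finite & ((vals <= CT_MIN) | (vals > CT_MAX))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise CtDataError(
                f"Ct value {vals[i, j]} for sample {self.ct.index[i]!r}, gene "
                f"{self.ct.columns[j]!r} outside plausible range ({CT_MIN}, {CT_MAX}]"
            )

    # -- convenience views -------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def genes(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def n_samples(self) -> int:
        return self.ct.shape[0]

    @property
    def values(self) -> np.ndarray:
        return self.ct.to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.ct.isna().to_numpy().any())


@dataclass(frozen=True)
class AnalysisBlock:
    """A CtMatrix restricted to one region and one time point.

    ``group_labels`` is the per-sample grouping used by NormFinder and the
    default is the surgical condition (SHAM vs tMCAO).
    """

    matrix: CtMatrix
    region: str
    time_point: str
    group_labels: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        meta = self.matrix.meta
        if not (meta["region"] == self.region).all():
            raise CtDataError("block samples must share one region")
        if not (meta["time_point"] == self.time_point).all():
            raise CtDataError("block samples must share one time point")
        if self.group_labels is None:
            object.__setattr__(self, "group_labels", meta["condition"].copy())
        if not self.group_labels.index.equals(self.matrix.ct.index):
            raise CtDataError("group_labels index must match the sample index")

    @property
    def ct(self) -> pd.DataFrame:
        return self.matrix.ct

    @property
    def genes(self) -> list[str]:
        return self.matrix.genes

    @property
    def n_samples(self) -> int:
        return self.matrix.n_samples

    @property
    def label(self) -> str:
        return f"{self.region}-{self.time_point}"

    def group_sizes(self) -> dict[str, int]:
        return self.group_labels.value_counts().to_dict()


def _check_tokens(series: pd.Series, allowed: tuple[str, ...], name: str) -> None:
    bad = sorted(set(series) - set(allowed))
    if bad:
        raise CtDataError(
            f"unknown {name} token(s) {bad}; allowed tokens are {list(allowed)}"
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

_MISSING_TOKENS = {"", "NA", "NaN", "nan", "N/A", "ND", "Undetermined"}


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_ct_table(path, gene_columns=None, aliases=None) -> CtMatrix:
    """Read a wide Ct table (one row per sample, one column per gene).

    The header must contain ``sample_id``, the design columns and the gene
    columns.  ``gene_columns=None`` treats every non-metadata column as a
    gene.  ``aliases`` optionally maps input metadata tokens to canonical
    ones (e.g. ``{"sham": "SHAM"}``) before validation.
    """
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = ["sample_id", *META_COLUMNS]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise CtDataError(f"{path}: missing required column(s) {missing}")
    if gene_columns is None:
        gene_columns = [c for c in raw.columns if c not in required]
    else:
        absent = [g for g in gene_columns if g not in raw.columns]
        if absent:
            raise CtDataError(f"{path}: gene column(s) {absent} not in header")
    if not gene_columns:
        raise CtDataError(f"{path}: no gene columns found")

    if raw["sample_id"].duplicated().any():
        dupes = raw.loc[raw["sample_id"].duplicated(), "sample_id"].unique().tolist()
        raise CtDataError(f"{path}: duplicate sample_id values: {dupes}")

    meta = raw[list(META_COLUMNS)].copy()
    if aliases:
        meta = meta.replace(aliases)
    meta.index = pd.Index(raw["sample_id"], name="sample_id")

    ct = pd.DataFrame(index=meta.index, columns=list(gene_columns), dtype=float)
    for gene in gene_columns:
        for row, (sid, cell) in enumerate(zip(raw["sample_id"], raw[gene])):
            cell = cell.strip()
            if cell in _MISSING_TOKENS:
                ct.loc[sid, gene] = np.nan
                continue
            try:
                ct.loc[sid, gene] = float(cell)
            except ValueError:
                raise CtDataError(
                    f"{path}: non-numeric Ct {cell!r} at row {row + 2}, "
                    f"column {gene!r}"
                ) from None
    return CtMatrix(ct=ct, meta=meta)


def read_long_table(path, aliases=None) -> CtMatrix:
    """Read a long-format table with columns sample_id, gene, ct (+ metadata)."""
    raw = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    required = ["sample_id", "gene", "ct", *META_COLUMNS]
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise CtDataError(f"{path}: missing required column(s) {missing}")
    if raw.duplicated(subset=["sample_id", "gene"]).any():
        raise CtDataError(f"{path}: duplicate (sample_id, gene) entries")
    ct_num = raw["ct"].str.strip().map(
        lambda c: np.nan if c in _MISSING_TOKENS else float(c)
    )
    wide = raw.assign(_ct=ct_num).pivot(index="sample_id", columns="gene", values="_ct")
    wide.columns.name = None
    meta = raw.drop_duplicates("sample_id").set_index("sample_id")[list(META_COLUMNS)]
    meta = meta.reindex(wide.index)
    if aliases:
        meta = meta.replace(aliases)
    return CtMatrix(ct=wide, meta=meta)


def write_ct_table(m: CtMatrix, path) -> None:
    """Write a CtMatrix back to the wide CSV/TSV dialect of read_ct_table."""
    out = pd.concat([m.meta, m.ct], axis=1)
    out.index.name = "sample_id"
    out.to_csv(path, sep=_sep_for(path), na_rep="NA")


# ---------------------------------------------------------------------------
# Slicing
# ---------------------------------------------------------------------------

def slice_block(
    m: CtMatrix,
    region: str,
    time_point: str,
    composition: str = "pooled",
) -> AnalysisBlock:
    """Extract the (region, time point) analysis block.

    ``composition='pooled'`` keeps SHAM and tMCAO samples together (the
    default; 2 x n animals per block); ``'tmcao_only'`` restricts to the
    occluded animals.
    """
    if region not in set(m.meta["region"]):
        raise CtDataError(f"region {region!r} not present in the data")
    if time_point not in set(m.meta["time_point"]):
        raise CtDataError(f"time_point {time_point!r} not present in the data")
    if composition not in ("pooled", "tmcao_only"):
        raise CtDataError(f"unknown block composition {composition!r}")
    mask = (m.meta["region"] == region) & (m.meta["time_point"] == time_point)
    if composition == "tmcao_only":
        mask &= m.meta["condition"] == "tMCAO"
    if not mask.any():
        raise CtDataError(f"no samples for block ({region}, {time_point})")
    sub = CtMatrix(ct=m.ct.loc[mask].copy(), meta=m.meta.loc[mask].copy())
    return AnalysisBlock(matrix=sub, region=region, time_point=time_point)


def iter_blocks(m: CtMatrix, composition: str = "pooled"):
    """Yield every (region, time point) block present in the matrix.

    Regions iterate in canonical order (CX, HIP, DS) then time points
    (12h, 24h, 3d, 7d), so reports are deterministic.
    """
    present = set(zip(m.meta["region"], m.meta["time_point"]))
    for region in REGIONS:
        for tp in TIME_POINTS:
            if (region, tp) in present:
                yield slice_block(m, region, tp, composition=composition)


def drop_missing(b: AnalysisBlock, policy: str = "drop_sample") -> AnalysisBlock:
    """Handle missing Ct values in a block.

    ``drop_sample`` removes (and logs) every sample with at least one
    missing value; ``error`` aborts on any missing value.  Fewer than three
    remaining samples is an error under either policy.
    """
    if policy not in ("drop_sample", "error"):
        raise CtDataError(f"unknown missing-data policy {policy!r}")
    na_mask = b.ct.isna().any(axis=1)
    if not na_mask.any():
        return b
    if policy == "error":
        sid = b.ct.index[na_mask][0]
        raise CtDataError(f"block {b.label}: sample {sid!r} has missing Ct values")
    keep = ~na_mask
    if int(keep.sum()) < 3:
        raise CtDataError(
            f"block {b.label}: only {int(keep.sum())} samples remain after "
            "dropping samples with missing values (need >= 3)"
        )
    dropped = list(b.ct.index[na_mask])
    logger.warning("block %s: dropped %d sample(s) with missing Ct: %s",
                   b.label, len(dropped), dropped)
    sub = CtMatrix(ct=b.ct.loc[keep].copy(), meta=b.matrix.meta.loc[keep].copy())
    return AnalysisBlock(
        matrix=sub,
        region=b.region,
        time_point=b.time_point,
        group_labels=b.group_labels.loc[keep].copy(),
    )


def require_block_shape(b: AnalysisBlock, min_genes: int = 2, min_samples: int = 3) -> None:
    """Validate the minimum shape every stability computation needs."""
    if len(b.genes) < min_genes:
        raise CtDataError(f"block {b.label}: need >= {min_genes} genes")
    if b.n_samples < min_samples:
        raise CtDataError(f"block {b.label}: need >= {min_samples} samples")
    if b.matrix.has_missing():
        raise CtDataError(
            f"block {b.label}: missing Ct values present; apply drop_missing first"
        )
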