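"""Published stability rankings from a rat tMCAO reference-gene study.

Six candidate reference genes (Ywhaz, Ppia, Gapdh, Hprt1, Actb, B2m) were
ranked by four stability methods in 12 analysis blocks (three brain
regions x four post-reperfusion time points) and aggregated by the
geometric mean of rank positions.  The raw Ct data were never deposited,
so the printed per-method orderings, BestKeeper statistics and
comprehensive geomeans reproduced here are the only quantitative surface
against which the aggregation pipeline can be checked.

Each row of the table mirrors one printed row: the gene occupying one rank
position in each method's column of one block.  ``bk_bold`` records which
BestKeeper entries were typeset bold (the study's instability flag; note
one bold gene, CX 12h B2m, has SD < 1 — the flag and the SD rule disagree
there and this module takes no position).
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd

from .ranking import RankTable, round_half_up

#: Printed table, one row per (block, rank position).  Columns: the gene at
#: that position in the comprehensive / dCt / BestKeeper / NormFinder /
#: geNorm columns with each method's printed statistic.
_TABLE = """\
region,time_point,position,comp_gene,comp_geomean,dct_gene,dct_score,bk_gene,bk_sd,bk_cv,bk_r,bk_bold,nf_gene,nf_s,gn_gene,gn_m
CX,12h,1,Ywhaz,1.00,Ywhaz,0.45,Ywhaz,0.69,2.50,0.967,0,Ywhaz,0.151,Ywhaz,0.262
CX,12h,2,Ppia,2.00,Ppia,0.46,Ppia,0.68,2.81,0.961,0,Ppia,0.181,Ppia,0.262
CX,12h,3,Hprt1,3.22,Gapdh,0.50,Hprt1,0.80,2.86,0.958,0,Hprt1,0.295,Hprt1,0.303
CX,12h,4,Gapdh,3.72,Hprt1,0.51,Gapdh,0.50,2.19,0.921,0,Gapdh,0.300,Gapdh,0.341
CX,12h,5,B2m,5.00,B2m,0.66,B2m,0.43,1.81,0.763,1,B2m,0.550,B2m,0.440
CX,12h,6,Actb,6.00,Actb,0.82,Actb,1.05,4.41,0.877,0,Actb,0.753,Actb,0.567
CX,24h,1,Ppia,1.32,Ppia,0.55,Ywhaz,0.54,1.98,0.894,0,Ppia,0.224,Ppia,0.252
CX,24h,2,Hprt1,2.38,Hprt1,0.57,Gapdh,0.58,2.50,0.830,0,Hprt1,0.284,Hprt1,0.252
CX,24h,3,Ywhaz,2.45,Ywhaz,0.64,Ppia,0.33,1.47,0.728,0,Ywhaz,0.432,Gapdh,0.433
CX,24h,4,Gapdh,3.50,Actb,0.69,Hprt1,0.32,1.23,0.650,0,Actb,0.501,Ywhaz,0.497
CX,24h,5,Actb,4.47,Gapdh,0.71,Actb,0.40,1.69,0.456,0,Gapdh,0.586,Actb,0.583
CX,24h,6,B2m,6.00,B2m,0.83,B2m,0.42,1.88,0.001,0,B2m,0.738,B2m,0.666
CX,3d,1,Ppia,1.32,Ppia,0.65,Ppia,0.98,4.46,0.974,0,Ppia,0.109,Ywhaz,0.372
CX,3d,2,Ywhaz,1.68,Ywhaz,0.69,Ywhaz,0.92,3.62,0.934,0,Ywhaz,0.367,Hprt1,0.372
CX,3d,3,Hprt1,2.71,Hprt1,0.70,Hprt1,0.81,3.16,0.925,0,Hprt1,0.391,Ppia,0.434
CX,3d,4,Gapdh,4.47,Actb,0.80,Gapdh,0.63,2.90,0.745,0,Actb,0.541,Gapdh,0.584
CX,3d,5,Actb,4.68,Gapdh,0.95,Actb,1.13,5.20,0.939,1,Gapdh,0.841,Actb,0.691
CX,3d,6,B2m,6.00,B2m,1.03,B2m,1.46,6.70,0.931,1,B2m,0.945,B2m,0.804
CX,7d,1,Hprt1,1.00,Hprt1,0.65,Hprt1,0.37,1.54,0.873,0,Hprt1,0.221,Hprt1,0.477
CX,7d,2,Ppia,2.63,Ppia,0.76,Actb,0.66,3.28,0.851,0,Ppia,0.365,Ywhaz,0.477
CX,7d,3,Actb,3.08,Actb,0.81,Ppia,0.42,2.06,0.714,0,Actb,0.463,Gapdh,0.509
CX,7d,4,Ywhaz,3.36,Ywhaz,0.81,Ywhaz,0.49,2.09,0.496,0,Ywhaz,0.603,Ppia,0.599
CX,7d,5,Gapdh,4.40,Gapdh,0.85,Gapdh,0.47,2.25,0.338,0,Gapdh,0.665,Actb,0.656
CX,7d,6,B2m,6.00,B2m,1.25,B2m,1.22,6.04,0.838,1,B2m,1.179,B2m,0.855
HIP,12h,1,Ppia,1.19,Ppia,0.25,Actb,0.28,1.42,0.933,0,Ppia,0.076,Ppia,0.144
HIP,12h,2,Gapdh,2.21,Gapdh,0.26,Ppia,0.18,0.90,0.872,0,Gapdh,0.107,Gapdh,0.144
HIP,12h,3,Actb,2.28,Actb,0.27,Gapdh,0.20,1.02,0.856,0,Actb,0.156,Actb,0.182
HIP,12h,4,Hprt1,4.23,Hprt1,0.31,Ywhaz,0.26,1.26,0.671,0,Hprt1,0.213,Hprt1,0.221
HIP,12h,5,Ywhaz,4.73,Ywhaz,0.35,Hprt1,0.17,0.78,0.495,0,Ywhaz,0.292,Ywhaz,0.254
HIP,12h,6,B2m,6.00,B2m,0.43,B2m,0.26,1.25,0.138,0,B2m,0.394,B2m,0.313
HIP,24h,1,Ppia,1.68,B2m,0.29,Ywhaz,0.35,1.71,0.896,0,B2m,0.144,Ppia,0.168
HIP,24h,2,B2m,1.73,Ppia,0.30,Ppia,0.33,1.62,0.884,0,Ppia,0.177,Ywhaz,0.168
HIP,24h,3,Ywhaz,2.06,Ywhaz,0.31,B2m,0.26,1.25,0.857,0,Ywhaz,0.194,B2m,0.254
HIP,24h,4,Actb,4.23,Actb,0.32,Gapdh,0.39,1.99,0.848,0,Actb,0.215,Actb,0.268
HIP,24h,5,Gapdh,4.73,Gapdh,0.36,Actb,0.34,1.67,0.844,0,Gapdh,0.301,Gapdh,0.289
HIP,24h,6,Hprt1,6.00,Hprt1,0.42,Hprt1,0.22,0.96,0.385,0,Hprt1,0.368,Hprt1,0.332
HIP,3d,1,Gapdh,1.00,Gapdh,0.37,Gapdh,0.28,1.44,0.960,0,Gapdh,0.139,Gapdh,0.279
HIP,3d,2,Ywhaz,2.91,Ywhaz,0.45,Hprt1,0.65,2.80,0.896,0,Ppia,0.274,Ppia,0.279
HIP,3d,3,Ppia,2.99,Actb,0.45,Ywhaz,0.45,2.15,0.893,0,Actb,0.277,Ywhaz,0.325
HIP,3d,4,Actb,3.46,Ppia,0.46,Actb,0.47,2.24,0.890,0,Ywhaz,0.278,Actb,0.370
HIP,3d,5,Hprt1,3.97,Hprt1,0.54,Ppia,0.36,1.73,0.778,0,Hprt1,0.464,Hprt1,0.405
HIP,3d,6,B2m,6.00,B2m,0.66,B2m,0.32,1.48,0.131,0,B2m,0.603,B2m,0.489
HIP,7d,1,Ywhaz,1.00,Ywhaz,0.66,Ywhaz,0.51,2.26,0.946,0,Ywhaz,0.146,Ywhaz,0.293
HIP,7d,2,Hprt1,2.00,Hprt1,0.69,Hprt1,0.63,2.55,0.914,0,Hprt1,0.207,Hprt1,0.293
HIP,7d,3,Actb,3.00,Actb,0.84,Actb,0.82,3.58,0.826,0,Actb,0.557,Actb,0.459
HIP,7d,4,B2m,4.00,B2m,0.85,B2m,0.78,3.44,0.825,0,B2m,0.572,B2m,0.572
HIP,7d,5,Ppia,5.23,Ppia,1.10,Gapdh,0.68,3.17,0.501,0,Ppia,0.954,Ppia,0.746
HIP,7d,6,Gapdh,5.73,Gapdh,1.16,Ppia,0.68,3.00,0.364,0,Gapdh,1.038,Gapdh,0.883
DS,12h,1,Hprt1,1.32,Hprt1,0.81,Hprt1,0.28,1.10,0.809,0,Hprt1,0.206,Ppia,0.406
DS,12h,2,Ppia,1.68,Ppia,0.90,Ppia,0.58,2.56,0.722,0,Ppia,0.377,Ywhaz,0.406
DS,12h,3,Ywhaz,2.91,Ywhaz,0.90,Actb,0.80,3.72,0.511,0,Ywhaz,0.450,Hprt1,0.460
DS,12h,4,Gapdh,4.23,Gapdh,1.00,Ywhaz,0.52,2.28,0.553,0,Gapdh,0.623,Gapdh,0.550
DS,12h,5,Actb,4.40,Actb,1.27,Gapdh,0.33,1.59,0.129,0,Actb,1.064,Actb,0.792
DS,12h,6,B2m,4.73,B2m,1.71,B2m,1.43,6.25,0.823,1,B2m,1.602,B2m,1.097
DS,24h,1,Ppia,1.00,Ppia,0.91,Ppia,0.70,3.17,0.938,0,Ppia,0.201,Ppia,0.402
DS,24h,2,Hprt1,2.21,Hprt1,1.00,Ywhaz,0.91,4.05,0.851,0,Hprt1,0.464,Hprt1,0.402
DS,24h,3,Ywhaz,2.71,Ywhaz,1.04,Hprt1,0.56,2.23,0.832,0,Ywhaz,0.525,Ywhaz,0.632
DS,24h,4,B2m,4.42,B2m,1.25,Actb,0.61,2.99,0.209,0,B2m,0.929,B2m,0.865
DS,24h,5,Gapdh,5.00,Gapdh,1.46,Gapdh,1.86,8.53,0.969,1,Gapdh,1.273,Gapdh,1.040
DS,24h,6,Actb,5.42,Actb,1.52,B2m,1.20,5.34,0.867,1,Actb,1.369,Actb,1.199
DS,3d,1,Gapdh,1.32,Gapdh,0.72,Gapdh,0.68,3.41,0.897,0,Gapdh,0.389,Ywhaz,0.286
DS,3d,2,Hprt1,2.00,Hprt1,0.73,Hprt1,0.92,3.76,0.897,0,Hprt1,0.483,Hprt1,0.286
DS,3d,3,Ywhaz,2.28,Ywhaz,0.74,Ywhaz,0.74,3.40,0.841,0,Ywhaz,0.522,Gapdh,0.415
DS,3d,4,B2m,4.23,B2m,0.78,Ppia,0.49,2.41,0.836,0,B2m,0.529,B2m,0.626
DS,3d,5,Actb,5.23,Actb,0.89,B2m,1.06,5.27,0.937,1,Actb,0.723,Actb,0.716
DS,3d,6,Ppia,5.42,Ppia,0.99,Actb,1.18,6.22,0.923,1,Ppia,0.834,Ppia,0.809
DS,7d,1,Ppia,1.00,Ppia,0.77,Ppia,0.25,1.22,0.867,0,Ppia,0.170,Ppia,0.314
DS,7d,2,Hprt1,2.00,Hprt1,0.79,Hprt1,0.35,1.44,0.736,0,Hprt1,0.278,Hprt1,0.314
DS,7d,3,Ywhaz,3.00,Ywhaz,0.89,Ywhaz,0.34,1.56,0.184,0,Ywhaz,0.709,Ywhaz,0.364
DS,7d,4,Gapdh,4.00,Gapdh,0.93,Gapdh,0.27,1.33,0.043,0,Gapdh,0.739,Gapdh,0.404
DS,7d,5,Actb,5.23,Actb,1.12,B2m,1.74,9.04,0.955,1,Actb,0.761,Actb,0.725
DS,7d,6,B2m,5.73,B2m,1.61,Actb,1.17,6.27,0.952,1,B2m,1.564,B2m,1.020
"""

#: Method label -> (gene column, statistic column) in the tidy table.
METHOD_COLUMNS = {
    "delta_ct": ("dct_gene", "dct_score"),
    "bestkeeper": ("bk_gene", "bk_sd"),
    "normfinder": ("nf_gene", "nf_s"),
    "genorm": ("gn_gene", "gn_m"),
}

BLOCKS = [(r, t) for r in ("CX", "HIP", "DS") for t in ("12h", "24h", "3d", "7d")]


def published_rankings() -> pd.DataFrame:
    """The printed ranking table, tidy: one row per (block, rank position)."""
    df = pd.read_csv(_io.StringIO(_TABLE))
    df["bk_bold"] = df["bk_bold"].astype(bool)
    return df


def published_rank_tables() -> list[RankTable]:
    """Per-block integer rank tables implied by the printed column orders.

    The printed position of a gene inside each method's column is taken as
    its integer rank — the convention the published comprehensive geomeans
    are built on (tied geNorm top pairs and BestKeeper-excluded genes all
    occupy distinct printed positions).
    """
    df = published_rankings()
    tables = []
    for region, tp in BLOCKS:
        sub = df[(df.region == region) & (df.time_point == tp)]
        genes = sorted(sub["comp_gene"])
        ranks = {}
        for method, (gcol, _) in METHOD_COLUMNS.items():
            ranks[method] = pd.Series(
                sub["position"].values, index=sub[gcol].values
            ).reindex(genes).astype(int)
        tables.append(RankTable(region=region, time_point=tp,
                                ranks=pd.DataFrame(ranks)))
    return tables


def published_comprehensive() -> pd.DataFrame:
    """Printed comprehensive geomeans: region, time_point, gene, geomean, position."""
    df = published_rankings()
    return df[["region", "time_point", "position", "comp_gene", "comp_geomean"]].rename(
        columns={"comp_gene": "gene", "comp_geomean": "geomean"}
    )


def published_bestkeeper_stats() -> pd.DataFrame:
    """Printed BestKeeper statistics (SD, CV, r) with printed positions."""
    df = published_rankings()
    return df[["region", "time_point", "position", "bk_gene", "bk_sd", "bk_cv",
               "bk_r", "bk_bold"]].rename(columns={"bk_gene": "gene"})


def verify_published_geomeans(tol: float = 0.005) -> pd.DataFrame:
    """Recompute every comprehensive geomean from the printed ranks.

    Returns one row per (block, gene) with the printed value, the geometric
    mean of the four printed rank positions (rounded half-up to 2 decimals,
    as printed) and a ``consistent`` flag.  Inconsistent cells are reported,
    never corrected: they indicate typesetting or arithmetic slips in the
    source table.
    """
    printed = published_comprehensive().set_index(["region", "time_point", "gene"])
    rows = []
    for rt in published_rank_tables():
        gm = rt.ranks.apply(
            lambda r: round_half_up(float(np.exp(np.log(r.astype(float)).mean()))),
            axis=1,
        )
        for gene, val in gm.items():
            ref = printed.loc[(rt.region, rt.time_point, gene), "geomean"]
            rows.append({
                "region": rt.region,
                "time_point": rt.time_point,
                "gene": gene,
                "printed_geomean": float(ref),
                "computed_geomean": float(val),
                "consistent": abs(float(val) - float(ref)) <= tol,
            })
    return pd.DataFrame(rows)
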