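"""Naive, loop-based reference implementations of every statistic.

These deliberately avoid numpy vectorization and the package's own code
paths: plain Python loops over explicit definitions, used as independent
oracles in the tests.
"""

from __future__ import annotations

import math


def mean(xs):
    xs = list(xs)
    return sum(xs) / len(xs)


def sd(xs):
    """Sample standard deviation, n-1 denominator."""
    xs = list(xs)
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / (len(xs) - 1))


def pearson(xs, ys):
    mx, my = mean(xs), mean(ys)
    num = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    den = math.sqrt(sum((x - mx) ** 2 for x in xs)
                    * sum((y - my) ** 2 for y in ys))
    return num / den


def geomean(xs):
    xs = list(xs)
    prod = 1.0
    for x in xs:
        prod *= x
    return prod ** (1.0 / len(xs))


def delta_ct_scores(ct_rows, genes):
    """ct_rows: list of per-sample dicts gene -> Ct."""
    scores = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            sds.append(sd([row[j] - row[k] for row in ct_rows]))
        scores[j] = mean(sds)
    return scores


def genorm_m(q_rows, genes):
    """q_rows: list of per-sample dicts gene -> relative quantity."""
    m = {}
    for j in genes:
        vs = []
        for k in genes:
            if k == j:
                continue
            vs.append(sd([math.log2(row[j] / row[k]) for row in q_rows]))
        m[j] = mean(vs)
    return m


def genorm_v(q_rows, order):
    """V(n/n+1) for n = 2..G-1, from the definition via normalization factors."""
    out = {}
    for n in range(2, len(order)):
        ratios = []
        for row in q_rows:
            nf_n = geomean([row[g] for g in order[:n]])
            nf_n1 = geomean([row[g] for g in order[:n + 1]])
            ratios.append(math.log2(nf_n / nf_n1))
        out[n] = sd(ratios)
    return out


def bestkeeper(ct_rows, genes, cutoff=1.0):
    """Per-gene SD/CV, SD-based exclusion, index correlation."""
    res = {}
    for g in genes:
        vals = [row[g] for row in ct_rows]
        res[g] = {"sd": sd(vals), "cv": 100.0 * sd(vals) / mean(vals)}
    kept = [g for g in genes if res[g]["sd"] <= cutoff]
    index = [geomean([row[g] for g in kept]) for row in ct_rows]
    for g in genes:
        res[g]["excluded"] = g not in kept
        res[g]["r"] = pearson([row[g] for row in ct_rows], index)
    return res


def normfinder(y_rows, genes, groups):
    """Grouped NormFinder stability from the model formulas, all loops.

    y_rows: per-sample dicts gene -> log2 quantity; groups: per-sample
    labels aligned with y_rows.
    """
    G = len(genes)
    labels = sorted(set(groups), key=list(groups).index)
    J = len(labels)

    sigma2, zbar, n_j = {}, {}, {}
    for lab in labels:
        rows = [r for r, gl in zip(y_rows, groups) if gl == lab]
        n = len(rows)
        n_j[lab] = n
        # double-centered residuals
        sample_means = [mean(r[g] for g in genes) for r in rows]
        gene_means = {g: mean(r[g] for r in rows) for g in genes}
        grand = mean(sample_means)
        u = {}
        for g in genes:
            rs = [rows[i][g] - sample_means[i] - gene_means[g] + grand
                  for i in range(n)]
            u[g] = sum(x * x for x in rs) / (n - 1)
        ubar = mean(u.values())
        for g in genes:
            sigma2[(g, lab)] = max(0.0, (G / (G - 2)) * (u[g] - ubar / (G - 1)))
        for g in genes:
            zbar[(g, lab)] = mean(r[g] - mean(r[k] for k in genes) for r in rows)

    d = {}
    for g in genes:
        for lab in labels:
            d[(g, lab)] = zbar[(g, lab)] - mean(zbar[(g, l)] for l in labels)
    for lab in labels:
        offset = mean(d[(g, lab)] for g in genes)
        for g in genes:
            d[(g, lab)] -= offset

    samp_var = {k: sigma2[k] / n_j[k[1]] for k in d}
    gamma2 = max(0.0, sum(v * v for v in d.values()) / ((G - 1) * (J - 1))
                 - mean(samp_var.values()))

    s = {}
    for g in genes:
        rhos = []
        for lab in labels:
            sv = samp_var[(g, lab)]
            shrink = gamma2 / (gamma2 + sv) if (gamma2 + sv) > 0 else 0.0
            rhos.append(abs(d[(g, lab)] * shrink) + math.sqrt(sv))
        s[g] = mean(rhos)
    return s


def normfinder_ungrouped(y_rows, genes):
    """Ungrouped stability: corrected SD of sample-centered values."""
    G = len(genes)
    n = len(y_rows)
    sample_means = [mean(r[g] for g in genes) for r in y_rows]
    gene_means = {g: mean(r[g] for r in y_rows) for g in genes}
    grand = mean(sample_means)
    u = {}
    for g in genes:
        rs = [y_rows[i][g] - sample_means[i] - gene_means[g] + grand
              for i in range(n)]
        u[g] = sum(x * x for x in rs) / (n - 1)
    ubar = mean(u.values())
    return {g: math.sqrt(max(0.0, (G / (G - 2)) * (u[g] - ubar / (G - 1))))
            for g in genes}
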