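import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import refstab as rs
import oracles
from conftest import make_block, random_block

GENES3 = ["Ppia", "Hprt1", "Actb"]


def block_to_rows(b):
    return [row._asdict() if hasattr(row, "_asdict") else dict(row)
            for _, row in b.ct.iterrows()]


# ---------------------------------------------------------------------------
# Relative quantities
# ---------------------------------------------------------------------------

class TestRelativeQuantities:
    def test_closed_form_efficiency_two(self):
        b = make_block([[20.0, 25.0], [21.0, 25.0], [22.0, 25.0]],
                       ["a_gene", "b_gene"])
        q = rs.to_relative_quantities(b, efficiency=2.0)
        np.testing.assert_allclose(q.q["a_gene"], [1.0, 0.5, 0.25])
        np.testing.assert_allclose(q.q["b_gene"], 1.0)  # constant gene -> all 1

    def test_closed_form_other_efficiency(self):
        b = make_block([[20.0, 24.0], [21.0, 25.0], [22.0, 23.0]],
                       ["a_gene", "b_gene"])
        q = rs.to_relative_quantities(b, efficiency=1.9)
        assert q.q["a_gene"].iloc[1] == pytest.approx(1 / 1.9)
        assert (q.q.max(axis=0) == 1.0).all()
        assert ((q.q > 0) & (q.q <= 1)).all().all()

    def test_efficiency_at_most_one_rejected(self):
        b = make_block(np.full((3, 2), 20.0), ["a_gene", "b_gene"])
        with pytest.raises(ValueError, match="efficiency"):
            rs.to_relative_quantities(b, efficiency=1.0)


# ---------------------------------------------------------------------------
# Comparative dCt
# ---------------------------------------------------------------------------

class TestDeltaCt:
    def test_zero_variance_pair_halves_score(self):
        # gene B = gene A + 1 cycle exactly, so SD(A-B) = 0 and A's score
        # is half its SD against C.
        rng = np.random.default_rng(3)
        a = 20 + rng.normal(0, 0.5, 8)
        ct = np.column_stack([a, a + 1.0, 24 + rng.normal(0, 0.5, 8)])
        b = make_block(ct, GENES3)
        res = rs.delta_ct_stability(b)
        sd_ac = np.std(ct[:, 0] - ct[:, 2], ddof=1)
        assert res.scores["Ppia"] == pytest.approx(sd_ac / 2)

    def test_constant_offsets_give_zero_scores(self):
        base = np.linspace(20, 23, 6)
        ct = np.column_stack([base, base + 2.0, base - 1.5])
        res = rs.delta_ct_stability(make_block(ct, GENES3))
        np.testing.assert_allclose(res.scores, 0.0, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        b = random_block(rng, 4, 3)
        res = rs.delta_ct_stability(b)
        expect = oracles.delta_ct_scores(block_to_rows(b), b.genes)
        for g in b.genes:
            assert res.scores[g] == pytest.approx(expect[g], abs=1e-12)


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

class TestGenorm:
    def test_two_gene_m_is_symmetric_ratio_sd(self, rng):
        b = random_block(rng, 8, 2)
        q = rs.to_relative_quantities(b)
        m = rs.genorm_m(q)
        ratio_sd = np.std(np.log2(q.q.iloc[:, 0] / q.q.iloc[:, 1]), ddof=1)
        assert m.iloc[0] == pytest.approx(m.iloc[1]) == pytest.approx(ratio_sd)

    def test_offset_only_genes_have_zero_m(self):
        base = np.linspace(20, 22, 5)
        ct = np.column_stack([base, base + 1, base + 3])
        q = rs.to_relative_quantities(make_block(ct, GENES3))
        np.testing.assert_allclose(rs.genorm_m(q), 0.0, atol=1e-12)

    def test_full_panel_m_equals_delta_ct_at_e2(self, rng):
        b = random_block(rng, 10, 5)
        q = rs.to_relative_quantities(b, efficiency=2.0)
        np.testing.assert_allclose(rs.genorm_m(q).to_numpy(),
                                   rs.delta_ct_stability(b).scores.to_numpy(),
                                   rtol=0, atol=1e-12)

    def test_noise_gene_excluded_first(self, rng):
        base = 21 + rng.normal(0, 0.2, size=(12, 3))
        noise = 25 + rng.normal(0, 2.5, size=(12, 1))
        b = make_block(np.hstack([base, noise]),
                       ["Ppia", "Hprt1", "Ywhaz", "B2m"])
        r = rs.genorm_rank(rs.to_relative_quantities(b))
        assert r.order[-1] == "B2m"
        assert r.m_at_exclusion["B2m"] == r.m_at_exclusion.max()

    def test_rank_order_reverses_exclusion_and_flags_tie(self, rng):
        b = random_block(rng, 12, 5)
        r = rs.genorm_rank(rs.to_relative_quantities(b))
        assert sorted(r.order) == sorted(b.genes)
        # the final two genes share the identical lowest M
        assert (r.m_at_exclusion[r.order[0]]
                == pytest.approx(r.m_at_exclusion[r.order[1]]))
        assert set(r.tied_pair) == set(r.order[:2])

    def test_identical_genes_all_m_zero_tie_flagged(self):
        base = np.linspace(19, 23, 6)
        ct = np.column_stack([base, base + 1, base + 2, base - 1])
        r = rs.genorm_rank(rs.to_relative_quantities(
            make_block(ct, ["Ppia", "Hprt1", "Ywhaz", "B2m"])))
        np.testing.assert_allclose(r.m_at_exclusion, 0.0, atol=1e-12)
        assert r.tie_broken  # exclusion needed a logged tie-break


class TestPairwiseV:
    def test_offset_only_genes_all_v_zero_recommend_two(self):
        base = np.linspace(20, 22, 6)
        ct = np.column_stack([base + k for k in (0.0, 1.0, 2.5, 4.0, 0.5)])
        genes = ["Ppia", "Hprt1", "Ywhaz", "Gapdh", "B2m"]
        q = rs.to_relative_quantities(make_block(ct, genes))
        prof = rs.genorm_pairwise_v(q, rs.genorm_rank(q))
        np.testing.assert_allclose(prof.v, 0.0, atol=1e-12)
        assert prof.recommended_n == 2
        assert not prof.all_above_cutoff

    def test_matches_definition_oracle(self, rng):
        b = random_block(rng, 9, 5)
        q = rs.to_relative_quantities(b)
        ranking = rs.genorm_rank(q)
        prof = rs.genorm_pairwise_v(q, ranking)
        rows = [dict(r) for _, r in q.q.iterrows()]
        expect = oracles.genorm_v(rows, list(ranking.order))
        for n, v in expect.items():
            assert prof.v[n] == pytest.approx(v, abs=1e-12)

    def test_no_v_below_cutoff_flagged(self, rng):
        b = random_block(rng, 8, 4, noise_sd=2.0)  # hopelessly noisy panel
        q = rs.to_relative_quantities(b)
        prof = rs.genorm_pairwise_v(q, cutoff=0.15)
        assert prof.recommended_n is None and prof.all_above_cutoff
        assert prof.effective_n() == 4


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

class TestNormFinder:
    def test_noiseless_no_effect_gives_zero(self):
        base = np.full((8, 4), 0.0) + np.array([20.0, 22.0, 24.0, 19.0])
        b = make_block(base, ["Ppia", "Hprt1", "Ywhaz", "B2m"])
        res = rs.normfinder_s(b, use_groups=True)
        assert (res.scores.abs() <= 1e-9).all()

    def test_shifted_gene_has_largest_s(self, rng):
        ct = 21 + rng.normal(0, 0.3, size=(16, 4))
        ct[8:, 0] -= 2.0  # +2-cycle expression shift in the tMCAO half
        b = make_block(ct, ["Actb", "Ppia", "Hprt1", "Ywhaz"])
        res = rs.normfinder_s(b, use_groups=True)
        assert res.scores.idxmax() == "Actb"

    def test_matches_loop_oracle_grouped_and_ungrouped(self, rng):
        b = random_block(rng, 12, 6)
        y = np.log2(rs.to_relative_quantities(b).q)
        rows = [dict(r) for _, r in y.iterrows()]
        grouped = rs.normfinder_s(b, use_groups=True)
        expect = oracles.normfinder(rows, b.genes, list(b.group_labels))
        for g in b.genes:
            assert grouped.scores[g] == pytest.approx(expect[g], abs=1e-10)
        ungrouped = rs.normfinder_s(b, use_groups=False)
        expect_u = oracles.normfinder_ungrouped(rows, b.genes)
        for g in b.genes:
            assert ungrouped.scores[g] == pytest.approx(expect_u[g], abs=1e-10)

    def test_grouped_and_ungrouped_agree_on_ordering_under_null(self, rng):
        # identical group distributions: the two modes are on different
        # scales (the grouped S carries a 1/sqrt(n) standard error) but
        # must recover the same stability ordering of clearly separated
        # noise levels.
        n = 60
        sds = np.array([0.15, 0.3, 0.6, 1.0])
        ct = 21 + rng.normal(0, 1, size=(n, 4)) * sds
        b = make_block(ct, ["Ppia", "Hprt1", "Ywhaz", "B2m"])
        g = rs.normfinder_s(b, use_groups=True).scores
        u = rs.normfinder_s(b, use_groups=False).scores
        assert list(g.sort_values().index) == list(u.sort_values().index)

    def test_single_sample_group_rejected(self, rng):
        ct = 21 + rng.normal(0, 0.3, size=(5, 3))
        b = make_block(ct, GENES3, conditions=["SHAM"] * 4 + ["tMCAO"])
        with pytest.raises(rs.CtDataError, match="< 2 samples"):
            rs.normfinder_s(b, use_groups=True)


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

class TestBestKeeper:
    def test_constant_gene_zero_sd_cv_and_missing_r(self, rng):
        ct = np.column_stack([np.full(8, 20.0),
                              22 + rng.normal(0, 0.4, 8),
                              24 + rng.normal(0, 0.4, 8)])
        res = rs.bestkeeper(make_block(ct, GENES3))
        assert res.aux.at["Ppia", "sd"] == 0.0
        assert res.aux.at["Ppia", "cv"] == 0.0
        assert np.isnan(res.aux.at["Ppia", "r"])
        assert res.order[-1] == "Ppia"  # undefined r ranks last

    def test_gene_equal_to_index_has_r_one(self):
        base = np.linspace(19, 21, 10)
        ct = np.column_stack([base, base, base])
        res = rs.bestkeeper(make_block(ct, GENES3))
        np.testing.assert_allclose(res.aux["r"], 1.0, atol=1e-12)

    def test_sd_above_cutoff_excluded_from_index(self, rng):
        stable = 21 + rng.normal(0, 0.3, size=(12, 3))
        wild = 23 + rng.normal(0, 1.8, size=(12, 1))
        b = make_block(np.hstack([stable, wild]),
                       ["Ppia", "Hprt1", "Ywhaz", "B2m"])
        res = rs.bestkeeper(b, sd_exclusion_cutoff=1.0)
        assert res.excluded == frozenset({"B2m"})
        assert res.order[-1] == "B2m"
        # index built from the kept genes only
        expect = np.exp(np.log(b.ct[["Ppia", "Hprt1", "Ywhaz"]]).mean(axis=1))
        r_manual = np.corrcoef(b.ct["Ppia"], expect)[0, 1]
        assert res.aux.at["Ppia", "r"] == pytest.approx(r_manual)

    def test_matches_loop_oracle(self, rng):
        b = random_block(rng, 10, 5)
        res = rs.bestkeeper(b)
        expect = oracles.bestkeeper(block_to_rows(b), b.genes)
        for g in b.genes:
            assert res.aux.at[g, "sd"] == pytest.approx(expect[g]["sd"], abs=1e-12)
            assert res.aux.at[g, "cv"] == pytest.approx(expect[g]["cv"], abs=1e-12)
            assert res.aux.at[g, "r"] == pytest.approx(expect[g]["r"], abs=1e-12)
            assert (g in res.excluded) == expect[g]["excluded"]

    def test_all_genes_excluded_is_fatal(self, rng):
        ct = 21 + rng.normal(0, 3.0, size=(10, 3))
        with pytest.raises(rs.CtDataError, match="cutoff"):
            rs.bestkeeper(make_block(ct, GENES3), sd_exclusion_cutoff=0.01)


# ---------------------------------------------------------------------------
# Cross-metric invariance properties
# ---------------------------------------------------------------------------

@st.composite
def plausible_blocks(draw):
    n = draw(st.integers(4, 12))
    G = draw(st.integers(3, 6))
    seed = draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(seed)
    return random_block(rng, n, G)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(plausible_blocks(), st.floats(-3, 3))
def test_gene_offset_invariance(b, offset):
    """Adding a constant to one gene's Ct leaves every stability statistic
    unchanged (dCt score, geNorm M and V, NormFinder S, BestKeeper SD, r)."""
    shifted_ct = b.ct.copy()
    shifted_ct.iloc[:, 0] += offset
    b2 = make_block(shifted_ct.to_numpy(), b.genes,
                    conditions=list(b.group_labels))

    np.testing.assert_allclose(rs.delta_ct_stability(b).scores,
                               rs.delta_ct_stability(b2).scores, atol=1e-9)
    q1, q2 = rs.to_relative_quantities(b), rs.to_relative_quantities(b2)
    np.testing.assert_allclose(rs.genorm_m(q1), rs.genorm_m(q2), atol=1e-9)
    order = rs.genorm_rank(q1).order
    np.testing.assert_allclose(rs.genorm_pairwise_v(q1, order).v,
                               rs.genorm_pairwise_v(q2, order).v, atol=1e-9)
    np.testing.assert_allclose(rs.normfinder_s(b).scores,
                               rs.normfinder_s(b2).scores, atol=1e-9)
    bk1, bk2 = rs.bestkeeper(b), rs.bestkeeper(b2)
    np.testing.assert_allclose(bk1.aux["sd"], bk2.aux["sd"], atol=1e-9)
    # the BestKeeper index is a geometric mean on the Ct scale, so r is
    # only approximately shift-invariant (it would be exact for an
    # arithmetic-mean index); exact r values are oracle-checked elsewhere
    np.testing.assert_allclose(bk1.aux["r"], bk2.aux["r"], atol=0.1)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(plausible_blocks())
def test_sample_effect_invariance(b):
    """A per-sample constant added to all genes (loading) leaves dCt,
    geNorm and NormFinder untouched; BestKeeper SD must increase."""
    # alternating +/-5-cycle loading: variance large enough that every
    # gene's Ct SD must strictly increase whatever the block looks like
    shifts = 5.0 * (-1.0) ** np.arange(b.n_samples)[:, None]
    b2 = make_block(b.ct.to_numpy() + shifts, b.genes,
                    conditions=list(b.group_labels))

    np.testing.assert_allclose(rs.delta_ct_stability(b).scores,
                               rs.delta_ct_stability(b2).scores, atol=1e-9)
    q1, q2 = rs.to_relative_quantities(b), rs.to_relative_quantities(b2)
    np.testing.assert_allclose(rs.genorm_m(q1), rs.genorm_m(q2), atol=1e-9)
    order = rs.genorm_rank(q1).order
    np.testing.assert_allclose(rs.genorm_pairwise_v(q1, order).v,
                               rs.genorm_pairwise_v(q2, order).v, atol=1e-9)
    np.testing.assert_allclose(rs.normfinder_s(b).scores,
                               rs.normfinder_s(b2).scores, atol=1e-8)
    # loading variance inflates every raw-Ct SD (cutoff disabled so the
    # inflated panel cannot trip the all-genes-excluded guard)
    inf = float("inf")
    gain = (rs.bestkeeper(b2, sd_exclusion_cutoff=inf).aux["sd"]
            - rs.bestkeeper(b, sd_exclusion_cutoff=inf).aux["sd"])
    assert (gain > 0).all()


def test_noise_inflation_raises_dct_and_m_in_expectation(rng):
    """Inflating one gene's technical noise raises its dCt score and geNorm
    M in almost every replicate (one-sided sign test over 200 seeds)."""
    wins_dct = wins_m = 0
    n_rep = 200
    for k in range(n_rep):
        r = np.random.default_rng(1000 + k)
        quiet = 21 + r.normal(0, 0.3, size=(10, 4))
        loud = quiet.copy()
        loud[:, 0] = 21 + r.normal(0, 0.9, size=10)
        b_q = make_block(quiet, ["Actb", "Ppia", "Hprt1", "Ywhaz"])
        b_l = make_block(loud, ["Actb", "Ppia", "Hprt1", "Ywhaz"])
        if (rs.delta_ct_stability(b_l).scores["Actb"]
                > rs.delta_ct_stability(b_q).scores["Actb"]):
            wins_dct += 1
        if (rs.genorm_m(rs.to_relative_quantities(b_l))["Actb"]
                > rs.genorm_m(rs.to_relative_quantities(b_q))["Actb"]):
            wins_m += 1
    # one-sided binomial: >=132/200 rejects p=0.5 at far below 1e-5
    assert wins_dct >= 132
    assert wins_m >= 132
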