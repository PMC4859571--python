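"""Statistical core: t-test, Bonferroni, SAM d/s0/permutation FDR, top-N union."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from voxscreen.diffexpr import (
    SamParams,
    _fdr_table,
    bonferroni,
    choose_s0,
    sam_d,
    sam_screen,
    student_t,
    t_screen,
    top_n_union,
)

# ---------------------------------------------------------------------------
# Independent oracles.


def pooled_t_oracle(a, b):
    """Textbook pooled-variance two-sample t, written step by step."""
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    ss = sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)
    sp2 = ss / (na + nb - 2)
    se = math.sqrt(sp2 * (1 / na + 1 / nb))
    t = (mb - ma) / se
    p = 2 * stats.t.sf(abs(t), na + nb - 2)
    return t, p


def sam_oracle(values_a, values_b, s0):
    """Exhaustive-enumeration SAM for a 3-vs-3 instance, plain loops only.

    Returns (d, q) per gene following the same procedure definition:
    asymmetric cutoffs scanned outward from the origin, median permuted
    exceedance count over all balanced label assignments, q as the smallest
    FDR at which the gene is called, then monotone in |d|.
    """
    m = len(values_a)
    X = [list(values_a[i]) + list(values_b[i]) for i in range(m)]
    n = len(X[0])
    na = len(values_a[0])

    def dstat(row, cols_a):
        a = [row[c] for c in cols_a]
        b = [row[c] for c in range(n) if c not in cols_a]
        ma, mb = sum(a) / len(a), sum(b) / len(b)
        ss = sum((v - ma) ** 2 for v in a) + sum((v - mb) ** 2 for v in b)
        s = math.sqrt((1 / len(a) + 1 / len(b)) * ss / (len(a) + len(b) - 2))
        return (mb - ma) / (s + s0)

    obs = [dstat(row, tuple(range(na))) for row in X]
    order = sorted(range(m), key=lambda i: obs[i])
    d_sorted = [obs[i] for i in order]
    cols = []
    for combo in itertools.combinations(range(n), na):
        cols.append(sorted(dstat(row, combo) for row in X))
    n_perm = len(cols)
    dbar = [sum(col[i] for col in cols) / n_perm for i in range(m)]

    diffs = [d_sorted[i] - dbar[i] for i in range(m)]
    origin = min(range(m), key=lambda i: abs(d_sorted[i]))
    deltas = sorted({0.0} | {abs(v) for v in diffs})
    q_sorted = [None] * m
    for delta in deltas:
        cut_up = math.inf
        for i in range(origin, m):
            if diffs[i] >= delta:
                cut_up = d_sorted[i]
                break
        cut_low = -math.inf
        for i in range(origin, -1, -1):
            if diffs[i] <= -delta:
                cut_low = d_sorted[i]
                break
        called = [d_sorted[i] >= cut_up or d_sorted[i] <= cut_low for i in range(m)]
        n_called = sum(called)
        if n_called == 0:
            continue
        counts = sorted(
            sum(1 for v in col if v >= cut_up or v <= cut_low) for col in cols
        )
        mid = n_perm // 2
        med = (
            counts[mid]
            if n_perm % 2
            else (counts[mid - 1] + counts[mid]) / 2
        )
        fdr = min(1.0, med / n_called)
        for i in range(m):
            if called[i] and (q_sorted[i] is None or fdr < q_sorted[i]):
                q_sorted[i] = fdr
    q_sorted = [1.0 if q is None else q for q in q_sorted]
    by_absd = sorted(range(m), key=lambda i: -abs(d_sorted[i]))
    running = -math.inf
    for i in by_absd:
        running = max(running, q_sorted[i])
        q_sorted[i] = running
    q = [None] * m
    for pos, gene in enumerate(order):
        q[gene] = q_sorted[pos]
    return obs, q


# ---------------------------------------------------------------------------
# student_t / bonferroni.


def test_identical_groups_give_zero_t_unit_p():
    assert student_t([1, 1], [1, 1]) == (0.0, 1.0)


def test_student_t_matches_closed_form_oracle(rng):
    for _ in range(200):
        a = rng.normal(size=rng.integers(2, 8))
        b = rng.normal(size=rng.integers(2, 8))
        t, p = student_t(a, b)
        t0, p0 = pooled_t_oracle(list(a), list(b))
        assert abs(t - t0) < 1e-10 and abs(p - p0) < 1e-10


def test_student_t_matches_scipy(rng):
    a, b = rng.normal(size=6), rng.normal(size=9)
    t, p = student_t(a, b)
    ref = stats.ttest_ind(b, a, equal_var=True)
    assert abs(t - ref.statistic) < 1e-12 and abs(p - ref.pvalue) < 1e-12


def test_insufficient_replicates_rejected():
    with pytest.raises(ValueError, match=">=2"):
        student_t([1.0], [1.0, 2.0])


def test_null_p_values_uniform(rng):
    """Exactly-null normal groups: p-values from the vectorized screen are
    uniform (Kolmogorov-Smirnov at the seed-batch level)."""
    m, na, nb = 10_000, 6, 6
    a = rng.normal(size=(m, na))
    b = rng.normal(size=(m, nb))
    res = t_screen(a, b, [f"g{i}" for i in range(m)])
    ks = stats.kstest(res["p"], "uniform")
    assert ks.pvalue > 0.01


@given(
    p=st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30),
    extra=st.integers(min_value=0, max_value=100),
)
@settings(deadline=None, derandomize=True)
def test_bonferroni_properties(p, extra):
    m = len(p) + extra
    adj = bonferroni(p, m=m)
    assert np.all(adj >= np.asarray(p))
    assert np.all(adj <= 1.0)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in p


def test_bonferroni_examples_and_validation():
    assert bonferroni([0.01], m=10)[0] == pytest.approx(0.1)
    assert bonferroni([0.5], m=3)[0] == 1.0
    with pytest.raises(ValueError):
        bonferroni([1.5])


# ---------------------------------------------------------------------------
# sam_d / choose_s0.


def test_sam_d_zero_for_equal_means():
    d, _ = sam_d([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], s0=0.5)
    assert d == 0.0


def test_sam_d_with_zero_s0_equals_t_statistic(rng):
    for _ in range(100):
        a = rng.normal(size=5)
        b = rng.normal(size=4)
        d, _ = sam_d(a, b, s0=0.0)
        t, _ = student_t(a, b)
        assert d == t


def test_sam_d_hand_evaluated_three_vs_three():
    a, b = [1.0, 2.0, 3.0], [4.0, 6.0, 8.0]
    # step-by-step arithmetic: means 2 and 6; SS = 2 + 8 = 10
    # s = sqrt((1/3+1/3) * 10/4) = sqrt(5/3); d = 4 / (s + 0.5)
    d, s = sam_d(a, b, s0=0.5)
    assert s == pytest.approx(math.sqrt(5.0 / 3.0), abs=1e-12)
    assert d == pytest.approx(4.0 / (math.sqrt(5.0 / 3.0) + 0.5), abs=1e-12)


def test_sam_d_zero_scatter_zero_s0_flags_infinity():
    d, s = sam_d([1.0, 1.0], [2.0, 2.0], s0=0.0)
    assert s == 0.0 and d == math.inf


def test_choose_s0_nonnegative_and_matches_grid_oracle(rng):
    m = 300
    s = np.abs(rng.normal(1.0, 0.4, size=m)) + 0.05
    r = rng.normal(0.0, 1.0, size=m) * s
    picked = choose_s0(s, r)
    assert picked >= 0
    # brute-force oracle over the same candidate set and windows
    order = np.argsort(s, kind="stable")
    ss, rr = s[order], r[order]
    windows = np.array_split(np.arange(m), 10)
    best, best_cv = None, np.inf
    for cand in np.percentile(ss, np.arange(0, 101, 5)):
        d = rr / (ss + cand)
        mads = np.array([np.median(np.abs(d[w] - np.median(d[w]))) for w in windows])
        cv = mads.std(ddof=1) / mads.mean()
        if cv < best_cv - 1e-15:
            best, best_cv = cand, cv
    assert picked == pytest.approx(best)


def test_choose_s0_stable_under_homoscedastic_noise(rng):
    """Same candidate percentile chosen in >=90% of 50 homoscedastic replicates."""
    picks = []
    for _ in range(50):
        m, na, nb = 1000, 10, 10
        a = rng.normal(size=(m, na))
        b = rng.normal(size=(m, nb))
        diff = b.mean(1) - a.mean(1)
        ss = ((a - a.mean(1, keepdims=True)) ** 2).sum(1) + (
            (b - b.mean(1, keepdims=True)) ** 2
        ).sum(1)
        s = np.sqrt((1 / na + 1 / nb) * ss / (na + nb - 2))
        s0 = choose_s0(s, diff)
        cands = np.percentile(s, np.arange(0, 101, 5))
        picks.append(int(np.argmin(np.abs(cands - s0))))
    most_common = max(set(picks), key=picks.count)
    assert picks.count(most_common) >= 45


def test_choose_s0_few_genes_falls_back_to_median():
    s = np.array([1.0, 2.0, 3.0])
    assert choose_s0(s, np.zeros(3)) == 2.0


# ---------------------------------------------------------------------------
# sam_screen.


def test_sam_screen_matches_exhaustive_enumeration_oracle(rng):
    """20 genes, 3-vs-3 voxels: q-values equal brute force over all 20
    balanced label assignments exactly."""
    m = 20
    a = rng.normal(1.0, 0.5, size=(m, 3))
    b = rng.normal(1.0, 0.5, size=(m, 3))
    b[:4] += 2.0  # a few differential genes
    genes = [f"g{i:02d}" for i in range(m)]
    res = sam_screen(np.abs(a), np.abs(b), genes, SamParams(s0=0.2))
    assert bool(res["exact_permutations"].iloc[0])
    d_oracle, q_oracle = sam_oracle(np.abs(a), np.abs(b), s0=0.2)
    np.testing.assert_allclose(res["d"].to_numpy(), d_oracle, rtol=1e-12)
    assert list(res["q"]) == q_oracle


def test_identity_permutation_fdr_capped_at_one(rng):
    """With the null equal to the observed labeling (single permutation),
    numerator and denominator coincide at delta 0 and FDR caps at 1."""
    d_sorted = np.sort(rng.normal(size=15))
    perm_sorted = d_sorted[:, None]  # the one 'permutation' is the original
    table = _fdr_table(d_sorted, perm_sorted.mean(axis=1), perm_sorted)
    at_zero = table.loc[table["delta"] == 0.0].iloc[0]
    if at_zero["n_called"] > 0:
        assert at_zero["fdr"] == 1.0
    assert (table["fdr"] <= 1.0).all()


def test_vectorized_fdr_table_matches_scalar_reference(rng):
    """The batched FDR curve agrees with the single-delta scan at every
    change point (cutoffs, called counts and FDR)."""
    from voxscreen.diffexpr import _fdr_at

    d_sorted = np.sort(rng.normal(size=40))
    perm_sorted = np.sort(rng.normal(size=(40, 25)), axis=0)
    dbar = perm_sorted.mean(axis=1)
    table = _fdr_table(d_sorted, dbar, perm_sorted)
    for row in table.itertuples():
        fdr, n_called, cut_up, cut_low = _fdr_at(d_sorted, dbar, perm_sorted, row.delta)
        assert (cut_up, cut_low) == (row.cut_up, row.cut_low)
        assert n_called == row.n_called
        assert fdr == row.fdr


def test_called_at_delta_zero_includes_extreme_genes(rng):
    a = rng.normal(size=(30, 5))
    b = rng.normal(size=(30, 5))
    b[:3] += 4.0
    res = sam_screen(a, b, [f"g{i}" for i in range(30)], SamParams(s0=0.1, delta=0.0))
    assert res.loc[res["rank_sam"] == 1, "called"].iloc[0]


def test_sam_screen_q_monotone_in_absolute_d(small_screen):
    matrix, pair, _ = small_screen
    res = sam_screen(
        pair.values_a, pair.values_b, matrix.genes, SamParams(n_permutations=100, seed=5)
    )
    tested = res.loc[res["tested"]].sort_values(
        "d", key=lambda c: -c.abs(), kind="stable"
    )
    assert (np.diff(tested["q"].to_numpy()) >= -1e-12).all()


def test_sam_screen_deterministic_for_fixed_seed(small_screen):
    matrix, pair, _ = small_screen
    params = SamParams(n_permutations=50, seed=123)
    r1 = sam_screen(pair.values_a, pair.values_b, matrix.genes, params)
    r2 = sam_screen(pair.values_a, pair.values_b, matrix.genes, SamParams(n_permutations=50, seed=123))
    pd.testing.assert_frame_equal(r1, r2)


def test_genes_with_insufficient_voxels_reported_untested(rng):
    a = rng.normal(size=(3, 4))
    b = rng.normal(size=(3, 4))
    a[0, 1:] = np.nan  # gene 0 has a single usable voxel in group a
    res = t_screen(a, b, ["g0", "g1", "g2"])
    assert not res.loc[res["gene_id"] == "g0", "tested"].iloc[0]
    assert res["tested"].sum() == 2
    sam = sam_screen(a, b, ["g0", "g1", "g2"], SamParams(s0=0.1))
    assert not sam.loc[sam["gene_id"] == "g0", "tested"].iloc[0]
    assert np.isnan(sam.loc[sam["gene_id"] == "g0", "q"].iloc[0])


# ---------------------------------------------------------------------------
# top_n_union.


def _mini_results(rng, m=30):
    genes = [f"g{i:02d}" for i in range(m)]
    a = rng.normal(size=(m, 5))
    b = rng.normal(size=(m, 5))
    t_res = t_screen(a, b, genes)
    sam_res = sam_screen(a, b, genes, SamParams(s0=0.1, n_permutations=50, seed=1))
    return t_res, sam_res, genes


def test_union_is_all_genes_when_n_large(rng):
    t_res, sam_res, genes = _mini_results(rng)
    hits = top_n_union(t_res, sam_res, n=100)
    assert hits.union == set(genes)


def test_union_cardinality_bounds(rng):
    t_res, sam_res, _ = _mini_results(rng)
    hits = top_n_union(t_res, sam_res, n=10)
    assert len(hits.union) <= 20
    assert len(hits.union) >= max(len(hits.top_t), len(hits.top_sam))


def test_top_t_ordering_by_p(rng):
    t_res, sam_res, _ = _mini_results(rng)
    hits = top_n_union(t_res, sam_res, n=5)
    chosen_p = t_res.set_index("gene_id").loc[hits.top_t, "p"]
    assert (chosen_p.max() <= t_res.loc[~t_res["gene_id"].isin(hits.top_t), "p"]).all()


def test_mismatched_universes_rejected(rng):
    t_res, sam_res, _ = _mini_results(rng)
    with pytest.raises(ValueError, match="universe"):
        top_n_union(t_res.iloc[:-1], sam_res, n=5)
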