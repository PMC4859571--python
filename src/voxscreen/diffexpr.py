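"""Per-gene two-group statistics over ROI voxels.

Two parallel screening routes, mirroring classical microarray practice:

* Student's t-test (pooled variance, two-sided) with Bonferroni correction
  across the tested genes.
* Significance Analysis of Microarrays (SAM): relative difference
  ``d = (mean_b - mean_a) / (s + s0)`` where ``s`` is the pooled standard
  error and ``s0`` a fudge factor stabilizing low-variance genes; a null
  distribution from balanced label permutations; asymmetric calling
  cutoffs at threshold delta; permutation-estimated FDR and per-gene q.

Voxels within each ROI enter as replicate observations.  Because adjacent
voxels from one sagittal plane are not truly independent, the screen is a
*ranking* device, not calibrated inference on real atlas data; the q-values
and adjusted p-values are exact only under the independence the synthetic
atlas actually has.

Missing values are excluded pairwise per gene; a gene with fewer than two
usable voxels in either group is reported as untested rather than dropped.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SamParams",
    "ScreenHits",
    "student_t",
    "bonferroni",
    "sam_d",
    "choose_s0",
    "t_screen",
    "sam_screen",
    "top_n_union",
]

logger = logging.getLogger(__name__)


@dataclass
class SamParams:
    """SAM tuning knobs: fudge factor, permutation count, calling threshold.

    ``s0="auto"`` selects the fudge factor by minimizing the coefficient of
    variation of windowed median absolute deviations of d (see
    :func:`choose_s0`).  When the number of distinct balanced label
    assignments is at most ``max_exact``, exact enumeration replaces random
    sampling of ``n_permutations`` assignments.
    """

    s0: float | str = "auto"
    n_permutations: int = 1000
    delta: float = 0.0
    seed: int = 0
    max_exact: int = 10_000

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if isinstance(self.s0, str):
            if self.s0 != "auto":
                raise ValueError(f"s0 must be a number or 'auto', got {self.s0!r}")
        elif self.s0 < 0:
            raise ValueError("s0 must be >= 0")
        if self.delta < 0:
            raise ValueError("delta must be >= 0")


@dataclass
class ScreenHits:
    """Top-n gene sets from each screening route and their union."""

    top_t: list[str]
    top_sam: list[str]
    n: int
    union: set[str] = field(init=False)

    def __post_init__(self) -> None:
        self.union = set(self.top_t) | set(self.top_sam)


# ---------------------------------------------------------------------------
# Elementary statistics.


def _clean_groups(values_a, values_b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise ValueError(
            f"need >=2 finite values per group, got {a.size} and {b.size}"
        )
    return a, b


def _pooled_se(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    ss = np.sum((a - a.mean()) ** 2) + np.sum((b - b.mean()) ** 2)
    return math.sqrt((1.0 / na + 1.0 / nb) * ss / (na + nb - 2))


def student_t(values_a, values_b) -> tuple[float, float]:
    """Classical two-sample pooled-variance t-test, two-sided.

    Returns (t, p) with ``t`` signed as mean(b) - mean(a) and
    ``n_a + n_b - 2`` degrees of freedom.  When both groups have zero
    variance and equal means the convention is (0, 1); zero variance with
    unequal means yields signed infinity with p = 0.
    """
    a, b = _clean_groups(values_a, values_b)
    diff = b.mean() - a.mean()
    se = _pooled_se(a, b)
    if se == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / se
    df = a.size + b.size - 2
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p), m = number of tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size if m is None else m
    return np.minimum(1.0, m * p)


def sam_d(values_a, values_b, s0: float) -> tuple[float, float]:
    """SAM relative difference and scatter for one gene.

    ``s`` is the pooled standard deviation scaled by sqrt(1/n_a + 1/n_b);
    ``d = (mean_b - mean_a) / (s + s0)``.  With ``s0 = 0``, d is exactly the
    pooled-variance t statistic.  Zero scatter with zero s0 and unequal
    means gives signed infinity.
    """
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    a, b = _clean_groups(values_a, values_b)
    diff = b.mean() - a.mean()
    s = _pooled_se(a, b)
    if s + s0 == 0.0:
        d = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
        return d, s
    return float(diff / (s + s0)), float(s)


def choose_s0(
    all_s, all_r, n_windows: int = 10, percentile_step: int = 5
) -> float:
    """Select the SAM fudge factor from candidate percentiles of the scatter.

    Candidates are percentiles 0, 5, ..., 100 of the per-gene scatters
    ``all_s``; the winner minimizes the coefficient of variation of the
    median absolute deviation of d = r / (s + s0) across contiguous
    s-quantile windows.  Zero-scatter genes are excluded from the windows.
    Deterministic: ties resolve to the smallest candidate.  With fewer than
    10 usable genes the fallback is median(s).
    """
    s = np.asarray(all_s, dtype=float)
    r = np.asarray(all_r, dtype=float)
    keep = np.isfinite(s) & np.isfinite(r) & (s > 0)
    s, r = s[keep], r[keep]
    if s.size < 10:
        logger.warning("choose_s0: only %d usable genes; falling back to median(s)", s.size)
        return float(np.median(s)) if s.size else 0.0
    order = np.argsort(s, kind="stable")
    s, r = s[order], r[order]
    windows = np.array_split(np.arange(s.size), min(n_windows, s.size))
    candidates = np.percentile(s, np.arange(0, 101, percentile_step))
    best_s0, best_cv = 0.0, np.inf
    for cand in candidates:
        d = r / (s + cand)
        mads = np.array([
            np.median(np.abs(d[w] - np.median(d[w]))) for w in windows
        ])
        mean_mad = mads.mean()
        cv = np.inf if mean_mad == 0 else mads.std(ddof=1) / mean_mad
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(cand)
    return best_s0


# ---------------------------------------------------------------------------
# Vectorized group statistics (NaN-aware), shared by both screening routes.


def _group_stats(x: np.ndarray, mask: np.ndarray, in_a: np.ndarray):
    """Per-gene mean difference, pooled scatter, and usable counts.

    ``in_a`` is a boolean (n,) or (n, B) membership matrix for group a;
    returns arrays broadcast to (m,) or (m, B).
    """
    squeeze = in_a.ndim == 1
    in_a = np.atleast_2d(in_a.astype(float).T).T  # (n, B)
    xz = np.where(mask, x, 0.0)
    sq = xz**2
    n1 = mask.astype(float) @ in_a
    n_tot = mask.sum(axis=1, keepdims=True)
    n2 = n_tot - n1
    s1 = xz @ in_a
    s_tot = xz.sum(axis=1, keepdims=True)
    q1 = sq @ in_a
    q_tot = sq.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        mean1 = s1 / n1
        mean2 = (s_tot - s1) / n2
        ss = (q1 - n1 * mean1**2) + ((q_tot - q1) - n2 * mean2**2)
        ss = np.maximum(ss, 0.0)  # guard tiny negative rounding
        df = n1 + n2 - 2
        scatter = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / df)
    diff = mean2 - mean1
    if squeeze:
        return diff[:, 0], scatter[:, 0], n1[:, 0], n2[:, 0]
    return diff, scatter, n1, n2


def t_screen(values_a: np.ndarray, values_b: np.ndarray, genes: list[str]) -> pd.DataFrame:
    """Pooled t-test per gene with Bonferroni adjustment and ascending-p ranks.

    Returns a DataFrame (gene_id, t, p, p_adj, rank_t, tested).  m for the
    Bonferroni factor is the number of *tested* genes.
    """
    x = np.hstack([values_a, values_b]).astype(float)
    mask = np.isfinite(x)
    in_a = np.zeros(x.shape[1], dtype=bool)
    in_a[: values_a.shape[1]] = True
    diff, scatter, n1, n2 = _group_stats(x, mask, in_a)
    tested = (n1 >= 2) & (n2 >= 2)
    df = n1 + n2 - 2
    t = np.full(len(genes), np.nan)
    p = np.full(len(genes), np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        tt = diff / scatter
    zero_se = tested & (scatter == 0)
    t[tested] = tt[tested]
    t[zero_se & (diff == 0)] = 0.0
    t[zero_se & (diff != 0)] = np.sign(diff[zero_se & (diff != 0)]) * np.inf
    p[tested] = 2.0 * stats.t.sf(np.abs(t[tested]), df[tested])
    p[zero_se & (diff == 0)] = 1.0
    p[zero_se & (diff != 0)] = 0.0
    np.minimum(p, 1.0, out=p, where=np.isfinite(p))
    out = pd.DataFrame({"gene_id": genes, "t": t, "p": p, "tested": tested})
    m = int(tested.sum())
    out["p_adj"] = np.nan
    out.loc[tested, "p_adj"] = bonferroni(out.loc[tested, "p"].to_numpy(), m=m)
    order = out.loc[tested].sort_values(
        by=["p", "t", "gene_id"],
        ascending=[True, True, True],
        key=lambda col: -col.abs() if col.name == "t" else col,
    ).index
    out["rank_t"] = np.nan
    out.loc[order, "rank_t"] = np.arange(1, len(order) + 1)
    return out


# ---------------------------------------------------------------------------
# SAM screen.


def _balanced_assignments(
    n: int, n_a: int, params: SamParams
) -> tuple[np.ndarray, bool]:
    """Boolean (n, B) membership matrix of group-size-preserving label permutations.

    Exact enumeration of all C(n, n_a) assignments when that count is at
    most ``params.max_exact``; otherwise ``n_permutations`` sampled
    assignments.
    """
    n_distinct = math.comb(n, n_a)
    if n_distinct <= params.max_exact:
        if n_distinct < params.n_permutations:
            logger.info(
                "sam_screen: %d distinct balanced permutations <= %d requested;"
                " switching to exact enumeration",
                n_distinct,
                params.n_permutations,
            )
        cols = np.zeros((n, n_distinct), dtype=bool)
        for j, combo in enumerate(itertools.combinations(range(n), n_a)):
            cols[list(combo), j] = True
        return cols, True
    rng = np.random.default_rng(params.seed)
    cols = np.zeros((n, params.n_permutations), dtype=bool)
    for j in range(params.n_permutations):
        cols[rng.choice(n, size=n_a, replace=False), j] = True
    return cols, False


def _cutoffs(d_sorted: np.ndarray, dbar: np.ndarray, delta: float) -> tuple[float, float]:
    """Asymmetric SAM calling cutoffs at threshold delta.

    Scanning outward from the d value closest to zero: the first sorted
    position whose observed-minus-expected deviation reaches +delta sets the
    upper cutoff (all larger d called); symmetrically for -delta below.
    """
    diff = d_sorted - dbar
    origin = int(np.argmin(np.abs(d_sorted)))
    cut_up = np.inf
    for i in range(origin, d_sorted.size):
        if diff[i] >= delta:
            cut_up = d_sorted[i]
            break
    cut_low = -np.inf
    for i in range(origin, -1, -1):
        if diff[i] <= -delta:
            cut_low = d_sorted[i]
            break
    return cut_up, cut_low


def _fdr_at(
    d_sorted: np.ndarray,
    dbar: np.ndarray,
    perm_sorted: np.ndarray,
    delta: float,
) -> tuple[float, int, float, float]:
    """Estimated FDR at one delta: (fdr, n_called, cut_up, cut_low).

    FDR = median over permutations of the count of permuted d beyond the
    cutoffs, divided by the observed called count, capped at 1.
    """
    cut_up, cut_low = _cutoffs(d_sorted, dbar, delta)
    called = (d_sorted >= cut_up) | (d_sorted <= cut_low)
    n_called = int(called.sum())
    if n_called == 0:
        return 0.0, 0, cut_up, cut_low
    m = perm_sorted.shape[0]
    counts = np.empty(perm_sorted.shape[1])
    for b in range(perm_sorted.shape[1]):
        col = perm_sorted[:, b]
        n_up = m - np.searchsorted(col, cut_up, side="left")
        n_low = np.searchsorted(col, cut_low, side="right")
        counts[b] = n_up + n_low
    fdr = float(np.median(counts)) / n_called
    return min(fdr, 1.0), n_called, cut_up, cut_low


def _fdr_table(
    d_sorted: np.ndarray, dbar: np.ndarray, perm_sorted: np.ndarray
) -> pd.DataFrame:
    """Estimated FDR at every delta where the called set changes.

    Vectorized equivalent of :func:`_fdr_at` over the full delta grid:
    cutoffs come from running maxima of the observed-minus-expected
    deviations outward from the origin, and permuted exceedance counts from
    per-permutation binary searches.
    """
    m = d_sorted.size
    deviations = d_sorted - dbar
    origin = int(np.argmin(np.abs(d_sorted)))
    finite = np.abs(deviations[np.isfinite(deviations)])
    deltas = np.unique(np.concatenate([[0.0], finite]))

    up_run = np.maximum.accumulate(deviations[origin:])
    lo_run = np.maximum.accumulate(-deviations[origin::-1])
    t_up = np.searchsorted(up_run, deltas, side="left")
    t_lo = np.searchsorted(lo_run, deltas, side="left")
    cut_up = np.where(
        t_up < up_run.size, d_sorted[np.minimum(origin + t_up, m - 1)], np.inf
    )
    cut_low = np.where(
        t_lo < lo_run.size, d_sorted[np.maximum(origin - t_lo, 0)], -np.inf
    )
    n_called = (m - np.searchsorted(d_sorted, cut_up, side="left")) + np.searchsorted(
        d_sorted, cut_low, side="right"
    )
    counts = np.empty((perm_sorted.shape[1], deltas.size))
    for b in range(perm_sorted.shape[1]):
        col = perm_sorted[:, b]
        counts[b] = (m - np.searchsorted(col, cut_up, side="left")) + np.searchsorted(
            col, cut_low, side="right"
        )
    med = np.median(counts, axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_called > 0, np.minimum(1.0, med / n_called), 0.0)
    return pd.DataFrame({
        "delta": deltas,
        "cut_up": cut_up,
        "cut_low": cut_low,
        "n_called": n_called,
        "fdr": fdr,
    })


def sam_screen(
    values_a: np.ndarray,
    values_b: np.ndarray,
    genes: list[str],
    params: SamParams | None = None,
    return_fdr_table: bool = False,
):
    """Full SAM procedure over a two-group voxel matrix.

    Returns a DataFrame (gene_id, d, s, d_expected, q, rank_sam, tested)
    where ``d_expected`` is the mean permuted order statistic aligned to the
    gene's rank, ``q`` the smallest estimated FDR at which the gene is
    called, monotone non-increasing in |d|, and ``rank_sam`` the descending
    |d| rank among tested genes.
    """
    params = params or SamParams()
    x = np.hstack([values_a, values_b]).astype(float)
    mask = np.isfinite(x)
    n = x.shape[1]
    n_a = values_a.shape[1]
    in_a = np.zeros(n, dtype=bool)
    in_a[:n_a] = True

    diff, scatter, n1, n2 = _group_stats(x, mask, in_a)
    tested = (n1 >= 2) & (n2 >= 2)
    idx_tested = np.flatnonzero(tested)
    if idx_tested.size == 0:
        raise ValueError("no testable genes (need >=2 usable voxels per group)")

    if params.s0 == "auto":
        s0 = choose_s0(scatter[tested], diff[tested])
    else:
        s0 = float(params.s0)

    with np.errstate(divide="ignore", invalid="ignore"):
        d_all = diff / (scatter + s0)
    if s0 == 0.0:
        exploded = tested & (scatter == 0) & (diff != 0)
        d_all[exploded] = np.sign(diff[exploded]) * np.inf
        d_all[tested & (scatter == 0) & (diff == 0)] = 0.0

    d_obs = d_all[idx_tested]
    order = np.argsort(d_obs, kind="stable")
    d_sorted = d_obs[order]

    # Permutation null: same d formula under balanced relabelings.
    assign, exact = _balanced_assignments(n, n_a, params)
    xt, maskt = x[idx_tested], mask[idx_tested]
    pdiff, pscatter, pn1, pn2 = _group_stats(xt, maskt, assign)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_perm = pdiff / (pscatter + s0)
    if s0 == 0.0:
        d_perm = np.where((pscatter == 0) & (pdiff == 0), 0.0, d_perm)
        d_perm = np.where(
            (pscatter == 0) & (pdiff != 0), np.sign(pdiff) * np.inf, d_perm
        )
    bad = (pn1 < 2) | (pn2 < 2)
    d_perm = np.where(bad, 0.0, d_perm)
    perm_sorted = np.sort(d_perm, axis=0)
    dbar = perm_sorted.mean(axis=1)

    # q: smallest FDR over deltas at which each gene is called.
    fdr_table = _fdr_table(d_sorted, dbar, perm_sorted)
    q_sorted = np.full(d_sorted.size, np.nan)
    for row in fdr_table.itertuples():
        if row.n_called == 0:
            continue
        called = (d_sorted >= row.cut_up) | (d_sorted <= row.cut_low)
        q_sorted[called] = np.fmin(q_sorted[called], row.fdr)
    q_sorted[np.isnan(q_sorted)] = 1.0

    # Monotonicity: q non-increasing as |d| increases.
    by_absd = np.argsort(-np.abs(d_sorted), kind="stable")
    q_sorted[by_absd] = np.maximum.accumulate(q_sorted[by_absd])

    d_expected = np.empty_like(d_sorted)
    d_expected[order] = dbar
    q = np.empty_like(d_sorted)
    q[order] = q_sorted

    # Calling at the configured delta threshold.
    _, _, cut_up, cut_low = _fdr_at(d_sorted, dbar, perm_sorted, params.delta)
    called_sorted = (d_sorted >= cut_up) | (d_sorted <= cut_low)
    called = np.empty(d_sorted.size, dtype=bool)
    called[order] = called_sorted

    out = pd.DataFrame({
        "gene_id": genes,
        "d": d_all,
        "s": scatter,
        "d_expected": np.nan,
        "q": np.nan,
        "tested": tested,
        "s0": s0,
        "exact_permutations": exact,
    })
    out.loc[tested, "d_expected"] = d_expected
    out.loc[tested, "q"] = q
    out["called"] = False
    out.loc[tested, "called"] = called
    ranked = out.loc[tested].sort_values(
        by=["d", "gene_id"],
        key=lambda col: -col.abs() if col.name == "d" else col,
    ).index
    out["rank_sam"] = np.nan
    out.loc[ranked, "rank_sam"] = np.arange(1, len(ranked) + 1)
    if return_fdr_table:
        return out, fdr_table
    return out


def top_n_union(
    t_results: pd.DataFrame, sam_results: pd.DataFrame, n: int = 1000
) -> ScreenHits:
    """Top-n genes by each route and their union.

    t route: ascending p, ties by descending |t| then gene_id; SAM route:
    descending |d|, ties by gene_id.  Untested genes never enter.  The
    default n of 1000 per method matches standard screening practice for
    this contrast.
    """
    if set(t_results["gene_id"]) != set(sam_results["gene_id"]):
        raise ValueError("t and SAM results cover different gene universes")
    tt = t_results.loc[t_results["tested"]].copy()
    tt = tt.sort_values(
        by=["p", "t", "gene_id"],
        key=lambda col: -col.abs() if col.name == "t" else col,
    )
    ss = sam_results.loc[sam_results["tested"]].copy()
    ss = ss.sort_values(
        by=["d", "gene_id"],
        key=lambda col: -col.abs() if col.name == "d" else col,
    )
    return ScreenHits(
        top_t=list(tt["gene_id"].head(n)),
        top_sam=list(ss["gene_id"].head(n)),
        n=n,
    )
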