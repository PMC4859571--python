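"""Formalized surrogates of manual candidate curation.

The screen's statistical stage over-calls badly on real in-situ data, so
candidates are narrowed by two reproducible filters that stand in for
by-eye image curation:

* **Detectability**: a candidate must be detectable in exactly one region
  of interest ("undetectable in one ROI" — an absolute expression
  difference, not merely a significant one).  A gene is detectable in an
  ROI when the fraction of its voxels with energy above ``threshold``
  reaches ``min_fraction``.
* **Pattern concordance**: the gene's per-lobule expression profile must
  match, or be the inverse of, the reference Purkinje-cell survival
  pattern; scored as the Pearson correlation between the profile and the
  reference over lobule segments.

Surviving genes are classified by the ROI in which they are detectable:
expression restricted to the resistant posterior region (lobule X) marks a
candidate neuroprotective gene, restriction to the vulnerable anterior
region (lobules II/III) a candidate susceptibility gene.  Candidates are
then hierarchically clustered for heatmap display, and annotation-term
over-representation is scored with a hypergeometric test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .atlas_io import ExpressionMatrix, RoiPair

__all__ = [
    "CandidateGene",
    "EnrichmentResult",
    "detectability_filter",
    "lobule_profile",
    "pattern_concordance",
    "classify_candidates",
    "cluster_candidates",
    "ClusterResult",
    "enrichment",
]


@dataclass
class CandidateGene:
    """One curated candidate with filter diagnostics."""

    gene_id: str
    region: str  # "posterior" (candidate neuroprotective) | "anterior" (susceptibility)
    detect_fraction_a: float
    detect_fraction_b: float
    concordance: float
    passed_filters: dict[str, bool] = field(default_factory=dict)
    conflict: bool = False


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one annotation term."""

    term_id: str
    k: int  # candidates annotated with the term
    K: int  # universe genes annotated
    n: int  # candidates
    N: int  # universe size
    p: float
    significant: bool


def detectability_filter(
    gene_values_a: np.ndarray,
    gene_values_b: np.ndarray,
    threshold: float = 0.0,
    min_fraction: float = 0.1,
) -> tuple[float, float, bool, str | None]:
    """Detectable-in-exactly-one-ROI test for one gene.

    Returns (detect_fraction_a, detect_fraction_b, passed, direction).  A
    gene is detectable in an ROI when the fraction of its usable voxels
    with energy strictly above ``threshold`` is at least ``min_fraction``.
    Direction is "posterior" when only ROI b (resistant) is detectable,
    "anterior" when only ROI a.  Defaults (threshold 0, min_fraction 0.1)
    make any appreciable positive signal count as detection.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    fracs = []
    for vals in (gene_values_a, gene_values_b):
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError("empty ROI (no usable voxels)")
        fracs.append(float(np.mean(vals > threshold)))
    frac_a, frac_b = fracs
    det_a, det_b = frac_a >= min_fraction, frac_b >= min_fraction
    passed = det_a != det_b
    direction = None
    if passed:
        direction = "anterior" if det_a else "posterior"
    return frac_a, frac_b, passed, direction


def lobule_profile(
    matrix: ExpressionMatrix,
    gene_id: str,
    max_lateral_um: float = 1400.0,
) -> dict[str, float]:
    """Per-lobule mean energy of one gene within the midline corridor."""
    row = matrix.row(gene_id)
    lateral = np.abs(matrix.voxels["z_um"].to_numpy()) <= max_lateral_um
    labels = matrix.voxels["label"].to_numpy()
    profile = {}
    for seg in sorted(set(labels)):
        sel = lateral & (labels == seg)
        vals = row[sel]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            profile[seg] = float(vals.mean())
    return profile


def pattern_concordance(
    profile: dict[str, float], pattern: dict[str, float]
) -> tuple[float, bool]:
    """Signed concordance of a gene's lobule profile with the survival pattern.

    The profile is min-max rescaled to [0, 1] and Pearson-correlated with
    the reference over shared segments (>= 3 required).  Returns
    (score, scoreable); a zero-variance profile is not scoreable.  Positive
    scores track survival (neuroprotective pattern), negative its inverse
    (susceptibility pattern).  Pearson correlation is invariant to affine
    rescaling, so the rescale is presentational only.
    """
    shared = sorted(set(profile) & set(pattern))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared segments, got {len(shared)}")
    x = np.array([profile[s] for s in shared], dtype=float)
    y = np.array([pattern[s] for s in shared], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), False
    x = (x - x.min()) / np.ptp(x)
    r = stats.pearsonr(x, y).statistic
    return float(r), True


def classify_candidates(
    roi_pair: RoiPair,
    candidate_genes: list[str],
    pattern: dict[str, float],
    threshold: float = 0.0,
    min_fraction: float = 0.1,
    concordance_min: float = 0.7,
    max_lateral_um: float = 1400.0,
    return_diagnostics: bool = False,
):
    """Apply both curation filters and assign each surviving gene a region.

    Genes pass when detectable in exactly one ROI and |concordance| >=
    ``concordance_min``.  Region comes from the detectability direction; a
    gene whose concordance sign contradicts its region (posterior genes
    should track survival positively, anterior negatively) is emitted with
    a conflict flag rather than dropped.  Output is sorted by region then
    gene_id; with ``return_diagnostics`` a per-gene filter table over all
    examined genes is returned alongside.
    """
    matrix = roi_pair.matrix
    gene_index = {g: i for i, g in enumerate(matrix.genes)}
    values_a, values_b = roi_pair.values_a, roi_pair.values_b
    lateral = np.abs(matrix.voxels["z_um"].to_numpy()) <= max_lateral_um
    labels = matrix.voxels["label"].to_numpy()
    segment_masks = {
        seg: lateral & (labels == seg) for seg in sorted(set(labels))
    }
    results: list[CandidateGene] = []
    diag_rows = []
    for gene_id in candidate_genes:
        i = gene_index[gene_id]
        frac_a, frac_b, det_pass, direction = detectability_filter(
            values_a[i], values_b[i], threshold, min_fraction
        )
        row = matrix.values[i]
        profile = {}
        for seg, sel in segment_masks.items():
            vals = row[sel]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                profile[seg] = float(vals.mean())
        try:
            score, scoreable = pattern_concordance(profile, pattern)
        except ValueError:
            score, scoreable = float("nan"), False
        conc_pass = scoreable and abs(score) >= concordance_min
        is_candidate = det_pass and conc_pass
        conflict = False
        if is_candidate:
            assert direction is not None
            expected_sign = 1.0 if direction == "posterior" else -1.0
            conflict = bool(np.sign(score) != expected_sign)
            results.append(
                CandidateGene(
                    gene_id=gene_id,
                    region=direction,
                    detect_fraction_a=frac_a,
                    detect_fraction_b=frac_b,
                    concordance=score,
                    passed_filters={"detectability": det_pass, "concordance": conc_pass},
                    conflict=conflict,
                )
            )
        diag_rows.append({
            "gene_id": gene_id,
            "detect_fraction_a": frac_a,
            "detect_fraction_b": frac_b,
            "detect_pass": det_pass,
            "direction": direction,
            "concordance": score,
            "scoreable": scoreable,
            "concordance_pass": conc_pass,
            "candidate": is_candidate,
            "conflict": conflict,
        })
    results.sort(key=lambda c: (c.region, c.gene_id))
    if return_diagnostics:
        return results, pd.DataFrame(diag_rows)
    return results


@dataclass
class ClusterResult:
    """Deterministic two-way ordering of the candidate sub-matrix."""

    gene_order: list[str]
    voxel_order: np.ndarray
    gene_linkage: np.ndarray | None
    voxel_linkage: np.ndarray | None
    two_cluster_labels: dict[str, int]


def _correlation_distance(values: np.ndarray) -> np.ndarray:
    """1 - Pearson correlation between rows; zero-variance rows pin to distance 1."""
    centered = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    unit = centered / safe[:, None]
    corr = unit @ unit.T
    zero = norms == 0
    corr[zero, :] = 0.0
    corr[:, zero] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    return dist[np.triu_indices_from(dist, k=1)]


def cluster_candidates(
    values: np.ndarray, gene_ids: list[str]
) -> ClusterResult:
    """Average-linkage two-way clustering for heatmap display.

    Genes (rows) cluster on correlation distance, voxels (columns) on
    Euclidean distance; leaf orders are deterministic for identical input.
    The 2-cluster gene cut is returned for anterior/posterior separation
    checks.  A single candidate degenerates to a single-leaf result.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != len(gene_ids):
        raise ValueError("values must be (len(gene_ids), n_voxels)")
    if len(gene_ids) < 2:
        return ClusterResult(
            gene_order=list(gene_ids),
            voxel_order=np.arange(values.shape[1]),
            gene_linkage=None,
            voxel_linkage=None,
            two_cluster_labels={g: 1 for g in gene_ids},
        )
    gene_link = hierarchy.linkage(_correlation_distance(values), method="average")
    gene_leaves = hierarchy.leaves_list(gene_link)
    if values.shape[1] >= 2:
        voxel_link = hierarchy.linkage(pdist(values.T), method="average")
        voxel_leaves = hierarchy.leaves_list(voxel_link)
    else:
        voxel_link = None
        voxel_leaves = np.arange(values.shape[1])
    cut = hierarchy.fcluster(gene_link, t=2, criterion="maxclust")
    return ClusterResult(
        gene_order=[gene_ids[i] for i in gene_leaves],
        voxel_order=voxel_leaves,
        gene_linkage=gene_link,
        voxel_linkage=voxel_link,
        two_cluster_labels={g: int(c) for g, c in zip(gene_ids, cut)},
    )


def linkage_to_newick(linkage: np.ndarray, leaf_names: list[str]) -> str:
    """Render a SciPy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(linkage)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.get_left(), node.dist)
        right = render(node.get_right(), node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"


def enrichment(
    candidates: set[str] | list[str],
    annotation: pd.DataFrame,
    universe: set[str] | list[str],
    alpha: float = 0.01,
    correct: bool = False,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of annotation terms among candidates.

    ``annotation`` is a two-column table (gene_id, term_id).  For a term
    annotating K of the N universe genes, the upper-tail probability of
    seeing >= k annotated genes among the n candidates is
    ``hypergeom.sf(k - 1, N, K, n)``.  Terms with p < alpha (default 0.01)
    are flagged significant; no multiplicity correction by default, a
    Bonferroni correction across terms behind ``correct=True``.
    """
    universe = set(universe)
    candidates = set(candidates)
    stray = candidates - universe
    if stray:
        raise ValueError(f"candidates absent from universe: {sorted(stray)[:5]}")
    ann = annotation.loc[annotation["gene_id"].isin(universe)]
    n, N = len(candidates), len(universe)
    results = []
    terms = ann.groupby("term_id")["gene_id"].agg(set)
    n_terms = len(terms)
    for term_id, genes in sorted(terms.items()):
        K = len(genes)
        k = len(genes & candidates)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        p_eff = min(1.0, p * n_terms) if correct else p
        results.append(
            EnrichmentResult(
                term_id=str(term_id), k=k, K=K, n=n, N=N, p=p,
                significant=p_eff < alpha,
            )
        )
    results.sort(key=lambda r: (r.p, r.term_id))
    return results
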