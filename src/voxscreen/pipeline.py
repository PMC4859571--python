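"""End-to-end screen: simulate/ingest -> matrix -> statistics -> curation -> report.

A single :class:`ScreenConfig` drives the whole funnel; a single global
seed fans out deterministically to the atlas generator and the SAM
permutation stream, so identical (config, seed) reproduce the output
tables byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atlas_io import (
    AnnotationVolume,
    RoiSpec,
    build_matrix,
    load_annotation,
    load_volumes,
    select_roi_pair,
)
from .curation import classify_candidates, cluster_candidates, enrichment, linkage_to_newick
from .diffexpr import SamParams, sam_screen, t_screen, top_n_union
from .synthetic_atlas import AtlasConfig, generate_atlas, generate_survival_pattern

__all__ = ["ScreenConfig", "ScreenReport", "run_screen"]

logger = logging.getLogger(__name__)


@dataclass
class ScreenConfig:
    """Full configuration of one screen run.

    Defaults encode the screen's printed settings: ROI lateral bound
    1400 um, top 1000 genes per method, enrichment alpha 0.01.  With no
    input paths the atlas is simulated inline from ``atlas``.
    """

    atlas: AtlasConfig = field(default_factory=AtlasConfig)
    volumes_path: str | None = None
    annotation_path: str | None = None
    roi_a_labels: tuple[str, ...] = ("II", "III")
    roi_b_labels: tuple[str, ...] = ("X",)
    max_lateral_um: float = 1400.0
    sam: SamParams = field(default_factory=SamParams)
    top_n: int = 1000
    detect_threshold: float = 0.0
    detect_min_fraction: float = 0.1
    concordance_min: float = 0.7
    enrichment_alpha: float = 0.01
    annotation_table: str | None = None  # optional gene_id/term_id TSV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        # Fan the global seed out to per-stage streams.
        state = np.random.SeedSequence(self.seed).generate_state(2)
        self.atlas = dataclasses.replace(self.atlas, seed=int(state[0] % 2**31))
        self.sam = dataclasses.replace(self.sam, seed=int(state[1] % 2**31))

    @classmethod
    def from_file(cls, path: str | Path) -> "ScreenConfig":
        """Flat key/value YAML; atlas.* and sam.* keys prefixed."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        atlas_kw = {k[6:]: v for k, v in raw.items() if k.startswith("atlas_")}
        sam_kw = {k[4:]: v for k, v in raw.items() if k.startswith("sam_")}
        top = {
            k: v
            for k, v in raw.items()
            if not k.startswith(("atlas_", "sam_"))
        }
        if "grid_shape" in atlas_kw:
            atlas_kw["grid_shape"] = tuple(atlas_kw["grid_shape"])
        for key in ("roi_a_labels", "roi_b_labels"):
            if key in top:
                top[key] = tuple(top[key])
        return cls(atlas=AtlasConfig(**atlas_kw), sam=SamParams(**sam_kw), **top)

    def to_flat_dict(self) -> dict:
        out = {}
        for k, v in dataclasses.asdict(self.atlas).items():
            if k == "lobule_map":
                continue
            out[f"atlas_{k}"] = list(v) if isinstance(v, tuple) else v
        for k, v in dataclasses.asdict(self.sam).items():
            out[f"sam_{k}"] = v
        for f in dataclasses.fields(self):
            if f.name in ("atlas", "sam"):
                continue
            v = getattr(self, f.name)
            out[f.name] = list(v) if isinstance(v, tuple) else v
        return out


@dataclass
class ScreenReport:
    """Funnel counts and provenance of one run."""

    counts: dict[str, int]
    candidates_by_region: dict[str, int]
    config: dict
    version: str
    s0: float
    exact_permutations: bool

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    """Decorator-ish context: re-raise stage errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done", name)
            return False

    return _Ctx()


def run_screen(
    config: ScreenConfig, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, ScreenReport]:
    """Execute the whole funnel; optionally write all artifacts under out_dir.

    Returns (per-gene results table, candidate table, report).  The results
    table carries both methods' statistics, filter diagnostics and the
    final anterior/posterior call per gene.
    """
    with _stage("simulate/ingest"):
        if config.volumes_path is not None:
            volumes = load_volumes(config.volumes_path)
            if config.annotation_path is None:
                raise ValueError("annotation_path required with volumes_path")
            annotation: AnnotationVolume = load_annotation(config.annotation_path)
            truth = None
        else:
            if config.atlas.n_genes < 1:
                raise ValueError("n_genes must be >= 1 to run the screen")
            volumes, annotation, truth = generate_atlas(config.atlas)

    with _stage("matrix"):
        matrix = build_matrix(volumes, annotation)
        roi_a = RoiSpec("vulnerable", frozenset(config.roi_a_labels), config.max_lateral_um)
        roi_b = RoiSpec("resistant", frozenset(config.roi_b_labels), config.max_lateral_um)
        pair = select_roi_pair(matrix, roi_a, roi_b)

    with _stage("statistics"):
        t_res = t_screen(pair.values_a, pair.values_b, matrix.genes)
        sam_res = sam_screen(pair.values_a, pair.values_b, matrix.genes, config.sam)
        hits = top_n_union(t_res, sam_res, config.top_n)

    with _stage("curation"):
        pattern = generate_survival_pattern(annotation)
        union_sorted = sorted(hits.union)
        candidates, diag = classify_candidates(
            pair,
            union_sorted,
            pattern,
            threshold=config.detect_threshold,
            min_fraction=config.detect_min_fraction,
            concordance_min=config.concordance_min,
            max_lateral_um=config.max_lateral_um,
            return_diagnostics=True,
        )
        cand_ids = [c.gene_id for c in candidates]
        rows = [matrix.genes.index(g) for g in cand_ids]
        cols = np.concatenate([pair.idx_a, pair.idx_b])
        clust = (
            cluster_candidates(matrix.values[np.ix_(rows, cols)], cand_ids)
            if len(cand_ids) >= 2
            else None
        )

    results = t_res.merge(
        sam_res.drop(columns=["tested"]), on="gene_id", how="left"
    ).merge(diag, on="gene_id", how="left")
    results["in_top_t"] = results["gene_id"].isin(hits.top_t)
    results["in_top_sam"] = results["gene_id"].isin(hits.top_sam)
    results["in_union"] = results["gene_id"].isin(hits.union)
    results["candidate"] = results["candidate"].eq(True)
    results.loc[~results["candidate"], "direction"] = None
    results = results.sort_values("gene_id").reset_index(drop=True)

    cand_table = pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "region": c.region,
                "detect_fraction_a": c.detect_fraction_a,
                "detect_fraction_b": c.detect_fraction_b,
                "concordance": c.concordance,
                "conflict": c.conflict,
            }
            for c in candidates
        ],
        columns=[
            "gene_id", "region", "detect_fraction_a", "detect_fraction_b",
            "concordance", "conflict",
        ],
    )

    counts = {
        "genes": len(matrix.genes),
        "tested": int(t_res["tested"].sum()),
        "top_t": len(hits.top_t),
        "top_sam": len(hits.top_sam),
        "union": len(hits.union),
        "post_detectability": int(diag["detect_pass"].sum()) if len(diag) else 0,
        "post_concordance": int(diag["candidate"].sum()) if len(diag) else 0,
        "candidates": len(candidates),
    }
    by_region = {
        "posterior": sum(c.region == "posterior" for c in candidates),
        "anterior": sum(c.region == "anterior" for c in candidates),
    }
    report = ScreenReport(
        counts=counts,
        candidates_by_region=by_region,
        config=config.to_flat_dict(),
        version=__version__,
        s0=float(sam_res["s0"].iloc[0]),
        exact_permutations=bool(sam_res["exact_permutations"].iloc[0]),
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        results.to_csv(out / "results.tsv", sep="\t", index=False, float_format="%.10g")
        cand_table.to_csv(out / "candidates.tsv", sep="\t", index=False, float_format="%.10g")
        (out / "report.json").write_text(
            json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        if clust is not None and clust.gene_linkage is not None:
            (out / "dendrogram.newick").write_text(
                linkage_to_newick(clust.gene_linkage, cand_ids) + "\n"
            )
            ordered = matrix.values[np.ix_(
                [matrix.genes.index(g) for g in clust.gene_order],
                cols[clust.voxel_order],
            )]
            heat = pd.DataFrame(
                ordered, index=pd.Index(clust.gene_order, name="gene_id")
            )
            heat.columns = [f"v{j}" for j in cols[clust.voxel_order]]
            heat.to_csv(out / "heatmap_matrix.tsv", sep="\t", float_format="%.10g")
        if config.annotation_table is not None:
            ann = pd.read_csv(config.annotation_table, sep="\t")
            universe = set(results.loc[results["tested"], "gene_id"])
            enr = enrichment(
                set(cand_ids) & universe, ann, universe, alpha=config.enrichment_alpha
            )
            pd.DataFrame([dataclasses.asdict(e) for e in enr]).to_csv(
                out / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
            )

    return results, cand_table, report
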