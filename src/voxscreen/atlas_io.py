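"""Volumetric expression data: containers, file formats, matrix assembly, ROI selection.

The screen's central object is a gene x voxel matrix built from per-gene
3-D "expression energy" grids plus an integer annotation volume that labels
each voxel with a cerebellar lobule (or background).  Axes are ordered
(anterior-posterior, dorsal-ventral, medio-lateral); physical coordinates
are voxel centers in micrometers, with the medio-lateral (ML) coordinate
zeroed at the midline plane.

On-disk formats are all plain text: a minimal ASCII-encoded NRRD (one grid
per file) or a long-format TSV (gene_id, x, y, z, energy); annotation label
names travel in a two-column TSV sidecar.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionVolume",
    "AnnotationVolume",
    "ExpressionMatrix",
    "RoiSpec",
    "RoiPair",
    "read_nrrd",
    "write_nrrd",
    "load_volumes",
    "write_volumes",
    "load_annotation",
    "write_annotation",
    "build_matrix",
    "select_roi_pair",
    "write_matrix",
    "load_matrix",
]

BACKGROUND_LABEL = "background"


@dataclass
class ExpressionVolume:
    """One gene's 3-D expression-energy grid with voxel geometry."""

    gene_id: str
    grid: np.ndarray  # float, shape (n_ap, n_dv, n_ml); NaN = missing
    voxel_size_um: float = 200.0
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"{self.gene_id}: grid must be 3-D, got {self.grid.ndim}-D")
        finite = self.grid[np.isfinite(self.grid)]
        if finite.size and finite.min() < 0:
            raise ValueError(f"{self.gene_id}: negative expression energy")


@dataclass
class AnnotationVolume:
    """Integer label grid plus label code -> name mapping (code 0 = background)."""

    labels: np.ndarray  # int, same shape as expression grids
    names: dict[int, str]
    voxel_size_um: float = 200.0
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if 0 not in self.names:
            self.names = {0: BACKGROUND_LABEL, **self.names}

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def name_of(self, code: int) -> str:
        return self.names[int(code)]

    def segment_names(self) -> list[str]:
        """Non-background label names present in the volume, sorted."""
        present = np.unique(self.labels)
        return sorted(self.names[c] for c in present if c != 0)

    def ml_coordinate(self, k: int | np.ndarray) -> np.ndarray:
        """Physical ML coordinate (um) of voxel center(s) at ML index k."""
        return self.origin_um[2] + np.asarray(k) * self.voxel_size_um


class ExpressionMatrix:
    """Genes x voxels energy matrix with per-voxel coordinates and labels.

    Rows follow lexicographic gene_id order; columns follow raster order of
    the non-background voxels (C order over the grid).  Missing values are
    NaN.
    """

    def __init__(self, genes: Sequence[str], voxels: pd.DataFrame, values: np.ndarray):
        genes = list(genes)
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene_ids in matrix")
        values = np.asarray(values, dtype=float)
        if values.shape != (len(genes), len(voxels)):
            raise ValueError(
                f"values shape {values.shape} != ({len(genes)}, {len(voxels)})"
            )
        self.genes = genes
        self.voxels = voxels.reset_index(drop=True)
        self.values = values

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.genes.index(gene_id)]


@dataclass(frozen=True)
class RoiSpec:
    """Region of interest: lobule label set plus a bound on |ML| of voxel centers.

    The default lateral bound of 1400 um matches the screen's midline
    corridor; the bound is inclusive (|ML| <= max_lateral_um).
    """

    name: str
    labels: frozenset[str]
    max_lateral_um: float = 1400.0

    def __post_init__(self) -> None:
        if not self.labels:
            raise ValueError(f"RoiSpec {self.name!r}: empty label set")
        if self.max_lateral_um <= 0:
            raise ValueError(f"RoiSpec {self.name!r}: max_lateral_um must be > 0")

    def mask(self, voxels: pd.DataFrame) -> np.ndarray:
        """Boolean mask over matrix voxel records satisfying the ROI predicate."""
        in_labels = voxels["label"].isin(self.labels).to_numpy()
        lateral = np.abs(voxels["z_um"].to_numpy()) <= self.max_lateral_um
        return in_labels & lateral


@dataclass
class RoiPair:
    """Two disjoint voxel groups for a two-group contrast.

    Group "a" is the vulnerable region (anterior lobules II/III by default),
    group "b" the resistant one (lobule X).  Selected voxel columns are
    treated downstream as replicate observations.
    """

    roi_a: RoiSpec
    roi_b: RoiSpec
    matrix: ExpressionMatrix
    idx_a: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    idx_b: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    @property
    def values_a(self) -> np.ndarray:
        return self.matrix.values[:, self.idx_a]

    @property
    def values_b(self) -> np.ndarray:
        return self.matrix.values[:, self.idx_b]

    @property
    def genes(self) -> list[str]:
        return self.matrix.genes


# ---------------------------------------------------------------------------
# Minimal ASCII NRRD codec.  Only what this package writes is supported:
# NRRD0004, encoding "ascii", types "double"/"int", dimension 3, data stored
# in C order with sizes listed as the numpy shape.

_NRRD_MAGIC = "NRRD0004"


def write_nrrd(
    path: str | Path,
    array: np.ndarray,
    voxel_size_um: float,
    origin_um: Sequence[float] = (0.0, 0.0, 0.0),
    extra: Mapping[str, str] | None = None,
) -> None:
    array = np.asarray(array)
    dtype = "int" if np.issubdtype(array.dtype, np.integer) else "double"
    lines = [
        _NRRD_MAGIC,
        "# ascii nrrd; data in C order, sizes = numpy shape",
        f"type: {dtype}",
        f"dimension: {array.ndim}",
        "sizes: " + " ".join(str(s) for s in array.shape),
        "encoding: ascii",
        "spacings: " + " ".join(f"{voxel_size_um:g}" for _ in array.shape),
        "origin_um:=" + " ".join(f"{v:g}" for v in origin_um),
    ]
    for key, val in (extra or {}).items():
        lines.append(f"{key}:={val}")
    flat = array.ravel(order="C")
    if dtype == "int":
        body = " ".join(str(int(v)) for v in flat)
    else:
        body = " ".join(f"{float(v):.17g}" for v in flat)
    Path(path).write_text("\n".join(lines) + "\n\n" + body + "\n")


def read_nrrd(path: str | Path) -> tuple[np.ndarray, float, tuple[float, ...], dict[str, str]]:
    """Return (array, voxel_size_um, origin_um, extra key-values)."""
    text = Path(path).read_text()
    header_text, _, body = text.partition("\n\n")
    lines = header_text.splitlines()
    if not lines or not lines[0].startswith("NRRD"):
        raise ValueError(f"{path}: not an NRRD file")
    fields: dict[str, str] = {}
    extra: dict[str, str] = {}
    for line in lines[1:]:
        if not line or line.startswith("#"):
            continue
        if ":=" in line:
            key, _, val = line.partition(":=")
            extra[key.strip()] = val.strip()
        elif ":" in line:
            key, _, val = line.partition(":")
            fields[key.strip()] = val.strip()
    if fields.get("encoding") != "ascii":
        raise ValueError(f"{path}: only ascii encoding supported")
    shape = tuple(int(s) for s in fields["sizes"].split())
    dtype = int if fields.get("type") == "int" else float
    data = np.array(body.split(), dtype=dtype).reshape(shape, order="C")
    spacing = float(fields["spacings"].split()[0])
    origin = tuple(float(v) for v in extra.pop("origin_um", "0 0 0").split())
    return data, spacing, origin, extra


# ---------------------------------------------------------------------------
# Volume I/O: per-gene NRRD directory or long-format TSV.

_LONG_COLUMNS = ["gene_id", "x", "y", "z", "energy"]


def write_volumes(
    volumes: Iterable[ExpressionVolume], out: str | Path, fmt: str = "nrrd"
) -> None:
    """Write volumes as one NRRD per gene under a directory, or one long TSV."""
    out = Path(out)
    volumes = list(volumes)
    if fmt == "nrrd":
        out.mkdir(parents=True, exist_ok=True)
        for vol in volumes:
            write_nrrd(
                out / f"{vol.gene_id}.nrrd",
                vol.grid,
                vol.voxel_size_um,
                vol.origin_um,
                extra={"gene_id": vol.gene_id},
            )
    elif fmt == "tsv":
        rows = []
        for vol in volumes:
            idx = np.argwhere(np.isfinite(vol.grid))
            frame = pd.DataFrame(idx, columns=["x", "y", "z"])
            frame.insert(0, "gene_id", vol.gene_id)
            frame["energy"] = vol.grid[tuple(idx.T)]
            rows.append(frame)
        table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=_LONG_COLUMNS)
        out.parent.mkdir(parents=True, exist_ok=True)
        table.to_csv(out, sep="\t", index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown volume format {fmt!r}")


def load_volumes(
    path: str | Path,
    grid_shape: tuple[int, int, int] | None = None,
    voxel_size_um: float = 200.0,
    origin_um: Sequence[float] = (0.0, 0.0, 0.0),
) -> list[ExpressionVolume]:
    """Load volumes from an NRRD directory or a long-format TSV file.

    Both routes produce identical grids for round-tripped data.  For the TSV
    route the grid shape is inferred from the maximal voxel index unless
    given; voxels absent from the table are missing (NaN).
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(path.glob("*.nrrd"))
        if not files:
            raise FileNotFoundError(f"no volumes found in {path}")
        volumes = []
        seen: set[str] = set()
        shape_ref: tuple[int, ...] | None = None
        for f in files:
            grid, spacing, origin, extra = read_nrrd(f)
            gene_id = extra.get("gene_id", f.stem)
            if gene_id in seen:
                raise ValueError(f"duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if shape_ref is None:
                shape_ref = grid.shape
            elif grid.shape != shape_ref:
                raise ValueError(
                    f"{f.name}: grid shape {grid.shape} != {shape_ref}"
                )
            volumes.append(ExpressionVolume(gene_id, grid, spacing, tuple(origin)))
        return volumes
    if not path.exists():
        raise FileNotFoundError(f"no volumes found at {path}")
    table = pd.read_csv(path, sep="\t")
    missing_cols = set(_LONG_COLUMNS) - set(table.columns)
    if missing_cols:
        raise ValueError(f"long-format TSV missing columns {sorted(missing_cols)}")
    if table.empty:
        raise ValueError(f"no volumes found in {path}")
    if grid_shape is None:
        grid_shape = tuple(int(table[c].max()) + 1 for c in ("x", "y", "z"))  # type: ignore[assignment]
    volumes = []
    for gene_id, sub in table.groupby("gene_id", sort=True):
        grid = np.full(grid_shape, np.nan)
        ix = sub[["x", "y", "z"]].to_numpy(dtype=int)
        if len(np.unique(ix, axis=0)) != len(ix):
            raise ValueError(f"duplicate voxel rows for gene {gene_id!r}")
        grid[ix[:, 0], ix[:, 1], ix[:, 2]] = sub["energy"].to_numpy()
        volumes.append(ExpressionVolume(str(gene_id), grid, voxel_size_um, tuple(origin_um)))
    return volumes


def write_annotation(annotation: AnnotationVolume, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_nrrd(
        out_dir / "annotation.nrrd",
        annotation.labels,
        annotation.voxel_size_um,
        annotation.origin_um,
    )
    labels = pd.DataFrame(
        sorted(annotation.names.items()), columns=["code", "name"]
    )
    labels.to_csv(out_dir / "labels.tsv", sep="\t", index=False)


def load_annotation(path: str | Path) -> AnnotationVolume:
    path = Path(path)
    grid, spacing, origin, _ = read_nrrd(path / "annotation.nrrd")
    labels = pd.read_csv(path / "labels.tsv", sep="\t")
    names = {int(r.code): str(r.name) for r in labels.itertuples()}
    return AnnotationVolume(grid.astype(int), names, spacing, tuple(origin))


# ---------------------------------------------------------------------------
# Matrix assembly and ROI selection.


def build_matrix(
    volumes: Sequence[ExpressionVolume], annotation: AnnotationVolume
) -> ExpressionMatrix:
    """Assemble the gene x voxel matrix over non-background voxels.

    Gene order is lexicographic; voxel order is raster (C) order over the
    annotation grid.  Raises on geometry mismatch or if no voxel carries a
    non-background label.
    """
    if not volumes:
        raise ValueError("no volumes to assemble")
    shape = annotation.shape
    for vol in volumes:
        if vol.grid.shape != shape:
            raise ValueError(
                f"{vol.gene_id}: grid shape {vol.grid.shape} != annotation {shape}"
            )
    keep = annotation.labels != 0
    if not keep.any():
        raise ValueError("no annotated voxels (all background)")
    idx = np.argwhere(keep)  # raster order
    voxels = pd.DataFrame(idx, columns=["i", "j", "k"])
    for axis, col in enumerate(["x_um", "y_um", "z_um"]):
        voxels[col] = annotation.origin_um[axis] + idx[:, axis] * annotation.voxel_size_um
    voxels["label"] = [annotation.names[c] for c in annotation.labels[keep]]
    order = np.argsort([v.gene_id for v in volumes], kind="stable")
    genes = [volumes[i].gene_id for i in order]
    values = np.vstack([volumes[i].grid[keep] for i in order])
    return ExpressionMatrix(genes, voxels, values)


def select_roi_pair(
    matrix: ExpressionMatrix, roi_a: RoiSpec, roi_b: RoiSpec
) -> RoiPair:
    """Select the two ROI voxel groups: label in the ROI's set and |ML| within bound."""
    mask_a = roi_a.mask(matrix.voxels)
    mask_b = roi_b.mask(matrix.voxels)
    if not mask_a.any():
        raise ValueError(f"ROI {roi_a.name!r} selects no voxels")
    if not mask_b.any():
        raise ValueError(f"ROI {roi_b.name!r} selects no voxels")
    if (mask_a & mask_b).any():
        raise ValueError(
            f"ROIs {roi_a.name!r} and {roi_b.name!r} overlap; label sets must be disjoint"
        )
    return RoiPair(
        roi_a=roi_a,
        roi_b=roi_b,
        matrix=matrix,
        idx_a=np.flatnonzero(mask_a),
        idx_b=np.flatnonzero(mask_b),
    )


def write_matrix(matrix: ExpressionMatrix, out_dir: str | Path) -> None:
    """Matrix TSV (genes x voxels) plus voxel-metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(matrix.values, index=pd.Index(matrix.genes, name="gene_id"))
    frame.columns = [f"v{j}" for j in range(matrix.shape[1])]
    frame.to_csv(out_dir / "matrix.tsv", sep="\t", float_format="%.17g")
    matrix.voxels.to_csv(out_dir / "voxels.tsv", sep="\t", index=False)


def load_matrix(path: str | Path) -> ExpressionMatrix:
    path = Path(path)
    frame = pd.read_csv(path / "matrix.tsv", sep="\t", index_col="gene_id")
    voxels = pd.read_csv(path / "voxels.tsv", sep="\t")
    return ExpressionMatrix(list(frame.index), voxels, frame.to_numpy())
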