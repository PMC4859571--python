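"""Synthetic volumetric expression atlas with planted region-restricted genes.

Emulates the statistical structure the screen assumes in a quantitative
in-situ-hybridization atlas: a 3-D voxel grid partitioned into labeled
cerebellar lobule segments, zero-inflated non-negative "expression energy"
per gene and voxel, a subset of genes whose expression is restricted to one
region (lobule X, or lobules II/III), and an optional shared per-sagittal-
plane batch factor mimicking the fact that voxels in one sagittal plane
derive from the same hybridization experiment.

The noise model is Bernoulli(detected) x LogNormal(mu, sigma): non-negative,
zero-inflated, with (mu, sigma) parameterized by the target mean energy and
a coefficient of variation.  Geometry is an axis-aligned block partition —
the screen only consumes voxel labels, so anatomical realism is not needed.
Axes are (anterior-posterior, dorsal-ventral, medio-lateral); the default
grid covers one hemisphere with the midline at ML index 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .atlas_io import AnnotationVolume, ExpressionVolume

__all__ = [
    "AtlasConfig",
    "SyntheticTruth",
    "default_lobule_map",
    "generate_atlas",
    "generate_survival_pattern",
    "DEFAULT_SURVIVAL_PATTERN",
]

#: Anterior-to-posterior order of the modeled lobule segments.
LOBULE_ORDER = ("II", "III", "VI", "VII", "VIII", "IX", "X")

#: Reference Purkinje-cell survival values per lobule segment, in [0, 1]:
#: 1 = fully resistant (lobule X), 0 = most vulnerable (anterior lobules
#: II/III).  Intermediate and posterior lobules show patchy survival; the
#: graded values chosen here place caudal-lobule-IX sparing (IX) above
#: lobule VIII, and the spared VI/VII boundary slightly above VI.
DEFAULT_SURVIVAL_PATTERN: dict[str, float] = {
    "II": 0.0,
    "III": 0.0,
    "VI": 0.4,
    "VII": 0.45,
    "VIII": 0.3,
    "IX": 0.6,
    "X": 1.0,
}

POSTERIOR_LABELS = frozenset({"X"})
ANTERIOR_LABELS = frozenset({"II", "III"})


def default_lobule_map(
    grid_shape: tuple[int, int, int], voxel_size_um: float = 200.0
) -> AnnotationVolume:
    """Axis-aligned block partition of the grid into lobule segments.

    A cortical slab (central dorsal-ventral band, all ML planes) is split
    into seven equal anterior-to-posterior blocks labeled II..X; everything
    else is background.  ML origin is the midline (ML index 0).
    """
    n_ap, n_dv, n_ml = grid_shape
    labels = np.zeros(grid_shape, dtype=int)
    dv_lo, dv_hi = n_dv // 5, n_dv - n_dv // 5
    edges = np.linspace(0, n_ap, len(LOBULE_ORDER) + 1).round().astype(int)
    names = {0: "background"}
    for code, name in enumerate(LOBULE_ORDER, start=1):
        labels[edges[code - 1] : edges[code], dv_lo:dv_hi, :] = code
        names[code] = name
    return AnnotationVolume(labels, names, voxel_size_um, (0.0, 0.0, 0.0))


@dataclass
class AtlasConfig:
    """Parameters of the synthetic atlas.

    ``effect_energy`` is the mean energy of planted genes inside their
    expressing lobules; ``background_energy`` the mean energy of null genes
    everywhere (defaults to ``effect_energy`` so null genes occupy the same
    scale).  ``zero_inflation`` is the probability that a null gene is
    undetected (energy 0) at a voxel.  ``plane_batch_sd`` adds a per-gene,
    per-sagittal-plane multiplicative log-normal batch factor shared by all
    voxels of that plane.
    """

    grid_shape: tuple[int, int, int] = (40, 20, 29)
    voxel_size_um: float = 200.0
    lobule_map: AnnotationVolume | None = None
    n_genes: int = 2000
    n_posterior: int = 20
    n_anterior: int = 20
    effect_energy: float = 2.0
    background_energy: float | None = None
    zero_inflation: float = 0.3
    noise_cv: float = 0.3
    plane_batch_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lobule_map is None:
            self.lobule_map = default_lobule_map(self.grid_shape, self.voxel_size_um)
        if self.background_energy is None:
            self.background_energy = self.effect_energy
        self.validate()

    def validate(self) -> None:
        if self.n_genes < 0 or self.n_posterior < 0 or self.n_anterior < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_posterior + self.n_anterior > self.n_genes:
            raise ValueError(
                "invariant violated: n_posterior + n_anterior <= n_genes "
                f"({self.n_posterior} + {self.n_anterior} > {self.n_genes})"
            )
        if self.effect_energy <= 0:
            raise ValueError("invariant violated: effect_energy > 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("invariant violated: 0 <= zero_inflation <= 1")
        if self.noise_cv < 0 or self.plane_batch_sd < 0:
            raise ValueError("noise_cv and plane_batch_sd must be >= 0")
        assert self.lobule_map is not None
        if self.lobule_map.shape != tuple(self.grid_shape):
            raise ValueError(
                f"lobule_map shape {self.lobule_map.shape} != grid_shape {self.grid_shape}"
            )
        missing = (POSTERIOR_LABELS | ANTERIOR_LABELS) - set(self.lobule_map.names.values())
        if missing:
            raise ValueError(f"lobule_map missing labels {sorted(missing)}")


@dataclass
class SyntheticTruth:
    """Ground truth of planted differential genes for recovery scoring."""

    direction: dict[str, str]  # gene_id -> "posterior" | "anterior" | "null"
    effect_energy: dict[str, float] = field(default_factory=dict)
    expressing_labels: dict[str, frozenset[str]] = field(default_factory=dict)

    def planted(self, which: str | None = None) -> set[str]:
        if which is None:
            return {g for g, d in self.direction.items() if d != "null"}
        return {g for g, d in self.direction.items() if d == which}


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given mean and coefficient of variation."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_atlas(
    config: AtlasConfig,
) -> tuple[list[ExpressionVolume], AnnotationVolume, SyntheticTruth]:
    """Generate per-gene expression volumes, the annotation volume, and truth.

    Planted posterior genes have positive mean energy only in voxels labeled
    X (anterior genes in II/III) and are zero elsewhere; null genes follow
    the zero-inflated log-normal noise model everywhere.  Identical config
    and seed give bit-identical output.
    """
    config.validate()
    annotation = config.lobule_map
    assert annotation is not None
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    n_ml = shape[2]

    names = {name: code for code, name in annotation.names.items()}
    post_mask = np.isin(annotation.labels, [names[l] for l in sorted(POSTERIOR_LABELS)])
    ant_mask = np.isin(annotation.labels, [names[l] for l in sorted(ANTERIOR_LABELS)])

    width = max(4, len(str(max(config.n_genes - 1, 0))))
    gene_ids = [f"gene_{i:0{width}d}" for i in range(config.n_genes)]
    order = rng.permutation(config.n_genes)
    posterior = {gene_ids[i] for i in order[: config.n_posterior]}
    anterior = {
        gene_ids[i]
        for i in order[config.n_posterior : config.n_posterior + config.n_anterior]
    }

    mu_e, sigma = _lognormal_params(config.effect_energy, config.noise_cv)
    mu_0, _ = _lognormal_params(config.background_energy, config.noise_cv)

    direction: dict[str, str] = {}
    effect: dict[str, float] = {}
    expressing: dict[str, frozenset[str]] = {}
    volumes: list[ExpressionVolume] = []
    for gene_id in gene_ids:
        if gene_id in posterior:
            direction[gene_id] = "posterior"
            mask = post_mask
            labels = frozenset(POSTERIOR_LABELS)
        elif gene_id in anterior:
            direction[gene_id] = "anterior"
            mask = ant_mask
            labels = frozenset(ANTERIOR_LABELS)
        else:
            direction[gene_id] = "null"
            mask = None
            labels = frozenset()
        if mask is not None:
            grid = np.zeros(shape)
            grid[mask] = rng.lognormal(mu_e, sigma, size=int(mask.sum()))
            effect[gene_id] = config.effect_energy
            expressing[gene_id] = labels
        else:
            detected = rng.random(shape) >= config.zero_inflation
            grid = np.where(detected, rng.lognormal(mu_0, sigma, size=shape), 0.0)
        if config.plane_batch_sd > 0:
            batch = np.exp(rng.normal(0.0, config.plane_batch_sd, size=n_ml))
            grid = grid * batch[None, None, :]
        volumes.append(
            ExpressionVolume(gene_id, grid, config.voxel_size_um, annotation.origin_um)
        )
    truth = SyntheticTruth(direction, effect, expressing)
    return volumes, annotation, truth


def generate_survival_pattern(
    lobule_map: AnnotationVolume,
    values: dict[str, float] | None = None,
) -> dict[str, float]:
    """Reference Purkinje-cell survival pattern over the lobule segments.

    Returns segment name -> survival value in [0, 1]; lobule X maps to 1
    (fully resistant), anterior lobules II/III to 0, intermediate and
    posterior segments to graded values.  ``values`` overrides the default
    graded pattern.
    """
    values = dict(DEFAULT_SURVIVAL_PATTERN if values is None else values)
    segments = lobule_map.segment_names()
    missing = [s for s in segments if s not in values]
    if missing:
        raise ValueError(f"survival pattern missing labels {missing}")
    pattern = {s: float(values[s]) for s in segments}
    bad = {s: v for s, v in pattern.items() if not 0.0 <= v <= 1.0}
    if bad:
        raise ValueError(f"survival values outside [0, 1]: {bad}")
    return pattern
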