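"""Simulate a demonstration atlas with planted region-restricted genes.

Generates a small synthetic expression-energy atlas (150 genes on a
21 x 10 x 9 voxel grid, 4 genes restricted to lobule X and 4 to lobules
II/III), and writes the ground truth, the lobule annotation, and the
reference Purkinje-cell survival pattern under results/demo/.  The
expression volumes themselves are not persisted: the generator is
seeded, so downstream steps regenerate them deterministically from the
same configuration.
"""

from pathlib import Path

import pandas as pd

from voxscreen.atlas_io import write_annotation
from voxscreen.diffexpr import SamParams
from voxscreen.pipeline import ScreenConfig
from voxscreen.synthetic_atlas import AtlasConfig, generate_atlas, generate_survival_pattern

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"

# One shared configuration for the whole demo; the pipeline fans the global
# seed out to the atlas and SAM permutation streams, so the atlas generated
# here is exactly the one the screen in 02 re-derives.
DEMO_CONFIG = ScreenConfig(
    atlas=AtlasConfig(grid_shape=(21, 10, 9), n_genes=150, n_posterior=4, n_anterior=4),
    sam=SamParams(n_permutations=200),
    top_n=30,  # 20% of the demo's 150 genes; the full-scale default is 1000
    seed=0,
)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    volumes, annotation, truth = generate_atlas(DEMO_CONFIG.atlas)
    write_annotation(annotation, OUT / "annotation")
    pd.DataFrame(
        [
            {"gene_id": g, "direction": d,
             "effect_energy": truth.effect_energy.get(g, "")}
            for g, d in sorted(truth.direction.items())
        ]
    ).to_csv(OUT / "truth.tsv", sep="\t", index=False)
    pattern = generate_survival_pattern(annotation)
    pd.DataFrame(
        sorted(pattern.items()), columns=["segment", "survival"]
    ).to_csv(OUT / "survival_pattern.tsv", sep="\t", index=False)

    planted = sorted(truth.planted())
    print(f"simulated {len(volumes)} gene volumes on grid {DEMO_CONFIG.atlas.grid_shape}")
    print(f"planted {len(planted)} differential genes: {', '.join(planted)}")
    print(f"annotation, truth and survival pattern written to {OUT}")


if __name__ == "__main__":
    main()
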