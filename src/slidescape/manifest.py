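"""Frozen enumeration of the 524-entry patch feature vector.

Every patch is summarized by exactly 524 named scalar features built
from its typed nuclei records. The enumeration below is the single
source of truth for feature names, order and grouping; it is generated
by code (not a data file) so that names, the featurizer and the
documentation can never drift apart. ``write_manifest_yaml`` exports it
for external consumers.

The core categories cover cell-type composition, per-type nuclear
morphology summaries, cross-type nearest-distance statistics, per-type
nearest-neighbor distances, the average nearest neighbor ratio (ANNR),
and Voronoi join-count autocorrelation. The remaining entries are
documented extras of the same families (pooled/all-cell variants,
pairwise count ratios, Delaunay degree summaries, densities, in-tumor
counts, distance quartiles) that complete the fixed 524-entry contract.
"""
from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

import pandas as pd
import yaml

from .core_io import CELL_TYPES, MORPHOLOGY_MEASURES

#: the seven canonical descriptive statistics used throughout
STAT_NAMES: tuple[str, ...] = (
    "mean", "median", "variance", "skewness", "kurtosis", "min", "max",
)

N_FEATURES = 524


@dataclass(frozen=True)
class FeatureSpec:
    name: str
    category: str
    description: str


def _pairs() -> list[tuple[str, str]]:
    """The 15 unordered cross-type pairs, in CELL_TYPES order."""
    return list(combinations(CELL_TYPES, 2))


@lru_cache(maxsize=1)
def build_manifest() -> tuple[FeatureSpec, ...]:
    specs: list[FeatureSpec] = []

    def add(name, category, description):
        specs.append(FeatureSpec(name, category, description))

    # 1. composition (13)
    for t in CELL_TYPES:
        add(f"count_{t}", "composition", f"number of {t} cells in the patch")
    for t in CELL_TYPES:
        add(f"frac_{t}", "composition", f"fraction of cells that are {t}")
    add("count_total", "composition", "total cell count in the patch")

    # 2. per-type morphology (6 x 4 x 7 = 168)
    for t in CELL_TYPES:
        for m in MORPHOLOGY_MEASURES:
            for s in STAT_NAMES:
                add(f"morph_{t}_{m}_{s}", "morphology",
                    f"{s} of {t} nuclear {m}")

    # 3. cross-type nearest distances (15 x 7 = 105)
    for a, b in _pairs():
        for s in STAT_NAMES:
            add(f"xdist_{a}_{b}_{s}", "cross_type_distance",
                f"{s} of symmetric nearest {a}<->{b} distances (px)")

    # 4. per-type nearest-neighbor distances (6 x 7 = 42)
    for t in CELL_TYPES:
        for s in STAT_NAMES:
            add(f"nndist_{t}_{s}", "nn_distance",
                f"{s} of {t}-to-{t} nearest neighbor distances (px)")

    # 5. ANNR per type (6)
    for t in CELL_TYPES:
        add(f"annr_{t}", "annr",
            f"average nearest neighbor ratio of {t} cells (patch-area null)")

    # 6. join-count autocorrelation per type (6)
    for t in CELL_TYPES:
        add(f"join_autocorr_{t}", "join_autocorrelation",
            f"(J_BB - J_BW)/J_T with {t} as the positive label")

    # 7. join fractions (3 x 6 = 18)
    for t in CELL_TYPES:
        for kind in ("bb", "bw", "ww"):
            add(f"join_frac_{kind}_{t}", "join_fractions",
                f"fraction of Voronoi joins of kind {kind.upper()} for focal type {t}")

    # 8. within-tumor-region cell fractions (6)
    for t in CELL_TYPES:
        add(f"tumor_region_frac_{t}", "tumor_region_fraction",
            f"fraction of {t} cells lying inside the tumor mask")

    # 9. ordered pairwise count ratios (30)
    for a, b in permutations(CELL_TYPES, 2):
        add(f"ratio_{a}_{b}", "count_ratio", f"count_{a} / count_{b}")

    # 10. pooled morphology over all cells (4 x 7 = 28)
    for m in MORPHOLOGY_MEASURES:
        for s in STAT_NAMES:
            add(f"morph_all_{m}_{s}", "pooled_morphology",
                f"{s} of nuclear {m} over all cells")

    # 11. pooled nearest-neighbor distances (7)
    for s in STAT_NAMES:
        add(f"nndist_all_{s}", "pooled_nn",
            f"{s} of all-cell nearest neighbor distances (px)")

    # 12. pooled ANNR (1)
    add("annr_all", "pooled_annr", "ANNR over all cells pooled")

    # 13. Delaunay degree statistics (7 x 7 = 49)
    for t in CELL_TYPES:
        for s in STAT_NAMES:
            add(f"degree_{t}_{s}", "degree",
                f"{s} of Voronoi-neighbor counts of {t} cells")
    for s in STAT_NAMES:
        add(f"degree_all_{s}", "degree",
            f"{s} of Voronoi-neighbor counts over all cells")

    # 14. densities (7)
    for t in CELL_TYPES:
        add(f"density_{t}", "density", f"{t} cells per mm² of patch area")
    add("density_all", "density", "all cells per mm² of patch area")

    # 15. tumor-region counts and area (8)
    for t in CELL_TYPES:
        add(f"tumor_region_count_{t}", "tumor_region_extra",
            f"number of {t} cells inside the tumor mask")
    add("tumor_region_count_total", "tumor_region_extra",
        "total cells inside the tumor mask")
    add("tumor_region_area_frac", "tumor_region_extra",
        "fraction of patch area covered by the tumor mask")

    # 16. cross-type distance quartiles (15 x 2 = 30)
    for a, b in _pairs():
        for s in ("q25", "q75"):
            add(f"xdist_{a}_{b}_{s}", "cross_type_quartiles",
                f"{s} of symmetric nearest {a}<->{b} distances (px)")

    if len(specs) != N_FEATURES:  # pragma: no cover - construction guard
        raise AssertionError(f"manifest has {len(specs)} entries, expected {N_FEATURES}")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):  # pragma: no cover
        raise AssertionError("duplicate feature names in manifest")
    return tuple(specs)


FEATURE_NAMES: tuple[str, ...] = tuple(s.name for s in build_manifest())


def manifest_frame() -> pd.DataFrame:
    """The manifest as a DataFrame (index = position in the vector)."""
    return pd.DataFrame([{"name": s.name, "category": s.category,
                          "description": s.description}
                         for s in build_manifest()])


def write_manifest_yaml(path) -> None:
    entries = [{"index": i, "name": s.name, "category": s.category,
                "description": s.description}
               for i, s in enumerate(build_manifest())]
    with open(path, "w") as fh:
        yaml.safe_dump({"n_features": N_FEATURES, "features": entries},
                       fh, sort_keys=False)
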