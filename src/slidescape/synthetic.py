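"""Synthetic cohorts of nuclei maps, region masks and attribution maps.

No public nuclei-segmentation dataset accompanies the progression-risk
analysis this package implements, so every downstream stage is
exercised on simulated slides that reproduce the *statistical structure*
the analysis assumes:

* a smooth elliptical tissue region and a tumor blob covering 20–60% of
  the tissue;
* tumor cells placed by a Thomas cluster process inside the tumor
  (Poisson parents, isotropic Gaussian offspring with dispersion σ) —
  smaller σ means tighter clustering and lower ANNR; σ = None disables
  clustering and places tumor cells by a homogeneous Poisson process
  (the CSR null);
* non-tumor cell types placed by homogeneous Poisson processes over the
  tissue at configurable per-patch densities;
* intermixing: each tumor-process cell inside the tumor mask is flipped
  to a random non-tumor type with probability ``intermix_prob``,
  lowering the tumor join-count autocorrelation;
* per-type nuclear morphology drawn from Gamma (area) and Beta
  (eccentricity/solidity/extent) distributions, with group contrasts in
  the tumor-cell parameters;
* a step-plus-noise attribution surrogate whose high-score region is
  the deep tumor interior for non-progressors and the border stripe
  (inner ring plus surrounding tissue) for progressors.

The two phenotype defaults encode the progression contrasts in the
directions reported for cSCC: progressor tumor cells cluster more
tightly, intermix more with other cell types, and have smaller, more
eccentric, less solid nuclei. Effect sizes are conventions calibrated
so that the patch-level common-language effect size on tumor-cell ANNR
between groups is ≈ 0.6–0.7; see docs/methods.md.

Everything is deterministic given (seed, config): per-slide seeds are
spawned from the cohort seed with ``numpy.random.SeedSequence``.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attribution import AttributionMap, interior_region, tumor_stripe_region
from .core_io import (CELL_TYPES, MORPHOLOGY_MEASURES, NucleiMap, Patch,
                      RegionMask, SlideGeometry, write_nuclei_map,
                      write_region_mask)

_OTHER_TYPES = tuple(t for t in CELL_TYPES if t != "tumor")

#: morphology distributions shared by both phenotypes for non-tumor types:
#: area ~ Gamma(shape, scale) in px² at 0.5 µm/px, the shape measures ~ Beta.
_BASE_MORPHOLOGY: dict[str, dict[str, tuple]] = {
    "granulocyte": {"area": ("gamma", 25.0, 6.0), "eccentricity": ("beta", 5.0, 5.0),
                    "solidity": ("beta", 20.0, 3.0), "extent": ("beta", 12.0, 5.0)},
    "lymphocyte": {"area": ("gamma", 30.0, 4.0), "eccentricity": ("beta", 4.0, 9.0),
                   "solidity": ("beta", 25.0, 2.0), "extent": ("beta", 14.0, 4.0)},
    "plasma": {"area": ("gamma", 28.0, 6.0), "eccentricity": ("beta", 6.0, 6.0),
               "solidity": ("beta", 20.0, 3.0), "extent": ("beta", 12.0, 5.0)},
    "stroma": {"area": ("gamma", 20.0, 7.0), "eccentricity": ("beta", 10.0, 3.0),
               "solidity": ("beta", 12.0, 4.0), "extent": ("beta", 8.0, 6.0)},
    "epithelial": {"area": ("gamma", 35.0, 8.0), "eccentricity": ("beta", 6.0, 7.0),
                   "solidity": ("beta", 18.0, 3.0), "extent": ("beta", 12.0, 4.0)},
}

#: cells per 256² patch; the tumor entry is the density *within* the tumor.
_DEFAULT_DENSITIES: dict[str, float] = {
    "tumor": 120.0, "stroma": 40.0, "lymphocyte": 25.0,
    "granulocyte": 8.0, "plasma": 8.0, "epithelial": 20.0,
}


@dataclass
class PhenotypeConfig:
    """Generative parameters of one patient group."""

    label: str
    tumor_cluster_scale: float | None  # Thomas offspring σ in px; None = CSR
    intermix_prob: float
    attribution_focus: str  # "interior" or "border_exterior"
    tumor_parents_per_patch: float = 5.0
    densities: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_DENSITIES))
    morphology: dict[str, dict[str, tuple]] = field(default_factory=dict)
    attribution_bonus: float = 1.0
    attribution_noise: float = 0.6
    attribution_stripe_um: float = 128.0
    #: probability that a background (non-tumor-process) cell falling inside
    #: the tumor mask is removed — tumor nests displace the surrounding tissue
    tumor_displacement: float = 0.6

    def __post_init__(self) -> None:
        if self.label not in ("progress", "non_progress"):
            raise ValueError(f"unknown label {self.label!r}")
        if not (0.0 <= self.intermix_prob <= 1.0):
            raise ValueError("intermix_prob must be in [0, 1]")
        if self.attribution_focus not in ("interior", "border_exterior"):
            raise ValueError(f"unknown attribution_focus {self.attribution_focus!r}")
        if self.tumor_cluster_scale is not None and self.tumor_cluster_scale <= 0:
            raise ValueError("tumor_cluster_scale must be positive or None")
        if self.tumor_parents_per_patch <= 0:
            raise ValueError("tumor_parents_per_patch must be positive")
        if not (0.0 <= self.tumor_displacement <= 1.0):
            raise ValueError("tumor_displacement must be in [0, 1]")
        for d in self.densities.values():
            if d < 0:
                raise ValueError("densities must be non-negative")
        for t, meas in self.morphology.items():
            for m, dist in meas.items():
                if dist[0] not in ("gamma", "beta") or min(dist[1:]) <= 0:
                    raise ValueError(f"bad distribution for {t}/{m}: {dist}")


def default_phenotype(label: str) -> PhenotypeConfig:
    """The frozen study-condition defaults for one group.

    The tumor-cell contrasts (σ, intermixing, area, eccentricity,
    solidity, extent) follow the reported progression directions; all
    other parameters are shared between groups.
    """
    morph = {t: dict(v) for t, v in _BASE_MORPHOLOGY.items()}
    if label == "non_progress":
        morph["tumor"] = {
            "area": ("gamma", 40.0, 10.0),        # mean 400 px² ≈ 100 µm²
            "eccentricity": ("beta", 8.0, 6.0),   # mean 0.571
            "solidity": ("beta", 24.0, 3.0),
            "extent": ("beta", 14.0, 5.0),
        }
        return PhenotypeConfig(label=label, tumor_cluster_scale=46.0,
                               intermix_prob=0.06,
                               attribution_focus="interior",
                               morphology=morph)
    morph["tumor"] = {
        "area": ("gamma", 40.0, 9.7),             # smaller nuclei
        "eccentricity": ("beta", 8.6, 6.0),       # more eccentric, mean 0.589
        "solidity": ("beta", 21.0, 3.0),
        "extent": ("beta", 9.0, 3.5),             # lower median, higher variance
    }
    return PhenotypeConfig(label=label, tumor_cluster_scale=45.0,
                           intermix_prob=0.32,
                           attribution_focus="border_exterior",
                           morphology=morph)


@dataclass
class CohortConfig:
    """Cohort-level simulation parameters (seed fixes everything)."""

    n_patients_per_label: int = 10
    slides_per_patient: int = 1
    width_px: int = 2048
    height_px: int = 2048
    mpp: float = 0.5
    patch_size_px: int = 256
    mask_downsample: int = 8
    seed: int = 0
    progress: PhenotypeConfig = field(
        default_factory=lambda: default_phenotype("progress"))
    non_progress: PhenotypeConfig = field(
        default_factory=lambda: default_phenotype("non_progress"))

    def __post_init__(self) -> None:
        if self.n_patients_per_label < 1 or self.slides_per_patient < 1:
            raise ValueError("cohort sizes must be >= 1")

    def geometry(self, slide_id: str) -> SlideGeometry:
        return SlideGeometry(slide_id=slide_id, width_px=self.width_px,
                             height_px=self.height_px, mpp=self.mpp,
                             patch_size_px=self.patch_size_px)


@dataclass
class SlideBundle:
    """In-memory product of one simulated slide."""

    nuclei: NucleiMap
    tumor_mask: RegionMask
    tissue_mask: RegionMask
    attribution: AttributionMap


def _ellipse_grid(shape, center, semi_axes) -> np.ndarray:
    h, w = shape
    ii, jj = np.mgrid[0:h, 0:w]
    cy, cx = center
    ay, ax = semi_axes
    return ((jj + 0.5 - cx) / ax) ** 2 + ((ii + 0.5 - cy) / ay) ** 2 <= 1.0


def _uniform_in_mask(rng, mask: RegionMask, n: int, width: int, height: int
                     ) -> np.ndarray:
    """Rejection-sample n points uniformly over the mask's true region."""
    pts = np.empty((0, 2))
    if n == 0 or not mask.grid.any():
        return pts
    while len(pts) < n:
        batch = max(64, int(1.6 * (n - len(pts)) / max(mask.grid.mean(), 1e-3)))
        xy = rng.uniform([0, 0], [width, height], size=(batch, 2))
        keep = mask.contains(xy[:, 0], xy[:, 1])
        pts = np.vstack([pts, xy[keep]])
    return pts[:n]


def _sample_morphology(rng, dist, size: int) -> np.ndarray:
    kind = dist[0]
    if kind == "gamma":
        return rng.gamma(dist[1], dist[2], size)
    if kind == "beta":
        return rng.beta(dist[1], dist[2], size)
    raise ValueError(f"unknown distribution kind {kind!r}")


def generate_slide(
    phenotype: PhenotypeConfig,
    geometry: SlideGeometry,
    seed,
    mask_downsample: int = 8,
    patient_id: str = "",
) -> tuple[NucleiMap, RegionMask, RegionMask]:
    """Simulate one slide: nuclei map plus tumor and tissue masks."""
    rng = np.random.default_rng(seed)
    w, h = geometry.width_px, geometry.height_px
    ds = mask_downsample
    shape = RegionMask.expected_shape(geometry, ds)

    # tissue: one large ellipse, ~65-70% of the slide
    ax = 0.47 * (w / ds) * rng.uniform(0.92, 1.0)
    ay = 0.47 * (h / ds) * rng.uniform(0.92, 1.0)
    tissue_grid = _ellipse_grid(shape, (h / ds / 2, w / ds / 2), (ay, ax))
    tissue = RegionMask(grid=tissue_grid, downsample=ds, role="tissue")

    # tumor: an ellipse blob constrained to cover 20-60% of the tissue
    cy = (h / 2 + rng.uniform(-0.08, 0.08) * h) / ds
    cx = (w / 2 + rng.uniform(-0.08, 0.08) * w) / ds
    r = rng.uniform(0.28, 0.36) * min(w, h) / ds
    sq = (rng.uniform(0.85, 1.0), rng.uniform(0.85, 1.0))
    tumor_grid = _ellipse_grid(shape, (cy, cx), (r * sq[0], r * sq[1])) & tissue_grid
    for _ in range(8):  # nudge radius into the 20-60%-of-tissue band
        cover = tumor_grid.sum() / max(tissue_grid.sum(), 1)
        if 0.2 <= cover <= 0.6:
            break
        r *= 1.12 if cover < 0.2 else 0.9
        tumor_grid = _ellipse_grid(shape, (cy, cx), (r * sq[0], r * sq[1])) & tissue_grid
    tumor = RegionMask(grid=tumor_grid, downsample=ds, role="tumor")

    patch_area = float(geometry.patch_size_px) ** 2
    tissue_area = tissue.area_px()
    tumor_area = tumor.area_px()

    pts_list, type_list = [], []

    # tumor process
    dens_t = phenotype.densities.get("tumor", 0.0)
    if dens_t > 0 and tumor_area > 0:
        if phenotype.tumor_cluster_scale is None:
            n_t = rng.poisson(dens_t * tumor_area / patch_area)
            tumor_pts = _uniform_in_mask(rng, tumor, n_t, w, h)
        else:
            n_par = rng.poisson(phenotype.tumor_parents_per_patch
                                * tumor_area / patch_area)
            parents = _uniform_in_mask(rng, tumor, n_par, w, h)
            mean_off = dens_t / phenotype.tumor_parents_per_patch
            offspring = []
            for p in parents:
                k = rng.poisson(mean_off)
                if k:
                    offspring.append(p + rng.normal(
                        0.0, phenotype.tumor_cluster_scale, (k, 2)))
            tumor_pts = np.vstack(offspring) if offspring else np.empty((0, 2))
            if len(tumor_pts):
                inb = ((tumor_pts[:, 0] >= 0) & (tumor_pts[:, 0] < w)
                       & (tumor_pts[:, 1] >= 0) & (tumor_pts[:, 1] < h))
                tumor_pts = tumor_pts[inb]
                tumor_pts = tumor_pts[tissue.contains(tumor_pts[:, 0],
                                                      tumor_pts[:, 1])]
        n_t = len(tumor_pts)
        t_types = np.full(n_t, "tumor", dtype=object)
        if n_t and phenotype.intermix_prob > 0:
            inside = tumor.contains(tumor_pts[:, 0], tumor_pts[:, 1])
            flip = inside & (rng.random(n_t) < phenotype.intermix_prob)
            t_types[flip] = rng.choice(_OTHER_TYPES, size=int(flip.sum()))
        pts_list.append(tumor_pts)
        type_list.append(t_types)

    # homogeneous Poisson processes for the other types over the tissue
    for t in _OTHER_TYPES:
        dens = phenotype.densities.get(t, 0.0)
        if dens <= 0 or tissue_area == 0:
            continue
        n = rng.poisson(dens * tissue_area / patch_area)
        p = _uniform_in_mask(rng, tissue, n, w, h)
        if len(p) and phenotype.tumor_displacement > 0:
            inside = tumor.contains(p[:, 0], p[:, 1])
            drop = inside & (rng.random(len(p)) < phenotype.tumor_displacement)
            p = p[~drop]
        pts_list.append(p)
        type_list.append(np.full(len(p), t, dtype=object))

    if pts_list:
        pts = np.vstack(pts_list)
        types = np.concatenate(type_list)
    else:
        pts = np.empty((0, 2))
        types = np.empty(0, dtype=object)

    cells = pd.DataFrame({"x": pts[:, 0] if len(pts) else [],
                          "y": pts[:, 1] if len(pts) else [],
                          "cell_type": types})
    for m in MORPHOLOGY_MEASURES:
        cells[m] = np.nan
    morph = {**_BASE_MORPHOLOGY, **phenotype.morphology}
    for t in CELL_TYPES:
        sel = (types == t)
        k = int(sel.sum())
        if k == 0 or t not in morph:
            continue
        for m in MORPHOLOGY_MEASURES:
            cells.loc[sel, m] = _sample_morphology(rng, morph[t][m], k)

    nuclei = NucleiMap(geometry=geometry, cells=cells, patient_id=patient_id,
                       label=phenotype.label)
    return nuclei, tumor, tissue


def generate_attribution(
    tumor_mask: RegionMask,
    phenotype: PhenotypeConfig,
    patches: list[Patch],
    seed,
    slide_id: str = "",
    mpp: float = 0.5,
) -> AttributionMap:
    """Step-plus-noise attribution surrogate on the patch grid.

    Scores are Gaussian base noise plus a bonus on patches whose center
    lies in the phenotype's focus region: the tumor interior (tumor
    eroded by the stripe width) for non-progressors, or the border
    stripe (tumor ∪ stripe minus interior) for progressors.
    """
    rng = np.random.default_rng(seed)
    stripe_um = phenotype.attribution_stripe_um
    interior = interior_region(tumor_mask, stripe_um, mpp)
    if phenotype.attribution_focus == "interior":
        focus = interior
    else:
        outer = tumor_stripe_region(tumor_mask, stripe_um, mpp)
        focus = RegionMask(grid=outer.grid & ~interior.grid,
                           downsample=tumor_mask.downsample, role="tumor")
    scores = {}
    for p in patches:
        cx, cy = p.center
        bonus = phenotype.attribution_bonus if focus.contains(cx, cy) else 0.0
        scores[(p.row, p.col)] = float(
            rng.normal(0.0, phenotype.attribution_noise) + bonus)
    return AttributionMap(slide_id=slide_id, scores=scores, normalization="raw")


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, list[SlideBundle]]:
    """Generate the full cohort in memory; returns (manifest, bundles).

    The manifest has one row per slide (patient_id, slide_id, label);
    patient labels are balanced per config. Byte-identical under a
    fixed seed.
    """
    from .core_io import tile_slide

    ss = np.random.SeedSequence(config.seed)
    bundles: list[SlideBundle] = []
    manifest_rows = []
    phenos = {"progress": config.progress, "non_progress": config.non_progress}
    prefixes = {"progress": "PR", "non_progress": "NP"}
    for label in ("progress", "non_progress"):
        for p_idx in range(config.n_patients_per_label):
            patient_id = f"{prefixes[label]}{p_idx:03d}"
            for s_idx in range(config.slides_per_patient):
                slide_id = f"{patient_id}_S{s_idx}"
                child = ss.spawn(1)[0]
                slide_seed, attr_seed = child.spawn(2)
                geom = config.geometry(slide_id)
                nuclei, tumor, tissue = generate_slide(
                    phenos[label], geom, slide_seed,
                    mask_downsample=config.mask_downsample,
                    patient_id=patient_id)
                patches = tile_slide(geom)
                amap = generate_attribution(tumor, phenos[label], patches,
                                            attr_seed, slide_id=slide_id,
                                            mpp=config.mpp)
                bundles.append(SlideBundle(nuclei=nuclei, tumor_mask=tumor,
                                           tissue_mask=tissue, attribution=amap))
                manifest_rows.append({"patient_id": patient_id,
                                      "slide_id": slide_id, "label": label})
    return pd.DataFrame(manifest_rows), bundles


def _config_to_dict(config: CohortConfig) -> dict:
    d = dataclasses.asdict(config)
    for k in ("progress", "non_progress"):
        d[k] = {kk: (dict(vv) if isinstance(vv, dict) else vv)
                for kk, vv in d[k].items()}
    return d


def generate_cohort(config: CohortConfig, out_dir) -> pd.DataFrame:
    """Simulate and write the cohort bundle to disk.

    Layout: ``cohort.csv`` manifest; ``slides/<id>.ndjson`` nuclei;
    ``masks/<id>.{tumor,tissue}.txt`` (+ JSON sidecars);
    ``attributions/<id>.csv``; ``config.yaml`` with every resolved
    parameter and the seed.
    """
    out = Path(out_dir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    (out / "attributions").mkdir(exist_ok=True)
    manifest, bundles = simulate_cohort(config)
    for b in bundles:
        sid = b.nuclei.geometry.slide_id
        write_nuclei_map(b.nuclei, out / "slides" / f"{sid}.ndjson")
        write_region_mask(b.tumor_mask, out / "masks" / f"{sid}.tumor.txt")
        write_region_mask(b.tissue_mask, out / "masks" / f"{sid}.tissue.txt")
        b.attribution.write_csv(out / "attributions" / f"{sid}.csv")
    manifest.to_csv(out / "cohort.csv", index=False)
    with (out / "config.yaml").open("w") as fh:
        yaml.safe_dump(_config_to_dict(config), fh, sort_keys=False)
    return manifest
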