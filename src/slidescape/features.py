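"""Cell-based patch featurization: composition, morphology, spatial stats.

The operations here turn the typed nuclei of one 256×256 px patch into
the fixed-order 524-entry feature vector enumerated in
:mod:`slidescape.manifest`. Two spatial point-pattern statistics carry
most of the biological signal:

* **ANNR** (average nearest neighbor ratio): the observed mean
  nearest-neighbor distance of one cell type divided by its expectation
  ``0.5/sqrt(n/A)`` under complete spatial randomness in the patch area
  ``A``; values below 1 indicate clustering, above 1 regularity. No
  edge-effect correction is applied.
* **Join-count autocorrelation**: the patch is partitioned into a
  Voronoi tessellation seeded at nuclei centroids; two cells are
  neighbors iff their Voronoi regions share a boundary (equivalently a
  Delaunay edge). For a focal type, cells are binary-labeled
  black/white and ``(J_BB − J_BW)/J_T`` summarizes whether neighboring
  cells tend to share the focal type.

Missing policy: any statistic that is undefined on a patch (too few
cells, empty type, no joins) is emitted as NaN and never imputed here;
the downstream comparisons drop missing values per feature and the tree
classifier handles them natively.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import Delaunay, cKDTree
from scipy.spatial import QhullError

from .core_io import (CELL_TYPES, MORPHOLOGY_MEASURES, NucleiMap, Patch,
                      RegionMask, assign_cells_to_patches)
from .manifest import FEATURE_NAMES, STAT_NAMES, _pairs

logger = logging.getLogger(__name__)

#: metadata columns preceding the 524 feature columns in feature tables
METADATA_COLUMNS: tuple[str, ...] = ("slide_id", "patient_id", "label", "row", "col")


class DegenerateGeometryError(ValueError):
    """Point configuration admits no tessellation (e.g. all coincident)."""


# ---------------------------------------------------------------------------
# descriptive statistics

def descriptive_stats(values, quartiles: bool = False) -> dict[str, float]:
    """The seven canonical summaries (population-moment conventions).

    variance is the population variance (ddof=0); skewness and kurtosis
    use biased population moment formulas, kurtosis as excess kurtosis.
    Fewer than 2 values -> variance missing; fewer than 3 values or zero
    variance -> skewness/kurtosis missing.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    keys = list(STAT_NAMES) + (["q25", "q75"] if quartiles else [])
    out = {k: float("nan") for k in keys}
    n = v.size
    if n == 0:
        return out
    out["mean"] = float(v.mean())
    out["median"] = float(np.median(v))
    out["min"] = float(v.min())
    out["max"] = float(v.max())
    if quartiles:
        out["q25"] = float(np.percentile(v, 25))
        out["q75"] = float(np.percentile(v, 75))
    if n >= 2:
        out["variance"] = float(v.var())
    if n >= 3 and v.var() > 0:
        out["skewness"] = float(sps.skew(v, bias=True))
        out["kurtosis"] = float(sps.kurtosis(v, fisher=True, bias=True))
    return out


# ---------------------------------------------------------------------------
# point-pattern statistics

def nearest_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Euclidean distance from each point to its nearest other point."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two 2-D points")
    d, _ = cKDTree(pts).query(pts, k=2)
    return d[:, 1]


@dataclass(frozen=True)
class ANNRResult:
    cell_type: str | None
    n: int
    observed_mean_nn: float
    expected_mean_nn: float
    annr: float


def annr(points: np.ndarray, area: float, cell_type: str | None = None) -> ANNRResult:
    """Average nearest neighbor ratio with the CSR null ``0.5/sqrt(n/A)``.

    Fewer than two points leave the ratio (and the observed mean)
    undefined. No boundary correction is applied.
    """
    if area <= 0:
        raise ValueError("patch area must be positive")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    expected = 0.5 / np.sqrt(n / area) if n > 0 else float("nan")
    if n < 2:
        return ANNRResult(cell_type, n, float("nan"), float(expected), float("nan"))
    observed = float(nearest_neighbor_distances(pts).mean())
    return ANNRResult(cell_type, n, observed, float(expected),
                      float(observed / expected))


def neighbor_graph(points: np.ndarray) -> np.ndarray:
    """Undirected Voronoi-neighbor pairs as an (m, 2) index array.

    Pair ``(i, j)`` is present iff the Voronoi regions of i and j share
    a boundary segment, i.e. iff (i, j) is a Delaunay edge in
    non-degenerate position. Coincident duplicates are merged onto their
    first occurrence (logged); fully collinear configurations fall back
    to a fixed-seed jitter of 1e-6 px (logged). All points coincident is
    a degenerate input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 2:
        raise ValueError("need at least two 2-D points")
    uniq, inverse = np.unique(pts, axis=0, return_inverse=True)
    inverse = inverse.ravel()
    if len(uniq) < len(pts):
        logger.warning("neighbor_graph: merged %d coincident duplicate points",
                       len(pts) - len(uniq))
    if len(uniq) < 2:
        raise DegenerateGeometryError("all points coincident")
    # representative original index of each unique point (first occurrence)
    rep = np.empty(len(uniq), dtype=int)
    rep[inverse[::-1]] = np.arange(len(pts) - 1, -1, -1)
    if len(uniq) == 2:
        e = np.sort(rep[np.array([[0, 1]])], axis=1)
        return e
    try:
        tri = Delaunay(uniq)
    except QhullError:
        logger.warning("neighbor_graph: degenerate (collinear) configuration; "
                       "applying 1e-6 px fixed-seed jitter")
        jit = uniq + np.random.default_rng(0).normal(0.0, 1e-6, uniq.shape)
        try:
            tri = Delaunay(jit)
        except QhullError as exc:
            raise DegenerateGeometryError("tessellation failed after jitter") from exc
    s = tri.simplices
    e = np.vstack([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    e = rep[e]
    e.sort(axis=1)
    return np.unique(e, axis=0)


@dataclass(frozen=True)
class JoinCountResult:
    cell_type: str
    j_bb: int
    j_bw: int
    j_ww: int
    j_total: int
    autocorrelation: float


def join_count(
    points: np.ndarray,
    types,
    focal_type: str,
    edges: np.ndarray | None = None,
) -> JoinCountResult:
    """Join counts over the Voronoi neighbor graph for a binary labeling.

    Cells of ``focal_type`` are black, the rest white; BB/BW/WW joins
    are counted over graph edges and the autocorrelation is
    ``(J_BB − J_BW)/J_T``. Inputs without any join yield a result with
    the autocorrelation missing.
    """
    types = np.asarray(types)
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(types) != len(pts):
        raise ValueError("points and types must align")
    if edges is None:
        if len(pts) < 2:
            edges = np.empty((0, 2), dtype=int)
        else:
            try:
                edges = neighbor_graph(pts)
            except DegenerateGeometryError:
                edges = np.empty((0, 2), dtype=int)
    j_total = len(edges)
    if j_total == 0:
        return JoinCountResult(focal_type, 0, 0, 0, 0, float("nan"))
    black = types == focal_type
    b0, b1 = black[edges[:, 0]], black[edges[:, 1]]
    j_bb = int((b0 & b1).sum())
    j_bw = int((b0 ^ b1).sum())
    j_ww = j_total - j_bb - j_bw
    return JoinCountResult(focal_type, j_bb, j_bw, j_ww, j_total,
                           float((j_bb - j_bw) / j_total))


def cross_type_distance_stats(
    points_a: np.ndarray, points_b: np.ndarray, quartiles: bool = True
) -> dict[str, float]:
    """Summaries of symmetric nearest-cross-type distances.

    For each cell of type a the distance to its nearest type-b cell,
    pooled with the b->a direction, then summarized. Either set empty
    -> all statistics missing.
    """
    a = np.asarray(points_a, dtype=float).reshape(-1, 2)
    b = np.asarray(points_b, dtype=float).reshape(-1, 2)
    if len(a) == 0 or len(b) == 0:
        keys = list(STAT_NAMES) + (["q25", "q75"] if quartiles else [])
        return {k: float("nan") for k in keys}
    d_ab, _ = cKDTree(b).query(a)
    d_ba, _ = cKDTree(a).query(b)
    return descriptive_stats(np.concatenate([d_ab, d_ba]), quartiles=quartiles)


def morphology_stats(cells: pd.DataFrame) -> dict[str, dict[str, float]]:
    """Descriptive statistics of the four nuclear morphology measures."""
    return {m: descriptive_stats(cells[m].to_numpy()) if len(cells) else
            descriptive_stats([]) for m in MORPHOLOGY_MEASURES}


def composition_features(cells: pd.DataFrame) -> dict[str, float]:
    """Per-type counts, per-type fractions of total, and total count."""
    out: dict[str, float] = {}
    total = len(cells)
    counts = cells["cell_type"].value_counts() if total else {}
    for t in CELL_TYPES:
        out[f"count_{t}"] = float(counts.get(t, 0) if total else 0)
    for t in CELL_TYPES:
        out[f"frac_{t}"] = out[f"count_{t}"] / total if total > 0 else float("nan")
    out["count_total"] = float(total)
    return out


# ---------------------------------------------------------------------------
# full patch featurization

def featurize_patch(
    cells: pd.DataFrame,
    patch: Patch,
    mpp: float = 0.5,
    tumor_mask: RegionMask | None = None,
) -> pd.Series:
    """Assemble the frozen 524-entry feature vector for one patch.

    ``cells`` are the records whose centroids fall inside the patch
    (absolute slide coordinates; all statistics are translation
    invariant). When ``tumor_mask`` is omitted the tumor-region features
    are missing. The result is a Series indexed by
    :data:`slidescape.manifest.FEATURE_NAMES` in manifest order.
    """
    area = patch.area
    feats: dict[str, float] = {}
    feats.update(composition_features(cells))
    n = len(cells)
    pts_all = cells[["x", "y"]].to_numpy(dtype=float) if n else np.empty((0, 2))
    types = cells["cell_type"].to_numpy() if n else np.empty(0, dtype=object)
    by_type = {t: pts_all[types == t] for t in CELL_TYPES}
    cells_by_type = {t: cells[types == t] if n else cells for t in CELL_TYPES}

    # per-type morphology
    for t in CELL_TYPES:
        ms = morphology_stats(cells_by_type[t])
        for m in MORPHOLOGY_MEASURES:
            for s in STAT_NAMES:
                feats[f"morph_{t}_{m}_{s}"] = ms[m][s]

    # cross-type distances (7 stats + quartile extras)
    for a, b in _pairs():
        st = cross_type_distance_stats(by_type[a], by_type[b], quartiles=True)
        for s in STAT_NAMES:
            feats[f"xdist_{a}_{b}_{s}"] = st[s]
        feats[f"xdist_{a}_{b}_q25"] = st["q25"]
        feats[f"xdist_{a}_{b}_q75"] = st["q75"]

    # per-type NN distances and ANNR
    for t in CELL_TYPES:
        pts = by_type[t]
        if len(pts) >= 2:
            nnd = nearest_neighbor_distances(pts)
            st = descriptive_stats(nnd)
        else:
            st = descriptive_stats([])
        for s in STAT_NAMES:
            feats[f"nndist_{t}_{s}"] = st[s]
        feats[f"annr_{t}"] = annr(pts, area, t).annr if len(pts) else float("nan")

    # shared tessellation: joins and degrees
    edges = None
    if n >= 2:
        try:
            edges = neighbor_graph(pts_all)
        except DegenerateGeometryError:
            edges = None
    degree = np.zeros(n, dtype=float)
    if edges is not None and len(edges):
        degree = np.bincount(edges.ravel(), minlength=n).astype(float)
    for t in CELL_TYPES:
        jc = join_count(pts_all, types, t,
                        edges=edges if edges is not None else np.empty((0, 2), int))
        feats[f"join_autocorr_{t}"] = jc.autocorrelation
        if jc.j_total > 0:
            feats[f"join_frac_bb_{t}"] = jc.j_bb / jc.j_total
            feats[f"join_frac_bw_{t}"] = jc.j_bw / jc.j_total
            feats[f"join_frac_ww_{t}"] = jc.j_ww / jc.j_total
        else:
            feats[f"join_frac_bb_{t}"] = float("nan")
            feats[f"join_frac_bw_{t}"] = float("nan")
            feats[f"join_frac_ww_{t}"] = float("nan")

    # tumor-region features
    in_tumor = tumor_mask.contains(pts_all[:, 0], pts_all[:, 1]) \
        if (tumor_mask is not None and n) else None
    for t in CELL_TYPES:
        sel = types == t
        n_t = int(sel.sum())
        if tumor_mask is None:
            feats[f"tumor_region_frac_{t}"] = float("nan")
            feats[f"tumor_region_count_{t}"] = float("nan")
        else:
            n_in = int(in_tumor[sel].sum()) if n_t else 0
            feats[f"tumor_region_count_{t}"] = float(n_in)
            feats[f"tumor_region_frac_{t}"] = n_in / n_t if n_t else float("nan")
    if tumor_mask is None:
        feats["tumor_region_count_total"] = float("nan")
        feats["tumor_region_area_frac"] = float("nan")
    else:
        feats["tumor_region_count_total"] = float(in_tumor.sum()) if n else 0.0
        from .core_io import mask_fraction
        feats["tumor_region_area_frac"] = mask_fraction(tumor_mask, patch)

    # ordered count ratios
    for a in CELL_TYPES:
        for b in CELL_TYPES:
            if a == b:
                continue
            cb = feats[f"count_{b}"]
            feats[f"ratio_{a}_{b}"] = feats[f"count_{a}"] / cb if cb > 0 else float("nan")

    # pooled variants
    ms_all = {m: descriptive_stats(cells[m].to_numpy()) if n else descriptive_stats([])
              for m in MORPHOLOGY_MEASURES}
    for m in MORPHOLOGY_MEASURES:
        for s in STAT_NAMES:
            feats[f"morph_all_{m}_{s}"] = ms_all[m][s]
    if n >= 2:
        st = descriptive_stats(nearest_neighbor_distances(pts_all))
    else:
        st = descriptive_stats([])
    for s in STAT_NAMES:
        feats[f"nndist_all_{s}"] = st[s]
    feats["annr_all"] = annr(pts_all, area).annr if n else float("nan")

    # degrees
    for t in CELL_TYPES:
        st = descriptive_stats(degree[types == t]) if edges is not None \
            else descriptive_stats([])
        for s in STAT_NAMES:
            feats[f"degree_{t}_{s}"] = st[s]
    st = descriptive_stats(degree) if edges is not None else descriptive_stats([])
    for s in STAT_NAMES:
        feats[f"degree_all_{s}"] = st[s]

    # densities (cells per mm²)
    area_mm2 = area * (mpp * 1e-3) ** 2
    for t in CELL_TYPES:
        feats[f"density_{t}"] = feats[f"count_{t}"] / area_mm2
    feats["density_all"] = feats["count_total"] / area_mm2

    vec = pd.Series([feats[name] for name in FEATURE_NAMES],
                    index=list(FEATURE_NAMES), dtype=float)
    return vec


def featurize_slide(
    nuclei: NucleiMap,
    patches: list[Patch],
    tumor_mask: RegionMask | None = None,
) -> pd.DataFrame:
    """Feature table for all given patches of one slide.

    Returns one row per patch with :data:`METADATA_COLUMNS` followed by
    the 524 feature columns in manifest order.
    """
    assignment = assign_cells_to_patches(nuclei, patches)
    rows = []
    meta = []
    for p in patches:
        idx = assignment[(p.row, p.col)]
        sub = nuclei.cells.iloc[idx]
        rows.append(featurize_patch(sub, p, mpp=nuclei.geometry.mpp,
                                    tumor_mask=tumor_mask))
        meta.append({"slide_id": nuclei.geometry.slide_id,
                     "patient_id": nuclei.patient_id,
                     "label": nuclei.label, "row": p.row, "col": p.col})
    if not rows:
        return pd.DataFrame(columns=list(METADATA_COLUMNS) + list(FEATURE_NAMES))
    feat = pd.DataFrame(rows).reset_index(drop=True)
    meta_df = pd.DataFrame(meta)
    return pd.concat([meta_df, feat], axis=1)
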