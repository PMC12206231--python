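"""Data model, coordinate conventions, tiling and on-disk formats.

A slide is described at its working magnification (default 0.5 µm/px,
i.e. ×20) by a :class:`SlideGeometry`. Nuclei-segmentation output is a
table of typed cell centroids with per-nucleus morphology
(:class:`NucleiMap`); binary tissue/tumor regions are stored as
downsampled grids (:class:`RegionMask`).

Conventions (frozen for the whole package):

* pixel coordinates are 0-based floats with the origin at the top-left;
  ``x`` runs along image columns (width), ``y`` along rows (height);
* patches are axis-aligned half-open rectangles
  ``[x0, x0+size) × [y0, y0+size)`` laid out on a row-major grid;
* partial patches on the right/bottom margin are dropped, so the tiling
  is an exact partition of ``[0, size·⌊w/size⌋) × [0, size·⌊h/size⌋)``.

Nuclei maps are serialized as line-delimited JSON: one header object
followed by one object per cell, a format chosen so that no image
decoding is ever required downstream.
"""
from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

CELL_TYPES: tuple[str, ...] = (
    "granulocyte",
    "lymphocyte",
    "plasma",
    "stroma",
    "tumor",
    "epithelial",
)
MORPHOLOGY_MEASURES: tuple[str, ...] = ("area", "eccentricity", "solidity", "extent")
LABELS: tuple[str, ...] = ("progress", "non_progress")

#: column order of the cells table inside a NucleiMap
CELL_COLUMNS: tuple[str, ...] = ("x", "y", "cell_type") + MORPHOLOGY_MEASURES


class NucleiParseError(ValueError):
    """Malformed record in a nuclei file (message names the line)."""


class NucleiValidationError(ValueError):
    """Structurally valid record violating a domain invariant."""


@dataclass(frozen=True)
class SlideGeometry:
    """Pixel geometry of one slide at working magnification."""

    slide_id: str
    width_px: int
    height_px: int
    mpp: float = 0.5
    patch_size_px: int = 256

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("slide dimensions must be positive")
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if self.mpp <= 0:
            raise ValueError("mpp must be positive")


@dataclass
class Patch:
    """One tile of the slide grid; bounds derive from (row, col, size)."""

    row: int
    col: int
    size: int
    tissue_fraction: float = float("nan")

    @property
    def bounds(self) -> tuple[int, int, int, int]:
        """Half-open pixel rectangle ``(x0, y0, x1, y1)``."""
        x0 = self.col * self.size
        y0 = self.row * self.size
        return (x0, y0, x0 + self.size, y0 + self.size)

    @property
    def center(self) -> tuple[float, float]:
        x0, y0, _, _ = self.bounds
        return (x0 + self.size / 2.0, y0 + self.size / 2.0)

    @property
    def area(self) -> float:
        """Patch area in px²."""
        return float(self.size) ** 2


@dataclass
class RegionMask:
    """Binary region grid at an integer downsample of the working scale.

    Grid cell ``(i, j)`` covers pixels
    ``[j·ds, (j+1)·ds) × [i·ds, (i+1)·ds)``.
    """

    grid: np.ndarray
    downsample: int
    role: str  # "tissue" or "tumor"

    def __post_init__(self) -> None:
        if self.downsample < 1:
            raise ValueError("downsample factor must be >= 1")
        if self.role not in ("tissue", "tumor"):
            raise ValueError(f"unknown mask role {self.role!r}")
        self.grid = np.asarray(self.grid, dtype=bool)
        if self.grid.ndim != 2:
            raise ValueError("mask grid must be 2-D")

    @staticmethod
    def expected_shape(geometry: SlideGeometry, downsample: int) -> tuple[int, int]:
        return (
            math.ceil(geometry.height_px / downsample),
            math.ceil(geometry.width_px / downsample),
        )

    def validate_for(self, geometry: SlideGeometry) -> None:
        exp = self.expected_shape(geometry, self.downsample)
        if self.grid.shape != exp:
            raise ValueError(
                f"mask grid {self.grid.shape} inconsistent with geometry "
                f"{geometry.width_px}x{geometry.height_px} at downsample "
                f"{self.downsample} (expected {exp})"
            )

    def contains(self, x, y) -> np.ndarray:
        """Vectorized membership lookup for pixel coordinates."""
        j = (np.asarray(x, dtype=float) // self.downsample).astype(int)
        i = (np.asarray(y, dtype=float) // self.downsample).astype(int)
        i = np.clip(i, 0, self.grid.shape[0] - 1)
        j = np.clip(j, 0, self.grid.shape[1] - 1)
        return self.grid[i, j]

    def area_px(self) -> float:
        return float(self.grid.sum()) * self.downsample**2


@dataclass
class NucleiMap:
    """All typed cell records of one slide plus its geometry and label.

    ``cells`` is a DataFrame with columns :data:`CELL_COLUMNS`; morphology
    entries may be NaN (missing) but must lie in their domain otherwise.
    """

    geometry: SlideGeometry
    cells: pd.DataFrame
    patient_id: str = ""
    label: str = "non_progress"

    def __post_init__(self) -> None:
        self.cells = _normalize_cells(self.cells)
        validate_cells(self.cells, self.geometry)
        if self.label not in LABELS:
            raise NucleiValidationError(f"unknown label {self.label!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _normalize_cells(cells: pd.DataFrame) -> pd.DataFrame:
    if cells is None or len(cells) == 0:
        return pd.DataFrame({c: pd.Series(dtype=float if c != "cell_type" else object)
                             for c in CELL_COLUMNS})
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise NucleiValidationError(f"cells table missing columns {missing}")
    out = cells.loc[:, list(CELL_COLUMNS)].reset_index(drop=True)
    for c in ("x", "y") + MORPHOLOGY_MEASURES:
        out[c] = pd.to_numeric(out[c], errors="raise").astype(float)
    return out


def validate_cells(cells: pd.DataFrame, geometry: SlideGeometry) -> None:
    """Raise :class:`NucleiValidationError` on any invariant violation."""
    if len(cells) == 0:
        return
    bad_type = ~cells["cell_type"].isin(CELL_TYPES)
    if bad_type.any():
        bad = cells.loc[bad_type, "cell_type"].iloc[0]
        raise NucleiValidationError(f"unknown cell_type {bad!r}")
    x, y = cells["x"].to_numpy(), cells["y"].to_numpy()
    if not np.isfinite(x).all() or not np.isfinite(y).all():
        raise NucleiValidationError("non-finite cell coordinates")
    if (x < 0).any() or (x >= geometry.width_px).any() \
            or (y < 0).any() or (y >= geometry.height_px).any():
        raise NucleiValidationError("cell centroid outside slide bounds")
    ranges = {"area": (0.0, math.inf), "eccentricity": (0.0, 1.0),
              "solidity": (0.0, 1.0), "extent": (0.0, 1.0)}
    for m, (lo, hi) in ranges.items():
        v = cells[m].to_numpy()
        ok = np.isnan(v) | ((v >= lo) & (v <= hi))
        if m == "area":
            ok = np.isnan(v) | (v > 0)
        if not ok.all():
            raise NucleiValidationError(f"morphology measure {m!r} out of range")


# ---------------------------------------------------------------------------
# tiling and patch/mask geometry

def tile_slide(geometry: SlideGeometry) -> list[Patch]:
    """Row-major grid of non-overlapping full-size patches.

    Margins that would exceed the slide bounds are dropped; a slide
    smaller than one patch yields an empty list.
    """
    size = geometry.patch_size_px
    n_cols = geometry.width_px // size
    n_rows = geometry.height_px // size
    return [Patch(row=r, col=c, size=size)
            for r in range(n_rows) for c in range(n_cols)]


def mask_fraction(mask: RegionMask, patch: Patch) -> float:
    """Area-weighted fraction of ``patch`` covered by ``mask``.

    Computed at the mask's downsample: each grid cell contributes the
    area of its overlap with the patch rectangle.
    """
    ds = mask.downsample
    x0, y0, x1, y1 = patch.bounds
    j0, j1 = x0 // ds, min(math.ceil(x1 / ds), mask.grid.shape[1])
    i0, i1 = y0 // ds, min(math.ceil(y1 / ds), mask.grid.shape[0])
    if j1 <= j0 or i1 <= i0:
        return 0.0
    cols = np.arange(j0, j1)
    rows = np.arange(i0, i1)
    ox = np.minimum((cols + 1) * ds, x1) - np.maximum(cols * ds, x0)
    oy = np.minimum((rows + 1) * ds, y1) - np.maximum(rows * ds, y0)
    ox = np.clip(ox, 0, None).astype(float)
    oy = np.clip(oy, 0, None).astype(float)
    sub = mask.grid[i0:i1, j0:j1]
    return float((oy[:, None] * ox[None, :] * sub).sum() / patch.area)


def tissue_filter(
    patches: list[Patch],
    tissue_mask: RegionMask,
    geometry: SlideGeometry,
    threshold: float = 0.5,
) -> list[Patch]:
    """Retain patches with tissue fraction >= ``threshold``.

    The boundary is inclusive: patches with *less than* the threshold
    are discarded. Each input patch gets its ``tissue_fraction`` set.
    """
    if tissue_mask.role != "tissue":
        raise ValueError(f"expected a tissue mask, got role {tissue_mask.role!r}")
    tissue_mask.validate_for(geometry)
    retained = []
    for p in patches:
        p.tissue_fraction = mask_fraction(tissue_mask, p)
        if p.tissue_fraction >= threshold:
            retained.append(p)
    return retained


def assign_cells_to_patches(
    nuclei: NucleiMap, patches: list[Patch]
) -> dict[tuple[int, int], np.ndarray]:
    """Map ``(row, col)`` -> indices of cells whose centroid lies in the patch.

    Half-open bounds make this a partition of the tiled area; cells in
    dropped margins are unassigned.
    """
    keys = {(p.row, p.col) for p in patches}
    out: dict[tuple[int, int], list[int]] = {(p.row, p.col): [] for p in patches}
    if nuclei.n_cells == 0:
        return {k: np.empty(0, dtype=int) for k in out}
    size = nuclei.geometry.patch_size_px
    col = (nuclei.cells["x"].to_numpy() // size).astype(int)
    row = (nuclei.cells["y"].to_numpy() // size).astype(int)
    for idx, rc in enumerate(zip(row, col)):
        if rc in keys:
            out[rc].append(idx)
    return {k: np.asarray(v, dtype=int) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Euclidean-disk morphology on mask grids (used for tumor stripe/interior)

def dilate_grid(grid: np.ndarray, radius: int) -> np.ndarray:
    """Binary dilation by a Euclidean disk of the given cell radius.

    Implemented via the exact Euclidean distance transform: a cell is in
    the dilation iff its distance to the nearest foreground cell is
    <= radius, which is identical to dilation with a disk structuring
    element but costs O(grid) instead of O(grid·radius²).
    """
    grid = np.asarray(grid, dtype=bool)
    if radius <= 0 or not grid.any():
        return grid.copy()
    dist = ndimage.distance_transform_edt(~grid)
    return dist <= radius


def erode_grid(grid: np.ndarray, radius: int) -> np.ndarray:
    """Binary erosion by a Euclidean disk (dual of :func:`dilate_grid`)."""
    grid = np.asarray(grid, dtype=bool)
    if radius <= 0:
        return grid.copy()
    dist = ndimage.distance_transform_edt(grid)
    return dist > radius


# ---------------------------------------------------------------------------
# nuclei map serialization (line-delimited JSON)

_HEADER_KEYS = ("slide_id", "width_px", "height_px", "mpp", "patch_size_px",
                "patient_id", "label")


def write_nuclei_map(nuclei: NucleiMap, path) -> None:
    """Write header line + one JSON record per cell (NaN -> null)."""
    path = Path(path)
    g = nuclei.geometry
    header = {
        "format": "nuclei-map", "version": 1,
        "slide_id": g.slide_id, "width_px": g.width_px, "height_px": g.height_px,
        "mpp": g.mpp, "patch_size_px": g.patch_size_px,
        "patient_id": nuclei.patient_id, "label": nuclei.label,
        "n_cells": nuclei.n_cells,
    }
    with path.open("w") as fh:
        fh.write(json.dumps(header) + "\n")
        for rec in nuclei.cells.itertuples(index=False):
            d = {"x": rec.x, "y": rec.y, "cell_type": rec.cell_type}
            for m in MORPHOLOGY_MEASURES:
                v = getattr(rec, m)
                d[m] = None if (v is None or (isinstance(v, float) and math.isnan(v))) else v
            fh.write(json.dumps(d) + "\n")


def read_nuclei_map(path) -> NucleiMap:
    """Parse and validate a nuclei file; errors name the offending line."""
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise NucleiParseError(f"{path}: empty file")
    try:
        header = json.loads(lines[0])
    except json.JSONDecodeError as exc:
        raise NucleiParseError(f"{path}:1: malformed header: {exc}") from exc
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise NucleiParseError(f"{path}:1: header missing keys {missing}")
    geometry = SlideGeometry(
        slide_id=header["slide_id"], width_px=int(header["width_px"]),
        height_px=int(header["height_px"]), mpp=float(header["mpp"]),
        patch_size_px=int(header["patch_size_px"]),
    )
    records = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
        except json.JSONDecodeError as exc:
            raise NucleiParseError(f"{path}:{lineno}: malformed record: {exc}") from exc
        row = {}
        try:
            row["x"] = float(rec["x"])
            row["y"] = float(rec["y"])
            row["cell_type"] = rec["cell_type"]
        except (KeyError, TypeError, ValueError) as exc:
            raise NucleiParseError(f"{path}:{lineno}: bad record fields: {exc}") from exc
        for m in MORPHOLOGY_MEASURES:
            v = rec.get(m)
            row[m] = float("nan") if v is None else float(v)
        records.append(row)
    cells = pd.DataFrame(records, columns=list(CELL_COLUMNS))
    try:
        return NucleiMap(geometry=geometry, cells=cells,
                         patient_id=header["patient_id"], label=header["label"])
    except NucleiValidationError as exc:
        raise NucleiValidationError(f"{path}: {exc}") from exc


def nuclei_from_hovernet(
    nuc_dict: dict,
    geometry: SlideGeometry,
    type_map: dict[int, str],
    patient_id: str = "",
    label: str = "non_progress",
) -> NucleiMap:
    """Convert a HoverNet-style instance dictionary to a :class:`NucleiMap`.

    Expects the segmenter's JSON layout ``{"nuc": {id: {"centroid": [x, y],
    "type": int, ...}}}``; ``type_map`` translates integer type codes to the
    six cell-type names. Morphology measures are taken from per-instance
    keys of the same names when present, else marked missing.
    """
    nuc = nuc_dict.get("nuc", nuc_dict)
    rows = []
    for inst in nuc.values():
        t = type_map.get(int(inst["type"]))
        if t is None:
            continue
        row = {"x": float(inst["centroid"][0]), "y": float(inst["centroid"][1]),
               "cell_type": t}
        for m in MORPHOLOGY_MEASURES:
            row[m] = float(inst[m]) if m in inst else float("nan")
        rows.append(row)
    cells = pd.DataFrame(rows, columns=list(CELL_COLUMNS))
    return NucleiMap(geometry=geometry, cells=cells, patient_id=patient_id, label=label)


# ---------------------------------------------------------------------------
# region mask serialization: plain-text 0/1 grid + JSON sidecar

def write_region_mask(mask: RegionMask, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for row in mask.grid:
            fh.write("".join("1" if v else "0" for v in row) + "\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "downsample": mask.downsample, "role": mask.role,
        "shape": list(mask.grid.shape),
    }))


def read_region_mask(path) -> RegionMask:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    rows = [line for line in path.read_text().splitlines() if line]
    grid = np.array([[ch == "1" for ch in line] for line in rows], dtype=bool)
    if list(grid.shape) != list(meta["shape"]):
        raise ValueError(f"{path}: grid shape {grid.shape} != sidecar {meta['shape']}")
    return RegionMask(grid=grid, downsample=int(meta["downsample"]), role=meta["role"])
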