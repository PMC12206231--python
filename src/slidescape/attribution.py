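"""Integrated-gradients attribution, slide heatmaps and patch selection.

Integrated Gradients (IG) attributes a scalar scorer's output to its
input dimensions via the path integral of the gradient from a baseline
to the input:

    attr_d = (x_d − x'_d) · ∫₀¹ ∂f/∂x_d (x' + α(x − x')) dα

approximated here with a midpoint Riemann sum. IG satisfies the
completeness axiom — attributions sum to ``f(x) − f(x')`` — and the
residual (completeness gap) is reported with every call.

The selection procedure mirrors the explainability protocol of
patch-based slide classifiers: restrict to patches inside the tumor
region plus a surrounding stripe of tissue next to the tumor border,
keep patches whose attribution toward the slide's true class is
positive, rank by raw score, take the top fraction (default 10%) and
cap the count per slide (default 200) so large tumors are not
over-represented.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import Patch, RegionMask, dilate_grid, erode_grid


@dataclass
class AttributionMap:
    """Per-patch attribution scores of one slide on the patch grid."""

    slide_id: str
    scores: dict[tuple[int, int], float]
    normalization: str = "raw"  # "raw" or "slide_minmax"

    def to_frame(self) -> pd.DataFrame:
        rows = [{"slide_id": self.slide_id, "row": r, "col": c, "score": s,
                 "normalization": self.normalization}
                for (r, c), s in sorted(self.scores.items())]
        return pd.DataFrame(rows, columns=["slide_id", "row", "col",
                                           "score", "normalization"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "AttributionMap":
        if df.empty:
            raise ValueError("empty attribution frame")
        sid = df["slide_id"].iloc[0]
        norm = df["normalization"].iloc[0] if "normalization" in df else "raw"
        scores = {(int(r.row), int(r.col)): float(r.score)
                  for r in df.itertuples(index=False)}
        return cls(slide_id=sid, scores=scores, normalization=norm)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "AttributionMap":
        return cls.from_frame(pd.read_csv(path))


@dataclass(frozen=True)
class SelectionConfig:
    """Explanatory-patch selection parameters."""

    top_fraction: float = 0.10
    per_slide_cap: int = 200
    stripe_width_um: float = 800.0

    def __post_init__(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.per_slide_cap < 1:
            raise ValueError("per_slide_cap must be >= 1")
        if self.stripe_width_um < 0:
            raise ValueError("stripe_width_um must be >= 0")


@dataclass(frozen=True)
class IGResult:
    attributions: np.ndarray
    completeness_gap: float
    score_input: float
    score_baseline: float


def integrated_gradients(
    scorer,
    x,
    baseline=None,
    steps: int = 64,
    grad=None,
    fd_eps: float = 1e-4,
) -> IGResult:
    """Midpoint-rule integrated gradients for a scalar scorer.

    ``scorer`` maps a 1-D feature vector to a float; ``grad``, if given,
    returns its analytic gradient, otherwise central finite differences
    (step ``fd_eps``, exact for polynomials up to degree 2) are used at
    each of the ``steps`` midpoint interpolants. The baseline defaults
    to the zero vector.
    """
    x = np.asarray(x, dtype=float).ravel()
    baseline = np.zeros_like(x) if baseline is None else \
        np.asarray(baseline, dtype=float).ravel()
    if baseline.shape != x.shape:
        raise ValueError("baseline shape mismatch")
    if steps < 8:
        raise ValueError("steps must be >= 8")

    def _grad(p: np.ndarray) -> np.ndarray:
        if grad is not None:
            return np.asarray(grad(p), dtype=float).ravel()
        g = np.empty_like(p)
        for d in range(p.size):
            h = fd_eps * max(1.0, abs(p[d]))
            pp, pm = p.copy(), p.copy()
            pp[d] += h
            pm[d] -= h
            g[d] = (float(scorer(pp)) - float(scorer(pm))) / (2 * h)
        return g

    alphas = (np.arange(steps) + 0.5) / steps
    mean_grad = np.zeros_like(x)
    for a in alphas:
        mean_grad += _grad(baseline + a * (x - baseline))
    mean_grad /= steps
    attributions = (x - baseline) * mean_grad
    f_x, f_b = float(scorer(x)), float(scorer(baseline))
    if not (math.isfinite(f_x) and math.isfinite(f_b)):
        raise FloatingPointError("non-finite scorer output")
    gap = abs(float(attributions.sum()) - (f_x - f_b))
    return IGResult(attributions=attributions, completeness_gap=gap,
                    score_input=f_x, score_baseline=f_b)


def slide_normalize(amap: AttributionMap) -> AttributionMap:
    """Min-max rescale scores to [0, 1] per slide (constant maps -> 0.5).

    Display/report-only: selection always uses raw scores, and min-max
    rescaling is monotone per slide so it could not change a selection
    anyway.
    """
    if not amap.scores:
        raise ValueError("attribution map has no patches")
    vals = np.array(list(amap.scores.values()), dtype=float)
    lo, hi = vals.min(), vals.max()
    if hi == lo:
        scores = {k: 0.5 for k in amap.scores}
    else:
        scores = {k: float((v - lo) / (hi - lo)) for k, v in amap.scores.items()}
    return AttributionMap(slide_id=amap.slide_id, scores=scores,
                          normalization="slide_minmax")


def tumor_stripe_region(
    tumor_mask: RegionMask, stripe_width_um: float, mpp: float
) -> RegionMask:
    """Tumor region plus a surrounding stripe of the given physical width.

    The stripe is a Euclidean-disk dilation of the tumor mask by
    ``round(stripe_width_um / (mpp · downsample))`` grid cells; the
    returned region is tumor ∪ stripe.
    """
    if mpp <= 0:
        raise ValueError("mpp must be positive")
    if not tumor_mask.grid.any():
        warnings.warn("empty tumor mask: stripe region is empty")
        return RegionMask(grid=tumor_mask.grid.copy(),
                          downsample=tumor_mask.downsample, role="tumor")
    radius = round(stripe_width_um / (mpp * tumor_mask.downsample))
    return RegionMask(grid=dilate_grid(tumor_mask.grid, radius),
                      downsample=tumor_mask.downsample, role="tumor")


def interior_region(
    tumor_mask: RegionMask, stripe_width_um: float, mpp: float
) -> RegionMask:
    """Tumor mask eroded by the stripe width (the 'deep tumor' interior)."""
    radius = round(stripe_width_um / (mpp * tumor_mask.downsample))
    return RegionMask(grid=erode_grid(tumor_mask.grid, radius),
                      downsample=tumor_mask.downsample, role="tumor")


def select_explanatory_patches(
    amap: AttributionMap,
    patches: list[Patch],
    region: RegionMask,
    config: SelectionConfig = SelectionConfig(),
) -> pd.DataFrame:
    """Top-fraction-then-cap selection of positively attributed patches.

    Candidates are patches whose center lies inside ``region`` and whose
    raw score toward the slide's true class is positive. They are ranked
    by score descending (ties broken by (row, col) lexicographic), the
    top ``ceil(top_fraction · n_candidates)`` kept, then truncated to
    ``per_slide_cap``. Returns a DataFrame (slide_id, row, col, score).
    """
    cand = []
    for p in patches:
        key = (p.row, p.col)
        if key not in amap.scores:
            raise ValueError(f"attribution map does not cover patch {key}")
        cx, cy = p.center
        h, w = region.grid.shape
        ds = region.downsample
        i, j = int(cy // ds), int(cx // ds)
        inside = 0 <= i < h and 0 <= j < w and bool(region.grid[i, j])
        score = amap.scores[key]
        if inside and score > 0:
            cand.append((p.row, p.col, score))
    if not cand:
        warnings.warn(f"slide {amap.slide_id}: no candidate patches selected")
        return pd.DataFrame(columns=["slide_id", "row", "col", "score"])
    cand.sort(key=lambda t: (-t[2], t[0], t[1]))
    n_keep = min(config.per_slide_cap,
                 math.ceil(config.top_fraction * len(cand)))
    kept = cand[:n_keep]
    return pd.DataFrame([{"slide_id": amap.slide_id, "row": r, "col": c,
                          "score": s} for r, c, s in kept])


def form_groups(
    cohort_manifest: pd.DataFrame,
    selections: pd.DataFrame,
    feature_table: pd.DataFrame,
    predictions: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Join selected patches to their feature rows and assign groups.

    positive = selected patches of progress slides, negative = selected
    patches of non-progress slides (labels from the cohort manifest).
    All slides participate by default; passing ``predictions`` (columns
    slide_id, predicted_label) drops misclassified slides first.
    Raises if a selection has no matching feature row.
    """
    if selections.empty:
        raise ValueError("no selected patches to group")
    labels = cohort_manifest.set_index("slide_id")["label"]
    sel = selections.copy()
    if predictions is not None:
        pred = predictions.set_index("slide_id")["predicted_label"]
        correct = {sid for sid, lab in labels.items()
                   if pred.get(sid) == lab}
        dropped = set(sel["slide_id"]) - correct
        if dropped:
            warnings.warn(f"excluding {len(dropped)} misclassified slides "
                          "from group formation")
        sel = sel[sel["slide_id"].isin(correct)]
        if sel.empty:
            raise ValueError("no correctly classified slides left")
    unknown = set(sel["slide_id"]) - set(labels.index)
    if unknown:
        raise ValueError(f"selections reference slides missing from manifest: {sorted(unknown)}")
    merged = sel.merge(feature_table, on=["slide_id", "row", "col"],
                       how="left", validate="one_to_one", indicator=True)
    if (merged["_merge"] != "both").any():
        bad = merged.loc[merged["_merge"] != "both", ["slide_id", "row", "col"]]
        raise ValueError(f"selections without feature rows:\n{bad.head()}")
    merged = merged.drop(columns=["_merge"])
    merged["group"] = np.where(
        merged["slide_id"].map(labels).eq("progress"), "positive", "negative")
    for grp in ("positive", "negative"):
        if not (merged["group"] == grp).any():
            warnings.warn(f"{grp} group is empty")
    return merged


def aggregate_patient_score(slide_scores) -> float:
    """Patient-level score: maximum positive-class score over slides."""
    scores = np.asarray(list(slide_scores), dtype=float)
    if scores.size == 0:
        raise ValueError("need at least one slide score")
    return float(scores.max())
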