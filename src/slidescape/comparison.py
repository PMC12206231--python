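"""Per-feature group comparison: brute-force CLES and Mann–Whitney U.

The common language effect size (probability of superiority)

    CLES = P(X > Y) + 0.5 · P(X = Y)

is computed by exhaustive pairwise comparison of the two samples; the
0.5 tie credit preserves the antisymmetry ``cles(x, y) + cles(y, x) = 1``
and the identity ``U = cles · |x|·|y|`` with the Mann–Whitney statistic.
Each of the 524 features is compared independently between the positive
(progressor) and negative (non-progressor) patch groups, and the
reported CLES is oriented toward the group with the larger mean.

Raw two-sided Mann–Whitney p-values are emitted for fidelity with the
source protocol; Benjamini–Hochberg adjusted values are added because
524 simultaneous tests demand it. Patches within a slide are treated as
independent units — a known limitation inherited from the protocol.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .manifest import FEATURE_NAMES


def cles(x, y) -> float:
    """Brute-force P(X > Y) with 0.5 credit for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    diff = x[:, None] - y[None, :]
    wins = np.count_nonzero(diff > 0)
    ties = np.count_nonzero(diff == 0)
    return float((wins + 0.5 * ties) / (x.size * y.size))


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact enumeration when ``|x|·|y| <= 400`` and there are no ties
    across the pooled samples, otherwise the normal approximation with
    tie and continuity corrections. Fully tied inputs give p = 1 with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values tied across both samples; p = 1")
        return float(x.size * y.size / 2.0), 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size * y.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def compare_groups(
    group_table: pd.DataFrame,
    feature_names=None,
    flag_threshold: float = 0.55,
) -> pd.DataFrame:
    """One comparison per feature between positive and negative groups.

    Missing values are dropped per feature; features entirely missing in
    one group are flagged not comparable. Results carry the CLES (as
    P(positive > negative)), its orientation to the larger-mean group,
    the U statistic, raw and BH-adjusted p-values, and a flag for
    ``cles_reported > flag_threshold``. Rows are ranked by
    ``|cles − 0.5|`` descending.
    """
    feature_names = list(FEATURE_NAMES) if feature_names is None else list(feature_names)
    pos = group_table[group_table["group"] == "positive"]
    neg = group_table[group_table["group"] == "negative"]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both groups must be non-empty")
    rows = []
    for name in feature_names:
        xp = pos[name].to_numpy(dtype=float)
        xn = neg[name].to_numpy(dtype=float)
        xp = xp[np.isfinite(xp)]
        xn = xn[np.isfinite(xn)]
        row = {"feature": name, "n_pos": xp.size, "n_neg": xn.size,
               "cles": np.nan, "cles_reported": np.nan,
               "larger_mean_group": None, "u_statistic": np.nan,
               "p_value": np.nan, "comparable": xp.size > 0 and xn.size > 0}
        if row["comparable"]:
            c = cles(xp, xn)
            larger = "positive" if xp.mean() >= xn.mean() else "negative"
            row["cles"] = c
            row["larger_mean_group"] = larger
            row["cles_reported"] = c if larger == "positive" else 1.0 - c
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                u, p = mann_whitney(xp, xn)
            row["u_statistic"] = u
            row["p_value"] = p
        rows.append(row)
    out = pd.DataFrame(rows)
    out["p_bh"] = np.nan
    valid = out["p_value"].notna()
    if valid.any():
        out.loc[valid, "p_bh"] = multipletests(
            out.loc[valid, "p_value"].to_numpy(), method="fdr_bh")[1]
    out["flagged"] = out["comparable"] & (out["cles_reported"] > flag_threshold)
    out["effect_distance"] = (out["cles"] - 0.5).abs()
    out = out.sort_values(["effect_distance", "feature"],
                          ascending=[False, True], kind="mergesort")
    return out.reset_index(drop=True)
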