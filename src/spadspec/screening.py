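"""Correlation screening of spectral features against SPAD.

Pearson correlations between each vegetation index (or each raw band)
and SPAD are computed per (stage, leaf position) group and preprocessing
chain, classified into descriptive magnitude bins, and the strongest
chain × index combination per group is selected for downstream modelling.
The magnitude bins are descriptive, not hypothesis tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indices import IndexTable
from .io import SampleSet

#: |r| class edges; a boundary value belongs to the lower class
STRENGTH_CLASSES = [
    (0.3, "none"),
    (0.5, "weak"),
    (0.8, "significant"),
    (1.0, "highly_significant"),
]


def pearson_r(x, y) -> float:
    """Product-moment correlation; pairs with a masked (NaN) side dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx**2).sum() * (dy**2).sum())
    if denom == 0:
        raise ValueError("zero variance")
    return float((dx * dy).sum() / denom)


def classify_strength(r: float) -> str:
    a = abs(r)
    if a > 1 + 1e-12:
        raise ValueError(f"|r| = {a} exceeds 1")
    for edge, label in STRENGTH_CLASSES:
        if a <= edge:
            return label
    return "highly_significant"


def correlate_indices(
    table: IndexTable,
    spad,
    group=None,
) -> pd.DataFrame:
    """Correlate every index column with SPAD (listwise NaN deletion).

    Returns a tidy frame with one row per feature: r, n complete pairs,
    masked count and strength class; ``group`` annotates the rows.
    """
    spad = np.asarray(spad, dtype=float)
    rows = []
    for name in table.values.columns:
        v = table.column(name)
        keep = np.isfinite(v) & np.isfinite(spad)
        row = {
            "stage": group[0] if group else None,
            "leaf_position": group[1] if group else None,
            "chain": table.preprocessing_tag,
            "feature": name,
            "n": int(keep.sum()),
            "n_masked": int((~keep).sum()),
        }
        if keep.sum() >= 3 and np.std(v[keep]) > 0:
            r = pearson_r(v, spad)
            row["r"] = r
            row["strength_class"] = classify_strength(r)
        else:
            row["r"] = np.nan
            row["strength_class"] = "masked"
        rows.append(row)
    return pd.DataFrame(rows)


def bandwise_correlogram(samples: SampleSet) -> pd.Series:
    """Pearson r between reflectance and SPAD at every grid wavelength.

    Zero-variance bands are masked (NaN).  Useful for locating the
    strongest-responding spectral regions, e.g. the red-edge minimum.
    """
    if samples.n < 3:
        raise ValueError("need at least 3 samples")
    X = samples.reflectance
    y = samples.spad
    dy = y - y.mean()
    dX = X - X.mean(axis=0)
    sy = np.sqrt((dy**2).sum())
    sx = np.sqrt((dX**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (dX * dy[:, None]).sum(axis=0) / (sx * sy)
    r[sx == 0] = np.nan
    return pd.Series(r, index=pd.Index(samples.wavelengths, name="wavelength"), name="r")


def select_optimal(results: pd.DataFrame) -> pd.DataFrame:
    """Per-group argmax of |r| over chain × feature candidates.

    Ties on |r| break by (a) fewer masked samples, (b) lexicographic
    feature name; ties are recorded in the ``tied`` column.  Rows with
    masked r are ignored.
    """
    if results.empty:
        raise ValueError("no correlation results")
    valid = results.dropna(subset=["r"]).copy()
    if valid.empty:
        raise ValueError("all correlation results masked")
    valid["abs_r"] = valid["r"].abs()
    out = []
    for (stage, pos), grp in valid.groupby(["stage", "leaf_position"], sort=False):
        ordered = grp.sort_values(
            ["abs_r", "n_masked", "feature"], ascending=[False, True, True]
        )
        best = ordered.iloc[0]
        n_tied = int((grp["abs_r"] == best["abs_r"]).sum())
        out.append(
            {
                "stage": stage,
                "leaf_position": pos,
                "chain": best["chain"],
                "feature": best["feature"],
                "r": float(best["r"]),
                "strength_class": best["strength_class"],
                "tied": n_tied > 1,
            }
        )
    return pd.DataFrame(out)
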