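"""SPAD prediction models: SPXY partitioning, single-index function
regression, and multi-index random-forest regression.

SPXY is the joint-X/Y extension of Kennard-Stone sample selection: a
deterministic farthest-point sweep on the combined distance
d = dX/max(dX) + dY/max(dY) picks a calibration (training) set that
covers both predictor and response space; the remainder is the test set.

Single-index models regress SPAD on one vegetation index with linear,
quadratic, exponential (a·e^{bx}) or power (a·x^b) forms, reporting
in-sample R²/RMSE.  The power form is declared not fittable when the
index takes non-positive values, as a real-exponent power law is then
undefined.

The random forest averages T regression trees, ŷ = (1/T) Σ f_t(x); its
two hyperparameters — number of trees and features tried per split
(mtry) — are searched over 5-1000 and 1-⌊2p/3⌋ respectively, scored by
out-of-bag R² on the training partition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform
from sklearn.ensemble import RandomForestRegressor

from . import metrics
from .indices import IndexTable

SINGLE_INDEX_FORMS = ("linear", "quadratic", "exponential", "power")

#: coarse logarithmic tree-count grid spanning the 5-1000 search range
DEFAULT_N_TREES_GRID = (5, 10, 50, 100, 200, 500, 1000)


@dataclass
class SplitResult:
    train_ids: list
    test_ids: list
    ratio: float

    @property
    def n(self) -> int:
        return len(self.train_ids) + len(self.test_ids)


@dataclass
class ModelReport:
    model_form: str
    params: dict
    train_metrics: metrics.MetricSet | None = None
    test_metrics: metrics.MetricSet | None = None
    chain: str | None = None
    group: tuple | None = None
    status: str = "ok"
    notes: dict = field(default_factory=dict)


# -- SPXY partitioning ---------------------------------------------------

def spxy_split(features, target, test_fraction: float = 0.2, ids=None) -> SplitResult:
    """Deterministic SPXY train/test partition.

    Seeds the training set with the pair at maximum combined distance,
    then repeatedly adds the sample whose minimum combined distance to
    the already-selected set is largest, until the training set holds
    round((1 − test_fraction)·n) samples.  Distance ties break toward
    the lower index.  No randomness is involved.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    y = np.asarray(target, dtype=float)
    n = y.size
    if n < 5:
        raise ValueError("need at least 5 samples to partition")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    dX = squareform(pdist(X))
    dY = np.abs(y[:, None] - y[None, :])
    if dX.max() == 0 and dY.max() == 0:
        raise ValueError("degenerate data: all samples identical in X and Y")
    d = (dX / dX.max() if dX.max() > 0 else dX) + (
        dY / dY.max() if dY.max() > 0 else dY
    )

    n_train = int(round((1 - test_fraction) * n))
    n_train = min(max(n_train, 2), n - 1)
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    remaining = [r for r in range(n) if r not in selected]
    while len(selected) < n_train:
        min_d = d[np.ix_(remaining, selected)].min(axis=1)
        k = remaining[int(np.argmax(min_d))]
        selected.append(k)
        remaining.remove(k)

    if ids is None:
        ids = list(range(n))
    ids = list(ids)
    return SplitResult(
        train_ids=[ids[s] for s in selected],
        test_ids=[ids[r] for r in remaining],
        ratio=1 - test_fraction,
    )


# -- single-index function regression ------------------------------------

def _fit_form(x, y, form):
    if form == "linear":
        c = np.polyfit(x, y, 1)
        return {"slope": c[0], "intercept": c[1]}, np.polyval(c, x)
    if form == "quadratic":
        c = np.polyfit(x, y, 2)
        return {"a": c[0], "b": c[1], "c": c[2]}, np.polyval(c, x)
    if form == "exponential":
        # log-linearised start values, then NLS with additive errors
        b0, loga0 = np.polyfit(x, np.log(y), 1)
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(b * t),
            x,
            y,
            p0=[np.exp(loga0), b0],
            maxfev=20000,
        )
        return {"a": popt[0], "b": popt[1]}, popt[0] * np.exp(popt[1] * x)
    if form == "power":
        b0, loga0 = np.polyfit(np.log(x), np.log(y), 1)
        popt, _ = curve_fit(
            lambda t, a, b: a * np.power(t, b),
            x,
            y,
            p0=[np.exp(loga0), b0],
            maxfev=20000,
        )
        return {"a": popt[0], "b": popt[1]}, popt[0] * np.power(x, popt[1])
    raise ValueError(f"unknown model form {form!r}")


def fit_single_index(vi, spad, form: str, chain=None, group=None) -> ModelReport:
    """Fit SPAD ~ f(index) for one functional form, in-sample metrics.

    Returns a report with ``status="not_fittable"`` instead of raising
    when the power form meets non-positive index values.
    """
    x = np.asarray(vi, dtype=float)
    y = np.asarray(spad, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 5:
        raise ValueError("need at least 5 complete pairs")
    if form == "power" and np.any(x <= 0):
        return ModelReport(
            model_form=form,
            params={},
            chain=chain,
            group=group,
            status="not_fittable",
            notes={"reason": "power law undefined for non-positive index values"},
        )
    try:
        params, fitted = _fit_form(x, y, form)
    except RuntimeError as err:  # NLS failed to converge
        return ModelReport(
            model_form=form,
            params={},
            chain=chain,
            group=group,
            status="not_fittable",
            notes={"reason": str(err)},
        )
    return ModelReport(
        model_form=form,
        params={k: float(v) for k, v in params.items()},
        train_metrics=metrics.metric_set(fitted, y),
        chain=chain,
        group=group,
    )


def predict_single_index(report: ModelReport, vi) -> np.ndarray:
    x = np.asarray(vi, dtype=float)
    p = report.params
    if report.model_form == "linear":
        return p["slope"] * x + p["intercept"]
    if report.model_form == "quadratic":
        return p["a"] * x**2 + p["b"] * x + p["c"]
    if report.model_form == "exponential":
        return p["a"] * np.exp(p["b"] * x)
    if report.model_form == "power":
        return p["a"] * np.power(x, p["b"])
    raise ValueError(f"no prediction rule for {report.model_form!r}")


# -- random-forest regression --------------------------------------------

def fit_rf(
    index_table: IndexTable,
    spad,
    split: SplitResult,
    n_trees_grid=DEFAULT_N_TREES_GRID,
    mtry_values=None,
    seed: int = 0,
    group=None,
) -> ModelReport:
    """Random-forest SPAD regression on the vegetation-index table.

    Index columns containing masked values are dropped (and logged in
    the report) before fitting.  The (n_trees, mtry) pair maximising
    out-of-bag R² on the SPXY training partition is selected — ties
    break toward the smaller forest — and train/test metrics of the
    refitted winner are reported.  Fixed seed ⇒ reproducible report.
    """
    values = index_table.values
    spad = np.asarray(spad, dtype=float)
    good_cols = [c for c in values.columns if np.isfinite(values[c]).all()]
    dropped = [c for c in values.columns if c not in good_cols]
    if not good_cols:
        raise ValueError("all index columns masked; nothing to fit")
    X = values[good_cols].to_numpy(dtype=float)
    pos = {sid: i for i, sid in enumerate(values.index)}
    tr = np.array([pos[s] for s in split.train_ids])
    te = np.array([pos[s] for s in split.test_ids])
    p = len(good_cols)
    if mtry_values is None:
        mtry_values = range(1, max(1, int(np.floor(2 * p / 3))) + 1)

    spad_tr = spad[tr]
    best = (-np.inf, None, None)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small forests may miss OOB coverage
        for T in n_trees_grid:
            for m in mtry_values:
                rf = RandomForestRegressor(
                    n_estimators=T,
                    max_features=m,
                    oob_score=True,
                    random_state=seed,
                    n_jobs=1,
                )
                rf.fit(X[tr], spad_tr)
                score = rf.oob_score_
                if np.isfinite(score) and score > best[0]:
                    best = (score, T, m)
    if best[1] is None:
        raise RuntimeError("hyperparameter search produced no valid OOB score")
    _, T, m = best
    rf = RandomForestRegressor(
        n_estimators=T, max_features=m, oob_score=True, random_state=seed, n_jobs=1
    )
    rf.fit(X[tr], spad_tr)
    return ModelReport(
        model_form="rf",
        params={"n_trees": int(T), "mtry": int(m), "oob_r2": float(best[0])},
        train_metrics=metrics.metric_set(rf.predict(X[tr]), spad_tr),
        test_metrics=metrics.metric_set(rf.predict(X[te]), spad[te]),
        chain=index_table.preprocessing_tag,
        group=group,
        notes={"dropped_columns": dropped, "n_features": p},
    )
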