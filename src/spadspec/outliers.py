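"""Two-pronged anomaly screening for paired spectra + SPAD datasets.

SPAD side: K-means (Euclidean) clustering of the univariate SPAD values;
a point farther from its assigned centre than the pooled mean distance
plus two pooled standard deviations is an outlier.  With the default
k = 1 this degenerates gracefully to a centre-distance (mean ± 2 SD of
distances) rule, appropriate for a single unimodal group.

Spectral side: Monte-Carlo PLSR residual analysis.  The PLSR component
count is chosen by 10-fold cross-validation (capped at 20); repeated
random calibration subsets are fitted and every sample's prediction
residual recorded; samples whose mean absolute residual exceeds the mean
plus three standard deviations of that per-sample statistic are flagged.

Because anomalies on either side invalidate the pair, flagged SPAD
values and flagged spectra are excluded simultaneously (the union).
Screening is applied per (stage, leaf position) group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

from .io import SampleSet


@dataclass
class OutlierReport:
    spad_outlier_ids: list
    spectral_outlier_ids: list
    removed_ids: list
    n_before: int
    n_after: int
    thresholds_used: dict = field(default_factory=dict)


def spad_outliers_kmeans(
    spad,
    sample_ids=None,
    k: int = 1,
    sd_multiplier: float = 2.0,
    random_state: int = 0,
) -> list:
    """Flag anomalous SPAD values by K-means centre distance.

    Distances of every point to its assigned cluster centre are pooled;
    points with distance strictly greater than mean + ``sd_multiplier``
    × SD (n−1) are flagged.  Returns sample ids (or integer positions
    when ``sample_ids`` is None).
    """
    spad = np.asarray(spad, dtype=float)
    n = spad.size
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < 3 * k:
        raise ValueError(f"need at least 3·k = {3 * k} points, got {n}")
    if k == 1:
        centers = np.array([spad.mean()])
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=k, n_init=10, random_state=random_state)
        labels = km.fit_predict(spad.reshape(-1, 1))
        centers = km.cluster_centers_.ravel()
    dist = np.abs(spad - centers[labels])
    threshold = dist.mean() + sd_multiplier * np.std(dist, ddof=1)
    flags = np.flatnonzero(dist > threshold)
    if sample_ids is None:
        return flags.tolist()
    sample_ids = list(sample_ids)
    return [sample_ids[i] for i in flags]


def _truncated_pls_predictions(pls: PLSRegression, X: np.ndarray) -> np.ndarray:
    """Predictions of a fitted PLSR at every component count 1..kmax.

    NIPALS components are computed sequentially, so the first k
    components of a kmax-component fit equal a k-component fit; the
    truncated coefficient matrix is rotations[:, :k] @ loadings[:, :k].T.
    Returns an (n, kmax) array of predictions.
    """
    Xc = X - pls._x_mean
    kmax = pls.x_rotations_.shape[1]
    preds = np.empty((X.shape[0], kmax))
    for k in range(1, kmax + 1):
        B = pls.x_rotations_[:, :k] @ pls.y_loadings_[:, :k].T
        preds[:, k - 1] = (Xc @ B).ravel() + pls.intercept_.ravel()
    return preds


def select_pls_components(
    X: np.ndarray,
    y: np.ndarray,
    max_components: int = 20,
    n_folds: int = 10,
    seed: int = 0,
) -> int:
    """Component count minimising 10-fold CV RMSE of PLSR y ~ X."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    kmax = int(min(max_components, n - int(np.ceil(n / n_folds)) - 1, X.shape[1]))
    if kmax < 1:
        raise ValueError("too few samples for PLSR component selection")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    sse = np.zeros(kmax)
    for tr, te in kf.split(X):
        pls = PLSRegression(n_components=kmax, scale=False)
        pls.fit(X[tr], y[tr])
        preds = _truncated_pls_predictions(pls, X[te])
        sse += ((preds - y[te, None]) ** 2).sum(axis=0)
    return int(np.argmin(sse)) + 1


def spectral_outliers_mcplsr(
    spectra,
    spad,
    sample_ids=None,
    max_components: int = 20,
    n_iter: int = 1000,
    sd_multiplier: float = 3.0,
    cal_fraction: float = 0.8,
    holdout_only: bool = False,
    seed: int = 0,
) -> list:
    """Monte-Carlo PLSR residual screening of spectra against SPAD.

    Steps: (1) pick the PLSR component count by 10-fold CV RMSE, capped
    at ``max_components``; (2) fit the full-data model and record its
    residuals; (3) for each of ``n_iter`` iterations fit PLSR on a
    random ``cal_fraction`` subset (without replacement) and store every
    sample's absolute prediction residual (all samples by default, only
    held-out samples with ``holdout_only``); (4) flag samples whose mean
    absolute residual exceeds the mean + ``sd_multiplier`` × SD of the
    per-sample means.  Deterministic for a fixed seed.
    """
    X = np.asarray(spectra, dtype=float)
    y = np.asarray(spad, dtype=float)
    n = X.shape[0]
    if n <= max_components:
        max_components = max(1, n - 2)
    if np.allclose(X, X[0]):
        raise ValueError("degenerate spectra: no variance for PLSR")
    rng = np.random.default_rng(seed)

    n_comp = select_pls_components(X, y, max_components, seed=seed)
    full = PLSRegression(n_components=n_comp, scale=False).fit(X, y)
    _initial_residuals = y - full.predict(X).ravel()  # step-2 record

    n_cal = max(n_comp + 2, int(round(cal_fraction * n)))
    abs_sum = np.zeros(n)
    counts = np.zeros(n)
    for _ in range(n_iter):
        cal = rng.choice(n, size=n_cal, replace=False)
        pls = PLSRegression(n_components=n_comp, scale=False).fit(X[cal], y[cal])
        resid = np.abs(y - pls.predict(X).ravel())
        if holdout_only:
            mask = np.ones(n, dtype=bool)
            mask[cal] = False
            abs_sum[mask] += resid[mask]
            counts[mask] += 1
        else:
            abs_sum += resid
            counts += 1
    counts[counts == 0] = 1  # samples never held out keep statistic 0
    stat = abs_sum / counts
    # residuals below 1% of the response spread are numerical slop from a
    # (near-)exact fit, not anomaly information: nothing stands out
    if stat.max() <= 1e-2 * max(1e-12, float(np.std(y, ddof=1))):
        return []
    threshold = stat.mean() + sd_multiplier * np.std(stat, ddof=1)
    flags = np.flatnonzero(stat > threshold)
    if sample_ids is None:
        return flags.tolist()
    sample_ids = list(sample_ids)
    return [sample_ids[i] for i in flags]


def paired_exclude(
    samples: SampleSet, spad_ids, spectral_ids
) -> tuple[SampleSet, OutlierReport]:
    """Remove the union of SPAD- and spectrum-flagged samples."""
    all_ids = set(samples.sample_ids)
    spad_ids = list(spad_ids)
    spectral_ids = list(spectral_ids)
    unknown = (set(spad_ids) | set(spectral_ids)) - all_ids
    if unknown:
        raise KeyError(f"unknown sample id(s): {sorted(unknown)[:5]}")
    removed = set(spad_ids) | set(spectral_ids)
    keep = np.array([sid not in removed for sid in samples.sample_ids])
    cleaned = samples.subset(keep)
    report = OutlierReport(
        spad_outlier_ids=sorted(spad_ids),
        spectral_outlier_ids=sorted(spectral_ids),
        removed_ids=sorted(removed),
        n_before=samples.n,
        n_after=cleaned.n,
    )
    cleaned.log(
        f"paired_exclude: removed {len(removed)} of {samples.n} "
        f"({len(spad_ids)} SPAD-flagged, {len(spectral_ids)} spectrum-flagged)"
    )
    return cleaned, report


def screen_sample_set(
    samples: SampleSet,
    k: int = 1,
    max_components: int = 20,
    n_iter: int = 1000,
    sd_multiplier: float = 3.0,
    cal_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[SampleSet, OutlierReport]:
    """Run both screening rules per (stage, leaf position) group.

    Group-wise screening matches the per-group structure of the SPAD
    summaries and downstream analyses.  Returns the cleaned set and a
    combined report.
    """
    spad_ids: list = []
    spectral_ids: list = []
    for (stage, pos), group in samples.groupby_position():
        spad_ids += spad_outliers_kmeans(group.spad, group.sample_ids, k=k)
        spectral_ids += spectral_outliers_mcplsr(
            group.reflectance,
            group.spad,
            group.sample_ids,
            max_components=max_components,
            n_iter=n_iter,
            sd_multiplier=sd_multiplier,
            cal_fraction=cal_fraction,
            seed=seed,
        )
    cleaned, report = paired_exclude(samples, spad_ids, spectral_ids)
    report.thresholds_used = {
        "kmeans_k": k,
        "kmeans_sd_multiplier": 2.0,
        "mcplsr_max_components": max_components,
        "mcplsr_n_iter": n_iter,
        "mcplsr_sd_multiplier": sd_multiplier,
        "mcplsr_cal_fraction": cal_fraction,
        "seed": seed,
    }
    return cleaned, report
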