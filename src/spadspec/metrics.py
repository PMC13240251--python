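"""Model-evaluation statistics for SPAD calibration.

R² here is the squared Pearson correlation between predicted and actual
values (not 1 − SSE/SST).  The two agree for an unbiased least-squares fit
but differ for offset-biased predictors: the squared-correlation form is
invariant to affine transforms of the prediction, so it measures ranking
fidelity rather than absolute agreement.  RMSE uses the n denominator.
RPD — the ratio of the reference data's standard deviation (n−1) to the
prediction RMSE — is the standard chemometrics model-capability index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleSet

#: RPD capability classes; upper edges, boundary assigned to the lower class
RPD_CLASSES = [
    (1.0, "Extremely poor"),
    (1.4, "Poor"),
    (1.8, "Acceptable"),
    (2.0, "Good"),
    (2.5, "Very good"),
    (np.inf, "Excellent"),
]


@dataclass
class MetricSet:
    r2: float
    rmse: float
    rpd: float
    rpd_class: str


def r_squared(pred, actual) -> float:
    """Squared Pearson correlation between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.size < 3:
        raise ValueError("need at least 3 points")
    dp = pred - pred.mean()
    da = actual - actual.mean()
    denom = np.sqrt((dp**2).sum() * (da**2).sum())
    if denom == 0:
        raise ValueError("zero variance in predictions or observations")
    return float(((dp * da).sum() / denom) ** 2)


def rmse(pred, actual) -> float:
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.size == 0:
        raise ValueError("empty input")
    if pred.shape != actual.shape:
        raise ValueError("length mismatch")
    return float(np.sqrt(np.mean((pred - actual) ** 2)))


def classify_rpd(value: float) -> str:
    if value <= 0:
        raise ValueError("RPD must be positive")
    for edge, label in RPD_CLASSES:
        if value <= edge:
            return label
    raise AssertionError("unreachable")


def rpd(actual, rmse_value: float) -> tuple[float, str]:
    """RPD = sd(actual, n−1) / RMSE, with its capability class."""
    if rmse_value <= 0:
        raise ValueError("RMSE must be positive for RPD")
    sd = float(np.std(np.asarray(actual, dtype=float), ddof=1))
    value = sd / rmse_value
    return value, classify_rpd(value)


def metric_set(pred, actual) -> MetricSet:
    """Bundle R², RMSE and RPD (+ class) for one prediction vector.

    A numerically perfect fit (RMSE 0) gets an infinite RPD in the top
    capability class rather than an error.
    """
    e = rmse(pred, actual)
    if e == 0:
        v, c = float("inf"), RPD_CLASSES[-1][1]
    else:
        v, c = rpd(actual, e)
    return MetricSet(r2=r_squared(pred, actual), rmse=e, rpd=v, rpd_class=c)


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100·sd/mean."""
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * sd / mean


def group_summary(samples: SampleSet, rounded: bool = False) -> pd.DataFrame:
    """Per-(stage, leaf position) SPAD summary: n, max, min, mean, sd, CV%.

    CV is the coefficient of variation, 100·sd/mean, with sd on the n−1
    denominator.  ``rounded`` gives the one-decimal presentation used in
    reports; machine consumers keep full precision.
    """
    rows = []
    for (stage, pos), group in samples.groupby_position():
        spad = group.spad
        if spad.size < 2:
            raise ValueError(f"group ({stage}, {pos}) too small for sd")
        mean = float(spad.mean())
        sd = float(np.std(spad, ddof=1))
        rows.append(
            {
                "stage": stage,
                "leaf_position": pos,
                "n": int(spad.size),
                "max": float(spad.max()),
                "min": float(spad.min()),
                "mean": mean,
                "sd": sd,
                "cv_percent": cv_percent(mean, sd),
            }
        )
    out = pd.DataFrame(rows)
    if rounded:
        for c in ["max", "min", "mean", "sd", "cv_percent"]:
            out[c] = out[c].round(1)
    return out


def relative_spad(test_spad: float, high_n_control_spad: float) -> tuple[float, str]:
    """Relative SPAD (plot / high-nitrogen control) and topdressing call.

    A ratio below 0.95 flags nitrogen shortage needing topdressing; at or
    above 0.95 the supply is sufficient.
    """
    if high_n_control_spad <= 0:
        raise ValueError("control SPAD must be positive")
    ratio = test_spad / high_n_control_spad
    return ratio, ("topdress" if ratio < 0.95 else "sufficient")
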