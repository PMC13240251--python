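"""Spectral preprocessing: SG smoothing, SNV, detrend, MSC, and chains.

The scatter-removal transforms target the two dominant leaf-spectroscopy
artifacts: a multiplicative gain (optical path / surface roughness) and an
additive baseline offset.  SNV removes both within a single spectrum by
standardisation; MSC removes them by regression against a reference
spectrum; detrend removes smooth polynomial baselines; Savitzky-Golay
smoothing suppresses band-to-band noise first.  Chains therefore always
lead with SG when it is present.

All standard deviations use the n−1 denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .io import SampleSet, Spectrum

VALID_STEPS = ("SG", "SNV", "DT", "MSC")

#: the four preprocessing chains used throughout the pipeline
STANDARD_CHAINS = ("SG", "SG-SNV", "SG-SNV-DT", "SG-MSC")


@dataclass
class PreprocessingChain:
    """An ordered list of steps from {SG, SNV, DT, MSC} plus parameters.

    SG defaults (window 15, polyorder 2) suit 1 nm-sampled leaf spectra
    from a 3 nm-resolution instrument; detrend degree 2 is the standard
    pairing with SNV.  After applying MSC the reference spectrum used is
    stored (per group) on the chain for reuse on held-out data.
    """

    steps: tuple
    sg_window: int = 15
    sg_polyorder: int = 2
    dt_degree: int = 2
    msc_reference: str | np.ndarray = "mean"
    fitted_msc_references_: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.steps = tuple(s.upper() for s in self.steps)
        for s in self.steps:
            if s not in VALID_STEPS:
                raise ValueError(f"unknown preprocessing step {s!r}")
        if "SG" in self.steps and self.steps[0] != "SG":
            raise ValueError("SG smoothing, when used, must be the first step")

    @property
    def tag(self) -> str:
        return "-".join(self.steps) if self.steps else "raw"

    @classmethod
    def from_tag(cls, tag: str, **params) -> "PreprocessingChain":
        return cls(steps=tuple(tag.upper().split("-")), **params)


# -- single-spectrum / matrix primitives ---------------------------------

def sg_smooth(x: np.ndarray, window: int = 15, polyorder: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis, length preserving.

    Edges are handled by fitting the boundary polynomial to the truncated
    window, so polynomials up to ``polyorder`` pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if window % 2 == 0:
        raise ValueError("SG window must be odd")
    if polyorder >= window:
        raise ValueError("SG polyorder must be smaller than window")
    if window > x.shape[-1]:
        raise ValueError("SG window exceeds grid length")
    return savgol_filter(x, window_length=window, polyorder=polyorder, mode="interp")


def snv(x: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-spectrum centre and scale to sd 1."""
    x = np.asarray(x, dtype=float)
    mean = x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, ddof=1, keepdims=True)
    if np.any(sd <= 1e-12 * np.maximum(1.0, np.abs(mean))):
        raise ValueError("SNV undefined for a constant spectrum")
    return (x - mean) / sd


def detrend(x: np.ndarray, wavelengths: np.ndarray, degree: int = 2) -> np.ndarray:
    """Subtract the least-squares polynomial baseline of given degree."""
    arr = np.asarray(x, dtype=float)
    one_d = arr.ndim == 1
    X = np.atleast_2d(arr)
    wavelengths = np.asarray(wavelengths, dtype=float)
    if degree < 1:
        raise ValueError("detrend degree must be >= 1")
    if degree >= wavelengths.size:
        raise ValueError("detrend degree must be below grid length")
    # centred/scaled wavelength axis keeps the Vandermonde well conditioned
    t = (wavelengths - wavelengths.mean()) / (wavelengths.max() - wavelengths.min())
    V = np.vander(t, degree + 1, increasing=True)
    coef, *_ = np.linalg.lstsq(V, X.T, rcond=None)
    resid = X - (V @ coef).T
    return resid[0] if one_d else resid


def msc(
    spectra: np.ndarray,
    reference: np.ndarray | str = "mean",
) -> tuple[np.ndarray, np.ndarray]:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum x is regressed as x = a + b·ref over bands (OLS) and
    returned as (x − a)/b, inverting the fitted additive and
    multiplicative scatter.  Returns (corrected, reference) so the
    reference — by default the mean spectrum of the input set — can be
    frozen and reused on test data.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if isinstance(reference, str):
        if reference != "mean":
            raise ValueError(f"unknown MSC reference {reference!r}")
        if X.shape[0] < 2:
            raise ValueError("MSC with mean reference needs >= 2 spectra")
        ref = X.mean(axis=0)
    else:
        ref = np.asarray(reference, dtype=float)
    dref = ref - ref.mean()
    denom = (dref**2).sum()
    if denom == 0:
        raise ValueError("MSC reference is constant")
    out = np.empty_like(X)
    for i, x in enumerate(X):
        b = ((x - x.mean()) * dref).sum() / denom
        if abs(b) < 1e-8:
            raise ValueError(f"MSC slope ~0 for spectrum {i}; correction undefined")
        a = x.mean() - b * ref.mean()
        out[i] = (x - a) / b
    return out, ref


# -- Spectrum-level conveniences -----------------------------------------

def sg_smooth_spectrum(s: Spectrum, window: int = 15, polyorder: int = 2) -> Spectrum:
    return Spectrum(s.wavelengths, sg_smooth(s.reflectance, window, polyorder), "SG")


def snv_spectrum(s: Spectrum) -> Spectrum:
    return Spectrum(s.wavelengths, snv(s.reflectance), "SNV")


def detrend_spectrum(s: Spectrum, degree: int = 2) -> Spectrum:
    return Spectrum(s.wavelengths, detrend(s.reflectance, s.wavelengths, degree), "DT")


# -- chain application on SampleSets -------------------------------------

def apply_chain(
    samples: SampleSet,
    chain: PreprocessingChain | str,
    per_group: bool = True,
) -> SampleSet:
    """Apply a preprocessing chain, returning a new tagged SampleSet.

    SG, SNV and DT act per spectrum.  MSC needs a reference: with
    ``per_group`` (default) the reference is the mean spectrum of each
    (stage, leaf position) group, matching per-group downstream analysis;
    otherwise one global reference is used.  Fitted references are stored
    on the chain under the group key (or ``"__all__"``).
    """
    if isinstance(chain, str):
        chain = PreprocessingChain.from_tag(chain)
    X = samples.reflectance.copy()
    for step in chain.steps:
        if step == "SG":
            X = sg_smooth(X, chain.sg_window, chain.sg_polyorder)
        elif step == "SNV":
            X = snv(X)
        elif step == "DT":
            X = detrend(X, samples.wavelengths, chain.dt_degree)
        elif step == "MSC":
            if per_group and isinstance(chain.msc_reference, str):
                keys = list(zip(samples.meta["stage"], samples.meta["leaf_position"]))
                for key in dict.fromkeys(keys):
                    idx = np.array([k == key for k in keys])
                    X[idx], ref = msc(X[idx], chain.msc_reference)
                    chain.fitted_msc_references_[key] = ref
            else:
                X, ref = msc(X, chain.msc_reference)
                chain.fitted_msc_references_["__all__"] = ref
    out = samples.with_reflectance(X, chain.tag)
    out.log(f"apply_chain: {chain.tag}")
    return out
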