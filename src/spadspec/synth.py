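"""Synthetic paired (leaf spectrum, SPAD, metadata) data generator.

Real maize leaf reflectance in 325-1075 nm is shaped by chlorophyll
absorption in the visible (strong blue and red troughs, a green peak
between them), a sharp red-edge ramp near 700-750 nm, and a bright,
pigment-insensitive NIR plateau.  The generator renders

    reflectance = gain · (floor + (base(λ) − floor) · e^(−γ·chl·absorb(λ)))
                  + offset + noise

``base`` is a smooth NIR-plateau template; ``absorb`` is a fixed
nonnegative absorption kernel concentrated in 450-700 nm that ramps to
zero across the 700-750 nm red edge.  The Beer-Lambert exponential
matters: at field-typical chlorophyll the blue and red troughs are
optically saturated (reflectance pinned near the residual ``floor``,
nearly insensitive to chlorophyll), while the red-edge shoulder stays
in its responsive regime — which is why red-edge features carry most of
the SPAD information, the defining trait of real leaf spectra that the
screening stage is expected to rediscover.  Reflectance is negatively
and monotonically coupled to chlorophyll wherever the kernel is
positive and uncoupled on the NIR plateau.  Latent chlorophyll is an
affine, monotone function of SPAD.  Per-sample multiplicative ``gain``
and additive ``offset`` emulate the scatter artifacts SNV/MSC are
designed to remove; white noise emulates sensor noise that SG smoothing
suppresses.

Per-group SPAD distributions default to the observed field summary
(stage × leaf position means and SDs, all with CV below 10%).  Planted
outliers — gross SPAD shifts or corrupted spectra — are flagged in a
:class:`SyntheticTruth` table before corruption so screening rules can
be scored against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import DEFAULT_WAVELENGTHS, META_COLUMNS, SampleSet

# -- spectral model constants --------------------------------------------

#: SPAD → latent chlorophyll (kernel units); affine and monotone increasing
CHL_PER_SPAD = 0.0012
CHL_OFFSET = 0.0

#: residual visible reflectance of a fully absorbing leaf
REFLECTANCE_FLOOR = 0.05
#: Beer-Lambert absorptivity scale; γ·chl·absorb ≈ 4 in the red trough at
#: field-typical SPAD, putting 450/670 nm deep in saturation while the
#: red-edge shoulder stays responsive
ABSORPTIVITY = 70.0

#: SPAD-502 physical reading range; draws are truncated to it
SPAD_RANGE = (0.0, 100.0)

#: planted-anomaly effect sizes, in group-SD units
SPAD_OUTLIER_SHIFT_SD = (5.0, 8.0)  # recorded-SPAD displacement from group mean
SPECTRAL_MISMATCH_SD = 3.0  # spectrum-implied SPAD displacement toward group mean


def spad_to_chlorophyll(spad):
    """Monotone affine link from SPAD reading to latent chlorophyll."""
    return CHL_OFFSET + CHL_PER_SPAD * np.asarray(spad, dtype=float)


def baseline_template(wavelengths) -> np.ndarray:
    """Pigment-free leaf template: dim visible rising to the NIR plateau."""
    wl = np.asarray(wavelengths, dtype=float)
    return 0.12 + 0.42 / (1.0 + np.exp(-(wl - 715.0) / 18.0))


def absorption_kernel(wavelengths) -> np.ndarray:
    """Nonnegative chlorophyll absorption kernel.

    Blue (450 nm) and red (670 nm) Gaussian lobes span 450-700 nm; a
    linear ramp extinguishes the kernel across the 700-750 nm red edge,
    leaving the NIR plateau (≥ 750 nm) exactly chlorophyll-free.
    """
    wl = np.asarray(wavelengths, dtype=float)
    blue = 0.85 * np.exp(-((wl - 450.0) ** 2) / (2 * 50.0**2))
    red = np.exp(-((wl - 670.0) ** 2) / (2 * 60.0**2))
    ramp = np.clip((750.0 - wl) / 50.0, 0.0, 1.0)
    ramp[wl <= 700.0] = 1.0
    return (blue + red) * ramp


def generate_spectrum(
    latent_chlorophyll: float,
    wavelengths=DEFAULT_WAVELENGTHS,
    gain: float = 1.0,
    offset: float = 0.0,
    noise: np.ndarray | None = None,
) -> np.ndarray:
    """Render one reflectance spectrum from latent chlorophyll + artifacts.

    ``noise`` is a per-band additive array (or None).  Output is clipped
    to the open unit interval, as a real reflectance factor must be.
    """
    wl = np.asarray(wavelengths, dtype=float)
    if np.any(np.diff(wl) != 1):
        raise ValueError("wavelength grid must be strictly increasing at 1 nm steps")
    if latent_chlorophyll <= 0:
        raise ValueError("latent chlorophyll must be positive")
    base = baseline_template(wl)
    depth_term = np.exp(-ABSORPTIVITY * latent_chlorophyll * absorption_kernel(wl))
    r = gain * (REFLECTANCE_FLOOR + (base - REFLECTANCE_FLOOR) * depth_term)
    r = r + offset
    if noise is not None:
        r = r + np.asarray(noise, dtype=float)
    return np.clip(r, 1e-6, 1 - 1e-6)


# -- dataset-level configuration -----------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """One (stage, leaf position) group with its SPAD distribution."""

    stage: str
    leaf_position: str
    n: int
    spad_mean: float
    spad_sd: float

    def __post_init__(self):
        if self.spad_sd <= 0:
            raise ValueError("spad_sd must be positive")
        if self.n < 1:
            raise ValueError("group size must be positive")


#: field-campaign group summary the generator targets by default:
#: (stage, leaf position, n, SPAD mean, SPAD sd) — every CV below 10%
FIELD_GROUP_SPECS = (
    GroupSpec("V6", "apical", 225, 54.2, 3.0),
    GroupSpec("V8", "apical", 219, 53.5, 3.4),
    GroupSpec("V12", "apical", 228, 50.6, 4.3),
    GroupSpec("R1", "upper_ear", 227, 55.9, 5.3),
    GroupSpec("R1", "ear", 228, 55.8, 5.3),
    GroupSpec("R1", "lower_ear", 228, 50.6, 4.3),
    GroupSpec("R2", "upper_ear", 224, 61.7, 5.8),
    GroupSpec("R2", "ear", 228, 60.0, 5.2),
    GroupSpec("R2", "lower_ear", 229, 61.2, 5.0),
)

VARIETIES = ("Zhengdan958", "Yuke918")
NITROGEN = ("N0", "N2", "N4")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Scatter and noise scales are free parameters of the emulation (the
    field campaign reports none): gain sd 0.02 and offset sd 0.008
    reflect the few-percent repositioning reproducibility of a
    white-reference-corrected leaf-clip measurement, and noise sd 0.003
    reflectance units is typical shot/dark noise for a field
    spectroradiometer after three-scan averaging.
    """

    groups: tuple = FIELD_GROUP_SPECS
    wavelengths: np.ndarray = field(default_factory=lambda: DEFAULT_WAVELENGTHS.copy())
    scatter_gain_sd: float = 0.02
    scatter_offset_sd: float = 0.008
    noise_sd: float = 0.003
    spad_outlier_fraction: float = 0.0
    spectral_outlier_fraction: float = 0.0
    spectral_outlier_kind: str = "mismatch"  # "mismatch", "gain" or "spike"
    seed: int = 0

    def __post_init__(self):
        if not self.groups:
            raise ValueError("at least one group required")
        for f in (self.spad_outlier_fraction, self.spectral_outlier_fraction):
            if not 0.0 <= f <= 0.2:
                raise ValueError("outlier fractions must lie in [0, 0.2]")
        if self.spectral_outlier_kind not in ("mismatch", "gain", "spike"):
            raise ValueError("spectral_outlier_kind must be mismatch, gain or spike")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


def scaled_field_groups(n_per_group: int) -> tuple:
    """The default group grid with every group resized to ``n_per_group``."""
    return tuple(replace(g, n=n_per_group) for g in FIELD_GROUP_SPECS)


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests.

    ``table`` has one row per sample: latent_chlorophyll, gain, offset,
    spad_outlier, spectral_outlier (flags set before corruption was
    applied).
    """

    table: pd.DataFrame
    seed: int

    @property
    def planted_outlier_ids(self) -> list:
        m = self.table["spad_outlier"] | self.table["spectral_outlier"]
        return self.table.loc[m, "sample_id"].tolist()

    @property
    def spad_outlier_ids(self) -> list:
        return self.table.loc[self.table["spad_outlier"], "sample_id"].tolist()

    @property
    def spectral_outlier_ids(self) -> list:
        return self.table.loc[self.table["spectral_outlier"], "sample_id"].tolist()


def _truncated_normal(rng, mean, sd, size):
    lo, hi = SPAD_RANGE
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_dataset(config: GeneratorConfig) -> tuple[SampleSet, SyntheticTruth]:
    """Draw one full dataset plus its ground truth.

    Per group: SPAD ~ Normal(mean, sd) truncated to the meter range;
    latent chlorophyll follows the affine link; each leaf is rendered
    with its own scatter gain/offset and white noise.  Planted outliers
    are flagged first, then corrupted: SPAD outliers get their recorded
    SPAD displaced 5-8 group SDs from the group mean (spectrum
    untouched); spectral outliers keep their SPAD but get a corrupted
    spectrum — by default one whose pigment signature implies a SPAD 3
    group SDs toward the group mean (a spectrum-SPAD mismatch, the
    anomaly a residual-based screen detects), alternatively a gross ×2
    gain or a band-localised spike.  The same config (including seed)
    reproduces the same dataset bit for bit.
    """
    rng = np.random.default_rng(config.seed)
    wl = np.asarray(config.wavelengths)
    meta_rows, truth_rows, spectra = [], [], []

    for g in config.groups:
        spad = _truncated_normal(rng, g.spad_mean, g.spad_sd, g.n)
        chl = spad_to_chlorophyll(spad)
        gains = 1.0 + rng.normal(0.0, config.scatter_gain_sd, g.n)
        gains = np.clip(gains, 0.3, None)
        offsets = rng.normal(0.0, config.scatter_offset_sd, g.n)

        n_spad_out = int(round(config.spad_outlier_fraction * g.n))
        n_spec_out = int(round(config.spectral_outlier_fraction * g.n))
        order = rng.permutation(g.n)
        spad_out = np.zeros(g.n, dtype=bool)
        spec_out = np.zeros(g.n, dtype=bool)
        spad_out[order[:n_spad_out]] = True
        spec_out[order[n_spad_out : n_spad_out + n_spec_out]] = True

        # SPAD corruption displaces the recorded value 5-8 group SDs from the
        # group mean, so every planted outlier is >= 5 SD off-centre
        recorded_spad = spad.copy()
        for i in np.flatnonzero(spad_out):
            shift = rng.uniform(5.0, 8.0) * g.spad_sd * rng.choice([-1.0, 1.0])
            recorded_spad[i] = np.clip(g.spad_mean + shift, 0.5, 99.5)

        for i in range(g.n):
            noise = rng.normal(0.0, config.noise_sd, wl.size) if config.noise_sd else None
            render_chl = chl[i]
            if spec_out[i] and config.spectral_outlier_kind == "mismatch":
                # spectrum-SPAD mismatch: the pigment signature is washed
                # toward an average-looking leaf (glare / poor clip contact /
                # target swap); displacement fixed at 3 group SDs so the
                # planted effect size is a single calibrated quantity
                sign = -1.0 if spad[i] >= g.spad_mean else 1.0
                implied = np.clip(
                    spad[i] + sign * SPECTRAL_MISMATCH_SD * g.spad_sd, 1.0, 99.0
                )
                render_chl = float(spad_to_chlorophyll(implied))
            r = generate_spectrum(render_chl, wl, gains[i], offsets[i], noise)
            if spec_out[i] and config.spectral_outlier_kind == "gain":
                r = np.clip(r * 2.0, 1e-6, 1 - 1e-6)
            elif spec_out[i] and config.spectral_outlier_kind == "spike":
                center = rng.uniform(500.0, 900.0)
                r = np.clip(
                    r + 0.3 * np.exp(-((wl - center) ** 2) / (2 * 8.0**2)),
                    1e-6,
                    1 - 1e-6,
                )
            spectra.append(r)

        for i in range(g.n):
            sid = f"{g.stage}-{g.leaf_position}-{i:04d}"
            meta_rows.append(
                {
                    "sample_id": sid,
                    "stage": g.stage,
                    "leaf_position": g.leaf_position,
                    "variety": VARIETIES[i % 2],
                    "nitrogen": NITROGEN[i % 3],
                    "spad": float(recorded_spad[i]),
                }
            )
            truth_rows.append(
                {
                    "sample_id": sid,
                    "latent_chlorophyll": float(chl[i]),
                    "gain": float(gains[i]),
                    "offset": float(offsets[i]),
                    "spad_outlier": bool(spad_out[i]),
                    "spectral_outlier": bool(spec_out[i]),
                }
            )

    meta = pd.DataFrame(meta_rows)[META_COLUMNS]
    samples = SampleSet(wl, np.vstack(spectra), meta)
    samples.log(
        f"generate_dataset: {samples.n} samples, seed={config.seed}, "
        f"{sum(r['spad_outlier'] for r in truth_rows)} SPAD / "
        f"{sum(r['spectral_outlier'] for r in truth_rows)} spectral planted outliers"
    )
    return samples, SyntheticTruth(pd.DataFrame(truth_rows), config.seed)
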