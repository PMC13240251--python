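"""Core containers and tabular I/O for paired leaf spectra + SPAD data.

A :class:`SampleSet` couples a shared wavelength grid, one reflectance row
per leaf, and a metadata table (growth stage, leaf position, variety,
nitrogen rate, SPAD).  All pipeline stages consume and return SampleSets.

Canonical on-disk layout is a pair of CSV files: a wide spectra table
(rows = samples, columns = integer wavelengths in nm) and a SPAD/metadata
table keyed by ``sample_id``.  A long spectra dialect
(sample_id, wavelength, reflectance) is supported read-only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: growth stages, vegetative (V) then reproductive (R)
STAGES = ("V6", "V8", "V12", "R1", "R2")

#: leaf positions measured per stage: the fully expanded apical leaf during
#: vegetative growth, the three ear leaves once silking starts
LEAF_POSITIONS = ("apical", "upper_ear", "ear", "lower_ear")

VALID_STAGE_POSITIONS = {
    "V6": ("apical",),
    "V8": ("apical",),
    "V12": ("apical",),
    "R1": ("upper_ear", "ear", "lower_ear"),
    "R2": ("upper_ear", "ear", "lower_ear"),
}

NITROGEN_RATES = ("N0", "N2", "N4")

#: default 1 nm grid of the handheld spectroradiometer, 325-1075 nm
DEFAULT_WAVELENGTHS = np.arange(325, 1076)

META_COLUMNS = ["sample_id", "stage", "leaf_position", "variety", "nitrogen", "spad"]


class SpectraFormatError(ValueError):
    """Raised when an input table violates the spectral data contract."""


@dataclass
class Spectrum:
    """A single leaf reflectance spectrum on an integer-nm grid.

    Raw reflectance lies in [0, 1]; preprocessed values (SNV, detrend ...)
    are unrestricted in sign, so range checks apply only to ``raw`` data.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    preprocessing_tag: str = "raw"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.wavelengths.shape != self.reflectance.shape:
            raise SpectraFormatError(
                f"wavelengths ({self.wavelengths.shape}) and reflectance "
                f"({self.reflectance.shape}) lengths differ"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectraFormatError("wavelength grid must be strictly increasing")
        if np.any(~np.isfinite(self.reflectance)):
            raise SpectraFormatError("reflectance contains non-finite values")


def band(spectrum: Spectrum, wavelength: float) -> float:
    """Reflectance at the grid wavelength nearest to ``wavelength``.

    Ties between two equidistant grid points resolve toward the lower
    wavelength.  On the native 1 nm grid an integer query is an exact hit.
    """
    wl = spectrum.wavelengths
    if wavelength < wl[0] or wavelength > wl[-1]:
        raise ValueError(
            f"wavelength {wavelength} nm outside grid span {wl[0]}-{wl[-1]} nm"
        )
    idx = int(np.argmin(np.abs(wl - wavelength)))  # argmin takes first = lower
    return float(spectrum.reflectance[idx])


@dataclass
class SampleSet:
    """Aligned collection of leaf spectra, SPAD values and group metadata.

    Attributes
    ----------
    wavelengths : (p,) array of int nm, shared by every sample.
    reflectance : (n, p) float array, one row per sample.
    meta : DataFrame with columns ``sample_id, stage, leaf_position,
        variety, nitrogen, spad``; row order matches ``reflectance``.
    preprocessing_tag : chain label, ``"raw"`` for unprocessed data.
    provenance : free-text log of operations applied so far.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    meta: pd.DataFrame
    preprocessing_tag: str = "raw"
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths)
        self.reflectance = np.atleast_2d(np.asarray(self.reflectance, dtype=float))
        if self.reflectance.shape[1] != self.wavelengths.size:
            raise SpectraFormatError(
                "reflectance width does not match wavelength grid"
            )
        if len(self.meta) != self.reflectance.shape[0]:
            raise SpectraFormatError("metadata rows do not match spectra rows")
        ids = self.meta["sample_id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise SpectraFormatError(f"duplicate sample_id(s): {dups[:5]}")
        self.meta = self.meta.reset_index(drop=True)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.reflectance.shape[0]

    @property
    def sample_ids(self) -> list:
        return self.meta["sample_id"].tolist()

    @property
    def spad(self) -> np.ndarray:
        return self.meta["spad"].to_numpy(dtype=float)

    def spectrum(self, i: int) -> Spectrum:
        return Spectrum(self.wavelengths, self.reflectance[i], self.preprocessing_tag)

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        return (self.spectrum(i) for i in range(self.n))

    # -- structural operations -------------------------------------------
    def subset(self, mask_or_ids) -> "SampleSet":
        """Row subset by boolean mask, integer positions, or sample ids."""
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        elif np.issubdtype(arr.dtype, np.integer):
            idx = arr
        else:
            pos = {sid: i for i, sid in enumerate(self.meta["sample_id"])}
            missing = [s for s in arr if s not in pos]
            if missing:
                raise KeyError(f"unknown sample_id(s): {missing[:5]}")
            idx = np.array([pos[s] for s in arr], dtype=int)
        return replace(
            self,
            reflectance=self.reflectance[idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            provenance=list(self.provenance),
        )

    def groupby_position(self):
        """Yield ((stage, leaf_position), SampleSet) in first-seen order."""
        keys = list(zip(self.meta["stage"], self.meta["leaf_position"]))
        seen: list = []
        for k in keys:
            if k not in seen:
                seen.append(k)
        for k in seen:
            mask = np.array([key == k for key in keys])
            yield k, self.subset(mask)

    def with_reflectance(self, reflectance: np.ndarray, tag: str) -> "SampleSet":
        return replace(
            self,
            reflectance=np.asarray(reflectance, dtype=float),
            preprocessing_tag=tag,
            provenance=list(self.provenance),
        )

    def log(self, message: str) -> None:
        logger.info(message)
        self.provenance.append(message)


def _validate_stage_positions(meta: pd.DataFrame) -> None:
    for _, row in meta.iterrows():
        valid = VALID_STAGE_POSITIONS.get(row["stage"])
        if valid is None:
            raise SpectraFormatError(f"unknown stage {row['stage']!r}")
        if row["leaf_position"] not in valid:
            raise SpectraFormatError(
                f"leaf position {row['leaf_position']!r} invalid for stage "
                f"{row['stage']!r} (sample {row['sample_id']})"
            )


def _check_raw_range(values: np.ndarray, ids, wavelengths) -> None:
    bad = np.argwhere((values < 0) | (values > 1))
    if bad.size:
        i, j = bad[0]
        raise SpectraFormatError(
            f"raw reflectance {values[i, j]:g} outside [0, 1] "
            f"(sample {ids[i]}, wavelength {wavelengths[j]} nm)"
        )


def read_sample_set(
    spectra_path,
    spad_path,
    dialect: str = "wide",
    validate_range: bool = True,
) -> SampleSet:
    """Read paired spectra + SPAD/metadata CSVs and join on ``sample_id``.

    Samples present in only one of the two files are dropped, with the
    count logged — unmatched spectra and unmatched SPAD readings cannot
    enter a paired calibration.
    """
    if dialect == "wide":
        spec = pd.read_csv(spectra_path)
        id_col = spec.columns[0]
        wavelengths = np.array([int(round(float(c))) for c in spec.columns[1:]])
        values = spec.iloc[:, 1:].to_numpy(dtype=float)
        spec_ids = spec[id_col].astype(str).tolist()
    elif dialect == "long":
        long = pd.read_csv(spectra_path)
        pivot = long.pivot(index="sample_id", columns="wavelength", values="reflectance")
        wavelengths = np.array([int(w) for w in pivot.columns])
        values = pivot.to_numpy(dtype=float)
        spec_ids = [str(s) for s in pivot.index]
    else:
        raise ValueError(f"unknown spectra dialect {dialect!r}")

    if pd.Series(spec_ids).duplicated().any():
        raise SpectraFormatError("duplicate sample_id in spectra file")
    if np.any(~np.isfinite(values)):
        raise SpectraFormatError("non-numeric or missing reflectance value")
    if validate_range:
        _check_raw_range(values, spec_ids, wavelengths)

    meta = pd.read_csv(spad_path)
    meta["sample_id"] = meta["sample_id"].astype(str)
    if meta["sample_id"].duplicated().any():
        raise SpectraFormatError("duplicate sample_id in SPAD/metadata file")

    spec_index = {sid: i for i, sid in enumerate(spec_ids)}
    common = [sid for sid in meta["sample_id"] if sid in spec_index]
    n_dropped = (len(spec_ids) - len(common)) + (len(meta) - len(common))
    meta = meta[meta["sample_id"].isin(common)].reset_index(drop=True)
    order = [spec_index[sid] for sid in meta["sample_id"]]
    _validate_stage_positions(meta)

    ss = SampleSet(wavelengths, values[order], meta[META_COLUMNS])
    if n_dropped:
        ss.log(f"read_sample_set: dropped {n_dropped} unpaired record(s)")
    ss.log(f"read_sample_set: {ss.n} paired samples, {wavelengths.size} bands")
    return ss


def write_sample_set(samples: SampleSet, spectra_path, spad_path) -> None:
    """Write the wide spectra CSV and the SPAD/metadata CSV."""
    spec = pd.DataFrame(
        samples.reflectance, columns=[str(w) for w in samples.wavelengths]
    )
    spec.insert(0, "sample_id", samples.sample_ids)
    spec.to_csv(spectra_path, index=False, float_format="%.10g")
    samples.meta[META_COLUMNS].to_csv(spad_path, index=False, float_format="%.10g")
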