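"""The 21 vegetation indices used for leaf SPAD screening.

Each index combines reflectance at five nominal bands — 450, 550, 670,
720 and 800 nm — chosen to bracket chlorophyll absorption (blue, red),
the green reflectance peak, the red edge and the NIR plateau.  Formulas
are implemented exactly in their published variants, including the
nonstandard SAVI (2.5 factor with +0.5), CCI2 (+0.1 in the denominator)
and PVI difference forms, because the screening results are defined by
these variants rather than by the literature's canonical versions.

Ratios whose denominator magnitude falls below 1e-10 yield NaN rather
than raising: preprocessed spectra (SNV, detrend) legitimately cross
zero, and the screening stage drops masked entries listwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SampleSet, Spectrum, band

#: nominal bands (nm) feeding every index
INDEX_BANDS = (450, 550, 670, 720, 800)

_GUARD = 1e-10


def _div(num, den):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.where(np.abs(den) < _GUARD, np.nan, num / np.where(den == 0, 1, den))
    return out


# Each formula maps band reflectances (R450, R550, R670, R720, R800) to the
# index value; vectorised over arrays.
INDEX_FORMULAS = {
    "ARVI": lambda b: _div(b[800] - (2 * b[670] - b[450]), b[800] + b[670] + 0.5),
    "CARI": lambda b: (b[670] - b[450]) - (b[670] - b[800]),
    "CCI2": lambda b: _div(b[800] - b[670], b[800] + b[670] + 0.1),
    "CIgreen": lambda b: _div(b[800], b[550]) - 1,
    "CIrededge": lambda b: _div(b[800], b[720]) - 1,
    "CNDVI": lambda b: _div(
        (b[800] - b[670]) - (b[800] - b[450]),
        (b[800] - b[670]) + (b[800] - b[450]),
    ),
    "CVI": lambda b: _div(b[800] ** 2, b[670]),
    "CVI2": lambda b: _div(b[800], b[720] + 1),
    "DVI": lambda b: b[800] - b[670],
    "EVI": lambda b: 2.5 * _div(b[800] - b[670], b[800] + 6 * b[670] - 7.5 * b[450] + 1),
    "GNDVI": lambda b: _div(b[800] - b[550], b[800] + b[550]),
    "MCARI": lambda b: _div((b[670] - b[450]) - (b[670] - b[800]), b[670]),
    "NDRE": lambda b: _div(b[800] - b[720], b[800] + b[720]),
    "NDVI": lambda b: _div(b[800] - b[670], b[800] + b[670]),
    "NLI": lambda b: _div(b[800], b[670] + b[550]),
    "PVI": lambda b: (b[800] - b[670]) - 0.5 * (b[800] + b[670]),
    "RVI": lambda b: _div(b[800], b[670]),
    "SAVI": lambda b: 2.5 * _div(b[800] - b[670], b[800] + b[670] + 0.5),
    "TGI": lambda b: b[550] - 0.39 * b[670] - 0.61 * b[450],
    "VARI": lambda b: _div(b[550] - b[670], b[550] + b[670] - b[450]),
    "VIG": lambda b: _div(
        b[800] - (2 * b[670] + b[450]), b[800] + (2 * b[670] + b[450])
    ),
}

INDEX_NAMES = tuple(sorted(INDEX_FORMULAS))


@dataclass
class IndexTable:
    """samples × 21 vegetation-index values for one preprocessing chain."""

    values: pd.DataFrame  # index = sample_id, columns = INDEX_NAMES
    preprocessing_tag: str

    @property
    def n_masked(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def column(self, name: str) -> np.ndarray:
        return self.values[name].to_numpy(dtype=float)


def compute_index_from_bands(bands: dict, name: str):
    """Evaluate one index from a {wavelength: reflectance} band mapping."""
    if name not in INDEX_FORMULAS:
        raise KeyError(f"unknown vegetation index {name!r}")
    return INDEX_FORMULAS[name](bands)


def compute_index(spectrum: Spectrum, name: str) -> float:
    bands = {w: band(spectrum, w) for w in INDEX_BANDS}
    return float(compute_index_from_bands(bands, name))


def compute_index_table(samples: SampleSet) -> IndexTable:
    """All 21 indices for every sample; NaN entries are masked and logged."""
    if samples.n == 0:
        raise ValueError("empty SampleSet")
    grid = {w: int(np.argmin(np.abs(samples.wavelengths - w))) for w in INDEX_BANDS}
    bands = {w: samples.reflectance[:, i] for w, i in grid.items()}
    data = {name: INDEX_FORMULAS[name](bands) for name in INDEX_NAMES}
    values = pd.DataFrame(data, index=pd.Index(samples.sample_ids, name="sample_id"))
    table = IndexTable(values=values, preprocessing_tag=samples.preprocessing_tag)
    if table.n_masked:
        masked = values.isna()
        where = [
            (sid, col)
            for sid in values.index
            for col in values.columns
            if masked.loc[sid, col]
        ]
        samples.log(f"compute_index_table: {table.n_masked} masked entries {where[:10]}")
    return table
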