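"""Centroided MS2 spectrum container, mzML reading and pre-processing."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional

import numpy as np


@dataclass
class MsnSpectrum:
    """One centroided MSn spectrum.

    ``mz`` is strictly ascending after preprocessing; intensities are finite
    and non-negative.  ``precursor_charge`` is None when the acquisition did
    not annotate a charge.
    """

    native_id: str
    precursor_mz: float
    precursor_charge: Optional[int]
    retention_time: float            # seconds
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if np.any(~np.isfinite(self.intensity)) or np.any(self.intensity < 0):
            raise ValueError(f"non-finite or negative intensity in spectrum {self.native_id}")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def tic(self) -> float:
        return float(self.intensity.sum())

    def is_empty(self) -> bool:
        return self.mz.size == 0


def read_ms2(path: str) -> Iterator[MsnSpectrum]:
    """Stream MS level-2 spectra with a selected precursor from an mzML file.

    Spectra without an annotated precursor charge are emitted with
    ``precursor_charge=None``; profile-mode spectra are skipped with a
    warning.  Malformed files raise :class:`nuclink._mzml.MzmlParseError`
    naming the scan.
    """
    from ._mzml import iter_spectra

    yield from iter_spectra(path)


def preprocess(
    spectrum: MsnSpectrum,
    top_n_per_window: int = 20,
    window: float = 100.0,
    min_peaks: int = 10,
) -> MsnSpectrum:
    """Window-wise intensity filtering.

    Keeps the ``top_n_per_window`` most intense peaks in every ``window``-m/z
    bin and empties spectra left with fewer than ``min_peaks`` peaks.  m/z
    values and retained intensities are never mutated, only filtered, which
    makes the operation idempotent.
    """
    if spectrum.is_empty():
        return spectrum
    bins = np.floor(spectrum.mz / window).astype(np.int64)
    keep = np.zeros(spectrum.n_peaks, dtype=bool)
    for b in np.unique(bins):
        idx = np.flatnonzero(bins == b)
        if idx.size <= top_n_per_window:
            keep[idx] = True
        else:
            top = idx[np.argsort(spectrum.intensity[idx], kind="stable")[-top_n_per_window:]]
            keep[top] = True
    mz, inten = spectrum.mz[keep], spectrum.intensity[keep]
    if mz.size < min_peaks:
        mz, inten = mz[:0], inten[:0]
    return replace(spectrum, mz=mz, intensity=inten)
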