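"""NIR spectral preprocessing for berry cell-death modelling.

Handheld NIR spectrometers of the microPHAZIR class record absorbance on a
fixed, uniform wavelength grid between 1596 and 2396 nm. The feature matrix
for regression modelling is built in three steps, in this fixed order:

1. Savitzky–Golay first derivative on the full instrument range (computing
   the derivative before slicing avoids filter edge artifacts inside the
   modelling band);
2. band selection down to 1596–1919 nm, the region carrying the hydrogen
   peroxide overtone signal associated with cell death;
3. replicate averaging to one spectrum per berry (derivative and mean are
   both linear, so the order is immaterial; it is fixed for
   reproducibility).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

__all__ = [
    "Spectrum",
    "SpectraSet",
    "INSTRUMENT_RANGE_NM",
    "MODEL_BAND_NM",
    "savitzky_golay_first_derivative",
    "select_band",
    "average_replicates",
    "preprocess",
    "read_spectra_csv",
    "write_spectra_csv",
]

INSTRUMENT_RANGE_NM = (1596.0, 2396.0)
#: wavelength band used as regression inputs (H2O2 overtone region)
MODEL_BAND_NM = (1596.0, 1919.0)
DEFAULT_SG_WINDOW = 9
DEFAULT_SG_POLYORDER = 2


@dataclass
class Spectrum:
    """One absorbance reading on a uniform wavelength grid (nm)."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    berry_id: str = ""
    replicate: int = 1

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavelengths.shape != self.absorbance.shape:
            raise ValueError("wavelengths and absorbance must have equal length")
        d = np.diff(self.wavelengths)
        if len(d) and (d <= 0).any():
            raise ValueError("wavelength grid must be strictly increasing")
        if len(d) and np.ptp(d) > 1e-6:
            raise ValueError("wavelength grid must be uniform (required by the derivative filter)")

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])


@dataclass
class SpectraSet:
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.spectra:
            g = self.spectra[0].wavelengths
            for s in self.spectra[1:]:
                if s.wavelengths.shape != g.shape or not np.allclose(s.wavelengths, g):
                    raise ValueError("all spectra must share one wavelength grid")

    @property
    def grid(self) -> np.ndarray:
        return self.spectra[0].wavelengths

    def to_matrix(self) -> tuple[np.ndarray, list[str]]:
        """(n_spectra x n_wavelengths) matrix plus the berry ids, in order."""
        return (np.vstack([s.absorbance for s in self.spectra]),
                [s.berry_id for s in self.spectra])


def savitzky_golay_first_derivative(
    s: Spectrum,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
) -> Spectrum:
    """Smoothed first derivative d(absorbance)/d(wavelength), AU/nm.

    Local least-squares polynomial fits over a sliding window; the terminal
    windows are handled by polynomial extrapolation so the output stays on
    the full grid.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if not window > polyorder >= 1:
        raise ValueError("require window > polyorder >= 1")
    if len(s.absorbance) < window:
        raise ValueError("spectrum shorter than the filter window")
    d = savgol_filter(s.absorbance, window_length=window, polyorder=polyorder,
                      deriv=1, delta=s.step, mode="interp")
    return replace(s, absorbance=d)


def select_band(s: Spectrum, lo: float, hi: float) -> Spectrum:
    """Inclusive wavelength slice [lo, hi] nm."""
    if lo >= hi:
        raise ValueError("band bounds must satisfy lo < hi")
    keep = (s.wavelengths >= lo) & (s.wavelengths <= hi)
    if not keep.any():
        raise ValueError("band selects no wavelengths")
    return replace(s, wavelengths=s.wavelengths[keep], absorbance=s.absorbance[keep])


def average_replicates(spectra_set: SpectraSet) -> SpectraSet:
    """Pointwise mean per berry_id; one spectrum per berry, input order kept."""
    by_berry: dict[str, list[Spectrum]] = {}
    order: list[str] = []
    for s in spectra_set.spectra:
        if s.berry_id not in by_berry:
            order.append(s.berry_id)
        by_berry.setdefault(s.berry_id, []).append(s)
    out = []
    for bid in order:
        reps = by_berry[bid]
        mean = np.mean([r.absorbance for r in reps], axis=0)
        out.append(Spectrum(wavelengths=reps[0].wavelengths, absorbance=mean,
                            berry_id=bid, replicate=len(reps)))
    return SpectraSet(spectra=out)


def preprocess(
    spectra_set: SpectraSet,
    window: int = DEFAULT_SG_WINDOW,
    polyorder: int = DEFAULT_SG_POLYORDER,
    band: tuple[float, float] = MODEL_BAND_NM,
) -> SpectraSet:
    """Derivative on the full range, then band selection, then replicate mean."""
    deriv = [savitzky_golay_first_derivative(s, window, polyorder)
             for s in spectra_set.spectra]
    sliced = [select_band(s, *band) for s in deriv]
    return average_replicates(SpectraSet(spectra=sliced))


# ---------------------------------------------------------------------------
# wide-CSV IO (first column berry_id, optional replicate, wavelength headers)
# ---------------------------------------------------------------------------

def read_spectra_csv(path: str | Path) -> SpectraSet:
    df = pd.read_csv(path)
    meta_cols = [c for c in df.columns if c in ("berry_id", "replicate")]
    wl_cols = [c for c in df.columns if c not in meta_cols]
    grid = np.array([float(c) for c in wl_cols])
    spectra = []
    for _, row in df.iterrows():
        spectra.append(Spectrum(
            wavelengths=grid,
            absorbance=row[wl_cols].to_numpy(dtype=float),
            berry_id=str(row["berry_id"]) if "berry_id" in meta_cols else "",
            replicate=int(row["replicate"]) if "replicate" in meta_cols else 1,
        ))
    return SpectraSet(spectra=spectra)


def write_spectra_csv(spectra_set: SpectraSet, path: str | Path) -> None:
    rows = []
    for s in spectra_set.spectra:
        row = {"berry_id": s.berry_id, "replicate": s.replicate}
        row.update({f"{w:g}": a for w, a in zip(s.wavelengths, s.absorbance)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
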