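"""Reflectance calibration and spectral preprocessing (MSC, SNV, min-max).

Calibration converts raw counts to reflectance against all-white and
all-black references. The three preprocessing treatments operate on a
samples x channels matrix:

* MSC (multiplicative scatter correction): regress each spectrum on a
  reference spectrum (the channel-wise mean of a fitting set) and invert the
  fitted affine map. The reference is fitted on the training partition only.
* SNV (standard normal variate): per-row standardisation to mean 0 / sd 1
  (sample sd, n-1 denominator).
* Min-max normalisation: per-row rescaling onto [0, 1]; a per-channel axis
  is exposed but row-wise is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: |slope| below this in the MSC regression means the spectrum carries no
#: signal correlated with the reference and inversion would blow up
MSC_SLOPE_TOL = 1e-12


@dataclass(frozen=True)
class CalibrationFrames:
    """Raw signal plus all-white / all-black reference arrays (same shape)."""

    Rr: np.ndarray
    Rw: np.ndarray
    Rd: np.ndarray

    def __post_init__(self) -> None:
        Rr, Rw, Rd = (np.asarray(a, dtype=float) for a in (self.Rr, self.Rw, self.Rd))
        if not (Rr.shape == Rw.shape == Rd.shape):
            raise ValueError("Rr, Rw, Rd must share one shape")
        object.__setattr__(self, "Rr", Rr)
        object.__setattr__(self, "Rw", Rw)
        object.__setattr__(self, "Rd", Rd)


@dataclass(frozen=True)
class MSCReference:
    """Reference spectrum for MSC: channel-wise mean of a fitting set."""

    reference_spectrum: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.reference_spectrum, dtype=float)
        if ref.ndim != 1:
            raise ValueError("reference spectrum must be 1-D")
        if not np.all(np.isfinite(ref)):
            raise ValueError("reference spectrum must be finite")
        if np.ptp(ref) == 0:
            raise ValueError("reference spectrum is constant")
        object.__setattr__(self, "reference_spectrum", ref)


def calibrate_reflectance(frames: CalibrationFrames) -> np.ndarray:
    """Element-wise reflectance Rc = (Rr - Rd) / (Rw - Rd)."""
    denom = frames.Rw - frames.Rd
    bad = np.flatnonzero(np.ravel(denom) == 0)
    if bad.size:
        raise ZeroDivisionError(
            f"white and dark references coincide at flat index {bad[0]} "
            f"({bad.size} element(s) total)"
        )
    return (frames.Rr - frames.Rd) / denom


def fit_msc(spectra: np.ndarray) -> MSCReference:
    """Fit the MSC reference as the channel-wise mean of ``spectra`` rows."""
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("MSC reference needs a matrix with at least 2 rows")
    return MSCReference(X.mean(axis=0))


def apply_msc(spectra: np.ndarray, ref: MSCReference) -> np.ndarray:
    """Correct each row x via OLS fit x ~ a + b*ref, returning (x - a) / b."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    r = ref.reference_spectrum
    if X.shape[1] != r.shape[0]:
        raise ValueError("spectra and reference channel counts differ")
    rc = r - r.mean()
    denom = float(rc @ rc)
    b = (X - X.mean(axis=1, keepdims=True)) @ rc / denom
    if np.any(np.abs(b) < MSC_SLOPE_TOL):
        i = int(np.flatnonzero(np.abs(b) < MSC_SLOPE_TOL)[0])
        raise ValueError(f"row {i}: spectrum uncorrelated with MSC reference (|b| < {MSC_SLOPE_TOL})")
    a = X.mean(axis=1) - b * r.mean()
    return (X - a[:, None]) / b[:, None]


def snv(spectra: np.ndarray) -> np.ndarray:
    """Standard normal variate: per-row (x - mean) / sd with n-1 denominator."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        i = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"row {i} is constant; SNV undefined")
    return (X - X.mean(axis=1, keepdims=True)) / sd[:, None]


def normalize_minmax(spectra: np.ndarray, axis: int = 1) -> np.ndarray:
    """Min-max rescale onto [0, 1]; default per spectrum (axis=1), per channel with axis=0."""
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    lo = X.min(axis=axis, keepdims=True)
    hi = X.max(axis=axis, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        i = int(np.flatnonzero(np.ravel(span) == 0)[0])
        what = "row" if axis == 1 else "channel"
        raise ValueError(f"{what} {i} is constant; min-max normalisation undefined")
    return (X - lo) / span
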