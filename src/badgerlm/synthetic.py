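"""Synthetic SWIR reflectance spectra with pesticide-residue class structure.

Emulates ROI-averaged short-wave-infrared (1000-2500 nm) diffuse reflectance
spectra of melon surfaces carrying one of four pesticide residues or none.
The generator produces a shared smooth base curve with Gaussian peaks and
valleys at fixed wavelengths, adds a class-dependent reflectance offset
localised in the 1493-2038 nm window (no-residue lowest, Malathion highest),
then applies per-sample multiplicative/additive scatter and Gaussian noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_NAMES = ("None", "Acetamiprid", "Malathion", "Difenoconazole", "Beta-cypermethrin")
N_CLASSES = 5

#: window (nm) where class reflectance differences are concentrated
OFFSET_WINDOW = (1493.0, 2038.0)

DEFAULT_PEAKS = (1125.0, 1340.0, 1801.0, 2000.0, 2313.0, 2370.0)
DEFAULT_VALLEYS = (1020.0, 1269.0, 1552.0, 1929.0, 2432.0, 2466.0)


@dataclass(frozen=True)
class SpectraConfig:
    """Parameters of the synthetic spectra generator.

    ``class_offsets`` are reflectance deltas (one per class, class 0 first)
    applied as a smooth bump over the 1493-2038 nm window; class 0 (no
    residue) must hold the minimum and class 2 (Malathion) the maximum.
    """

    n_per_class: int = 160
    n_channels: int = 233
    wl_min: float = 1000.0
    wl_max: float = 2500.0
    peak_centers: tuple[float, ...] = DEFAULT_PEAKS
    valley_centers: tuple[float, ...] = DEFAULT_VALLEYS
    peak_width: float = 40.0
    class_offsets: tuple[float, ...] = (0.0, 0.05, 0.125, 0.075, 0.10)
    noise_sd: float = 0.01
    scatter_slope_range: tuple[float, float] = (0.95, 1.05)
    scatter_offset_range: tuple[float, float] = (-0.02, 0.02)
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_class < 0:
            raise ValueError("n_per_class must be non-negative")
        if self.n_channels < 2:
            raise ValueError("n_channels must be at least 2")
        if not self.wl_min < self.wl_max:
            raise ValueError("wl_min must be below wl_max")
        for c in (*self.peak_centers, *self.valley_centers):
            if not (self.wl_min <= c <= self.wl_max):
                raise ValueError(f"band center {c} nm outside [{self.wl_min}, {self.wl_max}]")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if len(self.class_offsets) != N_CLASSES:
            raise ValueError(f"class_offsets needs {N_CLASSES} entries")
        offs = self.class_offsets
        if offs[0] != min(offs) or any(offs[0] == o for o in offs[1:]):
            raise ValueError("class 0 (no residue) offset must be the strict minimum")
        if offs[2] != max(offs) or any(offs[2] == o for o in (*offs[:2], *offs[3:])):
            raise ValueError("class 2 (Malathion) offset must be the strict maximum")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for lo, hi in (self.scatter_slope_range, self.scatter_offset_range):
            if lo > hi:
                raise ValueError("scatter ranges must satisfy low <= high")


@dataclass
class LabeledSpectra:
    """Wavelength grid, reflectance matrix and integer class labels.

    The universal exchange object of the package: ``reflectance`` is
    n_samples x n_channels, ``labels`` take values 0-4 indexing
    ``class_names``.
    """

    wavelengths: np.ndarray
    reflectance: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.reflectance.ndim != 2:
            raise ValueError("reflectance must be a 2-D matrix")
        if self.reflectance.shape[0] != self.labels.shape[0]:
            raise ValueError("reflectance row count must equal number of labels")
        if self.reflectance.shape[1] != self.wavelengths.shape[0]:
            raise ValueError("reflectance column count must equal grid length")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.wavelengths)) or not np.all(np.isfinite(self.reflectance)):
            raise ValueError("non-finite values in spectra")
        if self.labels.size and (self.labels.min() < 0 or self.labels.max() >= len(self.class_names)):
            raise ValueError("labels outside 0..K-1")

    @property
    def n_samples(self) -> int:
        return self.reflectance.shape[0]

    @property
    def n_channels(self) -> int:
        return self.reflectance.shape[1]

    def replace(self, **kw) -> "LabeledSpectra":
        return dataclasses.replace(self, **kw)


def wavelength_grid(config: SpectraConfig) -> np.ndarray:
    return np.linspace(config.wl_min, config.wl_max, config.n_channels)


def _gaussian_bumps(wl: np.ndarray, centers, width: float) -> np.ndarray:
    out = np.zeros_like(wl)
    for c in centers:
        out += np.exp(-0.5 * ((wl - c) / width) ** 2)
    return out


def offset_window_weight(wl: np.ndarray) -> np.ndarray:
    """Hann-shaped weight supported on the 1493-2038 nm window, peak 1 at centre."""
    lo, hi = OFFSET_WINDOW
    u = np.clip((wl - lo) / (hi - lo), 0.0, 1.0)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    w[(wl < lo) | (wl > hi)] = 0.0
    return w


def base_curve(config: SpectraConfig) -> np.ndarray:
    """Shared noiseless base spectrum: smooth baseline plus signed Gaussian bumps."""
    wl = wavelength_grid(config)
    u = (wl - config.wl_min) / (config.wl_max - config.wl_min)
    baseline = 0.45 - 0.10 * u + 0.05 * u**2
    bumps = 0.08 * _gaussian_bumps(wl, config.peak_centers, config.peak_width)
    dips = 0.08 * _gaussian_bumps(wl, config.valley_centers, config.peak_width)
    return baseline + bumps - dips


def class_mean_curves(config: SpectraConfig) -> np.ndarray:
    """Noiseless expected spectrum per class (5 x n_channels)."""
    wl = wavelength_grid(config)
    base = base_curve(config)
    w = offset_window_weight(wl)
    return base[None, :] + np.asarray(config.class_offsets)[:, None] * w[None, :]


def generate_spectra(config: SpectraConfig) -> LabeledSpectra:
    """Draw ``n_per_class`` spectra per class with scatter and noise.

    Each sample is ``a * mean_k(wl) + b + eps`` with a, b uniform on the
    configured scatter ranges and eps i.i.d. Gaussian with sd ``noise_sd``;
    fully reproducible from ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    wl = wavelength_grid(config)
    means = class_mean_curves(config)
    n = config.n_per_class * N_CLASSES
    labels = np.repeat(np.arange(N_CLASSES), config.n_per_class)
    refl = np.empty((n, config.n_channels))
    a_lo, a_hi = config.scatter_slope_range
    b_lo, b_hi = config.scatter_offset_range
    for i, k in enumerate(labels):
        a = rng.uniform(a_lo, a_hi)
        b = rng.uniform(b_lo, b_hi)
        eps = rng.normal(0.0, config.noise_sd, size=config.n_channels) if config.noise_sd > 0 else 0.0
        refl[i] = a * means[k] + b + eps
    return LabeledSpectra(wavelengths=wl, reflectance=refl, labels=labels)


def apply_scatter(spectra: LabeledSpectra, slope: float, offset: float) -> LabeledSpectra:
    """Affine per-row distortion x -> slope*x + offset (fixture for MSC/SNV tests)."""
    if slope == 0:
        raise ValueError("slope must be non-zero (distortion must be invertible)")
    return spectra.replace(reflectance=slope * spectra.reflectance + offset)


def stratified_split(
    spectra: LabeledSpectra, train_fraction: float, seed: int
) -> tuple[LabeledSpectra, LabeledSpectra]:
    """Per-class random split; test size floored per class, remainder to train.

    With 160 samples per class and train_fraction 0.75 this yields the 3:1
    protocol of 600 training and 200 test spectra (40 test per class).
    """
    if spectra.n_samples == 0:
        raise ValueError("cannot split an empty spectra set")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for k in np.unique(spectra.labels):
        idx = np.flatnonzero(spectra.labels == k)
        if idx.size < 2:
            raise ValueError(f"class {k} has fewer than 2 samples")
        perm = rng.permutation(idx)
        n_test = int(np.floor(idx.size * (1.0 - train_fraction)))
        test_idx.append(perm[:n_test])
        train_idx.append(perm[n_test:])
    tr = np.sort(np.concatenate(train_idx))
    te = np.sort(np.concatenate(test_idx))

    def take(ix: np.ndarray) -> LabeledSpectra:
        return spectra.replace(reflectance=spectra.reflectance[ix], labels=spectra.labels[ix])

    return take(tr), take(te)


def _header(wl: np.ndarray) -> list[str]:
    return ["label"] + [f"wl_{round(float(w), 4)}" for w in wl]


def write_csv(spectra: LabeledSpectra, path) -> None:
    """Write the spectra CSV dialect: ``label,wl_1000.0,...`` one row per sample."""
    df = pd.DataFrame(spectra.reflectance, columns=_header(spectra.wavelengths)[1:])
    df.insert(0, "label", spectra.labels)
    df.to_csv(path, index=False)


def read_csv(path) -> LabeledSpectra:
    df = pd.read_csv(path)
    if df.columns[0] != "label" or not all(c.startswith("wl_") for c in df.columns[1:]):
        raise ValueError("not a spectra CSV: expected header label,wl_<nm>,...")
    wl = np.array([float(c[3:]) for c in df.columns[1:]])
    return LabeledSpectra(
        wavelengths=wl,
        reflectance=df.iloc[:, 1:].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=int),
    )
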