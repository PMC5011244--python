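"""Synthetic study inputs: the two-tone benchmark signal and
Beer–Lambert glucose-solution NIR transmission spectra.

The benchmark signal is y(t) = cos(4*pi*t) + sin(15*pi*t) sampled at
t = k/N for k = 0..N-1 (N = 1024 by default: 2 and 7.5 cycles per
record), with white Gaussian noise rescaled so the realized SNR is
exactly the requested value (5 dB by default).

The spectra generator emulates a transmission experiment on aqueous
glucose over 833-2630 nm: a handful of concentration-proportional
Gaussian absorption bands (Beer-Lambert by construction), fixed
interferent bands, a smooth low-order baseline, and iid Gaussian noise
per replicate; replicates are averaged per sample, as a spectrometer
operator would average repeated scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpectraDataset",
    "SpectraGenConfig",
    "simulated_signal",
    "add_noise_snr",
    "synthetic_spectra",
]


def simulated_signal(n: int = 1024) -> np.ndarray:
    """Two-tone benchmark y(t) = cos(4*pi*t) + sin(15*pi*t), t = k/n."""
    if n < 8:
        raise ValueError("need at least 8 samples")
    t = np.arange(n) / n
    return np.cos(4 * np.pi * t) + np.sin(15 * np.pi * t)


def add_noise_snr(signal, snr_db: float = 5.0, seed: int = 0) -> np.ndarray:
    """Add white Gaussian noise rescaled so the realized SNR is exact.

    The drawn noise vector is deterministically rescaled so that
    10*log10(sum(y^2)/sum(e^2)) equals ``snr_db`` to machine precision.
    """
    y = np.asarray(signal, dtype=float).ravel()
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite; use the clean signal for no noise")
    rng = np.random.default_rng(seed)
    e = rng.standard_normal(y.size)
    e *= np.sqrt(np.sum(y * y) / (np.sum(e * e) * 10.0 ** (snr_db / 10.0)))
    return y + e


@dataclass
class SpectraDataset:
    """Wavelength grid (nm), absorbance matrix and reference concentrations."""

    wavelengths: np.ndarray        # (n_channels,), strictly increasing
    absorbance: np.ndarray         # (n_samples, n_channels)
    concentrations: np.ndarray     # (n_samples,), mg/dL
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.absorbance.shape != (self.concentrations.size, self.wavelengths.size):
            raise ValueError("absorbance shape must be (n_samples, n_channels)")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not self.sample_ids:
            self.sample_ids = [f"S{i+1:02d}" for i in range(self.concentrations.size)]

    @property
    def n_samples(self) -> int:
        return int(self.concentrations.size)

    @property
    def n_channels(self) -> int:
        return int(self.wavelengths.size)


@dataclass(frozen=True)
class SpectraGenConfig:
    """Generator settings for synthetic glucose-solution spectra.

    Defaults mirror the transmission experiment the calibration study
    assumes: 15 concentration levels evenly spanning 50-1000 mg/dL,
    five replicate scans per solution averaged into one training
    spectrum, 500 channels over 833-2630 nm.  Analyte bands sit near
    the first-overtone (~1600 nm) and combination (~2100, 2270 nm)
    regions with absorbance proportional to concentration; two
    interferent (water-like) bands are concentration-independent.
    ``noise_sd`` is the per-replicate absorbance noise (AU).
    """

    n_samples: int = 15
    conc_min: float = 50.0
    conc_max: float = 1000.0
    wl_min: float = 833.0
    wl_max: float = 2630.0
    n_channels: int = 500
    band_centers: tuple[float, ...] = (1590.0, 2100.0, 2270.0)
    band_widths: tuple[float, ...] = (60.0, 45.0, 55.0)
    band_strengths: tuple[float, ...] = (0.35, 0.55, 0.40)  # AU at 1000 mg/dL
    interferent_centers: tuple[float, ...] = (1450.0, 1940.0)
    interferent_widths: tuple[float, ...] = (80.0, 100.0)
    interferent_strengths: tuple[float, ...] = (0.50, 0.80)
    baseline_amplitude: float = 0.02
    replicates: int = 5
    noise_sd: float = 0.01
    seed: int = 0

    def concentrations(self) -> np.ndarray:
        return np.linspace(self.conc_min, self.conc_max, self.n_samples)

    def wavelengths(self) -> np.ndarray:
        return np.linspace(self.wl_min, self.wl_max, self.n_channels)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def synthetic_spectra(cfg: SpectraGenConfig | None = None,
                      return_replicates: bool = False):
    """Generate a :class:`SpectraDataset` of replicate-averaged spectra.

    Absorbance(λ) = Σ_b strength_b · (c/1000) · gauss(λ; center_b, width_b)
    + interferent bands + a smooth per-sample baseline + iid noise per
    replicate; the returned spectra are replicate means.  With
    ``return_replicates=True`` also returns the raw replicate stack of
    shape (n_samples, replicates, n_channels).
    """
    cfg = cfg or SpectraGenConfig()
    rng = np.random.default_rng(cfg.seed)
    wl = cfg.wavelengths()
    conc = cfg.concentrations()
    wl01 = (wl - wl[0]) / (wl[-1] - wl[0])

    analyte = np.zeros((cfg.n_samples, cfg.n_channels))
    for c, w, s in zip(cfg.band_centers, cfg.band_widths, cfg.band_strengths):
        analyte += np.outer(conc / 1000.0 * s, _gauss(wl, c, w))
    background = np.zeros(cfg.n_channels)
    for c, w, s in zip(cfg.interferent_centers, cfg.interferent_widths,
                       cfg.interferent_strengths):
        background += s * _gauss(wl, c, w)

    reps = np.empty((cfg.n_samples, cfg.replicates, cfg.n_channels))
    for i in range(cfg.n_samples):
        # smooth per-sample baseline: quadratic with random coefficients
        coeffs = cfg.baseline_amplitude * rng.standard_normal(3)
        baseline = coeffs[0] + coeffs[1] * wl01 + coeffs[2] * wl01 ** 2
        clean = analyte[i] + background + baseline
        reps[i] = clean + cfg.noise_sd * rng.standard_normal(
            (cfg.replicates, cfg.n_channels))
    ds = SpectraDataset(wavelengths=wl, absorbance=reps.mean(axis=1),
                        concentrations=conc)
    if return_replicates:
        return ds, reps
    return ds
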