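"""Reconstruction- and calibration-quality metrics.

Signal reconstruction is scored by SNR (dB), RMSE and the Pearson
correlation against the clean signal.  Calibration models are scored by
the correlation coefficient R = sqrt(1 - SSres/SStot) and by RMSEP with
an (n - 1) denominator; both conventions follow the chemometric usage
this package targets (see the methods note for the SStot centring
choice).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .selection import correlative_coefficient

__all__ = [
    "ReconstructionReport",
    "CalibrationReport",
    "snr_db",
    "rmse",
    "r_coefficient",
    "rmsep",
    "reconstruction_report",
]


@dataclass
class ReconstructionReport:
    snr_db: float
    rmse: float
    rho: float

    def to_dict(self) -> dict:
        return {"snr_db": self.snr_db, "rmse": self.rmse, "rho": self.rho}


@dataclass
class CalibrationReport:
    r: float
    rmsep: float
    predictions: np.ndarray
    truth: np.ndarray

    @property
    def errors(self) -> np.ndarray:
        return self.predictions - self.truth

    def to_dict(self) -> dict:
        return {
            "R": self.r,
            "RMSEP": self.rmsep,
            "predictions": [float(v) for v in self.predictions],
            "truth": [float(v) for v in self.truth],
            "errors": [float(v) for v in self.errors],
        }


def _pair(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    return a, b


def snr_db(original, reconstructed) -> float:
    """10*log10(sum(y^2) / sum((y_hat - y)^2)); raises on a zero error vector."""
    y, yh = _pair(original, reconstructed)
    err = float(np.sum((yh - y) ** 2))
    if err == 0.0:
        raise ValueError("reconstruction is exact: SNR is infinite")
    return float(10.0 * np.log10(np.sum(y * y) / err))


def rmse(original, reconstructed) -> float:
    y, yh = _pair(original, reconstructed)
    return float(np.sqrt(np.mean((yh - y) ** 2)))


def r_coefficient(true_vals, predicted, center: str = "predictions") -> float:
    """R = sqrt(1 - SSres/SStot), clipped at 0 when SSres > SStot.

    SStot centres on the mean *prediction* by default (``center=
    "predictions"``); pass ``center="truth"`` for the textbook centring
    on the mean of the reference values.
    """
    y, yh = _pair(true_vals, predicted)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    ss_res = float(np.sum((yh - y) ** 2))
    c = float(yh.mean()) if center == "predictions" else float(y.mean())
    ss_tot = float(np.sum((c - y) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R undefined: zero total sum of squares")
    return float(np.sqrt(max(0.0, 1.0 - ss_res / ss_tot)))


def rmsep(true_vals, predicted) -> float:
    """Root mean square error of prediction with the (n - 1) denominator."""
    y, yh = _pair(true_vals, predicted)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    return float(np.sqrt(np.sum((yh - y) ** 2) / (y.size - 1)))


def reconstruction_report(original, reconstructed) -> ReconstructionReport:
    return ReconstructionReport(
        snr_db=snr_db(original, reconstructed),
        rmse=rmse(original, reconstructed),
        rho=correlative_coefficient(original, reconstructed),
    )
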