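"""Sensitive-IMF selection and denoised reconstruction.

After an (ensemble) EMD, only some modes carry signal; the rest are
noise.  The primary selector keeps the modes whose correlation with the
measured signal exceeds an adaptive threshold

    mu_h = max(mu) / (10 * max(mu) - 3),

after unconditionally discarding the first ``forced_drop`` modes (the
highest-frequency modes, where broadband noise concentrates).  Negative
correlations are folded to positive by absolute value before
thresholding.

Three alternative selectors from the denoising literature are provided
for comparison — consecutive mean squared error (CMSE), Hausdorff
distance between amplitude densities (HD), and mutual information (MI).
Their internals follow the cited literature's ideas, not this package's
primary rule; bin counts and density estimates are this package's own
choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emd import Decomposition

__all__ = [
    "SelectionResult",
    "correlative_coefficient",
    "selection_threshold",
    "select_sensitive",
    "select_cmse",
    "select_hd",
    "select_mi",
    "select",
]


@dataclass
class SelectionResult:
    """Per-mode scores, threshold, kept index set and reconstruction."""

    mu: np.ndarray                # raw per-IMF score (correlation for the primary rule)
    mu_used: np.ndarray           # score after negative-handling, in [0, 1]
    threshold: float
    forced_drop: int
    kept: tuple[int, ...]         # 1-based IMF indices
    reconstructed: np.ndarray
    criterion: str = "corr"

    def to_dict(self) -> dict:
        return {
            "criterion": self.criterion,
            "mu": [float(v) for v in self.mu],
            "mu_used": [float(v) for v in self.mu_used],
            "threshold": float(self.threshold),
            "forced_drop": int(self.forced_drop),
            "kept": list(self.kept),
        }


def correlative_coefficient(x, y) -> float:
    """Pearson product-moment correlation between two equal-length vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt(np.sum(xc * xc) * np.sum(yc * yc))
    if denom == 0.0:
        raise ValueError("correlation undefined for a constant vector")
    return float(np.clip(np.dot(xc, yc) / denom, -1.0, 1.0))


def selection_threshold(mu_used) -> float:
    """Adaptive threshold mu_h = max(mu)/(10*max(mu) - 3).

    Defined only for max(mu) > 0.3 (the denominator changes sign at
    0.3); below that the caller should fall back to keeping the single
    highest-correlation mode.
    """
    mu_used = np.asarray(mu_used, dtype=float)
    m = float(np.max(mu_used))
    if m <= 0.3:
        raise ValueError(
            "threshold undefined for max correlation <= 0.3; "
            "keep the single highest-correlation mode instead"
        )
    return m / (10.0 * m - 3.0)


def select_sensitive(decomp: Decomposition, reference, forced_drop: int = 3
                     ) -> SelectionResult:
    """Correlation-threshold selection of sensitive IMFs.

    ``reference`` is the measured (noisy) signal the decomposition came
    from.  The first ``forced_drop`` modes are removed unconditionally;
    the threshold is computed over *all* modes' folded correlations.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    if decomp.n_modes == 0:
        raise ValueError("empty decomposition")
    if ref.size != decomp.source_length:
        raise ValueError("reference length does not match decomposition")
    mu = np.array([correlative_coefficient(imf, ref) for imf in decomp.imfs])
    mu_used = np.abs(mu)
    th = selection_threshold(mu_used)
    kept = tuple(i + 1 for i in range(decomp.n_modes)
                 if i >= forced_drop and mu_used[i] > th)
    if not kept:
        raise ValueError(
            "no mode passed selection; consider lowering forced_drop")
    return SelectionResult(mu=mu, mu_used=mu_used, threshold=th,
                           forced_drop=forced_drop, kept=kept,
                           reconstructed=decomp.reconstruct(kept),
                           criterion="corr")


def select_cmse(decomp: Decomposition, reference=None) -> SelectionResult:
    """Consecutive-MSE selection (literature comparison rule).

    The partial reconstruction from mode j to the end changes, when j
    advances by one, by exactly mode j; the consecutive MSE between the
    two partial reconstructions is therefore the mean energy of mode j.
    Reconstruction starts at the mode where this quantity is minimal —
    the presumed noise/signal boundary.
    """
    k = decomp.n_modes
    if k < 2:
        raise ValueError("CMSE selection needs at least 2 modes")
    cmse = np.array([float(np.mean(imf ** 2)) for imf in decomp.imfs[:-1]])
    j_star = int(np.argmin(cmse)) + 1  # 1-based
    kept = tuple(range(j_star, k + 1))
    return SelectionResult(mu=cmse, mu_used=cmse / cmse.max(),
                           threshold=float(cmse[j_star - 1]), forced_drop=0,
                           kept=kept, reconstructed=decomp.reconstruct(kept),
                           criterion="cmse")


def _density(v: np.ndarray, edges: np.ndarray) -> np.ndarray:
    h, _ = np.histogram(v, bins=edges)
    h = h.astype(float)
    return h / h.sum()


def _fd_bins(v: np.ndarray) -> int:
    # Freedman–Diaconis, clipped to a sane range
    q75, q25 = np.percentile(v, [75, 25])
    iqr = q75 - q25
    if iqr <= 0:
        return 10
    width = 2.0 * iqr / v.size ** (1.0 / 3.0)
    return int(np.clip(np.ceil(np.ptp(v) / width), 10, 200))


def select_hd(decomp: Decomposition, reference) -> SelectionResult:
    """Hausdorff-distance selection (literature comparison rule).

    Each mode's amplitude density (normalized histogram on a common
    grid) is compared with the reference signal's density; modes whose
    Hausdorff distance between the two point sets {(bin, p)} falls
    below the largest gap in the sorted distances are kept.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    k = decomp.n_modes
    if k < 2:
        raise ValueError("HD selection needs at least 2 modes")
    nbins = _fd_bins(ref)
    lo = min(ref.min(), decomp.imfs.min())
    hi = max(ref.max(), decomp.imfs.max())
    edges = np.linspace(lo, hi, nbins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])
    scale = np.ptp(centers) or 1.0
    p_ref = _density(ref, edges)
    pts_ref = np.column_stack([centers / scale, p_ref])

    def hausdorff(pa, pb):
        d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
        return max(d.min(axis=1).max(), d.min(axis=0).max())

    dists = np.empty(k)
    for i, imf in enumerate(decomp.imfs):
        pts = np.column_stack([centers / scale, _density(imf, edges)])
        dists[i] = hausdorff(pts, pts_ref)
    order = np.argsort(dists)
    gaps = np.diff(dists[order])
    if gaps.size == 0 or np.all(gaps <= 0):
        cut = dists.max() + 1.0
    else:
        g = int(np.argmax(gaps))
        cut = 0.5 * (dists[order[g]] + dists[order[g + 1]])
    kept = tuple(i + 1 for i in range(k) if dists[i] <= cut)
    sim = 1.0 - dists / dists.max() if dists.max() > 0 else np.ones(k)
    return SelectionResult(mu=dists, mu_used=sim, threshold=float(cut),
                           forced_drop=0, kept=kept,
                           reconstructed=decomp.reconstruct(kept),
                           criterion="hd")


def _mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    nb = min(_fd_bins(a), _fd_bins(b))
    h, _, _ = np.histogram2d(a, b, bins=nb)
    pxy = h / h.sum()
    px = pxy.sum(axis=1, keepdims=True)
    py = pxy.sum(axis=0, keepdims=True)
    mask = pxy > 0
    return float(np.sum(pxy[mask] * np.log(pxy[mask] / (px @ py)[mask])))


def select_mi(decomp: Decomposition, reference) -> SelectionResult:
    """Mutual-information selection (literature comparison rule).

    Histogram MI between each mode and the reference; modes above the
    mean MI are kept.
    """
    ref = np.asarray(reference, dtype=float).ravel()
    k = decomp.n_modes
    if k < 2:
        raise ValueError("MI selection needs at least 2 modes")
    mi = np.array([_mutual_information(imf, ref) for imf in decomp.imfs])
    cut = float(mi.mean())
    kept = tuple(i + 1 for i in range(k) if mi[i] > cut)
    if not kept:
        kept = (int(np.argmax(mi)) + 1,)
    mmax = mi.max() if mi.max() > 0 else 1.0
    return SelectionResult(mu=mi, mu_used=mi / mmax, threshold=cut,
                           forced_drop=0, kept=kept,
                           reconstructed=decomp.reconstruct(kept),
                           criterion="mi")


_CRITERIA = {
    "corr": select_sensitive,
    "cmse": lambda d, ref, **kw: select_cmse(d),
    "hd": lambda d, ref, **kw: select_hd(d, ref),
    "mi": lambda d, ref, **kw: select_mi(d, ref),
}


def select(decomp: Decomposition, reference, criterion: str = "corr",
           **kwargs) -> SelectionResult:
    """Dispatch by criterion name: corr | cmse | hd | mi."""
    key = criterion.lower()
    if key not in _CRITERIA:
        raise ValueError(f"unknown criterion {criterion!r}")
    return _CRITERIA[key](decomp, reference, **kwargs)
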