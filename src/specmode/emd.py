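"""Plain empirical mode decomposition (EMD).

Sifting decomposes a 1-D signal into intrinsic mode functions (IMFs):
oscillatory components whose upper/lower cubic-spline envelopes have a
local mean near zero.  Each IMF is obtained by repeatedly subtracting
the envelope mean from the current residue; the process repeats on
successive residues until the residue is (near-)monotone.

Two sifting stop criteria are provided:

* ``"rilling"`` (default) — the envelope-amplitude criterion of the
  classical MATLAB implementations: stop when |envelope mean| /
  envelope amplitude is below ``rilling_sd`` on all but a ``rilling_tol``
  fraction of samples and below ``rilling_sd2`` everywhere.  This is the
  criterion under which white noise behaves as a dyadic filter bank
  (about log2(N) modes), which the ensemble variants rely on.
* ``"cauchy"`` — the standard-deviation criterion
  ``sum((h_prev-h)**2)/sum(h_prev**2) < stop_threshold``.

Two operators used throughout the ensemble variants live here:
``emd_mode(x, j)`` — the *j*-th EMD mode of ``x`` (zero vector when
fewer than *j* modes exist) — and ``local_mean(x)`` — the mean of the
two spline envelopes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
from scipy.linalg import solve_banded

__all__ = [
    "SiftConfig",
    "Decomposition",
    "find_extrema",
    "local_mean",
    "sift_imf",
    "emd",
    "emd_mode",
]

MIN_SIGNAL_LENGTH = 4


@dataclass(frozen=True)
class SiftConfig:
    """Controls for the sifting loop.

    ``criterion`` selects the stop rule (see module docstring);
    ``stop_threshold`` applies to the Cauchy rule only.  ``max_imfs``
    caps the number of extracted modes (``None`` = unbounded).
    ``boundary_mode`` is the envelope edge rule: ``"mirror"`` reflects
    the two nearest extrema across each edge, ``"clamp"`` pins the
    envelope to the end samples.
    """

    max_siftings: int = 100
    stop_threshold: float = 0.2
    criterion: Literal["rilling", "cauchy"] = "rilling"
    rilling_sd: float = 0.05
    rilling_sd2: float = 0.5
    rilling_tol: float = 0.05
    max_imfs: int | None = None
    boundary_mode: Literal["mirror", "clamp"] = "mirror"

    def __post_init__(self) -> None:
        if self.max_siftings < 1:
            raise ValueError("max_siftings must be >= 1")
        if not self.stop_threshold > 0:
            raise ValueError("stop_threshold must be > 0")
        if self.max_imfs is not None and self.max_imfs < 1:
            raise ValueError("max_imfs must be >= 1 or None")
        if self.criterion not in ("rilling", "cauchy"):
            raise ValueError("criterion must be 'rilling' or 'cauchy'")


@dataclass
class Decomposition:
    """Ordered IMFs (high → low frequency) plus the final residue."""

    imfs: np.ndarray  # shape (K, N)
    residue: np.ndarray  # shape (N,)
    method: str = "EMD"

    @property
    def n_modes(self) -> int:
        return int(self.imfs.shape[0])

    @property
    def source_length(self) -> int:
        return int(self.residue.shape[0])

    def reconstruct(self, indices=None) -> np.ndarray:
        """Sum of the selected IMFs (1-based indices); all + residue if None."""
        if indices is None:
            return self.imfs.sum(axis=0) + self.residue
        idx = np.asarray(sorted(indices), dtype=int) - 1
        if idx.size == 0:
            return np.zeros(self.source_length)
        if idx.min() < 0 or idx.max() >= self.n_modes:
            raise IndexError("IMF index out of range")
        return self.imfs[idx].sum(axis=0)


def _as_signal(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < MIN_SIGNAL_LENGTH:
        raise ValueError(f"signal must have at least {MIN_SIGNAL_LENGTH} samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite samples")
    return x


def find_extrema(signal) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Strict interior local extrema; plateaus resolved to their middle index.

    Returns ``(max_idx, max_val, min_idx, min_val)`` in index order.
    """
    x = _as_signal(signal)
    sign = np.sign(np.diff(x))
    nz = np.flatnonzero(sign)
    if nz.size < 2:
        e = np.empty(0, dtype=int)
        return e, x[e], e.copy(), x[e]
    s = sign[nz]
    turn = s[:-1] != s[1:]
    # extremum (possibly a plateau) spans nz[i]+1 .. nz[i+1]; take the middle
    mid = (nz[:-1] + 1 + nz[1:]) // 2
    max_idx = mid[turn & (s[:-1] > 0)]
    min_idx = mid[turn & (s[:-1] < 0)]
    return max_idx, x[max_idx], min_idx, x[min_idx]


def _spline_envelope(ei: np.ndarray, ev: np.ndarray, n: int) -> np.ndarray:
    """Evaluate the not-a-knot cubic spline through (ei, ev) at 0..n-1.

    Direct banded tridiagonal solve; several times faster than building
    a scipy interpolator object per sifting iteration.
    """
    m = ei.size
    h = np.diff(ei).astype(float)
    dy = np.diff(ev) / h
    # tridiagonal system for interior second-derivative-continuity rows
    ab = np.zeros((3, m))
    rhs = np.zeros(m)
    ab[0, 2:] = h[:-1]                # upper diag: coeff of s[i+1] is h[i-1]
    ab[1, 1:-1] = 2.0 * (h[:-1] + h[1:])
    ab[2, :-2] = h[1:]                # lower diag: coeff of s[i-1] is h[i]
    rhs[1:-1] = 3.0 * (dy[1:] * h[:-1] + dy[:-1] * h[1:])
    # not-a-knot end conditions
    ab[1, 0] = h[1]
    ab[0, 1] = ei[2] - ei[0]
    rhs[0] = ((h[0] + 2.0 * ab[0, 1]) * h[1] * dy[0] + h[0] ** 2 * dy[1]) / ab[0, 1]
    ab[1, -1] = h[-2]
    ab[2, -2] = ei[-1] - ei[-3]
    rhs[-1] = (h[-1] ** 2 * dy[-2]
               + (2.0 * ab[2, -2] + h[-1]) * h[-2] * dy[-1]) / ab[2, -2]
    slope = solve_banded((1, 1), ab, rhs)

    xq = np.arange(n, dtype=float)
    seg = np.clip(np.searchsorted(ei, xq, side="right") - 1, 0, m - 2)
    t = xq - ei[seg]
    hs = h[seg]
    c2 = (3.0 * dy[seg] - 2.0 * slope[seg] - slope[seg + 1]) / hs
    c3 = (slope[seg] + slope[seg + 1] - 2.0 * dy[seg]) / hs ** 2
    return ev[seg] + t * (slope[seg] + t * (c2 + t * c3))


_NBSYM = 2  # extrema mirrored across each edge


def _mirror_left(max_i, max_v, min_i, min_v, x):
    """Symmetrized left-boundary extrema (classical MATLAB edge rule).

    Mirrors the first ``_NBSYM`` extrema across the edge; when the edge
    sample sticks out beyond the first opposite extremum, the edge
    itself is promoted to an extremum so the envelope encloses it.
    Returns (lmax_i, lmax_v, lmin_i, lmin_v) of the prepended points.
    """
    nb = _NBSYM
    if max_i[0] < min_i[0]:
        if x[0] > min_v[0]:  # envelope of minima would undershoot the edge
            lmax_i, lmax_v = max_i[1:nb + 1][::-1], max_v[1:nb + 1][::-1]
            lmin_i, lmin_v = min_i[:nb][::-1], min_v[:nb][::-1]
            sym = max_i[0]
        else:
            lmax_i, lmax_v = max_i[:nb][::-1], max_v[:nb][::-1]
            lmin_i = np.concatenate((min_i[:nb - 1][::-1], [0]))
            lmin_v = np.concatenate((min_v[:nb - 1][::-1], [x[0]]))
            sym = 0
    else:
        if x[0] < max_v[0]:
            lmax_i, lmax_v = max_i[:nb][::-1], max_v[:nb][::-1]
            lmin_i, lmin_v = min_i[1:nb + 1][::-1], min_v[1:nb + 1][::-1]
            sym = min_i[0]
        else:
            lmax_i = np.concatenate((max_i[:nb - 1][::-1], [0]))
            lmax_v = np.concatenate((max_v[:nb - 1][::-1], [x[0]]))
            lmin_i, lmin_v = min_i[:nb][::-1], min_v[:nb][::-1]
            sym = 0
    tmax = 2 * sym - lmax_i
    tmin = 2 * sym - lmin_i
    if sym != 0 and ((tmax.size and tmax[0] > 0) or (tmin.size and tmin[0] > 0)):
        # mirrored support does not reach the edge: re-mirror about it
        if sym == max_i[0]:
            lmax_i, lmax_v = max_i[:nb][::-1], max_v[:nb][::-1]
        else:
            lmin_i, lmin_v = min_i[:nb][::-1], min_v[:nb][::-1]
        tmax = -lmax_i
        tmin = -lmin_i
    return tmax, lmax_v, tmin, lmin_v


def _boundary_extrema(max_i, max_v, min_i, min_v, x, mode):
    """Extended extrema sets (upper, lower) including boundary support."""
    n = x.size
    if mode == "clamp":
        ui = np.concatenate(([0], max_i, [n - 1]))
        uv = np.concatenate(([x[0]], max_v, [x[-1]]))
        li = np.concatenate(([0], min_i, [n - 1]))
        lv = np.concatenate(([x[0]], min_v, [x[-1]]))
        return ui, uv, li, lv
    lmax_i, lmax_v, lmin_i, lmin_v = _mirror_left(max_i, max_v, min_i, min_v, x)
    # right edge: mirror the reversed problem
    xr = x[::-1]
    rmax_i, rmax_v, rmin_i, rmin_v = _mirror_left(
        (n - 1) - max_i[::-1], max_v[::-1], (n - 1) - min_i[::-1], min_v[::-1], xr)
    ui = np.concatenate((lmax_i, max_i, (n - 1) - rmax_i[::-1]))
    uv = np.concatenate((lmax_v, max_v, rmax_v[::-1]))
    li = np.concatenate((lmin_i, min_i, (n - 1) - rmin_i[::-1]))
    lv = np.concatenate((lmin_v, min_v, rmin_v[::-1]))
    return ui, uv, li, lv


def _eval_envelope(ei: np.ndarray, ev: np.ndarray, n: int) -> np.ndarray:
    keep = np.concatenate(([True], np.diff(ei) > 0))
    ei, ev = ei[keep], ev[keep]
    if ei.size < 2:
        return np.full(n, ev[0] if ev.size else 0.0)
    if ei.size < 4:
        return np.interp(np.arange(n), ei, ev)
    return _spline_envelope(ei.astype(float), ev, n)


def _envelopes(x: np.ndarray, mode: str) -> tuple[np.ndarray, np.ndarray] | None:
    max_idx, max_val, min_idx, min_val = find_extrema(x)
    if max_idx.size < 1 or min_idx.size < 1:
        return None
    ui, uv, li, lv = _boundary_extrema(max_idx, max_val, min_idx, min_val, x, mode)
    n = x.size
    return _eval_envelope(ui, uv, n), _eval_envelope(li, lv, n)


def local_mean(signal, cfg: SiftConfig | None = None) -> np.ndarray:
    """Mean of the upper and lower spline envelopes of ``signal``.

    Requires at least one interior maximum and one interior minimum;
    raises ``ValueError`` otherwise (callers treat that as "residue
    reached").
    """
    cfg = cfg or SiftConfig()
    x = _as_signal(signal)
    env = _envelopes(x, cfg.boundary_mode)
    if env is None:
        raise ValueError("too few extrema for an envelope mean")
    return 0.5 * (env[0] + env[1])


def _n_interior_extrema(x: np.ndarray) -> int:
    max_idx, _, min_idx, _ = find_extrema(x)
    return max_idx.size + min_idx.size


def sift_imf(signal, cfg: SiftConfig | None = None) -> tuple[np.ndarray, bool]:
    """Extract one candidate IMF by iterated envelope-mean subtraction.

    Returns ``(imf, converged)``; degenerate inputs (too few extrema)
    are returned unchanged with ``converged=False``.
    """
    cfg = cfg or SiftConfig()
    h = _as_signal(signal).copy()
    if _n_interior_extrema(h) < 2:
        return h, False
    for _ in range(cfg.max_siftings):
        env = _envelopes(h, cfg.boundary_mode)
        if env is None:
            return h, False
        m = 0.5 * (env[0] + env[1])
        if cfg.criterion == "rilling":
            a = 0.5 * np.abs(env[0] - env[1])
            with np.errstate(divide="ignore", invalid="ignore"):
                sigma = np.abs(m) / a
            sigma[~np.isfinite(sigma)] = 0.0
            if (np.mean(sigma > cfg.rilling_sd) < cfg.rilling_tol
                    and np.all(sigma < cfg.rilling_sd2)):
                return h, True
            h = h - m
        else:  # cauchy
            h_new = h - m
            denom = float(np.sum(h * h))
            if denom == 0.0:
                return h_new, False
            sd = float(np.sum((h - h_new) ** 2)) / denom
            h = h_new
            if sd < cfg.stop_threshold:
                return h, True
    return h, True


def emd(signal, cfg: SiftConfig | None = None) -> Decomposition:
    """Full empirical mode decomposition.

    Iterates :func:`sift_imf` on successive residues until the residue
    has fewer than two interior extrema (near-monotone trend), falls to
    numerical round-off, or ``cfg.max_imfs`` modes have been extracted.
    Completeness — ``sum(imfs) + residue == signal`` — holds to
    round-off by construction.
    """
    cfg = cfg or SiftConfig()
    x = _as_signal(signal)
    residue = x.copy()
    imfs: list[np.ndarray] = []
    # relative floor: a residue this far below the input scale is round-off
    # chatter whose spurious "extrema" would keep the loop alive forever
    floor = 1e-12 * float(np.max(np.abs(x))) if np.any(x) else 0.0
    while _n_interior_extrema(residue) >= 2:
        if cfg.max_imfs is not None and len(imfs) >= cfg.max_imfs:
            break
        if float(np.max(np.abs(residue))) <= floor:
            break
        imf, converged = sift_imf(residue, cfg)
        if float(np.max(np.abs(imf))) <= floor:
            break  # no progress: numerically empty mode
        if not converged and _n_interior_extrema(imf) < 2:
            break
        imfs.append(imf)
        residue = residue - imf
    k = len(imfs)
    arr = np.asarray(imfs) if k else np.empty((0, x.size))
    return Decomposition(imfs=arr, residue=residue, method="EMD")


def emd_mode(signal, j: int, cfg: SiftConfig | None = None) -> np.ndarray:
    """E_j(x): the j-th EMD mode of ``x``; zeros when fewer than j modes exist."""
    if j < 1:
        raise ValueError("mode index j must be >= 1")
    cfg = cfg or SiftConfig()
    x = _as_signal(signal)
    dec = emd(x, replace(cfg, max_imfs=j))
    if dec.n_modes < j:
        return np.zeros(x.size)
    return dec.imfs[j - 1]
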