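"""Spectral preprocessing: TIC normalization, Savitzky-Golay smoothing and
adaptive iterative baseline correction.

The baseline corrector is an iteratively reweighted asymmetric penalized
least-squares smoother (airPLS-style): a Whittaker smoother with a
second-difference roughness penalty whose point weights are adaptively
driven to zero where the signal rises above the current baseline estimate,
so that peaks stop attracting the fit while troughs keep anchoring it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .spectra import Spectrum

__all__ = [
    "BaselineFit",
    "PreprocessConfig",
    "tic_normalize",
    "smooth_savitzky_golay",
    "correct_baseline",
    "preprocess",
]


@dataclass
class BaselineFit:
    baseline: np.ndarray
    iterations_used: int
    converged: bool


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain, in application order."""

    target_tic: float = 1e6
    sg_window: int = 11
    sg_polyorder: int = 3
    baseline_lambda: float = 1e7
    baseline_max_iter: int = 15
    baseline_tol: float = 1e-3
    renormalize: bool = True  # restore TIC after baseline subtraction


def tic_normalize(s: Spectrum, target_tic: float) -> Spectrum:
    """Scale the spectrum so its total ion current equals ``target_tic``."""
    if target_tic <= 0:
        raise ValueError("target_tic must be positive")
    tic = s.tic
    if tic <= 0:
        raise ValueError(f"cannot TIC-normalize all-zero spectrum {s.sample_id!r}")
    return s.with_intensity(s.intensity * (target_tic / tic), stage="normalized")


def smooth_savitzky_golay(s: Spectrum, window: int = 11, polyorder: int = 3) -> Spectrum:
    """Local least-squares polynomial smoothing (Savitzky-Golay)."""
    if window % 2 == 0:
        raise ValueError(f"window must be odd, got {window}")
    if window <= polyorder:
        raise ValueError(f"window ({window}) must exceed polyorder ({polyorder})")
    if window > len(s):
        raise ValueError("window wider than spectrum")
    smoothed = savgol_filter(s.intensity, window, polyorder)
    return s.with_intensity(np.clip(smoothed, 0.0, None), stage="smoothed")


def _penalty_diagonals(n: int) -> np.ndarray:
    """Banded (lower) form of D2'D2, the second-difference penalty matrix."""
    d0 = np.full(n, 6.0)
    d0[[0, -1]] = 1.0
    if n > 1:
        d0[[1, -2]] = 5.0
    d1 = np.full(n, -4.0)
    d1[[0, -2]] = -2.0
    d2 = np.full(n, 1.0)
    ab = np.zeros((3, n))
    ab[0] = d0
    ab[1] = d1  # trailing entries unused by solveh_banded
    ab[2] = d2
    return ab


def _whittaker(y: np.ndarray, w: np.ndarray, lam: float, pen: np.ndarray) -> np.ndarray:
    ab = lam * pen.copy()
    ab[0] += w
    return solveh_banded(ab, w * y, lower=True)


def correct_baseline(
    s: Spectrum,
    lam: float = 1e7,
    max_iter: int = 15,
    tol: float = 1e-3,
) -> tuple[Spectrum, BaselineFit]:
    """Estimate and subtract a smooth adaptive baseline.

    At iteration t the baseline ``z`` solves the weighted Whittaker problem
    ``min Σ w_i (y_i - z_i)² + lam Σ (Δ²z)²``; points above the baseline get
    weight 0 while points below get exponentially growing weight
    ``exp(t·|d_i| / |d|₁)`` with ``d = y - z`` restricted to negative
    residuals, so the fit sinks into the noise floor under the peaks.
    Convergence is declared when the negative-residual mass falls below
    ``tol`` times the total intensity.  Negative corrected intensities are
    clipped to zero (areas must stay non-negative).
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    s.require_finite()
    y = s.intensity
    n = len(y)
    if n < 5:
        raise ValueError("spectrum too short for baseline estimation")
    pen = _penalty_diagonals(n)
    w = np.ones(n)
    abs_y = float(np.abs(y).sum())
    z = np.zeros(n)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        z = _whittaker(y, w, lam, pen)
        d = y - z
        neg = d < 0
        dssn = float(np.abs(d[neg]).sum())
        if dssn < tol * abs_y:
            converged = True
            break
        w = np.zeros(n)
        w[neg] = np.exp(it * np.abs(d[neg]) / dssn)
        # anchor the ends so the fit cannot peel away at the boundaries
        w[0] = w[-1] = np.exp(it)
    corrected = np.clip(y - z, 0.0, None)
    return (
        s.with_intensity(corrected, stage="baseline_corrected"),
        BaselineFit(baseline=z, iterations_used=it, converged=converged),
    )


def preprocess(s: Spectrum, cfg: PreprocessConfig | None = None) -> Spectrum:
    """Full chain: TIC-normalize, smooth, baseline-correct (then optionally
    re-normalize so relative areas stay comparable across samples)."""
    cfg = cfg or PreprocessConfig()
    s.require_finite()
    out = tic_normalize(s, cfg.target_tic)
    out = smooth_savitzky_golay(out, cfg.sg_window, cfg.sg_polyorder)
    out, _ = correct_baseline(
        out, lam=cfg.baseline_lambda, max_iter=cfg.baseline_max_iter, tol=cfg.baseline_tol
    )
    if cfg.renormalize and out.tic > 0:
        out = out.with_intensity(
            out.intensity * (cfg.target_tic / out.tic), stage="baseline_corrected"
        )
    return out
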