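"""Voxelwise reference fits for multi-echo data.

Two fitters are provided: complex nonlinear least squares of the full
water-fat-R2*-B0 model (or its 3-parameter fat-free variant, as used with
Cartesian reference data), and magnitude-exponential fitting
y_m = rho * exp(-TE_m * R2*) as used for multi-echo EPI R2* maps.

The complex fit multi-starts over the off-resonance fB0 because phase
wrapping across echoes creates periodic local minima; the starts span the
aliasing-free band +-1/(2*delta_TE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .signal_model import FatSpectrum, fat_modulation
from .trajectory import EchoTrain

__all__ = ["VoxelFitResult", "fit_voxel_complex", "fit_magnitude_exp", "fit_image_complex"]


@dataclass
class VoxelFitResult:
    water: complex = 0.0
    fat: complex = 0.0
    r2star: float = 0.0
    fb0: float = 0.0
    amplitude: float = 0.0  # rho of the magnitude-exponential model
    residual: float = 0.0
    converged: bool = True


def _model(params, te_s, z, with_fat):
    if with_fat:
        wr, wi, fr, fi, r2s, fb0 = params
        rho = (wr + 1j * wi) + (fr + 1j * fi) * z
    else:
        wr, wi, r2s, fb0 = params
        rho = wr + 1j * wi
    return rho * np.exp((2j * np.pi * fb0 - r2s) * te_s)


def _residual(params, te_s, z, signal, with_fat):
    diff = _model(params, te_s, z, with_fat) - signal
    return np.concatenate([diff.real, diff.imag])


def fit_voxel_complex(
    signal: np.ndarray,
    echoes: EchoTrain,
    spectrum: FatSpectrum | None = None,
    with_fat: bool = True,
    n_starts: int = 5,
) -> VoxelFitResult:
    """Nonlinear least-squares fit of the complex multi-echo signal.

    Minimizes sum_m |model(TE_m) - signal_m|^2 over (W, F, R2*, fB0) with
    R2* >= 0, multi-starting over fB0 in the aliasing-free band.
    """
    signal = np.asarray(signal, dtype=complex)
    n_par = 6 if with_fat else 4
    if signal.size < n_par // 2:
        raise ValueError("need at least as many echoes as complex parameters")
    if not np.all(np.isfinite(signal)):
        raise ValueError("signal must be finite")
    if spectrum is None:
        spectrum = FatSpectrum()
    te_s = echoes.times_s[: signal.size]
    z = fat_modulation(spectrum, echoes.times_ms[: signal.size])

    half_band = 1.0 / (2.0 * echoes.delta_te * 1e-3)
    starts = np.linspace(-half_band, half_band, n_starts + 2)[1:-1] if n_starts > 1 else [0.0]

    w0 = signal[0]
    lb = [-np.inf] * (n_par - 2) + [0.0, -np.inf]
    ub = [np.inf] * n_par
    best = None
    for fb0_0 in starts:
        if with_fat:
            x0 = [w0.real * 0.7, w0.imag * 0.7, w0.real * 0.3, w0.imag * 0.3, 20.0, fb0_0]
        else:
            x0 = [w0.real, w0.imag, 20.0, fb0_0]
        try:
            sol = least_squares(
                _residual, x0, bounds=(lb, ub), args=(te_s, z, signal, with_fat),
                method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        return VoxelFitResult(converged=False)
    p = best.x
    res = float(np.sqrt(2.0 * best.cost))
    if with_fat:
        return VoxelFitResult(
            water=p[0] + 1j * p[1], fat=p[2] + 1j * p[3], r2star=p[4], fb0=p[5],
            residual=res, converged=bool(best.success),
        )
    return VoxelFitResult(
        water=p[0] + 1j * p[1], fat=0.0, r2star=p[2], fb0=p[3],
        residual=res, converged=bool(best.success),
    )


def fit_magnitude_exp(magnitudes: np.ndarray, echoes: EchoTrain) -> VoxelFitResult:
    """Least-squares fit of rho * exp(-TE * R2*) to echo magnitudes.

    A log-linear solve initializes a bounded nonlinear refinement; if any
    magnitude is non-positive the log-linear step is skipped.
    """
    y = np.asarray(magnitudes, dtype=float)
    if y.size < 2:
        raise ValueError("need at least two echoes")
    te_s = echoes.times_s[: y.size]

    if np.all(y > 0):
        # weighted log-linear LS (weights y^2 approximate magnitude LS)
        wgt = y**2
        A = np.stack([np.ones_like(te_s), -te_s], axis=-1)
        W = wgt[:, None]
        coef, *_ = np.linalg.lstsq(A * np.sqrt(W), np.log(y) * np.sqrt(wgt), rcond=None)
        rho0, r2s0 = np.exp(coef[0]), max(coef[1], 0.0)
    else:
        rho0, r2s0 = max(y.max(), 1e-12), 0.0

    def resid(p):
        return p[0] * np.exp(-te_s * p[1]) - y

    sol = least_squares(
        resid, [rho0, r2s0], bounds=([0.0, 0.0], [np.inf, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=200,
    )
    return VoxelFitResult(
        amplitude=float(sol.x[0]), r2star=float(sol.x[1]),
        residual=float(np.sqrt(2.0 * sol.cost)), converged=bool(sol.success),
    )


def fit_image_complex(
    images: np.ndarray,
    echoes: EchoTrain,
    spectrum: FatSpectrum | None = None,
    with_fat: bool = True,
    mask: np.ndarray | None = None,
    n_starts: int = 5,
):
    """Apply :func:`fit_voxel_complex` over an echo stack (M, n1, n2).

    Returns a dict of parameter maps; voxels outside ``mask`` stay zero.
    """
    M, n1, n2 = images.shape
    if mask is None:
        mask = np.ones((n1, n2), dtype=bool)
    out = {
        "water": np.zeros((n1, n2), complex),
        "fat": np.zeros((n1, n2), complex),
        "r2star": np.zeros((n1, n2)),
        "fb0": np.zeros((n1, n2)),
        "converged": np.zeros((n1, n2), bool),
    }
    for i, j in zip(*np.nonzero(mask)):
        r = fit_voxel_complex(images[:, i, j], echoes, spectrum, with_fat, n_starts)
        out["water"][i, j] = r.water
        out["fat"][i, j] = r.fat
        out["r2star"][i, j] = r.r2star
        out["fb0"][i, j] = r.fb0
        out["converged"][i, j] = r.converged
    return out
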