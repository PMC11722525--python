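"""Calibrationless model-based reconstruction (IRGNM-FISTA).

The unknowns x = (x_p, x_c) — parameter maps x_p = (W, F, R2*, fB0) and
coil sensitivities x_c = (c_1..c_K) — are estimated directly from
multi-echo radial k-space y by minimizing

    1/2 sum_m || P F { C . M_TEm(x_p) } - Y_TEm ||_2^2  +  alpha R(x),
    subject to R2* in [0, r2s_max],

with a joint l1-wavelet penalty on (W, F, R2*)^T and quadratic Sobolev
smoothness penalties on fB0 (weights (1 + s|k|^2)^(l/2) in physical
cycles/mm) and on every coil map (much stronger weights in normalized
spatial frequency, as in joint nonlinear-inversion parallel imaging —
otherwise object detail migrates into the sensitivities).  The outer loop
is an iteratively regularized Gauss-Newton method with
alpha_n = max(alpha_min, alpha0 / reduction_factor^n); each linearized
subproblem is solved by FISTA with all data-consistency products applied
as FFT convolutions with precomputed point-spread functions (Toeplitz
embedding).

Numerical design
----------------
* Sobolev penalties act through variable preconditioning: fB0 and coils
  are parameterized as x = IFFT( w^-1 . FFT(x_hat) ), turning the Sobolev
  norm into a plain l2 norm on x_hat.
* The joint coil-object estimation is gauge-degenerate in scale
  ((c, x_p) -> (g c, x_p / g)), so the unknown blocks (maps / fB0 / coils)
  can sit at arbitrarily different curvatures.  Every Gauss-Newton step
  therefore estimates per-block curvatures L_b of A^H A by restricted
  power iteration and runs FISTA in a block-diagonal metric with
  regularization weights alpha * L_b — both choices are invariant to the
  gauge scale.
* A backtracking line search damps each outer step until the nonlinear
  misfit does not increase (the linearized step can overshoot the validity
  of the linearization, most prominently through off-resonance phase
  wraps at late echoes).
* fB0 and R2* are seeded from a quick-look estimate (CG-deconvolved
  single-echo images followed by a per-pixel variable-projection search;
  see ``_Workspace.quicklook_seed``).  W starts at 1 and coils at zero,
  making the first outer step a linear coil calibration; starting every
  unknown at zero would annihilate the bilinear linearization and
  Gauss-Newton could not move.
* All penalties act on the deviation from the initial guess (the
  classical Gauss-Newton reference point); penalizing the maps themselves
  would let the strong early-alpha thresholds erase seeded structure that
  has no data curvature yet.  The quadratic reference pull on R2* fades
  out at the alpha floor, so converged maps are governed by data and the
  stated regularizer alone.
* Solver internals run in single precision by default; the final maps are
  returned in double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
import scipy.fft as spfft

from .containers import CoilSensitivities, MultiEchoKspace
from .nufft import GriddedOperatorPlan, NufftPlan, ramp_dcf
from .signal_model import FatSpectrum, ParameterMaps, echo_image, fat_modulation
from .trajectory import EchoTrain, RadialTrajectory

__all__ = [
    "ReconConfig",
    "ReconState",
    "ReconDivergenceError",
    "sobolev_weight",
    "alpha_schedule",
    "forward_operator",
    "joint_l1_prox",
    "project_constraints",
    "irgnm_fista",
    "synthesize_weighted_image",
]


@dataclass
class ReconConfig:
    """Solver settings; defaults follow the validated pipeline."""

    alpha0: float = 1.0
    alpha_min: float = 0.002
    reduction_factor: float = 3.0
    n_gn: int = 15
    n_fista: int = 50
    sobolev_s: float = 22.0  # mm^2, B0 field-map smoothness
    sobolev_l: float = 4.0
    coil_sobolev_a: float = 220.0  # normalized k in [-0.5, 0.5) per axis
    coil_sobolev_l: float = 16.0
    wavelet: str = "db4"
    wavelet_levels: int = 4
    r2s_max: float = 500.0  # 1/s
    scale_r2s: float = 25.0  # 1/s per solver unit
    scale_fb0: float = 1.0  # Hz per solver unit
    with_fat: bool = True
    data_norm: float = 100.0
    power_iters: int = 8
    fb0_init: str = "quicklook"  # or "zero"
    l1_scale: float = 0.25  # joint-l1 weight relative to alpha * L_maps
    single_precision: bool = True
    echo_chunk: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.alpha0 >= self.alpha_min > 0):
            raise ValueError("need alpha0 >= alpha_min > 0")
        if self.reduction_factor <= 1:
            raise ValueError("reduction_factor must be > 1")
        if self.sobolev_s <= 0:
            raise ValueError("sobolev_s must be > 0")
        if self.fb0_init not in ("quicklook", "zero"):
            raise ValueError("fb0_init must be 'quicklook' or 'zero'")


@dataclass
class ReconState:
    maps: ParameterMaps
    coils: CoilSensitivities
    alpha: float
    gn_iteration: int
    misfit_history: list = field(default_factory=list)


class ReconDivergenceError(RuntimeError):
    def __init__(self, message, history):
        super().__init__(f"{message}; misfit history: {history}")
        self.history = history


def sobolev_weight(k_coords: np.ndarray, s: float, l: float) -> np.ndarray:
    """Sobolev weights w(k) = (1 + s*|k|^2)^(l/2); penalty is ||w.F{x}||^2.

    ``k_coords``: array of shape (..., 2) of k-space coordinates (units
    must be consistent with ``s``: cycles/mm for s in mm^2).
    """
    if s <= 0 or l <= 0:
        raise ValueError("s and l must be positive")
    k = np.asarray(k_coords, dtype=float)
    k2 = np.sum(k**2, axis=-1)
    return (1.0 + s * k2) ** (l / 2.0)


def alpha_schedule(n: int, cfg: ReconConfig) -> float:
    """Regularization weight of outer iteration n (0-based)."""
    if n < 0:
        raise ValueError("iteration index must be >= 0")
    return max(cfg.alpha_min, cfg.alpha0 / cfg.reduction_factor**n)


def project_constraints(state: ReconState, cfg: ReconConfig) -> ReconState:
    """Clamp R2* to the convex set [0, r2s_max]; other unknowns unchanged."""
    state.maps.r2star = np.clip(state.maps.r2star, 0.0, cfg.r2s_max)
    return state


# ---------------------------------------------------------------------------
# joint l1-wavelet proximal map
# ---------------------------------------------------------------------------

def joint_l1_prox(maps_triplet, threshold: float, wavelet: str = "db4", levels: int = 4):
    """Group soft-thresholding of wavelet coefficients across maps.

    Each map is transformed with an orthogonal separable wavelet
    (periodized, hence orthonormal); at every detail-coefficient position
    the cross-map l2 magnitude is shrunk by ``threshold`` (the
    approximation band is left untouched); the maps are inverse-
    transformed.  With threshold 0 this is the identity up to round-off.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    decs = [
        pywt.wavedec2(np.asarray(m), wavelet, mode="periodization", level=levels)
        for m in maps_triplet
    ]
    out = [[decs[i][0]] for i in range(len(decs))]  # approximation untouched
    for lev in range(1, len(decs[0])):
        bands = []
        for b in range(3):
            stack = np.stack([d[lev][b] for d in decs], axis=0)
            mag = np.sqrt(np.sum(np.abs(stack) ** 2, axis=0))
            shrink = np.maximum(0.0, 1.0 - threshold / np.maximum(mag, 1e-300))
            bands.append(stack * shrink)
        for i in range(len(decs)):
            out[i].append(tuple(b[i] for b in bands))
    return [pywt.waverec2(c, wavelet, mode="periodization") for c in out]


# ---------------------------------------------------------------------------
# forward operator
# ---------------------------------------------------------------------------

def forward_operator(
    state: ReconState,
    traj: RadialTrajectory,
    echoes: EchoTrain,
    spectrum: FatSpectrum | None = None,
    frame: int = 0,
) -> np.ndarray:
    """Model data (K, M, S, T): per echo m and coil k, the NUFFT of
    c_k . M_TEm(x_p) at that echo's spoke coordinates."""
    if spectrum is None:
        spectrum = FatSpectrum()
    maps, coils = state.maps, state.coils
    if maps.shape != coils.grid_shape:
        raise ValueError("parameter-map and coil grids differ")
    n = maps.shape[0]
    K = coils.n_coils
    M, S, T = traj.n_echoes, traj.n_shots, traj.samples_per_spoke
    data = np.empty((K, M, S, T), dtype=complex)
    for m in range(M):
        img = echo_image(maps, echoes.times_ms[m], spectrum)
        plan = NufftPlan((n, n), traj.echo_coords(m, frame))
        data[:, m] = plan.forward(coils.maps * img[None]).reshape(K, S, T)
    return data


def synthesize_weighted_image(
    state: ReconState, te_ms: float, spectrum: FatSpectrum | None = None
) -> np.ndarray:
    """Magnitude of the model image |M(TE)| at an arbitrary echo time."""
    if te_ms < 0:
        raise ValueError("echo time must be >= 0")
    if spectrum is None:
        spectrum = FatSpectrum()
    return np.abs(echo_image(state.maps, te_ms, spectrum))


# ---------------------------------------------------------------------------
# IRGNM-FISTA solver
# ---------------------------------------------------------------------------

class _Workspace:
    """Per-reconstruction precomputation: plans, filters, channel layout."""

    def __init__(self, y: MultiEchoKspace, cfg: ReconConfig, spectrum: FatSpectrum):
        self.cfg = cfg
        self.spectrum = spectrum
        self.traj = y.traj
        self.echoes = y.echoes
        self.fov = y.fov_mm
        self.n = self.traj.samples_per_spoke
        self.K = y.n_coils
        self.M = y.n_echoes
        self.cdt = np.complex64 if cfg.single_precision else np.complex128
        n, M = self.n, self.M

        self.te_s = self.echoes.times_s
        self.z = fat_modulation(spectrum, self.echoes.times_ms)

        self.plans = [NufftPlan((n, n), self.traj.echo_coords(m)) for m in range(M)]
        offsets = np.arange(n) - n // 2
        self.toeplitz = np.stack(
            [
                GriddedOperatorPlan.from_radial(
                    (n, n), self.traj.angles[0, :, m], offsets
                ).fourier_weights
                for m in range(M)
            ],
            axis=0,
        ).astype(self.cdt)  # (M, 2n, 2n)

        fx = spfft.fftfreq(n) * n / self.fov  # cycles/mm, unshifted layout
        kk = np.stack(np.meshgrid(fx, fx, indexing="ij"), axis=-1)
        self.inv_w_b0 = (
            1.0 / sobolev_weight(kk, cfg.sobolev_s, cfg.sobolev_l)
        ).astype(np.float32 if cfg.single_precision else np.float64)
        fn = spfft.fftfreq(n)  # cycles/pixel
        kn = np.stack(np.meshgrid(fn, fn, indexing="ij"), axis=-1)
        self.inv_w_coil = (
            1.0 / sobolev_weight(kn, cfg.coil_sobolev_a, cfg.coil_sobolev_l)
        ).astype(np.float32 if cfg.single_precision else np.float64)

        self.nch = 4 + self.K
        # solver channel blocks: l1 maps / B0 / coils
        self.blocks = (slice(0, 3), slice(3, 4), slice(4, None))

        # persistent 2x-padded buffer for the Toeplitz convolutions, kept in
        # the FFT (corner) layout so no fftshift copies are needed; only the
        # four corner blocks are ever written, the middle stays zero
        self._pad_buf = np.zeros((cfg.echo_chunk, self.K, 2 * n, 2 * n), self.cdt)

    def _toeplitz_chunk(self, u: np.ndarray, kernels: np.ndarray) -> np.ndarray:
        """Apply the per-echo Toeplitz normal operators to a chunk.

        ``u``: (mc, K, n, n) centred images; ``kernels``: (mc, 2n, 2n)
        Fourier weights.  Returns (mc, K, n, n).  The centre-to-corner
        index mapping implements ifftshift/fftshift without copies.
        """
        n = self.n
        h = n // 2
        mc = u.shape[0]
        buf = self._pad_buf[:mc]
        buf[:, :, :h, :h] = u[:, :, h:, h:]
        buf[:, :, :h, 2 * n - h :] = u[:, :, h:, :h]
        buf[:, :, 2 * n - h :, :h] = u[:, :, :h, h:]
        buf[:, :, 2 * n - h :, 2 * n - h :] = u[:, :, :h, :h]
        spec = spfft.fft2(buf, axes=(-2, -1))
        spec *= kernels[:, None, :, :]
        y = spfft.ifft2(spec, axes=(-2, -1))
        out = np.empty_like(u)
        out[:, :, :h, :h] = y[:, :, 2 * n - h :, 2 * n - h :]
        out[:, :, :h, h:] = y[:, :, 2 * n - h :, :h]
        out[:, :, h:, :h] = y[:, :, :h, 2 * n - h :]
        out[:, :, h:, h:] = y[:, :, :h, :h]
        return out

    def _filter(self, xhat: np.ndarray, inv_w: np.ndarray) -> np.ndarray:
        spec = spfft.fft2(xhat, axes=(-2, -1), norm="ortho")
        return spfft.ifft2(spec * inv_w, axes=(-2, -1), norm="ortho")

    # preconditioners: x = IFFT( w^-1 . FFT(x_hat) ), orthonormal FFTs
    def smooth_b0(self, xhat: np.ndarray) -> np.ndarray:
        return self._filter(xhat, self.inv_w_b0)

    def smooth_coil(self, xhat: np.ndarray) -> np.ndarray:
        return self._filter(xhat, self.inv_w_coil)

    def decode(self, x: np.ndarray):
        """Solver channels -> physical (W, F, R2*, fB0, coil maps)."""
        cfg = self.cfg
        W, F = x[0], x[1]
        r2s = cfg.scale_r2s * x[2].real
        fb0 = cfg.scale_fb0 * self.smooth_b0(x[3].real).real
        coils = self.smooth_coil(x[4:])
        return W, F, r2s, fb0, coils

    def linearize(self, x: np.ndarray):
        """Evaluate model images and Jacobian factors at x."""
        W, F, r2s, fb0, coils = self.decode(x)
        te = self.te_s[:, None, None]
        E = np.exp((2j * np.pi * fb0 - np.clip(r2s, 0.0, None)) * te).astype(self.cdt)
        rho = (W[None] + F[None] * self.z[:, None, None]).astype(self.cdt)
        Mimg = rho * E
        return {
            "E": E,
            "Mimg": Mimg,
            "coils": coils.astype(self.cdt),
            "dR": (-te * self.cfg.scale_r2s).astype(np.float32) * Mimg,
            "dB": (2j * np.pi * te * self.cfg.scale_fb0).astype(self.cdt) * Mimg,
        }

    def model_data(self, x: np.ndarray) -> np.ndarray:
        """Nonlinear forward F(x) over all echoes and coils."""
        lin = self.linearize(x)
        return self.model_data_lin(lin)

    def model_data_lin(self, lin) -> np.ndarray:
        n, K, M = self.n, self.K, self.M
        S, T = self.traj.n_shots, self.traj.samples_per_spoke
        out = np.empty((K, M, S, T), dtype=complex)
        for m in range(M):
            out[:, m] = self.plans[m].forward(
                lin["coils"] * lin["Mimg"][m]
            ).reshape(K, S, T)
        return out

    # -- linearized forward / adjoint / normal ----------------------------
    def _dmaps(self, lin, x):
        """dM images (M, n, n) of the map channels of perturbation x."""
        dM = x[0][None] * lin["E"]
        if self.cfg.with_fat:
            dM = dM + x[1][None] * (self.z[:, None, None].astype(self.cdt) * lin["E"])
        dM = dM + x[2].real[None] * lin["dR"]
        fb_img = self.smooth_b0(x[3].real).real
        dM = dM + fb_img[None] * lin["dB"]
        return dM

    def _dmaps_adjoint(self, lin, dMbar, out):
        """Accumulate the adjoint of _dmaps into channels of ``out``."""
        out[0] += np.sum(np.conj(lin["E"]) * dMbar, axis=0)
        if self.cfg.with_fat:
            out[1] += np.sum(
                np.conj(self.z[:, None, None].astype(self.cdt) * lin["E"]) * dMbar,
                axis=0,
            )
        out[2] += np.sum(np.conj(lin["dR"]) * dMbar, axis=0).real
        t = np.sum(np.conj(lin["dB"]) * dMbar, axis=0)
        out[3] += self.smooth_b0(t).real
        return out

    def lin_forward(self, lin, x) -> np.ndarray:
        """A x: derivative of the forward operator at the linearization point."""
        K, M = self.K, self.M
        S, T = self.traj.n_shots, self.traj.samples_per_spoke
        dM = self._dmaps(lin, x)
        dc = self.smooth_coil(x[4:])
        data = np.empty((K, M, S, T), dtype=complex)
        for m in range(M):
            imgs = lin["coils"] * dM[m] + dc * lin["Mimg"][m]
            data[:, m] = self.plans[m].forward(imgs).reshape(K, S, T)
        return data

    def lin_adjoint(self, lin, data) -> np.ndarray:
        """A^H y for data-space y (K, M, S, T)."""
        n = self.n
        out = np.zeros((self.nch, n, n), dtype=self.cdt)
        cbar = np.zeros((self.K, n, n), dtype=self.cdt)
        dMbar = np.empty((self.M, n, n), dtype=self.cdt)
        for m in range(self.M):
            g = self.plans[m].adjoint(data[:, m].reshape(self.K, -1)).astype(self.cdt)
            dMbar[m] = np.sum(np.conj(lin["coils"]) * g, axis=0)
            cbar += np.conj(lin["Mimg"][m]) * g
        self._dmaps_adjoint(lin, dMbar, out)
        out[4:] = self.smooth_coil(cbar)
        return out

    def lin_normal(self, lin, x) -> np.ndarray:
        """A^H A x via the Toeplitz/PSF embedding (no data-space round trip)."""
        n, K = self.n, self.K
        dM = self._dmaps(lin, x)  # (M, n, n)
        dc = self.smooth_coil(x[4:])  # (K, n, n)
        out = np.zeros((self.nch, n, n), dtype=self.cdt)
        cbar = np.zeros((K, n, n), dtype=self.cdt)
        dMbar = np.empty((self.M, n, n), dtype=self.cdt)
        chunk = max(1, self.cfg.echo_chunk)
        for m0 in range(0, self.M, chunk):
            m1 = min(self.M, m0 + chunk)
            u = (
                lin["coils"][None, :, :, :] * dM[m0:m1, None, :, :]
                + dc[None, :, :, :] * lin["Mimg"][m0:m1, None, :, :]
            )  # (mc, K, n, n)
            v = self._toeplitz_chunk(u, self.toeplitz[m0:m1])
            dMbar[m0:m1] = np.sum(np.conj(lin["coils"])[None] * v, axis=1)
            cbar += np.sum(np.conj(lin["Mimg"][m0:m1, None]) * v, axis=0)
        self._dmaps_adjoint(lin, dMbar, out)
        out[4:] = self.smooth_coil(cbar)
        return out

    def _echo_image_cg(
        self, ydat: np.ndarray, m: int, n_iter: int = 8, damping: float = 3e-3
    ) -> np.ndarray:
        """Per-coil regularized single-echo images, (A^H A + lam) x = A^H y.

        A few conjugate-gradient iterations on the echo's Toeplitz normal
        operator suppress the streak sidelobes of plain gridding, which
        would otherwise leak neighbouring-region signal into fast-decaying
        voxels and bias the field-map seed.
        """
        H = self.toeplitz[m]
        lam = damping * float(np.abs(H).max())

        def apply(x):
            return self._toeplitz_chunk(x[None], H[None])[0] + lam * x

        rhs = self.plans[m].adjoint(ydat[:, m].reshape(self.K, -1)).astype(self.cdt)
        x = np.zeros_like(rhs)
        r = rhs.copy()
        p = r.copy()
        rs = np.sum(np.abs(r) ** 2)
        for _ in range(n_iter):
            Ap = apply(p)
            denom = np.real(np.vdot(p, Ap))
            if denom <= 0:
                break
            a = rs / denom
            x = x + a * p
            r = r - a * Ap
            rs_new = np.sum(np.abs(r) ** 2)
            if rs_new < 1e-12 * rs:
                break
            p = r + (rs_new / rs) * p
            rs = rs_new
        return x

    def quicklook_seed(
        self,
        ydat: np.ndarray,
        n_fit_echoes: int = 20,
        band_hz: float = 150.0,
        step_hz: float = 0.5,
        r2s_candidates=(5.0, 15.0, 30.0, 60.0, 100.0, 150.0),
    ):
        """Seed maps (fB0, R2*) from gridded echo images and a VARPRO search.

        Early echoes are reconstructed by density-compensated gridding and
        coil-combined against the first-echo phase (sum_k I_m conj(I_1),
        which cancels coil phases).  For every candidate (off-resonance,
        R2*) pair the water/fat amplitudes have a closed-form least-squares
        solution (the basis [e_m, z_m e_m] is pixel-independent), and each
        pixel keeps the candidate with the smallest residual.  Because the
        multi-peak fat spectrum is asymmetric this resolves the
        fat-water/off-resonance ambiguity that a plain two-echo phase
        difference cannot.  Results are masked to the object support and
        smoothed with the B0 Sobolev low-pass.
        """
        Mfit = min(self.M, n_fit_echoes)
        if Mfit < 3:
            zeros = np.zeros((self.n, self.n))
            return zeros, zeros.copy()
        imgs = np.asarray(
            [self._echo_image_cg(ydat, m) for m in range(Mfit)]
        )  # (Mfit, K, n, n)
        ref = imgs[0]
        S = np.sum(imgs * np.conj(ref)[None], axis=1)  # (Mfit, n, n)
        mag = np.abs(S[0])
        mask = mag > 0.05 * mag.max()

        te = self.te_s[:Mfit]
        z = self.z[:Mfit]
        Spix = S.reshape(Mfit, -1)
        npix = Spix.shape[1]
        freqs = np.arange(-band_hz, band_hz + step_hz / 2, step_hz)
        best_fit = np.full(npix, -np.inf)
        best_f = np.zeros(npix)
        best_r = np.zeros(npix)
        best_w = np.zeros(npix, complex)
        best_fat = np.zeros(npix, complex)
        eye = 1e-12 * np.eye(2)
        for r in r2s_candidates:
            decay = np.exp(-r * te)
            for f in freqs:
                e = decay * np.exp(2j * np.pi * f * te)
                A = np.stack([e, z * e], axis=1)  # (Mfit, 2)
                Ginv = np.linalg.inv(A.conj().T @ A + eye)
                b = A.conj().T @ Spix  # (2, npix)
                wf = Ginv @ b
                fit = np.real(np.sum(np.conj(b) * wf, axis=0))
                better = fit > best_fit
                best_fit[better] = fit[better]
                best_f[better] = f
                best_r[better] = r
                best_w[better] = wf[0, better]
                best_fat[better] = wf[1, better]
        mflat = mask.ravel()
        fb0_raw = (best_f * mflat).reshape(self.n, self.n)
        r2s_raw = (best_r * mflat).reshape(self.n, self.n)
        W_seed = (best_w * mflat).reshape(self.n, self.n)
        F_seed = (best_fat * mflat).reshape(self.n, self.n)
        # the field-map seed is left unsmoothed (the solver's own Sobolev
        # prior supplies the smoothing; pre-filtering attenuates tube-scale
        # features and the attenuated values would be held by the prior);
        # the coarse rate seed gets a mild low-pass
        inv_w_half = np.sqrt(self.inv_w_b0)
        fb0 = fb0_raw
        r2s = np.clip(self._filter(r2s_raw, inv_w_half).real, 0.0, None)
        return fb0, r2s, W_seed, F_seed


def irgnm_fista(
    y: MultiEchoKspace,
    traj: RadialTrajectory | None = None,
    echoes: EchoTrain | None = None,
    spectrum: FatSpectrum | None = None,
    cfg: ReconConfig | None = None,
    callback=None,
) -> ReconState:
    """Run the IRGNM-FISTA joint reconstruction.

    Returns the final :class:`ReconState`; ``state.misfit_history`` holds
    the data misfit ||F(x) - y|| after every outer iteration.  Raises
    :class:`ReconDivergenceError` if the misfit grows for two consecutive
    outer steps despite the line search.
    """
    cfg = cfg or ReconConfig()
    spectrum = spectrum or FatSpectrum()
    if traj is not None and traj is not y.traj:
        y = MultiEchoKspace(
            data=y.data, traj=traj, echoes=echoes or y.echoes, fov_mm=y.fov_mm,
            noise_sd=y.noise_sd, seed=y.seed, provenance=y.provenance,
        )
    ws = _Workspace(y, cfg, spectrum)
    n, K, nch = ws.n, ws.K, ws.nch

    ynorm = np.linalg.norm(y.data)
    if ynorm == 0:
        # zero data: the regularized solution is identically zero
        state = ReconState(
            maps=ParameterMaps.zeros((n, n)),
            coils=CoilSensitivities(np.zeros((K, n, n), complex)),
            alpha=alpha_schedule(cfg.n_gn - 1, cfg),
            gn_iteration=cfg.n_gn,
            misfit_history=[0.0] * cfg.n_gn,
        )
        return project_constraints(state, cfg)
    scale = cfg.data_norm / ynorm
    ydat = y.data * scale

    rng = np.random.default_rng(cfg.seed)
    x = np.zeros((nch, n, n), dtype=ws.cdt)
    x[0] = 1.0  # uniform object; coils start at zero
    if cfg.fb0_init == "quicklook" and ynorm > 0:
        # seed only the nonlinear unknowns; warm-starting W/F as well would
        # bias the first coil-calibration step toward seed artefacts
        fb0_seed, r2s_seed, _, _ = ws.quicklook_seed(ydat)
        x[3] = (fb0_seed / cfg.scale_fb0).astype(np.float32)
        x[2] = (r2s_seed / cfg.scale_r2s).astype(np.float32)
    x_ref = x.copy()  # the l2 penalties pull toward the initial guess

    u_r_cap = cfg.r2s_max / cfg.scale_r2s

    def project(xc):
        xc[2] = np.clip(xc[2].real, 0.0, u_r_cap)
        xc[3] = xc[3].real
        return xc

    history = []
    bad_steps = 0
    misfit = float(np.linalg.norm(ydat - ws.model_data(x)))
    pv_blocks = [None, None, None]  # warm-started power-iteration vectors
    pv_mu = None
    for it in range(cfg.n_gn):
        alpha = alpha_schedule(it, cfg)
        history.append(misfit)
        lin = ws.linearize(x)
        resid = ydat - ws.model_data_lin(lin)

        q = ws.lin_adjoint(lin, resid) + ws.lin_normal(lin, x)

        # per-block curvature of A^H A (restricted power iteration,
        # warm-started across Gauss-Newton steps)
        L_blocks = []
        for bi, blk in enumerate(ws.blocks):
            v = pv_blocks[bi]
            if v is None:
                v = np.zeros((nch, n, n), dtype=ws.cdt)
                v[blk] = (
                    rng.standard_normal(v[blk].shape)
                    + 1j * rng.standard_normal(v[blk].shape)
                ).astype(ws.cdt)
                v[2:4] = v[2:4].real
                iters = cfg.power_iters
            else:
                iters = 2  # warm-started from the previous outer step
            nrm = np.linalg.norm(v)
            Lb = 0.0
            if nrm > 0:
                v = v / nrm
                for _ in range(iters):
                    w = ws.lin_normal(lin, v)
                    v = np.zeros_like(v)
                    v[blk] = w[blk]
                    v[2:4] = v[2:4].real
                    Lb = float(np.linalg.norm(v))
                    if Lb < 1e-30:
                        break
                    v /= Lb
                pv_blocks[bi] = v
            L_blocks.append(Lb)
        Lmax = max(max(L_blocks), 1e-30)
        L_blocks = [max(Lb, 1e-9 * Lmax) for Lb in L_blocks]
        L1, L2, L3 = L_blocks

        lam1 = alpha * cfg.l1_scale * L1  # joint l1 weight (maps block)
        lam2 = alpha * L2  # l2 weight on the preconditioned B0 variable
        lam3 = alpha * L3  # l2 weight on the preconditioned coils
        # classical Gauss-Newton damping toward the reference for the R2*
        # channel: during early strongly regularized steps the object
        # amplitude is still wrong and the R2* gradient is unreliable; the
        # alpha-weighted pull keeps the seeded rate maps intact until the
        # data term takes over (fB0 enjoys the same protection via lam2).
        # The pull vanishes at the alpha floor so the converged R2* is
        # governed by data and the l1 penalty alone, not by the coarse seed.
        lam_r = max(alpha - cfg.alpha_min, 0.0) * L1
        base = np.empty(nch)
        base[0:3], base[3], base[4:] = L1, L2, L3
        lam_ch = np.zeros(nch)
        lam_ch[2], lam_ch[3], lam_ch[4:] = lam_r, lam2, lam3
        # tighten the block metric with the norm of the block-preconditioned
        # Hessian (bounded by the number of blocks)
        sinv = (1.0 / np.sqrt(base))[:, None, None].astype(np.float32)
        v = pv_mu
        if v is None:
            v = (
                rng.standard_normal((nch, n, n))
                + 1j * rng.standard_normal((nch, n, n))
            ).astype(ws.cdt)
            v[2:4] = v[2:4].real
            v /= np.linalg.norm(v)
        mu = 3.0
        for _ in range(3):
            w = sinv * ws.lin_normal(lin, sinv * v)
            w[2:4] = w[2:4].real
            mu = float(np.linalg.norm(w))
            if mu < 1e-30:
                break
            v = w / mu
        pv_mu = v
        # mu <= n_blocks in exact arithmetic; no upper cap, since block
        # norms from a finite power iteration can be underestimates and
        # capping would break the majorization
        mu = max(mu, 1e-2)
        d = 1.1 * mu * base + lam_ch
        inv_d = (1.0 / d)[:, None, None].astype(np.float32)

        # FISTA on the linearized subproblem in the block metric
        z = x.copy()
        zy = x.copy()
        t_mom = 1.0
        thr = lam1 / d[0]
        for _ in range(cfg.n_fista):
            grad = ws.lin_normal(lin, zy) - q
            grad[2] += lam_r * (zy[2] - x_ref[2])
            grad[3] += lam2 * (zy[3] - x_ref[3])
            grad[4:] += lam3 * (zy[4:] - x_ref[4:])
            znew = zy - inv_d * grad
            # the l1 penalty, like the quadratic ones, acts on the deviation
            # from the initial guess (the classical Gauss-Newton reference):
            # penalizing the maps themselves would let the strong early-alpha
            # thresholds erase seeded structure that has no data curvature yet
            if cfg.with_fat:
                tri = [znew[0] - x_ref[0], znew[1] - x_ref[1],
                       (znew[2] - x_ref[2]).real]
            else:
                tri = [znew[0] - x_ref[0], (znew[2] - x_ref[2]).real]
            tri = joint_l1_prox(
                tri, thr, wavelet=cfg.wavelet, levels=cfg.wavelet_levels
            )
            znew[0] = (tri[0] + x_ref[0]).astype(ws.cdt)
            if cfg.with_fat:
                znew[1] = (tri[1] + x_ref[1]).astype(ws.cdt)
                znew[2] = np.clip(tri[2].real + x_ref[2].real, 0.0, u_r_cap)
            else:
                znew[1] = 0.0
                znew[2] = np.clip(tri[1].real + x_ref[2].real, 0.0, u_r_cap)
            znew[3] = znew[3].real
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
            zy = znew + ((t_mom - 1.0) / t_new) * (znew - z)
            zy[2] = np.clip(zy[2].real, 0.0, u_r_cap)
            zy[3] = zy[3].real
            z = znew
            t_mom = t_new

        # backtracking line search on the Gauss-Newton step
        step = z - x
        s = 1.0
        accepted, misfit_new = None, np.inf
        for _ in range(6):
            xc = project(x + s * step)
            mc = float(np.linalg.norm(ydat - ws.model_data(xc)))
            if np.isfinite(mc) and mc < misfit_new:
                accepted, misfit_new = xc, mc
            if np.isfinite(mc) and mc <= misfit * 1.0001:
                break
            s *= 0.5
        if accepted is None:  # every trial non-finite: keep the iterate
            accepted, misfit_new = x, misfit
        x = accepted
        if misfit_new > misfit * 1.0001:
            bad_steps += 1
            if bad_steps >= 2:
                history.append(misfit_new)
                raise ReconDivergenceError(
                    "data misfit grew for two consecutive Gauss-Newton steps",
                    history,
                )
        else:
            bad_steps = 0
        misfit = misfit_new
        if callback is not None:
            callback(it, alpha, misfit, x)

    W, F, r2s, fb0, coils = ws.decode(x.astype(complex))
    maps = ParameterMaps(
        water=np.asarray(W, complex) / scale,
        fat=np.asarray(F, complex) / scale,
        r2star=np.clip(np.asarray(r2s, float), 0.0, cfg.r2s_max),
        fb0=np.asarray(fb0, float),
    )
    state = ReconState(
        maps=maps,
        coils=CoilSensitivities(maps=np.asarray(coils, complex)),
        alpha=alpha_schedule(cfg.n_gn - 1, cfg),
        gn_iteration=cfg.n_gn,
        misfit_history=history,
    )
    return project_constraints(state, cfg)
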