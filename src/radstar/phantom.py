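"""Analytic multi-coil multi-echo k-space simulation of ellipse phantoms.

The phantom is a set of (ellipse, tissue) regions; its ideal k-space is the
sum of closed-form ellipse Fourier transforms weighted by the tissue signal
of the echo.  Coil sensitivities are represented as truncated Fourier
series, so multiplying a region by a coil profile becomes an exact shift of
its analytic k-space — the ground-truth data never touches a pixel grid,
which keeps the simulation free of the inverse crime.  A rasterized NUFFT
path is provided as the independent cross-check.

The default phantom reproduces a standard validation object for joint
water/fat/R2*/B0 mapping: ten circular tubes in a water background, with
fat fractions 5..95 % (step 10), off-resonance -50..50 Hz (step 10, the
0 Hz value assigned to the background), a T2* grid of 10..190 ms (step
20 ms), eight circular receive coils, a 128 mm FOV and base resolution 192.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import j1

from .containers import CoilSensitivities, MultiEchoKspace
from .nufft import NufftPlan
from .signal_model import FatSpectrum, ParameterMaps, fat_modulation
from .trajectory import EchoTrain, RadialTrajectory

__all__ = [
    "Ellipse",
    "Tissue",
    "PhantomSpec",
    "CoilModel",
    "FourierCoilSeries",
    "ellipse_ft",
    "make_numerical_phantom",
    "simulate_coils",
    "simulate_kspace",
    "simulate_kspace_rasterized",
    "ground_truth_maps",
    "tube_roi_masks",
]

# grid of tube T2* values (ms); R2* = 1000 / T2*
T2S_GRID_MS = tuple(10.0 + 20.0 * i for i in range(10))
# alternative reading of the tube relaxation grid: R2* 10..200 1/s
R2S_GRID_PER_S = tuple(10.0 + 20.0 * i for i in range(10))
FAT_FRACTION_GRID_PCT = tuple(5.0 + 10.0 * i for i in range(10))
OFF_RESONANCE_GRID_HZ = tuple(h for h in range(-50, 60, 10) if h != 0)


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse: centre (mm) and semi-axes (mm)."""

    center: tuple
    semi_axes: tuple

    def __post_init__(self) -> None:
        if min(self.semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        a, b = self.semi_axes
        return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0

    @property
    def area(self) -> float:
        return np.pi * self.semi_axes[0] * self.semi_axes[1]


@dataclass(frozen=True)
class Tissue:
    """Signal parameters of a region.

    ``amplitude`` is the total proton signal; water and fat amplitudes are
    ``amplitude * (1 - ff)`` and ``amplitude * ff`` with ff the fat
    fraction, so the ground-truth fat fraction |F|/(|W|+|F|) equals the
    requested value.
    """

    amplitude: float = 1.0
    fat_fraction_pct: float = 0.0
    r2star: float = 0.0  # 1/s
    fb0: float = 0.0  # Hz

    def __post_init__(self) -> None:
        if not 0.0 <= self.fat_fraction_pct <= 100.0:
            raise ValueError("fat fraction must lie in [0, 100] %")
        if self.r2star < 0:
            raise ValueError("R2* must be non-negative")

    @property
    def water(self) -> float:
        return self.amplitude * (1.0 - self.fat_fraction_pct / 100.0)

    @property
    def fat(self) -> float:
        return self.amplitude * self.fat_fraction_pct / 100.0

    def echo_signal(self, te_ms: float, spectrum: FatSpectrum) -> complex:
        """Region signal (W + F z(TE)) * exp(i 2pi fB0 TE - TE R2*)."""
        te_s = te_ms * 1e-3
        z = fat_modulation(spectrum, te_ms)
        return (self.water + self.fat * z) * np.exp(
            (2j * np.pi * self.fb0 - self.r2star) * te_s
        )


@dataclass
class PhantomSpec:
    """Piecewise-elliptical phantom; later regions override earlier ones."""

    regions: list  # list[(Ellipse, Tissue)]
    fov_mm: float = 128.0
    base_resolution: int = 192

    def __post_init__(self) -> None:
        if not self.regions:
            raise ValueError("phantom needs at least one region")
        half = self.fov_mm / 2.0
        for ell, _ in self.regions:
            cx, cy = ell.center
            a, b = ell.semi_axes
            if abs(cx) + a > half or abs(cy) + b > half:
                raise ValueError(f"ellipse {ell} exceeds the FOV")

    @property
    def background(self):
        return self.regions[0]

    @property
    def tubes(self):
        return self.regions[1:]


def ellipse_ft(semi_axes, center, k) -> np.ndarray:
    """Continuous 2D Fourier transform of an ellipse indicator.

    ``k`` has shape (..., 2) in cycles/mm; returns
    a*b*J1(2*pi*rho)/rho * exp(-i*2*pi*k.center), rho^2 = (a kx)^2 + (b ky)^2,
    with the continuous limit pi*a*b at k = 0 (the area).
    """
    a, b = semi_axes
    k = np.asarray(k, dtype=float)
    kx, ky = k[..., 0], k[..., 1]
    rho = np.hypot(a * kx, b * ky)
    with np.errstate(invalid="ignore", divide="ignore"):
        radial = np.where(rho > 1e-12, j1(2.0 * np.pi * rho) / np.where(rho > 0, rho, 1.0), np.pi)
    phase = np.exp(-2j * np.pi * (kx * center[0] + ky * center[1]))
    return a * b * radial * phase


def make_numerical_phantom(
    fov_mm: float = 128.0,
    base_resolution: int = 192,
    relaxation_grid: str = "t2s",
    background_r2star: float = 20.0,
) -> PhantomSpec:
    """The ten-tube validation phantom.

    ``relaxation_grid='t2s'`` assigns tube T2* = 10..190 ms step 20 ms
    (R2* = 100..5.26 1/s); ``'r2s'`` assigns R2* = 10..200 1/s step 20
    directly.  The water-only background carries fB0 = 0 Hz and a mid-range
    R2* of 20 1/s.
    """
    if relaxation_grid == "t2s":
        r2s_values = [1000.0 / t2s for t2s in T2S_GRID_MS]
    elif relaxation_grid == "r2s":
        r2s_values = list(R2S_GRID_PER_S)
    else:
        raise ValueError("relaxation_grid must be 't2s' or 'r2s'")

    bg_radius = 0.43 * fov_mm
    ring_radius = 0.30 * fov_mm
    tube_radius = 0.086 * fov_mm
    regions = [
        (
            Ellipse((0.0, 0.0), (bg_radius, bg_radius)),
            Tissue(amplitude=1.0, fat_fraction_pct=0.0, r2star=background_r2star, fb0=0.0),
        )
    ]
    for i in range(10):
        ang = 2.0 * np.pi * i / 10.0
        center = (ring_radius * np.cos(ang), ring_radius * np.sin(ang))
        regions.append(
            (
                Ellipse(center, (tube_radius, tube_radius)),
                Tissue(
                    amplitude=1.0,
                    fat_fraction_pct=FAT_FRACTION_GRID_PCT[i],
                    r2star=r2s_values[i],
                    fb0=float(OFF_RESONANCE_GRID_HZ[i]),
                ),
            )
        )
    return PhantomSpec(regions=regions, fov_mm=fov_mm, base_resolution=base_resolution)


# ---------------------------------------------------------------------------
# Coils
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoilModel:
    """Circular receive array around the object.

    Profiles are Gaussians centred on a ring of radius
    ``placement_radius_frac * FOV`` with width ``width_frac * FOV``, each
    with a random (seeded) global phase and a mild linear phase ramp.
    """

    n_coils: int = 8
    placement_radius_frac: float = 0.45
    width_frac: float = 0.35
    n_harmonics: int = 4  # Fourier orders kept per axis (series is (2n+1)^2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")


@dataclass
class FourierCoilSeries:
    """Coil maps as truncated Fourier series over the FOV-periodic cell.

    c_k(x, y) = sum_{p,q} b_k[p, q] * exp(i*2*pi*(p*x + q*y)/FOV)

    Products of a coil with the phantom become exact integer-harmonic
    k-space shifts, keeping the simulated data analytic.
    """

    coefficients: np.ndarray  # (K, 2P+1, 2P+1) complex
    fov_mm: float

    @property
    def n_coils(self) -> int:
        return self.coefficients.shape[0]

    @property
    def order(self) -> int:
        return (self.coefficients.shape[1] - 1) // 2

    @property
    def harmonics(self) -> np.ndarray:
        """(H, 2) integer harmonic indices matching flattened coefficients."""
        p = np.arange(-self.order, self.order + 1)
        P1, P2 = np.meshgrid(p, p, indexing="ij")
        return np.stack([P1.ravel(), P2.ravel()], axis=-1)

    def evaluate(self, n: int) -> CoilSensitivities:
        """Evaluate the series on an n x n grid of FOV pixel centres."""
        x = (np.arange(n) - n // 2) / n  # position in FOV units
        p = np.arange(-self.order, self.order + 1)
        E = np.exp(2j * np.pi * np.outer(x, p))  # (n, 2P+1)
        maps = np.einsum("xp,kpq,yq->kxy", E, self.coefficients, E)
        return CoilSensitivities(maps=maps)


def simulate_coils(model: CoilModel, grid_n: int, fov_mm: float) -> FourierCoilSeries:
    """Build the seeded coil array as a truncated Fourier series.

    The Gaussian ring profiles are projected onto the series by FFT on a
    fine grid; the truncated series itself is the ground-truth coil.
    ``grid_n`` only sets the projection grid (>= 4 * n_harmonics + 2).
    """
    rng = np.random.default_rng(model.seed)
    n_fine = max(64, int(grid_n))
    x = (np.arange(n_fine) - n_fine // 2) / n_fine  # FOV units, [-0.5, 0.5)
    X, Y = np.meshgrid(x, x, indexing="ij")
    P = model.n_harmonics
    coeffs = np.empty((model.n_coils, 2 * P + 1, 2 * P + 1), dtype=complex)
    for k in range(model.n_coils):
        ang = 2.0 * np.pi * k / model.n_coils + rng.normal(scale=0.03)
        cx = model.placement_radius_frac * np.cos(ang)
        cy = model.placement_radius_frac * np.sin(ang)
        w = model.width_frac * (1.0 + rng.normal(scale=0.05))
        prof = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2.0 * w**2))
        phase = rng.uniform(0, 2 * np.pi)
        ramp = rng.normal(scale=0.3, size=2)
        prof = prof * np.exp(1j * (phase + 2 * np.pi * (ramp[0] * X + ramp[1] * Y)))
        spec = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(prof))) / n_fine**2
        c0 = n_fine // 2
        coeffs[k] = spec[c0 - P : c0 + P + 1, c0 - P : c0 + P + 1]
    return FourierCoilSeries(coefficients=coeffs, fov_mm=fov_mm)


# ---------------------------------------------------------------------------
# k-space simulation
# ---------------------------------------------------------------------------

def _region_weights(phantom: PhantomSpec, te_ms: float, spectrum: FatSpectrum):
    """Per-region k-space weights at one echo, with tubes overriding the
    background by signal differencing."""
    bg_tissue = phantom.background[1]
    bg_sig = bg_tissue.echo_signal(te_ms, spectrum)
    weights = [bg_sig]
    for _, tissue in phantom.tubes:
        weights.append(tissue.echo_signal(te_ms, spectrum) - bg_sig)
    return np.asarray(weights)


def simulate_kspace(
    phantom: PhantomSpec,
    coils: FourierCoilSeries,
    traj: RadialTrajectory,
    echoes: EchoTrain,
    spectrum: FatSpectrum | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dc_norm: float | None = None,
    frame: int = 0,
) -> MultiEchoKspace:
    """Analytic multi-coil k-space of the phantom on the radial trajectory.

    If ``dc_norm`` is given, the ideal data are first scaled so the
    root-sum-of-squares coil DC sample of the first echo equals it, and
    complex Gaussian noise of standard deviation ``noise_sd`` is then added
    per coil and sample.  Deterministic given ``seed``.
    """
    if spectrum is None:
        spectrum = FatSpectrum()
    if abs(coils.fov_mm - phantom.fov_mm) > 1e-9:
        raise ValueError(
            f"coil FOV {coils.fov_mm} mm does not match phantom FOV {phantom.fov_mm} mm"
        )
    K = coils.n_coils
    M, S, T = traj.n_echoes, traj.n_shots, traj.samples_per_spoke
    harmonics = coils.harmonics  # (H, 2) integers, cycles/FOV
    b = coils.coefficients.reshape(K, -1)  # (K, H)
    geoms = [(ell.semi_axes, ell.center) for ell, _ in phantom.regions]
    te_ms = echoes.times_ms

    data = np.empty((K, M, S, T), dtype=complex)
    for m in range(M):
        coords = traj.echo_coords(m, frame)  # (S*T, 2) cycles/FOV
        kmm = (coords[None, :, :] - harmonics[:, None, :]) / phantom.fov_mm
        G = np.stack(
            [ellipse_ft(sa, c, kmm) for sa, c in geoms], axis=0
        )  # (R, H, S*T)
        w = _region_weights(phantom, te_ms[m], spectrum)  # (R,)
        data[:, m] = (np.einsum("kh,rhj,r->kj", b, G, w)).reshape(K, S, T)

    if dc_norm is not None:
        dc = data[:, 0, 0, T // 2]
        rss = np.sqrt(np.sum(np.abs(dc) ** 2))
        if rss == 0:
            raise ValueError("cannot DC-normalize all-zero data")
        data *= dc_norm / rss

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = data + noise_sd * (
            rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        )

    return MultiEchoKspace(
        data=data,
        traj=traj,
        echoes=echoes,
        fov_mm=phantom.fov_mm,
        noise_sd=noise_sd,
        seed=seed,
        provenance="radstar.phantom.simulate_kspace (analytic)",
    )


def ground_truth_maps(phantom: PhantomSpec, n: int | None = None) -> ParameterMaps:
    """Rasterized ground-truth parameter maps (pixel-centre painting)."""
    n = n or phantom.base_resolution
    half_px = phantom.fov_mm / n
    x = (np.arange(n) - n // 2) * half_px
    X, Y = np.meshgrid(x, x, indexing="ij")
    maps = ParameterMaps.zeros((n, n))
    for ell, tissue in phantom.regions:
        mask = ell.contains(X, Y)
        maps.water[mask] = tissue.water
        maps.fat[mask] = tissue.fat
        maps.r2star[mask] = tissue.r2star
        maps.fb0[mask] = tissue.fb0
    return maps


def simulate_kspace_rasterized(
    phantom: PhantomSpec,
    coils: FourierCoilSeries,
    traj: RadialTrajectory,
    echoes: EchoTrain,
    spectrum: FatSpectrum | None = None,
    oversample: int = 2,
    frame: int = 0,
) -> np.ndarray:
    """Independent noiseless simulation path: NUFFT of an oversampled
    rasterization.  Returns data shaped like ``simulate_kspace`` output."""
    from .signal_model import echo_image

    if spectrum is None:
        spectrum = FatSpectrum()
    n = oversample * phantom.base_resolution
    maps = ground_truth_maps(phantom, n)
    cmaps = coils.evaluate(n).maps
    dx2 = (phantom.fov_mm / n) ** 2
    K = coils.n_coils
    M, S, T = traj.n_echoes, traj.n_shots, traj.samples_per_spoke
    data = np.empty((K, M, S, T), dtype=complex)
    for m in range(M):
        img = echo_image(maps, echoes.times_ms[m], spectrum)
        plan = NufftPlan((n, n), traj.echo_coords(m, frame))
        for k in range(K):
            data[k, m] = (plan.forward(cmaps[k] * img) * dx2).reshape(S, T)
    return data


def tube_roi_masks(
    phantom: PhantomSpec, n: int | None = None, radius_fraction: float = 0.5
):
    """Central-disk ROI masks for each tube (partial-volume safe)."""
    n = n or phantom.base_resolution
    dx = phantom.fov_mm / n
    x = (np.arange(n) - n // 2) * dx
    X, Y = np.meshgrid(x, x, indexing="ij")
    masks = []
    for ell, _ in phantom.tubes:
        shrunk = Ellipse(
            ell.center,
            (ell.semi_axes[0] * radius_fraction, ell.semi_axes[1] * radius_fraction),
        )
        masks.append(shrunk.contains(X, Y))
    return masks
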