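"""Blip-gradient multi-echo radial trajectory generation.

A multi-echo radial FLASH shot acquires one spoke per echo; small blip
gradients rotate the spoke between echoes so that the spokes of all shots
and all echoes of one frame tile the full circle uniformly.  Consecutive
frames are rotated by the small golden angle 180/phi^2 (~68.75 deg) for
complementary coverage.

Conventions
-----------
* Angles are measured counterclockwise from the +kx axis, in radians.
* Spokes are full diameters.  ``samples_per_spoke`` is even and the centre
  sample (index ``samples_per_spoke // 2``) sits exactly at k = 0, matching
  the FFT convention of an even grid.
* k-space coordinates are stored in cycles/FOV, so a spoke spans
  [-n/2, n/2) with n = samples_per_spoke.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GOLDEN_RATIO",
    "SMALL_GOLDEN_ANGLE_DEG",
    "EchoTrain",
    "RadialTrajectory",
    "spoke_angle",
    "frame_angle_offset",
    "echo_times",
    "build_trajectory",
]

GOLDEN_RATIO = (1.0 + np.sqrt(5.0)) / 2.0
#: Frame-to-frame rotation increment, 180/phi^2 ~ 68.7539 degrees.
SMALL_GOLDEN_ANGLE_DEG = 180.0 / GOLDEN_RATIO**2


@dataclass(frozen=True)
class EchoTrain:
    """Arithmetic echo-time train TE_m = te_first + (m-1) * delta_te (ms)."""

    te_first: float
    delta_te: float
    n_echoes: int

    def __post_init__(self) -> None:
        if self.te_first <= 0:
            raise ValueError(f"te_first must be > 0, got {self.te_first}")
        if self.delta_te <= 0:
            raise ValueError(f"delta_te must be > 0, got {self.delta_te}")
        if self.n_echoes < 1:
            raise ValueError(f"n_echoes must be >= 1, got {self.n_echoes}")

    @property
    def times_ms(self) -> np.ndarray:
        return self.te_first + self.delta_te * np.arange(self.n_echoes)

    @property
    def times_s(self) -> np.ndarray:
        return self.times_ms * 1e-3


def spoke_angle(l: int, m: int, n_shots: int, n_echoes: int) -> float:
    """Spoke angle (rad) of shot ``l`` (1-based) and echo ``m`` (1-based).

    theta_{l,m} = 2*pi / (NE*NS) * ((l-1)*NE + (m-1)); the spokes of one
    frame enumerate the NS*NE-point uniform grid on the circle, stepping
    fastest along the echo dimension.
    """
    if not (1 <= l <= n_shots):
        raise ValueError(f"shot index {l} outside 1..{n_shots}")
    if not (1 <= m <= n_echoes):
        raise ValueError(f"echo index {m} outside 1..{n_echoes}")
    return 2.0 * np.pi / (n_echoes * n_shots) * ((l - 1) * n_echoes + (m - 1))


def frame_angle_offset(frame: int) -> float:
    """Rotation offset (degrees, in [0, 360)) of a frame, small-golden-angle scheme."""
    if frame < 0:
        raise ValueError(f"frame index must be >= 0, got {frame}")
    return (frame * SMALL_GOLDEN_ANGLE_DEG) % 360.0


def echo_times(train: EchoTrain) -> np.ndarray:
    """Echo times in ms as an arithmetic sequence of length ``n_echoes``."""
    return train.times_ms


@dataclass
class RadialTrajectory:
    """Spoke angles and explicit k-space sample coordinates.

    Attributes
    ----------
    angles : (n_frames, n_shots, n_echoes) array, radians (offset applied)
    frame_offsets : (n_frames,) array, degrees
    coords : (n_frames, n_echoes, n_shots, samples_per_spoke, 2) array,
        cycles/FOV, last axis = (kx, ky).
    """

    n_shots: int
    n_echoes: int
    samples_per_spoke: int
    n_frames: int = 1
    angles: np.ndarray = field(repr=False, default=None)
    frame_offsets: np.ndarray = field(repr=False, default=None)
    coords: np.ndarray = field(repr=False, default=None)

    @property
    def spokes_per_frame(self) -> int:
        return self.n_shots * self.n_echoes

    def frame_coords(self, frame: int = 0) -> np.ndarray:
        """Coordinates of one frame, shape (n_echoes, n_shots, n_samples, 2)."""
        return self.coords[frame]

    def echo_coords(self, echo: int, frame: int = 0) -> np.ndarray:
        """Flat (n_shots * n_samples, 2) coordinates of one echo of one frame."""
        return self.coords[frame, echo].reshape(-1, 2)


def _radial_offsets(n_samples: int) -> np.ndarray:
    # even count: centre sample at index n/2 sits at k = 0
    return np.arange(n_samples) - n_samples // 2


def build_trajectory(
    n_shots: int,
    n_echoes: int,
    samples_per_spoke: int,
    n_frames: int = 1,
) -> RadialTrajectory:
    """Build the full multi-echo radial sampling pattern.

    Every frame holds ``n_shots * n_echoes`` spokes whose angles tile
    [0, 2*pi) uniformly; frame f is rotated by ``frame_angle_offset(f)``.
    """
    if min(n_shots, n_echoes, samples_per_spoke, n_frames) < 1:
        raise ValueError("all trajectory counts must be >= 1")

    base = np.array(
        [
            [spoke_angle(l, m, n_shots, n_echoes) for m in range(1, n_echoes + 1)]
            for l in range(1, n_shots + 1)
        ]
    )  # (n_shots, n_echoes)
    offsets_deg = np.array([frame_angle_offset(f) for f in range(n_frames)])
    angles = base[None, :, :] + np.deg2rad(offsets_deg)[:, None, None]

    t = _radial_offsets(samples_per_spoke).astype(float)  # (n_samples,)
    # coords indexed (frame, echo, shot, sample, axis)
    ang_esl = np.transpose(angles, (0, 2, 1))  # (frame, echo, shot)
    direction = np.stack([np.cos(ang_esl), np.sin(ang_esl)], axis=-1)
    coords = direction[..., None, :] * t[None, None, None, :, None]

    return RadialTrajectory(
        n_shots=n_shots,
        n_echoes=n_echoes,
        samples_per_spoke=samples_per_spoke,
        n_frames=n_frames,
        angles=angles,
        frame_offsets=offsets_deg,
        coords=coords,
    )
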