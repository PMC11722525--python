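"""Shared data containers for k-space data and coil sensitivities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import EchoTrain, RadialTrajectory

__all__ = ["MultiEchoKspace", "CoilSensitivities"]


@dataclass
class CoilSensitivities:
    """Stack of K smooth complex receive-sensitivity maps on the image grid."""

    maps: np.ndarray  # (K, n1, n2) complex

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=complex)
        if self.maps.ndim != 3 or self.maps.shape[0] < 1:
            raise ValueError("coil maps must have shape (K, n1, n2) with K >= 1")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("coil maps must be finite")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self):
        return self.maps.shape[1:]

    def sum_of_squares(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.maps) ** 2, axis=0))


@dataclass
class MultiEchoKspace:
    """Acquired or simulated multi-coil multi-echo radial k-space data.

    ``data`` is indexed [coil, echo, spoke, sample]; the trajectory supplies
    the matching sample coordinates (frame 0 unless stated otherwise).
    """

    data: np.ndarray
    traj: RadialTrajectory
    echoes: EchoTrain
    fov_mm: float
    noise_sd: float = 0.0
    seed: int | None = None
    provenance: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 4:
            raise ValueError("data must be indexed [coil, echo, spoke, sample]")
        k, m, s, t = self.data.shape
        if m != self.traj.n_echoes or s != self.traj.n_shots:
            raise ValueError(
                f"data echo/spoke dims {(m, s)} do not match trajectory "
                f"{(self.traj.n_echoes, self.traj.n_shots)}"
            )
        if t != self.traj.samples_per_spoke:
            raise ValueError("data sample dim does not match trajectory")
        if m != self.echoes.n_echoes:
            raise ValueError("data echo dim does not match echo train")

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[1]
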