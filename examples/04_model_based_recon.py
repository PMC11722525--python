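"""Calibrationless model-based reconstruction of a small phantom.

Simulates one off-centre tube (FF 30 %, R2* 25 1/s, fB0 20 Hz) at reduced
resolution, reconstructs water/fat/R2*/B0 maps jointly with the coil
sensitivities directly from k-space, and compares tube-ROI means with the
ground truth.  Runtime is a few minutes on one CPU.
"""
import numpy as np

from radstar import (
    CoilModel, EchoTrain, Ellipse, PhantomSpec, ReconConfig, Tissue,
    build_trajectory, fat_fraction, ground_truth_maps, irgnm_fista,
    roi_stats, simulate_coils, simulate_kspace, tube_roi_masks,
)

n = 64
phantom = PhantomSpec(
    regions=[
        (Ellipse((0, 0), (55, 55)), Tissue(1.0, 0.0, 20.0, 0.0)),
        (Ellipse((10, -8), (11, 11)), Tissue(1.0, 30.0, 25.0, 20.0)),
    ],
    fov_mm=128.0, base_resolution=n,
)
coils = simulate_coils(CoilModel(seed=2), n, 128.0)
traj = build_trajectory(30, 35, n)
echoes = EchoTrain(2.37, 1.88, 35)
ks = simulate_kspace(phantom, coils, traj, echoes, noise_sd=0.0, dc_norm=100.0)

state = irgnm_fista(ks, cfg=ReconConfig(),
                    callback=lambda it, a, mf, _:
                    print(f"  Gauss-Newton {it:2d}: alpha {a:.4g}, misfit {mf:.3f}"))

mask = tube_roi_masks(phantom, n)[0]
truth = ground_truth_maps(phantom, n)
ff = fat_fraction(state.maps.water, state.maps.fat)
for name, rec, tru in [("FF [%]", ff, fat_fraction(truth.water, truth.fat)),
                       ("R2* [1/s]", state.maps.r2star, truth.r2star),
                       ("B0 [Hz]", state.maps.fb0, truth.fb0)]:
    mr, sr = roi_stats(rec, mask)
    mt, _ = roi_stats(tru, mask)
    print(f"{name:10s} recon {mr:7.3f} +- {sr:.3f} | truth {mt:7.3f} | diff {mr - mt:+.3f}")
# The misfit decreases monotonically across Gauss-Newton steps; the final
# ROI differences are fractions of the ground-truth values.
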