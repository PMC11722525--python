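# File formats

## HDF5 k-space container (`*.h5`)

Written by `radstar.io.write_kspace`, read by `read_kspace`.  The root
carries the attribute `format_version` (currently `"1"`); readers reject
other versions.

```
/data                 complex128 [coil, echo, spoke, sample]
/traj
    @n_shots          int
    @n_echoes         int
    @samples_per_spoke int
    @n_frames         int
    angles            float64 [frame, shot, echo]      (radians, offsets applied)
    frame_offsets     float64 [frame]                  (degrees)
    coords            float64 [frame, echo, shot, sample, 2]  (cycles/FOV, kx ky)
/echoes
    @te_first         float (ms)
    @delta_te         float (ms)
    @n_echoes         int
/meta
    @fov_mm           float
    @noise_sd         float
    @seed             int (-1 when unset)
    @provenance       str
```

Round trips are bit exact.  Missing groups or datasets raise
`KspaceFormatError` naming the offending field.

## NIfTI parameter maps

Written by `radstar.io.write_maps` with a prefix, one volume per file:

| suffix                  | content                              | units |
|-------------------------|--------------------------------------|-------|
| `_water_real/_imag`     | complex water component              | a.u.  |
| `_fat_real/_imag`       | complex fat component                | a.u.  |
| `_r2star`               | effective relaxation rate, >= 0      | 1/s   |
| `_fb0`                  | off-resonance field map              | Hz    |
| `_fat_fraction`         | \|F\|/(\|W\|+\|F\|) * 100, 0/0 -> 0  | %     |

The affine is `diag(vox, vox, slice, 1)` with `vox = FOV / matrix` (mm)
and a 3 mm slice thickness.

## Trajectory table (plain text)

`radstar.io.export_trajectory_table` writes one line per sample:

```
# echo spoke sample kx ky
0 0 0 -96 0
...
```

`kx`, `ky` are in cycles/FOV (integer +-N/2 range at the spoke ends).

## Statistics CSV

The CLI `analyze` subcommand writes one row per ROI label:
`roi, mean_a, sd_a, mean_b, sd_b`; the Bland-Altman summary and ICC are
logged, and scatter data can be reconstructed from the per-ROI means.

## Phantom / reconstruction config (YAML)

Keys of `radstar.pipeline.PhantomRunConfig` at the top level and of
`radstar.recon.ReconConfig` under `recon:`; unknown keys are rejected.

```yaml
base_resolution: 96
noise_sd: 0.1
n_coils: 8
recon:
  alpha0: 1.0
  alpha_min: 0.002
  reduction_factor: 3.0
  n_gn: 18
  n_fista: 50
```
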