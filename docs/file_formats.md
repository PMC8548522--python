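# File formats

## Trajectory CSV

One row per detection; occlusions are absent rows (NaN coordinate rows are
accepted on input and converted). Coordinates are continuous pixel units by
default; pass `pixel_size` to the readers/writers to convert to μm at the
I/O boundary. Required columns: `track_id, frame, time_s, x, y`. Optional:
`z`, `group_id` (cell; defaults to "0"), `sigma_x, sigma_y[, sigma_z]`
(per-point localization s.d.; default 0 with a logged notice).

```csv
track_id,group_id,frame,time_s,x,y,sigma_x,sigma_y
a,cell1,0,0.0,12.31,40.02,0.08,0.08
a,cell1,1,0.5,12.44,39.87,0.08,0.08
a,cell1,3,1.5,12.70,39.60,0.09,0.09
b,cell1,0,0.0,30.10,22.51,0.08,0.08
b,cell1,1,0.5,30.05,22.69,0.08,0.08
```

(track `a` frame 2 is occluded). Readers reject files with missing required
columns, duplicate `(track_id, frame)` pairs, or non-increasing `time_s`
within a track, naming the offending rows.

## Results JSON (+ flat CSV)

`write_results` produces a JSON document and a flat per-track CSV next to
it. Floats round-trip to 1e−12, integers exactly.

```json
{
 "software": {"name": "gpfbm", "version": "0.1.0"},
 "tracks": [
  {"track_id": "a", "group_id": "cell1",
   "D_alpha": 0.512, "alpha": 0.63, "mu": [0.0, 0.0],
   "log_posterior": -310.2, "converged": true,
   "D_alpha_ci95": [0.41, 0.64], "alpha_ci95": [0.55, 0.72],
   "mh_acceptance": 0.31, "mh_seed": 7}
 ],
 "groups": {"cell1": {"substrate_D_alpha": 0.8, "substrate_alpha": 1.4,
                      "log_posterior": -612.0, "independent_fallback": false}},
 "settings": {"min_length": 10, "mh_samples": 10000, "seed": 7}
}
```

This schema is this package's own dialect (documented here, not a clone of
any other tool's output).

## Ground-truth JSON (simulator)

Per simulated record: generating particle/substrate parameters, the
`SimulationSpec` fields, and the record seed — enough to regenerate the
trajectories exactly.

```json
[{"particles": [{"D_alpha": 0.8, "alpha": 0.6, "mu": [0.0, 0.0]}],
  "substrate": null,
  "spec": {"n_points": 250, "dt": 0.5, "D_alpha": 0.8, "alpha": 0.6,
           "sigma": 0.1, "occlusion_rate": 0.1, "n_dims": 2, "seed": 7},
  "seed": 7}]
```

## Alignment JSON

Raw affine parameters plus the composed 3×3 matrix:

```json
{"s_x": 1.001, "s_y": 0.999, "d_x": 2.39, "d_y": -1.27,
 "theta": 0.0005, "c_x": 24.0, "c_y": 24.0, "W": 48, "H": 48,
 "matrix": [[1.001, 0.0005, 2.37], [-0.0005, 0.999, -1.25], [0.0, 0.0, 1.0]]}
```

## TIFF input

Multi-page TIFF stacks are read with `tifffile` into `(T, H, W)` float
arrays; OME tags are tolerated but not required. Pixel centers sit at
integer coordinates, origin top-left, x = column, y = row.

## Run configuration

`RunConfig` serializes all pipeline settings (minimum track length, MH
settings, lag fractions, seeds, paths) to JSON and round-trips losslessly,
so any run is reproducible from its logged configuration.
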