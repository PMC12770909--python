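# File formats

All on-disk formats are plain text or HDF5. Node indexing is 0-based in
every dstacs file; Gmsh MSH files are 1-based on disk and converted on
read/write.

## Meshes

**Gmsh MSH v2 ASCII** (`.msh`): `$Nodes` (id x y z, mm) and `$Elements`
sections; only 3-node triangles (element type 2) are read, other element
types are ignored. Arbitrary node ids are remapped to dense 0-based
indices in file order.

**PLY** (`.ply`): vertices + triangular faces, read/written via trimesh
(ASCII export).

## Region labels (`labels.tsv`)

| column | type | meaning |
|---|---|---|
| `node_index` | int | 0-based node index |
| `label` | int | region label; −1 = unlabelled |

Region-set definitions (which labels form "M1_left", "M1_right",
"surrounding") are configuration, not file content
(`RunConfig.region_set_labels`).

## Basis fields

**HDF5** (`.h5`): datasets `/fields/ER1`, `/fields/EC1`, `/fields/ER2`,
each N×3 float64 in V/m per mA of channel current; attributes `Io` (mA),
`f` (Hz), `montage_id`, `individual_id` on group `/meta`.

**Wide TSV** (`.tsv`): columns `node_index`, then `ER1_x … ER2_z`
(9 field columns, `%.17g` so values round-trip exactly); metadata in a
`<name>.tsv.meta.json` sidecar with keys `Io`, `f`, `montage_id`,
`individual_id`.

## Threshold masks (`mask.tsv`)

`node_index`, `status` ∈ {`kept`, `excluded`, `zeroed`}.

## Metric table (`metrics.tsv`)

One row per (individual, montage, phase lag, region set, metric).

| column | meaning |
|---|---|
| `individual_id`, `montage_id` | identifiers |
| `phase_lag` | rad, in [0, 2π) |
| `region_set` | `M1s`, `surrounding`, or `M1_left`/`M1_right` (effective area) |
| `metric` | `peak_magnitude`, `peak_normal`, `peak_normal_inward`, `rdm`, `dotp`, `ideal_dotp`, `delta_dotp`, `effective_area` |
| `value` | metric value |
| `units` | `V/m`, `mm^2`, or empty (dimensionless) |

## Test table (`tests.tsv`)

One row per (metric, montage, region set): `statistic` (weighted
Hermans–Rasson T), `p_raw`, `p_adjusted` (Holm across montages within a
metric × region set), `significant` (p_adjusted < alpha),
`n_permutations`, `seed`.

## Selection table (`selection.tsv`)

One row per (objective, individual): `objective` (`rdm` or `delta_dotp`),
`individual_id`, `montage_id` (chosen), `value` (lag-averaged objective).

## JSON outputs

`individualization.json`: per objective, `best_fixed_montage`,
`mean_fixed_best`, `mean_individualized`, `cv_fixed_best`,
`cv_individualized` (CVs in %).

`provenance.json`: full config dict, its SHA-256, package/numpy/pandas
versions, master seed.

Rows of all TSV tables are sorted on all columns and floats written with
`%.12g`, so repeated runs of the same configuration are byte-identical.
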