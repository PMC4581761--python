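# File formats

## PDB structures and trajectories

Structures are read from standard PDB `ATOM`/`HETATM` records (fixed
columns). Only the first `MODEL` is kept for a structure; the number of
models seen is reported on `StructureModel.n_models_in_source`. Alternate
locations other than blank or `A` are dropped; occupancy and B-factor are
ignored. Residue identity is `(chain_id, residue_seq, icode)` exactly as
written in the file. A malformed coordinate field raises a parse error
naming the line number.

Trajectories are multi-model PDB files: each frame is a
`MODEL n` ... `ENDMDL` block whose `ATOM` records appear in topology order.
Every frame must carry exactly the topology's atom count, otherwise the
reader fails naming the offending frame index. Frame times are implicit:
frame *k* (1-based) is at `k * frame_spacing` ps.

The writer emits

```
ATOM  {serial:>5} {name:<4} {resName:<3} {chain}{resSeq:>4}{iCode}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {element:>2}
```

so read → write → read round-trips coordinates to 3 decimals (PDB
precision) and preserves atom order.

## Plain-coordinate frame format

A compact alternative for trajectories. Each frame is:

```
<n_atoms> <free-text comment>
x y z          # one whitespace-separated line per atom, Angstroms
...
```

Frames are concatenated; blank lines and `#` comment lines are ignored.
The reader is selected automatically when the first record of the file is
not a PDB record name.

## Force-field parameter dialect

A sectioned, whitespace-separated text format. Comments start with `#`.

```
[atoms]
# chain resseq name charge lj_sigma lj_epsilon gb_radius gb_scale
A 1 N -0.30 3.25 0.17 1.55 0.80
...
[bonds]
# serial_i serial_j k_b r0          (kcal/mol/A^2, A)
1 2 300.0 1.46
[angles]
# serial_i serial_j serial_k k_a theta0   (kcal/mol/rad^2, rad)
1 2 3 50.0 1.91
[dihedrals]
# serial_i serial_j serial_k serial_l barrier periodicity phase  (kcal/mol, -, rad)
1 2 3 5 0.5 2 3.14159
```

`[atoms]` rows are keyed by `(chain, resseq, atom name)` and must cover
every atom of the structure they are read against (missing atoms raise a
coverage error listing them). Bonded sections reference atom *serial
numbers*; a serial absent from the structure raises an index error.
Units: charge in e, lengths in A, energies in kcal/mol, angles in rad.

## Run configuration (YAML)

```yaml
systems:
  - name: dg_analog
    structure: dg_analog.pdb
    trajectory: dg_analog_traj.pdb
    forcefield: dg_analog.ff
    chain_roles: {A: ligand_alpha, R: receptor}
    frame_spacing: 100.0      # ps per frame
baseline: dg_analog           # differencing reference system
output_dir: report
thresholds:
  shift: 1.5                  # A
  rmsf_diff: 0.50             # A
  bridge_cutoff: 3.5          # A
  sasa_diff: 40.0             # A^2
  contact: 4.5                # A
skip_fraction: 0.125          # equilibration fraction discarded
sasa_stride: 10               # frames between SASA evaluations
snapshot_interval: 1000.0     # ps between energy snapshots
energy_mode: absolute         # or "binding"
energy:
  gb_model: HCT               # or OBC-II
seed: 0
```
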