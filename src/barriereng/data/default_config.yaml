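# Default pipeline configuration.  Every parameter any stage consumes is
# listed here; unknown keys are rejected at validation time.
seed: 0
output_dir: runs/synthetic
linker: GG

weights:                  # fractional factor weights; must sum to 1
  binding_energy: 0.10    # A, kcal/mol (lower is better)
  hbonds: 0.30            # B, count (higher is better)
  attack_distance: 0.40   # C, Å (lower is better)
  cavity_volume: 0.20     # D, Å³ (higher is better)

hbond:
  max_da_distance: 3.5    # Å, heavy-atom donor-acceptor cutoff
  min_dha_angle: 120.0    # degrees, applied only when hydrogens are present

cavity:
  spacing: 0.6            # Å, grid voxel edge
  probe_in: 1.4           # Å, water-sized probe
  probe_out: 4.0          # Å, bulk-solvent probe
  padding: 6.0            # Å, sub-box margin
  shell_cutoff: 4.0       # Å, ligand residue-shell radius

site:
  cutoff: 6.0             # Å, binding-site sphere around the Ser OG

window:
  start_ns: 60.0          # analysis window = the last 40 ns of a 100 ns run
  end_ns: 100.0

generator:
  n_residues: 60
  n_ligands: 30           # substrate copies in the box
  n_waters: 60
  frame_interval_ns: 0.5  # storage interval
  duration_ns: 100.0
  n_variants: 5
  protein_sigma: 0.1      # Å, per-frame protein jitter
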