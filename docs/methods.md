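# Methods

## Scope and data model

The package operates on heavy-atom geometry only. Hydrogens are tolerated
on input (they matter solely for the optional hydrogen-bond angle
criterion) and ignored by every distance, surface and volume computation,
because docking poses and predicted structures usually lack them. Author
residue numbering from the PDB columns is authoritative everywhere; variant
renumbering is sequential 1..N with an explicit old→new map. Alternate
conformations are collapsed to the highest-occupancy atom with a warning. A
ligand is exactly one residue; multi-residue ligands are rejected.

PDB parsing goes through gemmi; MODEL/ENDMDL blocks become trajectory
frames. Writing is plain fixed-column output, round-tripping coordinates to
the 0.001 Å precision of the format. mmCIF, compressed transport and
symmetry expansion are out of scope.

## Truncation design

A barrier region is an inclusive author-numbered range `[start, end]`. The
variant sequence is `prefix + linker + suffix` with the Gly-Gly linker as
default (configurable). Residues after the region shift by
`len(linker) − (end − start + 1)`; deleted positions map to nothing.
Overlapping regions in the built-in tables (BsEst Δ4/Δ5, ChryBHETase
Δ1/Δ2) are each designed independently — the workflow scores candidates,
it does not assume they are disjoint. Variant structures are *not*
rebuilt: geometric factors for a variant require an externally provided
(e.g. predicted) structure or the synthetic builder. No loop modelling is
attempted.

## Pocket factors

**Hydrogen bonds.** Donor/acceptor-capable atoms are heavy N and O on
either partner. Without hydrogens the criterion is a donor–acceptor
distance ≤ 3.5 Å (the community default for heavy-atom detection). When
hydrogens are present, at least one X–H on either partner must give a
D–H···A angle ≥ 120° at the hydrogen; a polar pair where neither partner
carries hydrogens falls back to the distance rule. Each
protein-atom/ligand-atom pair counts once.

**Attack distance.** Euclidean distances from the catalytic Ser OG to the
ligand atoms named C7 and C10 (the two ester carbonyl carbons of BHET).
Scoring consumes the minimum of the two — nucleophilic attack proceeds on
whichever carbonyl is closer; `mode="both"` returns the pair for distance
series and reporting.

**Cavity volume.** A dual-probe grid method restricted to the sub-box
around the ligand plus its residue shell (default 4 Å selection, 6 Å
padding, 0.6 Å spacing). The exact signed distance to the nearest van der
Waals surface is evaluated at every voxel (radii: C 1.70, N 1.55, O 1.52,
S 1.80 Å, default 1.70 — a fixed internal table for determinism). A voxel
is *cavity* when (i) it lies outside every vdW sphere, (ii) the small probe
(1.4 Å, water-sized) can sweep it, and (iii) the large probe (4.0 Å, bulk
solvent) cannot reach it rolling in from the box boundary. Bulk
reachability uses a connected-component flood fill of large-probe center
space from the grid edges, so fully enclosed voids that happen to fit the
large probe still count as cavities. Probe sweeps use a certified-radius
dilation: a grid center with clearance `d` covers everything within `d`
of it (valid because the surface-distance field is 1-Lipschitz), which
removes the quantization slivers a fixed-radius dilation leaves along
curved walls. Finally, connected cavity components smaller than
`min_cavity_volume` (default 5 Å³) are discarded: the probe-size
differential otherwise accumulates thin, physically meaningless slivers in
surface crevices between atoms. Volume is voxel count × spacing³; on a
hollow-shell benchmark with a 4 Å accessible radius the default grid is
within ~5% of the analytic volume and the error decreases with spacing.

**Binding energy.** Always ingested from a delimited table
(`variant_id,binding_energy_kcal_mol`); computing docking energies is a
non-goal.

## Scoring

Each factor column is min–max normalized within the scored table; binding
energy and attack distance (lower is better) are inverted as
`1 − fraction`. Weights default to 0.10/0.30/0.40/0.20 for
energy/H-bonds/distance/volume and must sum to 1. A degenerate column
(max = min) contributes a neutral 0.5 for every variant — it cannot
discriminate, and this avoids 0/0. Ties rank by smaller attack distance
first (the heaviest-weighted factor), then lexicographic variant id, making
ranking deterministic and permutation-invariant. Normalization is per
input table; score one parent enzyme's candidates together unless
cross-enzyme comparability is explicitly intended.

## Trajectory observables

Superposition is closed-form Kabsch (SVD with reflection guard); RMSD is
the post-fit value over the fitted selection. RMSF is computed over an
analysis window specified in nanoseconds (frames filtered by time, so "the
last 40 ns" is well defined for any storage interval): frames are fitted to
the first window frame, averaged, re-fitted to the mean, and the
per-residue root-mean-square fluctuation about the mean is reported for one
representative atom per residue (CA, else the first heavy atom). The fit
selection can be restricted to a rigid subset so a mobile region's motion
does not leak into the frame alignment.

SASA is Shrake–Rupley with a deterministic Fibonacci point set (default
960 points, 1.4 Å probe); the isolated-atom error at 960 points is below
2%. Coincident duplicate atoms are counted once.

Binding-site occupancy counts molecules (substrate copies or waters) with
at least one heavy atom within 6.0 Å of the catalytic Ser OG — the site
itself is never defined geometrically in structural terms, so this simple
sphere is the operational proxy; the cutoff is configurable. Per-10-ns bin
means are provided alongside the per-frame series. The spatial
distribution (SDF) grid reports, per voxel, the fraction of window frames
in which the species occupies the voxel after superposing each frame onto
the first window frame on protein heavy atoms; an occupancy fraction is
bounded and resolution-robust, unlike a number density.

## Assay models

Thermal inactivation is single-exponential; the default fit is linear least
squares on log activity (exact for multiplicative noise, and the model's
log-linear form), with a nonlinear option for noisy tails. Half-life is
ln2/k, defined only for k > 0; non-decaying series are flagged as fit
failures rather than returning a negative rate.

DSC percent crystallinity divides the melting/cold-crystallization
enthalpy difference by the reference enthalpy of 100% crystalline PET
(140.1 J/g). Dividing by the sample's own ΔH_m instead would make the
result insensitive to the melting enthalpy's magnitude, contradicting the
quantity's meaning; the reference denominator is used. A negative result
(ΔH_c > ΔH_m) is returned with a warning — physically suspect, not an
error.

Glycolysis bookkeeping uses the PET repeating unit TPA–EG at 192.2 g/mol
and BHET at 254.24 g/mol: purity is an HPLC area ratio; yield divides the
recovered BHET mass by `m_PET/192.2 × 254.24`; the theoretical maximum
hydrolysis yield divides the measured TPA concentration (mM) by
`c_PET [g/L]/192.2 × 1000`. All four are homogeneous of degree zero in
consistent unit rescalings.

Michaelis–Menten fitting is nonlinear least squares of
`v = Vmax·S/(K_M + S)` with data-driven starting values and non-negative
bounds; standard errors come from the covariance of the fit. k_cat is
reported only when an enzyme concentration is supplied — the rate units
are otherwise not reconcilable to a turnover number — and catalytic
efficiency is k_cat/K_M of the same fit. A design spanning 0.8–15 mM
recovers a K_M of ~0.1 mM but with a large standard error, since almost no
design point sits below K_M; the fit reports this rather than hiding it.
Fold changes are computed from their inputs (never hard-coded) and rounded
half-up at the requested decimals.

## Synthetic generators

All generators are pure functions of a seeded configuration (NumPy
`default_rng`); identical seeds give byte-identical outputs, and a JSON
manifest of the ground truth (schedules, parameters, designated best
variant) accompanies generated data for closed-loop tests.

The toy protein is a coiled solenoid: a local α-helix parameterization
(1.5 Å rise, 100° phase per residue) wound around a circular axis so the
wall encloses a central pocket, with one mid-wall serine whose OG points
into the pocket mouth. Realism is deliberately minimal — no side chains
beyond that OG — because every downstream operation needs only heavy-atom
geometry, names and numbering. The BHET ligand is an idealized planar
terephthalate with two hydroxyethyl ester tails: 18 heavy atoms (C12O6),
bond lengths within 1.2–1.6 Å, and a C7–C10 para-dicarbonyl span of
≈5.76 Å.

Trajectories default to the simulated study conditions the analyses
assume: 30 substrate copies, frames every 0.5 ns for 100 ns (so the "last
40 ns" window is 60–100 ns), plus free single-oxygen waters. Substrate
copies perform rigid random walks in a reflective box (reflective
boundaries conserve molecule counts without periodic-boundary machinery);
during a schedule window the prescribed number of copies is parked inside
the site cutoff while free copies are excluded from a zone of
`cutoff + ligand extent` around the OG, so analysis-side occupancy counts
reproduce the schedule *exactly* — the scheduled occupancy is ground
truth, not an emergent property. Protein atoms receive per-frame Gaussian
jitter (default σ = 0.1 Å) to exercise RMSF. Assay generators apply
multiplicative log-normal noise (keeping activities positive for the
log-linear fit); zero noise returns exact model values. Decay series are
sampled every 0.5 h over 10 h; the kinetics design spans 0.8–15 mM.

What passing tests on these fixtures shows: the *analysis* code computes
occupancy, distances, fluctuations, surfaces, volumes and fits correctly
against known ground truth. What it does not show: anything about real MD
force fields, water thermodynamics, docking-pose realism, or whether a
specific real enzyme's barrier behaves as scheduled. Statements about real
systems require real structures and trajectories as input.

## Pipeline and reproducibility

The end-to-end synthetic run (simulate → design → factors → score)
executes in seconds on one CPU. A single validated YAML document carries
every parameter any stage consumes; unknown keys are rejected, and the run
manifest records the config hash, per-stage outputs with SHA-256 checksums
and timings. Identical config and seed reproduce identical CSV outputs.
The default problem sizes used by the shipped tests and the acceptance
script — a 60-residue toy protein, 5 variants, 200-replicate recovery
studies, 0.6 Å cavity grids — were chosen as the smallest sizes at which
the statistical checks are stable.

## Known limitations

* Cavity volumes are grid estimates: translations reproduce to a few
  voxels and general rotations to a few percent; results at different
  spacings differ within the documented convergence behaviour.
* The hydrogen-bond model is geometric only — no protonation-state or
  donor-capacity bookkeeping beyond element identity.
* Trajectory input is multi-model PDB (or in-memory); compressed MD
  formats (XTC/TRR/DCD) and PBC unwrapping are out of scope.
* Variant structures are not modelled; scoring real variants requires
  externally predicted structures and docking energies.
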