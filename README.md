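# barriereng

Mechanism-guided **barrier engineering** of BHET hydrolases, as a reusable,
fully synthetic-testable pipeline.

BHET (bis-2-hydroxyethyl terephthalate) is the main product of chemical PET
glycolysis; BHETases hydrolyse it via MHET to terephthalic acid (TPA). In
several of these enzymes a rigid structural segment — a *barrier*, distinct
from a classical lipase lid — occludes the substrate binding cleft around
the catalytic Ser-His-Glu triad and keeps the bulky BHET out while water
slips in. Barrier engineering deletes such a segment (an inclusive residue
range) and bridges the junction with a flexible `-GG-` linker, then selects
among candidate truncations *in silico* before any cloning.

This package implements that workflow end to end for anyone designing or
evaluating truncation variants of PET/BHET hydrolases:

* **variant design** — delete a barrier region, insert a linker, track the
  old→new residue-number map (so the catalytic Ser is still addressable);
  the ten published barrier regions of BsEst and ChryBHETase ship as
  built-in constants,
* **pocket factors** — protein–ligand hydrogen-bond count, the serine
  attack distance from the Ser hydroxyl oxygen (OG) to the BHET ester
  carbonyl carbons C7/C10, and a dual-probe grid cavity volume between the
  ligand and its 4 Å residue shell; docking binding energies are *inputs*
  (a CSV), never computed here,
* **weighted min–max scoring** — each factor column is min–max normalized,
  lower-is-better columns inverted, and combined as

  `score = 0.10·a + 0.30·b + 0.40·c + 0.20·d`

  (binding energy, H-bonds, attack distance, cavity volume); the top-ranked
  variant is the candidate for wet-lab validation,
* **trajectory observables** — RMSD (Kabsch), radius of gyration,
  per-residue RMSF over a time window, Shrake–Rupley SASA, substrate/water
  occupancy of the binding site (any heavy atom within 6 Å of the Ser OG),
  OG–C7/C10 distance series, and spatial occupancy grids (SDF) written as
  Gaussian cube files,
* **assay models** — first-order thermal inactivation `E_t = E_0·e^(−kt)`
  with half-life `t½ = ln2/k`, DSC percent crystallinity
  `(ΔH_m − ΔH_c)/ΔH_ref × 100` against the 140.1 J/g crystalline-PET
  reference, BHET purity/yield and theoretical maximum hydrolysis yield
  from the PET repeating unit (192.2 g/mol) and BHET (254.24 g/mol)
  stoichiometry, Michaelis–Menten fits with standard errors, and half-up
  rounded fold changes,
* **synthetic data** — seeded generators for a pocket-bearing toy protein
  with a catalytic Ser, an idealized 18-heavy-atom BHET, trajectories whose
  binding-site occupancy follows a prescribed schedule, factor tables with
  a known dominating variant, and noisy decay/kinetics datasets — so every
  stage is testable with no downloads.

## Worked example

The closed-loop synthetic run simulates a complex and a five-variant factor
table with a designated dominator, designs truncations, computes the
geometric factors of the reference complex, and scores the table:

```bash
$ barriereng run --seed 42 --out runs/demo
run complete -> runs/demo/manifest.json
top variant: D4 (closed loop ok: True)
```

`runs/demo/scores.csv` (columns abridged):

| variant_id | a | b | c | d | score | rank |
|---|---|---|---|---|---|---|
| D4 | 1.000 | 1.000 | 1.000 | 1.000 | 1.000 | 1 |
| D1 | 0.091 | 0.000 | 0.853 | 0.884 | 0.527 | 2 |
| D2 | 0.451 | 0.667 | 0.320 | 0.442 | 0.461 | 3 |
| D3 | 0.000 | 0.333 | 0.452 | 0.190 | 0.319 | 4 |
| D5 | 0.821 | 0.333 | 0.000 | 0.000 | 0.182 | 5 |

D4 was generated to dominate all four factors, so its normalized fractions
are all 1 and its weighted score is exactly 1.0; `closed loop ok: True`
records that scoring ranked the known-best variant first. The assay side
works the same way from delimited tables:

```bash
$ barriereng assay decay --in decay.csv
k = 0.0181311 1/h  t1/2 = 38.23 h  R^2 = 1.0000
```

i.e. an enzyme losing activity with rate constant 0.0181311 h⁻¹ has a
half-life of 38.23 h. Other subcommands: `inspect`, `design`, `factors`,
`score`, `traj`, `simulate`, `validate-config` (see `barriereng --help`).

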