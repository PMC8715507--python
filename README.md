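# jchi

Protein side-chain **χ₁ conformations from vicinal ³J coupling
constants**: extended Karplus (Fourier) equations fitted to dihedral
scans, rotamer-population inference under three conformer models, and
circular statistics for validating predicted angles against NMR- and
X-ray-derived references.

## What it does

For Val, Leu and Ile, nine vicinal couplings cross the Cα–Cβ bond (six
coupling types: J(Hα,Hβ), J(Hα,Cγ), J(C′,Hβ), J(C′,Cγ), J(N′,Hβ),
J(N′,Cγ)), each with a path dihedral θ = χ₁ + Δθ (Δθ nominally
0/±120°). The package:

- **`jchi.karplus`** — represents, evaluates, fits and compares
  six-term Karplus curves `J(θ) = C0 + C1 cosθ + C2 cos2θ + C3 cos3θ +
  S1 sinθ + S2 sin2θ`. Fitting is ordinary least squares on scan
  tables; on the canonical six angles (0, ±60, ±120, 180°) the fit
  interpolates exactly. Comparison metrics: coupling rmsd, the
  equivalent coefficient-space rmsd, and the |C0|-weighted average
  relative rmsd (awrmsd, %).
- **`jchi.conformers`** — per-residue χ₁ inference from experimental
  couplings: **UMS** (single conformer; rmsd profile over χ₁ with
  minima ranking, staggered-preferring selection and a ±0.2 Hz
  uncertainty window), **TMSS** (populations of the three staggered
  rotamers, solved exactly on the probability simplex by active-set
  enumeration) and **TMST** (three conformers 120° apart with a fitted
  anchor angle). Residues are classified unimodal/trimodal by the
  staggered-proximity (±30°) and dominant-population (>60%) criteria.
- **`jchi.circstats`** — circular distance/mean, circular rmsd between
  angle sets with a 40° exclusion rule, and outlier-robust averaging of
  X-ray angles (30° threshold, iterated to a fixed point).
- **`jchi.structure`** / **`jchi.io`** — χ₁ extraction from PDB files
  (Biopython backend, altloc by occupancy) and delimited-text readers
  and writers for coefficient, scan, coupling and angle tables.
- **`jchi.fixtures`** — packaged reference tables for 29 flavodoxin
  Val/Leu/Ile residues (checksummed), with `jchi.report` reproducing
  the cross-method agreement statistics from them.
- **`jchi.synth`** — seeded synthetic scan tables and residue
  couplings with known ground truth (pure conformer, staggered or
  trigonal mixtures, Gaussian noise, missing-coupling masks), so every
  inference stage is testable offline.

## Command line

The console script `jchi` exposes the pipeline:

```sh
jchi simulate --mode staggered --populations 0.2,0.5,0.3 --sigma 0.2 \
     --seed 7 --out couplings.csv                  # + couplings.truth.json
jchi fit-karplus --scan scan.csv --residue-type VAL --out coeffs.csv
jchi predict --couplings couplings.csv --karplus coeffs.csv \
     --model all --out report.csv                  # + report.json
jchi compare --set1 pred.csv --set2 xray.csv --exclusion 40
jchi compare-coefficients --set1 a.csv --set2 b.csv
jchi xray-average --angles angles.csv --threshold 30
jchi reproduce-paper-stats
```

`jchi reproduce-paper-stats` prints the pairwise circular-rmsd matrix
between the χ₁ columns of the packaged tables and the
unimodal/trimodal classification counts.

## Conventions

- Angles are degrees, wrapped to (−180, 180]; couplings are Hz.
- Staggered rotamers are χ₁ = 60, 180, −60°.
- Exclusion rules: >40° pairs dropped from circular rmsd (=40 kept);
  ±30° inclusive for the staggered-proximity test; >30° removed in
  X-ray averaging.
- Randomness uses numpy's `default_rng` (PCG64); fixed seeds give
  identical output across platforms.
- The default Δθ registry (`jchi/data/topology.csv`) uses ideal
  tetrahedral phases; per-coupling overrides are supported
  (`ResidueTopology.with_overrides`, `--delta-theta-table`).
- The coefficients from `jchi.synth.demo_karplus_set` are synthetic
  demonstration values, not a published parameterization.
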