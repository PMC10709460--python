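# cdtraj

Trajectory analysis for cyclodextrin host–guest inclusion complexes.

Cyclodextrins (CDs) are cyclic oligosaccharides — β-cyclodextrin (βCD) is a
ring of 7 glucose units — whose hydrophobic cavity can encapsulate poorly
soluble guests such as cholesterol. Molecular-dynamics studies of these
carriers all revolve around the same set of post-processing computations:
how the macrocycle deforms, how and when the guest binds, how cavity water
responds, what the hydrogen-bond network does, and what the thermodynamics
of binding are. `cdtraj` implements that analysis pipeline as a reusable,
tested library with a CLI, for people who have such trajectories (or want to
validate an analysis against synthetic ground truth before trusting it on
real data).

## What it computes

**Macrocycle geometry** (`cdtraj.geometry`). The three rim-oxygen rings —
primary hydroxyl rim (PHR, O6), middle rim (MID, glycosidic O1) and
secondary hydroxyl rim (SHR, O3) — give per-frame rim areas *A*
(projected-polygon shoelace areas), circularity Ω (ratio of the smallest to
the largest cross-ring chord; 1 for a regular ring), rim heights *h*₁₂,
*h*₁₆ between mass-weighted rim centroids, and a cavity volume *V*_C modelled
as two conical frustums stacked at the middle rim. Guest binding kinetics:
per-frame state (unbound / surface / inserted) from the guest-COG distance
to the cavity center plus a 45° axis-alignment cone, and guest orientation
(hydroxyl oxygen toward PHR or SHR).

**Shape anisotropy** (`cdtraj.shape`). Gyration-tensor eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ with R_g² = λ₁+λ₂+λ₃, relative shape anisotropy

    κ² = 1 − 3 (λ₁λ₂ + λ₂λ₃ + λ₁λ₃) / (λ₁+λ₂+λ₃)²   ∈ [0, 1]

(0 = spherical, 1 = ideal linear chain) and asphericity
b = λ₁ − (λ₂+λ₃)/2, plus their probability densities.

**Cavity hydration** (`cdtraj.hydration`). Water-oxygen counts in
concentric shells around the cavity center (default edges 0/0.5/0.8/0.9/1.0
nm) with block-averaged mean ± SE, and the radial distribution function
g(r) of water around the cavity.

**Hydrogen bonds** (`cdtraj.hbonds`). Geometric criterion
(r(D,A) ≤ 0.35 nm, ∠H–D–A ≤ 30°), counts per group pair (water–CD,
water–guest, guest–CD, CD–CD) and continuous or intermittent lifetimes.

**Free energies** (`cdtraj.energetics`). Thermodynamic integration
ΔG = ∫₀¹ ⟨∂H/∂λ⟩ dλ (trapezoid), the Bennett acceptance ratio solved per
adjacent λ-window pair from forward/reverse energy differences, the
binding thermodynamic cycle ΔG_bind = ΔG_decouple(water) −
ΔG_decouple(complex), seeded bootstrap standard errors, block averaging,
and dipole moments.

**Free-energy landscapes** (`cdtraj.fel`). Kabsch-superposition RMSD,
2D landscapes F = −kT ln(P/P_max) over (RMSD, R_g), basin detection and
minimax-path barriers.

**Synthetic ground truth** (`cdtraj.synthetic`). Because real 100+-ns
trajectories are rarely shareable, every analysis is exercised against
generators with known answers: a βCD-scale three-rim ring, a scripted
rigid-rod guest with known insertion frame and orientation, water baths
with exact shell occupancies, planted hydrogen-bond episodes, and
Crooks-consistent Gaussian work samples with known ΔG.

## Worked example

Generate a synthetic binding trajectory (200 frames, guest scripted to
insert at frame 120) and analyse its geometry over the last 10 % of frames:

```sh
cdtraj simulate --out demo --n-frames 200 --insertion-frame 120 --seed 7
cdtraj analyze-geometry demo/trajectory.pdb demo/topology.yaml --out demo/geo
```

```
              descriptor         mean           se
                   A_PHR 1.099931e+00 0.000000e+00
                   A_MID 8.299946e-01 0.000000e+00
                   A_SHR 1.319923e+00 0.000000e+00
               Omega_MID 9.998934e-01 0.000000e+00
                     h12 2.200001e-01 1.387779e-17
                     h16 3.299999e-01 0.000000e+00
                     V_C 5.518112e-01 0.000000e+00
```

The generator's default ring reproduces the βCD scale — rim areas
1.10/0.83/1.32 nm², heights 0.22/0.33 nm — so the frustum cavity volume
comes out at 0.55 nm³; the near-1 circularities and zero SEs reflect the
rigid, regular synthetic ring. On a real trajectory every descriptor
fluctuates and the SE columns are block-averaged errors.

Free energies from Crooks-consistent synthetic work samples with planted
ΔG = −77.49 kJ/mol (σ_W = 5 kJ/mol, kT = 2.577 kJ/mol, 10⁴ samples/side):

```python
from cdtraj import synthetic, energetics
s = synthetic.make_bar_samples(synthetic.WorkSampleSpec(delta_g_true=-77.49, seed=7))
res = energetics.bar_from_lambda_samples(s, seed=7)
print(f"BAR: {res.delta_g:.2f} +/- {res.se:.2f} kJ/mol")
# BAR: -77.53 +/- 0.04 kJ/mol
print(energetics.binding_cycle(11.18, 11.18 + 77.49).delta_g)
# -77.49  (decoupling 77.49 kJ/mol harder from the complex than from water)
```

A full run over all stages — geometry, shape, hydration, hydrogen bonds,
FEL, and TI/BAR when λ samples are supplied — goes through a config file:

```sh
cdtraj run-all config.yaml
```

which emits per-frame and summary TSVs shaped like the usual per-system
tables, plus a JSON run report with seeds and output checksums
(same config + inputs + seed ⇒ byte-identical outputs).

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
generates a seeded hydrated host–guest system, runs every analysis stage
end-to-end through `run-all`, estimates the decoupling free energy by BAR
from Crooks-consistent λ samples, and writes the result summary to `--out`.

See `docs/methods.md` for the models, conventions, numerical choices and
limitations.
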