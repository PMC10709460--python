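# Methods

This note records the models behind each analysis, the conventions and
defaults that matter, what the synthetic generators do and do not emulate,
and the numerical choices a maintainer would want to know.

Units everywhere: coordinates nm, times ps, energies kJ/mol, charges e,
masses u. kT = 2.577 kJ/mol corresponds to 310 K
(k_B = 0.008314462618 kJ/mol/K).

## Trajectory model and windows

Trajectories are ordered frames with a constant spacing `dt` and an
orthorhombic box per frame; minimum-image displacements use per-axis
wrapping only. Multi-model PDB is read/written through MDAnalysis
(Å ↔ nm conversion on the boundary); concatenated GRO frames are parsed
by a small fixed-width reader because no installed reader handles
multi-frame GRO. The topology is an explicit YAML annotation — atom
records plus named index groups — never inferred from chemistry; in
particular the three rim rings must be listed in cyclic order, since ring
order defines the rim polygons and is ambiguous in distorted frames.

Summary statistics are taken over a *tail window*: the final
`ceil(fraction · N)` frames (default fraction 0.10). Frame counts, not
timestamps, define the window, which keeps it deterministic when the time
origin is missing.

## Rim geometry

* **Rim area**: the ordered oxygen ring is projected onto its total
  least-squares plane (SVD of the centred coordinates) and the shoelace
  formula applied to the projected polygon. A self-intersecting projection
  warns but still reports the shoelace value, flagging a badly distorted
  frame.
* **Circularity Ω**: by default the ratio of the smallest to the largest
  *cross-ring* chord — for each atom the chords to its most distant ring
  partners, i → i+⌊n/2⌋ and i → i+⌈n/2⌉. A regular n-gon scores exactly 1
  under this convention for every n, which matches the near-1 values such
  tables report for rims of a heptagon. The literal all-pairs min/max
  ratio is available as an option, but note it is bounded by
  sin(π/7)/sin(3π/7) ≈ 0.445 for any regular heptagon (the shortest pair
  is always an edge, the longest a cross-ring chord), so it cannot
  reproduce near-1 rim circularities.
* **Rim heights**: Euclidean distances between mass-weighted rim
  centroids; h12 = MID–SHR, h16 = MID–PHR, h = PHR–SHR. h = h12 + h16
  holds exactly only when the three centroids are collinear; the per-frame
  deviation is reported alongside.
* **Cavity volume V_C**: two conical frustums stacked at the middle rim,

      V = (h16/3)(A_PHR + A_MID + √(A_PHR·A_MID))
        + (h12/3)(A_SHR + A_MID + √(A_SHR·A_MID)).

  This is a declared geometric model chosen because it consumes exactly
  the tabulated rim areas and heights, degenerates correctly to cylinder
  (2Ah) and cone (Ah/3) limits, and is monotone in every input. A
  convex-hull volume of the 21 rim oxygens is available as an alternative
  estimator; the two agree to within a factor well inside 2 on regular
  rings. Published cavity volumes computed with other (unavailable)
  protocols are not oracle values for either estimator, though on
  βCD-scale inputs the frustum model lands at 0.55 nm³, the right scale.

## Binding classification

Cavity axis = unit vector from the SHR centroid to the PHR centroid;
cavity center = midpoint of that segment — deterministic and frame-local.
A guest is **inserted** when its center of geometry is within
`d_insert = 0.35 nm` of the cavity center *and* its long axis (leading
principal axis of its coordinates) lies within 45° of the cavity axis;
**surface**-bound when within `d_surface = 0.80 nm` but not inserted;
otherwise unbound. All three thresholds are configurable because no
numeric criterion for "fully penetrated" is standard. Orientation is the
sign of the guest-hydroxyl-oxygen offset from the guest COG projected on
the PHR-pointing axis, reported only when the guest is in contact.
Group centers use uniform weights (centers of geometry); rim heights use
masses. Groups are assumed whole (not split across the periodic
boundary); only center-to-center displacements are minimum-imaged.

## Shape descriptors

The gyration tensor is mass-weighted by default (uniform weighting
selectable; which one the original analyses used is not stated, and for a
near-homogeneous heavy-atom ring the difference is small). Eigenvalues are
sorted descending; κ² is clamped to [0,1] only against round-off below
1e-10, anything larger raises. The zero tensor maps to κ² = 0 (a point is
perfectly symmetric — the continuous limit of shrinking any symmetric
cloud). Densities are normalized histograms by default (50 bins; κ²
support [0, 0.5] since the structure of interest lives around 0.1–0.3);
a Gaussian KDE is available.

## Hydration

A water molecule is located by its oxygen. Shell bins are half-open and
lower-inclusive, `[e_k, e_{k+1})`, so a water exactly on an edge belongs to
the outer shell. The cavity center is the same frame-local midpoint the
geometry module uses. The RDF normalizes per-bin counts by an ideal-gas
expectation at bulk density ρ = N_water/V_box using *exact* shell volumes
(4π/3)(r₂³−r₁³) rather than 4πr²Δr; this makes g(r) = 1 exact in
expectation for a uniform bath at any bin width, and makes
Σ g·ρ·V_shell recover the mean count inside r_max identically.
r_max must not exceed half the smallest box edge.

## Hydrogen bonds

Criterion: minimum-image r(D,A) ≤ 0.35 nm and ∠H–D–A ≤ 30° — the common
geometric default, declared here because the source analyses name no
cutoff; both numbers are configurable. Bonds are labelled by the
donor/acceptor group pair; CD–CD means the macrocycle's internal bonds
(one host per box). Lifetimes: **continuous** (default) is the mean
uninterrupted-episode length × dt, appropriate for the tens-of-ps episode
scale; a bond spanning the whole window is censored and flagged, a bond
never present has an undefined lifetime (missing, not 0).
**intermittent** integrates the normalized existence autocorrelation up to
its first decay below 1/e. The two definitions differ by design; printed
lifetimes from analyses with unstated estimators validate neither.

## Free-energy estimators

* **TI**: trapezoidal quadrature of per-window ⟨∂H/∂λ⟩ over the
  (possibly nonuniform) λ grid — exact for integrands affine in λ;
  Simpson available for uniform odd-length grids. An optional per-window
  equilibration discard fraction is provided since within-window
  equilibration handling is protocol-dependent.
* **BAR**: per adjacent window pair, ΔG solves the maximum-likelihood
  condition Σ_F f(β(W_F − ΔG) + M) = Σ_R f(β(W_R + ΔG) − M) with f the
  logistic function and M = ln(n_F/n_R), by bracketed Brent root-finding
  (xtol 1e-12). The residual is strictly increasing from −n_R to +n_F, so
  the root is unique; a bracket that cannot be established after
  expansion raises an overlap error. Window results sum exactly.
  Swapping the forward and reverse sample *sets* negates the estimate
  (label-swap antisymmetry); note that negating the work values instead
  does **not** — for equal sample sizes bar(−W_R, −W_F) = +bar(W_F, W_R)
  algebraically, because negated works correspond to an invalid
  Crooks pair, and the test suite asserts the swap form.
* **Standard errors**: seeded bootstrap, 200 resamples, for both
  estimators (estimator-agnostic and reproducible); the bootstrap BAR
  solves all resamples simultaneously by a clamped vectorised Newton
  iteration started from the full-sample root.
* **Cycle**: ΔG_bind = ΔG_decouple(water) − ΔG_decouple(complex).
  Decoupling values are the work to annihilate guest–environment
  interactions, so binding is favourable (negative) when annihilation
  costs more inside the complex. The convention travels in the result
  metadata. No restraint corrections are applied (none are modelled).
* **Dipole**: |Σ qᵢrᵢ| × 48.0321 D/(e·nm). For net-charged groups the
  origin is the |q|-weighted centroid and is part of the reported value.
* Soft-core parameters and the λ schedule are carried as metadata only;
  evaluating λ-coupled energies is the MD engine's job and out of scope.

## Free-energy landscapes

F(x,y) = −kT ln(P/P_max) over a 2D histogram of (RMSD, R_g), so the
global minimum is exactly 0 on the most occupied bin; empty bins stay
masked and are never assigned a finite value. Default 60×60 bins over the
observed range padded 5 %. RMSD uses Kabsch superposition (centroid
removal, SVD rotation with det = +1 enforced) against a user-supplied
reference (typically an energy-minimized structure); RMSD after
superposition is symmetric but not a metric. Basins are occupied-bin
local minima under 4-connectivity; the barrier between two basins is the
minimax ridge level, computed exactly by a union-find sweep over occupied
bins in order of increasing F. No reweighting or smoothing is applied —
the estimator is the raw Boltzmann inversion of the sampled histogram.

## Synthetic generators: what they emulate, what they do not

The generators produce the *stated world* the tests measure against, not
physics:

* `make_cd_ring` builds three regular (optionally jittered/elliptic)
  oxygen rings whose default radii and offsets reproduce the βCD rim
  areas (1.10/0.83/1.32 nm²) and heights (h16 = 0.33, h12 = 0.22 nm); a
  methylated-CD-like variant shrinks both. There are no glucose rings, no
  puckering, no flexibility.
* `make_binding_trajectory` moves a rigid 8-bead, 1.7-nm rod (one end
  tagged as the hydroxyl oxygen) along a scripted path: hold beyond the
  surface threshold, then a 2-frame transit to the center
  (`direct_insert`), or a horizontal dwell on the SHR face followed by a
  cubic-ease upright rotation over 10 frames (`surface_then_insert`,
  mirroring the surface-first pathway reported for the methylated host,
  scaled down from its ~160 ns dwell to desk scale), or `never_bind`.
  Guest-COG noise σ = 0.02 nm. Frames default to dt = 10 ps — an output
  stride chosen as typical, since none is prescribed. The ground-truth
  ledger records the scripted state per frame; the steep easing profile
  keeps the classifier's detected insertion within ±2 frames of the
  scripted one by construction, which is what the recovery tests assert.
* `make_water_bath` places exact shell occupancies via inverse-CDF radial
  sampling (r³ uniform), so uniform density within each shell is exact,
  not approximate. Waters are points (plus one hydrogen in the hydrated
  fixture); there is no water–water structure, so RDFs of these baths
  test normalization, not solvation physics.
* `make_bar_samples` draws forward work ~ N(ΔG + σ²/2kT, σ²) and reverse
  work ~ N(−ΔG + σ²/2kT, σ²), which satisfy the Crooks fluctuation
  theorem exactly in distribution — the canonical validation target for
  BAR. Real decoupling work distributions are neither Gaussian nor
  symmetric between directions.

Consequently a green test establishes estimator/descriptor correctness on
known ground truth, never agreement with any particular published MD
numbers: those derive from 200–370-ns atomistic sampling that a desk-scale
synthetic world cannot and does not reproduce.

## Pipeline

`run-all` executes geometry, shape, hydration, hydrogen bonds, FEL and
(when λ samples are supplied) TI/BAR over the same trajectory and tail
window. Stages inapplicable to the input (no waters, no hydrogen
annotations) are skipped with a warning recorded in the run report; any
stage *failure* aborts the run naming the stage. Configs are validated
strictly — unknown keys are errors, defaults are materialized and echoed —
and every output file is checksummed in the report, so identical config +
inputs + seed yields byte-identical outputs.

## Known limitations

* Orthorhombic boxes only; no triclinic support.
* No binary trajectory formats (XTC/TRR/DCD) in core.
* Group COGs are not PBC-aware (groups must be whole).
* The cavity-volume model is geometric; it is not a probe-based or
  grid-based cavity detection and will not match such methods numerically.
* Interaction-energy time series (vdW/Coulomb decompositions) are only
  block-averaged if supplied; computing them requires a force field and
  is out of scope.
* The intermittent lifetime uses a simple 1/e cutoff on C(t), not a
  fitted kinetic model.
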