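# Methods

## The statistic

Given two structural ensembles of the same protein — each an ordered set
of models sharing one topology — the package renders each ensemble as a
model-based electron-density map and compares the maps residue by residue
with the local density correlation (LDC): the Pearson product-moment
correlation of the two maps' values over the grid points lying within a
fixed radius of the residue's atoms,

LDC(r) = Σ_p (ρ_ref(p) − ⟨ρ_ref⟩)(ρ_alt(p) − ⟨ρ_alt⟩) /
         √( Σ_p (ρ_ref(p) − ⟨ρ_ref⟩)² · Σ_p (ρ_alt(p) − ⟨ρ_alt⟩)² ),

with p running over the region of residue r and the means taken over that
region. The mean-centred form makes the statistic exactly invariant under
ρ → aρ + b (a > 0) applied to either map, so neither the number of models
behind a map nor any overall scale matters; ensemble maps are therefore
plain sums over models with no 1/N normalisation. The statistic is also
exactly symmetric in the two ensembles. Both invariances are enforced by
property tests.

Classification uses strict thresholds: LDC > 0.7 → *strong* (the local
density environments are essentially the same), LDC < 0.5 → *very weak*,
otherwise *weak*. Ties at a threshold fall to the weaker class. Profiles
of near-identical comparisons can be averaged per residue
(`average_profiles`), with classes re-derived from the averaged values.

## Density model

Each atom contributes an isotropic Gaussian carrying `occupancy · Z`
electrons with variance σ² = B/(8π²) + σ_min². Choices, with rationale:

- **Single Gaussian per atom** instead of 4–5-term scattering-factor
  expansions. LDC compares two maps built by the same recipe and is
  invariant to scale; the exact radial profile cancels to first order.
- **σ_min = 0.25 Å** keeps the density representable on the grid when
  B → 0 (a delta spike would alias).
- **Truncation at 5σ** per atom: < 1e-5 relative mass loss. The
  mass-conservation test requires the map integral to match Σ occ·Z
  within 1 % (dominated by grid discretisation, not truncation).
- **Grid spacing 0.3 Å** by default, roughly d_min/4 for a ~1.1 Å
  resolution reference; regions and maps share one grid covering both
  ensembles plus a margin.
- **Hydrogens excluded** by default (small Z, usually unmodelled in X-ray
  ensembles); a flag includes them.
- **Residue regions** are unions of spheres (default radius 1.75 Å, the
  midpoint of the conventional 1.5–2.0 Å atom-radius policy) around the
  residue's atoms in the *mean* structure of the reference ensemble. One
  shared point set is used for both maps; points shared by adjacent
  residues are counted in both residues' regions with equal weight.

## Superposition and diagnostics

All models are independently superposed onto one reference model by the
SVD (Kabsch) solution of the orthogonal Procrustes problem, with the
determinant correction that excludes reflections, pairing atoms by
residue key plus atom name over a Cα selection by default. The fit
rejects < 3 pairs or collinear selections. Cα-RMSD and per-model RMSD
traces reproduce the usual trajectory-vs-reference diagnostic.

Structure factors are computed by direct summation over an orthorhombic
P1 box (bounding box + 5 Å padding), F(h) = Σ occ·Z·exp(−B s²/4)·
exp(2πi h·x_frac) over Friedel-unique reflections with d ≥ d_min
(default 1.5 Å; 1.8 Å in the acceptance run to keep reflection counts
modest at 20 residues × 4 models). The R-factor uses a single
least-squares scale k, R = Σ||Fo| − k|Fc|| / Σ|Fo|. No bulk solvent,
anomalous terms, symmetry, or refinement of any kind: the module is a
coherence diagnostic (R grows with the positional spread of the ensemble
being scored), not a crystallographic engine, and its absolute values are
not comparable to refinement-grade R-factors against experimental data.

## Synthetic ensembles

The generator emulates the *phenomenology* of the protein dynamical
transition, not the physics. Per residue i and temperature T (K):

σ_i(T) = √( σ_h²·(T/300) + 𝟙[i ∈ functional]·σ_a²·s(T) ),
s(T) = 1/(1 + exp(−(T − T_D)/width)),

then a centred moving average of window `corr_window` residues over the
σ_i profile (averaging the amplitude itself; windows truncate at chain
ends) emulates the chain continuity of real loop motions. Each model
displaces every residue rigidly by an isotropic Gaussian draw with
per-component std σ_i(T), plus per-atom jitter of std `sigma_atom`;
models are independent draws (snapshots treated as decorrelated).

Defaults: 30-residue ideal poly-alanine α-helix (φ = −57°, ψ = −47°,
B = 15 Å², built from ideal bond geometry; ~1.5 Å rise, 3.6
residues/turn), functional regions 10–14 and 20–24, σ_h = 0.3 Å,
σ_a = 1.2 Å, T_D = 215 K, width = 5 K, sigma_atom = 0.1 Å,
corr_window = 3, temperatures (200, 210, 220, 230, 300) K with 100
models each. These are the package's canonical study conditions; all
seeds derive deterministically from a single integer.

What the generator does *not* emulate: bonded continuity between
displaced residues (rigid per-residue moves break bonds), side-chain
rotamers, solvent, trajectory autocorrelation, crystal contacts, and
model-building/refinement error. Consequently, passing the planted-truth
tests shows that the pipeline recovers localized positional spread of a
known amplitude — it does not validate force fields or refinement
protocols on real data.

## Edge behaviour of the planted-truth recovery

Two effects soften the LDC contrast at the *boundary* of a planted mobile
block, and are visible in every run:

1. **Smoothing dilution.** The moving average pulls the first/last
   residue of a block toward its static neighbours (for the defaults,
   from σ = 1.20 Å to ≈ 0.89 Å at 230 K).
2. **Region overlap with static density.** The 1.75 Å region of a
   boundary residue contains density from the adjacent static residue,
   which correlates perfectly between the two maps, and the Pearson form
   is insensitive to width-only broadening about a shared centre.

Measured at the default conditions over 20 seeds, interior functional
residues read LDC ≈ 0.58–0.65 (weak) while block-edge residues read
≈ 0.74–0.85 (strong) against a far-residue baseline of ≥ 0.98. The
distance-based diagnostics (RMSF, RMSD) see the planted amplitude at
those edge residues; the density correlation partially does not. This is
an intrinsic property of region-based density correlation at block
boundaries, not a sampling artefact — interpretations of per-residue LDC
profiles on real ensembles should treat the first/last residue of a
mobile segment as attenuated. The unit suite asserts the recoverable
ground truth (interior residues non-strong, residues beyond the halo
strong); one end-to-end acceptance test asserts the stricter
every-functional-residue form and documents this limit by failing.

## Numerical choices and degenerate inputs

- LDC raises on zero variance over a region (correlation undefined)
  rather than returning 0, and on grid mismatch; values are clipped to
  [−1, 1] against rounding.
- Empty regions (radius too small for the grid) are errors, as are
  residues absent from the reference.
- Kabsch collinearity is detected via the second singular value of the
  centred coordinate matrix (< 1e-8 relative).
- PDB writing validates fixed-width field ranges and fails rather than
  truncating; reading validates coordinate records line by line and
  reports the first offending line number. Alternate locations keep
  'A'/blank; waters and hetero groups are excluded by default.
- Ensembles validate topology congruence on construction, naming the
  first divergent residue.

## Problem sizes

Tests and the acceptance script run the full default study (30 residues,
100 models, 0.3 Å grids, five temperatures, 20 seeds for the stochastic
checks; structure factors at 20 residues, 4 models, d_min 1.8 Å). These
sizes resolve every planted effect with comfortable statistical margins
while keeping a complete run in minutes on one core.
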