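# densemble

Local density correlation analysis of multi-model protein structure
ensembles.

A single crystal structure hides most of a protein's conformational
repertoire. When many models of the same protein are available — snapshots
of a molecular-dynamics trajectory, the outputs of multi-start simulated
annealing refinement, or independently solved crystal structures in
different space groups — the *spread* of those models carries information
about which residues move, and whether those motions are the functionally
relevant ones that switch on above the protein dynamical transition
temperature (T_D ≈ 215 K for hydrated proteins).

`densemble` quantifies that spread residue by residue. Two ensembles are
superposed into a common frame, each is rendered as a model-based
electron-density map (every atom an isotropic Gaussian of weight *Z*,
variance σ² = B/8π² + σ_min², all models summed), and for each residue the
**local density correlation**

```
LDC = Σ (ρ_ref − ⟨ρ_ref⟩)(ρ_alt − ⟨ρ_alt⟩) / sqrt( Σ(ρ_ref − ⟨ρ_ref⟩)² · Σ(ρ_alt − ⟨ρ_alt⟩)² )
```

is the Pearson correlation of the two maps over the grid points within a
small radius (default 1.75 Å) of the residue's atoms. LDC is invariant to
the scale of either map — ensembles of different sizes compare directly,
with no 1/N normalisation — and symmetric in the two ensembles. Residues
with LDC > 0.7 are classed *strong* (locally similar), below 0.5
*very weak* (strong disorder mismatch), otherwise *weak*.

Around this statistic the package provides:

- multi-model PDB I/O (MODEL/ENDMDL framing) with topology validation
  (`densemble.structures`),
- Kabsch least-squares superposition and Cα-RMSD traces
  (`densemble.superposition`),
- Gaussian density synthesis on a shared orthogonal grid
  (`densemble.density`),
- per-residue LDC, profile averaging and classification (`densemble.ldc`),
- direct-summation structure factors and a scaled R-factor as an
  ensemble-vs-reference diagnostic (`densemble.sfactors`),
- a synthetic-ensemble generator that plants harmonic + anharmonic
  disorder with a sigmoidal dynamical transition at T_D, standing in for
  MD and crystallographic ensembles (`densemble.synthetic`),
- a thin CLI (`densemble simulate|compare|rmsd|rfactor`) over the library
  (`densemble.cli`, `densemble.pipeline`).

## Worked example

Generate 100-model ensembles of a 30-residue helix whose residues 10–14
and 20–24 acquire anharmonic motion above T_D = 215 K, then compare the
200 K ensemble against the 230 K ensemble (`examples/02_compare_ldc.py`):

```python
from densemble import DisorderSpec, build_toy_structure, generate_ensemble
from densemble.pipeline import compare_ensembles

spec = DisorderSpec()
ref = build_toy_structure(spec.n_residues)
cold = generate_ensemble(ref, spec, 200.0, n_models=100, seed=11)
warm = generate_ensemble(ref, spec, 230.0, n_models=100, seed=13)
result = compare_ensembles(cold, warm)
```

This prints (abridged):

```
res  ldc    class      planted
  8  0.979  strong
  9  0.871  strong
 10  0.751  strong     functional
 11  0.633  weak       functional
 12  0.581  weak       functional
 13  0.618  weak       functional

summary: 24 strong / 6 weak / 0 very weak of 30 residues
```

The planted anharmonic residues drop out of the strong class while the
rest of the chain stays near LDC ≈ 1; the first/last residue of each
mobile block sits in between because chain smoothing and density overlap
with static neighbours dilute the contrast there (see
`docs/methods.md`). The same comparison at 200 K vs 210 K — both below
T_D — classes all 30 residues strong.

The RMSD counterpart (`examples/03_rmsd_transition.py`) shows the
transition directly:

```
  200 K   mean  0.51 A   min  0.42   max  0.59
  210 K   mean  0.74 A   min  0.59   max  0.91
  220 K   mean  1.05 A   min  0.81   max  1.36
  230 K   mean  1.16 A   min  0.92   max  1.45
  300 K   mean  1.24 A   min  0.95   max  1.57
```

The 210→220 K step exceeds the 200→210 K step: the anharmonic amplitude
switches on across T_D, and the 230 K ensemble already moves like the
300 K one.

The same workflow runs from the shell on any multi-model PDB files:

```sh
densemble simulate --n-residues 30 --temps 200,210,220,230,300 \
    --n-models 100 --seed 1 --out sim/
densemble compare --reference sim/ensemble_200K.pdb \
    --alt sim/ensemble_230K.pdb --out ldc/
```

## Limitations

Maps use a single Gaussian per atom rather than tabulated scattering
factors, grids are Cartesian with no crystal symmetry or bulk solvent, and
the structure-factor module is a diagnostic, not a refinement engine.
`docs/methods.md` documents the model, its defaults, and the known edge
effects of the region-based correlation.
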