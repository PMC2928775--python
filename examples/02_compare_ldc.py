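"""Per-residue local density correlation across the dynamical transition.

Compares a 200 K ensemble (harmonic motions only) against a 230 K ensemble
(anharmonic motions active in the functional regions).  Each ensemble is
superposed onto the reference, rendered as a summed electron-density map,
and correlated residue by residue over grid points within 1.75 Å of the
residue's atoms.  Residues with LDC > 0.7 are "strong" (locally similar);
the planted functional regions drop well below that.
"""

from densemble import DisorderSpec, build_toy_structure, generate_ensemble
from densemble.pipeline import compare_ensembles

spec = DisorderSpec()
ref = build_toy_structure(spec.n_residues)
cold = generate_ensemble(ref, spec, 200.0, n_models=100, seed=11)
warm = generate_ensemble(ref, spec, 230.0, n_models=100, seed=13)

result = compare_ensembles(cold, warm)
print("res  ldc    class      planted")
for e in result.profile.entries:
    i = e.residue_key[1]
    mark = "functional" if spec.is_functional(i) else ""
    print(f"{i:3d}  {e.ldc:5.3f}  {e.klass:9s}  {mark}")

c = result.counts
print(f"\nsummary: {c.n_strong} strong / {c.n_weak} weak / "
      f"{c.n_very_weak} very weak of {c.n_total} residues")
print("Low-LDC residues coincide with the planted anharmonic regions;")
print("flanking residues are diluted by chain smoothing and density overlap.")
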