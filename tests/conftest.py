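import pytest

from densemble import (DisorderSpec, Ensemble, build_toy_structure,
                       generate_ensemble)


@pytest.fixture(scope="session")
def helix10():
    return build_toy_structure(10)


@pytest.fixture(scope="session")
def helix10_ensemble(helix10):
    return Ensemble(models=[helix10], label="helix10")


@pytest.fixture(scope="session")
def small_spec():
    """Hard planted displacement on residues 6-9 of a 16-mer, no smoothing.

    Sized so that a 40-model pair resolves the planted block decisively on a
    0.4 A grid in well under a second.
    """
    return DisorderSpec(n_residues=16, functional_regions=((6, 9),),
                        sigma_h=0.05, sigma_a=2.5, t_d=215.0, width=5.0,
                        sigma_atom=0.02, corr_window=1)


@pytest.fixture(scope="session")
def small_planted_pair(small_spec):
    ref = build_toy_structure(small_spec.n_residues)
    cold = generate_ensemble(ref, small_spec, 200.0, n_models=40, seed=7)
    hot = generate_ensemble(ref, small_spec, 300.0, n_models=40, seed=8)
    return cold, hot


def random_model(rng, n_atoms=10):
    """Random Cα-only cloud usable as a StructureModel for fitting tests."""
    from densemble import AtomRecord, StructureModel
    atoms = [AtomRecord(serial=i + 1, name="CA", element="C",
                        residue_index=i + 1, residue_name="ALA", chain_id="A",
                        position=rng.uniform(-10, 10, size=3),
                        occupancy=1.0, b_factor=15.0)
             for i in range(n_atoms)]
    return StructureModel(atoms=atoms)
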