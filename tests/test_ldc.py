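"""Local density correlation: oracle equivalence, invariances, classification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import pearsonr, spearmanr

from densemble import (Ensemble, StructureModel, AtomRecord, ldc, ldc_profile,
                       average_profiles, classify_summary, residue_region,
                       make_grid)
from densemble.density import DensityMap, GridSpec
from densemble.ldc import LDCEntry, LDCProfile, ResidueRegion, classify
from densemble.pipeline import compare_ensembles


def _map_pair(rng, shape=(6, 6, 6)):
    grid = GridSpec(origin=(0, 0, 0), spacing=0.5, shape=shape)
    a = DensityMap(grid=grid, values=rng.uniform(0, 10, size=shape))
    b = DensityMap(grid=grid, values=rng.uniform(0, 10, size=shape))
    return grid, a, b


def _region(grid, indices, key=("A", 1), radius=1.75):
    return ResidueRegion(residue_key=key, grid_indices=np.asarray(indices),
                         radius=radius)


def _single_atom_ens(position=(2.0, 2.0, 2.0), b=15.0):
    atom = AtomRecord(serial=1, name="CA", element="C", residue_index=1,
                      residue_name="ALA", chain_id="A",
                      position=np.asarray(position, float), b_factor=b)
    return Ensemble(models=[StructureModel(atoms=[atom])])


def test_region_matches_exhaustive_grid_scan():
    ens = _single_atom_ens((2.05, 2.2, 1.9))
    grid = GridSpec(origin=(0, 0, 0), spacing=0.5, shape=(9, 9, 9))
    region = residue_region(("A", 1), ens, grid, radius=1.75)
    pts = grid.points()
    center = ens.models[0].atoms[0].position
    brute = np.where(np.linalg.norm(pts - center, axis=1) <= 1.75)[0]
    np.testing.assert_array_equal(np.sort(region.grid_indices), brute)


def test_tiny_radius_mid_cell_gives_empty_region_error():
    ens = _single_atom_ens((2.5, 2.5, 2.5))   # mid-cell on a 1 A grid
    grid = GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(6, 6, 6))
    with pytest.raises(ValueError, match="empty region"):
        residue_region(("A", 1), ens, grid, radius=0.1)


def test_adjacent_residue_regions_may_overlap(helix10_ensemble):
    grid = make_grid(helix10_ensemble, spacing=0.5, margin=3.0)
    r3 = residue_region(("A", 3), helix10_ensemble, grid, radius=2.0)
    r4 = residue_region(("A", 4), helix10_ensemble, grid, radius=2.0)
    union = np.union1d(r3.grid_indices, r4.grid_indices)
    assert len(union) >= max(r3.n_points, r4.n_points)
    assert len(np.intersect1d(r3.grid_indices, r4.grid_indices)) > 0


def test_self_correlation_is_exactly_one_and_scale_free():
    rng = np.random.default_rng(0)
    grid, a, _ = _map_pair(rng)
    region = _region(grid, np.arange(40))
    assert ldc(a, a, region) == 1.0
    scaled = DensityMap(grid=grid, values=3.7 * a.values)
    assert ldc(a, scaled, region) == 1.0


def test_perfect_anticorrelation():
    grid = GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(3, 1, 1))
    a = DensityMap(grid=grid, values=np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
    b = DensityMap(grid=grid, values=np.array([3.0, 2.0, 1.0]).reshape(3, 1, 1))
    assert ldc(a, b, _region(grid, [0, 1, 2])) == pytest.approx(-1.0, abs=1e-15)


def test_matches_textbook_correlation_on_random_regions():
    rng = np.random.default_rng(1)
    for _ in range(100):
        grid, a, b = _map_pair(rng, shape=(8, 8, 8))
        n = rng.integers(10, 500)
        idx = rng.choice(grid.n_points, size=n, replace=False)
        region = _region(grid, idx)
        expected = pearsonr(a.values.ravel()[idx], b.values.ravel()[idx]).statistic
        assert ldc(a, b, region) == pytest.approx(expected, rel=1e-12, abs=1e-12)


def test_symmetry_is_exact():
    rng = np.random.default_rng(2)
    for _ in range(20):
        grid, a, b = _map_pair(rng)
        region = _region(grid, rng.choice(grid.n_points, 30, replace=False))
        assert ldc(a, b, region) == ldc(b, a, region)


@given(a=st.floats(min_value=1e-3, max_value=1e3),
       b=st.floats(min_value=-100, max_value=100))
@settings(max_examples=50, deadline=None)
def test_affine_invariance(a, b):
    rng = np.random.default_rng(3)
    grid, m1, m2 = _map_pair(rng)
    region = _region(grid, np.arange(50))
    base = ldc(m1, m2, region)
    rescaled = DensityMap(grid=grid, values=a * m2.values + b)
    assert ldc(m1, rescaled, region) == pytest.approx(base, abs=1e-12)


def test_zero_variance_raises_not_zero():
    grid = GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(4, 4, 4))
    flat = DensityMap(grid=grid, values=np.full((4, 4, 4), 2.0))
    rng = np.random.default_rng(4)
    noisy = DensityMap(grid=grid, values=rng.uniform(size=(4, 4, 4)))
    with pytest.raises(ValueError, match="variance"):
        ldc(flat, noisy, _region(grid, np.arange(10)))


def test_grid_mismatch_rejected():
    g1 = GridSpec(origin=(0, 0, 0), spacing=1.0, shape=(4, 4, 4))
    g2 = GridSpec(origin=(0, 0, 0), spacing=0.5, shape=(4, 4, 4))
    a = DensityMap(grid=g1, values=np.ones((4, 4, 4)))
    b = DensityMap(grid=g2, values=np.ones((4, 4, 4)))
    with pytest.raises(ValueError, match="grid"):
        ldc(a, b, _region(g1, [0, 1, 2]))


def test_profile_against_self_is_all_strong(small_planted_pair):
    cold, _ = small_planted_pair
    profile = ldc_profile(cold, cold, radius=1.75, spacing=0.5)
    assert len(profile.entries) == 16
    assert all(e.ldc == 1.0 and e.klass == "strong" for e in profile.entries)


def test_planted_displacement_is_localised(small_spec, small_planted_pair):
    """Displaced residues read non-strong; residues beyond the region-overlap
    halo stay strong."""
    cold, hot = small_planted_pair
    result = compare_ensembles(cold, hot, spacing=0.4)
    vals = {e.residue_key[1]: e.ldc for e in result.profile.entries}
    planted = set(small_spec.functional_residues())
    for i in planted:
        assert vals[i] <= 0.7, f"residue {i} should be non-strong, ldc={vals[i]}"
    for i in set(range(1, 17)) - planted - {5, 10}:   # halo: bonded neighbours
        assert vals[i] > 0.7, f"residue {i} should be strong, ldc={vals[i]}"


def test_profile_robust_to_region_radius(small_planted_pair):
    cold, hot = small_planted_pair
    p_small = compare_ensembles(cold, hot, radius=1.5, spacing=0.4).profile
    p_large = compare_ensembles(cold, hot, radius=2.0, spacing=0.4).profile
    rho, _ = spearmanr(p_small.values(), p_large.values())
    assert rho > 0.9


def _profile_from_values(values):
    entries = [LDCEntry(residue_key=("A", i + 1), residue_name="ALA",
                        ldc=v, n_grid_points=10) for i, v in enumerate(values)]
    return LDCProfile(entries=entries, skipped=[])


def test_average_profiles_idempotent_and_threshold_boundary():
    p = _profile_from_values([0.9, 0.3, -0.2])
    avg = average_profiles([p, p])
    np.testing.assert_array_equal(avg.values(), p.values())
    boundary = average_profiles([_profile_from_values([0.6]),
                                 _profile_from_values([0.8])])
    assert boundary.entries[0].ldc == pytest.approx(0.7)
    assert boundary.entries[0].klass == "weak"     # strict '>' for strong
    with pytest.raises(ValueError):
        average_profiles([])
    with pytest.raises(ValueError, match="residue"):
        average_profiles([p, _profile_from_values([0.9, 0.3])])


def test_classification_thresholds_and_summary():
    assert classify(0.71) == "strong"
    assert classify(0.7) == "weak"
    assert classify(0.5) == "weak"
    assert classify(0.49) == "very_weak"
    all_one = _profile_from_values([1.0] * 129)
    c = classify_summary(all_one)
    assert (c.n_strong, c.n_weak, c.n_very_weak, c.n_total) == (129, 0, 0, 129)
    mixed = classify_summary(_profile_from_values([0.9, 0.6, 0.4]))
    assert (mixed.n_strong, mixed.n_weak, mixed.n_very_weak) == (1, 1, 1)


@given(st.lists(st.floats(min_value=-1, max_value=1), min_size=1, max_size=60))
@settings(max_examples=50, deadline=None)
def test_summary_counts_partition_total(values):
    counts = classify_summary(_profile_from_values(values))
    assert counts.n_strong + counts.n_weak + counts.n_very_weak == len(values)


def test_ldc_declines_with_planted_amplitude(small_spec):
    """Per-residue LDC is non-increasing (in expectation) in the planted
    displacement amplitude of that residue."""
    from densemble import build_toy_structure, generate_ensemble
    from dataclasses import replace
    ref = build_toy_structure(16)
    amplitudes = [0.2, 0.8, 2.0]
    mid = 8
    means = []
    for amp in amplitudes:
        vals = []
        for seed in range(20):
            spec = replace(small_spec, sigma_a=amp)
            cold = generate_ensemble(ref, spec, 200.0, n_models=15, seed=seed)
            hot = generate_ensemble(ref, spec, 300.0, n_models=15, seed=500 + seed)
            res = compare_ensembles(cold, hot, spacing=0.6)
            vals.append(res.profile.by_key()[("A", mid)].ldc)
        means.append(np.mean(vals))
    assert means[0] > means[1] > means[2]
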