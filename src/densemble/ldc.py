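"""Per-residue local density correlation (LDC) between two ensemble maps.

The LDC of a residue is the Pearson product-moment correlation of two
electron-density maps evaluated over the grid points lying within a small
radius (1.5–2.0 Å per atom, default 1.75 Å) of that residue's atoms.  The
statistic is invariant to affine rescaling of either map, so neither
absolute electron counts nor the number of models behind each map affect
it, and it is symmetric in the two ensembles.

Classification follows the convention for ensemble similarity:
LDC > 0.7 → "strong" (the residue's local density is essentially the same
in both ensembles); LDC < 0.5 → "very_weak" (strong local disorder
mismatch); anything between → "weak".  Ties at the thresholds fall to the
weaker class.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil, floor

import numpy as np
import pandas as pd

from .density import DensityMap, GridSpec, make_grid, render_ensemble_map
from .structures import Ensemble

__all__ = ["ResidueRegion", "LDCEntry", "LDCProfile", "ClassCounts",
           "residue_region", "ldc", "ldc_profile", "average_profiles",
           "classify_summary", "classify",
           "STRONG_THRESHOLD", "VERY_WEAK_THRESHOLD", "DEFAULT_RADIUS"]

STRONG_THRESHOLD = 0.7
VERY_WEAK_THRESHOLD = 0.5
DEFAULT_RADIUS = 1.75   # Å; midpoint of the 1.5–2.0 Å atom-radius policy


def classify(value: float) -> str:
    if value > STRONG_THRESHOLD:
        return "strong"
    if value < VERY_WEAK_THRESHOLD:
        return "very_weak"
    return "weak"


@dataclass(frozen=True)
class ResidueRegion:
    """Grid points within ``radius`` of any atom of one residue.

    ``grid_indices`` are flat (C-order) indices into the map's value array.
    The region is built once, from the reference ensemble's mean
    coordinates, and the same point set is used in both maps.
    """

    residue_key: tuple[str, int]
    grid_indices: np.ndarray
    radius: float

    @property
    def n_points(self) -> int:
        return len(self.grid_indices)


def residue_region(residue_key: tuple[str, int], ens_ref: Ensemble,
                   grid: GridSpec, radius: float = DEFAULT_RADIUS,
                   include_hydrogens: bool = False) -> ResidueRegion:
    """Union of grid points within ``radius`` of the residue's atoms.

    Atom positions are taken from the mean structure of the reference
    ensemble, which keeps the region stable against individual-model noise.
    """
    if radius <= 0:
        raise ValueError(f"region radius must be positive, got {radius}")
    mean = ens_ref.mean_model()
    if residue_key not in mean.residue_segments:
        raise KeyError(f"residue {residue_key} absent from reference ensemble")
    atoms = [a for a in mean.residue_atoms(residue_key)
             if include_hydrogens or not a.is_hydrogen]
    origin = np.array(grid.origin)
    h = grid.spacing
    flat: list[np.ndarray] = []
    for atom in atoms:
        c = atom.position
        lo = [max(0, ceil((c[i] - radius - origin[i]) / h - 1e-12)) for i in range(3)]
        hi = [min(grid.shape[i] - 1, floor((c[i] + radius - origin[i]) / h + 1e-12))
              for i in range(3)]
        if any(lo[i] > hi[i] for i in range(3)):
            continue
        ax = [origin[i] + h * np.arange(lo[i], hi[i] + 1) - c[i] for i in range(3)]
        r2 = (ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
              + ax[2][None, None, :] ** 2)
        ii, jj, kk = np.nonzero(r2 <= radius * radius)
        flat.append(np.ravel_multi_index(
            (ii + lo[0], jj + lo[1], kk + lo[2]), grid.shape))
    if not flat:
        raise ValueError(f"residue {residue_key}: empty region (radius {radius} Å "
                         f"too small for grid spacing {h} Å)")
    indices = np.unique(np.concatenate(flat))
    if indices.size == 0:
        raise ValueError(f"residue {residue_key}: empty region")
    return ResidueRegion(residue_key=residue_key, grid_indices=indices, radius=radius)


def ldc(map_ref: DensityMap, map_alt: DensityMap, region: ResidueRegion) -> float:
    """Pearson correlation of the two maps over the region's grid points.

    Raises if either map has zero variance over the region — the
    correlation is undefined there and silently returning 0 would fake a
    classification.
    """
    if map_ref.grid != map_alt.grid:
        raise ValueError("maps are on different grids")
    if region.n_points == 0:
        raise ValueError("empty region")
    x = map_ref.values.ravel()[region.grid_indices]
    y = map_alt.values.ravel()[region.grid_indices]
    x = x - x.mean()
    y = y - y.mean()
    vx = float(np.dot(x, x))
    vy = float(np.dot(y, y))
    if vx == 0.0 or vy == 0.0:
        raise ValueError(f"zero density variance over region of residue "
                         f"{region.residue_key}; correlation undefined")
    r = float(np.dot(x, y)) / np.sqrt(vx * vy)
    return float(min(1.0, max(-1.0, r)))


@dataclass(frozen=True)
class LDCEntry:
    residue_key: tuple[str, int]
    residue_name: str
    ldc: float
    n_grid_points: int

    @property
    def klass(self) -> str:
        return classify(self.ldc)


@dataclass
class LDCProfile:
    """Ordered per-residue LDC values with classification."""

    entries: list[LDCEntry]
    skipped: list[tuple[str, int]]          # residues present in only one ensemble

    def values(self) -> np.ndarray:
        return np.array([e.ldc for e in self.entries])

    def residue_keys(self) -> list[tuple[str, int]]:
        return [e.residue_key for e in self.entries]

    def by_key(self) -> dict[tuple[str, int], LDCEntry]:
        return {e.residue_key: e for e in self.entries}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chain": [e.residue_key[0] for e in self.entries],
            "residue_index": [e.residue_key[1] for e in self.entries],
            "residue_name": [e.residue_name for e in self.entries],
            "ldc": [e.ldc for e in self.entries],
            "n_grid_points": [e.n_grid_points for e in self.entries],
            "class": [e.klass for e in self.entries],
        })

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


def ldc_profile(ens_ref: Ensemble, ens_alt: Ensemble,
                radius: float = DEFAULT_RADIUS, spacing: float = 0.3,
                grid: GridSpec | None = None,
                include_hydrogens: bool = False) -> LDCProfile:
    """Per-residue LDC between two ensembles already in a common frame.

    Both ensembles are rendered on one shared grid; residues present in
    only one ensemble are skipped (reported, not errored).  One entry per
    shared residue, in reference chain order.
    """
    if grid is None:
        grid = make_grid([ens_ref, ens_alt], spacing=spacing,
                         margin=radius + 2.0)
    map_ref = render_ensemble_map(ens_ref, grid, include_hydrogens)
    map_alt = render_ensemble_map(ens_alt, grid, include_hydrogens)
    keys_ref = ens_ref.residue_keys()
    keys_alt = set(ens_alt.residue_keys())
    shared = [k for k in keys_ref if k in keys_alt]
    skipped = ([k for k in keys_ref if k not in keys_alt]
               + [k for k in ens_alt.residue_keys() if k not in set(keys_ref)])
    if not shared:
        raise ValueError("ensembles share no residues")
    names = {a.residue_key: a.residue_name for a in ens_ref.models[0].atoms}
    entries = []
    for key in shared:
        region = residue_region(key, ens_ref, grid, radius, include_hydrogens)
        value = ldc(map_ref, map_alt, region)
        entries.append(LDCEntry(residue_key=key, residue_name=names[key],
                                ldc=value, n_grid_points=region.n_points))
    return LDCProfile(entries=entries, skipped=skipped)


def average_profiles(profiles: list[LDCProfile]) -> LDCProfile:
    """Arithmetic per-residue mean of several profiles.

    Used when two ensembles give near-identical profiles (e.g. both below
    the dynamical transition) and a single averaged profile represents
    them; classes are re-derived from the averaged values.
    """
    if not profiles:
        raise ValueError("cannot average an empty list of profiles")
    keys = profiles[0].residue_keys()
    for p in profiles[1:]:
        if p.residue_keys() != keys:
            raise ValueError("profiles cover different residue sets")
    entries = []
    for i, key in enumerate(keys):
        vals = [p.entries[i].ldc for p in profiles]
        first = profiles[0].entries[i]
        entries.append(LDCEntry(residue_key=key, residue_name=first.residue_name,
                                ldc=float(np.mean(vals)),
                                n_grid_points=first.n_grid_points))
    skipped = sorted({k for p in profiles for k in p.skipped})
    return LDCProfile(entries=entries, skipped=skipped)


@dataclass(frozen=True)
class ClassCounts:
    n_strong: int
    n_weak: int
    n_very_weak: int

    @property
    def n_total(self) -> int:
        return self.n_strong + self.n_weak + self.n_very_weak


def classify_summary(profile: LDCProfile) -> ClassCounts:
    """Counts of strong / weak / very-weak residues; they partition the total."""
    if not profile.entries:
        raise ValueError("empty profile")
    classes = [e.klass for e in profile.entries]
    return ClassCounts(n_strong=classes.count("strong"),
                       n_weak=classes.count("weak"),
                       n_very_weak=classes.count("very_weak"))
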