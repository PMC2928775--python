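"""Structure-factor amplitudes by direct summation, and the R-factor.

This is a deliberately simplified diagnostic, not a refinement engine: the
model (or ensemble, summed without 1/N scaling) is placed in an orthogonal
P1 box, and

    F(h) = Σ_atoms  occ · Z · exp(−B·s²/4) · exp(2πi h·x_frac),   s = 1/d(h)

is evaluated over all unique reflections with d ≥ d_min.  Z replaces the
full scattering-factor curve, consistent with the single-Gaussian atom
model used for real-space maps.  No bulk solvent, no anomalous terms.

The R-factor between two amplitude sets uses a single least-squares scale:
R = Σ| |Fo| − k|Fc| | / Σ|Fo| with k minimizing Σ(|Fo| − k|Fc|)².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, StructureModel

__all__ = ["ReflectionSet", "make_cell", "calc_structure_factors", "r_factor",
           "write_reflections", "DEFAULT_D_MIN", "DEFAULT_CELL_PADDING"]

DEFAULT_D_MIN = 1.5          # Å
DEFAULT_CELL_PADDING = 5.0   # Å per axis around the bounding box


@dataclass
class ReflectionSet:
    """Amplitudes on an integer (h,k,l) lattice of an orthorhombic cell."""

    cell: tuple[float, float, float]      # a, b, c in Å, 90° angles
    d_min: float
    hkl: np.ndarray                       # (n, 3) int
    amplitudes: np.ndarray                # (n,) float, >= 0

    def __post_init__(self):
        self.hkl = np.asarray(self.hkl, dtype=int)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.hkl) != len(self.amplitudes):
            raise ValueError("hkl and amplitude lengths differ")
        if np.any(~np.isfinite(self.amplitudes)) or np.any(self.amplitudes < 0):
            raise ValueError("amplitudes must be finite and non-negative")
        if np.any(np.all(self.hkl == 0, axis=1)):
            raise ValueError("(0,0,0) must be excluded")

    @property
    def n_reflections(self) -> int:
        return len(self.hkl)


def make_cell(ens: Ensemble, padding: float = DEFAULT_CELL_PADDING,
              ) -> tuple[tuple[float, float, float], np.ndarray]:
    """Orthogonal P1 box (bounding box + padding) and the origin shift.

    Returns ``(cell_lengths, shift)`` with ``shift`` the translation that
    moves the ensemble into the box's positive octant.
    """
    coords = np.concatenate([m.coordinates() for m in ens.models])
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    cell = tuple(float(v) for v in (hi - lo + 2 * padding))
    shift = padding - lo
    return cell, shift


def _unique_hkl(cell: tuple[float, float, float], d_min: float) -> np.ndarray:
    """Friedel-unique reflections with d >= d_min, (0,0,0) excluded."""
    a, b, c = cell
    smax2 = 1.0 / (d_min * d_min)
    hmax = int(np.floor(a / d_min))
    kmax = int(np.floor(b / d_min))
    lmax = int(np.floor(c / d_min))
    h, k, l = np.meshgrid(np.arange(0, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    s2 = (hkl[:, 0] / a) ** 2 + (hkl[:, 1] / b) ** 2 + (hkl[:, 2] / c) ** 2
    keep = s2 <= smax2 + 1e-12
    # keep one hemisphere: h>0, or h==0 & k>0, or h==k==0 & l>0
    hemi = ((hkl[:, 0] > 0)
            | ((hkl[:, 0] == 0) & (hkl[:, 1] > 0))
            | ((hkl[:, 0] == 0) & (hkl[:, 1] == 0) & (hkl[:, 2] > 0)))
    return hkl[keep & hemi]


def calc_structure_factors(model_or_ens: Ensemble | StructureModel,
                           cell: tuple[float, float, float] | None = None,
                           d_min: float = DEFAULT_D_MIN,
                           shift: np.ndarray | None = None) -> ReflectionSet:
    """Direct-summation amplitudes |F(h)| of a model or ensemble.

    Ensembles sum over all models without 1/N scaling (only the overall
    scale changes, and the R-factor fits a scale anyway).  With
    ``cell=None`` a padded P1 bounding box is built and atoms are shifted
    into it; a shifted origin only changes phases, never amplitudes.
    """
    if isinstance(model_or_ens, StructureModel):
        ens = Ensemble(models=[model_or_ens])
    else:
        ens = model_or_ens
    if d_min <= 0:
        raise ValueError(f"d_min must be positive, got {d_min}")
    if cell is None:
        cell, shift = make_cell(ens)
    if shift is None:
        shift = np.zeros(3)
    abc = np.asarray(cell, dtype=float)
    hkl = _unique_hkl(tuple(abc), d_min)
    s2 = ((hkl[:, 0] / abc[0]) ** 2 + (hkl[:, 1] / abc[1]) ** 2
          + (hkl[:, 2] / abc[2]) ** 2)
    F = np.zeros(len(hkl), dtype=complex)
    chunk = 128
    for model in ens.models:
        coords = model.coordinates() + shift
        if np.any(coords < 0) or np.any(coords > abc):
            bad = np.where(np.any((coords < 0) | (coords > abc), axis=1))[0][0]
            raise ValueError(f"atom {model.atoms[bad].name} of residue "
                             f"{model.atoms[bad].residue_key} lies outside the cell")
        frac = coords / abc
        w = np.array([a.occupancy * a.atomic_number for a in model.atoms])
        bfac = np.array([a.b_factor for a in model.atoms])
        for start in range(0, len(frac), chunk):
            f = frac[start:start + chunk]
            dw = np.exp(-np.outer(s2, bfac[start:start + chunk]) / 4.0)
            phase = 2.0 * np.pi * (hkl @ f.T)
            F += (w[start:start + chunk] * dw * np.exp(1j * phase)).sum(axis=1)
    return ReflectionSet(cell=tuple(abc), d_min=d_min, hkl=hkl,
                         amplitudes=np.abs(F))


def r_factor(f_obs: ReflectionSet, f_calc: ReflectionSet) -> float:
    """Scaled crystallographic R-factor between two amplitude sets."""
    if f_obs.hkl.shape != f_calc.hkl.shape or not np.array_equal(f_obs.hkl, f_calc.hkl):
        raise ValueError("reflection index sets differ")
    fo, fc = f_obs.amplitudes, f_calc.amplitudes
    denom = fo.sum()
    if denom == 0:
        raise ValueError("all observed amplitudes are zero")
    fc2 = float(np.dot(fc, fc))
    k = float(np.dot(fo, fc)) / fc2 if fc2 > 0 else 0.0
    return float(np.abs(fo - k * fc).sum() / denom)


def write_reflections(refl: ReflectionSet, path) -> None:
    with open(path, "w") as fh:
        fh.write("h\tk\tl\tamplitude\n")
        for (h, k, l), amp in zip(refl.hkl, refl.amplitudes):
            fh.write(f"{h}\t{k}\t{l}\t{amp:.6f}\n")
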