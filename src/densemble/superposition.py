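"""Rigid-body least-squares superposition (Kabsch) and RMSD diagnostics.

Every ensemble is superposed onto a single reference model before maps are
synthesized, so that all density comparisons happen in one Cartesian frame.
The fit minimizes the RMSD over a selected atom set (Cα by default, matching
the convention that ensemble RMSDs are reported over Cα atoms only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, StructureModel

__all__ = ["FitResult", "kabsch_fit", "apply_fit", "superpose_ensemble",
           "rmsd_ca", "rmsd_trace", "write_rmsd_trace"]


@dataclass(frozen=True)
class FitResult:
    """A proper rigid transform x ↦ R·x + t and the RMSD it achieves."""

    rotation: np.ndarray        # 3x3, det = +1
    translation: np.ndarray     # Å
    rmsd: float                 # Å, over the atoms used for the fit
    n_atoms_used: int

    def transform(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def _paired_coords(mobile: StructureModel, reference: StructureModel,
                   selection: tuple[str, ...] | None) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates paired by (residue key, atom name), reference order."""
    def index(model: StructureModel) -> dict[tuple, np.ndarray]:
        out = {}
        for a in model.atoms:
            if selection is None or a.name in selection:
                out[(a.chain_id, a.residue_index, a.name)] = a.position
        return out

    mob = index(mobile)
    ref = index(reference)
    keys = [k for k in ref if k in mob]
    if not keys:
        raise ValueError("no paired atoms between mobile and reference for "
                         f"selection {selection}")
    return (np.array([mob[k] for k in keys]), np.array([ref[k] for k in keys]))


def kabsch_fit(mobile: StructureModel, reference: StructureModel,
               selection: tuple[str, ...] | None = ("CA",)) -> FitResult:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Atoms are paired by residue key plus atom name over ``selection``
    (``None`` pairs all atoms).  Uses the SVD solution of the orthogonal
    Procrustes problem with the determinant correction that excludes
    reflections.  Requires at least 3 non-collinear pairs.
    """
    P, Q = _paired_coords(mobile, reference, selection)
    n = len(P)
    if n < 3:
        raise ValueError(f"need at least 3 paired atoms, got {n}")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    sv = np.linalg.svd(P0, compute_uv=False)
    if sv[1] < 1e-8 * max(sv[0], 1.0):
        raise ValueError("selection is collinear; rotation is underdetermined")
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    return FitResult(rotation=R, translation=t, rmsd=rmsd, n_atoms_used=n)


def apply_fit(model: StructureModel, fit: FitResult) -> StructureModel:
    return model.with_coordinates(fit.transform(model.coordinates()))


def superpose_ensemble(ens: Ensemble, reference: StructureModel,
                       selection: tuple[str, ...] | None = ("CA",)) -> Ensemble:
    """Independently Kabsch-fit every model of the ensemble onto ``reference``."""
    models = []
    for i, model in enumerate(ens.models):
        try:
            fit = kabsch_fit(model, reference, selection)
        except ValueError as exc:
            raise ValueError(f"model {i + 1}: {exc}") from exc
        models.append(apply_fit(model, fit))
    return Ensemble(models=models, label=ens.label, temperature=ens.temperature)


def rmsd_ca(model: StructureModel, reference: StructureModel) -> float:
    """Root-mean-square Cα distance between two already-superposed models."""
    P, Q = _paired_coords(model, reference, ("CA",))
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1))))


def rmsd_trace(series, reference: StructureModel) -> list[tuple[int, float]]:
    """Per-model Cα-RMSD (after per-model fitting) along a series.

    ``series`` is an ordered iterable of :class:`Ensemble` or
    :class:`StructureModel`; ensembles are flattened in model order.  The
    result mirrors an RMSD-vs-time trace of a trajectory against a fixed
    reference structure.
    """
    models: list[StructureModel] = []
    for entry in series:
        if isinstance(entry, Ensemble):
            models.extend(entry.models)
        else:
            models.append(entry)
    out = []
    for i, model in enumerate(models):
        fit = kabsch_fit(model, reference, ("CA",))
        out.append((i, float(fit.rmsd)))
    return out


def write_rmsd_trace(trace: list[tuple[int, float]], path) -> None:
    with open(path, "w") as fh:
        fh.write("model_index\trmsd_angstrom\n")
        for idx, value in trace:
            fh.write(f"{idx}\t{value:.6f}\n")
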