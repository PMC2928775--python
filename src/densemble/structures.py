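"""Multi-model coordinate I/O and the in-memory structural model.

A structural *ensemble* is an ordered set of models of the same molecule —
MD snapshots, independently solved crystal structures, or multi-start
refinement outputs — stored in a single PDB file whose models are delimited
by MODEL/ENDMDL records.  All models of an ensemble must share one topology
(same atoms, same residues, same order); this is validated on load because
every downstream step (superposition, per-residue density regions) pairs
atoms across models by position in the atom list.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "StructureModel",
    "Ensemble",
    "TopologyError",
    "PDBParseError",
    "PDBWriteError",
    "read_multimodel",
    "write_multimodel",
    "set_uniform_bfactor",
]


class TopologyError(ValueError):
    """Models of one ensemble do not share the same atoms/residues."""


class PDBParseError(ValueError):
    """A coordinate file could not be parsed."""


class PDBWriteError(ValueError):
    """A model cannot be represented in fixed-width PDB columns."""


@dataclass
class AtomRecord:
    """One atom of one model.

    ``b_factor`` is the isotropic Debye–Waller factor in Å²; it sets the
    Gaussian smearing width of the atom's electron density (σ² = B/8π²).
    ``occupancy`` is the fractional population of this position in [0, 1].
    """

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 15.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError(f"position must be a 3-vector, got {self.position.shape}")
        if self.b_factor < 0:
            raise ValueError(f"negative B-factor {self.b_factor} on atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if self.atomic_number < 1:
            raise ValueError(f"element {self.element!r} not resolvable on atom {self.name}")

    @property
    def atomic_number(self) -> int:
        return gemmi.Element(self.element).atomic_number

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def residue_key(self) -> tuple[str, int]:
        return (self.chain_id, self.residue_index)


@dataclass
class StructureModel:
    """One model: an ordered atom list plus residue index ranges.

    ``residue_segments`` maps (chain_id, residue_index) to the half-open
    ``(start, stop)`` range of ``atoms`` belonging to that residue; atoms of
    one residue are contiguous.
    """

    atoms: list[AtomRecord]
    residue_segments: dict[tuple[str, int], tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.residue_segments:
            self.residue_segments = _build_segments(self.atoms)

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def with_coordinates(self, coords: np.ndarray) -> "StructureModel":
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coordinate array shape {coords.shape} does not match "
                             f"{len(self.atoms)} atoms")
        atoms = [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        return StructureModel(atoms=atoms)

    def residue_atoms(self, key: tuple[str, int]) -> list[AtomRecord]:
        start, stop = self.residue_segments[key]
        return self.atoms[start:stop]

    def residue_keys(self) -> list[tuple[str, int]]:
        return list(self.residue_segments)

    def atom_signature(self) -> list[tuple[str, int, str, str]]:
        return [(a.chain_id, a.residue_index, a.residue_name, a.name) for a in self.atoms]


def _build_segments(atoms: list[AtomRecord]) -> dict[tuple[str, int], tuple[int, int]]:
    segments: dict[tuple[str, int], tuple[int, int]] = {}
    current: tuple[str, int] | None = None
    start = 0
    for i, atom in enumerate(atoms):
        key = atom.residue_key
        if key != current:
            if current is not None:
                segments[current] = (start, i)
            if key in segments:
                raise TopologyError(f"residue {key} appears in non-contiguous blocks")
            current = key
            start = i
    if current is not None:
        segments[current] = (start, len(atoms))
    return segments


@dataclass
class Ensemble:
    """Ordered models sharing one topology, with label/temperature metadata."""

    models: list[StructureModel]
    label: str = ""
    temperature: float | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("ensemble must contain at least one model")
        _check_topology(self.models)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def residue_keys(self) -> list[tuple[str, int]]:
        return self.models[0].residue_keys()

    def mean_model(self) -> StructureModel:
        """Model at the per-atom arithmetic mean of all model positions."""
        coords = np.mean([m.coordinates() for m in self.models], axis=0)
        return self.models[0].with_coordinates(coords)

    def map_models(self, fn) -> "Ensemble":
        return Ensemble(models=[fn(m) for m in self.models],
                        label=self.label, temperature=self.temperature)


def _check_topology(models: list[StructureModel]) -> None:
    ref_sig = models[0].atom_signature()
    ref_keys = set(models[0].residue_keys())
    for i, model in enumerate(models[1:], start=2):
        keys = set(model.residue_keys())
        if keys != ref_keys:
            diverging = sorted(keys.symmetric_difference(ref_keys),
                               key=lambda k: (k[0], k[1]))
            raise TopologyError(
                f"model {i} topology mismatch: residue {diverging[0]} present in "
                f"only one of the models")
        sig = model.atom_signature()
        if sig != ref_sig:
            for a, b in zip(sig, ref_sig):
                if a != b:
                    raise TopologyError(
                        f"model {i} topology mismatch at residue "
                        f"({a[0]}, {a[1]}): atom {a[3]} vs {b[3]}")
            raise TopologyError(f"model {i} has {len(sig)} atoms, expected {len(ref_sig)}")


def read_multimodel(path, *, include_hetero: bool = False,
                    label: str | None = None) -> Ensemble:
    """Read a (multi-model) PDB file into an :class:`Ensemble`.

    Models are split by MODEL/ENDMDL records; a file without MODEL records
    yields a single-model ensemble.  Alternate locations keep altloc 'A' or
    blank only, so every model has exactly one position per atom.  Waters and
    hetero compounds are dropped unless ``include_hetero`` is set.  Hydrogens
    are retained (flagged via :attr:`AtomRecord.is_hydrogen`); density
    synthesis skips them by default.
    """
    path = str(path)
    if not path.endswith((".cif", ".mmcif", ".cif.gz")):
        _validate_pdb_lines(path)
    try:
        st = gemmi.read_structure(path, format=gemmi.CoorFormat.Detect)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    st.setup_entities()
    models = []
    for gm in st:
        atoms: list[AtomRecord] = []
        for chain in gm:
            for res in chain:
                if not include_hetero and res.het_flag != "A":
                    continue
                for at in res:
                    if at.altloc not in ("", "\0", "A"):
                        continue
                    elem = at.element.name
                    if elem in ("", "X"):
                        raise PDBParseError(
                            f"{path}: element of atom {at.name} in residue "
                            f"{res.seqid.num} not resolvable")
                    atoms.append(AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=elem,
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        occupancy=min(max(at.occ, 0.0), 1.0),
                        b_factor=max(at.b_iso, 0.0),
                    ))
        if atoms:
            models.append(StructureModel(atoms=atoms))
    if not models:
        raise PDBParseError(f"{path}: no atoms read")
    return Ensemble(models=models, label=label if label is not None else path)


def _validate_pdb_lines(path: str) -> None:
    """Fail fast, with a line number, on coordinate records gemmi would
    silently mangle (non-numeric fixed-width fields)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            try:
                int(line[6:11])
                int(line[22:26])
                for lo, hi in ((30, 38), (38, 46), (46, 54)):
                    float(line[lo:hi])
                for lo, hi in ((54, 60), (60, 66)):
                    fieldvalue = line[lo:hi].strip()
                    if fieldvalue:
                        float(fieldvalue)
            except (ValueError, IndexError) as exc:
                raise PDBParseError(
                    f"{path}: unparseable coordinate record at line {lineno}: "
                    f"{line.rstrip()}") from exc


_PDB_ATOM = ("ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
             "{resnum:>4d}{icode:1s}   {x:>8.3f}{y:>8.3f}{z:>8.3f}"
             "{occ:>6.2f}{b:>6.2f}          {elem:>2s}\n")


def _format_atom_name(name: str, element: str) -> str:
    # PDB v3: element symbol occupies columns 13-14; 1-letter elements with
    # short names are left-padded by one space.
    if len(name) >= 4 or len(element) == 2:
        return f"{name:<4s}"
    return f" {name:<3s}"


def write_multimodel(ens: Ensemble, path) -> None:
    """Write an ensemble as a fixed-width PDB file with MODEL/ENDMDL framing."""
    lines: list[str] = []
    for imodel, model in enumerate(ens.models, start=1):
        lines.append(f"MODEL     {imodel:>4d}\n")
        for i, a in enumerate(model.atoms, start=1):
            x, y, z = a.position
            if not (-999.999 <= x <= 9999.999 and -999.999 <= y <= 9999.999
                    and -999.999 <= z <= 9999.999):
                raise PDBWriteError(
                    f"coordinate {a.position} of atom {a.name} exceeds the "
                    "8-column PDB field width")
            if a.residue_index > 9999 or a.residue_index < -999:
                raise PDBWriteError(f"residue index {a.residue_index} exceeds PDB width")
            lines.append(_PDB_ATOM.format(
                serial=min(i, 99999), name=_format_atom_name(a.name, a.element),
                altloc=" ", resname=a.residue_name, chain=a.chain_id,
                resnum=a.residue_index, icode=" ", x=x, y=y, z=z,
                occ=a.occupancy, b=a.b_factor, elem=a.element.upper()))
        lines.append("ENDMDL\n")
    lines.append("END\n")
    with open(path, "w") as fh:
        fh.writelines(lines)


def set_uniform_bfactor(ens: Ensemble, value: float | str) -> Ensemble:
    """Return a copy of the ensemble with every B-factor set to one value.

    ``value="mean"`` uses the ensemble-wide arithmetic mean of the input
    B-factors — the preprocessing applied to MD snapshots before computing
    structure factors, so that positional spread rather than per-atom
    smearing carries the ensemble's disorder signal.
    """
    if value == "mean":
        bvals = [a.b_factor for m in ens.models for a in m.atoms]
        target = float(np.mean(bvals))
    else:
        target = float(value)
        if target <= 0:
            raise ValueError(f"uniform B-factor must be positive, got {target}")

    def _set(model: StructureModel) -> StructureModel:
        atoms = [replace(a, position=a.position.copy(), b_factor=target)
                 for a in model.atoms]
        return StructureModel(atoms=atoms)

    return ens.map_models(_set)
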