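"""Synthetic conformational ensembles with planted, temperature-dependent disorder.

Stands in for MD trajectories and crystallographic ensembles of a real
protein.  The displacement model captures the phenomenology of the protein
dynamical transition rather than the physics: every residue carries a
harmonic amplitude that scales linearly with temperature, and residues in
designated *functional regions* additionally acquire an anharmonic
amplitude that switches on sigmoidally above the transition temperature
T_D (~215 K for hydrated proteins),

    σ_i(T) = sqrt( σ_h² · T/300  +  1[i ∈ functional] · σ_a² · s(T) ),
    s(T)   = 1 / (1 + exp(−(T − T_D)/width)),

smoothed along the chain with a moving average of ``corr_window`` residues
to emulate the spatial correlation of real loop motions.  Each ensemble
model displaces every residue rigidly by an isotropic Gaussian draw of
standard deviation σ_i(T) per Cartesian component, plus a small per-atom
jitter.  Models are independent draws — snapshot spacing is treated as
decorrelated sampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import AtomRecord, Ensemble, StructureModel

__all__ = ["DisorderSpec", "TemperatureSeriesSpec", "build_toy_structure",
           "amplitude_profile", "generate_ensemble", "generate_temperature_series",
           "DEFAULT_TEMPERATURES"]

DEFAULT_TEMPERATURES = (200.0, 210.0, 220.0, 230.0, 300.0)


@dataclass(frozen=True)
class DisorderSpec:
    """Per-residue displacement-amplitude model driving the generator.

    Amplitudes are per-Cartesian-component standard deviations in Å.
    Defaults are sized so that the LDC contrast across T_D is decisive for
    100-model ensembles of the 30-residue toy helix.
    """

    n_residues: int = 30
    functional_regions: tuple[tuple[int, int], ...] = ((10, 14), (20, 24))
    sigma_h: float = 0.3        # harmonic amplitude at 300 K, Å
    sigma_a: float = 1.2        # anharmonic amplitude above T_D, Å
    t_d: float = 215.0          # dynamical transition temperature, K
    width: float = 5.0          # sigmoid width, K
    sigma_atom: float = 0.1     # per-atom jitter, Å
    corr_window: int = 3        # chain-smoothing moving-average window, residues

    def __post_init__(self):
        if self.sigma_h < 0 or self.sigma_a < 0 or self.sigma_atom < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.width <= 0:
            raise ValueError("sigmoid width must be positive")
        for lo, hi in self.functional_regions:
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"functional region ({lo}, {hi}) outside "
                                 f"residues 1..{self.n_residues}")

    def is_functional(self, residue_index: int) -> bool:
        return any(lo <= residue_index <= hi for lo, hi in self.functional_regions)

    def functional_residues(self) -> list[int]:
        return [i for i in range(1, self.n_residues + 1) if self.is_functional(i)]

    def halo_residues(self) -> list[int]:
        """Non-functional residues within corr_window of a functional region."""
        out = []
        for i in range(1, self.n_residues + 1):
            if self.is_functional(i):
                continue
            dist = min(min(abs(i - lo), abs(i - hi))
                       for lo, hi in self.functional_regions)
            if dist < self.corr_window:
                out.append(i)
        return out


@dataclass(frozen=True)
class TemperatureSeriesSpec:
    temperatures: tuple[float, ...] = DEFAULT_TEMPERATURES
    n_models: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_models < 1:
            raise ValueError("n_models must be >= 1")
        if any(t <= 0 for t in self.temperatures):
            raise ValueError("temperatures must be positive")


# Engh–Huber-like ideal backbone geometry (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N = 1.458, 1.525, 1.329
_B_C_O, _B_CA_CB = 1.231, 1.521
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.8, 110.5
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to A-B-C."""
    theta = np.deg2rad(angle_deg)
    chi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([-np.cos(theta),
                               np.sin(theta) * np.cos(chi),
                               np.sin(theta) * np.sin(chi)])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_toy_structure(n_residues: int, chain_id: str = "A",
                        b_factor: float = 15.0) -> StructureModel:
    """Ideal poly-alanine α-helix (N, CA, C, O, CB per residue).

    Built from ideal bond lengths/angles with φ = −57°, ψ = −47°, ω = 180°,
    giving the canonical ~1.5 Å rise and ~3.8 Å Cα–Cα spacing.
    Deterministic: identical input gives bit-identical output.
    """
    if n_residues < 4:
        raise ValueError(f"need at least 4 residues, got {n_residues}")
    # seed atoms of residue 1 in the xy-plane
    n1 = np.zeros(3)
    ca1 = np.array([_B_N_CA, 0.0, 0.0])
    theta = np.deg2rad(_A_N_CA_C)
    c1 = ca1 + _B_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    backbone = [(n1, ca1, c1)]
    for _ in range(1, n_residues):
        n_prev, ca_prev, c_prev = backbone[-1]
        n_next = _nerf(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, _PSI)
        ca_next = _nerf(ca_prev, c_prev, n_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        c_next = _nerf(c_prev, n_next, ca_next, _B_CA_C, _A_N_CA_C, _PHI)
        backbone.append((n_next, ca_next, c_next))
    atoms: list[AtomRecord] = []
    serial = 1
    for i, (n_pos, ca_pos, c_pos) in enumerate(backbone):
        resnum = i + 1
        o_pos = _nerf(n_pos, ca_pos, c_pos, _B_C_O, _A_CA_C_O, _PSI + 180.0)
        cb_pos = _nerf(c_pos, n_pos, ca_pos, _B_CA_CB, _A_N_CA_CB, 122.6)
        for name, elem, pos in (("N", "N", n_pos), ("CA", "C", ca_pos),
                                ("C", "C", c_pos), ("O", "O", o_pos),
                                ("CB", "C", cb_pos)):
            atoms.append(AtomRecord(serial=serial, name=name, element=elem,
                                    residue_index=resnum, residue_name="ALA",
                                    chain_id=chain_id, position=pos.copy(),
                                    occupancy=1.0, b_factor=b_factor))
            serial += 1
    return StructureModel(atoms=atoms)


def amplitude_profile(spec: DisorderSpec, temperature: float,
                      smooth: bool = True) -> np.ndarray:
    """Per-residue displacement amplitudes σ_i(T) in Å (1-based residues).

    ``smooth=False`` returns the raw profile before chain smoothing —
    useful for checking the closed-form values at the sigmoid midpoint.
    """
    idx = np.arange(1, spec.n_residues + 1)
    s = 1.0 / (1.0 + np.exp(-(temperature - spec.t_d) / spec.width))
    func = np.array([spec.is_functional(i) for i in idx], dtype=float)
    sigma = np.sqrt(spec.sigma_h ** 2 * (temperature / 300.0)
                    + func * spec.sigma_a ** 2 * s)
    if smooth and spec.corr_window > 1:
        sigma = _moving_average(sigma, spec.corr_window)
    return sigma


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the chain ends."""
    half = window // 2
    out = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        out[i] = x[lo:hi].mean()
    return out


def generate_ensemble(ref: StructureModel, spec: DisorderSpec,
                      temperature: float, n_models: int = 100,
                      seed: int = 0) -> Ensemble:
    """Draw an ensemble of displaced copies of ``ref`` at one temperature.

    Each model displaces every residue rigidly by an isotropic Gaussian
    with per-component std σ_i(T), plus per-atom jitter of std
    ``sigma_atom``; reproducible for a fixed seed.
    """
    keys = ref.residue_keys()
    if len(keys) != spec.n_residues:
        raise ValueError(f"reference has {len(keys)} residues, spec expects "
                         f"{spec.n_residues}")
    sigma = amplitude_profile(spec, temperature)
    rng = np.random.default_rng(seed)
    coords0 = ref.coordinates()
    models = []
    for _ in range(n_models):
        coords = coords0.copy()
        disp = rng.normal(size=(spec.n_residues, 3)) * sigma[:, None]
        for r, key in enumerate(keys):
            start, stop = ref.residue_segments[key]
            coords[start:stop] += disp[r]
        if spec.sigma_atom > 0:
            coords += rng.normal(scale=spec.sigma_atom, size=coords.shape)
        models.append(ref.with_coordinates(coords))
    return Ensemble(models=models, label=f"synthetic-{temperature:g}K",
                    temperature=temperature)


def generate_temperature_series(ref: StructureModel, spec: DisorderSpec,
                                series: TemperatureSeriesSpec) -> list[Ensemble]:
    """One ensemble per temperature; per-temperature seeds derived from
    ``series.seed`` and the temperature index, so any subset is reproducible."""
    out = []
    for t_idx, temperature in enumerate(series.temperatures):
        child = int(np.random.SeedSequence([series.seed, t_idx]).generate_state(1)[0]
                    % (2 ** 31))
        out.append(generate_ensemble(ref, spec, temperature,
                                     n_models=series.n_models, seed=child))
    return out
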