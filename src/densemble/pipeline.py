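"""High-level orchestration: superpose → synthesize maps → LDC → classify.

This is the programmatic counterpart of the command-line workflow; the CLI
is a thin wrapper around these functions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .density import DEFAULT_SPACING
from .ldc import (DEFAULT_RADIUS, ClassCounts, LDCProfile, classify_summary,
                  ldc_profile)
from .structures import Ensemble, StructureModel, set_uniform_bfactor
from .superposition import superpose_ensemble

__all__ = ["CompareResult", "compare_ensembles", "apply_bfactor_policy",
           "write_manifest"]


@dataclass
class CompareResult:
    profile: LDCProfile
    counts: ClassCounts
    reference_label: str
    alternative_label: str


def apply_bfactor_policy(ens: Ensemble, policy: str) -> Ensemble:
    """``keep``, ``mean`` or a numeric value (as string or float)."""
    if policy == "keep":
        return ens
    if policy == "mean":
        return set_uniform_bfactor(ens, "mean")
    return set_uniform_bfactor(ens, float(policy))


def compare_ensembles(ens_ref: Ensemble, ens_alt: Ensemble,
                      reference_model: StructureModel | None = None,
                      radius: float = DEFAULT_RADIUS,
                      spacing: float = DEFAULT_SPACING,
                      bfactor: str = "keep") -> CompareResult:
    """Full per-residue LDC comparison of two ensembles.

    Both ensembles are superposed (Cα Kabsch fit per model) onto
    ``reference_model`` — by default the first model of the reference
    ensemble — then rendered on one grid and correlated residue by residue.
    """
    if reference_model is None:
        reference_model = ens_ref.models[0]
    ens_ref = apply_bfactor_policy(ens_ref, bfactor)
    ens_alt = apply_bfactor_policy(ens_alt, bfactor)
    ens_ref = superpose_ensemble(ens_ref, reference_model)
    ens_alt = superpose_ensemble(ens_alt, reference_model)
    profile = ldc_profile(ens_ref, ens_alt, radius=radius, spacing=spacing)
    return CompareResult(profile=profile, counts=classify_summary(profile),
                         reference_label=ens_ref.label,
                         alternative_label=ens_alt.label)


def write_manifest(path, params: dict) -> None:
    """Flat key=value manifest sufficient to re-execute a seeded run."""
    from . import __version__
    with open(path, "w") as fh:
        fh.write(f"densemble_version={__version__}\n")
        for key, value in params.items():
            fh.write(f"{key}={value}\n")
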