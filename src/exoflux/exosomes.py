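"""Exosome cargo delivery and dosimetry.

When producer fibroblasts are grown on 13C substrates, their secreted
exosomes carry partially labeled metabolite cargo.  Feeding those exosomes
to cancer cells and measuring 13C enrichment in the recipient pools gives a
direct estimate of how much of each pool the exosomes supplied: the
recipient's mean enrichment divided by the enrichment of the same metabolite
inside the exosomes.  For essential amino acids (which the recipient cannot
synthesize) that ratio is a proper fraction; for other metabolites de novo
synthesis or exchange can push it above 1, which is flagged rather than
clipped.

The dosimetry helpers convert between exosomal protein mass, particle
counts, and producer-cell equivalents using a mass-per-particle calibration
(e.g. 4.9 ug of exosomal protein per 1e9 particles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ExosomeDose",
    "CargoContribution",
    "ESSENTIAL_AMINO_ACIDS",
    "cargo_contribution",
    "particles_from_mass",
    "mass_from_particles",
    "caf_equivalents",
    "summarize_contributions",
]

#: Amino acids the recipient cell line cannot synthesize.  Glutamine is
#: conditionally essential and treated as non-essential here.
ESSENTIAL_AMINO_ACIDS = frozenset(
    {
        "histidine",
        "isoleucine",
        "leucine",
        "lysine",
        "methionine",
        "phenylalanine",
        "threonine",
        "tryptophan",
        "valine",
    }
)


@dataclass(frozen=True)
class ExosomeDose:
    """An exosome preparation: protein mass, particle count and provenance."""

    protein_mass_ug: float
    particle_count: float
    volume_ml: float
    mass_per_1e9_particles_ug: float = 4.9
    per_producer_yield: float | None = None  # particles per producer cell per 48 hr
    producer_cells: float | None = None

    def __post_init__(self) -> None:
        for name in ("protein_mass_ug", "particle_count", "volume_ml", "mass_per_1e9_particles_ug"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("per_producer_yield", "producer_cells"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when given")
        implied = particles_from_mass(self.protein_mass_ug, self.mass_per_1e9_particles_ug)
        if abs(implied - self.particle_count) > 0.02 * implied:
            raise ValueError(
                f"particle count {self.particle_count:.3g} inconsistent with "
                f"{self.protein_mass_ug} ug at {self.mass_per_1e9_particles_ug} ug/1e9 "
                f"(implies {implied:.3g})"
            )


@dataclass(frozen=True)
class CargoContribution:
    """Estimated fraction of a recipient pool supplied by exosomes."""

    metabolite: str
    me_cell: float
    me_exosome: float
    contribution: float
    essential_amino_acid: bool
    exceeds_source: bool = False

    def __post_init__(self) -> None:
        if self.contribution < 0:
            raise ValueError("contribution must be non-negative")
        if self.essential_amino_acid and self.contribution > 1 + 1e-9:
            raise ValueError(
                f"{self.metabolite}: essential amino acid enrichment in the cell "
                "exceeds the exosome source; check normalization"
            )


def cargo_contribution(
    me_cell: float, me_exosome: float, metabolite: str
) -> CargoContribution:
    """Exosome contribution to a recipient pool: me_cell / me_exosome.

    ``me_cell`` and ``me_exosome`` are mean enrichments of the (natural-
    abundance corrected) metabolite MIDs in the recipient cells and inside
    the labeled exosomes.  Because the recipient keeps consuming the
    metabolite over the chase period, the estimate is a lower bound on
    cumulative supply.
    """
    if me_exosome <= 0:
        raise ValueError(f"{metabolite}: source unlabeled (exosome enrichment is zero)")
    if me_cell < 0:
        raise ValueError("cell enrichment must be non-negative")
    ratio = me_cell / me_exosome
    essential = metabolite.lower() in ESSENTIAL_AMINO_ACIDS
    return CargoContribution(
        metabolite=metabolite,
        me_cell=me_cell,
        me_exosome=me_exosome,
        contribution=ratio,
        essential_amino_acid=essential,
        exceeds_source=(not essential and ratio > 1),
    )


def particles_from_mass(protein_mass_ug: float, mass_per_1e9_particles_ug: float = 4.9) -> float:
    """Particle count equivalent to an exosomal protein mass."""
    if protein_mass_ug <= 0 or mass_per_1e9_particles_ug <= 0:
        raise ValueError("protein mass and calibration must be positive")
    return protein_mass_ug / mass_per_1e9_particles_ug * 1e9


def mass_from_particles(particles: float, mass_per_1e9_particles_ug: float = 4.9) -> float:
    """Exosomal protein mass (ug) equivalent to a particle count."""
    if particles <= 0 or mass_per_1e9_particles_ug <= 0:
        raise ValueError("particle count and calibration must be positive")
    return particles / 1e9 * mass_per_1e9_particles_ug


def caf_equivalents(
    dose_particles_per_ml: float,
    cancer_cells_per_ml: float,
    per_producer_yield: float = 28000.0,
) -> float:
    """Producer-fibroblast : cancer-cell ratio implied by an exosome dose.

    Divides the applied particle density by the per-fibroblast secretion
    yield (particles per producer cell per 48 hr) and by the recipient cell
    density.  A physiologically styled dose lands between roughly 1 and 5
    producer cells per cancer cell.
    """
    if min(dose_particles_per_ml, cancer_cells_per_ml, per_producer_yield) <= 0:
        raise ValueError("dose, cell density and yield must all be positive")
    return dose_particles_per_ml / per_producer_yield / cancer_cells_per_ml


def summarize_contributions(
    per_replicate: np.ndarray,
    *,
    n_boot: int = 1000,
    seed: int | None = None,
) -> dict[str, float]:
    """Median and bootstrap 95% CI of per-replicate contribution estimates."""
    values = np.asarray(per_replicate, dtype=float)
    if values.ndim != 1 or values.size == 0:
        raise ValueError("expected a non-empty 1-D array of per-replicate contributions")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_boot, values.size))
    medians = np.median(values[idx], axis=1)
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return {
        "median": float(np.median(values)),
        "ci_low": float(lo),
        "ci_high": float(hi),
        "n": int(values.size),
    }
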