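"""Scalar readouts derived from corrected MIDs.

These are the figure-level quantities of a tracer study on exosome-treated
cancer cells: the oxidative/reductive split of glutamine entry into citrate
(M4 vs M5 citrate under U-13C5 glutamine), the alpha-ketoglutarate/citrate
pool ratio, the percentage contribution of a substrate to a downstream pool,
and the M1-pyruvate glycolysis index for the 1:1 U-13C6 / 1-13C1 glucose
tracer mixture.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .mid import IsotopologueVector, mean_enrichment

__all__ = [
    "OxRedSplit",
    "TracerExperiment",
    "GLUCOSE_1TO1_MIX",
    "citrate_ox_red",
    "pool_ratio",
    "substrate_contribution",
    "m1_glycolysis_index",
]


@dataclass(frozen=True)
class TracerExperiment:
    """A labeling experiment: which substrate, what pattern, for how long.

    ``mixture`` lists (tracer name, proportion) pairs, e.g. the 1:1 mix of
    uniformly labeled and C1-labeled glucose; proportions must sum to 1.
    ``label_positions`` maps each tracer name to the labeled carbon
    positions (1-based).
    """

    substrate: str
    mixture: tuple[tuple[str, float], ...]
    label_positions: dict[str, tuple[int, ...]]
    duration_hr: float = 24.0
    n_carbons: int = 6

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.mixture)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, not 1")
        for name, _ in self.mixture:
            if name not in self.label_positions:
                raise ValueError(f"no label pattern given for tracer {name!r}")

    def achievable_enrichment(self) -> float:
        """Average fraction of substrate carbons labeled across the mixture.

        This is the mean enrichment a downstream pool would reach if it were
        built entirely from the tracer substrate: e.g. 7/12 for the 1:1
        U-13C6 / 1-13C1 glucose mix.
        """
        labeled = sum(p * len(self.label_positions[name]) for name, p in self.mixture)
        return labeled / self.n_carbons


#: The 1:1 mixture of uniformly labeled and C1-labeled glucose.
GLUCOSE_1TO1_MIX = TracerExperiment(
    substrate="glucose",
    mixture=(("U13C6-glucose", 0.5), ("1-13C1-glucose", 0.5)),
    label_positions={
        "U13C6-glucose": (1, 2, 3, 4, 5, 6),
        "1-13C1-glucose": (1,),
    },
    n_carbons=6,
)


@dataclass(frozen=True)
class OxRedSplit:
    """Oxidative (M4 citrate) vs reductive (M5 citrate) glutamine entry.

    ``ox_over_red`` is infinity when the reductive fraction is zero; a lower
    ratio means more reductive carboxylation.
    """

    oxidative_fraction: float
    reductive_fraction: float
    ox_over_red: float

    def __post_init__(self) -> None:
        for frac in (self.oxidative_fraction, self.reductive_fraction):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")
        if self.ox_over_red < 0:
            raise ValueError("ox_over_red must be non-negative")


def citrate_ox_red(citrate: IsotopologueVector) -> OxRedSplit:
    """Split glutamine entry into citrate under U-13C5 glutamine.

    Oxidative TCA turns produce M4 citrate (labeled oxaloacetate condensed
    with unlabeled acetyl-CoA); reductive carboxylation of M5
    alpha-ketoglutarate produces M5 citrate.  The ratio M4/M5 therefore
    reads out oxidative over reductive glutamine metabolism.
    """
    if citrate.n_carbons != 6:
        raise ValueError(f"citrate must have 6 carbons, got {citrate.n_carbons}")
    ox = citrate.fractions[4]
    red = citrate.fractions[5]
    ratio = ox / red if red > 0 else math.inf
    return OxRedSplit(oxidative_fraction=ox, reductive_fraction=red, ox_over_red=ratio)


def pool_ratio(a_abundance: float, b_abundance: float) -> float:
    """Ratio of two metabolite pool sizes (normalized ion currents).

    For alpha-ketoglutarate over citrate, a higher ratio accompanies higher
    glutamine-driven reductive carboxylation.
    """
    if a_abundance <= 0 or b_abundance <= 0:
        raise ValueError("pool abundances must be positive")
    return a_abundance / b_abundance


def substrate_contribution(
    downstream: IsotopologueVector,
    tracer_enrichment: float = 1.0,
) -> float:
    """Fraction of a downstream pool's carbon supplied by the tracer substrate.

    Operationalized as the downstream mean enrichment divided by the
    enrichment the substrate could at most transmit (1 for a uniformly
    labeled tracer, 7/12 for the 1:1 glucose mix), capped at 1.
    """
    if tracer_enrichment <= 0 or tracer_enrichment > 1:
        raise ValueError("tracer_enrichment must lie in (0, 1]")
    return min(1.0, mean_enrichment(downstream) / tracer_enrichment)


def m1_glycolysis_index(
    pyruvate_or_lactate: IsotopologueVector,
    tracer: TracerExperiment = GLUCOSE_1TO1_MIX,
) -> float:
    """M1 fraction of pyruvate (or lactate) under the 1:1 glucose mix.

    M1 pyruvate can only arise from C1-labeled glucose-6-phosphate routed
    through phosphoglucoisomerase into glycolysis; the oxidative pentose
    phosphate pathway removes that C1 as CO2.  A higher index therefore
    marks glycolytic (non-PPP) routing of glucose.
    """
    patterns = {frozenset(pos) for pos in tracer.label_positions.values()}
    if patterns != {frozenset(range(1, 7)), frozenset({1})}:
        raise ValueError("index undefined for tracer: requires the 1:1 U-13C6/1-13C1 glucose mix")
    if pyruvate_or_lactate.n_carbons != 3:
        raise ValueError("expected a 3-carbon MID (pyruvate or lactate)")
    return pyruvate_or_lactate.fractions[1]
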