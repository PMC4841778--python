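"""Bioenergetic metrics from extracellular-flux (Seahorse-style) time series.

A mitochondrial stress test measures the oxygen consumption rate (OCR) and
extracellular acidification rate (ECAR) of a well over time while injecting,
in order, oligomycin (ATP-synthase inhibitor), FCCP (uncoupler) and
rotenone/antimycin (electron-transport-chain block).  From the segment means
the assay derives, per microgram of cell protein:

- ``nonmito_ocr``  — mean OCR after the ETC block (non-mitochondrial floor)
- ``basal_ocr``    — pre-injection OCR minus the floor
- ``maximal_ocr``  — post-FCCP OCR minus the floor
- ``reserve_ocr``  — maximal minus basal
- ``basal_ecar``   — pre-injection ECAR

Each segment statistic is the mean of the last ``window`` measurements
before the next injection, discarding mixing transients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FluxTimeSeries",
    "InjectionSchedule",
    "BioenergeticsResult",
    "derive_bioenergetics",
]

# injection compounds treated as the ETC block
_ETC_BLOCK = {"rotenone", "antimycin", "rotenone/antimycin", "antimycin/rotenone"}


@dataclass(frozen=True)
class FluxTimeSeries:
    """OCR/ECAR measurements of one well with its protein normalizer."""

    well_id: str
    condition: str
    timepoints_min: tuple[float, ...]
    ocr: tuple[float, ...]
    ecar: tuple[float, ...]
    protein_mass_ug: float

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints_min, dtype=float)
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing (>= 2 points)")
        if len(self.ocr) != t.size or len(self.ecar) != t.size:
            raise ValueError("ocr/ecar must align with timepoints")
        if self.protein_mass_ug <= 0:
            raise ValueError("protein mass must be positive")


@dataclass(frozen=True)
class InjectionSchedule:
    """Ordered (time, compound, concentration) injection events."""

    events: tuple[tuple[float, str, float], ...]

    def __post_init__(self) -> None:
        times = [t for t, _, _ in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("injection times must be strictly increasing")

    def time_of(self, *compounds: str) -> float | None:
        wanted = {c.lower() for c in compounds}
        for t, compound, _ in self.events:
            if compound.lower() in wanted:
                return t
        return None


@dataclass(frozen=True)
class BioenergeticsResult:
    """Derived per-ug-protein metrics; absent segments yield ``None``."""

    basal_ocr: float | None
    maximal_ocr: float | None
    reserve_ocr: float | None
    nonmito_ocr: float | None
    basal_ecar: float | None
    basal_ocr_raw: float | None  # basal without the non-mitochondrial subtraction


def _segment_mean(values, times, start, stop, window):
    mask = (times >= start) & (times < stop)
    if mask.sum() < 3:
        return None
    return float(np.asarray(values)[mask][-window:].mean())


def _floor_nonneg(value, name):
    if value is None:
        return None
    if value < 0:
        warnings.warn(f"{name} was negative ({value:.3g}); floored at 0", stacklevel=3)
        return 0.0
    return value


def derive_bioenergetics(
    series: FluxTimeSeries,
    schedule: InjectionSchedule,
    window: int = 3,
) -> BioenergeticsResult:
    """Derive basal/maximal/reserve OCR and basal ECAR from one well.

    Segments with fewer than 3 measurements, or missing injections, leave
    the dependent metrics as ``None``; everything that can be computed is.
    Negative derived rates are floored at 0 with a warning.
    """
    times = np.asarray(series.timepoints_min, dtype=float)
    end = times[-1] + 1.0
    t_first = schedule.events[0][0] if schedule.events else end
    t_fccp = schedule.time_of("fccp")
    t_block = schedule.time_of(*_ETC_BLOCK)

    pre_ocr = _segment_mean(series.ocr, times, -np.inf, t_first, window)
    pre_ecar = _segment_mean(series.ecar, times, -np.inf, t_first, window)
    fccp_stop = t_block if (t_fccp is not None and t_block is not None and t_block > t_fccp) else end
    fccp_ocr = (
        _segment_mean(series.ocr, times, t_fccp, fccp_stop, window)
        if t_fccp is not None
        else None
    )
    nonmito = (
        _segment_mean(series.ocr, times, t_block, end, window) if t_block is not None else None
    )

    protein = series.protein_mass_ug

    def per_ug(x):
        return None if x is None else x / protein

    basal_raw = per_ug(pre_ocr)
    nonmito_n = per_ug(nonmito)
    basal = None if (basal_raw is None or nonmito_n is None) else basal_raw - nonmito_n
    maximal = (
        None
        if (fccp_ocr is None or nonmito_n is None)
        else per_ug(fccp_ocr) - nonmito_n
    )
    basal = _floor_nonneg(basal, "basal OCR")
    maximal = _floor_nonneg(maximal, "maximal OCR")
    reserve = None if (basal is None or maximal is None) else maximal - basal
    reserve = _floor_nonneg(reserve, "reserve OCR")

    return BioenergeticsResult(
        basal_ocr=basal,
        maximal_ocr=maximal,
        reserve_ocr=reserve,
        nonmito_ocr=_floor_nonneg(nonmito_n, "non-mitochondrial OCR"),
        basal_ecar=_floor_nonneg(per_ug(pre_ecar), "basal ECAR"),
        basal_ocr_raw=basal_raw,
    )
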