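"""Mass isotopologue distributions (MIDs) and the arithmetic every stage shares.

A GC-MS measurement of a metabolite with N backbone carbons yields ion
intensities for the mass variants M+0 .. M+N.  Normalizing those intensities
to unit sum gives the mass isotopologue distribution, the basic currency of
13C tracer analysis.  This module provides the container
(:class:`IsotopologueVector`), proportional normalization, mean enrichment
(the average fraction of backbone carbons that are 13C), and isotopologue
convolution (the distribution of a condensation product whose carbon units
label independently).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "IsotopologueVector",
    "EmptySpectrumError",
    "normalize_mid",
    "mean_enrichment",
    "convolve_mids",
]

_SUM_TOL = 1e-9


class EmptySpectrumError(ValueError):
    """Raised when a spectrum carries no signal (all intensities zero)."""


@dataclass(frozen=True)
class IsotopologueVector:
    """One metabolite's MID: fractions of M+0 .. M+n_carbons.

    Parameters
    ----------
    metabolite_id:
        Free-text metabolite name.
    n_carbons:
        Number of backbone carbons that can carry tracer label (the ``N``
        of the mean-enrichment formula).
    fractions:
        Length ``n_carbons + 1``; entry ``i`` is the fraction of M+i.
        Must be non-negative and sum to 1 within 1e-9.
    corrected:
        True once natural isotope abundance has been removed.
    """

    metabolite_id: str
    n_carbons: int
    fractions: tuple[float, ...] = field(default=())
    corrected: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError("n_carbons must be a positive integer")
        frac = np.asarray(self.fractions, dtype=float)
        if frac.shape != (self.n_carbons + 1,):
            raise ValueError(
                f"{self.metabolite_id}: expected {self.n_carbons + 1} fractions "
                f"(M+0..M+{self.n_carbons}), got {frac.size}"
            )
        if np.any(frac < -_SUM_TOL) or np.any(frac > 1 + _SUM_TOL):
            raise ValueError(f"{self.metabolite_id}: fractions must lie in [0, 1]")
        if abs(frac.sum() - 1.0) > _SUM_TOL:
            raise ValueError(
                f"{self.metabolite_id}: fractions sum to {frac.sum():.12g}, not 1"
            )
        object.__setattr__(self, "fractions", tuple(float(x) for x in frac))

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions, dtype=float)

    def with_fractions(self, fractions, *, corrected: bool | None = None) -> "IsotopologueVector":
        return replace(
            self,
            fractions=tuple(float(x) for x in fractions),
            corrected=self.corrected if corrected is None else corrected,
        )


def normalize_mid(
    raw_intensities,
    *,
    metabolite_id: str = "unknown",
    corrected: bool = False,
) -> IsotopologueVector:
    """Normalize raw M+0..M+n intensities to a unit-sum MID.

    Raises :class:`EmptySpectrumError` if every intensity is zero and
    ``ValueError`` on negative intensities.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    if raw.ndim != 1 or raw.size < 2:
        raise ValueError("expected a 1-D vector of at least two intensities")
    if np.any(raw < 0):
        raise ValueError("intensities must be non-negative")
    total = raw.sum()
    if total <= 0:
        raise EmptySpectrumError(f"{metabolite_id}: empty spectrum (all intensities zero)")
    return IsotopologueVector(
        metabolite_id=metabolite_id,
        n_carbons=raw.size - 1,
        fractions=tuple(raw / total),
        corrected=corrected,
    )


def mean_enrichment(mid: IsotopologueVector) -> float:
    """Average 13C fraction of the backbone: ME = (sum_i i * M_i) / N.

    0 for a fully unlabeled metabolite, 1 for a fully labeled one.
    """
    frac = mid.as_array()
    return float(np.arange(frac.size) @ frac / mid.n_carbons)


def convolve_mids(a: IsotopologueVector, b: IsotopologueVector) -> IsotopologueVector:
    """MID of a condensation product of ``a`` and ``b``.

    Assumes the two moieties label independently, so the product MID is the
    discrete convolution of the two input MIDs; carbon counts add.
    """
    out = np.convolve(a.as_array(), b.as_array())
    out = out / out.sum()
    return IsotopologueVector(
        metabolite_id=f"{a.metabolite_id}+{b.metabolite_id}",
        n_carbons=a.n_carbons + b.n_carbons,
        fractions=tuple(out),
        corrected=a.corrected and b.corrected,
    )
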