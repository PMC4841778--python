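"""Natural-isotope-abundance correction of measured MIDs.

A GC-MS fragment carries many atoms besides the metabolite backbone —
derivatization carbons, hydrogens, silicons of a TBDMS group — whose natural
heavy isotopes (13C, 29/30Si, 18O, ...) shift the observed mass exactly like
tracer label does.  The correction models those shifts as a linear operator:
entry ``(j, i)`` of the correction matrix is the probability that a molecule
carrying ``i`` tracer-derived 13C atoms is observed at nominal mass shift
``j``.  Backbone carbons are treated as tracer positions and do not
contribute natural abundance; every other atom does.  An impure tracer
(13C enrichment below 1) spreads mass downward and is folded into the same
matrix.  Inversion is by non-negative least squares, which enforces the
physical constraint that corrected fractions cannot be negative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.optimize import nnls
from scipy.stats import binom

from .mid import IsotopologueVector

__all__ = [
    "FragmentFormula",
    "CorrectionMatrix",
    "UnsupportedElementError",
    "load_isotope_abundances",
    "build_correction_matrix",
    "correct_natural_abundance",
]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class UnsupportedElementError(ValueError):
    """Raised when a formula contains an element without an isotope table."""


def load_isotope_abundances(path=None) -> dict[str, list[tuple[int, float]]]:
    """Load the element -> [(mass shift, abundance), ...] table.

    Reads the packaged IUPAC table by default, or a user YAML file with the
    same layout.  Abundances for each element must sum to 1.
    """
    if path is None:
        text = resources.files("exoflux").joinpath("data/isotopes.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    table: dict[str, list[tuple[int, float]]] = {}
    for element, rows in raw.items():
        pairs = [(int(shift), float(ab)) for shift, ab in rows]
        total = sum(ab for _, ab in pairs)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{element}: isotope abundances sum to {total}, not 1")
        table[element] = pairs
    return table


@dataclass(frozen=True)
class FragmentFormula:
    """Elemental composition of a measured fragment, derivatization included.

    ``n_backbone_carbons`` is the subset of ``C`` that comes from the
    metabolite skeleton and can carry tracer label; the remaining atoms are
    the natural-abundance background.
    """

    elements: dict[str, int]
    n_backbone_carbons: int

    def __post_init__(self) -> None:
        counts = {el: int(n) for el, n in self.elements.items() if int(n) > 0}
        if any(n < 0 for n in self.elements.values()):
            raise ValueError("element counts must be non-negative")
        if self.n_backbone_carbons < 0:
            raise ValueError("backbone carbon count must be non-negative")
        if self.n_backbone_carbons > counts.get("C", 0):
            raise ValueError("backbone carbons exceed total carbon count")
        object.__setattr__(self, "elements", counts)

    @classmethod
    def from_string(cls, formula: str, n_backbone_carbons: int) -> "FragmentFormula":
        """Parse e.g. ``"C14H28O2Si"`` (Hill-ish notation, integer counts)."""
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_RE.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            pos = match.end()
            el, num = match.group(1), match.group(2)
            counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(elements=counts, n_backbone_carbons=n_backbone_carbons)

    def background_elements(self) -> dict[str, int]:
        """Atom counts contributing natural abundance (backbone C excluded)."""
        bg = dict(self.elements)
        if "C" in bg:
            bg["C"] -= self.n_backbone_carbons
            if bg["C"] == 0:
                del bg["C"]
        return bg


@dataclass(frozen=True)
class CorrectionMatrix:
    """Square operator mapping a tracer MID to the observed raw MID.

    Column ``i`` is the observed mass-shift distribution of a molecule with
    ``i`` tracer carbons, truncated to the measured window M+0..M+n, so
    columns may sum to less than 1.
    """

    matrix: np.ndarray = field(repr=False)
    n_backbone_carbons: int
    tracer_purity: float = 1.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        n = self.n_backbone_carbons + 1
        if m.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("correction matrix entries must be non-negative")
        if np.any(m.sum(axis=0) > 1 + 1e-9):
            raise ValueError("correction matrix columns must sum to at most 1")
        object.__setattr__(self, "matrix", m)

    def forward(self, corrected_fractions) -> np.ndarray:
        """Predict the raw spectrum produced by a tracer-only MID."""
        return self.matrix @ np.asarray(corrected_fractions, dtype=float)


def _element_shift_distribution(pairs: list[tuple[int, float]]) -> np.ndarray:
    size = max(shift for shift, _ in pairs) + 1
    dist = np.zeros(size)
    for shift, ab in pairs:
        dist[shift] += ab
    return dist


def natural_shift_distribution(
    formula: FragmentFormula,
    abundances: dict[str, list[tuple[int, float]]],
) -> np.ndarray:
    """Mass-shift distribution of all non-backbone atoms, by exact convolution."""
    dist = np.array([1.0])
    for element, count in formula.background_elements().items():
        if element not in abundances:
            raise UnsupportedElementError(f"no isotope table for element {element!r}")
        single = _element_shift_distribution(abundances[element])
        for _ in range(count):
            dist = np.convolve(dist, single)
    return dist


def build_correction_matrix(
    formula: FragmentFormula,
    abundances: dict[str, list[tuple[int, float]]] | None = None,
    tracer_purity: float = 1.0,
) -> CorrectionMatrix:
    """Build the natural-abundance (and tracer-purity) correction matrix.

    Column ``i``: the ``i`` tracer positions are 13C with probability
    ``tracer_purity`` (binomial downshift), and every non-backbone atom adds
    its natural shift; shifts beyond M+n_backbone are truncated.
    """
    if abundances is None:
        abundances = load_isotope_abundances()
    if not 0 < tracer_purity <= 1:
        raise ValueError("tracer_purity must lie in (0, 1]")
    n = formula.n_backbone_carbons
    background = natural_shift_distribution(formula, abundances)
    matrix = np.zeros((n + 1, n + 1))
    for i in range(n + 1):
        # binomial over how many of the i tracer positions are actually 13C
        tracer_dist = binom.pmf(np.arange(i + 1), i, tracer_purity)
        column = np.convolve(tracer_dist, background)[: n + 1]
        matrix[: column.size, i] = column
    return CorrectionMatrix(matrix=matrix, n_backbone_carbons=n, tracer_purity=tracer_purity)


def correct_natural_abundance(
    raw: IsotopologueVector, matrix: CorrectionMatrix
) -> IsotopologueVector:
    """Remove natural-abundance (and purity) effects from a raw MID.

    Solves ``argmin_{x >= 0} ||M x - raw||^2`` and renormalizes to unit sum,
    so the result is a proper MID reflecting tracer labeling only.
    """
    if raw.corrected:
        raise ValueError(f"{raw.metabolite_id}: MID is already corrected")
    if raw.n_carbons != matrix.n_backbone_carbons:
        raise ValueError(
            f"{raw.metabolite_id}: MID has {raw.n_carbons} carbons but the "
            f"matrix was built for {matrix.n_backbone_carbons}"
        )
    x, _ = nnls(matrix.matrix, raw.as_array())
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{raw.metabolite_id}: correction produced an empty spectrum")
    return raw.with_fractions(x / total, corrected=True)
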