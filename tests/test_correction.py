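"""Natural-abundance correction: matrix construction and NNLS inversion."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from exoflux import (
    FragmentFormula,
    UnsupportedElementError,
    build_correction_matrix,
    correct_natural_abundance,
    load_isotope_abundances,
    normalize_mid,
)
from exoflux.correction import natural_shift_distribution


def exhaustive_shift_oracle(formula, abundances):
    """Shift distribution by explicit enumeration over every atom's isotope."""
    atoms = []
    for el, count in formula.background_elements().items():
        atoms.extend([abundances[el]] * count)
    dist = {}
    for combo in itertools.product(*atoms) if atoms else [()]:
        shift = sum(s for s, _ in combo)
        prob = np.prod([p for _, p in combo]) if combo else 1.0
        dist[shift] = dist.get(shift, 0.0) + prob
    out = np.zeros(max(dist) + 1 if dist else 1)
    for s, p in dist.items():
        out[s] = p
    return out


def test_formula_parsing_and_backbone_constraint():
    f = FragmentFormula.from_string("C14H28O2Si", 6)
    assert f.elements == {"C": 14, "H": 28, "O": 2, "Si": 1}
    assert f.background_elements()["C"] == 8
    with pytest.raises(ValueError):
        FragmentFormula.from_string("C3", 4)  # backbone exceeds total C


def test_no_background_atoms_gives_identity():
    f = FragmentFormula(elements={"C": 3}, n_backbone_carbons=3)
    cm = build_correction_matrix(f)
    assert np.allclose(cm.matrix, np.eye(4))


def test_single_background_carbon_binomial():
    abundances = {"C": [(0, 0.989), (1, 0.011)]}
    f = FragmentFormula(elements={"C": 3}, n_backbone_carbons=2)
    cm = build_correction_matrix(f, abundances=abundances)
    assert cm.matrix[0, 0] == pytest.approx(0.989)
    assert cm.matrix[1, 0] == pytest.approx(0.011)
    # Toeplitz structure at purity 1: column i is column 0 shifted by i
    assert cm.matrix[2, 1] == pytest.approx(0.011)


def test_tbdms_fragment_columns_match_exhaustive_oracle():
    abundances = load_isotope_abundances()
    f = FragmentFormula.from_string("C9H5O2Si2", 3)  # small enough to enumerate
    background = natural_shift_distribution(f, abundances)
    oracle = exhaustive_shift_oracle(f, abundances)
    assert np.allclose(background, oracle, atol=1e-12)
    cm = build_correction_matrix(f, abundances=abundances)
    sums = cm.matrix.sum(axis=0)
    assert np.all(sums <= 1 + 1e-12)
    assert np.all(cm.matrix >= 0)


def test_unknown_element_rejected():
    f = FragmentFormula.from_string("C3B2", 3)
    with pytest.raises(UnsupportedElementError):
        build_correction_matrix(f)


def test_identity_matrix_leaves_mid_unchanged():
    f = FragmentFormula(elements={"C": 4}, n_backbone_carbons=4)
    cm = build_correction_matrix(f)
    mid = normalize_mid([4, 3, 2, 1, 0])
    out = correct_natural_abundance(mid, cm)
    assert np.allclose(out.as_array(), mid.as_array(), atol=1e-12)
    assert out.corrected


def test_column_zero_corrects_to_pure_unlabeled():
    cm = build_correction_matrix(FragmentFormula.from_string("C12H20O4Si", 4))
    raw = normalize_mid(cm.matrix[:, 0], metabolite_id="unlabeled")
    out = correct_natural_abundance(raw, cm)
    assert out.fractions[0] >= 0.999
    assert np.allclose(out.as_array(), [1, 0, 0, 0, 0], atol=1e-8)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    st.integers(min_value=2, max_value=6),
    st.integers(min_value=0, max_value=6),
    st.integers(min_value=0, max_value=10),
    st.integers(min_value=0, max_value=2),
    st.lists(st.floats(min_value=0.001, max_value=1.0), min_size=3, max_size=7),
)
def test_forward_then_correct_round_trip(n_backbone, extra_c, n_h, n_si, weights):
    """correct(M @ x) recovers x to 1e-10 for random MIDs and fragments."""
    weights = (weights + [0.5] * 7)[: n_backbone + 1]
    x = np.array(weights) / np.sum(weights)
    formula = FragmentFormula(
        elements={"C": n_backbone + extra_c, "H": n_h, "Si": n_si},
        n_backbone_carbons=n_backbone,
    )
    cm = build_correction_matrix(formula)
    raw = normalize_mid(cm.forward(x), metabolite_id="synthetic")
    recovered = correct_natural_abundance(raw, cm)
    assert np.abs(recovered.as_array() - x).max() < 1e-10


def test_purity_below_one_spreads_mass_downward():
    f = FragmentFormula(elements={"C": 3}, n_backbone_carbons=3)
    cm = build_correction_matrix(f, tracer_purity=0.99)
    # a fully labeled molecule leaks into lower isotopologues
    assert cm.matrix[2, 3] > 0
    assert cm.matrix[3, 3] == pytest.approx(0.99**3)
    x = np.array([0.0, 0.0, 0.0, 1.0])
    raw = normalize_mid(cm.forward(x))
    rec = correct_natural_abundance(raw, cm)
    assert np.abs(rec.as_array() - x).max() < 1e-10


def test_dimension_mismatch_and_double_correction_rejected():
    cm = build_correction_matrix(FragmentFormula(elements={"C": 3}, n_backbone_carbons=3))
    with pytest.raises(ValueError):
        correct_natural_abundance(normalize_mid([1, 0, 0]), cm)
    done = correct_natural_abundance(normalize_mid([1, 0, 0, 0]), cm)
    with pytest.raises(ValueError):
        correct_natural_abundance(done, cm)
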