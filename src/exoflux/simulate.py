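"""Synthetic 13C tracer data with known ground truth.

The generator propagates positional isotopomer distributions through a
small atom-mapped network of central carbon metabolism — glycolysis with an
oxidative pentose-phosphate shunt, pyruvate dehydrogenase, an oxidative TCA
turn, reductive carboxylation of alpha-ketoglutarate, glutaminolysis,
citrate cleavage to lipogenic acetyl-CoA and palmitate synthesis — to a
steady state, collapses the isotopomers to MIDs, convolves them with the
natural-abundance background of a representative GC-MS fragment, adds
measurement noise, and writes tables in the package's MID CSV dialect with
the generating parameters saved alongside.

Each metabolite with ``n`` backbone carbons is represented as a probability
vector over the ``2**n`` binary labeling patterns (bit ``k`` set means
carbon ``k+1`` is 13C).  Reactions are bit permutations (plus explicit CO2
and biomass-sink losses), condensations are Kronecker products, and cleavages
are marginalizations, so carbon atoms are conserved by construction.  The
cyclic TCA part is solved by damped fixed-point iteration.

The network is structural, not calibrated: its branch fractions are chosen
to reproduce the qualitative contrasts an exosome-treated vs control
experiment shows (more reductive carboxylation, less pyruvate oxidation,
more glycolysis), never to match any measured magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .correction import FragmentFormula, build_correction_matrix
from .bioenergetics import FluxTimeSeries, InjectionSchedule
from .io import mids_to_frame

__all__ = [
    "NetworkSpec",
    "SimulationConfig",
    "ConvergenceError",
    "FRAGMENTS",
    "PRESETS",
    "preset_config",
    "steady_state_isotopomers",
    "simulate_mids",
    "simulate_exosome_transfer",
    "simulate_flux_series",
    "check_carbon_conservation",
    "pattern_to_mid",
    "independent_pattern",
    "remap_bits",
    "symmetrize",
    "condense",
    "expected_labels",
    "bit_marginal",
]


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach the requested tolerance."""


# ---------------------------------------------------------------------------
# positional-isotopomer primitives
# ---------------------------------------------------------------------------

def _popcounts(n_bits: int) -> np.ndarray:
    idx = np.arange(1 << n_bits)
    return np.array([bin(i).count("1") for i in idx])


_POP = {n: _popcounts(n) for n in range(1, 7)}


def pattern_to_mid(dist: np.ndarray, n_carbons: int) -> np.ndarray:
    """Collapse a 2**n pattern distribution to an (n+1)-entry MID."""
    return np.bincount(_POP[n_carbons], weights=dist, minlength=n_carbons + 1)


def independent_pattern(n_carbons: int, p_label) -> np.ndarray:
    """Pattern distribution with carbon ``k`` labeled w.p. ``p_label[k]``."""
    p = np.broadcast_to(np.asarray(p_label, dtype=float), (n_carbons,))
    dist = np.ones(1 << n_carbons)
    idx = np.arange(1 << n_carbons)
    for k in range(n_carbons):
        bit = (idx >> k) & 1
        dist *= np.where(bit, p[k], 1 - p[k])
    return dist


def remap_bits(dist: np.ndarray, n_in: int, bit_map: dict[int, int], n_out: int) -> np.ndarray:
    """Apply an atom map: output bit ``bit_map[k]`` takes input bit ``k``.

    Input bits absent from ``bit_map`` are lost carbons (CO2 or sink) and
    are marginalized out.
    """
    idx = np.arange(1 << n_in)
    out_idx = np.zeros_like(idx)
    for k_in, k_out in bit_map.items():
        out_idx |= ((idx >> k_in) & 1) << k_out
    out = np.zeros(1 << n_out)
    np.add.at(out, out_idx, dist)
    return out


def symmetrize(dist: np.ndarray, n_carbons: int) -> np.ndarray:
    """Average a pattern distribution with its carbon-order reversal.

    Models the rotational symmetry of succinate/fumarate, which scrambles
    positional label between the two molecule halves.
    """
    rev = remap_bits(dist, n_carbons, {k: n_carbons - 1 - k for k in range(n_carbons)}, n_carbons)
    return 0.5 * (dist + rev)


def condense(dist_a: np.ndarray, n_a: int, dist_b: np.ndarray) -> np.ndarray:
    """Joint pattern of a condensation; product bits = [a bits, then b bits]."""
    return np.kron(dist_b, dist_a)  # index = (b << n_a) | a


def expected_labels(dist: np.ndarray, n_carbons: int) -> float:
    """Expected number of 13C atoms under a pattern distribution."""
    return float(_POP[n_carbons] @ dist)


def bit_marginal(dist: np.ndarray, n_carbons: int, k: int) -> float:
    """Probability that carbon ``k+1`` is labeled."""
    idx = np.arange(1 << n_carbons)
    return float(dist[(idx >> k) & 1 == 1].sum())


# ---------------------------------------------------------------------------
# network and configuration
# ---------------------------------------------------------------------------

_UNL = {n: independent_pattern(n, 0.0) for n in range(1, 7)}

#: Representative TBDMS/methyl-ester GC-MS fragment per metabolite
#: (formula, backbone carbons).  Synthetic stand-ins for real library
#: fragments; any valid elemental composition exercises the correction.
FRAGMENTS: dict[str, tuple[str, int]] = {
    "pyruvate": ("C9H18NO3Si", 3),
    "lactate": ("C11H25O3Si2", 3),
    "citrate": ("C16H29O7Si2", 6),
    "akg": ("C14H26NO5Si2", 5),
    "glutamate": ("C19H42NO4Si3", 5),
    "glutamine": ("C19H41N2O3Si3", 5),
    "fumarate": ("C12H21O4Si2", 4),
    "malate": ("C18H37O5Si3", 4),
    "palmitate": ("C17H33O2", 16),
    "leucine": ("C18H41NO2Si2", 6),
    "lysine": ("C24H55N2O2Si3", 6),
    "phenylalanine": ("C21H39NO2Si2", 9),
}


@dataclass(frozen=True)
class NetworkSpec:
    """Branch fractions of the atom-mapped toy network.

    All fractions live in [0, 1].  ``f_ppp`` routes glucose through the
    oxidative pentose-phosphate shunt (loses glucose C1 as CO2); ``f_red``
    is the reductive-carboxylation share of citrate production;
    ``pyruvate_from_glucose`` and ``pdh_share`` are the labeled shares of
    the pyruvate and mitochondrial acetyl-CoA pools;
    ``glutamine_share_of_akg`` the glutaminolytic share of the
    alpha-ketoglutarate pool.
    """

    f_red: float = 0.15
    f_ppp: float = 0.0
    pyruvate_from_glucose: float = 0.8
    pdh_share: float = 0.7
    glutamine_share_of_akg: float = 0.5

    def __post_init__(self) -> None:
        for name in ("f_red", "f_ppp", "pyruvate_from_glucose", "pdh_share", "glutamine_share_of_akg"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything one synthetic tracer experiment needs.

    ``tracer`` is one of ``U13C6-glucose``, ``glucose-1to1-mix``,
    ``U13C5-glutamine``, ``U13C3-pyruvate``, ``U13C2-acetate`` or
    ``unlabeled``.  The ``*_share_of_acetyl`` fractions give each
    substrate's share of the lipogenic acetyl-CoA pool (their sum at most
    1; the remainder is unlabeled); the tracer substrate's share is the ISA
    ground truth ``D``.  ``g_true`` is the newly synthesized palmitate
    fraction.  ``noise_sd`` is a per-isotopologue Gaussian sd applied to
    MID fractions before renormalization.
    """

    tracer: str = "U13C6-glucose"
    network: NetworkSpec = field(default_factory=NetworkSpec)
    glucose_share_of_acetyl: float = 0.5
    glutamine_share_of_acetyl: float = 0.12
    acetate_share_of_acetyl: float = 0.05
    pyruvate_share_of_acetyl: float = 0.08
    g_true: float = 0.6
    tracer_purity: float = 1.0
    exosome_label_fraction: float = 0.6
    cargo_supply_fraction: dict = field(
        default_factory=lambda: {"leucine": 0.05, "lysine": 0.12, "glutamine": 0.14, "phenylalanine": 0.16}
    )
    cargo_turnover: float = 0.0
    pool_sizes: dict = field(
        default_factory=lambda: {
            "pyruvate": 1.0,
            "lactate": 2.0,
            "citrate": 1.0,
            "akg": 0.5,
            "glutamate": 3.0,
            "fumarate": 0.4,
            "malate": 0.6,
            "palmitate": 1.5,
        }
    )
    noise_sd: float = 0.005
    n_replicates: int = 4
    seed: int = 0
    condition: str = "control"

    def __post_init__(self) -> None:
        shares = (
            self.glucose_share_of_acetyl
            + self.glutamine_share_of_acetyl
            + self.acetate_share_of_acetyl
            + self.pyruvate_share_of_acetyl
        )
        if shares > 1 + 1e-9:
            raise ValueError(f"acetyl shares sum to {shares:.3g} > 1")
        for name in ("g_true", "tracer_purity", "exosome_label_fraction", "cargo_turnover"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _glucose_pattern(tracer: str, purity: float) -> np.ndarray:
    if tracer == "U13C6-glucose":
        return independent_pattern(6, purity)
    if tracer == "glucose-1to1-mix":
        u = independent_pattern(6, purity)
        c1 = independent_pattern(6, [purity, 0, 0, 0, 0, 0])
        return 0.5 * u + 0.5 * c1
    return _UNL[6]


def steady_state_isotopomers(
    config: SimulationConfig,
    *,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> dict[str, np.ndarray]:
    """Propagate the tracer to a steady-state positional-isotopomer state.

    Returns pattern distributions for every tracked metabolite, the
    lipogenic acetyl-CoA pool (``acetyl_lipo``) and palmitate's MID is left
    to :func:`simulate_mids` (17 entries exceed the pattern representation).

    Raises :class:`ConvergenceError` with iteration diagnostics if the TCA
    fixed point does not converge.
    """
    net = config.network
    tracer = config.tracer
    purity = config.tracer_purity

    glucose = _glucose_pattern(tracer, purity)
    glutamine = independent_pattern(5, purity) if tracer == "U13C5-glutamine" else _UNL[5]
    medium_pyruvate = independent_pattern(3, purity) if tracer == "U13C3-pyruvate" else _UNL[3]
    acetate = independent_pattern(2, purity) if tracer == "U13C2-acetate" else _UNL[2]

    # glycolysis: the two triose arms of fructose-1,6-bisphosphate
    # arm A inverts C1-C2-C3 (pyr C1,C2,C3 <- glc C3,C2,C1); arm B is C4,C5,C6
    arm_a = remap_bits(glucose, 6, {2: 0, 1: 1, 0: 2}, 3)
    arm_b = remap_bits(glucose, 6, {3: 0, 4: 1, 5: 2}, 3)
    # oxidative PPP: glucose C1 -> CO2, C2/C3 -> biomass sink, C4-C6 -> one triose
    pyr_glycolysis = 0.5 * (arm_a + arm_b)
    pyr_from_glucose = (1 - net.f_ppp) * pyr_glycolysis + net.f_ppp * arm_b
    pyruvate = (
        net.pyruvate_from_glucose * pyr_from_glucose
        + (1 - net.pyruvate_from_glucose) * medium_pyruvate
    )
    lactate = pyruvate.copy()

    # PDH: pyruvate C1 -> CO2; C2,C3 -> acetyl C1,C2
    acetyl_from_pyr = remap_bits(pyruvate, 3, {1: 0, 2: 1}, 2)
    acetyl_mito = net.pdh_share * acetyl_from_pyr + (1 - net.pdh_share) * _UNL[2]

    # cyclic TCA part: solve for akg, citrate, fumarate, malate, oaa
    akg = _UNL[5].copy()
    oaa = _UNL[4].copy()
    history = []
    for iteration in range(max_iter):
        # citrate: bits 0-3 from OAA C1-C4, bits 4-5 from acetyl; reductive
        # carboxylation prepends an unlabeled CO2-derived carbon at C1
        cit_synthase = condense(oaa, 4, acetyl_mito)
        cit_reductive = remap_bits(akg, 5, {0: 1, 1: 2, 2: 3, 3: 4, 4: 5}, 6)
        citrate = net.f_red * cit_reductive + (1 - net.f_red) * cit_synthase
        # oxidative IDH: citrate C1 (OAA-derived) -> CO2, C2-C6 -> akg
        akg_from_cit = remap_bits(citrate, 6, {1: 0, 2: 1, 3: 2, 4: 3, 5: 4}, 5)
        akg_new = (
            net.glutamine_share_of_akg * glutamine
            + (1 - net.glutamine_share_of_akg) * akg_from_cit
        )
        # the symmetric four-carbon pool mixes the oxidative route (akg
        # decarboxylation, akg C1 -> CO2) with the reductive/cataplerotic one
        # (citrate cleavage OAA, citrate C1-C4); fumarase scrambles both
        fum_ox = remap_bits(akg_new, 5, {1: 0, 2: 1, 3: 2, 4: 3}, 4)
        oaa_cleaved = remap_bits(citrate, 6, {0: 0, 1: 1, 2: 2, 3: 3}, 4)
        fumarate = symmetrize((1 - net.f_red) * fum_ox + net.f_red * oaa_cleaved, 4)
        malate = fumarate.copy()
        oaa_new = malate.copy()
        delta = max(np.abs(akg_new - akg).max(), np.abs(oaa_new - oaa).max())
        akg, oaa = akg_new, oaa_new
        history.append(delta)
        if delta < tol:
            break
    else:
        raise ConvergenceError(
            f"TCA fixed point did not converge: last deltas {history[-5:]} after {max_iter} iterations"
        )

    cit_synthase = condense(oaa, 4, acetyl_mito)
    cit_reductive = remap_bits(akg, 5, {0: 1, 1: 2, 2: 3, 3: 4, 4: 5}, 6)
    citrate = net.f_red * cit_reductive + (1 - net.f_red) * cit_synthase
    fum_ox = remap_bits(akg, 5, {1: 0, 2: 1, 3: 2, 4: 3}, 4)
    oaa_cleaved = remap_bits(citrate, 6, {0: 0, 1: 1, 2: 2, 3: 3}, 4)
    fumarate = symmetrize((1 - net.f_red) * fum_ox + net.f_red * oaa_cleaved, 4)
    malate = fumarate.copy()
    glutamate = (
        net.glutamine_share_of_akg * glutamine + (1 - net.glutamine_share_of_akg) * akg
    )

    # Lipogenic acetyl-CoA delivered by each substrate, conditional on the
    # two carbons actually deriving from it: glucose via PDH of
    # glucose-derived pyruvate, glutamine via reductive carboxylation and
    # citrate cleavage (citrate C5,C6 = akg C4,C5 = glutamine C4,C5),
    # pyruvate via PDH, acetate directly.
    acetyl_via = {
        "glucose": remap_bits(pyr_from_glucose, 3, {1: 0, 2: 1}, 2),
        "glutamine": remap_bits(glutamine, 5, {3: 0, 4: 1}, 2),
        "pyruvate": remap_bits(medium_pyruvate, 3, {1: 0, 2: 1}, 2),
        "acetate": acetate,
    }
    shares = {
        "glucose": config.glucose_share_of_acetyl,
        "glutamine": config.glutamine_share_of_acetyl,
        "pyruvate": config.pyruvate_share_of_acetyl,
        "acetate": config.acetate_share_of_acetyl,
    }
    acetyl_lipo = (1 - sum(shares.values())) * _UNL[2]
    for key, share in shares.items():
        acetyl_lipo = acetyl_lipo + share * acetyl_via[key]

    return {
        "glucose": glucose,
        "glutamine": glutamine,
        "pyruvate": pyruvate,
        "lactate": lactate,
        "acetyl_mito": acetyl_mito,
        "citrate": citrate,
        "akg": akg,
        "glutamate": glutamate,
        "fumarate": fumarate,
        "malate": malate,
        "oaa": oaa,
        "acetyl_lipo": acetyl_lipo,
    }


_N_CARBONS = {
    "glucose": 6,
    "glutamine": 5,
    "pyruvate": 3,
    "lactate": 3,
    "acetyl_mito": 2,
    "citrate": 6,
    "akg": 5,
    "glutamate": 5,
    "fumarate": 4,
    "malate": 4,
    "oaa": 4,
    "acetyl_lipo": 2,
}


def check_carbon_conservation(config: SimulationConfig, state: dict[str, np.ndarray]) -> dict[str, float]:
    """Per-reaction 13C balance at steady state.

    For every atom-mapped reaction, compares the expected labeled carbons
    entering against those leaving in products plus explicit CO2/sink
    losses; returns the absolute imbalance per reaction (all should be ~0).
    """
    net = config.network
    glucose, pyruvate, akg, citrate = (
        state["glucose"],
        state["pyruvate"],
        state["akg"],
        state["citrate"],
    )
    out = {}
    # glycolysis: glucose -> 2 trioses (all six carbons retained)
    arm_a = remap_bits(glucose, 6, {2: 0, 1: 1, 0: 2}, 3)
    arm_b = remap_bits(glucose, 6, {3: 0, 4: 1, 5: 2}, 3)
    out["glycolysis"] = abs(
        expected_labels(glucose, 6) - expected_labels(arm_a, 3) - expected_labels(arm_b, 3)
    )
    # oxidative PPP: C1 -> CO2, C2/C3 -> sink, C4-C6 -> triose
    co2 = bit_marginal(glucose, 6, 0)
    sink = bit_marginal(glucose, 6, 1) + bit_marginal(glucose, 6, 2)
    out["ppp_shunt"] = abs(expected_labels(glucose, 6) - (co2 + sink + expected_labels(arm_b, 3)))
    # PDH: pyruvate -> acetyl + CO2(C1)
    acetyl = remap_bits(pyruvate, 3, {1: 0, 2: 1}, 2)
    co2_pdh = bit_marginal(pyruvate, 3, 0)
    out["pdh"] = abs(expected_labels(pyruvate, 3) - expected_labels(acetyl, 2) - co2_pdh)
    # citrate synthase: oaa + acetyl -> citrate
    cit = condense(state["oaa"], 4, state["acetyl_mito"])
    out["citrate_synthase"] = abs(
        expected_labels(state["oaa"], 4)
        + expected_labels(state["acetyl_mito"], 2)
        - expected_labels(cit, 6)
    )
    # oxidative IDH: citrate -> akg + CO2 (citrate C1)
    akg_ox = remap_bits(citrate, 6, {1: 0, 2: 1, 3: 2, 4: 3, 5: 4}, 5)
    co2_idh = bit_marginal(citrate, 6, 0)
    out["idh_oxidative"] = abs(expected_labels(citrate, 6) - expected_labels(akg_ox, 5) - co2_idh)
    # reductive carboxylation: akg + CO2(unlabeled) -> citrate
    cit_red = remap_bits(akg, 5, {0: 1, 1: 2, 2: 3, 3: 4, 4: 5}, 6)
    out["idh_reductive"] = abs(expected_labels(akg, 5) - expected_labels(cit_red, 6))
    # akg dehydrogenase + scrambling: akg -> fumarate + CO2 (akg C1)
    fum = symmetrize(remap_bits(akg, 5, {1: 0, 2: 1, 3: 2, 4: 3}, 4), 4)
    co2_akgdh = bit_marginal(akg, 5, 0)
    out["akg_dehydrogenase"] = abs(expected_labels(akg, 5) - expected_labels(fum, 4) - co2_akgdh)
    # citrate cleavage: citrate -> acetyl(C5,C6) + oaa(C1-C4)
    ac = remap_bits(citrate, 6, {4: 0, 5: 1}, 2)
    oaa_cl = remap_bits(citrate, 6, {0: 0, 1: 1, 2: 2, 3: 3}, 4)
    out["citrate_lyase"] = abs(
        expected_labels(citrate, 6) - expected_labels(ac, 2) - expected_labels(oaa_cl, 4)
    )
    _ = net
    return out


# ---------------------------------------------------------------------------
# table emission
# ---------------------------------------------------------------------------

_OBSERVED = ["pyruvate", "lactate", "citrate", "akg", "glutamate", "fumarate", "malate"]


def _noisy_fractions(fractions: np.ndarray, rng: np.random.Generator, sd: float) -> np.ndarray:
    noisy = fractions + rng.normal(0.0, sd, size=fractions.size) if sd > 0 else fractions.copy()
    noisy = np.clip(noisy, 0.0, None)
    total = noisy.sum()
    if total <= 0:  # pathological draw; fall back to the clean spectrum
        return fractions
    return noisy / total


def _self_convolve(dist: np.ndarray, n: int) -> np.ndarray:
    out = np.array([1.0])
    for _ in range(n):
        out = np.convolve(out, dist)
    return out


def _emit_rows(mids: dict[str, np.ndarray], config: SimulationConfig, rng, *, sample_prefix: str):
    """Forward-convolve clean MIDs with natural abundance, add noise, scale."""
    rows = []
    matrices = {}
    for metabolite, clean in mids.items():
        formula_str, n = FRAGMENTS[metabolite]
        if metabolite not in matrices:
            formula = FragmentFormula.from_string(formula_str, n)
            matrices[metabolite] = build_correction_matrix(formula, tracer_purity=config.tracer_purity)
        raw = matrices[metabolite].forward(clean)
        pool = config.pool_sizes.get(metabolite, 1.0)
        for rep in range(config.n_replicates):
            fractions = _noisy_fractions(raw / raw.sum(), rng, config.noise_sd)
            scale = pool * 1e6 * (raw.sum())
            rows.append(
                {
                    "sample_id": f"{sample_prefix}_rep{rep + 1}",
                    "condition": config.condition,
                    "metabolite": metabolite,
                    "fragment_formula": formula_str,
                    "backbone_carbons": n,
                    "intensities": list(fractions * scale),
                }
            )
    return rows


def simulate_mids(config: SimulationConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate one tracer experiment; returns (raw MID table, ground truth).

    The table is in the MID CSV dialect with natural-abundance-convolved raw
    intensities whose total ion current encodes the pool size.  The ground
    truth records the generating branch fractions and the lipogenic-acetyl
    ISA parameters (D per substrate, g).
    """
    state = steady_state_isotopomers(config)
    mids = {m: pattern_to_mid(state[m], _N_CARBONS[m]) for m in _OBSERVED}
    # palmitate: 8 acetyl units drawn from the lipogenic pool, diluted by
    # pre-existing unlabeled molecules
    acetyl_mid = pattern_to_mid(state["acetyl_lipo"], 2)
    palmitate = config.g_true * _self_convolve(acetyl_mid, 8)
    palmitate += (1 - config.g_true) * _self_convolve(np.array([1.0, 0.0, 0.0]), 8)
    mids["palmitate"] = palmitate

    rng = np.random.default_rng(config.seed)
    rows = _emit_rows(mids, config, rng, sample_prefix=config.condition)
    table = mids_to_frame(rows)

    tracer_share = {
        "U13C6-glucose": config.glucose_share_of_acetyl,
        "glucose-1to1-mix": config.glucose_share_of_acetyl,
        "U13C5-glutamine": config.glutamine_share_of_acetyl,
        "U13C3-pyruvate": config.pyruvate_share_of_acetyl,
        "U13C2-acetate": config.acetate_share_of_acetyl,
    }.get(config.tracer, 0.0)
    ground_truth = {
        "tracer": config.tracer,
        "condition": config.condition,
        "f_red": config.network.f_red,
        "f_ppp": config.network.f_ppp,
        "pyruvate_from_glucose": config.network.pyruvate_from_glucose,
        "pdh_share": config.network.pdh_share,
        "glutamine_share_of_akg": config.network.glutamine_share_of_akg,
        "D_true": tracer_share,
        "g_true": config.g_true,
        "acetyl_mid_true": [float(x) for x in acetyl_mid],
        "pool_sizes": dict(config.pool_sizes),
        "noise_sd": config.noise_sd,
        "n_replicates": config.n_replicates,
        "seed": config.seed,
    }
    return table, ground_truth


# cargo metabolites: (n backbone carbons, fully labeled positions)
_CARGO_TRACERS = {
    "leucine": 6,
    "lysine": 6,
    "glutamine": 5,
    "phenylalanine": 9,
}


def simulate_exosome_transfer(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Simulate labeled-exosome feeding; returns (exosome table, cell table, truth).

    Producer cells grown on 13C substrates for a sub-replication interval
    yield exosomes whose cargo is only partially labeled
    (``exosome_label_fraction``); recipient-cell pools mix exosome-supplied
    molecules (``cargo_supply_fraction``) with unlabeled endogenous ones.
    Optional catabolic turnover removes a fraction of the supplied label
    from the measured pool (and, for glutamine, routes some of it into
    glutamate), making the measured contribution a lower bound on
    cumulative supply.
    """
    if config.exosome_label_fraction >= 1:
        raise ValueError("exosome_label_fraction must be below 1 (sub-replication labeling)")
    rng = np.random.default_rng(config.seed)
    elf = config.exosome_label_fraction
    exo_mids: dict[str, np.ndarray] = {}
    cell_mids: dict[str, np.ndarray] = {}
    truth_measurable = {}
    for metabolite, supply in config.cargo_supply_fraction.items():
        if metabolite not in _CARGO_TRACERS:
            raise ValueError(f"unsupported cargo metabolite {metabolite!r}")
        if not 0 <= supply <= 1:
            raise ValueError("cargo supply fractions must lie in [0, 1]")
        n = _CARGO_TRACERS[metabolite]
        labeled = np.zeros(n + 1)
        labeled[n] = 1.0  # uniformly labeled tracer molecule
        unlabeled = np.zeros(n + 1)
        unlabeled[0] = 1.0
        exo = elf * labeled + (1 - elf) * unlabeled
        retained = supply * (1 - config.cargo_turnover)
        cell = retained * exo + (1 - retained) * unlabeled
        exo_mids[metabolite] = exo
        cell_mids[metabolite] = cell
        truth_measurable[metabolite] = retained
    # stylized turnover read-through: catabolized glutamine label appears in
    # glutamate (half retained in the pool over the chase)
    if config.cargo_turnover > 0 and "glutamine" in config.cargo_supply_fraction:
        shed = config.cargo_supply_fraction["glutamine"] * config.cargo_turnover * 0.5
        glu = np.zeros(6)
        glu[0], glu[5] = 1 - shed * elf, shed * elf
        cell_mids["glutamate"] = glu

    exo_cfg = replace(config, condition=config.condition + "_exo")
    cell_cfg = replace(config, condition=config.condition + "_cell")
    exo_table = mids_to_frame(_emit_rows(exo_mids, exo_cfg, rng, sample_prefix="exo"))
    cell_table = mids_to_frame(_emit_rows(cell_mids, cell_cfg, rng, sample_prefix="cell"))
    truth = {
        "exosome_label_fraction": elf,
        "cargo_supply_fraction": dict(config.cargo_supply_fraction),
        "cargo_turnover": config.cargo_turnover,
        "measurable_contribution": truth_measurable,
        "seed": config.seed,
    }
    return exo_table, cell_table, truth


def simulate_flux_series(
    basal: float,
    maximal: float,
    nonmito: float,
    protein_ug: float = 1.0,
    *,
    basal_ecar: float = 30.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    well_id: str = "A1",
    condition: str = "control",
    points_per_segment: int = 5,
    interval_min: float = 6.5,
) -> tuple[FluxTimeSeries, InjectionSchedule]:
    """Synthesize a mitochondrial stress-test series with known parameters.

    ``basal``, ``maximal`` and ``nonmito`` are the per-ug-protein ground
    truths (``maximal >= basal >= nonmito >= 0`` is required); the raw well
    signal is their protein-scaled piecewise-constant profile with a
    two-point mixing transient after each injection and optional Gaussian
    noise.  With zero noise, :func:`~exoflux.bioenergetics.derive_bioenergetics`
    recovers the inputs exactly.
    """
    if not maximal >= basal >= nonmito >= 0:
        raise ValueError("require maximal >= basal >= nonmito >= 0")
    if points_per_segment < 5:
        raise ValueError("need at least 5 points per segment (2 transient + 3 plateau)")
    rng = np.random.default_rng(seed)
    # raw well levels per segment: pre, oligomycin, FCCP, ETC block
    levels = np.array(
        [
            (basal + nonmito) * protein_ug,
            (0.3 * basal + nonmito) * protein_ug,
            (maximal + nonmito) * protein_ug,
            nonmito * protein_ug,
        ]
    )
    ecar_levels = np.array([basal_ecar, 1.5 * basal_ecar, 1.5 * basal_ecar, 1.2 * basal_ecar]) * protein_ug
    times, ocr, ecar = [], [], []
    t = 0.0
    prev_ocr, prev_ecar = levels[0], ecar_levels[0]
    inject_times = []
    for seg, (lvl, elvl) in enumerate(zip(levels, ecar_levels)):
        if seg > 0:
            inject_times.append(t - interval_min / 2)
        for j in range(points_per_segment):
            # two-point mixing transient, then exact plateau
            w = {0: 0.5, 1: 0.1}.get(j, 0.0) if seg > 0 else 0.0
            times.append(t)
            ocr.append(lvl + w * (prev_ocr - lvl))
            ecar.append(elvl + w * (prev_ecar - elvl))
            t += interval_min
        prev_ocr, prev_ecar = lvl, elvl
    ocr = np.asarray(ocr) + (rng.normal(0, noise_sd, len(ocr)) if noise_sd > 0 else 0.0)
    ecar = np.asarray(ecar) + (rng.normal(0, noise_sd, len(ecar)) if noise_sd > 0 else 0.0)
    series = FluxTimeSeries(
        well_id=well_id,
        condition=condition,
        timepoints_min=tuple(times),
        ocr=tuple(ocr),
        ecar=tuple(ecar),
        protein_mass_ug=protein_ug,
    )
    schedule = InjectionSchedule(
        events=(
            (inject_times[0], "oligomycin", 2.0),
            (inject_times[1], "fccp", 2.5),
            (inject_times[2], "rotenone", 2.0),
        )
    )
    return series, schedule


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

#: Two study conditions: an untreated control and exosome-treated cells.
#: Branch fractions are set only to reproduce the directional contrasts of
#: the treated phenotype (more reductive carboxylation and glycolysis, less
#: pyruvate oxidation); magnitudes are not calibrated to any measurement.
PRESETS: dict[str, dict] = {
    "control": {
        "network": dict(
            f_red=0.15, f_ppp=0.05, pyruvate_from_glucose=0.75, pdh_share=0.7, glutamine_share_of_akg=0.5
        ),
        "glucose_share_of_acetyl": 0.5,
        "glutamine_share_of_acetyl": 0.12,
        "acetate_share_of_acetyl": 0.05,
        "pyruvate_share_of_acetyl": 0.08,
        "g_true": 0.6,
        "pool_sizes": {
            "pyruvate": 1.0,
            "lactate": 2.0,
            "citrate": 1.0,
            "akg": 0.5,
            "glutamate": 3.0,
            "fumarate": 0.4,
            "malate": 0.6,
            "palmitate": 1.5,
        },
        "flux": dict(basal=90.0, maximal=240.0, nonmito=10.0, basal_ecar=30.0),
    },
    "cde": {
        "network": dict(
            f_red=0.4, f_ppp=0.05, pyruvate_from_glucose=0.9, pdh_share=0.5, glutamine_share_of_akg=0.6
        ),
        "glucose_share_of_acetyl": 0.35,
        "glutamine_share_of_acetyl": 0.25,
        "acetate_share_of_acetyl": 0.09,
        "pyruvate_share_of_acetyl": 0.05,
        "g_true": 0.6,
        "pool_sizes": {
            "pyruvate": 1.1,
            "lactate": 3.0,
            "citrate": 0.9,
            "akg": 0.8,
            "glutamate": 3.2,
            "fumarate": 0.45,
            "malate": 0.65,
            "palmitate": 1.6,
        },
        "flux": dict(basal=55.0, maximal=140.0, nonmito=10.0, basal_ecar=50.0),
    },
}


def preset_config(name: str, tracer: str, *, seed: int = 0, **overrides) -> SimulationConfig:
    """Build a SimulationConfig for a named preset and tracer."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    p = PRESETS[name]
    kwargs = dict(
        tracer=tracer,
        network=NetworkSpec(**p["network"]),
        glucose_share_of_acetyl=p["glucose_share_of_acetyl"],
        glutamine_share_of_acetyl=p["glutamine_share_of_acetyl"],
        acetate_share_of_acetyl=p["acetate_share_of_acetyl"],
        pyruvate_share_of_acetyl=p["pyruvate_share_of_acetyl"],
        g_true=p["g_true"],
        pool_sizes=dict(p["pool_sizes"]),
        condition=name,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)
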