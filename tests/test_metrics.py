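"""Scalar MID-derived metrics: ox/red split, pool ratio, contributions, M1 index."""

import math

import numpy as np
import pytest

from exoflux import (
    GLUCOSE_1TO1_MIX,
    IsotopologueVector,
    TracerExperiment,
    citrate_ox_red,
    m1_glycolysis_index,
    normalize_mid,
    pool_ratio,
    substrate_contribution,
)
from exoflux.simulate import (
    NetworkSpec,
    SimulationConfig,
    pattern_to_mid,
    steady_state_isotopomers,
)


def citrate(fractions):
    return IsotopologueVector("citrate", 6, tuple(fractions), corrected=True)


class TestOxRedSplit:
    def test_pure_oxidative_hits_infinity_sentinel(self):
        split = citrate_ox_red(citrate([0, 0, 0, 0, 1, 0, 0]))
        assert split.oxidative_fraction == 1.0
        assert split.reductive_fraction == 0.0
        assert math.isinf(split.ox_over_red)

    def test_direct_read_off(self):
        split = citrate_ox_red(citrate([0.4, 0, 0, 0, 0.2, 0.4, 0]))
        assert split.oxidative_fraction == pytest.approx(0.2)
        assert split.reductive_fraction == pytest.approx(0.4)
        assert split.ox_over_red == pytest.approx(0.5)

    def test_wrong_carbon_count_rejected(self):
        with pytest.raises(ValueError):
            citrate_ox_red(normalize_mid([1, 0, 0, 0, 0]))

    def test_reductive_dominates_at_high_reductive_flux(self):
        config = SimulationConfig(
            tracer="U13C5-glutamine", network=NetworkSpec(f_red=0.7), noise_sd=0
        )
        state = steady_state_isotopomers(config)
        split = citrate_ox_red(citrate(pattern_to_mid(state["citrate"], 6)))
        assert split.reductive_fraction > split.oxidative_fraction


class TestPoolRatio:
    def test_basic_ratio_and_errors(self):
        assert pool_ratio(2.0, 1.0) == pytest.approx(2.0)
        assert pool_ratio(3.5, 3.5) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            pool_ratio(1.0, 0.0)


class TestSubstrateContribution:
    def test_boundary_cases(self):
        full = IsotopologueVector("akg", 5, (0, 0, 0, 0, 0, 1), corrected=True)
        empty = IsotopologueVector("akg", 5, (1, 0, 0, 0, 0, 0), corrected=True)
        assert substrate_contribution(full, 1.0) == pytest.approx(1.0)
        assert substrate_contribution(empty, 1.0) == pytest.approx(0.0)
        with pytest.raises(ValueError):
            substrate_contribution(full, 0.0)

    def test_capped_at_one(self):
        full = IsotopologueVector("akg", 5, (0, 0, 0, 0, 0, 1), corrected=True)
        assert substrate_contribution(full, 0.5) == 1.0

    def test_known_mixture_share_recovered(self):
        # downstream pool: 40% built from the fully labeled substrate
        labeled = np.zeros(6)
        labeled[5] = 1.0
        unlabeled = np.zeros(6)
        unlabeled[0] = 1.0
        downstream = IsotopologueVector(
            "akg", 5, tuple(0.4 * labeled + 0.6 * unlabeled), corrected=True
        )
        assert substrate_contribution(downstream, 1.0) == pytest.approx(0.40, abs=1e-12)

    def test_mixture_enrichment_for_1to1_glucose(self):
        assert GLUCOSE_1TO1_MIX.achievable_enrichment() == pytest.approx(7 / 12)

    def test_mixture_proportions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            TracerExperiment(
                substrate="glucose",
                mixture=(("a", 0.5), ("b", 0.2)),
                label_positions={"a": (1,), "b": (2,)},
            )


class TestM1GlycolysisIndex:
    def test_read_off(self):
        assert m1_glycolysis_index(
            IsotopologueVector("pyruvate", 3, (1, 0, 0, 0), corrected=True)
        ) == pytest.approx(0.0)
        assert m1_glycolysis_index(
            IsotopologueVector("pyruvate", 3, (0.4, 0.2, 0, 0.4), corrected=True)
        ) == pytest.approx(0.2)

    def test_undefined_for_other_tracers(self):
        plain_glucose = TracerExperiment(
            substrate="glucose",
            mixture=(("U13C6-glucose", 1.0),),
            label_positions={"U13C6-glucose": (1, 2, 3, 4, 5, 6)},
        )
        mid = IsotopologueVector("pyruvate", 3, (1, 0, 0, 0), corrected=True)
        with pytest.raises(ValueError, match="index undefined"):
            m1_glycolysis_index(mid, plain_glucose)

    def test_oxidative_ppp_lowers_the_index(self):
        indices = []
        for f_ppp in (0.0, 0.3):
            config = SimulationConfig(
                tracer="glucose-1to1-mix",
                network=NetworkSpec(f_ppp=f_ppp, pyruvate_from_glucose=1.0),
                noise_sd=0,
            )
            state = steady_state_isotopomers(config)
            mid = IsotopologueVector(
                "pyruvate", 3, tuple(pattern_to_mid(state["pyruvate"], 3)), corrected=True
            )
            indices.append(m1_glycolysis_index(mid))
        assert indices[1] < indices[0]


def test_metrics_invariant_to_intensity_rescaling():
    raw = [300.0, 60.0, 15.0, 9.0, 120.0, 90.0, 6.0]
    a = citrate(normalize_mid(raw).fractions)
    b = citrate(normalize_mid([x * 7.3 for x in raw]).fractions)
    sa, sb = citrate_ox_red(a), citrate_ox_red(b)
    assert sa.oxidative_fraction == pytest.approx(sb.oxidative_fraction)
    assert sa.ox_over_red == pytest.approx(sb.ox_over_red)
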