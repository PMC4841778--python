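"""Synthetic tracer generator: atom maps, steady state, determinism."""

import numpy as np
import pytest

from exoflux import mean_enrichment, normalize_mid
from exoflux.io import iter_mids, write_mid_table
from exoflux.simulate import (
    FRAGMENTS,
    NetworkSpec,
    SimulationConfig,
    check_carbon_conservation,
    independent_pattern,
    pattern_to_mid,
    preset_config,
    remap_bits,
    simulate_exosome_transfer,
    simulate_mids,
    steady_state_isotopomers,
    symmetrize,
)


def mid_of(state, metabolite, n):
    return pattern_to_mid(state[metabolite], n)


class TestPatternPrimitives:
    def test_independent_pattern_collapses_to_binomial(self):
        dist = independent_pattern(4, 0.3)
        mid = pattern_to_mid(dist, 4)
        from scipy.stats import binom

        assert np.allclose(mid, binom.pmf(np.arange(5), 4, 0.3), atol=1e-12)

    def test_remap_is_mass_preserving(self, rng):
        dist = rng.dirichlet(np.ones(16))
        out = remap_bits(dist, 4, {0: 3, 1: 2, 2: 1, 3: 0}, 4)
        assert out.sum() == pytest.approx(1.0)
        assert np.allclose(np.sort(out), np.sort(dist))  # permutation only

    def test_symmetrize_is_idempotent(self, rng):
        dist = rng.dirichlet(np.ones(16))
        once = symmetrize(dist, 4)
        assert np.allclose(symmetrize(once, 4), once, atol=1e-15)


class TestSteadyState:
    def test_unlabeled_tracer_stays_unlabeled(self):
        config = SimulationConfig(tracer="unlabeled", noise_sd=0)
        state = steady_state_isotopomers(config)
        for met, n in (("pyruvate", 3), ("citrate", 6), ("akg", 5), ("malate", 4)):
            mid = mid_of(state, met, n)
            assert mid[0] == pytest.approx(1.0, abs=1e-12)

    def test_pure_reductive_gives_m5_citrate(self):
        config = SimulationConfig(
            tracer="U13C5-glutamine",
            network=NetworkSpec(f_red=1.0, glutamine_share_of_akg=1.0, pdh_share=0.0),
            noise_sd=0,
        )
        mid = mid_of(steady_state_isotopomers(config), "citrate", 6)
        assert mid[5] == pytest.approx(1.0, abs=1e-9)

    def test_pure_oxidative_with_unlabeled_acetyl_gives_m4_citrate(self):
        config = SimulationConfig(
            tracer="U13C5-glutamine",
            network=NetworkSpec(f_red=0.0, glutamine_share_of_akg=1.0, pdh_share=0.0),
            noise_sd=0,
        )
        mid = mid_of(steady_state_isotopomers(config), "citrate", 6)
        assert mid[4] == pytest.approx(1.0, abs=1e-9)

    def test_glucose_mix_triose_arms_give_quarter_m1_pyruvate(self):
        config = SimulationConfig(
            tracer="glucose-1to1-mix",
            network=NetworkSpec(f_ppp=0.0, pyruvate_from_glucose=1.0),
            noise_sd=0,
        )
        mid = mid_of(steady_state_isotopomers(config), "pyruvate", 3)
        assert mid[1] == pytest.approx(0.25, abs=1e-12)
        assert mid[3] == pytest.approx(0.5, abs=1e-12)

    def test_distributions_sum_to_one_everywhere(self):
        config = preset_config("cde", "U13C5-glutamine", noise_sd=0)
        state = steady_state_isotopomers(config)
        for dist in state.values():
            assert dist.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(dist >= -1e-15)

    def test_carbon_conservation_per_reaction(self):
        for tracer in ("U13C5-glutamine", "glucose-1to1-mix", "U13C6-glucose"):
            config = preset_config("cde", tracer, noise_sd=0)
            state = steady_state_isotopomers(config)
            balance = check_carbon_conservation(config, state)
            assert max(balance.values()) < 1e-9, balance

    def test_reductive_share_moves_labels_monotonically(self):
        m5, m4, m3f = [], [], []
        for f_red in (0.1, 0.3, 0.5, 0.7):
            config = SimulationConfig(
                tracer="U13C5-glutamine", network=NetworkSpec(f_red=f_red), noise_sd=0
            )
            state = steady_state_isotopomers(config)
            cit = mid_of(state, "citrate", 6)
            m5.append(cit[5])
            m4.append(cit[4])
            m3f.append(mid_of(state, "fumarate", 4)[3])
        assert np.all(np.diff(m5) > 0)
        assert np.all(np.diff(m4) < 0)
        assert np.all(np.diff(m3f) > 0)


class TestTables:
    def test_mid_table_shape_and_ground_truth(self):
        config = preset_config("control", "U13C5-glutamine", seed=9)
        table, truth = simulate_mids(config)
        mets = set(table["metabolite"])
        assert {"citrate", "akg", "palmitate", "lactate"} <= mets
        assert truth["D_true"] == config.glutamine_share_of_acetyl
        per_met = table.groupby("metabolite").size()
        assert (per_met == config.n_replicates).all()
        for met in mets:
            assert FRAGMENTS[met][1] == int(
                table.loc[table["metabolite"] == met, "backbone_carbons"].iloc[0]
            )

    def test_noise_free_unlabeled_rows_match_natural_background(self):
        config = SimulationConfig(tracer="unlabeled", noise_sd=0, n_replicates=1)
        table, _ = simulate_mids(config)
        for row, mid in iter_mids(table):
            # raw intensities include natural abundance: M0 below 1, M1 > 0
            assert mid.fractions[0] < 1.0
            assert mid.fractions[1] > 0.0

    def test_byte_identical_output_under_fixed_seed(self, tmp_path):
        paths = []
        for run in range(2):
            config = preset_config("cde", "U13C5-glutamine", seed=42)
            table, _ = simulate_mids(config)
            p = tmp_path / f"run{run}.csv"
            write_mid_table(table, p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_seed_changes_noise(self):
        t1, _ = simulate_mids(preset_config("cde", "U13C5-glutamine", seed=1))
        t2, _ = simulate_mids(preset_config("cde", "U13C5-glutamine", seed=2))
        assert not t1.equals(t2)


class TestExosomeTransfer:
    def test_zero_supply_leaves_cells_unlabeled(self):
        from exoflux.io import correct_mid_table

        config = SimulationConfig(
            cargo_supply_fraction={"leucine": 0.0}, noise_sd=0, n_replicates=1
        )
        _, cell, _ = simulate_exosome_transfer(config)
        # raw table carries the natural background; correction removes it
        _, mid = next(iter_mids(correct_mid_table(cell, tracer_purity=1.0), corrected=True))
        assert mid.fractions[0] == pytest.approx(1.0, abs=1e-8)

    def test_full_supply_full_label_reproduces_tracer_pattern(self):
        config = SimulationConfig(
            cargo_supply_fraction={"leucine": 1.0},
            exosome_label_fraction=0.999,
            noise_sd=0,
            n_replicates=1,
        )
        exo, cell, _ = simulate_exosome_transfer(config)
        _, cell_mid = next(iter_mids(cell))
        _, exo_mid = next(iter_mids(exo))
        assert np.allclose(cell_mid.as_array(), exo_mid.as_array(), atol=1e-9)

    def test_turnover_makes_measured_contribution_a_lower_bound(self):
        base = dict(
            cargo_supply_fraction={"lysine": 0.2}, noise_sd=0, n_replicates=1,
            exosome_label_fraction=0.6,
        )
        from exoflux.io import correct_mid_table

        results = {}
        for turnover in (0.0, 0.4):
            config = SimulationConfig(cargo_turnover=turnover, **base)
            exo, cell, truth = simulate_exosome_transfer(config)
            cell_c = correct_mid_table(cell, tracer_purity=1.0)
            exo_c = correct_mid_table(exo, tracer_purity=1.0)
            _, cell_mid = next(iter_mids(cell_c, corrected=True))
            _, exo_mid = next(iter_mids(exo_c, corrected=True))
            results[turnover] = mean_enrichment(cell_mid) / mean_enrichment(exo_mid)
        assert results[0.4] < results[0.0]
        assert results[0.4] == pytest.approx(0.2 * 0.6, abs=0.02)

    def test_label_fraction_must_be_sub_replication(self):
        with pytest.raises(ValueError):
            simulate_exosome_transfer(SimulationConfig(exosome_label_fraction=1.0))


def test_nonsense_configuration_rejected():
    with pytest.raises(ValueError):
        NetworkSpec(f_red=1.4)
    with pytest.raises(ValueError):
        SimulationConfig(glucose_share_of_acetyl=0.8, glutamine_share_of_acetyl=0.4)
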