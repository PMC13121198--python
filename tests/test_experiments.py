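"""Suppression statistics and sweep bookkeeping on fixture inputs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from finblock.experiments import (
    DEFAULT_AMPLITUDES_UA,
    DEFAULT_FREQUENCIES_HZ,
    SweepConfig,
    classify_outcome,
    find_th_sup,
    sp_grid,
    suppression_probability,
    th_sup_table,
)
from finblock.fixtures import make_sweep_fixture, worked_example_sweep


def test_default_grids_match_study_design():
    assert DEFAULT_AMPLITUDES_UA == tuple(float(a) for a in range(0, 401, 40))
    assert len(DEFAULT_AMPLITUDES_UA) == 11
    assert DEFAULT_FREQUENCIES_HZ[:12] == (10., 25., 50., 100., 250., 350.,
                                           450., 500., 550., 650., 750., 1000.)
    assert DEFAULT_FREQUENCIES_HZ[-1] == 10_000.0
    assert len(DEFAULT_FREQUENCIES_HZ) == 21
    cfg = SweepConfig.full_study()
    assert cfg.n_conditions == 2 * 3 * 36 * 3 * 11 * 21


class TestClassifyOutcome:
    @pytest.mark.parametrize("n,base,expected", [
        (1, 6, "maximal"),      # one remaining onset spike
        (0, 6, "maximal"),
        (7, 6, "excitation"),
        (3, 6, "partial"),
        (6, 6, "unaffected"),
        (1, 1, "maximal"),
    ])
    def test_classes(self, n, base, expected):
        assert classify_outcome(n, base) == expected

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            classify_outcome(-1, 6)


class TestSuppressionProbability:
    def test_published_worked_example(self):
        """7/11 amplitudes suppressive for 1.4 um, 9/11 for 2.8 and 4.3 um,
        at all three z-shifts, weighted 0.903/0.094/0.003 -> SP = 0.654."""
        df = worked_example_sweep()
        sp = suppression_probability(df, 0.0, 0.0, 10_000.0)
        expected = (7 * 3 * 0.903 + 9 * 3 * 0.094 + 9 * 3 * 0.003) / (33 * 1.0)
        assert sp == pytest.approx(expected, abs=1e-12)
        assert sp == pytest.approx(0.654, abs=5e-4)

    def test_no_suppression_gives_zero(self):
        df = make_sweep_fixture({1.4: None, 2.8: None, 4.3: None})
        assert suppression_probability(df, 0.0, 0.0, 10_000.0) == 0.0

    def test_full_suppression_saturates(self):
        """Every condition suppressed: SP = 1 without the zero-amplitude
        baseline in the denominator, 10/11 with it."""
        df = make_sweep_fixture({1.4: 40.0, 2.8: 40.0, 4.3: 40.0})
        sp_fin_only = suppression_probability(df, 0.0, 0.0, 10_000.0,
                                              include_zero_amplitude=False)
        assert sp_fin_only == pytest.approx(1.0)
        sp_all = suppression_probability(df, 0.0, 0.0, 10_000.0)
        assert sp_all == pytest.approx(10.0 / 11.0)

    def test_invariant_under_row_permutation(self, rng):
        df = worked_example_sweep()
        shuffled = df.sample(frac=1.0, random_state=7).reset_index(drop=True)
        assert suppression_probability(shuffled, 0.0, 0.0, 10_000.0) == \
            suppression_probability(df, 0.0, 0.0, 10_000.0)

    def test_invariant_under_z_shift_relabelling(self):
        df = worked_example_sweep()
        relabel = {0.0: 0.5, 0.25: 0.0, 0.5: 0.25}
        swapped = df.assign(z_shift=df["z_shift"].map(relabel))
        assert suppression_probability(swapped, 0.0, 0.0, 10_000.0) == \
            suppression_probability(df, 0.0, 0.0, 10_000.0)

    def test_missing_condition_is_reported(self):
        df = worked_example_sweep()
        dropped = df[~((df["d_f"] == 2.8) & (df["z_shift"] == 0.25)
                       & (df["amplitude_ua"] == 80.0))]
        with pytest.raises(ValueError, match="missing"):
            suppression_probability(dropped, 0.0, 0.0, 10_000.0)

    def test_mixed_cell_types_need_selector(self):
        df = worked_example_sweep()
        other = df.assign(cell_type="OFF")
        both = pd.concat([df, other], ignore_index=True)
        with pytest.raises(ValueError, match="cell_type"):
            suppression_probability(both, 0.0, 0.0, 10_000.0)
        assert suppression_probability(both, 0.0, 0.0, 10_000.0,
                                       cell_type="ON") == \
            suppression_probability(df, 0.0, 0.0, 10_000.0)

    def test_sp_grid_bounds(self):
        grid = sp_grid(worked_example_sweep())
        assert ((grid["sp"] >= 0) & (grid["sp"] <= 1)).all()


@pytest.fixture(scope="module")
def tiny_run():
    from finblock.experiments import run_sweep
    from finblock.fixtures import fibre_grid_spec, make_field_fixture
    zeros = make_field_fixture("zeros", fibre_grid_spec(200.0))
    cfg = SweepConfig(amplitudes_ua=(0.0, 80.0),
                      frequencies_hz=(1000.0,),
                      z_shifts=(0.0,),
                      diameters_um=(1.4, 4.3),
                      cell_types=("ON",))
    cache = {}
    return cfg, zeros, run_sweep(cfg, zeros, cache=cache), cache


class TestSweepOrchestration:
    """Bookkeeping checks on a null-coupling sweep (the zero field makes
    every FIN condition reproduce its baseline, so these run quickly while
    exercising the full orchestration path)."""

    def test_one_row_per_condition(self, tiny_run):
        cfg, _, df, _ = tiny_run
        assert len(df) == cfg.n_conditions == 4
        key = ["cell_type", "d_f", "x", "y", "z_shift", "amplitude_ua",
               "frequency_hz"]
        assert not df.duplicated(subset=key).any()
        assert (df.loc[df["amplitude_ua"] == 0, "n_spike"]
                == df.loc[df["amplitude_ua"] == 0, "baseline_n_spike"]).all()

    def test_null_field_rows_are_unaffected(self, tiny_run):
        _, _, df, _ = tiny_run
        assert (df["outcome"] == "unaffected").all()

    def test_rerun_from_cache_is_identical_and_free(self, tiny_run):
        from finblock.experiments import run_sweep
        cfg, zeros, df, cache = tiny_run
        before = dict(cache)
        again = run_sweep(cfg, zeros, cache=cache)
        pd.testing.assert_frame_equal(df, again)
        assert cache == before  # nothing re-simulated

    def test_fin_alone_turns_off_the_soma_drive(self, tiny_run):
        """With a null field and no soma drive nothing spikes anywhere."""
        from finblock.experiments import fin_alone
        cfg, zeros, _, _ = tiny_run
        df = fin_alone(cfg, zeros)
        assert (df["n_spike"] == 0).all()
        assert (df["baseline_n_spike"] == 0).all()

    def test_gna_identity_factor_matches_unperturbed(self, tiny_run):
        from finblock.experiments import gna_experiment
        cfg, zeros, df, _ = tiny_run
        tab = gna_experiment(cfg, zeros, factors=(1.0,))
        base = th_sup_table(df)
        merged = tab.merge(base, on=["cell_type", "d_f", "frequency_hz"],
                           suffixes=("_pert", "_base"))
        assert len(merged) == len(base)
        for _, r in merged.iterrows():
            a, b = r["th_sup_ua_pert"], r["th_sup_ua_base"]
            assert (pd.isna(a) and pd.isna(b)) or a == b

    def test_gna_rejects_nonpositive_factor(self, tiny_run):
        from finblock.experiments import gna_experiment
        cfg, zeros, _, _ = tiny_run
        with pytest.raises(ValueError):
            gna_experiment(cfg, zeros, factors=(0.0,))


class TestFindThSup:
    def test_monotone_series(self):
        n = [6, 6, 6, 1, 1, 1, 1, 1, 1, 1, 1]
        assert find_th_sup(DEFAULT_AMPLITUDES_UA, n) == 120.0

    def test_reappearance_at_top_gives_none(self):
        n = [6, 6, 6, 1, 1, 1, 1, 1, 1, 1, 4]
        assert find_th_sup(DEFAULT_AMPLITUDES_UA, n) is None

    def test_all_baseline_gives_none(self):
        assert find_th_sup(DEFAULT_AMPLITUDES_UA, [6] * 11) is None

    def test_mid_series_reappearance_skipped(self):
        n = [6, 1, 1, 6, 1, 1, 1, 1, 1, 1, 1]
        assert find_th_sup(DEFAULT_AMPLITUDES_UA, n) == 160.0

    def test_zero_amplitude_never_counts(self):
        """A silent baseline does not make 0 uA a suppression threshold."""
        n = [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
        assert find_th_sup(DEFAULT_AMPLITUDES_UA, n) == 40.0

    def test_unsorted_amplitudes_rejected(self):
        with pytest.raises(ValueError):
            find_th_sup([40.0, 0.0], [1, 1])

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.integers(0, 8), min_size=11, max_size=11),
           st.data())
    def test_matches_brute_force_scan(self, n_spikes, data):
        """Oracle: explicit scan over candidate thresholds."""
        amps = list(DEFAULT_AMPLITUDES_UA)

        def brute(a, n):
            for i in range(len(a)):
                if a[i] > 0 and all(x <= 1 for x in n[i:]):
                    return a[i]
            return None

        assert find_th_sup(amps, n_spikes) == brute(amps, n_spikes)

    def test_fixture_thresholds_recovered(self):
        df = make_sweep_fixture({(1.4, 0.0): 80.0, (1.4, 0.25): 120.0,
                                 (1.4, 0.5): None, 2.8: 200.0, 4.3: 40.0})
        truth = df.attrs["th_true"]
        for (d, z), th in truth.items():
            sel = df[(df["d_f"] == d) & (df["z_shift"] == z)].sort_values(
                "amplitude_ua")
            assert find_th_sup(sel["amplitude_ua"].to_numpy(),
                               sel["n_spike"].to_numpy()) == th

    def test_th_sup_table_layout(self):
        df = make_sweep_fixture({1.4: 160.0, 2.8: 80.0, 4.3: None})
        tab = th_sup_table(df, 0.0, 0.0, 0.0)
        assert set(tab.columns) == {"cell_type", "d_f", "frequency_hz",
                                    "th_sup_ua"}
        by_d = tab.set_index("d_f")["th_sup_ua"]
        assert by_d[1.4] == 160.0
        assert by_d[2.8] == 80.0
        assert by_d[4.3] is None or np.isnan(by_d[4.3])
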