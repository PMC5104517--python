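"""Simulator unit and property tests: initialization, dynamics, stretch, beads."""

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from straincycle import (
    CONDITIONS,
    Condition,
    CycleParams,
    FieldParams,
    advance_state,
    apply_stretch,
    condition_from_name,
    equilibrate_cycle,
    initialize_quiescent_monolayer,
    simulate_bead_fixture,
)
from straincycle.simulate import _sample_tail_activity, effective_activity
from straincycle.timelapse import simulate_timelapse


def positions(state):
    return np.array([(c.x, c.y) for c in state.cells])


class TestInitialize:
    def test_default_density_and_quiescence(self):
        """~430 cells on a 0.43 mm^2 field at 1000 cells/mm^2, >=95% in G0."""
        state = initialize_quiescent_monolayer(seed=5)
        n = len(state.cells)
        area = FieldParams().area_mm2
        assert n / area == pytest.approx(1000.0, rel=0.15)
        assert state.phase_fractions()["G0"] >= 0.95

    def test_deterministic_given_seed(self):
        a = initialize_quiescent_monolayer(seed=3)
        b = initialize_quiescent_monolayer(seed=3)
        assert positions(a).tolist() == positions(b).tolist()
        assert [c.phase for c in a.cells] == [c.phase for c in b.cells]
        assert [c.red_level for c in a.cells] == [c.red_level for c in b.cells]

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"density_per_mm2": 0.0},
            {"density_per_mm2": -5.0},
            {"field_size": (0.0, 100.0)},
            {"field_size": (100.0, -1.0)},
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            initialize_quiescent_monolayer(seed=0, **kwargs)

    def test_positions_inside_field(self, small_state):
        pts = positions(small_state)
        w, h = small_state.field_size
        assert (pts[:, 0] >= 0).all() and (pts[:, 0] <= w).all()
        assert (pts[:, 1] >= 0).all() and (pts[:, 1] <= h).all()

    def test_equilibrated_green_fraction_matches_flux_balance(self):
        """At the basal steady state, S/G2 occupancy = flux x dwell (~10%)."""
        p = CycleParams()
        expected = p.nominal_s_entry_flux * p.nominal_sg2_dwell_h
        fracs = []
        for seed in (1, 2, 3):
            state = initialize_quiescent_monolayer(seed=seed)
            equilibrate_cycle(state)
            f = state.phase_fractions()
            fracs.append(f["S"] + f["G2"])
        assert np.mean(fracs) == pytest.approx(expected, abs=0.02)


class TestAdvance:
    def test_control_sg2_fraction_stationary(self):
        """Control monolayers hold a low, constant S/G2 pool (~10%)."""
        slopes, means = [], []
        for seed in (1, 2, 3):
            _, truth = simulate_timelapse(
                Condition(), 24.0, seed=seed, render=False
            )
            frac = truth.cells.groupby("frame")["phase"].apply(
                lambda s: s.isin(["S", "G2"]).mean()
            )
            hours = np.arange(len(frac)) * 0.25
            slopes.append(np.polyfit(hours, frac.to_numpy(), 1)[0])
            means.append(frac.mean())
        assert abs(np.mean(slopes)) < 0.002
        assert np.mean(means) == pytest.approx(0.10, abs=0.03)

    def test_icrt3_blocks_all_s_entries(self):
        cond = condition_from_name("strain-d4476-icrt3")
        _, truth = simulate_timelapse(cond, 24.0, seed=4, render=False)
        assert truth.n_s_entries() == 0
        assert truth.n_mitoses() == 0

    def test_frozen_kinetics_leave_phases_unchanged(self, frozen_params, small_field):
        state = initialize_quiescent_monolayer(
            seed=7, field_params=small_field
        )
        equilibrate_cycle(state)
        state.params = frozen_params
        before = [(c.cell_id, c.phase) for c in state.cells]
        advance_state(state, 1.0, Condition())
        after = [(c.cell_id, c.phase) for c in state.cells]
        assert before == after
        assert state.time == 1.0

    def test_dt_must_be_positive(self, small_state):
        with pytest.raises(ValueError):
            advance_state(small_state, 0.0, Condition())

    def test_cell_count_ledger(self):
        """Final count = initial count + mitoses; divisions add exactly one."""
        _, truth = simulate_timelapse(
            condition_from_name("strain-wnt"), 12.0, seed=2, render=False
        )
        first = (truth.cells["frame"] == 0).sum()
        last_frame = truth.cells["frame"].max()
        last = (truth.cells["frame"] == last_frame).sum()
        assert last == first + truth.n_mitoses()
        mit = truth.events[truth.events["type"] == "mitosis"]
        assert (mit["daughter1_id"] >= 0).all() and (mit["daughter2_id"] >= 0).all()
        assert (mit["daughter1_id"] != mit["daughter2_id"]).all()

    def test_green_only_in_s_g2_m(self):
        _, truth = simulate_timelapse(Condition(), 8.0, seed=9, render=False)
        red_phases = truth.cells[truth.cells["phase"].isin(["G0", "G1"])]
        assert (red_phases["green"] == 0).all()

    def test_basal_trigger_activity_clears_upper_threshold(self):
        p = CycleParams()
        rng = np.random.default_rng(0)
        samples = _sample_tail_activity(rng, p, 500)
        assert (samples >= p.theta2).all()

    def test_icrt3_zeroes_effective_activity(self):
        p = CycleParams()
        cond = Condition(strain_applied=True, wnt=True, icrt3=True)
        assert effective_activity(5.0, 10.0, cond, p) == 0.0


class TestDeterminism:
    def test_identical_seed_gives_identical_ground_truth(self):
        cond = condition_from_name("strain-wnt")
        _, a = simulate_timelapse(cond, 6.0, seed=13, render=False)
        _, b = simulate_timelapse(cond, 6.0, seed=13, render=False)
        assert_frame_equal(a.cells, b.cells)
        assert_frame_equal(a.events, b.events)

    def test_duration_zero_gives_single_consistent_frame(self):
        _, truth = simulate_timelapse(Condition(), 0.0, seed=1, render=False)
        assert truth.cells["frame"].nunique() == 1
        assert truth.events.empty


class TestStretch:
    def test_identity_factor(self, small_state):
        before = positions(small_state)
        apply_stretch(small_state, 1.0)
        assert np.allclose(positions(small_state), before)

    def test_pairwise_distances_scale_exactly(self, small_state):
        """Brute-force all-pairs check of the similarity transform."""
        before = positions(small_state)
        d_before = np.linalg.norm(before[:, None] - before[None, :], axis=2)
        apply_stretch(small_state, 1.085)
        after = positions(small_state)
        d_after = np.linalg.norm(after[:, None] - after[None, :], axis=2)
        assert np.allclose(d_after, 1.085 * d_before)
        assert small_state.field_size[0] == pytest.approx(160.0 * 1.085)

    def test_shrink_rejected(self, small_state):
        with pytest.raises(ValueError):
            apply_stretch(small_state, 0.9)


class TestBeadFixture:
    def test_noiseless_is_exact_dilation(self):
        pre, post = simulate_bead_fixture(50, 1.085, 0.0, seed=2)
        centre = np.array([328.0, 328.0])
        assert np.allclose(post, centre + 1.085 * (pre - centre))

    def test_matched_order_and_minimal_n(self):
        pre, post = simulate_bead_fixture(3, 1.05, 0.0, seed=0)
        assert pre.shape == post.shape == (3, 2)

    def test_too_few_beads_rejected(self):
        with pytest.raises(ValueError):
            simulate_bead_fixture(2, 1.05, 0.0, seed=0)


class TestConditions:
    def test_known_names(self):
        assert set(CONDITIONS) == {
            "control", "strain", "wnt", "strain-wnt", "d4476",
            "strain-d4476", "strain-d4476-icrt3",
        }
        with pytest.raises(ValueError):
            condition_from_name("mystery")

    def test_stretch_factor_validated(self):
        with pytest.raises(ValueError):
            Condition(stretch_factor=0.5)
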