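import numpy as np
import pytest

import oracles
from conftest import make_state
from loomcd.direction_nets import (
    DIRECTIONS,
    InhibitoryLayer,
    decay_inhibition,
    distance_weighted_inhibition,
    hemicircle_offsets,
    layer_excitation,
    make_layers,
    update_i_potentials,
)


def fresh_layer(direction="right", shape=(10, 10)):
    return make_layers(shape)[direction]


class TestHemicircle:
    def test_eleven_offsets_for_every_direction(self):
        for d in DIRECTIONS:
            offsets = hemicircle_offsets(d)
            assert len(offsets) == 11
            assert all(np.hypot(dx, dy) <= 3.0 for dx, dy in offsets)

    def test_offsets_lie_strictly_on_the_null_side(self):
        assert all(dx >= 1 for dx, dy in hemicircle_offsets("right"))
        assert all(dx <= -1 for dx, dy in hemicircle_offsets("left"))
        assert all(dy <= -1 for dx, dy in hemicircle_offsets("up"))
        assert all(dy >= 1 for dx, dy in hemicircle_offsets("down"))

    def test_radius_one_has_single_offset(self):
        assert hemicircle_offsets("right", radius=1) == [(1, 0)]

    def test_layers_are_quarter_turn_rotations(self):
        right = set(hemicircle_offsets("right"))
        up = set(hemicircle_offsets("up"))
        assert up == {(dy, -dx) for dx, dy in right}


class TestDistanceWeightedInhibition:
    def test_zero_input_gives_zero(self):
        layer = fresh_layer()
        assert (distance_weighted_inhibition(np.zeros((10, 10)), layer) == 0).all()

    def test_single_adjacent_neighbour(self):
        layer = fresh_layer()
        e = np.zeros((10, 10))
        e[5, 6] = 2.0  # offset (1, 0) from focal (5, 5)
        i_dist = distance_weighted_inhibition(e, layer)
        assert i_dist[5, 5] == pytest.approx(0.35 * 2.0)

    def test_uniform_field_interior_lattice_sum(self):
        layer = fresh_layer()
        e = np.ones((10, 10))
        expected = 0.35 * sum(1 / np.hypot(dx, dy) for dx, dy in layer.offsets)
        assert distance_weighted_inhibition(e, layer)[5, 4] == pytest.approx(expected)

    def test_border_offsets_contribute_nothing(self):
        layer = fresh_layer()
        e = np.ones((10, 10))
        # rightmost column: the whole hemicircle falls outside the frame
        assert distance_weighted_inhibition(e, layer)[5, 9] == 0.0

    @pytest.mark.parametrize("direction", DIRECTIONS)
    def test_matches_loop_oracle(self, direction, rng):
        layer = fresh_layer(direction, (12, 14))
        e = rng.uniform(0, 3, (12, 14))
        ours = distance_weighted_inhibition(e, layer)
        assert np.allclose(ours, oracles.i_dist(e, layer.offsets), atol=1e-9)


class TestDecay:
    @pytest.mark.parametrize(
        "stored, counter, expected", [(5.0, 1, 3.0), (5.0, 3, 0.0), (5.0, 0, 5.0)]
    )
    def test_linear_decay_clamped_at_zero(self, stored, counter, expected):
        layer = fresh_layer(shape=(1, 1))
        layer.stored_inhibition = np.array([[stored]])
        layer.decay_counter = np.array([[counter]])
        assert decay_inhibition(layer)[0, 0] == expected


class TestUpdate:
    def test_i_potential_is_excitation_minus_decay(self):
        layer = fresh_layer(shape=(1, 1))
        layer.stored_inhibition = np.array([[0.5]])
        update_i_potentials(np.array([[2.0]]), layer, np.zeros((1, 1)))
        assert layer.i_potentials[0, 0] == pytest.approx(1.5)

    def test_negative_i_potentials_clamped(self):
        layer = fresh_layer(shape=(1, 1))
        layer.stored_inhibition = np.array([[2.0]])
        update_i_potentials(np.array([[0.5]]), layer, np.zeros((1, 1)))
        assert layer.i_potentials[0, 0] == 0.0

    def test_reset_rule_saves_fresh_inhibition(self):
        layer = fresh_layer(shape=(1, 1))
        layer.stored_inhibition = np.array([[1.0]])
        # fresh 3.0 exceeds decayed 1.0 by more than 1.5: save and restart
        update_i_potentials(np.zeros((1, 1)), layer, np.array([[3.0]]))
        assert layer.stored_inhibition[0, 0] == 3.0
        assert layer.decay_counter[0, 0] == 0

    def test_counter_advances_without_reset(self):
        layer = fresh_layer(shape=(1, 1))
        layer.stored_inhibition = np.array([[1.0]])
        update_i_potentials(np.zeros((1, 1)), layer, np.array([[2.0]]))  # 2 < 1+1.5
        assert layer.stored_inhibition[0, 0] == 1.0
        assert layer.decay_counter[0, 0] == 1

    def test_one_step_delay_trace(self):
        # excitation saved at step 1 first inhibits at step 2 (the stored
        # value passes the reset threshold 1.5 and is applied undecayed)
        layer = fresh_layer(shape=(3, 5))
        e1 = np.zeros((3, 5))
        e1[1, 2] = 5.0
        update_i_potentials(e1, layer)
        assert layer.i_potentials[1, 1] == 0.0  # nothing to inhibit yet
        assert layer.stored_inhibition[1, 1] == pytest.approx(0.35 * 5.0)
        e2 = np.zeros((3, 5))
        e2[1, 1] = 4.0  # leftward (null-direction) displacement
        update_i_potentials(e2, layer)
        assert layer.i_potentials[1, 1] == pytest.approx(4.0 - 0.35 * 5.0)

    def test_i_potentials_never_negative(self, rng):
        layers = make_layers((16, 16))
        for _ in range(6):
            e = np.where(rng.random((16, 16)) < 0.3, rng.uniform(0, 4, (16, 16)), 0.0)
            for d in DIRECTIONS:
                update_i_potentials(e, layers[d])
                assert (layers[d].i_potentials >= 0).all()

    @pytest.mark.parametrize("seed", range(3))
    def test_i_potential_matches_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        layer = fresh_layer(shape=(12, 14))
        layer.stored_inhibition = rng.uniform(0, 5, (12, 14))
        layer.decay_counter = rng.integers(0, 4, (12, 14))
        stored, counter = layer.stored_inhibition.copy(), layer.decay_counter.copy()
        e = rng.uniform(0, 4, (12, 14))
        update_i_potentials(e, layer, np.zeros((12, 14)))
        assert np.allclose(
            layer.i_potentials, oracles.i_potential(e, stored, counter), atol=1e-9
        )


class TestRotationEquivariance:
    def test_quarter_turn_permutes_layers_exactly(self, rng):
        """np.rot90 maps rightward motion to upward motion; the up layer on
        the rotated input must equal the rotated right layer, exactly."""
        shape = (12, 12)
        e_seq = [
            np.where(rng.random(shape) < 0.3, rng.uniform(0, 4, shape), 0.0)
            for _ in range(5)
        ]
        layers = make_layers(shape)
        layers_rot = make_layers(shape)
        perm = {"right": "up", "up": "left", "left": "down", "down": "right"}
        for e in e_seq:
            e_rot = np.rot90(e)
            for d in DIRECTIONS:
                update_i_potentials(e, layers[d])
                update_i_potentials(e_rot, layers_rot[d])
        for d in DIRECTIONS:
            # equal up to float summation order in the kernel correlation
            assert np.allclose(
                layers_rot[perm[d]].i_potentials,
                np.rot90(layers[d].i_potentials),
                atol=1e-12,
            )


class TestLayerExcitation:
    def make_zone(self):
        from loomcd.danger_zone import build_zone

        return build_zone((20, 20), center=(10, 10), radius=8.0, top_exclusion=0.0,
                          bottom_exclusion=0.0)

    def set_i(self, layer, i):
        layer.i_potentials = i

    def test_all_subthreshold_gives_zero(self):
        zone = self.make_zone()
        layer = fresh_layer(shape=(20, 20))
        self.set_i(layer, np.where(zone.mask, 0.1, 0.0))  # not > 0.1
        assert layer_excitation(layer, zone).value == 0.0

    def test_strong_members_weighting(self):
        zone = self.make_zone()
        layer = fresh_layer(shape=(20, 20))
        i = np.zeros((20, 20))
        members = np.argwhere(zone.mask)[:10]
        for r, c in members:
            i[r, c] = 2.0
        self.set_i(layer, i)
        exc = layer_excitation(layer, zone)
        assert exc.m == 10
        assert exc.value == pytest.approx((10 / zone.s) * 20.0)

    def test_weak_activity_annihilated_by_m_weight(self):
        zone = self.make_zone()
        layer = fresh_layer(shape=(20, 20))
        self.set_i(layer, np.where(zone.mask, 0.9, 0.0))  # > 0.1 but none > 1.0
        exc = layer_excitation(layer, zone)
        assert exc.m == 0 and exc.value == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_loop_oracle(self, seed):
        zone = self.make_zone()
        rng = np.random.default_rng(seed)
        layer = fresh_layer(shape=(20, 20))
        self.set_i(layer, rng.uniform(0, 2, (20, 20)))
        members = [(c, r) for r, c in np.argwhere(zone.mask)]
        expected = oracles.layer_excitation(layer.i_potentials, members, zone.s)
        assert layer_excitation(layer, zone).value == pytest.approx(expected, abs=1e-9)
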