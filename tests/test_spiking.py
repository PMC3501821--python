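"""Rank-order encoding, PSP accumulation, map training and classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spikeface.errors import DataError, DimensionError, ParameterError, StateError
from spikeface.spiking import (
    IFNeuron,
    InhibitionProfile,
    NeuronalMap,
    SpikeWave,
    classify,
    compute_psp,
    encode_rank_order,
    fires,
    lateral_inhibition,
    set_thresholds,
    train_map,
)


class TestEncodeRankOrder:
    def test_descending_sort_example(self):
        wave = encode_rank_order(np.array([0.9, 0.1, 0.5]), 1.0)
        assert wave.order_of == {0: 0, 2: 1, 1: 2}

    def test_keep_frac_selects_largest(self, rng):
        a = rng.random(100)
        wave = encode_rank_order(a, 0.1)
        assert wave.n_spikes == 10
        top10 = set(np.argsort(-a)[:10])
        assert set(wave.neuron_ids.tolist()) == top10

    def test_zero_activations_never_spike(self):
        wave = encode_rank_order(np.array([0.0, 0.3, 0.0, 0.1]), 1.0)
        assert set(wave.neuron_ids.tolist()) == {1, 3}

    def test_all_zero_gives_empty_wave(self):
        wave = encode_rank_order(np.zeros(5), 1.0)
        assert wave.n_spikes == 0

    def test_ties_broken_by_ascending_index(self):
        wave = encode_rank_order(np.array([0.5, 0.9, 0.5]), 1.0)
        np.testing.assert_array_equal(wave.neuron_ids, [1, 0, 2])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_monotone_transform_invariance(self, seed):
        """Rank coding sees only the order, not the values."""
        a = np.random.default_rng(seed).random(30) + 0.01
        base = encode_rank_order(a, 0.5)
        for f in (np.sqrt, np.square, lambda x: np.log1p(10 * x)):
            other = encode_rank_order(f(a), 0.5)
            np.testing.assert_array_equal(base.neuron_ids, other.neuron_ids)

    def test_one_spike_discipline(self, rng):
        for _ in range(20):
            wave = encode_rank_order(rng.random(50), rng.uniform(0.1, 1.0))
            assert np.unique(wave.neuron_ids).size == wave.n_spikes

    @pytest.mark.parametrize("bad", [-0.1, 0.0, 1.5])
    def test_keep_frac_domain(self, bad):
        with pytest.raises(ParameterError):
            encode_rank_order(np.ones(4), bad)

    def test_negative_activation_rejected(self):
        with pytest.raises(ParameterError):
            encode_rank_order(np.array([0.1, -0.2]), 1.0)


class TestComputePsp:
    def test_empty_wave_is_zero(self):
        wave = encode_rank_order(np.zeros(3), 1.0)
        neuron = IFNeuron(weights=np.ones(3), threshold=0.0, mod=0.5)
        assert compute_psp(wave, neuron) == 0.0

    def test_single_spike_rank_zero(self):
        wave = SpikeWave(neuron_ids=np.array([1]), values=np.array([0.7]), n_inputs=3)
        neuron = IFNeuron(weights=np.array([0.0, 0.42, 0.0]), threshold=0.0, mod=0.5)
        assert compute_psp(wave, neuron) == pytest.approx(0.42)

    def test_geometric_hand_example(self):
        wave = SpikeWave(
            neuron_ids=np.array([0, 1, 2]), values=np.array([3.0, 2.0, 1.0]), n_inputs=3
        )
        neuron = IFNeuron(weights=np.ones(3), threshold=0.0, mod=0.5)
        assert compute_psp(wave, neuron) == pytest.approx(1.75)

    def test_length_mismatch(self):
        wave = encode_rank_order(np.ones(4), 1.0)
        neuron = IFNeuron(weights=np.ones(3), threshold=0.0, mod=0.5)
        with pytest.raises(DimensionError):
            compute_psp(wave, neuron)

    def test_matches_naive_loop_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            a = rng.random(n) * (rng.random(n) > 0.2)
            mod = float(rng.uniform(0.1, 0.99))
            w = rng.standard_normal(n)
            wave = encode_rank_order(a, 1.0)
            neuron = IFNeuron(weights=w, threshold=0.0, mod=mod)
            expected = sum(
                mod**rank * w[j] for j, rank in wave.order_of.items()
            )
            assert abs(compute_psp(wave, neuron) - expected) <= 1e-12

    def test_psp_bounded_by_geometric_series(self, rng):
        for mod in (0.3, 0.7, 0.95):
            a = rng.random(200)
            w = rng.random(200)  # weights in [0, 1]
            wave = encode_rank_order(a, 1.0)
            neuron = IFNeuron(weights=w, threshold=0.0, mod=mod)
            assert compute_psp(wave, neuron) < 1.0 / (1.0 - mod)


class TestFires:
    def test_boundary_is_inclusive(self):
        neuron = IFNeuron(weights=np.ones(1), threshold=1.0, mod=0.5)
        assert fires(neuron, 1.0)
        assert not fires(neuron, 1.0 - 1e-12)

    def test_zero_threshold_always_fires(self):
        neuron = IFNeuron(weights=np.ones(1), threshold=0.0, mod=0.5)
        assert fires(neuron, 0.0)


def _blank(label, n, mod=0.5):
    return NeuronalMap(class_label=label, shared_weights=np.zeros(n), mod=mod)


class TestTrainMap:
    def test_single_wave_rank_zero_weight_one(self):
        wave = SpikeWave(neuron_ids=np.array([2]), values=np.array([1.0]), n_inputs=4)
        out = train_map(_blank("c", 4), [wave], 0.5)
        np.testing.assert_allclose(out.shared_weights, [0, 0, 1.0, 0])

    def test_duplicate_waves_average_to_same(self):
        wave = encode_rank_order(np.array([0.9, 0.5, 0.1, 0.0]), 1.0)
        one = train_map(_blank("c", 4), [wave], 0.5)
        two = train_map(_blank("c", 4), [wave, wave], 0.5)
        np.testing.assert_allclose(one.shared_weights, two.shared_weights)

    def test_partial_presence_hand_example(self):
        # rank 1 in wave A (0.5), absent in wave B -> (0.5 + 0)/2
        wave_a = SpikeWave(
            neuron_ids=np.array([0, 3]), values=np.array([0.9, 0.4]), n_inputs=4
        )
        wave_b = SpikeWave(neuron_ids=np.array([1]), values=np.array([1.0]), n_inputs=4)
        out = train_map(_blank("c", 4), [wave_a, wave_b], 0.5)
        assert out.shared_weights[3] == pytest.approx(0.25)

    def test_batch_equals_mean_of_singles(self, rng):
        waves = [encode_rank_order(rng.random(10), 0.6) for _ in range(5)]
        batch = train_map(_blank("c", 10), waves, 0.7)
        singles = [train_map(_blank("c", 10), [w], 0.7).shared_weights for w in waves]
        np.testing.assert_allclose(batch.shared_weights, np.mean(singles, axis=0))

    def test_empty_training_set(self):
        with pytest.raises(DataError):
            train_map(_blank("c", 4), [], 0.5)


class TestSetThresholds:
    def _setup(self, rng):
        waves = {
            "a": [encode_rank_order(rng.random(20), 1.0) for _ in range(4)],
            "b": [encode_rank_order(rng.random(20), 1.0) for _ in range(4)],
        }
        maps = [
            train_map(_blank(c, 20), waves[c], 0.9) for c in ("a", "b")
        ]
        return maps, waves

    def test_margin_one_guarantees_own_fire(self, rng):
        maps, waves = self._setup(rng)
        maps = set_thresholds(maps, waves, 1.0)
        for nmap in maps:
            for wave in waves[nmap.class_label]:
                assert nmap.psp(wave) >= nmap.threshold

    def test_margin_zero_zeroes_thresholds(self, rng):
        maps, waves = self._setup(rng)
        maps = set_thresholds(maps, waves, 0.0)
        assert all(m.threshold == 0.0 for m in maps)

    def test_margin_below_one_strictly_clears(self, rng):
        maps, waves = self._setup(rng)
        maps = set_thresholds(maps, waves, 0.9)
        for nmap in maps:
            for wave in waves[nmap.class_label]:
                assert nmap.psp(wave) > nmap.threshold

    def test_missing_class_waves(self, rng):
        maps, waves = self._setup(rng)
        with pytest.raises(DataError):
            set_thresholds(maps, {"a": waves["a"]}, 0.9)


class TestLateralInhibition:
    def test_single_class_unchanged(self):
        grids = {"a": np.array([[1.0, 0.5]])}
        out = lateral_inhibition(
            grids, InhibitionProfile(0.5, 2.0), {"a": 0.1}
        )
        np.testing.assert_array_equal(out["a"], grids["a"])

    def test_zero_amplitude_is_noop(self):
        grids = {"a": np.array([[1.0]]), "b": np.array([[0.8]])}
        out = lateral_inhibition(grids, InhibitionProfile(0.0, 2.0), {"a": 0.1, "b": 0.1})
        np.testing.assert_array_equal(out["b"], grids["b"])

    def test_colocated_winner_suppresses_loser(self):
        # B drops below its threshold after suppression, so it never
        # fires back and A keeps its full potential
        grids = {"a": np.array([[1.0]]), "b": np.array([[0.8]])}
        out = lateral_inhibition(grids, InhibitionProfile(0.5, 2.0), {"a": 0.5, "b": 0.5})
        assert out["b"][0, 0] == pytest.approx(0.3)
        assert out["a"][0, 0] == pytest.approx(1.0)

    def test_suppressed_survivor_can_fire_back(self):
        # with a low threshold the suppressed map still fires and inhibits
        grids = {"a": np.array([[1.0]]), "b": np.array([[0.8]])}
        out = lateral_inhibition(grids, InhibitionProfile(0.5, 2.0), {"a": 0.1, "b": 0.1})
        assert out["b"][0, 0] == pytest.approx(0.3)
        assert out["a"][0, 0] == pytest.approx(0.5)

    def test_suppression_decays_with_distance(self):
        a = np.zeros((5, 5))
        a[2, 2] = 1.0
        b = np.full((5, 5), 0.5)
        out = lateral_inhibition(
            {"a": a, "b": b}, InhibitionProfile(0.4, 1.0), {"a": 0.9, "b": 10.0}
        )
        assert out["b"][2, 2] == pytest.approx(0.1)
        assert out["b"][2, 4] > out["b"][2, 3] > out["b"][2, 2]

    def test_shape_mismatch(self):
        with pytest.raises(DimensionError):
            lateral_inhibition(
                {"a": np.zeros((2, 2)), "b": np.zeros((3, 3))},
                InhibitionProfile(0.1, 1.0),
                {"a": 0, "b": 0},
            )


def _make_patterns(rng, n_features=60, n_per_class=20, sep=1.0):
    """Two separable activation-pattern classes with within-class jitter."""
    protos = {"alpha": rng.random(n_features), "beta": rng.random(n_features)}
    data = []
    for label, proto in protos.items():
        for _ in range(n_per_class):
            x = proto * sep + 0.15 * rng.random(n_features)
            data.append((np.maximum(x, 0.0), label))
    rng.shuffle(data)
    return data


class TestClassify:
    def _trained(self, rng, data):
        waves = {}
        for x, label in data:
            waves.setdefault(label, []).append(encode_rank_order(x, 0.5))
        maps = [
            train_map(_blank(c, len(data[0][0]), mod=0.95), waves[c], 0.95)
            for c in sorted(waves)
        ]
        return set_thresholds(maps, waves, 0.9)

    def test_all_zero_features_rejected(self, rng):
        maps = self._trained(rng, _make_patterns(rng))
        label, scores = classify(np.zeros(60), maps, 0.5)
        assert label == "rejected"
        assert all(s["raw"] == 0.0 for s in scores.values())

    def test_contrast_and_monotone_invariance(self, rng):
        maps = self._trained(rng, _make_patterns(rng))
        profile = InhibitionProfile(0.05, 1.0)
        for _ in range(25):
            x = rng.random(60) + 0.01
            base, _ = classify(x, maps, 0.5, profile)
            assert classify(3.7 * x, maps, 0.5, profile)[0] == base
            assert classify(np.sqrt(x), maps, 0.5, profile)[0] == base

    def test_separable_patterns_heldout_accuracy(self):
        rng = np.random.default_rng(3)
        train = _make_patterns(rng, n_per_class=20)
        # held-out samples from the same seed-3 prototypes, fresh jitter
        protos_rng = np.random.default_rng(3)
        protos = {"alpha": protos_rng.random(60), "beta": protos_rng.random(60)}
        test_rng = np.random.default_rng(4)
        test = [
            (proto + 0.15 * test_rng.random(60), label)
            for label, proto in protos.items()
            for _ in range(20)
        ]
        maps = self._trained(np.random.default_rng(3), train)
        hits = sum(int(classify(x, maps, 0.5)[0] == label) for x, label in test)
        assert hits / len(test) >= 0.95

    def test_untrained_maps_rejected(self):
        blank = _blank("c", 5)
        with pytest.raises(StateError):
            classify(np.ones(5), [blank], 0.5)
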