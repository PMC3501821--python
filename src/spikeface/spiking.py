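"""Rank-order coding and the integrate-and-fire output layer.

A stimulus is encoded by the *order* in which afferents fire their first
spike (earliest = largest activation), not by rates.  A receiving
integrate-and-fire neuron accumulates

    P(i) = Σ_j mod^order(j) · w_{j,i}

over the spike wave, where mod ∈ (0, 1) is the modulation factor: earlier
spikes dominate, and each afferent spikes at most once.  The neuron emits
a spike iff P(i) ≥ P_th(i).

The supervised output layer holds one neuronal map per class; all neurons
of a map share a single weight vector, set to the average of
mod^order(a_j) over the training waves (Δw_{j,i} = mod^order(a_j)/N), so
each map responds to the average rank pattern of its category.  At
decision time, competing class maps are suppressed inside a Gaussian zone
centred on each firing winner (lateral inhibition); the surviving map
with the highest above-threshold potential gives the label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import (
    DataError,
    DimensionError,
    ParameterError,
    StateError,
)

__all__ = [
    "SpikeWave",
    "IFNeuron",
    "NeuronalMap",
    "InhibitionProfile",
    "encode_rank_order",
    "compute_psp",
    "fires",
    "train_map",
    "set_thresholds",
    "lateral_inhibition",
    "classify",
]


@dataclass(frozen=True)
class SpikeWave:
    """First-spike events of one stimulus, ordered by rank.

    neuron_ids : afferent ids in firing order (index = rank, 0 earliest)
    values : the analog activations that produced those ranks
    n_inputs : total afferent count (spiking or not)
    """

    neuron_ids: np.ndarray
    values: np.ndarray
    n_inputs: int

    def __post_init__(self) -> None:
        ids = np.asarray(self.neuron_ids, dtype=np.int64)
        vals = np.asarray(self.values, dtype=np.float64)
        if ids.ndim != 1 or vals.shape != ids.shape:
            raise DimensionError("neuron_ids and values must be matching 1-D")
        if ids.size and (np.unique(ids).size != ids.size):
            raise ParameterError("a neuron may spike at most once per wave")
        if ids.size and (ids.min() < 0 or ids.max() >= self.n_inputs):
            raise ParameterError("neuron id outside 0..n_inputs-1")
        object.__setattr__(self, "neuron_ids", ids)
        object.__setattr__(self, "values", vals)

    @property
    def n_spikes(self) -> int:
        return int(self.neuron_ids.size)

    @property
    def order_of(self) -> dict[int, int]:
        """Mapping neuron_id -> rank for the neurons that spiked."""
        return {int(j): r for r, j in enumerate(self.neuron_ids)}


def encode_rank_order(activations: np.ndarray, keep_frac: float = 1.0) -> SpikeWave:
    """Rank-order encode an analog activation vector.

    The top ``ceil(keep_frac · n)`` activations spike, ordered by
    descending value with ties broken by ascending index; zero
    activations never spike (an all-zero vector yields an empty wave).
    The code is invariant under any strictly increasing transform of the
    activations that fixes zero.
    """
    a = np.asarray(activations, dtype=np.float64).ravel()
    if not np.all(np.isfinite(a)) or (a.size and a.min() < 0):
        raise ParameterError("activations must be finite and non-negative")
    if not (0.0 < keep_frac <= 1.0):
        raise ParameterError("keep_frac must lie in (0, 1]")
    k = math.ceil(keep_frac * a.size)
    order = np.argsort(-a, kind="stable")[:k]
    order = order[a[order] > 0]
    return SpikeWave(neuron_ids=order, values=a[order], n_inputs=a.size)


@dataclass(frozen=True)
class IFNeuron:
    """Integrate-and-fire unit: afferent weights, threshold, modulation."""

    weights: np.ndarray
    threshold: float
    mod: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if not np.all(np.isfinite(w)):
            raise ParameterError("weights must be finite")
        if not (0.0 < self.mod < 1.0):
            raise ParameterError("mod must lie strictly in (0, 1)")
        if self.threshold < 0:
            raise ParameterError("threshold must be non-negative")
        object.__setattr__(self, "weights", w)


def compute_psp(wave: SpikeWave, neuron: IFNeuron) -> float:
    """P = Σ_j mod^order(j) · w_{j}; afferents that never spiked add 0."""
    return _psp(wave, neuron.weights, neuron.mod)


def _psp(wave: SpikeWave, weights: np.ndarray, mod: float) -> float:
    if weights.size != wave.n_inputs:
        raise DimensionError(
            f"wave has {wave.n_inputs} afferents, weights {weights.size}"
        )
    if wave.n_spikes == 0:
        return 0.0
    ranks = np.arange(wave.n_spikes, dtype=np.float64)
    return float(np.sum(mod**ranks * weights[wave.neuron_ids]))


def fires(neuron: IFNeuron, psp: float) -> bool:
    """Output spike iff psp >= threshold (inclusive boundary)."""
    return bool(psp >= neuron.threshold)


@dataclass(frozen=True)
class NeuronalMap:
    """A class-labelled map of IF neurons sharing one weight vector.

    Every neuron in the ``grid_shape`` grid references the same
    ``shared_weights``; with a flat (non-spatial) feature vector the grid
    degenerates to a single neuron.
    """

    class_label: str
    shared_weights: np.ndarray
    mod: float
    threshold: float | None = None
    n_trained: int = 0
    grid_shape: tuple[int, int] = (1, 1)

    def __post_init__(self) -> None:
        if not (0.0 < self.mod < 1.0):
            raise ParameterError("mod must lie strictly in (0, 1)")
        object.__setattr__(
            self, "shared_weights", np.asarray(self.shared_weights, dtype=np.float64)
        )

    def psp(self, wave: SpikeWave) -> float:
        return _psp(wave, self.shared_weights, self.mod)


def train_map(nmap: NeuronalMap, waves: list[SpikeWave], mod: float) -> NeuronalMap:
    """Batch-average supervised update: w_j = (1/N) Σ_waves mod^rank(j).

    Afferents absent from a wave contribute 0 for that wave.  The
    previous weights are replaced (the rule is an average over the
    training batch, not incremental drift).
    """
    if not waves:
        raise DataError("cannot train a map on an empty wave list")
    n_inputs = waves[0].n_inputs
    w = np.zeros(n_inputs)
    for wave in waves:
        if wave.n_inputs != n_inputs:
            raise DimensionError("all training waves must share n_inputs")
        if wave.n_spikes:
            ranks = np.arange(wave.n_spikes, dtype=np.float64)
            w[wave.neuron_ids] += mod**ranks
    w /= len(waves)
    return replace(nmap, shared_weights=w, mod=mod, n_trained=len(waves))


def set_thresholds(
    maps: list[NeuronalMap],
    waves_by_class: dict[str, list[SpikeWave]],
    target_margin: float = 0.9,
) -> list[NeuronalMap]:
    """Calibrate P_th per map from its own class's training waves.

    threshold = target_margin × min own-class PSP, so with margin ≤ 1
    every training sample fires its own class map.
    """
    if target_margin < 0:
        raise ParameterError("target_margin must be non-negative")
    out = []
    for nmap in maps:
        waves = waves_by_class.get(nmap.class_label)
        if not waves:
            raise DataError(f"no training waves for class {nmap.class_label!r}")
        own = [nmap.psp(w) for w in waves]
        out.append(replace(nmap, threshold=target_margin * min(own)))
    return out


@dataclass(frozen=True)
class InhibitionProfile:
    """Gaussian lateral-inhibition zone: peak ``amplitude``, width sigma."""

    amplitude: float
    radius_sigma: float

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ParameterError("amplitude must be non-negative")
        if self.radius_sigma <= 0:
            raise ParameterError("radius_sigma must be positive")


def lateral_inhibition(
    psp_grids: dict[str, np.ndarray],
    profile: InhibitionProfile,
    thresholds: dict[str, float],
    max_rounds: int | None = None,
) -> dict[str, np.ndarray]:
    """Winner-based subtractive suppression of competing class maps.

    Iteratively find the globally strongest above-threshold potential not
    yet declared a winner; subtract ``amplitude·exp(−d²/(2σ²))`` from all
    *other* classes' grids around the winner's location; stop when no new
    above-threshold winner remains or after ``max_rounds`` (default: the
    number of classes).
    """
    labels = list(psp_grids)
    shapes = {g.shape for g in psp_grids.values()}
    if len(shapes) > 1:
        raise DimensionError("all PSP grids must share one shape")
    grids = {lbl: np.array(g, dtype=np.float64) for lbl, g in psp_grids.items()}
    shape = next(iter(shapes))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    winners: set[tuple[str, int, int]] = set()
    rounds = len(labels) if max_rounds is None else max_rounds
    for _ in range(rounds):
        best = None
        for lbl in labels:
            g = grids[lbl]
            thr = thresholds[lbl]
            mask = g >= thr
            for key in winners:
                if key[0] == lbl:
                    mask[key[1], key[2]] = False
            if not mask.any():
                continue
            flat = np.where(mask, g, -np.inf)
            pos = np.unravel_index(np.argmax(flat), shape)
            if best is None or flat[pos] > best[3]:
                best = (lbl, pos[0], pos[1], flat[pos])
        if best is None:
            break
        lbl, wy, wx, _ = best
        winners.add((lbl, wy, wx))
        d2 = (yy - wy) ** 2.0 + (xx - wx) ** 2.0
        zone = profile.amplitude * np.exp(-d2 / (2.0 * profile.radius_sigma**2))
        for other in labels:
            if other != lbl:
                grids[other] = grids[other] - zone
    return grids


def classify(
    features: np.ndarray,
    maps: list[NeuronalMap],
    keep_frac: float = 0.2,
    profile: InhibitionProfile | None = None,
) -> tuple[str, dict[str, dict[str, float]]]:
    """Label an analog feature vector with the trained class maps.

    Pipeline: rank-order encode → PSP per class map → lateral inhibition
    → label of the map with the highest surviving above-threshold PSP;
    ``"rejected"`` if no map fires.  The score table reports raw and
    post-inhibition PSPs plus each map's threshold.
    """
    if not maps:
        raise StateError("no trained maps")
    for nmap in maps:
        if nmap.threshold is None or nmap.n_trained == 0:
            raise StateError(f"map {nmap.class_label!r} is not trained/calibrated")
    if profile is None:
        profile = InhibitionProfile(amplitude=0.0, radius_sigma=1.0)
    wave = encode_rank_order(features, keep_frac)
    raw = {m.class_label: m.psp(wave) for m in maps}
    thresholds = {m.class_label: float(m.threshold) for m in maps}
    grids = {
        m.class_label: np.full(m.grid_shape, raw[m.class_label]) for m in maps
    }
    post_grids = lateral_inhibition(grids, profile, thresholds)
    post = {lbl: float(g.max()) for lbl, g in post_grids.items()}
    fired = [lbl for lbl in raw if raw[lbl] >= thresholds[lbl]]
    label = max(fired, key=lambda lbl: post[lbl]) if fired else "rejected"
    scores = {
        lbl: {"raw": raw[lbl], "post": post[lbl], "threshold": thresholds[lbl]}
        for lbl in raw
    }
    return label, scores
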