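"""Hierarchical generative network for visual numerosity.

Architecture (bottom to top):

1. a *fixed* first hidden layer of centre-surround spatial filters
   (difference-of-Gaussians on-centre and off-centre detectors tiled over the
   image), mimicking retinal ganglion / LGN receptive fields that develop
   independently of visual experience;
2. a second hidden layer of stochastic binary units trained purely
   unsupervised as a restricted Boltzmann machine (single-step contrastive
   divergence) to model the distribution of filter activity over object-set
   images — no labels or task signal reach this stage;
3. a supervised linear read-out trained with the delta rule that maps the
   concatenated hidden representations of two images onto a two-alternative
   "which side has more objects" choice.

The untrained second layer (random weights) is the "initial" network; after
generative learning it is the "mature" network. All analyses use the
deterministic mean-field hidden activations, so neuron-level statistics are
exactly reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stimuli import GRID_SIDE, StimulusImage, StimulusPair


class DivergenceError(RuntimeError):
    """Unsupervised training produced non-finite weights."""


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30.0, 30.0)))


# ---------------------------------------------------------------------------
# fixed filter bank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterBank:
    """Hard-wired on/off-centre difference-of-Gaussians detectors.

    ``kernels`` holds the two balanced prototype patches (on-centre first);
    each is replicated at every anchor position of a regular grid, so the
    bank has ``2 * len(anchors)`` feature channels. ``weight_matrix`` is the
    dense embedding of every kernel into the image plane (kernels overhanging
    the border are truncated, equivalent to zero-padding the image) used for
    fast batched propagation.
    """

    kernels: np.ndarray          # (2, k, k): on-centre, off-centre
    anchors: np.ndarray          # (n_anchors, 2) int
    side: int
    stride: int
    gain: float
    weight_matrix: np.ndarray    # (n_anchors, side*side): on-centre rows

    @property
    def n_features(self) -> int:
        return 2 * len(self.anchors)


def build_filterbank(side: int = GRID_SIDE, stride: int = 2,
                     kernel_size: int = 9, sigma_center: float = 1.0,
                     sigma_surround: float = 2.0) -> FilterBank:
    """Construct the centre-surround bank; deterministic given its config.

    Each prototype kernel is a difference of two unit-mass Gaussians, so its
    weights sum to exactly zero (balanced antagonism); the gain normalizes
    responses of binary images into [-1, 1].
    """
    if kernel_size > side:
        raise ValueError("kernel larger than image")
    if not (1 <= stride <= side):
        raise ValueError("invalid stride")
    half = kernel_size // 2
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1]
    r2 = (yy ** 2 + xx ** 2).astype(float)
    g_c = np.exp(-r2 / (2 * sigma_center ** 2))
    g_s = np.exp(-r2 / (2 * sigma_surround ** 2))
    dog = g_c / g_c.sum() - g_s / g_s.sum()
    gain = 1.0 / dog[dog > 0].sum()
    on = gain * dog
    kernels = np.stack([on, -on])

    coords = np.arange(0, side, stride)
    anchors = np.array([(r, c) for r in coords for c in coords], dtype=int)

    weight = np.zeros((len(anchors), side, side))
    for i, (r, c) in enumerate(anchors):
        r0, r1 = max(r - half, 0), min(r + half + 1, side)
        c0, c1 = max(c - half, 0), min(c + half + 1, side)
        weight[i, r0:r1, c0:c1] = on[
            r0 - r + half:r1 - r + half, c0 - c + half:c1 - c + half
        ]
    for arr in (kernels, anchors, weight):
        arr.setflags(write=False)
    return FilterBank(kernels=kernels, anchors=anchors, side=side,
                      stride=stride, gain=gain,
                      weight_matrix=weight.reshape(len(anchors), -1))


def propagate_batch(pixels: np.ndarray, bank: FilterBank) -> np.ndarray:
    """Filter responses for a stack of images, half-wave rectified.

    Returns (M, n_features): on-centre channels first, then off-centre.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 2:
        pixels = pixels[None]
    if pixels.shape[-2:] != (bank.side, bank.side):
        raise ValueError(
            f"image geometry {pixels.shape[-2:]} does not match bank "
            f"({bank.side}x{bank.side})"
        )
    flat = pixels.reshape(len(pixels), -1)
    resp = flat @ bank.weight_matrix.T
    return np.concatenate([np.maximum(resp, 0.0), np.maximum(-resp, 0.0)],
                          axis=1)


def propagate(image, bank: FilterBank) -> np.ndarray:
    """Feature vector (one value per kernel) for a single image."""
    pix = image.pixels if isinstance(image, StimulusImage) else np.asarray(image)
    return propagate_batch(pix[None], bank)[0]


# ---------------------------------------------------------------------------
# generative second layer (restricted Boltzmann machine)
# ---------------------------------------------------------------------------

@dataclass
class GenerativeLayer:
    """Stochastic binary hidden layer with symmetric generative weights."""

    weights: np.ndarray   # (n_visible, n_hidden)
    vbias: np.ndarray     # (n_visible,)
    hbias: np.ndarray     # (n_hidden,)
    epoch: int = 0

    @classmethod
    def initialize(cls, n_visible: int, n_hidden: int = 400,
                   rng: np.random.Generator | None = None,
                   scale: float = 0.1) -> "GenerativeLayer":
        if rng is None:
            rng = np.random.default_rng()
        return cls(
            weights=rng.normal(0.0, scale, size=(n_visible, n_hidden)),
            vbias=np.zeros(n_visible),
            hbias=np.zeros(n_hidden),
            epoch=0,
        )

    @property
    def n_hidden(self) -> int:
        return self.weights.shape[1]

    @property
    def n_visible(self) -> int:
        return self.weights.shape[0]

    def hidden_probs(self, visible: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(visible) @ self.weights + self.hbias)

    def visible_probs(self, hidden: np.ndarray) -> np.ndarray:
        return _sigmoid(np.asarray(hidden) @ self.weights.T + self.vbias)

    def copy(self) -> "GenerativeLayer":
        return GenerativeLayer(self.weights.copy(), self.vbias.copy(),
                               self.hbias.copy(), self.epoch)


@dataclass
class TrainingTrajectory:
    """Checkpoints of the generative layer at a fixed epoch interval."""

    snapshots: list[GenerativeLayer]
    epochs: list[int]
    interval: int
    initial: GenerativeLayer
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        if list(self.epochs) != sorted(set(self.epochs)):
            raise ValueError("snapshot epochs must be strictly increasing")
        for prev, nxt in zip(self.epochs, self.epochs[1:]):
            if nxt - prev != self.interval:
                raise ValueError("snapshots not spaced by the interval")

    @property
    def final(self) -> GenerativeLayer:
        return self.snapshots[-1] if self.snapshots else self.initial


def corpus_features(corpus: Sequence[StimulusImage],
                    bank: FilterBank) -> np.ndarray:
    """Rectified filter features for every image (consumes pixels only)."""
    stack = np.stack([
        (im.pixels if isinstance(im, StimulusImage) else np.asarray(im))
        for im in corpus
    ])
    return propagate_batch(stack, bank)


def reconstruction_error(layer: GenerativeLayer,
                         features: np.ndarray) -> float:
    """Mean squared single-step reconstruction error (mean-field pass)."""
    recon = layer.visible_probs(layer.hidden_probs(features))
    return float(np.mean((features - recon) ** 2))


def train_unsupervised(corpus: Sequence[StimulusImage], bank: FilterBank,
                       layer: GenerativeLayer, epochs: int,
                       checkpoint_interval: int = 30,
                       rng: np.random.Generator | None = None,
                       batch_size: int = 100, learning_rate: float = 0.05,
                       momentum_start: float = 0.5, momentum_final: float = 0.9,
                       momentum_switch_epoch: int = 5,
                       weight_decay: float = 2e-4,
                       sparsity_target: float | None = 0.05,
                       sparsity_cost: float = 0.5) -> TrainingTrajectory:
    """Single-step contrastive-divergence training on unlabelled images.

    Hidden activity is encouraged to be sparse (running mean activation
    pulled toward ``sparsity_target``), which drives units toward local
    item-detector features rather than dense area-like codes; set
    ``sparsity_target=None`` to disable.

    Only the pixels of the corpus are consulted — numerosity labels are not
    an argument anywhere in this code path. Returns checkpoints taken every
    ``checkpoint_interval`` epochs (the initial state is kept separately on
    the trajectory).
    """
    if len(corpus) == 0:
        raise ValueError("corpus must be nonempty")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    feats = corpus_features(corpus, bank)
    if feats.shape[1] != layer.n_visible:
        raise ValueError("layer shape inconsistent with filter bank output")

    initial = layer.copy()
    d_w = np.zeros_like(layer.weights)
    d_vb = np.zeros_like(layer.vbias)
    d_hb = np.zeros_like(layer.hbias)
    snapshots, snap_epochs = [], []
    mean_act = None     # running estimate of per-unit activation probability
    n = len(feats)
    for epoch in range(1, epochs + 1):
        mom = momentum_start if epoch <= momentum_switch_epoch else momentum_final
        order = rng.permutation(n)
        for start in range(0, n, batch_size):
            v0 = feats[order[start:start + batch_size]]
            h0p = layer.hidden_probs(v0)
            h0s = (rng.random(h0p.shape) < h0p).astype(float)
            v1 = layer.visible_probs(h0s)
            h1p = layer.hidden_probs(v1)
            b = len(v0)
            g_w = (v0.T @ h0p - v1.T @ h1p) / b - weight_decay * layer.weights
            g_hb = (h0p - h1p).mean(axis=0)
            if sparsity_target is not None:
                batch_act = h0p.mean(axis=0)
                mean_act = (batch_act if mean_act is None
                            else 0.9 * mean_act + 0.1 * batch_act)
                excess = mean_act - sparsity_target
                g_hb -= sparsity_cost * excess
                g_w -= sparsity_cost * np.outer(v0.mean(axis=0), excess)
            d_w = mom * d_w + learning_rate * g_w
            d_vb = mom * d_vb + learning_rate * (v0 - v1).mean(axis=0)
            d_hb = mom * d_hb + learning_rate * g_hb
            layer.weights += d_w
            layer.vbias += d_vb
            layer.hbias += d_hb
        layer.epoch = initial.epoch + epoch
        if not np.isfinite(layer.weights).all():
            raise DivergenceError(
                f"non-finite weights at epoch {layer.epoch} "
                f"(|W|max before failure unavailable; reduce learning rate)"
            )
        if epoch % checkpoint_interval == 0:
            snapshots.append(layer.copy())
            snap_epochs.append(layer.epoch)
    return TrainingTrajectory(
        snapshots=snapshots, epochs=snap_epochs,
        interval=checkpoint_interval, initial=initial,
        config={
            "epochs": epochs, "batch_size": batch_size,
            "learning_rate": learning_rate, "weight_decay": weight_decay,
            "momentum": (momentum_start, momentum_final, momentum_switch_epoch),
            "sparsity": (sparsity_target, sparsity_cost),
            "corpus_size": n,
        },
    )


def encode_batch(features_or_images, bank: FilterBank,
                 layer: GenerativeLayer) -> np.ndarray:
    """Deterministic mean-field hidden representation, one row per image."""
    arr = features_or_images
    if not isinstance(arr, np.ndarray) or arr.ndim != 2 or \
            arr.shape[1] != layer.n_visible:
        arr = corpus_features(list(arr), bank)
    return layer.hidden_probs(arr)


def encode(image, bank: FilterBank, layer: GenerativeLayer) -> np.ndarray:
    """Mean-field hidden activation vector (values in [0, 1]) for one image."""
    return layer.hidden_probs(propagate(image, bank))


# ---------------------------------------------------------------------------
# supervised read-out (delta rule)
# ---------------------------------------------------------------------------

@dataclass
class ReadoutHead:
    """Linear read-out over the concatenated pair representation.

    A single logistic unit: output > 0.5 means "left side has more". Trained
    with the delta rule (Rescorla-Wagner / Widrow-Hoff error-driven updates);
    no upstream weight is ever modified.
    """

    weights: np.ndarray   # (2 * n_hidden,)
    bias: float
    learning_rate: float
    n_trained: int = 0    # number of distinct pairs that received feedback

    def decision_value(self, h_left: np.ndarray, h_right: np.ndarray) -> float:
        x = np.concatenate([h_left, h_right])
        return float(x @ self.weights + self.bias)

    def choose(self, h_left: np.ndarray, h_right: np.ndarray) -> str:
        return "left" if self.decision_value(h_left, h_right) > 0 else "right"


def _pair_representations(pairs: Sequence[StimulusPair], bank: FilterBank,
                          layer: GenerativeLayer):
    lefts = corpus_features([p.left for p in pairs], bank)
    rights = corpus_features([p.right for p in pairs], bank)
    return layer.hidden_probs(lefts), layer.hidden_probs(rights)


def train_readout(pairs: Sequence[StimulusPair], bank: FilterBank,
                  layer: GenerativeLayer, feedback_fraction: float = 0.25,
                  rng: np.random.Generator | None = None,
                  learning_rate: float = 0.1, epochs: int = 40,
                  lr_decay: float = 0.2,
                  average_fraction: float = 0.5) -> ReadoutHead:
    """Delta-rule training of the read-out on a random subset of the pairs.

    ``feedback_fraction`` models limited explicit feedback: only that
    fraction of the available pairs (sampled without replacement) is ever
    seen with its correct answer. Each selected pair is presented in both
    left/right orders so the head cannot learn a side bias. The per-trial
    learning rate anneals as ``learning_rate / (1 + lr_decay * epoch)`` and
    the returned weights average the iterates of the last
    ``average_fraction`` of epochs, the standard stochastic-approximation
    recipe for converging error-driven updates onto the asymptotic solution.
    """
    if len(pairs) == 0:
        raise ValueError("pairs must be nonempty")
    if not (0.0 < feedback_fraction <= 1.0):
        raise ValueError("feedback_fraction must be in (0, 1]")
    if rng is None:
        rng = np.random.default_rng()
    n_sel = max(1, int(round(feedback_fraction * len(pairs))))
    chosen = rng.choice(len(pairs), size=n_sel, replace=False)
    subset = [pairs[i] for i in chosen]

    h_l, h_r = _pair_representations(subset, bank, layer)
    x_fwd = np.concatenate([h_l, h_r], axis=1)
    x_swp = np.concatenate([h_r, h_l], axis=1)
    t_fwd = np.array([1.0 if p.correct_side == "left" else 0.0 for p in subset])
    x_all = np.concatenate([x_fwd, x_swp], axis=0)
    t_all = np.concatenate([t_fwd, 1.0 - t_fwd])

    w = np.zeros(x_all.shape[1])
    b = 0.0
    w_sum = np.zeros_like(w)
    b_sum = 0.0
    n_avg = 0
    n = len(x_all)
    first_avg_epoch = int(np.ceil(epochs * (1.0 - average_fraction)))
    for epoch in range(epochs):
        lr = learning_rate / (1.0 + lr_decay * epoch)
        for i in rng.permutation(n):
            y = _sigmoid(x_all[i] @ w + b)
            err = t_all[i] - y
            w += lr * err * x_all[i]
            b += lr * err
        if epoch >= first_avg_epoch:
            w_sum += w
            b_sum += b
            n_avg += 1
    if n_avg:
        w, b = w_sum / n_avg, b_sum / n_avg
    return ReadoutHead(weights=w, bias=float(b), learning_rate=learning_rate,
                       n_trained=n_sel)


@dataclass(frozen=True)
class ComparisonOutcome:
    pair: StimulusPair
    choice: str
    correct: bool


def compare(pair: StimulusPair, bank: FilterBank, layer: GenerativeLayer,
            head: ReadoutHead) -> ComparisonOutcome:
    """Deterministic two-alternative choice for one pair."""
    choice = head.choose(encode(pair.left, bank, layer),
                         encode(pair.right, bank, layer))
    return ComparisonOutcome(pair=pair, choice=choice,
                             correct=choice == pair.correct_side)


def evaluate_pairs(pairs: Sequence[StimulusPair], bank: FilterBank,
                   layer: GenerativeLayer, head: ReadoutHead
                   ) -> list[ComparisonOutcome]:
    """Vectorized :func:`compare` over a pair set."""
    h_l, h_r = _pair_representations(pairs, bank, layer)
    scores = np.concatenate([h_l, h_r], axis=1) @ head.weights + head.bias
    outcomes = []
    for pair, s in zip(pairs, scores):
        choice = "left" if s > 0 else "right"
        outcomes.append(ComparisonOutcome(pair=pair, choice=choice,
                                          correct=choice == pair.correct_side))
    return outcomes


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(path, bank: FilterBank, layer: GenerativeLayer,
               head: ReadoutHead | None = None, config: dict | None = None):
    """HDF5 container with named groups: filterbank/, generative/, readout/."""
    import json

    import h5py

    with h5py.File(path, "w") as f:
        g = f.create_group("filterbank")
        g.create_dataset("kernels", data=bank.kernels)
        g.create_dataset("anchors", data=bank.anchors)
        g.attrs.update(side=bank.side, stride=bank.stride, gain=bank.gain)
        g = f.create_group("generative")
        g.create_dataset("weights", data=layer.weights)
        g.create_dataset("vbias", data=layer.vbias)
        g.create_dataset("hbias", data=layer.hbias)
        g.attrs["epoch"] = layer.epoch
        if head is not None:
            g = f.create_group("readout")
            g.create_dataset("weights", data=head.weights)
            g.attrs.update(bias=head.bias, learning_rate=head.learning_rate)
        f.attrs["config"] = json.dumps(config or {})


def load_model(path):
    """Inverse of :func:`save_model`; returns (bank, layer, head_or_None, config)."""
    import json

    import h5py

    with h5py.File(path, "r") as f:
        g = f["filterbank"]
        bank = build_filterbank(side=int(g.attrs["side"]),
                                stride=int(g.attrs["stride"]))
        g = f["generative"]
        layer = GenerativeLayer(
            weights=g["weights"][...], vbias=g["vbias"][...],
            hbias=g["hbias"][...], epoch=int(g.attrs["epoch"]),
        )
        head = None
        if "readout" in f:
            g = f["readout"]
            head = ReadoutHead(weights=g["weights"][...],
                               bias=float(g.attrs["bias"]),
                               learning_rate=float(g.attrs["learning_rate"]))
        config = json.loads(f.attrs["config"])
    return bank, layer, head, config
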