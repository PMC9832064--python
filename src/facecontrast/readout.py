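"""Layerwise linear readouts with noise matching.

For each block of a (fixed, untrained-by-us) layered image
representation, a hinge-loss linear classifier is fit to the 10
training stimuli, every stimulus receives a *classification score* (its
signed distance to the decision hyperplane, positive on the target
side), and a test pair counts as correct when the target's score
exceeds the distractor's.  Because a noiseless high-dimensional readout
separates 10 stimuli perfectly, zero-mean Gaussian noise is added to
the representation and its standard deviation calibrated by bisection
until training-pair accuracy matches a behavioral target (default the
80% training criterion).

For a linear rule, i.i.d. Gaussian noise on the activation vector
projects onto the signed distance as N(0, sigma^2); the simulator
therefore draws the scalar projection directly, which is
distribution-identical and cheap.  Uncertainty on per-layer summaries
uses leave-one-pair-out jackknife standard errors.

Two activation providers are bundled: a raw-pixel identity provider and
a deterministic random-weight convolutional hierarchy exposing the
standard 13 block names (conv1 ... fc8).  Any object with
``layer_names`` and ``activate(images, layer)`` can stand in, e.g. an
adapter around a pretrained network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.svm import LinearSVC

from .analysis import PairwiseMatrix, matrix_correlation

__all__ = [
    "TrainingFailureError",
    "InfeasibleTargetError",
    "LayerActivationProvider",
    "PixelProvider",
    "SmallConvNetProvider",
    "LinearReadout",
    "CalibrationResult",
    "ReadoutResult",
    "train_readout",
    "pair_generalization",
    "calibrate_noise",
    "jackknife_ci",
    "layer_behavior_correlation",
    "run_layer_readouts",
]

ALEXNET_BLOCKS = (
    "conv1", "norm1", "pool1", "conv2", "norm2", "pool2",
    "conv3", "conv4", "conv5", "pool5", "fc6", "fc7", "fc8",
)


class TrainingFailureError(RuntimeError):
    """Readout training failed (e.g. degenerate identical features)."""


class InfeasibleTargetError(ValueError):
    """Calibration target exceeds the noiseless training accuracy."""


@runtime_checkable
class LayerActivationProvider(Protocol):
    """Deterministic mapping from images to per-layer feature vectors."""

    layer_names: Sequence[str]

    def activate(self, images: Sequence, layer: str) -> np.ndarray:
        """Return an (n_images, n_features) activation matrix."""
        ...


def _image_stack(images: Sequence) -> np.ndarray:
    arrs = [np.asarray(im.pixels if hasattr(im, "pixels") else im, dtype=float) for im in images]
    return np.stack(arrs)


class PixelProvider:
    """Identity provider: the flattened pixel grid is the representation."""

    layer_names: tuple[str, ...] = ("pixels",)

    def activate(self, images: Sequence, layer: str = "pixels") -> np.ndarray:
        if layer not in self.layer_names:
            raise ValueError(f"unknown layer {layer!r}")
        x = _image_stack(images)
        return x.reshape(x.shape[0], -1)


class SmallConvNetProvider:
    """Seeded random-weight convolutional hierarchy with 13 named blocks.

    Mirrors the block structure of the classic five-conv / three-fc
    architecture (conv, response normalization and pooling blocks, then
    fully connected blocks); weights are Gaussian with He scaling drawn
    once from ``seed``, so the provider is deterministic.  Convolutional
    and fully connected blocks expose their pre-rectification responses;
    normalization and pooling blocks expose their outputs.
    """

    layer_names: tuple[str, ...] = ALEXNET_BLOCKS

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)

        def conv_w(kh, kw, cin, cout):
            return rng.normal(0.0, np.sqrt(2.0 / (kh * kw * cin)), size=(kh, kw, cin, cout))

        def fc_w(din, dout):
            return rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout))

        self._w = {
            "conv1": conv_w(7, 7, 1, 8),
            "conv2": conv_w(5, 5, 8, 16),
            "conv3": conv_w(3, 3, 16, 32),
            "conv4": conv_w(3, 3, 32, 32),
            "conv5": conv_w(3, 3, 32, 16),
        }
        self._fc_dims = {"fc6": 96, "fc7": 64, "fc8": 16}
        self._fc: dict[str, np.ndarray] = {}  # built lazily once input dim is known
        self._rng_state = rng.bit_generator.state
        self._cache: dict[bytes, dict[str, np.ndarray]] = {}

    # -- primitive layers ---------------------------------------------------

    @staticmethod
    def _conv(x: np.ndarray, w: np.ndarray, stride: int = 1, pad: int = 0) -> np.ndarray:
        if pad:
            x = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
        kh, kw = w.shape[:2]
        win = sliding_window_view(x, (kh, kw), axis=(1, 2))
        win = win[:, ::stride, ::stride]
        return np.einsum("nhwcij,ijco->nhwo", win, w)

    @staticmethod
    def _lrn(x: np.ndarray, size: int = 5, k: float = 2.0, alpha: float = 1e-4,
             beta: float = 0.75) -> np.ndarray:
        sq = x**2
        c = x.shape[-1]
        half = size // 2
        denom = np.empty_like(x)
        for i in range(c):
            lo, hi = max(0, i - half), min(c, i + half + 1)
            denom[..., i] = sq[..., lo:hi].sum(axis=-1)
        return x / (k + alpha * denom) ** beta

    @staticmethod
    def _maxpool2(x: np.ndarray) -> np.ndarray:
        n, h, w, c = x.shape
        h2, w2 = h - h % 2, w - w % 2
        x = x[:, :h2, :w2]
        x = x.reshape(n, h2 // 2, 2, w2 // 2, 2, c)
        return x.max(axis=(2, 4))

    def _ensure_fc(self, din: int) -> None:
        if self._fc:
            return
        rng = np.random.default_rng()
        rng.bit_generator.state = self._rng_state
        prev = din
        for name, dout in self._fc_dims.items():
            self._fc[name] = rng.normal(0.0, np.sqrt(2.0 / prev), size=(prev, dout))
            prev = dout

    def _forward(self, images: Sequence) -> dict[str, np.ndarray]:
        x = _image_stack(images)[..., None]  # (n, H, W, 1)
        acts: dict[str, np.ndarray] = {}
        relu = lambda a: np.maximum(a, 0.0)  # noqa: E731

        a = self._conv(x, self._w["conv1"], stride=3)
        acts["conv1"] = a
        a = self._lrn(relu(a))
        acts["norm1"] = a
        a = self._maxpool2(a)
        acts["pool1"] = a
        a2 = self._conv(a, self._w["conv2"])
        acts["conv2"] = a2
        a2 = self._lrn(relu(a2))
        acts["norm2"] = a2
        a2 = self._maxpool2(a2)
        acts["pool2"] = a2
        a3 = self._conv(a2, self._w["conv3"], pad=1)
        acts["conv3"] = a3
        a4 = self._conv(relu(a3), self._w["conv4"], pad=1)
        acts["conv4"] = a4
        a5 = self._conv(relu(a4), self._w["conv5"], pad=1)
        acts["conv5"] = a5
        p5 = self._maxpool2(relu(a5))
        acts["pool5"] = p5
        flat = p5.reshape(p5.shape[0], -1)
        self._ensure_fc(flat.shape[1])
        f6 = flat @ self._fc["fc6"]
        acts["fc6"] = f6
        f7 = relu(f6) @ self._fc["fc7"]
        acts["fc7"] = f7
        acts["fc8"] = relu(f7) @ self._fc["fc8"]
        return acts

    def activate(self, images: Sequence, layer: str) -> np.ndarray:
        if layer not in self.layer_names:
            raise ValueError(f"unknown layer {layer!r}")
        keys = [
            np.ascontiguousarray(
                np.asarray(im.pixels if hasattr(im, "pixels") else im, dtype=float)
            ).tobytes()
            for im in images
        ]
        missing = [i for i, k in enumerate(keys) if k not in self._cache]
        if missing:
            acts = self._forward([images[i] for i in missing])
            for j, i in enumerate(missing):
                self._cache[keys[i]] = {
                    name: acts[name][j].ravel().copy() for name in self.layer_names
                }
        return np.stack([self._cache[k][layer] for k in keys])


# ---------------------------------------------------------------------------
# linear readout


@dataclass(frozen=True)
class LinearReadout:
    """A trained linear decision rule ``sign(w . x + b)``."""

    layer: str
    weights: np.ndarray
    offset: float

    def score(self, features: np.ndarray) -> np.ndarray:
        """Signed distance to the hyperplane (positive = target side)."""
        features = np.atleast_2d(np.asarray(features, dtype=float))
        norm = np.linalg.norm(self.weights)
        return (features @ self.weights + self.offset) / norm


def train_readout(
    provider: LayerActivationProvider,
    layer: str,
    train_images: Sequence,
    labels: Sequence[int],
    regularization: float = 10.0,
) -> LinearReadout:
    """Fit a hinge-loss linear classifier to the training stimuli.

    ``labels`` are +1 for targets and 0/-1 for distractors.  The SVM's
    box constraint is ``regularization / n_samples`` so the objective is
    ridge plus *mean* hinge loss (invariant to duplicating the training
    set).  Deterministic given fixed solver settings.
    """
    x = provider.activate(train_images, layer)
    y = np.where(np.asarray(labels, dtype=float) > 0, 1, -1)
    if len(set(y.tolist())) < 2:
        raise ValueError("need both classes among the training labels")
    if np.allclose(x, x[0]):
        raise TrainingFailureError(f"layer {layer!r}: all feature vectors identical")
    clf = LinearSVC(
        C=regularization / x.shape[0],
        loss="hinge",
        tol=1e-10,
        max_iter=200_000,
        random_state=0,
    )
    clf.fit(x, y)
    return LinearReadout(layer=layer, weights=clf.coef_.ravel().copy(), offset=float(clf.intercept_[0]))


def _pair_scores(
    rule: LinearReadout,
    provider: LayerActivationProvider,
    layer: str,
    targets: Sequence,
    distractors: Sequence,
) -> tuple[np.ndarray, np.ndarray]:
    st = rule.score(provider.activate(targets, layer))
    sd = rule.score(provider.activate(distractors, layer))
    return st, sd


def pair_generalization(
    rule: LinearReadout,
    provider: LayerActivationProvider,
    layer: str,
    targets: Sequence,
    distractors: Sequence,
    noise_sd: float = 0.0,
    n_draws: int = 1,
    seed: int = 0,
) -> np.ndarray:
    """Per-pair accuracy grid (targets x distractors) under score noise.

    Each simulated trial adds independent Gaussian noise of sd
    ``noise_sd`` to the two stimuli's classification scores (the exact
    projection of activation noise through the linear rule); the pair is
    correct when the noisy target-minus-distractor score difference is
    positive.  With ``noise_sd = 0`` a single deterministic draw is used
    and the grid is 0/1-valued.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    st, sd = _pair_scores(rule, provider, layer, targets, distractors)
    diff = st[:, None] - sd[None, :]
    if noise_sd == 0:
        return (diff > 0).astype(float)
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd * np.sqrt(2.0), size=(n_draws,) + diff.shape)
    return np.mean(diff[None] + noise > 0, axis=0)


@dataclass(frozen=True)
class CalibrationResult:
    noise_sd: float
    achieved_accuracy: float
    n_iterations: int


def calibrate_noise(
    provider: LayerActivationProvider,
    layer: str,
    train_images: Sequence,
    labels: Sequence[int],
    target_accuracy: float = 0.80,
    tolerance: float = 0.01,
    seed: int = 0,
    n_draws: int = 4000,
    max_iter: int = 60,
    regularization: float = 10.0,
) -> CalibrationResult:
    """Bisection on the noise sd until training-pair accuracy hits target.

    Training-pair accuracy is the mean over all target x distractor
    pairs of the training set under :func:`pair_generalization` noise.
    Raises :class:`InfeasibleTargetError` when ``target_accuracy``
    exceeds the noiseless accuracy (or is not above chance).
    """
    if not 0.5 < target_accuracy <= 1.0:
        raise InfeasibleTargetError("target accuracy must lie in (0.5, 1]")
    labels = np.asarray(labels)
    images = list(train_images)
    targets = [im for im, l in zip(images, labels) if l > 0]
    distractors = [im for im, l in zip(images, labels) if l <= 0]
    rule = train_readout(provider, layer, images, labels, regularization=regularization)

    def accuracy(sd: float, salt: int) -> float:
        grid = pair_generalization(
            rule, provider, layer, targets, distractors,
            noise_sd=sd, n_draws=n_draws if sd > 0 else 1,
            seed=np.random.SeedSequence([seed, salt]).generate_state(1)[0],
        )
        return float(grid.mean())

    noiseless = accuracy(0.0, 0)
    if target_accuracy > noiseless + 1e-12:
        raise InfeasibleTargetError(
            f"target {target_accuracy} exceeds noiseless training accuracy {noiseless}"
        )
    if abs(noiseless - target_accuracy) <= tolerance:
        return CalibrationResult(0.0, noiseless, 0)

    st, sd_scores = _pair_scores(rule, provider, layer, targets, distractors)
    scale = float(np.abs(st[:, None] - sd_scores[None, :]).mean()) or 1.0
    hi = scale
    it = 0
    while accuracy(hi, it + 1) > target_accuracy and it < max_iter:
        hi *= 2.0
        it += 1
    lo = 0.0
    best_sd, best_acc = hi, accuracy(hi, 1000)
    for i in range(max_iter - it):
        mid = 0.5 * (lo + hi)
        acc = accuracy(mid, 2000 + i)
        if abs(acc - target_accuracy) < abs(best_acc - target_accuracy):
            best_sd, best_acc = mid, acc
        if abs(acc - target_accuracy) <= tolerance:
            return CalibrationResult(mid, acc, it + i + 1)
        if acc > target_accuracy:
            lo = mid
        else:
            hi = mid
    return CalibrationResult(best_sd, best_acc, max_iter)


def jackknife_ci(values: Sequence[float], confidence_z: float = 1.96) -> tuple[float, float, float, float]:
    """Leave-one-out jackknife for the mean of per-unit statistics.

    Returns ``(estimate, ci_low, ci_high, se)`` with
    ``se = sqrt((n-1)/n * sum((theta_i - theta_bar)^2))`` over the
    leave-one-out estimates.
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise ValueError("jackknife needs at least 2 units")
    total = v.sum()
    loo = (total - v) / (n - 1)
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    est = float(v.mean())
    return est, est - confidence_z * se, est + confidence_z * se, se


def layer_behavior_correlation(
    score_diff_grids: dict[str, np.ndarray],
    rat_matrix: PairwiseMatrix,
    model,
    reliability: float,
) -> dict[str, dict[str, float]]:
    """Correlate each layer's score-difference grid with behavior and model.

    Returns per layer ``{"r_behavior", "r_model", "r_behavior_normalized"}``
    where the normalized value divides ``r_behavior`` by the (Spearman-
    Brown corrected) reliability of the behavioral data.
    """
    out: dict[str, dict[str, float]] = {}
    for layer, grid in score_diff_grids.items():
        rb = matrix_correlation(grid, rat_matrix)
        rm = matrix_correlation(grid, model)
        out[layer] = {
            "r_behavior": rb,
            "r_model": rm,
            "r_behavior_normalized": rb / reliability,
        }
    return out


@dataclass(frozen=True)
class ReadoutResult:
    """Per-layer readout summary over the 10x15 test grid."""

    layer: str
    rule: LinearReadout
    noise_sd: float
    train_accuracy: float
    score_diff: np.ndarray  # target-minus-distractor clean score differences
    pair_accuracy: np.ndarray  # under calibrated noise
    test_accuracy: float
    ci_low: float
    ci_high: float


def run_layer_readouts(
    provider: LayerActivationProvider,
    stimulus_set,
    calibrate_to: float | None = 0.80,
    tolerance: float = 0.01,
    n_draws: int = 2000,
    seed: int = 0,
    regularization: float = 10.0,
) -> dict[str, ReadoutResult]:
    """Train, calibrate and evaluate a readout for every provider layer.

    For each layer: fit the readout on the 10 training stimuli,
    calibrate score noise to ``calibrate_to`` training accuracy (skip
    calibration when None), compute the noisy per-pair test accuracy
    grid and its mean with a leave-one-pair-out jackknife CI, plus the
    clean score-difference grid used for model/behavior correlations.
    """
    train_images = list(stimulus_set.train_targets) + list(stimulus_set.train_distractors)
    labels = [1] * len(stimulus_set.train_targets) + [-1] * len(stimulus_set.train_distractors)
    targets = list(stimulus_set.test_targets)
    distractors = list(stimulus_set.test_distractors)
    results: dict[str, ReadoutResult] = {}
    for li, layer in enumerate(provider.layer_names):
        rule = train_readout(provider, layer, train_images, labels, regularization=regularization)
        train_grid = pair_generalization(
            rule, provider, layer,
            train_images[: len(stimulus_set.train_targets)],
            train_images[len(stimulus_set.train_targets):],
        )
        if calibrate_to is not None:
            cal = calibrate_noise(
                provider, layer, train_images, labels,
                target_accuracy=calibrate_to, tolerance=tolerance,
                seed=seed + li, n_draws=n_draws, regularization=regularization,
            )
            noise_sd, train_acc = cal.noise_sd, cal.achieved_accuracy
        else:
            noise_sd, train_acc = 0.0, float(train_grid.mean())
        st, sd_sc = _pair_scores(rule, provider, layer, targets, distractors)
        score_diff = st[:, None] - sd_sc[None, :]
        grid = pair_generalization(
            rule, provider, layer, targets, distractors,
            noise_sd=noise_sd, n_draws=n_draws if noise_sd > 0 else 1,
            seed=seed + 1000 + li,
        )
        pair_means = grid.ravel()
        est, lo, hi, _ = jackknife_ci(pair_means)
        results[layer] = ReadoutResult(
            layer=layer,
            rule=rule,
            noise_sd=noise_sd,
            train_accuracy=train_acc,
            score_diff=score_diff,
            pair_accuracy=grid,
            test_accuracy=est,
            ci_low=lo,
            ci_high=hi,
        )
    return results
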