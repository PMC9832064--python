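"""Synthetic face/non-face stimuli with controlled contrast-feature counts.

The behavioral design needs grayscale stimuli whose number of correct
contrast features (CF, 0-12) is known exactly: training targets with
11-12 CF, training distractors with 6, and test stimuli spanning the
six hypothesis cells.  The original photographic set is not
redistributable, so this module synthesizes stand-ins by painting the
template regions at sampled luminances on a uniform background, adding
Gaussian pixel noise, and accepting a candidate only when re-scoring the
rendered image yields exactly the requested CF count.

Selection within a CF category uses the same pixel-dissimilarity measure
as the study: root-sum-squared pixel difference normalized by the square
root of the pixel count (a scaled Euclidean distance), with a greedy
maximin rule favouring mutually dissimilar exemplars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .template import (
    ContrastTemplate,
    FeatureProfile,
    ModelMatrix,
    evaluate_conditions,
    feature_strength_model,
    ideal_assignment,
)

__all__ = [
    "GenerationFailureError",
    "StimulusImage",
    "StimulusSet",
    "render_stimulus",
    "generate_with_k_features",
    "pixel_dissimilarity",
    "dissimilarity_matrix",
    "select_dissimilar",
    "build_stimulus_set",
]

#: Default pixel-noise standard deviation (luminance units on [0,1]).
DEFAULT_NOISE_SD = 0.05

#: Minimum |condition strength| accepted by the exact-k generator, so
#: that the CF count is stable under 8-bit quantization round-trips.
STRENGTH_MARGIN = 0.005


class GenerationFailureError(RuntimeError):
    """Raised when rejection sampling cannot hit the requested CF count."""

    def __init__(self, k: int, max_tries: int):
        super().__init__(
            f"could not generate a stimulus with exactly {k} correct contrast "
            f"features within {max_tries} tries"
        )
        self.k = k
        self.max_tries = max_tries


@dataclass(frozen=True)
class StimulusImage:
    """A labeled grayscale stimulus.

    ``cf_group`` is the nominal category used by the experimental design
    (1, 6 or 12 for distractors; 6 or 12 for targets) and may differ by
    one from ``n_correct`` where the design tolerates it (e.g. 11-CF
    images in the nominal-12 group).
    """

    id: str
    pixels: np.ndarray
    label: str  # {"target", "distractor"}
    role: str  # {"train", "test"}
    n_correct: int
    cf_group: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(f"stimulus {self.id}: pixels outside [0,1]")
        if self.label not in ("target", "distractor"):
            raise ValueError(f"stimulus {self.id}: bad label {self.label!r}")
        if self.role not in ("train", "test"):
            raise ValueError(f"stimulus {self.id}: bad role {self.role!r}")


@dataclass(frozen=True)
class StimulusSet:
    """The experiment's stimulus complement plus the template that scored it.

    Defaults follow the study design: 5 training targets (11-12 CF),
    5 training distractors (6 CF), 10 test targets (first five 6 CF,
    last five 12 CF) and 15 test distractors (five each in the nominal
    1 / 6 / 12 CF groups).
    """

    template: ContrastTemplate
    train_targets: tuple[StimulusImage, ...]
    train_distractors: tuple[StimulusImage, ...]
    test_targets: tuple[StimulusImage, ...]
    test_distractors: tuple[StimulusImage, ...]

    @property
    def all_images(self) -> tuple[StimulusImage, ...]:
        return (
            self.train_targets
            + self.train_distractors
            + self.test_targets
            + self.test_distractors
        )

    def image(self, stim_id: str) -> StimulusImage:
        for im in self.all_images:
            if im.id == stim_id:
                return im
        raise KeyError(stim_id)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "id": im.id,
                "label": im.label,
                "role": im.role,
                "n_correct": im.n_correct,
                "cf_group": im.cf_group,
            }
            for im in self.all_images
        ]
        return pd.DataFrame(rows)

    def profiles(self, images: Sequence[StimulusImage]) -> list[FeatureProfile]:
        return [evaluate_conditions(im.pixels, self.template) for im in images]

    def feature_strength_matrix(self) -> ModelMatrix:
        """Per-pair feature-strength model over the 10x15 test grid."""
        return feature_strength_model(
            self.profiles(self.test_targets),
            self.profiles(self.test_distractors),
            row_labels=[im.id for im in self.test_targets],
            col_labels=[im.id for im in self.test_distractors],
        )

    def condition_map(self) -> dict[tuple[str, str], str]:
        """Map each test (target_id, distractor_id) pair to its hypothesis cell.

        Labels follow the "T vs D CF" convention, e.g. ``"12 vs 1 CF"``.
        """
        out: dict[tuple[str, str], str] = {}
        for t in self.test_targets:
            for d in self.test_distractors:
                out[(t.id, d.id)] = f"{t.cf_group} vs {d.cf_group} CF"
        return out


# ---------------------------------------------------------------------------
# rendering and exact-k generation


def render_stimulus(
    template: ContrastTemplate,
    region_luminances: Mapping[str, float],
    background: float = 0.5,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | np.random.Generator = 0,
    stim_id: str = "stim",
    label: str = "distractor",
    role: str = "test",
) -> StimulusImage:
    """Paint each region at its luminance on a uniform background.

    Independent Gaussian pixel noise of sd ``noise_sd`` is added and the
    result clipped to [0,1].  Deterministic given ``seed``.
    """
    for name, lum in region_luminances.items():
        if name not in template.regions:
            raise ValueError(f"unknown region {name!r}")
        if not 0.0 <= lum <= 1.0:
            raise ValueError(f"region {name!r}: luminance {lum} outside [0,1]")
    if not 0.0 <= background <= 1.0:
        raise ValueError(f"background luminance {background} outside [0,1]")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    pixels = np.full(template.canvas_size, float(background))
    for name, lum in region_luminances.items():
        pixels[template.regions[name]] = float(lum)
    if noise_sd > 0:
        pixels = pixels + rng.normal(0.0, noise_sd, size=pixels.shape)
    pixels = np.clip(pixels, 0.0, 1.0)
    profile = evaluate_conditions(pixels, template)
    return StimulusImage(
        id=stim_id, pixels=pixels, label=label, role=role, n_correct=profile.n_correct
    )


def _assignment_strengths(
    template: ContrastTemplate, assignment: Mapping[str, float]
) -> np.ndarray:
    return np.array(
        [assignment[b] - assignment[d] for b, d in template.conditions], dtype=float
    )


def generate_with_k_features(
    template: ContrastTemplate,
    k: int,
    seed: int | np.random.Generator = 0,
    max_tries: int = 5000,
    noise_sd: float = DEFAULT_NOISE_SD,
    background: float = 0.5,
    margin: float = STRENGTH_MARGIN,
    stim_id: str | None = None,
    label: str = "distractor",
    role: str = "test",
) -> StimulusImage:
    """Rejection-sample a stimulus satisfying exactly ``k`` conditions.

    Candidate region luminances are drawn by blending a uniform draw
    with the template's ideal (or luminance-inverted ideal) assignment
    by a random weight, which covers the full CF range efficiently.  A
    candidate is accepted only if (a) its assignment-level strengths
    give exactly ``k`` positives with every |strength| above ``margin``,
    and (b) the rendered, noisy image still re-scores to exactly ``k``.
    """
    if not 0 <= k <= 12:
        raise ValueError(f"k must lie in 0..12, got {k}")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    names = list(template.region_names)
    ideal = ideal_assignment(template, bright=0.9, dark=0.1)
    ideal_vec = np.array([ideal[n] for n in names])
    inverted_vec = 1.0 - ideal_vec
    for _ in range(max_tries):
        u = rng.uniform(0.05, 0.95, size=len(names))
        w = rng.uniform(-1.0, 1.0)
        base = ideal_vec if w >= 0 else inverted_vec
        x = (1.0 - abs(w)) * u + abs(w) * base
        assignment = dict(zip(names, x))
        strengths = _assignment_strengths(template, assignment)
        if np.abs(strengths).min() <= margin:
            continue
        if int(np.sum(strengths > 0)) != k:
            continue
        stim = render_stimulus(
            template,
            assignment,
            background=background,
            noise_sd=noise_sd,
            seed=rng,
            stim_id=stim_id or f"k{k}",
            label=label,
            role=role,
        )
        rendered = evaluate_conditions(stim.pixels, template)
        if rendered.n_correct == k and np.abs(rendered.strengths).min() > margin / 2:
            return stim
    raise GenerationFailureError(k, max_tries)


# ---------------------------------------------------------------------------
# pixel dissimilarity


def _pixels(obj) -> np.ndarray:
    return np.asarray(obj.pixels if hasattr(obj, "pixels") else obj, dtype=float)


def pixel_dissimilarity(img1, img2) -> float:
    """Root-sum-squared pixel difference over sqrt(number of pixels).

    ``sqrt(sum((p1 - p2)**2)) / sqrt(N)`` -- a scaled Euclidean distance,
    hence symmetric, non-negative and metric.
    """
    a, b = _pixels(img1), _pixels(img2)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.sum((a - b) ** 2)) / np.sqrt(a.size))


def dissimilarity_matrix(images: Sequence) -> np.ndarray:
    """Symmetric pairwise pixel-dissimilarity grid with zero diagonal."""
    if len(images) < 2:
        raise ValueError("need at least 2 images")
    arrs = [_pixels(im) for im in images]
    shapes = {a.shape for a in arrs}
    if len(shapes) > 1:
        raise ValueError(f"images have mixed shapes: {sorted(shapes)}")
    n = len(arrs)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pixel_dissimilarity(arrs[i], arrs[j])
    return out


def select_dissimilar(images: Sequence, m: int) -> list:
    """Greedy maximin selection of ``m`` mutually dissimilar images.

    Start from the most dissimilar pair, then repeatedly add the
    candidate whose minimum dissimilarity to the selected set is
    largest.  Ties break toward the lowest index, so the selection is
    deterministic.
    """
    n = len(images)
    if m > n:
        raise ValueError(f"cannot select {m} from {n} candidates")
    if m <= 0:
        return []
    if n == 1 or m == 1:
        return [images[0]]
    d = dissimilarity_matrix(images)
    iu = np.triu_indices(n, k=1)
    best = int(np.argmax(d[iu]))
    selected = [int(iu[0][best]), int(iu[1][best])]
    while len(selected) < m:
        remaining = [i for i in range(n) if i not in selected]
        min_d = [d[i, selected].min() for i in remaining]
        selected.append(remaining[int(np.argmax(min_d))])
    return [images[i] for i in selected[:m]]


# ---------------------------------------------------------------------------
# the experiment's stimulus complement


def _pool(
    template: ContrastTemplate,
    ks: Sequence[int],
    rng: np.random.Generator,
    noise_sd: float,
    **kwargs,
) -> list[StimulusImage]:
    return [
        generate_with_k_features(template, k, seed=rng, noise_sd=noise_sd, **kwargs)
        for k in ks
    ]


def build_stimulus_set(
    template: ContrastTemplate,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    pool_extra: int = 3,
) -> StimulusSet:
    """Generate and select the full 5/5/10/15 stimulus complement.

    For each design category a pool of ``count + pool_extra`` candidates
    is generated with the exact-k sampler, and the required number is
    chosen by greedy maximin pixel dissimilarity (mirroring the study's
    preference for mutually dissimilar stimuli within a CF category).
    """
    rng = np.random.default_rng(seed)

    def cycle(ks: Sequence[int], count: int) -> list[int]:
        return [ks[i % len(ks)] for i in range(count)]

    def make(ks, need, ids, label, role, group):
        pool = _pool(template, cycle(ks, need + pool_extra), rng, noise_sd, label=label, role=role)
        chosen = select_dissimilar(pool, need)
        return tuple(
            replace(im, id=ids(i), cf_group=group) for i, im in enumerate(chosen)
        )

    train_targets = make([12, 11], 5, lambda i: f"trainT{i + 1}", "target", "train", 12)
    train_distractors = make([6], 5, lambda i: f"trainD{i + 1}", "distractor", "train", 6)
    test_t6 = make([6], 5, lambda i: f"testT{i + 1}", "target", "test", 6)
    test_t12 = make([12], 5, lambda i: f"testT{i + 6}", "target", "test", 12)
    test_d1 = make([1], 5, lambda i: f"testD{i + 1}", "distractor", "test", 1)
    test_d6 = make([6, 5], 5, lambda i: f"testD{i + 6}", "distractor", "test", 6)
    test_d12 = make([12, 11], 5, lambda i: f"testD{i + 11}", "distractor", "test", 12)

    return StimulusSet(
        template=template,
        train_targets=train_targets,
        train_distractors=train_distractors,
        test_targets=test_t6 + test_t12,
        test_distractors=test_d1 + test_d6 + test_d12,
    )
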