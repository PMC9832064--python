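"""Ordinal contrast-feature templates and the two contrast models.

A coarse "ratio template" describes a face not by its shape but by a
small set of ordinal luminance relations between named facial regions
(e.g. the forehead is brighter than the eyes, the cheeks are brighter
than the mouth).  Because only the *direction* of each luminance
difference matters, such a template is largely invariant to overall
illumination changes.  An image is scored by how many of the twelve
pairwise conditions it satisfies (its number of *correct contrast
features*, CF, 0-12) and, in a graded variant, by the signed magnitude
of each difference (its *feature strength*).

This module houses:

* :class:`ContrastTemplate` -- named region masks plus the ordered list
  of twelve (brighter, darker) region pairs;
* :func:`evaluate_conditions` -- score an image into a
  :class:`FeatureProfile` (strengths, CF count, mean strength);
* :func:`simple_contrast_model` -- the design matrix of
  target-CF minus distractor-CF for each test cell;
* :func:`feature_strength_model` -- the targets x distractors matrix of
  target mean strength minus distractor mean strength;
* :func:`category_average_images` -- pixelwise average image per CF
  category.

The exact region geometry of the original template exists only as a
figure, so the default template below uses axis-aligned rectangles for
eight regions on a 100x100 canvas, with a bipartite condition set in
which forehead, cheeks, nose and chin are expected brighter than eyes
and mouth.  Both the geometry and the condition list are fully
user-overridable (see :mod:`facecontrast.io` for the YAML format).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Rect",
    "DEFAULT_CANVAS",
    "DEFAULT_REGIONS",
    "DEFAULT_CONDITIONS",
    "ContrastTemplate",
    "FeatureProfile",
    "ModelMatrix",
    "default_template",
    "region_luminance",
    "region_means",
    "ideal_assignment",
    "evaluate_conditions",
    "simple_contrast_model",
    "feature_strength_model",
    "category_average_images",
]

#: (row_start, row_stop, col_start, col_stop) -- 0-based, row-major, half-open
Rect = tuple[int, int, int, int]

DEFAULT_CANVAS: tuple[int, int] = (100, 100)

#: Axis-aligned rectangles for the eight template regions, chosen to
#: resemble a frontal face on a 100x100 canvas.  Regions are pairwise
#: disjoint so that a stimulus can be rendered by painting each region
#: at an arbitrary luminance.
DEFAULT_REGIONS: dict[str, Rect] = {
    "forehead": (5, 25, 25, 75),
    "left_eye": (30, 45, 25, 45),
    "right_eye": (30, 45, 55, 75),
    "nose": (48, 65, 42, 58),
    "left_cheek": (50, 70, 14, 34),
    "right_cheek": (50, 70, 66, 86),
    "mouth": (72, 85, 35, 65),
    "chin": (88, 98, 38, 62),
}

#: The twelve ordinal conditions, ordered, as (expected_brighter,
#: expected_darker) pairs.  The set is bipartite: {forehead, cheeks,
#: nose, chin} always appear on the brighter side, {eyes, mouth} on the
#: darker side, consistent with the ratio-template account of face
#: detection.
DEFAULT_CONDITIONS: tuple[tuple[str, str], ...] = (
    ("forehead", "left_eye"),
    ("forehead", "right_eye"),
    ("left_cheek", "left_eye"),
    ("right_cheek", "right_eye"),
    ("nose", "left_eye"),
    ("nose", "right_eye"),
    ("left_cheek", "mouth"),
    ("right_cheek", "mouth"),
    ("nose", "mouth"),
    ("forehead", "mouth"),
    ("chin", "left_eye"),
    ("chin", "right_eye"),
)

N_CONDITIONS = 12


def _rect_mask(canvas: tuple[int, int], rect: Rect) -> np.ndarray:
    r0, r1, c0, c1 = rect
    h, w = canvas
    if not (0 <= r0 < r1 <= h and 0 <= c0 < c1 <= w):
        raise ValueError(f"rectangle {rect} does not fit canvas {canvas}")
    mask = np.zeros(canvas, dtype=bool)
    mask[r0:r1, c0:c1] = True
    return mask


@dataclass(frozen=True)
class ContrastTemplate:
    """Named region masks plus an ordered list of 12 ordinal conditions.

    Parameters
    ----------
    canvas_size
        (height, width) in pixels.
    regions
        Mapping region name -> boolean mask of shape ``canvas_size``.
    conditions
        Ordered tuple of exactly 12 ``(expected_brighter, expected_darker)``
        region-name pairs.
    rectangles
        Optional rectangle specification the masks were built from; kept
        for lossless serialization.
    """

    canvas_size: tuple[int, int]
    regions: Mapping[str, np.ndarray]
    conditions: tuple[tuple[str, str], ...]
    rectangles: Mapping[str, Rect] | None = None

    def __post_init__(self) -> None:
        if len(self.conditions) != N_CONDITIONS:
            raise ValueError(
                f"a contrast template has exactly {N_CONDITIONS} conditions, "
                f"got {len(self.conditions)}"
            )
        for name, mask in self.regions.items():
            mask = np.asarray(mask)
            if mask.dtype != bool:
                raise ValueError(f"region {name!r}: mask must be boolean")
            if mask.shape != tuple(self.canvas_size):
                raise ValueError(
                    f"region {name!r}: mask shape {mask.shape} != canvas "
                    f"{tuple(self.canvas_size)}"
                )
            if not mask.any():
                raise ValueError(f"region {name!r}: mask is empty")
        for bright, dark in self.conditions:
            for name in (bright, dark):
                if name not in self.regions:
                    raise ValueError(f"condition names unknown region {name!r}")

    @classmethod
    def from_rectangles(
        cls,
        canvas_size: tuple[int, int],
        rectangles: Mapping[str, Rect],
        conditions: Sequence[tuple[str, str]],
    ) -> "ContrastTemplate":
        masks = {name: _rect_mask(tuple(canvas_size), tuple(r)) for name, r in rectangles.items()}
        return cls(
            canvas_size=tuple(canvas_size),
            regions=masks,
            conditions=tuple((b, d) for b, d in conditions),
            rectangles={name: tuple(r) for name, r in rectangles.items()},
        )

    @property
    def region_names(self) -> tuple[str, ...]:
        return tuple(self.regions)


def default_template() -> ContrastTemplate:
    """The built-in 100x100 eight-region template with 12 conditions."""
    return ContrastTemplate.from_rectangles(DEFAULT_CANVAS, DEFAULT_REGIONS, DEFAULT_CONDITIONS)


@dataclass(frozen=True)
class FeatureProfile:
    """Per-stimulus contrast-feature summary.

    ``strengths[i]`` is the signed luminance difference (brighter minus
    darker region mean) for condition ``i``; positive values are in the
    face-typical direction.  ``n_correct`` counts strictly positive
    strengths (exact ties count as *not met*).  ``mean_strength`` is the
    arithmetic mean of the twelve strengths.
    """

    strengths: np.ndarray
    n_correct: int
    mean_strength: float

    @classmethod
    def from_strengths(cls, strengths: np.ndarray) -> "FeatureProfile":
        strengths = np.asarray(strengths, dtype=float)
        if strengths.shape != (N_CONDITIONS,):
            raise ValueError(f"expected {N_CONDITIONS} strengths, got {strengths.shape}")
        return cls(
            strengths=strengths,
            n_correct=int(np.sum(strengths > 0.0)),
            mean_strength=float(strengths.mean()),
        )


@dataclass(frozen=True)
class ModelMatrix:
    """A targets x distractors model grid (rows = targets)."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("values shape does not match labels")

    def cell(self, row_label: str, col_label: str) -> float:
        i = self.row_labels.index(row_label)
        j = self.col_labels.index(col_label)
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# scoring


def region_luminance(image: np.ndarray, mask: np.ndarray) -> float:
    """Mean luminance of the masked pixels of ``image`` (both in [0,1])."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if mask.shape != image.shape:
        raise ValueError(f"mask shape {mask.shape} != image shape {image.shape}")
    if mask.dtype != bool:
        raise ValueError("mask must be boolean")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(image[mask].mean())


def region_means(image: np.ndarray, template: ContrastTemplate) -> dict[str, float]:
    """Mean luminance per template region."""
    return {name: region_luminance(image, mask) for name, mask in template.regions.items()}


def evaluate_conditions(image: np.ndarray, template: ContrastTemplate) -> FeatureProfile:
    """Score ``image`` against the template's twelve ordinal conditions.

    Returns a :class:`FeatureProfile` whose ``strengths[i]`` equals the
    mean luminance of the expected-brighter region minus that of the
    expected-darker region of condition ``i``.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != tuple(template.canvas_size):
        raise ValueError(
            f"image shape {image.shape} != template canvas {tuple(template.canvas_size)}"
        )
    means = region_means(image, template)
    strengths = np.array(
        [means[bright] - means[dark] for bright, dark in template.conditions], dtype=float
    )
    return FeatureProfile.from_strengths(strengths)


def ideal_assignment(
    template: ContrastTemplate, bright: float = 0.8, dark: float = 0.2
) -> dict[str, float]:
    """A region-luminance assignment satisfying all twelve conditions.

    Regions are layered by longest-path depth in the brighter->darker
    condition digraph and mapped linearly from ``bright`` (sources) to
    ``dark`` (deepest sinks).  Raises ``ValueError`` if the condition
    digraph contains a cycle (no assignment can then satisfy all 12).
    """
    names = list(template.region_names)
    edges = list(template.conditions)
    # longest-path depth via Kahn's algorithm
    indeg = {n: 0 for n in names}
    for _, d in edges:
        indeg[d] += 1
    depth = {n: 0 for n in names}
    queue = [n for n in names if indeg[n] == 0]
    seen = 0
    while queue:
        n = queue.pop()
        seen += 1
        for b, d in edges:
            if b == n:
                depth[d] = max(depth[d], depth[n] + 1)
                indeg[d] -= 1
                if indeg[d] == 0:
                    queue.append(d)
    if seen < len(names):
        raise ValueError("condition digraph has a cycle; no ideal assignment exists")
    max_depth = max(depth.values()) or 1
    return {n: bright - (bright - dark) * depth[n] / max_depth for n in names}


# ---------------------------------------------------------------------------
# the two contrast models


def simple_contrast_model(
    target_cfs: Sequence[int], distractor_cfs: Sequence[int]
) -> ModelMatrix:
    """Design matrix of target-CF minus distractor-CF.

    Cell (i, j) is ``target_cfs[i] - distractor_cfs[j]``; e.g. targets
    {6, 12} against distractors {1, 6, 12} yield the six hypothesis
    cells (11, 6, 0, 5, 0, -6).
    """
    t = np.asarray(target_cfs, dtype=int)
    d = np.asarray(distractor_cfs, dtype=int)
    for arr, what in ((t, "target"), (d, "distractor")):
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError(f"{what} CF counts must be a non-empty 1-D sequence")
        if ((arr < 0) | (arr > 12)).any():
            raise ValueError(f"{what} CF counts must lie in 0..12")
    return ModelMatrix(
        row_labels=tuple(f"{c}CF" for c in t),
        col_labels=tuple(f"{c}CF" for c in d),
        values=t[:, None] - d[None, :],
        kind="simple_contrast",
    )


def feature_strength_model(
    targets: Sequence[FeatureProfile],
    distractors: Sequence[FeatureProfile],
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
) -> ModelMatrix:
    """Targets x distractors grid of mean-strength differences.

    Cell (i, j) = ``targets[i].mean_strength - distractors[j].mean_strength``:
    the higher the value, the stronger (on average) the face-typical
    contrasts in the target relative to the distractor.
    """
    if len(targets) == 0 or len(distractors) == 0:
        raise ValueError("targets and distractors must be non-empty")
    tm = np.array([p.mean_strength for p in targets], dtype=float)
    dm = np.array([p.mean_strength for p in distractors], dtype=float)
    rows = tuple(row_labels) if row_labels is not None else tuple(
        f"T{i + 1}" for i in range(len(targets))
    )
    cols = tuple(col_labels) if col_labels is not None else tuple(
        f"D{j + 1}" for j in range(len(distractors))
    )
    return ModelMatrix(
        row_labels=rows,
        col_labels=cols,
        values=tm[:, None] - dm[None, :],
        kind="feature_strength",
    )


def category_average_images(images: Sequence) -> dict[int, np.ndarray]:
    """Pixelwise average image per CF category.

    ``images`` is a sequence of objects with ``pixels`` and ``n_correct``
    attributes (e.g. :class:`facecontrast.stimuli.StimulusImage`).
    Categories with no member are simply absent from the result.
    """
    shapes = {np.asarray(im.pixels).shape for im in images}
    if len(shapes) > 1:
        raise ValueError(f"images have mixed shapes: {sorted(shapes)}")
    out: dict[int, np.ndarray] = {}
    for k in range(N_CONDITIONS + 1):
        members = [np.asarray(im.pixels, dtype=float) for im in images if im.n_correct == k]
        if members:
            out[k] = np.mean(members, axis=0)
    return out
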