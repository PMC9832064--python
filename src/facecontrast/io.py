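"""File formats: templates (YAML/JSON), images (PNG/PGM), trials and matrices (CSV).

Conventions: UTF-8 CSV with a header row and "." decimals; undefined
matrix cells serialize as empty fields; images are single-channel 8-bit
with luminance rescaled by 255 (round-half-even on write); pixel
coordinates are 0-based, row-major, with half-open rectangle intervals.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .analysis import PairwiseMatrix
from .behavior import TRIAL_COLUMNS
from .template import ContrastTemplate, ModelMatrix

__all__ = [
    "read_template",
    "write_template",
    "read_image",
    "write_image",
    "read_trials",
    "write_trials",
    "read_matrix",
    "write_matrix",
    "write_stimulus_set",
    "read_stimulus_set",
]


# ---------------------------------------------------------------------------
# templates


def write_template(template: ContrastTemplate, path: str | Path) -> None:
    if template.rectangles is None:
        raise ValueError("only rectangle-based templates can be serialized")
    doc = {
        "canvas_size": list(template.canvas_size),
        "regions": {name: list(rect) for name, rect in template.rectangles.items()},
        "conditions": [[b, d] for b, d in template.conditions],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(doc, indent=2))
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def read_template(path: str | Path) -> ContrastTemplate:
    path = Path(path)
    text = path.read_text()
    doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    try:
        return ContrastTemplate.from_rectangles(
            tuple(doc["canvas_size"]),
            {name: tuple(r) for name, r in doc["regions"].items()},
            [tuple(c) for c in doc["conditions"]],
        )
    except (KeyError, TypeError) as exc:
        raise ValueError(f"malformed template file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# images


def write_image(pixels: np.ndarray, path: str | Path) -> None:
    """Write a [0,1] luminance grid as single-channel 8-bit PNG/PGM."""
    pixels = np.asarray(pixels, dtype=float)
    if pixels.min() < 0 or pixels.max() > 1:
        raise ValueError("pixels outside [0,1]")
    data = np.round(pixels * 255.0).astype(np.uint8)  # numpy rounds half to even
    Image.fromarray(data, mode="L").save(Path(path))


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel 8-bit image into a [0,1] luminance grid."""
    with Image.open(Path(path)) as img:
        if img.mode != "L":
            img = img.convert("L")
        return np.asarray(img, dtype=float) / 255.0


# ---------------------------------------------------------------------------
# trials


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"trial log missing columns: {missing}")
    trials.to_csv(Path(path), index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial log {path} missing columns: {missing}")
    for col in ("chose_target", "rewarded", "correction_trial"):
        df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# matrices


def write_matrix(matrix, path: str | Path) -> None:
    """Write a PairwiseMatrix / ModelMatrix / labeled grid as CSV.

    Undefined (NaN) cells become empty fields; row labels land in the
    first column.
    """
    if isinstance(matrix, PairwiseMatrix):
        values, rows, cols = matrix.percent_correct, matrix.row_labels, matrix.col_labels
    elif isinstance(matrix, ModelMatrix):
        values, rows, cols = matrix.values, matrix.row_labels, matrix.col_labels
    else:
        values = np.asarray(matrix, dtype=float)
        rows = [f"r{i}" for i in range(values.shape[0])]
        cols = [f"c{j}" for j in range(values.shape[1])]
    pd.DataFrame(values, index=list(rows), columns=list(cols)).to_csv(Path(path))


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a labeled matrix CSV; empty fields become NaN."""
    df = pd.read_csv(Path(path), index_col=0)
    if df.empty or df.shape[1] == 0:
        raise ValueError(f"matrix file {path} has no data cells")
    return df


# ---------------------------------------------------------------------------
# stimulus sets on disk: PNGs plus a manifest CSV plus the template


def write_stimulus_set(stimulus_set, outdir: str | Path) -> Path:
    """Write PNGs, a manifest CSV and the template; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for im in stimulus_set.all_images:
        fname = f"{im.id}.png"
        write_image(im.pixels, outdir / fname)
        rows.append(
            {
                "id": im.id,
                "label": im.label,
                "role": im.role,
                "n_correct": im.n_correct,
                "cf_group": im.cf_group,
                "file": fname,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    write_template(stimulus_set.template, outdir / "template.yaml")
    return manifest


def read_stimulus_set(stimdir: str | Path):
    """Rebuild a StimulusSet from a directory written by write_stimulus_set.

    Note the quantization bound: pixel values may differ from the
    in-memory originals by up to 1/255.
    """
    from .stimuli import StimulusImage, StimulusSet

    stimdir = Path(stimdir)
    manifest = pd.read_csv(stimdir / "manifest.csv")
    required = {"id", "label", "role", "n_correct", "cf_group", "file"}
    if not required.issubset(manifest.columns):
        raise ValueError(f"manifest missing columns: {sorted(required - set(manifest.columns))}")
    template = read_template(stimdir / "template.yaml")
    groups: dict[tuple[str, str], list] = {}
    for rec in manifest.to_dict("records"):
        im = StimulusImage(
            id=str(rec["id"]),
            pixels=read_image(stimdir / rec["file"]),
            label=str(rec["label"]),
            role=str(rec["role"]),
            n_correct=int(rec["n_correct"]),
            cf_group=None if pd.isna(rec["cf_group"]) else int(rec["cf_group"]),
        )
        groups.setdefault((im.role, im.label), []).append(im)
    return StimulusSet(
        template=template,
        train_targets=tuple(groups.get(("train", "target"), [])),
        train_distractors=tuple(groups.get(("train", "distractor"), [])),
        test_targets=tuple(groups.get(("test", "target"), [])),
        test_distractors=tuple(groups.get(("test", "distractor"), [])),
    )
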