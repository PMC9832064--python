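"""End-to-end pipeline: stimuli -> behavior -> analysis -> readouts.

A :class:`RunConfig` holds every parameter and seed; :func:`run_pipeline`
executes the four stages, writes all declared outputs under one
directory and finishes with a manifest recording the configuration,
derived stage seeds and SHA-256 hashes of every output file, so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analysis import (
    condition_accuracy,
    matrix_correlation,
    pairwise_matrix,
    permutation_test,
    spearman_brown,
    split_half_reliability,
)
from .behavior import DecisionModel, simulate_experiment
from .io import read_template, write_matrix, write_stimulus_set, write_trials
from .readout import (
    PixelProvider,
    SmallConvNetProvider,
    layer_behavior_correlation,
    run_layer_readouts,
)
from .stimuli import build_stimulus_set
from .template import default_template

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "make_provider"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """Every knob of the end-to-end run, with study-condition defaults."""

    seed: int = 0
    template_path: str | None = None  # None -> built-in default template
    # stimuli
    noise_sd: float = 0.05
    # behavior
    n_rats: int = 8
    criterion: str = "strict"
    include_training: bool = True
    sensitivity: float = 4.0
    lapse: float = 0.25
    side_bias: float = 0.0
    p_old: float = 0.95
    # analysis
    n_perm: int = 1000
    # readout
    provider: str = "smallnet"  # {"pixels", "smallnet"}
    calibrate: float | None = 0.80
    readout_draws: int = 2000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)


def make_provider(name: str, seed: int = 0):
    if name == "pixels":
        return PixelProvider()
    if name == "smallnet":
        return SmallConvNetProvider(seed=seed)
    raise ValueError(f"unknown provider {name!r} (expected 'pixels' or 'smallnet')")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages; returns the manifest dict (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    stage_seeds = [int(s.generate_state(1)[0] % 2**31) for s in root.spawn(4)]
    manifest: dict = {
        "facecontrast_version": __version__,
        "config": asdict(config),
        "stage_seeds": {
            "stimuli": stage_seeds[0],
            "behavior": stage_seeds[1],
            "analysis": stage_seeds[2],
            "readout": stage_seeds[3],
        },
        "outputs": {},
    }

    def fail(stage: str, exc: Exception):
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    # --- stimuli ---
    try:
        template = (
            read_template(config.template_path) if config.template_path else default_template()
        )
        sset = build_stimulus_set(template, seed=stage_seeds[0], noise_sd=config.noise_sd)
        stimdir = outdir / "stimuli"
        write_stimulus_set(sset, stimdir)
    except Exception as exc:  # noqa: BLE001
        fail("stimuli", exc)

    # --- behavior ---
    try:
        model = DecisionModel(
            sensitivity=config.sensitivity,
            lapse=config.lapse,
            side_bias=config.side_bias,
            p_old=config.p_old,
        )
        train_trials, test_trials = simulate_experiment(
            sset,
            model,
            n_rats=config.n_rats,
            criterion=config.criterion,
            seed=stage_seeds[1],
            include_training=config.include_training,
        )
        if config.include_training:
            write_trials(train_trials, outdir / "training_trials.csv")
        write_trials(test_trials, outdir / "testing_trials.csv")
    except Exception as exc:  # noqa: BLE001
        fail("behavior", exc)

    # --- analysis ---
    try:
        target_ids = [im.id for im in sset.test_targets]
        distractor_ids = [im.id for im in sset.test_distractors]
        pooled = pairwise_matrix(test_trials, target_ids, distractor_ids)
        r1 = pairwise_matrix(test_trials, target_ids, distractor_ids, rounds=[1])
        r2 = pairwise_matrix(test_trials, target_ids, distractor_ids, rounds=[2])
        fsm = sset.feature_strength_matrix()
        reliability_half = split_half_reliability(r1, r2)
        reliability = spearman_brown(reliability_half)
        perm = permutation_test(pooled, fsm, n_perm=config.n_perm, seed=stage_seeds[2])
        cond = condition_accuracy(test_trials, sset.condition_map())
        write_matrix(pooled, outdir / "pairwise_matrix.csv")
        write_matrix(r1, outdir / "pairwise_matrix_round1.csv")
        write_matrix(r2, outdir / "pairwise_matrix_round2.csv")
        write_matrix(fsm, outdir / "feature_strength_model.csv")
        cond.to_csv(outdir / "condition_accuracy.csv", index=False)
        stats = {
            "split_half_reliability": reliability_half,
            "spearman_brown_reliability": reliability,
            "behavior_model_r": perm.observed_r,
            "permutation": {
                "null_mean": perm.null_mean,
                "null_sd": perm.null_sd,
                "p_value": perm.p_value,
                "n_perm": perm.n_perm,
                "seed": perm.seed,
            },
        }
        (outdir / "behavior_stats.json").write_text(json.dumps(stats, indent=2))
    except Exception as exc:  # noqa: BLE001
        fail("analysis", exc)

    # --- readout ---
    try:
        provider = make_provider(config.provider, seed=stage_seeds[3])
        readouts = run_layer_readouts(
            provider,
            sset,
            calibrate_to=config.calibrate,
            n_draws=config.readout_draws,
            seed=stage_seeds[3],
        )
        grids = {layer: r.score_diff for layer, r in readouts.items()}
        corr = layer_behavior_correlation(grids, pooled, fsm, reliability)
        rows = []
        for layer, r in readouts.items():
            rows.append(
                {
                    "layer": layer,
                    "noise_sd": r.noise_sd,
                    "train_accuracy": r.train_accuracy,
                    "test_accuracy": r.test_accuracy,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    **corr[layer],
                }
            )
        pd.DataFrame(rows).to_csv(outdir / "layer_readouts.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        fail("readout", exc)

    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
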