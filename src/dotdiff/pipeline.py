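"""End-to-end orchestration: simulate -> train -> predict -> reconstruct -> evaluate.

A :class:`RunConfig` plus its seed fully determines every artifact.  The
pipeline writes stage checkpoints (corpus HDF5, model npz, report JSON /
CSV, figures) into the output directory and can resume from any existing
checkpoint.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import io as dio
from .ann import TrainConfig, build_model, constant_predictor_mse, predict_perturbation, train
from .geometry import ProbeGeometry, default_probe
from .metrics import centroid_distance, simulation_test_summary
from .perturbation import compute_perturbation, rytov_linearize
from .reconstruction import (
    assemble_sensitivity,
    build_dual_mesh,
    reconstruct,
    roi_from_target,
)
from .synthdata import (
    build_corpus,
    make_mismatch_pair,
    sample_scene,
)

log = logging.getLogger("dotdiff")


@dataclass
class RunConfig:
    """Everything needed to reproduce a full run."""

    out_dir: str = "dotdiff_run"
    n_corpus: int = 2000
    n_test: int = 60
    n_mismatch: int = 20
    noise_fraction: float = 0.02
    train_fraction: float = 0.8
    seed: int = 0
    train: TrainConfig = field(default_factory=TrainConfig)
    mismatch_wall_depth: float = 3.0
    mismatch_shift: float = 1.0
    reuse_corpus: bool = True
    reuse_model: bool = True
    make_figures: bool = True


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            out = fn(*args, **kwargs)
            log.info("stage %-12s %.1fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


@_stage("corpus")
def stage_corpus(config: RunConfig, geometry: ProbeGeometry, path: Path):
    if config.reuse_corpus and path.exists():
        tr, va, _ = dio.load_corpus(path)
        return tr, va
    tr, va = build_corpus(
        config.n_corpus,
        geometry,
        train_fraction=config.train_fraction,
        noise_fraction=config.noise_fraction,
        rng_seed=config.seed,
    )
    dio.save_corpus(
        path, tr, va,
        manifest={"n_corpus": config.n_corpus, "seed": config.seed,
                  "noise_fraction": config.noise_fraction},
    )
    return tr, va


@_stage("train")
def stage_train(config: RunConfig, tr, va, path: Path):
    if config.reuse_model and path.exists():
        model, _ = dio.load_model(path)
        return model, None
    model = build_model(rng_seed=config.seed)
    tc = TrainConfig(**{**asdict(config.train), "rng_seed": config.seed})
    model, history = train(model, tr, va, tc)
    dio.save_model(
        path, model,
        extra_meta={"best_val_loss": history["best_val_loss"],
                    "baseline_val_mse": constant_predictor_mse(tr, va)},
    )
    (path.parent / "loss_history.json").write_text(
        json.dumps({k: history[k] for k in ("train_loss", "val_loss", "lr")})
    )
    return model, history


def sample_test_scenes(n: int, seed: int, require_wall: bool = False, wall_depth=None):
    """Held-out scenes from an independent seed stream."""
    rng = np.random.default_rng([seed, 0xD07])
    scenes = []
    while len(scenes) < n:
        s = sample_scene(rng)
        if require_wall:
            if not s.chest_wall.present:
                continue
            if wall_depth is not None:
                s.chest_wall.depth = wall_depth
                if s.target.center[2] + s.target.radius >= wall_depth - 0.1:
                    continue
        scenes.append(s)
    return scenes


@_stage("evaluate")
def stage_evaluate(config: RunConfig, model, geometry: ProbeGeometry):
    scenes = sample_test_scenes(config.n_test, config.seed)
    return simulation_test_summary(
        scenes, model, geometry,
        noise_fraction=config.noise_fraction, rng_seed=config.seed,
    )


@_stage("mismatch")
def stage_mismatch(config: RunConfig, model, geometry: ProbeGeometry):
    """Three-way comparison on chest-wall-mismatch scenes.

    Lesion-side wall at ``mismatch_wall_depth``; the mismatched reference's
    wall is shallower by ``mismatch_shift``.  Per scene, reconstructs from
    the matched, mismatched and network-predicted perturbations and
    records localization (centroid error) for each.
    """
    from .forward import fit_background

    scenes = sample_test_scenes(
        config.n_mismatch, config.seed + 1, require_wall=True,
        wall_depth=config.mismatch_wall_depth,
    )
    rng = np.random.default_rng([config.seed, 0x515])
    rows = []
    for scene in scenes:
        Ul, Ur_mis, Ur_match = make_mismatch_pair(
            scene, geometry, config.mismatch_shift, config.noise_fraction, rng
        )
        p_match = compute_perturbation(Ul, Ur_match)
        p_mis = compute_perturbation(Ul, Ur_mis)
        p_mis.provenance = "measured_mismatched"
        p_ann = predict_perturbation(model, Ul)

        roi = roi_from_target(scene.target.center, scene.target.radius)
        mesh = build_dual_mesh(roi)
        cx, cz = scene.target.center[0], scene.target.center[2]
        # each pathway reconstructs with the background its workflow supplies:
        # the reference fit for difference imaging, the lesion-side fit for
        # the reference-free pathway
        backgrounds = {
            "matched": fit_background(Ur_match, geometry),
            "mismatched": fit_background(Ur_mis, geometry),
            "ann": fit_background(Ul, geometry),
        }
        rec = {}
        for k, p in (("matched", p_match), ("mismatched", p_mis), ("ann", p_ann)):
            sens = assemble_sensitivity(mesh, geometry, backgrounds[k])
            rec[k] = reconstruct(rytov_linearize(p), sens)
        rows.append(
            {
                "radius": scene.target.radius,
                "mean_real_matched": float(p_match.real.mean()),
                "mean_real_mismatched": float(p_mis.real.mean()),
                "mean_real_ann": float(p_ann.real.mean()),
                **{
                    f"centroid_err_{k}": centroid_distance(
                        r.delta_mua, mesh.centers, mesh.volumes, (cx, cz)
                    )
                    for k, r in rec.items()
                },
                **{f"max_mua_{k}": r.max_mua for k, r in rec.items()},
            }
        )
    return rows


def _mismatch_figure(rows, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    axes[0].scatter([r["mean_real_matched"] for r in rows],
                    [r["mean_real_mismatched"] for r in rows], s=14, label="mismatched")
    axes[0].scatter([r["mean_real_matched"] for r in rows],
                    [r["mean_real_ann"] for r in rows], s=14, label="predicted")
    lim = axes[0].get_xlim()
    axes[0].plot(lim, lim, "k--", lw=0.8)
    axes[0].set_xlabel("mean Re(pert), matched reference")
    axes[0].set_ylabel("mean Re(pert)")
    axes[0].legend()
    axes[1].boxplot(
        [[r["centroid_err_matched"] for r in rows],
         [np.nan_to_num(r["centroid_err_mismatched"], nan=5.0) for r in rows],
         [r["centroid_err_ann"] for r in rows]],
        tick_labels=["matched", "mismatched", "predicted"],
    )
    axes[1].set_ylabel("centroid error (cm)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(config: RunConfig, geometry: ProbeGeometry | None = None) -> dict:
    """Execute the full workflow; returns the report dict (also written to disk)."""
    geometry = geometry or default_probe()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tr, va = stage_corpus(config, geometry, out / "corpus.h5")
    model, history = stage_train(config, tr, va, out / "model.npz")
    summary = stage_evaluate(config, model, geometry)
    mismatch_rows = stage_mismatch(config, model, geometry)

    ann_ok = [
        r["centroid_err_ann"] < r["radius"]
        for r in mismatch_rows
        if np.isfinite(r["centroid_err_ann"])
    ] + [False for r in mismatch_rows if not np.isfinite(r["centroid_err_ann"])]
    report = {
        "n_train": len(tr),
        "n_validation": len(va),
        "n_test": summary.n,
        "mean_abs_max_mua_diff": summary.mean_abs_diff,
        "ci95": [summary.ci_low, summary.ci_high],
        "baseline_val_mse": constant_predictor_mse(tr, va),
        "best_val_mse": history["best_val_loss"] if history else None,
        "mismatch": {
            "n_scenes": len(mismatch_rows),
            "ann_localization_rate": float(np.mean(ann_ok)) if mismatch_rows else None,
            "mean_real_shift_positive_rate": float(
                np.mean(
                    [
                        r["mean_real_mismatched"] > r["mean_real_matched"]
                        for r in mismatch_rows
                    ]
                )
            )
            if mismatch_rows
            else None,
        },
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    import pandas as pd

    pd.DataFrame(
        [
            {"max_mua_matched": c.max_mua_matched, "max_mua_ann": c.max_mua_ann,
             "abs_diff": c.abs_diff, "centroid_error_ann": c.centroid_error_ann}
            for c in summary.cases
        ]
    ).to_csv(out / "test_cases.csv", index=False)
    pd.DataFrame(mismatch_rows).to_csv(out / "mismatch_cases.csv", index=False)
    if config.make_figures and mismatch_rows:
        _mismatch_figure(mismatch_rows, out / "mismatch.png")
    return report
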