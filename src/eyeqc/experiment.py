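"""End-to-end experiment driver: generate -> classify -> score.

Ties the synthetic generator, the expert-system detector, the ML baselines,
and the latency-aware figure of merit into one reproducible run driven by a
single master seed.  The output mirrors the instrument study's comparison
table: one row per approach with accuracy, 90th-percentile SFPT, and FOM.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .expert import ESParams, classify_frame, scale_params
from .fom import calibrate_tau, compute_fom, measure_sfpt
from .ml import (
    ClassifierConfig,
    EvalReport,
    FeatureConfig,
    evaluate,
    features_matrix,
    train_classifier,
)
from .synth import DatasetProfile, generate_frames

__all__ = ["ExperimentConfig", "ExperimentError", "run_experiment"]

log = logging.getLogger("eyeqc")


class ExperimentError(RuntimeError):
    """A named stage of the experiment failed."""


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one comparison run.

    ``profile_scale`` shrinks the study's train/test split proportionally;
    ``ml_combos`` lists (feature kind, input side, classifier kind) triples.
    """

    seed: int = 0
    profile_scale: float = 0.05
    noise_sigma: float = 4.0
    run_es: bool = True
    es_side: int = 520
    ml_combos: Tuple[Tuple[str, int, str], ...] = (("unrolled", 32, "svm"),)
    timing_frames: int = 60
    out_dir: Optional[Path] = None

    def validate(self) -> None:
        from .ml import CLASSIFIER_KINDS, FEATURE_KINDS

        for kind, side, clf in self.ml_combos:
            if kind not in FEATURE_KINDS:
                raise ExperimentError(f"config.ml_combos: unknown feature kind {kind!r}")
            if clf not in CLASSIFIER_KINDS:
                raise ExperimentError(f"config.ml_combos: unknown classifier {clf!r}")
        if self.profile_scale <= 0:
            raise ExperimentError("config.profile_scale must be positive")


def _es_row(config: ExperimentConfig, test, tau: float) -> Dict:
    params = (
        ESParams()
        if config.es_side == 520
        else scale_params(ESParams(), config.es_side)
    )
    from .ml import resize_frame
    from .synth import crop_square

    def prep(frame):
        sq = crop_square(frame)
        return sq if config.es_side == sq.shape[0] else resize_frame(sq, config.es_side)

    frames = [prep(f) for f, *_ in test]
    truth = [gt.label for _, gt, *_ in test]
    preds = [classify_frame(f, params)[0] for f in frames]
    acc = float(np.mean([p is t for p, t in zip(preds, truth)]))
    n_t = min(config.timing_frames, len(frames) - 11)
    stats = measure_sfpt(lambda f: classify_frame(f, params), frames[: n_t + 11], warmup=10)
    return {
        "approach": "ES",
        "input_side": config.es_side,
        "classifier": "pre-defined",
        "accuracy": acc,
        "p90_sfpt_s": stats.p90_sfpt,
        "mean_sfpt_s": stats.mean_sfpt,
        "fom": compute_fom(acc, stats.p90_sfpt, tau),
    }


def _ml_row(combo, train, test, seed: int, timing_frames: int, tau: float) -> Dict:
    kind, side, clf = combo
    fc = FeatureConfig(kind=kind, input_side=side)
    cc = ClassifierConfig(kind=clf, seed=seed)
    from .synth import crop_square

    tr_frames = [crop_square(f) for f, *_ in train]
    te_frames = [crop_square(f) for f, *_ in test]
    X_tr = features_matrix(tr_frames, fc)
    X_te = features_matrix(te_frames, fc)
    y_tr = [gt.label for _, gt, *_ in train]
    y_te = [gt.label for _, gt, *_ in test]
    model = train_classifier(X_tr, y_tr, cc)
    report = evaluate(model, X_te, y_te, fc, cc)

    from .ml import extract_features

    def predict_one(frame):
        return model.predict(extract_features(frame, fc)[None, :])[0]

    n_t = min(timing_frames, len(te_frames) - 11)
    stats = measure_sfpt(predict_one, te_frames[: n_t + 11], warmup=10)
    return {
        "approach": "ML",
        "input_side": side,
        "classifier": f"{clf} ({kind})",
        "accuracy": report.accuracy,
        "p90_sfpt_s": stats.p90_sfpt,
        "mean_sfpt_s": stats.mean_sfpt,
        "fom": compute_fom(report.accuracy, stats.p90_sfpt, tau),
        "confusion": report.confusion.tolist(),
    }


def run_experiment(config: ExperimentConfig) -> Dict:
    """Run the configured comparison and return (and optionally write) it.

    Deterministic up to wall-clock timings: the same (config, seed) yields
    identical datasets, predictions, and accuracy figures; latency columns
    vary with the host and are reported but never compared.
    """
    config.validate()
    t_start = time.perf_counter()
    profile = DatasetProfile.paper_like(scale=config.profile_scale)
    tau = calibrate_tau()

    rng = np.random.default_rng(config.seed)
    train_seed = int(rng.integers(0, 2 ** 31))
    test_seed = int(rng.integers(0, 2 ** 31))
    ml_seed = int(rng.integers(0, 2 ** 31))

    def stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            out = fn(*args)
        except ExperimentError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            raise ExperimentError(f"stage {name!r} failed: {exc}") from exc
        log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
        return out

    train = stage(
        "generate-train",
        generate_frames,
        profile.train,
        train_seed,
        config.noise_sigma,
    )
    test = stage(
        "generate-test", generate_frames, profile.test, test_seed, config.noise_sigma
    )

    rows: List[Dict] = []
    if config.run_es:
        rows.append(stage("expert-system", _es_row, config, test, tau))
    for combo in config.ml_combos:
        rows.append(
            stage(
                f"ml-{combo[2]}-{combo[0]}{combo[1]}",
                _ml_row,
                combo,
                train,
                test,
                ml_seed,
                config.timing_frames,
                tau,
            )
        )

    bundle = {
        "config": {
            "seed": config.seed,
            "profile_scale": config.profile_scale,
            "noise_sigma": config.noise_sigma,
            "es_side": config.es_side,
            "ml_combos": [list(c) for c in config.ml_combos],
        },
        "tau_s": tau,
        "n_train": len(train),
        "n_test": len(test),
        "rows": rows,
        "elapsed_s": time.perf_counter() - t_start,
    }
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "comparison.json").write_text(json.dumps(bundle, indent=2))
        (out / "comparison.txt").write_text(format_table(rows))
    return bundle


def format_table(rows: Sequence[Dict]) -> str:
    """Human-readable comparison table (approach / size / accuracy / SFPT / FOM)."""
    header = f"{'approach':<10}{'input':>7}  {'classifier':<22}{'accuracy':>9}{'p90 SFPT (ms)':>15}{'FOM':>8}"
    lines = [header, "-" * len(header)]
    for r in rows:
        lines.append(
            f"{r['approach']:<10}{r['input_side']:>7}  {r['classifier']:<22}"
            f"{r['accuracy']:>9.3f}{r['p90_sfpt_s'] * 1e3:>15.3f}{r['fom']:>8.3f}"
        )
    return "\n".join(lines) + "\n"
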