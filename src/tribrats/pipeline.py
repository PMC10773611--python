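"""End-to-end orchestration: preprocess -> per-plane training -> fused evaluation."""

from __future__ import annotations

import dataclasses

import numpy as np

from . import preprocess as pp
from .ensemble import predict_case_triplanar
from .nets import ModelConfig, build_model
from .planes import PLANES
from .training import TrainConfig, build_slice_dataset, evaluate_model, train_model


#: Desk-scale phantom study conditions: a width-0.25 EfficientUNet on
#: 64 x 64 inputs, 5 epochs on 12 training phantoms.  With the epoch and
#: data budget shrunk ~60x relative to the full-scale schedule (30
#: epochs, lr 1e-4), the Adam step size is scaled up one decade so the
#: optimizer can traverse a comparable distance in the available steps.
DESK_SCALE = {
    "model": dict(architecture="efficientunet", input_size=64, in_channels=3,
                  width_mult=0.25),
    "train": dict(epochs=5, learning_rate=1e-3, batch_size=8),
    "n_train_cases": 12,
    "n_test_cases": 4,
}


def desk_scale_experiment(seed: int, combo=None, n_extra_epochs: int = 0):
    """Run the scaled-down tri-planar study on phantoms for one seed.

    Generates 16 phantom cases (12 train / 4 held out), preprocesses
    them, trains one width-0.25 EfficientUNet per plane, and returns
    ``(fused_report, per_plane_reports, per_case_df)`` on the held-out
    cases.
    """
    from .planes import ChannelCombo
    from .synthetic import PhantomParams, make_dataset

    combo = combo or ChannelCombo(("FLAIR", "T1ce", "T2"))
    n = DESK_SCALE["n_train_cases"] + DESK_SCALE["n_test_cases"]
    cases = make_dataset(n, PhantomParams(), defect_rate=0.0, seed=seed)
    processed, _ = prepare_cases(cases)
    train = processed[: DESK_SCALE["n_train_cases"]]
    test = processed[DESK_SCALE["n_train_cases"] :]
    mc = ModelConfig(**DESK_SCALE["model"], seed=seed)
    tc = TrainConfig(
        epochs=DESK_SCALE["train"]["epochs"] + n_extra_epochs,
        learning_rate=DESK_SCALE["train"]["learning_rate"],
        batch_size=DESK_SCALE["train"]["batch_size"],
        seed=seed,
    )
    models = train_triplanar(train, combo, mc, tc)
    size = (mc.input_size, mc.input_size)
    return evaluate_triplanar(models, test, target_inplane=size)


def prepare_cases(cases, alpha=0.001, bias_correct=True, target_inplane=None):
    """Run the preprocessing flow: defect screen, bias correction, z-score.

    Returns (preprocessed kept cases, rejected (case_id, QTestResult) list).
    """
    kept, rejected = pp.filter_defective_cases(cases, alpha=alpha)
    processed = [
        pp.preprocess_case(c, target_inplane=target_inplane, bias_correct=bias_correct)
        for c in kept
    ]
    return processed, rejected


def train_plane_model(
    cases,
    plane: str,
    channels,
    model_config: ModelConfig,
    train_config: TrainConfig,
    val_cases=None,
    sampling: str = "balanced",
):
    """Train one plane's model on the given (already preprocessed) cases."""
    size = (model_config.input_size, model_config.input_size)
    X, Y = build_slice_dataset(cases, plane, channels, size,
                               sampling=sampling, seed=train_config.seed)
    model = build_model(model_config)
    val = None
    if val_cases:
        val = build_slice_dataset(val_cases, plane, channels, size)
    history = train_model(model, (X, Y), train_config, val_data=val)
    return model, history


def select_plane_combo(
    cases,
    plane: str,
    combos,
    model_config: ModelConfig,
    train_config: TrainConfig,
    val_cases=None,
    metric: str = "loss",
    sampling: str = "balanced",
):
    """Train one model per channel combo for a plane and pick the best.

    Each candidate combo gets its own model; candidates are ranked by
    the final epoch's metrics (validation slices when ``val_cases`` is
    given, else training slices), minimum loss by default.  Returns
    ``(best_combo, models, reports)``.
    """
    from .ensemble import select_best_plane_model
    from .metrics import evaluate_pair

    models, reports = {}, {}
    eval_cases = val_cases or cases
    size = (model_config.input_size, model_config.input_size)
    for combo in combos:
        model, _ = train_plane_model(cases, plane, combo, model_config,
                                     train_config, sampling=sampling)
        X, Y = build_slice_dataset(eval_cases, plane, combo, size)
        probs = model.predict_proba(X, batch_size=train_config.batch_size)
        reports[combo] = evaluate_pair(probs, Y, epsilon=train_config.epsilon)
        models[combo] = model
    best = select_best_plane_model(reports, metric=metric)
    return best, models, reports


def train_triplanar(
    cases,
    combo,
    model_config: ModelConfig,
    train_config: TrainConfig,
    sampling: str = "balanced",
):
    """Train one model per anatomical plane with a shared channel combo.

    Per-plane seeds are derived from ``train_config.seed`` so the three
    models are independently initialized yet fully reproducible.
    """
    models = {}
    for k, plane in enumerate(PLANES):
        mc = dataclasses.replace(model_config, seed=model_config.seed + 1000 * k)
        tc = dataclasses.replace(train_config, seed=train_config.seed + 1000 * k)
        model, _ = train_plane_model(cases, plane, channels=combo,
                                     model_config=mc, train_config=tc,
                                     sampling=sampling)
        models[plane] = (model, combo)
    return models


def evaluate_triplanar(models, cases, target_inplane=None, threshold: float = 0.5):
    """Fused and per-plane aggregate reports over held-out cases.

    Returns ``(fused_report, per_plane_reports, per_case_df)`` where
    ``per_plane_reports`` maps plane -> aggregate EvalReport of that
    plane's 3D prediction alone.
    """
    vote_results = [
        predict_case_triplanar(c, models, target_inplane, threshold) for c in cases
    ]
    fused_report, df = evaluate_model(
        lambda c: vote_results[[x.case_id for x in cases].index(c.case_id)].fused.voxels,
        cases,
        threshold,
    )
    plane_reports = {}
    for i, plane in enumerate(PLANES):
        rep, _ = evaluate_model(
            lambda c: vote_results[[x.case_id for x in cases].index(c.case_id)]
            .inputs[i]
            .probabilities,
            cases,
            threshold,
        )
        plane_reports[plane] = rep
    return fused_report, plane_reports, df
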