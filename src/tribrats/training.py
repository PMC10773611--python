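"""Dataset splitting, slice-stream training, and evaluation.

Splits are by case (not by slice) so no subject leaks across sets.
Training optimizes the generalized Dice loss with Adam at the study
defaults (learning rate 1e-4, 30 epochs at full scale); every source of
randomness is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .metrics import EvalReport, evaluate_pair
from .nn.loss import generalized_dice_loss
from .nn.optim import Adam
from .planes import assemble_channel_slices


@dataclass
class DatasetSplit:
    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    ratio: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train_ids), len(self.val_ids), len(self.test_ids))


@dataclass
class TrainConfig:
    """Training hyperparameters (study defaults)."""

    learning_rate: float = 1e-4
    optimizer: str = "adam"
    activation: str = "sigmoid"
    epochs: int = 30
    batch_size: int = 8
    loss: str = "gdl"
    seed: int = 0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the Adam optimizer is implemented")


def split_dataset(case_ids, ratio=(7.0, 1.5, 1.5), seed: int = 0) -> DatasetSplit:
    """Deterministic shuffled case-level split.

    Validation and test sizes are ``floor(fraction * N)`` each; the
    remainder trains (the convention that yields 233/49/49 from 331 at
    7 : 1.5 : 1.5).
    """
    case_ids = list(case_ids)
    n = len(case_ids)
    if n < 3:
        raise ValueError("need at least 3 cases for non-empty splits")
    total = float(sum(ratio))
    n_val = int(np.floor(ratio[1] / total * n))
    n_test = int(np.floor(ratio[2] / total * n))
    if n_val < 1 or n_test < 1:
        raise ValueError("too few cases for non-empty validation/test splits")
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [case_ids[i] for i in order]
    n_train = n - n_val - n_test
    return DatasetSplit(
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
        tuple(ratio),
        seed,
    )


def build_slice_dataset(
    cases, plane: str, channels, target_inplane=None,
    sampling: str = "all", seed: int = 0,
):
    """Stack case slices for one plane into (X, Y) training arrays.

    ``sampling='all'`` keeps every slice.  ``sampling='balanced'`` — the
    training default — keeps every tumor-containing slice plus an equal
    number of tumor-free slices drawn deterministically per case, the
    usual counter to the severe foreground/background imbalance of 2D
    slice streams (tumor voxels are a percent-scale minority).
    """
    if sampling not in ("all", "balanced"):
        raise ValueError(f"unknown sampling policy {sampling!r}")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for case in cases:
        inputs, masks, _ = assemble_channel_slices(case, channels, plane, target_inplane)
        if sampling == "balanced":
            positive = masks.reshape(len(masks), -1).any(axis=1)
            pos_idx = np.flatnonzero(positive)
            neg_idx = np.flatnonzero(~positive)
            take = min(len(pos_idx), len(neg_idx))
            neg_idx = rng.choice(neg_idx, size=take, replace=False) if take else neg_idx[:0]
            keep = np.sort(np.concatenate([pos_idx, neg_idx])).astype(int)
            inputs, masks = inputs[keep], masks[keep]
        xs.append(inputs)
        ys.append(masks)
    return np.concatenate(xs, axis=0), np.concatenate(ys, axis=0)


def _epoch_eval(model, X, Y, config: TrainConfig) -> EvalReport:
    probs = model.predict_proba(X, batch_size=config.batch_size)
    return evaluate_pair(probs, Y, epsilon=config.epsilon)


def train_model(
    model,
    train_data,
    config: TrainConfig,
    val_data=None,
    verbose: bool = False,
) -> list[dict]:
    """Train a :class:`~tribrats.nets.SegmentationModel` on a slice stream.

    ``train_data`` is ``(X, Y)`` with X (N, C, H, W) float inputs and Y
    (N, 1, H, W) binary masks.  Returns the per-epoch history (running
    mean training loss, plus loss/accuracy/DSC on the validation slices
    when given).  Raises on empty data or a non-finite loss.
    """
    X, Y = train_data
    if len(X) == 0:
        raise ValueError("empty training data")
    X = np.asarray(X, dtype=np.float32)
    Y = np.asarray(Y, dtype=np.float32)
    optimizer = Adam(model.net.parameters(), lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    history = []
    model.net.train()
    for epoch in range(config.epochs):
        order = rng.permutation(len(X))
        losses = []
        for i in range(0, len(order), config.batch_size):
            idx = order[i : i + config.batch_size]
            optimizer.zero_grad()
            pred = model.forward(X[idx])
            loss = generalized_dice_loss(pred, Y[idx], config.epsilon)
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // config.batch_size}"
                )
            loss.backward()
            optimizer.step()
            losses.append(value)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses))}
        if val_data is not None:
            rep = _epoch_eval(model, val_data[0], val_data[1], config)
            row.update(val_loss=rep.loss, val_accuracy=rep.accuracy, val_dsc=rep.dsc)
        history.append(row)
        if verbose:
            print(
                "  ".join(f"{k}={v:.4f}" if isinstance(v, float) else f"{k}={v}"
                          for k, v in row.items())
            )
    model.net.eval()
    return history


def evaluate_model(predictor, cases, threshold: float = 0.5):
    """Per-case and aggregate loss/accuracy/DSC over 3D cases.

    ``predictor`` is a callable mapping a :class:`CaseRecord` to a 3D
    probability (or binary) grid of the case's shape — e.g. a closure
    around :func:`tribrats.ensemble.predict_case_triplanar`.  Returns
    ``(aggregate EvalReport, per-case DataFrame)``.
    """
    cases = list(cases)
    if not cases:
        raise ValueError("empty case list")
    rows = []
    for case in cases:
        probs = np.asarray(predictor(case), dtype=np.float64)
        rep = evaluate_pair(probs, case.truth.voxels, threshold)
        rows.append(
            {"case_id": case.case_id, "loss": rep.loss,
             "accuracy": rep.accuracy, "dsc": rep.dsc}
        )
    df = pd.DataFrame(rows)
    agg = EvalReport(
        float(df["loss"].mean()), float(df["accuracy"].mean()), float(df["dsc"].mean())
    )
    return agg, df
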