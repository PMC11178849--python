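"""Training protocol, metrics, and the brain-age-gap analysis.

Implements the experimental protocol used throughout: a seeded random
80/20 split, Adam at learning rate 0.001 with batch size 4, L1 loss by
default (MSE selectable), per-epoch validation MAE/RMSE/MSE, run summaries
as the minimum / maximum / mean of the per-epoch validation MAE, and
evaluation of a healthy-trained model on held-out disease-like cohorts via
per-group error metrics and mean signed brain-age gap (predicted minus
chronological age).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .nn import Adam, no_grad
from .nn import tensor as T
from .nn.tensor import Tensor
from .phantom import CohortManifest
from .volume_io import RegionSpec, crop_or_pad_center, extract_region, normalize_intensity, read_labelmap, read_volume


@dataclass
class TrainConfig:
    """Optimizer and protocol settings (defaults follow the study protocol)."""

    learning_rate: float = 0.001
    epochs: int = 60
    batch_size: int = 4
    optimizer: str = "adam"
    loss: str = "l1"  # "l1" or "mse"
    split_fraction: float = 0.8
    seed: int = 0
    normalize: bool = False  # per-volume z-scoring before the network

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")
        if self.loss not in ("l1", "mse"):
            raise ValueError(f"loss must be 'l1' or 'mse', got '{self.loss}'")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown training parameter(s): {sorted(unknown)}")
        return cls(**d)


class Metrics(NamedTuple):
    mae: float
    rmse: float
    mse: float


def compute_metrics(predicted: Sequence[float], actual: Sequence[float]) -> Metrics:
    """MAE, RMSE and MSE between predicted and chronological ages (years)."""
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape or p.ndim != 1:
        raise ValueError(f"prediction/actual shape mismatch: {p.shape} vs {a.shape}")
    if p.size == 0:
        raise ValueError("cannot compute metrics of empty vectors")
    err = p - a
    mse = float(np.mean(err ** 2))
    return Metrics(mae=float(np.mean(np.abs(err))), rmse=float(np.sqrt(mse)), mse=mse)


@dataclass
class MetricsReport:
    """Per-epoch validation trace of one training run."""

    per_epoch: pd.DataFrame  # epoch, val_mae, val_rmse, val_mse
    best_epoch: int
    baseline_mae: float  # MAE of predicting the train-set mean age on the val set

    def summary(self) -> tuple[float, float, float]:
        return summarize_run(self)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.per_epoch.to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        mn, mx, mean = self.summary()
        payload = {
            "per_epoch": self.per_epoch.to_dict(orient="records"),
            "summary": {"min_mae": mn, "max_mae": mx, "mean_mae": mean},
            "best_epoch": self.best_epoch,
            "baseline_mae": self.baseline_mae,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def summarize_run(report: MetricsReport | Sequence[float]) -> tuple[float, float, float]:
    """(MinMAE, MaxMAE, MeanMAE) over the per-epoch validation MAE of a run."""
    if isinstance(report, MetricsReport):
        maes = report.per_epoch["val_mae"].to_numpy(dtype=float)
    else:
        maes = np.asarray(report, dtype=float)
    if maes.size == 0:
        raise ValueError("empty run: no epochs recorded")
    return float(maes.min()), float(maes.max()), float(maes.mean())


@dataclass
class GapReport:
    """Per-group error metrics and mean signed brain-age gap."""

    per_group: pd.DataFrame  # group, n, mae, rmse, mse, mean_gap

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.per_group.to_csv(path, index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.per_group.to_dict(orient="records"), indent=2))
        return path


# -- dataset handling ---------------------------------------------------------

def split_dataset(manifest: CohortManifest, fraction: float = 0.8,
                  seed: int = 0) -> tuple[CohortManifest, CohortManifest]:
    """Seeded random partition into train (floor(fraction*n)) and validation."""
    n = len(manifest)
    if n == 0:
        raise ValueError("cannot split an empty manifest")
    n_train = int(np.floor(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"split of {n} subjects at fraction {fraction} leaves an empty partition"
        )
    perm = np.random.default_rng(seed).permutation(n)
    df = manifest.records
    train = df.iloc[perm[:n_train]].reset_index(drop=True)
    val = df.iloc[perm[n_train:]].reset_index(drop=True)
    mk = lambda d: CohortManifest(d, seed=manifest.seed, params=manifest.params)
    return mk(train), mk(val)


def load_volumes(manifest: CohortManifest, edge: int,
                 channels: Sequence[RegionSpec] | None = None,
                 normalize: bool = False,
                 split_lr: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Read a cohort into a channels-last batch array plus its age vector.

    With ``channels`` given, each region spec contributes one input channel
    (the volume masked to that region); with ``split_lr`` additionally set,
    every spec contributes its left and right parts as two channels.
    Volumes are center-cropped/padded to ``edge``.
    """
    from .volume_io import split_left_right

    ages = manifest.records["age"].to_numpy(dtype=np.float32)
    vols = []
    for _, row in manifest.records.iterrows():
        v = read_volume(row["volume_path"])
        if normalize:
            v = normalize_intensity(v)
        if channels:
            m = read_labelmap(row["labelmap_path"])
            chans = []
            for spec in channels:
                if split_lr:
                    l, r = split_left_right(v, m, spec)
                    chans.extend([l, r])
                else:
                    chans.append(extract_region(v, m, spec))
            stacked = np.stack(
                [crop_or_pad_center(cv, edge).values for cv in chans], axis=-1
            )
        else:
            stacked = crop_or_pad_center(v, edge).values[..., None]
        vols.append(stacked)
    return np.stack(vols).astype(np.float32), ages


# -- training loop ------------------------------------------------------------

def _loss_tensor(pred: Tensor, target: np.ndarray, kind: str) -> Tensor:
    diff = T.sub(pred, Tensor(target))
    if kind == "l1":
        return T.mean_all(T.abs_(diff))
    return T.mean_all(T.square(diff))


def train_model(net, train_manifest: CohortManifest, val_manifest: CohortManifest,
                cfg: TrainConfig, channels: Sequence[RegionSpec] | None = None,
                split_lr: bool = False, verbose: bool = True):
    """Run the training protocol; returns (trained net, MetricsReport).

    The model state with the lowest validation MAE is restored at the end
    (best-epoch checkpoint); the full per-epoch trace is reported. All
    randomness (batch order) derives from ``cfg.seed``.
    """
    import sys

    edge = getattr(net, "input_edge", None) or net.cfg.input_edge
    x_tr, y_tr = load_volumes(train_manifest, edge, channels, cfg.normalize, split_lr)
    x_va, y_va = load_volumes(val_manifest, edge, channels, cfg.normalize, split_lr)
    if len(y_tr) == 0:
        raise ValueError("empty training split")
    baseline_mae = float(np.mean(np.abs(y_va - y_tr.mean())))

    opt = Adam(net.parameters(), lr=cfg.learning_rate)
    rows = []
    best = (np.inf, None)
    for epoch in range(1, cfg.epochs + 1):
        order = np.random.default_rng([cfg.seed, epoch]).permutation(len(y_tr))
        for bi, start in enumerate(range(0, len(order), cfg.batch_size)):
            idx = order[start : start + cfg.batch_size]
            pred = net(Tensor(x_tr[idx]))
            loss = _loss_tensor(pred, y_tr[idx], cfg.loss)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {bi}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
        preds = _predict(net, x_va, batch_size=2 * cfg.batch_size)
        m = compute_metrics(preds, y_va)
        rows.append((epoch, m.mae, m.rmse, m.mse))
        if m.mae < best[0]:
            best = (m.mae, net.state_dict())
        if verbose:
            print(
                f"epoch {epoch:3d}  val MAE {m.mae:6.2f}  RMSE {m.rmse:6.2f}  MSE {m.mse:8.2f}",
                file=sys.stderr, flush=True,
            )
    if best[1] is not None:
        net.load_state_dict(best[1])
    per_epoch = pd.DataFrame(rows, columns=["epoch", "val_mae", "val_rmse", "val_mse"])
    best_epoch = int(per_epoch.loc[per_epoch["val_mae"].idxmin(), "epoch"])
    return net, MetricsReport(per_epoch, best_epoch=best_epoch, baseline_mae=baseline_mae)


def _predict(net, x: np.ndarray, batch_size: int = 8) -> np.ndarray:
    preds = []
    with no_grad():
        for s in range(0, len(x), batch_size):
            preds.append(net(Tensor(x[s : s + batch_size])).data)
    return np.concatenate(preds)


def evaluate_model(net, manifest: CohortManifest,
                   channels: Sequence[RegionSpec] | None = None,
                   normalize: bool = False, split_lr: bool = False):
    """Deterministic evaluation: (Metrics, per-subject prediction table)."""
    if len(manifest) == 0:
        raise ValueError("cannot evaluate an empty manifest")
    edge = getattr(net, "input_edge", None) or net.cfg.input_edge
    x, y = load_volumes(manifest, edge, channels, normalize, split_lr)
    preds = _predict(net, x)
    m = compute_metrics(preds, y)
    table = pd.DataFrame({
        "subject_id": manifest.records["subject_id"],
        "age": y,
        "predicted_age": preds,
        "gap": preds - y,
    })
    return m, table


def group_gap_analysis(net, manifests: Sequence[tuple[str, CohortManifest]],
                       channels: Sequence[RegionSpec] | None = None,
                       normalize: bool = False) -> GapReport:
    """Evaluate a (healthy-trained) model per group with identical preprocessing.

    Reports n, MAE, RMSE, MSE and the mean signed brain-age gap
    (mean of predicted minus chronological age) for each non-empty group.
    """
    rows = []
    for group, manifest in manifests:
        if len(manifest) == 0:
            warnings.warn(f"group '{group}' has no subjects; skipped")
            continue
        m, table = evaluate_model(net, manifest, channels, normalize)
        rows.append((group, len(manifest), m.mae, m.rmse, m.mse, float(table["gap"].mean())))
    return GapReport(pd.DataFrame(rows, columns=["group", "n", "mae", "rmse", "mse", "mean_gap"]))
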