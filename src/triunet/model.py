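"""Model/Results facade over the training pipeline.

`BrainAgeModel` binds a cohort manifest to an architecture and protocol
configuration; `fit()` runs the training loop and returns a
`BrainAgeResults` carrying the trained network, the per-epoch validation
trace, summaries, and evaluation/gap-analysis/plotting methods — the shape
familiar from statistical modelling libraries (model object in, results
object out).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .networks import NetworkConfig, build_network, load_checkpoint, save_checkpoint
from .phantom import CohortManifest
from .training import (
    GapReport,
    MetricsReport,
    TrainConfig,
    evaluate_model,
    group_gap_analysis,
    split_dataset,
    train_model,
)
from .volume_io import RegionSpec


class BrainAgeModel:
    """A brain-age regression model bound to a training cohort.

    Parameters
    ----------
    manifest : CohortManifest
        Subject table with volume (and label-map) paths and ages.
    network : str
        One of ``triunet``, ``unet3d``, ``resnet34``.
    network_config, train_config : optional
        Architecture and protocol settings; defaults follow the package's
        study protocol (Adam, lr 0.001, batch 4, L1 loss, 80/20 split).
    channels : optional sequence of RegionSpec
        Anatomical regions fed as separate input channels (multi-channel
        region network); ``split_lr`` additionally splits each region into
        left/right channels.
    """

    def __init__(self, manifest: CohortManifest, network: str = "triunet",
                 network_config: NetworkConfig | None = None,
                 train_config: TrainConfig | None = None,
                 channels: Sequence[RegionSpec] | None = None,
                 split_lr: bool = False):
        self.manifest = manifest
        self.network_name = network
        in_channels = (2 if split_lr else 1) * len(channels) if channels else 1
        self.network_config = network_config or NetworkConfig(in_channels=in_channels)
        if channels and self.network_config.in_channels != in_channels:
            raise ValueError(
                f"network_config.in_channels={self.network_config.in_channels} does not "
                f"match {in_channels} region channels"
            )
        self.train_config = train_config or TrainConfig()
        self.channels = list(channels) if channels else None
        self.split_lr = split_lr

    @classmethod
    def from_manifest(cls, path: str | Path, **kw) -> "BrainAgeModel":
        return cls(CohortManifest.from_csv(path), **kw)

    def fit(self, verbose: bool = True) -> "BrainAgeResults":
        """Split, train, and return a results object (best epoch restored)."""
        train_man, val_man = split_dataset(
            self.manifest, self.train_config.split_fraction, self.train_config.seed
        )
        net = build_network(self.network_name, self.network_config)
        net, report = train_model(
            net, train_man, val_man, self.train_config,
            channels=self.channels, split_lr=self.split_lr, verbose=verbose,
        )
        return BrainAgeResults(self, net, report, train_man, val_man)


@dataclass
class BrainAgeResults:
    """Fit results: trained network, validation trace, evaluation helpers."""

    model: BrainAgeModel
    net: object
    report: MetricsReport
    train_manifest: CohortManifest
    val_manifest: CohortManifest

    # -- evaluation -----------------------------------------------------------
    def evaluate(self, manifest: CohortManifest | None = None):
        """(Metrics, per-subject table) on a manifest (default: validation split)."""
        manifest = manifest if manifest is not None else self.val_manifest
        return evaluate_model(
            self.net, manifest, channels=self.model.channels,
            normalize=self.model.train_config.normalize,
            split_lr=self.model.split_lr,
        )

    def predict(self, manifest: CohortManifest) -> pd.DataFrame:
        return self.evaluate(manifest)[1]

    def gap_analysis(self, groups: Sequence[tuple[str, CohortManifest]]) -> GapReport:
        """Per-group brain-age-gap report with identical preprocessing."""
        return group_gap_analysis(
            self.net, groups, channels=self.model.channels,
            normalize=self.model.train_config.normalize,
        )

    # -- reporting ------------------------------------------------------------
    def summary(self) -> str:
        mn, mx, mean = self.report.summary()
        n_epochs = len(self.report.per_epoch)
        lines = [
            "Brain-age regression results",
            "=" * 60,
            f"network:            {self.model.network_name}",
            f"input edge:         {self.model.network_config.input_edge}",
            f"input channels:     {self.model.network_config.in_channels}",
            f"parameters:         {self.net.n_parameters():,}",
            f"train / val:        {len(self.train_manifest)} / {len(self.val_manifest)}",
            f"epochs:             {n_epochs} (best: {self.report.best_epoch})",
            f"loss:               {self.model.train_config.loss}",
            "-" * 60,
            f"MinMAE / MaxMAE / MeanMAE (y): {mn:.2f} / {mx:.2f} / {mean:.2f}",
            f"best-epoch val MAE (y):        {mn:.2f}",
            f"mean-age baseline MAE (y):     {self.report.baseline_mae:.2f}",
            "=" * 60,
        ]
        return "\n".join(lines)

    def plot_metrics(self, path: str | Path | None = None):
        """Plot per-epoch validation MAE/RMSE/MSE curves (matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = self.report.per_epoch
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
        for ax, col, unit in zip(
            axes, ("val_mae", "val_rmse", "val_mse"), ("years", "years", "years$^2$")
        ):
            ax.plot(df["epoch"], df[col])
            ax.set_xlabel("epoch")
            ax.set_ylabel(f"{col.replace('val_', '').upper()} ({unit})")
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
            return Path(path)
        return fig

    def save(self, path: str | Path) -> None:
        save_checkpoint(self.net, self.model.network_name, self.model.network_config, path)

    @staticmethod
    def load_network(path: str | Path):
        return load_checkpoint(path)
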