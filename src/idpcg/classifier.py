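"""Model/Results interface for the five-class heart-sound classifier.

:class:`HeartSoundClassifier` is constructed from a feature matrix and
class labels (or directly from annotated PCG records); ``fit()`` runs
Levenberg-Marquardt training and returns a
:class:`HeartSoundClassifierResults` carrying the fitted weights, the
per-epoch error path, fit diagnostics (final MSE, regression R) and a
``summary()`` table.  Prediction, fixed-point quantisation, persistence
and training-curve plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activation import ActivationSpec
from .network import (
    FeatureScaler,
    FixedPointFormat,
    MLPModel,
    forward,
    forward_fixed,
    mse,
    quantize_model,
    regression_r,
    save_model,
)
from .pipeline import FEATURE_NAMES, PipelineConfig, features_from_record
from .synth import CLASS_NAMES
from .train import TrainConfig, TrainingRecord, train_lm

__all__ = ["HeartSoundClassifier", "HeartSoundClassifierResults", "one_hot_targets"]

TARGET_HI = 0.9  # one-hot coding inside the activation's reachable range
TARGET_LO = -0.9


def one_hot_targets(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """+/-0.9 one-hot target coding (exact +/-1 is unreachable under clamping)."""
    T = np.full((len(labels), n_classes), TARGET_LO)
    T[np.arange(len(labels)), labels] = TARGET_HI
    return T


class HeartSoundClassifier:
    """The 6-12-5 feedforward classifier over Table-style murmur features.

    Parameters
    ----------
    features:
        (n, 6) array or DataFrame of F1..F6 descriptors.
    labels:
        length-n class labels — integer indices or names from
        ``class_names``.
    n_hidden:
        hidden-layer width (12 by default).
    activation:
        :class:`ActivationSpec`; defaults to the hardware cubic form.
    """

    def __init__(
        self,
        features,
        labels,
        n_hidden: int = 12,
        activation: ActivationSpec | None = None,
        class_names: tuple = CLASS_NAMES,
    ):
        if isinstance(features, pd.DataFrame):
            features = features[list(FEATURE_NAMES)].to_numpy()
        self.exog = np.atleast_2d(np.asarray(features, dtype=float))
        self.class_names = tuple(class_names)
        self.endog = self._encode_labels(labels)
        if self.exog.shape[0] != len(self.endog):
            raise ValueError("features and labels disagree in length")
        self.n_hidden = int(n_hidden)
        self.activation = activation or ActivationSpec()
        counts = np.bincount(self.endog, minlength=len(self.class_names))
        if np.any(counts[counts > 0] < 1):
            raise ValueError("each present class needs at least one sample")

    def _encode_labels(self, labels) -> np.ndarray:
        out = []
        for lab in labels:
            if isinstance(lab, (int, np.integer)):
                out.append(int(lab))
            else:
                out.append(self.class_names.index(str(lab)))
        return np.asarray(out, dtype=int)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_records(
        cls,
        records,
        segmentation: str = "oracle",
        pipeline_config: PipelineConfig | None = None,
        **kwargs,
    ) -> "HeartSoundClassifier":
        """Build the design matrix by running the feature pipeline on records.

        Records whose segmentation fails are skipped; the count of skipped
        records is stored on the instance as ``n_excluded``.
        """
        feats, labs, excluded = [], [], 0
        for rec in records:
            try:
                fv = features_from_record(rec, segmentation, pipeline_config)
            except Exception:
                excluded += 1
                continue
            feats.append(fv.as_array())
            labs.append(rec.label)
        obj = cls(np.array(feats), labs, **kwargs)
        obj.n_excluded = excluded
        return obj

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, label_col: str = "label", **kwargs
    ) -> "HeartSoundClassifier":
        return cls(df[list(FEATURE_NAMES)].to_numpy(), df[label_col].tolist(), **kwargs)

    # -- fitting ---------------------------------------------------------
    def fit(self, config: TrainConfig | None = None) -> "HeartSoundClassifierResults":
        cfg = config or TrainConfig()
        scaler = FeatureScaler().fit(self.exog)
        X = scaler.transform(self.exog)
        T = one_hot_targets(self.endog, len(self.class_names))
        mlp, record = train_lm(
            X,
            T,
            cfg,
            act=self.activation,
            n_hidden=self.n_hidden,
            scaler=scaler,
            class_names=self.class_names,
        )
        return HeartSoundClassifierResults(model=self, mlp=mlp, history=record, config=cfg)


@dataclass
class HeartSoundClassifierResults:
    """Fitted classifier: weights, error path, diagnostics, persistence."""

    model: HeartSoundClassifier
    mlp: MLPModel
    history: TrainingRecord
    config: TrainConfig
    _cache: dict = field(default_factory=dict, repr=False)

    # -- error paths -----------------------------------------------------
    @property
    def mse_path(self) -> np.ndarray:
        return np.asarray(self.history.train_mse)

    @property
    def val_mse_path(self) -> np.ndarray:
        return np.asarray(self.history.val_mse)

    @property
    def final_mse(self) -> float:
        return float(self.mse_path[-1]) if len(self.mse_path) else float("nan")

    @property
    def n_epochs(self) -> int:
        return self.history.n_epochs

    @property
    def stop_reason(self) -> str:
        return self.history.stop_reason

    # -- prediction ------------------------------------------------------
    def predict_scores(self, features) -> np.ndarray:
        """Raw 5-vector network scores for (unscaled) feature rows."""
        X = np.atleast_2d(np.asarray(features, dtype=float))
        Z = self.mlp.scaler.transform(X)
        out = forward(self.mlp, Z)
        return out[0] if np.asarray(features).ndim == 1 else out

    def predict(self, features) -> np.ndarray:
        scores = np.atleast_2d(self.predict_scores(features))
        return np.argmax(scores, axis=1)

    def predict_label(self, features) -> list:
        return [self.model.class_names[i] for i in self.predict(features)]

    # -- diagnostics -----------------------------------------------------
    @property
    def train_mse(self) -> float:
        """MSE of the fitted network over the full training design."""
        if "train_mse" not in self._cache:
            T = one_hot_targets(self.model.endog, len(self.model.class_names))
            self._cache["train_mse"] = mse(self.predict_scores(self.model.exog), T)
        return self._cache["train_mse"]

    @property
    def regression_r(self) -> float:
        """Pearson correlation between network outputs and coded targets."""
        T = one_hot_targets(self.model.endog, len(self.model.class_names))
        return regression_r(self.predict_scores(self.model.exog), T)

    def training_accuracy(self) -> float:
        return float(np.mean(self.predict(self.model.exog) == self.model.endog))

    def summary(self) -> str:
        ni, nh, no = self.mlp.shape
        lines = [
            "Heart-sound classifier (inverse-delayed activation)",
            "=" * 55,
            f"Architecture:        {ni}-{nh}-{no} feedforward",
            f"Activation:          {self.mlp.act.form} (K={self.mlp.act.K})",
            f"Training samples:    {len(self.model.endog)}",
            f"Epochs run:          {self.n_epochs}  (stop: {self.stop_reason})",
            f"Final train MSE:     {self.final_mse:.3e}",
        ]
        if len(self.val_mse_path):
            lines.append(f"Final val MSE:       {self.val_mse_path[-1]:.3e}")
        lines += [
            f"Regression R:        {self.regression_r:.4f}",
            f"Training accuracy:   {self.training_accuracy():.4f}",
            "-" * 55,
            "Classes: " + ", ".join(self.model.class_names),
        ]
        return "\n".join(lines)

    # -- deployment ------------------------------------------------------
    def quantized(self, fmt: FixedPointFormat | None = None) -> MLPModel:
        """Fixed-point copy of the fitted weights (default Q32.24)."""
        return quantize_model(self.mlp, fmt or FixedPointFormat())

    def predict_scores_fixed(self, features, fmt: FixedPointFormat | None = None) -> np.ndarray:
        fmt = fmt or FixedPointFormat()
        X = np.atleast_2d(np.asarray(features, dtype=float))
        Z = self.mlp.scaler.transform(X)
        out = forward_fixed(self.quantized(fmt), Z, fmt)
        return out[0] if np.asarray(features).ndim == 1 else out

    def save(self, path) -> None:
        save_model(self.mlp, path)

    # -- plotting --------------------------------------------------------
    def plot_training(self, ax=None):
        """Plot train/validation MSE per epoch (log scale)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(np.arange(1, self.n_epochs + 1), self.mse_path, label="train")
        if len(self.val_mse_path):
            ax.semilogy(
                np.arange(1, len(self.val_mse_path) + 1), self.val_mse_path, label="validation"
            )
        ax.set_xlabel("epoch")
        ax.set_ylabel("MSE")
        ax.legend()
        return ax
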