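"""Scikit-learn-style estimators: the public modelling surface of the package.

`GafImageSequencer` is a (stateless) transformer turning triaxial recordings
into GAF image sequences; `MultimodalAdhdClassifier` is a fit/predict binary
classifier over (image-sequence, clinical-vector) pairs. Both follow sklearn
conventions — ``get_params``/``set_params``, fitted attributes with a trailing
underscore, ``check_is_fitted``-compatible state — so they compose with
sklearn pipelines and model selection, even though the sample type is richer
than a 2-D feature matrix.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.exceptions import NotFittedError

from .autodiff import Tensor
from .gaf import TriaxialSeries, WindowingConfig, compute_enmo, window_to_sequence
from .model import BiLstmConfig, FusionConfig, MultimodalNet, ViTConfig
from .training import TrainConfig, evaluate, subject_split, train

__all__ = ["GafImageSequencer", "MultimodalAdhdClassifier"]


class GafImageSequencer(TransformerMixin, BaseEstimator):
    """Transform triaxial acceleration series into GAF image sequences.

    Parameters mirror the windowing configuration: `window_seconds` of signal
    per frame, PAA-reduced to `image_size` points, `frames_per_sequence`
    consecutive non-overlapping frames per sample. The transform is stateless;
    `fit` only validates parameters.
    """

    def __init__(self, window_seconds: float = 10.0, image_size: int = 224,
                 frames_per_sequence: int = 5, channel_mode: str = "replicate",
                 clip_negative_enmo: bool = False):
        self.window_seconds = window_seconds
        self.image_size = image_size
        self.frames_per_sequence = frames_per_sequence
        self.channel_mode = channel_mode
        self.clip_negative_enmo = clip_negative_enmo

    def _config(self) -> WindowingConfig:
        return WindowingConfig(
            window_seconds=self.window_seconds, image_size=self.image_size,
            frames_per_sequence=self.frames_per_sequence,
            channel_mode=self.channel_mode,
            clip_negative_enmo=self.clip_negative_enmo)

    def fit(self, X=None, y=None):
        self._config()  # parameter validation
        self.n_features_in_ = 3
        return self

    def transform(self, X):
        """X: iterable of :class:`TriaxialSeries` (or (series, subject_id)
        pairs). Returns a list of lists of :class:`ImageSequence`, one inner
        list per input series."""
        cfg = self._config()
        out = []
        for item in X:
            series, sid = item if isinstance(item, tuple) else (item, "")
            if not isinstance(series, TriaxialSeries):
                raise TypeError(f"expected TriaxialSeries, got {type(series).__name__}")
            enmo = compute_enmo(series, clip_negative=cfg.clip_negative_enmo)
            axes = (series.x, series.y, series.z) if cfg.channel_mode == "per_axis" else None
            out.append(window_to_sequence(enmo, cfg, subject_id=sid, axes=axes))
        return out


class MultimodalAdhdClassifier(ClassifierMixin, BaseEstimator):
    """Binary classifier fusing GAF image sequences with clinical vectors.

    ``X`` is a pair of aligned arrays ``(frames, tabular)`` — frames of shape
    (n, F, 3, H, W) in [0, 1] and tabular of shape (n, d) — or an object with
    ``frames``/``tabular`` attributes (e.g. a
    :class:`~actifuse.dataset.SequenceDataset`). ``y`` is the per-sample
    binary label. Architecture defaults are the CPU-scale tiny preset; the
    study-scale configuration is available via ``preset='study'``.
    """

    def __init__(self, fusion: str = "cross_attention", preset: str = "tiny",
                 d_k: int = None, fusion_heads: int = None, single_token: bool = False,
                 epochs: int = None, learning_rate: float = None, batch_size: int = 8,
                 weight_decay: float = 1e-5, dropout: float = 0.5,
                 focal_gamma: float = 2.0, class_weight_mode: str = "inverse",
                 validation_fraction: float = 0.15, seed: int = 42):
        self.fusion = fusion
        self.preset = preset
        self.d_k = d_k
        self.fusion_heads = fusion_heads
        self.single_token = single_token
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.dropout = dropout
        self.focal_gamma = focal_gamma
        self.class_weight_mode = class_weight_mode
        self.validation_fraction = validation_fraction
        self.seed = seed

    # ------------------------------------------------------------- internals
    def _configs(self):
        if self.preset == "tiny":
            vit = ViTConfig.tiny()
            lstm = BiLstmConfig.tiny()
            tcfg = TrainConfig.tiny(seed=self.seed)
            d_k = 32 if self.d_k is None else self.d_k
            heads = 2 if self.fusion_heads is None else self.fusion_heads
        elif self.preset == "study":
            vit = ViTConfig()
            lstm = BiLstmConfig()
            tcfg = TrainConfig(seed=self.seed)
            d_k = 128 if self.d_k is None else self.d_k
            heads = 4 if self.fusion_heads is None else self.fusion_heads
        else:
            raise ValueError(f"unknown preset {self.preset!r}; use 'tiny' or 'study'")
        if self.epochs is not None:
            tcfg.epochs = self.epochs
        if self.learning_rate is not None:
            tcfg.learning_rate = self.learning_rate
        tcfg.batch_size = self.batch_size
        tcfg.weight_decay = self.weight_decay
        tcfg.dropout = self.dropout
        tcfg.focal_gamma = self.focal_gamma
        tcfg.class_weight_mode = self.class_weight_mode
        fusion = FusionConfig(kind=self.fusion, d_k=d_k, heads=heads,
                              dropout=self.dropout, single_token=self.single_token)
        return vit, lstm, fusion, tcfg

    @staticmethod
    def _unpack(X):
        if hasattr(X, "frames") and hasattr(X, "tabular"):
            return np.asarray(X.frames, dtype=np.float64), np.asarray(X.tabular, dtype=np.float64)
        frames, tabular = X
        return np.asarray(frames, dtype=np.float64), np.asarray(tabular, dtype=np.float64)

    def _validate(self, frames, tabular, fit: bool):
        if frames.ndim != 5 or frames.shape[2] != 3:
            raise ValueError(f"frames must be (n, F, 3, H, W); got {frames.shape}")
        if tabular.ndim != 2 or len(tabular) != len(frames):
            raise ValueError("tabular must be (n, d) aligned with frames")
        if not (np.isfinite(frames).all() and np.isfinite(tabular).all()):
            raise ValueError("non-finite values in input")
        if not fit:
            if tabular.shape[1] != self.n_features_in_:
                raise ValueError(
                    f"tabular width {tabular.shape[1]} != fitted {self.n_features_in_}")

    # ------------------------------------------------------------ public API
    def fit(self, X, y):
        frames, tabular = self._unpack(X)
        self._validate(frames, tabular, fit=True)
        y = np.asarray(y).astype(int)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("binary classifier: y must contain exactly two classes")
        vit, lstm, fusion, tcfg = self._configs()
        if frames.shape[3] != vit.image_size:
            raise ValueError(
                f"frame size {frames.shape[3]} != configured image_size {vit.image_size}")
        self.n_features_in_ = tabular.shape[1]
        self.model_ = MultimodalNet(vit, lstm, fusion, tabular.shape[1], seed=self.seed)
        idx = np.arange(len(y))
        if self.validation_fraction > 0 and len(y) >= 10:
            plan = subject_split(idx, y, fractions=(1 - self.validation_fraction,
                                                    self.validation_fraction, 0.0),
                                 seed=tcfg.seed)
            train_idx, val_idx = np.array(plan.train), np.array(plan.val)
        else:
            train_idx, val_idx = idx, np.array([], dtype=int)

        from .dataset import SequenceDataset
        data = SequenceDataset(frames=frames, tabular=tabular, y=y,
                               subject_index=np.arange(len(y)),
                               subject_ids=np.arange(len(y)).astype(str),
                               subject_labels=y, feature_columns=[])
        self.history_ = train(self.model_, data, train_idx, val_idx, tcfg)
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise NotFittedError("fit the classifier before predicting")

    def predict_proba(self, X):
        self._check_fitted()
        frames, tabular = self._unpack(X)
        self._validate(frames, tabular, fit=False)
        return self.model_.predict_proba(frames, tabular)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]

    def decision_function(self, X):
        proba = self.predict_proba(X)
        return proba[:, 1] - proba[:, 0]
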