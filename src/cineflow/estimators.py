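"""Estimator-style interfaces to the two trainable models.

Both classes follow the scikit-learn protocol: ``get_params``/``set_params``,
``fit`` returning ``self``, fitted state in trailing-underscore attributes,
and input validation at the public boundary.  They are thin wrappers over
:mod:`cineflow.training`; the functional interface remains available for the
pipeline and CLI.
"""

from __future__ import annotations

import numpy as np

from .containers import CineSequence
from .mopnet import (DEFAULT_PROFILE, TINY_PROFILE, FlowTable, Mopnet,
                     MopnetConfig, full_cycle_inference)
from .training import TrainConfig, run_training_stage
from .unet import TINY_PROFILE as UNET_TINY
from .unet import UNet, UnetConfig, segment


class _ParamsMixin:
    _param_names: tuple[str, ...] = ()

    def get_params(self, deep: bool = True) -> dict:
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self


class MopnetRegistrar(_ParamsMixin):
    """Multi-frame cine registration as a fit/predict estimator.

    fit(X): self-supervised training on a list of (T, H, W) magnitude
    sequences (no flow supervision is used).  predict(X): full-cycle flow
    table for one sequence.

    Parameters
    ----------
    profile : 'tiny' or 'default' network size.
    steps : optimization steps (self-supervised photometric + smoothness).
    learning_rate, batch_size, weight_decay : optimizer settings.
    seed : controls weight init and window sampling.
    """

    _param_names = ("profile", "steps", "learning_rate", "batch_size",
                    "weight_decay", "seed")

    def __init__(self, profile: str = "tiny", steps: int = 300,
                 learning_rate: float = 1e-3, batch_size: int = 4,
                 weight_decay: float = 5e-4, seed: int = 0):
        self.profile = profile
        self.steps = steps
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.seed = seed

    def _make_model(self) -> Mopnet:
        prof = {"tiny": TINY_PROFILE, "default": DEFAULT_PROFILE}[self.profile]
        return Mopnet(MopnetConfig(seed=self.seed, **prof))

    @staticmethod
    def _sequences(X) -> list[np.ndarray]:
        seqs = []
        for s in X:
            arr = s.magnitude() if isinstance(s, CineSequence) else np.asarray(s)
            if arr.ndim != 3 or arr.shape[0] < 5:
                raise ValueError("each sequence must be (T>=5, H, W)")
            if not np.isfinite(arr).all():
                raise ValueError("non-finite values in input sequence")
            seqs.append(arr.astype(np.float32))
        return seqs

    def fit(self, X, y=None) -> "MopnetRegistrar":
        seqs = self._sequences(X)
        model = self._make_model()
        cfg = TrainConfig(batch_size=self.batch_size,
                          learning_rate=self.learning_rate,
                          weight_decay=self.weight_decay,
                          steps=self.steps, seed=self.seed)
        result = run_training_stage("registration", {"sequences": seqs}, cfg,
                                    models={"mopnet": model})
        self.model_ = model
        self.loss_log_ = result.log
        self.n_sequences_ = len(seqs)
        return self

    def predict(self, X) -> list[FlowTable]:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the registrar before predicting")
        from .unet import normalize_image

        tables = []
        for seq in self._sequences(X):
            norm = np.stack([normalize_image(f) for f in seq])
            tables.append(full_cycle_inference(norm, self.model_))
        return tables


class UNetSegmenter(_ParamsMixin):
    """Four-class cine segmentation as a fit/predict estimator.

    fit(X, y): images (N, H, W) with integer label maps (N, H, W), trained
    with the soft multi-class Dice loss.  predict(X): per-frame label maps.
    """

    _param_names = ("profile", "steps", "learning_rate", "batch_size",
                    "weight_decay", "seed")

    def __init__(self, profile: str = "tiny", steps: int = 200,
                 learning_rate: float = 1e-3, batch_size: int = 4,
                 weight_decay: float = 5e-4, seed: int = 0):
        self.profile = profile
        self.steps = steps
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.weight_decay = weight_decay
        self.seed = seed

    def _make_model(self) -> UNet:
        prof = {"tiny": UNET_TINY, "default": {}}[self.profile]
        return UNet(UnetConfig(seed=self.seed, **prof))

    def fit(self, X, y) -> "UNetSegmenter":
        from .training import _onehot

        images = np.asarray(X, dtype=np.float32)
        labels = np.asarray(y)
        if images.ndim != 3 or labels.shape != images.shape:
            raise ValueError("X must be (N, H, W) with matching labels")
        model = self._make_model()
        onehot = np.stack([_onehot(l) for l in labels])
        cfg = TrainConfig(batch_size=self.batch_size,
                          learning_rate=self.learning_rate,
                          weight_decay=self.weight_decay,
                          steps=self.steps, seed=self.seed)
        result = run_training_stage("segmentation",
                                    {"images": images, "onehot": onehot}, cfg,
                                    models={"unet": model})
        self.model_ = model
        self.loss_log_ = result.log
        self.classes_ = np.arange(4)
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the segmenter before predicting")
        masks = segment(np.asarray(X, dtype=np.float32), self.model_)
        return np.stack([m.labels for m in masks])

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("fit the segmenter before predicting")
        masks = segment(np.asarray(X, dtype=np.float32), self.model_)
        return np.stack([m.probs for m in masks])
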