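"""Deep-feature matrices: FV1 (residual reference net) and FV2 (six-branch net).

A :class:`FeatureMatrix` is the package's sample x feature container: values,
per-row class labels, a provenance tag, and feature names.  It round-trips
through comma-delimited text with a header row and a trailing label column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import forward, resize_batch
from .resnet import ResNet50Features

__all__ = ["FeatureMatrix", "extract_6bnet_features", "extract_reference_features"]

_SOURCES = {"FV1_reference", "FV2_6bnet", "selected", "fused", "fused_selected"}


@dataclass
class FeatureMatrix:
    values: np.ndarray          # n x d reals
    labels: np.ndarray          # class index per row
    source: str
    feature_names: list = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2 or self.values.shape[1] == 0:
            raise ValueError("feature matrix must be n x d with d > 0")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("one label per row required")
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite entries")
        if self.source not in _SOURCES:
            raise ValueError(f"unknown source tag {self.source!r}")
        if self.feature_names is None:
            self.feature_names = [f"f{j}" for j in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("one name per feature column required")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def d(self) -> int:
        return self.values.shape[1]

    def select(self, mask, source: str = "selected") -> "FeatureMatrix":
        mask = np.asarray(mask, dtype=bool)
        return FeatureMatrix(
            values=self.values[:, mask], labels=self.labels, source=source,
            feature_names=[n for n, m in zip(self.feature_names, mask) if m],
            meta=dict(self.meta, parent=self.source))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, source: str = "selected") -> "FeatureMatrix":
        df = pd.read_csv(path)
        labels = df.pop("label").to_numpy()
        return cls(values=df.to_numpy(dtype=float), labels=labels,
                   source=source, feature_names=list(df.columns))


def extract_6bnet_features(graph, params, images, layer_name: str = "fc1",
                           labels=None, batch: int = 32) -> FeatureMatrix:
    """Tap activations of ``layer_name`` for every image (row order preserved).

    The default tap is the 4096-unit fully connected layer, giving the FV2
    deep-feature vector (d = 4096 at full width).
    """
    graph.node(layer_name)  # raises KeyError for unknown layers
    if labels is None:
        labels = np.asarray(images.labels)
        images = images.images
    side = graph.input_shape[0]
    x = resize_batch(images, side)
    rows = []
    for s in range(0, x.shape[0], batch):
        out, _, _ = forward(graph, params, x[s:s + batch], mode="infer",
                            capture=(), upto=layer_name)
        rows.append(out.reshape(out.shape[0], -1))
    values = np.concatenate(rows, axis=0)
    return FeatureMatrix(values=values, labels=np.asarray(labels),
                         source="FV2_6bnet",
                         meta={"layer": layer_name, "input_side": side})


def extract_reference_features(images, backbone_weights=None, labels=None,
                               input_side: int = 224,
                               seed: int = 0) -> FeatureMatrix:
    """fc1000 activations of the 50-layer residual network (d = 1000).

    With ``backbone_weights=None`` the network uses seeded random weights:
    deterministic, class-agnostic projections for offline testing.
    """
    if labels is None:
        labels = np.asarray(images.labels)
        images = images.images
    net = ResNet50Features(input_side=input_side, weights=backbone_weights,
                           random_state=seed).fit()
    values = net.transform(images)
    return FeatureMatrix(values=values, labels=np.asarray(labels),
                         source="FV1_reference",
                         meta={"layer": "fc1000", "input_side": input_side,
                               "seed": seed})
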