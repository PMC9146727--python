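"""A standard 50-layer residual network as a deep-feature extractor.

Only the forward pass is needed: features are tapped at the final 1000-way
fully connected layer ("fc1000", d = 1000).  Pretrained weights can be
plugged in as a parameter dict; when none are supplied the network runs with
seeded He-initialised random weights, which still yields deterministic,
image-dependent projections suitable for exercising the selection and fusion
stages offline.

Architecture: 7x7/2 conv (64) -> 3x3/2 max pool -> bottleneck stages of
[3, 4, 6, 3] blocks (base widths 64/128/256/512, expansion 4, stride 2 at
each stage entry after the first) -> global average pool -> fc 1000.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .layers import conv2d, maxpool, relu
from .network import resize_batch

__all__ = ["ResNet50Features", "resnet50_init", "resnet50_forward"]

_STAGES = ((64, 3, 1), (128, 4, 2), (256, 6, 2), (512, 3, 2))
_EXPANSION = 4


def _conv_spec(name, kh, kw, cin, cout, stride):
    return dict(name=name, kh=kh, kw=kw, cin=cin, cout=cout, stride=stride)


def _specs():
    specs = [_conv_spec("conv1", 7, 7, 3, 64, 2)]
    cin = 64
    for s, (base, blocks, stride0) in enumerate(_STAGES, start=1):
        cout = base * _EXPANSION
        for b in range(blocks):
            stride = stride0 if b == 0 else 1
            pre = f"stage{s}.block{b}"
            specs += [
                _conv_spec(f"{pre}.conv_a", 1, 1, cin, base, stride),
                _conv_spec(f"{pre}.conv_b", 3, 3, base, base, 1),
                _conv_spec(f"{pre}.conv_c", 1, 1, base, cout, 1),
            ]
            if b == 0:
                specs.append(_conv_spec(f"{pre}.shortcut", 1, 1, cin, cout, stride))
            cin = cout
    return specs


def resnet50_init(seed: int = 0) -> dict:
    """Seeded He-initialised weights for every conv plus the fc1000 head."""
    rng = np.random.default_rng(seed)
    params: dict[str, dict] = {}
    for sp in _specs():
        fan_in = sp["kh"] * sp["kw"] * sp["cin"]
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (sp["kh"], sp["kw"], sp["cin"], sp["cout"]))
        params[sp["name"]] = {"w": w.astype(np.float32),
                              "b": np.zeros(sp["cout"], dtype=np.float32),
                              "stride": sp["stride"]}
    w = rng.normal(0.0, np.sqrt(2.0 / 2048), (2048, 1000))
    params["fc1000"] = {"w": w.astype(np.float32),
                        "b": np.zeros(1000, dtype=np.float32)}
    return params


def _conv(x, p):
    return conv2d(x, p["w"], p["b"], stride=(p["stride"], p["stride"]),
                  padding="same")


def resnet50_forward(x: np.ndarray, params: dict) -> np.ndarray:
    """Batch NHWC floats -> (N, 1000) fc1000 activations."""
    y = relu(_conv(x, params["conv1"]))
    y = maxpool(y, 3, 2, padding="same")
    for s, (base, blocks, _) in enumerate(_STAGES, start=1):
        for b in range(blocks):
            pre = f"stage{s}.block{b}"
            r = relu(_conv(y, params[f"{pre}.conv_a"]))
            r = relu(_conv(r, params[f"{pre}.conv_b"]))
            r = _conv(r, params[f"{pre}.conv_c"])
            sc = _conv(y, params[f"{pre}.shortcut"]) if b == 0 else y
            y = relu(r + sc)
    pooled = y.mean(axis=(1, 2))
    return pooled @ params["fc1000"]["w"] + params["fc1000"]["b"]


class ResNet50Features(BaseEstimator, TransformerMixin):
    """Deep features from the fc1000 layer of a 50-layer residual network.

    Parameters
    ----------
    input_side : images are bilinear-resized to this square side (224 is the
        network's native input; smaller sides trade fidelity for speed).
    weights : optional pretrained parameter dict (see :func:`resnet50_init`
        for the layout); when None, seeded random weights are used.
    random_state : seed for the random-weight mode.
    """

    def __init__(self, input_side: int = 224, weights: dict | None = None,
                 random_state: int = 0):
        self.input_side = input_side
        self.weights = weights
        self.random_state = random_state

    def fit(self, images=None, labels=None):
        self.params_ = (self.weights if self.weights is not None
                        else resnet50_init(self.random_state))
        return self

    def transform(self, images, batch: int = 16) -> np.ndarray:
        if not hasattr(self, "params_"):
            self.fit()
        x = resize_batch(images, self.input_side)
        return np.concatenate(
            [resnet50_forward(x[s:s + batch], self.params_)
             for s in range(0, x.shape[0], batch)], axis=0)
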