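"""Forward/backward execution and desk-scale SGD training of a layer graph.

Parameters live in a plain ``{node name: {...arrays}}`` dict so a trained
network is a (graph, params) pair; :func:`save_network` stores the arrays in
one ``.npz`` archive with a JSON sidecar describing the graph.
"""

from __future__ import annotations

import json
from dataclasses import asdict

import numpy as np
from PIL import Image
from sklearn.base import BaseEstimator

from . import layers as L
from .graph import LayerGraph, LayerSpec, build_6bnet

__all__ = [
    "init_network",
    "forward",
    "train_backbone",
    "SixBranchNet",
    "save_network",
    "load_network",
    "resize_batch",
]


def _pad_out(size, k, stride, padding, dilation=1):
    k_eff = (k - 1) * dilation + 1
    if padding == "same":
        return -(-size // stride)
    return (size - k_eff) // stride + 1


def infer_shapes(graph: LayerGraph) -> dict[str, tuple]:
    """Output shape (H, W, C) or (width,) of every node."""
    shapes: dict[str, tuple] = {}
    for name in graph.topological_order():
        spec = graph.node(name)
        preds = [s for s, d in graph.edges if d == name]
        if spec.kind == "input":
            shapes[name] = graph.input_shape
            continue
        ins = [shapes[p] for p in preds]
        s = ins[0]
        if spec.kind in ("conv", "groupedconv"):
            h = _pad_out(s[0], spec.kernel_h, spec.stride_h, spec.padding, spec.dilation)
            w = _pad_out(s[1], spec.kernel_w, spec.stride_w, spec.padding, spec.dilation)
            shapes[name] = (h, w, spec.n_filters)
        elif spec.kind == "maxpool":
            h = _pad_out(s[0], spec.kernel_h, spec.stride_h, spec.padding)
            w = _pad_out(s[1], spec.kernel_w, spec.stride_w, spec.padding)
            shapes[name] = (h, w, s[2])
        elif spec.kind == "globalmaxpool":
            shapes[name] = (1, 1, s[2])
        elif spec.kind == "depthconcat":
            if any(i[:2] != s[:2] for i in ins):
                raise ValueError("depth concat inputs must share spatial size")
            shapes[name] = (s[0], s[1], sum(i[2] for i in ins))
        elif spec.kind == "fc":
            shapes[name] = (spec.width,)
        else:  # relu, batchnorm, dropout, softmax, classification
            shapes[name] = s
    return shapes


def init_network(graph: LayerGraph, seed: int = 0) -> dict:
    """He fan-in initialisation of all learnable parameters, seeded."""
    rng = np.random.default_rng(seed)
    shapes = infer_shapes(graph)
    softmax_feeders = {p for n in graph.nodes if n.kind == "softmax"
                       for p in graph.predecessors(n.name)}
    params: dict[str, dict] = {}
    for name in graph.topological_order():
        spec = graph.node(name)
        preds = graph.predecessors(name)
        if spec.kind in ("conv", "groupedconv"):
            cin = shapes[preds[0]][2]
            cin_g = cin // spec.groups
            fan_in = spec.kernel_h * spec.kernel_w * cin_g
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           (spec.kernel_h, spec.kernel_w, cin_g, spec.n_filters))
            params[name] = {"w": w.astype(np.float32),
                            "b": np.zeros(spec.n_filters, dtype=np.float32)}
        elif spec.kind == "fc":
            fan_in = int(np.prod(shapes[preds[0]]))
            # class-score head starts near zero so initial losses are tame;
            # hidden fc layers use Xavier scaling
            std = 0.01 if name in softmax_feeders else np.sqrt(
                1.0 / (fan_in + spec.width))
            w = rng.normal(0.0, std, (fan_in, spec.width))
            params[name] = {"w": w.astype(np.float32),
                            "b": np.zeros(spec.width, dtype=np.float32)}
        elif spec.kind == "batchnorm":
            c = shapes[preds[0]][-1]
            params[name] = {"bn": L.BatchNormParams(np.ones(c), np.zeros(c))}
    return params


def forward(graph: LayerGraph, params: dict, x: np.ndarray, mode: str = "infer",
            rng=None, capture=None, upto: str | None = None):
    """Run the graph on a batch ``x`` (N,H,W,3).

    Returns ``(output, activations, caches)``; ``activations`` holds only the
    nodes named in ``capture`` (or all nodes if ``capture`` is None and
    caches are requested).  ``upto`` stops after the named node and returns
    its activation as the output.
    """
    acts: dict[str, np.ndarray] = {}
    caches: dict[str, object] = {}
    captured: dict[str, np.ndarray] = {}
    order = graph.topological_order()
    consumers = {n: len(graph.successors(n)) for n in order}
    out = None
    train = mode == "train"
    for name in order:
        spec = graph.node(name)
        preds = graph.predecessors(name)
        if spec.kind == "input":
            y = np.asarray(x, dtype=np.float32)
        elif spec.kind in ("conv", "groupedconv"):
            p = params[name]
            y, c = L.conv2d_forward(acts[preds[0]], p["w"], p["b"],
                                    stride=(spec.stride_h, spec.stride_w),
                                    padding=spec.padding,
                                    dilation=(spec.dilation, spec.dilation),
                                    groups=spec.groups)
            caches[name] = c
        elif spec.kind == "relu":
            y, c = L.relu_forward(acts[preds[0]])
            caches[name] = c
        elif spec.kind == "maxpool":
            y, c = L.maxpool_forward(acts[preds[0]],
                                     (spec.kernel_h, spec.kernel_w),
                                     (spec.stride_h, spec.stride_w),
                                     spec.padding)
            caches[name] = c
        elif spec.kind == "globalmaxpool":
            y, c = L.global_maxpool_forward(acts[preds[0]])
            caches[name] = c
        elif spec.kind == "depthconcat":
            parts = [acts[p] for p in preds]
            y = np.concatenate(parts, axis=-1)
            caches[name] = [p.shape[-1] for p in parts]
        elif spec.kind == "batchnorm":
            y, c = L.batchnorm_forward(acts[preds[0]], params[name]["bn"],
                                       "train" if train else "infer")
            caches[name] = c
        elif spec.kind == "dropout":
            y, c = L.dropout_forward(acts[preds[0]], spec.rate, rng, train)
            caches[name] = c
        elif spec.kind == "fc":
            p = params[name]
            y, c = L.fc_forward(acts[preds[0]], p["w"], p["b"])
            caches[name] = c
        elif spec.kind == "softmax":
            y = L.softmax(acts[preds[0]])
        elif spec.kind == "classification":
            y = acts[preds[0]]
        acts[name] = y
        if capture and name in capture:
            captured[name] = y
        out = y
        if name == upto:
            break
        # free activations no longer needed when not training
        if not train and capture is not None:
            for p in preds:
                consumers[p] -= 1
                if consumers[p] == 0 and p not in (capture or ()):
                    acts.pop(p, None)
    return out, (captured if capture is not None else acts), caches


def backward(graph: LayerGraph, params: dict, acts: dict, caches: dict,
             d_logits: np.ndarray, logits_node: str):
    """Backpropagate from ``logits_node``; returns grads per learnable node."""
    grads_out: dict[str, np.ndarray] = {logits_node: d_logits}
    pgrads: dict[str, dict] = {}
    order = graph.topological_order()
    for name in reversed(order[:order.index(logits_node) + 1]):
        if name not in grads_out:
            continue
        dy = grads_out.pop(name)
        spec = graph.node(name)
        preds = graph.predecessors(name)

        def send(node, g):
            if node in grads_out:
                grads_out[node] = grads_out[node] + g
            else:
                grads_out[node] = g

        if spec.kind == "input":
            continue
        if spec.kind in ("conv", "groupedconv"):
            dx, dw, db = L.conv2d_backward(dy, caches[name])
            pgrads[name] = {"w": dw, "b": db}
            send(preds[0], dx)
        elif spec.kind == "relu":
            send(preds[0], L.relu_backward(dy, caches[name]))
        elif spec.kind == "maxpool":
            send(preds[0], L.maxpool_backward(dy, caches[name]))
        elif spec.kind == "globalmaxpool":
            send(preds[0], L.global_maxpool_backward(dy, caches[name]))
        elif spec.kind == "depthconcat":
            sizes = caches[name]
            ofs = 0
            for p, c in zip(preds, sizes):
                send(p, dy[..., ofs:ofs + c])
                ofs += c
        elif spec.kind == "batchnorm":
            dx, dg, dbeta = L.batchnorm_backward(dy, caches[name])
            pgrads[name] = {"gamma": dg, "beta": dbeta}
            send(preds[0], dx)
        elif spec.kind == "dropout":
            send(preds[0], L.dropout_backward(dy, caches[name]))
        elif spec.kind == "fc":
            dx, dw, db = L.fc_backward(dy, caches[name])
            pgrads[name] = {"w": dw, "b": db}
            send(preds[0], dx)
        else:
            send(preds[0], dy)
    return pgrads


def _logits_node(graph: LayerGraph) -> str:
    """The node feeding the softmax (class scores)."""
    soft = next(n.name for n in graph.nodes if n.kind == "softmax")
    return graph.predecessors(soft)[0]


def _clip_grads(pgrads: dict, max_norm: float) -> dict:
    total = np.sqrt(sum(float((g ** 2).sum())
                        for gs in pgrads.values() for g in gs.values()))
    if total > max_norm:
        scale = max_norm / total
        for gs in pgrads.values():
            for k in gs:
                gs[k] = gs[k] * scale
    return pgrads


def train_backbone(graph: LayerGraph, images: np.ndarray, labels: np.ndarray,
                   epochs: int, lr: float = 0.01, batch_size: int = 16,
                   seed: int = 0, params: dict | None = None,
                   clip_norm: float = 5.0):
    """Cross-entropy SGD training; returns ``(params, loss_trace)``.

    ``images`` must already be resized/normalised floats of the graph's input
    shape.  Gradients are clipped to a global norm of ``clip_norm`` per batch
    (the deep unnormalised head otherwise blows up early).  ``epochs == 0``
    returns freshly initialised weights and an empty trace.  Fully
    deterministic for a fixed seed.
    """
    images = np.asarray(images, dtype=np.float32)
    labels = np.asarray(labels)
    if images.shape[0] == 0:
        raise ValueError("cannot train on an empty image set")
    if labels.max() >= graph.num_classes:
        raise ValueError("labels exceed the graph's class count")
    if params is None:
        params = init_network(graph, seed)
    rng = np.random.default_rng(seed + 1)
    logits_node = _logits_node(graph)
    trace = []
    n = images.shape[0]
    for _ in range(int(epochs)):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            if idx.size < 2:
                continue  # batch norm needs >= 2 samples
            xb, yb = images[idx], labels[idx]
            logits, acts, caches = forward(graph, params, xb, mode="train",
                                           rng=rng, upto=logits_node)
            loss, d_logits = L.cross_entropy(logits, yb)
            losses.append(loss)
            pgrads = backward(graph, params, acts, caches, d_logits, logits_node)
            pgrads = _clip_grads(pgrads, clip_norm)
            for name, gs in pgrads.items():
                p = params[name]
                if "bn" in p:
                    p["bn"].gamma -= lr * gs["gamma"]
                    p["bn"].beta -= lr * gs["beta"]
                else:
                    p["w"] -= (lr * gs["w"]).astype(p["w"].dtype)
                    p["b"] -= (lr * gs["b"]).astype(p["b"].dtype)
        trace.append(float(np.mean(losses)))
    return params, trace


# ---------------------------------------------------------------------------
# image preparation


def resize_batch(images, side: int) -> np.ndarray:
    """Bilinear-resize 8-bit RGB images to (N, side, side, 3) in [-0.5, 0.5]."""
    out = np.empty((len(images), side, side, 3), dtype=np.float32)
    for i, img in enumerate(images):
        arr = np.asarray(img)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("images must be HxWx3 RGB")
        if arr.shape[0] != side or arr.shape[1] != side:
            arr = np.asarray(
                Image.fromarray(arr.astype(np.uint8)).resize(
                    (side, side), Image.BILINEAR))
        out[i] = arr.astype(np.float32) / 255.0 - 0.5
    return out


# ---------------------------------------------------------------------------
# estimator


class SixBranchNet(BaseEstimator):
    """The six-branch CNN as a fit/transform estimator.

    ``fit`` trains the network on labelled RGB images with SGD;
    ``transform`` returns deep features from a named layer (default the
    4096-unit fully connected layer, the network's feature-vector tap).

    Parameters
    ----------
    input_side : input image side in pixels (canonical network: 227).
    width_scale : proportional thinning of all channel widths; 1.0 is the
        canonical architecture, smaller values keep CPU training tractable.
    epochs, lr, batch_size : SGD schedule.
    random_state : seed for weight init, shuffling and dropout.
    """

    def __init__(self, input_side: int = 227, width_scale: float = 1.0,
                 epochs: int = 5, lr: float = 0.01, batch_size: int = 16,
                 random_state: int = 0):
        self.input_side = input_side
        self.width_scale = width_scale
        self.epochs = epochs
        self.lr = lr
        self.batch_size = batch_size
        self.random_state = random_state

    def _labels_images(self, images, labels):
        if labels is None:  # LabeledImageSet duck-typing
            labels = np.asarray(images.labels)
            images = images.images
        return images, np.asarray(labels)

    def fit(self, images, labels=None):
        images, labels = self._labels_images(images, labels)
        self.classes_ = np.unique(labels)
        self.graph_ = build_6bnet(int(self.classes_.size),
                                  input_side=self.input_side,
                                  width_scale=self.width_scale)
        x = resize_batch(images, self.input_side)
        y = np.searchsorted(self.classes_, labels)
        self.params_, self.loss_trace_ = train_backbone(
            self.graph_, x, y, epochs=self.epochs, lr=self.lr,
            batch_size=self.batch_size, seed=self.random_state)
        return self

    def _forward(self, images, upto, batch=32):
        x = resize_batch(images, self.input_side)
        outs = []
        for s in range(0, x.shape[0], batch):
            out, _, _ = forward(self.graph_, self.params_, x[s:s + batch],
                                mode="infer", capture=(), upto=upto)
            outs.append(out.reshape(out.shape[0], -1))
        return np.concatenate(outs, axis=0)

    def transform(self, images, layer: str = "fc1"):
        self.graph_.node(layer)  # KeyError for unknown layers
        return self._forward(images, upto=layer)

    def predict_proba(self, images):
        return self._forward(images, upto="softmax")

    def predict(self, images):
        return self.classes_[self.predict_proba(images).argmax(axis=1)]


# ---------------------------------------------------------------------------
# serialization


def save_network(path, graph: LayerGraph, params: dict) -> None:
    """Write weights to ``<path>.npz`` with a JSON graph sidecar ``<path>.json``."""
    arrays = {}
    for name, p in params.items():
        if "bn" in p:
            bn = p["bn"]
            for k in ("gamma", "beta", "running_mean", "running_var"):
                arrays[f"{name}.bn.{k}"] = np.asarray(getattr(bn, k))
        else:
            arrays[f"{name}.w"] = p["w"]
            arrays[f"{name}.b"] = p["b"]
    np.savez_compressed(f"{path}.npz", **arrays)
    side = {
        "num_classes": graph.num_classes,
        "input_shape": list(graph.input_shape),
        "nodes": [asdict(n) for n in graph.nodes],
        "edges": [list(e) for e in graph.edges],
    }
    with open(f"{path}.json", "w") as fh:
        json.dump(side, fh, indent=1)


def load_network(path):
    with open(f"{path}.json") as fh:
        side = json.load(fh)
    graph = LayerGraph(
        nodes=[LayerSpec(**n) for n in side["nodes"]],
        edges=[tuple(e) for e in side["edges"]],
        num_classes=side["num_classes"],
        input_shape=tuple(side["input_shape"]),
    )
    data = np.load(f"{path}.npz")
    params: dict[str, dict] = {}
    for key in data.files:
        name, *rest = key.split(".")
        if rest[0] == "bn":
            entry = params.setdefault(name, {"bn": None})
            if entry["bn"] is None:
                entry["bn"] = L.BatchNormParams(np.ones(1), np.zeros(1))
            setattr(entry["bn"], rest[1], data[key])
        else:
            params.setdefault(name, {})[rest[0]] = data[key]
    return graph, params
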