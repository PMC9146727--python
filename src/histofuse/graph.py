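"""The six-branch network architecture as a typed layer graph.

The canonical network takes 227x227x3 RGB input and runs: a 9x9 stride-2
convolution with 128 kernels, ReLU, 5x5 stride-2 max pooling, then a block of
six concurrent branches (conv -> ReLU -> batch norm, kernel sizes 13x13 down
to 3x3, 96 filters each, stride 2) merged by depth concatenation, followed by
ReLU, global max pooling, a 1x1 grouped convolution to 9216 channels, ReLU,
a 5x5 stride-1 max pool, dropout, a 4096-unit fully connected layer, ReLU,
dropout, the class-score layer, softmax and the classification output:
35 layer nodes joined by 39 directed connections.

``input_side`` and ``width_scale`` shrink the spatial and channel extents for
desk-scale CPU training without changing the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LayerSpec",
    "LayerGraph",
    "build_6bnet",
    "count_layers",
    "count_connections",
    "BRANCH_KERNEL_SIZES",
]

#: kernel side lengths of the six concurrent branches (largest to smallest
#: receptive field)
BRANCH_KERNEL_SIZES = (13, 11, 9, 7, 5, 3)

_KINDS = {
    "input", "conv", "relu", "batchnorm", "maxpool", "globalmaxpool",
    "groupedconv", "depthconcat", "dropout", "fc", "softmax", "classification",
}


@dataclass(frozen=True)
class LayerSpec:
    """One node of the layer graph."""

    kind: str
    name: str
    kernel_h: int | None = None
    kernel_w: int | None = None
    n_filters: int | None = None
    stride_h: int = 1
    stride_w: int = 1
    padding: str = "same"
    dilation: int = 1
    groups: int = 1
    rate: float | None = None
    width: int | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        if self.kind in ("conv", "groupedconv"):
            for k in (self.kernel_h, self.kernel_w):
                if k is None or k <= 0 or k % 2 == 0:
                    raise ValueError("conv kernels must be positive and odd")
        if self.kind == "dropout" and not (0 < self.rate < 1):
            raise ValueError("dropout rate must lie in (0, 1)")
        if self.kind == "fc" and (self.width is None or self.width <= 0):
            raise ValueError("fc width must be positive")


@dataclass
class LayerGraph:
    """A directed acyclic graph of :class:`LayerSpec` nodes."""

    nodes: list[LayerSpec]
    edges: list[tuple[str, str]]
    num_classes: int
    input_shape: tuple[int, int, int] = (227, 227, 3)

    def __post_init__(self):
        self.validate()

    # -- structure queries ---------------------------------------------------

    def node(self, name: str) -> LayerSpec:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(f"no layer named {name!r}")

    def successors(self, name: str) -> list[str]:
        return [d for s, d in self.edges if s == name]

    def predecessors(self, name: str) -> list[str]:
        return [s for s, d in self.edges if d == name]

    def topological_order(self) -> list[str]:
        indeg = {n.name: 0 for n in self.nodes}
        for _, d in self.edges:
            indeg[d] += 1
        queue = sorted(n for n, k in indeg.items() if k == 0)
        order = []
        while queue:
            n = queue.pop(0)
            order.append(n)
            for d in self.successors(n):
                indeg[d] -= 1
                if indeg[d] == 0:
                    queue.append(d)
        if len(order) != len(self.nodes):
            raise ValueError("layer graph contains a cycle")
        return order

    def validate(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")
        known = set(names)
        for s, d in self.edges:
            if s not in known or d not in known:
                raise ValueError(f"edge ({s!r}, {d!r}) references unknown node")
        kinds = [n.kind for n in self.nodes]
        if kinds.count("input") != 1 or kinds.count("classification") != 1:
            raise ValueError("graph needs exactly one input and one classification node")
        self.topological_order()  # raises on cycles
        # reachability from the input node
        start = next(n.name for n in self.nodes if n.kind == "input")
        seen, stack = {start}, [start]
        while stack:
            for d in self.successors(stack.pop()):
                if d not in seen:
                    seen.add(d)
                    stack.append(d)
        if seen != known:
            raise ValueError("every node must be reachable from the input")

    def branch_paths(self) -> list[list[str]]:
        """Parallel paths between the fan-out node and the merge node."""
        merge = [n.name for n in self.nodes if n.kind == "depthconcat"]
        if not merge:
            return []
        merge = merge[0]
        paths = []
        heads = sorted({s for s, _ in self.edges if len(self.successors(s)) > 1})
        for head in heads:
            for nxt in self.successors(head):
                path, cur = [], nxt
                while cur != merge:
                    path.append(cur)
                    nxts = self.successors(cur)
                    if len(nxts) != 1:
                        path = None
                        break
                    cur = nxts[0]
                if path:
                    paths.append(path)
        return paths


def count_layers(graph: LayerGraph) -> int:
    """Number of layer nodes (every node counts once)."""
    return len(graph.nodes)


def count_connections(graph: LayerGraph) -> int:
    """Number of directed edges."""
    return len(graph.edges)


def _scaled(value: int, width_scale: float) -> int:
    return max(1, int(round(value * width_scale)))


def build_6bnet(num_classes: int, input_side: int = 227,
                width_scale: float = 1.0) -> LayerGraph:
    """Build the canonical six-branch layer graph for ``num_classes``.

    Defaults give the full-size architecture; ``width_scale`` < 1 thins every
    channel dimension proportionally (topology, kernel sizes and strides are
    untouched) so the NumPy trainer stays tractable on one CPU.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if input_side < 32:
        raise ValueError("input side must be >= 32")
    ws = float(width_scale)

    nodes: list[LayerSpec] = []
    edges: list[tuple[str, str]] = []

    def add(spec: LayerSpec, after: str | list[str] | None):
        nodes.append(spec)
        if after is not None:
            for a in ([after] if isinstance(after, str) else after):
                edges.append((a, spec.name))
        return spec.name

    prev = add(LayerSpec("input", "input"), None)
    prev = add(LayerSpec("conv", "conv1", kernel_h=9, kernel_w=9,
                         n_filters=_scaled(128, ws), stride_h=2, stride_w=2,
                         padding="same", dilation=1), prev)
    prev = add(LayerSpec("relu", "relu1"), prev)
    stem = add(LayerSpec("maxpool", "pool1", kernel_h=5, kernel_w=5,
                         stride_h=2, stride_w=2, padding="same"), prev)

    branch_tails = []
    for i, k in enumerate(BRANCH_KERNEL_SIZES, start=1):
        c = add(LayerSpec("conv", f"branch{i}_conv", kernel_h=k, kernel_w=k,
                          n_filters=_scaled(96, ws), stride_h=2, stride_w=2,
                          padding="same", dilation=1), stem)
        r = add(LayerSpec("relu", f"branch{i}_relu"), c)
        b = add(LayerSpec("batchnorm", f"branch{i}_bn"), r)
        branch_tails.append(b)

    prev = add(LayerSpec("depthconcat", "concat"), branch_tails)
    prev = add(LayerSpec("relu", "relu2"), prev)
    prev = add(LayerSpec("globalmaxpool", "gmp"), prev)
    prev = add(LayerSpec("groupedconv", "gconv", kernel_h=1, kernel_w=1,
                         n_filters=_scaled(9216, ws), stride_h=1, stride_w=1,
                         padding="same", groups=1), prev)
    prev = add(LayerSpec("relu", "relu3"), prev)
    prev = add(LayerSpec("maxpool", "pool2", kernel_h=5, kernel_w=5,
                         stride_h=1, stride_w=1, padding="same"), prev)
    prev = add(LayerSpec("dropout", "drop1", rate=0.5), prev)
    prev = add(LayerSpec("fc", "fc1", width=_scaled(4096, ws)), prev)
    prev = add(LayerSpec("relu", "relu4"), prev)
    prev = add(LayerSpec("dropout", "drop2", rate=0.5), prev)
    prev = add(LayerSpec("fc", "fc2", width=num_classes), prev)
    prev = add(LayerSpec("softmax", "softmax"), prev)
    add(LayerSpec("classification", "output"), prev)

    return LayerGraph(nodes=nodes, edges=edges, num_classes=num_classes,
                      input_shape=(input_side, input_side, 3))
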