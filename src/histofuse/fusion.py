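"""Entropy-based feature scoring, serial (horizontal) fusion, final selection.

Each feature's value distribution is discretised into equal-width bins over
its observed range; the Shannon entropy (in bits) of the bin probabilities
scores the feature.  Serial fusion is column-wise concatenation of two
feature matrices over the same samples; the entropy-based selector then keeps
the top-ranked fraction of the fused columns.

The entropy here is the standard non-negative Shannon form
``H = -sum p log2 p``; ranking direction defaults to keeping HIGH-entropy
(well-spread) features and can be flipped via ``direction``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from .features import FeatureMatrix
from .pso import SelectionResult

__all__ = [
    "EntropyProfile",
    "feature_entropy",
    "ebs_select",
    "serial_fuse",
    "fuse_and_select",
    "EntropySelector",
]


@dataclass
class EntropyProfile:
    """Per-feature Shannon entropies of discretised value distributions."""

    entropies: np.ndarray       # d reals, bits
    n_bins: int
    bin_edges: list             # per feature
    probabilities: list         # per feature, sums to 1

    def __post_init__(self):
        self.entropies = np.asarray(self.entropies, dtype=float)
        if (self.entropies < -1e-12).any():
            raise ValueError("entropies must be non-negative")
        if (self.entropies > np.log2(self.n_bins) + 1e-9).any():
            raise ValueError("entropy cannot exceed log2(n_bins)")


def _column_entropy(col: np.ndarray, n_bins: int):
    lo, hi = col.min(), col.max()
    if hi == lo:  # constant feature: all mass in one bin, zero entropy
        edges = np.linspace(lo - 0.5, lo + 0.5, n_bins + 1)
        probs = np.zeros(n_bins)
        probs[0] = 1.0
        return 0.0, edges, probs
    counts, edges = np.histogram(col, bins=n_bins, range=(lo, hi))
    probs = counts / counts.sum()
    nz = probs[probs > 0]
    return float(-(nz * np.log2(nz)).sum()), edges, probs


def feature_entropy(fm, n_bins: int = 16) -> EntropyProfile:
    """Equal-width-histogram Shannon entropy (bits) of every feature."""
    if n_bins < 2:
        raise ValueError("need n_bins >= 2")
    X = fm.values if isinstance(fm, FeatureMatrix) else np.asarray(fm, dtype=float)
    ents, edges, probs = [], [], []
    for j in range(X.shape[1]):
        e, be, p = _column_entropy(X[:, j], n_bins)
        ents.append(e)
        edges.append(be)
        probs.append(p)
    return EntropyProfile(entropies=np.array(ents), n_bins=n_bins,
                          bin_edges=edges, probabilities=probs)


def _resolve_keep(keep, d: int) -> int:
    if isinstance(keep, float) and 0 < keep <= 1:
        k = int(round(keep * d))
    else:
        k = int(keep)
    if not 1 <= k <= d:
        raise ValueError(f"keep must resolve to 1..{d} features, got {k}")
    return k


def ebs_select(profile: EntropyProfile, fm, keep,
               direction: str = "high") -> SelectionResult:
    """Keep the ``keep`` top-entropy features (ties: lower column index)."""
    ents = profile.entropies
    d = ents.size
    k = _resolve_keep(keep, d)
    key = -ents if direction == "high" else ents
    order = np.lexsort((np.arange(d), key))  # stable: index breaks ties
    mask = np.zeros(d, dtype=bool)
    mask[order[:k]] = True
    return SelectionResult(mask=mask, scores=ents.copy(), method="ebs", seed=0)


def serial_fuse(left: FeatureMatrix, right: FeatureMatrix) -> FeatureMatrix:
    """Column-wise concatenation (left columns first) over identical samples."""
    if left.n != right.n:
        raise ValueError("fusion requires the same number of rows")
    if not np.array_equal(left.labels, right.labels):
        raise ValueError("fusion requires identical row order and labels")
    names = ([f"{left.source}.{n}" for n in left.feature_names]
             + [f"{right.source}.{n}" for n in right.feature_names])
    return FeatureMatrix(values=np.hstack([left.values, right.values]),
                         labels=left.labels, source="fused",
                         feature_names=names,
                         meta={"left": left.source, "right": right.source,
                               "d_left": left.d, "d_right": right.d})


def fuse_and_select(fv2_selected: FeatureMatrix, fv1_selected: FeatureMatrix,
                    keep=0.5, n_bins: int = 16,
                    direction: str = "high") -> FeatureMatrix:
    """Serial fusion of the two selected vectors followed by entropy selection.

    Fusion order matches the selection chain: the swarm-selected vector first,
    the colony-selected vector second.  The path is deterministic — no RNG.
    """
    fused = serial_fuse(fv2_selected, fv1_selected)
    profile = feature_entropy(fused, n_bins=n_bins)
    sel = ebs_select(profile, fused, keep, direction=direction)
    out = fused.select(sel.mask, source="fused_selected")
    out.meta["entropy_bits"] = sel.scores[sel.mask]
    return out


class EntropySelector(SelectorMixin, BaseEstimator):
    """Entropy-ranking feature selector (scikit-learn transformer).

    Parameters
    ----------
    keep : count (int) or fraction (float in (0, 1]) of features to retain.
    n_bins : equal-width histogram bins used to discretise each feature.
    direction : 'high' keeps the highest-entropy features, 'low' the lowest.
    """

    def __init__(self, keep=0.5, n_bins: int = 16, direction: str = "high"):
        self.keep = keep
        self.n_bins = n_bins
        self.direction = direction

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.profile_ = feature_entropy(X, n_bins=self.n_bins)
        self.result_ = ebs_select(self.profile_, X, self.keep,
                                  direction=self.direction)
        self.entropies_ = self.profile_.entropies
        return self

    def _get_support_mask(self):
        return self.result_.mask
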