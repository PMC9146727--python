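"""End-to-end orchestration of the four evaluation configurations.

From one data source (a class-per-subdirectory image tree, an in-memory
image set, or a pair of feature csv files standing in for FV1/FV2) the
pipeline produces cross-validated reports for:

1. ``fv1_raw``   — raw reference-backbone features;
2. ``fv2_raw``   — raw six-branch-net features;
3. ``fv1_acs`` / ``fv2_pso`` — the third configuration's two selected
   vectors (colony selection on FV1, swarm selection on FV2);
4. ``fused_ebs`` — serial fusion of the two selected vectors followed by
   entropy-based selection.

Each run writes per-(configuration x classifier) reports, a summary table
with accuracy (Ac%) and training time (T(s)) per configuration, and a
manifest (config hash, seed, versions) sufficient to reproduce the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .acs import acs_select
from .classify import ClassifierSpec, crossval_evaluate
from .features import FeatureMatrix, extract_6bnet_features, extract_reference_features
from .fusion import fuse_and_select
from .network import SixBranchNet
from .pso import pso_select
from .synth import read_image_set

__all__ = ["PipelineConfig", "run_pipeline", "CONFIGURATIONS"]

log = logging.getLogger("histofuse.pipeline")

#: evaluation configurations; the two ``*_acs``/``*_pso`` entries together
#: form the "selected vectors" configuration
CONFIGURATIONS = ("fv1_raw", "fv2_raw", "fv1_acs", "fv2_pso", "fused_ebs")


@dataclass
class PipelineConfig:
    # data source: exactly one of (image_dir | image_set) or (fv1.., fv2..)
    image_dir: str | None = None
    image_set: object | None = None
    fv1_csv: str | None = None
    fv2_csv: str | None = None
    fv1: FeatureMatrix | None = None
    fv2: FeatureMatrix | None = None

    configurations: tuple = CONFIGURATIONS
    classifiers: tuple = ("ESKNN", "ESD")
    folds: int = 5
    seed: int = 0
    out_dir: str | None = None

    # six-branch backbone (desk-scale defaults; canonical is side 227, width 1)
    net_input_side: int = 48
    net_width_scale: float = 0.25
    epochs: int = 3
    lr: float = 0.02
    batch_size: int = 16
    # reference backbone
    ref_input_side: int = 64

    # selector settings
    pso: dict = field(default_factory=lambda: dict(n_particles=10, n_iter=10))
    acs: dict = field(default_factory=lambda: dict(n_ants=10, n_iter=10))
    keep: float = 0.5
    n_bins: int = 16

    def __post_init__(self):
        image_src = self.image_dir is not None or self.image_set is not None
        feat_src = ((self.fv1_csv is not None or self.fv1 is not None)
                    and (self.fv2_csv is not None or self.fv2 is not None))
        if image_src == feat_src:
            raise ValueError(
                "exactly one data source required: images OR an FV1/FV2 pair")
        if self.folds not in (3, 5, 10):
            raise ValueError("fold scheme must be 3, 5 or 10")
        unknown = set(self.configurations) - set(CONFIGURATIONS)
        if unknown:
            raise ValueError(f"unknown configurations: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("configurations", "classifiers"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def public_dict(self) -> dict:
        d = asdict(self)
        for key in ("image_set", "fv1", "fv2"):  # in-memory objects: hash only
            obj = d.pop(key)
            if obj is not None:
                d[f"{key}_sha256"] = _object_hash(getattr(self, key))
        return d

    def content_hash(self) -> str:
        d = self.public_dict()
        d.pop("out_dir", None)  # where results land does not change them
        payload = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _object_hash(obj) -> str:
    h = hashlib.sha256()
    if isinstance(obj, FeatureMatrix):
        h.update(obj.values.tobytes())
        h.update(np.asarray(obj.labels).tobytes())
    else:  # LabeledImageSet
        for img in obj.images:
            h.update(np.ascontiguousarray(img).tobytes())
        h.update(np.asarray(obj.labels).tobytes())
    return h.hexdigest()[:16]


def _feature_vectors(cfg: PipelineConfig):
    """Stage 1: obtain the FV1/FV2 matrices from the configured source."""
    if cfg.fv1 is not None or cfg.fv1_csv is not None:
        fv1 = cfg.fv1 or FeatureMatrix.from_csv(cfg.fv1_csv, source="FV1_reference")
        fv2 = cfg.fv2 or FeatureMatrix.from_csv(cfg.fv2_csv, source="FV2_6bnet")
        log.info("loaded feature tables: FV1 d=%d, FV2 d=%d (n=%d)",
                 fv1.d, fv2.d, fv1.n)
        return fv1, fv2, None
    images = cfg.image_set or read_image_set(cfg.image_dir)
    log.info("image set: %d images, %d classes", len(images),
             len(images.class_names))
    net = SixBranchNet(input_side=cfg.net_input_side,
                       width_scale=cfg.net_width_scale, epochs=cfg.epochs,
                       lr=cfg.lr, batch_size=cfg.batch_size,
                       random_state=cfg.seed).fit(images)
    fv2 = extract_6bnet_features(net.graph_, net.params_, images)
    fv1 = extract_reference_features(images, input_side=cfg.ref_input_side,
                                     seed=cfg.seed)
    log.info("extracted FV1 d=%d, FV2 d=%d", fv1.d, fv2.d)
    return fv1, fv2, net


def run_pipeline(cfg: PipelineConfig):
    """Execute extract -> select -> fuse -> classify; returns a result dict.

    The result holds ``reports`` keyed by (configuration, classifier kind),
    a ``summary`` DataFrame (rows: classifiers; columns: Ac% and T(s) per
    configuration) and the stage dimensionalities.  When ``cfg.out_dir`` is
    set everything is also written to disk together with a manifest.
    """
    fv1, fv2, net = _feature_vectors(cfg)
    matrices: dict[str, FeatureMatrix] = {"fv1_raw": fv1, "fv2_raw": fv2}
    dims = {"fv1": fv1.d, "fv2": fv2.d}

    need_sel = {"fv1_acs", "fv2_pso", "fused_ebs"} & set(cfg.configurations)
    if need_sel:
        pso_res = pso_select(fv2.values, fv2.labels, seed=cfg.seed, **cfg.pso)
        acs_res = acs_select(fv1.values, fv1.labels, seed=cfg.seed, **cfg.acs)
        fv2_sel = fv2.select(pso_res.mask)
        fv1_sel = fv1.select(acs_res.mask)
        matrices["fv2_pso"] = fv2_sel
        matrices["fv1_acs"] = fv1_sel
        dims.update(fv2_pso=fv2_sel.d, fv1_acs=fv1_sel.d)
        log.info("selected: swarm kept %d/%d of FV2, colony kept %d/%d of FV1",
                 fv2_sel.d, fv2.d, fv1_sel.d, fv1.d)
        fused = fuse_and_select(fv2_sel, fv1_sel, keep=cfg.keep,
                                n_bins=cfg.n_bins)
        matrices["fused_ebs"] = fused
        dims.update(fused=fv2_sel.d + fv1_sel.d, fused_ebs=fused.d)
        log.info("fused d=%d -> entropy-selected d=%d",
                 fv2_sel.d + fv1_sel.d, fused.d)

    reports = {}
    rows = {}
    for kind in cfg.classifiers:
        row = {}
        for name in cfg.configurations:
            spec = ClassifierSpec(kind=kind, seed=cfg.seed)
            rep = crossval_evaluate(matrices[name], spec, cfg.folds,
                                    seed=cfg.seed)
            reports[(name, kind)] = rep
            row[f"{name}_Ac%"] = round(rep.mean_accuracy, 2)
            row[f"{name}_T(s)"] = round(rep.train_time, 3)
            log.info("%s on %s (d=%d): %.2f%%", kind, name,
                     matrices[name].d, rep.mean_accuracy)
        rows[kind] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "classifier"

    result = {"reports": reports, "summary": summary, "dims": dims,
              "config_hash": cfg.content_hash()}
    if cfg.out_dir:
        _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: PipelineConfig, result) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for (name, kind), rep in result["reports"].items():
        rep.save(out / f"report_{name}_{kind}.json",
                 out / f"confusion_{name}_{kind}.csv")
    result["summary"].to_csv(out / "summary.csv")
    manifest = {
        "config": cfg.public_dict(),
        "config_hash": result["config_hash"],
        "seed": cfg.seed,
        "dims": result["dims"],
        "versions": {
            "histofuse": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
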